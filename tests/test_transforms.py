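import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dbpred.exceptions import DescriptorUndefinedError, ValidationError
from dbpred.sequence_io import ProteinRecord
from dbpred.track_providers import SSF_TRACKS, PropertyTrackSet, encode_aaindex
from dbpred.transforms import (
    BLOCK_ORDER,
    TransformConfig,
    ac,
    assemble,
    octd,
    saa,
    split_regions,
)
from oracles import naive_autocovariance, random_sequence


def ssf_tracks(*rows, protein_id="p"):
    """Build a 4-track ssf set, padding with copies of the first row."""
    rows = list(rows)
    while len(rows) < 4:
        rows.append(rows[0])
    return PropertyTrackSet(protein_id, "ssf", SSF_TRACKS, np.array(rows, dtype=float))


finite_tracks = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=2, max_size=60
)


class TestOCTD:
    def test_alternating_track_hand_values(self):
        block = octd(ssf_tracks([0, 1, 0, 1]))
        first = block.values[:13]
        np.testing.assert_allclose(
            first,
            [0.5, 0.5, 1.0]
            + [0.25, 0.25, 0.25, 0.75, 0.75]
            + [0.5, 0.5, 0.5, 1.0, 1.0],
        )

    def test_constant_track_degenerate_case(self):
        first = octd(ssf_tracks([3.5] * 6)).values[:13]
        np.testing.assert_allclose(first[:3], [1.0, 0.0, 0.0])
        assert not first[8:].any()  # empty group B -> five zeros
        assert first[7] == 1.0  # last group-A member is the final residue

    @given(finite_tracks)
    def test_composition_identity_and_ranges(self, row):
        first = octd(ssf_tracks(row)).values[:13]
        assert first[0] + first[1] == pytest.approx(1.0)
        assert 0.0 <= first[2] <= 1.0
        nonzero = first[3:][first[3:] > 0]
        assert ((nonzero > 0) & (nonzero <= 1.0)).all()

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False).map(
                lambda v: round(v, 3)  # keep the track range above float noise
            ),
            min_size=2,
            max_size=60,
        )
    )
    def test_affine_invariance(self, row):
        """Internal min-max normalization makes OCTD invariant to positive
        affine rescaling of the track."""
        row = np.asarray(row)
        base = octd(ssf_tracks(row)).values[:13]
        scaled = octd(ssf_tracks(row * 3.7 + 11.0)).values[:13]
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_too_short(self):
        with pytest.raises(DescriptorUndefinedError):
            octd(ssf_tracks([1.0]))


class TestAC:
    def test_hand_example(self):
        block = ac(ssf_tracks([1, 2, 3, 4]), lg_max=1)
        assert block.values[0] == pytest.approx(1.25 / 3)

    def test_constant_track_is_zero(self):
        assert not ac(ssf_tracks([2.0] * 20), lg_max=5).values.any()

    @given(finite_tracks.filter(lambda r: len(r) >= 12))
    def test_shift_invariance(self, row):
        row = np.asarray(row)
        base = ac(ssf_tracks(row), lg_max=3).values
        shifted = ac(ssf_tracks(row + 42.0), lg_max=3).values
        np.testing.assert_allclose(base, shifted, atol=1e-8)

    def test_matches_naive_double_loop(self, rng):
        """AC equals a brute-force autocovariance loop on 50 random tracks."""
        for _ in range(50):
            L = int(rng.integers(12, 80))
            row = rng.normal(size=L) * rng.uniform(0.5, 10)
            got = ac(ssf_tracks(row), lg_max=10).values[:10]
            np.testing.assert_allclose(got, naive_autocovariance(row, 10), atol=1e-10)

    def test_sequence_too_short_for_lag(self):
        with pytest.raises(DescriptorUndefinedError, match="p"):
            ac(ssf_tracks(list(range(5))), lg_max=5)


class TestSplitRegions:
    @pytest.mark.parametrize(
        "L, expected",
        [
            (200, ((1, 25), (26, 50), (51, 75), (76, 100), (101, 190), (191, 200))),
            (130, ((1, 25), (26, 50), (51, 75), (76, 100), (101, 120), (121, 130))),
            (120, ((1, 25), (26, 50), (51, 75), (76, 100), (91, 110), (111, 120))),
            (111, ((1, 25), (26, 50), (51, 75), (76, 100), (82, 101), (102, 111))),
            (110, ((1, 50), (1, 50), (1, 50), (1, 50), (51, 100), (101, 110))),
            (60, ((1, 25), (1, 25), (1, 25), (1, 25), (26, 50), (51, 60))),
            (31, ((1, 10), (1, 10), (1, 10), (1, 10), (11, 21), (22, 31))),
        ],
    )
    def test_case_geometry(self, L, expected):
        assert split_regions(L).regions == expected

    @pytest.mark.parametrize("L", range(130, 400, 37))
    def test_case_a_covers_sequence_without_gaps(self, L):
        regions = split_regions(L).regions
        assert regions[0][0] == 1 and regions[-1][1] == L
        for (_, end), (start, _) in zip(regions[3:], regions[4:]):
            assert start == end + 1

    def test_below_minimum_length(self):
        with pytest.raises(DescriptorUndefinedError):
            split_regions(30)


class TestSAA:
    def test_constant_track(self):
        block = saa(ssf_tracks([7.0] * 150), split_regions(150))
        np.testing.assert_allclose(block.values, 7.0)

    def test_position_index_track(self):
        """Track = 1-based position on L=200: region [191, 200] mean is 195.5."""
        block = saa(ssf_tracks(np.arange(1, 201)), split_regions(200))
        assert block.values[5] == pytest.approx(195.5)
        assert block.values[0] == pytest.approx(13.0)  # mean of 1..25

    def test_dimension_is_tracks_times_regions(self, rng):
        seq = random_sequence(rng, 140)
        block = saa(encode_aaindex(ProteinRecord("p", seq)), split_regions(140))
        assert len(block) == 28 * 6


class TestAssemble:
    def test_twelve_blocks_and_2040_selected_features(self, tiny_dataset):
        protein = tiny_dataset.proteins[0]
        tracks = protein.track_sets()
        blocks = assemble(
            protein.record, tracks["aaindex"], tracks["pssm"], tracks["ssf"]
        )
        assert tuple(b.block_name for b in blocks) == BLOCK_ORDER
        dims = {b.block_name: len(b) for b in blocks}
        assert dims["DPC"] == 1200
        selected_total = sum(400 if n == "DPC" else d for n, d in dims.items())
        assert selected_total == 2040

    def test_aaindex_only_subset(self, tiny_dataset):
        protein = tiny_dataset.proteins[0]
        tracks = protein.track_sets()
        blocks = assemble(
            protein.record, tracks["aaindex"], None, None, require=("aaindex",)
        )
        transform_dims = sum(len(b) for b in blocks if "AAIndex" in b.block_name)
        assert transform_dims == 364 + 252 + 168 == 784

    def test_missing_required_source_is_named(self, tiny_dataset):
        protein = tiny_dataset.proteins[0]
        tracks = protein.track_sets()
        with pytest.raises(ValidationError, match="pssm"):
            assemble(protein.record, tracks["aaindex"], None, tracks["ssf"])

    def test_schema_stable_across_proteins(self, tiny_dataset):
        names = []
        for protein in tiny_dataset.proteins[:3]:
            tracks = protein.track_sets()
            blocks = assemble(
                protein.record, tracks["aaindex"], tracks["pssm"], tracks["ssf"]
            )
            names.append([b.feature_names for b in blocks])
        assert names[0] == names[1] == names[2]


def test_transform_config_validation():
    with pytest.raises(Exception):
        TransformConfig(octd_threshold=1.5)
    with pytest.raises(Exception):
        TransformConfig(lg_pssm=0)
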