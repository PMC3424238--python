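import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episeq.alphabet import AA_INDEX, CANONICAL_AA
from episeq.errors import MissingTrackError, UndefinedFeatureError
from episeq.features import (
    ENCODER_NAMES,
    FUNCTION_GROUP_INDEX,
    FUNCTION_GROUPS,
    SCALE_ORDER,
    get_encoder,
    load_propensity_scales,
)
from episeq.io import ChainRecord
from episeq.windowing import extract_windows

from conftest import make_windows

EXPECTED_DIMS = {
    "propensity": lambda L: 6 * L,
    "sparse": lambda L: 20 * L,
    "composition": lambda L: 20,
    "function_group": lambda L: 13 * L,
    "functional_composition": lambda L: 13,
    "evolutionary": lambda L: 20 * L,
    "pair_profile": lambda L: 400,
    "ss": lambda L: 3 * L,
    "rasa": lambda L: L,
}


def full_track_windows(seq, L):
    n = len(seq)
    chain = ChainRecord(
        "A", seq,
        pssm=np.zeros((n, 20), dtype=int),
        ss="C" * n,
        rasa=np.full(n, 50.0),
    )
    return extract_windows(chain, L, "t")


@pytest.mark.parametrize("L", [5, 7, 9, 11, 13, 15])
@pytest.mark.parametrize("name", ENCODER_NAMES)
def test_dimension_registry(name, L):
    """Every encoder emits exactly its declared dim(L), finite everywhere."""
    enc = get_encoder(name)
    assert enc.dim(L) == EXPECTED_DIMS[name](L)
    w = full_track_windows("KVFGRCELAAAMKRHGLDNYRGYSL"[: L + 3], L)[2]
    v = enc.encode(w)
    assert v.shape == (enc.dim(L),)
    assert np.isfinite(v).all()


class TestPropensity:
    def test_padded_positions_contribute_zero_blocks(self):
        w = make_windows("K", L=5)[0]  # XXKXX
        vec = get_encoder("propensity").encode(w)
        assert vec.shape == (30,)
        np.testing.assert_array_equal(vec[:12], 0.0)
        np.testing.assert_array_equal(vec[18:], 0.0)
        assert np.any(vec[12:18] != 0.0)

    def test_single_residue_block_matches_scale_files(self):
        scales = load_propensity_scales()
        w = make_windows("A", L=3)[0]  # XAX
        vec = get_encoder("propensity").encode(w)
        expected = [scales[s]["A"] for s in SCALE_ORDER]
        np.testing.assert_allclose(vec[6:12], expected)

    def test_flank_padding_does_not_change_central_block(self):
        w_short = make_windows("KVF", L=5)[1]
        w_long = make_windows("AKVFA", L=5)[2]
        enc = get_encoder("propensity")
        np.testing.assert_allclose(
            enc.encode(w_short)[6:24], enc.encode(w_long)[6:24]
        )


class TestSparse:
    def test_a_sets_first_bit_of_its_block(self):
        vec = get_encoder("sparse").encode(make_windows("A", L=3)[0])
        block = vec[20:40]  # central position
        assert block[0] == 1.0 and block.sum() == 1.0

    def test_vector_sum_counts_non_x(self):
        w = make_windows("KVFGR", L=5)[2]  # fully inside, no X
        assert get_encoder("sparse").encode(w).sum() == 5.0
        w_edge = make_windows("KVFGR", L=5)[0]  # two padded positions
        assert get_encoder("sparse").encode(w_edge).sum() == 3.0


class TestComposition:
    @pytest.mark.parametrize(
        "seq,center,expected",
        [
            ("AAAAA", 2, {"A": 1.0}),
            ("K", 0, {"K": 1.0}),  # XXKXX: denominator excludes X
            ("KVFGR", 2, {aa: 0.2 for aa in "KVFGR"}),
        ],
    )
    def test_fractions(self, seq, center, expected):
        vec = get_encoder("composition").encode(make_windows(seq, L=5)[center])
        for aa, frac in expected.items():
            assert vec[AA_INDEX[aa]] == pytest.approx(frac)
        assert vec.sum() == pytest.approx(1.0)

    def test_all_x_window_is_undefined(self):
        chain = ChainRecord("A", "XXX")
        w = extract_windows(chain, 3)[1]
        with pytest.raises(UndefinedFeatureError):
            get_encoder("composition").encode(w)


class TestFunctionGroup:
    def test_printed_partition(self):
        groups = {}
        for aa, idx in FUNCTION_GROUP_INDEX.items():
            groups.setdefault(idx, set()).add(aa)
        expected = [
            {"R", "K"}, {"E", "D"}, {"S", "T"}, {"L", "V", "I"}, {"Q", "N"},
            {"W", "F"}, {"A"}, {"C"}, {"G"}, {"H"}, {"M"}, {"P"}, {"Y"},
        ]
        assert [groups[i] for i in range(13)] == expected
        assert len(FUNCTION_GROUPS) == 13
        assert set(FUNCTION_GROUP_INDEX) == set(CANONICAL_AA)

    def test_r_and_k_share_class_one(self):
        enc = get_encoder("function_group")
        vr = enc.encode(make_windows("R", L=3)[0])[13:26]
        vk = enc.encode(make_windows("K", L=3)[0])[13:26]
        np.testing.assert_array_equal(vr, vk)
        assert vr[0] == 1.0

    def test_y_is_class_thirteen(self):
        v = get_encoder("function_group").encode(make_windows("Y", L=3)[0])
        assert v[13 + 12] == 1.0

    def test_sum_counts_non_x(self):
        w = make_windows("KVFGR", L=5)[0]
        assert get_encoder("function_group").encode(w).sum() == 3.0


class TestFunctionalComposition:
    def test_pure_class_one_window(self):
        vec = get_encoder("functional_composition").encode(
            make_windows("RKRKR", L=5)[2]
        )
        assert vec[0] == pytest.approx(1.0)

    def test_mixed_classes(self):
        vec = get_encoder("functional_composition").encode(
            make_windows("STLVI", L=5)[2]
        )
        assert vec[2] == pytest.approx(0.4)  # S,T
        assert vec[3] == pytest.approx(0.6)  # L,V,I

    @given(st.text(alphabet=CANONICAL_AA, min_size=1, max_size=9))
    @settings(max_examples=40, deadline=None)
    def test_equals_composition_aggregated_by_class(self, seq):
        w = make_windows(seq, L=9)[len(seq) // 2]
        comp = get_encoder("composition").encode(w)
        func = get_encoder("functional_composition").encode(w)
        oracle = np.zeros(13)
        for aa, frac in zip(CANONICAL_AA, comp):
            oracle[FUNCTION_GROUP_INDEX[aa]] += frac
        np.testing.assert_allclose(func, oracle, atol=1e-12)


class TestEvolutionary:
    def test_zero_rows_become_halves(self):
        w = full_track_windows("KVFGR", 5)[2]
        vec = get_encoder("evolutionary").encode(w)
        np.testing.assert_allclose(vec, 0.5)

    def test_padded_flank_blocks_are_zero(self):
        w = full_track_windows("KVFGR", 5)[0]
        vec = get_encoder("evolutionary").encode(w)
        np.testing.assert_array_equal(vec[:40], 0.0)
        np.testing.assert_allclose(vec[40:], 0.5)

    def test_missing_pssm_raises_named_error(self):
        w = make_windows("KVFGR", L=5)[2]
        with pytest.raises(MissingTrackError, match="evolutionary"):
            get_encoder("evolutionary").encode(w)


class TestPairProfile:
    def _encode(self, seq, center, L=5):
        return get_encoder("pair_profile").encode(make_windows(seq, L)[center])

    def test_homopolymer(self):
        vec = self._encode("AAAAA", 2)
        assert vec[AA_INDEX["A"] * 20 + AA_INDEX["A"]] == pytest.approx(1.0)

    def test_x_touching_pairs_excluded(self):
        vec = self._encode("KV", 0)  # window XXKVX
        assert vec[AA_INDEX["K"] * 20 + AA_INDEX["V"]] == pytest.approx(1.0)
        assert vec.sum() == pytest.approx(1.0)

    def test_ordered_pairs(self):
        vec = self._encode("KVK", 1)  # window XKVKX
        assert vec[AA_INDEX["K"] * 20 + AA_INDEX["V"]] == pytest.approx(0.5)
        assert vec[AA_INDEX["V"] * 20 + AA_INDEX["K"]] == pytest.approx(0.5)

    def test_no_valid_pair_is_undefined(self):
        with pytest.raises(UndefinedFeatureError):
            self._encode("K", 0)  # XXKXX has no adjacent non-X pair


class TestStructureEncoders:
    def test_ss_one_hot_mapping(self):
        chain = ChainRecord("A", "KVF", ss="HEC", rasa=[0.0, 50.0, 100.0])
        w = extract_windows(chain, 3)[1]
        np.testing.assert_array_equal(
            get_encoder("ss").encode(w), [1, 0, 0, 0, 1, 0, 0, 0, 1]
        )
        np.testing.assert_allclose(
            get_encoder("rasa").encode(w), [0.0, 0.5, 1.0]
        )

    def test_padding_contributes_zeros(self):
        chain = ChainRecord("A", "K", ss="H", rasa=[100.0])
        w = extract_windows(chain, 5)[0]
        ss_vec = get_encoder("ss").encode(w)
        assert ss_vec.sum() == 1.0 and ss_vec[6] == 1.0
        rasa_vec = get_encoder("rasa").encode(w)
        np.testing.assert_allclose(rasa_vec, [0, 0, 1.0, 0, 0])

    @pytest.mark.parametrize("name", ["ss", "rasa"])
    def test_missing_track_raises(self, name):
        w = make_windows("KVFGR", L=5)[2]
        with pytest.raises(MissingTrackError):
            get_encoder(name).encode(w)


def test_encoders_are_pure(rng):
    seq = "".join(rng.choice(list(CANONICAL_AA), size=15))
    for name in ENCODER_NAMES:
        enc = get_encoder(name)
        w = full_track_windows(seq, 9)[7]
        np.testing.assert_array_equal(enc.encode(w), enc.encode(w))
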