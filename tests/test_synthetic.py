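import numpy as np
import pytest

from episeq.ensemble import train_bootstrap_ensemble
from episeq.errors import EpiseqError
from episeq.evaluation import auc
from episeq.features import get_encoder
from episeq.io import read_pssm
from episeq.synthetic import (
    PRESETS,
    SyntheticConfig,
    generate_dataset,
    preset_null,
    read_dataset,
    write_dataset,
)
from episeq.windowing import extract_windows

from conftest import FAST_FOREST


def small_cfg(**overrides):
    base = dict(
        n_antigens=3,
        chain_length_range=(60, 80),
        chains_per_antigen=(1, 2),
        patch_length_range=(10, 15),
        seed=2,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_patch_longer_than_chain_rejected(self):
        with pytest.raises(EpiseqError, match="patches cannot fit"):
            SyntheticConfig(chain_length_range=(30, 40), patch_length_range=(35, 50))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_antigens": 0},
            {"composition_shift": 1.5},
            {"rasa_shift": 150.0},
            {"coil_bias": -0.1},
            {"background_freqs": np.full(20, 0.1)},
        ],
    )
    def test_invalid_fields(self, kwargs):
        with pytest.raises(EpiseqError):
            small_cfg(**kwargs)


class TestGeneration:
    def test_same_seed_identical_datasets(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(generate_dataset(small_cfg()), d1)
        write_dataset(generate_dataset(small_cfg()), d2)
        for p1 in sorted(d1.rglob("*")):
            p2 = d2 / p1.relative_to(d1)
            if p1.is_file():
                assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_labels_are_patch_membership(self):
        records = generate_dataset(small_cfg())
        for rec in records:
            for ch in rec.chains:
                assert ch.labels is not None
                frac = ch.labels.mean()
                assert 0 < frac < 0.6  # patches are a minority of the chain

    def test_tracks_complete_and_in_range(self):
        records = generate_dataset(small_cfg())
        ch = records[0].chains[0]
        assert ch.pssm.shape == (len(ch), 20)
        assert set(ch.ss) <= set("HEC")
        assert (ch.rasa >= 0).all() and (ch.rasa <= 100).all()

    def test_window_imbalance_matches_patch_coverage(self):
        records = generate_dataset(small_cfg())
        for rec in records:
            for ch in rec.chains:
                windows = extract_windows(ch, 9, rec.antigen_id)
                pos = sum(w.label for w in windows)
                assert pos == ch.labels.sum()  # one window per residue


class TestRoundTrip:
    def test_write_read_reproduces_tracks(self, tmp_path):
        records = generate_dataset(small_cfg())
        write_dataset(records, tmp_path)
        back = read_dataset(tmp_path)
        assert [r.antigen_id for r in back] == [r.antigen_id for r in records]
        for r1, r2 in zip(records, back):
            for c1, c2 in zip(r1.chains, r2.chains):
                assert c1.sequence == c2.sequence
                np.testing.assert_array_equal(c1.labels, c2.labels)
                np.testing.assert_array_equal(c1.pssm, c2.pssm)
                assert c1.ss == c2.ss
                np.testing.assert_allclose(c1.rasa, c2.rasa, atol=1e-6)

    def test_pssm_files_parse_standalone(self, tmp_path):
        records = generate_dataset(small_cfg())
        write_dataset(records, tmp_path)
        ch = records[0].chains[0]
        mat = read_pssm(tmp_path / "pssm" / f"{records[0].antigen_id}_A.pssm")
        np.testing.assert_array_equal(mat, ch.pssm)

    def test_empty_dataset_rejected(self, tmp_path):
        with pytest.raises(EpiseqError):
            write_dataset([], tmp_path)


class TestEffectSizes:
    def _composition_holdout_auc(self, shift):
        cfg = small_cfg(
            n_antigens=6,
            composition_shift=shift,
            pssm_patch_noise=0.0,
            rasa_shift=0.0,
            coil_bias=0.0,
            seed=13,
        )
        records = generate_dataset(cfg)
        windows = {"train": [], "test": []}
        for i, rec in enumerate(records):
            part = "train" if i < 4 else "test"
            for ch in rec.chains:
                windows[part].extend(extract_windows(ch, 9, rec.antigen_id))
        enc = get_encoder("composition")
        ens = train_bootstrap_ensemble(
            windows["train"], enc, seed=13, base_params=FAST_FOREST
        )
        scores = ens.score_matrix(enc.encode_windows(windows["test"]))
        return auc(scores, np.array([w.label for w in windows["test"]]))

    def test_composition_auc_monotone_in_shift(self):
        """Stronger planted composition shift -> easier held-out
        discrimination (3-point grid, fixed seeds)."""
        aucs = [self._composition_holdout_auc(s) for s in (0.0, 0.5, 1.0)]
        assert aucs[0] - 0.03 <= aucs[1] <= aucs[2] + 0.03
        assert aucs[2] > aucs[0] + 0.1

    def test_null_preset_has_all_effects_off(self):
        cfg = preset_null()
        assert cfg.composition_shift == 0.0
        assert cfg.pssm_patch_noise == 0.0
        assert cfg.rasa_shift == 0.0
        assert cfg.coil_bias == 0.0


def test_presets_exist():
    assert set(PRESETS) == {"null", "single-signal", "complementary-signals"}
    for name, factory in PRESETS.items():
        cfg = factory(seed=3)
        assert cfg.seed == 3
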