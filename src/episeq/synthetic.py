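"""Self-contained synthetic antigen datasets with plantable epitope signal.

The generator emulates the statistical structure the predictor assumes:
epitope patches are (i) enriched in hydrophilic/charged residues,
(ii) less evolutionarily conserved (noisier PSSM rows), (iii) more
solvent-exposed (higher RASA) and (iv) biased toward coil secondary
structure. Each signal has its own effect-size knob so presets can plant
single or complementary signals, or none at all (the null).

It makes no attempt to mimic real antigen families, folds, or true
PSI-BLAST statistics; it exists so every pipeline stage is testable
without external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import CANONICAL_AA
from .errors import EpiseqError
from .io import (
    AntigenRecord,
    ChainRecord,
    load_dataset,
    write_fasta,
    write_labels,
    write_pssm,
    write_structprops,
)

#: residues boosted inside epitope patches (hydrophilic / charged)
EPITOPE_ENRICHED = "KRDENS"

# background residue frequencies: uniform over the 20 canonical letters
_UNIFORM = np.full(20, 1 / 20)


def _epitope_profile() -> np.ndarray:
    """Target patch composition: probability mass concentrated on the
    enriched alphabet, uniform elsewhere."""
    prof = np.full(20, 0.2 / 14)  # 20% spread over the other 14 residues
    for aa in EPITOPE_ENRICHED:
        prof[CANONICAL_AA.index(aa)] = 0.8 / len(EPITOPE_ENRICHED)
    return prof


@dataclass
class SyntheticConfig:
    """Study conditions for one generated dataset.

    Effect sizes: ``composition_shift`` in [0,1] interpolates patch
    residue frequencies from background toward the epitope-enriched
    profile; ``pssm_noise`` is the background integer jitter amplitude of
    PSSM entries; ``pssm_patch_noise`` the *extra* amplitude inside
    patches (lower conservation); ``rasa_shift`` (percentage points) is
    added to patch RASA; ``coil_bias`` in [0,1] mixes patch secondary
    structure toward pure coil.
    """

    n_antigens: int = 20
    chain_length_range: tuple[int, int] = (130, 170)
    chains_per_antigen: tuple[int, int] = (1, 2)
    n_patches: int = 1
    patch_length_range: tuple[int, int] = (15, 35)
    composition_shift: float = 0.6
    pssm_noise: float = 2.0
    pssm_patch_noise: float = 3.0
    rasa_shift: float = 30.0
    coil_bias: float = 0.4
    background_freqs: np.ndarray = field(default_factory=lambda: _UNIFORM.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_antigens < 1:
            raise EpiseqError("n_antigens must be >= 1")
        lo, hi = self.chain_length_range
        plo, phi = self.patch_length_range
        if not (1 <= lo <= hi) or not (1 <= plo <= phi):
            raise EpiseqError("invalid length ranges")
        if self.n_patches * phi > lo:
            raise EpiseqError(
                "patches cannot fit in the shortest chain "
                f"({self.n_patches} x {phi} > {lo})"
            )
        if not 0.0 <= self.composition_shift <= 1.0:
            raise EpiseqError("composition_shift must be in [0, 1]")
        if not 0.0 <= self.coil_bias <= 1.0:
            raise EpiseqError("coil_bias must be in [0, 1]")
        if self.pssm_noise < 0 or self.pssm_patch_noise < 0:
            raise EpiseqError("PSSM noise amplitudes must be >= 0")
        if not 0.0 <= self.rasa_shift <= 100.0:
            raise EpiseqError("rasa_shift must be in [0, 100]")
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.background_freqs.shape != (20,) or not np.isclose(
            self.background_freqs.sum(), 1.0
        ):
            raise EpiseqError("background_freqs must be a 20-simplex point")


def _place_patches(
    n: int, n_patches: int, patch_range: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Binary patch-membership mask with non-overlapping patches."""
    mask = np.zeros(n, dtype=np.int8)
    for _ in range(n_patches):
        length = int(rng.integers(patch_range[0], patch_range[1] + 1))
        for _attempt in range(200):
            start = int(rng.integers(0, n - length + 1))
            if mask[start : start + length].sum() == 0:
                mask[start : start + length] = 1
                break
        else:
            raise EpiseqError("could not place non-overlapping patches")
    return mask


def _generate_chain(
    chain_id: str, cfg: SyntheticConfig, rng: np.random.Generator
) -> ChainRecord:
    n = int(rng.integers(cfg.chain_length_range[0], cfg.chain_length_range[1] + 1))
    labels = _place_patches(n, cfg.n_patches, cfg.patch_length_range, rng)

    patch_profile = (
        (1 - cfg.composition_shift) * cfg.background_freqs
        + cfg.composition_shift * _epitope_profile()
    )
    seq_idx = np.empty(n, dtype=int)
    for i in range(n):
        p = patch_profile if labels[i] else cfg.background_freqs
        seq_idx[i] = rng.choice(20, p=p)
    sequence = "".join(CANONICAL_AA[j] for j in seq_idx)

    # PSSM: conserved one-hot-like rows, noisier (and flatter) in patches
    pssm = np.full((n, 20), -3, dtype=int)
    pssm[np.arange(n), seq_idx] = 7
    amp_out = int(round(cfg.pssm_noise))
    amp_in = amp_out + int(round(cfg.pssm_patch_noise)) * 3
    for i in range(n):
        amp = amp_in if labels[i] else amp_out
        if labels[i] and cfg.pssm_patch_noise > 0:
            pssm[i, seq_idx[i]] = 3  # weaker conservation peak
        if amp > 0:
            pssm[i] += rng.integers(-amp, amp + 1, size=20)

    # RASA: clipped-normal baseline, shifted upward inside patches
    rasa = rng.normal(40.0, 18.0, size=n)
    rasa[labels == 1] += cfg.rasa_shift
    rasa = np.clip(rasa, 0.0, 100.0)

    # SS: background H/E/C mixture, mixed toward coil inside patches
    base_p = np.array([0.35, 0.25, 0.40])
    patch_p = (1 - cfg.coil_bias) * base_p + cfg.coil_bias * np.array([0, 0, 1.0])
    ss_chars = []
    for i in range(n):
        p = patch_p if labels[i] else base_p
        ss_chars.append("HEC"[rng.choice(3, p=p)])

    return ChainRecord(
        chain_id=chain_id,
        sequence=sequence,
        labels=labels,
        pssm=pssm,
        ss="".join(ss_chars),
        rasa=rasa,
    )


def generate_dataset(cfg: SyntheticConfig) -> list[AntigenRecord]:
    """Generate a fully reproducible dataset of labelled antigens."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for a in range(cfg.n_antigens):
        n_chains = int(
            rng.integers(cfg.chains_per_antigen[0], cfg.chains_per_antigen[1] + 1)
        )
        chains = [
            _generate_chain(chr(ord("A") + c), cfg, rng) for c in range(n_chains)
        ]
        records.append(AntigenRecord(f"syn{a:03d}", chains))
    return records


def write_dataset(records: list[AntigenRecord], out_dir: str | Path) -> None:
    """Emit FASTA + label TSV + ASCII PSSMs + structure TSVs.

    Layout: ``antigens.fasta``, ``labels.tsv``, ``pssm/<ant>_<chain>.pssm``,
    ``struct/<ant>_<chain>.tsv`` — exactly what :func:`episeq.io.load_dataset`
    reads back.
    """
    if not records:
        raise EpiseqError("empty dataset")
    out = Path(out_dir)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    (out / "struct").mkdir(parents=True, exist_ok=True)
    write_fasta(
        (
            (f"{rec.antigen_id}|{ch.chain_id}", ch.sequence)
            for rec in records
            for ch in rec.chains
        ),
        out / "antigens.fasta",
    )
    write_labels(records, out / "labels.tsv")
    for rec in records:
        for ch in rec.chains:
            stem = f"{rec.antigen_id}_{ch.chain_id}"
            if ch.pssm is not None:
                write_pssm(ch.sequence, ch.pssm, out / "pssm" / f"{stem}.pssm")
            if ch.ss is not None and ch.rasa is not None:
                write_structprops(ch.ss, ch.rasa, out / "struct" / f"{stem}.tsv")


def read_dataset(in_dir: str | Path) -> list[AntigenRecord]:
    """Read back a directory written by :func:`write_dataset`."""
    d = Path(in_dir)
    return load_dataset(
        d / "antigens.fasta",
        labels_path=d / "labels.tsv",
        pssm_dir=d / "pssm",
        struct_dir=d / "struct",
    )


# ---------------------------------------------------------------------------
# Named presets


def preset_null(seed: int = 0) -> SyntheticConfig:
    """No planted signal anywhere: labels independent of every feature.

    Sized for resolution, not realism: windows overlapping one epitope
    patch share most of their residues, so each patch contributes
    roughly one independent unit to a per-antigen AUC. Several short
    patches per chain and a larger antigen count keep the Monte-Carlo
    error of the mean chance-level AUC small.
    """
    return SyntheticConfig(
        n_antigens=36,
        chain_length_range=(110, 140),
        chains_per_antigen=(1, 1),
        n_patches=3,
        patch_length_range=(8, 14),
        composition_shift=0.0,
        pssm_patch_noise=0.0,
        rasa_shift=0.0,
        coil_bias=0.0,
        seed=seed,
    )


def preset_single_signal(seed: int = 0) -> SyntheticConfig:
    """Composition signal only; all other tracks carry no label information."""
    return SyntheticConfig(
        n_antigens=12,
        chain_length_range=(110, 140),
        chains_per_antigen=(1, 1),
        composition_shift=0.8,
        pssm_patch_noise=0.0,
        rasa_shift=0.0,
        coil_bias=0.0,
        seed=seed,
    )


def preset_complementary(seed: int = 0) -> SyntheticConfig:
    """Three complementary signals: composition, conservation and RASA."""
    return SyntheticConfig(seed=seed)


PRESETS = {
    "null": preset_null,
    "single-signal": preset_single_signal,
    "complementary-signals": preset_complementary,
}

#: the sub-classifiers that carry planted signal in the complementary preset
COMPLEMENTARY_ENCODERS: tuple[str, ...] = ("composition", "evolutionary", "rasa")
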