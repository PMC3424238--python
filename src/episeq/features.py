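"""The nine window feature encodings.

Each encoder maps a :class:`~episeq.windowing.WindowInstance` to a
fixed-length numeric vector. Per-residue encodings (propensity, sparse,
function group, evolutionary, SS, RASA) concatenate one block per window
position in sequence order; 'X'/padded positions contribute all-zero
blocks. Composition-type encodings (composition, functional composition,
pair profile) are window-level frequency vectors over the non-X content
and sum to 1 whenever defined.

Encoder registry
----------------
==========================  =========  ==================
name                        dim(L)     required tracks
==========================  =========  ==================
propensity                  6*L        --
sparse                      20*L       --
composition                 20         --
function_group              13*L       --
functional_composition      13         --
evolutionary                20*L       pssm
pair_profile                400        --
ss                          3*L        ss
rasa                        L          rasa
==========================  =========  ==================
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .alphabet import AA_INDEX, CANONICAL_AA, PAD
from .errors import EpiseqError, MissingTrackError, UndefinedFeatureError
from .windowing import WindowInstance

# Partition of the 20 amino acids into 13 R-group function classes.
# Class order is the printed order: 1: R,K; 2: E,D; 3: S,T; 4: L,V,I;
# 5: Q,N; 6: W,F; 7: A; 8: C; 9: G; 10: H; 11: M; 12: P; 13: Y.
FUNCTION_GROUPS: tuple[str, ...] = (
    "RK", "ED", "ST", "LVI", "QN", "WF", "A", "C", "G", "H", "M", "P", "Y",
)
FUNCTION_GROUP_INDEX: dict[str, int] = {
    aa: i for i, grp in enumerate(FUNCTION_GROUPS) for aa in grp
}

#: order in which the six propensity scales are concatenated per residue
SCALE_ORDER: tuple[str, ...] = (
    "flexibility",
    "hydrophilicity",
    "surface",
    "polarity",
    "beta_turn",
    "accessibility",
)

_SS_ONEHOT = {"H": (1.0, 0.0, 0.0), "E": (0.0, 1.0, 0.0), "C": (0.0, 0.0, 1.0)}


def load_propensity_scales() -> dict[str, dict[str, float]]:
    """Load the six bundled propensity scales (residue -> value maps)."""
    scales: dict[str, dict[str, float]] = {}
    base = resources.files("episeq").joinpath("data/scales")
    for name in SCALE_ORDER:
        table: dict[str, float] = {}
        for line in base.joinpath(f"{name}.tsv").read_text().splitlines():
            if not line or line.startswith("#"):
                continue
            aa, val = line.split("\t")
            table[aa] = float(val)
        if set(table) != set(CANONICAL_AA):
            raise EpiseqError(f"scale {name!r} does not cover all 20 residues")
        scales[name] = table
    return scales


class FeatureEncoder:
    """Named encoding contract: ``encode(window) -> vector of dim(L)``."""

    name: str = ""
    requires: frozenset[str] = frozenset()

    def dim(self, L: int) -> int:
        raise NotImplementedError

    def encode(self, w: WindowInstance) -> np.ndarray:
        raise NotImplementedError

    def encode_windows(self, windows: list[WindowInstance]) -> np.ndarray:
        """Stack encodings of many windows into a (n, dim) matrix."""
        return np.vstack([self.encode(w) for w in windows])


class PropensityEncoder(FeatureEncoder):
    """Six physicochemical propensity values per window position."""

    name = "propensity"

    def __init__(self) -> None:
        scales = load_propensity_scales()
        # 21 rows: canonical residues then the all-zero 'X' row
        table = np.zeros((21, len(SCALE_ORDER)))
        for j, sname in enumerate(SCALE_ORDER):
            for aa, v in scales[sname].items():
                table[AA_INDEX[aa], j] = v
        self._table = table

    def dim(self, L: int) -> int:
        return 6 * L

    def encode(self, w: WindowInstance) -> np.ndarray:
        rows = [AA_INDEX.get(aa, 20) for aa in w.residues]
        return self._table[rows].ravel()


class SparseEncoder(FeatureEncoder):
    """20-bit one-hot residue identity per window position."""

    name = "sparse"

    def dim(self, L: int) -> int:
        return 20 * L

    def encode(self, w: WindowInstance) -> np.ndarray:
        out = np.zeros((w.L, 20))
        for k, aa in enumerate(w.residues):
            j = AA_INDEX.get(aa)
            if j is not None:
                out[k, j] = 1.0
        return out.ravel()


class CompositionEncoder(FeatureEncoder):
    """Amino-acid composition of the window's non-X content (20-simplex)."""

    name = "composition"

    def dim(self, L: int) -> int:
        return 20

    def encode(self, w: WindowInstance) -> np.ndarray:
        counts = np.zeros(20)
        for aa in w.residues:
            j = AA_INDEX.get(aa)
            if j is not None:
                counts[j] += 1
        total = counts.sum()
        if total == 0:
            raise UndefinedFeatureError(
                f"all-X window at {w.antigen_id}/{w.chain_id}:{w.center}"
            )
        return counts / total


class FunctionGroupEncoder(FeatureEncoder):
    """13-bit one-hot R-group function class per window position."""

    name = "function_group"

    def dim(self, L: int) -> int:
        return 13 * L

    def encode(self, w: WindowInstance) -> np.ndarray:
        out = np.zeros((w.L, 13))
        for k, aa in enumerate(w.residues):
            j = FUNCTION_GROUP_INDEX.get(aa)
            if j is not None:
                out[k, j] = 1.0
        return out.ravel()


class FunctionalCompositionEncoder(FeatureEncoder):
    """Fraction of each of the 13 function classes in the window."""

    name = "functional_composition"

    def dim(self, L: int) -> int:
        return 13

    def encode(self, w: WindowInstance) -> np.ndarray:
        counts = np.zeros(13)
        for aa in w.residues:
            j = FUNCTION_GROUP_INDEX.get(aa)
            if j is not None:
                counts[j] += 1
        total = counts.sum()
        if total == 0:
            raise UndefinedFeatureError(
                f"all-X window at {w.antigen_id}/{w.chain_id}:{w.center}"
            )
        return counts / total


class EvolutionaryEncoder(FeatureEncoder):
    """Logistic-rescaled PSSM rows of the window positions."""

    name = "evolutionary"
    requires = frozenset({"pssm"})

    def dim(self, L: int) -> int:
        return 20 * L

    def encode(self, w: WindowInstance) -> np.ndarray:
        if w.pssm_slice is None:
            raise MissingTrackError(
                f"encoder 'evolutionary' needs a PSSM for chain "
                f"{w.antigen_id}/{w.chain_id}"
            )
        return w.pssm_slice.ravel()


class PairProfileEncoder(FeatureEncoder):
    """Frequencies of ordered adjacent residue pairs (20x20 = 400 dims).

    Pairs touching an 'X' (padding or ambiguity) are excluded from both
    numerator and denominator.
    """

    name = "pair_profile"

    def dim(self, L: int) -> int:
        return 400

    def encode(self, w: WindowInstance) -> np.ndarray:
        counts = np.zeros((20, 20))
        n_pairs = 0
        for a, b in zip(w.residues, w.residues[1:]):
            ia, ib = AA_INDEX.get(a), AA_INDEX.get(b)
            if ia is not None and ib is not None:
                counts[ia, ib] += 1
                n_pairs += 1
        if n_pairs == 0:
            raise UndefinedFeatureError(
                f"no non-X adjacent pair at {w.antigen_id}/{w.chain_id}:"
                f"{w.center}"
            )
        return counts.ravel() / n_pairs


class SecondaryStructureEncoder(FeatureEncoder):
    """H -> (1,0,0), E -> (0,1,0), C -> (0,0,1) per position; padding -> zeros."""

    name = "ss"
    requires = frozenset({"ss"})

    def dim(self, L: int) -> int:
        return 3 * L

    def encode(self, w: WindowInstance) -> np.ndarray:
        if w.ss_slice is None:
            raise MissingTrackError(
                f"encoder 'ss' needs a secondary-structure track for chain "
                f"{w.antigen_id}/{w.chain_id}"
            )
        out = np.zeros((w.L, 3))
        for k, s in enumerate(w.ss_slice):
            if s != PAD:
                out[k] = _SS_ONEHOT[s]
        return out.ravel()


class RasaEncoder(FeatureEncoder):
    """Relative accessible surface area per position, rescaled to [0, 1]."""

    name = "rasa"
    requires = frozenset({"rasa"})

    def dim(self, L: int) -> int:
        return L

    def encode(self, w: WindowInstance) -> np.ndarray:
        if w.rasa_slice is None:
            raise MissingTrackError(
                f"encoder 'rasa' needs a RASA track for chain "
                f"{w.antigen_id}/{w.chain_id}"
            )
        return w.rasa_slice / 100.0


_ENCODER_CLASSES: dict[str, type[FeatureEncoder]] = {
    cls.name: cls
    for cls in (
        PropensityEncoder,
        SparseEncoder,
        CompositionEncoder,
        FunctionGroupEncoder,
        FunctionalCompositionEncoder,
        EvolutionaryEncoder,
        PairProfileEncoder,
        SecondaryStructureEncoder,
        RasaEncoder,
    )
}

ENCODER_NAMES: tuple[str, ...] = tuple(_ENCODER_CLASSES)


def get_encoder(name: str) -> FeatureEncoder:
    """Instantiate an encoder by registry name."""
    try:
        return _ENCODER_CLASSES[name]()
    except KeyError:
        raise EpiseqError(
            f"unknown encoder {name!r}; known: {sorted(_ENCODER_CLASSES)}"
        ) from None
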