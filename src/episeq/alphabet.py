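"""Canonical amino-acid alphabet and orderings.

Every 20-dimensional axis in the package (PSSM columns, sparse one-hot,
composition, pair profile) uses the alphabetical ordering
``ACDEFGHIKLMNPQRSTVWY``. PSI-BLAST PSSM files print their own column
order; it is remapped to this canonical order on read.
"""

from __future__ import annotations

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#: the padding / unknown-residue symbol
PAD = "X"

#: ambiguity and non-standard codes found in real antigen entries; all are
#: collapsed to 'X' on read and treated like padding by the encoders
AMBIGUOUS = frozenset("BZJUO")

#: column header order of PSI-BLAST `-out_ascii_pssm` files
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def sanitize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase *seq* and map every non-canonical letter to 'X'.

    Returns the cleaned sequence and the number of substituted positions.
    """
    seq = seq.upper()
    out = []
    n_sub = 0
    for ch in seq:
        if ch in AA_INDEX or ch == PAD:
            out.append(ch)
        else:
            out.append(PAD)
            n_sub += 1
    return "".join(out), n_sub
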