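"""Readers, writers and validated record assembly.

File conventions
----------------
* FASTA headers are ``>antigen_id|chain_id``; a header without ``|``
  denotes a single-chain antigen whose chain is named ``A``.
* All tabular files are tab-separated with a single header row.
* Positions are 1-based in every file and 0-based in memory.
* PSSMs come in the PSI-BLAST ``-out_ascii_pssm`` ASCII dialect; their
  column order is taken from the file header and remapped to the
  canonical ``ACDEFGHIKLMNPQRSTVWY`` order on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from scipy.special import expit

from .alphabet import AA_INDEX, CANONICAL_AA, PSIBLAST_ORDER, sanitize_sequence
from .errors import FormatError

logger = logging.getLogger(__name__)

SS_SYMBOLS = frozenset("HEC")


@dataclass
class ChainRecord:
    """One antigen chain with its optional per-residue tracks.

    Parameters
    ----------
    chain_id : str
        Chain identifier within the antigen.
    sequence : str
        Amino-acid sequence over the 20 canonical letters plus 'X'.
    labels : ndarray of {0,1}, optional
        Per-residue epitope labels (1 = epitope residue).
    pssm : ndarray of int, shape (N, 20), optional
        Raw log-odds PSSM, columns in canonical order.
    ss : str, optional
        Predicted secondary structure, one of H/E/C per residue.
    rasa : ndarray of float, optional
        Predicted relative accessible surface area, percent in [0, 100].
    """

    chain_id: str
    sequence: str
    labels: np.ndarray | None = None
    pssm: np.ndarray | None = None
    ss: str | None = None
    rasa: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise FormatError(f"chain {self.chain_id!r}: empty sequence")
        bad = set(self.sequence) - set(CANONICAL_AA) - {"X"}
        if bad:
            raise FormatError(
                f"chain {self.chain_id!r}: non-canonical letters {sorted(bad)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (n,):
                raise FormatError(
                    f"chain {self.chain_id!r}: labels length "
                    f"{self.labels.shape} != sequence length {n}"
                )
            if not np.isin(self.labels, (0, 1)).all():
                raise FormatError(f"chain {self.chain_id!r}: labels must be 0/1")
        if self.pssm is not None:
            self.pssm = np.asarray(self.pssm)
            if self.pssm.shape != (n, 20):
                raise FormatError(
                    f"chain {self.chain_id!r}: PSSM shape {self.pssm.shape} "
                    f"!= ({n}, 20)"
                )
        if self.ss is not None:
            if len(self.ss) != n:
                raise FormatError(f"chain {self.chain_id!r}: ss length mismatch")
            if set(self.ss) - SS_SYMBOLS:
                raise FormatError(
                    f"chain {self.chain_id!r}: ss symbols outside H/E/C"
                )
        if self.rasa is not None:
            self.rasa = np.asarray(self.rasa, dtype=float)
            if self.rasa.shape != (n,):
                raise FormatError(f"chain {self.chain_id!r}: rasa length mismatch")
            if (self.rasa < 0).any() or (self.rasa > 100).any():
                raise FormatError(
                    f"chain {self.chain_id!r}: rasa outside [0, 100]"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AntigenRecord:
    """One antigen: an ordered list of chains treated as a unit.

    Leave-one-out cross-validation folds are antigen-level: all chains of
    an antigen are held out together.
    """

    antigen_id: str
    chains: list[ChainRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.antigen_id:
            raise FormatError("antigen_id must be nonempty")
        if not self.chains:
            raise FormatError(f"antigen {self.antigen_id!r}: no chains")
        seen = set()
        for ch in self.chains:
            if ch.chain_id in seen:
                raise FormatError(
                    f"antigen {self.antigen_id!r}: duplicate chain "
                    f"{ch.chain_id!r}"
                )
            seen.add(ch.chain_id)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are uppercased; letters outside the 20 canonical amino
    acids become 'X' (with a logged warning). Empty files and duplicate
    ids are format errors.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq, n_sub = sanitize_sequence(str(rec.seq))
        if n_sub:
            logger.warning(
                "%s: %d non-canonical letter(s) in %r mapped to 'X'",
                path, n_sub, rec.id,
            )
        out.append((rec.id, seq))
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def split_fasta_id(fasta_id: str) -> tuple[str, str]:
    """Split ``antigen|chain`` headers; bare ids get chain 'A'."""
    if "|" in fasta_id:
        antigen, chain = fasta_id.split("|", 1)
        return antigen, chain
    return fasta_id, "A"


# ---------------------------------------------------------------------------
# Labels


def read_labels(
    path: str | Path,
    sequences: Mapping[tuple[str, str], str] | None = None,
) -> dict[tuple[str, str, int], int]:
    """Read per-residue epitope labels.

    Columns: antigen_id, chain_id, position (1-based), residue, label.
    Returns a map ``(antigen_id, chain_id, 0-based position) -> {0,1}``.
    When *sequences* is given, the residue column is cross-checked
    against it and any mismatch is an error.
    """
    path = Path(path)
    out: dict[tuple[str, str, int], int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["antigen_id", "chain_id", "position", "residue", "label"]
        if header != expected:
            raise FormatError(f"{path}: header {header} != {expected}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            ant, chain, pos_s, residue, label_s = fields
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            if label_s not in ("0", "1"):
                raise FormatError(f"{path}:{lineno}: label {label_s!r} not in 0/1")
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1")
            key = (ant, chain, pos - 1)
            if key in out:
                raise FormatError(
                    f"{path}:{lineno}: duplicate record for {ant}/{chain}:{pos}"
                )
            if sequences is not None:
                seq = sequences.get((ant, chain))
                if seq is None:
                    raise FormatError(
                        f"{path}:{lineno}: unknown chain {ant}/{chain}"
                    )
                if pos > len(seq):
                    raise FormatError(
                        f"{path}:{lineno}: position {pos} beyond chain length "
                        f"{len(seq)}"
                    )
                if seq[pos - 1] != residue:
                    raise FormatError(
                        f"{path}:{lineno}: residue {residue!r} != sequence "
                        f"{seq[pos - 1]!r} at {ant}/{chain}:{pos}"
                    )
            out[key] = int(label_s)
    return out


def write_labels(records: Sequence[AntigenRecord], path: str | Path) -> None:
    """Write the labels of *records* in the label TSV format."""
    with open(path, "w") as fh:
        fh.write("antigen_id\tchain_id\tposition\tresidue\tlabel\n")
        for rec in records:
            for ch in rec.chains:
                if ch.labels is None:
                    continue
                for i, (aa, lab) in enumerate(zip(ch.sequence, ch.labels)):
                    fh.write(
                        f"{rec.antigen_id}\t{ch.chain_id}\t{i + 1}\t{aa}\t{int(lab)}\n"
                    )


# ---------------------------------------------------------------------------
# PSSM


def _parse_pssm(path: Path) -> tuple[str, np.ndarray]:
    """Parse a PSI-BLAST ASCII PSSM, returning (query residues, N x 20 matrix).

    Only the first 20 numeric columns (log-odds) are consumed; the
    trailing percentage / information-content columns, when present, are
    ignored. Column order is remapped to the canonical alphabet.
    """
    lines = path.read_text().splitlines()
    header_cols: list[str] | None = None
    header_idx = -1
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(t in AA_INDEX for t in toks[:20]):
            header_cols = toks[:20]
            header_idx = i
            break
    if header_cols is None:
        raise FormatError(f"{path}: no PSSM column header found")
    if len(set(header_cols)) != 20:
        raise FormatError(f"{path}: PSSM header does not list 20 distinct residues")
    remap = [header_cols.index(aa) for aa in CANONICAL_AA]

    residues: list[str] = []
    rows: list[list[int]] = []
    expected_pos = 1
    for line in lines[header_idx + 1 :]:
        toks = line.split()
        if len(toks) < 22:
            if rows and not toks:
                break  # blank line after the matrix body ends it
            continue
        try:
            pos = int(toks[0])
        except ValueError:
            continue
        if pos != expected_pos:
            raise FormatError(
                f"{path}: row position {pos}, expected {expected_pos}"
            )
        aa = toks[1]
        try:
            vals = [int(v) for v in toks[2:22]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer log-odds at row {pos}") from exc
        residues.append(aa)
        rows.append([vals[j] for j in remap])
        expected_pos += 1
    if not rows:
        raise FormatError(f"{path}: no PSSM rows parsed")
    return "".join(residues), np.asarray(rows, dtype=int)


def read_pssm(path: str | Path) -> np.ndarray:
    """Read a PSI-BLAST ASCII PSSM into an N x 20 integer matrix.

    Columns are in canonical ``ACDEFGHIKLMNPQRSTVWY`` order regardless of
    the order printed in the file header.
    """
    _, matrix = _parse_pssm(Path(path))
    return matrix


def write_pssm(sequence: str, matrix: np.ndarray, path: str | Path) -> None:
    """Write *matrix* (canonical column order) in the PSI-BLAST ASCII dialect.

    The file prints columns in the standard PSI-BLAST order so that
    ``read_pssm`` exercises the header remapping on round trip.
    """
    matrix = np.asarray(matrix, dtype=int)
    if matrix.shape != (len(sequence), 20):
        raise FormatError(
            f"PSSM shape {matrix.shape} != ({len(sequence)}, 20)"
        )
    col_of = [AA_INDEX[aa] for aa in PSIBLAST_ORDER]
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("           " + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, aa in enumerate(sequence):
            vals = " ".join(f"{matrix[i, j]:3d}" for j in col_of)
            fh.write(f"{i + 1:5d} {aa}  {vals}\n")
        fh.write("\n")


def logistic_rescale(pssm: np.ndarray) -> np.ndarray:
    """Map raw log-odds elementwise through the standard logistic function.

    ``e -> 1 / (1 + exp(-e))``; strictly monotone, output in (0, 1).
    """
    return expit(np.asarray(pssm, dtype=float))


# ---------------------------------------------------------------------------
# Predicted structure tracks


def read_structprops(path: str | Path) -> tuple[str, np.ndarray]:
    """Read predicted secondary structure and RASA for one chain.

    Columns: position (1-based, contiguous from 1), ss in {H,E,C},
    rasa in [0, 100]. Returns ``(ss_string, rasa_array)``.
    """
    path = Path(path)
    ss: list[str] = []
    rasa: list[float] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["position", "ss", "rasa"]:
            raise FormatError(f"{path}: bad header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            pos = int(fields[0])
            if pos != len(ss) + 1:
                raise FormatError(
                    f"{path}:{lineno}: gap in positions (got {pos}, "
                    f"expected {len(ss) + 1})"
                )
            if fields[1] not in SS_SYMBOLS:
                raise FormatError(f"{path}:{lineno}: ss symbol {fields[1]!r}")
            val = float(fields[2])
            if not 0.0 <= val <= 100.0:
                raise FormatError(f"{path}:{lineno}: rasa {val} outside [0, 100]")
            ss.append(fields[1])
            rasa.append(val)
    if not ss:
        raise FormatError(f"{path}: empty structure file")
    return "".join(ss), np.asarray(rasa)


def write_structprops(ss: str, rasa: np.ndarray, path: str | Path) -> None:
    if len(ss) != len(rasa):
        raise FormatError("ss/rasa length mismatch")
    with open(path, "w") as fh:
        fh.write("position\tss\trasa\n")
        for i, (s, r) in enumerate(zip(ss, rasa)):
            fh.write(f"{i + 1}\t{s}\t{r:.6f}\n")


# ---------------------------------------------------------------------------
# Predictions


def write_predictions(
    records: Sequence[AntigenRecord],
    scores: Mapping[tuple[str, str], np.ndarray],
    path: str | Path,
    threshold: float = 0.5,
) -> None:
    """Write per-residue scores and thresholded calls.

    Columns: antigen_id, chain_id, position (1-based), residue, score
    (6 decimals), predicted_label (score >= threshold). Record order
    follows *records*; one row per residue.
    """
    with open(path, "w") as fh:
        fh.write("antigen_id\tchain_id\tposition\tresidue\tscore\tpredicted_label\n")
        for rec in records:
            for ch in rec.chains:
                key = (rec.antigen_id, ch.chain_id)
                if key not in scores:
                    raise FormatError(f"no scores for chain {key}")
                vec = np.asarray(scores[key], dtype=float)
                if vec.shape != (len(ch),):
                    raise FormatError(
                        f"chain {key}: {vec.shape[0] if vec.ndim else 0} scores "
                        f"for {len(ch)} residues"
                    )
                for i, (aa, s) in enumerate(zip(ch.sequence, vec)):
                    fh.write(
                        f"{rec.antigen_id}\t{ch.chain_id}\t{i + 1}\t{aa}\t"
                        f"{s:.6f}\t{int(s >= threshold)}\n"
                    )


def read_predictions(path: str | Path) -> dict[tuple[str, str], np.ndarray]:
    """Read a prediction TSV back into ``(antigen, chain) -> score array``."""
    out: dict[tuple[str, str], list[float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["antigen_id", "chain_id", "position", "residue", "score"]:
            raise FormatError(f"{path}: bad prediction header")
        for line in fh:
            if not line.strip():
                continue
            ant, chain, pos, _aa, score = line.rstrip("\n").split("\t")[:5]
            key = (ant, chain)
            lst = out.setdefault(key, [])
            if int(pos) != len(lst) + 1:
                raise FormatError(f"{path}: positions out of order for {key}")
            lst.append(float(score))
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Dataset assembly


def load_dataset(
    fasta_path: str | Path,
    labels_path: str | Path | None = None,
    pssm_dir: str | Path | None = None,
    struct_dir: str | Path | None = None,
) -> list[AntigenRecord]:
    """Assemble validated AntigenRecords from the on-disk file set.

    PSSM files are looked up as ``<pssm_dir>/<antigen>_<chain>.pssm`` and
    structure files as ``<struct_dir>/<antigen>_<chain>.tsv``; a missing
    file simply leaves the track unset.
    """
    entries = read_fasta(fasta_path)
    sequences = {split_fasta_id(fid): seq for fid, seq in entries}
    if len(sequences) != len(entries):
        raise FormatError(f"{fasta_path}: duplicate antigen/chain pair")

    labels = (
        read_labels(labels_path, sequences) if labels_path is not None else None
    )

    by_antigen: dict[str, list[ChainRecord]] = {}
    order: list[str] = []
    for fid, seq in entries:
        ant, chain = split_fasta_id(fid)
        lab = None
        if labels is not None:
            lab = np.zeros(len(seq), dtype=np.int8)
            any_row = False
            for i in range(len(seq)):
                v = labels.get((ant, chain, i))
                if v is not None:
                    lab[i] = v
                    any_row = True
            if not any_row:
                lab = None
        pssm = None
        if pssm_dir is not None:
            p = Path(pssm_dir) / f"{ant}_{chain}.pssm"
            if p.exists():
                residues, pssm = _parse_pssm(p)
                if len(residues) != len(seq):
                    raise FormatError(
                        f"{p}: PSSM rows ({len(residues)}) != chain length "
                        f"({len(seq)})"
                    )
        ss = rasa = None
        if struct_dir is not None:
            p = Path(struct_dir) / f"{ant}_{chain}.tsv"
            if p.exists():
                ss, rasa = read_structprops(p)
                if len(ss) != len(seq):
                    raise FormatError(f"{p}: track length != chain length")
        if ant not in by_antigen:
            order.append(ant)
        by_antigen.setdefault(ant, []).append(
            ChainRecord(chain, seq, labels=lab, pssm=pssm, ss=ss, rasa=rasa)
        )
    return [AntigenRecord(ant, by_antigen[ant]) for ant in order]
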