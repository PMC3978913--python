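"""Alignment-level sequence statistics for the COI fragment analysis.

Holds the equal-length DNA alignment container, FASTA round-trip I/O,
site classification (invariant / variable-uninformative /
parsimony-informative), average base composition, stop-codon screening
under the invertebrate mitochondrial code, and Kimura 2-parameter (K2P)
pairwise distances with transition/transversion proportions.

Only the plain {A, C, G, T} alphabet is supported: the target alignments
contain no gaps or ambiguity codes, and pairwise-deletion handling is
deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_PURINE = {"A", "G"}

#: NCBI translation table for invertebrate mitochondrial DNA.
INVERTEBRATE_MITO_TABLE = 5


class AlignmentError(ValueError):
    """Raised for ragged, empty or non-ACGT alignments."""


class SaturationError(ValueError):
    """K2P distance undefined: the log arguments are non-positive."""


# ---------------------------------------------------------------------------
# Alignment container and FASTA I/O
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Ordered equal-length DNA records.

    Record ids follow the ``sampleID|host|hapN`` convention produced by the
    synthetic generator, but arbitrary ids are accepted.
    """

    records: list[tuple[str, str]]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment must contain at least one record")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        self.length = lengths.pop()
        for rid, seq in self.records:
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise AlignmentError(
                    f"record {rid!r} contains non-ACGT symbols: {sorted(bad)}"
                )

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise KeyError(rid)

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        lookup = dict(self.records)
        missing = [i for i in wanted if i not in lookup]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        return Alignment([(i, lookup[i]) for i in wanted])

    def matrix(self) -> np.ndarray:
        """Integer-encoded (n_records, length) view, A=0 C=1 G=2 T=3."""
        return np.array(
            [[_CODE[b] for b in seq] for _, seq in self.records], dtype=np.uint8
        )


def read_fasta(path: str | Path) -> Alignment:
    # full description, not rec.id: the ``sampleID|host|hapN`` convention
    # contains spaces in host names
    records = [
        (rec.description, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return Alignment(records)


def write_fasta(alignment: Alignment, path: str | Path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in alignment.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

INVARIANT = "invariant"
VARIABLE_UNINFORMATIVE = "variable-uninformative"
PARSIMONY_INFORMATIVE = "parsimony-informative"


@dataclass
class SiteClassification:
    position: int  # 1-based
    states: dict[str, int]
    klass: str


def classify_sites(alignment: Alignment) -> list[SiteClassification]:
    """Classify every column.

    A column is parsimony-informative iff it carries at least two states
    that are each present in at least two sequences.
    """
    mat = alignment.matrix()
    out: list[SiteClassification] = []
    for j in range(alignment.length):
        col = mat[:, j]
        vals, counts = np.unique(col, return_counts=True)
        states = {ALPHABET[v]: int(c) for v, c in zip(vals, counts)}
        if len(vals) == 1:
            klass = INVARIANT
        elif int((counts >= 2).sum()) >= 2:
            klass = PARSIMONY_INFORMATIVE
        else:
            klass = VARIABLE_UNINFORMATIVE
        out.append(SiteClassification(j + 1, states, klass))
    return out


def site_class_counts(sites: Sequence[SiteClassification]) -> dict[str, int]:
    counts = {INVARIANT: 0, VARIABLE_UNINFORMATIVE: 0, PARSIMONY_INFORMATIVE: 0}
    for s in sites:
        counts[s.klass] += 1
    return counts


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------

@dataclass
class BaseComposition:
    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float

    def as_dict(self) -> dict[str, float]:
        return {
            "A": self.freq_A,
            "C": self.freq_C,
            "G": self.freq_G,
            "T": self.freq_T,
        }


def base_composition(alignment: Alignment) -> BaseComposition:
    """Base frequencies averaged over all records."""
    mat = alignment.matrix()
    counts = np.bincount(mat.ravel(), minlength=4).astype(float)
    freqs = counts / counts.sum()
    return BaseComposition(*map(float, freqs))


# ---------------------------------------------------------------------------
# Stop-codon screening
# ---------------------------------------------------------------------------

def stop_codon_scan(
    alignment: Alignment,
    code: int = INVERTEBRATE_MITO_TABLE,
    frame: int | None = None,
) -> dict[str, dict[int, int]]:
    """Count in-frame stop codons per record.

    With ``frame=None`` all three forward frames are reported; otherwise a
    single frame (0, 1 or 2). Trailing partial codons are ignored.
    """
    frames = (0, 1, 2) if frame is None else (frame,)
    for f in frames:
        if f not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {f}")
    out: dict[str, dict[int, int]] = {}
    for rid, seq in alignment.records:
        per_frame: dict[int, int] = {}
        for f in frames:
            sub = seq[f:]
            sub = sub[: len(sub) - len(sub) % 3]
            protein = str(Seq(sub).translate(table=code))
            per_frame[f] = protein.count("*")
        out[rid] = per_frame
    return out


def zero_stop_frame(
    alignment: Alignment, code: int = INVERTEBRATE_MITO_TABLE
) -> int | None:
    """Smallest forward frame with zero stops across all records, if any."""
    scan = stop_codon_scan(alignment, code=code)
    for f in (0, 1, 2):
        if all(per_frame[f] == 0 for per_frame in scan.values()):
            return f
    return None


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------

@dataclass
class K2PDistance:
    """Kimura 2-parameter distance with its P (transition) and Q
    (transversion) site proportions; d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""

    P: float
    Q: float
    d: float


def _k2p_from_counts(n_ts: int, n_tv: int, length: int) -> K2PDistance:
    P = n_ts / length
    Q = n_tv / length
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        raise SaturationError(
            f"K2P distance undefined at P={P:.4f}, Q={Q:.4f} (saturated)"
        )
    d = -0.5 * math.log(a) - 0.25 * math.log(b) + 0.0  # +0.0 normalises -0.0
    return K2PDistance(P=P, Q=Q, d=d)


def k2p(seq_a: str, seq_b: str) -> K2PDistance:
    """K2P distance between two aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences differ in length")
    n_ts = n_tv = 0
    for x, y in zip(seq_a, seq_b):
        if x == y:
            continue
        if x not in ALPHABET or y not in ALPHABET:
            raise AlignmentError(f"non-ACGT symbol in pair ({x}, {y})")
        if (x in _PURINE) == (y in _PURINE):
            n_ts += 1
        else:
            n_tv += 1
    return _k2p_from_counts(n_ts, n_tv, len(seq_a))


# ---------------------------------------------------------------------------
# Distance matrix and summaries
# ---------------------------------------------------------------------------

def round_percent(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, matching reported divergence precision."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal, substitutions/site

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.matrix < 0).any():
            raise ValueError("distance matrix must be non-negative")

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.matrix[i, j])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.matrix[np.ix_(idx, idx)].copy())

    def summary(
        self,
        ids_a: Sequence[str] | None = None,
        ids_b: Sequence[str] | None = None,
    ) -> dict:
        """Min / max / mean pairwise divergence over an id subset.

        With one subset, all unordered within-subset pairs are used; with
        two disjoint subsets, all between-subset pairs. Percent values are
        rounded half away from zero to one decimal, matching the reporting
        convention for divergence ranges.
        """
        if ids_a is None:
            ids_a = self.ids
        ia = [self.ids.index(i) for i in ids_a]
        if ids_b is None:
            vals = [
                float(self.matrix[ia[p], ia[q]])
                for p in range(len(ia))
                for q in range(p + 1, len(ia))
            ]
        else:
            ib = [self.ids.index(i) for i in ids_b]
            vals = [float(self.matrix[p, q]) for p in ia for q in ib]
        if not vals:
            return {"n_pairs": 0, "min": None, "max": None, "mean": None,
                    "min_pct": None, "max_pct": None, "mean_pct": None}
        arr = np.asarray(vals)
        return {
            "n_pairs": len(vals),
            "min": float(arr.min()),
            "max": float(arr.max()),
            "mean": float(arr.mean()),
            "min_pct": round_percent(100 * arr.min()),
            "max_pct": round_percent(100 * arr.max()),
            "mean_pct": round_percent(100 * arr.mean()),
        }

    def to_tsv(self, path: str | Path, decimals: int = 7) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                row = "\t".join(f"{v:.{decimals}f}" for v in self.matrix[i])
                fh.write(f"{rid}\t{row}\n")


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """All-pairs K2P distance matrix (vectorised over sites)."""
    if len(alignment) < 2:
        raise AlignmentError("distance matrix requires at least 2 records")
    mat = alignment.matrix()
    n, length = mat.shape
    purine = (mat == _CODE["A"]) | (mat == _CODE["G"])
    dm = np.zeros((n, n))
    for i in range(n):
        diff = mat[i + 1 :] != mat[i]  # (n-i-1, L)
        same_class = purine[i + 1 :] == purine[i]
        n_ts = (diff & same_class).sum(axis=1)
        n_tv = (diff & ~same_class).sum(axis=1)
        for k, (ts, tv) in enumerate(zip(n_ts, n_tv)):
            j = i + 1 + k
            try:
                dm[i, j] = dm[j, i] = _k2p_from_counts(int(ts), int(tv), length).d
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({alignment.ids[i]}, {alignment.ids[j]}): {exc}"
                ) from exc
    return DistanceMatrix(list(alignment.ids), dm)
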