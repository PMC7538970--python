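"""Kimura two-parameter (K2P) distances among haplotypes.

The K2P model corrects observed divergence separately for transitions
(A<->G, C<->T; proportion P) and transversions (proportion Q):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Columns with N, gaps or ambiguity codes in either sequence are excluded
pairwise; a pair with fewer than ``min_overlap`` comparable sites, or whose
log argument is non-positive (saturation), is *undefined* and excluded from
histograms and gap detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, CoverageError
from .partition import Partition
from .seqio import HaplotypeTable

#: default minimum number of comparable sites per pair, mirroring the 300-bp
#: floor below which barcode fragments are not assignable.
DEFAULT_MIN_OVERLAP = 300

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i  # A=0 C=1 G=2 T=3; purines even, pyrimidines odd


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8 codes; non-ACGT -> 255 (missing)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def k2p_from_pq(p: float, q: float) -> float:
    """Evaluate the K2P closed form; NaN when the log argument is <= 0."""
    arg = (1.0 - 2.0 * p - q) * np.sqrt(max(1.0 - 2.0 * q, 0.0))
    if arg <= 0.0:
        return float("nan")
    return float(-0.5 * np.log(arg))


def k2p(a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """K2P distance between two windowed sequences (NaN if undefined)."""
    if len(a) != len(b):
        raise AlignmentError(f"unequal sequence lengths {len(a)} vs {len(b)}")
    ca, cb = encode(a), encode(b)
    valid = (ca < 4) & (cb < 4)
    n = int(valid.sum())
    if n < min_overlap:
        return float("nan")
    da, db = ca[valid], cb[valid]
    diff = da != db
    transition = diff & ((da % 2) == (db % 2))
    p = float(transition.sum()) / n
    q = float((diff & ~transition).sum()) / n
    return k2p_from_pq(p, q)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distances among haplotypes.

    Undefined entries (insufficient overlap or saturation) are stored as NaN;
    the diagonal is zero.
    """

    ids: list[str]
    d: np.ndarray
    min_overlap: int = DEFAULT_MIN_OVERLAP
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        self._index = {h: i for i, h in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    @property
    def undefined_pairs(self) -> set[tuple[str, str]]:
        out = set()
        iu, ju = np.triu_indices(len(self.ids), k=1)
        for i, j in zip(iu, ju):
            if np.isnan(self.d[i, j]):
                out.add((self.ids[i], self.ids[j]))
        return out

    def upper_values(self, defined_only: bool = True) -> np.ndarray:
        iu, ju = np.triu_indices(len(self.ids), k=1)
        vals = self.d[iu, ju]
        return vals[~np.isnan(vals)] if defined_only else vals

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[h] for h in ids]
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)], self.min_overlap)

    def between(self, ids_a: list[str], ids_b: list[str]) -> np.ndarray:
        ia = [self._index[h] for h in ids_a]
        ib = [self._index[h] for h in ids_b]
        vals = self.d[np.ix_(ia, ib)].ravel()
        return vals[~np.isnan(vals)]


def k2p_matrix(
    haps: HaplotypeTable | dict[str, str],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All-pairs K2P with pairwise deletion of missing/ambiguous columns."""
    if isinstance(haps, HaplotypeTable):
        seqs = {h: haps.sequence(h) for h in haps.ids()}
    else:
        seqs = dict(haps)
    ids = list(seqs)
    n = len(ids)
    codes = np.stack([encode(seqs[h]) for h in ids])
    valid = codes < 4
    parity = codes % 2
    d = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        overlap = v.sum(axis=1)
        diff = (codes[i] != codes[i + 1 :]) & v
        transitions = (diff & (parity[i] == parity[i + 1 :])).sum(axis=1)
        transversions = diff.sum(axis=1) - transitions
        with np.errstate(divide="ignore", invalid="ignore"):
            p = transitions / overlap
            q = transversions / overlap
            arg = (1.0 - 2.0 * p - q) * np.sqrt(np.maximum(1.0 - 2.0 * q, 0.0))
            row = np.where(arg > 0, -0.5 * np.log(np.maximum(arg, 1e-300)), np.nan)
        row = np.where(overlap >= min_overlap, row, np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return DistanceMatrix(ids, d, min_overlap)


def distance_histogram(m: DistanceMatrix, bin_width: float) -> dict[float, int]:
    """Histogram of defined upper-triangle distances in half-open bins
    ``[lo, lo + bin_width)``, keyed by the bin lower bound."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = m.upper_values()
    hist: dict[float, int] = {}
    for v in vals:
        lo = np.floor(v / bin_width) * bin_width
        lo = round(float(lo), 10)
        hist[lo] = hist.get(lo, 0) + 1
    return dict(sorted(hist.items()))


@dataclass
class DistanceDecomposition:
    """Defined pairwise distances split by MOTU-label equality."""

    within: list[float]
    between: list[float]


def within_between(m: DistanceMatrix, p: Partition) -> DistanceDecomposition:
    """Classify each defined pair as within- or between-MOTU under ``p``."""
    missing = set(m.ids) - set(p.labels)
    if missing:
        raise CoverageError(f"partition does not cover matrix ids: {sorted(missing)[:5]}")
    within: list[float] = []
    between: list[float] = []
    iu, ju = np.triu_indices(len(m.ids), k=1)
    for i, j in zip(iu, ju):
        v = m.d[i, j]
        if np.isnan(v):
            continue
        (within if p.labels[m.ids[i]] == p.labels[m.ids[j]] else between).append(float(v))
    return DistanceDecomposition(within, between)


def write_matrix(m: DistanceMatrix, path, fmt: str = "tsv") -> None:
    """Write as long-form TSV (id_a, id_b, d) or PHYLIP square matrix."""
    if fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(m.ids)}\n")
            for i, h in enumerate(m.ids):
                row = " ".join(f"{v:.6f}" if not np.isnan(v) else "NA" for v in m.d[i])
                fh.write(f"{h} {row}\n")
        return
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\td\n")
        iu, ju = np.triu_indices(len(m.ids), k=1)
        for i, j in zip(iu, ju):
            v = m.d[i, j]
            fh.write(f"{m.ids[i]}\t{m.ids[j]}\t{'' if np.isnan(v) else f'{v:.6f}'}\n")
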