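"""Sequence, site-table and tree I/O plus haplotype collapsing.

Barcode datasets arrive as aligned FASTA (one entry per individual, header
``record|site``), a per-individual site table (TSV), and optionally a rooted
Newick tree.  The analysis window (e.g. a 530-nt region of the COI barcode)
is applied with :func:`trim_to_window` before individuals are collapsed into
haplotypes by exact string identity with :func:`collapse_haplotypes`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import (
    AlignmentError,
    CoverageError,
    EmptyInputError,
    FormatError,
)

logger = logging.getLogger("cryptomotu")

#: IUPAC nucleotide codes accepted in input sequences, plus N and gap.
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: Characters that carry no unambiguous base: excluded from overlap counts.
MISSING = set("N-") | (IUPAC_DNA - set("ACGTN-"))


@dataclass
class SequenceRecord:
    """A single barcoded individual."""

    record_id: str
    site_id: str
    sequence: str
    source: str = "new"  # "new" or "literature"

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def effective_length(self) -> int:
        """Number of unambiguous A/C/G/T positions (the 'bp' length used by
        sequence-length rules)."""
        return sum(1 for c in self.sequence if c in "ACGT")


@dataclass
class BarcodeAlignment:
    """An aligned set of barcode records plus the analysis window.

    ``window`` is a 0-based half-open column interval into the aligned
    columns; records all share one aligned length.
    """

    records: list[SequenceRecord]
    window: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        lengths = {r.length_nt for r in self.records}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal aligned lengths: {sorted(lengths)}")
        if self.records and self.window == (0, 0):
            self.window = (0, self.records[0].length_nt)
        n = self.aligned_length
        if not (0 <= self.window[0] <= self.window[1] <= n):
            raise AlignmentError(f"window {self.window} outside alignment of length {n}")

    @property
    def aligned_length(self) -> int:
        return self.records[0].length_nt if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]


@dataclass
class HaplotypeTable:
    """Result of collapsing records into haplotypes.

    ``entries`` maps ``haplotype_id -> (windowed sequence, member record ids)``;
    member sets partition the record set, and two records share a haplotype
    iff their windowed sequences are identical strings.
    """

    entries: dict[str, tuple[str, list[str]]]
    record_to_haplotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.record_to_haplotype:
            self.record_to_haplotype = {
                rid: hid for hid, (_, members) in self.entries.items() for rid in members
            }

    @property
    def n_haplotypes(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return list(self.entries)

    def sequence(self, haplotype_id: str) -> str:
        return self.entries[haplotype_id][0]

    def members(self, haplotype_id: str) -> list[str]:
        return self.entries[haplotype_id][1]

    def effective_length(self, haplotype_id: str) -> int:
        return sum(1 for c in self.entries[haplotype_id][0] if c in "ACGT")


@dataclass
class SiteTable:
    """Per-site geography: WGS84 coordinates, altitude and country."""

    table: pd.DataFrame  # index site_id; columns lat, lon, altitude_m, country

    def __post_init__(self) -> None:
        required = {"lat", "lon", "altitude_m", "country"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"site table missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise FormatError(f"duplicate site ids: {dups[:5]}")
        bad_lat = ~self.table["lat"].between(-90, 90)
        bad_lon = ~self.table["lon"].between(-180, 180)
        if bad_lat.any() or bad_lon.any():
            bad = self.table.index[bad_lat | bad_lon].tolist()
            raise FormatError(f"coordinates out of range for sites: {bad[:5]}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.table.index)

    def coords(self, site_id: str) -> tuple[float, float]:
        row = self.table.loc[site_id]
        return float(row["lat"]), float(row["lon"])

    def altitude(self, site_id: str) -> float:
        return float(self.table.loc[site_id, "altitude_m"])

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.table.index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_sites(path: str | Path) -> SiteTable:
    """Read a site table TSV with columns site_id, lat, lon, altitude_m, country."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "country": str})
    if "site_id" not in df.columns:
        raise FormatError(f"{path}: site table needs a 'site_id' column")
    return SiteTable(df.set_index("site_id"))


def write_sites(sites: SiteTable, path: str | Path) -> None:
    sites.table.rename_axis("site_id").reset_index().to_csv(path, sep="\t", index=False)


def read_fasta(
    path: str | Path,
    site_map: str | Path | None = None,
    allow_unaligned: bool = False,
) -> BarcodeAlignment:
    """Read aligned FASTA into a :class:`BarcodeAlignment`.

    The site id is parsed from the header field after the first ``|``; a
    ``site_map`` TSV (columns record_id, site_id) overrides the header
    convention.  Sequences must share one aligned length unless
    ``allow_unaligned`` is set (downstream window operations then reject the
    alignment).
    """
    overrides: dict[str, str] = {}
    if site_map is not None:
        m = pd.read_csv(site_map, sep="\t", dtype=str)
        if not {"record_id", "site_id"}.issubset(m.columns):
            raise FormatError(f"{site_map}: site map needs columns record_id, site_id")
        overrides = dict(zip(m["record_id"], m["site_id"]))

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.id
        record_id, _, site_from_header = header.partition("|")
        seq = str(entry.seq).upper()
        bad = set(seq) - IUPAC_DNA
        if bad:
            raise FormatError(f"record {record_id!r}: non-IUPAC characters {sorted(bad)}")
        if record_id in seen:
            raise FormatError(f"duplicate record id {record_id!r}")
        seen.add(record_id)
        site_id = overrides.get(record_id, site_from_header)
        records.append(SequenceRecord(record_id, site_id, seq))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA entries")

    lengths = {r.length_nt for r in records}
    if len(lengths) > 1 and not allow_unaligned:
        raise AlignmentError(
            f"{path}: sequences have unequal lengths {sorted(lengths)[:5]}; "
            "align them or pass allow_unaligned"
        )
    if len(lengths) > 1:
        # represented as-is; window ops will reject
        aln = BarcodeAlignment.__new__(BarcodeAlignment)
        aln.records = records
        aln.window = (0, 0)
        return aln
    return BarcodeAlignment(records)


def write_fasta(aln: BarcodeAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in aln:
            fh.write(f">{r.record_id}|{r.site_id}\n{r.sequence}\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError(f"{path}: unlabeled tip in tree")
    missing = [
        nd.taxon.label if nd.is_leaf() else "<internal>"
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and nd.edge.length is None
    ]
    if missing:
        raise FormatError(f"{path}: branches without lengths at {missing[:5]}")
    return tree


def check_tree_tips(tree: dendropy.Tree, haplotype_ids: list[str]) -> None:
    """Raise if tree tips and haplotype ids disagree, naming the offenders."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    extra = tips - set(haplotype_ids)
    if extra:
        raise CoverageError(f"tree tips absent from haplotype table: {sorted(extra)}")


# ---------------------------------------------------------------------------
# window trimming and haplotype collapsing
# ---------------------------------------------------------------------------


def trim_to_window(aln: BarcodeAlignment, start: int, length: int) -> BarcodeAlignment:
    """Cut every sequence to the half-open column interval [start, start+length).

    Records whose windowed sequence is entirely N/gap are dropped; the drop
    count is logged and recorded on the returned alignment's window metadata.
    """
    if len({r.length_nt for r in aln.records}) > 1:
        raise AlignmentError("cannot window an unaligned record set")
    if start < 0 or start + length > aln.aligned_length:
        raise AlignmentError(
            f"window [{start}, {start + length}) outside alignment of "
            f"length {aln.aligned_length}"
        )
    kept: list[SequenceRecord] = []
    dropped = 0
    for r in aln:
        sub = r.sequence[start : start + length]
        if all(c in "N-" for c in sub):
            dropped += 1
            continue
        kept.append(replace(r, sequence=sub))
    if dropped:
        logger.info("trim_to_window: dropped %d all-missing records", dropped)
    out = BarcodeAlignment(kept, window=(0, length))
    # remember the original coordinates for provenance
    out.window = (0, length)
    return out


def collapse_haplotypes(aln: BarcodeAlignment) -> HaplotypeTable:
    """Group records by exact string identity of the windowed sequence.

    Haplotype ids are assigned ``H0001…`` in order of first appearance, so
    the mapping is deterministic for a fixed record order while the grouping
    itself is order-invariant.  IUPAC ambiguity codes and N are ordinary
    characters here: two sequences differing only at an N position are
    distinct haplotypes.
    """
    if not aln.records:
        raise EmptyInputError("cannot collapse an empty alignment")
    by_seq: dict[str, list[str]] = {}
    for r in aln:
        by_seq.setdefault(r.sequence, []).append(r.record_id)
    entries = {
        f"H{i + 1:04d}": (seq, members)
        for i, (seq, members) in enumerate(by_seq.items())
    }
    return HaplotypeTable(entries)
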