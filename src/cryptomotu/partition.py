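"""MOTU partitions: the common currency of all delimitation methods.

A :class:`Partition` maps haplotype ids to MOTU labels under one method
(ABGD, RESL, PTP or Lagrue).  Partitions are compared structurally — two
partitions are "the same" when they induce the same grouping of ids,
regardless of the label strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CoverageError, FormatError

METHODS = ("ABGD", "RESL", "PTP", "LAGRUE", "TRUTH", "CUSTOM")


@dataclass
class Partition:
    """Assignment of haplotypes to MOTU labels under one method.

    Parameters
    ----------
    method:
        One of ``ABGD``, ``RESL``, ``PTP``, ``LAGRUE``, ``TRUTH`` or
        ``CUSTOM`` (externally supplied labels, e.g. major clades).
    labels:
        Mapping ``haplotype_id -> motu_label``.  Every id is labelled
        exactly once by construction of the mapping.
    provenance:
        Free-form record of the parameters that produced the partition.
    """

    method: str
    labels: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")

    @property
    def ids(self) -> list[str]:
        return list(self.labels)

    @property
    def n_motus(self) -> int:
        return len(set(self.labels.values()))

    def as_sets(self) -> list[frozenset[str]]:
        """The grouping induced by the labels, as frozensets of ids."""
        groups: dict[str, set[str]] = {}
        for hid, lab in self.labels.items():
            groups.setdefault(lab, set()).add(hid)
        return [frozenset(g) for g in groups.values()]

    def same_grouping(self, other: "Partition") -> bool:
        return set(self.as_sets()) == set(other.as_sets())

    def members(self, label: str) -> frozenset[str]:
        return frozenset(h for h, l in self.labels.items() if l == label)

    def restrict(self, ids: Iterable[str]) -> "Partition":
        ids = set(ids)
        missing = ids - set(self.labels)
        if missing:
            raise CoverageError(f"ids not covered by partition: {sorted(missing)[:5]}")
        return Partition(self.method, {i: self.labels[i] for i in ids}, dict(self.provenance))


def relabel_canonical(labels: Mapping[str, str], prefix: str) -> dict[str, str]:
    """Renumber labels as ``<prefix>001…`` in order of first appearance."""
    seen: dict[str, str] = {}
    out = {}
    for hid, lab in labels.items():
        if lab not in seen:
            seen[lab] = f"{prefix}{len(seen) + 1:03d}"
        out[hid] = seen[lab]
    return out


def write_partition(p: Partition, path: str | Path) -> None:
    """Write a partition as a 3-column TSV (haplotype_id, method, motu_label)."""
    df = pd.DataFrame(
        {"haplotype_id": list(p.labels), "method": p.method, "motu_label": list(p.labels.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"haplotype_id", "method", "motu_label"}
    if not required.issubset(df.columns):
        raise FormatError(f"partition file {path} must have columns {sorted(required)}")
    if df["haplotype_id"].duplicated().any():
        dups = df.loc[df["haplotype_id"].duplicated(), "haplotype_id"].tolist()
        raise FormatError(f"duplicate haplotype ids in partition file: {dups[:5]}")
    methods = df["method"].unique()
    if len(methods) != 1:
        raise FormatError(f"partition file mixes methods: {list(methods)}")
    return Partition(methods[0], dict(zip(df["haplotype_id"], df["motu_label"])))
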