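"""Strand-aware merging of structural variants across samples.

Two calls link when they sit on the same chromosome, share type and strands
(when required), and both breakpoints agree within ``max_dist`` bp. Clusters
are the single-linkage closure of that relation (chains can therefore span
more than ``max_dist`` end to end, as in SURVIVOR-style merging); each
cluster is reported once with its medoid member as representative and the
set of supporting samples. Insertions compare insertion point and inserted
length; translocations require both loci to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, VariantRecord

SV_TYPES = ("INS", "DEL", "INV", "DUP", "TRA")


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant call from one sample (1-based closed span)."""

    sample: str
    chrom: str
    start: int
    end: int
    svtype: str
    strands: str = "+-"
    length: int | None = None   # for INS, the inserted length
    chrom2: str | None = None   # second locus (TRA)
    pos2: int | None = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.end < self.start:
            raise ValueError(f"end < start at {self.chrom}:{self.start}")
        if self.svtype == "TRA" and (self.chrom2 is None or self.pos2 is None):
            raise ValueError("TRA record needs a second locus")

    @property
    def span_length(self) -> int:
        if self.length is not None:
            return self.length
        return self.end - self.start + 1


@dataclass
class MergedSV:
    """A cluster of equivalent calls across samples."""

    chrom: str
    start: int            # medoid representative coordinates
    end: int
    svtype: str
    strands: str
    members: list[SVRecord]
    support: int = 0      # distinct samples

    def __post_init__(self) -> None:
        self.support = len({m.sample for m in self.members})

    @property
    def samples(self) -> set[str]:
        return {m.sample for m in self.members}

    @property
    def span_length(self) -> int:
        rep = next(m for m in self.members
                   if (m.start, m.end) == (self.start, self.end))
        return rep.span_length


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _linked(a: SVRecord, b: SVRecord, max_dist: int) -> bool:
    if a.svtype == "INS":
        return (abs(a.start - b.start) <= max_dist
                and abs(a.span_length - b.span_length) <= max_dist)
    if a.svtype == "TRA":
        return (a.chrom2 == b.chrom2
                and abs(a.start - b.start) <= max_dist
                and abs((a.pos2 or 0) - (b.pos2 or 0)) <= max_dist)
    return (abs(a.start - b.start) <= max_dist
            and abs(a.end - b.end) <= max_dist)


def _medoid(members: Sequence[SVRecord]) -> SVRecord:
    if len(members) == 1:
        return members[0]

    def total_dist(m: SVRecord) -> int:
        return sum(abs(m.start - o.start) + abs(m.end - o.end)
                   for o in members)

    return min(members, key=lambda m: (total_dist(m), m.start, m.end,
                                       m.sample))


def merge_svs(
    callsets: Mapping[str, Sequence[SVRecord]] | Sequence[Sequence[SVRecord]],
    max_dist: int = 1000,
    require_type: bool = True,
    require_strand: bool = True,
    min_len: int = 50,
) -> list[MergedSV]:
    """Merge per-sample SV call sets into a non-redundant catalogue.

    Records shorter than ``min_len`` are dropped first. The result is
    invariant to sample and record order.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if isinstance(callsets, Mapping):
        flat = [r for recs in callsets.values() for r in recs]
    else:
        flat = [r for recs in callsets for r in recs]
    flat = [r for r in flat if r.span_length >= min_len]
    # canonical order makes clustering independent of input order
    flat.sort(key=lambda r: (r.chrom, r.svtype, r.strands, r.start, r.end,
                             r.sample))
    buckets: dict[tuple, list[int]] = {}
    for i, r in enumerate(flat):
        key = (r.chrom,
               r.svtype if require_type else None,
               r.strands if require_strand else None)
        buckets.setdefault(key, []).append(i)
    uf = _UnionFind(len(flat))
    for idxs in buckets.values():
        # records are start-sorted within a bucket: sliding window suffices
        for ai in range(len(idxs)):
            a = flat[idxs[ai]]
            for bi in range(ai + 1, len(idxs)):
                b = flat[idxs[bi]]
                if b.start - a.start > max_dist:
                    break
                if require_type and a.svtype != b.svtype:
                    continue
                if require_strand and a.strands != b.strands:
                    continue
                same_semantics = a.svtype == b.svtype
                if same_semantics:
                    ok = _linked(a, b, max_dist)
                else:  # only reachable with require_type=False
                    ok = (abs(a.start - b.start) <= max_dist
                          and abs(a.end - b.end) <= max_dist)
                if ok:
                    uf.union(idxs[ai], idxs[bi])
    clusters: dict[int, list[SVRecord]] = {}
    for i, r in enumerate(flat):
        clusters.setdefault(uf.find(i), []).append(r)
    merged = []
    for members in clusters.values():
        rep = _medoid(members)
        merged.append(MergedSV(
            chrom=rep.chrom, start=rep.start, end=rep.end,
            svtype=rep.svtype, strands=rep.strands,
            members=sorted(members, key=lambda m: (m.sample, m.start))))
    merged.sort(key=lambda m: (m.chrom, m.start, m.end, m.svtype, m.strands))
    return merged


@dataclass
class SVSummary:
    per_type: dict[str, int]
    per_chrom: dict[str, int]
    total: int
    genes_overlapped: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": pd.Series(self.per_type)})


def summarize_svs(
    merged: Iterable[MergedSV],
    genes: Sequence[GeneModel] = (),
) -> SVSummary:
    """Per-type and per-chromosome totals plus unique gene overlap.

    A merged SV overlaps a gene when their closed spans intersect.
    """
    per_type: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    total = 0
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    hit: set[str] = set()
    for m in merged:
        total += 1
        per_type[m.svtype] = per_type.get(m.svtype, 0) + 1
        per_chrom[m.chrom] = per_chrom.get(m.chrom, 0) + 1
        for g in genes_by_chrom.get(m.chrom, ()):
            if m.start <= g.end and g.start <= m.end:
                hit.add(g.gene_id)
    return SVSummary(per_type, per_chrom, total, len(hit))


# ---------------------------------------------------------------------------
# VCF bridge
# ---------------------------------------------------------------------------

def sv_records_from_vcf(records: Sequence[VariantRecord],
                        sample: str) -> list[SVRecord]:
    """Convert SV-bearing variant records of one sample's VCF."""
    out = []
    for r in records:
        if r.svtype is None:
            continue
        out.append(SVRecord(
            sample=sample, chrom=r.chrom, start=r.pos,
            end=r.end if r.end is not None else r.pos,
            svtype=r.svtype, strands=r.strands or "+-",
            length=r.ins_len))
    return out


def merged_to_vcf_records(merged: Sequence[MergedSV]) -> list[VariantRecord]:
    out = []
    for i, m in enumerate(merged, 1):
        out.append(VariantRecord(
            chrom=m.chrom, pos=m.start, ref="N", alt=f"<{m.svtype}>",
            qual=None, id=f"MSV{i:06d}", svtype=m.svtype, end=m.end,
            strands=m.strands,
            ins_len=m.span_length if m.svtype == "INS" else None))
    return out
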