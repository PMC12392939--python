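"""KASP genotype-matrix scoring.

A KASP assay reports each cultivar's call at a biallelic SNP as allele A,
allele B, heterozygous (H), or no call (NA); allele letters are local to
each marker. A marker is polymorphic when at least one non-donor cultivar's
homozygous call differs from the donor's call (H and NA calls are excluded
from the comparison but reported). A cultivar carries the superior allele at
a marker only when homozygous for the allele linked to the superior
haplotype — heterozygous calls never count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

VALID_CALLS = {"A", "B", "H", "NA"}


@dataclass
class KaspMatrix:
    """Markers x cultivars call matrix plus per-marker metadata.

    ``calls`` holds values in {A, B, H, NA}; ``superior_allele`` gives the
    allele (A or B) linked to the superior haplotype per marker; ``donor``
    names the donor genotype column of ``calls``.
    """

    calls: pd.DataFrame
    superior_allele: pd.Series
    donor: str

    def __post_init__(self) -> None:
        if self.donor not in self.calls.columns:
            raise ValueError(f"donor {self.donor!r} not a matrix column")
        bad = set(self.calls.values.ravel().astype(str)) - VALID_CALLS
        if bad:
            raise ValueError(f"invalid KASP calls: {sorted(bad)}")
        missing = set(self.calls.index) - set(self.superior_allele.index)
        if missing:
            raise ValueError(
                f"markers without a superior-linked allele: {sorted(missing)}")
        bad_alleles = set(self.superior_allele.astype(str)) - {"A", "B"}
        if bad_alleles:
            raise ValueError(
                f"superior-linked allele must be A or B, got {sorted(bad_alleles)}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, donor: str) -> "KaspMatrix":
        """Build from a table with a ``superior_allele`` column plus one
        column per cultivar (the donor among them)."""
        if "superior_allele" not in frame.columns:
            raise ValueError("table needs a superior_allele column")
        calls = frame.drop(columns=["superior_allele"])
        return cls(calls=calls.astype(str),
                   superior_allele=frame["superior_allele"].astype(str),
                   donor=donor)

    @classmethod
    def from_csv(cls, path, donor: str) -> "KaspMatrix":
        frame = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        return cls.from_frame(frame, donor)


@dataclass
class KaspReport:
    """Per-marker polymorphism flags and per-cultivar superior-allele presence."""

    polymorphic: pd.Series          # marker -> bool
    uninformative: pd.Series        # marker -> bool (all calls NA)
    presence: pd.DataFrame          # markers x cultivars bool
    n_excluded_calls: pd.Series     # marker -> H/NA calls excluded from comparison

    @property
    def n_polymorphic(self) -> int:
        return int(self.polymorphic.sum())


def score_markers(matrix: KaspMatrix) -> KaspReport:
    """Score each marker for polymorphism and superior-allele presence.

    Polymorphic: >= 1 non-donor cultivar with a homozygous call (A or B)
    differing from the donor's homozygous call. Markers whose donor call is
    H or NA, or with all-NA calls, are flagged uninformative and scored
    non-polymorphic.
    """
    calls = matrix.calls.astype(str)
    non_donor = [c for c in calls.columns if c != matrix.donor]
    polymorphic = {}
    uninformative = {}
    excluded = {}
    presence = pd.DataFrame(False, index=calls.index, columns=calls.columns)
    for marker in calls.index:
        row = calls.loc[marker]
        donor_call = row[matrix.donor]
        excluded[marker] = int((row.isin(["H", "NA"])).sum())
        all_na = (row == "NA").all()
        uninformative[marker] = bool(all_na or donor_call not in ("A", "B"))
        if uninformative[marker]:
            polymorphic[marker] = False
        else:
            others = row[non_donor]
            informative = others[others.isin(["A", "B"])]
            polymorphic[marker] = bool((informative != donor_call).any())
        sup = matrix.superior_allele[marker]
        presence.loc[marker] = (row == sup)
    return KaspReport(
        polymorphic=pd.Series(polymorphic, name="polymorphic"),
        uninformative=pd.Series(uninformative, name="uninformative"),
        presence=presence,
        n_excluded_calls=pd.Series(excluded, name="n_excluded_calls"),
    )
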