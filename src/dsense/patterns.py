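"""ABBA/BABA site-pattern counting on ordered quartets.

A site is ABBA when P2 and P3 share an allele while P1 and P4 share a
different allele; BABA when P1 and P3 share an allele while P2 and P4 share
a different one.  Both definitions imply exactly two alleles at the site:
monomorphic, BBBA-like and three/four-allele sites count toward neither
pattern, and any site carrying a missing symbol (N or another ambiguity
code) in one of the four sequences is skipped.

In diploid mode two genome copies are carried per taxon; any site that is
heterozygous in one of the four analysed taxa is excluded before the
haploid rule is applied to the homozygous consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .seqsim import LocusAlignment

ScenarioTag = Literal["no_flow", "H3_to_H2", "H2_to_H3"]

#: Quartet orderings used for the three sampling situations of the study.
SCENARIO_QUARTETS: dict[str, tuple[str, str, str, str]] = {
    # no gene flow: H1, H2, H3a, H4
    "no_flow": ("H1", "H2", "H3a", "H4"),
    # gene flow from H3 to H2: the introgressed H2 sequence is H3f
    "H3_to_H2": ("H1", "H3f", "H3a", "H4"),
    # gene flow from H2 to H3: the introgressed H3 sequence is H2f
    "H2_to_H3": ("H1", "H2", "H2f", "H4"),
}


@dataclass(frozen=True)
class QuartetSpec:
    """Ordered (P1, P2, P3, P4) labels; P4 is the outgroup."""

    p1: str
    p2: str
    p3: str
    p4: str
    scenario: str = "custom"

    @property
    def labels(self) -> tuple[str, str, str, str]:
        return (self.p1, self.p2, self.p3, self.p4)

    @classmethod
    def for_scenario(cls, tag: ScenarioTag) -> "QuartetSpec":
        try:
            p1, p2, p3, p4 = SCENARIO_QUARTETS[tag]
        except KeyError:
            raise ValueError(f"unknown scenario tag {tag!r}") from None
        return cls(p1, p2, p3, p4, scenario=tag)


@dataclass(frozen=True)
class PatternCounts:
    n_abba: int
    n_baba: int
    n_informative: int
    n_excluded_het: int = 0

    def __post_init__(self) -> None:
        if min(self.n_abba, self.n_baba, self.n_informative,
               self.n_excluded_het) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def s(self) -> int:
        """Numerator S = nABBA - nBABA."""
        return self.n_abba - self.n_baba


def classify_sites(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                   d: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised site classification on four int8 code rows.

    Returns boolean masks (abba, baba, valid); codes < 0 mark missing data.
    """
    valid = (a >= 0) & (b >= 0) & (c >= 0) & (d >= 0)
    abba = valid & (b == c) & (a == d) & (a != b)
    baba = valid & (a == c) & (b == d) & (a != b)
    return abba, baba, valid


def count_patterns(aln: LocusAlignment, q: QuartetSpec) -> PatternCounts:
    """Count ABBA and BABA sites for quartet ``q`` in one locus."""
    try:
        rows = [aln.row(lab) for lab in q.labels]
    except ValueError as exc:
        raise KeyError(f"quartet label missing from alignment: {exc}") from exc
    abba, baba, valid = classify_sites(*rows)
    return PatternCounts(n_abba=int(abba.sum()), n_baba=int(baba.sum()),
                         n_informative=int(valid.sum()))


def count_patterns_diploid(copy_a: LocusAlignment, copy_b: LocusAlignment,
                           q: QuartetSpec) -> PatternCounts:
    """Diploid counting: drop sites heterozygous in any quartet taxon, then
    apply the haploid rule to the homozygous consensus."""
    if copy_a.length != copy_b.length:
        raise ValueError("genome copies have different lengths")
    rows_a = [copy_a.row(lab) for lab in q.labels]
    rows_b = [copy_b.row(lab) for lab in q.labels]
    het = np.zeros(copy_a.length, dtype=bool)
    valid = np.ones(copy_a.length, dtype=bool)
    for ra, rb in zip(rows_a, rows_b):
        het |= ra != rb
        valid &= (ra >= 0) & (rb >= 0)
    abba, baba, _ = classify_sites(*rows_a)
    keep = valid & ~het
    abba = abba & keep
    baba = baba & keep
    return PatternCounts(
        n_abba=int(abba.sum()),
        n_baba=int(baba.sum()),
        n_informative=int(keep.sum()),
        n_excluded_het=int((het & valid).sum()),
    )
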