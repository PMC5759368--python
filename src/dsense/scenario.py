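"""Demographic scenarios for the four-taxon gene-flow simulation study.

A :class:`Scenario` bundles the species-tree node times (``T2`` < ``T3`` <
``T4``), the gene-flow time ``Tgf``, and a constant effective population size
``Ne``, together with dataset-shape parameters (locus count and length,
ploidy).  All times and ``Ne`` are stored pre-scaled by the reciprocal of the
per-generation substitution rate, i.e. a branch of (stored) length ``k``
accumulates ``k`` expected substitutions per site.  This makes every
downstream quantity independent of the actual mutation rate; ``mu_inv_scale``
is carried only as a label for reporting in natural units.

The module also provides the closed-form predictors used throughout the
analysis: the expected D-statistic under a single pulse of gene flow, the
relative population size ``Ne / T3``, and the linear-slope predictors for the
f-statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

Direction = Literal["H3_to_H2", "H2_to_H3", "none"]
DiploidMode = Literal["same_loci", "random_loci", "n/a"]

#: Gene-flow fractions used in the coarse sensitivity scan.
BASIC_F_LIST: tuple[float, ...] = (
    0.0,
    0.001, 0.002, 0.003, 0.004, 0.005, 0.006, 0.007, 0.008, 0.009,
    0.01, 0.015, 0.02,
    0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09,
    0.1, 0.15, 0.2, 0.3, 0.4, 0.5,
)


@dataclass(frozen=True)
class GeneFlowSpec:
    """Fraction of the recipient genome descending from the donor.

    ``f`` may not exceed 0.5: beyond that the donor would contribute the
    majority of the recipient's genome and the species tree itself would
    have to be redrawn.
    """

    f: float
    direction: Direction = "H3_to_H2"

    def __post_init__(self) -> None:
        if not 0.0 <= self.f <= 0.5:
            raise ValueError(f"gene-flow fraction f={self.f} outside [0, 0.5]")
        if self.direction not in ("H3_to_H2", "H2_to_H3", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class Scenario:
    """One simulated dataset's demography and shape.

    Times are expected substitutions per site (generations x mu); ``Ne`` is
    likewise ``Ne x mu``.  ``0 < Tgf < T2 < T3 < T4`` must hold.
    """

    T3: float
    T2: float
    Tgf: float
    T4: float
    Ne: float
    n_loci: int = 50_000
    locus_length: int = 20_000
    direction: Direction = "none"
    ploidy: int = 1
    diploid_mode: DiploidMode = "n/a"
    mu_inv_scale: float = 1.0
    replicate_id: int = 0
    rng_seed: int | None = None
    scheme: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.Tgf < self.T2 < self.T3 < self.T4):
            raise ValueError(
                f"times must satisfy 0 < Tgf < T2 < T3 < T4, got "
                f"Tgf={self.Tgf}, T2={self.T2}, T3={self.T3}, T4={self.T4}"
            )
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be >= 1")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")

    @property
    def relative_population_size(self) -> float:
        return relative_population_size(self.Ne, self.T3)

    def expected_d(self, f: float, mu: float = 1e-8) -> float:
        """Expected D for this scenario at gene-flow fraction ``f``.

        ``mu`` converts the scaled parameters back to generations and
        individuals for the exact ``(1 - 1/2N)^t`` factors; the result is
        insensitive to ``mu`` throughout the realistic range.
        """
        return expected_d(
            f, Ne=self.Ne / mu, T3=self.T3 / mu, T2=self.T2 / mu, Tgf=self.Tgf / mu
        )

    def with_reduction(self, n_loci: int | None = None,
                       locus_length: int | None = None) -> "Scenario":
        """Return a copy with a reduced dataset shape (same demography)."""
        kw = {}
        if n_loci is not None:
            kw["n_loci"] = n_loci
        if locus_length is not None:
            kw["locus_length"] = locus_length
        return replace(self, **kw)


def relative_population_size(Ne: float, T3: float) -> float:
    """``Ne / T3``: population size over generations since the deepest
    ingroup split.  The study's primary predictor of D-statistic
    sensitivity (detection is reliable roughly when this is <= 0.5)."""
    if T3 <= 0:
        raise ValueError("T3 must be positive")
    return Ne / T3


def expected_d(f: float, Ne: float, T3: float, T2: float, Tgf: float) -> float:
    """Expected value of the D-statistic under one pulse of gene flow.

    ``E(D) = 3f(T3-Tgf) / [3f(T3-Tgf) + 4N(1-f)(1-1/2N)^(T3-T2)
    + 4Nf(1-1/2N)^(T3-Tgf)]`` with all times in generations and ``Ne`` in
    individuals.  Zero exactly when ``f = 0`` or ``Tgf = T3``.
    """
    if not 0.0 <= f <= 0.5:
        raise ValueError("f must be in [0, 0.5]")
    if not (Tgf <= T2 <= T3):
        raise ValueError("need Tgf <= T2 <= T3")
    if Ne < 1:
        raise ValueError("Ne must be >= 1 individual")
    num = 3.0 * f * (T3 - Tgf)
    if num == 0.0:
        return 0.0
    retain = 1.0 - 1.0 / (2.0 * Ne)
    den = (
        num
        + 4.0 * Ne * (1.0 - f) * retain ** (T3 - T2)
        + 4.0 * Ne * f * retain ** (T3 - Tgf)
    )
    return num / den


def predicted_fg_slope(Tgf: float, T3: float) -> float:
    """Predicted slope of f_G on true f: ``1 - Tgf/T3``."""
    return 1.0 - Tgf / T3


def predicted_fhom_slope(Tgf: float, T3: float, Ne: float,
                         direction: Direction = "H3_to_H2",
                         T2: float | None = None) -> float:
    """Predicted slope of f_hom on true f.

    H3->H2 flow: ``(1 - Tgf/T3) / (1 + Ne/T3)``.  H2->H3 flow:
    ``(T2/T3 - Tgf/T3) / (1 + Ne/T3)`` (always the smaller of the two, since
    ``T2 < T3``), requiring ``T2``.
    """
    denom = 1.0 + Ne / T3
    if direction == "H3_to_H2":
        return (1.0 - Tgf / T3) / denom
    if direction == "H2_to_H3":
        if T2 is None:
            raise ValueError("T2 is required for the H2->H3 slope")
        return (T2 / T3 - Tgf / T3) / denom
    raise ValueError(f"unknown direction {direction!r}")


# --------------------------------------------------------------------------
# Scheme grids
# --------------------------------------------------------------------------

_NE_FACTORS = (0.2, 0.5, 1.0, 2.0, 5.0)
# Scheme 4 ties (Tgf/T2, T2/T3) into fixed pairs rather than a cross product.
_SCHEME4_TIME_PAIRS = ((0.25, 0.1), (0.5, 0.5), (0.75, 0.9))


def _make(T3: float, tgf_over_t2: float, t2_over_t3: float, t4_over_t3: float,
          ne_factor: float, n_loci: int, locus_length: int, scheme: int,
          replicate_id: int, **kw) -> Scenario:
    T2 = t2_over_t3 * T3
    return Scenario(
        T3=T3,
        T2=T2,
        Tgf=tgf_over_t2 * T2,
        T4=t4_over_t3 * T3,
        Ne=ne_factor * T3,
        n_loci=n_loci,
        locus_length=locus_length,
        scheme=scheme,
        replicate_id=replicate_id,
        **kw,
    )


def expand_scheme(scheme_id: int, n_replicates: int | None = None,
                  replicate_overrides: dict[int, int] | None = None) -> list[Scenario]:
    """Expand one of the four study parameter grids into Scenario objects.

    Scheme 1 varies branch lengths and population size (135 combinations x 3
    replicates = 405 datasets); Scheme 2 the outgroup distance (150); Scheme 3
    the number/size of loci at a constant 1 Gb (180); Scheme 4 repeats a
    Scheme-1 subset with diploid sampling (54).  ``replicate_overrides`` maps
    a combination index to a larger replicate count (used when a replicate
    has to be discarded and re-simulated).
    """
    reps = 3 if n_replicates is None else n_replicates
    combos: list[dict] = []
    if scheme_id == 1:
        for T3, r_gf, r_2, ne in itertools.product(
            (0.001, 0.01, 0.1), (0.25, 0.5, 0.75), (0.1, 0.5, 0.9), _NE_FACTORS
        ):
            combos.append(dict(T3=T3, tgf_over_t2=r_gf, t2_over_t3=r_2,
                               t4_over_t3=2.0, ne_factor=ne,
                               n_loci=50_000, locus_length=20_000))
    elif scheme_id == 2:
        for T3, r_4, ne in itertools.product(
            (0.001, 0.01), (1.5, 2.0, 5.0, 10.0, 20.0), _NE_FACTORS
        ):
            combos.append(dict(T3=T3, tgf_over_t2=0.5, t2_over_t3=0.5,
                               t4_over_t3=r_4, ne_factor=ne,
                               n_loci=50_000, locus_length=20_000))
    elif scheme_id == 3:
        # constant 1 Gb total: locus length = 1e9 / n_loci
        for T3, n_loci, ne in itertools.product(
            (0.001, 0.01),
            (2_000, 5_000, 10_000, 20_000, 50_000, 100_000),
            _NE_FACTORS,
        ):
            combos.append(dict(T3=T3, tgf_over_t2=0.5, t2_over_t3=0.5,
                               t4_over_t3=2.0, ne_factor=ne,
                               n_loci=n_loci, locus_length=int(1e9) // n_loci))
    elif scheme_id == 4:
        for T3, (r_gf, r_2), ne in itertools.product(
            (0.001, 0.01), _SCHEME4_TIME_PAIRS, (0.2, 1.0, 5.0)
        ):
            combos.append(dict(T3=T3, tgf_over_t2=r_gf, t2_over_t3=r_2,
                               t4_over_t3=2.0, ne_factor=ne,
                               n_loci=50_000, locus_length=20_000,
                               ploidy=2, diploid_mode="same_loci"))
    else:
        raise ValueError(f"unknown scheme_id {scheme_id!r}")

    out: list[Scenario] = []
    for i, combo in enumerate(combos):
        n_rep = reps
        if replicate_overrides and i in replicate_overrides:
            n_rep = replicate_overrides[i]
        for r in range(n_rep):
            out.append(_make(scheme=scheme_id, replicate_id=r, **combo))
    return out


def n_distinct_species_trees(scheme_id: int) -> int:
    """Number of distinct species-tree shapes (time combinations) in a
    scheme, before expansion over population sizes and replicates."""
    scns = expand_scheme(scheme_id, n_replicates=1)
    return len({(s.T3, s.T2, s.Tgf, s.T4) for s in scns})


def scenarios_to_manifest(scenarios: list[Scenario]) -> pd.DataFrame:
    """One row per dataset: scheme, all parameters, seed."""
    rows = []
    for s in scenarios:
        rows.append({
            "scheme": s.scheme, "T3": s.T3, "T2": s.T2, "Tgf": s.Tgf,
            "T4": s.T4, "Ne": s.Ne, "rel_pop_size": s.relative_population_size,
            "n_loci": s.n_loci, "locus_length": s.locus_length,
            "ploidy": s.ploidy, "diploid_mode": s.diploid_mode,
            "direction": s.direction, "replicate_id": s.replicate_id,
            "rng_seed": s.rng_seed,
        })
    return pd.DataFrame(rows)


def manifest_to_scenarios(df: pd.DataFrame) -> list[Scenario]:
    out = []
    for _, row in df.iterrows():
        seed = row.get("rng_seed")
        out.append(Scenario(
            T3=float(row["T3"]), T2=float(row["T2"]), Tgf=float(row["Tgf"]),
            T4=float(row["T4"]), Ne=float(row["Ne"]),
            n_loci=int(row["n_loci"]), locus_length=int(row["locus_length"]),
            ploidy=int(row.get("ploidy", 1)),
            diploid_mode=row.get("diploid_mode", "n/a"),
            direction=row.get("direction", "none"),
            replicate_id=int(row.get("replicate_id", 0)),
            rng_seed=None if seed is None or pd.isna(seed) else int(seed),
            scheme=None if pd.isna(row.get("scheme")) else int(row["scheme"]),
        ))
    return out
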