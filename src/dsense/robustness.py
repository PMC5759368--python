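"""Linearity and bootstrap robustness of the f-statistics.

f_G and f_hom are expected to grow linearly with the true gene-flow
fraction f; the regression slope over the basic f list estimates f_hat/f
and is compared with the closed-form predictors (``1 - Tgf/T3`` for f_G,
``(1 - Tgf/T3)/(1 + Ne/T3)`` for f_hom under H3->H2 flow, and
``(T2/T3 - Tgf/T3)/(1 + Ne/T3)`` under H2->H3 flow).

Robustness against locus sampling is probed by bootstrap: replicates draw
``n_draw`` loci without replacement from a pooled set of replicate datasets,
re-run the introgression test and attach the confidence interval
``statistic +/- 2 x jackknife SD``.  Replicate sets with different (or
equal) true f are then compared pairwise, a comparison being *significant*
when the confidence intervals do not overlap; f_G replicates whose
jackknife variance came out negative (possible because its denominator is a
difference of counts) have missing CIs and are excluded from significance
proportions.

f_G under H2->H3 flow is deliberately not computed: with the recipient
sampled twice one would need to model whether the introgressed haplotype is
fixed in the recipient population, which is outside this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .power import _MixingPools, n_introgressed_loci
from .scenario import BASIC_F_LIST
from .stats import block_sums, weighted_block_jackknife


class UnsupportedCombination(ValueError):
    """Raised for statistic/direction pairs the model cannot support."""


def _check_kind_direction(kind: str, direction: str) -> None:
    if kind not in ("G", "hom"):
        raise ValueError("kind must be 'G' or 'hom'")
    if kind == "G" and direction == "H2_to_H3":
        raise UnsupportedCombination(
            "f_G under H2->H3 gene flow requires modelling fixation of the "
            "introgressed haplotype in the recipient; not supported")


@dataclass
class FRegression:
    kind: str
    direction: str
    slope: float
    intercept: float
    r: float
    points: pd.DataFrame = field(repr=False)


def _fstat_for_mask(pools: _MixingPools, mask: np.ndarray, kind: str,
                    block_size_loci: int):
    num = np.where(mask[:, None], pools.numf, pools.num0)
    s = num[:, 0] - num[:, 1]
    if kind == "G":
        den = pools.fg_den
    else:
        den = np.where(mask, pools.hdenf, pools.hden0)
    return weighted_block_jackknife(block_sums(s, block_size_loci),
                                    block_sums(den, block_size_loci))


def regress_fstat(table: pd.DataFrame, kind: str, direction: str,
                  rng: np.random.Generator, f_list=BASIC_F_LIST,
                  n_reps: int = 3, block_size_loci: int = 250) -> FRegression:
    """OLS of the f-statistic on true f across the basic f list.

    Each f is tested ``n_reps`` times with fresh mixtures; undefined
    statistic values (zero denominators) are dropped pairwise.
    """
    _check_kind_direction(kind, direction)
    pools = _MixingPools(table, direction)
    rows = []
    for f in f_list:
        k = n_introgressed_loci(f, pools.n_loci)
        for rep in range(n_reps):
            mask = np.zeros(pools.n_loci, dtype=bool)
            if k:
                mask[rng.choice(pools.n_loci, size=k, replace=False)] = True
            res = _fstat_for_mask(pools, mask, kind, block_size_loci)
            rows.append({"f": f, "rep": rep, "value": res.value})
    pts = pd.DataFrame(rows).dropna(subset=["value"])
    if len(pts) < 3:
        raise ValueError("too few defined f-statistic values to regress")
    fit = sps.linregress(pts["f"], pts["value"])
    return FRegression(kind=kind, direction=direction, slope=float(fit.slope),
                       intercept=float(fit.intercept),
                       r=float(fit.rvalue), points=pts)


def bootstrap_fstats(pool_table: pd.DataFrame, f: float, kind: str,
                     direction: str, rng: np.random.Generator,
                     n_rep: int = 500, n_draw: int | None = None,
                     block_size_loci: int = 250) -> pd.DataFrame:
    """Bootstrap replicate f-statistics from a pooled locus table.

    ``pool_table`` is typically the concatenation of the replicate datasets
    of one parameter combination; each of the ``n_rep`` replicates draws
    ``n_draw`` loci without replacement (default: a third of the pool,
    matching three pooled replicates), assigns ``f * n_draw`` of them to
    gene flow, and records the statistic with its ``+/- 2 SD`` confidence
    interval (NaN bounds when the jackknife variance is negative).
    """
    _check_kind_direction(kind, direction)
    pools = _MixingPools(pool_table, direction)
    n_pool = pools.n_loci
    if n_draw is None:
        n_draw = n_pool // 3
    if not 0 < n_draw <= n_pool:
        raise ValueError("n_draw outside (0, pool size]")
    k = n_introgressed_loci(f, n_draw)
    rows = []
    for rep in range(n_rep):
        draw = rng.choice(n_pool, size=n_draw, replace=False)
        mask = np.zeros(n_pool, dtype=bool)
        if k:
            mask[draw[rng.choice(n_draw, size=k, replace=False)]] = True
        sub = np.zeros(n_pool, dtype=bool)
        sub[draw] = True
        res = _fstat_for_mask_subset(pools, sub, mask, kind, block_size_loci)
        sd = res.se if res.valid else np.nan
        rows.append({"f": f, "rep": rep, "value": res.value, "sd": sd,
                     "lo": res.value - 2 * sd, "hi": res.value + 2 * sd,
                     "valid": res.valid})
    return pd.DataFrame(rows)


def _fstat_for_mask_subset(pools: _MixingPools, subset: np.ndarray,
                           mask: np.ndarray, kind: str,
                           block_size_loci: int):
    idx = np.nonzero(subset)[0]
    num = np.where(mask[idx, None], pools.numf[idx], pools.num0[idx])
    s = num[:, 0] - num[:, 1]
    if kind == "G":
        den = pools.fg_den[idx]
    else:
        den = np.where(mask[idx], pools.hdenf[idx], pools.hden0[idx])
    return weighted_block_jackknife(block_sums(s, block_size_loci),
                                    block_sums(den, block_size_loci))


@dataclass(frozen=True)
class PairwiseCell:
    f_i: float
    f_j: float
    prop_numerically_smaller: float
    prop_significantly_smaller: float
    prop_not_significantly_different: float
    n_pairs: int
    n_pairs_with_ci: int


def pairwise_compare(rep_i: pd.DataFrame, rep_j: pd.DataFrame) -> PairwiseCell:
    """All-pairs comparison of two bootstrap replicate sets.

    Proportions over the ``n_i x n_j`` ordered pairs: value(i) numerically
    smaller than value(j); CI(i) entirely below CI(j) (significantly
    smaller); and CIs overlapping (not significantly different, the
    diagonal diagnostic).  Pairs with a missing CI on either side are
    excluded from the significance proportions.
    """
    vi = rep_i["value"].to_numpy(float)
    vj = rep_j["value"].to_numpy(float)
    if vi.size == 0 or vj.size == 0:
        raise ValueError("empty replicate set")
    num_smaller = (vi[:, None] < vj[None, :]).mean()
    ok = (rep_i["valid"].to_numpy(bool)[:, None]
          & rep_j["valid"].to_numpy(bool)[None, :])
    hi_i = rep_i["hi"].to_numpy(float)[:, None]
    lo_i = rep_i["lo"].to_numpy(float)[:, None]
    hi_j = rep_j["hi"].to_numpy(float)[None, :]
    lo_j = rep_j["lo"].to_numpy(float)[None, :]
    n_ci = int(ok.sum())
    if n_ci:
        sig_smaller = float((ok & (hi_i < lo_j)).sum() / n_ci)
        not_diff = float((ok & ~((hi_i < lo_j) | (hi_j < lo_i))).sum() / n_ci)
    else:
        sig_smaller = np.nan
        not_diff = np.nan
    return PairwiseCell(
        f_i=float(rep_i["f"].iloc[0]), f_j=float(rep_j["f"].iloc[0]),
        prop_numerically_smaller=float(num_smaller),
        prop_significantly_smaller=sig_smaller,
        prop_not_significantly_different=not_diff,
        n_pairs=int(vi.size * vj.size), n_pairs_with_ci=n_ci)


def pairwise_grid(replicates: dict[float, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise-comparison proportions for every ordered (f_i <= f_j)."""
    fs = sorted(replicates)
    rows = []
    for i, fi in enumerate(fs):
        for fj in fs[i:]:
            cell = pairwise_compare(replicates[fi], replicates[fj])
            rows.append(cell.__dict__)
    return pd.DataFrame(rows)
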