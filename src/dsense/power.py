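"""Introgression tests and the two-stage MF80 sensitivity analysis.

An *introgression test* mixes, at gene-flow fraction ``f``, the introgressed
and non-introgressed per-locus counts of one simulated dataset:
``round(f * n_loci)`` loci are drawn without replacement to carry the
donor haplotype, the D- and f-statistics are computed on the mixture, and
significance is judged by the weighted block-jackknife Z (one-sided
``Z > 3``; the simulated direction predicts an ABBA excess).

Sensitivity is summarised by MF80, the minimal fraction of gene flow that
yields a significant D-statistic with >= 80% probability:

1. a coarse scan over the basic f list finds ``f0`` (smallest f significant
   in all 3 of 3 tests) and the bracket ``[f_min, f_max]``;
2. a fine scan tests every 0.001 step in the bracket many times and fits a
   binomial logistic regression of significance on f; MF80 solves the
   fitted probability = 0.8, i.e. ``(ln 4 - b0) / b1``.

If even ``f = 0.5`` is predicted below 80%, MF80 is recorded as 0.501 ("not
usable on this dataset") rather than as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scenario import BASIC_F_LIST, Scenario
from .stats import (JackknifeResult, block_sums, significance,
                    weighted_block_jackknife)

LN4 = math.log(4.0)
MF80_INSENSITIVE = 0.501


@dataclass(frozen=True)
class IntrogressionResult:
    f: float
    direction: str
    n_introgressed: int
    d: JackknifeResult
    fg: JackknifeResult | None
    fhom: JackknifeResult | None


@dataclass
class CoarseScanResult:
    f0: float | None
    f_min: float | None
    f_max: float | None
    outcomes: dict[float, list[bool]]


@dataclass
class PowerResult:
    direction: str
    f0: float | None
    f_min: float | None
    f_max: float | None
    mf80: float
    beta0: float | None = None
    beta1: float | None = None
    null_z: float | None = None
    fine_table: pd.DataFrame | None = field(default=None, repr=False)


def n_introgressed_loci(f: float, n_loci: int) -> int:
    """round(f * n_loci), ties to even (f is validated to [0, 0.5])."""
    if not 0.0 <= f <= 0.5:
        raise ValueError(f"f={f} outside [0, 0.5]")
    return round(f * n_loci)


def safe_jackknife(num: np.ndarray, den: np.ndarray,
                   block_size_loci: int) -> JackknifeResult:
    """Block jackknife that degrades to an undefined (invalid) result when
    the data are too sparse to form two non-empty blocks."""
    try:
        return weighted_block_jackknife(block_sums(num, block_size_loci),
                                        block_sums(den, block_size_loci))
    except ValueError:
        return JackknifeResult(math.nan, math.nan, math.nan, 0, valid=False)


class _MixingPools:
    """Per-locus count arrays of one dataset, arranged for fast mixing.

    For the requested direction: ``num0``/``numf`` are (nABBA, nBABA) of the
    no-flow and introgressed numerator quartets; ``hden0``/``hdenf`` the
    f_hom denominator ABBA counts; ``fg_den`` the f_G denominator S (only
    for H3->H2, where the donor-side samples are unaffected by mixing).
    """

    def __init__(self, table: pd.DataFrame, direction: str):
        if direction not in ("H3_to_H2", "H2_to_H3", "none"):
            raise ValueError(f"unknown direction {direction!r}")
        self.diploid = "abba_n32_yy" in table.columns
        self.direction = direction
        c = lambda name: table[name].to_numpy(dtype=float)
        self.n_loci = len(table)
        self.num0 = np.stack([c("abba_n0"), c("baba_n0")], axis=1)
        if direction == "none":
            self.numf = self.num0
        elif direction == "H3_to_H2":
            self.numf = np.stack([c("abba_n32"), c("baba_n32")], axis=1)
        else:
            self.numf = np.stack([c("abba_n23"), c("baba_n23")], axis=1)
        if not self.diploid:
            self.fg_den = c("abba_dg") - c("baba_dg")
            self.hden0 = c("abba_dh0")
            self.hdenf = (c("abba_dh23") if direction == "H2_to_H3"
                          else self.hden0)
        else:
            self.fg_den = None
            self.hden0 = None
            self.hdenf = None


def _mixed_stats(pools: _MixingPools, mask: np.ndarray,
                 block_size_loci: int) -> tuple[JackknifeResult,
                                                JackknifeResult | None,
                                                JackknifeResult | None]:
    m = mask[:, None]
    num = np.where(m, pools.numf, pools.num0)
    s = num[:, 0] - num[:, 1]
    tot = num[:, 0] + num[:, 1]
    d_res = safe_jackknife(s, tot, block_size_loci)
    fg_res = None
    fhom_res = None
    if pools.fg_den is not None and pools.direction != "H2_to_H3":
        fg_res = safe_jackknife(s, pools.fg_den, block_size_loci)
    if pools.hden0 is not None:
        hden = np.where(mask, pools.hdenf, pools.hden0)
        fhom_res = safe_jackknife(s, hden, block_size_loci)
    return d_res, fg_res, fhom_res


def _draw_mask(pools: _MixingPools, f: float,
               rng: np.random.Generator) -> tuple[np.ndarray, int]:
    k = n_introgressed_loci(f, pools.n_loci)
    mask = np.zeros(pools.n_loci, dtype=bool)
    if k:
        mask[rng.choice(pools.n_loci, size=k, replace=False)] = True
    return mask, k


def introgression_test(table: pd.DataFrame, f: float, direction: str,
                       rng: np.random.Generator,
                       block_size_loci: int = 250,
                       diploid_mode: str = "same_loci") -> IntrogressionResult:
    """Run one introgression test at fraction ``f`` on a pattern table.

    ``table`` is the per-locus pattern table of one simulated dataset (see
    the pipeline module); the introgressed and non-introgressed counts are
    two readings of the same loci, so mixing selects columns per locus.
    Diploid tables (Scheme 4) support ``diploid_mode`` "same_loci" (both
    genome copies share the introgressed set) or "random_loci" (independent
    sets); only the D-statistic is computed for diploid data.
    """
    if "abba_n32_yy" in table.columns:
        return _introgression_test_diploid(table, f, direction, rng,
                                           block_size_loci, diploid_mode)
    pools = _MixingPools(table, direction)
    mask, k = _draw_mask(pools, f, rng)
    d_res, fg_res, fhom_res = _mixed_stats(pools, mask, block_size_loci)
    return IntrogressionResult(f=f, direction=direction, n_introgressed=k,
                               d=d_res, fg=fg_res, fhom=fhom_res)


def _introgression_test_diploid(table: pd.DataFrame, f: float, direction: str,
                                rng: np.random.Generator,
                                block_size_loci: int,
                                diploid_mode: str) -> IntrogressionResult:
    if diploid_mode not in ("same_loci", "random_loci"):
        raise ValueError(f"unknown diploid_mode {diploid_mode!r}")
    n = len(table)
    k = n_introgressed_loci(f, n)
    mask1 = np.zeros(n, dtype=bool)
    if k:
        mask1[rng.choice(n, size=k, replace=False)] = True
    if diploid_mode == "same_loci":
        mask2 = mask1
    else:
        mask2 = np.zeros(n, dtype=bool)
        if k:
            mask2[rng.choice(n, size=k, replace=False)] = True
    qt = "n32" if direction == "H3_to_H2" else "n23"
    if direction == "none":
        abba = table["abba_n0"].to_numpy(float)
        baba = table["baba_n0"].to_numpy(float)
    else:
        variants = {
            (False, False): "n0",
            (True, True): f"{qt}_yy",
            (True, False): f"{qt}_yn",
            (False, True): f"{qt}_ny",
        }
        abba = np.empty(n)
        baba = np.empty(n)
        for (c1, c2), name in variants.items():
            sel = (mask1 == c1) & (mask2 == c2)
            abba[sel] = table[f"abba_{name}"].to_numpy(float)[sel]
            baba[sel] = table[f"baba_{name}"].to_numpy(float)[sel]
    d_res = safe_jackknife(abba - baba, abba + baba, block_size_loci)
    return IntrogressionResult(f=f, direction=direction, n_introgressed=k,
                               d=d_res, fg=None, fhom=None)


def d_significance_scan(table: pd.DataFrame, direction: str,
                        f_values, n_reps: int, rng: np.random.Generator,
                        block_size_loci: int = 250, threshold: float = 3.0,
                        diploid_mode: str = "same_loci") -> pd.DataFrame:
    """Repeated introgression tests; returns one row per (f, replicate)
    with the D jackknife Z and its one-sided significance call."""
    diploid = "abba_n32_yy" in table.columns
    pools = None if diploid else _MixingPools(table, direction)
    rows = []
    for f in f_values:
        for rep in range(n_reps):
            if diploid:
                res = _introgression_test_diploid(
                    table, f, direction, rng, block_size_loci, diploid_mode)
                d_res = res.d
            else:
                mask, _ = _draw_mask(pools, f, rng)
                m = mask[:, None]
                num = np.where(m, pools.numf, pools.num0)
                s = num[:, 0] - num[:, 1]
                tot = num[:, 0] + num[:, 1]
                d_res = safe_jackknife(s, tot, block_size_loci)
            rows.append({"f": f, "rep": rep, "z": d_res.z,
                         "significant": significance(d_res.z, threshold)})
    return pd.DataFrame(rows)


def coarse_scan(table: pd.DataFrame, direction: str,
                rng: np.random.Generator, n_reps: int = 3,
                block_size_loci: int = 250, threshold: float = 3.0,
                f_list=BASIC_F_LIST,
                diploid_mode: str = "same_loci") -> CoarseScanResult:
    """First-stage scan over the basic f list.

    ``f0`` is the smallest f significant in all ``n_reps`` tests; ``f_min``
    sits two places before ``f0`` in the list (0.001 when f0 is 0.001 or
    0.002) and ``f_max`` immediately after (0.5 stays 0.5).  When no f
    qualifies the dataset is insensitive and MF80 becomes 0.501 downstream.
    """
    f_list = list(f_list)
    nonzero = [f for f in f_list if f > 0]
    scan = d_significance_scan(table, direction, nonzero, n_reps, rng,
                               block_size_loci, threshold, diploid_mode)
    outcomes = {f: list(scan.loc[scan["f"] == f, "significant"])
                for f in nonzero}
    f0 = next((f for f in nonzero if all(outcomes[f])), None)
    if f0 is None:
        return CoarseScanResult(None, None, None, outcomes)
    f_min, f_max = basic_f_bracket(f0, f_list)
    return CoarseScanResult(f0, f_min, f_max, outcomes)


def basic_f_bracket(f0: float, f_list=BASIC_F_LIST) -> tuple[float, float]:
    """(f_min, f_max) around ``f0`` on the basic f list: two places before
    and one after, clamped to the nonzero ends (f0 of 0.001 or 0.002 gives
    f_min 0.001; f0 of 0.5 gives f_max 0.5)."""
    f_list = list(f_list)
    i0 = f_list.index(f0)
    lo = max(i0 - 2, 1 if f_list[0] == 0.0 else 0)
    hi = min(i0 + 1, len(f_list) - 1)
    return f_list[lo], f_list[hi]


def mf80_from_outcomes(f_values, successes, n_reps) -> tuple[float,
                                                             float | None,
                                                             float | None]:
    """Fit significance ~ f by binomial logistic regression and solve the
    80% crossing; returns (mf80, beta0, beta1).

    Boundary rules: saturated data (all significant) report the scan floor;
    a fit whose predicted probability at f = 0.5 stays below 80% reports
    0.501.  Perfect separation falls back to the empirical smallest f with
    >= 80% success.
    """
    f = np.asarray(f_values, dtype=float)
    succ = np.asarray(successes, dtype=float)
    n = np.broadcast_to(np.asarray(n_reps, dtype=float), succ.shape)
    floor = float(f.min())
    if (succ == n).all():
        return floor, None, None
    if (succ == 0).all():
        return MF80_INSENSITIVE, None, None
    try:
        import warnings
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is handled explicitly via the boundary rules below
            warnings.simplefilter("ignore")
            model = sm.GLM(np.column_stack([succ, n - succ]),
                           sm.add_constant(f), family=sm.families.Binomial())
            fit = model.fit(maxiter=200)
        b0, b1 = float(fit.params[0]), float(fit.params[1])
        if not (np.isfinite(b0) and np.isfinite(b1)) or abs(b1) > 1e8:
            raise ValueError("degenerate fit")
    except Exception:
        rate = succ / n
        hit = np.nonzero(rate >= 0.8)[0]
        if hit.size == 0:
            return MF80_INSENSITIVE, None, None
        return float(f[hit[0]]), None, None
    if b1 <= 0:
        p_half = 1.0 / (1.0 + math.exp(-(b0 + 0.5 * b1)))
        return (floor if p_half >= 0.8 else MF80_INSENSITIVE), b0, b1
    mf80 = (LN4 - b0) / b1
    if mf80 > 0.5:
        return MF80_INSENSITIVE, b0, b1
    return max(mf80, floor), b0, b1


def fine_scan_mf80(table: pd.DataFrame, direction: str, f_min: float,
                   f_max: float, rng: np.random.Generator,
                   n_reps: int = 500, step: float = 0.001,
                   block_size_loci: int = 250, threshold: float = 3.0,
                   diploid_mode: str = "same_loci"
                   ) -> tuple[float, float | None, float | None, pd.DataFrame]:
    """Second-stage scan: every ``step`` between ``f_min`` and ``f_max`` is
    tested ``n_reps`` times; returns (mf80, beta0, beta1, scan table)."""
    if f_min > f_max:
        raise ValueError("f_min must be <= f_max")
    lo, hi = round(f_min * 1000), round(f_max * 1000)
    stp = max(round(step * 1000), 1)
    grid = [m / 1000 for m in range(lo, hi + 1, stp)]
    scan = d_significance_scan(table, direction, grid, n_reps, rng,
                               block_size_loci, threshold, diploid_mode)
    agg = scan.groupby("f", sort=True)["significant"].sum()
    mf80, b0, b1 = mf80_from_outcomes(agg.index.to_numpy(),
                                      agg.to_numpy(), n_reps)
    out = agg.reset_index().rename(columns={"significant": "n_significant"})
    out["n_reps"] = n_reps
    return mf80, b0, b1, out


def compute_mf80(table: pd.DataFrame, direction: str,
                 rng: np.random.Generator, coarse_reps: int = 3,
                 fine_reps: int = 500, block_size_loci: int = 250,
                 threshold: float = 3.0,
                 diploid_mode: str = "same_loci") -> PowerResult:
    """Full two-stage sensitivity analysis of one dataset and direction."""
    null = d_significance_scan(table, direction, [0.0], 1, rng,
                               block_size_loci, threshold, diploid_mode)
    null_z = float(null["z"].iloc[0])
    cs = coarse_scan(table, direction, rng, coarse_reps, block_size_loci,
                     threshold, diploid_mode=diploid_mode)
    if cs.f0 is None:
        return PowerResult(direction, None, None, None, MF80_INSENSITIVE,
                           null_z=null_z)
    mf80, b0, b1, fine = fine_scan_mf80(
        table, direction, cs.f_min, cs.f_max, rng, fine_reps,
        block_size_loci=block_size_loci, threshold=threshold,
        diploid_mode=diploid_mode)
    return PowerResult(direction, cs.f0, cs.f_min, cs.f_max, mf80,
                       beta0=b0, beta1=b1, null_z=null_z, fine_table=fine)


def null_z_sample(scn: Scenario, n_datasets: int, master_seed: int,
                  block_size_loci: int = 250, model=None) -> np.ndarray:
    """Jackknife Z of D at f = 0 across independent simulated datasets.

    Used for specificity (false-positive) calibration: under the null the
    fraction with |Z| > 1.96 should sit near 5% and |Z| > 3 should be rare.
    Dataset ``i`` uses the seed stream ``(master_seed, i)``.
    """
    from .pipeline import simulate_pattern_table

    zs = np.empty(n_datasets)
    for i in range(n_datasets):
        seed_rng = np.random.default_rng(
            np.random.SeedSequence((master_seed, i)))
        sim_seed = int(seed_rng.integers(2 ** 31))
        table = simulate_pattern_table(scn, seed=sim_seed, model=model)
        res = introgression_test(table, 0.0, "none", seed_rng,
                                 block_size_loci=block_size_loci)
        zs[i] = res.d.z
    return zs


def run_scheme_grid(scenarios: list[Scenario], master_seed: int,
                    directions=("H3_to_H2", "H2_to_H3"),
                    coarse_reps: int = 3, fine_reps: int = 500,
                    block_size_loci: int = 250, model=None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every scenario and measure MF80 for each direction.

    Returns the per-dataset result table and a Pearson-correlation report
    of MF80 (plain and log10) against the demographic predictors.
    """
    from scipy.stats import pearsonr

    from .pipeline import simulate_pattern_table

    rows = []
    for i, scn in enumerate(scenarios):
        seed_rng = np.random.default_rng(
            np.random.SeedSequence((master_seed, i)))
        sim_seed = int(seed_rng.integers(2 ** 31))
        table = simulate_pattern_table(scn, seed=sim_seed, model=model)
        for direction in directions:
            res = compute_mf80(table, direction, seed_rng, coarse_reps,
                               fine_reps, block_size_loci,
                               diploid_mode=scn.diploid_mode
                               if scn.diploid_mode != "n/a" else "same_loci")
            rows.append({
                "scenario": i, "T3": scn.T3, "T2": scn.T2, "Tgf": scn.Tgf,
                "T4": scn.T4, "Ne": scn.Ne,
                "rel_pop_size": scn.relative_population_size,
                "tgf_over_t3": scn.Tgf / scn.T3,
                "tgf_over_t2": scn.Tgf / scn.T2,
                "t2_over_t3": scn.T2 / scn.T3,
                "n_loci": scn.n_loci, "locus_length": scn.locus_length,
                "replicate_id": scn.replicate_id, "direction": direction,
                "f0": res.f0, "mf80": res.mf80, "null_z": res.null_z,
            })
    df = pd.DataFrame(rows)
    preds = ["T3", "Ne", "rel_pop_size", "tgf_over_t3", "tgf_over_t2",
             "t2_over_t3"]
    corr_rows = []
    for direction in directions:
        sub = df[df["direction"] == direction]
        for pred in preds:
            x, y = sub[pred].to_numpy(), sub["mf80"].to_numpy()
            if np.unique(x).size < 2:
                continue
            r, p = pearsonr(x, y)
            rlog, plog = pearsonr(np.log10(x), np.log10(y))
            corr_rows.append({"direction": direction, "predictor": pred,
                              "r": r, "p": p, "r_loglog": rlog,
                              "p_loglog": plog})
    return df, pd.DataFrame(corr_rows)
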