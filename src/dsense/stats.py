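"""D- and f-statistics with weighted block-jackknife significance.

``D = (N_ABBA - N_BABA) / (N_ABBA + N_BABA)``; the numerator summed over a
set of loci is written ``S``.  The introgression-fraction estimators are
ratio statistics ``f_G = S(H1,H2,H3,H4) / S(H1,H3a,H3b,H4)`` and
``f_hom = S(H1,H2,H3,H4) / S(H1,H3,H3,H4)`` (the latter denominator equals
an ABBA count, hence is never negative; the f_G denominator is a difference
of counts and can be zero or negative).

Standard errors come from a delete-one-block weighted jackknife over
consecutive locus blocks (250 loci = 5 Mb at the study's 20-kb loci), using
the delete-m estimator of Busing, Meijer & van der Leeden (1999) with each
block weighted by its share of the statistic's denominator.  Because f_G
block weights can be negative, its jackknife variance can come out
negative; such results are flagged invalid rather than silently clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class JackknifeResult:
    """A ratio statistic with its jackknife standard error.

    ``value`` is computed from the full data; ``se`` and ``z = value/se``
    from the delete-one-block jackknife.  ``valid`` is False when the
    jackknife variance is negative (possible for f_G) or undefined; ``z``
    is NaN when the SE is zero or invalid.
    """

    value: float
    se: float
    z: float
    n_blocks: int
    valid: bool = True


def d_statistic(n_abba: float, n_baba: float) -> float:
    """D from pooled counts; NaN (undefined) when both counts are zero."""
    tot = n_abba + n_baba
    if tot == 0:
        return math.nan
    return (n_abba - n_baba) / tot


def f_hat(numerator_counts: np.ndarray, denominator_counts: np.ndarray,
          kind: str = "G") -> float:
    """Ratio of summed numerator S over summed denominator S across loci.

    Each input is an (n_loci, 2) array of (nABBA, nBABA) per locus; for
    ``kind='hom'`` the denominator BABA column must be zero (H3 cannot
    differ from itself).  Returns NaN when the pooled denominator is zero.
    """
    if kind not in ("G", "hom"):
        raise ValueError("kind must be 'G' or 'hom'")
    num = np.asarray(numerator_counts, dtype=float)
    den = np.asarray(denominator_counts, dtype=float)
    if kind == "hom" and den[:, 1].any():
        raise ValueError("f_hom denominator has nonzero BABA counts")
    s_num = num[:, 0].sum() - num[:, 1].sum()
    s_den = den[:, 0].sum() - den[:, 1].sum()
    if s_den == 0:
        return math.nan
    return float(s_num / s_den)


def block_sums(per_locus: np.ndarray, block_size_loci: int = 250) -> np.ndarray:
    """Sum a per-locus quantity into consecutive blocks; a trailing partial
    block is kept (it simply carries a proportionally smaller weight)."""
    x = np.asarray(per_locus, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no loci")
    n_blocks = -(-n // block_size_loci)
    idx = np.arange(n) // block_size_loci
    return np.bincount(idx, weights=x, minlength=n_blocks)


def weighted_block_jackknife(num_blocks: np.ndarray,
                             den_blocks: np.ndarray) -> JackknifeResult:
    """Delete-one-block weighted jackknife for the ratio sum(num)/sum(den).

    Block j's weight is its denominator sum ``m_j``; with ``n = sum(m_j)``
    and ``h_j = n / m_j`` the variance is

        var = (1/G) * sum_j (h_j*t - (h_j-1)*t_j - t_dot)^2 / (h_j - 1)

    where ``t`` is the full estimate, ``t_j`` the leave-block-out estimate
    and ``t_dot = G*t - sum_j (1 - m_j/n) * t_j``.  Blocks with zero weight
    carry no information about the ratio and are dropped.
    """
    num = np.asarray(num_blocks, dtype=float)
    den = np.asarray(den_blocks, dtype=float)
    if num.shape != den.shape:
        raise ValueError("numerator/denominator block shapes differ")
    keep = den != 0.0
    num, den = num[keep], den[keep]
    g = len(num)
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks")
    n_tot = den.sum()
    s_tot = num.sum()
    if n_tot == 0:
        return JackknifeResult(math.nan, math.nan, math.nan, g, valid=False)
    theta = s_tot / n_tot
    theta_j = (s_tot - num) / (n_tot - den)
    h = n_tot / den
    theta_dot = g * theta - ((1.0 - den / n_tot) * theta_j).sum()
    pseudo = h * theta - (h - 1.0) * theta_j
    var = ((pseudo - theta_dot) ** 2 / (h - 1.0)).sum() / g
    if not np.isfinite(var) or var < 0.0:
        return JackknifeResult(float(theta), math.nan, math.nan, g, valid=False)
    se = math.sqrt(var)
    z = theta / se if se > 0.0 else math.nan
    return JackknifeResult(float(theta), se, z, g, valid=True)


def block_jackknife(per_locus_num: np.ndarray, per_locus_den: np.ndarray,
                    block_size_loci: int = 250) -> JackknifeResult:
    """Partition per-locus numerator/denominator into consecutive blocks and
    run the weighted delete-one-block jackknife.

    For D pass ``num = nABBA - nBABA`` and ``den = nABBA + nBABA`` per locus;
    for the f-statistics pass the numerator S and the denominator S.
    """
    nb = block_sums(per_locus_num, block_size_loci)
    db = block_sums(per_locus_den, block_size_loci)
    return weighted_block_jackknife(nb, db)


def significance(z: float, threshold: float = 3.0,
                 two_sided: bool = False) -> bool:
    """Strict-threshold significance call.

    Sensitivity scans use the signed one-sided rule ``z > threshold`` (the
    simulated gene-flow direction predicts an ABBA excess); null-calibration
    audits use ``|z| > threshold``.  NaN (undefined) is never significant.
    """
    if math.isnan(z):
        return False
    return abs(z) > threshold if two_sided else z > threshold
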