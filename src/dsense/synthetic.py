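"""Deterministic miniature generators for validation and testing.

These are small, seed-deterministic constructions with hand-computable
expectations: quartet alignments specified column by column, Bernoulli
outcomes from a known logistic curve (ground truth for the MF80 fit), and
an independent discrete-generation Wright-Fisher sampler for three-taxon
gene-tree topology frequencies (closed form: discordance ``(2/3) e^-t``
with ``t`` in coalescent units of ``2N`` generations).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .seqsim import LocusAlignment, _CODE

QUARTET_LABELS = ("P1", "P2", "P3", "P4")


def toy_quartet_alignment(columns: list[str],
                          labels: tuple[str, ...] = QUARTET_LABELS
                          ) -> LocusAlignment:
    """Build an alignment from per-site columns.

    Each column string gives the symbols of P1..P4 at one site, e.g.
    ``["ACCA", "CACA", "AAAA", "ACGT"]`` has one ABBA site, one BABA site,
    one monomorphic and one four-allele site.  Symbols must be in
    {A, C, G, T, N}; N marks missing data.
    """
    n = len(labels)
    for col in columns:
        if len(col) != n:
            raise ValueError(f"column {col!r} does not have {n} symbols")
        if any(ch not in "ACGTN" for ch in col.upper()):
            raise ValueError(f"bad symbol in column {col!r}")
    mat = np.full((n, len(columns)), -1, dtype=np.int8)
    for j, col in enumerate(columns):
        mat[:, j] = _CODE[np.frombuffer(col.upper().encode(), dtype=np.uint8)]
    return LocusAlignment(labels=tuple(labels), matrix=mat)


def logistic_bernoulli(beta0: float, beta1: float, f_grid, n_rep: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Binomial outcomes with success probability logistic(b0 + b1 * f).

    The analytic 80% crossing is ``(ln 4 - beta0) / beta1``; used as a
    parameter-recovery ground truth for the MF80 logistic fit.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    f = np.asarray(f_grid, dtype=float)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * f)))
    succ = rng.binomial(n_rep, p)
    return pd.DataFrame({"f": f, "n_significant": succ, "n_reps": n_rep})


def brute_force_coalescent(t: float, n_trees: int, rng: np.random.Generator,
                           n_pop: int = 10_000) -> dict[str, float]:
    """Three-taxon topology frequencies from a discrete Wright-Fisher model.

    Lineages A and B share an ancestral population for ``t`` coalescent
    units (``t * N`` generations, pair-coalescence probability ``1/N`` per
    generation, ``N`` gene copies) before C joins; afterwards all pairs are
    exchangeable.  Returns the frequency of each first-coalescing pair; the
    discordant classes AC and BC each approach ``(1/3) e^-t``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    gens = rng.geometric(1.0 / n_pop, size=n_trees)
    concordant_early = gens <= t * n_pop
    n_late = int(n_trees - concordant_early.sum())
    # panmictic phase: the first coalescence picks a uniform pair
    pick = rng.integers(0, 3, size=n_late)
    counts = {"AB": int(concordant_early.sum()) + int((pick == 0).sum()),
              "AC": int((pick == 1).sum()),
              "BC": int((pick == 2).sum())}
    return {k: v / n_trees for k, v in counts.items()}
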