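"""Dataset-level simulation: scenario -> per-locus pattern table.

For each locus a gene tree is drawn under the structured coalescent, a
sequence alignment is evolved on it, and ABBA/BABA counts are taken for
every quartet the downstream statistics need.  Because the same gene tree
carries the ordinary and the introgressed lineages, the table holds, per
locus, the counts for the no-flow quartet, both introgressed-numerator
quartets, and the f-statistic denominator quartets; the introgression test
then mixes loci by selecting columns, without re-simulating anything.

Per-locus RNG streams are derived deterministically from ``(seed, locus
index)``, so any locus can be reproduced in isolation and results do not
depend on evaluation order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coalsim import GeneTree, simulate_gene_tree
from .scenario import Scenario
from .seqsim import LocusAlignment, SubstitutionModel, simulate_states

# haploid leaf indices (order of coalsim.LEAF_LABELS)
_H1, _H2, _H2F, _H3A, _H3B, _H3F, _H4 = range(7)

#: column -> quartet (P1, P2, P3, P4) of leaf indices, haploid mode.
HAPLOID_QUARTETS: dict[str, tuple[int, int, int, int]] = {
    "n0": (_H1, _H2, _H3A, _H4),      # no-flow D/f numerator
    "n32": (_H1, _H3F, _H3A, _H4),    # H3->H2 introgressed numerator
    "n23": (_H1, _H2, _H2F, _H4),     # H2->H3 introgressed numerator
    "dg": (_H1, _H3A, _H3B, _H4),     # f_G denominator
    "dh0": (_H1, _H3A, _H3A, _H4),    # f_hom denominator, recipient native
    "dh23": (_H1, _H2F, _H2F, _H4),   # f_hom denominator, H3 introgressed
}

HAPLOID_COLUMNS: tuple[str, ...] = (
    "abba_n0", "baba_n0", "abba_n32", "baba_n32", "abba_n23", "baba_n23",
    "abba_dg", "baba_dg", "abba_dh0", "abba_dh23", "n_sites",
)

# diploid leaf indices follow coalsim.diploid_leaf_labels() order
_D = {lab: 2 * i for i, lab in
      enumerate(("H1", "H2", "H2f", "H3a", "H3b", "H3f", "H4"))}


def _dip(lab: str) -> tuple[int, int]:
    return (_D[lab], _D[lab] + 1)


# copy combinations for the recipient taxon: which of its two genome copies
# carry the introgressed haplotype (y) versus the native one (n)
def _combos(native: str, donor: str) -> dict[str, tuple[int, int]]:
    na, nb = _dip(native)
    da, db = _dip(donor)
    return {"yy": (da, db), "yn": (da, nb), "ny": (na, db)}


#: column -> quartet of (copyA idx, copyB idx) taxa, diploid mode.
DIPLOID_QUARTETS: dict[str, tuple[tuple[int, int], ...]] = {}


def _build_diploid_quartets() -> None:
    h1, h4 = _dip("H1"), _dip("H4")
    DIPLOID_QUARTETS["n0"] = (h1, _dip("H2"), _dip("H3a"), h4)
    for cc, x in _combos("H2", "H3f").items():
        DIPLOID_QUARTETS[f"n32_{cc}"] = (h1, x, _dip("H3a"), h4)
    for cc, x in _combos("H3a", "H2f").items():
        DIPLOID_QUARTETS[f"n23_{cc}"] = (h1, _dip("H2"), x, h4)
        DIPLOID_QUARTETS[f"dh23_{cc}"] = (h1, x, x, h4)
    DIPLOID_QUARTETS["dg"] = (h1, _dip("H3a"), _dip("H3b"), h4)
    DIPLOID_QUARTETS["dh0"] = (h1, _dip("H3a"), _dip("H3a"), h4)


_build_diploid_quartets()

def _diploid_columns() -> tuple[str, ...]:
    cols: list[str] = []
    for q in DIPLOID_QUARTETS:
        cols.append(f"abba_{q}")
        if not q.startswith("dh"):
            cols.append(f"baba_{q}")
    cols.append("n_sites")
    return tuple(cols)


DIPLOID_COLUMNS: tuple[str, ...] = _diploid_columns()


def _haploid_locus_counts(st: np.ndarray, out: np.ndarray) -> None:
    """Fill one row of quartet counts from the (7, L) leaf-state matrix."""
    eq: dict[tuple[int, int], np.ndarray] = {}

    def e(i: int, j: int) -> np.ndarray:
        key = (i, j) if i <= j else (j, i)
        m = eq.get(key)
        if m is None:
            m = st[key[0]] == st[key[1]]
            eq[key] = m
        return m

    k = 0
    for a, b, c, d in HAPLOID_QUARTETS.values():
        ab = e(a, b)
        out[k] = np.count_nonzero(e(b, c) & e(a, d) & ~ab)  # ABBA
        k += 1
        if not (b == c):  # BABA is identically zero when P2 is P3
            out[k] = np.count_nonzero(e(a, c) & e(b, d) & ~ab)
            k += 1
    out[k] = st.shape[1]


def _diploid_locus_counts(st: np.ndarray, out: np.ndarray) -> None:
    """Fill one row of quartet counts from the (14, L) leaf-state matrix,
    excluding sites heterozygous in any quartet taxon."""
    het: dict[tuple[int, int], np.ndarray] = {}

    def h(pair: tuple[int, int]) -> np.ndarray:
        m = het.get(pair)
        if m is None:
            m = st[pair[0]] != st[pair[1]]
            het[pair] = m
        return m

    k = 0
    for name, taxa in DIPLOID_QUARTETS.items():
        hom = ~(h(taxa[0]) | h(taxa[1]) | h(taxa[2]) | h(taxa[3]))
        a, b, c, d = (st[t[0]] for t in taxa)
        ab = a != b
        out[k] = np.count_nonzero((b == c) & (a == d) & ab & hom)
        k += 1
        if not name.startswith("dh"):
            out[k] = np.count_nonzero((a == c) & (b == d) & ab & hom)
            k += 1
    out[k] = st.shape[1]


def locus_rng(seed: int, locus: int) -> np.random.Generator:
    """Deterministic per-locus generator derived from (seed, locus)."""
    return np.random.default_rng(np.random.SeedSequence((seed, locus)))


def simulate_pattern_table(scn: Scenario, seed: int | None = None,
                           model: SubstitutionModel | None = None,
                           return_trees: bool = False,
                           return_alignments: bool = False):
    """Simulate all loci of a dataset and return the pattern-count table.

    The DataFrame has one row per locus with ABBA/BABA counts for every
    quartet needed downstream (see ``HAPLOID_QUARTETS`` /
    ``DIPLOID_QUARTETS``).  With ``return_trees`` / ``return_alignments``
    the per-locus gene trees and alignments are also returned (memory grows
    accordingly; counts are sufficient for all statistics).
    """
    if seed is None:
        seed = scn.rng_seed
    if seed is None:
        raise ValueError("a seed is required (argument or Scenario.rng_seed)")
    if model is None:
        model = SubstitutionModel()
    diploid = scn.ploidy == 2
    columns = DIPLOID_COLUMNS if diploid else HAPLOID_COLUMNS
    counts = np.zeros((scn.n_loci, len(columns)), dtype=np.int64)
    fill = _diploid_locus_counts if diploid else _haploid_locus_counts
    trees: list[GeneTree] = []
    alns: list[LocusAlignment] = []
    for locus in range(scn.n_loci):
        rng = locus_rng(seed, locus)
        tree = simulate_gene_tree(scn, rng)
        states = simulate_states(tree, model, scn.locus_length, rng)
        fill(states, counts[locus])
        if return_trees:
            trees.append(tree)
        if return_alignments:
            alns.append(LocusAlignment(labels=tuple(tree.labels),
                                       matrix=states))
    table = pd.DataFrame(counts, columns=list(columns))
    table.insert(0, "locus", np.arange(scn.n_loci))
    if return_trees or return_alignments:
        return table, trees, alns
    return table


def write_pattern_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pattern_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
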