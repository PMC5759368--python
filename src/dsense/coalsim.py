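"""Structured-coalescent gene-tree simulation on the fixed species tree.

The species tree has four extant populations (H1, H2, H3, H4) plus two
introgressed lineages: H2f splits from H2 at ``Tgf`` and H3f splits from H3
at ``Tgf``; H1 and H2 join at ``T2``, their ancestor joins H3 at ``T3``, and
the ingroup joins the outgroup H4 at ``T4``.  One lineage is sampled from
each tip population (two in diploid mode; H3a and H3b are two samples of the
same H3 population).  Within every population interval the coalescent runs
at rate ``C(k,2) / Ne`` per generation with a constant ``Ne`` counted in
gene copies (the haploid convention of coalescent gene-tree simulators: one
coalescent time unit is ``Ne`` generations, the reciprocal of the relative
population size ``Ne/T``).  Between the present and ``Tgf`` each
introgressed lineage is carried in its own population, so with a single
sample it cannot coalesce with anything before entering the donor
population.

Times are handled in the same mutation-scaled units as :class:`Scenario`
(generations x mu), so node-depth differences are directly branch lengths in
expected substitutions per site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import dendropy

from .scenario import Scenario

#: Tip populations in canonical order (haploid sampling).
LEAF_LABELS: tuple[str, ...] = ("H1", "H2", "H2f", "H3a", "H3b", "H3f", "H4")

# population ids
_H1, _H2, _H2F, _H3, _H3F, _H4 = range(6)
_LEAF_POPS = {"H1": _H1, "H2": _H2, "H2f": _H2F,
              "H3a": _H3, "H3b": _H3, "H3f": _H3F, "H4": _H4}


def diploid_leaf_labels() -> tuple[str, ...]:
    return tuple(f"{lab}_{c}" for lab in LEAF_LABELS for c in (1, 2))


@dataclass
class GeneTree:
    """Rooted binary genealogy of the sampled lineages.

    ``times[i]`` is the coalescence time of node ``i`` (0 for leaves) in
    mutation-scaled generations; ``parent[i]`` indexes the parent node (-1
    for the root).  Leaves occupy indices ``0 .. n_leaves-1`` in the order
    of ``labels``; internal nodes are appended in increasing time order, so
    ``parent[i] > i`` for every non-root node.
    """

    labels: tuple[str, ...]
    times: np.ndarray
    parent: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_length(self, i: int) -> float:
        """Branch above node ``i`` in expected substitutions per site."""
        p = self.parent[i]
        if p < 0:
            return 0.0
        return float(self.times[p] - self.times[i])

    def leaf_index(self, label: str) -> int:
        return self.labels.index(label)

    def mrca_time(self, label_a: str, label_b: str) -> float:
        """Time of the most recent common ancestor of two leaves."""
        anc_a = set()
        i = self.leaf_index(label_a)
        while i >= 0:
            anc_a.add(i)
            i = self.parent[i]
        j = self.leaf_index(label_b)
        while j not in anc_a:
            j = self.parent[j]
        return float(self.times[j])

    def triplet_topology(self, a: str, b: str, c: str) -> tuple[str, str]:
        """The pair among three leaves with the most recent common ancestor."""
        pairs = [(a, b), (a, c), (b, c)]
        times = [self.mrca_time(x, y) for x, y in pairs]
        return pairs[int(np.argmin(times))]

    def to_newick(self) -> str:
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(self.n_nodes - 1):
            children[self.parent[i]].append(i)

        def fmt(i: int) -> str:
            if i < self.n_leaves:
                body = self.labels[i]
            else:
                body = "(" + ",".join(fmt(c) for c in children[i]) + ")"
            return f"{body}:{self.branch_length(i):.10g}"

        inner = ",".join(fmt(c) for c in children[self.root])
        return f"({inner}):0;"


def species_tree_epochs(scn: Scenario) -> list[tuple[float, float, dict[int, int]]]:
    """Population intervals of the species tree as (start, end, merge-map).

    The merge map is applied when entering the epoch: population ``a`` is
    absorbed into population ``b``.
    """
    inf = math.inf
    return [
        (0.0, scn.Tgf, {}),
        (scn.Tgf, scn.T2, {_H2F: _H2, _H3F: _H3}),
        (scn.T2, scn.T3, {_H2: _H1}),
        (scn.T3, scn.T4, {_H3: _H1}),
        (scn.T4, inf, {_H4: _H1}),
    ]


def simulate_gene_tree(scn: Scenario, rng: np.random.Generator) -> GeneTree:
    """Draw one gene tree under the structured coalescent for ``scn``.

    Continuous exponential waiting times approximate the per-generation
    Wright-Fisher pair-coalescence probability ``1/Ne`` (``Ne`` in gene
    copies); above ``T4`` the remaining lineages coalesce with no upper
    time bound.
    """
    if scn.ploidy == 1:
        labels = LEAF_LABELS
        pops = [_LEAF_POPS[lab] for lab in labels]
    else:
        labels = diploid_leaf_labels()
        pops = [_LEAF_POPS[lab.rsplit("_", 1)[0]] for lab in labels]

    n_leaves = len(labels)
    times = [0.0] * n_leaves
    parent = [-1] * n_leaves
    # active lineages: node index -> population
    node_of: list[int] = list(range(n_leaves))
    pop_of: list[int] = list(pops)
    coal_n = scn.Ne  # gene copies: pair-coalescence rate 1/Ne per generation

    for start, end, merges in species_tree_epochs(scn):
        if merges:
            pop_of = [merges.get(p, p) for p in pop_of]
        t = start
        while len(node_of) > 1:
            # per-population pair counts
            counts: dict[int, int] = {}
            for p in pop_of:
                counts[p] = counts.get(p, 0) + 1
            pair_rates = {p: k * (k - 1) / 2.0 / coal_n
                          for p, k in counts.items() if k >= 2}
            total = sum(pair_rates.values())
            if total == 0.0:
                break
            t_next = t + rng.exponential(1.0 / total)
            if t_next >= end:
                break
            t = t_next
            # choose population proportional to its pair rate
            u = rng.random() * total
            acc = 0.0
            for p, r in pair_rates.items():
                acc += r
                if u < acc:
                    pop = p
                    break
            members = [i for i, q in enumerate(pop_of) if q == pop]
            a, b = rng.choice(len(members), size=2, replace=False)
            ia, ib = members[a], members[b]
            new = len(times)
            times.append(t)
            parent.append(-1)
            parent[node_of[ia]] = new
            parent[node_of[ib]] = new
            # replace the two lineages by their ancestor
            for idx in sorted((ia, ib), reverse=True):
                del node_of[idx]
                del pop_of[idx]
            node_of.append(new)
            pop_of.append(pop)
        if len(node_of) == 1:
            break

    return GeneTree(labels=labels,
                    times=np.asarray(times, dtype=float),
                    parent=np.asarray(parent, dtype=np.int64))


def write_gene_trees(trees: list[GeneTree], path) -> None:
    """Write one Newick string per line (branch lengths in subs/site)."""
    with open(path, "w") as fh:
        for tr in trees:
            fh.write(tr.to_newick() + "\n")


def read_gene_trees(path) -> list[dendropy.Tree]:
    """Read a one-tree-per-line Newick file into dendropy trees."""
    out: list[dendropy.Tree] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            out.append(dendropy.Tree.get(data=line, schema="newick"))
    return out
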