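# dsense

Simulation-based sensitivity and robustness analysis of the ABBA-BABA
**D-statistic** and the **f̂G / f̂hom** introgression-fraction estimators.

## The problem

Given four taxa with the known phylogeny (((H1,H2),H3),H4), gene flow
between the non-sister ingroups H2 and H3 leaves an excess of one of the two
species-tree-discordant site patterns:

    D(H1,H2,H3,H4) = (N_ABBA − N_BABA) / (N_ABBA + N_BABA)

Incomplete lineage sorting produces ABBA and BABA sites at equal rates, so
`E[D] = 0` without gene flow; a jackknife Z-score above 3 flags
introgression.  The companion estimators of the gene-flow fraction *f* are

    f̂G   = S(H1,H2,H3a,H4) / S(H1,H3a,H3b,H4)
    f̂hom = S(H1,H2,H3,H4)  / S(H1,H3,H3,H4),       S = N_ABBA − N_BABA

But when is the test actually *sensitive*?  `dsense` answers this by
simulation: gene trees under a structured coalescent on a species tree with
explicit introgressed lineages (H3f, H2f branching at time `Tgf`), HKY+Γ
sequence evolution on each gene tree, per-locus ABBA/BABA counting, weighted
block-jackknife significance, and a two-stage power analysis that reports
**MF80** — the minimal fraction of gene flow detected with ≥ 80% probability
(0.501 encodes "undetectable even at f = 0.5").  The headline result the
package reproduces at desk scale: sensitivity is governed primarily by the
**relative population size** `Ne/T3`, and gene flow H3→H2 is never harder to
detect than H2→H3.

All inputs are generated internally from a `Scenario` (times `Tgf < T2 <
T3 < T4` in expected substitutions per site, `Ne` in gene copies, locus
count/length, ploidy); user-supplied quartet alignments in FASTA can be fed
to the counting/statistics layers directly.

## Worked example

```python
import numpy as np
from dsense import (Scenario, simulate_pattern_table, introgression_test,
                    compute_mf80)

# small population (Ne/T3 = 0.2), gene flow at Tgf = 0.25 T3,
# reduced scale: 2,000 unlinked loci of 1 kb
scn = Scenario(T3=0.01, T2=0.005, Tgf=0.0025, T4=0.02, Ne=0.002,
               n_loci=2000, locus_length=1000)
table = simulate_pattern_table(scn, seed=1)

rng = np.random.default_rng(2)
for f in (0.0, 0.02, 0.1):
    r = introgression_test(table, f, "H3_to_H2", rng, block_size_loci=50)
    print(f"f={f:<5} D={r.d.value:+.4f}  Z={r.d.z:+.2f}  "
          f"fG={r.fg.value:+.4f}  fhom={r.fhom.value:+.4f}")

res = compute_mf80(table, "H3_to_H2", rng, fine_reps=100, block_size_loci=50)
print(f"f0={res.f0}  bracket=[{res.f_min}, {res.f_max}]  MF80={res.mf80:.4f}")
```

which prints

```
f=0.0   D=+0.0505  Z=+1.37  fG=+0.0034  fhom=+0.0029
f=0.02  D=+0.2348  Z=+5.60  fG=+0.0197  fhom=+0.0164
f=0.1   D=+0.5485  Z=+21.46  fG=+0.0770  fhom=+0.0644
f0=0.01  bracket=[0.008, 0.015]  MF80=0.0080
```

Read: with no gene flow D is insignificant (Z = 1.37); 2% gene flow is
already strongly significant; the fitted detection threshold is MF80 ≈
0.008, i.e. this favourable demography (relative population size 0.2)
detects sub-percent gene flow even at 2 Mb of data.  The f̂ values track
`f` linearly with slopes near the closed forms `1 − Tgf/T3 = 0.75` and
`(1 − Tgf/T3)/(1 + Ne/T3)` — here visibly scaled down by the reduced
information content at f below the percent level.

A command-line layer mirrors the library (`dsense scheme-expand`,
`simulate`, `dstat`, `power`, `robustness`, `run --config cfg.yaml`); all
tables are TSV, trees Newick, alignments FASTA.

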