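# cognatebias

Amino-acid biosynthesis under sudden starvation, and the genomic trait
that defuses its catch-22.

When an amino acid disappears from the environment, the bacterial
stringent response upregulates the corresponding biosynthetic pathway —
but translating those very enzymes may require the amino acid that is
now missing. Whether a cell recovers or collapses turns out to depend on
the **cognate bias** `n − m`: the number of cognate residues in the
pathway's critical enzyme (`n`) relative to the proteome-average count
per protein (`m`). This package implements, for modelers and
comparative genomicists:

* a kinetic model of **translation attenuation**: a protein with `n`
  limiting residues is produced at rate `v = kin·M·(S/(S+Km))^n`, making
  translation ultrasensitive to the free amino-acid pool `S`;
* the **normalized three-variable model** of biosynthesis and
  regulation (mRNA `x1`, critical enzyme `x2`, free cognate amino acid
  `x3`, with `h(x3) = (1+k23)·x3/(x3+k23)`):

  ```
  dx1/dτ = A·[ (1+k13)/(σ+k13) · (σ·x3^g13 + k13)/(x3^g13 + k13) − x1 ]
  dx2/dτ = x1·h^n − x2·h^m
  dx3/dτ = B·[ C·x2 + (1−C)·x7 − h^m ]
  ```

  with stiff starvation simulations (`x7: 1 → 0` at `τ = 0`), fate
  classification and response half-times;
* the **steady-state / bifurcation analysis** of the starved system:
  positive steady states solve
  `C·(1+k13)/(σ+k13)·(σ·x3^g13+k13)/(x3^g13+k13) = (1+k23)^(2m−n)·(x3/(x3+k23))^(2m−n)`,
  giving *safe* (`n ≤ 2m`), *bistable* (`2m < n < m_c`) and *fatal*
  (`n > m_c`) regimes, the saddle-node threshold `m_c`, and the
  normalized growth rate `μ/μM = [x3/(x3+k23)]^m` at each stable state;
* the **proteome-mining pipeline**: cognate bias `n − m`, critical bias
  `n − 2m` and composition bias (count − 5% of length) per organism and
  amino acid from FASTA proteomes plus a final-enzyme annotation table,
  exact one-sided sign tests of zero median bias, and single-linkage
  Euclidean clustering of bias profiles with Newick export;
* a **synthetic-cohort generator** with injectable, recoverable bias
  shifts, so the whole pipeline is testable without any database
  download.

## Worked example

```python
from cognatebias import DEFAULT_PARAMS, find_steady_states, simulate_starvation

p = DEFAULT_PARAMS          # A=100, B=1e6, C=0.01, g13=2, σ=1e-4,
                            # k13=0.001, k23=0.1, m=16

for n in (22, 33, 42):
    rep = find_steady_states(p.with_n(n))
    print(n, rep.regime, [(round(r.x3, 3), r.stability) for r in rep.roots])

res = simulate_starvation(p.with_n(12))
print(res.fate, round(res.final_x3, 3), round(res.tau_half, 2))
```

prints

```
22 safe [(0.0, 'unstable'), (0.277, 'stable')]
33 bistable [(0.0, 'stable'), (0.013, 'unstable'), (0.047, 'stable')]
42 fatal [(0.0, 'stable')]
recovered 0.381 4.65
```

At `n = 22` (cognate bias +6, critical bias −10) starvation always ends
at the single stable pool of 0.277: safe. At `n = 33` (critical bias
+1) recovery at 0.047 coexists with stable extinction: the outcome
depends on initial conditions. At `n = 42` only extinction remains. A
low-bias system (`n = 12`) recovers to a free pool of 0.381 with a
half-time of ~4.6 dilution times.

The same analyses are available from the shell:

```sh
cognatebias steady-states --n-list 22,29,31,32,33,35,42 --out roots.csv
cognatebias critical-n                       # prints m_c ≈ 33.144
cognatebias synth --seed 9 --n-organisms 50 --delta W:-3 --out cohort/
cognatebias bias --manifest cohort/manifest.tsv \
    --annotations cohort/annotations.tsv --out bias.csv
cognatebias sign-test --bias bias.csv --measure cognate --direction low
cognatebias cluster --bias bias.csv --out tree.nwk
```

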