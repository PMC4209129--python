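# Methods

## The model

Translation of one codon under amino-acid limitation is treated as an
enzymatic branch point: the ribosome–mRNA–peptide complex binds the
cognate aa-tRNA (`k1`), which may leave (`k2`) or be incorporated
irreversibly (`k3`); a stalled complex aborts at rate `k4`. At steady
state the flux through the step is attenuated by `S/(S + Km)` with
`Km = (k4/k3)(k2 + k3)/k1`. Because the steps of a message form a chain
in which non-limiting positions pass flux unchanged, a protein with `n`
limiting residues is produced at `kin·M·(S/(S+Km))^n`. `chain_oracle`
re-derives this without the closed form, solving the 2×2 linear balance
of every branch point explicitly; the two routes agree to 1e-10 relative
over randomized chains and the flux is invariant under permutation of
the limiting positions. With `n ≈ 15` for an average 300-residue
protein at 5% composition, translation is ultrasensitive: around `Km`, a
4-fold change in supply moves the rate by more than three decades.

The biosynthesis model couples three normalized concentrations: mRNA of
the pathway's critical enzyme (`x1`, transcribed under Hill-type
feedback repression by the free cognate amino acid, degraded first
order), the critical enzyme itself (`x2`, translated with attenuation
exponent `n`, diluted by growth), and the free cognate amino acid
(`x3`, supplied by biosynthesis — fraction `C` initially — and import
`x7`, consumed by bulk protein synthesis with average cognate count
`m`). Each gain and loss term is normalized to 1 at the pre-starvation
state `x1 = x2 = x3 = x7 = 1`, which is therefore an exact equilibrium
for every parameter set — the basis of a well-controlled comparison
across parameter values.

Dimensionless constants (reference values in parentheses): `A` (100),
mRNA turnover relative to dilution; `B` (1e6), maximum amino-acid
demand relative to the free pool; `C` (0.01), autosynthesized fraction
of the initial supply, i.e. a heavily repressed pathway; `g13` (2) and
`σ` (1e-4), Hill coefficient and floor of transcriptional repression;
`k13` (0.001) and `k23` (0.1), transcriptional and translational
thresholds relative to the initial pool; `m` (16), cognate residues per
average protein; `n`, cognate residues in the critical enzyme. `m` and
`n` are accepted as positive reals (`m` is a proteome average) and all
powers are computed as real exponentials.

## Starvation dynamics

Complete starvation is an instantaneous step of `x7` from 1 to 0 at
`τ = 0` — no smoothing. The system is stiff (exponents up to ~50, rate
ratios spanning eight decades), so trajectories are integrated with the
implicit BDF method at `rtol = 1e-8`, `atol = 1e-12`, with the analytic
Jacobian supplied and tiny negative overshoot clipped inside the Hill
terms before they are evaluated.

Steadiness is declared when the *normalized* residuals — the bracketed
balances of the three equations, not the raw derivatives, which carry
the prefactors `A` and `B` — stay below 1e-9 across a trailing window
of output points. The default horizon is `τ_end = 2e6`: near the
high-bias steady states the slow mode relaxes at a rate of order
`h(x3)^m ≈ 3e-5`, so the `n = 32` endpoint needs `τ ≈ 1.3e6` to settle
to solver precision. Early termination keeps the full seven-point bias
sweep under two seconds.

Fate is classified as **failed** when `x3` crosses 1e-6 while
decreasing, or when the horizon is reached with `x3` still declining
monotonically over the trailing window and the steadiness criterion
unmet. The second clause is the operative one: on the extinction
course the enzyme pool decays only algebraically (`x2 ~ 1/(C·τ)` on the
slow manifold), so `x3` drifts toward zero logarithmically and would
take astronomically long to reach any fixed floor. A steady endpoint is
labeled **recovered** when `x3 ≥ 2·k23` (per-step translational
saturation of at least 2/3) and **stabilized-low** otherwise; the label
is a reporting convention and no analysis depends on the split.

The response half-time `τ1/2` is the time to cover half the remaining
distance to the final steady value, measured from the post-drop minimum
when the trajectory recovers from below. High-bias systems instead
collapse onto the slow manifold and then drift *down* to the steady
state; there the reference point is the first output point after the
collapse (the collapse itself completes within `τ ≪ 1`, resolved by a
log-spaced initial output grid). Both branches reduce to the textbook
`ln 2` for a pure exponential approach. `τ1/2` is undefined for failed
trajectories and raises.

## Steady states, stability, regimes

With `x7 = 0`, `x3 = 0` is always a steady state. Eliminating `x1` and
`x2` at equilibrium leaves a scalar balance `f_left(x3) = f_right(x3)`
between the repressible supply curve and a demand curve with exponent
`2m − n`. Roots are located by scanning `log f_left − log f_right`
(overflow-safe for large negative exponents) for sign changes on a
log-spaced grid of 4000 points over `x3 ∈ [1e-8, 10]`, polishing each
bracket with Brent's method to 1e-12 and de-duplicating at 1e-6
relative. Below the floor a root is indistinguishable from extinction
at solver precision; above `x3 = 1` no root can exist once the external
supply is gone. Doubling the grid moves no root by more than 1e-8
relative, and the full vector field at each reconstructed `(x1, x2,
x3)` vanishes to better than 1e-9 on the normalized scale.

Interior roots are classified by the eigenvalues of the numerical
Jacobian (central differences, step `1e-7·max(|xi|, 1)`): stable iff
all real parts are below −1e-9, unstable iff any exceeds +1e-9. Two
degenerate situations need care. At the origin the linearization is
structurally singular — for `m, n, g13 > 1` every `x3`-dependent term
vanishes faster than linearly, leaving eigenvalues `{−A, 0, 0}`
regardless of parameters — so the extinction state is classified on the
slow manifold: the sign of `f_left − f_right` as `x3 → 0+` gives the
direction of the reduced flow (net production repels from extinction,
net demand attracts). Second, an interior root's slow eigenvalue scales
like `h(x3)^m` and can be as small as 1e-16 while of perfectly definite
sign; roots falling inside the ±1e-9 band are resolved by the slope of
the reduced field at the root (stable iff the gap crosses from + to −).
True tangencies (saddle-node points, slope below 1e-8) are flagged
degenerate and excluded from regime counting.

The regime follows from the root/stability pattern: **safe** (one
positive stable root, extinction unstable; guaranteed whenever
`n ≤ 2m`, i.e. critical bias `n − 2m ≤ 0`), **bistable** (two positive
roots, upper stable, lower unstable, extinction stable), **fatal** (no
positive root). `find_critical_n` bisects a continuous `n` between
`2m` (roots exist) and `3m` (none) for the saddle-node threshold `m_c`
to 1e-3; at the reference constants `m_c ≈ 33.14`, and it is
independent of `A` and `B`, which cancel from the balance. With `C = 1`
(all supply autosynthesized) the balance retains a positive root for
every `n` — starvation removes nothing the cell was using — so no
threshold exists and the bisection correctly refuses the bracket.

## Proteome mining

`n` is the cognate count of the *final* enzyme of the pathway — the one
step identifiable unambiguously per pathway — taken as the minimum over
annotated alternative pathways (the most resilient route); `m` is the
unweighted mean cognate count per protein over the whole putative
proteome. (The dynamic model's `m` strictly refers to the *expressed*
proteome; the mining follows the putative proteome, the only one
derivable from sequence.) Counting is exact and case-insensitive;
ambiguity codes (B, Z, X, U, O, J) never match a standard residue.
Composition bias is the mean of `count − 0.05·length` — a count-based
measure deliberately distinct from percentage composition: three
proteins of lengths 100/200/400 with two cognate residues each carry
identical count bias but 2% / 1% / 0.5% by composition.

Bias populations are tested with the classical exact sign test: zeros
dropped, sign counts binomial under the null, one-sided tail from
`scipy.stats.binomtest`. A confirmatory p-value requires a declared
direction; `direction="auto"` (test toward the sample median) is for
exploration only. Raw p-values are reported and flagged at p < 0.001;
no multiple-testing correction is applied. Profile matrices (organisms
× 20 amino acids, canonical residue order, missing pathways as NaN) are
clustered by single linkage on Euclidean distances, rows and columns
independently; missing cells are imputed with their column mean before
distance computation — neutral for ordering — while missingness is
preserved for display. Trees are exported as Newick with branch lengths
equal to merge-height increments, so root-to-tip distances reproduce
the dendrogram heights.

## Synthetic cohorts

The generator emulates the survey's inputs at toy scale: 200 bulk
proteins per organism (a real microbial proteome has 2,000–4,000; the
bias statistics concentrate fast enough that 200 suffices and keeps a
200-organism cohort in seconds), log-normal lengths with mean 300
residues and log-sd 0.35, per-organism compositions Dirichlet-jittered
around uniform 0.05 (concentration 2000, about 10% relative spread —
the scale of real inter-species composition variation). One extra
protein per amino acid is designated the final enzyme and sampled at a
shifted composition so that its *expected* cognate count equals
`composition·300 + δ` independent of its own sampled length, with
probability mass taken proportionally from the other residues; `δ` is
thereby the recoverable ground truth, and infeasible negative targets
clamp at zero with a warning. Organisms are assigned round-robin to
environment groups with distinct `δ` profiles; random per-(organism,
amino acid) annotation dropout exercises the missing-pathway path. All
draws derive from `(seed, organism index)`, so outputs are
byte-identical across runs.

What the generator does *not* emulate: codon structure, phylogenetic
correlation (group structure is the only non-independence — no tree),
real composition profiles, gene content, or homology between organisms.
Passing tests therefore demonstrate that the statistics recover known
injected signals under idealized i.i.d. sequences, not that real
proteomes are unbiased samplers; on real data, phylogenetic
non-independence inflates effective sample sizes and the sign-test
p-values should be read accordingly.

With one enzyme per amino acid per organism, the per-organism bias
estimate carries irreducible binomial noise (sd ≈ 3.8 residues at
length 300), so the median over 200 organisms has a standard error of
about 0.33 residues — the resolution at which injected shifts of ±3 are
recovered. The two-group clustering check uses opposite ±6 profiles
across all 20 amino acids, giving a between-group separation (~54 in
Euclidean distance) far above within-group spread (~24), which
single linkage — otherwise prone to chaining — splits cleanly.

## Numerical and interface conventions

Parameter files are flat key:value YAML restricted to the nine
dimensionless constants; unknown keys are rejected. All tabular writes
are atomic (temp file + rename). Annotation rows with unknown residue
codes or dangling protein references are skipped with logged warnings
rather than failing a whole run. Every CLI run logs version, resolved
configuration and input SHA-256 digests.

## Known limitations

The unnormalized equations are represented only through the
normalization map, not integrated directly. Basins of attraction in the
bistable regime are not computed (the outcome there depends on initial
conditions). Continuation is limited to the single saddle-node in `n`.
Ribosome and release-factor pools are assumed saturating; tRNA charging
and codon-level effects are deliberately outside the model's scope.
Fate labels at horizons much shorter than the slow relaxation time
(`τ ≲ 1e6` at the reference constants) can misread a slowly converging
trajectory as failing; the default horizon avoids this for the
reference parameter set.
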