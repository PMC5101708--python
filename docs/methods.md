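# Methods

## The synthetic twin cohort

The generator inverts the classical twin decomposition: the natural log
of apparent oral clearance for sibling j of pair i is

    log CL_ij = μ + A_ij + D_ij + C_i + E_ij

with Var(A) = a²σ², Var(D) = d²σ², Var(C) = c²σ², Var(E) = e²σ² and
a²+d²+c²+e² = 1. Within a pair, A correlates 1 (MZ) / 0.5 (DZ), D
correlates 1 (MZ) / 0.25 (DZ), C correlates 1 in both, E is
independent. Components act on the log scale: clearance is strictly
positive and spans several fold in vivo, so a multiplicative model is
the natural choice and keeps the decomposition additive.

Occasion-to-occasion variability multiplies the subject-level clearance
by a mean-preserving log-normal factor with natural-scale coefficient
of variation `within_subject_cv`. No distributional form for
within-subject noise is established for this design; log-normal is this
package's modelling assumption.

Defaults encode the study conditions of the motivating design: 42 MZ +
13 DZ pairs, 50 mg dose on 3 occasions, sampling at 0, 0.5, 1, 2, 3, 4,
5, 6, 22 h, mean Cl/F 0.97 l/min, Vz 1115 l, between-subject log-SD
0.41 (back-computed from a reported CV of ≈43 %), within-subject CV
0.25, assay CV 2 %, LLOQ 0.5 µg/l, CE truth with c² = 0.535. A 2.5-mg
low-dose preset (`low_dose_config`) uses a single occasion, sampling to
8 h, a dose-specific higher apparent clearance and slower absorption
(tmax ≈ 4 h), and c² = 0.685 for the AUC_7h phenotype; dose
nonlinearity is represented only by these dose-specific parameter sets,
not by a mechanistic saturation model.

Concentration profiles follow a one-compartment oral model,
C(t) = Dose·ka/(Vz(ka−ke))·(e^(−ke·t)−e^(−ka·t)) with ke = CL/Vz,
multiplied by log-normal assay noise; samples below the LLOQ are
missing with a BLQ flag (never 0 or LLOQ/2 — the NCA decides). With the
default parameters the model's Cmax is lower than real talinolol data
show (terminal-phase Vz overestimates the central volume); the
synthetic world is internally consistent, and the NCA recovers the
generating clearance from it to within 0.5 % on dense noise-free
sampling, but absolute Cmax levels should not be compared to clinical
tables. Likewise Cmax and tmax inherit clearance variability through
ke, so their synthetic rGC values are more structured than real data,
where absorption noise dominates them.

Genotypes: loci sharing a haplotype block are drawn as haplotypes with
adjacent-pair D′ = 0.9 by default (the three MDR1 variants form one
block); each pair has two simulated parents and DZ siblings inherit one
parental haplotype per block, so Mendelian sharing is exact rather than
a 0.5-correlation shortcut. MZ siblings are genetic copies. 23
independent markers ("ZYG" loci) support zygosity verification.
Genotype and covariate effects are added to log-clearance after
centring, so they shift variance, not the mean.

One seed drives everything; per-table RNG streams are split from a
single `SeedSequence` (phenotypes, genotypes, covariates, assay noise),
so adding a locus does not perturb phenotype draws, and identical seeds
give byte-identical output files.

## Non-compartmental analysis

* λz window: trailing windows of k = 3 … all points strictly after
  Cmax (Cmax excluded); the window with the highest adjusted R² wins,
  ties to more points. This mirrors the de-facto convention of
  standard NCA software; no published rule exists for the motivating
  analysis.
* Trapezoid dialect: linear when concentration is non-decreasing
  across an interval, log (Δt·(C1−C2)/ln(C1/C2)) when strictly
  decreasing with both values positive. On exact mono-exponential decay
  the whole chain (log trapezoid, log interpolation, regression) is
  exact to numerical precision.
* AUC_7h on the 50-mg schedule needs a concentration at 7 h between
  the 6- and 22-h samples; falling-limb interpolation is log-linear by
  default, switchable to linear (`auc7_interpolation`).
* AUC∞ adds Ĉ(tlast)/λz using the *predicted*, not observed, last
  concentration.
* BLQ: pre-Cmax → 0; post-Cmax → profile truncated at the last
  quantifiable point. Profiles with fewer than 3 usable post-peak
  points raise `InsufficientTerminalData`.
* Units are fixed bit-exactly: dose mg, concentration µg/l, time h,
  AUC mg·min/l (1 µg·h/l = 0.06 mg·min/l), clearance l/min,
  Vz = 60·(Cl/F)/λz litres.
* tmax ties break to the earliest time; per-subject parameters are
  arithmetic means over available occasions.

## Twin variance-component models

The likelihood is evaluated from per-zygosity sufficient statistics
(n, Σ(x₁+x₂), Σ(x₁²+x₂²), Σx₁x₂), so one evaluation is O(1) in the
number of pairs; a non-positive-definite implied covariance returns
−∞ rather than raising. Paths enter as squares of unconstrained reals.
Optimization is multi-start Nelder-Mead (moment/Falconer-informed plus
fixed perturbations, ≥4 deterministic starts, likelihood tolerance
1e-10). After convergence, nested fits with each genetic or
shared-environment path removed are compared; when a reduced model
attains the same likelihood within 1e-7 the boundary solution is
adopted exactly, so estimates like â² = 0 print as true zeros.

The saturated reference is the per-zygosity exchangeable bivariate
normal (mean, variance, covariance per zygosity; 6 parameters), fitted
in closed form via the sum/difference rotation. Likelihood-ratio χ²
and p-values are reported against it with df = 6 − k. Published twin
software may use a richer saturated parameterization; χ² values are
therefore comparable only within this package's convention.

D and C are never co-estimated (ACDE is rejected with an explanatory
error): with only MZ/DZ contrasts the twin design cannot identify both.

Default analysis scale is raw clearance, with a `--log` flag; CIs are
pair-level bootstrap percentile intervals by default (1000 replicates
in the library; the pipeline's default report uses 200, chosen as a
reporting default that keeps a full five-model comparison with CIs
interactive), with a finite-difference delta-method alternative.
Boundary components truncate at 0. Pairwise correlations are plain
Pearson r of (sib1, sib2) — no double entry — with sibling order
canonicalized by subject id, and Fisher-z intervals.

## Repeated-measures genetic component

vw is the mean per-subject sample variance (denominator n_occ−1,
subjects with ≥2 occasions); vb is the raw sample variance of
per-subject occasion means — deliberately without subtracting vw/n_occ,
following the original formulation of the statistic. Hence under pure
noise E[vb] ≈ vw/n_occ, and with subject-mean variance V_s and occasion
noise V_o the statistic converges to
(V_s − (1 − 1/n_occ)·V_o)/(V_s + V_o/n_occ), not to V_s/(V_s+V_o/n_occ).
rGC can be negative (vw > vb) and is reported as such, flagged, never
truncated. The resampling scheme (50 random one-sibling-per-pair
subsets) is the only stochastic element, so the 2.5/97.5 percentiles of
the resample values serve as the 95 % interval; no other CI method is
defined for this statistic here.

## Association battery

The Jonckheere–Terpstra statistic is the sum over ordered group pairs
of Mann–Whitney counts with ½ credit for ties; variance is the
standard tie-corrected expression and no continuity correction is
applied. Exact p-values enumerate every assignment of the pooled values
to the group sizes and are the default for pooled n ≤ 12. The
Mann–Whitney U convention is #(x<y)+½·ties for group 1 vs group 2, so
JT with two groups reduces to it identically. Genotype trend tests
order groups by variant-allele dose 0/1/2. Regression reports, per
factor, the marginal Pearson correlation with the phenotype alongside
the joint OLS coefficient (a partial-correlation alternative is
available by flag); rank-deficient designs fail with the most collinear
factor pair named. Zygosity verification declares MZ only on identity
at all 23 marker loci, DZ on any mismatch, and indeterminate (never
guessed) on missing genotypes.

## Problem sizes and what the tests show

Simulation-based checks use 5 000–10 000 pairs per zygosity for
recovery of variance proportions (Monte-Carlo SE of ĉ² ≈ 0.01 at that
size), 100 replicates for boundary-behaviour frequencies, and
100–200-case property sweeps for the exact-test oracles; these sizes
make the Monte-Carlo error comfortably smaller than the assertion
tolerances. Passing tests demonstrate internal correctness of the
estimators and generator consistency — they cannot validate the
biological realism of the generator's simplifications (one-compartment
kinetics, log-normal noise, no assay drift, no dropout, no
genotype-by-environment interaction).

A further caveat worth stating: under a CE truth the MZ and DZ
correlations are equal in expectation, so the ACE fit sits exactly on
the a = 0 boundary only in about half of finite samples (whenever the
sample MZ correlation does not exceed the DZ one); the frequency of
exact-boundary solutions approaches 1 only as n grows far beyond 5 000
pairs per zygosity, or when the DZ correlation genuinely exceeds the
MZ one as in the motivating data.
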