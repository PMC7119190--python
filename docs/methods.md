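# Methods

## Model

The core model treats one trait measured in `t` environments as `t`
correlated genetic effects. For plot-level records,

    y = X beta + Z u + e,
    Var(u) = G ⊗ K,
    Var(e) = blockdiag_i( sigma²_i I ),

with `X` containing environment means and, by default, replicate-within-
environment fixed effects when the data carry a replicate column; `u` is
the vector of genetic values of all `n` lines in all `t` environments
(including lines with no records, which are predicted through `K`); `G` is
the unstructured `t x t` genetic covariance of environments; residuals are
independent, homoskedastic within environment, heteroskedastic across.

Assumptions worth stating: additive genetic architecture only (the kernel
is a single additive `K`; no dominance or epistasis), residuals independent
across plots (no spatial field trend), replicate effects fixed (incomplete-
block random effects are out of scope), and one trait at a time.

`K` is VanRaden method I: `K = WW'/s`, `W` the column-centred dosage
matrix. The scaling is `s = 2 Σ p_j(1-p_j)` for biallelic 0/1/2 dosages.
For dominant 0/1 markers (presence/absence scores, as produced by some
amplicon platforms) the 0/1 score is treated as the dosage, centred by its
frequency, with `s = Σ p_j(1-p_j)` — a single Bernoulli draw per line
instead of two. Markers are first filtered on minor allele frequency
(strictly > 0.05) and missing-call fraction (strictly < 0.10), both strict
inequalities by definition, then mean-imputed per marker, which preserves
allele frequencies and adds no spurious covariance.

Population structure is summarised by `K = UDU'`. Plotted PC scores
multiply eigenvectors by their eigenvalues by default (the convention used
with relationship-matrix structure plots); conventional
`sqrt(eigenvalue)` scores are available via `scale="sqrt"`. Variance
proportions are `D_ii / tr(D)` after clamping eigenvalues within `-1e-8`
of zero.

## REML estimation

Variance components maximise the restricted likelihood

    -2 logREML = log|V| + log|X'V⁻¹X| + y'Py + (N - p) log 2π.

All linear algebra runs in the `n·t` cell space via the Woodbury identity
`V⁻¹ = R⁻¹ - R⁻¹Z Gc (I + D Gc)⁻¹ Z'R⁻¹` with `Gc = G ⊗ K` and
`D = Z'R⁻¹Z` diagonal, so a fit costs O((nt)³) per iteration rather than
O(N³), and a singular `K` (the generic case for marker-derived `K`) needs
no inverse.

Updates are average-information (AI) steps taken in an unconstrained
parameterisation — log-Cholesky for `G`, log for the `sigma²_i` — so every
visited point is a valid component set without projection. The score and
AI matrix are computed in the natural scale and transformed through the
Jacobian. Damping is Levenberg-Marquardt style: the AI matrix receives an
adaptive ridge that grows when a proposal fails and shrinks after success,
and each proposed step is step-halved until the restricted likelihood does
not decrease, making the iteration trace monotone nondecreasing (checked
by the tests). When even heavily damped steps cannot improve the
likelihood the current point is reported as a stationary point.

Convergence requires `|Δ logREML| < tol` (default `1e-6`) together with a
maximum relative parameter change below `10·tol` on a lightly damped
(near-Newton) step. Boundary optima — a genetic correlation pinned at ±1
or a variance at zero — stall the likelihood while the natural parameters
oscillate along the flat ridge, so a sustained stall (three consecutive
sub-`tol` improvements) is also accepted as converged. Non-convergence at
`max_iter` (default 100) is flagged on the result, never raised.

Initialisation: `g_ii = sigma²_i =` half the per-environment phenotypic
variance, `g_ij = 0.3 sqrt(g_ii g_jj)`. A user-supplied start is first
bent to positive definite (eigenvalue floor `1e-8 ×` the largest
eigenvalue); `fit(start=vc, maxiter=0)` returns the GLS/BLUP solution at
fixed components, which the oracle tests use.

BLUEs ("observed" values for accuracy) come from per-environment least
squares with genotype fixed plus replicate effects when present; the
reported BLUE is the line effect at the frequency-weighted average
replicate, so balanced data without blocks give per-line plot means and a
single plot per cell gives the raw observation. Model predictions for
masked cells are `beta_env + (mean replicate effect) + GEBV`, putting them
on the same scale as the BLUEs for pooled correlations.

## Training/validation designs

All masking operates on (line, environment) cells of the phenotype table;
`apply_mask` removes all plot records of a masked cell and nothing else,
so leakage is impossible by construction (audited in the tests via a fit
hook). Odd sets split with the masked half taking the ceiling. Every plan
is a pure function of (scheme, seed, line list).

- **KFOLD**: seeded shuffle into k folds; each fold masked in all
  environments; predictions pooled over folds before correlating.
- **DTS**: a random ceil(n/2) half masked everywhere.
- **FSTS**: ceil(size/2) masked within each family, everywhere.
- **ST2**: complementary halves masked in each of two environments; every
  line observed in exactly one.
- **ST3** (balanced, default): each family is split into quarters Q1-Q4
  and the scheme masks Q1+Q2 in the primary environment, Q1+Q3 in the
  first secondary, Q2+Q4 in the second. Quarter sizes are chosen so each
  environment masks exactly ceil(size/2) lines per family (odd families
  contribute one extra cell from a Q3 line, which stays observed in the
  primary environment). This makes the retained training-cell count
  identical to FSTS — the two designs are plot-budget-matched — while
  every line keeps at least one observed environment. The stricter
  literal variant (only one extra quarter masked from the retained half,
  1.25 cells masked per line) sits behind `balanced=False`; the balanced
  reading was chosen as the default because equal masking per environment
  and plot parity with FSTS make the design comparison interpretable.

Fully masked lines are disallowed in sparse-testing plans by default:
every line must anchor the across-environment genetic correlation
somewhere.

Accuracy is the Pearson correlation over masked cells only, against BLUEs
computed once from the full data (never from masked data). "Combined"
pools all masked cells across environments into one correlation; because
pooled correlations absorb environment mean differences, a
`center_envs=True` flag z-scores within environment first (off by
default, matching the raw-pooling convention; the caveat is documented
here deliberately). Replicates report the arithmetic mean and sample SD
(n-1); replicates with undefined accuracy (zero variance, < 3 pairs) are
excluded and counted, never coerced to 0.

## Simulator

The generator produces the two population structures the designs are
meant for, with full truth (breeding values, QTL effects, realized
heritabilities) emitted alongside.

**Genome and trait.** Loci (markers + QTL) are placed uniformly on a
chromosome map; ancestral allele frequencies are Uniform(0.1, 0.9) to
avoid near-fixed loci. Each QTL's per-environment effect vector is drawn
from a centred multivariate normal with correlation `Γ` and equal
variances, independent across QTL — so the across-environment genetic
correlation of true breeding values matches `Γ` up to sampling error.
Plot residual variances are set from the *empirical* genetic variance,
`sigma²_e = Var(g_e)(1-h²_e)/h²_e`, so realized plot heritability hits its
target by construction. QTL are excluded from the emitted marker panel by
default: markers tag causal loci only through linkage disequilibrium, as
in real data (an observed-QTL debug mode exists).

**Diverged subpopulations** (chickpea-like preset): group allele
frequencies follow the Balding-Nichols model at the configured Fst
(default 0.4, reproducing a clean two-cluster PC plot); each group gets an
independent founder pool of 10 haplotypes, and every line is a doubled
recombinant mosaic of its group's pool (Poisson breakpoints at 5 expected
crossovers per Morgan). Independent pools give each group its own
marker-QTL LD phase — the mechanism by which cross-group prediction
collapses in real diverged panels. Pool size and mosaic depth control
within-group LD; 10 founders / 5 generations reflect the small effective
size of an elite breeding pool and place within-group 10-fold CV accuracy
in the mid range observed for real diverged panels (~0.3-0.6 at h² 0.35),
with cross-group accuracy near zero and combined-group CV inflated by the
group contrast — the qualitative structure this preset exists to emulate.
The preset trait is moderately polygenic (100 QTL).

**DH half-sib families** (maize-like preset): fully inbred parents, one
shared; each DH line is a single F1 gamete (crossovers Poisson on map
distance — Haldane, no interference) doubled to homozygosity. Markers are
emitted as dominant 0/1 scores. Defaults: family sizes 91/108/88, ~6,800
markers, three environments with genetic correlations (0.54, 0.72, 0.40)
and plot heritabilities (0.30, 0.25, 0.30), two replicates.

Both presets add 2% missing marker calls (exercising the QC path) and are
size-configurable. One `default_rng` seed drives everything; identical
config + seed reproduces byte-identical outputs.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: no selection or drift during line development,
no mutation, no dominance/epistasis at QTL, equal QTL effect variances
across environments, normal iid plot residuals (no spatial trend, no
outliers), and LD generated by a founder-mosaic process rather than a
coalescent — realistic in broad strokes (block-sharing decay), not in its
fine-scale spectrum. Real marker ascertainment bias is absent.

## Problem sizes used by the tests and acceptance script

Solver-correctness checks run on instances of ≤ 200 records against dense
oracles (1e-6/1e-8 agreement). REML optimality is checked against a
Nelder-Mead search on five n = 40 datasets. Parameter recovery uses three
DH families of 60 at 1,000 markers over 20 simulations (mean genetic
correlations within ±0.10, mean plot h² within ±0.05 of truth). The
cross-population analysis runs the full 315-line two-group preset over 10
simulated datasets; the sparse-testing comparisons use 200-line panels
with 10 masking replicates per design at genetic correlations
{0.2, 0.5, 0.9}. These sizes were chosen to keep the complete suite in
the low minutes on a single CPU while leaving each check clear
statistical headroom; `scripts/acceptance.py` uses the same structures
with 3-5 simulation replicates per quantity.

## Numerical choices

- PSD tolerances: `K` eigenvalues ≥ -1e-8 accepted and clamped at 0 in
  PCA; `G` bending floor 1e-8 × its largest eigenvalue.
- `sigma²` and Cholesky log-parameters clipped to |log| ≤ 25 to keep
  exponentials finite; candidate steps whose factorisations fail
  numerically are treated as rejected, not fatal.
- Marker filters use strict inequalities; ties at a threshold drop the
  marker.
- Degenerate inputs raise early with the offending marker/line/term
  named: all-missing markers, monomorphic panels (`s = 0`), aliased
  fixed-effect columns, phenotyped lines absent from `K`, stale mask
  plans referencing unobserved cells.
- Pearson accuracy is undefined (reported as missing, never 0) with
  fewer than 3 pairs or zero variance.

## Known limitations

Fits scale as O((nt)³) per AI iteration — comfortable to ~1,000 lines ×
3 environments, not intended for tens of thousands. The unstructured `G`
has t(t+1)/2 parameters and becomes weakly identified when sparse designs
leave few lines (or only across-line kinship ties) connecting an
environment pair; estimates can then sit on the correlation boundary, and
the boundary-stall convergence rule reports them honestly rather than
polishing them. Factor-analytic or compound-symmetry structures for many
environments, multi-trait models, marker-effect (SNP-BLUP/Bayesian)
models, and training-set optimisation are out of scope.
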