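# Methods

This note documents the statistical machinery, the synthetic-data
model, and the design decisions behind `oralmicro`.

## Compositional geometry

All abundance analyses operate on centered log-ratios of the count
table.  For a sample with counts `x₁…x_D` and pseudocount `c`,

    clr(x)ᵢ = ln(xᵢ + c) − (1/D) Σⱼ ln(xⱼ + c)

The pseudocount defaults to `c = 1` added to every count (exposed
everywhere it matters, and pinned in tests).  Beta diversity is the
Aitchison distance, the Euclidean distance between CLR rows; it is a
proper metric and embeds exactly in Euclidean space, which the
dispersion test exploits (see below).  Exact scale invariance of the
Aitchison distance holds only in the limit `c → 0`; with `c = 1` the
distances are approximately invariant to per-sample depth rescaling,
and the test suite checks the exact identity at `c = 10⁻⁹`.

No rarefaction is applied anywhere.  Alpha diversity (Shannon in nats,
Simpson `1 − Σp²`, richness, Faith's PD) is computed on raw counts or
proportions; Faith's PD includes the path to the root, which shifts
absolute values by a constant per-tree offset but no trend across
samples.  Alpha diversity defaults to ASV level; aggregation to genus
or phylum is available and conserves per-sample totals exactly
(unclassified genera are kept distinct per parent phylum rather than
pooled).  Weighted UniFrac is the normalized variant so values lie in
[0, 1] and are comparable across pairs; both UniFrac variants delegate
to scikit-bio and are cross-checked against a naive per-branch
summation oracle in the tests.

## Matched-control subsampling

Every comparison runs on an ensemble of balanced subsamples (default
100).  Eligibility: control pools exclude samples with any reported
chronic disorder (cystic fibrosis, Down syndrome, celiac) unless the
tested variable *is* that disorder, samples missing age or gender, and
samples from regions absent from the tested group.  For binary
variables the group size is `min(100, size of the smaller eligible
group)` per repetition, with a configurable minimum (default 10) below
which the test refuses to run.

The matching algorithm is stratified sampling on the joint
gender × region × age-bin distribution of the yes group, with
proportional allocation, falling back to nearest-age donors within
gender × region (then within gender, then globally) when a stratum is
exhausted.  A per-repetition matching report records realized
distributions plus a Kolmogorov–Smirnov age check and chi-square
gender/region checks.  Matching is validated per repetition, not once
globally.

Age analyses draw from six bins (13–20, 20–30, 30–40, 40–50, 50–60,
>60) balanced on gender × region: the target joint distribution is the
pooled one over eligible samples (restricted to strata present in every
bin), each bin's size is the largest n whose proportional quotas fit
that bin's availability, and quotas are apportioned by largest
remainder.  Per-bin sizes are therefore constant across repetitions.
The same ensembles serve age-as-continuous models, guaranteeing an even
age spread with balanced gender and region.  One master seed derives
per-repetition seeds, recorded in the ensemble for replay.

## Multivariate tests

**PERMANOVA.**  The distance matrix is Gower-centered
(`G = −½ J D² J`), and sums of squares are extracted by projection
(hat) matrices built from the ordered term list — the variable of
interest first, then gender, age, and log₁₀ town population.  The
default is sequential (order-of-entry) sums of squares, so the per-term
R² plus the residual partition the total exactly; a marginal mode
(each term against the model holding all others) is available with the
documented caveat that marginal R² values need not partition the
total.  P-values come from free permutation of sample labels with the
observed statistic included in the null set (default 999 permutations);
an exhaustive-enumeration mode exists for tiny fixtures.  Terms that
add no rank (constant or confounded) are dropped with a warning.  Town
population enters as log₁₀ of the numeric population size — a choice,
flagged as an assumption, over treating town as categorical.
One-vs-rest bin tests replace the age term by a binary indicator for
the bin, keeping the other covariates.

**Dispersion homogeneity.**  Principal-coordinate embedding of `G`
(negative-eigenvalue axes kept separately), per-group spatial medians
by Weiszfeld iteration (tolerance 1e-8, with the standard fix at data
points), squared sample-to-median distances corrected as
`max(d²_real − d²_imag, 0)` before the square root, and a one-way ANOVA
on the distances across groups.  On Aitchison matrices the embedding is
exact and the negative-eigenvalue branch never triggers (asserted in
tests).  The ANOVA on distances is approximate and known to run
slightly liberal; the null simulation in the acceptance suite measures
its realized level (≈5–7% at n = 40).

**Anosim.**  All pairwise distances are ranked once (average ranks on
ties); `R = (r̄_between − r̄_within)/(M/2)` with `M` the number of
pairs, p by permuting unit labels.  For relationship units, only
samples belonging to a unit of size ≥ 2 enter, and between-unit
distances are restricted to that included set.  Classmates are treated
as units by school id exactly like families.  The twins-vs-siblings
contrast is a two-sided Mann–Whitney test of within-twin versus
within-sibling distances, exact for small samples.

## Trend models and consensus

Responses (CLR abundances, alpha measures, pH, BMI) are fitted by
ordinary least squares on the focal variable plus gender, age, and
log₁₀ town population.  CLR values are real-valued, so the
Gaussian-identity linear model is the coherent choice for them.
Per-term p-values are type-II: each term is tested by the F statistic
of dropping it from the model containing all other terms, making the
p-values invariant to term order (verified against statsmodels'
type-II ANOVA).  A parabolic age trend is modelled by a degree-2
orthogonal polynomial basis — the minimal faithful reading of a
"second-order" age effect; richer spline bases are under-determined
without knot information, so none is guessed.  The quadratic age term
is tested jointly (2 df).

Across an ensemble, each repetition is fitted separately and
Benjamini–Hochberg adjusted across the batch of responses within that
repetition (the FDR family is the batch — all genera, or all alpha
measures — and is configurable).  The consensus reports the mean
adjusted p, the number of repetitions significant at 0.05, and a
direction label: increase/decrease by majority coefficient sign;
"parabolic" when the quadratic term is significant and the fitted
vertex lies in the interior of the observed age range; "late-rise" when
the sub-50 trend is flat but the overall slope is positive.  pH
associations reuse the same machinery with pH as the focal covariate
(requiring ≥ 30 non-missing pH values; constant pH is an error).

## Co-occurrence networks and uniqueness

Rare taxa are removed first: keep taxa with ≥ 15 counts in ≥ 20 samples
(thresholds rescale proportionally, with a warning, on tables under 100
samples so the rule stays meaningful on reduced fixtures).  Networks
are estimated on standardized CLR data.  The default backend is
penalized inverse covariance over a geometric penalty path with
StARS-style stability selection: edge-selection frequencies over random
subsamples (size `10√n`, or `0.8n` below n = 144), walking the path
from sparse to dense and keeping the last penalty whose mean edge
instability `2θ(1−θ)` stays below 0.05; edges must be selected in
≥ 80% of subsamples.  A fast deterministic backend fits a single
penalized model at a fixed penalty (default 0.3).  Either way, edge
strength is the signed partial correlation `−Ωᵢⱼ/√(ΩᵢᵢΩⱼⱼ)` from the
selected precision matrix, and edges below |0.1| are suppressed: an
unpenalized partial correlation is ill-defined on CLR data because the
closure constraint makes the covariance singular — the penalty is what
keeps the conditioning sparse — and the floor removes the faint
spillover closure induces.

The uniqueness score compares ensembles of group-of-interest networks
across variables.  For the ordered pair (v, w): sum over edges present
in *all* of v's subsample networks and in *none* of w's of the edge's
mean |strength| across v's networks.  An edge missing from even one of
v's repetitions contributes nothing.  Edge identity is the unordered
taxon pair, sign-insensitive by default.  Per variable, both the sum
and the mean over pairwise comparisons are reported.  When matched
control networks are supplied, edges seen in any control network are
excluded from a variable's core set first.

## Synthetic cohort model

Counts follow a logistic-normal–multinomial: per-taxon baseline
log-abundances (drawn N(0, 1.5) or supplied explicitly), plus
CLR-scale effects added to a latent vector `z` per sample —

* per-taxon age slopes times (age − 40),
* condition shifts (alternating sign over an internally chosen taxon
  subset) for flagged samples,
* optional extra shifts for the extreme age ranges (< 20 and > 60),
* family / classroom / twin shared random shifts,
* heteroscedastic noise with s.d. `a·age² + b·age + c` (validated
  positive on ages 7–85), optionally rescaled per condition group,
* optional group-exclusive co-occurrence: a shared latent factor added
  to a taxon pair in flagged samples, scaled to a target correlation —

then `softmax(z)` feeds a multinomial draw at fixed depth, so column
sums equal the configured depth exactly.  The logistic-normal family
(rather than Dirichlet-multinomial) was chosen because effects are
planted additively on the CLR scale the analyses operate on, making
parameter recovery well-posed.

Metadata: ages uniform within six bins with configurable bin weights
(the bundled default reproduces a teen-heavy cohort shape of roughly
80/3/2/7/4/3%); gender balanced; six regions with uneven weights;
lognormal town population; chronic flags (CF, Down syndrome, celiac)
mutually exclusive, lifestyle flags independent Bernoulli; family units
of size 2–4 with relationship labels (twins share an age); school ids
for under-20s (~30 per school); pH decreasing and BMI increasing
linearly in age with noise (pH clipped to the 5–10 strip range, with
optional 0.5-step quantization mirroring test strips); a small fraction
of age/gender values set missing.  Sequencing depth is a free
parameter — a real cohort's depth distribution is not modelled.  Every
planted effect is recorded in a JSON-serializable truth ledger.

What the generator does *not* emulate: read-level noise (no FASTQ),
chimeras, contamination, batch effects, taxonomic misassignment, or
realistic phylogenetic signal in the effects (the tree is a random
coalescent-style topology with exponential branch lengths).  Passing
recovery tests therefore demonstrates the statistical machinery is
correct and well-calibrated under the stated generative model, not that
the biological conclusions of any particular cohort are right.

## Validation experiments and problem sizes

The `validation` module runs the stack end to end at sizes chosen for
single-CPU minutes:

* **Type-I control** — 600 null cohorts (n = 40, 25 taxa); PERMANOVA
  (199 permutations), dispersion ANOVA, anosim over families, and the
  per-term trend test all reject near 5%.
* **Parabolic age structure** — 10 cohorts (n = 300, 60 taxa) with
  1.0-CLR effects on eight-taxon subsets in the extreme age ranges and
  noise s.d. minimal (0.30) at age 45: one-vs-rest PERMANOVA
  (100-repetition ensembles, 99 permutations, BH across bins) is
  significant only for the extreme bins, the 40–50 bin has the smallest
  mean distance to its spatial median, and quadratic Shannon models
  beat linear ones.
* **Trend directions** — one cohort (n = 900, 40 genera, depth 10 000)
  with six planted increasers at low abundance (baseline −1.5 CLR,
  +0.025/yr) and six decreasers at high abundance (+2.0, −0.025/yr):
  all 12 recovered with the correct direction in ≥ 80/100 repetitions,
  no null genus called.  The low baseline is kept above the
  count-truncation regime: rarer baselines let the pseudocount convert
  the age-driven mass shift of the decreasers into a spurious trend in
  the CLR centering term.
* **Dispersion flag** — 10 cohorts (n = 200) with a 30%-prevalence flag
  whose group noise is scaled by 0.55: the flagged group sits tighter
  around its spatial median with ANOVA p < 0.05.
* **Uniqueness ranking** — 5 cohorts (n = 900, 30 taxa) with four
  variables, one carrying two group-exclusive pair dependencies
  (ρ = 0.7): the fast backend at penalty 0.4 over 5-repetition
  ensembles ranks the planted variable strictly highest.  The penalized
  detector is what makes the strict all-repetitions/zero-repetitions
  rule work: the full-strength dependency always passes, while its
  diluted echo inside other variables' groups (carriers are present
  there at their population rate) stays below the penalty threshold.

`scripts/acceptance.py` re-runs all of the above plus the analytic
oracles and writes the numbers as JSON.

## Known limitations

* The dispersion ANOVA inherits betadisper's mild liberality; treat
  p-values near 0.05 with care.
* CLR differential abundance is relative: strong planted shifts in a
  few taxa perturb every other taxon's CLR slightly (closure), and with
  very rare taxa the pseudocount can turn depth reallocation into small
  systematic trends.
* BIOM support is the JSON (1.0) dialect only; HDF5 BIOM is not read.
* The matching algorithm is stratified draw with nearest-age fallback,
  not optimal or propensity-score matching.
* Permutations are free label permutations; no strata-restricted or
  residual permutation schemes.
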