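# Methods

## Turnover model

A pulse-labeling shift experiment switches a steadily growing culture from
light to heavy lysine at t = 0. Per cell, each protein species is modeled
with first-order kinetics at post-shift specific growth rate μ (h⁻¹):

- light (pre-existing) pool: L(t) = a₀ · e^−(μ+k_deg)·t — no new light
  synthesis; loss is dilution by growth plus optional active degradation
  k_deg;
- heavy (new) pool: H(t) = a₁ · (1 − e^−(μ+k_deg)·t) while synthesis runs,
  relaxing toward the post-shift steady level a₁; if synthesis stops at a
  stagnation time t_s, H decays as the light pool does from t_s on.

With unchanged expression (a₁ = a₀) and no degradation the ratio is
H/L = e^{μt} − 1, equal to 1 exactly at the doubling time ln 2/μ. In
general H/L = (a₁/a₀)(e^{μt} − 1), so induced proteins cross 1 earlier and
repressed proteins later — the basis for the correlation between
replacement time and steady-state differential expression.

The estimator is deliberately the simple field procedure, not a nonlinear
fit of the model above: log₁₀(H/L) is regressed on time by ordinary least
squares (t0 samples excluded — they carry no heavy label) and the
replacement time is the zero crossing −intercept/slope. Disappearance and
production rates are OLS slopes of log₁₀ relative abundance (intensity over
the per-sample total, removing arbitrary per-sample scale) of the light and
heavy channels separately, t0 included.

### Quality gates and outlier handling

A model is kept when R² ≥ 0.70 and n ≥ 4 observations (both
parameters). A failing model gets exactly one rescue round: observations
whose absolute residual strictly exceeds median(|r|) + 2·MAD(|r|) are
candidates (MAD uses the normal-consistency constant 1.4826 throughout);
the single worst one is removed and the model refit once. A removal that
would leave fewer than 4 observations discards the model instead. With
n = 4 the rule can never fire — the outlier inflates the median and MAD of
the residuals past its own residual (provable from the leverage structure) —
so 4-point models are effectively kept or discarded as fitted.
Replacement models additionally require ≥ 4 light and ≥ 4 heavy
observations, and a protein with < 4 H/L ratios that nevertheless passed
both component models keeps only the rate from the more abundant channel
(median relative abundance), the weaker channel being deemed untrustworthy
at that sparsity.

### Classification against growth

Half-life t½ = log₁₀2/(disappearance rate) is compared with the cohort:
outside median ± 2·MAD counts as faster/slower than growth, inside as
dilution by growth; fewer than three half-lives leave everything
unassessed. The thresholds are symmetric by choice. Because t½ is the
reciprocal of a noisy slope its distribution is right-skewed, so at
measurement noise CV 0.2 a symmetric rule flags ~5% of a purely
growth-diluted cohort on the slow side by construction, while false
active-degradation (fast-side) calls stay below 1%. The classifier's
specificity claim therefore refers to false fast-side calls.

### Known bias of the crossing estimator

log₁₀(e^{μt} − 1) is concave — steep early, asymptotically linear late — so
a straight-line fit crosses zero slightly late. The size of the bias
depends on where the true crossing sits in the sampling window: at ~80% of
the window (96-min doubling sampled 15–120 min; 202-min doubling sampled
30–240 min) the bias is under 2%, but mid-window (126-min doubling sampled
30–240 min) it reaches +10–12%. This is a property of the estimator itself,
reproduced faithfully here; the package reports what the procedure
computes. Detection-limit censoring of the earliest heavy points (which are
closest to the floor precisely in slow-growth shifts) trims the steep early
region and reduces, but does not remove, the bias.

## Synthetic-data generator

The generator emulates the experimental design: duplicate unlabeled t0
samples, 8 post-shift samples every 15 min (fast shifts) or 30 min (slow
shifts), per-sample relative abundances normalized to the within-sample
total over all light plus heavy species (summing to 1 before noise),
multiplied by an arbitrary per-sample scale factor, with multiplicative
log-normal noise on every intensity; H/L ratios are formed from the noisy
intensities. Defaults, chosen once as realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| noise_cv | 0.2 | per-intensity multiplicative CV typical of label-based protein quantification |
| detection_limit | 1e-4 (relative abundance) | one order below a median protein in a ~600-protein quantified set; makes the earliest heavy points of slow shifts borderline, as observed |
| sample_scale_cv | 0.1 | harvesting/injection variation that relative-iBAQ normalization must remove |
| abundance spread | 0.5 log₁₀ SD | ~1.5 orders of magnitude across the quantified proteome |
| n_t0_replicates | 2 | duplicate t0 harvest |

What it does **not** emulate: peptide-level quantification and roll-up,
shared/razor peptides, ratio compression, co-elution artifacts, the
pre-shift labeling history (light pools start at steady state), and
growth-rate acceleration during the first generation (μ is constant
post-shift). Passing recovery tests therefore demonstrate correctness of
the estimators under the stated kinetic model, not robustness to every
real-data pathology.

## Lysine-unique database construction

Digestion is trypsin/P (cleave after every K/R, no proline exception), ≤ 2
missed cleavages, minimum peptide length 7. Only fully cleaved lysine-free
fragments are concatenated into artificial proteins, but maximal runs of
*adjacent* lysine-free fragments are kept contiguous, so in-silico
digestion of an artificial entry regenerates every lysine-free
missed-cleavage variant as well (they are exactly the concatenations of
adjacent fragments). A run ending at its protein's C-terminus closes its
entry, preserving the C-terminal position — such peptides need not end in
K/R and would otherwise not be regenerated. Entries are chunked at ≤ 5000
residues (`ART_000001`, ...). Junction-spanning peptides between runs are
accepted: they match no real protein and only add decoy-like sequence. The
verifier digests the union database and asserts that every lysine-free
peptide occurs in ≥ 2 entries and that no lysine-containing peptide
collides with an artificial entry (structurally impossible — entries
contain no K — but checked as a hard failure).

## Steady-state analysis

Acceptance filtering keeps protein groups that are not reverse hits, not
identified only by site, have > 1 peptide with ≥ 1 unique, and are
quantified in ≥ 2 replicates of at least one condition. LFQ intensities are
log₁₀-transformed (zeros as missing) and missing values imputed per sample
from N(mean − 1.8·SD, (0.3·SD)²) — the conventional down-shifted normal
placing imputed values near the detection limit. Fold changes are
10^(Δ mean log₁₀) on imputed means (a protein partially missing in a
condition uses its imputed values); the differential cutoff is fivefold by
default and configurable (e.g. twofold). Proteome-allocation profiles sum
relative iBAQ (each iBAQ over its sample total) over a user-supplied class
map and report Pearson correlation with growth rate; correlation is left
undefined for < 3 samples or zero-variance profiles.

## Physiology

Maximal specific growth rate: ln(OD600) is regressed over every contiguous
window of ≥ 4 points; among windows with R² ≥ 0.99 the *most linear* one
(highest R², longest on ties) supplies the slope in h⁻¹. Selecting the
steepest qualifying window instead — a tempting reading of "maximal" —
systematically chases upward noise fluctuations in short windows and biases
μ̂ high by up to +0.03 h⁻¹ at 1% noise; the most-linear rule is unbiased to
within ±0.006 h⁻¹ (mean absolute error over seeded replicates) and returns
the exact slope on noiseless curves. When no window qualifies the best
available window is used and a warning issued (flat curves return ~0).

Fermentation: the acetate share of (acetate + lactate) rescales the two
measured organic acids to [0, 1]; volatile mixed-acid products (formate,
ethanol) are not quantifiable by the upstream measurement, so the split is
a proxy for pyruvate routing, not a complete carbon balance. Ornithine
normalized to OD600 proxies ADI-pathway activity. Group comparisons use the
two-sided Welch t-test (Satterthwaite degrees of freedom); two zero-variance
groups with equal means report (t, p) = (0, 1).

## Problem sizes and determinism

Simulation-based checks use 600-protein cohorts (matching the >650 proteins
a real experiment models), 8-point time courses, and up to 20 seeded
replicates; each full pipeline run takes well under a second. Every
stochastic component takes an explicit seed; identical seeds give
byte-identical tables, and the pipeline output is sorted by protein id, so
results are invariant to input row order.
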