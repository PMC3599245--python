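# Methods

## Data model and detection calling

The expression matrix holds normalized linear fluorescence intensities for
genes x samples, with sample IDs `treatment_stage_replicate` over treatments
{C, PB, V} and ordered stages {BV, EV, H}. All test statistics are computed
on log2 intensities (variance stabilization); all fold-change thresholds are
applied to signed linear fold changes, defined as mean(B)/mean(A) when
mean(B) ≥ mean(A) and −mean(A)/mean(B) otherwise, where means are arithmetic
means of linear intensities over replicates. The linear convention was
chosen because the workflow's thresholds (2, 3, 5) and reported values read
naturally on that scale; whether upstream tools used linear or log ratios is
not generally knowable, so the convention is documented rather than asserted.

A gene is called expressed in a (treatment, stage) group when its intensity
strictly exceeds the arithmetic mean of its own chip's negative-control
probes in at least 2 of the group's replicates (ties fail — conservative and
deterministic), and retained for analysis when expressed in at least one
group. Retention is applied before any differential testing.

Sample-level PCA runs on log2 intensities, gene-centered, without
unit-variance scaling — the standard construction for array sample plots;
scores are reproducible up to component sign.

## SAM

Studies in this workflow's lineage name the method but not its formulas; we
implement the canonical Tusher et al. (2001) statistics, the reference
method the original TMeV software implements:

* two-class unpaired: `d_i = (x̄_B − x̄_A)/(s_i + s0)` with
  `s_i = sqrt((1/n_A + 1/n_B)(SS_A + SS_B)/(n_A + n_B − 2))`;
* multiclass: `d_i = r_i/(s_i + s0)` with
  `r_i = sqrt((Σ_k 1/n_k) Σ_k n_k (x̄_ik − x̄_i)²)` and
  `s_i = sqrt((Σ_k 1/n_k)/(n − K) Σ_k SS_ik)`.

For K = 2 the multiclass statistic reduces algebraically to |d_i|, so the
two forms rank a two-group design identically (tested).

The fudge factor s0 is selected from percentiles of s_i by minimizing the
coefficient of variation of the median absolute deviation of d across 100
windows of s (the Tusher rule); `median_s` and `fixed` alternatives are
configurable. Genes with zero pooled variance at s0 = 0 produce non-finite
statistics and are excluded from ranking with a warning, never called.

The null permutes sample labels: when the number of distinct assignments is
at most `n_permutations` (and `exhaustive_if_fewer` is on, the default) all
distinct assignments are enumerated exactly once — 20 for a 3v3 design,
C(9;3,3,3) = 1680 for three stages of three replicates — otherwise
assignments are drawn uniformly from the configured seed. Expected order
statistics are rank-wise means over the permuted, sorted statistics.

Calling uses the classic delta band: sort observed d, scan outward from the
origin (rank of d = 0 two-class; rank 0 for the non-negative multiclass
statistic) for the first rank whose departure from the expected order
statistic reaches delta; the observed d at that rank is the cut, and all
genes beyond the cuts are called. False positives are estimated as the
median, over permutations, of permuted statistics beyond the cuts; estimated
FDR = median FP / number called, with no pi0 correction and no
90th-percentile variant. Delta is the smallest value on a 0.01-step grid
with estimated FDR at or below the target (default 0.02); if no delta with a
non-empty call meets the target the call is empty and flagged unattainable.

A caveat this package measures rather than hides: automating the delta
choice with a median-FP estimate is biased at the extreme tail of small
exhaustive permutation sets. On a pure-null 3v3 dataset, any delta that
passes a 2% target with fewer than 50 calls forces the median-FP estimate to
zero, yet the call that defines the cut always contains at least one
(necessarily false) gene; roughly half of null datasets contain such a fluke
delta. The acceptance script reports the realized and estimated
false-positive medians and the sign-test p-value for this experiment so the
bias is visible. In practice the effect is limited to ~1–3 spurious calls on
data with no signal; with planted signal the estimate behaves as intended.

DE sets are intersections: pairwise DE = SAM-significant AND |FC| ≥ 2
between the two groups at the stage; stage-modulated (multiclass) = SAM
multiclass-significant AND |FC| ≥ 2 for EV/BV or H/BV within the treatment.

## Venn partition and NDR/NUR

The EV-stage PB-vs-C and V-vs-C DE sets split into common / PB-only /
V-only; the sum identities |common| + |T-only| = |T-vs-C| are asserted at
run time. Each DE gene's direction (from the sign of its contrast fold
change, which is authoritative over the SAM d sign) is crossed with the
control's BV→EV trend — down iff FC(EV/BV in C) ≤ −2, up iff ≥ +2, else
flat; the threshold mirrors the DE threshold and is configurable since no
separate trend threshold is documented anywhere. DE-up on a control-down
gene is NDR, DE-down on a control-up gene is NUR, the rest are genuinely
up/down. Category summaries report counts and percentages per functional
category with unannotated genes under "no hit"; no enrichment statistics are
computed (composition only).

## Profile clustering and the shift taxonomy

Per condition, a gene's profile is its mean log2 intensity at (BV, EV, H).
Clustering each condition separately would leave cluster IDs incomparable
across conditions, so this package makes one deliberate structural choice:
a single k-means (k = 8 by default) is fit on the pooled standardized
profiles of all conditions, and every (gene, condition) profile is assigned
to the shared centroids. "Cluster shifting" between conditions is then well
defined while preserving the original intent.

Distance is 1 − Pearson correlation (in [0, 2], invariant to positive affine
transforms). Profiles are standardized to zero mean and unit norm, under
which correlation distance is a monotone function of squared Euclidean
distance; centroids are means of standardized member profiles; constant
profiles are excluded with a warning (correlation undefined). Initialization
is greedy farthest-point seeding from the seeded generator; the best of
n_init = 10 restarts by total within-cluster distance wins; the Lloyd loop
reseeds empty clusters to the worst-fit profile. A brute-force exhaustive
partition search over tiny inputs serves as the test oracle.

Each cluster's template is read off its mean log2 profile relative to BV,
thresholded at |FC| ≥ 2: a direction (down/flat/up) at EV and at H, a class
(down if ever down and never up; up symmetric; mixed profiles are flagged
"other"), and an onset (first non-flat stage). Shift classification is a
pure function of template labels and modulation flags: modulated in C but
not the treatment → non-modulation; modulated in the treatment only → novel
modulation; both modulated with identical labels → no effect; same class
with later onset → delayed; earlier onset → anticipated; class change →
other. With three time points "later" can only mean EV→H. The effect group
summarizes the two treatment shifts: common (both shifted, same class),
different (both shifted, different classes), PB-/V-specific (exactly one),
none. The exact published mapping of cluster pairs to these classes is not
available in any primary text we rely on; the onset-based rule is a
reconstruction and is labeled as such here.

Shift candidates for reporting are genes modulated in at least one condition
with max(|FC(EV/BV)|, |FC(H/BV)|) ≥ 3 somewhere, minus genes already found
by the direct stage-wise comparison; the shift table nevertheless labels
every clustered gene so recovery against planted truth can be measured.

## qPCR

Efficiency (E, per-cycle amplification factor in (1, 2]) is estimated per
well by the window-of-linearity approach: after subtracting the mean of
cycles 1–5 (baseline), every window of ≥ 4 cycles within the positive part
of the curve is fit as log10(F) vs cycle; the window with the highest R²
wins, ties broken toward longer then earlier windows; windows must reach
R² ≥ 0.998 or the curve is rejected as having no exponential phase.
E = 10^slope, clipped into (1, 2] with a flag. Per-gene efficiency is the
mean of its well-level estimates, matching common LinRegPCR usage.

Ct is the fractional cycle at the first threshold crossing, interpolated
linearly in log fluorescence — for an exact exponential this gives
Ct = log_E(threshold/F0) exactly, so doubling the template shifts Ct by
exactly log_E(2). The default plate threshold is 10% of the median
baseline-corrected plateau, which sits inside the exponential phase for
typical efficiencies.

Relative expression against the baseline stage (BV) uses
R = E_target^ΔCt_target / E_ref^ΔCt_ref with ΔCt = Ct(BV) − Ct(stage) and a
constant reference gene; R(BV) = 1 by construction. Replicate uncertainty is
the standard error of per-replicate ratios (each replicate's baseline and
test wells paired by replicate number, SE = sd/√n). This deterministic
summary deliberately replaces randomization-based error propagation — for
three biological replicates it is transparent and adequate, and the
deviation is intentional.

## Phenometrics

Di-hydroxylated anthocyanins = cyanidin-3-G % + peonidin-3-G %;
tri-hydroxylated = delphinidin + petunidin + malvidin percentages (B-ring
3′4′ vs 3′4′5′ substitution). Total leaf area = main + lateral (m² per
vine); leaf-to-fruit ratio = total / yield (m²/kg) — computed from the
definition; printed tables that round differently are not force-matched.
Heat exposure counts readings strictly above the threshold (default 30 °C,
the temperature above which anthocyanin synthesis is thought to decline in
grape) times the uniform sampling interval (default 15 min), in hours.

## Synthetic data

The simulator emulates the study design: 3 treatments x 3 ordered stages x
3 replicates. Gene classes (counts are floors of the configured fractions of
n_genes; the remainder is flat): a control ripening program of down- and
up-modulated genes whose full BV→EV change occurs in every treatment; genes
that follow the program in C and the other treatment but are shifted one
full stage later (EV→H) in PB or in V — delay is modeled as a clean cluster
shift, not an attenuation, since that is what the taxonomy classifies;
genes genuinely up- or down-modulated in exactly one treatment (flat in C);
silent genes planted 2 log2 units below the negative-control mean; and flat
expressed genes. Baseline log2 intensities are uniform on [8, 13]; every
planted modulation has |log2 effect| equal to the configured `effect_size`
(default 2.0) — constant rather than drawn, so recovery statistics are
deterministic functions of the noise; replicate noise is additive
Normal(0, `noise_sd`) on the log2 scale (default 0.2), i.e. multiplicative
on intensities, making planted fold changes exact in the noise-free limit.
Negative controls are 200 log-normal probes per chip (log2 SD 0.5 around a
mean of 100 fluorescence units) — enough to stabilize the per-chip mean. No
public noise or effect-size magnitudes exist for the original arrays; these
defaults are chosen as plausible for normalized oligonucleotide-array data,
not inferred.

What the simulator does **not** emulate: probe-level effects and
normalization artifacts, correlated noise between genes, partial or
heterogeneous delays, dose-dependent effect sizes, and batch structure.
Passing recovery tests therefore demonstrates the correctness of the
analysis logic under the stated statistical model, not field performance on
real arrays. There is likewise no planted class that is modulated in the
control but silent in a treatment, so the "non-modulation" shift class is
exercised by constructed cases in the unit tests rather than by planted
genes.

The qPCR simulator produces F_c = F0·E^c capped at a plateau with
multiplicative log-normal reading noise, a reference gene at constant
template, and per-gene starting-amount ratios between two stages. The
temperature simulator emits evenly spaced readings from a constant or
callable profile with optional Gaussian noise.

## Determinism and problem sizes

A single pipeline seed fans out to named substreams (simulation, SAM
permutations, k-means initialization) so module-level reruns reproduce the
pipeline run; identical configuration and seed give byte-identical output
tables. The demo configuration uses 2000 genes with 1000 permutations for
the multiclass null (the pairwise 3v3 null is always the exhaustive 20
assignments); the null-calibration experiment uses 20 simulations of 10,000
genes. These sizes are chosen so the full analysis and its tests complete in
seconds while keeping every planted class populated well enough for stable
recovery rates.

## Known limitations

* Set-level FDR only; no per-gene q-values (the workflow reports set calls).
* The delta automation's median-FP estimate is anti-conservative at the
  extreme tail on null data (see the SAM section).
* The s0 and FDR variants of the historical TMeV versions are not
  verifiable; the variants implemented here are documented, not asserted
  identical.
* Single-reference qPCR normalization only; no melt-curve analysis.
* No normalization of the expression matrix itself (inputs are assumed
  normalized); an experimental quantile utility is deliberately out of scope.
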