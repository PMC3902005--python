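# Methods

## The statistical model

The unit of inference is the stimulus-response pair (k, j): electrode k is
stimulated, electrode j records. For each pair the pipeline forms

    Z_kj = (1/T) Σ_t N_kj(t) − b_j

where N_kj(t) is the spike count at j in the observation window after the
t-th pulse at k (T = 50 trials) and b_j is the mean spontaneous count of j
over windows of the same length, recorded the same day from the same
culture. b_j is estimated by tiling the whole spontaneous session with
contiguous windows — the deterministic, lowest-variance placement; random
placement is available as an option. The per-electrode (rather than scalar)
baseline is used because spontaneous rates differ strongly across
electrodes.

Entries are modeled as a two-group mixture,

    Z ~ (1 − ε) N(0, σ²) + ε f₁,

and the local false discovery rate is the posterior-like statistic

    T_kj = (1 − ε) f₀(Z_kj) / f(Z_kj),   clipped to [0, 1],

with f the marginal mixture density. Ranking the T's ascending, the
selection keeps the largest prefix whose running mean is at or below the
FDR level (default 0.05); the mean local FDR of the selected set estimates
the expected false-discovery proportion, so the bound is on the average
fraction of spurious pairs among those reported. Ties are broken by flat
matrix index (stable sort) so output is deterministic. The prefix rule is
checked in the test suite against an exhaustive scan over every prefix.

### Estimators

The mixture leaves σ, ε and f free; all three estimators are swappable
keyword arguments.

* **Null scale σ** (`truncated-mle`, default): a robust pilot scale
  (25th percentile of |Z| rescaled for Gaussian consistency) selects the
  central window |Z| ≤ 1.5·σ_pilot; the ML scale of a zero-mean Gaussian
  truncated to that window is then solved numerically (bounded scalar
  minimization on log σ). With well-separated alternatives essentially no
  non-null mass enters the window, so the estimate is nearly unbiased
  (simulations in the test suite: within 0.3% at ε = 0.05). Quantile
  alternatives (`central-mad`, `mad`) are provided; they run 3–6% hot under
  5% contamination, which matters because a few percent of σ bias moves the
  Storey count of ε by its own magnitude.
* **Non-null proportion ε** (Storey): two-sided p-values under N(0, σ̂²);
  ε̂ = max(0, 1 − #{p > λ} / ((1 − λ) p)), λ = 0.5, clipped to
  [0, 1 − 10⁻⁶]. Conservative by the non-null mass with p > λ, which is
  negligible for the effect sizes of interest.
* **Marginal f** : Gaussian KDE with Silverman's bandwidth. The evaluator
  is floored at the smallest positive float and integrates to 1.

**Kernel-matched null.** A KDE of the marginal is the true f convolved with
the kernel; its tails are inflated by the bandwidth h relative to the raw
null density, which makes the raw ratio anti-conservative. The T statistic
therefore evaluates the null at the kernel-convolved scale
√(σ̂² + h²), so numerator and denominator are smoothed identically. In the
200-seed mixture simulation this moves the mean empirical FDP from 0.057
(slightly above the 0.05 budget) to 0.040; pass `kernel_sd=0` to
`local_fdr_statistics` for the unmatched form.

### Diagonal policy

A stimulated electrode's own channel is artifact-dominated. The default
(`diagonal_policy="zero"`) sets Z_kk = 0 and excludes the diagonal from
estimation, ranking and the test count (p = 59·58); `"include"` keeps the
full 59·59 for compatibility.

## Connectivity metrics

Significant pairs form a directed graph on the 59 analysis electrodes.
*Mean connection length* is the arithmetic mean of the Euclidean distances
between the electrode centers of each pair (µm); it is reported as missing
for an empty graph, never as 0. Identified connections may hide
intermediate hops — the metric describes electrode-level, not synaptic,
geometry. *Supernode counts* apply the threshold (≥ 4 significant
connections) per direction — nodes with in-degree ≥ 4 and, separately,
nodes with out-degree ≥ 4 — because incoming and outgoing hub counts are
tracked as separate longitudinal curves; a total-degree variant is
available (`mode="total"`).

## Longitudinal statistics

Batch summaries average each metric per (batch, day, window) over the
cultures recorded that day; SE = sd/√n, 0 for a single culture. Days
without recordings are emitted as flagged gap rows and never interpolated.

The batch-variability ANOVAs make their observational units explicit,
since "within and across batches" admits several designs:

* **across** — one observation per culture (its time-averaged metric),
  factor = batch;
* **within** — per batch, observations are per-day values, factor =
  culture.

One-way fixed-effects ANOVA is computed by `scipy.stats.f_oneway`
(the all-values-identical degenerate case is reported as F = 0, p = 1);
the test suite cross-checks F against explicit sums of squares at 10⁻¹⁰
relative tolerance and verifies uniform null p-values. The
observation-window comparison runs a one-way ANOVA over windows on a
batch's per-day means, followed by Tukey–Kramer pairwise intervals at 95%
(`statsmodels pairwise_tukeyhsd`); a pair is flagged different when its
interval excludes zero.

## The synthetic-data generator

No generative model accompanies the original recordings, so the generator
implements the minimal structure that makes every downstream claim
testable. It is a pure function of (parameters, seed); a single study seed
derives per-session seeds through a documented spawn-key scheme
(`session_seed`), so any session can be regenerated in isolation.

**Latent network.** Development follows a two-phase schedule: ~0 edges for
`quiescent_days` (5), linear growth over `growth_days` (12) to
`plateau_density` (5% of the 59·58 ordered pairs, ≈ 171 edges), then flat,
over a 40-day horizon. Edges are drawn with probability ∝ exp(−d/λ), λ
widening from 150 to 350 µm across the growth phase so mean connection
length rises and plateaus; the range is chosen to keep λ in the regime
where mean edge length on the 1.4 mm grid is actually sensitive to it
(beyond ~700 µm the exponential preference flattens and length saturates).
20% of nodes are designated hubs with a 4× attraction bias, which produces
nodes of degree ≥ 4 (supernodes) by plateau. Per density class the plateau
density scales by √(nominal plated cells / dense cells) — dense cultures
(20 µL × 2500 cells/µL = 50 000 cells) reach full density, small
(5 × 2500 = 12 500) and sparse (20 × 625 = 12 500) reach ~50%.

Functional connectivity in cultures is not static between sessions: a
`core_fraction` (0.3) of each day's edge budget forms a stable backbone
that accumulates and persists; the rest are transient edges redrawn fresh
every day from the same preference. Without this re-expression each culture
would carry a permanent edge-sampling offset in mean length far larger than
its day-to-day variability, and no within-batch ANOVA could ever be
non-significant — static functional graphs are also simply not what MEA
cultures show across days.

**Evoked responses.** Each latent edge k→j carries a weight (uniform on
[0.3, 0.9]) — the probability that one pulse at k evokes one extra spike at
j — and a latency class: direct (0–20 ms, 50%), early post-synaptic
(5–100 ms, 35%), culture-wide barrage (100–250 ms, 15%). The early band is
exposed as a parameter because the upper edge of that latency class is
ambiguous in the source literature. Latencies are uniform within the band;
evoked spikes always follow their pulse.

**Background activity.** Per-electrode Poisson firing at 0.5 Hz plus
network-wide burst epochs (onsets Poisson at 0.1 Hz, 0.3 s duration, 20×
rate multiplier) — the bursting phenotype of dissociated cortical cultures
— present in both spontaneous sessions (60 s by default) and stimulation
sessions.

**Batch structure.** Cultures of a batch share lognormal offsets on plateau
density and length scale (σ = 0.5), with small per-culture jitter
(σ = 0.02). The offsets are deliberately strong: they are the designed
structure whose detection (across-batch significant, within-batch not) the
pipeline is validated against.

**What the generator does not emulate** — and hence what passing tests do
not certify for laboratory data: stimulus artifacts (the blanking option
exists but synthetic data needs none), electrode drift and impedance
variation, refractoriness and short-term plasticity, spike-sorting errors,
inhibitory interactions, and the late-development decline in
responsiveness. Real recordings would exercise the artifact blanking and
likely need a wider empirical null.

## Validation scales

The heavy checks run at these sizes (chosen to keep the full suite within
a few minutes): FDR control and parameter recovery on 200 and 100 simulated
59×59 mixtures; the ranked-prefix selection against an exhaustive oracle on
1000 vectors up to length 10⁴; the developmental-trajectory recovery on 10
full spike-level 40-day cultures (the per-day trajectories are averaged
over the 10 seeds before correlating recovered with latent mean length —
the Monte-Carlo test of the systematic relationship); and the within/across
batch ANOVA pattern on 100 studies simulated at the latent-network level,
where the batch structure lives (spike-level simulation adds detection
noise but no batch information).

## Known limitations

* **Burst-coincidence false positives.** A spontaneous network-wide burst
  that overlaps a stimulation block inflates that block's counts at every
  recording electrode, producing a heavy right tail of the null Z
  concentrated in a few matrix rows. The Gaussian-null local FDR admits
  some of these as discoveries (occasionally dozens on an unconnected day),
  which is why quiescent-phase edge counts are small but not zero and why
  single-day mean lengths are noisy. This is inherent to the method's
  independent-Gaussian null; row-level corrections or resampling nulls are
  outside its scope.
* ε̂ inherits any σ̂ bias amplified ~9×; the truncated-MLE default keeps
  this controlled, but quantile σ estimators should not be combined with
  tight ε tolerances.
* The within-batch ANOVA design (per-day values by culture) is sensitive
  to any persistent per-culture offset; its non-significance depends on
  day-to-day variability dominating, which the core/transient generator
  produces but a different generative regime might not.
* Supernode counts at the default threshold are sensitive to the false
  positives above; they are reported per direction and not corrected for
  multiple days.
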