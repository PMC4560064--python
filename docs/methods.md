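# Methods

## The triplet model and its assumptions

`rmnet` assumes a cooperation–competition system: every candidate
relationship is an ordered triple {cooperator O_m, competitor O_c, target
O_t} of distinct genus-level taxa, and the target's standardized relative
proportion (SRP) is assumed high when the cooperator's SRP is high and the
competitor's is low (and conversely). The assumption is encoded as the
piecewise tanh surface in `nro_core.model_surface`. The surface is
antisymmetric in its two regulators — P(x, y) + P(y, x) = 1, with
P(x, x) = ½ — so both orderings (m, c, t) and (c, m, t) are scored and no
de-duplication is applied. The boundary lines P_m = ½ and P_c = ½ belong to
the additive "otherwise" branch. Because tanh(0.55) ≈ 0.5005, the additive
branch can overshoot [0, 1] by ≈ 5·10⁻⁴; outputs are clamped, which
preserves the antisymmetry exactly.

The method is deliberately rule-based rather than parametric: nothing is
estimated per triplet. A triplet is judged by how far the observed target
series deviates from the fixed surface (lack of fit L), how stable that
judgement is under deleting any single time point (adjustment D, with the
target mean recomputed on the k−1 remaining points — the alternative of
reusing the full-series mean is implemented behind the same interface and
changes little), and the integrated ranking score I = L(1 + D). The gain
constant 1.1 inside the tanh is a fixed model constant, not a tuning knob,
so scores are comparable across analyses.

Numerical conventions: x·log₁₀x is continued by 0 at x = 0; a perfect fit
(L = 0) gets D = 0 (any finite choice only reorders perfect fits); a
leave-one-out subseries that becomes constant contributes no term and emits
a warning; L_d = L/(1−L) is +∞ for L ≥ 1. Constant target series are
rejected outright — an OTU without dynamics cannot participate in a triplet,
and constant-series detection uses the series range (exact zero spread), not
the floating-point deviation sum, which retains rounding residue ~10⁻³³.

## Preprocessing

Order of operations: prevalence filter → relative abundance → rare-OTU
filter → time-point filter → imputation → per-OTU min–max standardization.

* **Prevalence**: drop OTUs observed (positive, non-missing) at fewer than
  half of all time points ("fewer than" is strict; the denominator includes
  missing time points).
* **Rare-OTU filter**: drop an OTU only if its maximum proportion is below
  0.1 **and** its coefficient of variation exceeds 3.4; an all-zero row has
  CV = +∞ and is dropped.
* **Time-point filter**: drop a time point only if its maximum proportion is
  below 0.1 **and** fewer than 60 % of OTUs are non-zero there.
* **Imputation** (K = 5 by default): iterative EM-style low-rank imputation —
  missing cells start at column means and are repeatedly replaced by a
  rank-K truncated-SVD reconstruction of the column-centred matrix until the
  imputed cells move less than 10⁻⁶ (max 500 sweeps). Observed cells are
  never altered; imputed cells are clipped to [0, 1]. This is a
  deterministic point-estimate variant of Bayesian PCA imputation; the
  interface allows swapping implementations.
* **Standardization**: per-OTU min–max scaling across time points, so each
  OTU spans its own high/low regimes. A global min–max would leave rare taxa
  permanently "low" and outside the surface's informative region.

## The simulation benchmark

The generator emulates a small gut community: 10 OTUs driven by 3 latent
factors (i.i.d. Uniform(0, 1) per time point) through a cascade of tanh
response equations whose inter-OTU coefficient signs define the 14-edge
signed ground truth; latent-factor edges are unobservable and excluded from
both truth and candidate universe. Defaults are the benchmark study
conditions: 13 time points, 5000 networks per condition, four noise regimes.

Noise: each OTU receives additive Gaussian noise with scale σ = Var(O_i)/R_i
(low), 5× that (medium) or 10× (high), where Var(O_i) is the sample variance
of that OTU's noiseless series under the same latent draws and R_i is an
integer signal-to-noise ratio drawn uniformly from {4, …, 12} per OTU. The
reference description fixes only the noise magnitude, not its distribution;
zero-mean Gaussian is the conventional SNR model and is isolated in
`noise_sigma`. Equations are evaluated in index order so noisy upstream
abundances feed downstream responses, and every row is clipped to [0, 1] as
produced, keeping abundances valid proportions.

Clipping has one rare side effect: in extreme draws an OTU (typically O5,
whose response argument can stay negative) is flattened to a constant
series. Such an OTU carries no triplet information; the benchmark excludes
it from the scan but keeps the full 10-OTU, 180-candidate universe, so its
edges simply go unpredicted. Simulated abundances are min–max standardized
per OTU before scanning — the same SRP transform real data receives — which
matters: feeding raw simulated abundances (which occupy narrow sub-ranges of
[0, 1]) collapses sensitivity nearly to zero.

What the simulator does **not** emulate: compositional coupling (rows are
not constrained to sum to 1), sequencing depth and count noise, missing
samples, autocorrelated latent dynamics, and taxa numbering in the hundreds.
Passing benchmarks therefore demonstrate that the scoring machinery recovers
tanh-generated directed structure under additive noise — a generating family
deliberately matched to the model's own response class — not field
performance on real compositional count data.

## Evaluation

The candidate universe is every (ordered pair, sign) combination:
2·n·(n−1) = 180 signed links for n = 10 (this is the only universe
consistent with the benchmark's reference confusion arithmetic, e.g.
TPR = 13/14 with accuracy = 155/180). The predicted link set is the union
over retained triplets of {m→t cooperative, c→t competitive}; both signs of
a contested pair enter and are scored independently. This union is monotone
in the L_d threshold, which yields the guarantee that TPR is nondecreasing
and TNR nonincreasing as L_d relaxes. (Resolving conflicts at evaluation
time — as `build_network(conflict="permissive")` does for the network
artifact, where a pair may not carry both signs — can flip an edge's sign
when the threshold relaxes and breaks that monotonicity; the two policies
are therefore kept distinct.)

Metrics are TPR, TNR, their harmonic mean (the F-measure here — not the
precision-recall F1), and accuracy. A network's *efficiency* is the largest
value attained by at least three of the four measures, i.e. their
third-largest order statistic. "Best performance" across simulated networks
is reported two ways: per-measure maxima, and the single best network
selected by F-measure (the one summary that balances sensitivity and
specificity); the latter is the network re-evaluated across the threshold
grid in the relaxation analysis. The Pr analysis computes, over retained
triplets carrying at least one true-positive link, the share whose
cooperator–target Spearman correlation is below 0.5 or whose
competitor–target correlation is above −0.5 — regulatory pairs a
correlation-threshold network would miss. Which networks contribute those
triplets is a free choice; the `rmnet pr` command uses the best-accuracy
network per threshold pair.

## Problem sizes and determinism

The shipped benchmark configuration is 5000 networks per noise regime at 13
time points — the full scan of one network (720 triplets including all
leave-one-out refits) is closed-form array work and takes under a
millisecond, so a four-regime benchmark completes in well under a minute.
One master seed spawns per-dataset substreams, making every dataset
individually regenerable and the whole benchmark reproducible; the
triplet pipeline itself is seedless and deterministic, with ranking ties
broken by (I, L, m, c, t).

## Known limitations

* The per-measure best F at the strict (0.8, 0.8) thresholds saturates
  around 0.85–0.88 on noiseless/low-noise simulations: networks recovering
  ≥ 13 of 14 true links always carry roughly 40+ false positives in this
  generator, so joint sensitivity/specificity beyond that frontier is not
  attained at any simulation size we ran (checked up to 50 000 networks).
* The method cannot represent purely pairwise (two-OTU) regulation: every
  retained relationship comes with both a cooperator and a competitor.
* Triplet scores carry no significance calibration (no permutation
  p-values); thresholds on L_d and D are the only gate.
* Validation is partially circular by construction: the benchmark generator
  and the inference surface share the tanh response family.
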