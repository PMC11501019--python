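# Methods

This note documents the models, estimators, numerical choices, and
known limitations of `obpc`.  Notation: X, Y are the two nodes of a
pair (OB and PC within one hemisphere); f is frequency in Hz; t is time
in seconds relative to odor arrival at the nose.

## Synthetic study generator

The generator exists because the human EEG/EBG source-space recordings
the analysis was designed for are not publicly available.  It emulates
the *structure* of such a study — not its biophysics — so that every
downstream stage can be validated against known ground truth.

**Ratings.**  Each trial draws a hidden affect class uniformly
(unpleasant/pleasant); the valence rating is truncated-normal on
[0, 100] with class means 25 and 70 and SDs 9 and 12, giving the
bimodal, ~45-point-separated distributions of the emulated studies.
Intensity is drawn from one shared truncated Normal(50, 10) so that it
carries no class information; an intensity-based re-analysis therefore
acts as a negative control.  Analyses never see the hidden class: they
re-derive classes from the per-participant rating tertiles, exactly as
the pipeline does.

**Epochs.**  Each ROI carries unit-variance 1/f^α background noise
(α = 1 by default), independent across trials and ROIs, generated by
spectral shaping of white Gaussian noise.  Communication is injected by
coupling components.  Each component has a carrier: a stationary
stochastic narrowband oscillation (an AR(2) process with complex poles
at the component frequency, pole radius 0.85, normalized to unit
variance).  The source node receives the carrier under a Gaussian
envelope (center time, SD as configured); the target node receives the
same enveloped carrier delayed by the transmission lag and scaled by
the gain of the trial's valence-tertile class (middle tertile: mean of
the extreme gains).  A stochastic carrier rather than a fixed sinusoid
is essential for directionality: a deterministic narrowband burst is
predictable from either channel over tens of milliseconds, so its
delayed copy generates *bidirectional* Granger causality; with an AR(2)
carrier the innovations enter the source first and propagate to the
target, making the injected causality genuinely directional while the
shared carrier still produces within-trial coherence with random
per-trial phase.  The pole radius trades band specificity against
directionality (radius → 1: narrower band, longer predictability
horizon, more reverse-direction leakage).

**Default coupling layout** (the communication structure under test):

| component | direction | f (Hz) | center (s) | env. SD (s) | lag (ms) | radius | band filter | amp | gain U / P |
|---|---|---|---|---|---|---|---|---|---|
| gamma | OB→PC | 65 | 0.15 | 0.05 | 20 | 0.75 | HP 40 Hz | 0.85 | 0.85 / 0.28 |
| mid beta | PC→OB | 15 | 0.60 | 0.08 | 40 | 0.85 | LP 30 Hz | 0.40 | 0.40 / 0.14 |
| late beta | PC→OB | 15 | 0.85 | 0.08 | 40 | 0.85 | LP 30 Hz | 0.40 | 0.40 / 0.14 |
| theta | PC→OB | 6 | 0.90 | 0.12 | 50 | 0.85 | LP 20 Hz | 0.22 | 0.17 / 0.06 |

Amplitudes are relative to the unit-SD background.  The
band/direction/timing layout encodes the hypothesis being tested (early
gamma feedforward, later beta feedback around the inhalation peak); the
amplitudes are a **calibration**, not an empirical value: they were
chosen once, by a sweep, so that searchlight decoding accuracy at the
injected points lands around 0.8–0.9 for 20 participants × 60 trials —
the range human studies report for such decodings — and frozen.

Three constraints shape the per-component carrier parameters.  (i)
*Directionality*: the transmission lag must exceed the carrier's
predictability horizon (≈ −1/ln r samples for pole radius r), otherwise
the target's past helps denoise the shared carrier and the estimated
causality leaks into the reverse direction — an inherent property of
shared-signal-plus-noise coupling (the classic latent-variable caveat
of Granger analysis), which can be made small but never exactly zero.
(ii) *Coherence*: at 65 Hz the adaptive analysis window is only ~58 ms,
so the lag must stay well below it or the window-overlap correlation —
which carries the decodable coherence — collapses; the gamma component
therefore pairs a short 20 ms lag with a broad (radius 0.75,
"broadband gamma") carrier, while the slow components afford 40–50 ms
lags under their ~250+ ms windows.  (iii) *Band confinement*: AR(2)
spectra have heavy polynomial tails (a radius-0.75 gamma carrier holds
~10 % of its power below 25 Hz), and a tail is *really transferred*
source→target, smearing the injected directionality across bands; each
carrier is therefore confined with a causal 4th-order Butterworth
filter (gamma high-passed at 40 Hz, beta/theta low-passed at 30/20 Hz),
which suppresses out-of-band power by 1–2 orders of magnitude while
adding only ~0.05 to the lag-horizon autocorrelation.

**Breathing.**  Raised-cosine inhalation per trial, peak time
~Normal(0.91 s, 0.05 s) (matching the reported group inhalation peak),
amplitude ~Normal(362, 225) in arbitrary thermistor-like units so the
area under the inhalation is ≈145; amplitude is class-independent by
default, with an optional class shift for power analyses.

**What the generator does not emulate** — volume conduction and source
leakage, participant-specific spectra and SNR heterogeneity, odorant
identity, breathing–neural coupling, non-stationary background, rating
drift.  Passing tests therefore demonstrate the *estimators'*
correctness and calibration under the assumed communication model, not
robustness to every property of real source-reconstructed EEG.

**VAR oracles.**  Bivariate VAR(p) processes provide closed-form ground
truth: transfer function H(f) = (I − Σ_k A_k e^{−i2πfk/fs})⁻¹, spectral
matrix S(f) = H Σ H*/fs (two-sided PSD; the one-sided integral of S_xx
over [0, Nyquist] is half the process variance), autocovariance via the
companion-form discrete Lyapunov equation, and Geweke causality
directly from (H, Σ).  Simulated realizations discard a 1000-sample
burn-in.

## Spectral estimation

**Time–frequency transform.**  At target frequency f the window length
is T_f = max(n_cyc/f, (K+1)/(2 W_f)) with n_cyc = 2, K = 2 DPSS tapers,
and half-bandwidth W_f = 0.4·f ("80 % of f" total smoothing
interpreted as total bandwidth 0.8·f, the convention of the standard
EEG toolboxes; configurable).  Since (K+1)/(2·0.4f) = 3.75/f > 2/f, the
bandwidth term always binds, so T_f = 3.75/f on the default grid.
Windows are unit-energy; |X|²/fs estimates the two-sided PSD.  Windows
that would cross an epoch boundary yield missing (NaN) cells rather
than zero-padded estimates, to avoid low-frequency edge bias; at 4 Hz
(T = 937.5 ms) only centers within roughly ±0.47 s of the epoch
interior are valid.

**Grids.**  The default analysis grid is 4–100 Hz in 1 Hz steps and
−0.4–1.4 s in 25 ms steps, chosen so the 11×11 searchlight spans
11 Hz × 275 ms.  Simulation-heavy validation uses coarser grids (5 Hz ×
50 ms for null calibration, 3 Hz × 50 ms for effect recovery); grid
spacing is an analysis parameter and the validation conclusions do not
depend on it.

**Coherence.**  Magnitude coherence (not squared) over trials × tapers,
per hemisphere pair, then hemisphere-averaged (the hemisphere averaging
is stated for the causality analysis in the emulated design and applied
to coherence as well, as an interpretive choice).  Under independence
of m estimates the null obeys P(C > c) = (1 − c²)^(m−1), giving the
closed-form 5 % quantile sqrt(1 − 0.05^(1/(m−1))) used for calibration
checks.  Because that quantile is exact, the *fraction* of null cells
below it fluctuates around 0.95; the calibration test asserts equality
with 0.95 within Monte Carlo error rather than a one-sided ≥ 95 %,
which a correctly calibrated estimator would fail half the time.

**Cross-spectra for causality.**  One 1 s window over the stimulation
period, T·W = 5 (±5 Hz smoothing), K = 7 DPSS tapers (2TW − 1 = 9 ≥ 7),
averaged over trials and tapers; the full 0–256 Hz grid at 1 Hz is
retained because the factorization needs 0 and Nyquist, while reporting
is restricted to 4–100 Hz.

## Spectral Granger causality

**Wilson–Burg factorization.**  S(f)·fs is factorized on the full
frequency circle (Hermitian extension) as ψψ* with ψ minimum-phase,
iterating ψ ← ψ·[ψ⁻¹Sψ⁻*+I]₊, where []₊ keeps non-negative lags (lag 0
halved and upper-triangularized).  Initialization: Cholesky factor of
the zero-lag autocovariance.  Convergence: relative update < 1e-9
(analytic inputs reach it in tens of iterations) or a stall of the
update norm — estimated spectra admit no exact causal factorization of
restricted lag order, so the iteration settles into a small limit
cycle, which is detected and accepted as the stationary point; the
reconstruction residual is always reported.  Channels are
power-equalized internally (a diagonal rescaling, exactly undone on
output): without it the max-norm convergence test is dominated by the
stronger channel and badly scaled inputs (e.g., one channel ×250)
produce invalid factors.  With it, causality estimates are invariant to
channel scaling to ~1e-14.

**Geweke causality.**  F_{y→x}(f) = ln[S_xx/(S_xx − (Σ_yy −
Σ²_xy/Σ_xx)|H_xy|²)], clipped at 0 within 1e-12; any constant spectral
scaling cancels.  Validation: on analytic VAR spectra the factorization
reconstructs S to ≤ 1e-6 and recovers Σ to ≤ 2 %; on 200 simulated 1 s
trials the estimated causality matches the analytic value within 15 %
at the spectral peaks, and a structurally absent direction estimates
below 1e-3 nats at the peak and on the frequency average.  (The
*maximum* over all 257 bins of the null direction is noise-limited
around 1–3 × 1e-3 at this sample size and is not a meaningful target.)
Geweke's decomposition of the total interdependence ln(S_xx S_yy/det S)
into the two directed terms plus the constant instantaneous term
ln(Σ_xx Σ_yy/det Σ) is asserted as the integral (frequency-mean)
identity it is; pointwise it does not hold.

**Group contrast.**  Per participant and condition the pipeline runs
CSD → factorization → Geweke → hemisphere average; the group statistic
is a paired two-tailed t per frequency of (unpleasant − pleasant), with
maximal runs of p < 0.05 bins reported as clusters (peak f, peak t,
paired Cohen's d = mean diff / SD of diffs).  No cluster-mass
correction is applied; clusters are a display of pointwise
significance.

## Searchlight decoding

**Features.**  Per participant, coherence maps are averaged within each
extreme valence class (middle tertile excluded) and hemisphere-
averaged.  At each grid center the ±5-bin neighborhood in f and t (121
bins in the interior, truncated at edges) is flattened; centers whose
neighborhood holds fewer than 10 valid bins are excluded ("valid bins
in the searchlight" reading; the alternative adjacent-bins reading is
available behind `neighbor_rule="valid_adjacent"`).  Missing cells are
excluded from the feature vector, never imputed.

**Classifier.**  Linear SVM, C = 1, features standardized by
training-fold statistics (label-independent, hence shared across
permutations).  Leave-one-participant-out: each fold trains on
2(P−1) samples and predicts the held-out participant's two class maps,
so fold accuracy is 0, 0.5, or 1, and the group map A(f,t) is the mean
over participants.  Decision ties predict the first class in label
order.  The solver is an L1-loss dual coordinate-descent SVM with the
bias absorbed as a constant feature, compiled with numba; a permutation
searchlight needs ~10⁶–10⁷ fits, which rules out a per-fit call into a
general-purpose library.  Its predictions are checked against
scikit-learn's SVC(kernel="linear", C=1) in the test suite (≥95 %
fold-prediction agreement on random problems; disagreements occur only
at near-boundary decisions).  A degenerate training fold (all feature
vectors identical) yields a zero decision function and accuracy 0.5 by
the tie rule.

**Permutation test.**  Each permutation independently swaps the two
class samples of each participant with probability ½; p = (1 +
#{A_perm ≥ A_obs})/(1 + n_perm), default n_perm = 5000.  The same
permutation draws are shared across grid points.  Optionally the test
runs sequentially (Besag–Clifford): sampling at a point stops once
enough exceedances have accumulated that p < α is impossible, in which
case p = exceedances/draws is reported.  The significance decision at α
is *exactly* that of the fixed-n test; only the reported p at
non-significant points is coarser.  This is what makes
simulation-based false-positive calibration affordable.  The 95 %
Monte Carlo CI width 2·1.96·√(p(1−p)/n) is reported per point.
Permutation testing can be restricted to an a-priori (f,t) region
(`region_mask`), the standard practice when hypotheses are regional;
the validation suite uses it for the injected-effect windows.

**Clusters, ROIs, controls.**  Significant points (p < 0.01) form
4-connected clusters.  ROI summaries (early gamma 50–100 Hz,
0.05–0.25 s; mid beta 10–20 Hz, 0.5–0.7 s; late beta 10–20 Hz,
0.75–0.95 s) report per-participant mean accuracy and a row-normalized
confusion matrix aggregated over ROI points and folds.  The intensity
control reruns the identical pipeline with intensity-tertile labels and
reports the count and Jaccard index of jointly significant points
against the valence mask.  A per-node OLS of ROI accuracy on mean
log-power (statsmodels) checks that decoding is not a power artifact.

**Confusion asymmetry.**  With one test sample per class per fold, the
margin of a linear SVM is symmetric between classes, so a homogeneous
gain asymmetry alone does not bias the confusion matrix (systematic
simulation across gain regimes found differences of ±0.02 with
inconsistent sign).  What does bias it is representational
*consistency*: when the unpleasant coupling sits at the same
time–frequency locus in every participant while the pleasant coupling's
locus varies across participants, the learned boundary aligns with the
stereotyped unpleasant pattern and the idiosyncratic pleasant maps fall
on its wrong side more often — unpleasant row accuracy exceeds pleasant
row accuracy, the qualitative asymmetry reported for real data (and
consonant with its account of early gamma carrying specifically
aversive content with larger individual variation for pleasant
percepts).  The validation suite asserts exactly this construction;
under the default homogeneous design the asymmetry is within noise.

## Statistical kernel

Student t tests (paired and classical pooled-variance two-sample;
Welch off by default, switchable) implemented in closed form with exact
df, two-tailed p, 95 % CI, and Cohen's d (paired: mean diff / SD of
diffs); verified against scipy to 1e-10 and against noncentral-t power
predictions within 3 percentage points at 1000 replicates.  The
breathing comparison integrates each trial's inhalation by trapezoid
from onset to return-to-baseline (trace ≤ 5 % of peak, a relative floor
because thermistor units are arbitrary), averages per participant and
class, and applies the paired t.

## Pipeline, seeding, determinism

One master seed is split with `numpy.random.SeedSequence.spawn` into
per-stage generators (simulate/preprocess/coherence/decode/granger/
report), so every run is bit-identical under a fixed seed; the manifest
records parameters, package version, and content hashes of the epochs
and result maps, and the smoke validation asserts manifest equality of
two independent runs.  Defaults follow the emulated design wherever it
states a value: 50 Hz notch, |z| > 7 rejection, more-than-half
exclusion, tertile classes, 200 ms onset correction, 4–100 Hz, 2/7
tapers, 0.8·f and ±5 Hz smoothing, 121-sample searchlight, 10-neighbor
rule, 5000 permutations, p < 0.01 decoding clusters, p < 0.05 causality
clusters.

## Validation problem sizes

The validation suite runs (sizes chosen as a compromise between
statistical resolution and a test suite that completes in minutes):
Granger oracles at 200 trials × 1 s; coherence null at 40 trials × 2
tapers (m = 80), 10 realizations; decoding false positives on 50 null
replicates of 20 participants × 60 trials on a 20 × 20 grid with 200
permutations (grand-mean accuracy pooled across replicates must lie in
[0.47, 0.53]; pooled fraction of p < 0.01 points ≤ 0.02); effect
recovery on 20 replicates of the default design (injected centers must
lie in significant clusters in ≥ 90 % of replicates; forward-direction
causality detected in ≥ 90 %; reverse-direction in-band significant-bin
rate ≤ 2× the nominal α = 0.05, i.e., consistent with no true reverse
effect — demanding literally zero reverse bins per replicate would fail
for a correctly calibrated test); confusion asymmetry on 10 replicates
of the high-gain construction.  `scripts/acceptance.py` recomputes the
same quantities at reduced replicate counts (stated in its JSON output)
to stay well inside a 20-minute budget.

## Known limitations

- Bivariate causality only; no conditional/multivariate extension, no
  time-varying causality, no bootstrap confidence bands.
- Pointwise significance with cluster display; no cluster-mass or
  max-statistic correction by default (max-statistic permutation is a
  natural extension of the existing machinery).
- The generator's homogeneous-participant assumption makes group
  statistics better behaved than in real cohorts; effect sizes from
  synthetic runs should not be read as forecasts for real data.
- Magnitude coherence only; no bias-corrected or imaginary-part
  variants.
- The linear SVM is the only decoder; kernels would require replacing
  the fast dual solver.
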