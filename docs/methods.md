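# Methods

This note documents the models and procedures implemented in `placestim`,
the assumptions behind them, the parameters that matter, and the design
choices made where the problem was genuinely open. Everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Task and session model

A session is a continuous timeline spanning four epochs — baseline (15 min),
pre (5 min), stimulation (10 min), post (5 min) by default — of trials on a
200-cm virtual linear track. Task rules, enforced by the simulator and
re-checked by an independent replay oracle in the tests:

* reward requires ≥ 3 s in the reward zone (160–178.6 cm) and ≥ 3 in-zone
  licks;
* the 11th lick outside the reward zone ends the trial instantly
  (`fail_lick`);
* running into the back wall ends the trial (`fail_overshoot`);
* correct trials are followed by a ≥ 5-s dark timeout, failures by a ≥ 10-s
  white timeout, and licking stops ≥ 3 s before the next trial.

During the stimulation epoch, crossing the 105-cm trigger point starts a
1045-ms photostimulation bout: five spatial clusters of targets illuminated
100 ms each with 5-ms gaps, cycled twice.

## Synthetic behavior

Running is piecewise-constant-velocity (2-s segments, N(15, 3) cm/s clipped
to [6, 35]) with a stochastic stop inside the reward zone on correct trials
and either a mid-track "false stop" with a lick burst (lick failures) or a
run into the wall (overshoots) otherwise. Licking is Poisson: 4 Hz while
waiting in the reward zone, 0.15 Hz elsewhere, with an optional planted
stimulation-zone lick surge for behavioral-effect tests.

The per-trial start latency (Exp, mean 10 s) was chosen analytically so the
expected trial cycle is ~31 s: with a 61% success rate, mean running speed
15 cm/s, 3.5-s reward dwell and the 5/10-s timeouts, the expected cycle
without latency is ~21 s, and 600 s / 31 s ≈ 19 completed trials per
10-minute stimulation epoch, matching the observed trial economy of the
task. Measured across 30–200 seeds the simulator yields 19.3–19.8 good
trials per stimulation epoch.

## Synthetic calcium

Each neuron emits transient events from an inhomogeneous Poisson process.
Place cells have a Gaussian event-rate bump over position (SD 6–12 cm,
in-field rate 2.5 events/s) active while the animal moves; all cells share
a 0.05 events/s floor. Events convolve with a single-exponential calcium
kernel (decay 0.4 s, instantaneous rise — adequate at frame-rate
resolution), and raw fluorescence is F0·(1 + ΔF/F + noise) with per-frame
Gaussian noise (SD 0.05) and F0 ~ U(80, 120).

Planted structure, all recorded as ground truth:

* **Zone cells.** Start-PC and Reward-PC counts default to 44 and 49 of 162
  place cells (27% of 600 neurons). A planted cell's zone label is derived
  from its *map-level* field extent — the rate bump widened by the 3-bin
  smoothing kernel plus the calcium tail (speed × decay ≈ 6 cm dragged in
  the running direction) — using the same > 50%-coverage rule as the
  classifier; draws with ambiguous coverage (40–60%) are redrawn so labels
  are unambiguous by construction. Field centers stay within [5, 174] cm:
  correct trials end at the in-zone stop, so later bins are visited only on
  overshoot trials and fields there are undetectable under the velocity
  filter. (The same occupancy cliff is why analyses of real sessions crop
  the track end.)
* **Stimulation responses.** Each target (and optional planted off-target
  responders near beamlets) emits a transient of `response_amp` (default
  0.6 ΔF/F) with per-trial probability `response_prob` (default 0.8) at the
  end of each of its cluster's two illuminations. The default evoked
  amplitude is below the endogenous in-field amplitude range (0.6–1.5),
  keeping the manipulation within the physiological ordering observed
  in vivo; a test asserts this calibration.
* **Suppression / enhancement.** Chosen non-target place cells with fields
  just past the stimulation zone (129–150 cm) have their transient
  amplitudes scaled by 1 ∓ magnitude (default 0.5) from bout onset to trial
  end on stimulation trials.
* **Remapping.** `post_shift_cm` displaces a category's field centers in
  the post epoch; `remap_fraction` re-draws centers between baseline and
  pre (for stability-filter tests).

What the generator does **not** emulate: imaging frames and true optical
artifacts (an artifact *mask* stands in for the frames a real recording
would need subtracted), neuropil and motion artifacts, theta-timescale
dynamics, shared trial-to-trial gain fluctuations beyond what position
tuning induces, and within-session learning beyond the planted parameter
changes. Passing recovery tests therefore validate the analysis logic and
its statistical calibration, not robustness to every nuisance in real data.

## Numerical choices

* **ΔF/F baseline.** F0(t) is the 8th percentile of a 10-s window centered
  on frame t, truncated at the recording edges. The incremental
  sorted-buffer implementation reproduces `numpy.percentile` bit for bit
  (including its two-branch linear interpolation); a brute-force per-frame
  oracle asserts exact equality.
* **Map smoothing.** Normalized (truncated-kernel) Gaussian convolution:
  unoccupied bins carry NaN, contribute nothing, and the kernel is
  renormalized over the bins present; no wraparound (the track is linear).
* **Strict thresholds.** The responsive criterion (> 0.40 ΔF/F on > 30% of
  trials) and the > 50% zone coverage use an epsilon guard so a value at
  exactly the printed threshold never passes through float summation error.
* **Factor analysis.** `sklearn` maximum-likelihood factor analysis on
  standardized columns (i.e. the correlation matrix), LAPACK SVD path so
  repeated fits are bit-identical, no rotation (scores feed a
  rotation-invariant Euclidean distance), uniqueness floored at 0.005 on
  Heywood cases. Its `transform` is the regression (Thomson) score
  estimator.
* **COM records.** The remapping COMs are computed on the trial-averaged
  map minus (baseline + 25% of the baseline-to-peak range) — the same floor
  field detection uses. Without it, the flat ΔF/F offset left by the
  percentile baseline plus clipped noise mass drags every COM toward the
  track center and shrinks planted shifts by ~10%.
* **Permutation p-values** use the add-one convention
  (1 + #{null ≥ obs}) / (n + 1), which is valid (conservative) under the
  null; calibration tests check near-uniformity where the statistic's grid
  is fine enough.

## Latent analysis design

The population matrix holds per-cell z-scores averaged into 2.27-cm bins
per trial, for the pre and stimulation epochs, place cells only. Three
choices here were driven by null-calibration simulations (sessions with the
stimulation light on but every planted effect set to zero):

1. **Frame-level artifact removal.** Frames acquired during bouts are
   dropped before binning; a (trial, bin) pair contributes a row only if it
   retains clean frames. Excluding whole bins whenever *any* trial's bout
   covered them would delete ~105–131 cm — the bout's spatial extent scales
   with running speed — which is exactly where the divergence effect lives.
2. **Symmetric z statistics.** Each epoch's per-cell mean/SD exclude the
   position band the bouts censor, in *both* epochs. Otherwise cells tuned
   to the stimulation zone lose their in-field frames from the stimulation
   epoch's statistics only, acquiring a spurious between-epoch z offset at
   every bin (null divergence detection was ~100% before this fix).
3. **Coverage rule for detection bins.** Divergence-detection bins require
   ≥ 80% of the trials that traversed them to have clean frames; bins the
   bout still covers on slower trials would otherwise compare a
   speed-selected subset of stimulation trials against all reference
   trials, and traversal speed shapes the spatial calcium profile (the
   faster the run, the longer the calcium tail in position).

**Divergence detection.** The reported curve is the Euclidean distance
between trial-averaged 10-D score trajectories per bin, with per-bin
two-sided sign-rank tests of per-trial distances against each trial's
average over the ten pre-zone bins, and contiguous significant runs
(reported with per-bin p-values and no multiplicity correction, and a known
positive bias: post-zone bins carry more trial-to-trial score variance than
pre-zone bins). The session-level *detection* statistic is therefore
different: the noise-corrected squared distance between trial-averaged
trajectories — Σ over the first 8 covered post-zone bins of
(‖Δmean‖² − Σ_k(s²ₐ/nₐ + s²_b/n_b)) — against an epoch-label permutation
null (trials are exchangeable between epochs under no perturbation).
Calibration simulations at the power-study conditions measured ~0.9 power
with planted perturbations at default magnitudes and a ~5–10% null rate at
α = 0.05. The 8-bin window matches the expected perturbation footprint:
evoked-calcium residue plus the suppressed-field region span roughly 18 cm
past the censored zone, beyond which reward-approach variability dominates.

**Perturbation scores** average the stim-minus-pre trial-averaged activity
over the three uncontaminated bins centered at 136 cm; suppressed/enhanced
cells are the within-session bottom/top deciles among eligible cells
(max |loading| ≥ 0.2 and pre-zone activity difference ≤ 0.2 SD).

## Problem sizes

Defaults reproduce the recorded cohort (600 neurons, 27% place cells,
15/5/10/5-min epochs). Power and null-calibration studies run on 20-session
cohorts with 170 place cells (the per-session place-cell scale of such
experiments), 49 reward-zone targets, 12 suppressed + 8 enhanced planted
cells, and 4/5/10/2-min epochs; recovery checks for detection and
classification run on one full-size default session. Permutation tests use
500–1,000 draws in the suite and 4,000–10,000 in reporting contexts; the
deceleration block-shuffle default remains 100,000, configurable.

## Known limitations

* The per-bin sign-rank divergence tests are reported uncorrected and
  carry the positive bias described above; only the permutation-based
  session-level detection is calibrated.
* Suppression planted as a pure amplitude scaling is partially absorbed by
  per-epoch z-scoring (a uniformly scaled signal has the same z-profile up
  to the noise floor); the decile analysis still recovers it through the
  noise-floor asymmetry, but weaker multiplicative effects than the default
  magnitude may be invisible by construction.
* Zone classification near the coverage boundary is genuinely ambiguous;
  the generator avoids planting ambiguous cells, so classification accuracy
  on synthetic sessions does not measure boundary behavior.
* `fail_overshoot` is assigned to any unrewarded trial within the lick
  budget (the only task-legal way such a trial can end); truncated trials
  never occur because the simulator ends sessions in an inter-trial
  interval.
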