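# Methods

This note documents the models, defaults and design choices behind
`brainstates`, and what the synthetic-data tests do and do not establish
about real data.

## Time-by-time similarity and the subtraction matrix

Each fMRI volume is represented by its spatial pattern over parcellated
nodes. The similarity matrix correlates patterns *across nodes* (not across
time): entry (i, j) is the Pearson correlation between the length-`N`
activity vectors at volumes i and j. Cortical and subcortical parcels are
concatenated without weighting. Volumes are 1-based; with the default
timing (TR = 2 s, injection at the end of minute 8) the last pre-injection
volume is 240, so pre = volumes 1–240 (8 min) and post = 241–840 (20 min).
The subtraction matrix is the group-mean drug matrix minus the group-mean
placebo matrix with the diagonal forced to zero; entries lie in [−2, 2].
Per-volume spatial correlations are invariant to positive affine rescaling
of a volume's pattern, which the test suite asserts as a property.

## Substate detection

**Thresholding.** The sweep covers Pearson-difference thresholds 0.20–0.30
in steps of 0.01. Entries ≥ r are kept *at their value* (weighted, not
binarized — the common Brain-Connectivity-Toolbox usage);
everything else, including all negative entries and the diagonal, is
zeroed. Positive-only thresholding targets periods of higher similarity
under the drug; an absolute-value variant is available behind a flag.

**Louvain.** Community detection maximizes signed-weight modularity on the
dense modularity matrix. With `W± ` the positive/negative parts,
`k± = W± 1`, `s± = 1ᵀW± 1` and `B± = W± − γ k± k±ᵀ / s±`:

* symmetric treatment: `B = (B⁺ − B⁻) / (s⁺ + s⁻)` — positive and
  negative contributions weighted equally;
* asymmetric treatment: `B = B⁺/s⁺ − B⁻/(s⁺ + s⁻)` — negative weights
  down-weighted.

After positive-only thresholding the two coincide with Newman modularity;
both are kept because the asymmetric variant is the designated control
path on signed inputs. Optimization is locally greedy node moving with
community aggregation, restarted `n_restarts = 100` times from seeded
random node orders; the maximum-Q partition wins, ties go to the first
encountered, and within a pass ties in the move gain go to the
lowest-index community. Zero-strength volumes are excluded from
optimization and returned as singleton substates. The implementation is
cross-checked in the tests against igraph's independent multilevel Louvain
on nonnegative graphs (identical partitions and Q on planted blocks). A
hand-rolled optimizer is used because the signed-modularity variant is the
method's defining quality function and no installed library provides it.

**Occupancy, separability, selection.** Occupancy divides a substate's
volume count in a period by the period's assigned volume count; minutes
are occupancy × period duration (8 / 20 min by default), with a 1-decimal
rounding helper for reporting. The separability index is the Pearson χ²
of the k×2 state-by-period contingency table; per-state tests use 2×2
tables (state vs rest × pre/post) without continuity correction — counts
are hundreds of volumes, and this matches common MATLAB usage. Whether the
published separability index is the omnibus k×2 statistic or a sum of
per-state 2×2 statistics is ambiguous; the omnibus reading is the default
and `method="sum"` exposes the alternative. A substate is retained when
its per-state p < 0.05 and it occupies ≥ 10% of either period. The sweep
selects the threshold with the most retained substates; ties break by
larger omnibus χ², then by the smaller threshold (the tie-break is this
package's choice — only the winning threshold is constrained by the
published analysis).

**k-means control.** Rows of the subtraction matrix are clustered with
k-means (default k = 3, 10,000 iterations, 10 replicates, best
within-cluster sum of squares). k is a config input; silhouette/elbow
model selection is out of scope.

## Activation maps and contrasts

The β GLM regresses each node's time series on one indicator per substate
with **no intercept and no nuisance regressors**, making β(node, state)
exactly the node's mean activity in that state (an algebraic identity the
tests assert on random inputs). z-maps reference the whole-scan mean/SD by
default; excluding the state's own volumes is a flag (the "rest of the
scan" reference is ambiguous). Paired t contrasts are computed per
substate with BH-FDR across nodes *within* the substate; nodes with
zero-variance paired differences are flagged rather than silently dropped
(t = 0, p = 1 if the mean difference is zero, else ±∞ / 0).

## Heart rate

The chain accepts any sampling rate, decimates to 250 Hz (polyphase,
anti-aliased) — matching a 5 kHz recording low-passed at 250 Hz — then:
rectification (negatives to 0; idempotent), stationary-wavelet band-pass
reconstruction (db4, detail levels whose dyadic pass-bands intersect
5–32 Hz, the standard QRS band; family and levels are configurable since
the original semi-automated procedure is not reproducible), peak detection
(minimum height 7,500 µV, minimum inter-beat distance 0.45 s; closer peaks
resolved by keeping the larger, ties to the earlier — deterministic
`findpeaks` semantics), instantaneous HR_t = 60/RR_ij as a
piecewise-constant 250 Hz signal (nearest RR extended before the first and
after the last peak to avoid edge gaps), then per-volume means over
non-overlapping TR windows ("down-sampling" is unspecified beyond the
rates; window means are robust). Windows without samples are NaN and are
excluded from state means.

## Synthetic cohort

The generator emulates the paired study design: 14 participants, 112
nodes, 840 volumes at TR 2 s, injection volume 240. The drug condition
carries five pattern-states tiling the scan (two pre-injection, three
post), identical windows across participants; the placebo condition
carries a two-pattern baseline alternating every 10 volumes, misaligned
with the drug windows. This makes the subtraction matrix block-positive
within drug-state windows at zero and moderate noise alike. A design in
which both conditions share windows and differ only in pattern amplitude
was considered and rejected: Pearson correlation is scale-invariant, so at
zero noise such a design produces an exactly zero subtraction matrix and
no recoverable structure. Noise is i.i.d. Gaussian per node and volume
(default sd 0.5 against unit-variance patterns); real BOLD autocorrelation
is deliberately not modelled, so recovery results speak to the pipeline's
correctness, not to its power on autocorrelated data. Regional condition
effects (default ±1 on 5 nodes each, drug condition, post-injection only,
per-participant amplitude sd 0.3) feed the contrast and ROI stages.

Heart rate is planted as a constant baseline (70 ± 5 bpm across
participants) with a post-injection increase under the drug
(+12 ± 3 bpm). EKG traces place a Mexican-hat QRS surrogate (80 ms main
lobe, 15,000 µV peak) at cumulative RR times; the wavelet band-pass
attenuates this template to roughly 60% of its amplitude, so the 15,000 µV
default keeps detection comfortably above the 7,500 µV criterion.

VAS ratings live on the 0.01 grid in [0, 1]. A coupled item's
drug-minus-placebo change is `0.2·c·z(source) + noise_sd·η` plus
independent per-condition rating noise; the 0.2 scale and item baselines
U(0.40, 0.60) were calibrated so that the observed change-vs-source
correlation sits near `c` at the default noise level while keeping
boundary clipping rare. Exact correlation of 1 at zero noise is
unattainable by construction (grid quantization and clipping); the
achieved value exceeds 0.99. An optional per-item mean shift models an
intensity-like main effect.

## PLS and small-sample statistics

PLS follows SIMPLS (de Jong 1993): X and Y column-centered, no variance
scaling (matching the MATLAB routine's default); each component's weight
is the dominant left singular vector of the running cross-product matrix,
deflated through an orthonormalized loading basis. Components are
sign-fixed so the largest-|loading| X entry is positive, for deterministic
output. A perfectly explained outcome leaves a degenerate later component,
which is reported as an error rather than returned as noise. Pearson
correlations are reported as (r, df = n − 2, p from the t transform);
median splits send values equal to the median to the low group (the
published analysis does not state a tie rule); order-of-dosing effects use
simple OLS on the binary order indicator, equivalent to a two-sample t.

## Pipeline and problem sizes

`run_pipeline` derives every stage seed from the single config seed, so a
fixed config reproduces the report byte for byte. When both conditions are
statistically identical the sweep finds no positive structure; the
pipeline reports zero retained substates instead of failing. Downstream
association stages focus on the post-injection-dominant retained substate
with the strongest contrast, mirroring the scientific focus on the state
emerging after injection. Tests exercise the full 840-volume, 14-participant
scale for partition recovery; contrast and PLS recovery simulations use
shorter scans (160 volumes) and 100 seeds, since those statistics depend on
participant count and effect size rather than scan length.

## Known limitations

* No voxel-level preprocessing, parcellation extraction, NIfTI I/O or EEG
  support: inputs are clean parcellated CSV time series.
* Gaussian, temporally white synthetic noise; no motion/scrubbing model
  (an exclusion mask is accepted and excluded volumes leave occupancy
  denominators).
* The Louvain optimizer is dense (O(T²) per pass) — fine for T ≈ 10³
  volumes, not intended for much larger graphs.
* Heart-rate variability metrics and BrainVision parsing are out of scope;
  EKG input is assumed gradient-artifact-corrected.
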