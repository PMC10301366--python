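# Methods

## Jump-height models

Both flight-time and impulse-momentum heights derive from free-fall
kinematics with `g = 9.81 m·s⁻²` exactly.

**Impulse-momentum (JH_TOV).** With body weight `W` estimated from quiet
standing, per-sample acceleration is `a = (F − W)·g/W` and velocity is its
trapezoidal cumulative integral with `v = 0` at the start of the
quiet-standing window — the only instant the centre of mass is known to be
stationary. (Whether integration should instead start at movement onset is
underdetermined; starting at the trace start is equivalent for a stable
baseline and needs no onset detector.) Take-off velocity is read at the
*last contact sample* (the final data point before flight) and
`h = TOV²/2g`. The wording "final point of the contact phase where data
were below threshold" is self-contradictory — contact samples are at or
above threshold — so the last-at-or-above-threshold sample is the default
and the first-below-threshold sample is available via
`take_off_velocity(..., convention="first_flight")`.

**Flight time (JH_TIA).** Take-off is the first sample of the first run of
at least `min_flight = 0.05 s` of consecutive samples below the 10 N
threshold; landing is the first sample at or above threshold after that
run; `h = g·TIA²/8`. The minimum-duration debounce is not part of the
classic threshold rule but is required for raw, unfiltered data, where a
brief noise dropout below 10 N mid-stance would otherwise end the trace
analysis early. The half-sample ambiguity in where "take-off" falls between
two samples is below measurement precision and is not modelled.

**Video (JH_MJ).** The camera protocol consumes only two frame indices —
first fully airborne frame, first re-contact frame — and the frame rate.
Flight is the index difference over fps (the airborne frame counts, the
contact frame does not; the off-by-one alternative is exposed as
`inclusive=True`) and the height formula is shared with JH_TIA. A one-frame
pick error changes height by at most `gT/(4·fps) + g/(8·fps²)`
(≈ 0.36 cm at `T = 0.35 s`, 240 fps).

## Agreement statistics

* **ICC**: single-measure absolute-agreement two-way model,
  `ICC = (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, with the
  F-based 95% CI (Satterthwaite degrees of freedom for the column/error
  mixture) and the `MSR/MSE` F test for ICC = 0 — the SPSS procedure.
  Zero total variance returns an error, never ICC = 1. Interpretation
  bands: poor < 0.5 ≤ moderate < 0.75 ≤ good ≤ 0.9 < excellent (the
  boundary 0.9 itself is ambiguous in the conventional banding and is
  classed "good" here).
* **CV**: per jump, the two tools' values give `SD = |a−b|/√2` and mean
  `(a+b)/2`; the reported CV is the mean of `SD/mean × 100` over jumps.
  (The inverted ratio sometimes printed, mean/SD, yields values in the
  hundreds of percent and cannot be what 4–7% summaries describe.)
* **SEM**: SD of between-tool differences over √2. Default is pooled over
  all jumps; a per-participant mode (SD within each participant's trials,
  then averaged) is provided because "individual differences" can be read
  either way, but with one difference per jump the pooled form is the only
  well-defined default.
* **Bland–Altman**: bias = mean difference, LoA = bias ± 1.96 × sample SD
  (the z-quantile, not a t-quantile, matching standard LoA arithmetic);
  `loa_from_bias_sd` computes limits from published summaries alone.
* **Group tests**: Friedman over within-row ranks is the primary omnibus
  across methods (the paired design), with Kruskal–Wallis exposed as an
  alternative; significant omnibus → pairwise Wilcoxon signed-rank with
  p multiplied by the number of comparisons, capped at 1. Effect size
  `r = |Z|/√n` uses the number of pairs (Wilcoxon) or the total sample
  size (Mann–Whitney); the convention's `n` is often left undefined, so
  these choices are stated rather than assumed. Bands: trivial ≤ 0.1 <
  small ≤ 0.3 < medium ≤ 0.5 < large.
* Report rounding is half-up (spreadsheet convention): CV and SEM to one
  decimal, ICC to three, bias/LoA to two.

## Synthetic-jump generator

The trace is piecewise smooth in closed form: quiet stance at `W = mg`;
a half-cosine unweighting dip to `W(1 − depth)` (default depth 0.3,
0.3 s); a half-cosine propulsive rise to a peak `P` followed by a
quarter-cosine release to exactly 0 N at take-off (release occupies 10% of
the 0.3 s propulsion); `P` is solved linearly so the net impulse from
movement onset to take-off equals `m·v` with `v = √(2gh)` — impulse
conservation holds to < 0.1% under trapezoidal integration at 1 kHz. If
the required peak exceeds 8 body weights (a tall jump forced through a
short propulsion) the generator refuses rather than emit unphysiological
force. Flight is exactly `2v/g + δ` at zero force, where the
landing-flexion delay `δ ≥ 0` models touching down with flexed joints;
landing is a quarter-sine rise to 3 W over 50 ms and a quarter-cosine
decay to stance. White Gaussian sensor noise is added throughout.

Numerical consequences worth knowing:

* the force spends ≈ 0.2 ms below 10 N before true take-off and ≈ 0.3 ms
  after true touchdown, so threshold-detected TIA exceeds true flight by
  a fraction of a sample plus grid quantization (≈ +0.5 ms on average);
* the last-contact TOV convention reads velocity up to one sample early,
  while force ≈ 0, so TOV overshoots by ≈ `g/fs`; the height error
  `v·Δv/g ≈ v/fs` stays under 2 mm for jumps below ~25 cm at 1 kHz. This
  bound is intrinsic to the convention at this sampling rate, not a
  simulator artefact.

**Camera model.** Frame `k` is exposed at `(k + φ)/fps` with phase `φ`
uniform on [0, 1) per jump (plate and camera unsynchronized). The first
flight frame is the first frame strictly after take-off; the first contact
frame the first at or after landing. Frame-count flight time is therefore
within one frame of true flight and mean-unbiased over φ. Observers
mis-pick each boundary by ±1 frame with probability 0.2, chosen from the
closed form `2√p · gT/(4·fps) ≈ 0.32 cm` to match a between-observer
difference SD of ≈ 0.3 cm.

**Cohort defaults** emulate a youth (≈ 9-year-old) soccer cohort: 30
participants (21 M / 9 F), 3 trials each, one trial dropped via an explicit
exclusion list (89 analysable jumps); mass ~ Normal(33, 2.8) kg;
participant-mean true height ~ Normal(0.155, 0.04) m truncated above
0.05 m, trial jitter SD 0.008 m; δ ~ Normal(0.0155, 0.008) s truncated at
zero — the mean chosen so the flight-time inflation `gTδ/4` is ≈ 1.3 cm at
a 15 cm jump; plate noise 1 N. Only summary statistics of the emulated
population are available, so the distributional forms (normals with
truncation) are a modelling choice.

## What the simulation does and does not show

With these defaults the pipeline reproduces the qualitative structure of
real method comparisons: mean JH_TIA − JH_TOV ≈ +1.4 cm; JH_MJ lies between
the two (the camera sees the true take-off/landing instants and so misses
the small threshold-crossing inflation of plate TIA, while sharing the
δ-driven inflation relative to TOV); all pairwise ICCs exceed 0.9 even in
the presence of that bias — a concrete illustration that ICC alone cannot
detect systematic error. The simulated plate-vs-video gap (≈ 0.05 cm) is
much smaller than gaps reported from human observers (≈ 1 cm), whose frame
picking involves perceptual latency this model deliberately does not
include; likewise the TIA-vs-video CV here (≈ 1%) is optimistic. Passing
tests therefore validate the computational chain and the direction and
mechanism of the biases, not the exact magnitudes human raters produce.
Between-method variance is also driven only by δ spread, frame
quantization, observer flips and sensor noise; real jumps add technique
variability (arm swing leakage, asymmetric landings) that widens CVs and
limits of agreement.

## Verification strategy

Every stage is checked against an independent route: height formulas
against hand arithmetic and the algebraic identity
`jh_tia(T) = jh_tov(gT/2)`; event detection against constructed traces
with known sample counts; integration against constant-force closed forms
and the simulator's exact ground truth; the δ bias against the analytic
`(g/8)((T+δ)² − T²)` using paired simulations (same jump with and without
δ, isolating the delay from threshold-crossing offsets); the ICC against
both a freshly fitted two-way ANOVA (statsmodels) and pingouin's ICC(A,1);
the Friedman and Mann–Whitney statistics against hand rank arithmetic and
exhaustive enumeration; and limits of agreement against published summary
worked examples. Simulation-based checks use fixed seeds; cohort-level
assertions are directional (sign and ordering) at 89 jumps, the scale the
emulated study design implies.
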