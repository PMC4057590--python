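# Methods

## Display compression and linearization

Quantification operates on echo power, which is proportional to the
local microbubble count; scanners display log-compressed 8-bit
intensity. The package's display law maps a reference power `e_ref` to
level 255 and the power `dr_db` decibels below it to level 0, linearly
in dB in between, with round-half-away-from-zero quantization. Zero
power is clamped to level 0. The inverse (`linearize`) recovers power
up to half a display level, a relative error of
`10^(dr_db / 5100) − 1` (0.32 % at 7 dB, 1.8 % at 40 dB). The true
scanner law is proprietary; this explicit convention is stated so the
round-trip tolerance is exact and testable. Time-gain compensation is
treated as identity.

The targeted-contrast display setting of interest uses a narrow 7 dB
range; the synthetic renderer defaults to a conventional 40 dB with
`e_ref = 2000 a.u.` so that bound + circulating signal at several times
the nominal receptor density stays inside the display range. Tests pin
the law explicitly wherever it matters.

## Circulating-pool model

After bolus injection the circulating concentration is modelled as a
gamma-variate first pass,

    C1(t) = A (t/t_p)^α exp(α (1 − t/t_p)),

peaking at `A` (default 100 a.u.) at `t_p` (default 8 s, a realistic
arterial transit for a mouse bolus) with shape `α = 2.5`, plus a
recirculating systemic pool

    C2(t) = A c_rec (1 − exp(−(t − 2 t_p)+ / τ_w)),

which builds up with time constant `τ_w` (`washout_tau`, default 45 s —
the washout of the first pass into the well-mixed systemic pool) to a
plateau `c_rec A` (default fraction 0.25). The delay `2 t_p` keeps the
curve's unique maximum exactly at `t_p`.

**Deliberate idealization:** terminal clearance of the agent is *not*
modelled — the plateau is constant over the ≤ 7-minute exam. Real
late-phase curves decline slowly, which biases the window-difference
dTE by the decay over the ~20 s between windows. Holding the plateau
constant makes the zero-binding dTE exactly zero (up to quantization),
i.e. the generator realizes the assumption the window-subtraction
method itself relies on; the pipeline is agnostic either way.

## Bound pool, flash, replenishment

Binding is linear in receptor density and circulating concentration:
`B(t) = ρ k_on ∫₀ᵗ C(s) ds` (`k_on` default 0.025 (a.u.·s)⁻¹, sized so
unit receptor density yields a dTE of ≈ 180 a.u. on a fully perfused
ROI, the few-hundred a.u. scale typical of targeted exams). The
1-second flash (default onset 360 s) zeroes both in-plane pools; the
circulating pool relaxes back to the unflashed trajectory with time
constant `replenish_tau` (default 2 s — fast reperfusion of a
hypervascular tumor; 15 s after the flash the plane is fully
replenished), while the bound pool does not re-form within the exam
(the depleted agent rebinding is negligible on this time scale). True
dTE is therefore ≈ `gain · B(flash_onset)` on perfused pixels.

## Rendering

The exam timeline is two 30 s clips at 10 Hz (0–30 s arterial phase;
355–385 s around the flash), matching a protocol with a second clip
from 5 min 55 s and destruction at 6 min. Per-pixel echo power is
`background + gain (C + B ρ_px)` on perfused tumor pixels and the
background level (default 1 a.u.) on necrotic and extra-tumoral pixels.
Speckle is multiplicative lognormal noise with unit mean; flash frames
are rendered saturated. Necrotic cores are built by pixel count
(nearest-to-center pixels, count = round(fraction × tumor area)) so
noise-free area readings are exact by construction.

## dTE quantification choices

* The 15-second post-flash offset is measured from flash **onset**:
  only then does the 10 s window fit inside the second clip
  (375–385 s); from flash end it would overrun the acquisition.
* Windows are half-open `[start, end)` in exam time; frames are
  assigned by timestamp; flash frames are excluded.
* TE is the **mean** (not integrated) per-pixel linearized power, so
  dTE is independent of ROI pixel count and comparable across tumors of
  different sizes.
* Negative dTE on noisy input is reported unclamped; downstream
  statistics are rank-based.
* Flash detection prefers sidecar metadata; the fallback flags frames
  whose mean display intensity exceeds median + 6 MAD of all frame
  means and takes the longest run. A MAD-based threshold is immune to
  the bolus-driven drift of frame means.

## Perfusion scoring

Peak enhancement is searched in the arterial clip only. The visual
scoring of non-enhanced area is operationalized as pixels below
`threshold_factor ×` the median linearized power outside the ROI
(background). The factor is configurable per reader (defaults 1.5 and
2.5 for the two simulated readers — any factor between 1 and the
contrast-to-background ratio gives identical noise-free readings, and
the spread emulates inter-reader variability). Readings are snapped to
the 10 % scale with half rounding up; disagreeing readers are resolved
by the quantized mean of their raw fractions, a deterministic stand-in
for consensus-by-discussion. Quantization tolerates the sub-pixel
difference between a requested fraction and what an integer pixel count
can realize.

## Elastography

Strain images are taken as given (scanner-internal strain estimation is
out of reach); the measurement is the ratio of mean tumor strain to
mean reference-pad strain, scale-invariant under the unknown
compression force, averaged over the three per-session replicates. The
simulator draws additive zero-mean pixel noise on the tumor region only
(the pad is of known homogeneous consistency).

## Growth cohorts

Volumes follow piecewise-exponential growth with daily rates by
schedule: untreated 0.075 d⁻¹ (~80 % growth over 8 days), on-drug
0.005 d⁻¹ (near stasis), and after a *permanent* stop (no later drug
days) `rebound_multiplier × untreated` (default 1.05 — a definitive
withdrawal regrows at least as fast as placebo). Baseline volume
150 mm³; per-animal lognormal baseline effect (sd 0.15) plus
per-reading lognormal measurement error at half that sd (tied to the
same parameter so a zero-noise cohort is exactly deterministic).
Volumes are reported as diameter triples with fixed anisotropy
1.2 : 1 : 1/1.2, whose half-ellipsoid product returns the volume
exactly; per-axis statistics are not modelled.

## Study orchestration

`simulate_study` writes cohort CSV, per-animal cines + ROI masks, and
strain stacks from a single seed (all child seeds derived via
`SeedSequence.spawn`); `run_study` reads only those files. Group-level
generator settings (receptor-density medians per exam day, per-animal
necrotic percentages, elasticity-ratio medians) default to the observed
values of a three-arm sorafenib-interruption experiment, with
per-animal lognormal random effects shared across time points so
per-animal deltas reflect the group effect rather than independent
draws. Deltas are always computed per animal and then summarized
(median-of-deltas); a fixture in the test suite demonstrates this
differs from the delta of medians. Missing animal/day records raise a
named-gap error — no silent imputation. Animals lost before
reassessment are simply absent from the cohort (listwise exclusion).

Tests performed: Kruskal–Wallis across groups per endpoint/timepoint,
pairwise Mann–Whitney on final-exam dTE, within-group Wilcoxon on dTE
across the two exams, Spearman correlation of dTE change with volume
change. Two-sided throughout; no multiple-testing correction. Exact
Mann–Whitney p-values come from the permutation null over the observed
multiset (subset-sum dynamic program over doubled midranks, so ties are
exact); the asymptotic path uses the tie-corrected normal
approximation. Note that for completely separated groups of 4 the
exact two-sided p is 2/70 ≈ 0.029 — an SPSS-style asymptotic value can
differ, which is documented rather than chased. All-identical data
yield p = 1 by convention.

## What a green test does and does not establish

The generators realize exactly the structure the analysis assumes:
linear binding, stationary late circulation, perfect co-registration
(probe on a fixed support), homogeneous receptor density over perfused
tissue. Green tests therefore establish correctness of the
quantification arithmetic and its inversion of the display law, and the
direction-of-effect behaviour of the statistics on cohorts with known
effects. They do not establish robustness to motion, attenuation,
nonlinear propagation, heterogeneous binding, or operator variability,
none of which are modelled. Headline animal-study numbers (growth and
dTE medians, elasticity medians) are covered qualitatively by
direction-of-effect properties, not as numeric targets, because the
underlying per-animal raw data are not available at desk scale.
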