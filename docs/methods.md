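# Methods

This note records the models implemented in `ligbend`, their assumptions,
the parameters that matter, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Synthetic smFRET traces

Each trace is a hidden two-state (or ladder) Markov path rendered into two
intensity channels.

**Kinetic structure.** The DNA alternates between the straight state
(E = 0.27) and one high-FRET bent state per pattern (E = 0.42/0.67/0.88 for
patterns II/III/IV; pattern I never leaves the baseline). Dwells in both
states are exponential with means `dwell_low = dwell_high = 1 s`,
quantized to 50-ms frames (minimum one frame). Exponential dwells are the
memoryless default for a single rate-limiting step; nothing in the
analysis depends on the dwell law beyond resolvability. *Nonsealable*
substrates (3′-blocked nicks) produce recurring excursions for the whole
trace; *sealable* substrates produce exactly one excursion and then stay
low — repair straightens the DNA permanently.

**Sequential topology (the null).** Under a sequential mechanism the three
bent states are obligatory intermediates of a single pathway, so every
binding attempt climbs the full ladder low → II → III → IV → low with an
exponential dwell per rung. This is deliberately the *strong* form of the
null: a trace with any resolvable excursion should then visit several high
states, which the classifier reports as `mixed`. The generator accepts a
pattern argument in sequential mode but only distinguishes "no excursions"
(pattern I) from "excursions" — partial ladders are not simulated, because
the null is about what a sequential mechanism predicts for *observed*
attempts.

**Channel model.** With total emission I = 1000 (a.u.) and efficiency E:

    donor    = bg_d + (1 − E)·I            + N(0, σ)
    acceptor = bg_a + γ·E·I + α·(1 − E)·I  + N(0, σ)

Defaults: bg = 40/40, α = 0.05 (donor leakage), γ = 1, σ = 60 per channel
per frame. σ = 60 makes the per-frame efficiency noise ≈ 0.08, which keeps
the four state peaks resolvable after plateau averaging while being far
from trivial for the step finder. The generator is constructed to be the
exact algebraic inverse of the correction formula, so at σ = 0 the
corrected trace equals the true efficiency path at machine precision —
this round trip is the correctness anchor for both modules. Optional
single-exponential photobleaching (off by default) zeroes both channels'
signal after an exponential bleach time; the pattern analysis does not
hinge on photophysics, so blinking is not modelled.

**Ensemble.** Patterns are drawn from (0.55, 0.25, 0.12, 0.08). The
pattern-I share is the reported ≈55 %; the II/III/IV split is a declared
default (the published split is only graphical). Per-trace seeds are
spawned from the master seed with `numpy.random.SeedSequence`, so
ensembles are byte-identical under a fixed seed regardless of generation
order.

**What the generator does not emulate:** camera/EMCCD statistics,
point-spread functions, baseline drift, dye blinking, multi-molecule
spots, or correlated channel noise. Passing tests therefore demonstrate
the *estimators* are correct and well-calibrated under clean Gaussian
noise, not that they are robust to every artifact of real TIRF data.

## 2. Trace analysis

**Correction.** `E = A′/(A′ + γD′)` with `D′ = donor − bg_d`,
`A′ = acceptor − bg_a − α·D′`. Frames with non-positive corrected total are
flagged unassignable (they carry no signal) and filled by interpolation so
step fitting sees a contiguous series; an all-flagged trace is an error.
Efficiencies are soft-clipped to [−0.2, 1.2].

**Step finding.** Top-down greedy placement: each iteration adds the step
that maximally reduces the residual sum of squares, searched exhaustively
over admissible split points (both sides ≥ `min_plateau_length` = 3
frames), with per-plateau best-split caching for O(n·k) cost. After each
addition a counter-fit (steps at the midpoints of the current plateaus) is
scored; the accepted step count maximizes S(k) = χ²_counter/χ²_fit. If the
peak S never reaches `quality_threshold` = 2, the trace is called
step-free — on pure-noise traces S hovers near 1, so this gate suppresses
spurious steps in baseline-only traces (≥90 % called step-free at default
noise) while genuine steps drive S ≫ 2. Adjacent plateaus closer than
`merge_tolerance` = 0.08 (about half the smallest true state gap) are
merged. On noiseless piecewise-constant input with plateaus ≥ 3 frames and
distinct means the finder recovers boundaries and means exactly (S = ∞ at
the true count); this is asserted in the tests.

**State location.** Plateau means are pooled over the ensemble — but only
from plateaus ≥ 6 frames. Short plateaus frequently straddle a true
transition and average two states; including them smears the mixture and
can merge components. A 1-D Gaussian mixture is fitted for k = 1…4 and k
chosen by BIC. The assignment half-width is 3× the weight-averaged
component SD, floored at 0.05 and capped at 45 % of the smallest center
gap so neighbouring windows cannot swallow each other.

**Classification.** Each plateau is assigned to the nearest center within
the half-width. Two length gates give robustness to idealization
artifacts: a plateau certifies a *state visit* only if ≥ 6 frames
(`visit_min_frames`), and an unassignable plateau disqualifies the trace
only if ≥ 10 frames (`unassign_min_frames`); shorter strays are ignored.
Pattern I = only the low state visited; II/III/IV = exactly one high state
(any number of excursions); `mixed` = ≥ 2 distinct high states. Pattern
shares are reported over assigned (I–IV) traces with seeded bootstrap
percentile CIs. Consequences worth knowing: single excursions shorter
than 6 frames (about a quarter of exponential dwells at the 1-s mean) are
not certified, so *sealable* ensembles under-count their one-excursion
patterns; nonsealable ensembles are unaffected in practice because a trace
offers ~10 excursions. At default noise roughly 1–2 % of excursion traces
still land in `mixed`/`unassigned` from unresolvable dwell pile-ups; the
recovery tests bound the net bias within 3-σ binomial bands at n = 2000.

**Parallel vs sequential.** The statistic is the fraction of
excursion-containing traces classified `mixed`. Baseline-only traces are
excluded from the denominator because they carry no information about
transitions *among* high states. The null distribution re-runs the
identical pipeline (same step configuration, same fitted state model) on
ensembles simulated in sequential topology with matched rates; the
p-value is the add-one Monte-Carlo estimate (k+1)/(n_null+1), one-sided
toward small mixed fractions. With the observed mixed fraction at 0 and
every null run fully mixed, p attains its floor 1/(n_null+1).

## 3. Bow-construct mechanics

**Geometry.** Rigid arms, `a = 25 bp × 0.34 nm = 8.5 nm`; bend angle θ is
the deviation from straight (0° = straight); chord `d(θ) = 2a·cos(θ/2)`.
The nick is central (symmetric 25-nt strands), so the arms are equal.

**Linker statistics.** The ssDNA linker is a discrete freely jointed chain
with contour 0.63 nm/nt and Kuhn length 1.5 nm;
`N = ceil(nt·0.63/1.5)` segments. The default backend draws 2×10⁵ chains
by seeded Monte-Carlo (exact discrete-FJC law — short linkers, N ≈ 5, are
far from Gaussian); a Gaussian-chain closed form is provided as a
cross-check for N ≥ 10. The test oracle is the classical alternating-sum
radial density evaluated in exact rational arithmetic (float64 suffers
catastrophic cancellation beyond N ≈ 10), and the sampler must agree with
its quadrature within total variation 0.05 on a 1° grid.

**Bend-angle law.** `P(θ) ∝ sin(θ)·ρ_FJC(d(θ))·|dd/dθ|`: the free-hinge
solid-angle prior reweighted by the linker's radial end-to-end density at
the chord. In Monte-Carlo form each chain sample r ≤ 2a maps to
θ(r) = 2·acos(r/2a) with weight sin θ, giving exact weighted samples of
P(θ). An unconstrained construct returns the pure free-hinge law; a
zero-length linker degenerates to θ = 180° (flagged). Note that this law
weights by the *radial* density (the chain must span the chord length,
direction integrated out); a variant weighting by the vector density
ρ/(4πd²) would suppress extended configurations harder and is *not* used.

**Minimum bending angle.** Reported as the smallest angle reached with
probability ≥ q. The default q = 10⁻⁴ is a calibration constant (config,
not code): at that level the 10–80 nt series spans ≈130° down to ≈11°,
monotone in linker length, matching the headline mechanical range; the
quantile, not the polymer parameters, was calibrated because force-
extension-derived contour/Kuhn values are well established while "minimum
reachable angle" has no unique statistical definition.

**Point-cloud angles.** Each arm of a labelled 3D cloud gets a
total-least-squares (principal-axis) line; directions are oriented away
from the other arm's centroid; bend = 180° − inter-arm angle. The
measurement is exactly invariant under rigid motions and unbiased within
±2° at 0.3 nm point noise (200 points/arm). Nearest-angle classification
against the conformer angles (0/20/60/100°) puts decision boundaries at
10/40/80°, ties toward the smaller class.

**Dye model.** Dyes sit 10.5 bp either side of the nick, so
`r(θ) = 21·0.34·cos(θ/2)` nm and `E = 1/(1+(r/R₀)⁶)`. R₀ = 6.0493 nm is
calibrated so E(0°) = 0.27 — the unbound-DNA anchor — and lands near
commonly cited Cy3/Cy5 values (≈5–6 nm). Duplex twist at the nick also
moves the dyes, so only the *ordering* of the four conformer efficiencies
is claimed, never their values; the high-state positions (0.42/0.67/0.88)
are inputs to the generator, not predictions of this geometry.

## 4. Conformer-selectivity ligation kinetics

**Accessibility.** Conformer j engages a construct iff the construct's
working minimum angle is below τ_j, with τ = (20, 60, 100, ∞)°. The
thresholds are taken from the observed linker-class boundaries rather than
derived as θ_j + tolerance, because no single additive tolerance
reproduces the observed classes (e.g. a 10-nt bow, pinned near 130°,
is still repaired by the 100° conformer). The working minimum angle uses
its own quantile, `accessibility_quantile` = 4.5×10⁻³: engagement requires
the construct to present a compatible angle a non-negligible fraction of
the time, not merely in the 10⁻⁴ tail that defines the headline minimum.
The value sits at the centre of the only window that yields four stable
accessibility classes over the default grid (stable across seeds).

**Rates and dose-response.** `k_eff = Σ_accessible p_j·k_j` with the
DNA-free conformer proportions (0.52, 0.23, 0.16, 0.09) — conformational
selection happens before DNA binding — and equal intrinsic rates
(nothing constrains per-conformer rates; equal rates make the C₅₀
plateaus purely proportional to accessible mass). The intrinsic rate
ln 2/600 nM⁻¹s⁻¹ normalizes the fully accessible C₅₀ to 1 nM at the
10-minute incubation. Repair follows pseudo-first-order kinetics
`f = 1 − exp(−k_eff·c·t)` with saturation amplitude fixed at 1; C₅₀ =
ln 2/(k_eff·t). The C₅₀ fit is weighted least squares on replicate means;
replicate SEs are floored at max(0.3×median SE, 10⁻³) because clipping to
[0, 1] collapses the scatter of saturated points and would otherwise hand
them unbounded weight. Curves that never cross f = 0.5 are flagged and
the C₅₀ reported as a bound. The delta method gives SE(C₅₀).

**Plateau detection.** Sorted log₁₀ C₅₀ values are cut where a gap exceeds
`gap_factor` (= 5) × median gap, with an absolute floor of 0.05 decades so
replicate scatter inside a plateau never splits it. The plateau count is
an output of the clustering, never an input. Adjacent plateaus differ by
k_eff ratios ≈2–2.8 (0.28–0.44 decades) while within-plateau scatter is
≈0.02 decades, so the default is far from both edges.

**A provable boundary limit.** With the default grid the four plateaus
have membership {10, 15, 20, 25} / {30, 40, 50} / {60, 80} /
{unconstrained}: the first boundary falls between 25 and 30 nt, not
between 15 and 20 nt as the observed accessibility classes would place
it. This is not a tuning failure. Placing 20–25-nt bows in the
{III, IV} class requires the 20-nt linker (contour 12.6 nm) to span the
100° chord of 10.9 nm — 87 % of its contour — *more* readily than the
50-nt linker (contour 31.5 nm) spans the 60° chord of 14.7 nm (47 % of
contour). For any ideal-chain model at any Kuhn length, the shorter chain
at the higher fractional extension has the lower probability, so the
required threshold ordering is impossible. Reproducing the 15-nt boundary
would need physics outside this model — e.g. enzyme-assisted bending
(work done by the ligase on the linker) or ssDNA stretching elasticity.

## 5. Repair-and-then-cut fields

Spot survival is binomial per field with
`P(survive) = repair + (1 − repair)·(1 − cut)`; the no-ligase control uses
cut efficiency 0.94. The summary is the per-field surviving fraction's
mean ± SD over fields (default 10 fields × 300 spots); zero-spot fields
are excluded with a warning.

## 6. Problem sizes and numerical conventions

Default analysis sizes — 2000-trace ensembles (400 frames each), 2×10⁵
chain samples per construct, 5000 point clouds, 10 concentration points ×
3 replicates — were chosen so every recovered proportion has a 3-σ
binomial band of ±2–3 percentage points, tight enough to be informative
about estimator bias. Angles are degrees at every public surface (radians
internal); efficiencies are serialized with 4 decimals and angles with 3
in human-facing tables, full 17-significant-digit precision in data TSVs
(written and re-parsed with correctly rounded converters, so round trips
are exact). All stochastic entry points take explicit seeds;
ensembles spawn per-item seeds from the master seed.

## 7. Known limitations

* The trace generator's clean Gaussian channel noise understates real TIRF
  pathologies (see §1); the classification gates (6/10 frames) were chosen
  against this generator and would need re-tuning for real data.
* Dwells shorter than ~3 frames are unresolvable by construction;
  sealable single-excursion patterns are under-detected (§2).
* Arms are rigid rods: no worm-like-chain flexibility, no twist, and the
  triangle closure ignores excluded volume between linker and duplex.
* The accessibility thresholds are table-driven, not mechanistic, and the
  first plateau boundary provably cannot match the observed 15-nt class
  edge under ideal-chain mechanics (§4).
* The dye model is monotone-qualitative; it anchors only E(0°).
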