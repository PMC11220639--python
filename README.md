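# ligbend

Analysis toolkit for the parallel-pathway picture of nicked-DNA repair by
T4 DNA ligase.

## The problem

T4 DNA ligase seals single-strand nicks in duplex DNA. Single-molecule FRET
(smFRET) of ligase acting on nicked substrates shows four recurring trace
phenotypes: a low-efficiency baseline (E ≈ 0.27, straight DNA) and
excursions to exactly one of three high-FRET states (E ≈ 0.42, 0.67, 0.88)
— never transitions *between* high states within one trace. Together with
electron-microscopy class averages showing ligase–AMP(-DNA) complexes at
DNA bend angles of ≈0°, 20°, 60° and 100°, this supports a model in which
four ligase–AMP conformers engage the nick **in parallel**, each bending
the DNA to its own angle, rather than passing through the bent states in
sequence. The decisive biochemical test uses "bow" constructs — a 50-bp
nicked duplex whose ends are tied by a 10–80 nt ssDNA linker that imposes a
minimum bend angle — and finds that the half-repair ligase concentration
C₅₀ takes only four discrete values across the whole linker series.

`ligbend` implements that entire analysis chain as tested, seedable code,
together with synthetic-data generators that reproduce the statistical
structure of each experiment. It is aimed at single-molecule and
structural-biophysics practitioners who want to re-run, stress or extend
the pipeline without access to raw traces or micrographs.

## The models at the core

**Trace idealization.** Corrected efficiency
`E = A′ / (A′ + γ·D′)` (with background, crosstalk α and detection factor γ
removed) is idealized by an unbiased top-down step finder: steps are placed
greedily at the split that maximally reduces χ², and the accepted step
count maximizes the counter-fit/fit χ² ratio S(k) (counter-steps at plateau
midpoints). FRET states are located by a 1-D Gaussian mixture with BIC
model selection; traces are classified I–IV / mixed / unassigned from the
set of visited high states, and the parallel hypothesis is tested against a
sequential-ladder Monte-Carlo null.

**Bow-construct mechanics.** Rigid duplex arms of length `a` hinge at the
nick; bending by θ puts the arm ends `d(θ) = 2a·cos(θ/2)` apart, which the
freely-jointed-chain linker (0.63 nm/nt contour, 1.5 nm Kuhn length) must
span. The equilibrium bend-angle law is

    P(θ) ∝ sin(θ) · ρ_FJC(d(θ)) · |dd/dθ|

and a low quantile of P(θ) is the construct's minimum bending angle. The
dye model `E(θ) = 1/(1 + (r(θ)/R₀)⁶)` with `r(θ) = 21 bp · 0.34 nm ·
cos(θ/2)` and R₀ calibrated to E(0°) = 0.27 links geometry back to FRET
(ordering only — twist also moves the dyes).

**Conformer-selectivity kinetics.** Conformer *j* (proportions
52/23/16/9 %, tolerance thresholds τ = 20/60/100/∞ degrees) can act on a
construct only if the construct's working minimum angle stays below τ_j.
The effective rate `k_eff = Σ_j accessible p_j·k_j` feeds pseudo-first-order
repair `f = 1 − exp(−k_eff·c·t)`, so `C₅₀ = ln 2/(k_eff·t)` — at most four
distinct values, detected as plateaus by 1-D gap clustering on log C₅₀.

## Worked example

```python
from ligbend import CorrectionParams, TraceGenParams, TracePatternModel
from ligbend.simulate import simulate_trace_ensemble

params = TraceGenParams(seed=0)                      # 400 frames @ 50 ms
traces = simulate_trace_ensemble(params, 500)        # patterns drawn 55/25/12/8 %
res = TracePatternModel(traces, CorrectionParams.from_generation(params)).fit(seed=0)
print(res.summary())
```

```
smFRET trace-pattern analysis
==============================================
traces analysed           500
assigned (I-IV)           494
state centers (E)      0.269, 0.417, 0.670, 0.881
assignment halfwidth    0.050

pattern   count   fraction   95% CI
      I     271      0.549   [0.506, 0.593]
     II     123      0.249   [0.211, 0.289]
    III      58      0.117   [0.089, 0.144]
     IV      42      0.085   [0.060, 0.113]

mixed: 0   unassigned: 6
```

The four mixture centers recover the generating state efficiencies
(0.27/0.42/0.67/0.88) and the pattern shares recover the generating
proportions; zero `mixed` traces is the parallel-pathway signature
(`res.parallel_test(...)` turns it into a Monte-Carlo p-value against the
sequential null). The mechanics module maps the linker series onto the
bend-angle range:

```python
from ligbend.mechanics import BowConstruct, min_bend_angle
min_bend_angle(BowConstruct(linker_nt=10), seed=0)   # 130.5 deg
min_bend_angle(BowConstruct(linker_nt=80), seed=0)   #  12.2 deg
```

A command-line pipeline wraps the same functions:

```
ligbend simulate --out run/sim --seed 0
ligbend analyze-traces --traces run/sim/traces/manifest.tsv --out run/ana
ligbend mechanics --out run/mech
ligbend ligation --out run/lig
ligbend report --out run/report --seed 0
```

`report` writes `report-summary.tsv` juxtaposing every recovered quantity
(state centers, pattern shares, θ_min grid, plateau count) with its nominal
value.

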