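"""smFRET trace analysis: correction, idealization, state and pattern calls.

The pipeline turns raw two-channel intensity traces into corrected
efficiency traces, idealizes them with an unbiased chi-square step finder,
locates the recurring FRET states by a 1-D Gaussian-mixture fit with BIC
model selection, classifies each trace into the four transition patterns

    I   : low-FRET state only (straight DNA throughout),
    II  : recurring excursions to the lowest high state,
    III : recurring excursions to the middle high state,
    IV  : recurring excursions to the highest high state,

plus ``mixed`` (>= 2 distinct high states: the signature a sequential
mechanism would leave) and ``unassigned`` (a long plateau outside every
state window), and finally tests the parallel-pathway hypothesis against a
sequential-ladder null by Monte-Carlo.

``TracePatternModel`` wraps the whole chain in a statsmodels-style
model/results pair; every stage is also available as a plain function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import defaults
from .simulate import (
    PATTERNS,
    FluorescenceTrace,
    TraceGenParams,
    simulate_trace_ensemble,
)

__all__ = [
    "CorrectionParams",
    "EfficiencyTrace",
    "StepFitConfig",
    "StepFit",
    "StateModel",
    "PatternAssignment",
    "ParallelStats",
    "correct_trace",
    "fit_steps",
    "locate_state_peaks",
    "classify_trace",
    "pattern_percentages",
    "parallel_vs_sequential_statistic",
    "TracePatternModel",
    "TracePatternResults",
]


@dataclass(frozen=True)
class CorrectionParams:
    """Calibration for converting channel intensities to FRET efficiency.

    ``crosstalk_alpha`` is the fraction of donor signal leaking into the
    acceptor channel; ``gamma`` absorbs the quantum-yield and
    detection-efficiency imbalance between the channels.
    """

    background_donor: float = 0.0
    background_acceptor: float = 0.0
    crosstalk_alpha: float = 0.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.crosstalk_alpha < 1:
            raise ValueError("crosstalk_alpha must lie in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def from_generation(cls, params: TraceGenParams) -> "CorrectionParams":
        """The calibration matched to a synthetic trace's generation."""
        return cls(
            background_donor=params.background_donor,
            background_acceptor=params.background_acceptor,
            crosstalk_alpha=params.crosstalk_alpha,
            gamma=params.gamma,
        )


@dataclass
class EfficiencyTrace:
    """Corrected FRET efficiency per frame, soft-clipped to [-0.2, 1.2]."""

    efficiency: np.ndarray
    trace_id: str = "trace"
    flagged: np.ndarray | None = None  # frames with no usable signal
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(self.efficiency.size, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.efficiency.size


def correct_trace(
    raw: FluorescenceTrace, cal: CorrectionParams | None = None
) -> EfficiencyTrace:
    """Compute the corrected FRET efficiency of a raw trace.

    Per frame: D' = donor - bg_d; A' = acceptor - bg_a - alpha * D';
    E = A' / (A' + gamma * D').  Frames with non-positive total corrected
    signal carry no information and are flagged unassignable; efficiencies
    are soft-clipped to [-0.2, 1.2] (noise may leave [0, 1]).
    """
    cal = cal or CorrectionParams()
    if raw.n_frames == 0:
        raise ValueError("trace is empty")
    d = raw.donor - cal.background_donor
    a = raw.acceptor - cal.background_acceptor - cal.crosstalk_alpha * d
    total = a + cal.gamma * d
    flagged = total <= 0
    if np.all(flagged):
        raise ValueError(f"{raw.trace_id}: no frame has usable signal")
    eff = np.full(raw.n_frames, np.nan)
    eff[~flagged] = a[~flagged] / total[~flagged]
    eff = np.clip(eff, -0.2, 1.2)
    # flagged frames get a neutral fill so downstream windows stay contiguous
    if np.any(flagged):
        eff[flagged] = np.interp(
            np.flatnonzero(flagged), np.flatnonzero(~flagged), eff[~flagged]
        )
    return EfficiencyTrace(
        efficiency=eff, trace_id=raw.trace_id, flagged=flagged,
        metadata=dict(raw.metadata),
    )


@dataclass(frozen=True)
class StepFitConfig:
    """Configuration of the chi-square step finder."""

    max_steps: int = 80
    min_plateau_length: int = 3
    quality_threshold: float = 2.0
    merge_tolerance: float = 0.08

    def __post_init__(self) -> None:
        if self.min_plateau_length < 2:
            raise ValueError("min_plateau_length must be >= 2")
        if self.max_steps < 0:
            raise ValueError("max_steps must be >= 0")
        if self.quality_threshold <= 0:
            raise ValueError("quality_threshold must be positive")
        if self.merge_tolerance < 0:
            raise ValueError("merge_tolerance must be >= 0")


@dataclass
class StepFit:
    """Piecewise-constant idealization of an efficiency trace.

    ``plateaus`` is an ordered list of (start, end, mean) with start
    inclusive, end exclusive, tiling [0, n_frames).  ``quality_curve`` holds
    the fit/counter-fit chi-square ratio per candidate step count.
    """

    plateaus: list[tuple[int, int, float]]
    n_frames: int
    rss: float
    quality_curve: list[float] = field(default_factory=list)
    trace_id: str = "trace"

    def __post_init__(self) -> None:
        if not self.plateaus:
            raise ValueError("a step fit needs at least one plateau")
        if self.plateaus[0][0] != 0 or self.plateaus[-1][1] != self.n_frames:
            raise ValueError("plateaus must tile the full frame range")
        for (s0, e0, _), (s1, e1, _) in zip(self.plateaus, self.plateaus[1:]):
            if e0 != s1:
                raise ValueError("plateaus must tile without gaps or overlaps")

    @property
    def n_steps(self) -> int:
        return len(self.plateaus) - 1

    @property
    def means(self) -> np.ndarray:
        return np.asarray([m for _, _, m in self.plateaus])

    def idealized(self) -> np.ndarray:
        out = np.empty(self.n_frames)
        for s, e, m in self.plateaus:
            out[s:e] = m
        return out


def _segment_rss(prefix: np.ndarray, prefix_sq: np.ndarray, s: int, e: int) -> float:
    n = e - s
    tot = prefix[e] - prefix[s]
    return float(prefix_sq[e] - prefix_sq[s] - tot * tot / n)


def _best_split(
    prefix: np.ndarray, prefix_sq: np.ndarray, s: int, e: int, min_len: int
) -> tuple[float, int]:
    """Largest RSS reduction over admissible split points of plateau [s, e)."""
    lo, hi = s + min_len, e - min_len
    if hi < lo:
        return 0.0, -1
    m = np.arange(lo, hi + 1)
    left_n = m - s
    right_n = e - m
    left_sum = prefix[m] - prefix[s]
    right_sum = prefix[e] - prefix[m]
    total_sum = prefix[e] - prefix[s]
    whole = prefix_sq[e] - prefix_sq[s] - total_sum**2 / (e - s)
    split = (
        prefix_sq[e] - prefix_sq[s]
        - left_sum**2 / left_n
        - right_sum**2 / right_n
    )
    gain = whole - split
    best = int(np.argmax(gain))
    return float(gain[best]), int(m[best])


def _rss_for_boundaries(
    prefix: np.ndarray, prefix_sq: np.ndarray, boundaries: Sequence[int], n: int
) -> float:
    edges = [0, *sorted(boundaries), n]
    return sum(
        _segment_rss(prefix, prefix_sq, s, e) for s, e in zip(edges, edges[1:])
    )


def fit_steps(trace: EfficiencyTrace, cfg: StepFitConfig | None = None) -> StepFit:
    """Idealize an efficiency trace with an unbiased top-down step search.

    Steps are added greedily, each at the split point that maximally reduces
    the residual sum of squares over all admissible positions.  After each
    addition the fit is scored against a counter-fit whose steps sit at the
    midpoints of the current plateaus; the accepted step count maximizes the
    counter-fit/fit chi-square ratio, provided the peak ratio reaches
    ``quality_threshold`` (otherwise the trace is called step-free).
    Adjacent plateaus closer than ``merge_tolerance`` are merged afterwards.
    """
    cfg = cfg or StepFitConfig()
    y = trace.efficiency
    n = y.size
    if n < 2 * cfg.min_plateau_length:
        raise ValueError(
            f"trace too short for step fitting: {n} < 2*{cfg.min_plateau_length}"
        )
    prefix = np.concatenate(([0.0], np.cumsum(y)))
    prefix_sq = np.concatenate(([0.0], np.cumsum(y * y)))
    total_rss = _segment_rss(prefix, prefix_sq, 0, n)

    # greedy nested boundary sequence
    boundaries: list[int] = []
    rss_at: list[float] = [total_rss]
    candidates = {}  # (s, e) -> (gain, split)
    candidates[(0, n)] = _best_split(prefix, prefix_sq, 0, n, cfg.min_plateau_length)
    scale = max(total_rss, 1.0) * 1e-12
    while len(boundaries) < cfg.max_steps:
        (s, e), (gain, split) = max(
            candidates.items(), key=lambda kv: kv[1][0]
        )
        if split < 0 or gain <= scale:
            break
        boundaries.append(split)
        rss_at.append(rss_at[-1] - gain)
        del candidates[(s, e)]
        candidates[(s, split)] = _best_split(
            prefix, prefix_sq, s, split, cfg.min_plateau_length
        )
        candidates[(split, e)] = _best_split(
            prefix, prefix_sq, split, e, cfg.min_plateau_length
        )

    # quality curve: counter-fit chi-square over fit chi-square per step count
    quality: list[float] = []
    for k in range(1, len(boundaries) + 1):
        edges = [0, *sorted(boundaries[:k]), n]
        counter = [
            (s + e) // 2 for s, e in zip(edges, edges[1:]) if e - s >= 2
        ]
        rss_fit = rss_at[k]
        rss_counter = _rss_for_boundaries(prefix, prefix_sq, counter, n)
        quality.append(
            math.inf if rss_fit <= scale else rss_counter / rss_fit
        )

    if quality and max(quality) >= cfg.quality_threshold:
        k_best = int(np.argmax(quality)) + 1
    else:
        k_best = 0

    edges = [0, *sorted(boundaries[:k_best]), n]
    plateaus = [
        (s, e, float((prefix[e] - prefix[s]) / (e - s)))
        for s, e in zip(edges, edges[1:])
    ]

    # merge adjacent plateaus with nearly equal means
    merged = [plateaus[0]]
    for s, e, m in plateaus[1:]:
        ps, pe, pm = merged[-1]
        if abs(m - pm) < cfg.merge_tolerance:
            w1, w2 = pe - ps, e - s
            merged[-1] = (ps, e, (pm * w1 + m * w2) / (w1 + w2))
        else:
            merged.append((s, e, m))

    rss = _rss_for_boundaries(prefix, prefix_sq, [s for s, _, _ in merged[1:]], n)
    return StepFit(
        plateaus=merged,
        n_frames=n,
        rss=rss,
        quality_curve=quality,
        trace_id=trace.trace_id,
    )


@dataclass
class StateModel:
    """Recurring FRET states: ordered centers plus an assignment window."""

    centers: np.ndarray
    assignment_halfwidth: float
    component_sds: np.ndarray | None = None
    bic_by_k: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.size < 1:
            raise ValueError("need at least one state center")
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("state centers must be strictly increasing")
        if self.assignment_halfwidth <= 0:
            raise ValueError("assignment_halfwidth must be positive")

    @property
    def k(self) -> int:
        return self.centers.size

    def assign(self, value: float) -> int | None:
        """Index of the nearest center within the window, else None."""
        idx = int(np.argmin(np.abs(self.centers - value)))
        if abs(self.centers[idx] - value) <= self.assignment_halfwidth:
            return idx
        return None


def locate_state_peaks(
    plateau_means: Sequence[float],
    k_max: int = 4,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> StateModel:
    """Locate FRET state centers from pooled plateau means.

    Fits 1-D Gaussian mixtures for k = 1..k_max and selects k by the
    Bayesian information criterion.  The assignment half-width is set from
    the fitted component spreads (3x their weighted mean), bounded by a
    floor of 0.05 and 45% of the smallest center gap.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(plateau_means, dtype=float).reshape(-1, 1)
    if x.size < k_max * min_cluster_size:
        raise ValueError(
            f"too few plateau means ({x.size}) for k_max={k_max} "
            f"(need >= {k_max * min_cluster_size})"
        )
    fits = {}
    bic = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, n_init=5, random_state=seed, covariance_type="full"
        ).fit(x)
        fits[k] = gm
        bic[k] = float(gm.bic(x))
    k_best = min(bic, key=bic.get)
    gm = fits[k_best]
    order = np.argsort(gm.means_.ravel())
    centers = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]
    halfwidth = 3.0 * float(np.sum(weights * sds))
    halfwidth = max(halfwidth, 0.05)
    if centers.size > 1:
        halfwidth = min(halfwidth, 0.45 * float(np.min(np.diff(centers))))
    return StateModel(
        centers=centers,
        assignment_halfwidth=halfwidth,
        component_sds=sds,
        bic_by_k=bic,
    )


@dataclass
class PatternAssignment:
    """Pattern call for one trace."""

    trace_id: str
    pattern: str  # I | II | III | IV | mixed | unassigned
    visited_high_states: frozenset
    n_excursions: int

    def __post_init__(self) -> None:
        if self.pattern in ("II", "III", "IV") and len(self.visited_high_states) != 1:
            raise ValueError("patterns II-IV must visit exactly one high state")
        if self.pattern == "mixed" and len(self.visited_high_states) < 2:
            raise ValueError("mixed requires >= 2 distinct high states")


def classify_trace(
    fit: StepFit,
    states: StateModel,
    visit_min_frames: int = 6,
    unassign_min_frames: int = 10,
) -> PatternAssignment:
    """Classify an idealized trace into pattern I-IV, mixed, or unassigned.

    Each plateau is assigned to the nearest state center within the
    assignment window.  Two length gates make the call robust to the step
    finder's transition artifacts (short plateaus straddling a true step
    average the two neighbouring states): a plateau certifies a state visit
    only when at least ``visit_min_frames`` long, and an unassignable
    plateau disqualifies the whole trace only when at least
    ``unassign_min_frames`` long (shorter strays are ignored).  The first
    (lowest) center is the low state; patterns are read off the set of
    visited high states.
    """
    labels = []
    for s, e, m in fit.plateaus:
        idx = states.assign(m)
        if idx is None:
            if e - s >= unassign_min_frames:
                return PatternAssignment(
                    trace_id=fit.trace_id,
                    pattern="unassigned",
                    visited_high_states=frozenset(),
                    n_excursions=0,
                )
            continue  # short stray plateau: ignore
        if e - s < visit_min_frames:
            continue  # too short to certify a state visit
        labels.append(idx)
    if not labels:
        return PatternAssignment(
            trace_id=fit.trace_id,
            pattern="unassigned",
            visited_high_states=frozenset(),
            n_excursions=0,
        )
    visited_high = frozenset(l for l in labels if l > 0)
    # count maximal runs of high-state plateaus as excursions
    n_exc = 0
    prev_high = False
    for l in labels:
        high = l > 0
        if high and not prev_high:
            n_exc += 1
        prev_high = high
    if not visited_high:
        pattern = "I"
    elif len(visited_high) == 1:
        pattern = PATTERNS[next(iter(visited_high))]
    else:
        pattern = "mixed"
    return PatternAssignment(
        trace_id=fit.trace_id,
        pattern=pattern,
        visited_high_states=visited_high,
        n_excursions=n_exc,
    )


def pattern_percentages(
    assignments: Sequence[PatternAssignment],
    n_bootstrap: int = 500,
    seed: int = 0,
):
    """Pattern fractions over assigned traces, with bootstrap CIs.

    Returns a DataFrame with one row per pattern I-IV: fraction of assigned
    traces (those called I-IV), bootstrap percentile 95% CI, and counts.
    """
    import pandas as pd

    assigned = [a for a in assignments if a.pattern in PATTERNS]
    if not assigned:
        raise ValueError("no assigned traces")
    calls = np.asarray([PATTERNS.index(a.pattern) for a in assigned])
    n = calls.size
    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, 4))
    for b in range(n_bootstrap):
        resample = calls[rng.integers(0, n, n)]
        boot[b] = np.bincount(resample, minlength=4) / n
    counts = np.bincount(calls, minlength=4)
    rows = []
    for i, p in enumerate(PATTERNS):
        lo, hi = np.percentile(boot[:, i], [2.5, 97.5])
        rows.append(
            {
                "pattern": p,
                "count": int(counts[i]),
                "fraction": counts[i] / n,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_assigned"] = n
    df.attrs["n_total"] = len(assignments)
    return df


@dataclass
class ParallelStats:
    """Mixed-trace statistic and its Monte-Carlo sequential null.

    ``fraction_mixed`` is computed over traces that visited at least one
    high state -- pattern-I traces carry no information about transitions
    among the high states.  The p-value is the add-one Monte-Carlo estimate
    of P(mixed fraction <= observed) under the sequential-ladder null: a
    small value rejects the sequential mechanism.
    """

    n_traces: int  # traces with >= 1 visited high state
    n_mixed: int
    fraction_mixed: float
    ci_low: float
    ci_high: float
    null_fractions: np.ndarray
    expected_null_fraction: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_mixed <= self.n_traces:
            raise ValueError("n_mixed must lie in [0, n_traces]")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _mixed_fraction(assignments: Sequence[PatternAssignment]) -> tuple[int, int]:
    excursion = [a for a in assignments if a.visited_high_states]
    mixed = [a for a in excursion if a.pattern == "mixed"]
    return len(mixed), len(excursion)


def parallel_vs_sequential_statistic(
    assignments: Sequence[PatternAssignment],
    generator_params: TraceGenParams,
    pattern_proportions: Sequence[float] = defaults.DEFAULT_PATTERN_PROPORTIONS,
    n_null: int = 19,
    n_traces_null: int | None = None,
    states: StateModel | None = None,
    step_config: StepFitConfig | None = None,
    seed: int = 0,
) -> ParallelStats:
    """Test the parallel-pathway claim against a sequential-ladder null.

    The statistic is the fraction of excursion-containing traces classified
    ``mixed``.  The null distribution re-runs the identical pipeline on
    ``n_null`` ensembles simulated with sequential topology and matched
    rates; under a sequential mechanism every repair attempt climbs through
    the lower high states, so mixed traces dominate.  The p-value is the
    add-one Monte-Carlo tail probability of a mixed fraction as small as
    observed.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    n_mixed, n_exc = _mixed_fraction(assignments)
    if n_exc == 0:
        raise ValueError("no excursion-containing traces to test")
    frac = n_mixed / n_exc
    # Wilson interval for the observed fraction
    from scipy.stats import norm

    z = norm.ppf(0.975)
    denom = 1 + z**2 / n_exc
    center = (frac + z**2 / (2 * n_exc)) / denom
    half = z * math.sqrt(frac * (1 - frac) / n_exc + z**2 / (4 * n_exc**2)) / denom
    n_traces_null = n_traces_null or max(len(assignments), 1)
    null_fracs = np.empty(n_null)
    master = np.random.SeedSequence(seed)
    for i, child in enumerate(master.spawn(n_null)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        params_i = replace(
            generator_params, topology="sequential", seed=sub_seed
        )
        traces = simulate_trace_ensemble(params_i, n_traces_null, pattern_proportions)
        cal = CorrectionParams.from_generation(params_i)
        null_assign = []
        for tr in traces:
            eff = correct_trace(tr, cal)
            sf = fit_steps(eff, step_config)
            if states is None:
                raise ValueError(
                    "a StateModel is required to classify the null ensembles"
                )
            null_assign.append(classify_trace(sf, states))
        m, e = _mixed_fraction(null_assign)
        null_fracs[i] = m / e if e else np.nan
    valid = null_fracs[~np.isnan(null_fracs)]
    k = int(np.sum(valid <= frac))
    p_value = (k + 1) / (valid.size + 1)
    return ParallelStats(
        n_traces=n_exc,
        n_mixed=n_mixed,
        fraction_mixed=frac,
        ci_low=max(0.0, center - half),
        ci_high=min(1.0, center + half),
        null_fractions=null_fracs,
        expected_null_fraction=float(np.nanmean(null_fracs)),
        p_value=p_value,
    )


class TracePatternModel:
    """End-to-end smFRET pattern analysis of a trace ensemble.

    Parameters
    ----------
    traces : raw two-channel traces (synthetic or read from TSV).
    calibration : channel correction; defaults to the neutral calibration.
    step_config : step-finder settings.
    k_max : maximum number of FRET states for the mixture peak locator.
    """

    def __init__(
        self,
        traces: Sequence[FluorescenceTrace],
        calibration: CorrectionParams | None = None,
        step_config: StepFitConfig | None = None,
        k_max: int = 4,
        visit_min_frames: int = 6,
    ) -> None:
        if not traces:
            raise ValueError("need at least one trace")
        self.traces = list(traces)
        self.calibration = calibration or CorrectionParams()
        self.step_config = step_config or StepFitConfig()
        self.k_max = k_max
        self.visit_min_frames = visit_min_frames

    def fit(self, n_bootstrap: int = 500, seed: int = 0) -> "TracePatternResults":
        """Run correction, step fitting, peak location and classification."""
        efficiency_traces = [
            correct_trace(tr, self.calibration) for tr in self.traces
        ]
        step_fits = [fit_steps(et, self.step_config) for et in efficiency_traces]
        # pool only plateaus long enough to certify a state: short plateaus
        # straddling a transition average two states and would smear the peaks
        means = [
            m
            for sf in step_fits
            for s, e, m in sf.plateaus
            if e - s >= self.visit_min_frames
        ]
        states = locate_state_peaks(means, k_max=self.k_max, seed=seed)
        assignments = [classify_trace(sf, states) for sf in step_fits]
        percentages = pattern_percentages(assignments, n_bootstrap, seed)
        return TracePatternResults(
            model=self,
            efficiency_traces=efficiency_traces,
            step_fits=step_fits,
            states=states,
            assignments=assignments,
            percentages=percentages,
        )


@dataclass
class TracePatternResults:
    """Results of :meth:`TracePatternModel.fit`."""

    model: TracePatternModel
    efficiency_traces: list[EfficiencyTrace]
    step_fits: list[StepFit]
    states: StateModel
    assignments: list[PatternAssignment]
    percentages: "object"  # DataFrame

    def parallel_test(
        self,
        generator_params: TraceGenParams,
        pattern_proportions: Sequence[float] = defaults.DEFAULT_PATTERN_PROPORTIONS,
        n_null: int = 19,
        n_traces_null: int | None = None,
        seed: int = 0,
    ) -> ParallelStats:
        """Monte-Carlo test of parallel vs sequential pathway topology."""
        return parallel_vs_sequential_statistic(
            self.assignments,
            generator_params,
            pattern_proportions,
            n_null=n_null,
            n_traces_null=n_traces_null,
            states=self.states,
            step_config=self.model.step_config,
            seed=seed,
        )

    def summary(self) -> str:
        lines = [
            "smFRET trace-pattern analysis",
            "=" * 46,
            f"traces analysed        {len(self.step_fits):>6d}",
            f"assigned (I-IV)        {self.percentages.attrs['n_assigned']:>6d}",
            f"state centers (E)      "
            + ", ".join(f"{c:.3f}" for c in self.states.centers),
            f"assignment halfwidth   {self.states.assignment_halfwidth:>6.3f}",
            "",
            "pattern   count   fraction   95% CI",
        ]
        for _, row in self.percentages.iterrows():
            lines.append(
                f"{row['pattern']:>7s} {row['count']:>7d} {row['fraction']:>10.3f}"
                f"   [{row['ci_low']:.3f}, {row['ci_high']:.3f}]"
            )
        n_unassigned = sum(1 for a in self.assignments if a.pattern == "unassigned")
        n_mixed = sum(1 for a in self.assignments if a.pattern == "mixed")
        lines += ["", f"mixed: {n_mixed}   unassigned: {n_unassigned}"]
        return "\n".join(lines)

    def plot_trace(self, index: int, ax=None):
        """Plot one corrected trace with its idealization overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        et = self.efficiency_traces[index]
        sf = self.step_fits[index]
        ax.plot(et.efficiency, lw=0.7, color="tab:blue", label="E")
        ax.plot(sf.idealized(), lw=1.5, color="tab:red", label="step fit")
        ax.set_xlabel("frame")
        ax.set_ylabel("FRET efficiency")
        ax.set_ylim(-0.1, 1.1)
        ax.legend(loc="upper right", fontsize=8)
        return ax
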