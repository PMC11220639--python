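"""Synthetic data generators for every stage of the pipeline.

Four experiment families are emulated:

* two-channel TIRF fluorescence traces (50-ms frames) in which a surface-bound
  ligase repeatedly bends a nicked DNA substrate: a low-FRET baseline
  (straight DNA, E ~ 0.27) with excursions to exactly one of three high-FRET
  states (E ~ 0.42 / 0.67 / 0.88) -- trace patterns I-IV;
* repair-and-then-cut spot-count fields (Cy5 spot survival after a nicking
  endonuclease attacks unrepaired substrates);
* ligation dose-response datasets (repaired fraction vs ligase concentration)
  for bending-constrained bow constructs;
* noisy two-arm 3D point clouds of ligase-DNA complexes at the four conformer
  bend angles.

All generators are deterministic under a master seed; per-trace streams are
split with ``numpy.random.SeedSequence`` so ensembles are reproducible under
any iteration order.  The trace generator is constructed to be the exact
inverse of :func:`ligbend.fret.correct_trace`: at zero noise, applying the
correction with the generating calibration returns the true efficiency path
at machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from . import defaults
from .mechanics import BowConstruct, ConformerGeometry

__all__ = [
    "TraceGenParams",
    "FluorescenceTrace",
    "SpotFieldDataset",
    "GelDataset",
    "PointCloud",
    "PointCloudSet",
    "PATTERNS",
    "simulate_trace",
    "simulate_trace_ensemble",
    "simulate_spot_fields",
    "simulate_gel_experiment",
    "simulate_complex_pointclouds",
]

PATTERNS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class TraceGenParams:
    """Generation parameters for a two-channel fluorescence trace.

    ``state_efficiencies`` orders the true FRET means (low, high_II,
    high_III, high_IV).  ``mode`` distinguishes nonsealable substrates
    (excursions recur for the whole trace) from sealable ones (exactly one
    excursion, then permanently low).  ``topology`` selects the kinetic
    null: ``parallel`` excursions visit a single high state; ``sequential``
    excursions climb the II->III->IV ladder (used only for model
    comparison).
    """

    frame_time: float = defaults.DEFAULT_FRAME_TIME_S
    n_frames: int = 400
    total_intensity: float = 1000.0
    noise_sd: float = 60.0
    background_donor: float = 40.0
    background_acceptor: float = 40.0
    crosstalk_alpha: float = 0.05
    gamma: float = 1.0
    state_efficiencies: tuple[float, float, float, float] = (
        defaults.DEFAULT_STATE_EFFICIENCIES
    )
    dwell_low: float = 1.0
    dwell_high: float = 1.0
    mode: Literal["nonsealable", "sealable"] = "nonsealable"
    topology: Literal["parallel", "sequential"] = "parallel"
    bleach_time: float | None = None  # mean photobleach time (s); None = off
    seed: int = 0

    def __post_init__(self) -> None:
        eff = np.asarray(self.state_efficiencies, dtype=float)
        if eff.shape != (4,) or not np.all(np.isfinite(eff)):
            raise ValueError("state_efficiencies must be 4 finite values")
        if np.any(eff <= 0) or np.any(eff >= 1):
            raise ValueError("state efficiencies must lie in (0, 1)")
        if np.any(np.diff(eff) <= 0):
            raise ValueError("state efficiencies must be strictly increasing")
        if not (self.frame_time > 0 and math.isfinite(self.frame_time)):
            raise ValueError("frame_time must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (self.dwell_low > 0 and self.dwell_high > 0):
            raise ValueError("dwell means must be positive")
        if self.noise_sd < 0 or self.total_intensity <= 0:
            raise ValueError("noise_sd must be >= 0 and total_intensity > 0")
        if not 0 <= self.crosstalk_alpha < 1:
            raise ValueError("crosstalk_alpha must lie in [0, 1)")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.bleach_time is not None and self.bleach_time <= 0:
            raise ValueError("bleach_time must be positive or None")
        if self.mode not in ("nonsealable", "sealable"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.topology not in ("parallel", "sequential"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for name in ("total_intensity", "noise_sd", "background_donor",
                     "background_acceptor"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class FluorescenceTrace:
    """Raw two-channel intensity time series (one immobilized molecule).

    ``metadata`` carries the generation parameters, the requested pattern and
    the true hidden state path (state index per frame, 0 = low) when the
    trace is synthetic.
    """

    donor: np.ndarray
    acceptor: np.ndarray
    trace_id: str = "trace"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D arrays of equal length")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.n_frames)


def _sample_dwell(rng: np.random.Generator, mean_s: float, frame_time: float) -> int:
    """Exponential dwell, quantized to frames, at least one frame long."""
    return max(1, int(round(rng.exponential(mean_s) / frame_time)))


def _state_path(params: TraceGenParams, pattern: str, rng: np.random.Generator) -> np.ndarray:
    """Hidden state index per frame: 0 = low, 1..3 = high II..IV."""
    n = params.n_frames
    path = np.zeros(n, dtype=int)
    if pattern == "I":
        return path
    target = PATTERNS.index(pattern)  # 1..3
    if params.topology == "sequential":
        # the high states act as obligatory rungs of a single pathway:
        # every excursion climbs II -> III -> IV before returning
        rungs = [1, 2, 3]
    else:
        rungs = [target]
    t = 0
    first = True
    while t < n:
        t += _sample_dwell(rng, params.dwell_low, params.frame_time)
        if t >= n:
            break
        if params.mode == "sealable" and not first:
            break  # nick sealed after the single excursion: low forever
        for rung in rungs:
            d = _sample_dwell(rng, params.dwell_high, params.frame_time)
            path[t : min(t + d, n)] = rung
            t += d
            if t >= n:
                break
        first = False
        if params.mode == "sealable":
            break
    return path


def simulate_trace(params: TraceGenParams, pattern: str) -> FluorescenceTrace:
    """Simulate one two-channel trace following a given pattern I-IV.

    The hidden path alternates between the low state and the pattern's high
    state with exponential dwells (pattern I never leaves the low state).
    Channel intensities are built so that the correction formula of
    :func:`ligbend.fret.correct_trace` is its exact inverse:

        donor    = bg_d + (1 - E) * I + noise
        acceptor = bg_a + gamma * E * I + alpha * (1 - E) * I + noise
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}, got {pattern!r}")
    rng = np.random.default_rng(params.seed)
    path = _state_path(params, pattern, rng)
    eff = np.asarray(params.state_efficiencies, dtype=float)[path]
    i_tot = params.total_intensity
    emitting = np.ones(path.size, dtype=bool)
    bleach_frame = None
    if params.bleach_time is not None:
        bleach_frame = int(rng.exponential(params.bleach_time) / params.frame_time)
        emitting[bleach_frame:] = False
    donor_signal = (1.0 - eff) * i_tot * emitting
    donor = params.background_donor + donor_signal
    acceptor = (
        params.background_acceptor
        + params.gamma * eff * i_tot * emitting
        + params.crosstalk_alpha * donor_signal
    )
    if params.noise_sd > 0:
        donor = donor + rng.normal(0.0, params.noise_sd, path.size)
        acceptor = acceptor + rng.normal(0.0, params.noise_sd, path.size)
    return FluorescenceTrace(
        donor=donor,
        acceptor=acceptor,
        trace_id=f"sim-{pattern}-{params.seed}",
        metadata={
            "params": params,
            "pattern": pattern,
            "true_state_path": path,
            "true_efficiency_path": eff,
            "bleach_frame": bleach_frame,
        },
    )


def simulate_trace_ensemble(
    params: TraceGenParams,
    n_traces: int,
    pattern_proportions: Sequence[float] = defaults.DEFAULT_PATTERN_PROPORTIONS,
) -> list[FluorescenceTrace]:
    """Simulate an ensemble with patterns drawn from a 4-simplex.

    Per-trace seeds are spawned deterministically from ``params.seed`` so the
    ensemble is byte-identical under a fixed master seed.
    """
    props = np.asarray(pattern_proportions, dtype=float)
    if props.shape != (4,):
        raise ValueError("pattern_proportions must have 4 entries")
    if np.any(props < 0):
        raise ValueError("pattern proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("pattern proportions must sum to 1")
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    master = np.random.SeedSequence(params.seed)
    pattern_rng = np.random.default_rng(master.spawn(1)[0])
    picks = pattern_rng.choice(4, size=n_traces, p=props)
    child_seeds = master.spawn(n_traces)
    traces = []
    for i, (pick, child) in enumerate(zip(picks, child_seeds)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        tr = simulate_trace(replace(params, seed=sub_seed), PATTERNS[pick])
        tr.trace_id = f"trace-{i:05d}"
        traces.append(tr)
    return traces


@dataclass
class SpotFieldDataset:
    """Spot counts before/after endonuclease cutting, one entry per field."""

    spots_before: np.ndarray
    spots_after: np.ndarray
    true_repair_prob: float
    true_cut_prob: float
    seed: int

    def __post_init__(self) -> None:
        self.spots_before = np.asarray(self.spots_before, dtype=int)
        self.spots_after = np.asarray(self.spots_after, dtype=int)
        if self.spots_before.shape != self.spots_after.shape:
            raise ValueError("before/after must have equal length")
        if np.any(self.spots_after < 0) or np.any(self.spots_after > self.spots_before):
            raise ValueError("spots_after must lie in [0, spots_before]")

    @property
    def n_fields(self) -> int:
        return self.spots_before.size


def simulate_spot_fields(
    n_fields: int = defaults.DEFAULT_N_FIELDS,
    spots_per_field: int = defaults.DEFAULT_SPOTS_PER_FIELD,
    repair_prob: float = 0.0,
    cut_prob: float = defaults.CONTROL_CUT_PROB,
    seed: int = 0,
) -> SpotFieldDataset:
    """Simulate the repair-and-then-cut assay.

    A spot survives the endonuclease if its nick was repaired (probability
    ``repair_prob``) or if it escaped cutting (probability ``1 - cut_prob``):
    survival = repair_prob + (1 - repair_prob) * (1 - cut_prob).
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    if spots_per_field < 0:
        raise ValueError("spots_per_field must be >= 0")
    for name, p in (("repair_prob", repair_prob), ("cut_prob", cut_prob)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    survive = repair_prob + (1.0 - repair_prob) * (1.0 - cut_prob)
    before = np.full(n_fields, spots_per_field, dtype=int)
    after = rng.binomial(before, survive)
    return SpotFieldDataset(
        spots_before=before,
        spots_after=after,
        true_repair_prob=repair_prob,
        true_cut_prob=cut_prob,
        seed=seed,
    )


@dataclass
class GelDataset:
    """Ligation dose-response data in tidy form.

    ``data`` columns: construct, linker_nt (NaN for unconstrained),
    concentration_nM, replicate, repaired_fraction.
    """

    data: "object"  # pandas.DataFrame
    incubation_time: float
    seed: int
    true_k_eff: dict = field(default_factory=dict)

    @property
    def constructs(self) -> list[str]:
        return list(dict.fromkeys(self.data["construct"]))


def simulate_gel_experiment(
    model,
    constructs: Sequence[BowConstruct],
    concentrations: Sequence[float],
    incubation_time: float = defaults.DEFAULT_INCUBATION_TIME_S,
    noise_sd: float = 0.03,
    n_replicates: int = 3,
    seed: int = 0,
) -> GelDataset:
    """Simulate gel-quantified repaired fractions for a construct series.

    The noiseless curve is the pseudo-first-order law with the conformer
    model's effective rate for each construct; replicate noise is Gaussian,
    clipped to [0, 1] (band-fraction estimates cannot leave that range).
    """
    import pandas as pd

    from .ligation import effective_rate, repair_fraction

    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("concentration grid must be non-empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    true_k = {}
    for j, construct in enumerate(constructs):
        label = construct.label if construct.label not in true_k else (
            f"{construct.label}-{j}"
        )
        k_eff = effective_rate(construct, model, seed=seed)
        true_k[label] = k_eff
        clean = repair_fraction(conc, incubation_time, k_eff)
        for rep in range(n_replicates):
            noisy = clean
            if noise_sd > 0:
                noisy = np.clip(clean + rng.normal(0.0, noise_sd, conc.size), 0.0, 1.0)
            for c, f in zip(conc, noisy):
                rows.append(
                    {
                        "construct": label,
                        "linker_nt": (
                            float("nan") if construct.unconstrained
                            else construct.linker_nt
                        ),
                        "concentration_nM": c,
                        "replicate": rep,
                        "repaired_fraction": float(f),
                    }
                )
    return GelDataset(
        data=pd.DataFrame(rows),
        incubation_time=incubation_time,
        seed=seed,
        true_k_eff=true_k,
    )


@dataclass
class PointCloud:
    """Labelled 3D point cloud of one ligase-DNA complex."""

    points: np.ndarray  # (n, 3) nm
    arm_labels: np.ndarray  # "arm1" | "arm2" per point
    true_angle: float  # degrees, after class jitter
    true_class: str  # conformer class the cloud was drawn from


@dataclass
class PointCloudSet:
    clouds: list[PointCloud]
    angle_set: tuple[float, ...]
    proportions: tuple[float, ...]
    angle_noise_sd: float
    points_per_arm: int
    arm_length: float
    positional_noise_sd: float
    seed: int


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def simulate_complex_pointclouds(
    n: int,
    angle_set: Sequence[float] = defaults.CONFORMER_ANGLES_DEG,
    proportions: Sequence[float] = defaults.LIGASE_AMP_DNA_PROPORTIONS,
    angle_noise_sd: float = 5.0,
    points_per_arm: int = 200,
    arm_length: float = 8.5,
    positional_noise_sd: float = 0.3,
    seed: int = 0,
) -> PointCloudSet:
    """Simulate two-arm point clouds of ligase-DNA complexes.

    Each cloud draws a conformer class from ``proportions``, jitters the
    class angle by a Gaussian (folded at 0 so the bend stays in [0, 180)),
    places two straight arms meeting at the origin in a random 3D
    orientation with inter-arm angle ``180 - bend``, and samples points
    uniformly along each arm with isotropic positional noise.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    angles = np.asarray(angle_set, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if angles.size != props.size:
        raise ValueError("angle_set and proportions must have equal length")
    if np.any(angles < 0) or np.any(angles >= 180):
        raise ValueError("angles must lie in [0, 180)")
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must be a simplex")
    if arm_length <= 0:
        raise ValueError("arm_length must be positive")
    if points_per_arm < 3:
        raise ValueError("points_per_arm must be >= 3 for a line fit")
    roman = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
    rng = np.random.default_rng(seed)
    classes = rng.choice(angles.size, size=n, p=props)
    clouds = []
    for k in classes:
        bend = angles[k]
        if angle_noise_sd > 0:
            bend = abs(bend + rng.normal(0.0, angle_noise_sd))
            bend = min(bend, 180.0 - 1e-9)
        inter = math.radians(180.0 - bend)
        u1 = _random_unit_vector(rng)
        # u2 at the inter-arm angle from u1, uniform in azimuth
        helper = _random_unit_vector(rng)
        perp = helper - np.dot(helper, u1) * u1
        while np.linalg.norm(perp) < 1e-12:  # helper parallel to u1: redraw
            helper = _random_unit_vector(rng)
            perp = helper - np.dot(helper, u1) * u1
        perp /= np.linalg.norm(perp)
        u2 = math.cos(inter) * u1 + math.sin(inter) * perp
        pts, labels = [], []
        for u, name in ((u1, "arm1"), (u2, "arm2")):
            t = rng.uniform(0.0, arm_length, points_per_arm)
            arm_pts = t[:, None] * u[None, :]
            if positional_noise_sd > 0:
                arm_pts = arm_pts + rng.normal(0.0, positional_noise_sd, (points_per_arm, 3))
            pts.append(arm_pts)
            labels.extend([name] * points_per_arm)
        clouds.append(
            PointCloud(
                points=np.vstack(pts),
                arm_labels=np.asarray(labels),
                true_angle=float(bend),
                true_class=roman[k],
            )
        )
    return PointCloudSet(
        clouds=clouds,
        angle_set=tuple(angles),
        proportions=tuple(props),
        angle_noise_sd=angle_noise_sd,
        points_per_arm=points_per_arm,
        arm_length=arm_length,
        positional_noise_sd=positional_noise_sd,
        seed=seed,
    )
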