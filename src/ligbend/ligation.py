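"""Conformer-selectivity model of ligation efficiency.

The ligase-AMP intermediate exists in four conformers (I-IV) that bend the
nicked DNA by ~0, 20, 60 and 100 degrees and act in parallel.  A bending
constraint on the substrate (a bow construct's minimum bend angle) blocks
the conformers that need the DNA straighter than the construct allows, so
the effective ligation rate is the proportion-weighted sum over accessible
conformers only:

    k_eff = sum_{j accessible} p_j * k_j,   j accessible iff theta_min < tau_j

With a fixed incubation time the repaired fraction follows a
pseudo-first-order law f = 1 - exp(-k_eff * c * t), giving a half-repair
concentration C50 = ln 2 / (k_eff * t).  Because theta_min maps every
construct onto one of at most four accessible sets, the C50 values of a
linker series collapse onto discrete plateaus -- the signature that the
conformers act in parallel rather than in sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import defaults
from .mechanics import BowConstruct, min_bend_angle
from .simulate import GelDataset, SpotFieldDataset

__all__ = [
    "ConformerModel",
    "C50Entry",
    "SpotFieldSummary",
    "accessible_conformers",
    "effective_rate",
    "repair_fraction",
    "fit_c50",
    "detect_plateaus",
    "analyze_spot_fields",
    "DoseResponseModel",
    "DoseResponseResults",
]

_ROMAN = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class ConformerModel:
    """The four ligase-AMP conformer states and their substrate tolerance.

    ``proportions`` defaults to the DNA-free ligase-AMP particle shares
    (conformational selection happens before DNA binding); the
    ligase-AMP-DNA shares are available in defaults for comparison.
    ``thresholds_deg[j]`` is the largest construct minimum-bend-angle
    conformer j still engages.  ``accessibility_quantile`` is the quantile
    of the bend-angle distribution used as that working minimum angle: a
    conformer needs the construct to present a compatible angle a
    non-negligible fraction of the time, not merely in the extreme tail.
    """

    angles_deg: tuple[float, ...] = defaults.CONFORMER_ANGLES_DEG
    proportions: tuple[float, ...] = defaults.LIGASE_AMP_PROPORTIONS
    rates: tuple[float, ...] = (defaults.DEFAULT_INTRINSIC_RATE,) * 4
    thresholds_deg: tuple[float, ...] = defaults.ACCESSIBILITY_THRESHOLDS_DEG
    accessibility_quantile: float = defaults.ACCESSIBILITY_QUANTILE

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        tau = np.asarray(self.thresholds_deg, dtype=float)
        th = np.asarray(self.angles_deg, dtype=float)
        k = np.asarray(self.rates, dtype=float)
        if not (p.size == tau.size == th.size == k.size):
            raise ValueError("angle/proportion/rate/threshold lengths must agree")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must be a simplex")
        if np.any(np.diff(tau) < 0):
            raise ValueError("thresholds must be non-decreasing")
        if np.any(th >= tau):
            raise ValueError("each conformer angle must lie below its threshold")
        if np.any(k < 0):
            raise ValueError("rates must be non-negative")
        if not 0 < self.accessibility_quantile <= 0.5:
            raise ValueError("accessibility_quantile must lie in (0, 0.5]")

    @property
    def n_conformers(self) -> int:
        return len(self.proportions)


def accessible_conformers(
    theta_min: float, model: ConformerModel | None = None
) -> frozenset:
    """Conformer classes that can engage a construct with the given theta_min.

    Conformer j is accessible iff theta_min < tau_j.  With the default
    thresholds (20/60/100/inf degrees) the accessible set shrinks from all
    four (unconstrained) down to {IV} (tightest bows) as theta_min grows.
    """
    model = model or ConformerModel()
    if not 0 <= theta_min < 180:
        raise ValueError("theta_min must lie in [0, 180)")
    return frozenset(
        _ROMAN[j]
        for j, tau in enumerate(model.thresholds_deg)
        if theta_min < tau
    )


def effective_rate(
    construct: BowConstruct,
    model: ConformerModel | None = None,
    n_samples: int = defaults.FJC_MC_SAMPLES,
    seed: int = 0,
) -> float:
    """Effective ligation rate (per nM per s) for one construct.

    The construct's working minimum bend angle (the model's accessibility
    quantile of its bend-angle distribution) selects the accessible
    conformers; their proportion-weighted intrinsic rates sum to k_eff.
    """
    model = model or ConformerModel()
    theta = min_bend_angle(
        construct,
        quantile=model.accessibility_quantile,
        n_samples=n_samples,
        seed=seed,
    )
    acc = accessible_conformers(theta, model)
    return float(
        sum(
            p * k
            for name, p, k in zip(_ROMAN, model.proportions, model.rates)
            if name in acc
        )
    )


def repair_fraction(concentration, time: float, k_eff: float):
    """Repaired fraction after incubating at a given ligase concentration.

    Pseudo-first-order kinetics: f = 1 - exp(-k_eff * c * t).
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0) or time < 0 or k_eff < 0:
        raise ValueError("concentration, time and k_eff must be non-negative")
    f = 1.0 - np.exp(-k_eff * c * time)
    return float(f) if np.isscalar(concentration) else f


@dataclass
class C50Entry:
    """Fitted dose-response summary for one construct."""

    construct: str
    linker_nt: float  # NaN for unconstrained
    k_eff: float
    k_eff_se: float
    c50_nM: float
    c50_se: float
    crossing: bool  # data span both sides of f = 0.5
    bound: str  # "" | "upper" | "lower" -- C50 is only a bound if not crossing
    accessible: frozenset = frozenset()
    plateau_id: int = -1


def fit_c50(
    dataset: GelDataset,
    construct: str,
) -> C50Entry:
    """Fit the pseudo-first-order law to one construct's dose-response data.

    Weighted least squares of f = 1 - exp(-k c t) on the replicate means
    over the log-spaced concentration grid, weights from replicate scatter;
    C50 = ln2 / (k t) with its standard error by the delta method.  When the
    measured fractions never cross 0.5 the fit is flagged and the C50 is
    reported as a bound (upper if everything repaired, lower if nothing).
    """
    from scipy.optimize import curve_fit

    sub = dataset.data[dataset.data["construct"] == construct]
    if sub.empty:
        raise ValueError(f"no rows for construct {construct!r}")
    grouped = sub.groupby("concentration_nM")["repaired_fraction"]
    conc = np.asarray(sorted(grouped.groups))
    if conc.size < 4:
        raise ValueError("need >= 4 concentration points")
    mean_f = grouped.mean().loc[conc].to_numpy()
    sd_f = grouped.std(ddof=1).loc[conc].to_numpy()
    n_rep = grouped.count().loc[conc].to_numpy()
    # replicate-based weights; the floor keeps saturated points (replicate
    # sd ~ 0 after clipping to [0, 1]) from dominating the fit
    se = np.where(n_rep > 1, sd_f / np.sqrt(n_rep), 0.0)
    se = np.nan_to_num(se)
    floor = max(0.3 * float(np.median(se[se > 0])) if np.any(se > 0) else 0.0, 1e-3)
    se = np.maximum(se, floor)
    t = dataset.incubation_time

    def law(c, k):
        return 1.0 - np.exp(-k * c * t)

    # initial guess from the concentration nearest half-repair
    idx = int(np.argmin(np.abs(mean_f - 0.5)))
    f0 = min(max(mean_f[idx], 1e-6), 1 - 1e-6)
    k0 = max(-math.log(1.0 - f0) / (conc[idx] * t), 1e-12)
    popt, pcov = curve_fit(
        law, conc, mean_f, p0=[k0], sigma=se, absolute_sigma=False, maxfev=10000
    )
    k_hat = float(popt[0])
    k_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    crossing = bool(mean_f.min() < 0.5 < mean_f.max())
    bound = ""
    if not crossing:
        bound = "upper" if mean_f.min() >= 0.5 else "lower"
    c50 = math.log(2.0) / (k_hat * t) if k_hat > 0 else math.inf
    c50_se = (
        math.log(2.0) / (k_hat**2 * t) * k_se
        if (k_hat > 0 and np.isfinite(k_se))
        else math.nan
    )
    linker = sub["linker_nt"].iloc[0]
    return C50Entry(
        construct=construct,
        linker_nt=float(linker) if np.isfinite(linker) else float("nan"),
        k_eff=k_hat,
        k_eff_se=k_se,
        c50_nM=c50,
        c50_se=c50_se,
        crossing=crossing,
        bound=bound,
    )


def detect_plateaus(
    entries: Sequence[C50Entry],
    gap_factor: float = 5.0,
    min_log_gap: float = 0.05,
) -> int:
    """Cluster C50 values into plateaus by 1-D gap clustering on log10(C50).

    Sorted log-C50 values are cut wherever the gap to the next value
    exceeds ``gap_factor`` times the median inter-value gap (with an
    absolute floor of ``min_log_gap`` decades, so replicate scatter inside
    a plateau never splits it).  The plateau count is an output of the
    clustering, never an input.  Assigns ``plateau_id`` (0 = smallest C50)
    in place and returns the number of plateaus.
    """
    if len(entries) < 2:
        raise ValueError("need >= 2 profiles to cluster")
    logs = np.log10([e.c50_nM for e in entries])
    if np.any(~np.isfinite(logs)):
        raise ValueError("non-finite C50 in plateau detection")
    order = np.argsort(logs)
    gaps = np.diff(logs[order])
    cut = gaps > max(gap_factor * float(np.median(gaps)), min_log_gap)
    ids_sorted = np.concatenate(([0], np.cumsum(cut)))
    for pos, entry_idx in enumerate(order):
        entries[entry_idx].plateau_id = int(ids_sorted[pos])
    return int(ids_sorted[-1]) + 1


@dataclass
class SpotFieldSummary:
    """Mean and spread of per-field spot survival."""

    mean_surviving: float
    sd_surviving: float
    n_fields: int

    @property
    def mean_lost(self) -> float:
        return 1.0 - self.mean_surviving


def analyze_spot_fields(data: SpotFieldDataset) -> SpotFieldSummary:
    """Per-field surviving fraction, averaged over fields (mean +- SD)."""
    import warnings

    before = data.spots_before
    after = data.spots_after
    usable = before > 0
    if not np.all(usable):
        warnings.warn(
            f"excluding {int(np.sum(~usable))} field(s) with zero spots",
            stacklevel=2,
        )
    if not np.any(usable):
        raise ValueError("no usable fields")
    frac = after[usable] / before[usable]
    sd = float(np.std(frac, ddof=1)) if frac.size > 1 else float("nan")
    return SpotFieldSummary(
        mean_surviving=float(np.mean(frac)),
        sd_surviving=sd,
        n_fields=int(frac.size),
    )


class DoseResponseModel:
    """C50 dose-response analysis of a gel-quantified ligation series.

    Parameters
    ----------
    dataset : GelDataset (tidy repaired-fraction table + incubation time).
    conformer_model : used only to annotate fitted entries with the
        accessible conformer set implied by each construct's linker; pass
        None to skip annotation.
    """

    def __init__(
        self,
        dataset: GelDataset,
        conformer_model: ConformerModel | None = None,
    ) -> None:
        self.dataset = dataset
        self.conformer_model = conformer_model

    def fit(
        self,
        gap_factor: float = 5.0,
        min_log_gap: float = 0.05,
        seed: int = 0,
    ) -> "DoseResponseResults":
        entries = [fit_c50(self.dataset, c) for c in self.dataset.constructs]
        if self.conformer_model is not None:
            for e in entries:
                if np.isfinite(e.linker_nt):
                    construct = BowConstruct(linker_nt=int(e.linker_nt))
                else:
                    construct = BowConstruct(linker_nt=None)
                theta = min_bend_angle(
                    construct,
                    quantile=self.conformer_model.accessibility_quantile,
                    seed=seed,
                )
                e.accessible = accessible_conformers(theta, self.conformer_model)
        n_plateaus = (
            detect_plateaus(entries, gap_factor, min_log_gap)
            if len(entries) >= 2
            else 1
        )
        return DoseResponseResults(model=self, entries=entries, n_plateaus=n_plateaus)


@dataclass
class DoseResponseResults:
    model: DoseResponseModel
    entries: list[C50Entry]
    n_plateaus: int

    def table(self):
        """Per-construct summary DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "construct": e.construct,
                    "linker_nt": e.linker_nt,
                    "k_eff": e.k_eff,
                    "c50_nM": e.c50_nM,
                    "c50_se": e.c50_se,
                    "crossing": e.crossing,
                    "bound": e.bound,
                    "accessible": "".join(
                        sorted(e.accessible, key=_ROMAN.index)
                    ) if e.accessible else "",
                    "plateau_id": e.plateau_id,
                }
                for e in self.entries
            ]
        )

    def summary(self) -> str:
        lines = [
            "ligation dose-response (C50) analysis",
            "=" * 56,
            f"constructs             {len(self.entries):>6d}",
            f"incubation time (s)    {self.model.dataset.incubation_time:>6.0f}",
            f"C50 plateaus           {self.n_plateaus:>6d}",
            "",
            "construct           linker  C50 (nM)   +-SE     plateau",
        ]
        for e in sorted(self.entries, key=lambda e: e.c50_nM):
            linker = "-" if not np.isfinite(e.linker_nt) else f"{e.linker_nt:.0f}"
            flag = f" ({e.bound} bound)" if e.bound else ""
            lines.append(
                f"{e.construct:<20s} {linker:>5s} {e.c50_nM:>9.3f} "
                f"{e.c50_se:>7.3f} {e.plateau_id:>7d}{flag}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of C50 per construct, colour-coded by plateau."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        entries = sorted(
            self.entries,
            key=lambda e: (e.linker_nt if np.isfinite(e.linker_nt) else 1e9),
        )
        xs = np.arange(len(entries))
        colors = plt.cm.tab10(np.array([e.plateau_id for e in entries]) % 10)
        ax.bar(xs, [e.c50_nM for e in entries], color=colors)
        ax.set_yscale("log")
        ax.set_xticks(xs)
        ax.set_xticklabels([e.construct for e in entries], rotation=60, ha="right")
        ax.set_ylabel("C50 (nM)")
        return ax
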