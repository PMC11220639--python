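"""Bending mechanics of linker-constrained nicked DNA ("bow" constructs).

A bow construct is a nicked 50-bp duplex whose two outer ends are tethered by
a single-stranded linker of 10-80 nt.  The duplex arms are treated as rigid
rods hinged at the nick; the ssDNA linker is a freely jointed chain (FJC).
Because ssDNA is orders of magnitude more flexible than the duplex, the
construct is well approximated by a triangle: two rigid arms of length
``a = arm_bp * rise_per_bp`` joined at the hinge, closed by the linker whose
end-to-end distance must match the chord ``d(theta) = 2 a cos(theta/2)``,
where ``theta`` is the bend angle (deviation from straight, 0 = straight).

The equilibrium bend-angle distribution is the free-hinge solid-angle law
reweighted by the linker's radial end-to-end density at the chord:

    P(theta) ~ sin(180 - theta) * rho_FJC(d(theta)) * |dd/dtheta|

A low quantile of this distribution is reported as the construct's minimum
bending angle.  The same module measures bend angles of two-arm 3D point
clouds (principal-axis line fits per arm) and maps bend angle to an expected
FRET efficiency through a calibrated Forster radius; the FRET map is
qualitative (monotone) only, since duplex twist also moves the dyes.

Angles are degrees at every public surface; radians are internal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import defaults

__all__ = [
    "SsDNAParams",
    "BowConstruct",
    "ConformerGeometry",
    "BendAngleDistribution",
    "chord_length",
    "fjc_end_to_end_samples",
    "fjc_radial_density",
    "gaussian_radial_density",
    "bend_angle_distribution",
    "min_bend_angle",
    "fret_vs_angle",
    "calibrate_forster_radius",
    "measure_bend_angle",
    "classify_complex",
]


@dataclass(frozen=True)
class SsDNAParams:
    """Freely-jointed-chain parameters for single-stranded DNA.

    contour_per_nt : nm of contour length per nucleotide.
    kuhn_length    : nm per rigid FJC segment.
    """

    contour_per_nt: float = defaults.CONTOUR_PER_NT_NM
    kuhn_length: float = defaults.KUHN_LENGTH_NM

    def __post_init__(self) -> None:
        if not (self.contour_per_nt > 0 and math.isfinite(self.contour_per_nt)):
            raise ValueError("contour_per_nt must be positive and finite")
        if not (self.kuhn_length > 0 and math.isfinite(self.kuhn_length)):
            raise ValueError("kuhn_length must be positive and finite")

    def n_segments(self, linker_nt: int) -> int:
        """Number of Kuhn segments for a linker of ``linker_nt`` nucleotides."""
        if linker_nt < 0:
            raise ValueError("linker_nt must be >= 0")
        return int(math.ceil(linker_nt * self.contour_per_nt / self.kuhn_length))


@dataclass(frozen=True)
class BowConstruct:
    """Geometric description of one bending-constrained nicked-DNA construct.

    ``linker_nt=None`` denotes the unconstrained control (no linker: the
    hinge explores its full solid angle).
    """

    arm_bp: int = defaults.ARM_BP
    rise_per_bp: float = defaults.RISE_PER_BP_NM
    linker_nt: int | None = 10
    ssdna: SsDNAParams = field(default_factory=SsDNAParams)

    def __post_init__(self) -> None:
        if self.arm_bp < 1:
            raise ValueError("arm_bp must be >= 1")
        if self.rise_per_bp <= 0:
            raise ValueError("rise_per_bp must be positive")
        if self.linker_nt is not None and self.linker_nt < 0:
            raise ValueError("linker_nt must be >= 0 or None (unconstrained)")

    @property
    def unconstrained(self) -> bool:
        return self.linker_nt is None

    @property
    def arm_length_nm(self) -> float:
        return self.arm_bp * self.rise_per_bp

    @property
    def label(self) -> str:
        return "unconstrained" if self.unconstrained else f"linker-{self.linker_nt}nt"


@dataclass(frozen=True)
class ConformerGeometry:
    """Dye geometry shared by the four ligase-DNA conformer classes."""

    angles_deg: tuple[float, ...] = defaults.CONFORMER_ANGLES_DEG
    dye_separation_bp: float = defaults.DYE_SEPARATION_BP
    rise_per_bp: float = defaults.RISE_PER_BP_NM
    forster_radius_nm: float = defaults.DEFAULT_FORSTER_RADIUS_NM

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, dtype=float)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("angles_deg must be a non-empty sequence")
        if np.any(a < 0) or np.any(a >= 180):
            raise ValueError("conformer angles must lie in [0, 180) degrees")
        if np.any(np.diff(a) <= 0):
            raise ValueError("conformer angles must be strictly increasing")
        if self.forster_radius_nm <= 0:
            raise ValueError("forster_radius_nm must be positive")


def chord_length(theta_deg: float, construct: BowConstruct) -> float:
    """Distance between the duplex outer ends at bend angle ``theta_deg``.

    With rigid arms of length ``a`` hinged at the nick and a bend of theta
    (deviation from straight) the outer ends sit ``2 a cos(theta/2)`` apart.
    """
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta > 180):
        raise ValueError("theta_deg must lie in [0, 180]")
    a = construct.arm_length_nm
    out = 2.0 * a * np.cos(np.radians(theta) / 2.0)
    return float(out) if np.isscalar(theta_deg) else out


def fjc_end_to_end_samples(
    linker_nt: int,
    ssdna: SsDNAParams | None = None,
    n_samples: int = defaults.FJC_MC_SAMPLES,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo end-to-end distances of a discrete freely jointed chain.

    Draws ``n_samples`` chains of ``N = ceil(linker_nt * contour / kuhn)``
    segments with isotropically random orientations and returns |end-to-end|
    in nm.  This is the exact discrete-FJC law (no Gaussian approximation),
    which matters for the short linkers (N ~ 5) used here.
    """
    ssdna = ssdna or SsDNAParams()
    n_seg = ssdna.n_segments(linker_nt)
    if n_seg == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed)
    end = np.zeros((n_samples, 3))
    b = ssdna.kuhn_length
    for _ in range(n_seg):
        cos_t = rng.uniform(-1.0, 1.0, n_samples)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_samples)
        sin_t = np.sqrt(1.0 - cos_t**2)
        end[:, 0] += b * sin_t * np.cos(phi)
        end[:, 1] += b * sin_t * np.sin(phi)
        end[:, 2] += b * cos_t
    return np.linalg.norm(end, axis=1)


def fjc_radial_density(
    r,
    linker_nt: int,
    ssdna: SsDNAParams | None = None,
    n_samples: int = defaults.FJC_MC_SAMPLES,
    seed: int = 0,
    n_bins: int = 400,
):
    """Radial end-to-end density (per nm) of the linker FJC, evaluated at ``r``.

    Estimated from seeded Monte-Carlo samples via a histogram on
    [0, contour length]; exactly zero beyond the contour length.  A zero
    length linker is degenerate (point mass at r=0) and rejected.
    """
    ssdna = ssdna or SsDNAParams()
    n_seg = ssdna.n_segments(linker_nt)
    if n_seg == 0:
        raise ValueError(
            "linker_nt=0 is degenerate: the end-to-end density is a point mass at r=0"
        )
    l_max = n_seg * ssdna.kuhn_length
    samples = fjc_end_to_end_samples(linker_nt, ssdna, n_samples, seed)
    hist, edges = np.histogram(samples, bins=n_bins, range=(0.0, l_max), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    r_arr = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r_arr < 0):
        raise ValueError("r must be >= 0")
    dens = np.interp(r_arr, centers, hist, left=hist[0], right=0.0)
    dens[r_arr > l_max] = 0.0
    return float(dens[0]) if np.isscalar(r) else dens


def gaussian_radial_density(r, linker_nt: int, ssdna: SsDNAParams | None = None):
    """Gaussian-chain radial density, the large-N cross-check for the FJC."""
    ssdna = ssdna or SsDNAParams()
    n_seg = ssdna.n_segments(linker_nt)
    if n_seg == 0:
        raise ValueError("linker_nt=0 is degenerate")
    nb2 = n_seg * ssdna.kuhn_length**2
    r = np.asarray(r, dtype=float)
    pref = 4.0 * np.pi * (3.0 / (2.0 * np.pi * nb2)) ** 1.5
    return pref * r**2 * np.exp(-3.0 * r**2 / (2.0 * nb2))


@dataclass
class BendAngleDistribution:
    """Equilibrium distribution of the bend angle theta in [0, 180) degrees.

    Monte-Carlo provenance stores weighted samples (theta_deg, weights);
    quadrature provenance stores a density on a regular grid.  Both expose
    cdf/quantile/density_on_grid.
    """

    provenance: str  # "monte_carlo" | "quadrature"
    theta_deg: np.ndarray
    weights: np.ndarray
    n_samples: int | None = None
    seed: int | None = None
    degenerate: bool = False
    _order: np.ndarray | None = None

    def __post_init__(self) -> None:
        total = float(np.sum(self.weights))
        if not total > 0:
            raise ValueError("bend-angle distribution has zero total weight")
        self.weights = np.asarray(self.weights, dtype=float) / total
        self.theta_deg = np.asarray(self.theta_deg, dtype=float)
        self._order = np.argsort(self.theta_deg, kind="stable")

    def cdf(self, theta_deg: float) -> float:
        """P(theta <= theta_deg)."""
        order = self._order
        th = self.theta_deg[order]
        cw = np.cumsum(self.weights[order])
        idx = np.searchsorted(th, theta_deg, side="right")
        return 0.0 if idx == 0 else float(cw[idx - 1])

    def quantile(self, q: float) -> float:
        """Smallest angle reached with probability >= q."""
        if not 0 < q <= 1:
            raise ValueError("quantile level must lie in (0, 1]")
        order = self._order
        th = self.theta_deg[order]
        cw = np.cumsum(self.weights[order])
        idx = int(np.searchsorted(cw, q, side="left"))
        idx = min(idx, th.size - 1)
        return float(th[idx])

    def density_on_grid(self, grid_deg: np.ndarray) -> np.ndarray:
        """Histogram density (per degree) on the bin edges ``grid_deg``."""
        hist, _ = np.histogram(self.theta_deg, bins=grid_deg, weights=self.weights)
        widths = np.diff(grid_deg)
        return hist / widths


def bend_angle_distribution(
    construct: BowConstruct,
    n_samples: int = defaults.FJC_MC_SAMPLES,
    seed: int = 0,
    grid_step_deg: float = 0.25,
) -> BendAngleDistribution:
    """Equilibrium bend-angle distribution of a bow construct.

    For a finite linker the free-hinge solid-angle law is reweighted by the
    linker's end-to-end density at the chord.  In Monte-Carlo form: draw
    chain end-to-end distances ``r``; each r with r <= 2a corresponds to a
    unique bend angle ``theta(r) = 2 acos(r / 2a)`` and carries the hinge
    weight sin(theta).  An unconstrained construct returns the pure
    free-hinge law on a quadrature grid.
    """
    if construct.unconstrained:
        grid = np.arange(0.0, 180.0, grid_step_deg) + grid_step_deg / 2.0
        w = np.sin(np.radians(grid))
        return BendAngleDistribution(
            provenance="quadrature", theta_deg=grid, weights=w
        )

    if construct.ssdna.n_segments(construct.linker_nt) == 0:
        # zero-length linker: the chord is pinned at 0, the duplex folds flat
        return BendAngleDistribution(
            provenance="monte_carlo",
            theta_deg=np.full(1, 180.0 - 1e-9),
            weights=np.ones(1),
            n_samples=n_samples,
            seed=seed,
            degenerate=True,
        )

    r = fjc_end_to_end_samples(construct.linker_nt, construct.ssdna, n_samples, seed)
    two_a = 2.0 * construct.arm_length_nm
    closed = r <= two_a
    if not np.any(closed):
        raise ValueError(
            f"{construct.label}: no chain conformation closes the bow "
            "(linker cannot span any chord)"
        )
    theta = np.degrees(2.0 * np.arccos(np.clip(r[closed] / two_a, -1.0, 1.0)))
    w = np.sin(np.radians(theta))
    if not np.any(w > 0):
        # all mass at exactly theta=180; treat as degenerate fold
        return BendAngleDistribution(
            provenance="monte_carlo",
            theta_deg=theta,
            weights=np.ones_like(theta),
            n_samples=n_samples,
            seed=seed,
            degenerate=True,
        )
    return BendAngleDistribution(
        provenance="monte_carlo",
        theta_deg=theta,
        weights=w,
        n_samples=n_samples,
        seed=seed,
    )


def min_bend_angle(
    construct: BowConstruct,
    quantile: float = defaults.MIN_ANGLE_QUANTILE,
    n_samples: int = defaults.FJC_MC_SAMPLES,
    seed: int = 0,
) -> float:
    """Minimum bending angle of a construct, as a low quantile of P(theta).

    The reported "minimum" is the smallest angle the construct reaches with
    probability >= ``quantile``.  Monotone non-increasing in linker length
    and non-decreasing in the quantile level.
    """
    if not 0 < quantile <= 0.5:
        raise ValueError("quantile must lie in (0, 0.5]")
    dist = bend_angle_distribution(construct, n_samples=n_samples, seed=seed)
    return dist.quantile(quantile)


def calibrate_forster_radius(
    efficiency_straight: float = defaults.UNBOUND_EFFICIENCY,
    dye_separation_bp: float = defaults.DYE_SEPARATION_BP,
    rise_per_bp: float = defaults.RISE_PER_BP_NM,
) -> float:
    """Forster radius (nm) that makes straight DNA read ``efficiency_straight``."""
    if not 0 < efficiency_straight < 1:
        raise ValueError("efficiency must lie in (0, 1)")
    r0 = dye_separation_bp * rise_per_bp
    return r0 / (1.0 / efficiency_straight - 1.0) ** (1.0 / 6.0)


def fret_vs_angle(theta_deg, geom: ConformerGeometry | None = None):
    """Expected FRET efficiency at bend angle theta (qualitative model).

    Dyes sit ``dye_separation_bp/2`` base pairs either side of the nick, so
    bending folds them together along the chord:
    ``r(theta) = dye_separation_bp * rise * cos(theta/2)`` and
    ``E = 1 / (1 + (r/R0)^6)``.  Strictly increasing in theta.  Twist at the
    nick also moves the dyes in reality, so only the ordering of the four
    conformer efficiencies is meaningful, not their exact values.
    """
    geom = geom or ConformerGeometry()
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 180):
        raise ValueError("theta_deg must lie in [0, 180)")
    r = geom.dye_separation_bp * geom.rise_per_bp * np.cos(np.radians(theta) / 2.0)
    eff = 1.0 / (1.0 + (r / geom.forster_radius_nm) ** 6)
    return float(eff) if np.isscalar(theta_deg) else eff


def _fit_arm_direction(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line fit: returns (centroid, unit direction)."""
    if points.shape[0] < 3:
        raise ValueError("each arm needs at least 3 points")
    centroid = points.mean(axis=0)
    centered = points - centroid
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate arm: all points identical")
    # first right singular vector = principal axis
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[0]


def measure_bend_angle(
    points: np.ndarray, arm_labels: Sequence[str] | np.ndarray
) -> float:
    """Bend angle (degrees) of a two-arm 3D point cloud.

    Fits a principal-axis line to each labelled arm, orients the two
    directions to point away from the shared junction, and returns
    ``180 - angle between the arms`` so that collinear arms measure 0.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(arm_labels)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if points.shape[0] != labels.shape[0]:
        raise ValueError("points and arm_labels must have equal length")
    names = sorted(set(labels.tolist()))
    if len(names) != 2:
        raise ValueError(f"expected exactly two arm labels, got {names!r}")
    c1, v1 = _fit_arm_direction(points[labels == names[0]])
    c2, v2 = _fit_arm_direction(points[labels == names[1]])
    # orient each axis to point outward, away from the other arm
    if np.dot(v1, c1 - c2) < 0:
        v1 = -v1
    if np.dot(v2, c2 - c1) < 0:
        v2 = -v2
    cos_inter = float(np.clip(np.dot(v1, v2), -1.0, 1.0))
    inter_deg = math.degrees(math.acos(cos_inter))
    return 180.0 - inter_deg


def classify_complex(angle_deg: float, geom: ConformerGeometry | None = None) -> str:
    """Assign a measured bend angle to the nearest conformer class I-IV.

    Ties at a midpoint go to the smaller class index.
    """
    geom = geom or ConformerGeometry()
    if not 0 <= angle_deg < 180:
        raise ValueError("angle_deg must lie in [0, 180)")
    angles = np.asarray(geom.angles_deg, dtype=float)
    dist = np.abs(angles - angle_deg)
    idx = int(np.argmin(dist))  # argmin takes the first (smaller) index on ties
    roman = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
    return roman[idx]
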