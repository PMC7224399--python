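"""Umbrella sampling over the diabody collective variables and WHAM.

The collective variables are rho_z, the height of the free nanobody's centre
of mass above the tethering wall, and rho_xy, the in-plane distance from the
tethering point to that centre of mass evaluated with rho_z restrained (5
sigma by default).  Windows are equally spaced harmonic biases; starting
structures are generated by dragging the free nanobody from window to window
with an equilibration stage at each centre.  The weighted-histogram analysis
method (WHAM) combines the biased histograms into a potential of mean force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import DiabodySystem
from .engine import UmbrellaBias, compiled, sample_equilibrium_mc

__all__ = [
    "CollectiveVariable",
    "UmbrellaWindow",
    "PMFProfile",
    "generate_windows",
    "run_umbrella",
    "wham",
    "pmf_flat_metric",
    "pmf_gradient",
]

#: default bias spring constant, kT/sigma^2
DEFAULT_SPRING = 10.0
#: default histogram bin width, sigma
DEFAULT_BIN_WIDTH = 0.25


@dataclass
class CollectiveVariable:
    """rho_z or rho_xy; rho_xy carries the height at which rho_z is restrained."""

    kind: str  # "rho_z" | "rho_xy"
    restraint_height: float = 5.0
    restraint_spring: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("rho_z", "rho_xy"):
            raise ValueError(f"unknown collective variable {self.kind!r}")

    def bias(self, spring: float, center: float) -> UmbrellaBias:
        return UmbrellaBias(
            kind=self.kind,
            spring=spring,
            center=center,
            z_spring=self.restraint_spring,
            z_center=self.restraint_height,
        )


@dataclass
class UmbrellaWindow:
    """One biased window: centre, spring and the sampled CV series."""

    center: float
    spring: float
    samples: np.ndarray
    flagged: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)


@dataclass
class PMFProfile:
    """Free energy (kT) on a CV grid, shifted so the minimum is zero."""

    grid: np.ndarray
    pmf: np.ndarray
    stderr: np.ndarray
    n_iterations: int = 0
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


def generate_windows(rc_min: float, rc_max: float, spacing: float) -> np.ndarray:
    """Inclusive arithmetic grid of window centres.

    (3, 30, 0.5) gives 55 centres; (5, 55, 0.5) gives 101.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if rc_max < rc_min:
        raise ValueError("rc_max must be >= rc_min")
    count = int(np.floor((rc_max - rc_min) / spacing + 1e-9)) + 1
    return rc_min + spacing * np.arange(count)


def run_umbrella(
    system: DiabodySystem,
    cv: CollectiveVariable,
    windows: np.ndarray,
    steps_per_window: int = 4000,
    drag_equilibration: int = 1000,
    spring: float = DEFAULT_SPRING,
    seed: int = 0,
    sample_every: int = 4,
) -> list[UmbrellaWindow]:
    """Biased CV series for each window, seeded by sequential dragging.

    Windows are visited in order; at each centre the system is equilibrated
    under the bias (the drag stage), then sampled.  The final configuration
    seeds the next window.  A window whose sampled mean ends up further than
    3 sigma-equivalents of the bias from its centre is flagged as unreachable
    and excluded by WHAM.
    """
    windows = np.asarray(windows, dtype=float)
    cs = compiled(system)
    state = cs.initial_state()
    out: list[UmbrellaWindow] = []
    sigma_bias = 1.0 / np.sqrt(spring)
    for w, center in enumerate(windows):
        bias = cv.bias(spring, float(center))
        traj = sample_equilibrium_mc(
            system,
            n_sweeps=steps_per_window,
            seed=seed + 7919 * w,
            sample_every=sample_every,
            bias=bias,
            burn_in=drag_equilibration,
            state=state,
        )
        cvs = np.array([cs.cv_value(f, cv.kind) for f in traj.frames])
        flagged = bool(abs(cvs.mean() - center) > 3.0 * max(sigma_bias, 0.5))
        out.append(
            UmbrellaWindow(
                float(center), spring, cvs, flagged,
                "unreachable centre" if flagged else "",
            )
        )
    return out


def _decorrelate(x: np.ndarray) -> np.ndarray:
    """Subsample a series at its estimated integrated autocorrelation time."""
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        return x
    y = x - x.mean()
    v = float(np.dot(y, y) / len(y))
    if v <= 0:
        return x[:: max(len(x) // 4, 1)]
    tau = 1.0
    for lag in range(1, min(len(x) // 4, 200)):
        rho = float(np.dot(y[:-lag], y[lag:]) / ((len(x) - lag) * v))
        if rho < 0.05:
            break
        tau += 2.0 * rho
    step = max(int(np.ceil(tau)), 1)
    return x[::step]


def wham(
    windows: list[UmbrellaWindow],
    kT: float = 1.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    decorrelate: bool = True,
    radial_jacobian: bool = False,
) -> PMFProfile:
    """Self-consistent WHAM reconstruction of the unbiased free energy.

    Iterates the standard coupled equations for the unbiased probabilities
    P(x_b) and window free energies f_i until the largest change in f_i drops
    below ``tol`` (kT).  Flagged windows are skipped; disjoint histograms (a
    gap with no samples between populated regions) raise a ValueError naming
    the gap.  Per-bin uncertainty is the Poisson estimate from total counts.

    For a planar-radius CV (rho_xy) pass ``radial_jacobian=True``: the 2D
    volume element contributes -kT ln(rho) of entropy to -kT ln P(rho), which
    is removed so the profile is the free energy of the in-plane displacement
    vector itself.
    """
    active = [w for w in windows if not w.flagged and len(w.samples) > 0]
    if not active:
        raise ValueError("no usable windows")
    samples = [
        _decorrelate(w.samples) if decorrelate else w.samples for w in active
    ]
    lo = min(s.min() for s in samples)
    hi = max(s.max() for s in samples)
    nbins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(s, bins=edges)[0] for s in samples], dtype=float)
    n_i = counts.sum(axis=1)
    total = counts.sum(axis=0)

    populated = np.nonzero(total > 0)[0]
    if len(populated) > 1:
        gaps = np.diff(populated)
        if gaps.max() > max(int(2.0 / bin_width), 2):
            g = int(np.argmax(gaps))
            raise ValueError(
                "windows do not overlap: no samples between "
                f"{centers[populated[g]]:.2f} and {centers[populated[g + 1]]:.2f}"
            )

    beta = 1.0 / kT
    bias_e = np.array(
        [0.5 * w.spring * (centers - w.center) ** 2 for w in active]
    )  # (n_win, n_bins)
    boltz = np.exp(-beta * bias_e)

    f = np.zeros(len(active))
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        denom = (n_i[:, None] * np.exp(beta * f)[:, None] * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        norm = p.sum()
        p /= norm
        f_new = -kT * np.log(np.maximum((boltz * p[None, :]).sum(axis=1), 1e-300))
        f_new -= f_new[0]
        delta = np.abs(f_new - f).max()
        f = f_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ValueError(f"WHAM did not converge in {max_iter} iterations")

    mask = p > 0
    pmf = np.full(nbins, np.nan)
    pmf[mask] = -kT * np.log(p[mask])
    if radial_jacobian:
        pmf[mask] += kT * np.log(np.maximum(centers[mask], 1e-12))
    pmf -= np.nanmin(pmf)
    stderr = np.full(nbins, np.nan)
    stderr[mask] = kT / np.sqrt(np.maximum(total[mask], 1.0))
    keep = ~np.isnan(pmf)
    return PMFProfile(
        grid=centers[keep],
        pmf=pmf[keep],
        stderr=stderr[keep],
        n_iterations=n_iter,
        converged=converged,
        metadata={"bin_width": bin_width, "n_windows": len(active), "kT": kT,
                  "radial_jacobian": radial_jacobian},
    )


def pmf_flat_metric(
    profile: PMFProfile, threshold: float = 1.0, reach: float | None = None
) -> tuple[float, float]:
    """Mean normalized CV over the flat region of a PMF, and the region's extent.

    The flat region is every grid point with PMF <= threshold (kT).  The mean
    of cv / reach over that region quantifies how far, relative to the maximum
    reach L of the tethered molecule, the free nanobody can wander at no free
    energy cost; the extent (width of the flat region) is the error-bar-style
    flatness measure.  Raises ValueError if the flat region is empty.
    """
    flat = profile.pmf <= threshold
    if not np.any(flat):
        raise ValueError("flat region is empty at this threshold")
    x = profile.grid[flat]
    scale = reach if reach is not None else 1.0
    bin_w = float(np.median(np.diff(profile.grid))) if len(profile.grid) > 1 else 0.0
    extent = float(x.max() - x.min() + bin_w)
    return float(np.mean(x / scale)), extent


def pmf_gradient(profile: PMFProfile) -> np.ndarray:
    """Derivative of the PMF: central differences, one-sided at the ends."""
    if len(profile.grid) < 3:
        raise ValueError("need at least 3 grid points")
    return np.gradient(profile.pmf, profile.grid)
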