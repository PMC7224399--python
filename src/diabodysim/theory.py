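"""Analytic tethered-Gaussian-polymer references and chain-stiffness estimators.

The central object is the equilibrium height distribution of the free end of a
Gaussian chain of ``N_k`` Kuhn segments of length ``b``, tethered at height
``z_t`` above a reflecting wall (image construction):

    P(z) = sqrt(3 / (2 pi N_k b^2)) / erf(z_t sqrt(3 / (2 N_k b^2)))
           * [exp(-3 (z - z_t)^2 / (2 N_k b^2)) - exp(-3 (z + z_t)^2 / (2 N_k b^2))]

In the limit z_t -> 0 this reduces to the wall-tethered result
P(z) = (3 z / <d^2>) exp(-3 z^2 / (2 <d^2>)) with <d^2> = N_k b^2 the mean
square end-to-end distance of the free chain.  From the threshold-crossing
probabilities P_> and P_< of an uncorrelated frame process, the geometric
run-length laws and the exponential tail constants of the flight/residence
survival probabilities follow directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf


@dataclass
class GaussianChainModel:
    """Tethered Gaussian chain: N_k Kuhn segments of length b at height z_t."""

    n_kuhn: float
    b: float = 3.0
    z_t: float = 0.0

    def __post_init__(self) -> None:
        if self.n_kuhn <= 0 or self.b <= 0 or self.z_t < 0:
            raise ValueError("n_kuhn and b must be positive, z_t non-negative")

    @property
    def mean_square_end_to_end(self) -> float:
        return self.n_kuhn * self.b**2


def tethered_end_pdf(z, model: GaussianChainModel) -> np.ndarray:
    """Reflecting-wall tethered-Gaussian end-height density, evaluated at z >= 0.

    For z_t = 0 the z_t -> 0 limit (3z/<d^2>) exp(-3z^2 / 2<d^2>) is returned.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("heights must be non-negative")
    d2 = model.mean_square_end_to_end
    if model.z_t == 0.0:
        return (3.0 * z / d2) * np.exp(-1.5 * z**2 / d2)
    a = np.sqrt(3.0 / (2.0 * d2))
    norm = np.sqrt(3.0 / (2.0 * np.pi * d2)) / erf(model.z_t * a)
    return norm * (
        np.exp(-1.5 * (z - model.z_t) ** 2 / d2)
        - np.exp(-1.5 * (z + model.z_t) ** 2 / d2)
    )


@dataclass
class ThresholdProbabilities:
    """Equilibrium probabilities of the free end being above/below z0."""

    p_above: float
    p_below: float
    z0: float
    frame_correlation_time: float = 1.0

    def __post_init__(self) -> None:
        for p in (self.p_above, self.p_below):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_above + self.p_below - 1.0) > 1e-9:
            raise ValueError("P_> + P_< must equal 1")


def threshold_probabilities(
    z0: float,
    model: GaussianChainModel | None = None,
    histogram: tuple[np.ndarray, np.ndarray] | None = None,
    frame_correlation_time: float = 1.0,
) -> ThresholdProbabilities:
    """P_> and P_< for a threshold height z0.

    The analytic branch uses the wall-tethered Gaussian chain, for which
    P_> = exp(-3 z0^2 / 2 <d^2>).  The empirical branch integrates a supplied
    ``(density, edges)`` histogram.
    """
    if z0 < 0:
        raise ValueError("z0 must be non-negative")
    if (model is None) == (histogram is None):
        raise ValueError("provide exactly one of model or histogram")
    if model is not None:
        p_above = float(np.exp(-1.5 * z0**2 / model.mean_square_end_to_end))
    else:
        density, edges = histogram
        density = np.asarray(density, dtype=float)
        edges = np.asarray(edges, dtype=float)
        widths = np.diff(edges)
        mass = density * widths
        total = mass.sum()
        if total <= 0:
            raise ValueError("histogram has no mass")
        mass = mass / total
        # split the bin containing z0 proportionally
        above = 0.0
        for k in range(len(mass)):
            lo, hi = edges[k], edges[k + 1]
            if lo >= z0:
                above += mass[k]
            elif hi > z0:
                above += mass[k] * (hi - z0) / (hi - lo)
        p_above = float(above)
    return ThresholdProbabilities(p_above, 1.0 - p_above, z0, frame_correlation_time)


def run_length_distribution(
    p_above: float, p_below: float, k, approximate: bool = False
):
    """Probabilities of k consecutive frames above (P_a) or below (P_b) z0.

    For an uncorrelated frame process,
    P_a(k) = P_> (1 - P_<)^(k-1) P_< and P_b(k) = P_< (1 - P_>)^(k-1) P_>.
    With ``approximate=True`` the small-probability exponential forms
    P_< e^(-P_< k) and P_> e^(-P_> k) are returned instead.
    """
    k = np.asarray(k)
    if np.any(k < 1):
        raise ValueError("run length k must be >= 1")
    if approximate:
        pa = p_below * np.exp(-p_below * k)
        pb = p_above * np.exp(-p_above * k)
    else:
        pa = p_above * (1.0 - p_below) ** (k - 1) * p_below
        pb = p_below * (1.0 - p_above) ** (k - 1) * p_above
    return pa, pb


@dataclass
class TailConstants:
    """Exponential tail constants of the flight/residence survival curves."""

    tau_flight: float
    tau_residence: float
    tau_flight_expanded: float
    tau_residence_expanded: float
    expansion_valid: bool


def tail_constants_theory(z0: float, d2: float, dt_c: float) -> TailConstants:
    """Tail constants tau_f = dt_c / P_< and tau_r = dt_c / P_> for the
    wall-tethered Gaussian chain, with their small-(z0^2/<d^2>) expansions
    tau_f ~ dt_c 2<d^2>/(3 z0^2) and tau_r ~ dt_c (1 + 3 z0^2/(2 <d^2>))."""
    if z0 <= 0 or d2 <= 0 or dt_c <= 0:
        raise ValueError("all arguments must be positive")
    x = 1.5 * z0**2 / d2
    p_above = np.exp(-x)
    return TailConstants(
        tau_flight=dt_c / (1.0 - p_above),
        tau_residence=dt_c / p_above,
        tau_flight_expanded=dt_c / x,
        tau_residence_expanded=dt_c * (1.0 + x),
        expansion_valid=bool(x < 0.2),
    )


# ---------------------------------------------------------------------------
# persistence length
# ---------------------------------------------------------------------------


@dataclass
class PersistenceFit:
    """Result of the bond-direction correlation fit."""

    persistence_length: float
    kuhn_length: float
    correlations: np.ndarray
    separations: np.ndarray
    warning: str | None = None


def persistence_length(
    conformations: np.ndarray,
    bond_length: float = 1.0,
    max_separation: int = 15,
) -> PersistenceFit:
    """Persistence length from the decay of bond-direction correlations.

    ``conformations`` is an (n_frames, n_beads, 3) array of decorrelated chain
    configurations.  C(s) = <u_i . u_{i+s}> is fitted by exp(-s b0 / l_p) with
    a weighted log-linear fit over separations 1..max_separation; the Kuhn
    length is b = 2 l_p.  A non-decaying correlation (rigid rod) triggers a
    fit-range warning and returns the lower bound from the largest separation.
    """
    x = np.asarray(conformations, dtype=float)
    if x.ndim != 3 or x.shape[1] < 3:
        raise ValueError("need (n_frames, n_beads >= 3, 3) conformations")
    u = np.diff(x, axis=1)
    u /= np.linalg.norm(u, axis=2, keepdims=True)
    n_bonds = u.shape[1]
    smax = min(max_separation, n_bonds - 1)
    seps = np.arange(1, smax + 1)
    C = np.array(
        [np.mean(np.einsum("fid,fid->fi", u[:, : n_bonds - s], u[:, s:])) for s in seps]
    )
    # fit only above the statistical noise floor of the correlation estimate
    floor = 3.0 / np.sqrt(x.shape[0] * n_bonds / 2.0)
    positive = C > max(floor, 1e-3)
    if positive.sum() < 2:
        # decorrelated beyond the first bond: bound l_p by the first point
        c1 = max(C[0], 1e-3)
        lp = -bond_length / np.log(c1)
        return PersistenceFit(lp, 2 * lp, C, seps, warning="correlation lost after one bond")
    s_fit = seps[positive]
    c_fit = C[positive]
    w = c_fit  # inverse std of ln C for a constant absolute noise level
    slope, _ = np.polyfit(s_fit, np.log(c_fit), 1, w=w)
    if slope >= -1e-9:
        lp = float(s_fit[-1] * bond_length)
        return PersistenceFit(
            lp, 2 * lp, C, seps,
            warning="non-decaying correlation; returned lower bound from fit range",
        )
    lp = float(-bond_length / slope)
    return PersistenceFit(lp, 2.0 * lp, C, seps)


def sample_wlc_chain(
    n_bonds: int,
    n_frames: int,
    bend_k: float = 1.8,
    style: str = "cosine",
    bond_length: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Direct (Markov) sampler of the discrete worm-like-chain measure.

    Each deflection angle gamma between consecutive bonds is drawn from
    sin(gamma) exp(-E(gamma)/kT) by rejection, with E either the Kratky-Porod
    cosine form k(1 - cos gamma) or the harmonic form k gamma^2 / 2; azimuths
    are uniform.  Used as the independent oracle for the persistence-length
    estimator (no simulation dynamics involved).
    """
    rng = np.random.default_rng(seed)
    conf = np.zeros((n_frames, n_bonds + 1, 3))
    for f in range(n_frames):
        u = _random_unit(rng)
        pts = [np.zeros(3)]
        for _ in range(n_bonds):
            pts.append(pts[-1] + bond_length * u)
            gamma = _sample_deflection(rng, bend_k, style)
            u = _deflect(u, gamma, rng.uniform(0, 2 * np.pi))
        conf[f] = np.array(pts[: n_bonds + 1])
    return conf


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _sample_deflection(rng, k: float, style: str) -> float:
    if k == 0:
        return float(np.arccos(rng.uniform(-1, 1)))
    while True:
        g = rng.uniform(0, np.pi)
        e = k * (1 - np.cos(g)) if style == "cosine" else 0.5 * k * g * g
        if rng.random() < np.sin(g) * np.exp(-e):
            return float(g)


def _deflect(u: np.ndarray, gamma: float, phi: float) -> np.ndarray:
    """New unit vector at polar angle gamma from u, azimuth phi about u."""
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return (
        np.cos(gamma) * u
        + np.sin(gamma) * (np.cos(phi) * e1 + np.sin(phi) * e2)
    )


# ---------------------------------------------------------------------------
# effective-polymer fit
# ---------------------------------------------------------------------------


@dataclass
class EffectiveFit:
    """Effective Kuhn-segment number fitted to a simulated height histogram."""

    n_kuhn_eff: float
    b: float
    z_t: float
    residual: float
    naive_guess: float
    centers: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)


def fit_effective_Nk(
    density: np.ndarray,
    edges: np.ndarray,
    b: float = 3.0,
    z_t: float = 7.5,
    linker_length: float | None = None,
    arm_half_span: float = 5.65,
    use_reflected: bool = True,
) -> EffectiveFit:
    """Fit the tethered-Gaussian height density with N_k free (b, z_t fixed).

    ``density, edges`` is the empirical (normalized) z-histogram of the free
    paratope.  The naive contour-length guess (N + 2r)/b is reported alongside
    when the linker length N is given (r is half the paratope-connector span
    of one nanobody arm).  ``use_reflected=False`` switches to the z_t -> 0
    form.  A non-normalized histogram is renormalized with a warning.
    """
    density = np.asarray(density, dtype=float)
    edges = np.asarray(edges, dtype=float)
    widths = np.diff(edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = float((density * widths).sum())
    if abs(total - 1.0) > 1e-6:
        import warnings

        warnings.warn("histogram not normalized; renormalizing", stacklevel=2)
        density = density / total

    zt_eff = z_t if use_reflected else 0.0

    def f(z, n_kuhn):
        return tethered_end_pdf(z, GaussianChainModel(abs(n_kuhn), b, zt_eff))

    d2_guess = max(float((density * widths * centers**2).sum()), 1e-6)
    p0 = max(d2_guess / b**2, 1.0)
    popt, _ = curve_fit(f, centers, density, p0=[p0], maxfev=20000)
    nk = float(abs(popt[0]))
    resid = float(np.sqrt(np.mean((f(centers, nk) - density) ** 2)))
    naive = float((linker_length + 2 * arm_half_span) / b) if linker_length else np.nan
    return EffectiveFit(nk, b, zt_eff, resid, naive, centers, density)
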