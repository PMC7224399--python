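"""Flight/residence decomposition of paratope height series and the kinetics
of the second binding.

A height series z(t) of the free paratope is split at a threshold z0 into
alternating flight (z >= z0) and residence (z < z0) events; stretches shorter
than a minimum duration are absorbed into the enclosing event (recrossing
filter).  The survival probabilities S_f(t), S_r(t) of the two domains are the
empirical complementary cumulative distributions of the event durations; their
time integrals are the mean flight/residence times, whose inverses estimate
the on- and off-rate of the paratope-wall encounter:

    k_on  = [ integral S_f(t) dt ]^-1 = 1 / <t_f>
    k_off = [ integral S_r(t) dt ]^-1 = 1 / <t_r>

Long events are exponentially distributed (tail constants tau_f, tau_r), while
the short-time behaviour of the survival curves follows the t^(-1/2) power law
of free three-dimensional diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventConfig",
    "Event",
    "EventSeries",
    "SurvivalCurve",
    "RateEstimate",
    "TailFit",
    "decompose_events",
    "survival_curve",
    "rates_from_survival",
    "fit_exponential_tail",
    "fit_shorttime_powerlaw",
    "rate_gain_ratios",
]


@dataclass
class EventConfig:
    """Threshold height and recrossing filter for event decomposition."""

    z0: float = 3.5
    min_duration: float = 0.0  # in time units; converted via frame_interval
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if self.z0 <= 0:
            raise ValueError("threshold height must be positive")
        if self.min_duration < 0:
            raise ValueError("min_duration must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def min_frames(self) -> int:
        return int(np.ceil(self.min_duration / self.frame_interval - 1e-9))


@dataclass
class Event:
    kind: str  # "flight" | "residence"
    duration: float  # time units
    n_frames: int
    censored: bool = False


@dataclass
class EventSeries:
    """Alternating flight/residence events extracted from one height series."""

    events: list[Event]
    config: EventConfig
    source: str = ""

    def __post_init__(self) -> None:
        for a, b in zip(self.events, self.events[1:]):
            if a.kind == b.kind:
                raise ValueError("event kinds must strictly alternate")

    def durations(self, kind: str, include_censored: bool = False) -> np.ndarray:
        return np.array(
            [
                e.duration
                for e in self.events
                if e.kind == kind and (include_censored or not e.censored)
            ]
        )

    @property
    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.events))


def _runs(above: np.ndarray) -> list[list[int]]:
    """[value, length] runs of a boolean series."""
    runs: list[list[int]] = []
    for v in above:
        if runs and runs[-1][0] == int(v):
            runs[-1][1] += 1
        else:
            runs.append([int(v), 1])
    return runs


def decompose_events(
    z: np.ndarray, config: EventConfig, source: str = ""
) -> EventSeries:
    """Split a height series into alternating flight/residence events.

    Frames with z >= z0 are flight, z < z0 residence.  Runs shorter than
    ``min_duration`` are merged into the surrounding event, shortest first
    (the two neighbours, being of the common opposite kind, coalesce with the
    short run into a single event), which guarantees strict alternation.  The
    first and last events are truncated by the trajectory ends and marked
    censored; they are excluded from duration statistics by default.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or len(z) < 2:
        raise ValueError("need a 1D series of at least 2 frames")
    if np.all(z == config.z0):
        raise ValueError("degenerate series: constant exactly at the threshold")
    above = z >= config.z0
    runs = _runs(above)

    min_frames = config.min_frames
    # absorb sub-threshold runs, shortest first; never absorb the sole run
    while len(runs) > 1:
        lengths = [r[1] for r in runs]
        k = int(np.argmin(lengths))
        if lengths[k] >= min_frames:
            break
        v, ln = runs.pop(k)
        if 0 < k < len(runs):  # interior: neighbours share a kind, coalesce
            runs[k - 1][1] += ln + runs[k][1]
            runs.pop(k)
        elif k == 0:
            runs[0][1] += ln
        else:
            runs[-1][1] += ln
    events = [
        Event(
            kind="flight" if v else "residence",
            duration=ln * config.frame_interval,
            n_frames=ln,
        )
        for v, ln in runs
    ]
    if events:
        events[0].censored = True
        events[-1].censored = True
    return EventSeries(events, config, source)


@dataclass
class SurvivalCurve:
    """Empirical survival probability S(t) of event durations.

    S(t) is the fraction of events lasting strictly longer than t: a
    right-continuous step function with S(0 <= t < min duration) = 1.
    """

    times: np.ndarray  # sorted unique durations
    survival: np.ndarray  # S evaluated AT each time (after the drop)
    domain: str  # "flight" | "residence"
    n_events: int
    durations: np.ndarray = field(repr=False, default=None)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.durations[None, :] > t[..., None]).mean(axis=-1)

    @property
    def mean_duration(self) -> float:
        return float(self.durations.mean())

    def integral(self) -> float:
        """Integral of S(t) dt over [0, inf) -- equals the mean duration."""
        return float(self.durations.mean())


def survival_curve(series: EventSeries | np.ndarray, kind: str = "flight") -> SurvivalCurve:
    """Empirical complementary cumulative distribution of event durations."""
    if isinstance(series, EventSeries):
        durations = series.durations(kind)
    else:
        durations = np.asarray(series, dtype=float)
    if len(durations) == 0:
        raise ValueError(f"no {kind} events")
    d = np.sort(durations)
    times = np.unique(d)
    surv = np.array([(d > t).mean() for t in times])
    return SurvivalCurve(times, surv, kind, len(d), durations=d)


@dataclass
class RateEstimate:
    """On/off rates as inverse mean flight/residence times (bootstrap errors)."""

    k_on: float
    k_off: float
    k_on_stderr: float
    k_off_stderr: float
    n_flights: int
    n_residences: int


def _bootstrap_rate(durations: np.ndarray, n_boot: int, rng) -> float:
    if len(durations) < 2:
        return float("inf")
    means = np.array(
        [durations[rng.integers(0, len(durations), len(durations))].mean()
         for _ in range(n_boot)]
    )
    return float(np.std(1.0 / means))


def rates_from_survival(
    s_flight: SurvivalCurve,
    s_residence: SurvivalCurve,
    n_boot: int = 1000,
    seed: int = 0,
) -> RateEstimate:
    """k_on = 1/mean flight time, k_off = 1/mean residence time.

    The trapezoidal integral of the empirical survival step function equals
    the direct mean of the durations identically; rates are its reciprocals.
    """
    rng = np.random.default_rng(seed)
    return RateEstimate(
        k_on=1.0 / s_flight.integral(),
        k_off=1.0 / s_residence.integral(),
        k_on_stderr=_bootstrap_rate(s_flight.durations, n_boot, rng),
        k_off_stderr=_bootstrap_rate(s_residence.durations, n_boot, rng),
        n_flights=s_flight.n_events,
        n_residences=s_residence.n_events,
    )


@dataclass
class TailFit:
    """Exponential-tail or power-law fit of a survival curve."""

    value: float  # tau or exponent alpha
    stderr: float
    window: tuple[float, float]
    n_events: int
    poor_fit: bool = False
    note: str = ""


def fit_exponential_tail(
    s: SurvivalCurve, t_min: float, min_events: int = 10
) -> TailFit:
    """Decay constant tau of the exponential tail of S(t).

    Weighted linear fit of ln S versus t over [t_min, last event), with
    weights proportional to the number of surviving events (the statistical
    precision of ln S).  Raises ValueError when fewer than ``min_events``
    events exceed t_min.
    """
    d = s.durations
    sel = (s.times >= t_min) & (s.survival > 0)
    if (d > t_min).sum() < min_events or sel.sum() < 3:
        raise ValueError(
            f"insufficient tail data: {(d > t_min).sum()} events beyond t_min"
        )
    t = s.times[sel]
    y = np.log(s.survival[sel])
    w = np.sqrt(s.survival[sel] * s.n_events)
    (slope, _), cov = np.polyfit(t, y, 1, w=w, cov=True)
    if slope >= 0:
        raise ValueError("survival tail does not decay; cannot fit tau")
    tau = -1.0 / slope
    tau_err = float(np.sqrt(cov[0, 0]) / slope**2)
    return TailFit(float(tau), tau_err, (float(t_min), float(d.max())), int((d > t_min).sum()))


def fit_shorttime_powerlaw(
    s: SurvivalCurve, t_window: tuple[float, float], min_events: int = 100
) -> TailFit:
    """Short-time power-law exponent alpha of S(t) ~ t^(-alpha).

    Log-log least squares over the window.  A quadratic curvature diagnostic
    flags the fit as poor when the survival curve is visibly non-power-law
    (e.g. exponential) inside the window.
    """
    t_lo, t_hi = t_window
    d = s.durations
    inside = (d >= t_lo) & (d <= t_hi)
    if inside.sum() < min_events:
        raise ValueError(
            f"insufficient data: {int(inside.sum())} events inside the window"
        )
    sel = (s.times >= t_lo) & (s.times <= t_hi) & (s.survival > 0)
    lt = np.log(s.times[sel])
    ly = np.log(s.survival[sel])
    (slope, _), cov = np.polyfit(lt, ly, 1, cov=True)
    quad = np.polyfit(lt, ly, 2)
    resid_lin = ly - np.polyval(np.polyfit(lt, ly, 1), lt)
    span = max(ly.max() - ly.min(), 1e-12)
    curvature = abs(quad[0]) * (lt.max() - lt.min()) ** 2 / span
    poor = bool(curvature > 0.5 or np.std(resid_lin) / span > 0.15)
    return TailFit(
        value=float(-slope),
        stderr=float(np.sqrt(cov[0, 0])),
        window=(float(t_lo), float(t_hi)),
        n_events=int(inside.sum()),
        poor_fit=poor,
        note="curvature diagnostic failed" if poor else "",
    )


def rate_gain_ratios(rates: pd.DataFrame, baseline_eps: float = 0.0) -> pd.DataFrame:
    """Avidity gain factors k(eps, N) / k(0, N) over a wall-attraction grid.

    ``rates`` needs columns (eps, N, k_on, k_off) and may carry k_on_stderr /
    k_off_stderr, which are propagated to the ratios in quadrature.  Raises
    KeyError when the baseline eps is absent.
    """
    req = {"eps", "N", "k_on", "k_off"}
    if not req.issubset(rates.columns):
        raise KeyError(f"rates table needs columns {sorted(req)}")
    base = rates[rates["eps"] == baseline_eps].set_index("N")
    if base.empty:
        raise KeyError(f"no baseline rows with eps = {baseline_eps}")
    rows = []
    for _, r in rates.iterrows():
        if r["N"] not in base.index:
            raise KeyError(f"no baseline for N = {r['N']}")
        b = base.loc[r["N"]]
        row = {
            "eps": r["eps"],
            "N": r["N"],
            "gain_on": r["k_on"] / b["k_on"],
            "gain_off": r["k_off"] / b["k_off"],
        }
        for which in ("on", "off"):
            sc, sb = f"k_{which}_stderr", f"k_{which}"
            if sc in rates.columns and np.isfinite(r.get(sc, np.nan)):
                rel = np.sqrt(
                    (r[sc] / r[sb]) ** 2 + (b[sc] / b[sb]) ** 2
                )
                row[f"gain_{which}_stderr"] = row[f"gain_{which}"] * rel
        rows.append(row)
    return pd.DataFrame(rows)
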