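"""First-order drug-release kinetics and delivery efficacy.

The cumulative concentration released from a porous matrix into a fixed
volume is modelled as a first-order relaxation

    c(t) = c0 + cs * (1 - exp(-t / tau))

with ``c0`` the baseline concentration (0 when release starts into pure
water), ``cs`` the steady-state concentration increment (uM) and ``tau`` the
time constant of the delivery system (h).  A first-order Taylor expansion of
the model at t = 0 gives the initial release velocity v = cs / tau (uM/h).

The biological efficacy of a drug-loaded substrate at a given time point is
quantified from adhering-cell counts as E = 1 - N_drug / N_ctrl, i.e. the
fraction of cells suppressed relative to the same substrate without drug.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ParameterError

__all__ = [
    "ReleaseModelParams",
    "ReleaseCurve",
    "ReleaseFit",
    "EfficacyRecord",
    "first_order_model",
    "fit_release",
    "initial_velocity",
    "release_efficiency",
    "drug_efficacy",
    "half_life_extension",
    "round_half_up",
]


@dataclass(frozen=True)
class ReleaseModelParams:
    """Parameters (c0, cs, tau) of the first-order release model."""

    c0: float = 0.0        # uM
    cs: float = 0.0        # uM
    tau: float = 1.0       # h

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ParameterError(f"tau must be > 0, got {self.tau}")
        if self.cs < 0:
            raise ParameterError(f"cs must be >= 0, got {self.cs}")


@dataclass
class ReleaseCurve:
    """Concentration-versus-time observations for one substrate."""

    times_h: np.ndarray
    concentrations_uM: np.ndarray
    c_load_uM: float | None = None   # loading concentration, e.g. 30 or 50 uM
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        c = np.asarray(self.concentrations_uM, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ParameterError("times and concentrations must be 1-D and equal length")
        if t.size and (t.min() < 0 or np.any(np.diff(t) <= 0)):
            raise ParameterError("times must be non-negative and strictly increasing")
        if c.size and c.min() < 0:
            raise ParameterError("concentrations must be non-negative")
        self.times_h = t
        self.concentrations_uM = c


@dataclass
class ReleaseFit:
    """Fitted model plus least-squares diagnostics."""

    params: ReleaseModelParams
    rss: float
    converged: bool
    message: str = ""
    param_sd: dict[str, float] = field(default_factory=dict)


@dataclass
class EfficacyRecord:
    """Drug efficacy from adhering-cell counts at one time point."""

    n_drug: float
    n_ctrl: float
    efficacy: float
    substrate: str = ""
    time_h: float = float("nan")


def first_order_model(t, p: ReleaseModelParams):
    """Evaluate c(t) = c0 + cs*(1 - exp(-t/tau)); monotone non-decreasing."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("t must be >= 0")
    out = p.c0 + p.cs * (1.0 - np.exp(-t / p.tau))
    return float(out) if out.ndim == 0 else out


def fit_release(curve: ReleaseCurve, fix_c0: bool = True) -> ReleaseFit:
    """Nonlinear least-squares fit of the first-order release model.

    With ``fix_c0=True`` (default) the baseline is pinned to 0, matching a
    release into pure water started at t = 0.  Initialization: cs0 is the
    observed concentration span and tau0 the first time the curve exceeds
    63% of that span (median observation time as fallback).  Bounds keep
    cs >= 0 and tau > 0.
    """
    t = curve.times_h
    c = curve.concentrations_uM
    min_pts = 2 if fix_c0 else 3
    if t.size < min_pts:
        raise ParameterError(f"need at least {min_pts} points, got {t.size}")

    c0_guess = 0.0 if fix_c0 else float(c[0])
    cs0 = float(c.max() - c.min())
    if cs0 <= 0:
        return ReleaseFit(
            params=ReleaseModelParams(c0=c0_guess, cs=0.0, tau=1.0),
            rss=0.0,
            converged=False,
            message="constant curve: cs ~ 0, tau unidentifiable",
        )
    above = t[c > c0_guess + 0.63 * cs0]
    tau0 = float(above[0]) if above.size else float(np.median(t))
    tau0 = max(tau0, 1e-6)

    tiny = 1e-12
    try:
        if fix_c0:
            popt, pcov = curve_fit(
                lambda tt, cs, tau: cs * (1.0 - np.exp(-tt / tau)),
                t, c, p0=[cs0, tau0], bounds=([0.0, tiny], [np.inf, np.inf]),
                maxfev=10000,
            )
            c0_hat, (cs_hat, tau_hat) = 0.0, popt
            names = ["cs", "tau"]
        else:
            popt, pcov = curve_fit(
                lambda tt, c0, cs, tau: c0 + cs * (1.0 - np.exp(-tt / tau)),
                t, c, p0=[c0_guess, cs0, tau0],
                bounds=([-np.inf, 0.0, tiny], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
            c0_hat, cs_hat, tau_hat = popt
            names = ["c0", "cs", "tau"]
    except RuntimeError as exc:
        raise FitError(f"release fit did not converge: {exc}") from exc

    params = ReleaseModelParams(c0=float(c0_hat), cs=float(cs_hat), tau=float(tau_hat))
    resid = c - first_order_model(t, params)
    sds = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(len(names), np.nan)
    return ReleaseFit(
        params=params,
        rss=float(np.sum(resid**2)),
        converged=True,
        param_sd=dict(zip(names, (float(s) for s in sds))),
    )


def initial_velocity(p: ReleaseModelParams) -> float:
    """Early-time release velocity v = cs / tau (uM/h).

    Equals the analytic slope of the model at t = 0, i.e. the first-order
    term of its Taylor expansion.
    """
    return p.cs / p.tau


def release_efficiency(
    p: ReleaseModelParams, c_load_uM: float, times_h=None
) -> tuple[np.ndarray, float]:
    """Release profile normalized to the loading concentration.

    Returns ``(c(t)/c_load over times_h, cs/c_load)``; the second element is
    the asymptotic efficiency of the delivery system.
    """
    if c_load_uM <= 0:
        raise ParameterError(f"c_load must be > 0, got {c_load_uM}")
    if times_h is None:
        times_h = np.linspace(0.0, 5.0 * p.tau, 101)
    profile = np.asarray(first_order_model(times_h, p)) / c_load_uM
    return profile, p.cs / c_load_uM


def drug_efficacy(
    n_drug: float, n_ctrl: float, substrate: str = "", time_h: float = float("nan")
) -> EfficacyRecord:
    """Efficacy E = 1 - N_drug/N_ctrl of a drug-loaded substrate."""
    if n_ctrl <= 0:
        raise ParameterError(f"n_ctrl must be > 0, got {n_ctrl}")
    if n_drug < 0:
        raise ParameterError(f"n_drug must be >= 0, got {n_drug}")
    return EfficacyRecord(
        n_drug=n_drug,
        n_ctrl=n_ctrl,
        efficacy=1.0 - n_drug / n_ctrl,
        substrate=substrate,
        time_h=time_h,
    )


def half_life_extension(release_duration_h: float, drug_half_life_h: float) -> tuple[float, float]:
    """How much a sustained-release device extends a drug's action window.

    Returns ``(fold, percent_increase)`` where fold = duration / half-life.
    """
    if release_duration_h <= 0 or drug_half_life_h <= 0:
        raise ParameterError("durations must be > 0")
    fold = release_duration_h / drug_half_life_h
    return fold, (fold - 1.0) * 100.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, matching report-table conventions."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))
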