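"""Biolayer-interferometry kinetic analysis via the kobs-vs-concentration route.

For a 1:1 interaction the association phase of a sensorgram follows
R(t) = Req·(1 − exp(−kobs·t)) with kobs = kon·C + koff, so fitting a single
exponential per analyte concentration and regressing kobs on C yields kon
(slope), koff (intercept) and Kd = koff/kon.  The dissociation phase gives an
independent koff as a consistency check.  Sensorgrams are baseline-aligned
before fitting and the first seconds of the association phase (mixing
artifact) are excluded from the fit window by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BLIStage",
    "BLITrace",
    "KobsFit",
    "KineticFit",
    "DissociationFit",
    "align_baseline",
    "fit_kobs",
    "kinetic_analysis",
    "fit_dissociation",
    "analyze_sensors",
]

#: Seconds trimmed from the start of the association phase (mixing artifact).
DEFAULT_WINDOW_START = 2.0

#: Fraction of the baseline tail averaged for alignment.
BASELINE_TAIL_FRACTION = 0.2


@dataclass(frozen=True)
class BLIStage:
    label: str  # "baseline" | "association" | "dissociation"
    time: np.ndarray  # seconds
    response: np.ndarray  # nm

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "response", np.asarray(self.response, dtype=float))
        if self.time.shape != self.response.shape:
            raise ValueError(f"stage {self.label!r}: time/response length mismatch")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError(f"stage {self.label!r}: time not strictly increasing")


@dataclass(frozen=True)
class BLITrace:
    """One sensor's staged interferogram at a single analyte concentration."""

    sensor_id: str
    analyte_conc: float  # molar
    stages: list[BLIStage]

    def stage(self, label: str) -> BLIStage | None:
        for s in self.stages:
            if s.label == label:
                return s
        return None


@dataclass(frozen=True)
class KobsFit:
    conc: float  # molar
    kobs: float = np.nan  # 1/s
    kobs_err: float = np.nan
    req: float = np.nan  # nm
    req_err: float = np.nan
    window: tuple = (np.nan, np.nan)
    usable: bool = False
    message: str = ""


@dataclass(frozen=True)
class KineticFit:
    kon: float  # 1/(M s)
    kon_err: float
    koff: float  # 1/s
    koff_err: float
    kd: float  # molar, koff/kon
    kd_err: float
    r_squared: float
    n_concs: int
    reliable: bool = True
    message: str = ""


@dataclass(frozen=True)
class DissociationFit:
    koff: float = np.nan
    koff_err: float = np.nan
    r0: float = np.nan
    usable: bool = False
    message: str = ""


# ---------------------------------------------------------------------------


def align_baseline(trace: BLITrace) -> BLITrace:
    """Zero a sensorgram on its buffer baseline and re-zero stage clocks.

    The mean response over the final 20% of the baseline stage is subtracted
    from every stage, and each stage's time axis is re-zeroed at its start.
    A missing baseline passes the trace through (warning, zero offset).
    """
    base = trace.stage("baseline")
    if base is None:
        warnings.warn(f"sensor {trace.sensor_id!r}: no baseline stage; offset 0 assumed", stacklevel=2)
        offset = 0.0
    else:
        n_tail = max(1, int(round(BASELINE_TAIL_FRACTION * base.time.size)))
        offset = float(np.mean(base.response[-n_tail:]))
    stages = [
        BLIStage(s.label, s.time - s.time[0], s.response - offset) for s in trace.stages
    ]
    return replace(trace, stages=stages)


def fit_kobs(trace: BLITrace, window: "tuple[float, float] | None" = None) -> KobsFit:
    """Fit R(t) = Req·(1 − exp(−kobs·t)) over the association phase.

    ``window`` is (start, end) in seconds relative to the association stage
    start; the default drops the first 2 s and keeps the rest.  Flagged
    unusable on non-convergence, on kobs ≤ 0 (a linear ramp has no plateau)
    or when the kobs error exceeds kobs.
    """
    assoc = trace.stage("association")
    if assoc is None or assoc.time.size < 10:
        return KobsFit(trace.analyte_conc, usable=False, message="association stage missing or too short")

    t = assoc.time - assoc.time[0]
    r = assoc.response
    t_end = float(t[-1])
    lo, hi = window if window is not None else (DEFAULT_WINDOW_START, t_end)
    mask = (t >= lo) & (t <= hi)
    if mask.sum() < 10:
        return KobsFit(trace.analyte_conc, usable=False, message="fewer than 10 points in fit window")
    tw, rw = t[mask], r[mask]

    def model(tt, req, kobs):
        return req * (1.0 - np.exp(-kobs * tt))

    req0 = float(np.max(np.abs(rw)) or 1.0)
    kobs0 = max(1.0 / t_end, 2.0 / (lo + t_end))
    try:
        popt, pcov = curve_fit(
            model, tw, rw, p0=(req0, kobs0),
            bounds=((0.0, 1e-6), (np.inf, 1e3)), maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return KobsFit(trace.analyte_conc, usable=False, message="optimizer failed")

    req, kobs = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.inf, np.inf])
    # a near-linear ramp pins kobs at its lower bound with a huge plateau
    if kobs <= 2e-6 or not np.isfinite(perr[1]) or perr[1] > kobs:
        return KobsFit(
            trace.analyte_conc, kobs=kobs, kobs_err=float(perr[1]), req=req,
            window=(lo, hi), usable=False, message="no resolvable exponential plateau",
        )
    return KobsFit(
        trace.analyte_conc, kobs=kobs, kobs_err=float(perr[1]),
        req=req, req_err=float(perr[0]), window=(lo, hi), usable=True,
    )


def kinetic_analysis(fits: "list[KobsFit]", linearity_sigma: float = 3.0) -> KineticFit:
    """Weighted linear regression kobs = kon·C + koff across concentrations.

    Weights are inverse-variance from the per-fit kobs errors (unweighted
    when errors are absent/zero, e.g. on exact data).  Kd = koff/kon with
    first-order error propagation.  A negative fitted intercept flags the Kd
    unreliable; a >``linearity_sigma``·σ residual at the top concentration
    triggers a mass-transport-limitation warning.
    """
    usable = [f for f in fits if f.usable]
    concs = np.array([f.conc for f in usable])
    if np.unique(concs).size < 3:
        raise ValueError("need usable kobs fits at >= 3 distinct concentrations")
    kobs = np.array([f.kobs for f in usable])
    errs = np.array([f.kobs_err for f in usable])

    if np.all(np.isfinite(errs)) and np.all(errs > 0):
        w = 1.0 / errs**2
    else:
        w = np.ones_like(kobs)

    # closed-form weighted least squares for y = a·x + b
    x, y = concs, kobs
    sw, swx, swy = np.sum(w), np.sum(w * x), np.sum(w * y)
    swxx, swxy = np.sum(w * x * x), np.sum(w * x * y)
    delta = sw * swxx - swx**2
    kon = (sw * swxy - swx * swy) / delta
    koff = (swxx * swy - swx * swxy) / delta

    resid = y - (kon * x + koff)
    n = x.size
    if np.all(w == 1.0):
        # scale parameter errors by the residual variance (unweighted case)
        s2 = float(np.sum(resid**2) / max(n - 2, 1))
        kon_err = np.sqrt(s2 * sw / delta)
        koff_err = np.sqrt(s2 * swxx / delta)
    else:
        kon_err = np.sqrt(sw / delta)
        koff_err = np.sqrt(swxx / delta)

    ss_tot = float(np.sum(w * (y - swy / sw) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0

    reliable, message = True, ""
    if koff <= 0:
        reliable = False
        message = "negative kobs intercept; koff/Kd unreliable (use dissociation-phase koff)"
        kd = np.nan
        kd_err = np.nan
    else:
        kd = koff / kon
        kd_err = kd * np.sqrt((kon_err / kon) ** 2 + (koff_err / koff) ** 2)

    top = int(np.argmax(x))
    sigma_top = errs[top] if np.isfinite(errs[top]) and errs[top] > 0 else np.std(resid) or np.inf
    if abs(resid[top]) > linearity_sigma * sigma_top:
        warnings.warn(
            "kobs at the top concentration deviates from linearity; "
            "possible mass-transport limitation", stacklevel=2,
        )

    return KineticFit(
        kon=float(kon), kon_err=float(kon_err), koff=float(koff), koff_err=float(koff_err),
        kd=float(kd), kd_err=float(kd_err), r_squared=float(r2),
        n_concs=int(np.unique(concs).size), reliable=reliable, message=message,
    )


def fit_dissociation(trace: BLITrace) -> DissociationFit:
    """Fit R(t) = R0·exp(−koff·t) to the dissociation phase (consistency check)."""
    diss = trace.stage("dissociation")
    if diss is None or diss.time.size < 10:
        return DissociationFit(usable=False, message="dissociation stage missing or too short")
    t = diss.time - diss.time[0]
    r = diss.response
    r0_est = float(r[0])
    noise = float(np.std(np.diff(r))) / np.sqrt(2.0)
    if abs(r0_est) <= 3.0 * noise or abs(r0_est) < 1e-12:
        return DissociationFit(usable=False, message="initial response below noise")

    def model(tt, r0, koff):
        return r0 * np.exp(-koff * tt)

    try:
        popt, pcov = curve_fit(
            model, t, r, p0=(r0_est, 1.0 / max(t[-1], 1e-6)),
            bounds=((0.0, 1e-8), (np.inf, 1e3)), maxfev=20000,
        )
    except (RuntimeError, ValueError):
        return DissociationFit(usable=False, message="optimizer failed")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.inf, np.inf])
    return DissociationFit(
        koff=float(popt[1]), koff_err=float(perr[1]), r0=float(popt[0]), usable=True
    )


def analyze_sensors(traces: "list[BLITrace]", window: "tuple[float, float] | None" = None):
    """Full pipeline over a concentration series: align, fit kobs, regress.

    Returns ``(kobs_fits, kinetic_fit, dissociation_fits)``.
    """
    aligned = [align_baseline(t) for t in traces]
    kfits = [fit_kobs(t, window=window) for t in aligned]
    kinetics = kinetic_analysis(kfits)
    dfits = [fit_dissociation(t) for t in aligned]
    return kfits, kinetics, dfits
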