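"""15N T1/T2 relaxation fitting and rotational-correlation-time estimation.

Per-residue longitudinal (T1) and transverse (T2) relaxation times are
obtained by fitting mono-exponential decays V(t) = V0·exp(−t/T) to peak
volumes measured over a delay series.  The effective rotational correlation
time of a domain follows from the T1/T2 ratio through the standard
approximation

    τc = (1/(4π·νN)) · sqrt(6·T1/T2 − 7)

(νN = 15N Larmor frequency), valid for isotropically tumbling domains in
the few-nanosecond regime where high-frequency spectral-density terms are
negligible.  Overlapped peaks are excluded before any averaging; a domain
estimate is the mean ± sd over a declared residue subset, optionally with
IQR trimming to guard against flexible tails and linkers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import nitrogen_larmor_MHz

__all__ = [
    "RelaxationSeries",
    "RelaxationFit",
    "CorrelationTimeEstimate",
    "fit_exponential_decay",
    "fit_series",
    "apply_overlap_exclusion",
    "tauc_from_t1t2",
    "t1t2_ratio_from_tauc",
    "domain_tauc",
    "residue_taucs",
]

#: Standard delay series for small-domain backbone relaxation (seconds).
T1_DELAYS = (0.02, 0.2, 0.4, 0.7, 1.0, 1.5)
T2_DELAYS = (0.01, 0.02, 0.04, 0.07, 0.10, 0.15)

#: Relative T error above which a fit is flagged excluded.
MAX_RELATIVE_T_ERROR = 0.5


@dataclass
class RelaxationSeries:
    """Per-delay peak volumes for one relaxation experiment (T1 or T2 type)."""

    kind: str  # "T1" | "T2"
    spectrometer_1H_freq: float  # MHz
    delays: np.ndarray  # seconds, strictly increasing
    volumes: dict[str, np.ndarray]  # residue_id -> volume per delay
    overlapped: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("T1", "T2"):
            raise ValueError(f"kind must be 'T1' or 'T2', got {self.kind!r}")
        self.delays = np.asarray(self.delays, dtype=float)
        if np.any(np.diff(self.delays) <= 0) or np.any(self.delays < 0):
            raise ValueError("delays must be non-negative and strictly increasing")
        for rid, v in self.volumes.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.delays.shape:
                raise ValueError(f"volume vector for {rid!r} does not match delay count")
            self.volumes[rid] = v


@dataclass
class RelaxationFit:
    """One residue's mono-exponential fit V(t) = V0·exp(−t/T)."""

    residue_id: str
    T: float = np.nan  # seconds
    T_err: float = np.nan
    V0: float = np.nan
    V0_err: float = np.nan
    excluded: bool = False
    reason: str = ""


@dataclass(frozen=True)
class CorrelationTimeEstimate:
    """Domain-level τc: mean ± sd over a residue subset (seconds)."""

    mean: float
    sd: float
    per_residue: dict[str, float]
    residues_used: tuple[str, ...]


# ---------------------------------------------------------------------------
# Decay fitting
# ---------------------------------------------------------------------------


def fit_exponential_decay(delays, volumes, residue_id: str = "") -> RelaxationFit:
    """Least-squares mono-exponential fit of a peak-volume decay.

    Seeds from a log-linear regression; flags the fit excluded when the decay
    is degenerate (constant volumes), the fitted T is non-positive, or the
    relative T error exceeds 50%.
    """
    t = np.asarray(delays, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if t.size < 4:
        return RelaxationFit(residue_id, excluded=True, reason="fewer than 4 points")
    if np.allclose(v, v[0]):
        return RelaxationFit(residue_id, excluded=True, reason="no decay")

    # log-linear seed over strictly positive volumes
    pos = v > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(v[pos]), 1)
        T0 = -1.0 / slope if slope < 0 else float(t[-1])
        V00 = math.exp(intercept)
    else:
        T0, V00 = float(t[-1]), float(np.max(np.abs(v)) or 1.0)
    T0 = min(max(T0, 1e-4), 100.0)

    def model(tt, v0, T):
        return v0 * np.exp(-tt / T)

    try:
        popt, pcov = curve_fit(
            model, t, v, p0=(V00, T0), bounds=((0.0, 1e-6), (np.inf, 1e3)), maxfev=10000
        )
    except (RuntimeError, ValueError):
        return RelaxationFit(residue_id, excluded=True, reason="optimizer failed")

    v0, T = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.inf, np.inf])
    if T <= 0:
        return RelaxationFit(residue_id, T=T, excluded=True, reason="non-positive T")
    if not np.isfinite(perr[1]) or perr[1] / T > MAX_RELATIVE_T_ERROR:
        return RelaxationFit(
            residue_id, T=T, T_err=float(perr[1]), V0=v0, V0_err=float(perr[0]),
            excluded=True, reason="relative T error > 50%",
        )
    return RelaxationFit(residue_id, T=T, T_err=float(perr[1]), V0=v0, V0_err=float(perr[0]))


def fit_series(series: RelaxationSeries) -> dict[str, RelaxationFit]:
    """Fit every residue in a series and apply the overlap exclusions."""
    fits = {
        rid: fit_exponential_decay(series.delays, v, residue_id=rid)
        for rid, v in series.volumes.items()
    }
    return apply_overlap_exclusion(series, fits)


def apply_overlap_exclusion(
    series: RelaxationSeries, fits: dict[str, RelaxationFit]
) -> dict[str, RelaxationFit]:
    """Mark residues whose peaks overlap as excluded (reason ``overlap``)."""
    for rid in series.overlapped:
        if rid in fits:
            f = fits[rid]
            fits[rid] = RelaxationFit(
                f.residue_id, f.T, f.T_err, f.V0, f.V0_err, excluded=True, reason="overlap"
            )
    return fits


# ---------------------------------------------------------------------------
# Correlation time
# ---------------------------------------------------------------------------


def tauc_from_t1t2(T1: float, T2: float, spectrometer_1H_freq: float) -> float:
    """Rotational correlation time (s) from the T1/T2 ratio.

    τc = sqrt(6·T1/T2 − 7) / (4π·νN).  Below the ratio 7/6 the expression is
    undefined (the approximation's zero-τc boundary); NaN is returned so the
    residue drops out of any domain mean.
    """
    if T1 <= 0 or T2 <= 0:
        return float("nan")
    ratio = T1 / T2
    if ratio < 7.0 / 6.0:
        return float("nan")
    nu_n = nitrogen_larmor_MHz(spectrometer_1H_freq) * 1e6  # Hz
    return math.sqrt(6.0 * ratio - 7.0) / (4.0 * math.pi * nu_n)


def t1t2_ratio_from_tauc(tau_c: float, spectrometer_1H_freq: float) -> float:
    """Inverse of :func:`tauc_from_t1t2`: T1/T2 = (7 + (4π·νN·τc)²)/6."""
    nu_n = nitrogen_larmor_MHz(spectrometer_1H_freq) * 1e6
    x = 4.0 * math.pi * nu_n * tau_c
    return (7.0 + x * x) / 6.0


def residue_taucs(
    t1_fits: dict[str, RelaxationFit],
    t2_fits: dict[str, RelaxationFit],
    spectrometer_1H_freq: float,
) -> dict[str, float]:
    """Per-residue τc for residues with usable T1 and T2 fits (NaN dropped)."""
    out: dict[str, float] = {}
    for rid in sorted(set(t1_fits) & set(t2_fits)):
        f1, f2 = t1_fits[rid], t2_fits[rid]
        if f1.excluded or f2.excluded:
            continue
        tc = tauc_from_t1t2(f1.T, f2.T, spectrometer_1H_freq)
        if math.isfinite(tc):
            out[rid] = tc
    return out


def domain_tauc(
    taucs: dict[str, float],
    subset: "list[str] | tuple[str, ...] | None" = None,
    trim: bool = True,
) -> CorrelationTimeEstimate:
    """Mean ± sd τc over a residue subset.

    ``trim=True`` discards residues outside median ± 1.5·IQR of the subset
    values before averaging — protection against flexible tails or linker
    residues that tumble faster than the domain core.  At least three usable
    residues are required.
    """
    ids = sorted(taucs) if subset is None else [r for r in subset if r in taucs]
    vals = np.array([taucs[r] for r in ids], dtype=float)
    keep = np.isfinite(vals)
    ids = [r for r, k in zip(ids, keep) if k]
    vals = vals[keep]
    if vals.size < 3:
        raise ValueError(f"need >= 3 usable residues for a domain estimate, have {vals.size}")

    if trim and vals.size >= 4:
        med = np.median(vals)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        inlier = np.abs(vals - med) <= 1.5 * iqr if iqr > 0 else np.ones_like(vals, bool)
        if inlier.sum() >= 3:
            if not inlier.all():
                dropped = [r for r, k in zip(ids, inlier) if not k]
                warnings.warn(f"trimmed {dropped} from domain tau_c mean", stacklevel=2)
            ids = [r for r, k in zip(ids, inlier) if k]
            vals = vals[inlier]

    return CorrelationTimeEstimate(
        mean=float(np.mean(vals)),
        sd=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        per_residue={r: float(v) for r, v in zip(ids, vals)},
        residues_used=tuple(ids),
    )
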