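"""Chemical-shift-perturbation titration analysis with fast-exchange Kd fitting.

In the fast-exchange regime each amide peak moves as the population-weighted
average of its free and bound positions, so the combined CSP at a titration
point is Δδ(L0) = Δδmax · f_b(P0, L0, Kd), with f_b the exact two-state bound
protein fraction from the mass-balance quadratic.  Per-residue Kd values are
obtained by nonlinear least squares against total ligand (no free≈total
approximation — at P0 well above Kd that approximation fails badly) and
merged into a global estimate as the unweighted mean across converged
residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import CSP_NITROGEN_WEIGHT, Peak, PeakList

__all__ = [
    "TitrationSeries",
    "ShiftTrajectory",
    "BindingFit",
    "GlobalKd",
    "TitrationResult",
    "combined_csp",
    "bound_fraction",
    "match_peaks",
    "track_trajectories",
    "fit_residue_kd",
    "global_kd",
    "analyze_titration",
    "compare_saturation",
    "interaction_surface",
]

#: Smallest final-point combined CSP (ppm) treated as evidence of binding.
#: Roughly 3x the shift precision of a well-set-up HSQC titration.
DEFAULT_NOISE_FLOOR = 0.015

#: Kd search bounds (molar) for the per-residue fit.
KD_BOUNDS = (1e-9, 1e-1)

#: Initial Kd guesses spanning three decades around the micromolar regime.
KD_STARTS = (1e-6, 1e-5, 1e-4)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class TitrationSeries:
    """Ordered peak lists across a titration at fixed total protein P0 (molar)."""

    construct_id: str
    P0: float
    points: list[tuple[float, PeakList]]

    def __post_init__(self) -> None:
        ratios = [r for r, _ in self.points]
        if ratios and ratios[0] != 0:
            raise ValueError("first titration point must be the free spectrum (ratio 0)")
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError("titration ratios must be strictly increasing")

    @property
    def ratios(self) -> np.ndarray:
        return np.asarray([r for r, _ in self.points], dtype=float)


@dataclass
class ShiftTrajectory:
    """One residue's (δH, δN) positions and combined CSP across the titration."""

    residue_id: str
    delta_H: np.ndarray
    delta_N: np.ndarray
    csp: np.ndarray

    @property
    def final_csp(self) -> float:
        return float(self.csp[-1])


@dataclass
class BindingFit:
    """Per-residue two-state fit of Δδ(ratio) = Δδmax·f_b(P0, ratio·P0, Kd)."""

    residue_id: str
    kd: float = np.nan
    kd_err: float = np.nan
    ddmax: float = np.nan
    ddmax_err: float = np.nan
    converged: bool = False
    message: str = ""
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass(frozen=True)
class GlobalKd:
    """Unweighted mean of converged per-residue Kd values."""

    mean: float
    sd: float
    n_residues: int


@dataclass
class TitrationResult:
    """End-to-end analysis of one titration series."""

    series_id: str
    trajectories: dict[str, ShiftTrajectory]
    fits: list[BindingFit]
    global_kd: GlobalKd | None
    verdict: str  # "binding detected" | "no significant binding"


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def combined_csp(dH, dN, weight: float = CSP_NITROGEN_WEIGHT):
    """Combined amide CSP sqrt(ΔδH² + (weight·ΔδN)²), in ppm.

    The default nitrogen weight of 0.152 down-scales the 15N dimension to
    make the two shift ranges commensurate.  Invariant to the signs of the
    inputs; accepts scalars or arrays.
    """
    dH = np.asarray(dH, dtype=float)
    dN = np.asarray(dN, dtype=float)
    out = np.hypot(dH, weight * dN)
    return float(out) if out.ndim == 0 else out


def bound_fraction(P0, L0, Kd):
    """Exact two-state bound protein fraction [PL]/P0 at totals (P0, L0).

    Root of the mass balance Kd·[PL] = (P0−[PL])·(L0−[PL]):

        f_b = ((P0+L0+Kd) − sqrt((P0+L0+Kd)² − 4·P0·L0)) / (2·P0)

    evaluated in the conjugate form 2·L0/(S + sqrt(S² − 4·P0·L0)) which is
    immune to catastrophic cancellation when Kd ≪ P0.  Always in [0, 1].
    """
    P0 = np.asarray(P0, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    Kd = np.asarray(Kd, dtype=float)
    s = P0 + L0 + Kd
    disc = np.maximum(s * s - 4.0 * P0 * L0, 0.0)
    # [PL] = 2·P0·L0/(S + sqrt(disc)); divide by P0 for the fraction
    frac = np.clip(2.0 * L0 / (s + np.sqrt(disc)), 0.0, 1.0)
    return float(frac) if frac.ndim == 0 else frac


# ---------------------------------------------------------------------------
# Peak tracking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakMatch:
    residue_id: str
    target: Peak | None
    distance: float
    status: str  # "matched" | "unmatched" | "ambiguous"


def match_peaks(
    reference: PeakList,
    target: PeakList,
    max_jump: float = 0.2,
    weight: float = CSP_NITROGEN_WEIGHT,
    ambiguity_ratio: float = 2.0,
) -> dict[str, PeakMatch]:
    """One-to-one greedy nearest-neighbour assignment transfer in weighted shift space.

    Distances are Euclidean in (δH, weight·δN).  Candidate pairs within
    ``max_jump`` ppm-equivalents are assigned greedily by ascending distance,
    each reference and target used at most once.  When two reference peaks
    contest the same nearest target at comparable distances (within
    ``ambiguity_ratio`` of each other) both are flagged ambiguous rather
    than silently swapped — the crossing-trajectory case.  Moves beyond
    ``max_jump`` are left unmatched.
    """
    if len(target) == 0:
        return {p.residue_id: PeakMatch(p.residue_id, None, np.inf, "unmatched") for p in reference}

    ref_xy = np.array([[p.delta_H, weight * p.delta_N] for p in reference])
    tgt_xy = np.array([[p.delta_H, weight * p.delta_N] for p in target])
    dist = np.linalg.norm(ref_xy[:, None, :] - tgt_xy[None, :, :], axis=2)

    n_ref = len(reference.entries)
    nearest = np.argmin(dist, axis=1)
    nearest_d = dist[np.arange(n_ref), nearest]

    # two refs whose nearest target coincides at comparable distance -> ambiguous
    ambiguous: set[int] = set()
    claims: dict[int, list[int]] = {}
    for i, (j, d) in enumerate(zip(nearest, nearest_d)):
        if d <= max_jump:
            claims.setdefault(int(j), []).append(i)
    for j, claimants in claims.items():
        if len(claimants) > 1:
            ds = sorted(float(nearest_d[i]) for i in claimants)
            if ds[0] <= 0 or ds[1] / max(ds[0], 1e-12) <= ambiguity_ratio:
                ambiguous.update(claimants)

    # greedy one-to-one over the remaining candidates, closest pairs first
    pairs = [
        (float(dist[i, j]), i, j)
        for i in range(n_ref)
        if i not in ambiguous
        for j in range(len(target.entries))
        if dist[i, j] <= max_jump
    ]
    pairs.sort()
    assigned_ref: dict[int, int] = {}
    taken_tgt: set[int] = set()
    for d, i, j in pairs:
        if i in assigned_ref or j in taken_tgt:
            continue
        assigned_ref[i] = j
        taken_tgt.add(j)

    result: dict[str, PeakMatch] = {}
    for i, ref_peak in enumerate(reference.entries):
        rid = ref_peak.residue_id
        if i in ambiguous:
            result[rid] = PeakMatch(rid, None, float(nearest_d[i]), "ambiguous")
        elif i in assigned_ref:
            j = assigned_ref[i]
            result[rid] = PeakMatch(rid, target.entries[j], float(dist[i, j]), "matched")
        else:
            result[rid] = PeakMatch(rid, None, float(nearest_d[i]), "unmatched")
    return result


def track_trajectories(
    series: TitrationSeries,
    max_jump: float = 0.2,
    weight: float = CSP_NITROGEN_WEIGHT,
) -> dict[str, ShiftTrajectory]:
    """Chain peak matching point-to-point through a titration.

    The free spectrum provides the assignments; each subsequent point is
    matched against the previous matched positions, so slow, large
    cumulative shifts are followed as long as per-step moves stay below
    ``max_jump``.  Residues that lose their peak (unmatched/ambiguous at any
    point) are dropped with a warning.
    """
    _, free = series.points[0]
    positions: dict[str, Peak] = {p.residue_id: p for p in free}
    tracks: dict[str, list[Peak]] = {rid: [pk] for rid, pk in positions.items()}
    lost: set[str] = set()

    for _, point in series.points[1:]:
        current = PeakList("tracking", [positions[rid] for rid in positions if rid not in lost])
        matches = match_peaks(current, point, max_jump=max_jump, weight=weight)
        for rid, m in matches.items():
            if rid in lost:
                continue
            if m.status != "matched":
                lost.add(rid)
                continue
            positions[rid] = Peak(rid, m.target.delta_H, m.target.delta_N, m.target.intensity, m.target.overlapped)
            tracks[rid].append(positions[rid])

    if lost:
        warnings.warn(f"lost track of {sorted(lost)} during titration {series.construct_id!r}", stacklevel=2)

    n_points = len(series.points)
    trajectories: dict[str, ShiftTrajectory] = {}
    for rid, pks in tracks.items():
        if rid in lost or len(pks) != n_points:
            continue
        dh = np.array([p.delta_H for p in pks])
        dn = np.array([p.delta_N for p in pks])
        csp = combined_csp(dh - dh[0], dn - dn[0], weight=weight)
        trajectories[rid] = ShiftTrajectory(rid, dh, dn, csp)
    return trajectories


# ---------------------------------------------------------------------------
# Kd fitting
# ---------------------------------------------------------------------------


def fit_residue_kd(
    traj: ShiftTrajectory,
    P0: float,
    ratios: Sequence[float],
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> BindingFit:
    """Nonlinear least-squares fit of one residue's CSP isotherm.

    Model: Δδ(r) = Δδmax · f_b(P0, r·P0, Kd).  Multi-start over three Kd
    decades with bounds Kd ∈ [1 nM, 100 mM-ish], Δδmax ∈ [0, 10× max CSP];
    errors from the fit covariance.  The fit is flagged non-converged when
    the optimizer pins a bound, the Kd error exceeds Kd itself, or the
    trajectory never rises above the noise floor (no-fit result, not an
    exception).
    """
    ratios = np.asarray(ratios, dtype=float)
    csp = np.asarray(traj.csp, dtype=float)
    if len(ratios) < 4:
        return BindingFit(traj.residue_id, converged=False, message="fewer than 4 titration points")
    max_csp = float(np.max(csp))
    if max_csp <= noise_floor:
        return BindingFit(traj.residue_id, converged=False, message="no significant shift")

    def model(r, kd, ddmax):
        return ddmax * bound_fraction(P0, r * P0, kd)

    lo = (KD_BOUNDS[0], 0.0)
    hi = (KD_BOUNDS[1], 10.0 * max_csp)
    best = None
    for kd0 in KD_STARTS:
        try:
            popt, pcov = curve_fit(
                model, ratios, csp, p0=(kd0, max_csp), bounds=(lo, hi), maxfev=10000
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(ratios, *popt) - csp) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        return BindingFit(traj.residue_id, converged=False, message="optimizer failed")

    _, (kd, ddmax), pcov = best
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.array([np.inf, np.inf])
    resid = csp - model(ratios, kd, ddmax)

    at_bound = kd <= KD_BOUNDS[0] * 1.001 or kd >= KD_BOUNDS[1] * 0.999
    converged = not at_bound and np.isfinite(perr[0]) and perr[0] <= kd
    message = "" if converged else ("Kd at fit bound" if at_bound else "Kd error exceeds Kd")
    return BindingFit(
        traj.residue_id,
        kd=float(kd),
        kd_err=float(perr[0]),
        ddmax=float(ddmax),
        ddmax_err=float(perr[1]),
        converged=bool(converged),
        message=message,
        residuals=resid,
    )


def global_kd(fits: Iterable[BindingFit], weighted: bool = False) -> GlobalKd:
    """Merge converged per-residue fits into a global Kd.

    Default is the plain unweighted mean across residues with the
    across-residue standard deviation as dispersion; ``weighted=True``
    switches to an inverse-variance-weighted mean.
    """
    kds = np.array([f.kd for f in fits if f.converged])
    errs = np.array([f.kd_err for f in fits if f.converged])
    if kds.size == 0:
        raise ValueError("no converged per-residue fits to merge")
    if weighted and np.all(errs > 0):
        w = 1.0 / errs**2
        mean = float(np.sum(w * kds) / np.sum(w))
    else:
        mean = float(np.mean(kds))
    sd = float(np.std(kds, ddof=1)) if kds.size > 1 else 0.0
    return GlobalKd(mean=mean, sd=sd, n_residues=int(kds.size))


def analyze_titration(
    series: TitrationSeries,
    max_jump: float = 0.2,
    weight: float = CSP_NITROGEN_WEIGHT,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> TitrationResult:
    """Full pipeline: track peaks, fit every residue, merge, and call a verdict."""
    trajectories = track_trajectories(series, max_jump=max_jump, weight=weight)
    ratios = series.ratios
    fits = [fit_residue_kd(t, series.P0, ratios, noise_floor=noise_floor) for t in trajectories.values()]
    try:
        merged = global_kd(fits)
        verdict = "binding detected"
    except ValueError:
        merged = None
        verdict = "no significant binding"
    return TitrationResult(series.construct_id, trajectories, fits, merged, verdict)


# ---------------------------------------------------------------------------
# Saturation comparison and surface calling
# ---------------------------------------------------------------------------


@dataclass
class SaturationComparison:
    ratio: float
    per_residue: dict[str, float]  # CSP_A / CSP_B
    median_ratio: float
    verdict: str  # "A stronger" | "B stronger" | "indistinguishable"


def compare_saturation(
    series_a: TitrationSeries,
    series_b: TitrationSeries,
    ratio: float,
    margin: float = 0.2,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    max_jump: float = 0.2,
) -> SaturationComparison:
    """Compare two RNAs' bound fractions through CSPs at a shared ratio.

    At equal protein:ligand ratio the tighter binder saturates more, so the
    per-residue CSP ratio CSP_A/CSP_B is a proxy for relative affinity.  The
    verdict requires the median ratio to clear 1 by a noise-derived margin.
    """
    for s in (series_a, series_b):
        if not np.any(np.isclose(s.ratios, ratio)):
            raise ValueError(f"ratio {ratio} absent from series {s.construct_id!r}; available: {list(s.ratios)}")

    def csps_at(series: TitrationSeries) -> dict[str, float]:
        idx = int(np.argmin(np.abs(series.ratios - ratio)))
        trajs = track_trajectories(series, max_jump=max_jump)
        return {rid: float(t.csp[idx]) for rid, t in trajs.items()}

    a, b = csps_at(series_a), csps_at(series_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared residues between the two series")

    per_residue = {}
    for rid in shared:
        denom = max(b[rid], noise_floor / 3.0)
        per_residue[rid] = a[rid] / denom
    med = float(np.median(list(per_residue.values())))

    informative = [rid for rid in shared if max(a[rid], b[rid]) > noise_floor]
    if not informative:
        verdict = "indistinguishable"
    elif med > 1.0 + margin:
        verdict = "A stronger"
    elif med < 1.0 / (1.0 + margin):
        verdict = "B stronger"
    else:
        verdict = "indistinguishable"
    return SaturationComparison(ratio=ratio, per_residue=per_residue, median_ratio=med, verdict=verdict)


@dataclass
class InteractionSurface:
    ranked: list[tuple[str, float]]  # residues sorted by CSP, descending
    surface: list[str]  # residues with CSP > mean + n_sd·sd
    threshold: float

    def top(self, k: int) -> list[str]:
        return [rid for rid, _ in self.ranked[:k]]


def interaction_surface(csps: dict[str, float], n_sd: float = 1.0) -> InteractionSurface:
    """Rank residues by final-point CSP and call the binding surface.

    The surface set is every residue whose CSP exceeds mean + ``n_sd``·sd of
    the profile; a flat profile (sd = 0) yields an empty surface.
    """
    finite = {rid: v for rid, v in csps.items() if np.isfinite(v)}
    if len(finite) < 5:
        raise ValueError("need at least 5 residues with finite CSP")
    values = np.array(list(finite.values()))
    mean, sd = float(np.mean(values)), float(np.std(values))
    threshold = mean + n_sd * sd
    ranked = sorted(finite.items(), key=lambda kv: (-kv[1], kv[0]))
    surface = [rid for rid, v in ranked if sd > 0 and v > threshold]
    return InteractionSurface(ranked=ranked, surface=surface, threshold=threshold)
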