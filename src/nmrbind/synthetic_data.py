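"""Ground-truth simulators for every input class the analysis stages consume.

Each simulator is a pure function of a ground-truth record (which includes
its seed): identical inputs give bit-identical outputs.  The defaults
reproduce the designs the analysis stages are built for — a 50 µM protein
titrated at protein:RNA ratios 0–12, SIA pools at a 1:4 ratio, T1/T2 delay
series for domains tumbling at ~4–5 ns at 800 MHz, and streptavidin-sensor
interferograms at 1–8 µM analyte.

The relaxation forward model is a rigid isotropic rotor with N–H dipolar
(rNH = 1.02 Å) and 15N CSA (−160 ppm) contributions and spectral density
J(ω) = (2/5)·τc/(1 + ω²τc²).  It exists only to manufacture internally
consistent T1/T2 pairs; the analysis stages never depend on its constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bli_kinetics import BLIStage, BLITrace
from .csp_titration import TitrationSeries, bound_fraction
from .io_formats import (
    N15_CSA,
    NH_BOND_LENGTH,
    Peak,
    PeakList,
    nitrogen_larmor_MHz,
)
from .relaxation import T1_DELAYS, T2_DELAYS, RelaxationSeries
from .sia_scoring import BASES, SIAPoolSet

__all__ = [
    "TitrationGroundTruth",
    "SIAGroundTruth",
    "RelaxationGroundTruth",
    "BLIGroundTruth",
    "simulate_titration",
    "simulate_sia_pools",
    "simulate_relaxation_series",
    "simulate_bli",
    "rigid_rotor_t1_t2",
]

#: HSQC shift precision (ppm): independent Gaussian noise per dimension.
DEFAULT_NOISE_H = 0.003
DEFAULT_NOISE_N = 0.02

#: Standard titration design: 50 uM protein, ratios 0-12.
DEFAULT_P0 = 50e-6
DEFAULT_RATIOS = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0)

# physical constants for the rigid-rotor model (SI)
_GAMMA_H = 2.6752218744e8  # rad/s/T
_GAMMA_N = 2.7126e7  # rad/s/T (magnitude)
_HBAR = 1.054571817e-34  # J s
_MU0_OVER_4PI = 1e-7  # T m / A


def _draw_reporter_set(rng: np.random.Generator, n_residues: int):
    """Free shifts and bound-state perturbations for a well-dispersed reporter set.

    Free positions are drawn over the amide region (δH 7.5–9.5, δN 105–130
    ppm) with a minimum pairwise separation of 0.6 ppm-equivalents in the
    weighted (δH, 0.152·δN) plane — reporters for shift-tracking analyses
    are by construction well-resolved peaks.  Bound-state perturbations are
    0.05–0.20 ppm (1H) and 0.2–1.2 ppm (15N), the scale seen for residues in
    direct contact at a small protein–RNA interface; the largest possible
    peak displacement (~0.27 ppm-equivalents) therefore stays below half the
    minimum peak separation, which keeps assignment transfer well-posed.
    """
    min_sep = 0.6
    free: dict[str, tuple[float, float]] = {}
    ddmax: dict[str, tuple[float, float]] = {}
    positions: list[tuple[float, float]] = []
    for i in range(n_residues):
        rid = f"res{i + 1:02d}"
        for _ in range(1000):
            h, n = rng.uniform(7.5, 9.5), rng.uniform(105.0, 130.0)
            if all(math.hypot(h - h2, 0.152 * (n - n2)) >= min_sep for h2, n2 in positions):
                break
        else:  # pragma: no cover - only reachable with absurd n_residues
            raise RuntimeError("could not place well-dispersed reporter peaks")
        positions.append((h, n))
        free[rid] = (h, n)
        ddmax[rid] = (rng.uniform(0.05, 0.20), rng.uniform(0.2, 1.2))
    return free, ddmax


# ---------------------------------------------------------------------------
# Titration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TitrationGroundTruth:
    """Known truth behind a fast-exchange CSP titration."""

    kd: float  # molar
    p0: float = DEFAULT_P0  # total protein, molar
    ratios: tuple = DEFAULT_RATIOS  # ligand:protein ratios
    free_shifts: dict = field(default_factory=dict)  # residue -> (dH, dN) ppm
    ddmax: dict = field(default_factory=dict)  # residue -> (ddH_max, ddN_max) ppm
    noise_h: float = DEFAULT_NOISE_H
    noise_n: float = DEFAULT_NOISE_N
    seed: int = 0
    construct_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.p0 <= 0:
            raise ValueError("kd and p0 must be positive")
        r = np.asarray(self.ratios)
        if np.any(r < 0) or np.any(np.diff(r) <= 0):
            raise ValueError("ratios must be non-negative and strictly increasing")
        if set(self.free_shifts) != set(self.ddmax):
            raise ValueError("free_shifts and ddmax must cover the same residues")

    @classmethod
    def default(
        cls,
        kd: float = 3.7e-6,
        n_residues: int = 10,
        seed: int = 0,
        noise_h: float = DEFAULT_NOISE_H,
        noise_n: float = DEFAULT_NOISE_N,
        ratios: tuple = DEFAULT_RATIOS,
        p0: float = DEFAULT_P0,
        construct_id: str = "synthetic",
    ) -> "TitrationGroundTruth":
        """A realistic reporter set: well-dispersed amides with interface-sized Δδmax."""
        rng = np.random.default_rng(seed)
        free, ddmax = _draw_reporter_set(rng, n_residues)
        return cls(
            kd=kd, p0=p0, ratios=tuple(ratios), free_shifts=free, ddmax=ddmax,
            noise_h=noise_h, noise_n=noise_n, seed=seed, construct_id=construct_id,
        )


def simulate_titration(gt: TitrationGroundTruth) -> TitrationSeries:
    """Generate an assigned fast-exchange titration series.

    At each point every residue sits at δ_free + f_b·Δδmax + noise, with f_b
    the exact two-state bound fraction at (P0, L0 = ratio·P0, Kd) — the
    fast-exchange population-weighted average position.
    """
    rng = np.random.default_rng(gt.seed)
    points = []
    for ratio in gt.ratios:
        fb = bound_fraction(gt.p0, ratio * gt.p0, gt.kd)
        peaks = []
        for rid in sorted(gt.free_shifts):
            h0, n0 = gt.free_shifts[rid]
            dh, dn = gt.ddmax[rid]
            peaks.append(
                Peak(
                    rid,
                    h0 + fb * dh + rng.normal(0.0, gt.noise_h),
                    n0 + fb * dn + rng.normal(0.0, gt.noise_n),
                )
            )
        points.append((float(ratio), PeakList(f"{gt.construct_id}_r{ratio:g}", peaks)))
    return TitrationSeries(construct_id=gt.construct_id, P0=gt.p0, points=points)


# ---------------------------------------------------------------------------
# SIA pools
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SIAGroundTruth:
    """Known truth behind a set of SIA pool spectra.

    ``prefs`` maps scanned position -> base -> relative affinity (1 = the
    reference affinity ``kd_ref``; a pool's effective dissociation constant
    is ``kd_ref / affinity``).  Competition inside a quasi-degenerate pool is
    collapsed into that single effective Kd, which is all the scoring stage
    consumes.
    """

    prefs: dict  # position -> {base: relative affinity > 0}
    kd_ref: float = 4e-6  # molar, Kd of an affinity-1 pool
    p0: float = 70e-6  # molar
    ratio: float = 4.0  # protein:RNA 1:4
    free_shifts: dict = field(default_factory=dict)
    ddmax: dict = field(default_factory=dict)
    noise_h: float = DEFAULT_NOISE_H
    noise_n: float = DEFAULT_NOISE_N
    seed: int = 0

    def __post_init__(self) -> None:
        for pos, by_base in self.prefs.items():
            if set(by_base) != set(BASES):
                raise ValueError(f"position {pos}: prefs must cover {BASES}")
            if any(a <= 0 for a in by_base.values()):
                raise ValueError(f"position {pos}: affinities must be positive")

    @classmethod
    def default(
        cls,
        prefs: "dict | None" = None,
        n_residues: int = 8,
        seed: int = 0,
        **kwargs,
    ) -> "SIAGroundTruth":
        """G-preferring at positions 1–2, no preference at position 3.

        The preferred base binds at ``kd_ref``; non-preferred bases bind 50×
        weaker, the contrast between a tight GG-recognizing complex and its
        single-base mutants, which is too weak to titrate to saturation.
        """
        if prefs is None:
            g_pref = {"A": 0.02, "C": 0.02, "G": 1.0, "U": 0.02}
            flat = {b: 0.2 for b in BASES}
            prefs = {1: dict(g_pref), 2: dict(g_pref), 3: dict(flat)}
        rng = np.random.default_rng(seed)
        free, ddmax = _draw_reporter_set(rng, n_residues)
        return cls(prefs=prefs, free_shifts=free, ddmax=ddmax, seed=seed, **kwargs)

    @classmethod
    def null(cls, n_positions: int = 3, **kwargs) -> "SIAGroundTruth":
        """All four bases equally preferred at every position."""
        prefs = {p: {b: 0.2 for b in BASES} for p in range(1, n_positions + 1)}
        return cls.default(prefs=prefs, **kwargs)


def simulate_sia_pools(gt: SIAGroundTruth) -> dict[int, SIAPoolSet]:
    """Generate free + four pool spectra per scanned position.

    Pool CSP magnitudes are ordered identically to the supplied per-base
    affinities: a higher affinity means a lower effective Kd, a larger bound
    fraction at the 1:4 ratio and therefore larger shifts at every peak.
    """
    rng = np.random.default_rng(gt.seed)
    l0 = gt.ratio * gt.p0

    def spectrum(spec_id: str, fb: float) -> PeakList:
        peaks = []
        for rid in sorted(gt.free_shifts):
            h0, n0 = gt.free_shifts[rid]
            dh, dn = gt.ddmax[rid]
            peaks.append(
                Peak(
                    rid,
                    h0 + fb * dh + rng.normal(0.0, gt.noise_h),
                    n0 + fb * dn + rng.normal(0.0, gt.noise_n),
                )
            )
        return PeakList(spec_id, peaks)

    out: dict[int, SIAPoolSet] = {}
    for pos in sorted(gt.prefs):
        free = spectrum(f"pos{pos}_free", 0.0)
        pools = {}
        for base in BASES:
            kd_eff = gt.kd_ref / gt.prefs[pos][base]
            fb = bound_fraction(gt.p0, l0, kd_eff)
            pools[base] = spectrum(f"pos{pos}_{base}", fb)
        out[pos] = SIAPoolSet(scanned_position=pos, free=free, pools=pools)
    return out


# ---------------------------------------------------------------------------
# Relaxation
# ---------------------------------------------------------------------------


def rigid_rotor_t1_t2(tau_c: float, spectrometer_1H_freq: float) -> tuple[float, float]:
    """(T1, T2) in seconds for a rigid isotropic rotor at the given field.

    Standard dipolar + CSA expressions with J(ω) = (2/5)·τc/(1+ω²τc²):

        R1 = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + c²·J(ωN)
        R2 = (d²/8)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
             + (c²/6)[4J(0) + 3J(ωN)]

    with d = (μ0/4π)·ħ·γH·γN/r³ and c = ωN·Δσ/√3.
    """
    nu_h = spectrometer_1H_freq * 1e6
    nu_n = nitrogen_larmor_MHz(spectrometer_1H_freq) * 1e6
    w_h = 2.0 * math.pi * nu_h
    w_n = 2.0 * math.pi * nu_n

    def J(w: float) -> float:
        return 0.4 * tau_c / (1.0 + (w * tau_c) ** 2)

    d = _MU0_OVER_4PI * _HBAR * _GAMMA_H * _GAMMA_N / NH_BOND_LENGTH**3
    c = w_n * abs(N15_CSA) / math.sqrt(3.0)

    r1 = (d**2 / 4.0) * (J(w_h - w_n) + 3.0 * J(w_n) + 6.0 * J(w_h + w_n)) + c**2 * J(w_n)
    r2 = (d**2 / 8.0) * (
        4.0 * J(0.0) + J(w_h - w_n) + 3.0 * J(w_n) + 6.0 * J(w_h) + 6.0 * J(w_h + w_n)
    ) + (c**2 / 6.0) * (4.0 * J(0.0) + 3.0 * J(w_n))
    return 1.0 / r1, 1.0 / r2


@dataclass(frozen=True)
class RelaxationGroundTruth:
    """Known truth behind a pair of T1/T2 relaxation series."""

    tau_c: float  # seconds
    spectrometer_1H_freq: float = 800.0  # MHz
    t1_delays: tuple = T1_DELAYS  # seconds
    t2_delays: tuple = T2_DELAYS
    v0: dict = field(default_factory=dict)  # residue -> initial volume
    noise_frac: float = 0.05  # Gaussian sd as a fraction of V0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        for delays in (self.t1_delays, self.t2_delays):
            d = np.asarray(delays)
            if np.any(d < 0) or np.any(np.diff(d) <= 0):
                raise ValueError("delays must be non-negative and strictly increasing")

    @classmethod
    def default(
        cls, tau_c: float = 4.2e-9, n_residues: int = 11, seed: int = 0, **kwargs
    ) -> "RelaxationGroundTruth":
        rng = np.random.default_rng(seed)
        v0 = {f"res{i + 1:02d}": float(rng.uniform(50.0, 150.0)) for i in range(n_residues)}
        return cls(tau_c=tau_c, v0=v0, seed=seed, **kwargs)


def simulate_relaxation_series(
    gt: RelaxationGroundTruth,
) -> tuple[RelaxationSeries, RelaxationSeries]:
    """Generate matched (T1-type, T2-type) decay series for one domain.

    Per-residue volumes follow V(t) = V0·exp(−t/T) + ε with T1 and T2 from
    the rigid-rotor model at the ground-truth τc and ε Gaussian with sd
    ``noise_frac``·V0.
    """
    t1, t2 = rigid_rotor_t1_t2(gt.tau_c, gt.spectrometer_1H_freq)
    rng = np.random.default_rng(gt.seed)

    def build(kind: str, delays, T: float) -> RelaxationSeries:
        delays = np.asarray(delays, dtype=float)
        volumes = {}
        for rid in sorted(gt.v0):
            v0 = gt.v0[rid]
            clean = v0 * np.exp(-delays / T)
            volumes[rid] = clean + rng.normal(0.0, gt.noise_frac * v0, size=delays.size)
        return RelaxationSeries(
            kind=kind, spectrometer_1H_freq=gt.spectrometer_1H_freq, delays=delays, volumes=volumes
        )

    return build("T1", gt.t1_delays, t1), build("T2", gt.t2_delays, t2)


# ---------------------------------------------------------------------------
# BLI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BLIGroundTruth:
    """Known truth behind a concentration series of 1:1 sensorgrams."""

    kon: float = 1e4  # 1/(M s)
    koff: float = 0.04  # 1/s
    rmax: float = 1.0  # nm
    concs: tuple = (1e-6, 2e-6, 4e-6, 8e-6)  # molar
    baseline_s: float = 60.0
    association_s: float = 120.0
    dissociation_s: float = 120.0
    dt: float = 0.2  # s between samples
    drift: float = 0.0  # nm/s baseline drift
    offset: float = 0.05  # nm static sensor offset (removed by alignment)
    noise_sd: float = 0.01  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.rmax) <= 0:
            raise ValueError("kon, koff and rmax must be positive")
        if any(c < 0 for c in self.concs):
            raise ValueError("concentrations must be non-negative")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


def simulate_bli(gt: BLIGroundTruth) -> list[BLITrace]:
    """Generate one staged sensorgram per analyte concentration.

    Association follows R(t) = Req·(1 − exp(−kobs·t)) with
    kobs = kon·C + koff and Req = Rmax·C/(C + Kd); dissociation decays from
    the association end point as R_end·exp(−koff·t).  Baseline drift, a
    static sensor offset and Gaussian read noise are superimposed; the
    offset and drift are what baseline alignment removes.
    """
    rng = np.random.default_rng(gt.seed)
    traces = []
    for i, conc in enumerate(gt.concs):
        kobs = gt.kon * conc + gt.koff
        req = gt.rmax * conc / (conc + gt.kd)

        t_base = np.arange(0.0, gt.baseline_s, gt.dt)
        t_assoc = np.arange(0.0, gt.association_s, gt.dt)
        t_diss = np.arange(0.0, gt.dissociation_s, gt.dt)

        base = gt.offset + gt.drift * t_base
        assoc_clean = req * (1.0 - np.exp(-kobs * t_assoc))
        r_end = float(assoc_clean[-1])
        assoc = gt.offset + gt.drift * (gt.baseline_s + t_assoc) + assoc_clean
        diss = (
            gt.offset
            + gt.drift * (gt.baseline_s + gt.association_s + t_diss)
            + r_end * np.exp(-gt.koff * t_diss)
        )

        stages = []
        for label, t, r, t0 in (
            ("baseline", t_base, base, 0.0),
            ("association", t_assoc, assoc, gt.baseline_s),
            ("dissociation", t_diss, diss, gt.baseline_s + gt.association_s),
        ):
            noisy = r + rng.normal(0.0, gt.noise_sd, size=t.size)
            stages.append(BLIStage(label=label, time=t0 + t, response=noisy))
        traces.append(BLITrace(sensor_id=f"sensor{i + 1}", analyte_conc=float(conc), stages=stages))
    return traces
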