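"""Scaffold Independent Analysis: nucleobase-preference scoring from pool CSPs.

SIA compares the binding of a domain to four quasi-degenerate RNA pools, each
fixing one base (A, C, G or U) at the scanned position.  A tighter-binding
base produces a larger bound fraction at a fixed protein:RNA ratio and hence
larger chemical-shift perturbations.  For a subset of reporter peaks, each
peak's four pool CSPs are normalized to that peak's largest shift; the
normalized values are averaged across reporters and rescaled so the best
base scores exactly 1, giving a comparative semi-quantitative preference
score per base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .csp_titration import combined_csp, match_peaks
from .io_formats import CSP_NITROGEN_WEIGHT, PeakList

__all__ = [
    "BASES",
    "SIAPoolSet",
    "SIAScoreTable",
    "pool_csp_profile",
    "select_reporter_peaks",
    "sia_scores",
    "rank_preference",
    "score_pool_set",
]

BASES = ("A", "C", "G", "U")

#: Second-best score must fall below 1 − margin for a base to be called.
DEFAULT_SPECIFICITY_MARGIN = 0.2


@dataclass
class SIAPoolSet:
    """Four pool spectra (one per fixed base) sharing one free reference."""

    scanned_position: int
    free: PeakList
    pools: dict[str, PeakList]

    def __post_init__(self) -> None:
        if set(self.pools) != set(BASES):
            raise ValueError(f"pools must cover exactly {BASES}, got {sorted(self.pools)}")


@dataclass
class SIAScoreTable:
    """Normalized preference scores for one scanned position."""

    scanned_position: int
    scores: dict[str, float]  # base -> score in [0, 1], max exactly 1
    reporters: tuple[str, ...]
    call: str = ""  # filled by rank_preference


def pool_csp_profile(
    free: PeakList,
    pool: PeakList,
    max_jump: float = 0.5,
    weight: float = CSP_NITROGEN_WEIGHT,
) -> dict[str, float]:
    """Combined CSP per peak between the free spectrum and one pool spectrum.

    Peaks are matched by nearest-neighbour transfer; unmatched peaks are
    excluded with a warning.  Fewer than three matched peaks makes the
    profile unusable and is an error.
    """
    matches = match_peaks(free, pool, max_jump=max_jump, weight=weight)
    profile: dict[str, float] = {}
    dropped: list[str] = []
    for rid, m in matches.items():
        if m.status != "matched":
            dropped.append(rid)
            continue
        ref = free.get(rid)
        profile[rid] = combined_csp(
            m.target.delta_H - ref.delta_H, m.target.delta_N - ref.delta_N, weight=weight
        )
    if dropped:
        warnings.warn(f"unmatched peaks excluded from pool profile: {sorted(dropped)}", stacklevel=2)
    if len(profile) < 3:
        raise ValueError(f"only {len(profile)} matched peaks; pool CSP profile unusable")
    return profile


def select_reporter_peaks(
    profiles: dict[str, dict[str, float]],
    n_sd: float = 1.0,
    min_reporters: int = 3,
) -> list[str]:
    """Choose the shifting peaks that report on binding.

    A peak qualifies when its maximum CSP across the four pools exceeds
    mean + ``n_sd``·sd of the pooled CSP distribution.  If fewer than
    ``min_reporters`` qualify, the top ``min_reporters`` by maximum CSP are
    taken instead (ties broken by peak id order, so the choice is
    deterministic and scale-free).
    """
    shared = sorted(set.intersection(*(set(p) for p in profiles.values())))
    if not shared:
        raise ValueError("pool profiles share no peaks")
    max_csp = {rid: max(profiles[b][rid] for b in profiles) for rid in shared}
    pooled = np.array([v for p in profiles.values() for v in p.values()])
    threshold = float(np.mean(pooled) + n_sd * np.std(pooled))
    chosen = [rid for rid in shared if max_csp[rid] > threshold]
    if len(chosen) < min_reporters:
        chosen = sorted(shared, key=lambda rid: (-max_csp[rid], rid))[:min_reporters]
    return sorted(chosen)


def sia_scores(
    profiles: dict[str, dict[str, float]],
    reporters: "list[str]",
    scanned_position: int = 0,
) -> SIAScoreTable:
    """Per-peak normalization against the largest shift, then averaging.

    For each reporter peak the four pool CSPs are divided by that peak's
    highest pool CSP; per-base scores are the mean over reporter peaks, and
    the table is rescaled so the top base scores exactly 1.  Reporters whose
    CSPs are all zero are dropped with a warning.
    """
    if len(reporters) < 3:
        raise ValueError("need >= 3 reporter peaks")
    per_base = {b: [] for b in BASES}
    used: list[str] = []
    for rid in reporters:
        vals = np.array([profiles[b][rid] for b in BASES])
        peak_max = float(np.max(vals))
        if peak_max <= 0:
            warnings.warn(f"reporter {rid!r} has all-zero CSPs; dropped", stacklevel=2)
            continue
        for b, v in zip(BASES, vals):
            per_base[b].append(v / peak_max)
        used.append(rid)
    if not used:
        raise ValueError("all reporter peaks had zero CSPs")
    means = {b: float(np.mean(per_base[b])) for b in BASES}
    top = max(means.values())
    scores = {b: means[b] / top for b in BASES}
    return SIAScoreTable(scanned_position=scanned_position, scores=scores, reporters=tuple(used))


def rank_preference(
    table: SIAScoreTable, specificity_margin: float = DEFAULT_SPECIFICITY_MARGIN
) -> SIAScoreTable:
    """Call the preferred base for one position.

    The base scoring 1 is called preferred only when the second-best score
    falls below 1 − margin; otherwise the position is reported as having low
    nucleobase preference.
    """
    ordered = sorted(table.scores.items(), key=lambda kv: -kv[1])
    best_base, _ = ordered[0]
    second = ordered[1][1]
    call = f"{best_base} preferred" if second < 1.0 - specificity_margin else "low preference"
    table.call = call
    return table


def score_pool_set(
    pool_set: SIAPoolSet,
    n_sd: float = 1.0,
    specificity_margin: float = DEFAULT_SPECIFICITY_MARGIN,
    max_jump: float = 0.5,
) -> SIAScoreTable:
    """Full SIA pipeline for one scanned position: profiles → reporters → scores → call."""
    profiles = {
        base: pool_csp_profile(pool_set.free, pl, max_jump=max_jump)
        for base, pl in pool_set.pools.items()
    }
    reporters = select_reporter_peaks(profiles, n_sd=n_sd)
    table = sia_scores(profiles, reporters, scanned_position=pool_set.scanned_position)
    return rank_preference(table, specificity_margin=specificity_margin)
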