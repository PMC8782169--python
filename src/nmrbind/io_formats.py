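"""Readers/writers for the tabular text formats the pipeline consumes and shared constants.

Peak lists circulate in two de-facto plain-text dialects: a minimal
whitespace/tab-delimited table with a header, and the Sparky ``.list``
export (``G10N-H  w1(15N)  w2(1H)  [height]``).  Both are accepted.
Constructs are FASTA records whose description carries the residue span in
full-length numbering (``>ZnF2 1293-1321``).  BLI sensorgrams are CSV with
columns ``time_s response_nm stage conc_M``.

All concentrations are stored in molar, chemical shifts in ppm as-is,
time in seconds.
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

# ---------------------------------------------------------------------------
# Shared constants
# ---------------------------------------------------------------------------

#: Weight applied to the 15N dimension in the combined amide CSP,
#: Δδ = sqrt(ΔδH² + (w·ΔδN)²).  Dimensionless, in (0, 1).
CSP_NITROGEN_WEIGHT = 0.152

#: 15N Larmor frequency expressed as a fraction of the 1H spectrometer
#: frequency (|γN/γH| for the backbone amide nitrogen).
N15_LARMOR_RATIO = 0.10136905

#: N–H bond length (m) and 15N CSA (dimensionless, −160 ppm) used only by the
#: rigid-rotor relaxation forward model in the synthetic-data module.
NH_BOND_LENGTH = 1.02e-10
N15_CSA = -160e-6

#: Stage labels a BLI sensorgram may carry, in their mandatory order.
BLI_STAGES = ("baseline", "association", "dissociation")


def nitrogen_larmor_MHz(spectrometer_1H_freq_MHz: float) -> float:
    """15N Larmor frequency (MHz) for a spectrometer of the given 1H frequency."""
    return N15_LARMOR_RATIO * spectrometer_1H_freq_MHz


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Peak:
    """One assigned 2D amide cross-peak."""

    residue_id: str
    delta_H: float
    delta_N: float
    intensity: float = 1.0
    overlapped: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_H) and math.isfinite(self.delta_N)):
            raise ValueError(f"non-finite shift for residue {self.residue_id!r}")
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(f"negative or non-finite intensity for {self.residue_id!r}")


@dataclass
class PeakList:
    """Assigned peaks of one 2D spectrum, keyed by residue id."""

    spectrum_id: str
    entries: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for peak in self.entries:
            if peak.residue_id in seen:
                raise ValueError(f"duplicate residue_id {peak.residue_id!r} in {self.spectrum_id!r}")
            seen.add(peak.residue_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def residue_ids(self) -> list[str]:
        return [p.residue_id for p in self.entries]

    def get(self, residue_id: str) -> Peak | None:
        for p in self.entries:
            if p.residue_id == residue_id:
                return p
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residue_ids,
                "dH_ppm": [p.delta_H for p in self.entries],
                "dN_ppm": [p.delta_N for p in self.entries],
                "intensity": [p.intensity for p in self.entries],
                "overlapped": [p.overlapped for p in self.entries],
            }
        )


@dataclass(frozen=True)
class ConstructSequence:
    """A protein construct: a residue span of the full-length protein.

    ``local_offset`` maps local index 1 to the full-length number
    ``span_start``; local index i corresponds to global residue
    ``span_start + i - 1``.
    """

    construct_id: str
    span_start: int
    span_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.span_end < self.span_start:
            raise ValueError("span_end precedes span_start")
        expected = self.span_end - self.span_start + 1
        if len(self.sequence) != expected:
            raise ValueError(
                f"{self.construct_id!r}: sequence length {len(self.sequence)} does not "
                f"match span {self.span_start}-{self.span_end} ({expected} residues)"
            )
        if not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWY]+", self.sequence.upper()):
            raise ValueError(f"{self.construct_id!r}: sequence contains non-amino-acid letters")

    @property
    def local_offset(self) -> int:
        return self.span_start - 1

    def __len__(self) -> int:
        return len(self.sequence)

    def local_to_global(self, local_index: int) -> int:
        if not 1 <= local_index <= len(self):
            raise IndexError(f"local index {local_index} outside 1..{len(self)}")
        return self.span_start + local_index - 1

    def global_to_local(self, global_number: int) -> int:
        if not self.span_start <= global_number <= self.span_end:
            raise IndexError(f"residue {global_number} outside span {self.span_start}-{self.span_end}")
        return global_number - self.local_offset


def expected_amide_count(construct: ConstructSequence) -> int:
    """Number of backbone amide resonances expected in a 15N correlation spectrum.

    Every residue in the span contributes one amide peak except prolines,
    which have no amide proton.  Cleavage-scar residues outside the annotated
    span are not counted.
    """
    return len(construct) - construct.sequence.upper().count("P")


# ---------------------------------------------------------------------------
# Peak-list I/O
# ---------------------------------------------------------------------------

_SPARKY_ASSIGNMENT = re.compile(r"^([A-Za-z]{1,3}\d+)N-H(?:N)?$")


def _as_lines(source: Union[str, Path, TextIO]) -> tuple[list[str], str]:
    """Return (lines, name) from a path, string path or open text handle."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        return path.read_text().splitlines(), path.stem
    return source.read().splitlines(), getattr(source, "name", "<stream>")


def read_peak_list(source: Union[str, Path, TextIO], spectrum_id: str | None = None) -> PeakList:
    """Read a peak list from tabular text (header dialect or Sparky ``.list``).

    The header dialect requires columns ``residue dH_ppm dN_ppm``;
    ``intensity`` (default 1.0) and ``overlapped`` (default False) are
    optional.  Sparky rows look like ``G10N-H  110.45  8.32  [height]`` with
    w1 = 15N and w2 = 1H.  Unparseable rows are reported with their line
    numbers as a warning; duplicate assignments are a hard error.
    """
    lines, name = _as_lines(source)
    spectrum_id = spectrum_id or name

    content = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip() and not ln.lstrip().startswith("#")]
    if not content:
        warnings.warn(f"empty peak list {spectrum_id!r}", stacklevel=2)
        return PeakList(spectrum_id=spectrum_id, entries=[])

    header_tokens = content[0][1].split()
    if "Assignment" in header_tokens or _SPARKY_ASSIGNMENT.match(header_tokens[0]):
        return _read_sparky(content, spectrum_id)
    return _read_header_table(content, spectrum_id)


def _read_header_table(content: list[tuple[int, str]], spectrum_id: str) -> PeakList:
    header = content[0][1].split()
    required = ("residue", "dH_ppm", "dN_ppm")
    for col in required:
        if col not in header:
            raise ValueError(f"peak list {spectrum_id!r}: missing required column {col!r}")
    idx = {col: header.index(col) for col in header}

    peaks: list[Peak] = []
    bad: list[int] = []
    for lineno, line in content[1:]:
        tokens = line.split()
        try:
            residue = tokens[idx["residue"]]
            dh = float(tokens[idx["dH_ppm"]])
            dn = float(tokens[idx["dN_ppm"]])
            inten = float(tokens[idx["intensity"]]) if "intensity" in idx and len(tokens) > idx["intensity"] else 1.0
            if "overlapped" in idx and len(tokens) > idx["overlapped"]:
                ovl = tokens[idx["overlapped"]].lower() in ("1", "true", "yes")
            else:
                ovl = False
            peaks.append(Peak(residue, dh, dn, inten, ovl))
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ValueError) and "duplicate" in str(exc):
                raise
            bad.append(lineno)
    if bad:
        warnings.warn(f"peak list {spectrum_id!r}: unparseable rows at lines {bad}", stacklevel=3)
    return PeakList(spectrum_id=spectrum_id, entries=peaks)


def _read_sparky(content: list[tuple[int, str]], spectrum_id: str) -> PeakList:
    peaks: list[Peak] = []
    bad: list[int] = []
    for lineno, line in content:
        tokens = line.split()
        if tokens[0] in ("Assignment", "w1"):  # header line
            continue
        m = _SPARKY_ASSIGNMENT.match(tokens[0])
        if m is None:
            bad.append(lineno)
            continue
        try:
            w1_n = float(tokens[1])
            w2_h = float(tokens[2])
            inten = float(tokens[3]) if len(tokens) > 3 else 1.0
        except (IndexError, ValueError):
            bad.append(lineno)
            continue
        peaks.append(Peak(m.group(1), delta_H=w2_h, delta_N=w1_n, intensity=abs(inten)))
    if bad:
        warnings.warn(f"peak list {spectrum_id!r}: unparseable rows at lines {bad}", stacklevel=3)
    return PeakList(spectrum_id=spectrum_id, entries=peaks)


def write_peak_list(peaks: PeakList, target: Union[str, Path, TextIO]) -> None:
    """Write the header-dialect TSV; numeric fields at full precision (round-trip safe)."""
    buf = io.StringIO()
    buf.write("residue\tdH_ppm\tdN_ppm\tintensity\toverlapped\n")
    for p in peaks:
        buf.write(f"{p.residue_id}\t{p.delta_H!r}\t{p.delta_N!r}\t{p.intensity!r}\t{int(p.overlapped)}\n")
    text = buf.getvalue()
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


# ---------------------------------------------------------------------------
# Construct I/O
# ---------------------------------------------------------------------------

_SPAN_RE = re.compile(r"(\d+)\s*[-–]\s*(\d+)")


def read_constructs_fasta(source: Union[str, Path, TextIO]) -> list[ConstructSequence]:
    """Parse constructs from FASTA with ``>id span_start-span_end`` headers."""
    if isinstance(source, (str, Path)):
        handle: TextIO = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        constructs = []
        for rec in SeqIO.parse(handle, "fasta"):
            m = _SPAN_RE.search(rec.description)
            if m is None:
                raise ValueError(f"construct {rec.id!r}: no span_start-span_end in FASTA header")
            constructs.append(
                ConstructSequence(
                    construct_id=rec.id,
                    span_start=int(m.group(1)),
                    span_end=int(m.group(2)),
                    sequence=str(rec.seq).upper(),
                )
            )
        return constructs
    finally:
        if close:
            handle.close()


def write_constructs_fasta(constructs: Iterable[ConstructSequence], target: Union[str, Path]) -> None:
    with open(target, "w") as fh:
        for c in constructs:
            fh.write(f">{c.construct_id} {c.span_start}-{c.span_end}\n{c.sequence}\n")


# ---------------------------------------------------------------------------
# BLI sensorgram I/O
# ---------------------------------------------------------------------------


def read_bli_trace(source: Union[str, Path, TextIO], sensor_id: str | None = None):
    """Read a staged BLI sensorgram CSV (``time_s,response_nm,stage,conc_M``).

    Time must increase monotonically within each stage and the stages must be
    contiguous blocks in baseline → association → dissociation order.  A
    missing stage is tolerated with a warning; an unknown stage label or a
    time reversal is an error.
    """
    from .bli_kinetics import BLIStage, BLITrace  # local import: avoid cycle

    if isinstance(source, (str, Path)):
        name = Path(source).stem
        df = pd.read_csv(source, comment="#")
    else:
        name = getattr(source, "name", "<stream>")
        df = pd.read_csv(source, comment="#")
    sensor_id = sensor_id or name

    for col in ("time_s", "response_nm", "stage", "conc_M"):
        if col not in df.columns:
            raise ValueError(f"BLI trace {sensor_id!r}: missing column {col!r}")

    labels = list(dict.fromkeys(df["stage"]))
    unknown = [s for s in labels if s not in BLI_STAGES]
    if unknown:
        raise ValueError(f"BLI trace {sensor_id!r}: unknown stage label(s) {unknown}")
    order = [s for s in BLI_STAGES if s in labels]
    if labels != order:
        raise ValueError(f"BLI trace {sensor_id!r}: stages out of order or non-contiguous: {labels}")
    missing = [s for s in BLI_STAGES if s not in labels]
    if missing:
        warnings.warn(f"BLI trace {sensor_id!r}: missing stage(s) {missing}", stacklevel=2)

    stages = []
    for label in labels:
        block = df[df["stage"] == label]
        t = block["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"BLI trace {sensor_id!r}: time not strictly increasing in stage {label!r}")
        stages.append(BLIStage(label=label, time=t, response=block["response_nm"].to_numpy(dtype=float)))

    conc = float(df["conc_M"].iloc[0])
    return BLITrace(sensor_id=sensor_id, analyte_conc=conc, stages=stages)


def write_bli_trace(trace, target: Union[str, Path]) -> None:
    frames = []
    for st in trace.stages:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": st.time,
                    "response_nm": st.response,
                    "stage": st.label,
                    "conc_M": trace.analyte_conc,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(target, index=False)


# ---------------------------------------------------------------------------
# Titration series manifest
# ---------------------------------------------------------------------------


def read_titration_manifest(source: Union[str, Path]):
    """Load a titration from a manifest CSV ``ratio,path`` plus metadata comments.

    The manifest may carry ``# construct_id=...`` and ``# P0_M=...`` comment
    lines; peak-list paths are resolved relative to the manifest location.
    """
    from .csp_titration import TitrationSeries  # local import: avoid cycle

    path = Path(source)
    construct_id, p0 = "unknown", float("nan")
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            m = re.match(r"#\s*construct_id\s*=\s*(\S+)", line)
            if m:
                construct_id = m.group(1)
            m = re.match(r"#\s*P0_M\s*=\s*(\S+)", line)
            if m:
                p0 = float(m.group(1))
    df = pd.read_csv(path, comment="#")
    points = []
    for _, row in df.sort_values("ratio").iterrows():
        pl = read_peak_list(path.parent / str(row["path"]))
        points.append((float(row["ratio"]), pl))
    return TitrationSeries(construct_id=construct_id, P0=p0, points=points)
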