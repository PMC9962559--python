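"""The raw CPMG relaxation curve container and its on-disk text format.

A curve is the echo train of a CPMG acquisition: amplitudes sampled at
echo times t_k = 2*tau*k.  The on-disk format is two-column delimited
text with header ``time_s,amplitude``, one row per echo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CurveParseError, InvalidInputError

CURVE_HEADER = "time_s,amplitude"


@dataclass(frozen=True)
class RelaxationCurve:
    """An echo-time grid with signal amplitudes plus acquisition metadata."""

    times: np.ndarray       # seconds, strictly increasing
    amplitudes: np.ndarray  # same length as times
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        if t.ndim != 1 or a.shape != t.shape:
            raise InvalidInputError("times and amplitudes must be 1-D arrays of equal length")
        if t.size == 0:
            raise InvalidInputError("curve must contain at least one echo")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("echo times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise InvalidInputError("curve amplitudes must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "amplitudes", a)

    def __len__(self) -> int:
        return self.times.size


def write_curve(curve: RelaxationCurve, path: str | Path) -> None:
    data = np.column_stack([curve.times, curve.amplitudes])
    np.savetxt(path, data, delimiter=",", header=CURVE_HEADER, comments="", fmt="%.9g")


def read_curve(path: str | Path) -> RelaxationCurve:
    """Parse a two-column ``time_s,amplitude`` text file into a curve."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise CurveParseError(f"{path}: file is empty")
    times, amps = [], []
    start = 1 if lines[0].strip().lower().replace(" ", "") == CURVE_HEADER else 0
    for lineno, line in enumerate(lines[start:], start + 1):
        line = line.strip()
        if not line:
            continue
        parts = [p for p in line.replace("\t", ",").split(",") if p != ""]
        if len(parts) != 2:
            raise CurveParseError(f"{path}: line {lineno}: expected two columns, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            amps.append(float(parts[1]))
        except ValueError as exc:
            raise CurveParseError(f"{path}: line {lineno}: {exc}") from exc
    if not times:
        raise CurveParseError(f"{path}: no data rows found")
    return RelaxationCurve(np.asarray(times), np.asarray(amps), meta={"source": str(path)})
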