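"""HSQC peak lists and their rendering as fixed-geometry images.

An HSQC spectrum is a sparse set of cross-peaks, one per proton-bearing
carbon, with coordinates (delta_1H, delta_13C) in ppm.  For the network the
peak list is rasterized onto a fixed 128x128 grid: one channel for a normal
HSQC, two channels (positive phase / negative phase) for a
multiplicity-edited HSQC, where CH and CH3 carbons give positive peaks and
CH2 carbons negative ones.

The grid frame is a fixed global ppm window (default 1H 0-12.8 ppm,
13C 0-230 ppm, covering even far-downfield aldehyde signals such as
delta_C/delta_H 207.6/9.73) so that every spectrum lands in a comparable
coordinate system.  High ppm sits at row/column 0, matching conventional
spectrum display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Phase",
    "Peak",
    "PeakList",
    "SpectrumBounds",
    "HSQCImage",
    "DEFAULT_BOUNDS",
    "GRID_SIZE",
    "parse_peak_table",
    "serialize_peak_table",
    "rasterize",
    "remove_peak",
]

GRID_SIZE = 128


class Phase(Enum):
    """Multiplicity-edited peak sign; CH/CH3 positive, CH2 negative."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Peak:
    """A single HSQC cross-peak.

    Parameters
    ----------
    h_shift : float
        1H chemical shift in ppm.
    c_shift : float
        13C chemical shift in ppm.
    phase : Phase
        Multiplicity-edited sign; ignored for normal HSQC.
    intensity : float
        Nonnegative relative amplitude, default 1.0.
    """

    h_shift: float
    c_shift: float
    phase: Phase = Phase.UNKNOWN
    intensity: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.h_shift) and math.isfinite(self.c_shift)):
            raise ValueError("peak shifts must be finite")
        if not math.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PeakList:
    """An ordered collection of peaks plus acquisition metadata."""

    peaks: tuple[Peak, ...] = ()
    edited: bool = False
    solvent: str | None = None
    source_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]


@dataclass(frozen=True)
class SpectrumBounds:
    """ppm window of the rasterized frame; low bound strictly below high."""

    h_min: float
    h_max: float
    c_min: float
    c_max: float

    def __post_init__(self) -> None:
        if not (self.h_min < self.h_max and self.c_min < self.c_max):
            raise ValueError(
                f"invalid bounds: need h_min < h_max and c_min < c_max, got {self}"
            )


#: Default frame wide enough for natural-product shift ranges.
DEFAULT_BOUNDS = SpectrumBounds(h_min=0.0, h_max=12.8, c_min=0.0, c_max=230.0)


@dataclass(frozen=True)
class HSQCImage:
    """A 128x128xC gridded rendering of a peak list (C=1 normal, C=2 edited)."""

    grid: np.ndarray
    bounds: SpectrumBounds
    edited: bool

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float32)
        expect_c = 2 if self.edited else 1
        if g.shape != (GRID_SIZE, GRID_SIZE, expect_c):
            raise ValueError(
                f"grid shape {g.shape} does not match edited={self.edited}; "
                f"expected {(GRID_SIZE, GRID_SIZE, expect_c)}"
            )
        if (g < 0).any():
            raise ValueError("grid cells must be nonnegative")
        object.__setattr__(self, "grid", g)

    @property
    def channels(self) -> int:
        return self.grid.shape[2]


_PHASE_TOKENS = {
    "+1": Phase.POSITIVE,
    "1": Phase.POSITIVE,
    "+": Phase.POSITIVE,
    "-1": Phase.NEGATIVE,
    "-": Phase.NEGATIVE,
    "ch": Phase.POSITIVE,
    "ch3": Phase.POSITIVE,
    "ch/ch3": Phase.POSITIVE,
    "ch2": Phase.NEGATIVE,
    "positive": Phase.POSITIVE,
    "negative": Phase.NEGATIVE,
    "unknown": Phase.UNKNOWN,
}


def _parse_phase(token: str, lineno: int) -> Phase:
    p = _PHASE_TOKENS.get(token.strip().lower())
    if p is None:
        raise ValueError(f"line {lineno}: unrecognized phase token {token!r}")
    return p


def _looks_like_header(fields: Sequence[str]) -> bool:
    try:
        float(fields[0])
        float(fields[1])
    except ValueError:
        return True
    return False


def parse_peak_table(
    text: str,
    edited: bool = False,
    solvent: str | None = None,
    source_id: str | None = None,
) -> PeakList:
    """Parse a delimited HSQC peak table into a :class:`PeakList`.

    Rows carry at least two numeric columns (1H ppm, 13C ppm), an optional
    phase column (``+1``/``-1`` or ``CH``/``CH3``/``CH2``) and an optional
    intensity column.  Tabs, commas or runs of whitespace delimit fields;
    blank lines and ``#`` comments are skipped, as is a single non-numeric
    header row.  An empty table parses to an empty peak list.

    Raises
    ------
    ValueError
        On a malformed numeric field, naming the offending line number.
    """
    peaks: list[Peak] = []
    header_skipped = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            fields = [f.strip() for f in line.split("\t")]
        elif "," in line:
            fields = [f.strip() for f in line.split(",")]
        else:
            fields = line.split()
        if sum(1 for f in fields if f) < 2:
            raise ValueError(f"line {lineno}: expected >= 2 columns, got {len(fields)}")
        if not peaks and not header_skipped and _looks_like_header(fields):
            header_skipped = True
            continue
        try:
            h = float(fields[0])
            c = float(fields[1])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed numeric field ({exc})") from None
        phase = Phase.UNKNOWN
        intensity = 1.0
        if len(fields) >= 3 and fields[2].strip():
            phase = _parse_phase(fields[2], lineno)
        if len(fields) >= 4 and fields[3].strip():
            try:
                intensity = float(fields[3])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: malformed intensity field {fields[3]!r}"
                ) from None
        peaks.append(Peak(h_shift=h, c_shift=c, phase=phase, intensity=intensity))
    return PeakList(peaks=tuple(peaks), edited=edited, solvent=solvent, source_id=source_id)


_PHASE_OUT = {Phase.POSITIVE: "+1", Phase.NEGATIVE: "-1", Phase.UNKNOWN: ""}


def serialize_peak_table(pl: PeakList, precision: int = 4) -> str:
    """Write a peak list back to TSV (H_ppm, C_ppm, phase, intensity)."""
    lines = ["H_ppm\tC_ppm\tphase\tintensity"]
    for p in pl:
        lines.append(
            f"{p.h_shift:.{precision}f}\t{p.c_shift:.{precision}f}\t"
            f"{_PHASE_OUT[p.phase]}\t{p.intensity:.{precision}f}"
        )
    return "\n".join(lines) + "\n"


def _pixel_index(value: float, lo: float, hi: float) -> int:
    # high ppm maps to index 0; out-of-frame shifts clamp to the edge pixel
    idx = math.floor(GRID_SIZE * (hi - value) / (hi - lo))
    return min(max(idx, 0), GRID_SIZE - 1)


def rasterize(
    pl: PeakList,
    bounds: SpectrumBounds = DEFAULT_BOUNDS,
    blur_sigma: float = 0.0,
    intensity_cap: float = float("inf"),
) -> HSQCImage:
    """Render a peak list onto the fixed 128x128 grid.

    Each peak is a single-pixel impulse at
    ``row = floor(128*(c_max - c)/(c_max - c_min))`` and
    ``col = floor(128*(h_max - h)/(h_max - h_min))``, both clamped to
    [0, 127]; coincident peaks combine by max.  Intensities are clipped at
    ``intensity_cap``; when the spectrum maximum exceeds 1 all intensities
    are divided by it, so cell values lie in (0, 1] and the weakest peak is
    never scaled away.  For an edited peak list, positive- and unknown-phase peaks
    write to channel 0 and negative-phase peaks to channel 1.  An optional
    Gaussian blur (``blur_sigma`` in pixels) spreads each impulse.
    """
    channels = 2 if pl.edited else 1
    grid = np.zeros((GRID_SIZE, GRID_SIZE, channels), dtype=np.float32)
    if len(pl) > 0:
        raw = np.array([min(p.intensity, intensity_cap) for p in pl], dtype=np.float64)
        peak_max = raw.max()
        scaled = raw / peak_max if peak_max > 1 else raw
        for p, v in zip(pl, scaled):
            row = _pixel_index(p.c_shift, bounds.c_min, bounds.c_max)
            col = _pixel_index(p.h_shift, bounds.h_min, bounds.h_max)
            ch = 1 if (pl.edited and p.phase is Phase.NEGATIVE) else 0
            grid[row, col, ch] = max(grid[row, col, ch], v)
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        for ch in range(channels):
            grid[:, :, ch] = gaussian_filter(grid[:, :, ch], sigma=blur_sigma)
        m = grid.max()
        if m > 0:
            grid /= m
    return HSQCImage(grid=grid, bounds=bounds, edited=pl.edited)


def remove_peak(pl: PeakList, index: int) -> PeakList:
    """Return a copy of ``pl`` with the peak at ``index`` removed."""
    if not 0 <= index < len(pl):
        raise IndexError(f"peak index {index} out of range for {len(pl)} peaks")
    return replace(pl, peaks=pl.peaks[:index] + pl.peaks[index + 1 :])
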