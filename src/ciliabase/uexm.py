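"""Expansion-microscopy metrics: expansion factor, rescaling, and the
transition-zone length from a two-channel fluorescence gap.

In U-ExM the physical expansion factor (EF) is estimated by measuring the
apparent width of axonemes in the expanded gel and comparing it to the known
unexpanded axoneme width (250 nm); all lengths measured in the gel are then
divided by the EF. The transition zone appears as a gap in polyglutamylated-
tubulin (GT335) fluorescence between the distal end of the basal body and
the proximal start of the axoneme; its length is the distance between the
half-maximum edges bounding that gap, EF-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoGapError

#: Unexpanded axoneme width used as the EF reference (nm).
DEFAULT_REFERENCE = 250.0


@dataclass(frozen=True)
class WidthMeasurements:
    """Axoneme widths measured on the expanded scale, plus the reference."""

    widths: np.ndarray
    reference: float = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        w = np.asarray(self.widths, dtype=float)
        if w.size == 0:
            raise ValueError("need at least one width measurement")
        if np.any(w <= 0) or self.reference <= 0:
            raise ValueError("widths and reference must be > 0")
        object.__setattr__(self, "widths", w)


@dataclass(frozen=True)
class IntensityProfile:
    """A 1D multi-channel intensity profile sampled on the expanded scale."""

    positions: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        chans = {}
        for name, inten in self.channels.items():
            inten = np.asarray(inten, dtype=float)
            if inten.shape != pos.shape:
                raise ValueError(f"channel {name!r} length disagrees with positions")
            if np.any(inten < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            chans[name] = inten
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "channels", chans)


@dataclass(frozen=True)
class ExpansionFactor:
    """EF with per-measurement values and their SD."""

    ef: float
    per_measurement: np.ndarray
    sd: float


def expansion_factor(wm: WidthMeasurements) -> ExpansionFactor:
    """EF = mean of per-measurement width/reference ratios.

    With a fixed reference this equals mean(width)/reference; per-measurement
    EFs are kept for spread reporting. Scale-equivariant: multiplying all
    widths by c multiplies the EF by c.
    """
    per = wm.widths / wm.reference
    return ExpansionFactor(
        ef=float(per.mean()),
        per_measurement=per,
        sd=float(per.std(ddof=1)) if per.size > 1 else 0.0,
    )


def rescale(length: float, ef: float) -> float:
    """Convert an expanded-scale length to the corrected (pre-expansion) scale."""
    if ef <= 0:
        raise ValueError("ef must be > 0")
    return length / ef


def _support_intervals(pos: np.ndarray, inten: np.ndarray, threshold: float):
    """Half-maximum support intervals with sub-sample edge interpolation.

    Returns a list of (start, end) positions where intensity ≥ threshold;
    edges between bracketing samples are placed by linear interpolation of
    the threshold crossing.
    """
    above = inten >= threshold
    intervals = []
    i = 0
    n = len(pos)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if i > 0:
            frac = (threshold - inten[i - 1]) / (inten[i] - inten[i - 1])
            start = pos[i - 1] + frac * (pos[i] - pos[i - 1])
        else:
            start = pos[0]
        if j + 1 < n:
            frac = (inten[j] - threshold) / (inten[j] - inten[j + 1])
            end = pos[j] + frac * (pos[j + 1] - pos[j])
        else:
            end = pos[-1]
        intervals.append((float(start), float(end)))
        i = j + 1
    return intervals


def gap_length(
    profile: IntensityProfile,
    channel: str = "gt335",
    threshold_frac: float = 0.5,
    ef: float = 1.0,
    min_gap: float = 0.0,
) -> float:
    """Transition-zone length from the fluorescence gap in one channel.

    Signal support is where intensity ≥ ``threshold_frac`` × channel max;
    the gap is the distance between the end of the proximal support interval
    and the start of the next one, divided by ``ef``. Invariant to overall
    intensity scaling. ``min_gap`` (expanded nm) lets callers ignore sub-
    resolution dropouts in noisy profiles. Raises :class:`NoGapError` if the
    channel has fewer than two support intervals.
    """
    if channel not in profile.channels:
        raise KeyError(f"channel {channel!r} not in profile")
    inten = profile.channels[channel]
    threshold = threshold_frac * inten.max()
    intervals = _support_intervals(profile.positions, inten, threshold)
    gaps = [
        (a_end, b_start)
        for (a_start, a_end), (b_start, b_end) in zip(intervals[:-1], intervals[1:])
        if (b_start - a_end) > min_gap
    ]
    if not gaps:
        raise NoGapError(
            f"channel {channel!r} has {len(intervals)} support interval(s); no gap to measure"
        )
    a_end, b_start = gaps[0]
    return rescale(b_start - a_end, ef)
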