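"""Contraction segmentation and dual-coordinate recruitment thresholds.

Each ramp-hold contraction is segmented into ramp-up / plateau / ramp-down,
and every motor unit's recruitment and de-recruitment thresholds are read at
the instants of its first and last discharge, expressed simultaneously in two
coordinates: the torque trace (%MVC) and the fascicle shortening trace
(delta length, mm).  Reading the same event in both coordinate systems is
what exposes how force-transmission delays distort torque-referenced
thresholds while length-referenced thresholds stay comparatively stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spiketools import SpikeTrainSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationOptions:
    onset_pct: float = 2.0  # torque level defining contraction onset
    onset_sustain_ms: float = 100.0  # must stay above onset_pct this long
    plateau_tolerance: float = 0.25  # fraction of target (covers +/-2.5 %MVC sinusoid at 20 %)
    max_slope_pct_per_s: float = 2.0  # derivative bound trimming plateau edges
    smooth_ms: float = 500.0  # derivative smoothing; 0 = none (ideal traces)


@dataclass(frozen=True)
class ContractionSegments:
    """Sample ranges (half-open) of the contraction phases."""

    ramp_up: tuple[int, int]
    plateau: tuple[int, int]
    ramp_down: tuple[int, int]
    target_pct: float

    def __post_init__(self):
        if not (self.ramp_up[1] <= self.plateau[0] and self.plateau[1] <= self.ramp_down[0]):
            raise ValueError("segments must be ordered and disjoint")
        if self.plateau[1] <= self.plateau[0]:
            raise ValueError("plateau must be nonempty")

    def plateau_duration_s(self, fs: float) -> float:
        return (self.plateau[1] - self.plateau[0]) / fs


@dataclass
class ThresholdRecord:
    """One unit's recruitment/de-recruitment thresholds in both coordinates."""

    unit_id: int
    rt_pct: float  # %MVC torque at first discharge
    drt_pct: float  # %MVC torque at last discharge
    rt_delta_mm: float  # fascicle shortening at first discharge
    drt_delta_mm: float  # fascicle shortening at last discharge
    first_sample: int
    last_sample: int
    flags: tuple[str, ...] = ()


def _sustained_crossing(mask: np.ndarray, sustain: int) -> int | None:
    """First index where ``mask`` holds for ``sustain`` consecutive samples."""
    if sustain <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    run = np.convolve(mask.astype(int), np.ones(sustain, dtype=int), mode="valid")
    idx = np.flatnonzero(run == sustain)
    return int(idx[0]) if idx.size else None


def _moving_average(x: np.ndarray, m: int) -> np.ndarray:
    if m <= 1:
        return x
    k = np.ones(m) / m
    return np.convolve(x, k, mode="same")


def segment_contraction(
    torque_pct: np.ndarray,
    target_pct: float,
    fs: float,
    opts: SegmentationOptions = SegmentationOptions(),
) -> ContractionSegments:
    """Detect ramp-up, plateau and ramp-down of a trapezoidal contraction.

    Onset (offset) is the first (last) sample where torque exceeds
    ``onset_pct`` sustained for ``onset_sustain_ms``.  The plateau is the
    longest run where the smoothed torque stays within
    ``plateau_tolerance * target`` of the target, with its edges then trimmed
    inward while the smoothed torque slope exceeds ``max_slope_pct_per_s``
    (so ramp tails that enter the amplitude band are excluded; interior slope
    excursions from firing fluctuations are not).  The +/-25 % amplitude band
    deliberately also contains the sinusoidally modulated plateau, so one code
    path segments both protocols.
    """
    x = np.asarray(torque_pct, dtype=float)
    n = x.size
    sustain = max(int(round(opts.onset_sustain_ms / 1000.0 * fs)), 1)
    onset = _sustained_crossing(x > opts.onset_pct, sustain)
    offset_rev = _sustained_crossing(x[::-1] > opts.onset_pct, sustain)
    if onset is None or offset_rev is None:
        raise ValueError("no contraction found above the onset level")
    offset = n - offset_rev

    m = int(round(opts.smooth_ms / 1000.0 * fs))
    xs = _moving_average(x, m)
    slope = np.gradient(xs) * fs
    if m > 1:
        slope = _moving_average(slope, m)

    inband = np.abs(xs - target_pct) < opts.plateau_tolerance * target_pct
    if not inband.any():
        raise ValueError("no samples within the plateau amplitude band")
    # longest run of in-band samples
    edges = np.diff(inband.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if inband[0]:
        starts.insert(0, 0)
    if inband[-1]:
        ends.append(n)
    lengths = [e - s for s, e in zip(starts, ends)]
    k = int(np.argmax(lengths))
    lo, hi = starts[k], ends[k]

    flat = np.abs(slope) < opts.max_slope_pct_per_s
    run_lo, run_hi = lo, hi
    while lo < hi and not flat[lo]:
        lo += 1
    while hi > lo and not flat[hi - 1]:
        hi -= 1
    if hi <= lo:
        raise ValueError("no qualifying plateau (slope never settles in the amplitude band)")
    # the smoothed slope blurs the trapezoid corners by half the kernel, so the
    # trim systematically overshoots into the plateau; give that margin back
    # (never beyond the amplitude-band run)
    lo = max(run_lo, lo - m // 2)
    hi = min(run_hi, hi + m // 2)

    return ContractionSegments(
        ramp_up=(onset, lo),
        plateau=(lo, hi),
        ramp_down=(hi, offset),
        target_pct=float(target_pct),
    )


def threshold_records(
    spikes: SpikeTrainSet,
    torque_pct: np.ndarray,
    delta_mm: np.ndarray,
    segments: ContractionSegments,
) -> list[ThresholdRecord]:
    """Read each unit's thresholds at its first and last discharge.

    Values are read at the discharge sample itself (no local averaging): the
    recruitment threshold at the first discharge, the de-recruitment threshold
    at the last.  Units whose first discharge falls after the ramp-up (or last
    before the ramp-down) are flagged rather than dropped; units recruited
    before contraction onset are flagged ``tonic``.  Units with no discharges
    are excluded with a log entry.
    """
    torque_pct = np.asarray(torque_pct, dtype=float)
    delta_mm = np.asarray(delta_mm, dtype=float)
    if torque_pct.size != delta_mm.size:
        raise ValueError("torque and fascicle traces must be aligned (equal length)")
    records = []
    for train in spikes:
        if train.n_discharges == 0:
            logger.info("unit %d has no discharges; excluded from thresholds", train.unit_id)
            continue
        first = int(train.discharges[0])
        last = int(train.discharges[-1])
        flags = []
        if first < segments.ramp_up[0]:
            flags.append("tonic")
        elif first >= segments.ramp_up[1]:
            flags.append("recruited_after_ramp_up")
        if last < segments.ramp_down[0]:
            flags.append("derecruited_before_ramp_down")
        elif last >= segments.ramp_down[1]:
            flags.append("derecruited_after_ramp_down")
        records.append(
            ThresholdRecord(
                unit_id=train.unit_id,
                rt_pct=float(torque_pct[first]),
                drt_pct=float(torque_pct[last]),
                rt_delta_mm=float(delta_mm[first]),
                drt_delta_mm=float(delta_mm[last]),
                first_sample=first,
                last_sample=last,
                flags=tuple(flags),
            )
        )
    return records


def records_to_frame(records: list[ThresholdRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [r.unit_id for r in records],
            "rt_pct": [r.rt_pct for r in records],
            "drt_pct": [r.drt_pct for r in records],
            "rt_delta_mm": [r.rt_delta_mm for r in records],
            "drt_delta_mm": [r.drt_delta_mm for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
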