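"""Acquisition frequency lists and their dummy/S0/retained bookkeeping.

The dynamic protocol acquires one image per saturation offset, 12.2 s each
(TR 40.41 ms x 302 radial spokes).  Three frequency lists are used:

* FL1 — dummy S0 block, then repeating cycles alternating the tracked thiol
  (-2.7 ppm) and amide (+3.6 ppm) offsets with interleaved S0 (333 ppm)
  images.
* FL2 / FL3 — partial Z-spectrum sweeps of five evenly spaced offsets
  (-4.3 ... -1.1 ppm upfield, 4.2 ... 3.0 ppm downfield) with an S0 image
  between sweeps.

Every non-S0 offset is acquired twice in a row; the first instance is
discarded (the saturation steady state is violated by the frequency switch),
so the retained-point time resolution is two image durations, 24.4 s under
the printed protocol timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bmc import S0_OFFSET_PPM

__all__ = [
    "ScheduleEntry",
    "TimingParams",
    "AcquisitionSchedule",
    "build_fl1",
    "build_fl2",
    "build_fl3",
    "build_partial_list",
    "build_full_zspec_list",
    "saturation_time_per_offset",
    "retained_time_resolution",
]


@dataclass(frozen=True)
class ScheduleEntry:
    """One image acquisition: offset, role and timing.

    ``retain`` is False for dummies and for the first instance of every
    repeated measurement frequency.  ``cycle`` indexes the FL1 cycle or the
    partial-spectrum sweep the entry belongs to (-1 for dummies).
    """

    offset_ppm: float
    role: str  # dummy | s0 | measure
    instance: int
    retain: bool
    t_start_s: float
    t_mid_s: float
    cycle: int = -1

    def __post_init__(self) -> None:
        if self.role not in ("dummy", "s0", "measure"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role in ("dummy", "s0") and self.offset_ppm != S0_OFFSET_PPM:
            raise ValueError("dummy/s0 entries must use the S0 reference offset")

    @property
    def t_mid_min(self) -> float:
        return self.t_mid_s / 60.0


@dataclass(frozen=True)
class TimingParams:
    """Protocol timing: TR 40.41 ms, 302 spokes, 30 ms saturation pulse,
    injection starting 23 min into the scan and lasting 1 min."""

    tr_s: float = 0.04041
    n_spokes: int = 302
    sat_pulse_s: float = 0.030
    injection_start_min: float = 23.0
    injection_duration_min: float = 1.0

    def __post_init__(self) -> None:
        if min(self.tr_s, self.sat_pulse_s, self.injection_start_min,
               self.injection_duration_min) <= 0 or self.n_spokes < 1:
            raise ValueError("timing parameters must be positive")

    @property
    def image_duration_s(self) -> float:
        return self.tr_s * self.n_spokes


@dataclass
class AcquisitionSchedule:
    """Ordered schedule entries plus the timing they were stamped with."""

    entries: list[ScheduleEntry]
    timing: TimingParams
    name: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def measure_offsets(self) -> np.ndarray:
        """Unique measurement offsets, in first-appearance order."""
        seen: dict[float, None] = {}
        for e in self.entries:
            if e.role == "measure":
                seen.setdefault(e.offset_ppm, None)
        return np.array(list(seen))

    @property
    def duration_s(self) -> float:
        return len(self.entries) * self.timing.image_duration_s

    def retained(self) -> list[ScheduleEntry]:
        return [e for e in self.entries if e.role == "measure" and e.retain]

    def s0_entries(self, include_dummies: bool = False) -> list[ScheduleEntry]:
        roles = ("s0", "dummy") if include_dummies else ("s0",)
        return [e for e in self.entries if e.role in roles]

    def to_frame(self) -> pd.DataFrame:
        """Tidy serialization (one row per entry) for CSV/JSON sidecars."""
        return pd.DataFrame(
            {
                "index": np.arange(len(self.entries)),
                "offset_ppm": [e.offset_ppm for e in self.entries],
                "role": [e.role for e in self.entries],
                "instance": [e.instance for e in self.entries],
                "retain": [e.retain for e in self.entries],
                "t_start_s": [e.t_start_s for e in self.entries],
                "t_mid_s": [e.t_mid_s for e in self.entries],
                "cycle": [e.cycle for e in self.entries],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, timing: TimingParams,
                   name: str = "") -> "AcquisitionSchedule":
        entries = [
            ScheduleEntry(
                float(r.offset_ppm), str(r.role), int(r.instance), bool(r.retain),
                float(r.t_start_s), float(r.t_mid_s), int(r.cycle),
            )
            for r in frame.itertuples()
        ]
        return cls(entries, timing, name)


def _stamp(proto: list[tuple[float, str, int, bool, int]],
           timing: TimingParams, name: str) -> AcquisitionSchedule:
    """Assign start/midpoint timestamps to a protocol entry list."""
    dur = timing.image_duration_s
    entries = [
        ScheduleEntry(off, role, inst, retain, i * dur, (i + 0.5) * dur, cyc)
        for i, (off, role, inst, retain, cyc) in enumerate(proto)
    ]
    return AcquisitionSchedule(entries, timing, name)


def build_fl1(
    timing: TimingParams | None = None,
    n_dummy: int = 12,
    n_cycles: int = 98,
    cycle_offsets: tuple[float, float] = (-2.7, 3.6),
) -> AcquisitionSchedule:
    """FL1: dummy S0 block, then cycles of [S0, w1, w1, S0, w2, w2].

    Each tracked offset is acquired as a consecutive pair with the first
    instance discarded.  The default 98 cycles give the ~122 min scan of the
    protocol.  The exact interleaving of the S0 images inside a cycle is
    configurable via the cycle structure (under-specified in the protocol
    description; one S0 before each tracked-offset pair is the default).
    """
    timing = timing or TimingParams()
    if n_dummy < 0:
        raise ValueError("n_dummy must be >= 0")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    proto: list[tuple[float, str, int, bool, int]] = [
        (S0_OFFSET_PPM, "dummy", 1, False, -1) for _ in range(n_dummy)
    ]
    for c in range(n_cycles):
        for w in cycle_offsets:
            proto.append((S0_OFFSET_PPM, "s0", 1, True, c))
            proto.append((w, "measure", 1, False, c))
            proto.append((w, "measure", 2, True, c))
    return _stamp(proto, timing, "FL1")


def build_partial_list(
    start_ppm: float,
    end_ppm: float,
    n_offsets: int = 5,
    timing: TimingParams | None = None,
    n_dummy: int = 9,
    n_cycles: int = 35,
    name: str = "partial",
) -> AcquisitionSchedule:
    """Partial Z-spectrum list: repeated sweeps of evenly spaced offsets.

    Each sweep is [S0, w1, w1, ..., w5, w5] with the first instance of every
    offset discarded; sweeps repeat ``n_cycles`` times after ``n_dummy`` dummy
    S0 images.  The default 35 sweeps give the ~80 min protocol scan.
    """
    timing = timing or TimingParams()
    if start_ppm == end_ppm:
        raise ValueError("start and end offsets must differ")
    if n_offsets < 2:
        raise ValueError("n_offsets must be >= 2")
    if n_dummy < 0:
        raise ValueError("n_dummy must be >= 0")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    offsets = np.linspace(start_ppm, end_ppm, n_offsets)
    proto: list[tuple[float, str, int, bool, int]] = [
        (S0_OFFSET_PPM, "dummy", 1, False, -1) for _ in range(n_dummy)
    ]
    for c in range(n_cycles):
        proto.append((S0_OFFSET_PPM, "s0", 1, True, c))
        for w in offsets:
            proto.append((float(w), "measure", 1, False, c))
            proto.append((float(w), "measure", 2, True, c))
    return _stamp(proto, timing, name)


def build_fl2(timing: TimingParams | None = None, n_cycles: int = 35,
              n_dummy: int = 9) -> AcquisitionSchedule:
    """FL2: upfield partial sweeps spanning the thiol resonance, -4.3...-1.1 ppm."""
    return build_partial_list(-4.3, -1.1, 5, timing, n_dummy, n_cycles, "FL2")


def build_fl3(timing: TimingParams | None = None, n_cycles: int = 35,
              n_dummy: int = 9) -> AcquisitionSchedule:
    """FL3: downfield partial sweeps spanning the amide resonance, 4.2...3.0 ppm."""
    return build_partial_list(4.2, 3.0, 5, timing, n_dummy, n_cycles, "FL3")


def build_full_zspec_list(half_range_ppm: float = 5.0, step_ppm: float = 0.2) -> np.ndarray:
    """Symmetric full Z-spectrum offset grid: +-5 ppm at 0.2 ppm = 51 offsets."""
    if step_ppm <= 0:
        raise ValueError("step_ppm must be positive")
    if step_ppm > half_range_ppm:
        raise ValueError("step_ppm must not exceed the half range")
    n_half = int(round(half_range_ppm / step_ppm))
    if not np.isclose(n_half * step_ppm, half_range_ppm):
        raise ValueError("half range must be an integer multiple of the step")
    return np.linspace(-half_range_ppm, half_range_ppm, 2 * n_half + 1)


def saturation_time_per_offset(timing: TimingParams) -> float:
    """Total saturation time per image: pulse duration x spokes (9.06 s)."""
    return timing.sat_pulse_s * timing.n_spokes


def retained_time_resolution(timing: TimingParams) -> float:
    """Retained-point time spacing: two image durations, at 0.1 s rounding
    (24.4 s under the printed protocol timing)."""
    return round(2.0 * timing.tr_s * timing.n_spokes, 1)
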