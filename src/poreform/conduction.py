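"""Ion and water permeation counting.

A crossing is scored with a three-region state machine per particle:
"below" (z < z_lo - buffer), "above" (z > z_hi + buffer) and the slab in
between.  The buffer planes add hysteresis so that thermal rattling at a
slab face is not counted.  An event is recorded only when a particle that
last committed to one outer region commits to the opposite one; excursions
that return to the starting side produce nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Track:
    """Time-ordered membrane-normal positions of one particle."""

    particle_id: int | str
    species: str
    times: np.ndarray            # ps
    z: np.ndarray                # Å
    lateral: np.ndarray | None = None   # (n, 2) in-plane coordinates, optional

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.times) != len(self.z):
            raise ValueError("times and z must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError(f"track {self.particle_id}: times not ordered")


@dataclass
class CrossingEvent:
    """One full permeation of the slab by one particle."""

    particle_id: int | str
    species: str
    direction: int               # +1 towards +z, -1 towards -z
    entry_time: float            # ps, last commit on the origin side
    exit_time: float             # ps, first commit on the far side

    def __post_init__(self) -> None:
        if self.exit_time < self.entry_time:
            raise ValueError("exit before entry")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


def crossing_events(
    tracks: list[Track],
    slab: tuple[float, float],
    buffer: float = 2.0,
) -> list[CrossingEvent]:
    """Detect complete slab crossings in a set of particle tracks."""
    z_lo, z_hi = slab
    if z_lo >= z_hi:
        raise ValueError("slab lower bound must be below upper bound")
    if buffer < 0:
        raise ValueError("buffer must be non-negative")
    lo_plane = z_lo - buffer
    hi_plane = z_hi + buffer
    events: list[CrossingEvent] = []
    for tr in tracks:
        region = np.zeros(len(tr.z), dtype=int)   # -1 below, +1 above, 0 slab
        region[tr.z < lo_plane] = -1
        region[tr.z > hi_plane] = 1
        committed = 0
        entry_t = None
        for t, r in zip(tr.times, region):
            if r == 0:
                continue
            if committed == 0:
                committed = r
            elif r != committed:
                events.append(
                    CrossingEvent(
                        particle_id=tr.particle_id,
                        species=tr.species,
                        direction=int(r),
                        entry_time=float(entry_t if entry_t is not None else t),
                        exit_time=float(t),
                    )
                )
                committed = r
            entry_t = t
    events.sort(key=lambda e: (e.exit_time, str(e.particle_id)))
    return events


@dataclass
class ConductionSummary:
    """Per-species permeation counts, rates and selectivity ratios."""

    counts: dict[str, int]
    rates: dict[str, float]                # events / μs
    direction_split: dict[str, tuple[int, int]]   # (+z count, -z count)
    selectivity: dict[str, float | None]
    duration_us: float
    voltage_mv: float | None = None
    water_volume_flux: float | None = None  # Å^3 / μs, 29.9 Å^3 per water

    @property
    def total(self) -> int:
        return sum(self.counts.values())


WATER_VOLUME_A3 = 29.9  # bulk molecular volume of water


def conduction_summary(
    events: list[CrossingEvent],
    duration_ps: float,
    species: list[str] | None = None,
    voltage_mv: float | None = None,
) -> ConductionSummary:
    """Aggregate events into per-species rates and selectivity ratios.

    Selectivity ratios with a zero denominator are reported as None
    (undefined), never infinite.
    """
    if duration_ps <= 0:
        raise ValueError("duration must be positive")
    duration_us = duration_ps * 1e-6
    if species is None:
        species = sorted({e.species for e in events})
    counts = {s: 0 for s in species}
    split = {s: [0, 0] for s in species}
    for e in events:
        counts.setdefault(e.species, 0)
        split.setdefault(e.species, [0, 0])
        counts[e.species] += 1
        split[e.species][0 if e.direction > 0 else 1] += 1
    rates = {s: c / duration_us for s, c in counts.items()}

    def ratio(a: str, b: str) -> float | None:
        if a not in rates or b not in rates or rates[b] == 0:
            return None
        return rates[a] / rates[b]

    cation = {s: rates.get(s, 0.0) for s in ("NA", "K")}
    sel = {
        "CL/cation": (
            rates["CL"] / sum(cation.values())
            if rates.get("CL") is not None and sum(cation.values()) > 0 and "CL" in rates
            else None
        ),
        "K/NA": ratio("K", "NA"),
    }
    water_flux = None
    if "water" in rates:
        water_flux = rates["water"] * WATER_VOLUME_A3
    return ConductionSummary(
        counts=counts,
        rates=rates,
        direction_split={s: (v[0], v[1]) for s, v in split.items()},
        selectivity=sel,
        duration_us=duration_us,
        voltage_mv=voltage_mv,
        water_volume_flux=water_flux,
    )


def conductance_pS(
    count: int, duration_ps: float, voltage_mv: float, charge_e: float = 1.0
) -> float:
    """Single-channel conductance estimate, count*charge/(duration*voltage).

    Order-of-magnitude helper: elementary charges per event, duration in
    ps, voltage in mV; returns picosiemens.
    """
    if duration_ps <= 0 or voltage_mv == 0:
        raise ValueError("need positive duration and nonzero voltage")
    current_amp = count * charge_e * 1.602176634e-19 / (duration_ps * 1e-12)
    return current_amp / (voltage_mv * 1e-3) * 1e12


def pore_axis_filter(
    events: list[CrossingEvent],
    tracks: list[Track],
    pore_trace: tuple[np.ndarray, np.ndarray],
    radius: float,
    slab: tuple[float, float],
) -> list[CrossingEvent]:
    """Keep events whose particle stayed within ``radius`` of the pore axis
    while inside the slab.

    ``pore_trace`` is (times, (n, 2) in-plane pore centre positions);
    particle lateral positions are compared against the nearest-in-time
    pore centre.  ``radius=inf`` reproduces the unfiltered list.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if pore_trace is None:
        raise ValueError("pore centre-of-mass trace is required")
    pt_times, pt_xy = np.asarray(pore_trace[0], float), np.asarray(pore_trace[1], float)
    by_id = {tr.particle_id: tr for tr in tracks}
    kept = []
    for e in events:
        tr = by_id[e.particle_id]
        if tr.lateral is None:
            raise ValueError(f"track {tr.particle_id} has no lateral coordinates")
        mask = (tr.times >= e.entry_time) & (tr.times <= e.exit_time)
        inside = (tr.z >= slab[0]) & (tr.z <= slab[1]) & mask
        if not inside.any():
            kept.append(e)
            continue
        idx = np.searchsorted(pt_times, tr.times[inside])
        idx = np.clip(idx, 0, len(pt_times) - 1)
        d = np.linalg.norm(tr.lateral[inside] - pt_xy[idx], axis=1)
        if np.all(d <= radius):
            kept.append(e)
    return kept


def phosphate_slab(frames, normal_axis: int = 2) -> tuple[float, float]:
    """Mean lipid leaflet planes over a trajectory, after midplane recentering."""
    from .core import recenter_frame

    lo, hi, n = 0.0, 0.0, 0
    for frame in frames:
        frame = recenter_frame(frame)
        z = frame.coords[frame.mask("lipid"), frame.normal_axis]
        if z.size == 0:
            raise ValueError("no lipid atoms for slab detection")
        lo += z[z < 0].mean()
        hi += z[z >= 0].mean()
        n += 1
    if n == 0:
        raise ValueError("no frames")
    return lo / n, hi / n
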