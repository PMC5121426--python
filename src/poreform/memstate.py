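"""Per-peptide membrane-insertion analysis.

A peptide is classified each frame as surface-bound (S) or transmembrane
(TM) from its helix tilt against the membrane normal and the depth of its
centre of mass relative to the bilayer midplane.  The two thresholds leave
a hysteresis dead band in which the previous state is kept, suppressing
single-frame flicker at the S/TM boundary.  The S<->TM free energy follows
from the two-state occupancy split, dG(S->TM) = -RT ln(p_TM / p_S).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import R_KCAL


def helix_axis(ca_coords: np.ndarray) -> np.ndarray:
    """Helix axis of a CA trace, oriented N-terminus -> C-terminus.

    Second differences of consecutive CA positions point radially at the
    axis, so cross products of successive second differences are parallel
    to it; their average is exact for an ideal helix of any length (a
    plain principal-component axis is biased on fractional turns).  A
    principal-axis fall-back covers straight or otherwise degenerate
    traces.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if len(ca) < 4:
        raise ValueError("helix axis needs at least 4 residues")
    centered = ca - ca.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError("degenerate coordinates: all CA atoms coincide")
    d2 = ca[2:] - 2.0 * ca[1:-1] + ca[:-2]
    cross = np.cross(d2[:-1], d2[1:])
    norms = np.linalg.norm(cross, axis=1)
    good = norms > 1e-8
    if good.any():
        axis = (cross[good] / norms[good, None]).mean(axis=0)
    else:
        # straight trace: fall back to the principal component
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("degenerate coordinates: helix axis undefined")
    return axis / n


def tilt_angle(axis: np.ndarray, normal: np.ndarray) -> float:
    """Angle (deg) between a helix axis and the membrane normal, folded to [0, 90]."""
    a = np.asarray(axis, dtype=float)
    n = np.asarray(normal, dtype=float)
    na, nn = np.linalg.norm(a), np.linalg.norm(n)
    if na == 0 or nn == 0:
        raise ValueError("tilt undefined for zero vectors")
    cosang = abs(a @ n) / (na * nn)
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def classify_state(
    tilt: float,
    com_depth: float,
    previous: str | None,
    tilt_tm: float = 50.0,
    tilt_s: float = 70.0,
    depth_tm: float = 8.0,
    depth_s: float = 12.0,
) -> str:
    """S/TM classification with a hysteresis dead band.

    TM requires small tilt and a centre of mass near the midplane; S
    requires large tilt or a centre of mass out at the interface.  Inside
    the dead band the previous state persists; on the first frame the
    nearer threshold decides.
    """
    depth = abs(com_depth)
    if tilt < tilt_tm and depth < depth_tm:
        return "TM"
    if tilt > tilt_s or depth > depth_s:
        return "S"
    if previous in ("S", "TM"):
        return previous
    # first frame inside the band: nearest threshold in normalised units
    d_tm = max((tilt - tilt_tm) / tilt_tm, (depth - depth_tm) / depth_tm)
    d_s = max((tilt_s - tilt) / tilt_s, (depth_s - depth) / depth_s)
    return "TM" if d_tm <= d_s else "S"


@dataclass
class StateSeries:
    """Per-peptide tilt, depth and S/TM label over a trajectory."""

    tilt: pd.DataFrame       # frames x peptides, degrees
    depth: pd.DataFrame      # frames x peptides, Å from midplane
    state: pd.DataFrame      # frames x peptides, "S"/"TM"

    def p_surface(self) -> float:
        return float((self.state == "S").to_numpy().mean())


def state_series(frames, chains, config=None) -> StateSeries:
    """Classify every peptide in every frame.

    Frames are recentered so depth is measured from the lipid midplane.
    """
    from .core import recenter_frame

    kw = {}
    if config is not None:
        kw = dict(
            tilt_tm=config.tilt_tm, tilt_s=config.tilt_s,
            depth_tm=config.depth_tm, depth_s=config.depth_s,
        )
    tilts, depths, states = [], [], []
    prev: list[str | None] = [None] * len(chains)
    times = []
    for frame in frames:
        frame = recenter_frame(frame)
        ax = frame.normal_axis
        normal = np.zeros(3)
        normal[ax] = 1.0
        row_t, row_d, row_s = [], [], []
        for k, ch in enumerate(chains):
            t = tilt_angle(helix_axis(ch.ca_coords(frame)), normal)
            d = float(ch.heavy_coords(frame)[:, ax].mean())
            s = classify_state(t, d, prev[k], **kw)
            prev[k] = s
            row_t.append(t)
            row_d.append(d)
            row_s.append(s)
        tilts.append(row_t)
        depths.append(row_d)
        states.append(row_s)
        times.append(frame.time)
    cols = [ch.chain_id for ch in chains]
    return StateSeries(
        tilt=pd.DataFrame(tilts, index=times, columns=cols),
        depth=pd.DataFrame(depths, index=times, columns=cols),
        state=pd.DataFrame(states, index=times, columns=cols),
    )


@dataclass
class TwoStateEquilibrium:
    """Surface/transmembrane two-state split and its free energy."""

    p_surface: float
    p_tm: float
    temperature: float
    dg_s_to_tm: float          # kcal/mol
    sem_p_surface: float = float("nan")


def two_state_dG(p_surface: float, temperature: float) -> float:
    """dG(S->TM) in kcal/mol from the surface-state fraction.

    Positive when the surface state dominates (p_S > 0.5).
    """
    if not 0.0 < p_surface < 1.0:
        raise ValueError(
            "free energy diverges for a fully one-sided split; "
            f"p_surface={p_surface} is censored"
        )
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(-R_KCAL * temperature * np.log((1.0 - p_surface) / p_surface))


def two_state_equilibrium(
    states: StateSeries, temperature: float, n_blocks: int = 10
) -> TwoStateEquilibrium:
    is_s = (states.state == "S").to_numpy().astype(float)
    p_s = float(is_s.mean())
    sem = block_sem(is_s.mean(axis=1), n_blocks) if len(is_s) >= n_blocks else float("nan")
    return TwoStateEquilibrium(
        p_surface=p_s, p_tm=1.0 - p_s, temperature=temperature,
        dg_s_to_tm=two_state_dG(p_s, temperature), sem_p_surface=sem,
    )


@dataclass
class DensityMap:
    """Peptide mass histogram along the membrane normal, over time.

    ``values`` has shape (n_z_bins, n_frames); columns before smoothing sum
    to the total peptide mass of the frame.
    """

    z_edges: np.ndarray
    times: np.ndarray
    values: np.ndarray
    raw: np.ndarray
    smooth_window: int


def density_map(
    frames,
    z_bin: float = 1.0,
    smooth_window: int = 10,
    z_range: tuple[float, float] | None = None,
) -> DensityMap:
    """Histogram of peptide mass vs membrane-normal position and time.

    The map is smoothed with a moving average over ``smooth_window``
    consecutive frames along the time axis; at the edges the window shrinks
    symmetrically.  Frames are recentered on the lipid midplane first.
    """
    from .core import recenter_frame

    cols, times = [], []
    edges = None
    for frame in frames:
        frame = recenter_frame(frame)
        ax = frame.normal_axis
        pep = frame.mask("peptide")
        z = frame.coords[pep, ax]
        w = frame.atom_masses()[pep]
        if edges is None:
            if z_range is None:
                half = frame.box[ax] / 2.0
                z_range = (-half, half)
            nbins = max(1, int(np.ceil((z_range[1] - z_range[0]) / z_bin)))
            edges = np.linspace(z_range[0], z_range[1], nbins + 1)
        hist, _ = np.histogram(np.clip(z, edges[0], edges[-1] - 1e-9), bins=edges, weights=w)
        cols.append(hist)
        times.append(frame.time)
    if not cols:
        raise ValueError("density map needs at least one frame")
    raw = np.stack(cols, axis=1)
    nframes = raw.shape[1]
    window = int(smooth_window)
    if nframes < window:
        import warnings

        warnings.warn(
            f"only {nframes} frames for a {window}-frame smoothing window; "
            "window reduced", stacklevel=2,
        )
        window = max(1, nframes)
    half = window // 2
    smoothed = np.empty_like(raw, dtype=float)
    for t in range(nframes):
        # symmetric shrink at the edges
        k = min(half, t, nframes - 1 - t)
        smoothed[:, t] = raw[:, t - k : t + k + 1].mean(axis=1)
    return DensityMap(
        z_edges=edges, times=np.asarray(times), values=smoothed,
        raw=raw.astype(float), smooth_window=window,
    )


def block_sem(series: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error of the mean by block averaging.

    The series is split into ``n_blocks`` contiguous equal blocks (any
    remainder at the end is truncated); the s.e.m. is the sample standard
    deviation of the block means divided by sqrt(n_blocks).  Appropriate
    for correlated time series where naive i.i.d. errors underestimate.
    """
    x = np.asarray(series, dtype=float).ravel()
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    size = len(x) // n_blocks
    if size < 1:
        raise ValueError(f"series of length {len(x)} too short for {n_blocks} blocks")
    means = x[: size * n_blocks].reshape(n_blocks, size).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_blocks))
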