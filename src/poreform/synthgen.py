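"""Synthetic membrane-peptide systems with known ground truth.

Everything the analysis modules consume — topologies, trajectories, ion
tracks, lifetime tables — can be generated here at desk scale with the
true answers recorded, so the whole toolkit is testable without running
molecular dynamics.  Peptides are ideal backbone-only α-helices (1.5 Å
rise, 100° per residue); the bilayer is a coarse placeholder slab of
pseudo-atoms at the two leaflet planes, sufficient for recentering, depth
measurement and slab detection.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conduction import Track
from .core import R_KCAL
from .kinetics import LifetimeSample

#: default peptide: maculatin 1.1, a 21-residue frog-skin antimicrobial peptide
MACULATIN_SEQUENCE = "GLFGVLAKVAAHVVPAIAEHF"

HELIX_RISE = 1.5          # Å per residue
HELIX_TWIST = 100.0       # degrees per residue
CA_RADIUS = 2.3           # Å, CA distance from helix axis

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def build_ideal_helix(sequence: str = MACULATIN_SEQUENCE) -> np.ndarray:
    """Backbone (N, CA, C per residue) of an ideal α-helix along +z.

    Returns an (n_residues, 3, 3) array; the N terminus sits at low z.  N
    and C atoms are placed on the same helical path at fractional residue
    offsets, giving near-physical bond geometry — adequate for contact,
    axis and RMSD analysis of synthetic systems.
    """
    n = len(sequence)
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    bad = set(sequence) - set(ONE_TO_THREE)
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")

    def point(t: float, radius: float) -> np.ndarray:
        ang = np.radians(HELIX_TWIST * t)
        return np.array([radius * np.cos(ang), radius * np.sin(ang), HELIX_RISE * t])

    out = np.empty((n, 3, 3))
    for i in range(n):
        out[i, 0] = point(i - 0.35, 1.9)   # N
        out[i, 1] = point(i, CA_RADIUS)    # CA
        out[i, 2] = point(i + 0.44, 1.9)   # C
    out -= out[:, 1].mean(axis=0)          # centre on the CA centroid
    return out


def _flip_down(coords: np.ndarray) -> np.ndarray:
    """Rotate a helix 180° about x so its N terminus points up (+z)."""
    out = coords.copy()
    out[..., 1] *= -1
    out[..., 2] *= -1
    return out


def _rot_z(coords: np.ndarray, degrees: float) -> np.ndarray:
    a = np.radians(degrees)
    rot = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
    return coords @ rot.T


def make_bundle(
    n: int,
    ring_radius: float | None = None,
    scheme: str = "",
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    sequence: str = MACULATIN_SEQUENCE,
    axial_offset: float = 0.0,
) -> np.ndarray:
    """n helices on a ring, one per scheme letter, as an (n, nres, 3, 3) array.

    Scheme letters follow the top-view convention: 'C' = C terminus up
    (helix axis along +z), 'N' = N terminus up (axis along -z); antiparallel
    neighbours may be offset axially by ``axial_offset`` Å, emulating the
    recurring antiparallel-dimer motif offset by a few helix turns.  A ring
    radius is chosen automatically (adjacent-helix spacing ~7.5 Å) when not
    given; Gaussian coordinate noise of width ``noise_sigma`` is added when
    a generator is supplied.
    """
    if n < 2:
        raise ValueError("a bundle needs at least 2 peptides")
    scheme = scheme or "NC" * (n // 2 + 1)
    scheme = scheme[:n]
    if len(scheme) != n or set(scheme) - {"N", "C"}:
        raise ValueError(f"scheme {scheme!r} must be n letters from {{N, C}}")
    if ring_radius is None:
        # adjacent-helix axis spacing of 6.2 Å puts neighbouring backbones
        # well inside the 3.5 Å contact cutoff while keeping non-adjacent
        # ring members well outside it
        ring_radius = 6.2 / (2 * np.sin(np.pi / n))
    if ring_radius < 3.0:
        import warnings

        warnings.warn("ring radius implies severe steric overlap", stacklevel=2)
    helix_up = build_ideal_helix(sequence)
    members = []
    for k, letter in enumerate(scheme):
        h = _flip_down(helix_up) if letter == "N" else helix_up.copy()
        h = _rot_z(h, 360.0 * k / n)
        ang = 2 * np.pi * k / n
        h[..., 0] += ring_radius * np.cos(ang)
        h[..., 1] += ring_radius * np.sin(ang)
        if letter == "N":
            h[..., 2] += axial_offset
        members.append(h)
    coords = np.stack(members)
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise requires a seeded random generator")
        coords = coords + rng.normal(0.0, noise_sigma, size=coords.shape)
    return coords


@dataclass
class ScheduleEntry:
    """One assembly episode: the frame range over which given peptides form
    one bundle with a given orientation scheme."""

    frame_start: int
    frame_stop: int              # exclusive
    members: tuple[int, ...]
    scheme: str = ""
    ring_radius: float | None = None


@dataclass
class SynthSpec:
    """Full recipe for a synthetic assembly trajectory."""

    n_peptides: int = 16
    sequence: str = MACULATIN_SEQUENCE
    half_thickness: float = 17.5         # Å, leaflet-plane distance from midplane
    n_frames: int = 100
    timestep: float = 100.0              # ps between frames
    schedule: list[ScheduleEntry] = field(default_factory=list)
    noise_sigma: float = 0.1             # Å positional noise (see docs: kept
                                         # small so truth labels stay sharp)
    box_xy: float = 160.0                # Å lateral box edge
    box_z: float = 90.0
    seed: int = 0
    tm_monomers: tuple[int, ...] = ()    # peptides held TM-inserted when free

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise must be non-negative")
        for entry in self.schedule:
            if len(entry.members) > self.n_peptides:
                raise ValueError("schedule composition exceeds peptide count")
            if max(entry.members, default=-1) >= self.n_peptides:
                raise ValueError("schedule names an unknown peptide")
            if not 0 <= entry.frame_start < entry.frame_stop <= self.n_frames:
                raise ValueError("schedule frame range outside the trajectory")


@dataclass
class FrameTruth:
    """Ground-truth labels for one frame."""

    oligomers: list[tuple[int, ...]]
    schemes: list[str]
    states: list[str]                    # per peptide, "S" or "TM"


@dataclass
class SyntheticAssembly:
    """In-memory synthetic trajectory plus its ground truth."""

    spec: SynthSpec
    coords: np.ndarray                   # (frames, atoms, 3)
    box: np.ndarray
    kinds: np.ndarray
    peptide_index: np.ndarray
    atom_names: list[str]
    resnames: list[str]
    resids: list[int]
    truth: list[FrameTruth]

    def frames(self):
        from .core import TrajectoryFrame

        for i in range(len(self.coords)):
            yield TrajectoryFrame(
                time=i * self.spec.timestep,
                box=self.box,
                coords=self.coords[i],
                kinds=self.kinds,
                peptide_index=self.peptide_index,
                frame_index=i,
            )

    def chains(self):
        from .core import PeptideChain

        nres = len(self.spec.sequence)
        chains = []
        for k in range(self.spec.n_peptides):
            base = k * nres * 3
            idx = np.arange(base, base + nres * 3).reshape(nres, 3)
            chains.append(
                PeptideChain(
                    chain_id=chr(ord("A") + k) if k < 26 else f"P{k}",
                    residue_names=[ONE_TO_THREE[c] for c in self.spec.sequence],
                    residue_numbers=list(range(1, nres + 1)),
                    n_indices=idx[:, 0],
                    ca_indices=idx[:, 1],
                    c_indices=idx[:, 2],
                    heavy_indices=idx.reshape(-1),
                )
            )
        return chains


def _surface_slots(spec: SynthSpec) -> np.ndarray:
    """Deterministic 4x4-style grid of monomer anchor positions."""
    side = int(np.ceil(np.sqrt(spec.n_peptides)))
    spacing = spec.box_xy / side
    slots = []
    for k in range(spec.n_peptides):
        i, j = divmod(k, side)
        slots.append([(j + 0.5) * spacing, (i + 0.5) * spacing])
    return np.array(slots)


def _bundle_anchor(slots: np.ndarray, entry: "ScheduleEntry") -> np.ndarray:
    """Lateral position for a bundle: the grid slot vacated by its first
    member, so bundles can never collide with remaining monomers."""
    return slots[entry.members[0]]


def simulate_assembly_trajectory(spec: SynthSpec) -> SyntheticAssembly:
    """Generate a trajectory following the spec's assembly schedule.

    Peptides not in a scheduled bundle lie surface-bound (axis in-plane,
    centre of mass at the leaflet surface, alternating leaflets) on a
    lateral grid whose spacing guarantees no spurious contacts; scheduled
    peptides stand in TM ring bundles at the designated anchor.  Ground
    truth (membership partition, schemes, S/TM state per peptide) is
    recorded per frame.
    """
    rng = np.random.default_rng(spec.seed)
    nres = len(spec.sequence)
    helix_up = build_ideal_helix(spec.sequence)
    helix_flat = helix_up.copy()
    # lay the helix down: rotate 90° about y so the axis runs along +x
    rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    helix_flat = helix_flat @ rot.T

    slots = _surface_slots(spec)
    n_pep_atoms = spec.n_peptides * nres * 3

    # placeholder lipid slab: pseudo-atoms on an 8x8 grid per leaflet
    grid = np.linspace(0, spec.box_xy, 9)[:-1] + spec.box_xy / 16
    gx, gy = np.meshgrid(grid, grid)
    leaf = np.stack([gx.ravel(), gy.ravel()], axis=1)
    lipid_xyz = np.concatenate(
        [
            np.column_stack([leaf, np.full(len(leaf), +spec.half_thickness)]),
            np.column_stack([leaf, np.full(len(leaf), -spec.half_thickness)]),
        ]
    )
    n_lipid = len(lipid_xyz)

    box = np.array([spec.box_xy, spec.box_xy, spec.box_z])
    z_center = spec.box_z / 2.0  # files store z in [0, box_z]; midplane at centre

    coords = np.empty((spec.n_frames, n_pep_atoms + n_lipid, 3))
    truth: list[FrameTruth] = []
    for f in range(spec.n_frames):
        active = [e for e in spec.schedule if e.frame_start <= f < e.frame_stop]
        in_bundle: dict[int, tuple[int, int, "ScheduleEntry"]] = {}
        for b, entry in enumerate(active):
            for pos, m in enumerate(entry.members):
                if m in in_bundle:
                    raise ValueError(
                        f"frame {f}: peptide {m} scheduled in two bundles"
                    )
                in_bundle[m] = (b, pos, entry)
        pep = np.empty((spec.n_peptides, nres, 3, 3))
        states = []
        bundle_coords = {}
        for b, entry in enumerate(active):
            scheme = entry.scheme or ("NC" * len(entry.members))[: len(entry.members)]
            bc = make_bundle(
                len(entry.members), entry.ring_radius, scheme,
                noise_sigma=0.0, sequence=spec.sequence,
            )
            anchor = _bundle_anchor(slots, entry)
            bc[..., 0] += anchor[0]
            bc[..., 1] += anchor[1]
            bundle_coords[b] = (bc, scheme)
        for k in range(spec.n_peptides):
            if k in in_bundle:
                b, pos, entry = in_bundle[k]
                pep[k] = bundle_coords[b][0][pos]
                states.append("TM")
            elif k in spec.tm_monomers:
                h = helix_up.copy()
                h[..., 0] += slots[k, 0]
                h[..., 1] += slots[k, 1]
                pep[k] = h
                states.append("TM")
            else:
                h = helix_flat.copy()
                leaflet = 1 if k % 2 == 0 else -1
                h[..., 0] += slots[k, 0]
                h[..., 1] += slots[k, 1]
                h[..., 2] += leaflet * (spec.half_thickness + 2.5)
                pep[k] = h
                states.append("S")
        if spec.noise_sigma > 0:
            pep = pep + rng.normal(0.0, spec.noise_sigma, size=pep.shape)
        frame_xyz = np.concatenate([pep.reshape(-1, 3), lipid_xyz])
        frame_xyz[:, 2] += z_center
        coords[f] = frame_xyz
        oligos = sorted(tuple(sorted(e.members)) for e in active)
        schemes = [bundle_coords[b][1] for b in range(len(active))]
        truth.append(FrameTruth(oligomers=oligos, schemes=schemes, states=states))

    kinds = np.array(["peptide"] * n_pep_atoms + ["lipid"] * n_lipid)
    pep_index = np.concatenate(
        [np.repeat(np.arange(spec.n_peptides), nres * 3), np.full(n_lipid, -1)]
    )
    atom_names, resnames, resids = [], [], []
    for k in range(spec.n_peptides):
        # residue numbering restarts per chain, as GRO topologies carry no
        # chain identifiers and chains are recovered from resid resets
        for r, letter in enumerate(spec.sequence):
            for name in ("N", "CA", "C"):
                atom_names.append(name)
                resnames.append(ONE_TO_THREE[letter])
                resids.append(r + 1)
    for i in range(n_lipid):
        atom_names.append("P")
        resnames.append("LIP")
        resids.append(i + 1)
    return SyntheticAssembly(
        spec=spec, coords=coords, box=box, kinds=kinds,
        peptide_index=pep_index, atom_names=atom_names,
        resnames=resnames, resids=resids, truth=truth,
    )


def write_assembly_files(
    assembly: SyntheticAssembly, out_prefix: str | Path
) -> dict[str, Path]:
    """Write GRO topology + XTC trajectory + JSON ground-truth labels."""
    import MDAnalysis as mda

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    n = assembly.coords.shape[1]
    resids = np.asarray(assembly.resids)
    # residues are consecutive (resid, resname) runs; resids repeat across
    # chains, so a unique-value grouping would merge them
    res_index = np.empty(n, dtype=int)
    res_ids, res_names = [], []
    for i in range(n):
        if not res_ids or res_ids[-1] != resids[i] or res_names[-1] != assembly.resnames[i]:
            res_ids.append(int(resids[i]))
            res_names.append(assembly.resnames[i])
        res_index[i] = len(res_ids) - 1
    u = mda.Universe.empty(
        n_atoms=n, n_residues=len(res_ids), n_segments=1,
        atom_resindex=res_index, residue_segindex=np.zeros(len(res_ids), int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", assembly.atom_names)
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("resids", res_ids)
    u.dimensions = [*assembly.box, 90.0, 90.0, 90.0]
    u.atoms.positions = assembly.coords[0]
    gro = out_prefix.with_suffix(".gro")
    xtc = out_prefix.with_suffix(".xtc")
    labels = out_prefix.parent / (out_prefix.name + "_truth.json")
    u.atoms.write(str(gro))
    with mda.Writer(str(xtc), n_atoms=n) as w:
        for f in range(len(assembly.coords)):
            u.atoms.positions = assembly.coords[f]
            u.trajectory.ts.time = f * assembly.spec.timestep
            u.trajectory.ts.frame = f
            w.write(u.atoms)
    payload = {
        "seed": assembly.spec.seed,
        "n_peptides": assembly.spec.n_peptides,
        "sequence": assembly.spec.sequence,
        "frames": [
            {
                "oligomers": [list(o) for o in t.oligomers],
                "schemes": t.schemes,
                "states": t.states,
            }
            for t in assembly.truth
        ],
    }
    labels.write_text(json.dumps(payload, indent=1))
    return {"topology": gro, "trajectory": xtc, "truth": labels}


@dataclass
class IonTrackTruth:
    """Generator truth for one synthetic conduction data set."""

    counts: dict[str, int]
    directions: dict[str, tuple[int, int]]
    duration_ps: float


def simulate_ion_tracks(
    rates_per_us: dict[str, float] | float,
    duration_us: float,
    seed: int,
    slab: tuple[float, float] = (-17.5, 17.5),
    buffer: float = 2.0,
    n_distractors: int = 5,
    dt_ps: float = 200.0,
) -> tuple[list[Track], IonTrackTruth]:
    """Poisson-distributed complete crossings plus non-crossing distractors.

    Each crossing is its own particle: a track that starts committed on one
    side, traverses the slab over ~10 ns and commits on the far side.
    Distractor particles enter the slab and return to their starting side,
    which must never be counted.  The true event census is returned.
    """
    if isinstance(rates_per_us, (int, float)):
        rates_per_us = {"ion": float(rates_per_us)}
    if any(v < 0 for v in rates_per_us.values()):
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    duration_ps = duration_us * 1e6
    z_lo, z_hi = slab
    margin = buffer + 8.0
    transit = 10_000.0  # ps spent traversing the slab
    tracks: list[Track] = []
    counts: dict[str, int] = {}
    dirs: dict[str, list[int]] = {}
    pid = 0
    for species, lam in sorted(rates_per_us.items()):
        n_events = rng.poisson(lam * duration_us)
        counts[species] = int(n_events)
        dirs[species] = [0, 0]
        for _ in range(n_events):
            direction = 1 if rng.random() < 0.5 else -1
            dirs[species][0 if direction > 0 else 1] += 1
            t0 = rng.uniform(0, max(duration_ps - transit, 1.0))
            times = np.arange(t0 - 2000.0, t0 + transit + 2000.0, dt_ps)
            z_start = (z_lo - margin) if direction > 0 else (z_hi + margin)
            z_end = (z_hi + margin) if direction > 0 else (z_lo - margin)
            z = np.interp(times, [t0, t0 + transit], [z_start, z_end])
            z += rng.normal(0, 0.4, size=z.shape)
            # clamp the committed ends so noise cannot fake a recrossing
            z[times <= t0] = z_start
            z[times >= t0 + transit] = z_end
            lateral = rng.normal(0.0, 2.0, size=(len(times), 2))
            tracks.append(Track(pid, species, times, z, lateral))
            pid += 1
        for _ in range(n_distractors):
            t0 = rng.uniform(0, duration_ps * 0.9)
            side = 1 if rng.random() < 0.5 else -1
            times = np.arange(t0, t0 + 6000.0, dt_ps)
            start = (z_hi + margin) if side > 0 else (z_lo - margin)
            # excursion to mid-slab and back to the same side
            half = len(times) // 2
            depth = rng.uniform(0.2, 0.8) * (z_hi - z_lo)
            turn = start - side * depth
            z = np.concatenate(
                [
                    np.linspace(start, turn, half),
                    np.linspace(turn, start, len(times) - half),
                ]
            )
            lateral = rng.normal(0.0, 10.0, size=(len(times), 2))
            tracks.append(Track(pid, species, times, z, lateral))
            pid += 1
    truth = IonTrackTruth(
        counts=counts,
        directions={s: (d[0], d[1]) for s, d in dirs.items()},
        duration_ps=duration_ps,
    )
    return tracks, truth


def simulate_unfolding_times(
    ea: float,
    prefactor: float,
    temperatures: list[float],
    n_replicates: int = 8,
    noise_sigma: float = 0.3,
    seed: int = 0,
    max_time: float | None = None,
) -> list[LifetimeSample]:
    """Lifetime replicates tau ~ A*exp(Ea/RT)*LogNormal(0, sigma).

    ``ea`` in kcal/mol, ``prefactor`` (A) in ps; samples exceeding
    ``max_time`` are censored at that limit.
    """
    if len(temperatures) < 2:
        raise ValueError("need at least 2 temperatures")
    rng = np.random.default_rng(seed)
    out = []
    for t in temperatures:
        base = prefactor * np.exp(ea / (R_KCAL * t))
        for rep in range(n_replicates):
            tau = base * (np.exp(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 1.0)
            if max_time is not None and tau > max_time:
                out.append(LifetimeSample(t, rep, None, censored=True))
            else:
                out.append(LifetimeSample(t, rep, float(tau)))
    return out
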