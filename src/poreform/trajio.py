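"""Trajectory/topology I/O, atom-group selection and run configuration.

File reading and writing is delegated to MDAnalysis; this module converts
between MDAnalysis universes and the toolkit's :class:`~poreform.core.TrajectoryFrame`
representation and validates the homo-oligomer assumption (all peptide
chains identical in layout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .core import PeptideChain, TrajectoryFrame, axis_index

logger = logging.getLogger("poreform")

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HSD",
    "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}

DEFAULT_LIPID_RESNAMES = {"LIP", "DMPC", "DPPC", "DSPC", "POPC", "POPG"}
DEFAULT_WATER_RESNAMES = {"SOL", "TIP3", "HOH", "WAT", "W"}
DEFAULT_ION_RESNAMES = {"NA", "SOD", "K", "POT", "CL", "CLA"}

ION_CANONICAL = {"SOD": "NA", "POT": "K", "CLA": "CL"}


@dataclass
class SelectionSpec:
    """Which residues belong to which analysis group.

    Peptides are taken as all residues with standard amino-acid names; the
    remaining groups are matched by residue name.  Selections must be
    disjoint by construction (a residue name belongs to one set).
    """

    peptide_chain_ids: list[str] | None = None
    lipid_resnames: set[str] = field(default_factory=lambda: set(DEFAULT_LIPID_RESNAMES))
    water_resnames: set[str] = field(default_factory=lambda: set(DEFAULT_WATER_RESNAMES))
    ion_resnames: set[str] = field(default_factory=lambda: set(DEFAULT_ION_RESNAMES))

    def __post_init__(self) -> None:
        sets = [self.lipid_resnames, self.water_resnames, self.ion_resnames]
        names = ["lipid", "water", "ion"]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(
                        f"{names[i]} and {names[j]} selections overlap: {sorted(overlap)}"
                    )


@dataclass
class RunConfig:
    """All tunable analysis parameters, mirrored one-to-one by CLI flags.

    Defaults follow the analysis protocol: 3.5 Å heavy-atom contact cutoff,
    4 Å permutational-RMSD cluster cutoff, 10-frame density smoothing and
    10-block standard errors.
    """

    contact_cutoff: float = 3.5        # Å, heavy-atom minimum distance
    cluster_cutoff: float = 4.0        # Å, backbone min-permutation RMSD
    decomposition_cutoff: float = 3.0  # Å, re-search inside >8-mers
    density_smooth_window: int = 10    # frames
    n_blocks: int = 10                 # block averaging for s.e.m.
    tilt_tm: float = 50.0              # deg, below => TM-compatible
    tilt_s: float = 70.0               # deg, above => surface-compatible
    depth_tm: float = 8.0              # Å, |COM z| below => TM-compatible
    depth_s: float = 12.0              # Å, |COM z| above => surface-compatible
    crossing_buffer: float = 2.0       # Å, hysteresis outside the slab
    unfold_baseline: float = 3.5       # Å, equilibrated pore RMSD level
    unfold_threshold: float = 6.0      # Å, sustained RMSD marking dissolution
    persistence_window: int = 50       # frames threshold must be held
    temperature: float = 373.0         # K, for the two-state free energy
    z_bin: float = 1.0                 # Å, density histogram bin
    max_perm_order: int = 8            # largest n! enumeration allowed
    cluster_stride: int = 1            # cluster every k-th frame
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("contact_cutoff", "cluster_cutoff", "decomposition_cutoff",
                     "crossing_buffer", "z_bin", "temperature"):
            if getattr(self, name) <= 0 and name != "crossing_buffer":
                raise ValueError(f"{name} must be positive")
        if self.crossing_buffer < 0:
            raise ValueError("crossing_buffer must be non-negative")
        if self.density_smooth_window < 1 or self.persistence_window < 1:
            raise ValueError("windows must be at least one frame")
        if self.n_blocks < 2:
            raise ValueError("block averaging needs at least 2 blocks")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def log_effective(self) -> None:
        logger.info("effective configuration: %s", self.to_dict())


def _universe(topology_path, trajectory_path=None):
    import MDAnalysis as mda

    try:
        if trajectory_path is None:
            return mda.Universe(str(topology_path))
        return mda.Universe(str(topology_path), str(trajectory_path))
    except (OSError, ValueError) as exc:
        raise ValueError(
            f"failed to load system {topology_path} / {trajectory_path}: {exc}"
        ) from exc


def _split_chains(protein_atoms) -> list:
    """Group protein atoms into chains by chainID/segid, else by contiguous
    equal-length residue blocks (GRO files carry no chain identifiers)."""
    residues = protein_atoms.residues
    chain_ids = None
    for attr in ("chainIDs", "segids"):
        if hasattr(residues, attr):
            vals = [str(v).strip() for v in getattr(residues, attr)]
            if len(set(vals)) > 1 and all(vals):
                chain_ids = vals
                break
    groups: list[list] = []
    if chain_ids is not None:
        order: dict[str, list] = {}
        for res, cid in zip(residues, chain_ids):
            order.setdefault(cid, []).append(res)
        groups = list(order.values())
    else:
        # contiguous blocks: a chain restarts when resid does not increase
        current: list = []
        last_resid = None
        for res in residues:
            if last_resid is not None and res.resid <= last_resid:
                groups.append(current)
                current = []
            current.append(res)
            last_resid = res.resid
        if current:
            groups.append(current)
    counts = {len(g) for g in groups}
    if len(counts) > 1:
        raise ValueError(
            f"peptide chains have unequal residue counts {sorted(counts)}; "
            "homo-oligomer analysis requires identical peptides"
        )
    return groups


def _chain_record(chain_residues, chain_id: str) -> PeptideChain:
    n_idx, ca_idx, c_idx, heavy = [], [], [], []
    resnames, resnums = [], []
    for res in chain_residues:
        resnames.append(str(res.resname))
        resnums.append(int(res.resid))
        by_name = {}
        for atom in res.atoms:
            name = str(atom.name).strip()
            by_name.setdefault(name, atom.ix)
            if not name.startswith("H"):
                heavy.append(atom.ix)
        try:
            n_idx.append(by_name["N"])
            ca_idx.append(by_name["CA"])
            c_idx.append(by_name["C"])
        except KeyError as exc:
            raise ValueError(
                f"residue {res.resname}{res.resid} lacks backbone atom {exc}"
            ) from exc
    return PeptideChain(
        chain_id=chain_id,
        residue_names=resnames,
        residue_numbers=resnums,
        n_indices=np.array(n_idx),
        ca_indices=np.array(ca_idx),
        c_indices=np.array(c_idx),
        heavy_indices=np.array(sorted(heavy)),
    )


def _classify_atoms(u, chains, selection: SelectionSpec):
    n = len(u.atoms)
    kinds = np.full(n, "", dtype="U8")
    pep_idx = np.full(n, -1, dtype=int)
    species = np.full(n, "", dtype="U4")
    resnames = np.array([str(r).strip().upper() for r in u.atoms.resnames])
    for k, ch_res in enumerate(chains):
        for res in ch_res:
            pep_idx[res.atoms.ix] = k
            kinds[res.atoms.ix] = "peptide"
    lipid_mask = np.isin(resnames, sorted(selection.lipid_resnames)) & (kinds == "")
    water_mask = np.isin(resnames, sorted(selection.water_resnames)) & (kinds == "")
    ion_mask = np.isin(resnames, sorted(selection.ion_resnames)) & (kinds == "")
    kinds[lipid_mask] = "lipid"
    kinds[water_mask] = "water"
    kinds[ion_mask] = "ion"
    species[ion_mask] = [
        ION_CANONICAL.get(rn, rn) for rn in resnames[ion_mask]
    ]
    unknown = kinds == ""
    if unknown.any():
        bad = sorted(set(resnames[unknown]))
        raise ValueError(
            f"residue names {bad} match no selection group "
            "(peptide/lipid/water/ion); extend the SelectionSpec"
        )
    return kinds, pep_idx, species


def load_system(
    topology_path: str | Path,
    trajectory_path: str | Path | None = None,
    selection: SelectionSpec | None = None,
    normal_axis: int | str = "z",
) -> tuple[Iterator[TrajectoryFrame], list[PeptideChain]]:
    """Open a topology (+ optional trajectory) and stream frames.

    Returns a lazy frame iterator and the validated list of peptide chains.
    Frames are produced one at a time; nothing beyond the current frame is
    held in memory.
    """
    selection = selection or SelectionSpec()
    u = _universe(topology_path, trajectory_path)
    ax = axis_index(normal_axis)
    protein = u.select_atoms("protein")
    if len(protein) == 0:
        raise ValueError("no peptide atoms found in topology")
    chain_groups = _split_chains(protein)
    if selection.peptide_chain_ids is not None:
        wanted = set(selection.peptide_chain_ids)
        have = {chr(ord("A") + i) for i in range(len(chain_groups))}
        missing = wanted - have
        if missing:
            raise ValueError(f"selection names missing chains: {sorted(missing)}")
    chains = [
        _chain_record(grp, chr(ord("A") + k)) for k, grp in enumerate(chain_groups)
    ]
    kinds, pep_idx, species = _classify_atoms(u, chain_groups, selection)
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
    except Exception:
        masses = None

    def frames() -> Iterator[TrajectoryFrame]:
        for i, ts in enumerate(u.trajectory):
            if ts.dimensions is None:
                raise ValueError("trajectory has no box information")
            box = np.asarray(ts.dimensions[:3], dtype=float)
            angles = np.asarray(ts.dimensions[3:6], dtype=float)
            if not np.allclose(angles, 90.0, atol=1e-3):
                raise ValueError(
                    f"triclinic box (angles {angles}) not supported; "
                    "orthorhombic boxes only"
                )
            yield TrajectoryFrame(
                time=float(ts.time),
                box=box,
                coords=np.array(ts.positions, dtype=float),
                kinds=kinds,
                peptide_index=pep_idx,
                species=species,
                masses=masses,
                normal_axis=ax,
                frame_index=i,
            )

    logger.info(
        "loaded system: %d atoms, %d peptide chains x %d residues, %d frames",
        len(u.atoms), len(chains), chains[0].n_residues, len(u.trajectory),
    )
    return frames(), chains


def write_structure(
    coords: np.ndarray,
    path: str | Path,
    *,
    atom_names: list[str],
    resnames: list[str],
    resids: list[int],
    chain_ids: list[str],
    box: np.ndarray | None = None,
) -> None:
    """Write a coordinate subset as a PDB file (fixed-width, Å).

    All per-atom metadata lists must match the coordinate count; typical use
    is exporting a cluster-representative oligomer with one chain ID per
    peptide.
    """
    import MDAnalysis as mda

    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    if n == 0:
        raise ValueError("cannot write an empty structure")
    if not (len(atom_names) == len(resnames) == len(resids) == len(chain_ids) == n):
        raise ValueError("per-atom metadata must match coordinate count")
    # residues are contiguous (chain, resid) runs
    keys = list(zip(chain_ids, resids))
    res_keys: list[tuple[str, int]] = []
    res_index = np.empty(n, dtype=int)
    for i, key in enumerate(keys):
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        res_index[i] = len(res_keys) - 1
    res_resnames = [""] * len(res_keys)
    for i in range(n):
        res_resnames[res_index[i]] = resnames[i]
    seg_ids = sorted({c for c, _ in res_keys})
    seg_index = [seg_ids.index(c) for c, _ in res_keys]
    u = mda.Universe.empty(
        n_atoms=n,
        n_residues=len(res_keys),
        n_segments=len(seg_ids),
        atom_resindex=res_index,
        residue_segindex=seg_index,
        trajectory=True,
    )
    u.add_TopologyAttr("names", atom_names)
    u.add_TopologyAttr("resnames", res_resnames)
    u.add_TopologyAttr("resids", [r for _, r in res_keys])
    u.add_TopologyAttr("segids", seg_ids)
    u.add_TopologyAttr("chainIDs", [keys[i][0] for i in range(n)])
    u.atoms.positions = coords
    if box is not None:
        u.dimensions = [*np.asarray(box, dtype=float), 90.0, 90.0, 90.0]
    with mda.Writer(str(path), n_atoms=n) as w:
        w.write(u.atoms)


def write_observation_pdb(obs, chains, path, box=None) -> None:
    """Export one oligomer observation's backbone as a multi-chain PDB."""
    nres = chains[0].n_residues
    names, resnames, resids, cids = [], [], [], []
    for m, member in enumerate(obs.members):
        cid = chr(ord("A") + m)
        for r in range(nres):
            for name in ("N", "CA", "C"):
                names.append(name)
                resnames.append(chains[0].residue_names[r])
                resids.append(chains[0].residue_numbers[r])
                cids.append(cid)
    write_structure(
        obs.backbone.reshape(-1, 3), path,
        atom_names=names, resnames=resnames, resids=resids, chain_ids=cids,
        box=box,
    )
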