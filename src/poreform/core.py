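"""Shared domain types and periodic-geometry primitives.

Conventions used throughout the toolkit: lengths in Å, times in ps,
temperatures in K.  Boxes are orthorhombic; the membrane normal is one of
the Cartesian axes (z by default) and the bilayer midplane sits at 0 along
that axis after recentering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.987e-3

AXIS_NAMES = {"x": 0, "y": 1, "z": 2}


def axis_index(axis: int | str) -> int:
    """Normalise an axis given as 'x'/'y'/'z' or 0/1/2 to an integer index."""
    if isinstance(axis, str):
        try:
            return AXIS_NAMES[axis.lower()]
        except KeyError:
            raise ValueError(f"unknown axis {axis!r}; expected x, y or z") from None
    if axis not in (0, 1, 2):
        raise ValueError(f"axis index must be 0, 1 or 2, got {axis}")
    return int(axis)


@dataclass
class TrajectoryFrame:
    """One trajectory snapshot with group indexing.

    Attributes
    ----------
    time : float
        Frame time in ps.
    box : (3,) ndarray
        Orthorhombic box edge lengths in Å.
    coords : (n_atoms, 3) ndarray
        Cartesian coordinates in Å.
    kinds : (n_atoms,) ndarray of str
        One of ``"peptide"``, ``"lipid"``, ``"water"``, ``"ion"`` per atom.
    peptide_index : (n_atoms,) ndarray of int
        0-based peptide (chain) index for peptide atoms, -1 elsewhere.
    species : (n_atoms,) ndarray of str, optional
        Ion species name for ion atoms ("" elsewhere).
    masses : (n_atoms,) ndarray, optional
        Atomic masses in g/mol; unit masses assumed when absent.
    normal_axis : int
        Membrane-normal axis (0, 1 or 2; default z).
    """

    time: float
    box: np.ndarray
    coords: np.ndarray
    kinds: np.ndarray
    peptide_index: np.ndarray
    species: np.ndarray | None = None
    masses: np.ndarray | None = None
    normal_axis: int = 2
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.coords = np.asarray(self.coords, dtype=float)
        self.kinds = np.asarray(self.kinds)
        self.peptide_index = np.asarray(self.peptide_index, dtype=int)
        if np.any(self.box <= 0):
            raise ValueError("all box edge lengths must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        if len(self.kinds) != n or len(self.peptide_index) != n:
            raise ValueError("group arrays must match the number of atoms")
        known = {"peptide", "lipid", "water", "ion"}
        bad = set(np.unique(self.kinds)) - known
        if bad:
            raise ValueError(f"unknown atom group kinds: {sorted(bad)}")
        self.normal_axis = axis_index(self.normal_axis)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def mask(self, kind: str) -> np.ndarray:
        return self.kinds == kind

    def atom_masses(self) -> np.ndarray:
        if self.masses is None:
            return np.ones(self.n_atoms)
        return np.asarray(self.masses, dtype=float)


@dataclass
class PeptideChain:
    """Atom bookkeeping for one peptide chain.

    Backbone indices are global atom indices into the frame, one (N, CA, C)
    triple per residue.  The heavy-atom set (all non-hydrogen atoms) is a
    superset of the backbone and drives the inter-peptide contact rule.
    """

    chain_id: str
    residue_names: list[str]
    residue_numbers: list[int]
    n_indices: np.ndarray
    ca_indices: np.ndarray
    c_indices: np.ndarray
    heavy_indices: np.ndarray

    def __post_init__(self) -> None:
        nres = len(self.residue_names)
        for arr_name in ("n_indices", "ca_indices", "c_indices"):
            arr = np.asarray(getattr(self, arr_name), dtype=int)
            setattr(self, arr_name, arr)
            if len(arr) != nres:
                raise ValueError(
                    f"{arr_name}: expected one atom per residue "
                    f"({nres}), got {len(arr)}"
                )
        self.heavy_indices = np.asarray(self.heavy_indices, dtype=int)
        backbone = set(self.backbone_indices.tolist())
        if not backbone <= set(self.heavy_indices.tolist()):
            raise ValueError("heavy-atom set must contain the backbone atoms")

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def backbone_indices(self) -> np.ndarray:
        """Global indices interleaved as N, CA, C per residue."""
        return np.stack(
            [self.n_indices, self.ca_indices, self.c_indices], axis=1
        ).reshape(-1)

    def backbone_coords(self, frame: TrajectoryFrame) -> np.ndarray:
        return frame.coords[self.backbone_indices]

    def ca_coords(self, frame: TrajectoryFrame) -> np.ndarray:
        return frame.coords[self.ca_indices]

    def heavy_coords(self, frame: TrajectoryFrame) -> np.ndarray:
        return frame.coords[self.heavy_indices]


@dataclass
class MembraneFrameConvention:
    """Coordinate convention: normal axis, midplane position, half thickness."""

    normal_axis: int = 2
    midplane: float = 0.0
    half_thickness: float = 17.5

    def __post_init__(self) -> None:
        self.normal_axis = axis_index(self.normal_axis)
        if self.half_thickness <= 0:
            raise ValueError("half_thickness must be positive")


def min_image_displacement(p1: np.ndarray, p2: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement p1 - p2 in an orthorhombic box."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p1, p2, box) -> float:
    """Minimum-image Euclidean distance between two points (Å)."""
    return float(np.linalg.norm(min_image_displacement(p1, p2, box)))


def pairwise_min_image_distances(
    a: np.ndarray, b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """All minimum-image distances between two point sets, shape (len(a), len(b))."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def recenter_frame(frame: TrajectoryFrame) -> TrajectoryFrame:
    """Shift the frame so the lipid centre of mass sits at 0 on the normal axis.

    All atoms are translated identically along the normal axis only; the box
    is unchanged, so all minimum-image distances are preserved.
    """
    lipid = frame.mask("lipid")
    if not lipid.any():
        raise ValueError("frame contains no lipid atoms; membrane undefined")
    w = frame.atom_masses()[lipid]
    ax = frame.normal_axis
    com = float(np.average(frame.coords[lipid, ax], weights=w))
    coords = frame.coords.copy()
    coords[:, ax] -= com
    return replace(frame, coords=coords)
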