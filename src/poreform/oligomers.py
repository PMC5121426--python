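"""Per-frame oligomer identification from heavy-atom contacts.

Two peptides are "in contact" when the minimum over all heavy-atom pairs of
their minimum-image distances is strictly below the cutoff (3.5 Å by
default).  An oligomer of order n is a set of n peptides that is mutually
connected through such contacts, i.e. a connected component of the contact
graph — transitive contact, not a clique: ring-shaped pores have
non-adjacent members that never touch.  A clique mode is available for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import PeptideChain, TrajectoryFrame, pairwise_min_image_distances
from .memstate import block_sem, helix_axis


@dataclass
class ContactGraph:
    """Peptide-peptide contact adjacency for one frame.

    ``min_distances[i, j]`` holds the minimum heavy-atom minimum-image
    distance between peptides i and j; the graph has an edge wherever that
    value is strictly below the cutoff.
    """

    frame_index: int
    cutoff: float
    min_distances: np.ndarray
    graph: nx.Graph
    frame: TrajectoryFrame | None = None
    chains: list[PeptideChain] | None = None

    @property
    def n_peptides(self) -> int:
        return len(self.min_distances)


@dataclass
class OligomerObservation:
    """A connected set of >=2 peptides in one frame.

    ``backbone`` has shape (n, 3*n_residues, 3): N/CA/C coordinates per
    member, in member order.  ``orientation`` holds +1 where the helix axis
    (oriented N->C) points along the membrane normal and -1 against it.
    """

    frame_index: int
    time: float
    order: int
    members: tuple[int, ...]
    backbone: np.ndarray
    orientation: np.ndarray
    sub_oligomers: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.order != len(self.members) or self.order < 2:
            raise ValueError("oligomer order must equal member count and be >= 2")
        self.backbone = np.asarray(self.backbone, dtype=float)
        if self.backbone.shape[0] != self.order:
            raise ValueError("backbone array must have one block per member")


@dataclass
class FrameCensus:
    """All oligomers plus the monomer list for one frame."""

    frame_index: int
    time: float
    oligomers: list[OligomerObservation]
    monomers: tuple[int, ...]

    def membership(self) -> list[tuple[int, ...]]:
        """Partition of all peptides: oligomer member-sets then singletons."""
        parts = [o.members for o in self.oligomers]
        parts.extend((m,) for m in self.monomers)
        return sorted(parts)


def contact_graph(
    frame: TrajectoryFrame,
    chains: list[PeptideChain],
    cutoff: float = 3.5,
) -> ContactGraph:
    """Build the heavy-atom contact graph over peptides for one frame."""
    if len(chains) < 2:
        raise ValueError("contact analysis needs at least two peptides")
    coords = []
    for ch in chains:
        c = ch.heavy_coords(frame)
        if len(c) == 0:
            raise ValueError(f"chain {ch.chain_id} has no heavy atoms")
        coords.append(c)
    n = len(chains)
    dmin = np.zeros((n, n))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(pairwise_min_image_distances(coords[i], coords[j], frame.box).min())
            dmin[i, j] = dmin[j, i] = d
            if d < cutoff:
                g.add_edge(i, j, weight=d)
    return ContactGraph(
        frame_index=frame.frame_index,
        cutoff=cutoff,
        min_distances=dmin,
        graph=g,
        frame=frame,
        chains=chains,
    )


def _observation(cg: ContactGraph, members: tuple[int, ...]) -> OligomerObservation:
    frame, chains = cg.frame, cg.chains
    if frame is None or chains is None:
        # topology-only graph: membership is still meaningful, coordinates are not
        n = len(members)
        return OligomerObservation(
            frame_index=cg.frame_index, time=float(cg.frame_index), order=n,
            members=members, backbone=np.zeros((n, 1, 3)),
            orientation=np.ones(n, dtype=int),
        )
    backbone = np.stack([chains[m].backbone_coords(frame) for m in members])
    ax = frame.normal_axis
    orient = np.array(
        [
            1 if helix_axis(chains[m].ca_coords(frame))[ax] >= 0 else -1
            for m in members
        ],
        dtype=int,
    )
    return OligomerObservation(
        frame_index=cg.frame_index,
        time=frame.time,
        order=len(members),
        members=members,
        backbone=backbone,
        orientation=orient,
    )


def find_oligomers(
    cg: ContactGraph,
    mode: str = "components",
    decompose_above: int = 8,
    decomposition_cutoff: float = 3.0,
) -> list[OligomerObservation]:
    """Extract oligomers (order >= 2) from a contact graph.

    ``mode="components"`` (default) takes connected components;
    ``mode="cliques"`` takes maximal cliques instead.  Aggregates larger
    than ``decompose_above`` are reported as-is but carry a decomposition
    into tighter sub-components found at ``decomposition_cutoff``.
    """
    if mode == "components":
        groups = [tuple(sorted(c)) for c in nx.connected_components(cg.graph)]
    elif mode == "cliques":
        groups = [tuple(sorted(c)) for c in nx.find_cliques(cg.graph)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    groups = sorted(g for g in groups if len(g) >= 2)
    out = []
    for members in groups:
        obs = _observation(cg, members)
        if len(members) > decompose_above:
            sub = nx.Graph()
            sub.add_nodes_from(members)
            for i in members:
                for j in members:
                    if i < j and cg.min_distances[i, j] < decomposition_cutoff:
                        sub.add_edge(i, j)
            obs.sub_oligomers = sorted(
                tuple(sorted(c)) for c in nx.connected_components(sub) if len(c) >= 2
            )
        out.append(obs)
    return out


def frame_census(cg: ContactGraph, **kwargs) -> FrameCensus:
    oligos = find_oligomers(cg, **kwargs)
    in_oligo = {m for o in oligos for m in o.members}
    monomers = tuple(i for i in range(cg.n_peptides) if i not in in_oligo)
    time = cg.frame.time if cg.frame is not None else float(cg.frame_index)
    return FrameCensus(cg.frame_index, time, oligos, monomers)


@dataclass
class PopulationSeries:
    """Mass-weighted oligomer occupancy over time.

    ``occupancy`` is a frames x orders table of the fraction of all
    peptides residing in order-n assemblies at each frame (order 1 =
    monomers), so each row sums to 1 exactly.  ``mean`` and ``sem`` carry
    block-averaged time statistics per order.
    """

    occupancy: pd.DataFrame
    counts: pd.DataFrame
    mean: pd.Series
    sem: pd.Series
    n_peptides: int
    censuses: list[FrameCensus] = field(default_factory=list)

    def check_mass_conservation(self) -> bool:
        return bool(np.allclose(self.occupancy.sum(axis=1), 1.0))


def population_series(
    frames,
    chains: list[PeptideChain],
    cutoff: float = 3.5,
    n_blocks: int = 10,
    mode: str = "components",
    keep_censuses: bool = True,
) -> PopulationSeries:
    """Census every frame and build the mass-weighted occupancy series.

    Occupancy of order n is (number of order-n oligomers) * n / N — the
    occupation percentage of oligomer n multiplied by its number of
    peptides, i.e. the fraction of peptide mass concentrated in that
    oligomeric state.
    """
    n_pep = len(chains)
    rows, counts_rows, censuses, times = [], [], [], []
    for frame in frames:
        cg = contact_graph(frame, chains, cutoff)
        census = frame_census(cg, mode=mode)
        counts: dict[int, int] = {1: len(census.monomers)}
        for o in census.oligomers:
            counts[o.order] = counts.get(o.order, 0) + 1
        rows.append({n: n * c / n_pep for n, c in counts.items()})
        counts_rows.append(counts)
        times.append(frame.time)
        if keep_censuses:
            censuses.append(census)
    if not rows:
        raise ValueError("population series needs at least one frame")
    occ = pd.DataFrame(rows, index=times).fillna(0.0).sort_index(axis=1)
    occ.index.name = "time_ps"
    cnt = pd.DataFrame(counts_rows, index=times).fillna(0).astype(int).sort_index(axis=1)
    cnt.index.name = "time_ps"
    mean = occ.mean(axis=0)
    if len(occ) >= n_blocks:
        sem = pd.Series(
            {n: block_sem(occ[n].to_numpy(), n_blocks) for n in occ.columns}
        )
    else:
        sem = pd.Series(np.nan, index=occ.columns)
    return PopulationSeries(occ, cnt, mean, sem, n_pep, censuses)
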