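"""Permutation-invariant structural clustering of homo-oligomers.

Because any order-n oligomer can be assembled from any n of the identical
peptides — or from the same peptides in a different order — a plain
backbone RMSD between two observations depends on an arbitrary labelling.
The similarity used here is therefore the minimum, over all n! member
correspondences, of the least-squares (Kabsch) superposition RMSD; within
one correspondence the residue-to-residue mapping is fixed by sequence.
Permutations are enumerated with Heap's algorithm.  Observations are
grouped by deterministic leader clustering at a 4 Å cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .oligomers import OligomerObservation


@dataclass
class PermutationRMSD:
    """Best correspondence between two same-order oligomers."""

    rmsd: float
    permutation: tuple[int, ...]   # members of B, reordered onto A
    rotation: np.ndarray           # (3, 3) proper rotation
    translation: np.ndarray        # (3,) applied after rotation


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal least-squares rigid superposition of y onto x.

    Returns (rmsd, R, t) with the proper rotation R (reflections excluded
    via the determinant sign correction) and translation t minimising
    ||x - (y R^T + t)||.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("superposition needs at least 3 atoms")
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    if np.allclose(x0, 0) or np.allclose(y0, 0):
        raise ValueError("degenerate geometry: all atoms coincide")
    h = y0.T @ x0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    y_fit = y0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((x0 - y_fit) ** 2, axis=1))))
    t = xc - yc @ rot.T
    return rmsd, rot, t


def heap_permutations(n: int, max_order: int = 8) -> Iterator[tuple[int, ...]]:
    """All n! permutations of range(n) in Heap's-algorithm order.

    Heap's algorithm produces each successive permutation from the previous
    one by a single swap.  ``n`` is capped (default 8, i.e. 40,320
    permutations) because the enumeration cost is factorial.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if n > max_order:
        raise ValueError(
            f"order {n} exceeds the permutation limit {max_order} "
            f"({n}! comparisons are combinatorially infeasible)"
        )
    a = list(range(n))
    yield tuple(a)
    c = [0] * n
    i = 1
    while i < n:
        if c[i] < i:
            j = 0 if i % 2 == 0 else c[i]
            a[j], a[i] = a[i], a[j]
            yield tuple(a)
            c[i] += 1
            i = 1
        else:
            c[i] = 0
            i += 1


def min_perm_rmsd(
    a: OligomerObservation | np.ndarray,
    b: OligomerObservation | np.ndarray,
    max_order: int = 8,
    prefilter: bool = False,
) -> PermutationRMSD:
    """Minimum Kabsch RMSD over all member correspondences of two oligomers.

    ``prefilter=True`` enables a provable lower-bound skip: for any rigid
    transform the mean squared deviation of member centroids is at most the
    mean squared deviation of all atoms (Jensen), so a correspondence whose
    centroid-Kabsch RMSD already exceeds the current best cannot win and
    its full superposition is skipped.  Results are identical either way.
    """
    xa = a.backbone if isinstance(a, OligomerObservation) else np.asarray(a, float)
    xb = b.backbone if isinstance(b, OligomerObservation) else np.asarray(b, float)
    if xa.shape != xb.shape:
        raise ValueError(f"oligomer order/layout mismatch: {xa.shape} vs {xb.shape}")
    n = xa.shape[0]
    flat_a = xa.reshape(-1, 3)
    cent_a = xa.mean(axis=1)
    cent_b = xb.mean(axis=1)
    best: PermutationRMSD | None = None
    for perm in heap_permutations(n, max_order=max_order):
        if prefilter and best is not None and n >= 3:
            try:
                lb, _, _ = kabsch_rmsd(cent_a, cent_b[list(perm)])
            except ValueError:  # coincident centroids: no usable bound
                lb = 0.0
            if lb >= best.rmsd:
                continue
        rmsd, rot, t = kabsch_rmsd(flat_a, xb[list(perm)].reshape(-1, 3))
        if best is None or rmsd < best.rmsd:
            best = PermutationRMSD(rmsd, perm, rot, t)
    assert best is not None
    return best


@dataclass
class OligomerCluster:
    """One structural cluster of same-order observations."""

    founder: int                   # index into the observation list
    members: list[int]
    population: float = 0.0
    representative: int = -1
    scheme: str = ""
    topology_class: str = ""


@dataclass
class ClusterResult:
    """Leader clustering of all observations of one oligomer order."""

    order: int
    cutoff: float
    clusters: list[OligomerCluster]
    observations: list[OligomerObservation]

    def assignments(self) -> list[int]:
        out = [-1] * len(self.observations)
        for ci, cl in enumerate(self.clusters):
            for m in cl.members:
                out[m] = ci
        return out


def cluster_oligomers(
    observations: Sequence[OligomerObservation],
    cutoff: float = 4.0,
    max_order: int = 8,
    prefilter: bool = False,
) -> ClusterResult:
    """Deterministic leader clustering at the permutational-RMSD cutoff.

    Observations are scanned in input (chronological) order; each joins the
    first existing cluster whose *founder* lies within the cutoff,
    otherwise it founds a new cluster.  Afterwards each cluster gets a
    representative (the member with minimal mean permutational RMSD to its
    co-members) and clusters are sorted by population.
    """
    observations = list(observations)
    if not observations:
        return ClusterResult(order=0, cutoff=cutoff, clusters=[], observations=[])
    orders = {o.order for o in observations}
    if len(orders) > 1:
        raise ValueError(f"observations mix oligomer orders {sorted(orders)}")
    order = orders.pop()
    clusters: list[OligomerCluster] = []
    for i, obs in enumerate(observations):
        placed = False
        for cl in clusters:
            d = min_perm_rmsd(
                observations[cl.founder], obs, max_order=max_order, prefilter=prefilter
            )
            if d.rmsd < cutoff:
                cl.members.append(i)
                placed = True
                break
        if not placed:
            clusters.append(OligomerCluster(founder=i, members=[i]))
    total = len(observations)
    for cl in clusters:
        cl.population = len(cl.members) / total
        if len(cl.members) == 1:
            cl.representative = cl.members[0]
        else:
            mean_r = []
            for m in cl.members:
                rs = [
                    min_perm_rmsd(
                        observations[m], observations[o],
                        max_order=max_order, prefilter=prefilter,
                    ).rmsd
                    for o in cl.members if o != m
                ]
                mean_r.append(float(np.mean(rs)))
            cl.representative = cl.members[int(np.argmin(mean_r))]
        rep = observations[cl.representative]
        try:
            cl.scheme, cl.topology_class = orientation_scheme(rep)
        except ValueError:
            cl.scheme, cl.topology_class = "", "undefined"
    clusters.sort(key=lambda c: (-c.population, c.founder))
    return ClusterResult(order=order, cutoff=cutoff, clusters=clusters,
                         observations=observations)


def _ring_order(obs: OligomerObservation, normal_axis: int = 2) -> list[int]:
    """Member order around the ring: angular sort of member centroids in the
    membrane plane about their common centre."""
    cents = obs.backbone.mean(axis=1)
    plane = [i for i in range(3) if i != normal_axis]
    xy = cents[:, plane] - cents[:, plane].mean(axis=0)
    ang = np.arctan2(xy[:, 1], xy[:, 0])
    return list(np.argsort(ang))


def canonical_scheme(labels: str) -> str:
    """Canonical form of a ring orientation string under ring rotation,
    ring reflection and the global up/down flip (N <-> C)."""
    flip = labels.translate(str.maketrans("NC", "CN"))
    candidates = []
    for s in (labels, labels[::-1], flip, flip[::-1]):
        for k in range(len(s)):
            candidates.append(s[k:] + s[:k])
    return min(candidates)


def orientation_scheme(
    obs: OligomerObservation, normal_axis: int = 2
) -> tuple[str, str]:
    """Ring orientation scheme (N: N terminus up, C: C terminus up).

    Member labels follow the sign of the helix axis (oriented N->C) on the
    membrane normal: 'C' when the C terminus points up, 'N' otherwise.  The
    string is read in ring order and canonicalised; the class is
    "parallel" when all members point the same way, else "antiparallel".
    """
    if np.any(obs.orientation == 0):
        raise ValueError("member with undefined helix axis orientation")
    ring = _ring_order(obs, normal_axis)
    labels = "".join("C" if obs.orientation[i] > 0 else "N" for i in ring)
    scheme = canonical_scheme(labels)
    cls = "parallel" if len(set(labels)) == 1 else "antiparallel"
    return scheme, cls


def antiparallel_fraction(
    observations: Sequence[OligomerObservation], normal_axis: int = 2
) -> float:
    """Fraction of ring-adjacent peptide pairs with opposite orientation,
    over a set of observations."""
    opp = tot = 0
    for obs in observations:
        ring = _ring_order(obs, normal_axis)
        n = len(ring)
        pairs = [(ring[i], ring[(i + 1) % n]) for i in range(n)] if n > 2 else [(ring[0], ring[1])]
        for i, j in pairs:
            tot += 1
            if obs.orientation[i] != obs.orientation[j]:
                opp += 1
    if tot == 0:
        raise ValueError("no observations")
    return opp / tot
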