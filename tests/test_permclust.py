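"""Permutation-invariant RMSD and clustering, checked against independent
oracles: scipy's rotation alignment for the superposition and exhaustive
itertools enumeration for the permutations."""

import itertools

import numpy as np
import pytest

from poreform.oligomers import OligomerObservation
from poreform.permclust import (
    antiparallel_fraction,
    canonical_scheme,
    cluster_oligomers,
    heap_permutations,
    kabsch_rmsd,
    min_perm_rmsd,
    orientation_scheme,
)
from poreform.synthgen import make_bundle
from conftest import reference_rmsd, rigid_move


def make_obs(coords, frame_index=0, orientation=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if orientation is None:
        orientation = np.array([1 if i % 2 == 0 else -1 for i in range(n)])
    return OligomerObservation(
        frame_index=frame_index, time=float(frame_index), order=n,
        members=tuple(range(n)), backbone=coords, orientation=orientation,
    )


class TestKabsch:
    def test_rigid_motion_gives_zero(self, rng):
        x = rng.uniform(-10, 10, (30, 3))
        y = rigid_move(x, rng)
        rmsd, rot, t = kabsch_rmsd(x, y)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(y @ rot.T + t, x, atol=1e-9)

    def test_identity(self, rng):
        x = rng.uniform(-10, 10, (12, 3))
        rmsd, rot, t = kabsch_rmsd(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)

    def test_unit_square_with_lifted_corner_matches_oracle(self):
        """Four-point case against the independent alignment oracle."""
        x = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
        y = x.copy()
        y[0] = [0, 0, 1]
        rmsd, _, _ = kabsch_rmsd(x, y)
        assert rmsd == pytest.approx(reference_rmsd(x, y), abs=1e-9)
        assert rmsd > 0

    def test_random_pairs_match_oracle(self, rng):
        for _ in range(20):
            x = rng.uniform(-8, 8, (15, 3))
            y = x + rng.normal(0, 1.0, x.shape)
            rmsd, _, _ = kabsch_rmsd(x, y)
            assert rmsd == pytest.approx(reference_rmsd(x, y), abs=1e-8)

    def test_no_reflection(self, rng):
        """A mirrored structure must not superpose to zero."""
        x = rng.uniform(-5, 5, (10, 3))
        y = x * np.array([1, 1, -1])
        rmsd, rot, _ = kabsch_rmsd(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestHeapPermutations:
    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8])
    def test_complete_and_distinct(self, n):
        import math

        perms = list(heap_permutations(n))
        assert len(perms) == math.factorial(n)
        assert len(set(perms)) == len(perms)
        assert set(perms) == set(itertools.permutations(range(n)))

    def test_order_limit(self):
        with pytest.raises(ValueError, match="combinatorial"):
            list(heap_permutations(9))
        # the cap is configurable
        assert len(list(heap_permutations(9, max_order=9))) == 362880


class TestMinPermRmsd:
    def test_relabelled_rigid_copy_is_zero(self, rng):
        b = make_bundle(4, scheme="NCNC", noise_sigma=0.3, rng=rng)
        a = make_obs(b.reshape(4, -1, 3))
        shuffled = b[[2, 3, 0, 1]].reshape(4, -1, 3)
        bb = make_obs(rigid_move(shuffled, rng))
        res = min_perm_rmsd(a, bb)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        # the found correspondence undoes the cyclic relabelling
        assert tuple(res.permutation) == (2, 3, 0, 1)

    def test_symmetry(self, rng):
        a = make_obs(make_bundle(3, scheme="NCN", noise_sigma=0.5, rng=rng).reshape(3, -1, 3))
        b = make_obs(make_bundle(3, scheme="NNC", noise_sigma=0.5, rng=rng).reshape(3, -1, 3))
        assert min_perm_rmsd(a, b).rmsd == pytest.approx(min_perm_rmsd(b, a).rmsd, abs=1e-6)

    def test_at_most_identity_rmsd(self, rng):
        for _ in range(10):
            a = make_obs(make_bundle(4, noise_sigma=0.8, rng=rng).reshape(4, -1, 3))
            b = make_obs(make_bundle(4, noise_sigma=0.8, rng=rng).reshape(4, -1, 3))
            best = min_perm_rmsd(a, b).rmsd
            ident = kabsch_rmsd(a.backbone.reshape(-1, 3), b.backbone.reshape(-1, 3))[0]
            assert best <= ident + 1e-9

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_matches_exhaustive_oracle(self, n, rng):
        """Brute force over itertools permutations with the independent
        superposition oracle must agree to 1e-6 Å."""
        for _ in range(5):
            a = make_bundle(n, noise_sigma=0.6, rng=rng).reshape(n, -1, 3)
            b = make_bundle(n, noise_sigma=0.6, rng=rng).reshape(n, -1, 3)
            oracle = min(
                reference_rmsd(a.reshape(-1, 3), b[list(p)].reshape(-1, 3))
                for p in itertools.permutations(range(n))
            )
            assert min_perm_rmsd(make_obs(a), make_obs(b)).rmsd == pytest.approx(
                oracle, abs=1e-6
            )

    def test_prefilter_identical(self, rng):
        a = make_obs(make_bundle(4, noise_sigma=0.7, rng=rng).reshape(4, -1, 3))
        b = make_obs(make_bundle(4, noise_sigma=0.7, rng=rng).reshape(4, -1, 3))
        plain = min_perm_rmsd(a, b, prefilter=False)
        fast = min_perm_rmsd(a, b, prefilter=True)
        assert plain.rmsd == pytest.approx(fast.rmsd, abs=1e-12)

    def test_order_mismatch(self, rng):
        a = make_obs(make_bundle(3).reshape(3, -1, 3))
        b = make_obs(make_bundle(4).reshape(4, -1, 3))
        with pytest.raises(ValueError):
            min_perm_rmsd(a, b)

    def test_triangle_inequality_on_sampled_triples(self, rng):
        obs = [
            make_obs(make_bundle(3, noise_sigma=0.5, rng=rng).reshape(3, -1, 3))
            for _ in range(6)
        ]
        for a, b, c in itertools.combinations(obs, 3):
            ab = min_perm_rmsd(a, b).rmsd
            bc = min_perm_rmsd(b, c).rmsd
            ac = min_perm_rmsd(a, c).rmsd
            assert ac <= ab + bc + 1e-6


class TestClustering:
    def _family(self, rng, n_obs, seed_structure, sigma=0.3):
        out = []
        for i in range(n_obs):
            pert = seed_structure + rng.normal(0, sigma, seed_structure.shape)
            order = seed_structure.shape[0]
            perm = rng.permutation(order)
            out.append(make_obs(rigid_move(pert[perm], rng), frame_index=i))
        return out

    def test_single_family_single_cluster(self, rng):
        base = make_bundle(4, scheme="NCNC").reshape(4, -1, 3)
        obs = self._family(rng, 8, base)
        res = cluster_oligomers(obs, cutoff=4.0)
        assert len(res.clusters) == 1
        assert res.clusters[0].population == pytest.approx(1.0)

    def test_two_families_recovered_with_fractions(self, rng):
        compact = make_bundle(4, ring_radius=4.4, scheme="NCNC").reshape(4, -1, 3)
        wide = make_bundle(4, ring_radius=11.0, scheme="NNNN").reshape(4, -1, 3)
        obs = self._family(rng, 6, compact) + self._family(rng, 2, wide)
        # interleave chronologically
        obs.sort(key=lambda o: o.frame_index)
        res = cluster_oligomers(obs, cutoff=4.0)
        assert len(res.clusters) == 2
        assert sorted(c.population for c in res.clusters) == pytest.approx([0.25, 0.75])

    def test_singleton(self, rng):
        obs = [make_obs(make_bundle(3).reshape(3, -1, 3))]
        res = cluster_oligomers(obs)
        assert len(res.clusters) == 1
        assert res.clusters[0].representative == 0

    def test_empty(self):
        assert cluster_oligomers([]).clusters == []

    def test_populations_sum_to_one(self, rng):
        base = make_bundle(3).reshape(3, -1, 3)
        obs = self._family(rng, 5, base, sigma=2.0)
        res = cluster_oligomers(obs, cutoff=3.0)
        assert sum(c.population for c in res.clusters) == pytest.approx(1.0)

    def test_invariant_to_relabelling_and_rigid_motion(self, rng):
        """Cluster assignments must not change when any observation's
        peptides are relabelled and the whole oligomer rigidly moved."""
        base_a = make_bundle(4, ring_radius=4.4, scheme="NCNC").reshape(4, -1, 3)
        base_b = make_bundle(4, ring_radius=11.0, scheme="NNNN").reshape(4, -1, 3)
        obs = self._family(rng, 5, base_a) + self._family(rng, 3, base_b)
        res1 = cluster_oligomers(obs, cutoff=4.0)
        transformed = []
        for o in obs:
            perm = rng.permutation(o.order)
            transformed.append(
                make_obs(
                    rigid_move(o.backbone[perm], rng),
                    frame_index=o.frame_index,
                    orientation=o.orientation[perm],
                )
            )
        res2 = cluster_oligomers(transformed, cutoff=4.0)
        assert res1.assignments() == res2.assignments()

    def test_deterministic_rerun(self, rng):
        base = make_bundle(3).reshape(3, -1, 3)
        obs = self._family(rng, 6, base, sigma=1.5)
        a = cluster_oligomers(obs, cutoff=3.5)
        b = cluster_oligomers(obs, cutoff=3.5)
        assert a.assignments() == b.assignments()
        assert [c.population for c in a.clusters] == [c.population for c in b.clusters]


class TestOrientationScheme:
    def test_alternating_tetramer(self):
        b = make_bundle(4, scheme="NCNC").reshape(4, -1, 3)
        obs = make_obs(b, orientation=np.array([-1, 1, -1, 1]))
        scheme, cls = orientation_scheme(obs)
        assert scheme == canonical_scheme("NCNC")
        assert cls == "antiparallel"

    def test_all_parallel(self):
        b = make_bundle(4, scheme="NNNN").reshape(4, -1, 3)
        obs = make_obs(b, orientation=np.array([-1, -1, -1, -1]))
        scheme, cls = orientation_scheme(obs)
        assert scheme == canonical_scheme("NNNN")
        assert cls == "parallel"

    def test_flip_symmetry(self):
        assert canonical_scheme("NCNC") == canonical_scheme("CNCN")
        assert canonical_scheme("NNC") == canonical_scheme("CCN")

    def test_rotation_reflection_invariance(self):
        s = "NNCNC"
        for k in range(5):
            rotated = s[k:] + s[:k]
            assert canonical_scheme(rotated) == canonical_scheme(s)
            assert canonical_scheme(rotated[::-1]) == canonical_scheme(s)

    def test_antiparallel_fraction(self):
        b = make_bundle(4, scheme="NCNC").reshape(4, -1, 3)
        alternating = make_obs(b, orientation=np.array([-1, 1, -1, 1]))
        parallel = make_obs(b, orientation=np.array([1, 1, 1, 1]))
        assert antiparallel_fraction([alternating]) == pytest.approx(1.0)
        assert antiparallel_fraction([parallel]) == pytest.approx(0.0)
        assert antiparallel_fraction([alternating, parallel]) == pytest.approx(0.5)
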