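"""Consensus energies, filtering, selection, optimization and clustering."""

import numpy as np
import pytest

from rnaforge._autograd import Tensor
from rnaforge.csor import (CsorConfig, Decoy, DecoyPool, EnergyBreakdown,
                           REFERENCE_BIN, bp_count_filter, cluster_decoys,
                           csor_pipeline, dist_energy, e2e_energy, global_energy,
                           optimize_conformation, optimization_energy,
                           select_models, _opt_objective_t, _rotations_to_quats)
from rnaforge.fold_losses import GFAPE_EPSILON
from rnaforge.geometry import (DEFAULT_TEMPLATE, FrameSet, RigidFrame,
                               atoms_from_frames, frames_from_atoms,
                               perturb_frames, random_rotation)
from rnaforge.metrics import kabsch_rmsd
from rnaforge.networks import Distogram
from rnaforge.synthdata import build_toy_structure, make_decoy_pool, sample_structure_spec


@pytest.fixture
def small_reference():
    spec = sample_structure_spec(16, 4, seed=8)
    return build_toy_structure(spec)


def pool_around(ref, n=5, scale=1.0, sharpness=0.9, seed=0):
    return make_decoy_pool(ref, n, (scale,), sharpness, seed=seed)


class TestE2eEnergy:
    def test_identity_floor_on_self_pool(self, small_reference):
        frames = frames_from_atoms(small_reference)
        pool = DecoyPool([Decoy(small_reference)])
        L = len(small_reference)
        expected = L * L * 3 * np.sqrt(GFAPE_EPSILON)  # uniform weights
        assert e2e_energy(frames, pool) == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_global_motion(self, small_reference, rng):
        pool = pool_around(small_reference, n=3)
        frames = frames_from_atoms(small_reference)
        g = RigidFrame(random_rotation(rng), rng.normal(0, 10, 3))
        assert e2e_energy(frames, pool) \
            == pytest.approx(e2e_energy(frames.transformed_by(g), pool), rel=1e-9)

    def test_pool_member_scores_below_outsider(self, small_reference):
        pool = pool_around(small_reference, n=2, scale=0.3, seed=1)
        member = pool.decoys[0].frames()
        outsider = perturb_frames(member, 0.3, 6.0, seed=99)
        assert e2e_energy(member, pool) < e2e_energy(outsider, pool)

    def test_empty_pool_rejected(self):
        with pytest.raises(Exception):
            DecoyPool([])


class TestDistEnergy:
    def test_uniform_slices_give_zero(self, small_reference):
        L = len(small_reference)
        uni = Distogram(np.full((3, L, L, 40), 1 / 40))
        pool = DecoyPool([Decoy(small_reference, uni)])
        assert dist_energy(small_reference, pool) == pytest.approx(0.0, abs=1e-9)

    def test_far_apart_with_matched_tail_bins_gives_zero(self):
        # all inter-nucleotide distances beyond 40 Å: observed bin 39; make
        # P(bin 39) equal P(bin 38) so every log-ratio vanishes
        coords = np.zeros((2, 3, 3))
        coords[0] = DEFAULT_TEMPLATE.array
        coords[1] = DEFAULT_TEMPLATE.array + [100.0, 0, 0]
        from rnaforge.geometry import CoarseStructure
        conf = CoarseStructure(coords)
        probs = np.full((3, 2, 2, 40), 0.4 / 38)
        probs[..., 38] = 0.3
        probs[..., 39] = 0.3
        pool = DecoyPool([Decoy(conf, Distogram(probs))])
        assert dist_energy(conf, pool) == pytest.approx(0.0, abs=1e-9)

    def test_single_pair_hand_value(self):
        # one off-diagonal pair, P(true bin) = 0.5, P(reference bin) = 0.001;
        # summed over 3 channels and both orderings
        coords = np.zeros((2, 3, 3))
        coords[0] = [[0, 0, 0], [0, 0, 1], [0, 1, 0.0]]
        coords[1] = [[10.0, 0, 0], [10.0, 0, 1], [10.0, 1, 0]]
        from rnaforge.geometry import CoarseStructure
        conf = CoarseStructure(coords)
        probs = np.zeros((3, 2, 2, 40))
        probs[..., 9] = 0.5       # true bin for 10 Å
        probs[..., REFERENCE_BIN] = 0.001
        rest = (1.0 - 0.501) / 38
        for b in range(40):
            if b not in (9, REFERENCE_BIN):
                probs[..., b] = rest
        # diagonal slices: observed bin 0
        pool = DecoyPool([Decoy(conf, Distogram(probs))])
        # off-diagonal (0,1) and (1,0), 3 channels each; diagonal slices are
        # excluded from the energy
        per_term = -np.log(0.501 / 0.002)
        expected = 6 * per_term
        assert dist_energy(conf, pool) == pytest.approx(expected, rel=1e-9)


class TestGlobalEnergy:
    def test_sum_identity(self, small_reference):
        pool = pool_around(small_reference, n=3)
        e = global_energy(small_reference, pool)
        assert e.total == pytest.approx(e.e2e + e.dist, abs=1e-9)
        frames = frames_from_atoms(small_reference)
        assert e.e2e == pytest.approx(e2e_energy(frames, pool), rel=1e-9)
        assert e.dist == pytest.approx(dist_energy(small_reference, pool), rel=1e-9)

    def test_breakdown_dict_roundtrip(self):
        e = EnergyBreakdown(1.5, -2.5)
        d = e.as_dict()
        assert d["total"] == pytest.approx(-1.0)


class TestBpCountFilter:
    def test_short_targets_pass_through(self, small_reference):
        pool = pool_around(small_reference, n=4, scale=3.0)
        assert bp_count_filter(pool) is pool

    def test_ninety_percent_rule_on_long_targets(self, monkeypatch):
        from rnaforge import csor as csor_mod
        pool = pool_around(build_toy_structure(sample_structure_spec(24, 8, seed=0)),
                           n=3, scale=0.0, sharpness=1.0)
        counts = iter([10, 9, 8])
        monkeypatch.setattr(csor_mod, "detect_base_pairs",
                            lambda s: frozenset((k, k + 4) for k in range(next(counts))))
        filtered = bp_count_filter(pool, min_length=20)
        assert len(filtered) == 2  # threshold 0.9 * 10 = 9 drops the count-8 decoy

    def test_equal_counts_keep_everything(self, small_reference):
        pool = pool_around(small_reference, n=3, scale=0.0, sharpness=1.0)
        assert len(bp_count_filter(pool, min_length=10)) == 3


class TestSelectModels:
    def test_single_decoy_pool(self, small_reference):
        pool = DecoyPool([Decoy(small_reference)])
        order, energies = select_models(pool, k=1)
        assert order == [0]

    def test_outlier_ranked_last(self, small_reference):
        pool = pool_around(small_reference, n=4, scale=0.3, seed=3)
        outlier = Decoy(atoms_from_frames(
            perturb_frames(frames_from_atoms(small_reference), 0.4, 12.0, seed=5),
            sequence=small_reference.sequence),
            pool.decoys[0].distogram, pool.decoys[0].error_map)
        full = DecoyPool(pool.decoys + [outlier])
        order, _ = select_models(full, k=5)
        assert order[-1] == 4
        assert order[0] != 4

    def test_deterministic(self, small_reference):
        pool = pool_around(small_reference, n=5, scale=1.0, seed=2)
        assert select_models(pool, 3) == select_models(pool, 3)

    def test_oversized_request_warns(self, small_reference):
        pool = pool_around(small_reference, n=2)
        with pytest.warns(UserWarning):
            order, _ = select_models(pool, k=5)
        assert len(order) == 2


class TestOptimizeConformation:
    def test_near_stationary_at_consensus(self, small_reference):
        pool = pool_around(small_reference, n=3, scale=0.0, sharpness=1.0)
        start = frames_from_atoms(small_reference)
        config = CsorConfig(lbfgs_maxiter=30)
        e_start = optimization_energy(start, pool, config)
        out = optimize_conformation(start, pool, config)
        e_end = optimization_energy(out, pool, config)
        assert e_end <= e_start + 1e-6

    def test_perturbed_start_moves_toward_consensus(self, small_reference):
        pool = pool_around(small_reference, n=3, scale=0.0, sharpness=1.0)
        consensus = frames_from_atoms(small_reference)
        start = perturb_frames(consensus, 0.05, 1.0, seed=13)
        out = optimize_conformation(start, pool, CsorConfig(lbfgs_maxiter=100))
        before = kabsch_rmsd(atoms_from_frames(start).p_atoms, small_reference.p_atoms)
        after = kabsch_rmsd(atoms_from_frames(out).p_atoms, small_reference.p_atoms)
        assert after < before

    def test_objective_gradient_matches_finite_differences(self, small_reference):
        pool = pool_around(small_reference, n=2, scale=0.5, seed=4)
        start = pool.decoys[0].frames()
        config = CsorConfig()
        L = len(start)
        q0 = _rotations_to_quats(start.rotations)
        t0 = start.translations.copy()
        q = Tensor(q0.copy(), requires_grad=True)
        t = Tensor(t0.copy(), requires_grad=True)
        _opt_objective_t(q, t, pool, config).backward()
        eps = 1e-6
        num = np.zeros(6)
        checks = [(0, 0), (1, 2), (2, 3)]
        for n_idx, (i, k) in enumerate(checks):
            up, dn = q0.copy(), q0.copy()
            up[i, k] += eps
            dn[i, k] -= eps
            fp = _opt_objective_t(Tensor(up), Tensor(t0), pool, config).data
            fm = _opt_objective_t(Tensor(dn), Tensor(t0), pool, config).data
            num[n_idx] = (float(fp) - float(fm)) / (2 * eps)
            rel = abs(q.grad[i, k] - num[n_idx]) / max(abs(num[n_idx]), 1.0)
            assert rel < 1e-4


class TestClusterDecoys:
    def test_identical_decoys_form_one_cluster(self, small_reference):
        pool = pool_around(small_reference, n=5, scale=0.0, sharpness=1.0)
        assert cluster_decoys(pool) == [0]

    def test_two_separated_groups(self, small_reference):
        near = pool_around(small_reference, n=3, scale=0.2, seed=1)
        shifted = small_reference.transformed_by(
            RigidFrame(np.eye(3), np.array([50.0, 0, 0])))
        # rigid shifts are removed by RMSD; bend the copy instead
        bent = atoms_from_frames(
            perturb_frames(frames_from_atoms(small_reference), 0.5, 15.0, seed=3),
            sequence=small_reference.sequence)
        far = [Decoy(bent, d.distogram, d.error_map) for d in
               make_decoy_pool(bent, 3, (0.2,), 0.9, seed=6)]
        pool = DecoyPool(near.decoys + far)
        centers = cluster_decoys(pool, CsorConfig(cluster_cutoffs=(2.0,)))
        assert len(centers) == 2
        assert {c < 3 for c in centers} == {True, False}

    def test_single_decoy(self, small_reference):
        assert cluster_decoys(DecoyPool([Decoy(small_reference)])) == [0]


class TestPipeline:
    def test_identical_decoys_reproduce_the_decoy(self, small_reference):
        pool = pool_around(small_reference, n=4, scale=0.0, sharpness=1.0)
        models = csor_pipeline(pool, CsorConfig(lbfgs_maxiter=40))
        assert len(models) == 1  # one cluster, center equals the best decoy
        # optimizer tolerance: the interpolated distance potential is minimized
        # at bin centers, so up to half a 1 Å bin of drift is expected
        assert kabsch_rmsd(models[0].structure.p_atoms,
                           small_reference.p_atoms) < 0.5

    def test_emits_at_most_five_ranked_models(self, small_reference):
        pool = pool_around(small_reference, n=10, scale=1.5, seed=21)
        models = csor_pipeline(pool, CsorConfig(lbfgs_maxiter=20))
        assert 1 <= len(models) <= 5
        totals = [m.energy.total for m in models]
        assert totals == sorted(totals)

    def test_refine_hook_applied(self, small_reference):
        calls = []

        def hook(structure):
            calls.append(len(structure))
            return structure

        pool = pool_around(small_reference, n=3, scale=0.5, seed=2)
        csor_pipeline(pool, CsorConfig(lbfgs_maxiter=10, refine_hook=hook))
        assert calls and all(c == len(small_reference) for c in calls)
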