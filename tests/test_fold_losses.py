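"""gFAPE, structure loss, distance binning, distogram cross-entropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaforge._autograd import Tensor
from rnaforge.fold_losses import (BLACKHOLE_DCUT, BLACKHOLE_WEIGHT, DEFAULT_BINNING,
                                  DistanceBinning, GfapeParams, bin_distance,
                                  bin_distances, distogram_loss, gfape,
                                  gfape_tensors, make_gfape_params, structure_loss,
                                  structure_loss_tensors, total_loss)
from rnaforge.geometry import (DEFAULT_TEMPLATE, FrameSet, RigidFrame,
                               atoms_from_frames, perturb_frames, random_rotation)
from rnaforge.networks import Distogram


EPS = 1e-3


class TestGfapeParams:
    def test_all_close_pairs_get_strong_weight(self, hairpin_structure):
        params = make_gfape_params(hairpin_structure)
        d = np.linalg.norm(hairpin_structure.c4_atoms[:, None]
                           - hairpin_structure.c4_atoms[None], axis=-1)
        assert np.all(params.lam[d < 20.0] == 3.0)
        assert np.all(np.isinf(params.dcut[d < 20.0]))

    def test_far_pairs_get_weak_weight_and_clamp(self):
        coords = np.zeros((2, 3, 3))
        coords[0] = DEFAULT_TEMPLATE.array
        coords[1] = DEFAULT_TEMPLATE.array + [50.0, 0.0, 0.0]
        from rnaforge.geometry import CoarseStructure
        params = make_gfape_params(CoarseStructure(coords))
        assert params.lam[0, 1] == 1.0
        assert params.dcut[0, 1] == 30.0

    def test_boundary_distance_twenty_takes_far_branch(self):
        from rnaforge.geometry import CoarseStructure
        coords = np.zeros((2, 3, 3))
        coords[0] = DEFAULT_TEMPLATE.array
        coords[1] = DEFAULT_TEMPLATE.array + [20.0, 0.0, 0.0]  # C4'-C4' exactly 20
        params = make_gfape_params(CoarseStructure(coords))
        assert params.lam[0, 1] == 1.0


class TestGfape:
    def test_identity_floor(self, random_frames):
        fs = random_frames(L=7)
        params = GfapeParams.uniform(7, 3.0, np.inf, EPS)
        expected = 3.0 * 3 * 49 * np.sqrt(EPS)
        assert gfape(fs, fs, params) == pytest.approx(expected, rel=1e-9)

    def test_floor_is_a_lower_bound(self, random_frames):
        fs = random_frames(L=6, seed=5)
        other = perturb_frames(fs, 0.2, 2.0, seed=9)
        params = GfapeParams.uniform(6, 3.0, np.inf, EPS)
        assert gfape(fs, other, params) >= 3.0 * 3 * 36 * np.sqrt(EPS)

    def test_invariance_to_global_rigid_motion(self, random_frames, rng):
        a = random_frames(L=6, seed=1)
        b = perturb_frames(a, 0.1, 1.0, seed=2)
        params = GfapeParams.uniform(6, 2.0, 25.0, EPS)
        g = RigidFrame(random_rotation(rng), rng.normal(0, 10, 3))
        v1 = gfape(b, a, params)
        v2 = gfape(b.transformed_by(g), a.transformed_by(g), params)
        assert v1 == pytest.approx(v2, abs=1e-6)

    def test_two_nucleotide_hand_computation(self):
        # frames: identity, and identity shifted by 1 Å in x, reference both
        # at identity positions 0 and (5, 0, 0)
        ref = FrameSet(np.stack([np.eye(3)] * 2), np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        pred = FrameSet(np.stack([np.eye(3)] * 2), np.array([[0.0, 0, 0], [6.0, 0, 0]]))
        params = GfapeParams.uniform(2, 1.0, np.inf, EPS)
        # per-term hand sum: identical local views for (i=j); cross terms see
        # a ±1 Å x-displacement on every template atom
        floor_term = np.sqrt(EPS)
        cross_term = np.sqrt(1.0 + EPS)
        expected = 2 * 3 * floor_term + 2 * 3 * cross_term
        assert gfape(pred, ref, params) == pytest.approx(expected, rel=1e-9)

    def test_gradient_matches_finite_differences(self, random_frames):
        fs = random_frames(L=4, seed=3)
        start = perturb_frames(fs, 0.05, 0.5, seed=4)
        params = make_gfape_params(atoms_from_frames(fs))
        rot = Tensor(start.rotations.copy(), requires_grad=True)
        tr = Tensor(start.translations.copy(), requires_grad=True)
        structure_loss_tensors(rot, tr, fs, params).backward()
        eps = 1e-6
        num = np.zeros_like(tr.data)
        for i in range(4):
            for k in range(3):
                up = start.translations.copy(); up[i, k] += eps
                dn = start.translations.copy(); dn[i, k] -= eps
                fp = structure_loss_tensors(Tensor(start.rotations), Tensor(up), fs, params)
                fm = structure_loss_tensors(Tensor(start.rotations), Tensor(dn), fs, params)
                num[i, k] = (float(fp.data) - float(fm.data)) / (2 * eps)
        rel = np.abs(tr.grad - num).max() / max(np.abs(num).max(), 1.0)
        assert rel < 1e-4

    def test_monotone_in_dcut(self, random_frames):
        a = random_frames(L=5, seed=6)
        b = perturb_frames(a, 0.3, 5.0, seed=7)
        values = [gfape(b, a, GfapeParams.uniform(5, 1.0, dc, EPS))
                  for dc in (0.5, 2.0, 10.0, np.inf)]
        assert all(x <= y + 1e-12 for x, y in zip(values, values[1:]))


class TestStructureLoss:
    def test_blackhole_term_is_bounded_by_clamp(self, random_frames):
        fs = random_frames(L=5, seed=8)
        params = GfapeParams.uniform(5, 1.0, np.inf, EPS)
        main = gfape(fs, fs, params)
        loss = structure_loss(fs, fs, params)
        bound = BLACKHOLE_WEIGHT * 25 * 3 * BLACKHOLE_DCUT
        assert main - loss <= bound + 1e-9

    def test_target_far_from_origin_scores_below_floor(self, random_frames):
        fs = random_frames(L=4, seed=9, spread=50.0)
        params = GfapeParams.uniform(4, 3.0, np.inf, EPS)
        floor = gfape(fs, fs, params)
        assert structure_loss(fs, fs, params) < floor


class TestBinning:
    @pytest.mark.parametrize("d,expected", [(1.5, 0), (0.0, 0), (2.0, 1), (2.5, 1),
                                            (3.0, 2), (39.5, 38), (40.0, 39), (45.0, 39)])
    def test_examples(self, d, expected):
        assert bin_distance(d) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            bin_distance(-0.1)

    def test_edges_and_widths(self):
        b = DistanceBinning()
        assert b.n_bins == 40
        assert b.edges[0] == 2.0 and b.edges[-1] == 40.0
        assert np.allclose(np.diff(b.edges), 1.0)

    @settings(max_examples=60, deadline=None)
    @given(st.floats(0.0, 60.0), st.floats(0.0, 60.0))
    def test_monotone_in_distance(self, d1, d2):
        lo, hi = sorted((d1, d2))
        assert bin_distance(lo) <= bin_distance(hi)

    def test_vectorized_matches_scalar(self, rng):
        ds = rng.uniform(0, 50, size=100)
        assert np.array_equal(bin_distances(ds), [bin_distance(d) for d in ds])


class TestDistogramLoss:
    def _one_hot_distogram(self, truth):
        from rnaforge.fold_losses import _true_bins
        bins = _true_bins(truth, DEFAULT_BINNING)
        L = len(truth)
        probs = np.zeros((3, L, L, 40))
        np.put_along_axis(probs, bins[..., None], 1.0, axis=-1)
        return Distogram(probs)

    def test_one_hot_truth_gives_zero(self, hairpin_structure):
        pred = self._one_hot_distogram(hairpin_structure)
        assert distogram_loss(pred, hairpin_structure) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_analytic_value(self, hairpin_structure):
        L = len(hairpin_structure)
        pred = Distogram(np.full((3, L, L, 40), 1 / 40))
        assert distogram_loss(pred, hairpin_structure) \
            == pytest.approx(3 * L * L * np.log(40), rel=1e-9)

    def test_two_nucleotide_hand_sum(self):
        from rnaforge.geometry import CoarseStructure
        coords = np.zeros((2, 3, 3))
        coords[1] = [[10.0, 0, 0], [10.0, 0, 1], [10.0, 1, 0]]
        coords[0] = [[0.0, 0, 0], [0.0, 0, 1], [0.0, 1, 0]]
        truth = CoarseStructure(coords)
        probs = np.full((3, 2, 2, 40), 1 / 40)
        # distances: diagonal 0 Å -> bin 0; cross terms 10 Å -> bin 9
        probs[:, 0, 1, :] = 0.0
        probs[:, 0, 1, 9] = 0.8
        probs[:, 0, 1, [0, 1]] = 0.1
        pred = Distogram(probs)
        expected = 3 * (np.log(40)          # (0,0) diagonal, uniform
                        + np.log(40)        # (1,1)
                        - np.log(0.8)       # (0,1) mass 0.8 on true bin
                        + np.log(40))       # (1,0) uniform
        assert distogram_loss(pred, truth) == pytest.approx(expected, rel=1e-9)

    def test_loss_decreases_as_mass_moves_to_true_bin(self, hairpin_structure):
        L = len(hairpin_structure)
        one_hot = self._one_hot_distogram(hairpin_structure).probs
        losses = []
        for t in np.linspace(0.0, 0.9, 7):
            probs = (1 - t) * np.full((3, L, L, 40), 1 / 40) + t * one_hot
            losses.append(distogram_loss(Distogram(probs), hairpin_structure))
        assert all(a > b for a, b in zip(losses, losses[1:]))


class TestTotalLoss:
    def test_zero(self):
        assert total_loss(0.0, 0.0) == 0.0

    def test_fixed_weight(self):
        assert total_loss(1.0, 5.0) == pytest.approx(2.0)

    def test_linearity(self, rng):
        a, b = rng.normal(size=2)
        assert total_loss(2 * a, b) - total_loss(a, b) == pytest.approx(a)
        assert total_loss(a, 2 * b) - total_loss(a, b) == pytest.approx(0.2 * b)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.inf, 0.0)
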