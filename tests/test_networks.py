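"""Neural components: embedder, transformer block, attention dropout, DRSM."""

import numpy as np
import pytest

from rnaforge import _autograd as ag
from rnaforge._autograd import Tensor
from rnaforge.geometry import FrameSet, perturb_frames
from rnaforge.networks import (DenoisingStructureModule, Distogram, Embedder,
                               NetworkConfig, PairErrorMap, PairRepresentation,
                               RCLMModel, SequenceRepresentation, TransformerBlock,
                               attention_dropout, drsm_forward, embed_sequence,
                               encode_sequence, transformer_block)


def small_cfg(**kw):
    base = dict(d_s=16, d_z=8, n_blocks=1, n_heads=4, pair_heads=2, opm_dim=4,
                ipa_iterations=2, ipa_heads=2, ipa_query_points=2)
    base.update(kw)
    return NetworkConfig(**base)


class TestEmbedder:
    def test_single_nucleotide_shapes(self, rng):
        emb = Embedder(small_cfg(), rng)
        s, z = embed_sequence(emb, "A")
        assert s.values.shape == (1, 16)
        assert z.values.shape == (1, 1, 8)

    def test_identical_symbols_share_rows_at_initialization(self, rng):
        # the absolute positional table starts at zero, so the embedding is
        # position-free before training
        emb = Embedder(small_cfg(), rng)
        s, _ = embed_sequence(emb, "ACGA")
        assert np.allclose(s.values[0], s.values[3])

    def test_pair_entries_match_direct_recomputation(self, rng):
        cfg = small_cfg()
        emb = Embedder(cfg, rng)
        seq = "GCAUGC"
        s, z = embed_sequence(emb, seq)
        with ag.no_grad():
            row = emb.row_proj(Tensor(s.values)).data
            col = emb.col_proj(Tensor(s.values)).data
        for i in range(6):
            for j in range(6):
                off = np.clip(j - i, -cfg.rel_pos_clip, cfg.rel_pos_clip) + cfg.rel_pos_clip
                expected = row[i] + col[j] + emb.rel_pos.data[off]
                assert np.allclose(z.values[i, j], expected, atol=1e-6)

    def test_empty_sequence_rejected(self, rng):
        emb = Embedder(small_cfg(), rng)
        with pytest.raises(ValueError):
            embed_sequence(emb, "")


class TestTransformerBlock:
    @pytest.mark.parametrize("L", [1, 5, 17])
    def test_shapes_preserved(self, rng, L):
        cfg = small_cfg()
        block = TransformerBlock(cfg, rng)
        s = SequenceRepresentation(rng.normal(size=(L, cfg.d_s)).astype(np.float32))
        z = PairRepresentation(rng.normal(size=(L, L, cfg.d_z)).astype(np.float32))
        so, zo = transformer_block(block, s, z)
        assert so.values.shape == s.values.shape
        assert zo.values.shape == z.values.shape

    def test_inference_deterministic(self, rng):
        cfg = small_cfg(attn_dropout=0.25)
        block = TransformerBlock(cfg, rng)
        s = SequenceRepresentation(rng.normal(size=(6, cfg.d_s)).astype(np.float32))
        z = PairRepresentation(rng.normal(size=(6, 6, cfg.d_z)).astype(np.float32))
        a = transformer_block(block, s, z)
        b = transformer_block(block, s, z)
        assert np.array_equal(a[0].values, b[0].values)
        assert np.array_equal(a[1].values, b[1].values)

    def test_zeroed_pair_bias_decouples_attention_from_z(self, rng):
        cfg = small_cfg(zero_init_residuals=False)
        block = TransformerBlock(cfg, rng)
        block.attention.pair_bias.weight.data[:] = 0.0
        s = Tensor(rng.normal(size=(1, 6, cfg.d_s)).astype(np.float32))
        z1 = Tensor(rng.normal(size=(1, 6, 6, cfg.d_z)).astype(np.float32))
        z2 = Tensor(rng.normal(size=(1, 6, 6, cfg.d_z)).astype(np.float32))
        with ag.no_grad():
            a1 = block.attention(block.norm_s_att(s), block.norm_z_att(z1))
            a2 = block.attention(block.norm_s_att(s), block.norm_z_att(z2))
        assert np.allclose(a1.data, a2.data, atol=1e-6)

    def test_full_block_reduces_to_rclm_block_with_zero_triangle_attention(self, rng):
        cfg = small_cfg(variant="full", zero_init_residuals=False)
        block = TransformerBlock(cfg, np.random.default_rng(0))
        block.tri_att_start.out.weight.data[:] = 0.0
        block.tri_att_start.out.bias.data[:] = 0.0
        block.tri_att_end.out.weight.data[:] = 0.0
        block.tri_att_end.out.bias.data[:] = 0.0
        s = Tensor(rng.normal(size=(1, 5, cfg.d_s)).astype(np.float32))
        z = Tensor(rng.normal(size=(1, 5, 5, cfg.d_z)).astype(np.float32))
        with ag.no_grad():
            s_full, z_full = block(s, z)
            # reduced composition using the same sub-modules
            s_red = s + block.attention(block.norm_s_att(s), block.norm_z_att(z))
            s_red = s_red + block.transition_s(block.norm_s_tr(s_red))
            z_red = z + block.opm(block.norm_opm(s_red))
            z_red = z_red + block.tri_mul_out(block.norm_tm_out(z_red))
            z_red = z_red + block.tri_mul_in(block.norm_tm_in(z_red))
            z_red = z_red + block.transition_z(block.norm_z_tr(z_red))
        assert np.allclose(s_full.data, s_red.data, atol=1e-6)
        assert np.allclose(z_full.data, z_red.data, atol=1e-6)


class TestAttentionDropout:
    def test_rate_zero_is_identity(self, rng):
        w = rng.dirichlet(np.ones(8), size=(4,))
        assert np.array_equal(attention_dropout(w, 0.0, training=True, seed=0), w)

    def test_inference_is_identity(self, rng):
        w = rng.dirichlet(np.ones(8), size=(4,))
        assert np.array_equal(attention_dropout(w, 0.9, training=False), w)

    def test_monte_carlo_rate_and_renormalization(self):
        rng = np.random.default_rng(0)
        w = rng.dirichlet(np.ones(10), size=(1000,))
        out = attention_dropout(w, 0.25, training=True, seed=1)
        zeroed = (out == 0.0).mean()
        se = np.sqrt(0.25 * 0.75 / w.size)
        assert abs(zeroed - 0.25) < 3 * se
        assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-6)

    def test_all_zero_rows_fall_back_to_input(self):
        w = np.array([[0.5, 0.5]])
        out = attention_dropout(w, 0.999, training=True, seed=3)
        assert np.allclose(out.sum(axis=-1), 1.0, atol=1e-9)

    def test_rate_one_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_dropout(rng.dirichlet(np.ones(4), size=(2,)), 1.0, training=True)


class TestDrsm:
    def _inputs(self, rng, cfg, L=6):
        s = rng.normal(size=(L, cfg.d_s)).astype(np.float32)
        z = rng.normal(size=(L, L, cfg.d_z)).astype(np.float32)
        return SequenceRepresentation(s), PairRepresentation(z)

    def test_output_contracts(self, rng):
        cfg = small_cfg()
        drsm = DenoisingStructureModule(cfg, rng)
        s, z = self._inputs(rng, cfg)
        frames, dist, perr = drsm_forward(drsm, s, z, FrameSet.identity(6))
        assert len(frames) == 6  # FrameSet validates rotations on construction
        assert isinstance(dist, Distogram)
        assert isinstance(perr, PairErrorMap)

    def test_blackhole_inference_deterministic(self, rng):
        cfg = small_cfg()
        drsm = DenoisingStructureModule(cfg, rng)
        s, z = self._inputs(rng, cfg)
        a = drsm_forward(drsm, s, z, FrameSet.identity(6))
        b = drsm_forward(drsm, s, z, FrameSet.identity(6))
        assert np.array_equal(a[0].translations, b[0].translations)
        assert np.array_equal(a[1].probs, b[1].probs)

    def test_training_noise_matches_perturb_frames(self, rng):
        # compositional oracle: with zero-initialized update head the frames
        # after one iteration equal the noised initialization exactly
        cfg = small_cfg(ipa_iterations=1)
        drsm = DenoisingStructureModule(cfg, rng)
        drsm.to_update.weight.data[:] = 0.0
        drsm.to_update.bias.data[:] = 0.0
        s, z = self._inputs(rng, cfg)
        init = FrameSet.identity(6)
        frames, _, _ = drsm_forward(drsm, s, z, init, training=True, seed=77)
        expected = perturb_frames(init, cfg.denoise_w, cfg.denoise_sigma, 77)
        assert np.allclose(frames.rotations, expected.rotations, atol=1e-5)
        assert np.allclose(frames.translations, expected.translations, atol=1e-5)


class TestFoldingOverfit:
    def test_single_target_structure_loss_drops_below_ten_percent(self):
        """A 2-block folding stack with the structure module overfits one
        synthetic target: the structure loss falls below 10 % of its initial
        value within 2,000 steps (it typically takes a few hundred)."""
        from rnaforge._nn import Adam
        from rnaforge.fold_losses import (DIST_LOSS_WEIGHT, distogram_loss_tensors,
                                          make_gfape_params, structure_loss_tensors)
        from rnaforge.geometry import frames_from_atoms
        from rnaforge.networks import FoldingModel
        from rnaforge.synthdata import build_toy_structure, sample_structure_spec

        spec = sample_structure_spec(12, 3, seed=1)
        target = build_toy_structure(spec, "AUGCAUGCAUGC")
        t_exp = frames_from_atoms(target)
        params = make_gfape_params(target)
        cfg = small_cfg(d_s=16, d_z=8, n_blocks=2, opm_dim=4, attn_dropout=0.25,
                        variant="full")
        rng = np.random.default_rng(0)
        model = FoldingModel(cfg, rng)
        opt = Adam(model.parameters(), lr=2e-3)
        initial = None
        for step in range(2000):
            rot, tr, dist, _ = model.forward(target.sequence, training=True,
                                             seed=step, rng=rng)
            s_loss = structure_loss_tensors(rot, tr, t_exp, params)
            loss = s_loss + DIST_LOSS_WEIGHT * distogram_loss_tensors(dist, target)
            if initial is None:
                initial = float(s_loss.data)
            if float(s_loss.data) < 0.1 * initial:
                break
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(s_loss.data) < 0.1 * initial


class TestRclmModelHeads:
    def test_distribution_heads_normalize(self, rng):
        model = RCLMModel(small_cfg(), rng)
        p1, p2 = model.predict("ACGUNACG")
        assert np.allclose(p1.sum(axis=-1), 1.0, atol=1e-6)
        assert np.allclose(p2.sum(axis=-1), 1.0, atol=1e-6)

    def test_mask_symbol_requires_five_classes(self):
        with pytest.raises(ValueError):
            encode_sequence("ACGN", n_classes=4)
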