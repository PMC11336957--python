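"""Pseudotime extraction, GMM phase calls, cycle-effect removal and joint
embeddings."""

import numpy as np
import pytest

import ccan.network as net
from ccan import (DomainDataset, PseudotimeResult, RunConfig, call_phases,
                  circular_correlation, joint_embedding, pseudotime,
                  remove_cycle_effect)
from ccan.downstream import JointProfile, TWO_PI


def _pt(values):
    return PseudotimeResult(pseudotime=np.asarray(values),
                            cell_ids=[f"c{i}" for i in range(len(values))])


class TestPseudotime:
    def test_modular_reduction(self, small_trained, small_pair):
        state, pair = small_trained
        pt = pseudotime(state, pair.source)
        assert np.all(pt.pseudotime >= 0) and np.all(pt.pseudotime < TWO_PI)

    def test_wraps_values_beyond_two_pi(self):
        assert np.isclose(np.mod(TWO_PI + 0.3, TWO_PI), 0.3)
        assert np.isclose(np.mod(-0.1, TWO_PI), TWO_PI - 0.1)

    def test_periodicity_through_private_shift(self, small_trained, small_pair):
        state, pair = small_trained
        pt1 = pseudotime(state, pair.source)
        # shifting every private code by 2π (through the last-layer bias)
        # leaves the extracted pseudotime unchanged
        params2 = state.params.copy()
        params2.private_encoder_source[-1][1].value += TWO_PI
        state2 = type(state)(params=params2, cfg=state.cfg)
        pt2 = pseudotime(state2, pair.source)
        np.testing.assert_allclose(pt1.pseudotime, pt2.pseudotime, atol=1e-9)

    def test_multidimensional_private_code_rejected(self, small_pair):
        pair, _ = small_pair
        cfg = RunConfig(encoder_dims=[16, 8], classifier_dims=[8],
                        latent_dim=4, private_dim=2, seed=0)
        params = net.init_params(pair.source.n_genes, ["a", "b"], cfg)
        with pytest.raises(ValueError, match="private_dim=1"):
            pseudotime(params, pair.source)


class TestCallPhases:
    def test_recovers_three_tight_clusters(self):
        rng = np.random.default_rng(0)
        centers = [0.5, 3.0, 5.5]
        vals = np.mod(np.concatenate(
            [rng.normal(c, 0.05, 50) for c in centers]), TWO_PI)
        out = call_phases(_pt(vals))
        truth = np.repeat(["G1", "S", "G2M"], 50)
        # same partition (names follow ascending mean order)
        expected = {frozenset(range(50)), frozenset(range(50, 100)),
                    frozenset(range(100, 150))}
        for phase in ("G1", "S", "G2M"):
            members = frozenset(np.flatnonzero(out.phase_call == phase))
            assert members in expected
        assert np.allclose(np.sort(out.gmm_means), centers, atol=0.05)
        assert np.isclose(out.gmm_weights.sum(), 1.0)
        del truth

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            call_phases(_pt(np.full(10, 1.0)))

    def test_partition_stable_under_seed(self):
        rng = np.random.default_rng(1)
        vals = np.mod(np.concatenate(
            [rng.normal(c, 0.1, 40) for c in (1.0, 3.0, 5.0)]), TWO_PI)
        a = call_phases(_pt(vals), seed=0)
        b = call_phases(_pt(vals), seed=7)
        # which cells co-occur in a phase never depends on component labels
        for phase in ("G1", "S", "G2M"):
            ga = frozenset(np.flatnonzero(a.phase_call == phase))
            assert any(ga == frozenset(np.flatnonzero(b.phase_call == p))
                       for p in ("G1", "S", "G2M"))

    def test_handles_wraparound_cluster(self):
        rng = np.random.default_rng(2)
        # one cluster straddles 0/2π; the circle cut must keep it together
        vals = np.mod(np.concatenate([
            rng.normal(0.0, 0.1, 50), rng.normal(2.5, 0.1, 50),
            rng.normal(4.5, 0.1, 50)]), TWO_PI)
        out = call_phases(_pt(vals))
        first = out.phase_call[:50]
        assert len(set(first)) == 1  # straddling cluster stays one phase


class TestRemoveCycleEffect:
    def test_null_circular_pathway_is_identity(self, small_trained, small_pair):
        state, pair = small_trained
        params = state.params.copy()
        params.decoder["V_circular"].value[:] = 0.0
        corrected = remove_cycle_effect(
            type(state)(params=params, cfg=state.cfg), pair.source)
        np.testing.assert_allclose(corrected.matrix, pair.source.matrix,
                                   atol=1e-12)

    def test_subtracted_component_matches_linear_path_oracle(
            self, small_trained, small_pair):
        state, pair = small_trained
        params = state.params
        ds = pair.source
        zp = net.encode_private(params, ds.matrix, "source").value
        dec = params.decoder
        # independent oracle: propagate V_circular·[sin;cos] through the
        # linear tail without biases
        h = np.concatenate([np.sin(zp), np.cos(zp)], 1) @ dec["V_circular"].value
        for W, _ in dec["linear"]:
            h = h @ W.value
        corrected = remove_cycle_effect(state, ds)
        np.testing.assert_allclose(ds.matrix - corrected.matrix, h, atol=1e-6)

    def test_shape_and_gene_order_preserved(self, small_trained, small_pair):
        state, pair = small_trained
        corrected = remove_cycle_effect(state, pair.target)
        assert corrected.matrix.shape == pair.target.matrix.shape
        assert corrected.gene_ids == pair.target.gene_ids


class TestJointEmbedding:
    def test_unpaired_shape_and_origin_tags(self, small_trained, small_pair):
        state, pair = small_trained
        jp = joint_embedding(state, pair)
        n = pair.source.n_cells + pair.target.n_cells
        assert jp.embedding.shape == (n, state.cfg.latent_dim)
        assert (jp.domain_of_origin == "source").sum() == pair.source.n_cells
        assert jp.mode == "unpaired_concat_cells"

    def test_paired_concatenates_features(self, small_trained, small_pair):
        state, pair = small_trained
        from ccan import AlignedPair
        # make an artificial paired view with equal cell counts
        n = min(pair.source.n_cells, pair.target.n_cells)
        src = DomainDataset(pair.source.matrix[:n], pair.source.cell_ids[:n],
                            pair.source.gene_ids,
                            labels=pair.source.labels[:n], role="source")
        tgt = DomainDataset(pair.target.matrix[:n], pair.source.cell_ids[:n],
                            pair.target.gene_ids, role="target")
        jp = joint_embedding(state, AlignedPair(src, tgt, paired=True))
        assert jp.embedding.shape == (n, 2 * state.cfg.latent_dim)
        assert jp.mode == "paired_concat_features"

    def test_target_row_permutation_permutes_rows_only(self, small_trained,
                                                       small_pair):
        state, pair = small_trained
        jp = joint_embedding(state, pair)
        rng = np.random.default_rng(0)
        perm = rng.permutation(pair.target.n_cells)
        from ccan import AlignedPair
        tgt2 = DomainDataset(pair.target.matrix[perm],
                             [pair.target.cell_ids[i] for i in perm],
                             pair.target.gene_ids, role="target")
        jp2 = joint_embedding(state, AlignedPair(pair.source, tgt2))
        ns = pair.source.n_cells
        np.testing.assert_array_equal(jp2.embedding[:ns], jp.embedding[:ns])
        np.testing.assert_allclose(jp2.embedding[ns:],
                                   jp.embedding[ns:][perm], atol=1e-12)

    def test_csv_roundtrip_bit_exact(self, tmp_path, small_trained, small_pair):
        state, pair = small_trained
        jp = joint_embedding(state, pair)
        path = str(tmp_path / "joint.csv")
        jp.save_csv(path)
        back = JointProfile.load_csv(path)
        np.testing.assert_array_equal(back.embedding, jp.embedding)
        assert back.cell_ids == jp.cell_ids
        assert back.mode == jp.mode


class TestCircularCorrelation:
    def test_rotation_invariance_and_reflection_sign(self):
        rng = np.random.default_rng(3)
        th = rng.uniform(0, TWO_PI, 300)
        assert circular_correlation(th, np.mod(th + 1.2, TWO_PI)) > 0.99
        assert circular_correlation(th, np.mod(-th + 0.4, TWO_PI)) < -0.99

    def test_independent_angles_near_zero(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0, TWO_PI, 2000), rng.uniform(0, TWO_PI, 2000)
        assert abs(circular_correlation(a, b)) < 0.06
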