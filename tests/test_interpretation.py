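"""Motif/variant effect scoring, negligible filter, deconvolution ranking."""

import numpy as np
import pandas as pd
import pytest

from scprofile.interpretation import (classify_negligible,
                                      differential_expression,
                                      precision_at_k, rank_by_accessibility,
                                      rank_by_expression, rank_cell_types,
                                      select_variable_eqtls,
                                      sign_concordance_by_distance,
                                      target_gene_effects, tf_motif_effect,
                                      variant_effect)
from scprofile.motifs import PWM, MutationConfig


class TestNegligibleFilter:
    def test_boundary_behaviour(self):
        mask, pct = classify_negligible(np.array([0.049, -0.05, 0.0, 0.2]))
        assert mask.tolist() == [True, False, True, False]
        assert pct == 3.5

    def test_custom_tau_percent(self):
        _, pct = classify_negligible([0.1], tau=0.1)
        assert pct == pytest.approx(round((2 ** 0.1 - 1) * 100, 1))


class TestRankings:
    def test_rank_by_absolute_magnitude(self):
        row = pd.Series({"A": 0.2, "B": -0.3, "C": 0.0})
        assert rank_cell_types(row) == ["B", "A", "C"]

    def test_lexicographic_tie_break_stable(self):
        row = pd.Series({"zeta": 0.5, "alpha": -0.5, "mid": 0.1})
        assert rank_cell_types(row) == ["alpha", "zeta", "mid"]
        assert rank_cell_types(row) == rank_cell_types(row)

    def test_expression_baseline_descending(self):
        expr = pd.Series({"T": 5.0, "B": 10.0, "NK": 1.0})
        assert rank_by_expression(expr) == ["B", "T", "NK"]

    def test_accessibility_baseline_overlap_and_nearest(self):
        peaks = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [100, 500],
            "end": [200, 600], "T": [5.0, 1.0], "B": [1.0, 9.0]})
        inside = rank_by_accessibility(peaks, {"chrom": "chr1", "pos": 150})
        assert inside == ["T", "B"]
        nearest = rank_by_accessibility(peaks, {"chrom": "chr1", "pos": 460})
        assert nearest == ["B", "T"]

    def test_accessibility_baseline_missing_chrom_warns(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                              "T": [1.0]})
        with pytest.warns(UserWarning, match="skipped"):
            assert rank_by_accessibility(peaks,
                                         {"chrom": "chrX", "pos": 5}) is None

    def test_precision_at_k_hand_count(self):
        assert precision_at_k(["B", "A", "C"], {"B"}, k=1) == 1.0
        assert precision_at_k(["A", "B", "C"], {"B"}, k=1) == 0.0
        assert precision_at_k(["A", "B", "C"], {"B", "C"}, k=2) == 0.5


class TestVariableEqtlSelection:
    def test_constant_row_excluded_by_variance(self):
        eff = pd.DataFrame({"T": [0.3, 0.3], "B": [0.3, 0.9]},
                           index=["v_const", "v_var"]).astype(float)
        kept = select_variable_eqtls(eff, variance_quantile=0.5)
        assert list(kept.index) == ["v_var"]

    def test_all_below_mean_threshold_empty(self):
        eff = pd.DataFrame(np.full((4, 3), 0.01))
        assert select_variable_eqtls(eff).empty

    def test_two_stage_filter_matches_manual(self, rng):
        eff = pd.DataFrame(rng.normal(0, 0.2, size=(20, 4)),
                           index=[f"v{i}" for i in range(20)])
        kept = select_variable_eqtls(eff, mean_threshold=0.05,
                                     variance_quantile=0.85)
        mean_ok = eff.abs().mean(axis=1) > 0.05
        sub = eff[mean_ok]
        cut = sub.var(axis=1, ddof=0).quantile(0.85)
        manual = sub[sub.var(axis=1, ddof=0) > cut]
        assert list(kept.index) == list(manual.index)


class TestSignConcordance:
    def test_all_concordant(self):
        out = sign_concordance_by_distance(
            [0.5, -0.5, 0.2], [1.0, -2.0, 0.5], [100, 5000, 40_000],
            bins=[0, 1000, 10_000, 100_000])
        assert np.allclose(out.concordance_all, 1.0)

    def test_random_signs_near_half(self, rng):
        n = 4000
        pred = rng.choice([-1.0, 1.0], size=n)
        obs = rng.choice([-1.0, 1.0], size=n)
        out = sign_concordance_by_distance(pred, obs,
                                           rng.integers(0, 1000, n),
                                           bins=[0, 1000])
        assert out.concordance_all[0] == pytest.approx(0.5, abs=0.03)

    def test_empty_bin_nan_with_zero_count(self):
        out = sign_concordance_by_distance([0.5], [1.0], [100],
                                           bins=[0, 1000, 2000])
        assert out.n_all[1] == 0 and np.isnan(out.concordance_all[1])


class TestTargetGenes:
    def test_manual_filter_of_six_genes(self):
        eff = pd.Series({"g1": 0.05, "g2": -0.2, "g3": 0.11, "g4": -0.1,
                         "g5": 0.0, "g6": -0.3})
        out = target_gene_effects(eff, threshold=0.1)
        assert set(out.index) == {"g2", "g3", "g6"}
        assert out.loc["g2", "direction"] == "repressed_by_mutation"
        assert out.loc["g3", "direction"] == "enhanced_by_mutation"


class TestDifferentialExpression:
    def test_marker_gene_detected_with_bh_correction(self, rng):
        n = 60
        labels = np.repeat(["a", "b"], n // 2)
        counts = pd.DataFrame({
            "marker": np.r_[rng.poisson(20, n // 2), rng.poisson(2, n // 2)],
            "flat": rng.poisson(5, n),
        }).astype(float)
        out = differential_expression(counts, labels)
        marker_a = out[(out.group == "a") & (out.gene == "marker")].iloc[0]
        assert marker_a.significant and marker_a.log2_fold_change > 0
        flat = out[out.gene == "flat"]
        assert (~flat.significant).all()


class TestModelBasedScores:
    """Effect scores on a small untrained model: structural guarantees."""

    @pytest.fixture
    def setup(self, tiny_dataset, small_model):
        ds = tiny_dataset
        # resize: the small model runs on 1024-bp windows; reuse contig0
        return ds, small_model

    def test_motif_ignored_by_model_scores_zero(self, tiny_dataset):
        """A decoder with zero hypernetwork output predicts identical
        profiles for any sequence, so the mutation effect is exactly 0."""
        from scprofile.backbone import ModelGeometry, make_mini_backbone
        from scprofile.decoder import ProfileModel

        ds = tiny_dataset
        geo = ModelGeometry(input_length=1024, bin_width=32, output_bins=16,
                            embedding_width=8)
        model = ProfileModel(make_mini_backbone(geo, channels=6, seed=0),
                             embedding_dim=14, hypernet_hidden=8, seed=1)
        for hn in (model.hypernet_rna, model.hypernet_atac):
            hn.fc2.weight.data[:] = 0
            hn.fc2.bias.data[:] = 0
        gid = sorted(ds.genome.genes)[0]
        pwm = ds.pwms["UBIQ"]
        scores, per_gene = tf_motif_effect(
            model, ds.genome, ds.genome.genes, [gid], pwm,
            ds.population.embeddings[:6],
            config=MutationConfig(n_replicates=2, seed=0))
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_equal_size_factors_make_normalization_noop(self):
        size = np.full(5, 3.0)
        sf = size / np.median(size)
        np.testing.assert_allclose(sf, 1.0)

    def test_variant_identity_allele_gives_zero_effect(self, tiny_dataset,
                                                       small_model):
        ds = tiny_dataset
        v = ds.variants.iloc[0].copy()
        v["alt"] = v["ref"]  # same base: alt sequence == ref sequence
        groups = {"g0": [0, 1, 2, 3], "g1": [4, 5, 6, 7]}
        eff = variant_effect(small_model, ds.genome, v, ds.genome.genes,
                             groups, ds.population.embeddings[:12])
        for key, val in eff.items():
            assert val == pytest.approx(0.0, abs=1e-12)

    def test_variant_ref_mismatch_raises(self, tiny_dataset, small_model):
        ds = tiny_dataset
        v = ds.variants.iloc[0].copy()
        wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[v["ref"]]
        v["ref"] = wrong
        with pytest.raises(ValueError, match="mismatch"):
            variant_effect(small_model, ds.genome, v, ds.genome.genes,
                           {"g": [0, 1]}, ds.population.embeddings[:2])

    def test_group_arithmetic_log2_definition(self):
        # group sums ref=1, alt=3 with pseudocount 1 -> log2(4/2) = 1
        assert np.log2((3 + 1) / (1 + 1)) == pytest.approx(1.0)


class TestGradientPWM:
    def test_zero_gradient_gives_uniform_matrix(self, tiny_dataset):
        from scprofile.backbone import ModelGeometry, make_mini_backbone
        from scprofile.decoder import ProfileModel
        from scprofile.interpretation import gradient_pwm

        geo = ModelGeometry(input_length=1024, bin_width=32, output_bins=16,
                            embedding_width=8)
        model = ProfileModel(make_mini_backbone(geo, channels=6, seed=0),
                             embedding_dim=14, hypernet_hidden=8, seed=1)
        # zero first conv: output independent of input -> zero gradient
        model.backbone.convs[0].weight.data[:] = 0
        seq = "ACGT" * 256
        pwm = gradient_pwm(model, seq, center=512,
                           cell_vectors=np.zeros((2, 14)))
        np.testing.assert_allclose(pwm.matrix, 0.25, atol=1e-12)
        assert len(pwm) == 10

    def test_exponentiation_normalization_arithmetic(self):
        grad = np.array([[1.0, 0.0, 0.0, 0.0]])
        w = 2.0 ** grad
        w = w / w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(w, [[0.4, 0.2, 0.2, 0.2]])

    def test_matches_finite_difference_within_tolerance(self, rng):
        from scprofile.backbone import ModelGeometry, make_mini_backbone, one_hot
        from scprofile.decoder import ProfileModel
        from scprofile.interpretation import gradient_pwm
        from scprofile.minigrad import Tensor, no_grad

        geo = ModelGeometry(input_length=1024, bin_width=32, output_bins=16,
                            embedding_width=8)
        model = ProfileModel(make_mini_backbone(geo, channels=6, seed=2),
                             embedding_dim=14, hypernet_hidden=8, seed=3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 1024))
        cells = rng.standard_normal((2, 14))
        pwm = gradient_pwm(model, seq, center=512, cell_vectors=cells)

        def readout(mat):
            with no_grad():
                emb = model.backbone(Tensor(mat[None])).data[0]
            from scprofile.decoder import decode
            par = model.hypernet_rna(Tensor(cells)).data[:, :, :]
            full = decode(emb, par[:, :, :, None]
                          if par.ndim == 3 else par)
            return float(full.sum())

        base = one_hot(seq).matrix
        x = Tensor(base[None], requires_grad=True)
        emb = model.backbone(x)
        par = model.hypernet_rna(Tensor(cells))
        E = geo.embedding_width
        w, b = par[:, :E, :], par[:, E:, :]
        out = (emb.reshape(1, 1, emb.shape[1], emb.shape[2]) @ w
               + b).softplus()
        out.sum().backward()
        # probe several positions; isolated kinks from the max-pool
        # downsampling can throw single finite differences off, so the
        # median agreement is the meaningful statistic
        eps = 1e-4
        errs = []
        for _ in range(10):
            nt, pos = int(rng.integers(4)), int(rng.integers(480, 544))
            up = base.copy()
            up[nt, pos] += eps
            dn = base.copy()
            dn[nt, pos] -= eps
            g = (readout(up) - readout(dn)) / (2 * eps)
            errs.append(abs(x.grad[0][nt, pos] - g) / max(abs(g), 1e-9))
        assert np.median(errs) <= 1e-3
        assert max(errs) <= 5e-2
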