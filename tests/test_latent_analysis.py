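"""dPCA marginalizations, reduced-rank fits, projections, distance metrics."""

import numpy as np
import pandas as pd
import pytest

from corticostriatal import latent_analysis as la
from corticostriatal.latent_analysis import (DPCAModel, PopulationTensor,
                                             centroid_compactness, fit_dpca,
                                             hemifield_separation_test,
                                             inter_sequence_distance,
                                             marginalize, paired_level_test,
                                             project)

SHAPE = (12, 8, 3, 20)  # units x sequences x certainty x time


def random_tensor(rng, shape=SHAPE):
    return rng.standard_normal(shape)


def as_pt(act):
    return PopulationTensor(act, sequence_ids=list(range(1, act.shape[1] + 1)),
                            levels=la.behavior_synth.CERTAINTY_LEVELS[:act.shape[2]])


class TestMarginalize:
    def test_constant_tensor_gives_all_zero_terms(self):
        out = marginalize(np.full(SHAPE, 3.5))
        for phi in la.MARGINALIZATIONS:
            assert np.allclose(out[phi], 0.0)
        assert np.allclose(out["noise"], 0.0)

    def test_pure_time_dependence(self, rng):
        t_profile = rng.standard_normal(SHAPE[-1])
        X = np.broadcast_to(t_profile, SHAPE).copy()
        out = marginalize(X)
        assert np.allclose(out["t"], X - X.mean(), atol=1e-12)
        for phi in ("s", "c", "st", "sc", "ct"):
            assert np.allclose(out[phi], 0.0, atol=1e-12)

    def test_exact_partition_of_random_tensor(self, rng):
        X = random_tensor(rng)
        out = marginalize(X)
        recon = sum(out[phi] for phi in la.MARGINALIZATIONS) + out["noise"]
        centered = X - X.mean(axis=(1, 2, 3), keepdims=True)
        assert np.abs(recon - centered).max() < 1e-10

    def test_unbalanced_tensor_rejected(self, rng):
        X = random_tensor(rng)
        X[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            marginalize(X)


class TestFitDpca:
    def test_planted_rank3_sequence_structure_recovered(self, rng):
        """>99% of sequence-marginal variance in 3 components."""
        N, S, C, T = 30, 8, 3, 25
        U = rng.standard_normal((N, 3))
        V = rng.standard_normal((3, S))
        X = np.broadcast_to((U @ V)[:, :, None, None], (N, S, C, T)).copy()
        X = X + rng.standard_normal((N, S, C, T)) * 1e-3
        model = fit_dpca(X, n_components=3, reg=0.0)
        cap = model.explained
        row = cap[(cap.marginalization == "s") & (cap.component == -1)]
        assert float(row.explained_var.iloc[0]) > 0.99

    def test_matches_least_squares_oracle_at_zero_reg(self, rng):
        """Full-rank unregularized fit equals the lstsq solution."""
        X = random_tensor(rng, (6, 4, 2, 5))
        margs = marginalize(X)
        mean = X.mean(axis=(1, 2, 3))
        Xf = (X - mean[:, None, None, None]).reshape(6, -1)
        model = fit_dpca(X, n_components=6, reg=0.0)
        for phi in ("s", "t", "sc"):
            Yf = margs[phi].reshape(6, -1)
            B_oracle = np.linalg.lstsq(Xf.T, Yf.T, rcond=None)[0].T
            B_model = model.encoders[phi] @ model.decoders[phi]
            assert np.allclose(B_model @ Xf, B_oracle @ Xf, atol=1e-8)

    def test_zero_components_allowed(self, rng):
        X = random_tensor(rng, (5, 4, 2, 6))
        model = fit_dpca(X, n_components={phi: 0 for phi in la.MARGINALIZATIONS})
        assert model.decoders["s"].shape == (0, 5)

    def test_excessive_rank_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_dpca(random_tensor(rng, (4, 3, 2, 5)), n_components=50)

    def test_shuffled_labels_capture_little_sequence_variance(self, rng):
        """Without true sequence structure the s-marginal is noise-level."""
        X = random_tensor(rng, (20, 8, 3, 15))
        out = marginalize(X)
        total = np.sum((X - X.mean(axis=(1, 2, 3), keepdims=True)) ** 2)
        frac = np.sum(out["s"] ** 2) / total
        # s has 7 dof of the 359 total cells per unit
        assert frac < 0.1


class TestProject:
    def test_zero_sigma_is_pure_linear_projection(self, rng):
        X = random_tensor(rng)
        model = fit_dpca(X, n_components=4)
        traces = rng.standard_normal((SHAPE[0], 30))
        z = project(traces, model, d=3, smoothing_sigma=0.0)
        manual = model.decoders["s"][:3] @ (traces - model.mean[:, None])
        assert np.allclose(z, manual)

    def test_constant_trace_projects_to_constant_point(self, rng):
        X = random_tensor(rng)
        model = fit_dpca(X, n_components=3)
        traces = np.tile(rng.standard_normal(SHAPE[0])[:, None], (1, 12))
        z = project(traces, model, d=2)
        assert np.allclose(z, z[:, :1])

    def test_projection_recovers_encoded_latents(self, rng):
        """D_s has orthonormal-encoder structure: D(F z) = z."""
        X = random_tensor(rng)
        model = fit_dpca(X, n_components=3)
        F, D = model.encoders["s"], model.decoders["s"]
        z = rng.standard_normal((3, 7))
        lifted = F @ z + model.mean[:, None]
        assert np.allclose(D[:3] @ (lifted - model.mean[:, None]),
                           (D @ F) @ z, atol=1e-10)
        assert np.allclose(F.T @ F, np.eye(3), atol=1e-10)

    def test_negative_sigma_rejected(self, rng):
        model = fit_dpca(random_tensor(rng), n_components=2)
        with pytest.raises(ValueError):
            project(np.zeros((SHAPE[0], 5)), model, smoothing_sigma=-1)


class TestDistances:
    def test_identical_trajectories_have_zero_distance(self):
        act = np.tile(np.random.default_rng(0).standard_normal(
            (10, 1, 2, 15)), (1, 8, 1, 1))
        df = inter_sequence_distance(as_pt(act))
        assert np.allclose(df["distance"], 0.0)

    def test_constant_offset_distance_is_exact(self, rng):
        act = np.tile(rng.standard_normal((10, 1, 1, 15)), (1, 2, 1, 1))
        v = rng.standard_normal(10)
        act[:, 1, 0, :] += v[:, None]
        pt = PopulationTensor(act, sequence_ids=[1, 2], levels=["50%"])
        df = inter_sequence_distance(pt)
        assert df["distance"].iloc[0] == pytest.approx(np.linalg.norm(v))

    def test_rotation_invariance(self, rng):
        act = random_tensor(rng)
        Q, _ = np.linalg.qr(rng.standard_normal((SHAPE[0], SHAPE[0])))
        rotated = np.einsum("mn,nsct->msct", Q, act)
        d1 = inter_sequence_distance(as_pt(act))["distance"]
        d2 = inter_sequence_distance(as_pt(rotated))["distance"]
        assert np.allclose(d1, d2, rtol=1e-9)

    def test_cluster_restriction_drops_cross_pairs(self, rng):
        pt = as_pt(random_tensor(rng))
        clusters = la.hemifield_clusters(pt)
        df = inter_sequence_distance(pt, clusters=clusters)
        # 2 clusters of 4 -> 2 * C(4,2) = 12 pairs per level
        assert (df.groupby("level").size() == 12).all()
        for _, row in df.iterrows():
            assert clusters[row.seq_a] == clusters[row.seq_b]

    def test_centroid_compactness_geometry(self):
        """Unit circle sampled uniformly: distance-to-centroid = 1."""
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        act = np.zeros((2, 1, 1, 64))
        act[0, 0, 0] = np.cos(theta)
        act[1, 0, 0] = np.sin(theta)
        pt = PopulationTensor(act, sequence_ids=[1], levels=["50%"])
        df = centroid_compactness(pt)
        assert df["compactness"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_trajectory_has_zero_compactness(self):
        act = np.tile(np.arange(5.0)[:, None, None, None], (1, 2, 1, 9))
        pt = PopulationTensor(act, sequence_ids=[1, 2], levels=["50%"])
        assert np.allclose(centroid_compactness(pt)["compactness"], 0.0)


class TestHemifieldSeparation:
    def planted(self, rng, gap):
        act = rng.standard_normal(SHAPE) * 0.1
        offset = rng.standard_normal(SHAPE[0])
        offset *= gap / np.linalg.norm(offset)
        for i, sid in enumerate(range(1, 9)):
            if sid in {1, 2, 5, 6}:
                act[:, i] += offset[:, None, None]
        return as_pt(act)

    def test_planted_clusters_detected(self, rng):
        res = hemifield_separation_test(self.planted(rng, gap=5.0))
        assert (res["p_bonferroni"] < 1e-3).all()

    def test_null_p_values_not_inflated(self, rng):
        """No planted structure: small-sample p-values stay non-tiny."""
        ps = []
        for _ in range(50):
            res = hemifield_separation_test(as_pt(random_tensor(rng)))
            ps.extend(res["p"].tolist())
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_single_hemifield_rejected(self, rng):
        act = random_tensor(rng, (6, 4, 2, 10))
        pt = PopulationTensor(act, sequence_ids=[1, 2, 5, 6],
                              levels=["50%", "76%"])
        with pytest.raises(ValueError):
            hemifield_separation_test(pt)


class TestPairedLevelTest:
    def test_detects_planted_increase(self, rng):
        rows = []
        for pair in range(10):
            rows.append(("50%", pair, 0, 1.0 + rng.normal(0, 0.05)))
            rows.append(("88-91%", pair, 0, 1.5 + rng.normal(0, 0.05)))
        df = pd.DataFrame(rows, columns=["level", "seq_a", "seq_b", "distance"])
        res = paired_level_test(df, "50%", "88-91%", "distance")
        assert res["p"] < 1e-4 and res["mean_high"] > res["mean_low"]
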