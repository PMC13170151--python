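"""CSP filters, LDA decoding, LOSOCV and evaluation metrics."""

import numpy as np
import pytest

from mseeg.decoding import (CspModel, DecodingError, csp_features,
                            csp_patterns_map, fit_csp, is_rank_deficient,
                            losocv, roc_auc, solve_csp, subject_covariances)

FS = 250.0


def random_spd(rng, d):
    A = rng.standard_normal((d, d))
    return A @ A.T + 0.1 * np.eye(d)


def whitening_oracle(sa, sb, n_filters=2):
    """Independent two-step route: whiten the composite, eigendecompose."""
    comp = sa + sb
    w, u = np.linalg.eigh(comp)
    P = u @ np.diag(w**-0.5) @ u.T  # symmetric whitener
    lam, v = np.linalg.eigh(P @ sa @ P)
    order = np.argsort(lam)[::-1]
    lam, v = lam[order], v[:, order]
    filters = P @ v
    half = n_filters // 2
    keep = list(range(half)) + list(range(len(lam) - half, len(lam)))
    return filters[:, keep], lam[keep]


def normalize_sign_scale(W):
    W = W / np.linalg.norm(W, axis=0)
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    return W * signs


class TestSubjectCovariances:
    def test_uncorrelated_unit_channels(self):
        rng = np.random.default_rng(0)
        n = int(60 * FS)
        freqs = np.fft.rfftfreq(n, 1 / FS)
        spec = np.zeros((2, len(freqs)), complex)
        mask = (freqs >= 7) & (freqs < 12)
        spec[:, mask] = rng.standard_normal((2, mask.sum())) * np.exp(
            2j * np.pi * rng.random((2, mask.sum())))
        data = np.fft.irfft(spec * n, n)
        covs = subject_covariances(data, FS)
        assert np.allclose(covs["alpha"], np.diag([0.5, 0.5]), atol=0.05)
        assert np.trace(covs["alpha"]) == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_channel_is_rank_deficient(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(20 * FS))
        covs = subject_covariances(np.vstack([x, x, rng.standard_normal(x.size)]), FS)
        assert is_rank_deficient(covs["alpha"])

    def test_scale_invariance_of_normalized_covariance(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, int(20 * FS)))
        a = subject_covariances(data, FS)
        b = subject_covariances(10.0 * data, FS)
        assert np.allclose(a["theta"], b["theta"], atol=1e-12)

    def test_short_segment_rejected(self):
        with pytest.raises(DecodingError):
            subject_covariances(np.zeros((2, 100)), FS)


class TestSolveCsp:
    def test_diagonal_toy_closed_form(self):
        model = solve_csp(np.diag([0.9, 0.1]), np.diag([0.1, 0.9]))
        assert np.allclose(sorted(model.eigenvalues), [0.1, 0.9], atol=1e-12)
        W = np.abs(normalize_sign_scale(model.filters))
        assert np.allclose(W, np.eye(2), atol=1e-10)

    def test_equal_covariances_give_half_eigenvalues(self):
        rng = np.random.default_rng(3)
        s = random_spd(rng, 5)
        model = solve_csp(s, s.copy())
        assert np.allclose(model.eigenvalues, 0.5, atol=1e-10)

    def test_matches_whitening_oracle_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            sa, sb = random_spd(rng, 10), random_spd(rng, 10)
            model = solve_csp(sa, sb)
            w_oracle, lam_oracle = whitening_oracle(sa, sb)
            assert np.allclose(model.eigenvalues, lam_oracle, atol=1e-8)
            assert np.allclose(normalize_sign_scale(model.filters),
                               normalize_sign_scale(w_oracle), atol=1e-8)

    def test_eigenvalues_in_unit_interval_and_complement_on_swap(self):
        rng = np.random.default_rng(5)
        sa, sb = random_spd(rng, 8), random_spd(rng, 8)
        m1 = solve_csp(sa, sb)
        m2 = solve_csp(sb, sa)
        assert np.all((m1.eigenvalues >= -1e-12) & (m1.eigenvalues <= 1 + 1e-12))
        assert np.allclose(sorted(m1.eigenvalues), sorted(1 - m2.eigenvalues), atol=1e-10)

    def test_generalized_eigen_equation_satisfied(self):
        rng = np.random.default_rng(6)
        sa, sb = random_spd(rng, 6), random_spd(rng, 6)
        model = solve_csp(sa, sb)
        for k in range(2):
            w = model.filters[:, k]
            lhs = sa @ w
            rhs = model.eigenvalues[k] * (sa + sb) @ w
            assert np.allclose(lhs, rhs, atol=1e-8)

    def test_odd_filter_count_rejected(self):
        with pytest.raises(DecodingError):
            solve_csp(np.eye(3), np.eye(3), n_filters=3)


class TestFeatures:
    def make_models(self, rng, d=6):
        models = {}
        for band in ("theta", "alpha", "beta1"):
            models[band] = solve_csp(random_spd(rng, d), random_spd(rng, d))
        return models

    def test_binary_feature_length_six(self):
        rng = np.random.default_rng(7)
        models = self.make_models(rng)
        covs = {b: random_spd(rng, 6) for b in models}
        assert csp_features(covs, models).shape == (6,)

    def test_identity_covariance_unit_filter_gives_zero(self):
        model = CspModel(filters=np.eye(2), patterns=np.eye(2),
                         eigenvalues=np.array([0.5, 0.5]))
        feats = csp_features({"theta": np.eye(2)}, {"theta": model})
        assert np.allclose(feats, 0.0)

    def test_pattern_map_normalized_and_localized(self, toy16_montage):
        model = solve_csp(np.diag([0.9, 0.1]), np.diag([0.1, 0.9]))
        df = csp_patterns_map({"alpha": model}, ["c1", "c2"])
        assert df.value.abs().max() == pytest.approx(1.0)
        comp0 = df[(df.component == 0)].set_index("channel").value
        assert abs(comp0["c1"]) == pytest.approx(1.0)  # largest-eigenvalue
        assert abs(comp0["c2"]) < 1e-9                 # pattern loads channel 1

    def test_filter_sign_flip_leaves_features_invariant_up_to_pairing(self):
        rng = np.random.default_rng(8)
        model = solve_csp(random_spd(rng, 4), random_spd(rng, 4))
        cov = random_spd(rng, 4)
        f1 = csp_features({"theta": cov}, {"theta": model})
        flipped = CspModel(filters=-model.filters, patterns=-model.patterns,
                           eigenvalues=model.eigenvalues)
        f2 = csp_features({"theta": cov}, {"theta": flipped})
        assert np.allclose(f1, f2)


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], positive=1)
        assert auc == 1.0

    def test_constant_scores_give_half(self):
        auc, _ = roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1], positive=1)
        assert auc == pytest.approx(0.5)

    def test_pairwise_concordance_example(self):
        """4 positive-negative pairs, 3 concordant -> AUC 0.75."""
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], positive=1)
        assert auc == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(DecodingError):
            roc_auc([0.1, 0.2], [1, 1], positive=1)


def planted_covs(rng, n_subjects, direction, d=8, strength=8.0):
    """Subject covariances with excess alpha variance along ``direction``."""
    out = []
    for _ in range(n_subjects):
        base = {b: random_spd(rng, d) * 0.05 for b in ("theta", "alpha", "beta1")}
        u = direction / np.linalg.norm(direction)
        base["alpha"] += strength * np.outer(u, u) * (1 + 0.1 * rng.standard_normal())
        out.append({b: c / np.trace(c) for b, c in base.items()})
    return out


class TestLosocv:
    def test_one_prediction_per_subject(self):
        rng = np.random.default_rng(9)
        covs = planted_covs(rng, 6, np.eye(8)[0]) + planted_covs(rng, 6, np.eye(8)[4])
        labels = ["a"] * 6 + ["b"] * 6
        res = losocv(covs, labels, task="binary")
        assert len(res.predictions) == 12
        assert len(set(res.subjects)) == 12
        assert res.confusion.to_numpy().sum() == 12

    def test_separable_classes_reach_perfect_accuracy(self):
        rng = np.random.default_rng(10)
        covs = planted_covs(rng, 10, np.eye(8)[0]) + planted_covs(rng, 10, np.eye(8)[4])
        labels = ["a"] * 10 + ["b"] * 10
        res = losocv(covs, labels, task="binary", positive="a")
        assert res.accuracy == 1.0
        assert res.auc == 1.0

    def test_three_class_concatenated_features(self):
        rng = np.random.default_rng(11)
        covs = (planted_covs(rng, 5, np.eye(9)[0], d=9)
                + planted_covs(rng, 5, np.eye(9)[4], d=9)
                + planted_covs(rng, 5, np.eye(9)[8], d=9))
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = losocv(covs, labels, task="three_class")
        assert res.accuracy == 1.0
        rows = res.confusion_normalized.sum(axis=1)
        assert np.allclose(rows, 1.0, atol=1e-12)

    def test_no_leakage_audit(self):
        rng = np.random.default_rng(12)
        covs = planted_covs(rng, 4, np.eye(8)[0]) + planted_covs(rng, 4, np.eye(8)[4])
        res = losocv(covs, ["a"] * 4 + ["b"] * 4, task="binary")
        assert res.audit_no_leakage()
        assert all(len(t) == 7 for t in res.fold_train_subjects)

    def test_training_fold_losing_class_rejected(self):
        rng = np.random.default_rng(13)
        covs = planted_covs(rng, 1, np.eye(8)[0]) + planted_covs(rng, 5, np.eye(8)[4])
        with pytest.raises(DecodingError, match="lost a class"):
            losocv(covs, ["a"] * 1 + ["b"] * 5, task="binary")

    def test_deterministic(self):
        rng = np.random.default_rng(14)
        covs = planted_covs(rng, 5, np.eye(8)[1]) + planted_covs(rng, 5, np.eye(8)[6])
        labels = ["a"] * 5 + ["b"] * 5
        r1 = losocv(covs, labels, task="binary")
        r2 = losocv(covs, labels, task="binary")
        assert np.array_equal(r1.scores, r2.scores)
        assert np.array_equal(r1.predictions, r2.predictions)
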