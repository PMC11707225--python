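"""Waveform PCA: standardization, retention, group tests, reconstruction, LOO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import balancekit as bk
from balancekit import kinem, pmpca, synthgen


def _tensor(arr, rate=100.0):
    return kinem.JointAngleTensor(np.asarray(arr, dtype=float), rate)


def _cohort_rows(rng, n_per_group, effects, rate=25.0, duration=10.0,
                 condition="moving", n_trials=3):
    """Participant-averaged waveform rows straight from the generator."""
    plat = bk.PlatformSpec(duration=duration, sample_rate=rate)
    rows, groups = [], []
    for group in ("CAI", "HC"):
        for _ in range(n_per_group):
            base = rng.normal(0, effects.between_sd_deg, (4, 3))
            trials = [bk.generate_joint_waveforms(group, condition, effects,
                                                  plat, rng, base)
                      for _ in range(n_trials)]
            rows.append(pmpca.intra_participant_average(trials))
            groups.append(group)
    return rows, np.array(groups)


def _planted_pattern_z(effects, params, n_time):
    """The planted CAI-HC contrast expressed in standardized column space."""
    pat = np.repeat(effects.angle_offsets_deg.reshape(-1), n_time)
    return (pat / np.where(params.sd > 0, params.sd, 1.0))[params.kept]


class TestAveraging:
    def test_identical_trials_average_to_themselves(self, rng):
        t = _tensor(rng.normal(size=(4, 3, 20)))
        avg = pmpca.intra_participant_average([t, t, t])
        np.testing.assert_allclose(avg.angles, t.angles)

    def test_constant_trials_arithmetic_mean(self):
        ts = [_tensor(np.full((4, 3, 5), v)) for v in (0.0, 3.0, 6.0)]
        avg = pmpca.intra_participant_average(ts)
        assert np.allclose(avg.angles, 3.0)

    def test_random_trials_match_direct_mean(self, rng):
        ts = [_tensor(rng.normal(size=(4, 3, 30))) for _ in range(3)]
        avg = pmpca.intra_participant_average(ts)
        ref = np.mean([t.angles for t in ts], axis=0)
        assert np.abs(avg.angles - ref).max() < 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(pmpca.AssemblyError):
            pmpca.intra_participant_average(
                [_tensor(np.zeros((4, 3, 5))), _tensor(np.zeros((4, 3, 6)))])


class TestStandardization:
    def test_column_zscore_values(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        Z, params = pmpca.assemble_and_standardize(X)
        np.testing.assert_allclose(Z[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_column_dropped_and_logged(self, caplog):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with caplog.at_level("WARNING", logger="balancekit.pmpca"):
            Z, params = pmpca.assemble_and_standardize(X)
        assert Z.shape == (3, 1)
        assert params.kept.tolist() == [True, False]
        assert "1 constant" in caplog.text

    def test_matrix_shape_participants_by_channels_times_samples(self, rng):
        rows = [_tensor(rng.normal(size=(4, 3, 50))) for _ in range(5)]
        Z, params = pmpca.assemble_and_standardize(rows)
        assert Z.shape == (5, 12 * 50)
        assert params.n_variables == 600

    def test_channel_major_column_layout(self):
        arr = np.zeros((4, 3, 4))
        arr[0, 0] = [1, 2, 3, 4]       # ankle sagittal occupies columns 0-3
        arr[3, 2] = [9, 9, 9, 9]       # torso horizontal occupies the last 4
        flat = _tensor(arr).flat()
        assert flat[:4].tolist() == [1, 2, 3, 4]
        assert flat[-4:].tolist() == [9, 9, 9, 9]


class TestFitPca:
    def test_rank_one_pattern_recovered(self, rng):
        pattern = rng.normal(size=120)
        weights = rng.normal(size=12)
        X = np.outer(weights, pattern) + rng.normal(0, 1e-4, (12, 120))
        Z, params = pmpca.assemble_and_standardize(X)
        fit = pmpca.fit_pca(Z)
        assert fit.retained_k == 1
        # column z-scoring maps the rank-1 pattern onto its sign profile
        pat_z = np.sign(pattern)[params.kept]
        r = np.corrcoef(fit.loadings[0], pat_z)[0, 1]
        assert abs(r) > 0.99

    def test_retained_cumulative_variance_brackets_threshold(self, rng):
        Z, _ = pmpca.assemble_and_standardize(rng.normal(size=(20, 100)))
        fit = pmpca.fit_pca(Z, 0.90)
        cum = np.cumsum(fit.explained_variance_ratio)
        assert cum[fit.retained_k - 1] >= 0.90
        if fit.retained_k > 1:
            assert cum[fit.retained_k - 2] < 0.90

    def test_loadings_orthonormal_and_evr_sorted(self, rng):
        Z, _ = pmpca.assemble_and_standardize(rng.normal(size=(15, 80)))
        fit = pmpca.fit_pca(Z)
        G = fit.loadings @ fit.loadings.T
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-9
        assert (np.diff(fit.explained_variance_ratio) <= 1e-12).all()
        assert np.abs(fit.scores.mean(axis=0)).max() < 1e-9

    def test_full_basis_reconstruction_identity(self, rng):
        X = rng.normal(size=(10, 40))
        Z, params = pmpca.assemble_and_standardize(X)
        fit = pmpca.fit_pca(Z)
        comps = np.arange(fit.n_components)
        Zc_hat = fit.reconstruct_standardized(fit.scores, comps)
        assert np.abs(Zc_hat + Z.mean(axis=0) - Z).max() < 1e-9
        X_hat = params.inverse(Zc_hat + Z.mean(axis=0))
        assert np.abs(X_hat - X).max() < 1e-9

    def test_sign_convention_positive_group_mean(self, rng):
        Z, _ = pmpca.assemble_and_standardize(rng.normal(size=(12, 60)))
        groups = np.array(["HC"] * 6 + ["CAI"] * 6)
        fit = pmpca.fit_pca(Z, groups=groups)
        hc_means = fit.scores[groups == "HC"].mean(axis=0)
        assert (hc_means >= -1e-12).all()

    def test_participant_permutation_permutes_scores(self, rng):
        X = rng.normal(size=(14, 70))
        perm = rng.permutation(14)
        groups = np.array(["HC"] * 7 + ["CAI"] * 7)
        Z1, _ = pmpca.assemble_and_standardize(X)
        Z2, _ = pmpca.assemble_and_standardize(X[perm])
        f1 = pmpca.fit_pca(Z1, groups=groups)
        f2 = pmpca.fit_pca(Z2, groups=groups[perm])
        assert np.abs(f2.scores - f1.scores[perm]).max() < 1e-8
        t1 = pmpca.test_group_scores(f1, groups)
        t2 = pmpca.test_group_scores(f2, groups[perm])
        np.testing.assert_allclose(t1.p.to_numpy(), t2.p.to_numpy(), atol=1e-10)

    def test_too_few_participants_rejected(self):
        with pytest.raises(pmpca.InsufficientDataError):
            pmpca.fit_pca(np.zeros((2, 10)))


class TestGroupScores:
    def _result_with_scores(self, scores):
        scores = np.asarray(scores, dtype=float)
        k = scores.shape[1]
        return pmpca.PCAResult(
            loadings=np.eye(k), scores=scores,
            explained_variance_ratio=np.full(k, 1.0 / k),
            retained_k=k, variance_threshold=0.9, sign_flips=np.ones(k))

    def test_hand_calculated_cohens_d(self):
        res = self._result_with_scores(np.array([[1], [2], [3], [3], [4], [5.0]]))
        groups = np.array(["HC", "HC", "HC", "CAI", "CAI", "CAI"])
        out = pmpca.test_group_scores(res, groups)
        assert np.isclose(out.cohens_d[0], 2.0)

    def test_identical_groups_zero_statistics(self):
        res = self._result_with_scores(np.array([[1], [2], [3], [1], [2], [3.0]]))
        groups = np.array(["HC", "HC", "HC", "CAI", "CAI", "CAI"])
        out = pmpca.test_group_scores(res, groups)
        assert out.t[0] == 0.0
        assert out.cohens_d[0] == 0.0

    def test_planted_offset_cohort_flagged_significant(self, rng):
        rows, groups = _cohort_rows(rng, 23, bk.GroupEffectSpec())
        Z, params = pmpca.assemble_and_standardize(rows)
        fit = pmpca.fit_pca(Z, groups=groups)
        pat = _planted_pattern_z(bk.GroupEffectSpec(), params,
                                 rows[0].n_samples)
        idx, r, _ = pmpca.match_component(pat, fit.loadings[:fit.retained_k])
        tests = pmpca.test_group_scores(fit, groups)
        assert tests.loc[tests.component == idx + 1, "p"].iloc[0] < 0.05


class TestReconstruction:
    def test_zero_scores_give_grand_mean(self, rng):
        X = rng.normal(size=(8, 24))
        Z, params = pmpca.assemble_and_standardize(X)
        fit = pmpca.fit_pca(Z)
        out = pmpca.reconstruct_group_waveforms(
            fit, params, {"ALL": np.zeros(fit.n_components)},
            np.arange(fit.retained_k), n_channels=4)
        # centred PCA: zero scores land on the column means, i.e. mu
        assert np.abs(out["ALL"].reshape(-1) - X.mean(axis=0)).max() < 1e-9

    def test_own_scores_reproduce_participant_waveforms(self, rng):
        rows = [_tensor(rng.normal(size=(4, 3, 25))) for _ in range(7)]
        Z, params = pmpca.assemble_and_standardize(rows)
        fit = pmpca.fit_pca(Z)
        i = 3
        out = pmpca.reconstruct_group_waveforms(
            fit, params, {"P": fit.scores[i]}, np.arange(fit.n_components),
            n_channels=12)
        assert np.abs(out["P"] - rows[i].angles.reshape(12, 25)).max() < 1e-9

    def test_planted_offset_profile_recovered(self, rng):
        # a dominant offset pattern so one component carries the contrast
        eff = bk.GroupEffectSpec(
            angle_offsets_deg=synthgen.DEFAULT_CAI_OFFSETS * 4.0,
            between_sd_deg=0.75)
        rows, groups = _cohort_rows(rng, 23, eff)
        Z, params = pmpca.assemble_and_standardize(rows)
        fit = pmpca.fit_pca(Z, groups=groups)
        pat_z = _planted_pattern_z(eff, params, rows[0].n_samples)
        idx, _, _ = pmpca.match_component(pat_z, fit.loadings[:fit.retained_k])
        means = pmpca.group_mean_scores(fit, groups)
        rec = pmpca.reconstruct_group_waveforms(
            fit, params, {g: means[g] for g in ("CAI", "HC")}, [idx],
            n_channels=12)
        diff = (rec["CAI"] - rec["HC"]).mean(axis=1)  # per-channel contrast
        planted = eff.angle_offsets_deg.reshape(-1)
        cos = diff @ planted / (np.linalg.norm(diff) * np.linalg.norm(planted))
        assert cos > 0.95

    def test_unknown_component_rejected(self, rng):
        Z, params = pmpca.assemble_and_standardize(rng.normal(size=(6, 12)))
        fit = pmpca.fit_pca(Z)
        with pytest.raises(IndexError):
            fit.reconstruct_standardized(fit.scores, [99])

    def test_sign_flip_leaves_reconstruction_and_p_unchanged(self, rng):
        X = rng.normal(size=(10, 30))
        groups = np.array(["HC"] * 5 + ["CAI"] * 5)
        Z, params = pmpca.assemble_and_standardize(X)
        fit = pmpca.fit_pca(Z, groups=groups)
        flipped = pmpca.PCAResult(
            loadings=fit.loadings.copy(), scores=fit.scores.copy(),
            explained_variance_ratio=fit.explained_variance_ratio,
            retained_k=fit.retained_k, variance_threshold=0.9,
            sign_flips=fit.sign_flips.copy())
        flipped.loadings[0] *= -1
        flipped.scores[:, 0] *= -1
        r1 = fit.reconstruct_standardized(fit.scores, np.arange(fit.retained_k))
        r2 = flipped.reconstruct_standardized(flipped.scores,
                                              np.arange(fit.retained_k))
        assert np.abs(r1 - r2).max() < 1e-12
        p1 = pmpca.test_group_scores(fit, groups).p.to_numpy()
        p2 = pmpca.test_group_scores(flipped, groups).p.to_numpy()
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestSurrogates:
    def test_matcher_prefers_correlated_component(self, rng):
        L = np.vstack([np.sin(np.linspace(0, 6, 50)),
                       np.cos(np.linspace(0, 6, 50))])
        L /= np.linalg.norm(L, axis=1, keepdims=True)
        idx, r, amb = pmpca.match_component(-L[1], L)
        assert idx == 1 and r < -0.99 and not amb

    def test_matcher_flags_ambiguity(self):
        v = np.linspace(-1, 1, 20)
        L = np.vstack([v, -v])
        idx, r, amb = pmpca.match_component(v, L)
        assert amb

    def test_loo_table_shape_and_classes(self, rng):
        eff = bk.GroupEffectSpec()
        rows, groups = _cohort_rows(rng, 8, eff, rate=20.0)
        out = pmpca.loo_surrogate_validation(rows, groups, 0)
        assert len(out) == 16
        assert (out.matrix_rows == 15).all()
        assert set(out.classification) <= {"significant", "marginal", "ns"}

    def test_strong_planted_effect_stable_across_surrogates(self, rng):
        eff = bk.GroupEffectSpec()
        rows, groups = _cohort_rows(rng, 23, eff)
        Z, params = pmpca.assemble_and_standardize(rows)
        fit = pmpca.fit_pca(Z, groups=groups)
        pat = _planted_pattern_z(eff, params, rows[0].n_samples)
        idx, _, _ = pmpca.match_component(pat, fit.loadings[:fit.retained_k])
        out = pmpca.loo_surrogate_validation(rows, groups, idx)
        frac = (out.classification == "significant").mean()
        assert frac >= 0.80


class TestCorrelations:
    def test_perfect_linear_relation(self):
        s = np.arange(10.0)
        out = bk.correlate_scores_with_balance(s, 2 * s + 1)
        assert np.isclose(out.loc[out.subset == "ALL", "r"].iloc[0], 1.0)

    def test_groupwise_rows_present(self, rng):
        s = rng.normal(size=20)
        m = rng.normal(size=20)
        g = np.array(["CAI"] * 10 + ["HC"] * 10)
        out = bk.correlate_scores_with_balance(s, m, g)
        assert set(out.subset) == {"ALL", "CAI", "HC"}

    def test_null_rejection_rate_close_to_alpha(self):
        rng = np.random.default_rng(99)
        hits = 0
        reps = 500
        for _ in range(reps):
            s = rng.normal(size=46)
            m = rng.normal(size=46)
            r, p = stats.pearsonr(s, m)
            hits += p < 0.05
        assert abs(hits / reps - 0.05) < 0.03

    def test_planted_coupling_recovered_within_ci(self, rng):
        n, rho = 200, 0.6
        s = rng.normal(size=n)
        m = rho * s + np.sqrt(1 - rho**2) * rng.normal(size=n)
        out = bk.correlate_scores_with_balance(s, m)
        r = out.loc[0, "r"]
        z = np.arctanh(r)
        half = 1.96 / np.sqrt(n - 3)
        assert np.tanh(z - half) < rho < np.tanh(z + half)

    def test_zero_variance_rejected(self):
        with pytest.raises(pmpca.UndefinedCorrelationError):
            bk.correlate_scores_with_balance(np.ones(5), np.arange(5.0))
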