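"""Noise covariance, trial RDMs, condition averaging, model fits, group test."""

import itertools

import numpy as np
import pandas as pd
import pytest

import ringmem as rm
from ringmem import rsa


class TestNoiseCovariance:
    def test_full_shrinkage_is_exactly_diagonal(self, rng):
        X = rng.standard_normal((50, 8))
        S = rm.estimate_noise_covariance(X, shrinkage=1.0)
        off = S - np.diag(np.diag(S))
        assert np.allclose(off, 0.0)

    def test_white_residuals_shrink_toward_identity(self, rng):
        X = rng.standard_normal((5000, 12)) * 2.0
        S = rm.estimate_noise_covariance(X, shrinkage="auto")
        corr = S / np.sqrt(np.outer(np.diag(S), np.diag(S)))
        off = corr[~np.eye(12, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_output_positive_definite_for_random_inputs(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 30))
            v = int(rng.integers(3, 40))
            X = rng.standard_normal((max(n, 3), v))
            S = rm.estimate_noise_covariance(X, shrinkage="auto")
            w = np.linalg.eigvalsh(S)
            assert w.min() > 0

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            rm.estimate_noise_covariance(np.ones((1, 4)))

    def test_known_covariance_recovered_at_scale(self, rng):
        L = np.array([[1.0, 0.0], [0.8, 0.6]])
        X = rng.standard_normal((20000, 2)) @ L.T
        S = rm.estimate_noise_covariance(X, shrinkage="auto")
        assert np.allclose(S, L @ L.T, atol=0.05)


class TestTrialRdm:
    def test_identical_patterns_give_zero_both_kinds(self):
        B = np.tile([1.0, 2.0, 3.0], (4, 1))
        info = pd.DataFrame(
            {"stim_first": [1] * 4, "stim_second": [2] * 4,
             "context": ["memory1"] * 4, "oddball": [False] * 4}
        )
        for kind in ("mahalanobis", "whitened_correlation"):
            D = rm.trial_rdm(B + 0.0, np.eye(3), info, kind).matrix
            assert np.allclose(D, 0.0, atol=1e-10)

    def test_mahalanobis_hand_example_sqrt2(self):
        B = np.array([[1.0, 0.0], [0.0, 1.0]])
        info = pd.DataFrame(
            {"stim_first": [1, 2], "stim_second": [1, 2],
             "context": ["memory1", "memory1"], "oddball": [False, False]}
        )
        D = rm.trial_rdm(B, np.eye(2), info, "mahalanobis").matrix
        assert D[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_symmetric_zero_diagonal_nonnegative(self, rng):
        B = rng.standard_normal((10, 6))
        cov = rm.estimate_noise_covariance(rng.standard_normal((40, 6)))
        info = pd.DataFrame(
            {"stim_first": rng.integers(1, 8, 10), "stim_second": rng.integers(1, 8, 10),
             "context": ["memory1"] * 10, "oddball": [False] * 10}
        )
        for kind in ("mahalanobis", "whitened_correlation"):
            D = rm.trial_rdm(B, cov, info, kind).matrix
            assert np.allclose(D, D.T)
            assert np.allclose(np.diag(D), 0.0)
            if kind == "mahalanobis":
                assert np.all(D >= 0)

    def test_dimension_mismatch_rejected(self, rng):
        B = rng.standard_normal((4, 5))
        info = pd.DataFrame(
            {"stim_first": [1] * 4, "stim_second": [2] * 4,
             "context": ["memory1"] * 4, "oddball": [False] * 4}
        )
        with pytest.raises(ValueError):
            rm.trial_rdm(B, np.eye(3), info)


def _brute_force_condition_rdm(D, info, conds, exclude_same_pair=True):
    """Direct enumeration over trial pairs (the oracle for the vectorized path)."""
    out = np.full((len(conds), len(conds)), np.nan)
    members = []
    for s, c in conds:
        members.append(
            [
                t
                for t in range(len(info))
                if not info.oddball[t]
                and info.context[t] == c
                and s in (info.stim_first[t], info.stim_second[t])
            ]
        )
    content = [
        tuple(sorted((info.stim_first[t], info.stim_second[t])))
        for t in range(len(info))
    ]
    for i, j in itertools.product(range(len(conds)), repeat=2):
        vals = []
        for t in members[i]:
            for u in members[j]:
                if t == u:
                    continue
                if exclude_same_pair and content[t] == content[u]:
                    continue
                vals.append(D[t, u])
        out[i, j] = np.mean(vals)
    return out


class TestConditionAverage:
    @pytest.fixture
    def small_rdm(self, rng):
        stims = [1, 2, 3]
        trials = []
        for c in ("memory1", "memory2"):
            for a, b in [(1, 2), (1, 3), (2, 3), (1, 2)]:
                trials.append((a, b, c))
        info = pd.DataFrame(
            {
                "stim_first": [t[0] for t in trials],
                "stim_second": [t[1] for t in trials],
                "context": [t[2] for t in trials],
                "oddball": [False] * len(trials),
            }
        )
        B = rng.standard_normal((len(trials), 5))
        return rm.trial_rdm(B, np.eye(5), info, "whitened_correlation")

    def test_matches_brute_force_enumeration(self, small_rdm):
        cond = rm.condition_average_rdm(small_rdm)
        oracle = _brute_force_condition_rdm(
            small_rdm.matrix, small_rdm.trial_info, cond.conditions
        )
        assert np.allclose(cond.matrix, oracle)

    def test_self_pair_only_variant_matches_brute_force(self, small_rdm):
        cond = rm.condition_average_rdm(small_rdm, exclude_same_pair=False)
        oracle = _brute_force_condition_rdm(
            small_rdm.matrix, small_rdm.trial_info, cond.conditions,
            exclude_same_pair=False,
        )
        assert np.allclose(cond.matrix, oracle)

    def test_equal_patterns_give_zero_cells(self):
        info = pd.DataFrame(
            {
                "stim_first": [1, 1, 2, 2],
                "stim_second": [2, 3, 3, 1],
                "context": ["memory1"] * 2 + ["memory2"] * 2,
                "oddball": [False] * 4,
            }
        )
        B = np.tile([0.3, -1.2, 0.8], (4, 1))
        rdm = rm.trial_rdm(B, np.eye(3), info, "whitened_correlation")
        cond = rm.condition_average_rdm(rdm)
        assert np.nanmax(np.abs(cond.matrix)) < 1e-10

    def test_cross_context_block_shape(self, small_rdm):
        cond = rm.condition_average_rdm(small_rdm)
        assert cond.cross_context().shape == (3, 3)

    def test_oddball_trials_excluded_from_pooling(self, small_rdm):
        info = small_rdm.trial_info.copy()
        info.loc[0, "oddball"] = True
        rdm2 = rm.RDM(small_rdm.matrix, info, small_rdm.distance_kind)
        a = rm.condition_average_rdm(small_rdm).matrix
        b = rm.condition_average_rdm(rdm2).matrix
        assert not np.allclose(a, b)


class TestKendallTauA:
    def test_matches_pair_counting_oracle(self, rng):
        """tau-a equals explicit concordant/discordant counting with ties."""
        for _ in range(10):
            x = rng.integers(0, 4, 15).astype(float)
            y = rng.integers(0, 4, 15).astype(float)
            conc = disc = 0
            for i in range(15):
                for j in range(i + 1, 15):
                    s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
                    conc += s > 0
                    disc += s < 0
            expected = (conc - disc) / (15 * 14 / 2)
            assert rsa.kendall_tau_a(x, y) == pytest.approx(expected)

    def test_perfect_and_reversed_orderings(self):
        x = np.arange(10.0)
        assert rsa.kendall_tau_a(x, 2 * x + 1) == pytest.approx(1.0)
        assert rsa.kendall_tau_a(x, -x) == pytest.approx(-1.0)


class TestModelFits:
    def test_rdm_proportional_to_model_attains_maximal_tau(self):
        """tau-a leaves tied pairs uncounted, so a binary model's best
        achievable fit is its self-fit (< 1); proportional data attain it,
        and any monotone perturbation cannot exceed it."""
        model = rm.context_separation_model()
        cond = rsa.ConditionRDM(matrix=2.5 * model.matrix, conditions=model.conditions)
        sel = model.mask & np.triu(np.ones_like(model.mask), k=1)
        self_fit = rsa.kendall_tau_a(model.matrix[sel], model.matrix[sel])
        fit = rm.rdm_model_fit(cond, model)
        assert fit == pytest.approx(self_fit)
        assert 0 < fit < 1

    def test_negated_model_attains_negated_maximal_tau(self):
        model = rm.context_separation_model()
        cond = rsa.ConditionRDM(matrix=-model.matrix, conditions=model.conditions)
        pos = rsa.ConditionRDM(matrix=model.matrix.copy(), conditions=model.conditions)
        assert rm.rdm_model_fit(cond, model) == pytest.approx(
            -rm.rdm_model_fit(pos, model)
        )

    def test_context_model_masks_same_stimulus_cells_and_diagonal(self):
        model = rm.context_separation_model()
        n = len(model.conditions)
        for i, (si, ci) in enumerate(model.conditions):
            for j, (sj, cj) in enumerate(model.conditions):
                if i == j or (si == sj and ci != cj):
                    assert not model.mask[i, j]

    def test_exclude_stimuli_masks_their_cells(self):
        model = rm.context_separation_model(exclude_stimuli=(3, 6))
        for i, (si, _) in enumerate(model.conditions):
            if si in (3, 6):
                assert not model.mask[i].any()

    def test_relational_model_encodes_swapped_cross_cells(self):
        model = rm.relational_separation_model(swapped=(3, 6))
        sel = model.mask
        assert sel.sum() == 14  # 7 same-stimulus cross cells, both triangles
        for i, (si, ci) in enumerate(model.conditions):
            for j, (sj, cj) in enumerate(model.conditions):
                if sel[i, j]:
                    assert si == sj and ci != cj
                    assert model.matrix[i, j] == (1.0 if si in (3, 6) else 0.0)

    def test_too_few_cells_rejected(self):
        model = rm.relational_separation_model()
        model.mask[:] = False
        cond = rsa.ConditionRDM(matrix=model.matrix, conditions=model.conditions)
        with pytest.raises(ValueError):
            rm.rdm_model_fit(cond, model)

    def test_fit_invariant_under_consistent_relabeling(self, rng):
        """Permuting stimulus labels in data and model together leaves the
        model fits unchanged."""
        base = rsa.ConditionRDM(
            matrix=np.abs(rng.standard_normal((14, 14))),
            conditions=rsa.condition_labels(),
        )
        base.matrix = 0.5 * (base.matrix + base.matrix.T)
        perm = [4, 2, 7, 1, 6, 3, 5]
        sigma = dict(zip(range(1, 8), perm))
        inv = {v: k for k, v in sigma.items()}
        order = [
            rsa.condition_labels().index((sigma[s], c))
            for (s, c) in rsa.condition_labels()
        ]
        relabeled = rsa.ConditionRDM(
            matrix=base.matrix[np.ix_(order, order)],
            conditions=rsa.condition_labels(),
        )
        m1 = rm.context_separation_model()
        fit_base = rm.rdm_model_fit(base, m1)
        fit_rel = rm.rdm_model_fit(relabeled, m1)
        assert fit_base == pytest.approx(fit_rel)
        # stimulus s in the relabeled RDM is sigma[s] of the base RDM, so the
        # matching relational model marks the preimages of (3, 6)
        rel_base = rm.rdm_model_fit(base, rm.relational_separation_model(swapped=(3, 6)))
        rel_rel = rm.rdm_model_fit(
            relabeled, rm.relational_separation_model(swapped=(inv[3], inv[6]))
        )
        assert rel_base == pytest.approx(rel_rel)


class TestGroupSignrank:
    def test_six_positive_values_exact_p(self):
        z, p = rm.group_signrank([0.2, 0.5, 0.1, 0.9, 0.3, 0.7])
        assert p == pytest.approx(2 / 64)
        assert z > 0

    def test_six_equal_positive_values_exact_p_with_ties(self):
        z, p = rm.group_signrank([0.4] * 6)
        assert p == pytest.approx(2 / 64)

    def test_scipy_exact_agreement_without_ties(self):
        from scipy.stats import wilcoxon

        v = [0.2, -0.5, 0.1, 0.9, -0.3, 0.7, 0.25, -0.15, 0.6, 0.05]
        _, p = rm.group_signrank(v)
        ref = wilcoxon(v, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(ref)

    def test_symmetric_values_give_large_p(self):
        v = np.concatenate([np.arange(1, 16), -np.arange(1, 16)])
        z, p = rm.group_signrank(v)
        assert p > 0.9
        assert abs(z) < 0.2

    def test_sign_flip_flips_z_keeps_p(self, rng):
        v = rng.standard_normal(30) + 0.3
        z1, p1 = rm.group_signrank(v)
        z2, p2 = rm.group_signrank(-v)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rm.group_signrank([0.0] * 8)

    def test_fewer_than_five_rejected(self):
        with pytest.raises(ValueError):
            rm.group_signrank([1.0, 2.0])
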