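"""Synthetic patterns, BOLD, behavior, metabolites, and cohorts."""

import dataclasses
import warnings

import numpy as np
import pytest

import ringmem as rm
from ringmem.synth import (
    METABOLITES,
    n_volumes_for,
    realize_subject_truth,
    simulate_mrs,
)


class TestPatterns:
    def test_planted_correlations_recovered_at_large_voxel_count(self, tax):
        truth = rm.GroundTruth(n_voxels=40_000)
        rng = np.random.default_rng(1)
        pats = rm.simulate_patterns(truth, tax, rng)
        z = (pats.array - truth.baseline_amplitude) / truth.pattern_scale
        z = z - z.mean(axis=1, keepdims=True)
        C = np.corrcoef(z)
        idx = {c: i for i, c in enumerate(pats.conditions)}
        # within context, different stimuli
        assert C[idx[(1, "memory1")], idx[(2, "memory1")]] == pytest.approx(
            truth.rho_within, abs=0.02
        )
        # across contexts, different stimuli
        assert C[idx[(1, "memory1")], idx[(2, "memory2")]] == pytest.approx(
            truth.rho_between, abs=0.02
        )
        # same stimulus across contexts: unswapped vs swapped
        assert C[idx[(1, "memory1")], idx[(1, "memory2")]] == pytest.approx(
            truth.rho_same_cross, abs=0.02
        )
        assert C[idx[(3, "memory1")], idx[(3, "memory2")]] == pytest.approx(
            truth.rho_same_cross - truth.delta_swap, abs=0.02
        )

    def test_swapped_stimuli_more_separated_across_contexts(self, tax):
        truth = rm.GroundTruth(n_voxels=5000)
        diffs = []
        for seed in range(5):
            pats = rm.simulate_patterns(truth, tax, np.random.default_rng(seed))
            C = np.corrcoef(pats.array - pats.array.mean(axis=1, keepdims=True))
            idx = {c: i for i, c in enumerate(pats.conditions)}
            swapped = np.mean(
                [C[idx[(s, "memory1")], idx[(s, "memory2")]] for s in (3, 6)]
            )
            others = np.mean(
                [C[idx[(s, "memory1")], idx[(s, "memory2")]] for s in (1, 2, 4, 5, 7)]
            )
            diffs.append(others - swapped)
        assert all(d > 0 for d in diffs)

    def test_non_psd_structure_rejected(self, tax):
        truth = rm.GroundTruth(rho_within=-0.5)
        with pytest.raises(ValueError, match="positive semidefinite"):
            rm.simulate_patterns(truth, tax, np.random.default_rng(0))

    def test_singular_but_psd_structure_accepted(self, tax):
        # identical patterns across contexts: PSD with rank 7
        truth = rm.null_truth(n_voxels=50)
        pats = rm.simulate_patterns(truth, tax, np.random.default_rng(0))
        idx = {c: i for i, c in enumerate(pats.conditions)}
        for s in range(1, 8):
            assert np.allclose(
                pats.array[idx[(s, "memory1")]], pats.array[idx[(s, "memory2")]]
            )


class TestBold:
    def test_fixed_seed_bit_identical(self, tax, small_params):
        truth = rm.GroundTruth(n_voxels=20)
        events = rm.generate_scan_block(tax, small_params, seed=5)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(9)
            pats = rm.simulate_patterns(truth, tax, rng)
            out.append(
                rm.simulate_bold(events, pats, truth, 1, rng, "aLOC", tax=tax).data
            )
        assert np.array_equal(out[0], out[1])

    def test_volume_count_tracks_block_duration(self, tax):
        events = rm.generate_scan_block(tax, rm.DesignParams(), seed=5)
        n = n_volumes_for(events, 1.512)
        last = max(t.onset + t.duration for t in events.trials)
        assert n * 1.512 >= last + 16.0
        assert (n - 1) * 1.512 < last + 16.0 + 1.512

    def test_block2_hidden_suppression_scales_with_gaba_drop(self, tax, small_params):
        """Noiseless forward check: the interference contrast in block 2
        equals kappa x gaba_drop, and block 1 carries none of it."""
        truth = rm.GroundTruth(
            n_voxels=10, noise_sd=0.0, drift_sd=0.0, pattern_scale=0.0,
            delta_suppress=0.0, beta_unstable=0.0, hippo_slope=0.0,
            kappa_couple=10.0, gaba_drop=0.02,
        )
        events = rm.generate_scan_block(tax, small_params, seed=6)
        rng = np.random.default_rng(0)
        pats = rm.simulate_patterns(truth, tax, rng)
        n_vol = n_volumes_for(events, small_params.tr)
        d = rm.build_design_matrix(events, "pairwise", small_params.tr, n_vol)
        spec = rm.contrast_specs(tax)["interference"]
        vals = {}
        for block in (1, 2):
            bold = rm.simulate_bold(events, pats, truth, block, rng, "aLOC", tax=tax)
            fit = rm.fit_glm(bold, d)
            vals[block] = rm.compute_contrast(fit, spec).roi_mean
        assert vals[1] == pytest.approx(0.0, abs=1e-9)
        assert vals[2] == pytest.approx(truth.kappa_couple * truth.gaba_drop, abs=1e-9)

    def test_unstable_boost_appears_only_in_hippocampus(self, tax, small_params):
        truth = rm.GroundTruth(
            n_voxels=10, noise_sd=0.0, drift_sd=0.0, pattern_scale=0.0,
            delta_suppress=0.0, kappa_couple=0.0, beta_unstable=0.4, hippo_slope=0.0,
        )
        events = rm.generate_scan_block(tax, small_params, seed=7)
        rng = np.random.default_rng(0)
        pats = rm.simulate_patterns(truth, tax, rng)
        n_vol = n_volumes_for(events, small_params.tr)
        d = rm.build_design_matrix(events, "pairwise", small_params.tr, n_vol)
        spec = rm.contrast_specs(tax)["opportunity"]
        res = {}
        for roi in ("hippocampus", "aLOC"):
            bold = rm.simulate_bold(events, pats, truth, 1, rng, roi, tax=tax)
            fit = rm.fit_glm(bold, d)
            res[roi] = rm.compute_contrast(fit, spec).roi_mean
        assert res["hippocampus"] == pytest.approx(0.4, abs=1e-9)
        assert res["aLOC"] == pytest.approx(0.0, abs=1e-9)


class TestBehavior:
    def test_training_stops_only_at_criterion(self, canonical_rings):
        truth = rm.GroundTruth()
        for seed in range(5):
            beh = rm.simulate_behavior(
                canonical_rings, truth, np.random.default_rng(seed)
            )
            for ctx in rm.CONTEXTS:
                n_blocks = len(beh.training_block_accuracy[ctx])
                assert n_blocks >= 5
                if n_blocks < truth.max_training_blocks:
                    assert np.all(beh.training_assoc_accuracy[ctx][-1] >= 0.9)

    def test_nonconvergent_training_capped_with_warning(self, canonical_rings):
        truth = rm.GroundTruth(learn_rate=1e-5, max_training_blocks=6)
        with pytest.warns(UserWarning, match="did not converge"):
            beh = rm.simulate_behavior(
                canonical_rings, truth, np.random.default_rng(0)
            )
        assert len(beh.training_block_accuracy["memory1"]) == 6

    def test_zero_interference_weight_symmetric_errors(self, canonical_rings):
        """With no interference weight the foil option is chosen no more
        often than the other lure, so normalized foil errors average ~0."""
        truth = rm.GroundTruth(
            lambda_interfere=0.0, lambda_slope=0.0, strength_slope=0.0
        )
        normed = []
        for seed in range(40):
            beh = rm.simulate_behavior(
                canonical_rings, truth, np.random.default_rng(seed)
            )
            normed.append(rm.foil_statistics(beh.records).normalized_foil_error_pct)
        assert abs(np.mean(normed)) < 3.0

    def test_foil_errors_increase_with_interference_weight(self, canonical_rings):
        rates = []
        for lam in (0.0, 1.0, 2.0):
            truth = rm.GroundTruth(
                lambda_interfere=lam, lambda_slope=0.0, strength_slope=0.0
            )
            vals = [
                rm.foil_statistics(
                    rm.simulate_behavior(
                        canonical_rings, truth, np.random.default_rng(seed)
                    ).records
                ).foil_error_pct
                for seed in range(12)
            ]
            rates.append(np.mean(vals))
        assert rates[0] < rates[1] < rates[2]


class TestMrs:
    def test_zero_drop_null_mean(self):
        truth = rm.GroundTruth(gaba_drop=0.0)
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(1000):
            ms, _ = simulate_mrs(truth, rng)
            g = {m.timepoint: m.ratio for m in ms if m.metabolite == "GABA"}
            diffs.append(g["t1"] - g["t2"])
        assert np.mean(diffs) == pytest.approx(0.0, abs=0.001)

    def test_planted_drop_recovered(self):
        truth = rm.GroundTruth(gaba_drop=0.025)
        rng = np.random.default_rng(0)
        diffs = []
        for _ in range(1000):
            ms, _ = simulate_mrs(truth, rng)
            g = {m.timepoint: m.ratio for m in ms if m.metabolite == "GABA"}
            diffs.append(g["t1"] - g["t2"])
        assert np.mean(diffs) == pytest.approx(0.025, abs=0.001)

    def test_high_crlb_measurement_dropped_by_filter(self):
        m = rm.MetaboliteMeasurement("t1", "GABA", 0.1, crlb=60.0, fwhm=10.0)
        assert rm.mrs_quality_filter([m]) == []

    def test_all_19_metabolites_at_three_timepoints(self):
        ms, _ = simulate_mrs(rm.GroundTruth(), np.random.default_rng(0))
        assert len(ms) == 19 * 3
        assert {m.metabolite for m in ms} == set(METABOLITES)

    def test_inestimable_subjects_have_broader_linewidth(self):
        rng = np.random.default_rng(0)
        truth = rm.GroundTruth()
        ok, _ = simulate_mrs(truth, rng, inestimable=False)
        bad, _ = simulate_mrs(truth, rng, inestimable=True)
        assert np.mean([m.fwhm for m in bad]) > np.mean([m.fwhm for m in ok]) + 2


class TestCohort:
    def test_subject_seeds_distinct_and_run_reproducible(self, tiny_truth):
        small = rm.DesignParams(nonrepeat_reps_per_context=2)
        a = rm.simulate_cohort(5, tiny_truth, master_seed=3, params=small)
        b = rm.simulate_cohort(5, tiny_truth, master_seed=3, params=small)
        assert len({s.seed for s in a}) == 5
        for sa, sb in zip(a, b):
            assert np.array_equal(
                sa.bold[("hippocampus", 1)].data, sb.bold[("hippocampus", 1)].data
            )
            assert sa.truth == sb.truth

    def test_subject_truth_couplings_follow_trait(self, tiny_truth):
        rng = np.random.default_rng(4)
        reals = [realize_subject_truth(tiny_truth, rng) for _ in range(300)]
        q = np.array([r.trait for r in reals])
        gaba = np.array([r.gaba_drop for r in reals])
        lam = np.array([r.lambda_interfere for r in reals])
        assert np.corrcoef(q, gaba)[0, 1] > 0.99
        assert np.corrcoef(q, lam)[0, 1] > 0.99
        assert np.mean(gaba) == pytest.approx(tiny_truth.gaba_drop, abs=0.005)

    def test_randomized_rings_preserve_taxonomy_structure(self, tiny_truth):
        small = rm.DesignParams(nonrepeat_reps_per_context=2)
        subjects = rm.simulate_cohort(4, tiny_truth, master_seed=9, params=small)
        from ringmem.rings import PairCategory

        orders = set()
        for s in subjects:
            t = s.tax
            assert len(t.pairs_in(PairCategory.HIDDEN, "memory1")) == 4
            assert len(t.unstable) == 11
            orders.add(s.rings[0].order)
        assert len(orders) > 1  # allocation really is randomized

    def test_invalid_cohort_size_rejected(self, tiny_truth):
        with pytest.raises(ValueError):
            rm.simulate_cohort(0, tiny_truth, master_seed=0)
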