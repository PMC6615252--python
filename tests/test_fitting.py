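"""Per-residue K_D estimation, residue selection, and aggregation."""

from dataclasses import replace

import numpy as np
import pytest

from cspfit import (
    BindingFitResult,
    CSPProfile,
    SelectionRule,
    SyntheticSpec,
    TitrationModel,
    WeightingScheme,
    aggregate_kd,
    fit_residue,
    fit_series,
    fraction_bound,
    generate_series,
    global_fit,
    select_residues,
)

RATIOS = (0.0, 1.0, 3.0, 5.0, 10.0, 20.0, 30.0)
P = 0.25  # mM


def synthetic_curve(kd_uM, delta_max, ratios=RATIOS, protein_conc=P):
    L = np.array(ratios) * protein_conc
    y = delta_max * fraction_bound(protein_conc, L, kd_uM / 1e3)
    return list(zip(L, y))


class TestFitResidue:
    def test_noise_free_recovery(self):
        fit = fit_residue(synthetic_curve(286.0, 0.12), P)
        assert fit.converged
        assert fit.kd_uM == pytest.approx(286.0, rel=1e-3)
        assert fit.delta_max == pytest.approx(0.12, rel=1e-3)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.endpoint_fraction_bound == pytest.approx(
            fraction_bound(P, 7.5, 0.286), rel=1e-3
        )

    @pytest.mark.parametrize("kd_true", [211.0, 286.0, 318.0, 661.0, 721.0, 2574.0])
    def test_round_trip_identifiability_grid(self, kd_true):
        fit = fit_residue(synthetic_curve(kd_true, 0.15), P)
        assert fit.converged
        assert fit.kd_uM == pytest.approx(kd_true, rel=5e-3)

    def test_all_zero_curve_reports_no_perturbation(self):
        fit = fit_residue([(L, 0.0) for L in (0, 0.25, 0.75, 2.5)], P)
        assert not fit.converged
        assert fit.note == "no perturbation"

    def test_instant_saturation_flagged_non_identifiable(self):
        curve = [(0.0, 0.0)] + [(r * P, 0.2) for r in RATIOS[1:]]
        fit = fit_residue(curve, P)
        assert not fit.converged
        assert "non-identifiable" in fit.note

    def test_preconditions(self):
        with pytest.raises(ValueError, match="3 non-missing"):
            fit_residue([(0.0, 0.0), (0.25, 0.05)], P)
        with pytest.raises(ValueError, match="apo"):
            fit_residue([(0.25, 0.05), (0.75, 0.1), (2.5, 0.12)], P)

    def test_deterministic_bit_identical(self):
        curve = synthetic_curve(500.0, 0.1)
        rng = np.random.default_rng(0)
        noisy = [(L, y + rng.normal(0, 0.003)) for L, y in curve]
        noisy = [(L, max(y, 0.0)) for L, y in noisy]
        a = fit_residue(noisy, P)
        b = fit_residue(noisy, P)
        assert a.kd_uM == b.kd_uM and a.delta_max == b.delta_max and a.rss == b.rss

    def test_hyperbolic_kind_recovers_hyperbolic_truth(self):
        L = np.array(RATIOS) * P
        y = 0.1 * fraction_bound(P, L, 0.5, "hyperbolic")
        fit = fit_residue(list(zip(L, y)), P, kind="hyperbolic")
        assert fit.converged and fit.kd_uM == pytest.approx(500.0, rel=1e-3)


def _profile(values_by_residue, ligand_conc=(0.0, 0.25, 7.5)):
    residues = sorted(values_by_residue)
    vals = np.array([values_by_residue[r] for r in residues], dtype=float)
    return CSPProfile(
        residues=residues,
        ligand_conc=np.array(ligand_conc),
        values=vals,
        scheme=WeightingScheme(),
    )


class TestSelectResidues:
    def test_explicit_list_intersection(self):
        prof = _profile({r: [0, 0.01, 0.05] for r in [23, 50, 52, 73, 80, 81, 90]})
        rule = SelectionRule.explicit([23, 50, 52, 73, 80, 81])
        assert select_residues(prof, rule) == [23, 50, 52, 73, 80, 81]

    def test_explicit_absentees_warn(self):
        prof = _profile({23: [0, 0.01, 0.05], 50: [0, 0.01, 0.05]})
        with pytest.warns(UserWarning, match="99"):
            assert select_residues(prof, SelectionRule.explicit([23, 99])) == [23]

    def test_explicit_empty_intersection_raises(self):
        prof = _profile({23: [0, 0.01, 0.05]})
        with pytest.raises(ValueError, match="no requested residue"):
            select_residues(prof, SelectionRule.explicit([98, 99]))

    def test_all_zero_profile_selects_nothing(self):
        prof = _profile({r: [0.0, 0.0, 0.0] for r in range(1, 20)})
        assert select_residues(prof, SelectionRule.threshold(1.0)) == []

    def test_single_responder_among_null_population(self):
        values = {r: [0.0, 0.0, 0.0] for r in range(1, 100)}
        values[42] = [0.0, 0.3, 0.5]
        prof = _profile(values)
        # by hand: mean = 0.5/99, SD(ddof=1) ~ 0.05025, cutoff ~ 0.0553
        assert select_residues(prof, SelectionRule.threshold(1.0)) == [42]


class TestAggregateKD:
    def _fit(self, res, kd, fb=0.95):
        return BindingFitResult(
            residue_index=res, kd_uM=kd, delta_max=0.1, rss=0.0,
            converged=True, endpoint_fraction_bound=fb, n_points_used=7,
        )

    def test_identical_fits(self):
        agg = aggregate_kd([self._fit(r, 286.0) for r in (1, 2, 3)])
        assert agg.kd_uM == 286.0 and agg.error_uM == 0.0
        assert agg.n_converged == 3 and not agg.partial_saturation_flag

    def test_spread_is_sample_sd(self):
        agg = aggregate_kd([self._fit(1, 200.0), self._fit(2, 300.0)])
        assert agg.kd_uM == pytest.approx(250.0)
        # sqrt(((200-250)² + (300-250)²)/1)
        assert agg.error_uM == pytest.approx(70.7107, abs=1e-3)

    def test_mean_within_contributing_range(self):
        fits = [self._fit(i, kd) for i, kd in enumerate([150.0, 300.0, 450.0], 1)]
        agg = aggregate_kd(fits)
        assert min(f.kd_uM for f in fits) <= agg.kd_uM <= max(f.kd_uM for f in fits)

    def test_single_fit_flagged(self):
        agg = aggregate_kd([self._fit(1, 286.0)])
        assert agg.error_uM == 0.0 and "spread undefined" in agg.note

    def test_partial_saturation_flag_from_median_endpoint(self):
        low = [self._fit(r, 2574.0, fb=0.74) for r in (1, 2, 3)]
        assert aggregate_kd(low).partial_saturation_flag
        high = [self._fit(r, 286.0, fb=0.96) for r in (1, 2, 3)]
        assert not aggregate_kd(high).partial_saturation_flag

    def test_permutation_invariance(self):
        fits = [self._fit(i, kd) for i, kd in enumerate([210, 290, 350, 400], 1)]
        a = aggregate_kd(fits)
        b = aggregate_kd(list(reversed(fits)))
        assert (a.kd_uM, a.error_uM) == (b.kd_uM, b.error_uM)

    def test_unconverged_excluded_and_empty_raises(self):
        bad = BindingFitResult(
            residue_index=9, kd_uM=None, delta_max=None, rss=None,
            converged=False, endpoint_fraction_bound=None, n_points_used=7,
            note="no perturbation",
        )
        agg = aggregate_kd([self._fit(1, 286.0), bad])
        assert agg.n_converged == 1
        with pytest.raises(ValueError, match="no converged"):
            aggregate_kd([bad])


class TestFitSeries:
    def test_noise_free_end_to_end(self):
        spec = SyntheticSpec(kd_true_uM=286.0, noise_sd_H=0.0, noise_sd_N=0.0, seed=11)
        series, truth = generate_series(spec)
        fits, agg = fit_series(series)
        # the mean + SD rule may drop the weakest responders but never a null
        assert set(f.residue_index for f in fits) <= set(truth.responding)
        assert len(fits) >= 3
        assert agg.kd_uM == pytest.approx(286.0, rel=5e-3)
        assert agg.error_uM == pytest.approx(0.0, abs=0.5)

    def test_noisy_recovery_within_tolerance(self):
        spec = SyntheticSpec(kd_true_uM=286.0, seed=21)
        series, _ = generate_series(spec)
        _, agg = fit_series(series)
        assert agg.kd_uM == pytest.approx(286.0, rel=0.25)

    def test_estimator_bias_shrinks_with_noise(self):
        # mean absolute error over replicates decreases on a sigma grid
        errs = []
        for sigma in (0.008, 0.002, 0.0005):
            kds = []
            for k in range(12):
                spec = SyntheticSpec(
                    kd_true_uM=286.0, noise_sd_H=sigma, noise_sd_N=5 * sigma,
                    seed=3000 + k,
                )
                series, _ = generate_series(spec)
                _, agg = fit_series(series)
                kds.append(agg.kd_uM)
            errs.append(abs(np.mean(kds) - 286.0))
        assert errs[2] <= errs[0]
        assert errs[2] < 286.0 * 0.02

    def test_no_perturbation_reported(self):
        spec = SyntheticSpec(responding_fraction=0.0, noise_sd_H=0.0, noise_sd_N=0.0, seed=7)
        series, _ = generate_series(spec)
        model = TitrationModel(series)
        results = model.fit()
        assert results.aggregate is None
        assert results.residue_fits == [] or all(
            not f.converged for f in results.residue_fits
        )

    def test_explicit_rule_missing_residues_raises(self):
        spec = SyntheticSpec(seed=13, missing_residues=(40, 41))
        series, _ = generate_series(spec)
        with pytest.raises(ValueError, match="no requested residue"):
            TitrationModel(series).fit(rule=SelectionRule.explicit([40, 41]))


class TestModelResults:
    def test_summary_and_reports(self, tmp_path):
        spec = SyntheticSpec(kd_true_uM=286.0, noise_sd_H=0.0, noise_sd_N=0.0, seed=11)
        series, _ = generate_series(spec)
        results = TitrationModel(series).fit()
        text = results.summary()
        assert "K_D" in text and "286" in text
        results.to_csv(tmp_path / "report.csv")
        assert (tmp_path / "report.csv").read_text().count("aggregate") == 1
        results.write_report(tmp_path / "report.yaml")
        import yaml

        doc = yaml.safe_load((tmp_path / "report.yaml").read_text())
        assert doc["model_kind"] == "quadratic"
        assert doc["aggregate"]["kd_uM"] == pytest.approx(286.0, rel=5e-3)

    def test_global_fit_agrees_with_per_residue_average(self):
        spec = SyntheticSpec(kd_true_uM=661.0, noise_sd_H=0.0, noise_sd_N=0.0, seed=17)
        series, truth = generate_series(spec)
        model = TitrationModel(series)
        results = model.fit()
        kd_global, dmax, rss = global_fit(
            model.profile, list(truth.responding), model.protein_conc
        )
        assert kd_global == pytest.approx(results.kd_uM, rel=1e-3)
        assert rss == pytest.approx(0.0, abs=1e-10)
        for r in truth.responding:
            assert dmax[r] == pytest.approx(truth.weighted_delta_max()[r], rel=1e-3)
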