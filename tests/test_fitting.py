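"""Global fitting, replicate summaries, derived parameters and SEM calculus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allopharm.exceptions import DomainError
from allopharm.fitting import (
    AssayDataset,
    FitResult,
    ParameterSpec,
    correct_efficacy_for_expression,
    derived_parameters,
    fit_atcm_global,
    fit_operational_allosterism_global,
    fit_saturation,
    format_estimate,
    propagate_sem,
    read_assay_csv,
    summarize_replicates,
    write_assay_csv,
)
from allopharm.synthetic import (
    PRESETS,
    NoiseModel,
    simulate_functional_interaction,
    simulate_interaction_binding,
    simulate_saturation,
)

NOISELESS = NoiseModel(sd=0.0)


class TestSemCalculus:
    def test_single_term_passthrough(self):
        assert propagate_sem([0.3, 0.0]) == pytest.approx(0.3)

    def test_hand_values(self):
        assert propagate_sem([0.07, 0.10]) == pytest.approx(0.1221, abs=1e-4)
        assert propagate_sem([0.1, 0.1, 0.1]) == pytest.approx(0.1732,
                                                              abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            propagate_sem([0.1, -0.2])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=6),
           st.floats(0.1, 10))
    def test_symmetric_homogeneous_and_dominates_max(self, sems, scale):
        a = propagate_sem(sems)
        assert a == pytest.approx(propagate_sem(sems[::-1]))
        assert propagate_sem([scale * s for s in sems]) == pytest.approx(
            scale * a, rel=1e-9)
        assert a >= max(sems) - 1e-12


class TestExpressionCorrection:
    def test_reference_is_identity(self):
        assert correct_efficacy_for_expression(1.3, 5e5, 5e5) == 1.3

    def test_tenfold_lower_expression_raises_tau(self):
        assert correct_efficacy_for_expression(1.0, 5e4, 5e5) == \
            pytest.approx(2.0)

    def test_tenfold_higher_expression_lowers_tau(self):
        assert correct_efficacy_for_expression(1.0, 5e6, 5e5) == \
            pytest.approx(0.0)

    def test_nonpositive_bmax_rejected(self):
        with pytest.raises(DomainError):
            correct_efficacy_for_expression(1.0, 0.0, 5e5)


class TestDerivedParameters:
    def test_occupied_state_affinity(self):
        fit = FitResult(estimates={"pKb_modulator": 5.65, "log_alpha": 1.86},
                        sems={"pKb_modulator": 0.07, "log_alpha": 0.10})
        out = derived_parameters(fit)
        v, s = out.derived["pKb_occupied"]
        assert v == pytest.approx(7.51)
        assert s == pytest.approx(math.hypot(0.07, 0.10))

    def test_neutral_cooperativity_degenerates(self):
        fit = FitResult(estimates={"pKb_modulator": 6.0, "log_alpha": 0.0},
                        sems={"pKb_modulator": 0.1, "log_alpha": 0.0})
        out = derived_parameters(fit)
        assert out.derived["alpha_fold"][0] == pytest.approx(1.0)
        assert out.derived["pKb_occupied"][0] == pytest.approx(6.0)

    def test_log_beta_with_propagated_sem(self):
        fit = FitResult(estimates={"log_alphabeta": 2.01},
                        sems={"log_alphabeta": 0.14})
        out = derived_parameters(fit, extra={"log_alpha": (2.59, 0.10)})
        v, s = out.derived["log_beta"]
        assert v == pytest.approx(-0.58)
        assert s == pytest.approx(0.172, abs=1e-3)

    def test_missing_primary_is_silently_absent(self):
        out = derived_parameters(FitResult(estimates={"log_tau_A": 1.0},
                                           sems={"log_tau_A": 0.1}))
        assert out.derived == {}


class TestReplicateSummary:
    def test_identical_replicates_have_zero_sem(self):
        fits = [FitResult(estimates={"pKb": 5.0}) for _ in range(3)]
        table = summarize_replicates(fits)
        assert table.loc["pKb", "sem"] == pytest.approx(0.0)

    def test_hand_summary_1_2_3(self):
        fits = [FitResult(estimates={"x": v}) for v in (1.0, 2.0, 3.0)]
        table = summarize_replicates(fits)
        assert table.loc["x", "formatted"] == "2.00 ± 0.58 (3)"

    def test_single_replicate_sem_undefined(self):
        table = summarize_replicates([FitResult(estimates={"x": 1.5})])
        assert math.isnan(table.loc["x", "sem"])
        assert "undefined" in table.loc["x", "formatted"]

    def test_table_cell_format(self):
        assert format_estimate(5.65, 0.07, 8) == "5.65 ± 0.07 (8)"

    def test_round_half_even(self):
        assert format_estimate(0.125, 0.135, 3) == "0.12 ± 0.14 (3)"


class TestSaturationFit:
    def test_noiseless_recovery_to_four_digits(self):
        truth = PRESETS["SATURATION_HUMAN_WT"].binding
        ds = simulate_saturation(truth, noise=NOISELESS, n_experiments=1)
        fit = fit_saturation(ds)
        assert fit.converged
        assert fit.estimates["bmax"] == pytest.approx(598111, rel=1e-4)
        assert fit.estimates["pKd_radioligand"] == pytest.approx(9.76,
                                                                abs=1e-4)

    def test_all_zero_data_flagged_degenerate(self):
        ds = [AssayDataset(agonist_conc=np.logspace(-11, -8, 8),
                           modulator_conc=np.zeros(8), value=np.zeros(8),
                           assay_kind="saturation")]
        fit = fit_saturation(ds)
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_noisy_recovery_within_tenth_log_unit(self):
        truth = PRESETS["SATURATION_HUMAN_WT"].binding
        ds = simulate_saturation(
            truth, noise=NoiseModel(kind="gaussian_multiplicative", sd=0.02),
            n_experiments=3, seed=0)
        fit = fit_saturation(ds)
        assert fit.converged
        assert abs(fit.estimates["pKd_radioligand"] - 9.76) < 0.1


def _binding_datasets(noise, n_experiments, seed=0):
    """Paired ACh/Ipx interaction-binding data from the human WT + LY298
    generating truths."""
    tA = PRESETS["HUMAN_WT_LY298_ACH"].binding
    tI = PRESETS["HUMAN_WT_LY298_IPX"].binding
    return (simulate_interaction_binding(tA, noise=noise,
                                         n_experiments=n_experiments,
                                         seed=seed, label="ACh")
            + simulate_interaction_binding(tI, noise=noise,
                                           n_experiments=n_experiments,
                                           seed=seed + 1, label="Ipx"))


class TestAtcmGlobalFit:
    def test_noiseless_global_recovery(self):
        fit = fit_atcm_global(_binding_datasets(NOISELESS, 1),
                              pKd_radioligand=9.76, seed=0)
        assert fit.converged
        truth = {"pKi_agonist__ACh": 4.50, "pKi_agonist__Ipx": 8.30,
                 "pKb_modulator": 5.65, "log_alpha__ACh": 2.59,
                 "log_alpha__Ipx": 1.86}
        for name, v in truth.items():
            assert fit.estimates[name] == pytest.approx(v, abs=1e-4), name

    def test_neutral_modulator_recovered_near_zero(self):
        truth = PRESETS["HUMAN_WT_LY298_ACH"].binding
        neutral = type(truth)(pKd_radioligand=truth.pKd_radioligand,
                              pKi_agonist=truth.pKi_agonist,
                              pKb_modulator=truth.pKb_modulator,
                              log_alpha=0.0, bmax=truth.bmax)
        ds = simulate_interaction_binding(neutral, noise=NOISELESS,
                                          n_experiments=1, label="ACh")
        fit = fit_atcm_global(ds, pKd_radioligand=9.76, seed=0)
        assert abs(fit.estimates["log_alpha__ACh"]) < 0.05

    def test_noisy_recovery_within_three_sems(self):
        from allopharm.fitting import TernaryComplexBindingModel

        model = TernaryComplexBindingModel(
            _binding_datasets(NoiseModel(sd=0.03), 3, seed=1),
            pKd_radioligand=9.76, seed=1)
        fit = model.fit(per_replicate=False)  # asymptotic SEs
        truth = {"pKi_agonist__ACh": 4.50, "pKi_agonist__Ipx": 8.30,
                 "pKb_modulator": 5.65, "log_alpha__ACh": 2.59,
                 "log_alpha__Ipx": 1.86}
        for name, v in truth.items():
            sem = fit.sems[name]
            assert sem > 0
            assert abs(fit.estimates[name] - v) < 3 * sem, name

    def test_shared_parameter_is_single_estimate(self):
        fit = fit_atcm_global(_binding_datasets(NOISELESS, 1),
                              pKd_radioligand=9.76, seed=0)
        # one shared modulator affinity, not one per agonist
        assert "pKb_modulator" in fit.estimates
        assert "pKb_modulator__ACh" not in fit.estimates

    def test_fixing_shared_parameter_to_truth_keeps_fit_good(self):
        datasets = _binding_datasets(NOISELESS, 1)
        free = fit_atcm_global(datasets, pKd_radioligand=9.76, seed=0)
        fixed = fit_atcm_global(
            datasets, pKd_radioligand=9.76, seed=0,
            specs=[ParameterSpec("pKb_modulator", initial=5.65, lower=5.65,
                                 upper=5.65, fixed=True)])
        assert fixed.residual_ss <= free.residual_ss + 1e-8

    def test_sparse_modulator_grid_warns(self):
        ds = _binding_datasets(NOISELESS, 1)[0]
        keep = ds.modulator_conc <= 1e-8  # leaves only 2 nonzero levels
        sparse = AssayDataset(
            agonist_conc=ds.agonist_conc[keep],
            modulator_conc=ds.modulator_conc[keep],
            value=ds.value[keep],
            radioligand_conc=ds.radioligand_conc, label="ACh")
        with pytest.warns(UserWarning, match="weak"):
            fit_atcm_global([sparse], pKd_radioligand=9.76, seed=0)


FIXED_WT = {"pKa": 4.51, "pKb": 4.89, "log_alpha": 1.97}


class TestOperationalGlobalFit:
    def test_noiseless_recovery_of_wt_truth(self):
        truth = PRESETS["PERK_WT_LY298_ACH"].functional
        ds = simulate_functional_interaction(truth, noise=NOISELESS,
                                             n_experiments=1, label="ACh")
        fit = fit_operational_allosterism_global(ds, FIXED_WT, seed=0)
        assert fit.converged
        assert fit.estimates["log_tau_A__ACh"] == pytest.approx(2.96,
                                                                abs=1e-4)
        assert fit.estimates["log_tau_B"] == pytest.approx(1.10, abs=1e-4)
        assert fit.estimates["log_alphabeta__ACh"] == pytest.approx(2.43,
                                                                    abs=1e-4)

    def test_silent_modulator_alone_curve_flat_but_shift_recoverable(self):
        truth = PRESETS["PERK_WT_LY298_ACH"].functional
        silent = type(truth)(pKa_agonist=truth.pKa_agonist,
                             pKb_modulator=truth.pKb_modulator,
                             log_tau_A=truth.log_tau_A,
                             log_tau_B=-math.inf,
                             log_alphabeta=truth.log_alphabeta,
                             log_alpha=truth.log_alpha)
        ds = simulate_functional_interaction(silent, noise=NOISELESS,
                                             n_experiments=1, label="ACh")
        # modulator-alone rows are flat at basal
        alone = ds[0].value[(ds[0].agonist_conc == 0)]
        assert np.all(np.abs(alone) < 1e-9)
        fit = fit_operational_allosterism_global(ds, FIXED_WT, seed=0)
        assert fit.estimates["log_alphabeta__ACh"] == pytest.approx(
            truth.log_alphabeta, abs=1e-3)

    def test_flat_response_flagged(self):
        ds = simulate_functional_interaction(
            PRESETS["PERK_WT_LY298_ACH"].functional, noise=NOISELESS,
            n_experiments=1, label="ACh")
        flat = AssayDataset(agonist_conc=ds[0].agonist_conc,
                            modulator_conc=ds[0].modulator_conc,
                            value=np.zeros_like(ds[0].value),
                            assay_kind="functional", label="ACh")
        fit = fit_operational_allosterism_global([flat], FIXED_WT, seed=0)
        assert not fit.converged

    def test_noisy_functional_cooperativity_within_02(self):
        truth = PRESETS["PERK_WT_LY298_ACH"].functional
        ds = simulate_functional_interaction(truth, noise=NoiseModel(sd=3.0),
                                             n_experiments=4, seed=7,
                                             label="ACh")
        fit = fit_operational_allosterism_global(ds, FIXED_WT, seed=7)
        assert abs(fit.estimates["log_alphabeta__ACh"] - 2.43) < 0.2


class TestRecoveryStudy:
    def test_log_alpha_errors_consistent_with_reported_sems(self):
        """Across many noisy synthetic experiments the median absolute
        error of the binding cooperativity must not exceed twice the median
        reported SEM (the reported uncertainty is honest)."""
        truth = PRESETS["HUMAN_WT_LY298_IPX"].binding
        errors, sems = [], []
        for i in range(100):
            ds = simulate_interaction_binding(
                truth, noise=NoiseModel(sd=0.03), n_experiments=3,
                seed=1000 + i, label="Ipx")
            fit = fit_atcm_global(ds, pKd_radioligand=9.76, n_starts=1,
                                  seed=i)
            errors.append(abs(fit.estimates["log_alpha__Ipx"] - 1.86))
            sems.append(fit.sems["log_alpha__Ipx"])
        assert np.median(errors) < 2 * np.median(sems)


class TestAssayCsvRoundTrip:
    def test_round_trip_preserves_grids_and_values(self, tmp_path):
        datasets = _binding_datasets(NoiseModel(sd=0.01), 2)
        path = tmp_path / "assay.csv"
        write_assay_csv(datasets, path)
        back = read_assay_csv(path)
        assert len(back) == len(datasets)
        key = {(d.replicate_id, d.label): d for d in datasets}
        for ds in back:
            orig = key[(ds.replicate_id, ds.label)]
            np.testing.assert_allclose(ds.value, orig.value)
            np.testing.assert_allclose(ds.agonist_conc, orig.agonist_conc)
            assert ds.radioligand_conc == pytest.approx(orig.radioligand_conc)
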