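"""Affinity-estimator unit tests: closed forms, round trips, error regimes."""

import math
import warnings

import numpy as np
import pytest

from zincomp import (
    AffinityEstimate,
    CIContext,
    CompetitionObservation,
    CompetitorLigand,
    FluorescenceCalibration,
    NoTransferError,
    NoTransitionError,
    OutOfRegimeError,
    ProbeSaturationError,
    SystemDefinition,
    ValidationError,
    combine_replicates,
    fit_transfer_isotherm,
    free_metal_from_fluorescence,
    kd1_from_ci,
    kd1_stepwise,
    kdav_cooperative,
    match_hypothetical_site,
    solve_speciation,
)
from zincomp import constants as C
from zincomp.simulate import ptp1b_activity_scenario, zf_saturation_scenario

WEAKEST = -math.log10(C.MT2_REF32_KDS[0])


def _obs(receptor_total, kd, stoich, lig_total, transferred):
    return CompetitionObservation(
        receptor_total=receptor_total,
        competitor=CompetitorLigand(kd=kd, stoich=stoich, total_conc=lig_total),
        transferred_metal=transferred,
    )


class TestKd1Stepwise:
    def test_symmetric_point_collapses_to_ratio(self):
        # transferred = R/2 with a 1:1 competitor: [depleted]=[loaded] so
        # K_d1 = kd_comp * transferred / free_ligand
        r, kd, lt = 2e-6, 1e-9, 1e-5
        x = r / 2
        est = kd1_stepwise(_obs(r, kd, 1, lt, x))
        assert est.neg_log_kd == pytest.approx(-math.log10(kd * x / (lt - x)), rel=1e-12)
        assert est.model == "stepwise"

    def test_round_trip_through_solver(self, mt2, par):
        ligand = par(5e-6)
        state = solve_speciation(
            SystemDefinition(receptors=(mt2,), ligands=(ligand,), total_metal=11.9e-6)
        )
        est = kd1_stepwise(
            CompetitionObservation(
                receptor_total=1.7e-6,
                competitor=ligand,
                transferred_metal=state.complex_conc[0],
            )
        )
        assert est.neg_log_kd == pytest.approx(WEAKEST, abs=0.05)

    def test_no_transfer_and_out_of_regime(self):
        with pytest.raises(NoTransferError):
            kd1_stepwise(_obs(1e-6, 1e-9, 1, 1e-5, 0.0))
        with pytest.raises(OutOfRegimeError):
            kd1_stepwise(_obs(1e-6, 1e-9, 1, 1e-5, 1e-6))


class TestKdavCooperative:
    def test_algebraic_identity_round_trip(self):
        # build concentrations, compute K_ex^coop by direct arithmetic and
        # check the estimator returns exactly the implied per-ion constant
        n, r, kd, lt = 7, 1.7e-6, C.PAR_KD12, 2e-4
        x = 0.8 * r
        apo, loaded, free_l = x / n, r - x / n, lt - 2 * x
        kex = x**n * apo / (loaded * free_l ** (2 * n))
        expected = -math.log10(kd**n * kex) / n
        est = kdav_cooperative(_obs(r, kd, 2, lt, x), n_sites=n)
        assert est.neg_log_kd == pytest.approx(expected, rel=1e-12)
        assert est.model == "cooperative"

    def test_forward_simulated_value_brackets_site_constants(self, mt2, par):
        ligand = par(2e-4)
        state = solve_speciation(
            SystemDefinition(receptors=(mt2,), ligands=(ligand,), total_metal=11.9e-6)
        )
        est = kdav_cooperative(
            CompetitionObservation(
                receptor_total=1.7e-6,
                competitor=ligand,
                transferred_metal=state.complex_conc[0],
            )
        )
        assert WEAKEST < est.neg_log_kd < -math.log10(C.MT2_REF32_KDS[-1])

    def test_concentration_dependence_is_monotone(self, mt2, par):
        # the apparent average tightens as competitor concentration grows:
        # the estimator, not the protein, changes
        values = []
        for conc in (5e-5, 1e-4, 2e-4, 4e-4):
            ligand = par(conc)
            state = solve_speciation(
                SystemDefinition(
                    receptors=(mt2,), ligands=(ligand,), total_metal=11.9e-6
                )
            )
            values.append(
                kdav_cooperative(
                    CompetitionObservation(
                        receptor_total=1.7e-6,
                        competitor=ligand,
                        transferred_metal=state.complex_conc[0],
                    )
                ).neg_log_kd
            )
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_literal_division_variant_differs_as_documented(self):
        obs = _obs(1.7e-6, C.PAR_KD12, 2, 2e-4, 1e-6)
        root = kdav_cooperative(obs, per_ion="root")
        divide = kdav_cooperative(obs, per_ion="divide")
        # divide leaves the bulk (M^7-scale) magnitude nearly intact
        assert divide.neg_log_kd > 7 * root.neg_log_kd - 10

    def test_rejects_empty_transfer(self):
        with pytest.raises(NoTransferError):
            kdav_cooperative(_obs(1e-6, 1e-9, 1, 1e-5, 0.0))


class TestKd1FromCI:
    def test_atp_like_arithmetic(self):
        # CI 5.1 at 20 mM, 38 uM protein, 0.46 eq transferred
        r, x, zt, ci = 38e-6, 0.46 * 38e-6, 20e-3, 5.1
        est = kd1_from_ci(_obs(r, 10**-ci, 1, zt, x), CIContext(ci=ci, ligand_total=zt))
        expected = -math.log10(10**-ci * x * x / ((r - x) * (zt - x)))
        assert est.neg_log_kd == pytest.approx(expected, rel=1e-12)
        assert est.neg_log_kd == pytest.approx(8.2, abs=0.05)

    def test_all_ratios_unity_returns_ci(self):
        r = 10e-6
        x = r / 2
        ctx = CIContext(ci=6.0, ligand_total=2 * x)  # [ZnZ] = [Z] = x
        est = kd1_from_ci(_obs(r, 1e-6, 1, 2 * x, x), ctx)
        assert est.neg_log_kd == pytest.approx(6.0, rel=1e-12)

    def test_equals_stepwise_for_true_one_to_one_competitor(self):
        kd, r, lt, x = 2e-7, 38e-6, 20e-3, 10e-6
        obs = _obs(r, kd, 1, lt, x)
        ci_est = kd1_from_ci(obs, CIContext(ci=-math.log10(kd), ligand_total=lt))
        sw_est = kd1_stepwise(obs)
        assert ci_est.neg_log_kd == pytest.approx(sw_est.neg_log_kd, rel=1e-12)

    def test_out_of_regime(self):
        with pytest.raises(OutOfRegimeError):
            kd1_from_ci(
                _obs(1e-6, 1e-7, 1, 1e-3, 1e-6),
                CIContext(ci=7.0, ligand_total=1e-3),
            )


class TestFreeMetalFromFluorescence:
    def test_midpoint_reads_probe_kd(self):
        cal = FluorescenceCalibration(f=550.0, f0=100.0, fmin=100.0, fmax=1000.0,
                                      probe_kd=5.5e-9)
        assert free_metal_from_fluorescence(cal) == pytest.approx(5.5e-9, rel=1e-12)

    def test_bound_to_free_ratio_of_two(self):
        # F such that (F - Fmin)/(Fmax - F) = 2 -> twice the probe constant
        fmin, fmax = 100.0, 1000.0
        f = (2 * fmax + fmin) / 3.0
        cal = FluorescenceCalibration(f=f, f0=fmin, fmin=fmin, fmax=fmax,
                                      probe_kd=C.ZNAF2F_KD)
        assert free_metal_from_fluorescence(cal) == pytest.approx(1.1e-8, rel=1e-9)

    def test_underflow_returns_zero_with_warning(self):
        cal = FluorescenceCalibration(f=100.0, f0=100.0, fmin=100.0, fmax=1000.0,
                                      probe_kd=5.5e-9)
        with pytest.warns(RuntimeWarning):
            assert free_metal_from_fluorescence(cal) == 0.0

    def test_saturation_error(self):
        cal = FluorescenceCalibration(f=1000.0, f0=100.0, fmin=100.0, fmax=1000.0,
                                      probe_kd=5.5e-9)
        with pytest.raises(ProbeSaturationError):
            free_metal_from_fluorescence(cal)

    def test_rejects_degenerate_calibration(self):
        with pytest.raises(ValidationError):
            FluorescenceCalibration(f=1.0, f0=1.0, fmin=2.0, fmax=2.0, probe_kd=1e-9)


class TestFitTransferIsotherm:
    def test_exact_recovery_of_noiseless_logistic(self):
        x = np.linspace(6.5, 10.0, 25)
        y = 1.0 / (1.0 + 10.0 ** (1.0 * (8.3 - x)))
        fit = fit_transfer_isotherm(list(zip(x, y)))
        assert fit.midpoint == pytest.approx(8.3, abs=1e-6)
        assert fit.hill_n == pytest.approx(1.0, abs=1e-6)
        assert fit.plateau == pytest.approx(1.0, abs=1e-6)

    def test_two_site_transfer_steepens_slope(self):
        # release from a second site (1.1e-10 M) leaking into the probe
        # window of the first (2e-8 M) steepens the apparent slope above 1
        # when transfer is normalised to one transferable equivalent
        kds = (2e-8, 1.1e-10)
        x = np.linspace(7.0, 8.7, 25)
        zf = 10.0**-x
        y = sum(k / (k + zf) for k in kds)
        fit = fit_transfer_isotherm(list(zip(x, y)), fix_plateau=1.0)
        assert fit.hill_n > 1.0

    def test_constant_data_raise_no_transition(self):
        pts = [(x, 0.7) for x in np.linspace(7, 9, 8)]
        with pytest.raises(NoTransitionError):
            fit_transfer_isotherm(pts)

    def test_requires_five_points(self):
        with pytest.raises(ValidationError):
            fit_transfer_isotherm([(7.0, 0.1), (8.0, 0.5), (9.0, 0.9)])


class TestMatchHypotheticalSite:
    def test_self_match_recovers_grid_member(self):
        scenario = zf_saturation_scenario()
        ratios = [0.5, 1.0, 1.5, 2.0]
        pts = [(r, scenario(8.6, r)) for r in ratios]
        est = match_hypothetical_site(pts, scenario)
        assert est.neg_log_kd == pytest.approx(8.6)
        assert est.flags == ()
        assert est.model == "grid_matched"

    def test_observed_enzyme_activity_maps_to_nanomolar_site(self):
        scenario = ptp1b_activity_scenario()
        family = np.round(np.arange(5.5, 10.0 + 1e-9, 0.1), 10)
        est = match_hypothetical_site([(1.0, 61.0)], scenario, family=family)
        assert est.neg_log_kd == pytest.approx(8.2)

    def test_off_grid_truth_flags_boundary(self):
        scenario = zf_saturation_scenario()
        pts = [(r, scenario(13.0, r)) for r in (0.5, 1.0, 2.0)]
        with pytest.warns(RuntimeWarning):
            est = match_hypothetical_site(pts, scenario)
        assert "boundary" in est.flags
        assert est.neg_log_kd == pytest.approx(12.0)

    def test_requires_points(self):
        with pytest.raises(ValidationError):
            match_hypothetical_site([], zf_saturation_scenario())


class TestModelTagDiscipline:
    def test_cooperative_and_stepwise_differ_on_same_observation(self, mt2, par):
        ligand = par(2e-5)  # sub-equivalent transfer, both estimators defined
        state = solve_speciation(
            SystemDefinition(receptors=(mt2,), ligands=(ligand,), total_metal=11.9e-6)
        )
        obs = CompetitionObservation(
            receptor_total=1.7e-6,
            competitor=ligand,
            transferred_metal=state.complex_conc[0],
        )
        assert kd1_stepwise(obs).neg_log_kd != pytest.approx(
            kdav_cooperative(obs).neg_log_kd, abs=0.1
        )

    def test_combine_refuses_mixed_tags(self):
        a = AffinityEstimate(neg_log_kd=8.0, model="stepwise")
        b = AffinityEstimate(neg_log_kd=10.0, model="cooperative")
        with pytest.raises(ValidationError):
            combine_replicates([a, b])

    def test_combine_same_tag_reports_mean_and_sd(self):
        ests = [AffinityEstimate(neg_log_kd=v, model="stepwise") for v in (8.0, 8.4)]
        combined = combine_replicates(ests)
        assert combined.neg_log_kd == pytest.approx(8.2)
        assert combined.uncertainty == pytest.approx(np.std([8.0, 8.4], ddof=1))
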