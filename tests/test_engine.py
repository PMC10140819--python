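"""Whole-body ODE engine: release model, mass balance, limiting cases."""

import dataclasses

import numpy as np
import pytest

from hcqpbpk.clearance import ClearanceSet
from hcqpbpk.drug import PartitionSet
from hcqpbpk.engine import (DosingRegimen, EngineError, PBPKModel,
                            default_time_grid, lint80_release_fraction)
from hcqpbpk.nca import run_nca
from hcqpbpk.physiology import TISSUE_ORGANS, PopulationSpec, sample_population


class TestLint80:
    def test_zero_before_lag(self):
        assert lint80_release_fraction(30.0, 300.0, 60.0) == 0.0

    def test_eighty_percent_at_dissolution_time(self):
        assert lint80_release_fraction(360.0, 300.0, 60.0) == pytest.approx(0.80)

    def test_linear_midpoint(self):
        assert lint80_release_fraction(210.0, 300.0, 60.0) == pytest.approx(0.40)

    def test_continuation_vs_cap(self):
        t = 60.0 + 300.0 * 1.25   # where the linear continuation reaches 100%
        assert lint80_release_fraction(t, 300.0, 60.0) == pytest.approx(1.0)
        assert lint80_release_fraction(t, 300.0, 60.0, cap_at_80pct=True) == \
            pytest.approx(0.80)

    def test_non_decreasing(self):
        t = np.linspace(0.0, 1000.0, 500)
        f = lint80_release_fraction(t, 300.0, 60.0)
        assert np.all(np.diff(f) >= 0)
        assert f.max() <= 1.0


def _zero_clearance(fub=0.0667):
    return ClearanceSet(CLint_total=0.0, per_enzyme_invitro={},
                        renal_clearance_plasma=0.0, fuB=fub)


class TestMassBalance:
    def test_zero_clearance_conserves_dose_1000h(self, drug, reference_adult):
        """With no elimination, an IV dose stays in the body indefinitely."""
        regimen = DosingRegimen(route="iv_infusion", dose_base=155.0,
                                infusion_duration=30.0)
        model = PBPKModel(reference_adult, drug, regimen,
                          clearances=_zero_clearance())
        sim = model.simulate(times=np.linspace(0.0, 1000.0, 201))
        total = sim.total_in_system()
        post_infusion = total[sim.times >= 0.5]
        assert np.all(np.abs(post_infusion - 155.0) <= 155.0 * 1e-4)
        assert sim.mass_balance_error() <= 1e-4

    @pytest.mark.parametrize("route", ["iv_infusion", "oral"])
    def test_full_accounting_with_elimination(self, drug, reference_adult, route):
        """body + lumen + eliminated + transit loss == dose to 0.1%."""
        regimen = (DosingRegimen(route="iv_infusion", dose_base=155.0)
                   if route == "iv_infusion"
                   else DosingRegimen(route="oral", dose_base=155.0))
        sim = PBPKModel(reference_adult, drug, regimen).simulate(
            times=default_time_grid(120.0, 0.5))
        assert sim.mass_balance_error() <= 1e-3

    def test_oral_cap_mode_leaves_20pct_unreleased(self, drug, reference_adult):
        regimen = DosingRegimen(route="oral", dose_base=155.0,
                                cap_release_at_80pct=True)
        sim = PBPKModel(reference_adult, drug, regimen).simulate(
            times=default_time_grid(48.0, 0.5))
        assert sim.amount("lumen_undissolved")[-1] == pytest.approx(
            0.20 * 155.0, rel=1e-6)
        assert sim.mass_balance_error() <= 1e-3


class TestLimitingBehaviour:
    def test_distribution_equilibrium_recovers_kp(self, drug, reference_adult):
        """At zero clearance the long-time tissue:plasma ratios equal Kp."""
        regimen = DosingRegimen(route="iv_infusion", dose_base=155.0,
                                infusion_duration=30.0)
        model = PBPKModel(reference_adult, drug, regimen,
                          clearances=_zero_clearance())
        sim = model.simulate(times=np.linspace(0.0, 500.0, 101))
        c_plasma = (sim.amount("venous_blood")[-1]
                    / reference_adult.organ_volumes["venous_blood"]) / model.bp_ratio
        for organ in TISSUE_ORGANS:
            c_tissue = sim.amount(organ)[-1] / reference_adult.organ_volumes[organ]
            assert c_tissue / c_plasma == pytest.approx(
                model.partitions.kp[organ], rel=0.01), organ

    def test_dose_proportionality(self, drug, reference_adult):
        """Linear kinetics: doubling the dose exactly doubles AUC."""
        grid = default_time_grid(72.0, 0.1)
        aucs = {}
        for dose in (155.0, 310.0):
            regimen = DosingRegimen(route="iv_infusion", dose_base=dose,
                                    infusion_duration=30.0)
            sim = PBPKModel(reference_adult, drug, regimen).simulate(times=grid)
            res = run_nca(sim.profile, dose)
            aucs[dose] = (res.AUC0_t, res.AUC0_inf)
        assert aucs[310.0][0] / aucs[155.0][0] == pytest.approx(2.0, rel=1e-3)
        assert aucs[310.0][1] / aucs[155.0][1] == pytest.approx(2.0, rel=1e-3)

    def test_tolerance_halving_converged(self, drug, reference_adult, iv_regimen):
        grid = default_time_grid(72.0, 0.25)
        a = PBPKModel(reference_adult, drug, iv_regimen).simulate(
            times=grid, rtol=1e-8, atol=1e-10)
        b = PBPKModel(reference_adult, drug, iv_regimen).simulate(
            times=grid, rtol=5e-9, atol=5e-11)
        auc_a = run_nca(a.profile, 155.0).AUC0_t
        auc_b = run_nca(b.profile, 155.0).AUC0_t
        assert abs(auc_a - auc_b) / auc_b < 1e-4

    def test_one_compartment_closed_form(self, drug, reference_adult):
        """Fast flows + unit partitioning collapse the body to one well-mixed
        volume: C(t) = (Dose/V) exp(-CL t / V)."""
        import copy

        ind = copy.deepcopy(reference_adult)
        ind.organ_blood_flows = {k: q * 1000.0
                                 for k, q in ind.organ_blood_flows.items()}
        mono = dataclasses.replace(drug, pKa_values=[], logP=0.0,
                                   fu_plasma=1.0, blood_to_plasma_ratio=1.0)
        partitions = PartitionSet(kp={o: 1.0 for o in TISSUE_ORGANS}, fu_blood=1.0)
        cl = 5.0   # L/h
        clearances = ClearanceSet(CLint_total=cl, per_enzyme_invitro={},
                                  renal_clearance_plasma=0.0, fuB=1.0)
        regimen = DosingRegimen(route="iv_infusion", dose_base=155.0,
                                infusion_duration=0.6)
        model = PBPKModel(ind, mono, regimen,
                          partitions=partitions, clearances=clearances)
        times = np.linspace(2.0, 200.0, 100)
        sim = model.simulate(times=np.concatenate(([0.0], times)))
        v_total = sum(ind.organ_volumes.values())
        expected = 155.0 / v_total * np.exp(-cl * times / v_total) * 1000.0
        assert sim.profile.concentration[1:] == pytest.approx(expected, rel=5e-3)


class TestOralRoute:
    def test_oral_auc_not_above_iv(self, drug):
        """Bioavailability <= 1 for every sampled individual."""
        grid = default_time_grid(72.0, 0.5)
        pop = sample_population(PopulationSpec(n=5, seed=2))
        for ind in pop:
            iv = PBPKModel(ind, drug, DosingRegimen(
                route="iv_infusion", dose_base=155.0)).simulate(times=grid)
            oral = PBPKModel(ind, drug, DosingRegimen(
                route="oral", dose_base=155.0)).simulate(times=grid)
            auc_iv = run_nca(iv.profile, 155.0).AUC0_t
            auc_oral = run_nca(oral.profile, 155.0).AUC0_t
            assert auc_oral <= auc_iv

    def test_profile_contract(self, oral_simulation):
        p = oral_simulation.profile
        assert np.all(np.diff(p.times) > 0)
        assert np.all(p.concentration >= 0)
        assert p.matrix == "blood"

    def test_plasma_conversion(self, iv_simulation):
        plasma = iv_simulation.plasma_profile()
        ratio = iv_simulation.profile.concentration[10] / plasma.concentration[10]
        assert ratio == pytest.approx(iv_simulation.model.bp_ratio)


class TestValidation:
    def test_unknown_route_rejected(self):
        with pytest.raises(EngineError):
            DosingRegimen(route="sublingual", dose_base=155.0).validate()

    def test_partition_organ_mismatch(self, drug, reference_adult, iv_regimen):
        bad = PartitionSet(kp={"liver": 10.0}, fu_blood=0.1)
        with pytest.raises(EngineError, match="lacks organ"):
            PBPKModel(reference_adult, drug, iv_regimen, partitions=bad)

    def test_non_monotone_grid_rejected(self, drug, reference_adult, iv_regimen):
        model = PBPKModel(reference_adult, drug, iv_regimen)
        with pytest.raises(EngineError):
            model.simulate(times=np.array([0.0, 1.0, 0.5]))
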