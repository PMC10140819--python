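"""Reference physiology, population sampling, and disease scaling."""

import numpy as np
import pytest

from hcqpbpk.physiology import (DiseaseSpec, PhysiologyError, PopulationSpec,
                                apply_disease, build_reference_adult,
                                load_disease_table, sample_population,
                                ARTERIAL_ORGANS)


class TestReferenceAdult:
    def test_flows_balance_cardiac_output(self, reference_adult):
        total = sum(reference_adult.organ_blood_flows[o] for o in ARTERIAL_ORGANS)
        assert total == pytest.approx(reference_adult.cardiac_output, rel=1e-9)

    def test_qh_is_artery_plus_portal(self, reference_adult):
        f = reference_adult.organ_blood_flows
        assert reference_adult.hepatic_blood_flow_QH == pytest.approx(
            f["liver"] + f["gut"] + f["spleen"])

    def test_deterministic(self):
        a = build_reference_adult("F", 22.6, 63.5)
        b = build_reference_adult("F", 22.6, 63.5)
        assert a.organ_volumes == b.organ_volumes
        assert a.organ_blood_flows == b.organ_blood_flows

    def test_linear_weight_scaling_doubles_volumes(self):
        base = build_reference_adult("F", 22.6, 63.5)
        double = build_reference_adult("F", 22.6, 127.0)
        for organ, v in base.organ_volumes.items():
            assert double.organ_volumes[organ] == pytest.approx(
                2.0 * v, rel=1e-9), organ
        for organ, q in base.organ_blood_flows.items():
            assert double.organ_blood_flows[organ] == pytest.approx(
                2.0 * q, rel=1e-9), organ

    @pytest.mark.parametrize("sex,age,weight", [
        ("F", 17.0, 63.5), ("F", 70.0, 63.5), ("M", 30.0, 35.0),
        ("M", 30.0, 140.0), ("X", 30.0, 70.0),
    ])
    def test_out_of_range_demographics_raise(self, sex, age, weight):
        with pytest.raises(PhysiologyError):
            build_reference_adult(sex, age, weight)


class TestPopulationSampling:
    def test_counts_and_female_fraction(self):
        pop = sample_population(PopulationSpec(n=100, female_fraction=0.60, seed=1))
        assert len(pop) == 100
        assert sum(1 for p in pop if p.sex == "F") == 60

    def test_zero_variance_reproduces_reference(self):
        spec = PopulationSpec(
            n=5, female_fraction=1.0, age_range=(22.6, 22.6),
            weight_range=(63.5, 63.5),
            variability_cv={"organ_volumes": 0.0, "organ_blood_flows": 0.0,
                            "hematocrit": 0.0, "body_weight": 0.0},
            seed=3)
        pop = sample_population(spec)
        ref = build_reference_adult("F", 22.6, 63.5)
        for ind in pop:
            assert ind.organ_volumes == pytest.approx(ref.organ_volumes)
            assert ind.organ_blood_flows == pytest.approx(ref.organ_blood_flows)
            assert ind.hematocrit == ref.hematocrit

    def test_weight_cv_recovered_monte_carlo(self):
        spec = PopulationSpec(
            n=1000, female_fraction=0.5, weight_range=(60, 80),
            variability_cv={"body_weight": 0.2, "organ_volumes": 0.0,
                            "organ_blood_flows": 0.0, "hematocrit": 0.0},
            seed=7)
        w = np.array([p.body_weight for p in sample_population(spec)])
        cv = w.std(ddof=1) / w.mean()
        assert 0.17 <= cv <= 0.23   # within 15% of the nominal 0.2

    def test_seeded_reproducibility(self):
        spec = PopulationSpec(n=20, seed=11)
        a, b = sample_population(spec), sample_population(spec)
        for x, y in zip(a, b):
            assert x.organ_volumes == y.organ_volumes
            assert x.organ_blood_flows == y.organ_blood_flows
            assert x.body_weight == y.body_weight

    def test_empty_population_rejected(self):
        with pytest.raises(PhysiologyError):
            sample_population(PopulationSpec(n=0))

    def test_flows_rebalance_after_perturbation(self):
        for ind in sample_population(PopulationSpec(n=10, seed=5)):
            total = sum(ind.organ_blood_flows[o] for o in ARTERIAL_ORGANS)
            assert total == pytest.approx(ind.cardiac_output, rel=1e-9)


class TestDiseaseScaling:
    def test_healthy_stage_is_identity(self, reference_adult):
        out = apply_disease(reference_adult, DiseaseSpec.from_stage("healthy"))
        assert out.organ_volumes == reference_adult.organ_volumes
        assert out.organ_blood_flows == reference_adult.organ_blood_flows
        assert out.GFR == reference_adult.GFR
        assert out.binding_protein_scalar == reference_adult.binding_protein_scalar

    def test_input_not_mutated(self, reference_adult):
        before = dict(reference_adult.organ_blood_flows)
        apply_disease(reference_adult, DiseaseSpec.from_stage("CP-C"))
        assert reference_adult.organ_blood_flows == before

    @pytest.mark.parametrize("stage,gfr", [("CKD-moderate", 45.0), ("CKD-severe", 20.0)])
    def test_ckd_gfr_overrides(self, reference_adult, stage, gfr):
        assert apply_disease(reference_adult, DiseaseSpec.from_stage(stage)).GFR == gfr

    def test_cirrhosis_severity_monotone(self, reference_adult):
        stages = [apply_disease(reference_adult, DiseaseSpec.from_stage(s))
                  for s in ("CP-A", "CP-B", "CP-C")]
        qh = [s.hepatic_blood_flow_QH for s in stages]
        binding = [s.binding_protein_scalar for s in stages]
        liver = [s.organ_volumes["liver"] for s in stages]
        assert qh[0] < reference_adult.hepatic_blood_flow_QH
        assert qh == sorted(qh, reverse=True)
        assert binding == sorted(binding, reverse=True)
        assert liver == sorted(liver, reverse=True)

    def test_ckd_gfr_monotone(self, reference_adult):
        gfrs = [apply_disease(reference_adult, DiseaseSpec.from_stage(s)).GFR
                for s in ("healthy", "CKD-moderate", "CKD-severe")]
        assert gfrs == sorted(gfrs, reverse=True)

    def test_flow_balance_survives_scaling(self, reference_adult):
        for stage in ("CP-A", "CP-B", "CP-C", "CKD-moderate", "CKD-severe"):
            out = apply_disease(reference_adult, DiseaseSpec.from_stage(stage))
            total = sum(out.organ_blood_flows[o] for o in ARTERIAL_ORGANS)
            assert total == pytest.approx(out.cardiac_output, rel=1e-6)

    def test_unknown_stage_raises(self, reference_adult):
        with pytest.raises(PhysiologyError):
            DiseaseSpec.from_stage("CP-D")
        with pytest.raises(PhysiologyError):
            apply_disease(reference_adult, DiseaseSpec(stage="CP-D"))

    def test_non_positive_scaler_raises(self, reference_adult):
        with pytest.raises(PhysiologyError):
            apply_disease(reference_adult,
                          DiseaseSpec(stage="CP-A", scalers={"hematocrit": 0.0}))
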