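"""Synthetic skeleton generator: determinism, truth recovery, scenarios."""

from collections import Counter
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from skeletochron.growth import element_growth
from skeletochron.io import records_from_table
from skeletochron.pairing import compare_skeleton
from skeletochron.records import (assess_cgm_loss, detect_narrow_zone,
                                  flag_partial_year, retrocalculate_missing)
from skeletochron.simulate import (ELEMENT_DEFAULTS, ElementShape,
                                   SimulationConfig, generate_cohort,
                                   generate_individual,
                                   resorption_rate_for_marks)

TWO_ELEMENTS = {"femur": ELEMENT_DEFAULTS["femur"],
                "radius": ELEMENT_DEFAULTS["radius"]}


def pipeline_records(ind):
    records, baseline = records_from_table(ind.measurements)
    return [flag_partial_year(r) for r in records], baseline


class TestDeterminismAndValidity:
    def test_fixed_seed_reproduces_measurements(self):
        cfg = SimulationConfig(seed=5, elements=TWO_ELEMENTS)
        a = generate_individual(cfg).measurements
        b = generate_individual(cfg).measurements
        pd.testing.assert_frame_equal(a, b)

    def test_contours_pass_geometry_invariants(self):
        import math
        from skeletochron.contours import enclosed_area, perimeter
        ind = generate_individual(SimulationConfig(seed=2))
        for (el, side), contours in ind.contours.items():
            for c in contours:
                p, a = perimeter(c), enclosed_area(c)
                assert a > 0 and p > 0
                assert p ** 2 >= 4 * math.pi * a

    def test_oversized_noise_raises_generation_error(self):
        cfg = SimulationConfig(seed=0, bilateral_noise_sigma=0.9,
                               elements=TWO_ELEMENTS)
        with pytest.raises(ValueError):
            generate_individual(cfg)


class TestTruthRecovery:
    def test_noiseless_increments_recovered_exactly(self):
        cfg = SimulationConfig(
            seed=3, bilateral_noise_sigma=0.0, fourier_amplitude=0.0,
            elements={"femur": ELEMENT_DEFAULTS["femur"]})
        ind = generate_individual(cfg)
        records, baseline = pipeline_records(ind)
        rec = next(r for r in records if r.side == "left")
        got = [g.annual_thickness
               for g in element_growth(rec, baseline) if g.year != 0]
        assert got == pytest.approx(list(ind.truth.elements["femur"]
                                         .increments), abs=1e-3)

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_resorbed_mark_count_recovered(self, k):
        # controlled scenario: deterministic increments place the final
        # resorption front between marks k and k+1 exactly
        cfg = SimulationConfig(seed=31 + k, n_years=6, increment_sigma=0.0,
                               elements=TWO_ELEMENTS)
        rate = resorption_rate_for_marks(cfg, "femur", k)
        ind = generate_individual(replace(cfg, resorption_rate=rate))
        records, baseline = pipeline_records(ind)
        idx = {(r.element, r.side): r for r in records}
        femur, radius = idx[("femur", "left")], idx[("radius", "left")]
        truth = ind.truth.elements["femur"].resorbed_count
        assert truth == k
        assert assess_cgm_loss(femur, baseline) == (k > 0)
        assert not assess_cgm_loss(radius, baseline)
        rc = retrocalculate_missing(femur, radius, baseline=baseline)
        assert rc.missing_count == k

    @pytest.mark.parametrize("seed", [32, 57])
    def test_recovery_matches_realized_truth_under_stochastic_growth(
            self, seed):
        cfg = SimulationConfig(seed=seed, n_years=6, elements=TWO_ELEMENTS)
        rate = resorption_rate_for_marks(cfg, "femur", 2)
        ind = generate_individual(replace(cfg, resorption_rate=rate))
        records, baseline = pipeline_records(ind)
        idx = {(r.element, r.side): r for r in records}
        rc = retrocalculate_missing(idx[("femur", "left")],
                                    idx[("radius", "left")],
                                    baseline=baseline)
        assert rc.missing_count == ind.truth.elements["femur"].resorbed_count

    def test_narrow_zone_flagged_at_configured_pair(self):
        ind = generate_individual(SimulationConfig(seed=42,
                                                   narrow_zone_year=3))
        records, baseline = pipeline_records(ind)
        votes = Counter()
        for r in records:
            for pair in detect_narrow_zone(r, baseline=baseline):
                votes[pair] += 1
        assert votes.most_common(1)[0][0] == (3, 4)
        assert votes[(3, 4)] > len(records) / 2

    def test_partial_final_year_flagged_only_when_simulated(self):
        for partial in (True, False):
            ind = generate_individual(SimulationConfig(
                seed=9, partial_final_year=partial, elements=TWO_ELEMENTS))
            records, _ = pipeline_records(ind)
            assert all(r.surface_partial_year == partial for r in records)


class TestCohort:
    def test_growth_scale_orders_cohort_rates(self):
        cfg = SimulationConfig(seed=8, elements=TWO_ELEMENTS)
        fast, slow = generate_cohort(2, cfg, increment_scales=[1.0, 0.6])

        def mean_rate(ind):
            records, baseline = pipeline_records(ind)
            vals = [g.annual_thickness for r in records
                    for g in element_growth(r, baseline)
                    if g.annual_thickness is not None and g.year != 0]
            return np.mean(vals)

        assert mean_rate(fast) > mean_rate(slow)

    def test_cohort_is_deterministic(self):
        cfg = SimulationConfig(seed=13, elements=TWO_ELEMENTS)
        a = generate_cohort(3, cfg)
        b = generate_cohort(3, cfg)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.measurements, y.measurements)

    def test_bilateral_regression_slope_near_unity(self):
        cohort = generate_cohort(12, SimulationConfig(seed=4))
        pooled = []
        for ind in cohort:
            records, baseline = records_from_table(ind.measurements)
            pooled.extend(records)
        _, reg = compare_skeleton(pooled, regression_levels="marks")
        assert reg.slope == pytest.approx(1.0, abs=0.02)

    def test_bad_scale_vector_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(2, SimulationConfig(seed=1),
                            increment_scales=[1.0])
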