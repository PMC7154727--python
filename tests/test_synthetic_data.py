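import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import single_mayfly_taxa, zn_only_design
from streammix import synthetic_data as sd


def _sens(ec50, b=4.0):
    return sd.MetalSensitivity(float(np.log10(ec50)), b)


class TestSurvivalFraction:
    def test_all_zero_concentrations_give_one(self):
        tp = sd.TaxonParams("t", "g", 10, 5, {"Zn": _sens(50), "Cu": _sens(5)})
        assert sd.survival_fraction({"Zn": 0.0, "Cu": 0.0}, tp) == 1.0

    def test_two_metals_at_own_ec50(self):
        tp = sd.TaxonParams("t", "g", 10, 5, {"Zn": _sens(50), "Cu": _sens(5)})
        assert sd.survival_fraction({"Zn": 50, "Cu": 5}, tp, theta=1.0) == pytest.approx(0.25)
        # theta = 0.5 raises the joint survival to sqrt(0.25)
        assert sd.survival_fraction({"Zn": 50, "Cu": 5}, tp, theta=0.5) == pytest.approx(0.5)

    def test_unknown_metal_is_nontoxic(self):
        tp = sd.TaxonParams("t", "g", 10, 5, {"Zn": _sens(50)})
        assert sd.survival_fraction({"Ni": 1e6}, tp) == 1.0

    def test_negative_concentration_rejected(self):
        tp = sd.TaxonParams("t", "g", 10, 5, {"Zn": _sens(50)})
        with pytest.raises(ValueError):
            sd.survival_fraction({"Zn": -1.0}, tp)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        c1=st.floats(0, 1e4), c2=st.floats(0, 1e4),
        bump=st.floats(0.1, 100), theta=st.floats(0.2, 3.0),
    )
    def test_nonincreasing_in_each_component_and_permutation_invariant(
        self, c1, c2, bump, theta
    ):
        tp = sd.TaxonParams("t", "g", 10, 5, {"A": _sens(50), "B": _sens(5)})
        s = sd.survival_fraction({"A": c1, "B": c2}, tp, theta)
        s_perm = sd.survival_fraction({"B": c2, "A": c1}, tp, theta)
        s_up = sd.survival_fraction({"A": c1 + bump, "B": c2}, tp, theta)
        assert s == pytest.approx(s_perm)
        assert s_up <= s + 1e-12
        assert 0 < s <= 1


class TestExposureSeriesGeneration:
    def test_background_at_time_zero(self):
        kin = sd.UptakeKinetics(c_ss=1.0, k_up=0.3, c_bg=2.5)
        assert kin.conc_at(100.0, 0.0) == pytest.approx(2.5)

    def test_first_order_rise_value(self):
        # C(10) = 100 * (1 - exp(-3)) with no background, k = 0.3/d
        kin = sd.UptakeKinetics(c_ss=1.0, k_up=0.3, c_bg=0.0)
        assert kin.conc_at(100.0, 10.0) == pytest.approx(100 * (1 - np.exp(-3)))
        assert kin.conc_at(100.0, 10.0) == pytest.approx(95.0, abs=0.05)

    def test_monotone_approach_to_plateau(self):
        kin = sd.UptakeKinetics(c_ss=0.9, k_up=0.2, c_bg=1.0)
        t = np.linspace(0, 60, 200)
        c = kin.conc_at(100.0, t)
        assert np.all(np.diff(c) > 0)
        assert c[-1] < 1.0 + 90.0
        assert kin.conc_at(100.0, 1e6) == pytest.approx(91.0)

    def test_noise_free_series_is_exact_curve(self):
        kin = sd.UptakeKinetics(c_ss=1.0, k_up=0.25, c_bg=1.3)
        rng = np.random.default_rng(0)
        s = sd.generate_exposure_series(kin, 100.0, [1, 5, 10, 20], 0.0, rng)
        np.testing.assert_allclose(s.conc, kin.conc_at(100.0, s.days))


class TestGenerateExperiment:
    def test_seeded_determinism(self):
        taxa, design = sd.default_taxa(), sd.default_design()
        s1, t1 = sd.generate_experiment(taxa, design, 42)
        s2, t2 = sd.generate_experiment(taxa, design, 42)
        pd.testing.assert_frame_equal(s1.counts.counts, s2.counts.counts)
        assert t1 == t2
        for a, b in zip(s1.exposures, s2.exposures):
            np.testing.assert_array_equal(a.conc, b.conc)
        assert [r.concentration for r in s1.residues] == [
            r.concentration for r in s2.residues
        ]

    def test_different_seeds_differ(self):
        s1, _ = sd.generate_experiment(sd.default_taxa(), sd.default_design(), 1)
        s2, _ = sd.generate_experiment(sd.default_taxa(), sd.default_design(), 2)
        assert not s1.counts.counts["count"].equals(s2.counts.counts["count"])

    def test_logistic_midpoint_count(self):
        """Zero noise, taxon with EC50 equal to the achieved exposure:
        expected count is half the control abundance."""
        design = zn_only_design(count_mode="expected").without_noise()
        probe, _ = sd.generate_experiment(
            single_mayfly_taxa(ec50=50.0), design, 0, add_total_mayflies=False
        )
        from streammix.exposure_chem import time_weighted_average

        twa = time_weighted_average(probe.exposure("Zn-3", "Zn"))
        study, _ = sd.generate_experiment(
            single_mayfly_taxa(lambda0=200.0, ec50=twa), design, 0,
            add_total_mayflies=False,
        )
        assert study.counts.count_for("Zn-3", "Mayfly pool") == 100

    def test_control_count_mean_matches_nb_moments(self):
        """Monte-Carlo against negative-binomial moments: with large
        dispersion (near-Poisson) the mean of 1000 control draws sits within
        3 standard errors of lambda0 = 200."""
        taxa = single_mayfly_taxa(lambda0=200.0, dispersion_k=1e6)
        design = zn_only_design()
        draws = []
        for seed in range(250):
            study, _ = sd.generate_experiment(taxa, design, seed,
                                              add_total_mayflies=False)
            draws.extend(study.counts.control_counts("Mayfly pool"))
        draws = np.array(draws)
        se = np.sqrt(200.0 / draws.size)
        assert abs(draws.mean() - 200.0) < 3 * se

    def test_ground_truth_matches_configured_parameters(self):
        taxa = sd.default_taxa()
        design = sd.default_design(theta=0.7)
        _, truth = sd.generate_experiment(taxa, design, 5)
        assert truth["theta"] == 0.7
        for tp in taxa:
            rec = truth["taxa"][tp.taxon]
            assert rec["lambda0"] == tp.lambda0
            for m, s in tp.sensitivity.items():
                assert rec["sensitivity"][m]["ec50_ugL"] == pytest.approx(
                    10**s.log10_ec50
                )
        assert truth["kinetics"]["Cd"]["k_up"] == design.kinetics["Cd"].k_up

    def test_total_mayflies_aggregate_sums_mayfly_taxa(self):
        study, _ = sd.generate_experiment(sd.default_taxa(), sd.default_design(), 3)
        sids = sorted(study.counts.streams)
        agg = study.counts.counts_by_stream("Total mayflies", sids)
        manual = study.counts.total_by_group_prefix("Ephemeroptera", sids)
        np.testing.assert_array_equal(agg, manual)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            sd.SeriesDef("Zn", ("Zn",), 100.0, n_levels=1)
        with pytest.raises(ValueError):
            sd.SeriesDef("Zn", ("Zn",), 100.0, dilution=1.0)
        with pytest.raises(ValueError):
            sd.SeriesDef("mix", ("Zn", "Cu"), 100.0)  # missing ratio
        with pytest.raises(ValueError):
            sd.DesignConfig(series=[], interaction_theta=0.0)
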