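"""Inhibition normalization and the four synergy reference models."""

import numpy as np
import pandas as pd
import pytest

from resistrace import simulate as sim
from resistrace import synergy as syn

MONO1 = dict(ymin=0, ymax=90, ec50=2, hill=1.3)
MONO2 = dict(ymin=0, ymax=70, ec50=4, hill=1.1)
DOSES = [0, 0.5, 1, 2, 4, 8]


def _surface(model, **kwargs):
    kwargs.setdefault("mono1", MONO1)
    kwargs.setdefault("mono2", MONO2)
    data = sim.simulate_dose_response(model, DOSES, DOSES, **kwargs)
    return syn.to_inhibition(syn.DoseResponse(data, 100.0, 0.0))


def _tiny(readings):
    df = pd.DataFrame(
        {"dose1": [0, 1, 0, 1], "dose2": [0, 0, 1, 1], "replicate": 0,
         "reading": readings}
    )
    return syn.to_inhibition(syn.DoseResponse(df, 100.0, 0.0))


class TestToInhibition:
    def test_control_anchoring(self):
        df = pd.DataFrame(
            {"dose1": [0, 1, 0, 1], "dose2": [0, 0, 1, 1], "replicate": 0,
             "reading": [200.0, 50.0, 125.0, 60.0]}
        )
        surface = syn.to_inhibition(syn.DoseResponse(df, 200.0, 50.0))
        assert surface.loc[0, 0] == 0.0
        assert surface.loc[1, 0] == 100.0
        assert surface.loc[0, 1] == 50.0

    def test_bad_controls_error(self):
        df = pd.DataFrame({"dose1": [0], "dose2": [0], "replicate": [0],
                           "reading": [1.0]})
        with pytest.raises(ValueError, match="control"):
            syn.DoseResponse(df, 0.0, 100.0)

    def test_out_of_range_flagged_not_clipped(self):
        df = pd.DataFrame(
            {"dose1": [0, 1, 0, 1], "dose2": [0, 0, 1, 1], "replicate": 0,
             "reading": [100.0, 110.0, 50.0, 40.0]}
        )
        with pytest.warns(UserWarning, match="outside"):
            surface = syn.to_inhibition(syn.DoseResponse(df, 100.0, 0.0))
        assert surface.loc[1, 0] == -10.0


class TestHsaBliss:
    def test_hsa_direct_formula(self):
        # monotherapies 20% and 30%, combination 50% -> excess 20
        surface = _tiny([100.0, 80.0, 70.0, 50.0])
        excess, mean = syn.hsa_excess(surface)
        assert mean == pytest.approx(20.0)
        assert excess.loc[1, 1] == pytest.approx(20.0)

    def test_hsa_zero_when_combo_equals_best_monotherapy(self):
        assert syn.hsa_excess(_tiny([100.0, 80.0, 70.0, 70.0]))[1] == 0.0

    def test_hsa_negative_when_combo_below_both(self):
        assert syn.hsa_excess(_tiny([100.0, 80.0, 70.0, 90.0]))[1] < 0

    def test_bliss_exact_independence_scores_zero(self):
        # 0.2 + 0.3 - 0.06 = 0.44
        assert syn.bliss_excess(_tiny([100.0, 80.0, 70.0, 56.0]))[1] == pytest.approx(0.0)

    def test_bliss_direct_formula(self):
        assert syn.bliss_excess(_tiny([100.0, 80.0, 70.0, 46.0]))[1] == pytest.approx(10.0)

    def test_bliss_absorbing_at_full_monotherapy_kill(self):
        surface = _tiny([100.0, 0.0, 70.0, 10.0])  # drug1 alone kills 100%
        assert syn.bliss_excess(surface)[1] == pytest.approx(90.0 - 100.0)

    def test_bliss_excess_never_exceeds_hsa_excess(self):
        surface = _surface("bliss-null", synergy_delta=3, noise_sd=1, seed=2)
        b = syn.bliss_excess(surface)[0].to_numpy()
        h = syn.hsa_excess(surface)[0].to_numpy()
        mask = ~np.isnan(b)
        assert (b[mask] <= h[mask] + 1e-9).all()


class TestFourPL:
    def test_parameters_recovered_on_noise_free_curve(self):
        doses = np.array([0, 0.25, 0.5, 1, 2, 4, 8, 16], dtype=float)
        truth = syn.FourPL(5.0, 85.0, 2.0, 1.4)
        fit = syn.fit_4pl(doses, truth(doses))
        assert fit.ymin == pytest.approx(5.0, rel=0.05, abs=0.5)
        assert fit.ymax == pytest.approx(85.0, rel=0.05)
        assert fit.ec50 == pytest.approx(2.0, rel=0.05)
        assert fit.hill == pytest.approx(1.4, rel=0.05)

    def test_inverse_round_trip(self):
        curve = syn.FourPL(0.0, 80.0, 3.0, 1.2)
        for d in (0.5, 3.0, 10.0):
            assert curve.inverse(float(curve(np.array([d]))[0])) == pytest.approx(d)

    def test_too_few_doses_error(self):
        with pytest.raises(ValueError, match=">=3"):
            syn.fit_4pl(np.array([0, 1.0]), np.array([0, 50.0]))


class TestLoeweZip:
    def test_sham_self_combination_loewe_excess_near_zero(self):
        data = sim.simulate_dose_response(
            "additive-shift", DOSES, DOSES, mono1=MONO1, mono2=MONO1
        )
        surface = syn.to_inhibition(syn.DoseResponse(data, 100.0, 0.0))
        assert abs(syn.loewe_excess(surface)[1]) < 1.0

    def test_loewe_detects_planted_shift(self):
        data = sim.simulate_dose_response(
            "additive-shift", DOSES, DOSES, mono1=MONO1, mono2=MONO1,
            synergy_delta=10,
        )
        surface = syn.to_inhibition(syn.DoseResponse(data, 100.0, 0.0))
        assert 8.0 <= syn.loewe_excess(surface)[1] <= 12.0

    def test_zip_null_on_bliss_consistent_surface(self):
        assert abs(syn.zip_excess(_surface("bliss-null"))[1]) < 1.0

    def test_zip_detects_planted_shift(self):
        assert 8.0 <= syn.zip_excess(_surface("bliss-null", synergy_delta=10))[1] <= 12.0

    def test_zip_degenerate_flat_partner_drug(self):
        flat = dict(ymin=0, ymax=0, ec50=4, hill=1.1)
        surface = _surface("bliss-null", mono2=flat)
        assert abs(syn.zip_excess(surface)[1]) < 1.0

    def test_drug_role_swap_leaves_means_unchanged(self):
        data = sim.simulate_dose_response(
            "bliss-null", [0, 1, 2, 4, 8], [0, 0.5, 2, 6, 12],
            mono1=MONO1, mono2=MONO2, synergy_delta=4,
        )
        swapped = data.rename(columns={"dose1": "dose2", "dose2": "dose1"})
        for model in syn.MODELS:
            m1 = syn.mean_synergy(syn.DoseResponse(data, 100, 0), model)
            m2 = syn.mean_synergy(syn.DoseResponse(swapped, 100, 0), model)
            assert m1 == pytest.approx(m2, abs=0.3)


class TestBootstrapAndCall:
    def _replicated(self, delta, noise, seed):
        data = sim.simulate_dose_response(
            "bliss-null", [0, 1, 2, 4], [0, 2, 5, 10],
            synergy_delta=delta, noise_sd=noise, replicates=3, seed=seed,
        )
        return syn.DoseResponse(data, 100.0, 0.0)

    def test_single_replicate_errors(self):
        dr = syn.DoseResponse(
            sim.simulate_dose_response("bliss-null", [0, 1, 2], [0, 1, 2]),
            100.0, 0.0,
        )
        with pytest.raises(ValueError, match="replicates"):
            syn.bootstrap_significance(dr, "bliss")

    def test_zero_resampling_variance_gives_minimum_p(self):
        data = sim.simulate_dose_response(
            "bliss-null", [0, 1, 2, 4], [0, 2, 5, 10],
            synergy_delta=10, noise_sd=0, replicates=3,
        )
        dr = syn.DoseResponse(data, 100.0, 0.0)
        with pytest.warns(UserWarning, match="coarse"):
            p = syn.bootstrap_significance(dr, "bliss", n_boot=10, seed=0)
        assert p == pytest.approx(2.0 / 11.0)

    def test_null_surface_gives_large_p_on_average(self):
        ps = []
        for s in range(8):
            with pytest.warns(UserWarning, match="coarse"):
                ps.append(
                    syn.bootstrap_significance(
                        self._replicated(0, 3, seed=s), "bliss", n_boot=20, seed=s
                    )
                )
        assert np.mean(ps) > 0.3

    def test_exactly_zero_mean_score_gives_p_one(self):
        data = sim.simulate_dose_response(
            "bliss-null", [0, 1, 2, 4], [0, 2, 5, 10], replicates=3
        )
        dr = syn.DoseResponse(data, 100.0, 0.0)
        assert syn.bootstrap_significance(dr, "bliss", n_boot=10, seed=0) == 1.0

    def test_planted_synergy_detected_despite_coarse_bootstrap(self):
        detected = 0
        for s in range(20):
            with pytest.warns(UserWarning, match="coarse"):
                p = syn.bootstrap_significance(
                    self._replicated(10, 2, seed=s), "bliss", n_boot=10, seed=s
                )
            detected += p < 0.2
        assert detected >= 16

    @pytest.mark.parametrize(
        "mean,expected", [(5.0, True), (4.99, False), (-3.0, False), (12.0, True)]
    )
    def test_synergy_call_boundary_is_inclusive(self, mean, expected):
        assert syn.classify(mean) is expected

    def test_nonfinite_mean_errors(self):
        with pytest.raises(ValueError):
            syn.classify(float("nan"))
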