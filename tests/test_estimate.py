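"""Parameter estimation: Bateman fitting, one-compartment → PBPK conversion
and the full-model refit, anchored by parameter-recovery oracles on
synthetic data whose generating truth is known."""

import warnings

import numpy as np
import pandas as pd
import pytest

from nicopbpk import estimate, ivive, pbpk, synth
from nicopbpk.estimate import bateman


def _bateman_dataset(dose, ka, kel, v, times):
    c = bateman(np.asarray(times), dose, ka, kel, v)
    return pd.DataFrame({
        "time_h": times, "compound": "nicotine", "matrix": "blood",
        "value": c, "unit": "ng/mL", "animal_id": 1,
    })


class TestBateman:
    def test_degenerate_limit_continuous(self):
        t = np.linspace(0.1, 10.0, 40)
        near = bateman(t, 100.0, 1.0 + 1e-10, 1.0, 2.0)
        limit = bateman(t, 100.0, 1.0, 1.0, 2.0)
        np.testing.assert_allclose(near, limit, rtol=1e-6)

    def test_zero_at_t0_and_positive_after(self):
        t = np.array([0.0, 0.5, 2.0])
        c = bateman(t, 100.0, 1.07, 0.4, 2.0)
        assert c[0] == 0.0 and np.all(c[1:] > 0.0)


class TestFitOneCompartment:
    def test_exact_recovery_noiseless(self):
        times = [0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0]
        df = _bateman_dataset(250.0, ka=1.07, kel=0.4, v=3.0, times=times)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flip-flop twin is expected
            fit = estimate.fit_one_compartment(df, dose=250.0)
        # the flip-flop twin (ka<->kel with V·kel/ka) is the same curve
        ka, kel = sorted([fit.ka, fit.kel], reverse=True)
        v = fit.v_over_f if fit.ka >= fit.kel else fit.v_over_f * fit.ka / fit.kel
        assert ka == pytest.approx(1.07, rel=1e-6)
        assert kel == pytest.approx(0.4, rel=1e-6)
        assert v == pytest.approx(3.0, rel=1e-6)
        assert fit.cl_tot_over_f == pytest.approx(fit.kel * fit.v_over_f, rel=1e-12)
        assert fit.auc_inf == pytest.approx(250.0 / fit.cl_tot_over_f, rel=1e-12)

    def test_flip_flop_warning_emitted(self):
        times = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
        df = _bateman_dataset(250.0, ka=2.0, kel=0.3, v=3.0, times=times)
        with pytest.warns(UserWarning, match="flip-flop"):
            estimate.fit_one_compartment(df, dose=250.0)

    def test_apparent_clearance_close_to_generator_truth(self, rat):
        """CL/F from the one-compartment analysis of full-PBPK data matches
        the generator's CL_tot/F within 10%."""
        nic, cot, phys, regimen = rat
        ds = synth.generate_rat_study(nic, cot, phys, regimen,
                                      noise_cv=0.0, n_animals=1, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = estimate.fit_one_compartment(ds, dose=250.0)
        cl_h, e_h = ivive.well_stirred_cl_h(phys.q_h, nic.fu_p, nic.cl_h_int, nic.rb)
        cl_tot_over_f = (cl_h + nic.cl_r) / (1.0 - e_h)
        assert fit.cl_tot_over_f == pytest.approx(cl_tot_over_f, rel=0.10)

    def test_degenerate_inputs_rejected(self):
        flat = _bateman_dataset(250.0, 1.0, 0.4, 3.0, [1.0, 2.0, 3.0, 4.0])
        flat["value"] = 0.0
        with pytest.raises(ValueError):
            estimate.fit_one_compartment(flat, dose=250.0)
        few = _bateman_dataset(250.0, 1.0, 0.4, 3.0, [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match=">= 4"):
            estimate.fit_one_compartment(few, dose=250.0)


class TestInitialPbpkParams:
    def test_renal_only_limit(self, rat):
        """CL_tot/F equal to CL_r implies zero hepatic clearance."""
        nic, _, phys, _ = rat
        fit = estimate.OneCompartmentFit(
            ka=1.0, kel=0.5, v_over_f=nic.cl_r / 0.5, auc_inf=1.0,
            cl_tot_over_f=nic.cl_r, rss=0.0, n=8,
        )
        out = estimate.initial_pbpk_params(fit, nic.cl_r, phys, nic)
        assert out.cl_h_int == pytest.approx(0.0, abs=1e-12)
        assert out.v1 == pytest.approx(fit.v_over_f)

    def test_round_trip_recovery(self, rat):
        """simulate → one-compartment fit → back-calculation recovers the
        generating CL_h,int within 15%."""
        nic, cot, phys, regimen = rat
        ds = synth.generate_rat_study(nic, cot, phys, regimen,
                                      noise_cv=0.0, n_animals=1, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = estimate.fit_one_compartment(ds, dose=250.0)
        out = estimate.initial_pbpk_params(fit, nic.cl_r, phys, nic)
        assert out.cl_h_int == pytest.approx(nic.cl_h_int, rel=0.15)
        assert out.v1 == pytest.approx(nic.v1, rel=0.15)


class TestFitPbpk:
    def test_noiseless_recovery_from_perturbed_start(self, rat):
        """Refitting noiseless synthetic data recovers the generating
        (CL_h,int, V_1, ka) within 1%, starting 30-50% off."""
        nic, cot, phys, regimen = rat
        ds = synth.generate_rat_study(nic, cot, phys, regimen,
                                      noise_cv=0.0, n_animals=1, seed=0)
        start = {
            "nicotine": nic.model_copy(update={"cl_h_int": 8.0, "v1": 0.5}),
            "cotinine": cot.model_copy(update={"cl_h_int": 0.3, "v1": 0.7}),
        }
        result = estimate.fit_pbpk(
            ds, start, phys, regimen.model_copy(update={"ka": 0.7}), n_starts=3
        )
        assert result.success
        assert result.ka == pytest.approx(1.07, rel=0.01)
        assert result.params["nicotine"].cl_h_int == pytest.approx(5.44, rel=0.01)
        assert result.params["nicotine"].v1 == pytest.approx(0.746, rel=0.01)
        assert result.params["cotinine"].cl_h_int == pytest.approx(0.208, rel=0.01)
        assert result.params["cotinine"].v1 == pytest.approx(0.451, rel=0.01)
        assert result.objective <= result.objective_start

    def test_no_free_parameters_returns_start(self, rat):
        nic, cot, phys, regimen = rat
        ds = synth.generate_rat_study(nic, cot, phys, regimen,
                                      noise_cv=0.0, n_animals=1, seed=0)
        start = {"nicotine": nic, "cotinine": cot}
        result = estimate.fit_pbpk(
            ds, start, phys, regimen,
            free={"nicotine": set(), "cotinine": set()},
        )
        assert result.params["nicotine"] == nic
        assert result.params["cotinine"] == cot
        assert result.objective == result.objective_start
        # truth generated the data, so the objective is numerically zero
        assert result.objective < 1e-10

    def test_unknown_free_parameter_rejected(self, rat):
        nic, cot, phys, regimen = rat
        ds = synth.generate_rat_study(nic, cot, phys, regimen,
                                      noise_cv=0.0, n_animals=1, seed=0)
        with pytest.raises(ValueError, match="unknown free"):
            estimate.fit_pbpk(ds, {"nicotine": nic}, phys, regimen,
                              free={"nicotine": {"kp_h"}})

    def test_joint_refinement_improves_combined_objective(self, rat):
        """The joint pass never worsens the combined objective and breaks the
        (ka, V_1) flip-flop ridge that sequential fitting leaves on sparse,
        censored nicotine data."""
        nic, cot, phys, regimen = rat
        ds = synth.generate_rat_study(nic, cot, phys, regimen,
                                      noise_cv=0.15, n_animals=5, seed=303)
        start = {
            "nicotine": nic.model_copy(update={"cl_h_int": 8.0, "v1": 1.1}),
            "cotinine": cot,
        }
        args = (start, phys, regimen.model_copy(update={"ka": 0.8}))
        seq = estimate.fit_pbpk(ds, *args, n_starts=3)
        joint = estimate.fit_pbpk(ds, *args, n_starts=3, joint_refine=True)
        assert joint.objective <= seq.objective + 1e-12
        truth_v1_err = abs(joint.params["nicotine"].v1 - nic.v1) / nic.v1
        seq_v1_err = abs(seq.params["nicotine"].v1 - nic.v1) / nic.v1
        assert truth_v1_err <= seq_v1_err

    def test_objective_decreases_with_noise(self, rat):
        nic, cot, phys, regimen = rat
        ds = synth.generate_rat_study(nic, cot, phys, regimen,
                                      noise_cv=0.15, n_animals=5, seed=7)
        start = {
            "nicotine": nic.model_copy(update={"cl_h_int": 9.0, "v1": 1.2}),
            "cotinine": cot,
        }
        result = estimate.fit_pbpk(ds, start, phys,
                                   regimen.model_copy(update={"ka": 0.6}),
                                   n_starts=2)
        assert result.objective < result.objective_start


def test_time_unit_invariance(rat):
    """Fitted clearances/volumes do not depend on the sampling grid density
    used to express the same underlying curve."""
    nic, cot, phys, regimen = rat
    coarse = synth.generate_rat_study(
        nic, cot, phys, regimen, noise_cv=0.0, n_animals=1, seed=0,
        sample_times=(0.25, 0.5, 1.0, 2.0, 4.0, 8.0),
    )
    dense = synth.generate_rat_study(
        nic, cot, phys, regimen, noise_cv=0.0, n_animals=1, seed=0,
        sample_times=(0.25, 0.4, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0),
    )
    start = {"nicotine": nic.model_copy(update={"cl_h_int": 7.0}), "cotinine": cot}
    fits = [
        estimate.fit_pbpk(ds, start, phys, regimen, n_starts=1,
                          free={"nicotine": {"cl_h_int", "v1"}})
        for ds in (coarse, dense)
    ]
    assert fits[0].params["nicotine"].cl_h_int == pytest.approx(
        fits[1].params["nicotine"].cl_h_int, rel=0.01
    )
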