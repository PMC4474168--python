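"""Non-compartmental analysis: AUC, terminal slope, clearance partition, occupancy time."""

import numpy as np
import pandas as pd
import pytest

import pedtmdd as pt
from pedtmdd.nca import NCAError, auc_trapezoid, lambda_z


def make_profile(t, c, occ=None, params=None):
    """Wrap arrays into a SimulationResult for metric functions."""
    data = {"time": np.asarray(t, float), "C": np.asarray(c, float), "A2": 0.0}
    if occ is not None:
        data["occupancy"] = np.asarray(occ, float)
    regimen = pt.DoseRegimen(mode="fixed", nominal=1.0, molar_dose=1.0)
    return pt.SimulationResult(
        data=pd.DataFrame(data), params=params or pt.make_reference_params(),
        regimen=regimen, kind="tmdd",
    )


class TestAUC:
    def test_exact_on_monoexponential(self):
        lam, c0 = 0.3, 12.0
        t = np.linspace(0.0, 40.0, 81)
        nca = pt.run_nca((t, c0 * np.exp(-lam * t)))
        assert nca.auc_0_inf == pytest.approx(c0 / lam, rel=1e-3)
        assert nca.lambda_z == pytest.approx(lam, rel=1e-6)
        assert nca.cmax == c0

    def test_linear_in_profile_scale(self):
        t = np.linspace(0.0, 40.0, 81)
        c = 5.0 * np.exp(-0.2 * t) + 2.0 * np.exp(-0.05 * t)
        a = pt.run_nca((t, c))
        b = pt.run_nca((t, 2.0 * c))
        assert b.auc_0_last == pytest.approx(2.0 * a.auc_0_last, rel=1e-12)
        assert b.auc_0_inf == pytest.approx(2.0 * a.auc_0_inf, rel=1e-10)

    def test_simulation_auc_matches_analytic_linear_model(self, ref_params, adult_regimen):
        p = ref_params.with_(kon=0.0, koff=0.0, kint=0.0)
        nca = pt.run_nca(pt.simulate_tmdd(p, adult_regimen))
        assert nca.auc_0_inf == pytest.approx(
            adult_regimen.molar_dose / (p.kel * p.v1), rel=5e-3
        )

    def test_grid_auc_matches_dense_quadrature(self, ref_params, adult_regimen):
        from scipy.integrate import trapezoid

        result = pt.simulate_tmdd(ref_params, adult_regimen)
        dense_grid = np.linspace(0.0, result.time[-1], 20001)
        dense = pt.simulate_tmdd(ref_params, adult_regimen, grid=dense_grid)
        auc_dense = trapezoid(dense.conc, dense.time)
        assert pt.run_nca(result).auc_0_last == pytest.approx(auc_dense, rel=5e-3)

    def test_log_down_segments_beat_linear_trapezoid_on_decay(self):
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        c = 10.0 * np.exp(-0.8 * t)
        exact = 10.0 / 0.8 * (1.0 - np.exp(-0.8 * 4.0))
        assert auc_trapezoid(t, c) == pytest.approx(exact, rel=1e-12)

    def test_all_zero_profile_not_estimable(self):
        with pytest.raises(NCAError):
            pt.run_nca((np.linspace(0, 10, 11), np.zeros(11)))

    def test_extrapolation_warning_flag(self):
        t = np.linspace(0.0, 2.0, 21)  # cut long before terminal decay
        c = 10.0 * np.exp(-0.1 * t)
        with pytest.warns(RuntimeWarning, match="extrapolated"):
            nca = pt.run_nca((t, c))
        assert nca.extrapolation_warning
        assert nca.extrapolated_fraction > 0.2


class TestLambdaZ:
    def test_recovers_terminal_slope_of_biexponential(self):
        t = np.linspace(0.0, 80.0, 161)
        c = 50.0 * np.exp(-1.0 * t) + 5.0 * np.exp(-0.07 * t)
        lz, n, _ = lambda_z(t, c)
        assert lz == pytest.approx(0.07, rel=1e-2)
        assert n >= 3

    def test_rejects_non_declining_tail(self):
        t = np.linspace(0.0, 10.0, 11)
        with pytest.raises(NCAError):
            lambda_z(t, np.ones(11) * 3.0 + 0.1 * t)


class TestClearancePartition:
    def test_linear_model_has_no_target_route(self, ref_params, adult_regimen):
        p = ref_params.with_(kon=0.0, koff=0.0, kint=0.0)
        nca = pt.run_nca(pt.simulate_tmdd(p, adult_regimen))
        part = pt.clearance_partition(adult_regimen.molar_dose, nca, p)
        assert part.cl_tot == pytest.approx(p.cl_linear, rel=5e-3)
        assert part.cl_fraction == pytest.approx(0.0, abs=5e-3)

    def test_half_linear_auc_means_half_target_route(self, ref_params):
        dose = 100.0
        cl_lin = ref_params.cl_linear
        t = np.linspace(0, 60, 121)
        lam = 0.2
        c0 = dose * lam / (cl_lin / 0.5) / 1.0  # AUC = c0/lam = dose/(cl_lin/0.5)
        nca = pt.run_nca((t, c0 * np.exp(-lam * t)))
        part = pt.clearance_partition(dose, nca, ref_params)
        assert part.cl_fraction == pytest.approx(0.5, rel=1e-2)

    def test_fraction_shrinks_with_dose(self, ref_params):
        subject = pt.Subject.from_age("18y")
        fractions = []
        for dose in (0.5, 4.5):
            regimen = pt.build_regimen(dose, "per_kg", subject)
            nca = pt.run_nca(pt.simulate_tmdd(ref_params, regimen))
            fractions.append(
                pt.clearance_partition(regimen.molar_dose, nca, ref_params).cl_fraction
            )
        assert fractions[1] < fractions[0]
        assert 0.0 <= fractions[1] < 1.0


class TestOccupancyDuration:
    def test_tent_profile_crossing_at_grid_points(self):
        # occupancy hits 0.9 exactly at t=2 and again at t=12 -> 10 days above
        profile = make_profile(
            [0.0, 2.0, 12.0, 14.0], np.ones(4), occ=[0.8, 0.9, 0.9, 0.7]
        )
        assert pt.occupancy_duration(profile, 0.9) == pytest.approx(10.0)

    def test_fractional_crossings(self):
        t = [0.0, 4.0, 12.0, 16.0]
        occ = [0.5, 0.98, 0.98, 0.5]
        profile = make_profile(t, np.ones(4), occ=occ)
        # up-crossing at t = 4*(0.4/0.48); down at 12 + 4*(0.08/0.48)
        t_up = 4.0 * (0.9 - 0.5) / 0.48
        t_down = 12.0 + 4.0 * (0.98 - 0.9) / 0.48
        assert pt.occupancy_duration(profile, 0.9) == pytest.approx(t_down - t_up, rel=1e-12)

    def test_never_reaching_threshold(self):
        profile = make_profile([0, 1, 2], np.ones(3), occ=[0.1, 0.5, 0.2])
        assert pt.occupancy_duration(profile, 0.9) == 0.0

    def test_zero_threshold_spans_horizon(self):
        profile = make_profile([0, 1, 5], np.ones(3), occ=[0.1, 0.5, 0.2])
        assert pt.occupancy_duration(profile, 0.0) == pytest.approx(5.0)

    def test_requires_occupancy_column(self, ref_params, adult_regimen):
        mm = pt.simulate_mm(pt.mm_from_micro(ref_params), adult_regimen)
        with pytest.raises(NCAError):
            pt.occupancy_duration(mm)


class TestAUCRatio:
    def test_identities(self):
        t = np.linspace(0, 40, 81)
        a = pt.run_nca((t, 10 * np.exp(-0.3 * t)))
        b = pt.run_nca((t, 5 * np.exp(-0.3 * t)))
        assert pt.auc_ratio(a, a) == 100.0
        assert pt.auc_ratio(b, a) == pytest.approx(50.0, rel=1e-10)
        assert pt.auc_ratio(a, b) * pt.auc_ratio(b, a) == pytest.approx(100.0**2, rel=1e-10)
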