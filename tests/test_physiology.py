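"""Steady-state detection, kinetics, gas conversions, FACS, ROS."""

import numpy as np
import pandas as pd
import pytest

from consortium_coupling.physiology import (
    GasConfig,
    Gate,
    PhysiologyError,
    SteadyStateWindow,
    TurbidostatLog,
    cmol_rate,
    detect_steady_state,
    dissolved_o2,
    facs_composition,
    growth_rate,
    min_window_rows,
    net_o2_rate,
    o2_sensitivity,
    percent_air_saturation,
    photosynthetic_quotient,
    ros_corrected,
)
from consortium_coupling.synthetic_data import (
    FacsTruth,
    KineticsParams,
    default_design,
    simulate_facs,
    simulate_ros_plate,
    simulate_turbidostat,
)

GAS = GasConfig()


def _constant_log(n=800, d=0.3, od=0.4, do2=100.0):
    df = pd.DataFrame(
        {
            "time_h": np.arange(n) / 60.0,
            "dilution_rate": np.full(n, d),
            "od730": np.full(n, od),
            "dissolved_o2_uM": np.full(n, do2),
            "offgas_o2_frac": np.full(n, 0.05),
            "offgas_co2_frac": np.full(n, 0.03),
        }
    )
    return TurbidostatLog(
        df=df,
        condition="X",
        gas_flow_L_h=30.0,
        volume_L=5.5,
        biomass_g_L=0.25,
        inlet_o2_frac=0.0,
    )


class TestSteadyStateDetection:
    def test_constant_channels_whole_log(self):
        log = _constant_log()
        window = detect_steady_state(log)
        assert window is not None
        assert (window.start, window.end) == (0, len(log))

    def test_minimum_window_is_604_rows_at_fastest_residence_time(self):
        # tau = 1 / 0.2976 = 3.36 h -> floor(3 * 3.36 * 60) = 604 rows
        assert min_window_rows(1.0 / 0.2976) == 604
        log = _constant_log(n=604, d=0.2976)
        window = detect_steady_state(log)
        assert window is not None and window.n_rows == 604
        short = _constant_log(n=603, d=0.2976)
        assert detect_steady_state(short) is None

    def test_step_change_excluded_from_window(self):
        log = _constant_log(n=1600, d=0.2)
        log.df.loc[:399, "od730"] = 1.2  # pre-step rows violate 10% stability
        window = detect_steady_state(log)
        assert window is not None
        assert window.start == 400

    def test_never_shorter_than_three_residence_times(self):
        for d in (0.1, 0.2, 0.3):
            log = _constant_log(n=int(3.5 * 60 / d), d=d)
            window = detect_steady_state(log)
            assert window is not None
            assert window.n_rows >= min_window_rows(1.0 / d)

    def test_unstable_log_returns_none(self):
        rng = np.random.default_rng(0)
        log = _constant_log(n=800)
        log.df["dilution_rate"] = 0.3 * (1 + 0.5 * rng.standard_normal(800))
        log.df["dilution_rate"] = log.df["dilution_rate"].abs()
        assert detect_steady_state(log) is None


class TestGrowthAndCmol:
    def test_doubling_time_identities(self):
        log = _constant_log(d=np.log(2))
        window = detect_steady_state(log)
        rate = growth_rate(log, window)
        assert rate.doubling_time_h == pytest.approx(1.0)
        log2 = _constant_log(d=0.289)
        rate2 = growth_rate(log2, detect_steady_state(log2))
        assert rate2.doubling_time_h == pytest.approx(2.398, abs=0.005)

    def test_cmol_rate_formula_weight(self):
        # CH1.8O0.5N0.2 weighs 24.626 g per Cmol
        assert GAS.grams_per_cmol == pytest.approx(24.6263, abs=0.001)
        assert cmol_rate(0.289, GAS) == pytest.approx(11.73, abs=0.01)
        assert cmol_rate(0.0, GAS) == 0.0

    def test_cmol_inverse_proportional_to_formula_weight(self):
        heavy = GasConfig(biomass_composition={"C": 1.0, "H": 3.6, "O": 1.0, "N": 0.4})
        assert heavy.grams_per_cmol == pytest.approx(2 * GAS.grams_per_cmol - 12.011, abs=0.01)
        doubled = GasConfig(
            biomass_composition={k: 2 * v for k, v in GAS.biomass_composition.items()}
        )
        assert cmol_rate(0.3, doubled) == pytest.approx(cmol_rate(0.3, GAS) / 2)


class TestNetO2:
    def test_zero_balance(self):
        log = _constant_log(do2=0.0)
        log.df["offgas_o2_frac"] = log.inlet_o2_frac
        window = detect_steady_state(log)
        assert net_o2_rate(log, window, GAS) == pytest.approx(0.0)

    def test_doubling_biomass_halves_specific_rate(self):
        log = _constant_log()
        window = detect_steady_state(log)
        q1 = net_o2_rate(log, window, GAS)
        log.biomass_g_L *= 2
        assert net_o2_rate(log, window, GAS) == pytest.approx(q1 / 2)


class TestSimulatorClosure:
    """Noise-free logs must return the configured parameters exactly."""

    @pytest.mark.parametrize("culture", ["axenic", "binary"])
    def test_mu_q_sensitivity_pq_closure(self, culture):
        params = (
            KineticsParams.axenic(noise_rel=0.0)
            if culture == "axenic"
            else KineticsParams.binary(noise_rel=0.0)
        )
        design = default_design(culture)
        sens_points, pq_points = [], []
        for label in ("HL-LO", "HL-MO", "HL-HO"):
            cond = design.condition(label)
            log = simulate_turbidostat(params, cond, 16.0, 1)
            window = detect_steady_state(log)
            mu = growth_rate(log, window).mu
            assert abs(mu - params.mu(cond)) <= 1e-9 * params.mu(cond)
            q = net_o2_rate(log, window, params.gas)
            q_model = cmol_rate(params.mu(cond), params.gas) / params.pq
            assert abs(q - q_model) <= 1e-9 * q_model
            sens_points.append((cond.pO2, mu))
            pq_points.append((q, cmol_rate(mu, params.gas)))
        fit = o2_sensitivity(sens_points)
        assert fit.slope_abs == pytest.approx(params.sensitivity, rel=1e-9)
        assert fit.se == pytest.approx(0.0, abs=1e-9)
        slope, se = photosynthetic_quotient(pq_points)
        assert slope == pytest.approx(params.pq, rel=1e-9)


class TestFits:
    def test_exact_line_slope_and_zero_se(self):
        slope, se = photosynthetic_quotient([(0.5, 1.0), (1.0, 2.0), (1.5, 3.0)])
        assert slope == pytest.approx(2.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_point_degenerate(self):
        with pytest.raises(PhysiologyError):
            photosynthetic_quotient([(1.0, 2.0), (1.0, 2.0)])

    def test_collinear_sensitivity_example(self):
        fit = o2_sensitivity([(0.0, 0.30), (0.30, 0.2742), (0.59, 0.24926)])
        assert fit.slope_abs == pytest.approx(0.086, abs=1e-12)
        assert fit.se == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.30)

    def test_constant_mu_zero_slope(self):
        fit = o2_sensitivity([(0.0, 0.25), (0.3, 0.25), (0.6, 0.25)])
        assert fit.slope_abs == pytest.approx(0.0, abs=1e-12)

    def test_identical_po2_rejected(self):
        with pytest.raises(PhysiologyError):
            o2_sensitivity([(0.3, 0.2), (0.3, 0.21), (0.3, 0.22)])

    def test_se_shrinks_with_replication(self):
        rng = np.random.default_rng(0)
        ses = []
        for n_rep in (3, 30, 300):
            pts = []
            for _ in range(n_rep):
                for po2 in (0.0, 0.3, 0.59):
                    pts.append((po2, 0.3 - 0.1 * po2 + rng.normal(0, 0.005)))
            ses.append(o2_sensitivity(pts).se)
        assert ses[1] < ses[0] and ses[2] < ses[1]
        # roughly 1/sqrt(n): a decade of replication shrinks SE ~3.2x
        assert ses[0] / ses[1] == pytest.approx(np.sqrt(10), rel=0.5)
        assert ses[1] / ses[2] == pytest.approx(np.sqrt(10), rel=0.5)


class TestGasConversions:
    def test_maximum_treatment_values(self):
        assert round(dissolved_o2(0.59, GAS)) == 366
        assert round(percent_air_saturation(0.59, GAS)) == 281

    def test_air_saturation_identity(self):
        assert dissolved_o2(GAS.atm_o2_fraction, GAS) == pytest.approx(GAS.air_sat_conc_uM)
        assert percent_air_saturation(GAS.atm_o2_fraction, GAS) == pytest.approx(100.0)
        assert dissolved_o2(0.0, GAS) == 0.0

    def test_linearity_and_ratio(self):
        for po2 in (0.01, 0.2, 0.45, 0.8):
            assert dissolved_o2(po2, GAS) / percent_air_saturation(po2, GAS) == pytest.approx(
                GAS.air_sat_conc_uM / 100.0
            )


class TestFacsComposition:
    def test_default_gates_recover_composition(self):
        truth = FacsTruth()
        events = simulate_facs(truth, 50_000, 1)
        comp = facs_composition(events, truth.default_gates())
        assert comp["cyanobacterium"] == pytest.approx(90.2, abs=0.5)
        assert comp["heterotroph"] == pytest.approx(9.1, abs=0.5)

    def test_gate_assignment_agrees_with_truth_labels(self):
        truth = FacsTruth()
        events = simulate_facs(truth, 50_000, 2)
        gates = truth.default_gates()
        assigned = np.select(
            [gates[name].contains(events) for name in gates], list(gates), "ungated"
        )
        agreement = (assigned == events["truth_label"]).mean()
        assert agreement >= 0.999

    def test_all_events_in_one_gate(self):
        events = pd.DataFrame(
            {"fsc": [10.0, 11.0], "ssc": [10.0, 12.0], "red_fl": 0.0, "green_fl": 0.0}
        )
        gates = {"only": Gate(fsc=(0, 20), ssc=(0, 20))}
        comp = facs_composition(events, gates)
        assert comp["only"] == 100.0
        assert comp["ungated"] == 0.0

    def test_overlapping_gates_rejected(self):
        gates = {
            "a": Gate(fsc=(0, 10), ssc=(0, 10)),
            "b": Gate(fsc=(5, 15), ssc=(5, 15)),
        }
        events = pd.DataFrame({"fsc": [1.0], "ssc": [1.0], "red_fl": 0.0, "green_fl": 0.0})
        with pytest.raises(PhysiologyError, match="overlap"):
            facs_composition(events, gates)


class TestRosCorrected:
    def test_background_subtraction(self):
        plate = pd.DataFrame(
            {
                "group": ["a"] * 3,
                "replicate": [1, 2, 3],
                "treated": [1000.0, 1010.0, 990.0],
                "control": [200.0, 210.0, 190.0],
            }
        )
        summary = ros_corrected(plate)
        assert summary.group_stats.loc["a", "mean"] == pytest.approx(800.0)

    def test_identical_groups_rarely_significant(self):
        # type-I control at alpha = 0.01: allow at most one flagged seed in ten
        flagged = 0
        for seed in range(1, 11):
            plate = simulate_ros_plate(
                {"a": 500.0, "b": 500.0}, control_mean=200.0, sd=30.0, n_reps=3, seed=seed
            )
            summary = ros_corrected(plate, alpha=0.01)
            flagged += int(summary.pairwise["significant"].any())
        assert flagged <= 1

    def test_widely_separated_groups_flagged(self):
        plate = simulate_ros_plate(
            {"low": 300.0, "high": 1500.0}, control_mean=200.0, sd=20.0, n_reps=3, seed=1
        )
        summary = ros_corrected(plate, alpha=0.01)
        assert summary.pairwise["significant"].all()

    def test_unmatched_wells_rejected(self):
        plate = pd.DataFrame(
            {
                "group": ["a", "a"],
                "replicate": [1, 2],
                "treated": [1000.0, 1010.0],
                "control": [200.0, np.nan],
            }
        )
        with pytest.raises(PhysiologyError, match="unmatched|missing"):
            ros_corrected(plate)
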