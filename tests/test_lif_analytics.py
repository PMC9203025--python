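"""Closed-form deterministic LIF theory against hand values and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gabafire import (
    LIFParams,
    RegimeLabel,
    SynapticDrive,
    build_phase_diagram,
    classify_regime,
    critical_EGABA,
    deterministic_rate,
    effective_input,
    firing_onset_gGlu,
    rate_derivative_gGABA,
    regime_summary,
    silencing_conductance,
)


class TestEffectiveInput:
    @pytest.mark.parametrize(
        "g_Glu, g_GABA, E_GABA, g_eff, E_eff",
        [
            (0.0, 0.0, -80.0, 1.0, -80.0),                 # leak only
            (0.4, 0.0, -80.0, 1.4, -80.0 / 1.4),           # hand evaluation
            (0.4, 0.6, -65.0, 2.0, (-80 - 39.0) / 2.0),    # mixed drive
        ],
    )
    def test_hand_values(self, lif, g_Glu, g_GABA, E_GABA, g_eff, E_eff):
        eff = effective_input(lif, SynapticDrive(g_Glu, g_GABA, E_GABA))
        assert eff.g_eff == pytest.approx(g_eff)
        assert eff.E_eff == pytest.approx(E_eff)
        assert eff.tau_eff == pytest.approx(lif.tau / g_eff)

    def test_large_gaba_limit(self, lif):
        eff = effective_input(lif, SynapticDrive(g_Glu=0.4, g_GABA=1e8, E_GABA=-63.0))
        assert eff.E_eff == pytest.approx(-63.0, abs=1e-5)

    @given(
        g_Glu=st.floats(0, 5), g_GABA=st.floats(0, 5), E_GABA=st.floats(-90, -50)
    )
    @settings(max_examples=200, deadline=None)
    def test_Eeff_bounded_by_reversals(self, g_Glu, g_GABA, E_GABA):
        lif = LIFParams()
        eff = effective_input(lif, SynapticDrive(g_Glu, g_GABA, E_GABA))
        lo = min(lif.E_L, E_GABA, lif.E_Glu)
        hi = max(lif.E_L, E_GABA, lif.E_Glu)
        assert lo - 1e-9 <= eff.E_eff <= hi + 1e-9
        assert eff.g_eff >= 1.0


class TestDeterministicRate:
    def test_hand_value(self, lif):
        # g_eff/tau / ln(4.5) with g_Glu = 0.4
        rate = deterministic_rate(lif, SynapticDrive(g_Glu=0.4))
        assert rate == pytest.approx(1000 * 1.4 / 20 / np.log(4.5), rel=1e-12)
        assert rate == pytest.approx(46.54, abs=0.01)

    def test_zero_at_and_below_onset(self, lif):
        onset = firing_onset_gGlu(lif)
        assert onset == pytest.approx(1 / 3)
        assert deterministic_rate(lif, SynapticDrive(g_Glu=onset)) == 0.0
        assert deterministic_rate(lif, SynapticDrive(g_Glu=onset - 1e-6)) == 0.0
        assert deterministic_rate(lif, SynapticDrive(g_Glu=onset + 1e-6)) > 0.0

    def test_monotone_in_gGlu(self, lif):
        rates = [
            deterministic_rate(lif, SynapticDrive(g_Glu=g))
            for g in np.linspace(0.34, 3.0, 40)
        ]
        assert np.all(np.diff(rates) > 0)

    def test_zero_iff_subthreshold(self, lif, rng):
        for _ in range(200):
            drive = SynapticDrive(
                g_Glu=rng.uniform(0, 2), g_GABA=rng.uniform(0, 3),
                E_GABA=rng.uniform(-85, -52),
            )
            rate = deterministic_rate(lif, drive)
            firing = effective_input(lif, drive).E_eff > lif.E_thr
            assert (rate > 0) == firing


class TestSilencingConductance:
    def test_hand_value(self, lif):
        assert silencing_conductance(lif, 0.4, -63.0) == pytest.approx(4 / 3)

    def test_silences_exactly(self, lif):
        gs = silencing_conductance(lif, 0.4, -63.0)
        assert deterministic_rate(lif, SynapticDrive(0.4, gs + 1e-9, -63.0)) == 0.0
        assert deterministic_rate(lif, SynapticDrive(0.4, gs - 1e-4, -63.0)) > 0.0

    def test_divergence_near_threshold(self, lif):
        assert silencing_conductance(lif, 0.4, -60.001) > 1e3
        assert silencing_conductance(lif, 0.4, -59.0) == np.inf
        with pytest.raises(ValueError):
            silencing_conductance(lif, 0.4, lif.E_thr)

    def test_subthreshold_drive_already_silent(self, lif):
        assert silencing_conductance(lif, 0.1, -70.0) == 0.0

    def test_scaling_collapse(self, lif):
        """g_s * (E_thr - E_GABA) is independent of E_GABA, and g_s is affine in g_Glu."""
        vals = [
            silencing_conductance(lif, 0.5, E) * (lif.E_thr - E)
            for E in (-75.0, -68.0, -61.0)
        ]
        assert np.allclose(vals, vals[0])
        g = np.array([silencing_conductance(lif, gg, -65.0) for gg in (0.4, 0.8, 1.2)])
        assert np.diff(g, 2) == pytest.approx(0.0, abs=1e-12)


class TestRateDerivative:
    def test_matches_finite_difference(self, lif, rng):
        h = 1e-5
        for _ in range(50):
            drive = SynapticDrive(
                g_Glu=rng.uniform(0.4, 2), g_GABA=rng.uniform(0, 1),
                E_GABA=rng.uniform(-80, -52),
            )
            if effective_input(lif, drive).E_eff < lif.E_thr + 0.5:
                continue
            r_plus = deterministic_rate(
                lif, SynapticDrive(drive.g_Glu, drive.g_GABA + h, drive.E_GABA)
            )
            r_minus = deterministic_rate(
                lif, SynapticDrive(drive.g_Glu, max(drive.g_GABA - h, 0), drive.E_GABA)
            )
            fd = (r_plus - r_minus) / (h + min(drive.g_GABA, h))
            assert rate_derivative_gGABA(lif, drive) == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_E_GABA_at_E_eff_gives_pure_conductance_term(self, lif):
        # choosing E_GABA = E_eff(g_GABA=0) keeps E_eff fixed for any g_GABA,
        # so the reversal-potential term vanishes and the slope is nu/g_eff
        E = effective_input(lif, SynapticDrive(g_Glu=0.5)).E_eff
        drive = SynapticDrive(g_Glu=0.5, g_GABA=0.3, E_GABA=E)
        eff = effective_input(lif, drive)
        assert eff.E_eff == pytest.approx(E)
        nu = deterministic_rate(lif, drive)
        slope = rate_derivative_gGABA(lif, drive)
        assert slope == pytest.approx(nu / eff.g_eff)
        assert slope > 0

    def test_hyperpolarized_reversal_is_inhibitory(self, lif):
        drive = SynapticDrive(g_Glu=1.0, g_GABA=0.2, E_GABA=-85.0)
        assert rate_derivative_gGABA(lif, drive) < 0

    def test_non_firing_point_raises(self, lif):
        with pytest.raises(ValueError):
            rate_derivative_gGABA(lif, SynapticDrive(g_Glu=0.1, E_GABA=-70.0))


class TestCriticalEGABA:
    def test_threshold_limit_at_onset(self, lif):
        assert critical_EGABA(lif, firing_onset_gGlu(lif) + 1e-7) == pytest.approx(
            lif.E_thr, abs=1e-3
        )

    def test_large_drive_limit(self, lif):
        # converges towards (E_reset + E_thr)/2 (exact limit differs by
        # ~0.26 mV because E_eff saturates at E_Glu)
        e3, e4 = critical_EGABA(lif, 1e3), critical_EGABA(lif, 1e4)
        assert abs(e4 - e3) < 0.01
        assert e4 == pytest.approx((lif.E_reset + lif.E_thr) / 2, abs=0.5)

    def test_zero_slope_at_critical_reversal(self, lif):
        for g_Glu in (0.4, 0.8, 1.5):
            Ec = critical_EGABA(lif, g_Glu)
            slope = rate_derivative_gGABA(lif, SynapticDrive(g_Glu=g_Glu, E_GABA=Ec))
            assert slope == pytest.approx(0.0, abs=1e-9)

    def test_monotone_decreasing_and_bounded(self, lif):
        g = np.linspace(0.35, 20.0, 60)
        Ec = np.array([critical_EGABA(lif, gg) for gg in g])
        assert np.all(np.diff(Ec) < 0)
        assert np.all(Ec <= lif.E_thr)
        assert np.all(Ec >= (lif.E_reset + lif.E_thr) / 2)

    def test_subthreshold_raises(self, lif):
        with pytest.raises(ValueError):
            critical_EGABA(lif, 0.2)


class TestRegimeSummary:
    def test_inhibitory_point(self, lif):
        s = regime_summary(lif, 0.4, -75.0)
        assert s.g_star == pytest.approx(0.0, abs=1e-4)
        assert s.strength_ratio == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self, lif):
        g_Glu, E_GABA = 0.4, -62.0
        gs = silencing_conductance(lif, g_Glu, E_GABA)
        grid = np.arange(0.0, gs, 1e-4)
        rates = [deterministic_rate(lif, SynapticDrive(g_Glu, g, E_GABA)) for g in grid]
        g_star_oracle = grid[int(np.argmax(rates))]
        s = regime_summary(lif, g_Glu, E_GABA)
        assert s.g_star == pytest.approx(g_star_oracle, abs=1e-3)
        assert s.nu_max >= max(rates) - 1e-6

    def test_ratio_grows_near_threshold(self, lif):
        ratios = [
            regime_summary(lif, 0.4, E).strength_ratio
            for E in (-62.0, -61.0, -60.2, -60.05)
        ]
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] > 5.0

    def test_gaba_activated_ratio_is_infinite(self, lif):
        s = regime_summary(lif, 0.1, -50.0, g_GABA_max=50.0)
        assert s.nu_init == 0.0 and s.nu_max > 0
        assert np.isinf(s.strength_ratio)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "g_Glu, E_GABA, expected",
        [
            (0.4, -75.0, RegimeLabel.INHIBITORY),
            (0.4, -62.0, RegimeLabel.NON_MONOTONIC),
            (0.1, -50.0, RegimeLabel.GABA_ACTIVATED),
            (0.1, -70.0, RegimeLabel.SILENT),
            (0.8, -55.0, RegimeLabel.EXCITATORY),
        ],
    )
    def test_examples(self, lif, g_Glu, E_GABA, expected):
        assert classify_regime(lif, g_Glu, E_GABA) is expected

    def test_agrees_with_brute_force_curve(self, lif, rng):
        """Label from a dense rate-vs-g_GABA evaluation matches the analytic rule."""
        checked = 0
        while checked < 100:
            g_Glu = rng.uniform(0.0, 2.0)
            E_GABA = rng.uniform(-80.0, -50.0)
            if abs(E_GABA - lif.E_thr) < 0.05 or abs(g_Glu - 1 / 3) < 0.01:
                continue  # skip measure-zero boundaries
            label = classify_regime(lif, g_Glu, E_GABA)
            if E_GABA < lif.E_thr:
                g_max = max(2 * silencing_conductance(lif, g_Glu, E_GABA), 1.0)
            else:
                g_max = 50.0
            grid = np.linspace(0, g_max, 2000)
            rates = np.array(
                [deterministic_rate(lif, SynapticDrive(g_Glu, g, E_GABA)) for g in grid]
            )
            k = int(np.argmax(rates))
            if rates[0] == 0.0:
                brute = (
                    RegimeLabel.GABA_ACTIVATED if rates[-1] > 0 else RegimeLabel.SILENT
                )
            elif k == 0:
                brute = RegimeLabel.INHIBITORY
            elif rates[-1] >= rates[k] - 1e-9:
                brute = RegimeLabel.EXCITATORY
            else:
                brute = RegimeLabel.NON_MONOTONIC
            assert label is brute, (g_Glu, E_GABA, label, brute)
            checked += 1


@pytest.fixture(scope="module")
def diagram(lif):
    return build_phase_diagram(
        lif,
        E_GABA_axis=np.arange(-80.0, -50.0 + 1e-9, 0.5),
        g_Glu_axis=np.arange(0.0, 2.0 + 1e-9, 0.1),
    )


class TestPhaseDiagram:
    def test_hyperpolarized_column_inhibitory(self, lif, diagram):
        j = int(np.argmin(np.abs(diagram.E_GABA_axis + 80.0)))
        supra = diagram.g_Glu_axis > firing_onset_gGlu(lif)
        assert all(
            lab is RegimeLabel.INHIBITORY for lab in diagram.labels[supra, j]
        )

    def test_boundary_brackets_critical_curve(self, lif, diagram):
        onset = firing_onset_gGlu(lif)
        for i, gE in enumerate(diagram.g_Glu_axis):
            if gE <= onset:
                continue
            row = diagram.labels[i]
            flips = [
                (diagram.E_GABA_axis[j], diagram.E_GABA_axis[j + 1])
                for j in range(len(row) - 1)
                if row[j] is RegimeLabel.INHIBITORY
                and row[j + 1] is RegimeLabel.NON_MONOTONIC
            ]
            assert len(flips) == 1
            lo, hi = flips[0]
            assert lo <= critical_EGABA(lif, gE) <= hi

    def test_nonmonotonic_band_within_5mV_of_threshold(self, lif, diagram):
        mask = np.vectorize(lambda lab: lab is RegimeLabel.NON_MONOTONIC)(diagram.labels)
        egaba = np.broadcast_to(diagram.E_GABA_axis, mask.shape)[mask]
        assert np.all(egaba > lif.E_thr - 5.0)
        assert np.all(egaba < lif.E_thr)

    def test_labels_consistent_with_slope(self, diagram, lif):
        for i in range(len(diagram.g_Glu_axis)):
            for j in range(len(diagram.E_GABA_axis)):
                lab = diagram.labels[i, j]
                s = diagram.slope0[i, j]
                if lab is RegimeLabel.NON_MONOTONIC:
                    assert s > 0 and diagram.E_GABA_axis[j] < lif.E_thr

    def test_round_trip_csv(self, diagram, tmp_path):
        diagram.save(tmp_path / "pd.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "pd.csv")
        assert len(df) == diagram.labels.size
        assert set(df.columns) >= {
            "E_GABA_mV", "g_Glu", "label", "slope0_Hz", "g_star",
            "nu_init_Hz", "nu_max_Hz", "strength_ratio",
        }
        assert (tmp_path / "pd.json").exists()
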