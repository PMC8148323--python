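import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vapordose.errors import InvalidArgumentError
from vapordose.puff_profiles import build_nasal_cycle, build_puff
from vapordose.room_exposure import (
    RoomScenario,
    bystander_inhaled_mass,
    nominal_ach,
    simulate_room,
)


def pulse_emission(mass, duration=0.1, dt=0.005):
    w = build_puff("custom", duration, mass, dt=dt)  # reuse unit-area shape
    return (w.times, w.flow)


class TestNominalACH:
    def test_reference_flow_implies_2_4_per_hour(self):
        # 0.018 m^3/s into 27 m^3
        assert nominal_ach(RoomScenario()) == pytest.approx(2.4)

    def test_zero_flow(self):
        assert nominal_ach(RoomScenario(ventilation_flow=0.0)) == 0.0

    def test_flow_consistent_with_declared_0_6(self):
        s = RoomScenario(ventilation_flow=0.0045, declared_ach=0.6)
        assert nominal_ach(s) == pytest.approx(0.6)

    def test_inconsistent_declared_ach_warns(self, caplog):
        s = RoomScenario(ventilation_flow=0.018, declared_ach=0.6)
        with caplog.at_level("WARNING"):
            nominal_ach(s)
        assert any("disagrees" in r.message for r in caplog.records)


class TestSimulateRoom:
    def test_zero_emission_all_zero(self):
        s = RoomScenario()
        out = simulate_room(s, None, window=5.0, dt=0.01)
        assert np.all(out.C_near == 0) and np.all(out.C_far == 0)
        assert out.inhaled_mass == 0.0

    def test_well_mixed_pulse_exponential_decay(self):
        # C(t) = (M/V) exp(-Q t / V); check inventory at one nominal time
        # constant and the regressed decay rate
        s = RoomScenario()
        M = 1e-6
        tau = s.volume / s.ventilation_flow
        out = simulate_room(s, pulse_emission(M), window=tau + 1.0, dt=0.05, mode="well_mixed")
        i = int(np.argmin(np.abs(out.times - (tau + 0.05))))  # pulse centred at 0.05 s
        inventory = out.C_far[i] * s.volume
        assert inventory == pytest.approx(M / np.e, rel=1e-3)
        # log-linear regression on the tail
        mask = out.times > 1.0
        slope = np.polyfit(out.times[mask], np.log(out.C_far[mask]), 1)[0]
        assert -slope == pytest.approx(s.ventilation_flow / s.volume, rel=1e-3)

    def test_soft_exhalation_never_reaches_bystander(self):
        # no direct transfer and no time for interzonal exchange: zero dose
        s = RoomScenario(direct_transfer_fraction=0.0, interzonal_flow=0.0)
        cycle = build_nasal_cycle(6e-3, 4.0)
        out = simulate_room(s, pulse_emission(1e-6), cycle=cycle, window=12.0, dt=0.005)
        assert out.inhaled_mass == 0.0

    def test_two_zone_mass_closure(self):
        s = RoomScenario()
        cycle = build_nasal_cycle(6e-3, 4.0)
        out = simulate_room(s, pulse_emission(1e-6), cycle=cycle, window=12.0, dt=0.005)
        assert out.closure_error(s) < 1e-6

    @given(
        f_d=st.floats(0.0, 1.0),
        beta=st.floats(0.0, 0.01),
        q=st.floats(0.0, 0.05),
        vn=st.floats(0.001, 1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_mass_closure_over_random_scenarios(self, f_d, beta, q, vn):
        s = RoomScenario(
            direct_transfer_fraction=f_d,
            interzonal_flow=beta,
            ventilation_flow=q,
            near_field_volume=vn,
        )
        cycle = build_nasal_cycle(6e-3, 4.0)
        out = simulate_room(s, pulse_emission(1e-6), cycle=cycle, window=10.0, dt=0.01)
        assert out.closure_error(s) < 1e-6

    def test_inhaled_monotone_nonincreasing_in_ventilation(self):
        cycle = build_nasal_cycle(6e-3, 4.0)
        doses = []
        for q in (0.0, 0.018, 0.1, 0.5):
            s = RoomScenario(ventilation_flow=q)
            out = simulate_room(s, pulse_emission(1e-6), cycle=cycle, window=12.0, dt=0.01)
            doses.append(out.inhaled_mass)
        assert np.all(np.diff(doses) <= 1e-15)


class TestBystanderInhaledMass:
    def test_constant_concentration_gives_c_times_volume(self):
        s = RoomScenario()
        cycle = build_nasal_cycle(6e-3, 4.0)
        times = np.arange(0.0, 12.0 + 1e-9, 0.001)
        c = 2.0e-6
        from vapordose.room_exposure import ExposureSeries

        series = ExposureSeries(
            times=times,
            C_far=np.full_like(times, c),
            C_near=np.full_like(times, c),
            inhaled_cumulative=np.zeros_like(times),
            exhausted_cumulative=np.zeros_like(times),
            emitted_cumulative=np.zeros_like(times),
        )
        got = bystander_inhaled_mass(series, cycle, (0.0, 12.0))
        inhaled_air = 3 * cycle.tidal_volume  # three breaths in 12 s
        assert got == pytest.approx(c * inhaled_air, rel=1e-4)

    def test_zero_concentration_zero_mass(self):
        cycle = build_nasal_cycle(6e-3, 4.0)
        times = np.arange(0.0, 12.0 + 1e-9, 0.01)
        from vapordose.room_exposure import ExposureSeries

        series = ExposureSeries(
            times=times,
            C_far=np.zeros_like(times),
            C_near=np.zeros_like(times),
            inhaled_cumulative=np.zeros_like(times),
            exhausted_cumulative=np.zeros_like(times),
            emitted_cumulative=np.zeros_like(times),
        )
        assert bystander_inhaled_mass(series, cycle, (0.0, 12.0)) == 0.0

    def test_window_outside_support_rejected(self):
        cycle = build_nasal_cycle(6e-3, 4.0)
        s = RoomScenario()
        out = simulate_room(s, pulse_emission(1e-6), window=5.0, dt=0.01)
        with pytest.raises(InvalidArgumentError):
            bystander_inhaled_mass(out, cycle, (0.0, 50.0))


def test_invalid_scenarios_rejected():
    with pytest.raises(InvalidArgumentError):
        RoomScenario(volume=-1.0)
    with pytest.raises(InvalidArgumentError):
        RoomScenario(near_field_volume=30.0)  # exceeds room volume
    with pytest.raises(InvalidArgumentError):
        RoomScenario(direct_transfer_fraction=1.5)
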