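import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from safy.params import SafyParameters
from safy.simulate import (
    SafyState,
    leaf_partition,
    light_interception,
    run_safy,
    step,
    temperature_stress,
)

from .reference import naive_safy


class TestLightInterception:
    def test_closed_form(self):
        assert light_interception(0.0, 0.5) == 0.0
        assert light_interception(2.0, 0.5) == pytest.approx(1 - math.exp(-1), abs=1e-12)
        assert light_interception(1e6, 0.5) == pytest.approx(1.0)

    def test_strictly_increasing_in_lai(self):
        lai = np.linspace(0, 10, 200)
        vals = light_interception(lai, 0.6)
        assert (np.diff(vals) > 0).all()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError):
            light_interception(-0.1, 0.5)


class TestTemperatureStress:
    def test_cardinal_anchors(self):
        p = SafyParameters()
        assert temperature_stress(p.t_opt, p) == 1.0
        assert temperature_stress(p.t_min, p) == 0.0
        assert temperature_stress(p.t_min - 5, p) == 0.0
        assert temperature_stress(p.t_max, p) == 0.0
        assert temperature_stress(p.t_max + 5, p) == 0.0

    def test_midway_linear_shape(self):
        # with beta_t = 1 the rise is linear: midway between t_min and t_opt -> 0.5
        p = SafyParameters(beta_t=1.0)
        assert temperature_stress((p.t_min + p.t_opt) / 2, p) == pytest.approx(0.5)

    def test_bounded_and_continuous(self):
        p = SafyParameters()
        t = np.linspace(-10, 50, 2001)
        v = temperature_stress(t, p)
        assert ((v >= 0) & (v <= 1)).all()
        assert np.abs(np.diff(v)).max() < 0.01  # no jumps on a fine grid

    def test_inconsistent_cardinals_rejected(self):
        with pytest.raises(ValueError):
            SafyParameters(t_min=20.0, t_opt=15.0)


class TestLeafPartition:
    def test_examples(self):
        assert leaf_partition(500.0, 0.2, 0.002) == pytest.approx(1 - 0.2 * math.e, abs=1e-12)
        assert leaf_partition(1e5, 0.2, 0.002) == 0.0  # raw value < 0 clips
        assert leaf_partition(1234.0, 0.0, 0.002) == 1.0

    def test_non_increasing(self):
        smt = np.linspace(0, 3000, 500)
        assert (np.diff(leaf_partition(smt, 0.15, 0.002)) <= 0).all()


class TestStep:
    def test_no_radiation_means_no_growth(self):
        p = SafyParameters(d0=10, stt=900)
        s = SafyState(day=50, dam=100.0, lai=2.0, gy=0.0, smt=500.0, senescent=False)
        s2 = step(s, rg=0.0, ta=15.0, params=p)
        assert s2.dam == s.dam
        assert s2.lai == s.lai  # smt < stt: no senescence either

    def test_growth_increment_hand_chained(self):
        # at t_opt, with Pl forced to 1 (pl_a=0), dLAI+ = rg*eps_c*(1-e^-k*lai)*elue*sla
        p = SafyParameters(d0=10, pl_a=0.0, stt=5000)
        s = SafyState(day=50, dam=100.0, lai=2.0, gy=0.0, smt=500.0, senescent=False)
        s2 = step(s, rg=20.0, ta=p.t_opt, params=p)
        d_dam = 20.0 * p.eps_c * (1 - math.exp(-p.k_ext * 2.0)) * p.elue
        assert s2.dam - s.dam == pytest.approx(d_dam, rel=1e-12)
        assert s2.lai - s.lai == pytest.approx(d_dam * p.sla, rel=1e-12)

    def test_senescence_hand_computed(self):
        p = SafyParameters(d0=10, stt=900, rs=6000.0, elue=0.0)
        s = SafyState(day=150, dam=100.0, lai=3.0, gy=0.0, smt=960.0, senescent=False)
        s2 = step(s, rg=20.0, ta=15.0, params=p)
        assert s.lai - s2.lai == pytest.approx(3.0 * (960.0 - 900.0) / 6000.0, rel=1e-12)

    def test_non_finite_forcing_rejected(self):
        p = SafyParameters(d0=10)
        s = SafyState(day=50, dam=1.0, lai=0.1, gy=0.0, smt=100.0, senescent=False)
        with pytest.raises(ValueError, match="day 51"):
            step(s, rg=float("nan"), ta=10.0, params=p)


class TestRunSafy:
    def test_pre_emergence_all_zero(self, forcing):
        p = SafyParameters(d0=60)
        traj = run_safy(p, forcing)
        assert (traj.lai[:59] == 0).all()
        assert (traj.dam[:59] == 0).all()
        assert traj.dam[59] == p.dam0
        assert traj.lai[59] == pytest.approx(p.dam0 * (1 - p.pl_a) * p.sla)

    def test_elue_zero_biomass_frozen(self, forcing):
        traj = run_safy(SafyParameters(d0=40, elue=0.0), forcing)
        assert (traj.dam[39:] == traj.params.dam0).all()

    def test_deterministic(self, forcing):
        p = SafyParameters(d0=70, elue=2.0, stt=800)
        a, b = run_safy(p, forcing), run_safy(p, forcing)
        for name in ("dam", "lai", "gy", "smt"):
            assert (getattr(a, name) == getattr(b, name)).all()

    def test_forcing_must_cover_emergence(self):
        from safy.forcing import ClimateForcing

        short = ClimateForcing(rg=np.full(50, 10.0), ta=np.full(50, 12.0))
        with pytest.raises(ValueError):
            run_safy(SafyParameters(d0=60), short)

    def test_matches_naive_reference(self, forcing):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            p = SafyParameters(
                d0=int(rng.integers(15, 121)),
                elue=float(rng.uniform(0, 10)),
                stt=float(rng.uniform(200, 1800)),
            )
            traj = run_safy(p, forcing)
            ref = naive_safy(p.d0, p.elue, p.stt, forcing.rg, forcing.ta)
            for name in ("dam", "lai", "gy", "smt"):
                np.testing.assert_allclose(
                    getattr(traj, name), ref[name], rtol=1e-9, atol=1e-12
                )


class TestTrajectoryInvariants:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        d0=st.integers(15, 120),
        elue=st.floats(0.0, 10.0),
        stt=st.floats(200.0, 1800.0),
    )
    def test_monotone_state_variables(self, d0, elue, stt):
        from safy.synth import generate_climate

        traj = run_safy(SafyParameters(d0=d0, elue=elue, stt=stt), generate_climate(seed=7))
        assert (np.diff(traj.gy) >= 0).all()
        assert (np.diff(traj.dam) >= 0).all()
        assert (np.diff(traj.smt) >= 0).all()
        assert (traj.lai >= 0).all()
        assert (traj.lai[: d0 - 1] == 0).all()

    def test_more_elue_never_less_biomass(self, forcing):
        base = SafyParameters(d0=60, elue=1.5, stt=900)
        hi = SafyParameters(d0=60, elue=3.0, stt=900)
        assert run_safy(hi, forcing).dam[-1] >= run_safy(base, forcing).dam[-1]

    def test_stt_above_season_total_means_no_senescence(self, forcing):
        total = np.maximum(forcing.ta, 0).sum()
        traj = run_safy(SafyParameters(d0=60, elue=2.0, stt=total + 100), forcing)
        assert (np.diff(traj.lai) >= 0).all()

    def test_lai_unimodal_on_smooth_season(self, smooth_forcing):
        traj = run_safy(SafyParameters(d0=60, elue=2.0, stt=900), smooth_forcing)
        peak = int(np.argmax(traj.lai))
        assert (np.diff(traj.lai[: peak + 1]) >= 0).all()
        assert (np.diff(traj.lai[peak:]) <= 1e-12).all()
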