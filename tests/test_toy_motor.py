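"""Coarse-grained rotary-motor simulator: determinism, thermodynamic sanity,
bias tracking, steering, and the synthetic dataset generators."""

import numpy as np
import pytest
from scipy.integrate import quad

from f1rotor import structure_io as sio
from f1rotor import toy_motor as tm
from f1rotor.flexible_rotor import RotorBias
from f1rotor.toy_motor import MotorParams, SimProtocol, build_motor


class TestBuildMotor:
    def test_default_build_has_expected_components(self):
        motor = build_motor(MotorParams(), seed=0)
        assert motor.core.shape == (8, 3)
        assert motor.prot.shape == (12, 3)
        assert motor.inh.shape == (8, 3)
        assert motor.stator_anchors.shape == (3, 3, 3)
        model = motor.to_structure()
        assert set(model.chains()) == {"A", "B", "C", "G", "I"}

    def test_same_seed_same_coordinates(self):
        p = MotorParams(jitter_sigma=0.1)
        a = build_motor(p, seed=42)
        b = build_motor(p, seed=42)
        assert np.array_equal(a.core, b.core)
        assert np.array_equal(a.inh, b.inh)
        c = build_motor(p, seed=43)
        assert not np.array_equal(a.core, c.core)

    def test_inhibitor_free_variant(self):
        motor = build_motor(MotorParams(n_inh=0), seed=0)
        assert len(motor.inh) == 0
        assert motor.short_contacts == [] and motor.long_contacts == []
        assert "I" not in motor.to_structure().chains()

    def test_nonphysical_parameters_rejected(self):
        with pytest.raises(ValueError):
            MotorParams(r_core=-1.0)
        with pytest.raises(ValueError):
            MotorParams(n_core=2)

    def test_export_reimport_round_trip(self, tmp_path):
        motor = build_motor(MotorParams(), seed=0)
        model = motor.to_structure()
        path = sio.write_multimodel_pdb(model, tmp_path / "motor.pdb")
        back = sio.read_pdb(path, role_map=tm.TOY_ROLE_MAP)
        np.testing.assert_allclose(back.coords, model.sorted().coords,
                                   atol=1.5e-3)


class TestRunLangevin:
    def test_bitwise_reproducible_under_fixed_seed(self):
        p = MotorParams()
        bias = RotorBias(kappa=1e4, omega_deg_per_ns=5.0)
        proto = SimProtocol(n_steps=200, dt=0.002, seed=1, bias=bias,
                            save_every=50)
        t1, l1 = tm.run_langevin(build_motor(p, seed=1), proto)
        t2, l2 = tm.run_langevin(build_motor(p, seed=1), proto)
        assert l1.work == l2.work and l1.theta == l2.theta
        np.testing.assert_array_equal(t1.frames[-1].coords,
                                      t2.frames[-1].coords)
        # a different seed takes a different thermal path
        _, l3 = tm.run_langevin(build_motor(p, seed=1),
                                SimProtocol(n_steps=200, dt=0.002, seed=2,
                                            bias=bias, save_every=50))
        assert l1.work != l3.work

    def test_zero_temperature_relaxation_is_monotone(self):
        motor = build_motor(MotorParams(kbt=0.0, jitter_sigma=0.3), seed=3)
        energies = [motor.total_energy()]
        m = motor
        for _ in range(5):
            traj, _ = tm.run_langevin(
                m, SimProtocol(n_steps=100, dt=0.002, seed=0,
                               save_every=10 ** 9))
            m = _state_from_frame(m, traj.frames[-1])
            energies.append(m.total_energy())
        assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))

    def test_cv_tracks_target_within_friction_lag(self):
        p = MotorParams(kbt=0.0, n_inh=0)
        motor = build_motor(p, seed=2)
        kappa, omega = 1e4, 10.0
        bias = RotorBias(kappa=kappa, omega_deg_per_ns=omega)
        proto = SimProtocol(n_steps=4000, dt=0.002, seed=2, bias=bias,
                            save_every=10 ** 9)
        _, ledger = tm.run_langevin(motor, proto)
        a = ledger.as_arrays()
        lag = a["theta0"][-1] - a["theta"][-1]
        # both rings corotate in steady state: friction is the sum
        gamma_rot = (p.n_prot * p.gamma_bead * p.r_prot ** 2
                     + p.n_core * p.gamma_bead * p.r_core ** 2)
        lag_pred = gamma_rot * np.deg2rad(omega) / kappa
        assert lag == pytest.approx(lag_pred, rel=0.10)

    def test_forced_rotation_switches_gates_in_sequence(self):
        p = MotorParams(n_inh=0, kbt=0.0)
        motor = build_motor(p, seed=4)
        bias = RotorBias(kappa=1e5, omega_deg_per_ns=50.0, direction="CCW")
        traj, _ = tm.run_langevin(
            motor, SimProtocol(n_steps=2000, dt=0.002, seed=4,
                               save_every=500, bias=bias))
        # 200 deg of rotation passes the 60 and 180 deg thresholds, not 300
        assert traj.metadata["theta_prot_deg"][-1] > 190.0
        assert traj.metadata["gate1"][-1] > 0.9
        assert traj.metadata["gate2"][-1] > 0.9
        assert traj.metadata["gate3"][-1] < 0.1

    def test_explicit_state_switch_event(self):
        p = MotorParams(n_inh=0, kbt=0.0)
        motor = build_motor(p, seed=4)
        traj, _ = tm.run_langevin(
            motor, SimProtocol(n_steps=400, dt=0.002, seed=4, save_every=100,
                               state_switch=((0.4, (1.0, 1.0, 1.0)),)))
        assert traj.metadata["gate1"][-1] > 0.8

    def test_divergence_raises_with_step_number(self):
        p = MotorParams(kbt=0.0, n_inh=0)
        motor = build_motor(p, seed=0)
        motor.prot[0] = [9.0e3, 0.0, 0.0]  # far outside any basin
        with pytest.raises(FloatingPointError, match="step"):
            tm.run_langevin(motor, SimProtocol(n_steps=50, dt=10.0, seed=0))

    def test_gate_occupancy_matches_boltzmann(self):
        p = MotorParams(n_core=3, n_prot=3, n_inh=0, gate_barrier=0.5,
                        gate_tilt=0.3, k_gate_couple=0.5, kbt=0.6)

        def U(g):
            return (p.gate_barrier * 16 * g ** 2 * (1 - g) ** 2
                    + p.gate_tilt * g + 0.5 * p.k_gate_couple * g ** 2)

        beta = 1.0 / p.kbt
        z_open = quad(lambda g: np.exp(-beta * U(g)), -np.inf, 0.5)[0]
        z_closed = quad(lambda g: np.exp(-beta * U(g)), 0.5, np.inf)[0]
        p_open_exact = z_open / (z_open + z_closed)

        motor = build_motor(p, seed=11)
        traj, _ = tm.run_langevin(
            motor, SimProtocol(n_steps=40000, dt=0.01, seed=11,
                               save_every=25))
        burn = len(traj.metadata["gate1"]) // 10
        gates = np.concatenate([traj.metadata[f"gate{j}"][burn:]
                                for j in (1, 2, 3)])
        p_open_sim = float(np.mean(gates < 0.5))
        assert p_open_sim == pytest.approx(p_open_exact, rel=0.10)

    def test_work_asymmetry_with_inhibitor_engaged(self):
        # the chiral inhibitor linkage makes CW rotation cost more than CCW
        # (regression on the generator's construction, not a claim about
        # the real enzyme)
        p = MotorParams(kbt=0.0)
        work = {}
        for direction in ("CCW", "CW"):
            motor = build_motor(p, seed=5)
            bias = RotorBias(kappa=1e4, omega_deg_per_ns=10.0,
                             direction=direction)
            _, ledger = tm.run_langevin(
                motor, SimProtocol(n_steps=2000, dt=0.002, seed=5,
                                   save_every=10 ** 9, bias=bias))
            work[direction] = ledger.work[-1]
        assert work["CW"] > work["CCW"] + 0.5


class TestRmsdSteer:
    def test_stationary_when_target_equals_current(self):
        motor = build_motor(MotorParams(kbt=0.0), seed=6)
        relaxed_traj, _ = tm.run_langevin(
            motor, SimProtocol(n_steps=2000, dt=0.002, seed=0,
                               save_every=10 ** 9))
        relaxed = _state_from_frame(motor, relaxed_traj.frames[-1])
        traj = tm.rmsd_steer(relaxed, relaxed.copy(), duration_ns=0.05)
        np.testing.assert_allclose(traj.frames[-1].coords,
                                   traj.frames[0].coords, atol=1e-3)

    def test_open_to_closed_gate_steering(self):
        motor = build_motor(MotorParams(kbt=0.0), seed=6)
        target = motor.copy()
        target.gates = np.ones(3)
        traj = tm.rmsd_steer(motor, target, duration_ns=1.0)
        gates = _decode_gates(motor.params, traj.frames[-1])
        np.testing.assert_allclose(gates, 1.0, atol=0.1)
        # final generalized RMSD < 10% of initial
        d0 = np.linalg.norm(traj.frames[0].coords - _target_coords(target))
        d1 = np.linalg.norm(traj.frames[-1].coords - _target_coords(target))
        assert d1 < 0.1 * d0

    def test_zero_duration_rejected(self):
        motor = build_motor(MotorParams(), seed=0)
        with pytest.raises(ValueError):
            tm.rmsd_steer(motor, motor.copy(), duration_ns=0.0)

    def test_topology_mismatch_rejected(self):
        a = build_motor(MotorParams(), seed=0)
        b = build_motor(MotorParams(n_inh=0), seed=0)
        with pytest.raises(ValueError, match="topology"):
            tm.rmsd_steer(a, b, duration_ns=1.0)


class TestGeneratePcaDataset:
    def test_zero_noise_covariance_is_rank_two(self):
        pairs, _, _, _ = tm.generate_pca_dataset(50, noise_sigma=0.0, seed=3,
                                                 rigid_motions=False)
        x = np.stack([p.coords for p in pairs])
        x -= x.mean(axis=0)
        s = np.linalg.svd(x, compute_uv=False)
        assert (s > 1e-9 * s[0]).sum() == 2

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            tm.generate_pca_dataset(1, seed=0)

    def test_ground_truth_modes_are_orthonormal(self):
        _, d1, d2, _ = tm.generate_pca_dataset(5, seed=0)
        assert np.linalg.norm(d1) == pytest.approx(1.0)
        assert np.linalg.norm(d2) == pytest.approx(1.0)
        assert d1 @ d2 == pytest.approx(0.0, abs=1e-12)


class TestGenerateHelixChain:
    @pytest.mark.parametrize("frac,n,expected", [
        (1.0, 20, 1.0), (0.0, 20, 0.0), (0.5, 30, 0.5), (0.6, 25, 0.6),
    ])
    def test_helicity_matches_requested_fraction(self, frac, n, expected):
        from f1rotor.traj_metrics import helicity
        chain = tm.generate_helix_chain(n, frac, seed=9)
        assert helicity(chain, (1, n)) == pytest.approx(expected,
                                                        abs=1.0 / n)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            tm.generate_helix_chain(10, 1.5)


# -- helpers ---------------------------------------------------------------

def _state_from_frame(motor, frame):
    """Rebuild a ToyMotor state from an exported frame (for chained runs)."""
    m = motor.copy()
    p = m.params
    g = frame.sorted()
    gm = g.chain_ids == "G"
    gam = g.coords[gm]
    order = np.argsort(g.res_ids[gm])
    gam = gam[order]
    m.core = gam[:p.n_core]
    m.prot = gam[p.n_core:p.n_core + p.n_prot]
    im = g.chain_ids == "I"
    if im.any():
        inh = g.coords[im][np.argsort(g.res_ids[im])]
        m.inh = inh
    m.gates = np.asarray(_decode_gates(p, g))
    return m


def _decode_gates(params, frame):
    gates = []
    for cid in "ABC":
        sel = frame.chain_ids == cid
        anchors = np.stack([frame.coords[sel & (frame.res_ids == r)][0]
                            for r in (1, 2, 3)])
        gate = frame.coords[sel & (frame.res_ids == 4)][0]
        center = anchors.mean(axis=0)
        inward = -center / np.linalg.norm(center)
        gates.append(float((gate - center) @ inward
                           / params.gate_amplitude))
    return gates


def _target_coords(target):
    return target.to_structure().sorted().coords
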