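"""Seeded coarse-grained rotary-motor simulator and synthetic-data source.

The toy motor mimics the statistical architecture the analysis modules
assume, at bead resolution:

* three stator units on a ring, each carrying a scalar *gate* coordinate
  g_j (double well: open ≈ 0, closed ≈ 1, the PC1-like motion) and a scalar
  *interface* coordinate h_j (loose ≈ 0 / tight ≈ 1, PC2-like);
* a two-layer rotor: a buried *core* bead ring and a *protruded* bead ring
  coupled by a torsion spring, so the core lags the protruded part when
  torque is applied to the latter;
* an inhibitor bead chain whose *short segment* makes native contacts with
  rotor-core beads and whose *long segment* is anchored to stator unit 1.

Dynamics are overdamped (Euler–Maruyama) Langevin updates on every
coordinate; the rotor bias acts on the protruded ring through the
mean-rotation-angle collective variable of :mod:`f1rotor.flexible_rotor`.
Forced rotation past a switch angle re-targets the gate double wells with
120° periodic offsets per unit (the 3-fold architecture); gate targets can
also be reassigned explicitly at protocol times, mirroring nucleotide-state
replacement at 120°/240°.

All parameters are toy-scale choices (documented defaults below), not
measured values for the real enzyme.  All randomness derives from a single
protocol seed through named ``numpy`` SeedSequence children (one stream per
coordinate block, drawn in a fixed order), so trajectories are bitwise
reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, fields

import numpy as np

from f1rotor import flexible_rotor
from f1rotor.flexible_rotor import RotorCV, WorkLedger, accumulate_work
from f1rotor.structure_io import StructureModel, Trajectory

__all__ = [
    "MotorParams",
    "ToyMotor",
    "SimProtocol",
    "build_motor",
    "run_langevin",
    "rmsd_steer",
    "generate_pca_dataset",
    "generate_helix_chain",
    "TOY_ROLE_MAP",
]

#: Chain-role map of the exported toy structure (no α ring in the toy).
TOY_ROLE_MAP = {"beta": ("A", "B", "C"), "gamma": ("G",), "inhibitor": ("I",)}

_DIVERGENCE_BOUND = 1e4  # Å


@dataclass(frozen=True)
class MotorParams:
    """Toy-scale defaults (Å, kcal/mol, ns).  Not values for the real enzyme."""

    n_core: int = 8
    n_prot: int = 12
    r_core: float = 5.0
    r_prot: float = 10.0
    z_core: float = 0.0
    z_prot: float = 8.0
    k_ring: float = 20.0      # neighbor springs within a ring, kcal/mol/Å²
    k_radial: float = 20.0    # radial + axial tether, kcal/mol/Å²
    kappa_tw: float = 200.0   # core↔protruded torsion, kcal/mol/rad²

    n_inh: int = 8
    k_bond: float = 50.0      # inhibitor backbone springs
    k_contact: float = 5.0    # native-contact springs
    contact_offset_deg: float = 15.0  # pre-strain of short-segment contacts

    r_stator: float = 18.0
    gate_amplitude: float = 4.0      # Å displacement of the gate bead per g
    gate_barrier: float = 2.0        # double-well barrier, kcal/mol
    gate_tilt: float = 0.0           # linear tilt on g (for occupancy tests)
    k_gate_couple: float = 10.0      # gate → target coupling
    switch_angle_deg: float = 60.0   # rotor angle that flips a gate target
    k_iface: float = 5.0             # interface coordinate well

    kbt: float = 0.6          # kcal/mol
    gamma_bead: float = 1.0   # kcal/mol·ns/Å²
    gamma_gate: float = 1.0   # kcal/mol·ns (dimensionless coordinate)
    jitter_sigma: float = 0.0  # build-time coordinate jitter, Å

    def __post_init__(self):
        for name in ("r_core", "r_prot", "r_stator", "gate_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_core", "n_prot"):
            if getattr(self, name) < 3:
                raise ValueError(f"{name} must be >= 3")
        if self.n_inh < 0:
            raise ValueError("n_inh must be >= 0")
        if self.kbt < 0 or self.gamma_bead <= 0 or self.gamma_gate <= 0:
            raise ValueError("invalid thermodynamic parameters")

    @property
    def stator_angles(self):
        """Azimuths of the three stator units, rad."""
        return np.deg2rad(np.array([0.0, 120.0, 240.0]))

    def rotational_friction(self):
        """Effective rotational friction of the protruded ring,
        Σ γ r², in kcal·mol⁻¹·ns·rad⁻² — the γ_f of the lag oracle."""
        return self.n_prot * self.gamma_bead * self.r_prot ** 2


def _ring(n, radius, z, phase=0.0):
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.full(n, float(z))], axis=1)


@dataclass
class ToyMotor:
    """Current state + build-time references of the coarse-grained motor."""

    params: MotorParams
    core: np.ndarray        # (n_core, 3)
    prot: np.ndarray        # (n_prot, 3)
    inh: np.ndarray         # (n_inh, 3)
    gates: np.ndarray       # (3,)
    ifaces: np.ndarray      # (3,)
    stator_anchors: np.ndarray  # (3, n_anchor, 3), fixed in space
    core_ref: np.ndarray
    prot_ref: np.ndarray
    bond_rest: np.ndarray   # inhibitor bond rest lengths
    short_contacts: list    # (inh index, core index, rest distance)
    long_contacts: list     # (inh index, anchor flat index, rest distance)
    gate_targets: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    iface_targets: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    # unwrapped CV memory
    theta_core: float = 0.0
    theta_prot: float = 0.0

    def __post_init__(self):
        self._cv_core = RotorCV(self.core_ref)
        self._cv_prot = RotorCV(self.prot_ref)

    def copy(self):
        return copy.deepcopy(self)

    # -- collective variables -------------------------------------------
    def update_angles(self):
        self.theta_core = flexible_rotor.mean_rotation_angle(
            self.core, self._cv_core, previous=self.theta_core)
        self.theta_prot = flexible_rotor.mean_rotation_angle(
            self.prot, self._cv_prot, previous=self.theta_prot)
        return self.theta_core, self.theta_prot

    # -- energies and forces --------------------------------------------
    def _ring_terms(self, xyz, ref, radius, z0, grad):
        """Elastic-network ring: neighbor springs + radial/axial tethers."""
        p = self.params
        n = len(xyz)
        u = 0.0
        chord = 2.0 * radius * np.sin(np.pi / n)
        for i in range(n):
            j = (i + 1) % n
            d = xyz[j] - xyz[i]
            dist = np.linalg.norm(d)
            u += 0.5 * p.k_ring * (dist - chord) ** 2
            f = p.k_ring * (dist - chord) * d / max(dist, 1e-12)
            grad[i] -= f
            grad[j] += f
        rho = np.hypot(xyz[:, 0], xyz[:, 1])
        u += 0.5 * p.k_radial * np.sum((rho - radius) ** 2)
        u += 0.5 * p.k_radial * np.sum((xyz[:, 2] - z0) ** 2)
        safe = np.maximum(rho, 1e-12)
        grad[:, 0] += p.k_radial * (rho - radius) * xyz[:, 0] / safe
        grad[:, 1] += p.k_radial * (rho - radius) * xyz[:, 1] / safe
        grad[:, 2] += p.k_radial * (xyz[:, 2] - z0)
        return u

    def energy_forces(self):
        """Total energy and per-block gradients.

        Returns ``(U, g_core, g_prot, g_inh, g_gates, g_ifaces)``.  The
        gate↔rotor coupling reads the rotor angle but exerts no reaction
        torque on the beads (one-way, documented toy simplification).
        """
        p = self.params
        g_core = np.zeros_like(self.core)
        g_prot = np.zeros_like(self.prot)
        g_inh = np.zeros_like(self.inh)
        g_gates = np.zeros(3)
        g_ifaces = np.zeros(3)

        u = self._ring_terms(self.core, self.core_ref, p.r_core, p.z_core,
                             g_core)
        u += self._ring_terms(self.prot, self.prot_ref, p.r_prot, p.z_prot,
                              g_prot)

        # torsion spring between the two ring angles
        th_c, th_p = self.update_angles()
        dth = th_c - th_p
        u += 0.5 * p.kappa_tw * dth ** 2
        gc = flexible_rotor.cv_gradient(self.core, self._cv_core)
        gp = flexible_rotor.cv_gradient(self.prot, self._cv_prot)
        g_core += p.kappa_tw * dth * gc
        g_prot += -p.kappa_tw * dth * gp

        # inhibitor backbone
        for i in range(len(self.inh) - 1):
            d = self.inh[i + 1] - self.inh[i]
            dist = np.linalg.norm(d)
            u += 0.5 * p.k_bond * (dist - self.bond_rest[i]) ** 2
            f = p.k_bond * (dist - self.bond_rest[i]) * d / max(dist, 1e-12)
            g_inh[i] -= f
            g_inh[i + 1] += f

        # native contacts: short segment ↔ rotor core (pair term, both sides)
        for i, j, d0 in self.short_contacts:
            d = self.inh[i] - self.core[j]
            dist = np.linalg.norm(d)
            u += 0.5 * p.k_contact * (dist - d0) ** 2
            f = p.k_contact * (dist - d0) * d / max(dist, 1e-12)
            g_inh[i] += f
            g_core[j] -= f
        # long segment ↔ stator-unit-1 anchors (anchors fixed)
        anchors_flat = self.stator_anchors.reshape(-1, 3)
        for i, a, d0 in self.long_contacts:
            d = self.inh[i] - anchors_flat[a]
            dist = np.linalg.norm(d)
            u += 0.5 * p.k_contact * (dist - d0) ** 2
            g_inh[i] += p.k_contact * (dist - d0) * d / max(dist, 1e-12)

        # gates: double well + tilt + piecewise-harmonic target coupling
        g = self.gates
        u += np.sum(p.gate_barrier * 16.0 * g ** 2 * (1.0 - g) ** 2)
        g_gates += p.gate_barrier * 16.0 * (
            2.0 * g * (1.0 - g) ** 2 - 2.0 * g ** 2 * (1.0 - g))
        u += p.gate_tilt * np.sum(g)
        g_gates += p.gate_tilt
        targets = self._effective_gate_targets(th_p)
        u += 0.5 * p.k_gate_couple * np.sum((g - targets) ** 2)
        g_gates += p.k_gate_couple * (g - targets)

        # interface coordinates
        u += 0.5 * p.k_iface * np.sum((self.ifaces - self.iface_targets) ** 2)
        g_ifaces += p.k_iface * (self.ifaces - self.iface_targets)

        return u, g_core, g_prot, g_inh, g_gates, g_ifaces

    def _effective_gate_targets(self, theta_prot):
        """Gate targets: explicit assignment, with unit j's target flipped
        once the unwrapped rotor angle has passed the unit's switch
        threshold (switch_angle + j·120°, in either direction)."""
        p = self.params
        targets = self.gate_targets.copy()
        thr = np.deg2rad(p.switch_angle_deg)
        step = np.deg2rad(120.0)
        for j in range(3):
            if abs(theta_prot) >= thr + j * step:
                targets[j] = 1.0 - targets[j]
        return targets

    def total_energy(self):
        return self.energy_forces()[0]

    # -- export ----------------------------------------------------------
    def to_structure(self, model_index=1) -> StructureModel:
        """Export the state as a role-labeled Cα-bead StructureModel.

        Chains: A/B/C stator units (anchor beads, then a gate bead displaced
        inward by g·amplitude, then an interface bead displaced axially by
        h), G rotor (core residues first, then protruded), I inhibitor.
        """
        p = self.params
        chains, resids, names, coords = [], [], [], []

        def add(chain, rid, xyz):
            chains.append(chain)
            resids.append(rid)
            names.append("CA")
            coords.append(xyz)

        for j, cid in enumerate("ABC"):
            anchors = self.stator_anchors[j]
            for k, a in enumerate(anchors):
                add(cid, k + 1, a)
            center = anchors.mean(axis=0)
            inward = -center / np.linalg.norm(center)
            gate_pos = center + inward * (self.gates[j] * p.gate_amplitude)
            add(cid, len(anchors) + 1, gate_pos)
            iface_pos = center + np.array([0.0, 0.0, 2.0 + self.ifaces[j]])
            add(cid, len(anchors) + 2, iface_pos)
        for k, x in enumerate(self.core):
            add("G", k + 1, x)
        for k, x in enumerate(self.prot):
            add("G", p.n_core + k + 1, x)
        for k, x in enumerate(self.inh):
            add("I", k + 1, x)

        n = len(coords)
        return StructureModel(
            chain_ids=np.array(chains, dtype="U4"),
            res_ids=np.array(resids, dtype=int),
            res_names=np.full(n, "BEA", dtype="U3"),
            atom_names=np.array(names, dtype="U4"),
            elements=np.full(n, "C", dtype="U2"),
            coords=np.array(coords, dtype=float),
            hetero=np.zeros(n, dtype=bool),
            model_index=model_index,
            role_map=dict(TOY_ROLE_MAP),
        )


@dataclass(frozen=True)
class SimProtocol:
    """Simulation protocol: step count, timestep, seed, optional bias,
    optional RMSD steering and gate-target reassignment events."""

    n_steps: int
    dt: float  # ns
    seed: int
    bias: object = None  # RotorBias or None
    save_every: int = 100
    state_switch: tuple = ()  # of (time_ns, (g1, g2, g3))

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


def build_motor(params: MotorParams = None, seed: int = 0,
                gate_targets=(0.0, 0.0, 0.0)) -> ToyMotor:
    """Deterministically construct a motor for a given seed.

    The geometry is the analytic ring/chain layout plus an optional seeded
    jitter (``params.jitter_sigma``).  The inhibitor's core-side end is
    skewed by ``contact_offset_deg`` about z while its stator-side end is
    not, so the core↔stator linkage is chiral: with a positive offset,
    rotating the rotor CCW costs less work than CW.  Native contacts are
    relaxed at build (rest lengths = built distances).
    """
    p = params or MotorParams()
    streams = np.random.SeedSequence(int(seed)).spawn(4)
    rngs = [np.random.default_rng(s) for s in streams]

    core = _ring(p.n_core, p.r_core, p.z_core)
    prot = _ring(p.n_prot, p.r_prot, p.z_prot)

    # stator anchors: 3 beads per unit on an outer arc
    anchors = np.zeros((3, 3, 3))
    for j, phi in enumerate(p.stator_angles):
        for k, dphi in enumerate((-0.15, 0.0, 0.15)):
            a = phi + dphi
            anchors[j, k] = [p.r_stator * np.cos(a), p.r_stator * np.sin(a),
                             4.0]

    # inhibitor chain from near the core ring out to stator unit 1 (index 0);
    # the core-side end is skewed by contact_offset_deg about z, making the
    # core↔stator linkage chiral — the built-in rotational asymmetry
    if p.n_inh:
        off = np.deg2rad(p.contact_offset_deg)
        rot_off = np.array([[np.cos(off), -np.sin(off), 0.0],
                            [np.sin(off), np.cos(off), 0.0],
                            [0.0, 0.0, 1.0]])
        start = rot_off @ np.array([p.r_core + 1.5, 0.0, 1.0])
        end = anchors[0].mean(axis=0) + np.array([-2.0, 0.0, -1.0])
        ts = np.linspace(0.0, 1.0, p.n_inh)
        inh = start[None, :] + ts[:, None] * (end - start)[None, :]
    else:
        inh = np.zeros((0, 3))

    if p.jitter_sigma > 0:
        core = core + rngs[0].normal(0.0, p.jitter_sigma, core.shape)
        prot = prot + rngs[1].normal(0.0, p.jitter_sigma, prot.shape)
        if p.n_inh:
            inh = inh + rngs[2].normal(0.0, p.jitter_sigma, inh.shape)

    bond_rest = (np.linalg.norm(np.diff(inh, axis=0), axis=1)
                 if p.n_inh > 1 else np.zeros(0))

    # native contacts, relaxed at build (rest = built distances)
    short_contacts, long_contacts = [], []
    if p.n_inh:
        n_short = min(3, p.n_inh)
        for i in range(n_short):
            j = int(np.argmin(np.linalg.norm(core - inh[i], axis=1)))
            d0 = float(np.linalg.norm(core[j] - inh[i]))
            short_contacts.append((i, j, d0))
        anchors_flat = anchors.reshape(-1, 3)
        n_long = min(3, p.n_inh - n_short)
        for m in range(n_long):
            i = p.n_inh - 1 - m
            a = int(np.argmin(np.linalg.norm(anchors_flat[:3] - inh[i],
                                             axis=1)))
            d0 = float(np.linalg.norm(anchors_flat[a] - inh[i]))
            long_contacts.append((i, a, d0))

    return ToyMotor(
        params=p, core=core, prot=prot, inh=inh,
        gates=np.zeros(3), ifaces=np.zeros(3),
        stator_anchors=anchors,
        core_ref=core.copy(), prot_ref=prot.copy(),
        bond_rest=bond_rest,
        short_contacts=short_contacts, long_contacts=long_contacts,
        gate_targets=np.asarray(gate_targets, dtype=float),
    )


def run_langevin(motor: ToyMotor, protocol: SimProtocol):
    """Overdamped Langevin run; returns ``(Trajectory, WorkLedger)``.

    The bias (if any) restrains the mean rotation angle of the protruded
    ring to the moving target; work is accumulated per step as
    target-displacement work.  The input motor is not modified.
    """
    m = motor.copy()
    p = m.params
    streams = np.random.SeedSequence(int(protocol.seed)).spawn(5)
    rngs = {name: np.random.default_rng(s)
            for name, s in zip(("core", "prot", "inh", "gates", "ifaces"),
                               streams)}
    bias = protocol.bias
    ledger = WorkLedger()
    frames, times = [], []
    switch_events = sorted(protocol.state_switch)
    next_switch = 0

    def noise(rng, shape, gamma):
        if p.kbt == 0:
            return 0.0
        return rng.normal(0.0, np.sqrt(2.0 * p.kbt * protocol.dt / gamma),
                          shape)

    scalars = {f"gate{j + 1}": [] for j in range(3)}
    scalars.update({f"iface{j + 1}": [] for j in range(3)})
    scalars.update({"theta_core_deg": [], "theta_prot_deg": []})

    def snapshot(t_now):
        m.update_angles()
        frames.append(m.to_structure(model_index=len(frames) + 1))
        times.append(t_now)
        for j in range(3):
            scalars[f"gate{j + 1}"].append(m.gates[j])
            scalars[f"iface{j + 1}"].append(m.ifaces[j])
        scalars["theta_core_deg"].append(np.degrees(m.theta_core))
        scalars["theta_prot_deg"].append(np.degrees(m.theta_prot))

    snapshot(0.0)
    for step in range(protocol.n_steps):
        t = step * protocol.dt
        t_next = (step + 1) * protocol.dt
        while (next_switch < len(switch_events)
               and switch_events[next_switch][0] <= t + 1e-12):
            m.gate_targets = np.asarray(switch_events[next_switch][1],
                                        dtype=float)
            next_switch += 1

        u, g_core, g_prot, g_inh, g_gates, g_ifaces = m.energy_forces()
        if bias is not None:
            theta = m.theta_prot
            _, tau_r = flexible_rotor.bias_energy(theta, t, bias)
            grad_cv = flexible_rotor.cv_gradient(m.prot, m._cv_prot)
            g_prot += -tau_r * grad_cv  # dV/dx = κ(θ-θ0)·∂θ/∂x
            accumulate_work(ledger, theta, t, t_next, bias)

        dtg = protocol.dt / p.gamma_bead
        m.core += -dtg * g_core + noise(rngs["core"], m.core.shape,
                                        p.gamma_bead)
        m.prot += -dtg * g_prot + noise(rngs["prot"], m.prot.shape,
                                        p.gamma_bead)
        if len(m.inh):
            m.inh += -dtg * g_inh + noise(rngs["inh"], m.inh.shape,
                                          p.gamma_bead)
        dtg_g = protocol.dt / p.gamma_gate
        m.gates += -dtg_g * g_gates + noise(rngs["gates"], 3, p.gamma_gate)
        m.ifaces += -dtg_g * g_ifaces + noise(rngs["ifaces"], 3,
                                              p.gamma_gate)

        for name, block in (("core", m.core), ("prot", m.prot),
                            ("inh", m.inh)):
            if len(block) and np.max(np.abs(block)) > _DIVERGENCE_BOUND:
                raise FloatingPointError(
                    f"divergence in {name} block at step {step + 1}")

        if (step + 1) % protocol.save_every == 0 \
                or step + 1 == protocol.n_steps:
            snapshot(t_next)

    metadata = {k: np.asarray(v) for k, v in scalars.items()}
    if bias is not None:
        a = ledger.as_arrays()
        idx = np.searchsorted(a["time"], np.asarray(times))
        idx = np.clip(idx, 0, len(a["time"]) - 1)
        metadata["theta0_deg"] = np.degrees(a["theta0"][idx])
        metadata["work_kcal_mol"] = a["work"][idx]
    traj = Trajectory(frames=frames, times=np.asarray(times),
                      metadata=metadata)
    return traj, ledger


def rmsd_steer(motor: ToyMotor, target: ToyMotor, duration_ns,
               k_steer=2e5, dt=2e-4, seed=0, temperature=None):
    """Steer the motor toward a target by a shrinking-RMSD restraint.

    The generalized coordinate vector (all bead coordinates plus the gate
    coordinates) is pushed by a harmonic penalty ½k(RMSD − ρ(t))² whose
    set-point ρ(t) decreases linearly from the initial RMSD to 0 over
    ``duration_ns``.  Runs at T=0 unless ``temperature`` (kcal/mol)
    overrides.  Returns the steered trajectory.

    The restraint's per-coordinate stiffness is ~``k_steer / n_dof``; the
    Euler step is stable for ``dt < 2·γ·n_dof/k_steer`` (defaults satisfy
    this with a ~4× margin for the default motor).
    """
    if duration_ns <= 0:
        raise ValueError("duration must be positive")
    for a, b in ((motor.core, target.core), (motor.prot, target.prot),
                 (motor.inh, target.inh)):
        if a.shape != b.shape:
            raise ValueError("topology mismatch between motor and target")
    m = motor.copy()
    if temperature is not None:
        m = ToyMotor(**{**_state_dict(m),
                        "params": _with(m.params, kbt=float(temperature))})
    else:
        m = ToyMotor(**{**_state_dict(m), "params": _with(m.params, kbt=0.0)})

    def coords_vec(mm):
        return np.concatenate([mm.core.ravel(), mm.prot.ravel(),
                               mm.inh.ravel(), mm.gates])

    tgt = np.concatenate([target.core.ravel(), target.prot.ravel(),
                          target.inh.ravel(), target.gates])
    n_dof = len(tgt)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    n_steps = max(1, int(round(duration_ns / dt)))
    frames, times = [m.to_structure(1)], [0.0]
    rmsd0 = float(np.sqrt(np.mean((coords_vec(m) - tgt) ** 2)))
    p = m.params
    save_every = max(1, n_steps // 50)
    for step in range(n_steps):
        rho = rmsd0 * (1.0 - (step + 1) / n_steps)
        u, g_core, g_prot, g_inh, g_gates, g_ifaces = m.energy_forces()
        x = coords_vec(m)
        diff = x - tgt
        rmsd = float(np.sqrt(np.mean(diff ** 2)))
        if rmsd > 1e-12:
            pref = k_steer * (rmsd - rho) / (n_dof * rmsd)
            g_steer = pref * diff
        else:
            g_steer = np.zeros_like(diff)
        nc, npr, ni = m.core.size, m.prot.size, m.inh.size
        g_core += g_steer[:nc].reshape(m.core.shape)
        g_prot += g_steer[nc:nc + npr].reshape(m.prot.shape)
        if ni:
            g_inh += g_steer[nc + npr:nc + npr + ni].reshape(m.inh.shape)
        g_gates += g_steer[nc + npr + ni:]

        dtg = dt / p.gamma_bead
        kick = (np.sqrt(2.0 * p.kbt * dt / p.gamma_bead)
                if p.kbt > 0 else 0.0)
        m.core += -dtg * g_core + (kick * rng.normal(size=m.core.shape)
                                   if kick else 0.0)
        m.prot += -dtg * g_prot + (kick * rng.normal(size=m.prot.shape)
                                   if kick else 0.0)
        if ni:
            m.inh += -dtg * g_inh + (kick * rng.normal(size=m.inh.shape)
                                     if kick else 0.0)
        m.gates += -(dt / p.gamma_gate) * g_gates
        m.ifaces += -(dt / p.gamma_gate) * g_ifaces
        if (step + 1) % save_every == 0 or step + 1 == n_steps:
            m.update_angles()
            frames.append(m.to_structure(len(frames) + 1))
            times.append((step + 1) * dt)
    return Trajectory(frames=frames, times=np.asarray(times))


def _state_dict(m: ToyMotor):
    return {f.name: getattr(m, f.name) for f in fields(ToyMotor)}


def _with(params: MotorParams, **kw):
    d = {f.name: getattr(params, f.name) for f in fields(MotorParams)}
    d.update(kw)
    return MotorParams(**d)


# ---------------------------------------------------------------------------
# synthetic datasets for the landscape analysis

def generate_pca_dataset(n, noise_sigma=0.05, seed=0, n_atoms=40,
                         variances=(0.9, 0.1), fractions=None,
                         rigid_motions=True):
    """Sample synthetic αβ-pair coordinate vectors with known structure.

    Pairs are ``base + a·d1 + b·d2 + noise`` (nm) where d1 (open↔closed,
    ground-truth PC1) and d2 (loose↔tight, PC2) are fixed orthonormal
    smooth displacement fields, a ~ N(0, variances[0]) and
    b ~ N(0, variances[1]) — or, with ``fractions`` given, a runs over the
    supplied open→closed grid and b = 0.  Each sample is then (optionally)
    rigidly moved so superposition has work to do.  Returns
    ``(pairs, d1, d2, amplitudes)``.
    """
    from f1rotor.conformation_pca import AlphaBetaPair
    from scipy.spatial.transform import Rotation

    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    # smooth base curve ("fold") in nm
    t = np.linspace(0.0, 4.0 * np.pi, n_atoms)
    base = np.stack([np.cos(t), np.sin(t), 0.3 * t], axis=1)
    base -= base.mean(axis=0)

    def smooth_field(phase):
        f = np.stack([np.sin(0.7 * t + phase), np.cos(1.3 * t - phase),
                      np.sin(0.4 * t + 2 * phase)], axis=1)
        return f.ravel()

    d1 = smooth_field(0.3)
    # remove rigid-motion content so the modes survive superposition:
    # project out global translations and infinitesimal rotations of base
    d1 = _remove_rigid_component(d1, base)
    d1 /= np.linalg.norm(d1)
    d2 = _remove_rigid_component(smooth_field(1.9), base)
    d2 -= d1 * (d1 @ d2)
    d2 /= np.linalg.norm(d2)

    if fractions is not None:
        a = np.asarray(fractions, dtype=float)
        if len(a) != n:
            raise ValueError("fractions length must equal n")
        b = np.zeros(n)
    else:
        a = rng.normal(0.0, np.sqrt(variances[0]), n)
        b = rng.normal(0.0, np.sqrt(variances[1]), n)

    pairs = []
    for i in range(n):
        x = (base.ravel() + a[i] * d1 + b[i] * d2
             + rng.normal(0.0, noise_sigma, 3 * n_atoms))
        pts = x.reshape(-1, 3)
        if rigid_motions and i > 0:
            # sample 0 keeps the generator frame so recovered modes are
            # directly comparable with the returned ground-truth vectors
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(0.0, 1.0, 3)
            pts = pts @ rot.T + shift
        pairs.append(AlphaBetaPair(source_id=f"synt{i}", pair_role="1",
                                   inhibitor_bound=False,
                                   coords=pts.ravel()))
    return pairs, d1, d2, (a, b)


def _remove_rigid_component(vec, base):
    """Project translations and infinitesimal rotations out of a 3N field."""
    n = len(base)
    basis = []
    for ax in range(3):
        e = np.zeros((n, 3))
        e[:, ax] = 1.0
        basis.append(e.ravel())
    for ax in range(3):
        omega = np.zeros(3)
        omega[ax] = 1.0
        basis.append(np.cross(np.broadcast_to(omega, (n, 3)), base).ravel())
    q, _ = np.linalg.qr(np.stack(basis, axis=1))
    vec = np.asarray(vec, dtype=float)
    return vec - q @ (q.T @ vec)


# ---------------------------------------------------------------------------
# helix-chain fixture for the helicity metric

# backbone geometry (Å / degrees), standard values
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_HELIX_PHI_PSI = (-57.0, -47.0)
_EXTENDED_PHI_PSI = (-120.0, 120.0)


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement: position d with |cd| = bond, ∠bcd = angle,
    dihedral(a,b,c,d) = torsion."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_helix_chain(n_res, helical_fraction, seed=0,
                         chain_id="I") -> StructureModel:
    """Backbone (N, CA, C) chain with ideal helical dihedrals on the first
    ``⌊f·n⌋`` residues and extended dihedrals on the rest.

    The seed sets only a random rigid orientation of the finished chain
    (useful for rigid-invariance tests); the internal geometry is exact.
    """
    if not 0.0 <= helical_fraction <= 1.0:
        raise ValueError("helical_fraction must be in [0, 1]")
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    n_helical = int(np.floor(helical_fraction * n_res))

    def phi_psi(i):
        return _HELIX_PHI_PSI if i < n_helical else _EXTENDED_PHI_PSI

    atoms = [np.array([0.0, 0.0, 0.0])]
    atoms.append(atoms[0] + np.array([_B_N_CA, 0.0, 0.0]))
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    atoms.append(atoms[1] + _B_CA_C * np.array([np.cos(ang), np.sin(ang),
                                                0.0]))
    # atoms: residue i holds (N, CA, C) at indices 3i, 3i+1, 3i+2
    for i in range(1, n_res):
        psi_prev = phi_psi(i - 1)[1]
        phi_i = phi_psi(i)[0]
        n_i = _place_atom(atoms[-3], atoms[-2], atoms[-1], _B_C_N,
                          _A_CA_C_N, psi_prev)
        atoms.append(n_i)
        ca_i = _place_atom(atoms[-3], atoms[-2], atoms[-1], _B_N_CA,
                           _A_C_N_CA, 180.0)  # omega trans
        atoms.append(ca_i)
        c_i = _place_atom(atoms[-3], atoms[-2], atoms[-1], _B_CA_C,
                          _A_N_CA_C, phi_i)
        atoms.append(c_i)

    coords = np.stack(atoms)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    from scipy.spatial.transform import Rotation
    coords = coords @ Rotation.random(rng=rng).as_matrix().T

    n_atoms = 3 * n_res
    return StructureModel(
        chain_ids=np.full(n_atoms, chain_id, dtype="U4"),
        res_ids=np.repeat(np.arange(1, n_res + 1), 3),
        res_names=np.full(n_atoms, "ALA", dtype="U3"),
        atom_names=np.array(["N", "CA", "C"] * n_res, dtype="U4"),
        elements=np.array(["N", "C", "C"] * n_res, dtype="U2"),
        coords=coords,
        hetero=np.zeros(n_atoms, dtype=bool),
        role_map={"inhibitor": (chain_id,)},
    )
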