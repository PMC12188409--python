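"""Mean-rotation-angle collective variable and moving harmonic torque bias.

The collective variable is the in-plane Procrustes angle: the single
rotation about the (z) axis that best fits the current in-plane positions of
a weighted atom group onto a reference,

    θ* = atan2( Σᵢ wᵢ (xᵢʳᵉᶠ yᵢ − yᵢʳᵉᶠ xᵢ),  Σᵢ wᵢ (xᵢʳᵉᶠ xᵢ + yᵢʳᵉᶠ yᵢ) ).

Only this average angle is restrained — individual atoms stay free so long
as the optimal mean rotation tracks the moving target θ₀(t) = θ₀ + s·ω·t.
The bias is harmonic, V = ½ κ (θ − θ₀)², and work is accounted as
target-displacement (external) work: dW = V(θ, t+dt) − V(θ, t) at fixed
coordinates.  The windowed mean of κ·(θ₀ − θ) estimates the applied torque.

Angle continuity is maintained by nearest-image unwrapping frame to frame,
so protocols beyond 360° accumulate correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from f1rotor._units import KCAL_PER_MOL_AS_PN_NM, wrap_angle_rad

__all__ = [
    "RotorCV",
    "RotorBias",
    "WorkLedger",
    "mean_rotation_angle",
    "cv_gradient",
    "bias_energy",
    "accumulate_work",
    "estimate_torque",
]


@dataclass
class RotorCV:
    """In-plane reference positions + normalized weights of the rotor group.

    The rotation axis is z by construction; ``reference_coords`` is (N, 3) Å
    (only x, y enter the CV).
    """

    reference_coords: np.ndarray
    weights: np.ndarray = None
    axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        self.reference_coords = np.asarray(self.reference_coords,
                                           dtype=float).reshape(-1, 3)
        n = len(self.reference_coords)
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != n:
            raise ValueError("weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("weights must have positive sum")
        self.weights = self.weights / total
        r2 = (self.reference_coords[:, 0] ** 2
              + self.reference_coords[:, 1] ** 2)
        if np.all(r2 * self.weights < 1e-24):
            raise ValueError("all weighted atoms lie on the rotation axis")


@dataclass(frozen=True)
class RotorBias:
    """Moving harmonic restraint on the mean rotation angle.

    ``kappa``: kcal mol⁻¹ rad⁻²; ``omega_deg_per_ns``: target speed
    (magnitude); ``direction``: "CCW" (hydrolysis, +) or "CW" (synthesis, −);
    ``theta0_init``: rad.
    """

    kappa: float
    omega_deg_per_ns: float = 1.0
    direction: str = "CCW"
    theta0_init: float = 0.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.direction not in ("CCW", "CW"):
            raise ValueError("direction must be 'CCW' or 'CW'")

    @property
    def sign(self):
        return +1.0 if self.direction == "CCW" else -1.0

    @property
    def omega_rad_per_ns(self):
        return np.deg2rad(abs(self.omega_deg_per_ns))

    def target(self, t_ns):
        """θ₀(t) in rad."""
        return self.theta0_init + self.sign * self.omega_rad_per_ns * t_ns


@dataclass
class WorkLedger:
    """Time series of CV, target, cumulative work and restraint torque."""

    time: list = field(default_factory=list)  # ns
    theta: list = field(default_factory=list)  # rad (unwrapped)
    theta0: list = field(default_factory=list)  # rad
    work: list = field(default_factory=list)  # kcal/mol, cumulative
    torque_series: list = field(default_factory=list)  # kcal/mol/rad

    def as_arrays(self):
        return {k: np.asarray(getattr(self, k), dtype=float)
                for k in ("time", "theta", "theta0", "work", "torque_series")}

    def to_frame(self):
        """Ledger as a pandas DataFrame in CSV-interface units."""
        import pandas as pd
        a = self.as_arrays()
        return pd.DataFrame({
            "time_ns": a["time"],
            "theta_deg": np.degrees(a["theta"]),
            "theta0_deg": np.degrees(a["theta0"]),
            "work_kcal_mol": a["work"],
            "torque_pN_nm_per_rad": a["torque_series"] * KCAL_PER_MOL_AS_PN_NM,
        })


def mean_rotation_angle(coords, cv: RotorCV, previous=None):
    """Optimal mean rotation angle (rad) of ``coords`` vs the reference.

    With ``previous`` (rad) given, the branch within ±π of it is returned so
    trajectories unwrap continuously; otherwise the principal value in
    (−π, π].
    """
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    xr, yr = cv.reference_coords[:, 0], cv.reference_coords[:, 1]
    x, y = xyz[:, 0], xyz[:, 1]
    w = cv.weights
    s = np.sum(w * (xr * y - yr * x))
    c = np.sum(w * (xr * x + yr * y))
    if abs(s) < 1e-300 and abs(c) < 1e-300:
        raise ValueError("rotation angle undefined: no in-plane signal")
    theta = np.arctan2(s, c)
    if previous is not None:
        theta = previous + wrap_angle_rad(theta - previous)
    return float(theta)


def cv_gradient(coords, cv: RotorCV):
    """Analytic ∂θ*/∂xᵢ, (N, 3) in rad/Å (z components are zero).

    With S = Σ w (xʳ y − yʳ x) and C = Σ w (xʳ x + yʳ y),
    θ* = atan2(S, C) gives
    ∂θ*/∂xᵢ = wᵢ (−yᵢʳ C − xᵢʳ S) / (S² + C²),
    ∂θ*/∂yᵢ = wᵢ ( xᵢʳ C − yᵢʳ S) / (S² + C²).
    """
    xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
    xr, yr = cv.reference_coords[:, 0], cv.reference_coords[:, 1]
    x, y = xyz[:, 0], xyz[:, 1]
    w = cv.weights
    s = np.sum(w * (xr * y - yr * x))
    c = np.sum(w * (xr * x + yr * y))
    denom = s * s + c * c
    if denom < 1e-300:
        raise ValueError("rotation angle undefined: no in-plane signal")
    grad = np.zeros_like(xyz)
    grad[:, 0] = w * (-yr * c - xr * s) / denom
    grad[:, 1] = w * (xr * c - yr * s) / denom
    return grad


def bias_energy(theta, t_ns, bias: RotorBias):
    """Bias energy and restraint torque at CV value ``theta`` (rad).

    Returns ``(V, tau_r)`` with V = ½ κ (θ − θ₀(t))² in kcal/mol and the
    torque exerted on the system τ_r = −κ (θ − θ₀(t)) in kcal mol⁻¹ rad⁻¹.
    """
    delta = theta - bias.target(t_ns)
    return 0.5 * bias.kappa * delta * delta, -bias.kappa * delta


def kappa_per_deg2(kappa_per_rad2):
    """Convert a force constant from kcal mol⁻¹ rad⁻² to kcal mol⁻¹ deg⁻²."""
    return kappa_per_rad2 * (np.pi / 180.0) ** 2


def accumulate_work(ledger: WorkLedger, theta_k, t_k, t_next,
                    bias: RotorBias):
    """Append one step to the ledger.

    The external-work increment is the bias-energy change caused by moving
    the target from t_k to t_next at fixed coordinates:
    dW = V(θ_k, t_next) − V(θ_k, t_k).
    """
    if t_next <= t_k:
        raise ValueError(f"time must advance: {t_k} -> {t_next}")
    v_before, _ = bias_energy(theta_k, t_k, bias)
    v_after, _ = bias_energy(theta_k, t_next, bias)
    # applied-torque snapshot before the target moves
    tau_applied = bias.kappa * (bias.target(t_k) - theta_k)
    w_prev = ledger.work[-1] if ledger.work else 0.0
    if not ledger.time:
        # opening entry at t_k so the work series starts at 0
        ledger.time.append(t_k)
        ledger.theta.append(theta_k)
        ledger.theta0.append(bias.target(t_k))
        ledger.work.append(0.0)
        ledger.torque_series.append(tau_applied)
    ledger.time.append(t_next)
    ledger.theta.append(theta_k)
    ledger.theta0.append(bias.target(t_next))
    ledger.work.append(w_prev + (v_after - v_before))
    ledger.torque_series.append(tau_applied)
    return ledger


def estimate_torque(ledger: WorkLedger, window_ns=None):
    """Windowed mean applied torque κ·(θ₀ − θ).

    Averages the ledger's torque series over the trailing ``window_ns``
    (whole run if None).  Returns ``(torque_kcal_mol_rad, torque_pn_nm_rad)``
    using 1 kcal/mol = 6.9477 pN·nm.
    """
    a = ledger.as_arrays()
    if len(a["time"]) == 0:
        raise ValueError("empty ledger")
    if window_ns is None:
        mask = np.ones(len(a["time"]), dtype=bool)
    else:
        t_end = a["time"][-1]
        mask = a["time"] >= t_end - window_ns
        if not mask.any():
            raise ValueError("window contains no samples")
        span = a["time"][-1] - a["time"][0]
        if window_ns > span + 1e-12:
            raise ValueError(
                f"window {window_ns} ns exceeds ledger span {span} ns")
    tau = float(np.mean(a["torque_series"][mask]))
    return tau, tau * KCAL_PER_MOL_AS_PN_NM
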