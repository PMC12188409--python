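"""Torque ↔ proton-motive-force bookkeeping.

A rotary ATP synthase driven at torque τ (pN·nm/rad) takes up
W = 2π·τ per turn; with n protons translocated per turn the work per
proton is W/n, and the proton motive force needed to supply it is

    pmf [mV] = 1000 · (τ · 1e-21 J/pN·nm · 2π / n) / e,

with e the exact SI elementary charge.  The torque needed to eject the
bound inhibitor is modeled as the standard catalytic torque scaled up by
the excess-work fraction of the inhibited state; with the canonical
baseline of 40 pN·nm/rad and a 20% excess this gives 48 pN·nm/rad and,
at 8 protons per turn, a pmf of 235 mV.

Rounding to integer mV happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from f1rotor._units import ELEMENTARY_CHARGE, PN_NM_AS_J

__all__ = [
    "PmfEstimate",
    "torque_for_ejection",
    "pmf_required",
    "torque_from_pmf",
]


@dataclass(frozen=True)
class PmfEstimate:
    """Self-consistent torque / work / pmf bundle."""

    torque: float  # pN·nm/rad
    protons_per_turn: int
    pmf: float  # mV (unrounded)
    work_per_turn: float  # pN·nm
    work_per_proton: float  # pN·nm

    def __post_init__(self):
        w_turn = 2.0 * np.pi * self.torque
        w_proton = w_turn / self.protons_per_turn
        pmf = 1000.0 * w_proton * PN_NM_AS_J / ELEMENTARY_CHARGE
        for got, want, name in ((self.work_per_turn, w_turn, "work_per_turn"),
                                (self.work_per_proton, w_proton,
                                 "work_per_proton"),
                                (self.pmf, pmf, "pmf")):
            if abs(got - want) > 1e-9 * max(1.0, abs(want)):
                raise ValueError(f"inconsistent {name}: {got} vs {want}")


def torque_for_ejection(baseline_torque, excess_fraction):
    """Torque to eject the inhibitor: baseline scaled by (1 + excess).

    ``baseline_torque`` in pN·nm/rad (> 0), ``excess_fraction`` ≥ 0 (0.20
    for a 20% work excess of the inhibited state).
    """
    if baseline_torque <= 0:
        raise ValueError("baseline torque must be positive")
    if excess_fraction < 0:
        raise ValueError("excess fraction must be non-negative")
    return baseline_torque * (1.0 + excess_fraction)


def pmf_required(torque, protons_per_turn):
    """Proton motive force (mV, unrounded) sustaining ``torque`` pN·nm/rad
    at the given proton stoichiometry."""
    if torque < 0:
        raise ValueError("torque must be non-negative")
    if protons_per_turn < 1:
        raise ValueError("need at least one proton per turn")
    work_per_proton_j = torque * PN_NM_AS_J * 2.0 * np.pi / protons_per_turn
    return 1000.0 * work_per_proton_j / ELEMENTARY_CHARGE


def torque_from_pmf(pmf_mv, protons_per_turn):
    """Exact inverse of :func:`pmf_required` (pN·nm/rad)."""
    if pmf_mv < 0:
        raise ValueError("pmf must be non-negative")
    if protons_per_turn < 1:
        raise ValueError("need at least one proton per turn")
    return (pmf_mv / 1000.0) * ELEMENTARY_CHARGE / (
        PN_NM_AS_J * 2.0 * np.pi / protons_per_turn)


def estimate(torque, protons_per_turn) -> PmfEstimate:
    """Bundle torque, per-turn/per-proton work and pmf consistently."""
    w_turn = 2.0 * np.pi * torque
    return PmfEstimate(
        torque=float(torque),
        protons_per_turn=int(protons_per_turn),
        pmf=pmf_required(torque, protons_per_turn),
        work_per_turn=w_turn,
        work_per_proton=w_turn / protons_per_turn,
    )
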