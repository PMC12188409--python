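"""Per-frame trajectory metrics.

Covers the observables used to characterize inhibitor release: secondary
structure (helicity) of the inhibitor's short (14–18) and long (21–45)
helices, residue–residue contact counts against an equilibrium baseline,
the long-helix bending angle (Cα triplet 21/38/45), the χ1 rotamer
two-state assignment (states near 200° and 300°), and minimum heavy-atom
distances (e.g. the E30–R408 salt bridge).

Helicity uses a dihedral-window criterion (φ ∈ [−100°, −30°],
ψ ∈ [−67°, −7°]); the window is configurable and the criterion pluggable,
since on ideal fixtures any reasonable assignment agrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from f1rotor.structure_io import StructureModel, MissingResidueError

__all__ = [
    "MetricSeries",
    "SegmentSpec",
    "dihedral",
    "helicity",
    "contact_count",
    "relative_contacts",
    "block_average",
    "bending_angle",
    "chi1_dihedral",
    "chi1_state",
    "min_distance",
]

#: default helical (φ, ψ) window, degrees
HELIX_PHI_WINDOW = (-100.0, -30.0)
HELIX_PSI_WINDOW = (-67.0, -7.0)

#: default heavy-atom contact cutoff, Å
CONTACT_CUTOFF = 4.5

#: γ-branch atom defining χ1 per residue type
CHI1_GAMMA_ATOM = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1", "SER": "OG", "THR": "OG1", "CYS": "SG",
}


@dataclass
class MetricSeries:
    """A named per-frame metric with times (ns), values and units."""

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""
    baseline: float = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")


@dataclass(frozen=True)
class SegmentSpec:
    """Named inhibitor segments and the bending-angle Cα triplet."""

    short_helix: tuple = (14, 18)
    long_helix: tuple = (21, 45)
    long_sub1: tuple = (21, 30)
    long_sub2: tuple = (31, 37)
    long_sub3: tuple = (38, 45)
    bend_triplet: tuple = (21, 38, 45)


# ---------------------------------------------------------------------------
# geometry primitives

def dihedral(p1, p2, p3, p4):
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (−180, 180]."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m @ n2
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


def _chain_of(model, chain, role="inhibitor"):
    if chain is not None:
        return chain
    rmap = model.role_map
    if rmap and role in rmap:
        return rmap[role][0]
    raise ValueError(f"no chain given and no {role!r} role in the model")


def _atom(model, chain, res_id, atom_name):
    mask = ((model.chain_ids == chain) & (model.res_ids == res_id)
            & (model.atom_names == atom_name))
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise MissingResidueError([(chain, res_id)])
    return model.coords[idx[0]]


# ---------------------------------------------------------------------------
# helicity

def helicity(frame: StructureModel, interval, chain=None,
             phi_window=HELIX_PHI_WINDOW, psi_window=HELIX_PSI_WINDOW,
             criterion=None):
    """Fraction of residues in ``interval`` (inclusive) that are helical.

    A residue is helical when every defined backbone dihedral falls in the
    helical window; φ needs the previous residue's C and ψ the next
    residue's N (neighbors outside the interval are used when present, so
    chain termini are judged on the dihedral they do have).  A custom
    ``criterion(phi, psi) -> bool`` (None-tolerant) may replace the window
    test.
    """
    a, b = int(interval[0]), int(interval[1])
    if b - a + 1 < 2:
        raise ValueError("interval must span at least 2 residues")
    cid = _chain_of(frame, chain)

    def get(res, name):
        try:
            return _atom(frame, cid, res, name)
        except MissingResidueError:
            return None

    if criterion is None:
        def criterion(phi, psi):
            ok = True
            if phi is not None:
                ok &= phi_window[0] <= phi <= phi_window[1]
            if psi is not None:
                ok &= psi_window[0] <= psi <= psi_window[1]
            return ok and not (phi is None and psi is None)

    n_helical = 0
    for res in range(a, b + 1):
        n_i, ca_i, c_i = get(res, "N"), get(res, "CA"), get(res, "C")
        if n_i is None or ca_i is None or c_i is None:
            raise MissingResidueError([(cid, res)])
        c_prev = get(res - 1, "C")
        n_next = get(res + 1, "N")
        phi = dihedral(c_prev, n_i, ca_i, c_i) if c_prev is not None else None
        psi = dihedral(n_i, ca_i, c_i, n_next) if n_next is not None else None
        if criterion(phi, psi):
            n_helical += 1
    return n_helical / (b - a + 1)


# ---------------------------------------------------------------------------
# contacts

def _group_atoms(model, sel_or_labels, role_map=None):
    """Resolve a group into (residue keys, per-residue heavy-atom coords)."""
    from f1rotor import structure_io

    if isinstance(sel_or_labels, structure_io.Selection):
        sel = sel_or_labels
        if sel.atom_filter == "CA":
            sel = structure_io.Selection(sel.chain_role, sel.residue_ranges,
                                         "heavy")
        xyz, labels = structure_io.select(model, sel, role_map=role_map)
    else:  # explicit list of (chain, res_id)
        keys = list(sel_or_labels)
        mask = np.zeros(len(model), dtype=bool)
        for c, r in keys:
            mask |= (model.chain_ids == c) & (model.res_ids == r)
        mask &= model.elements != "H"
        if not mask.any():
            raise MissingResidueError(keys)
        xyz = model.coords[mask]
        labels = list(zip(model.chain_ids[mask], model.res_ids[mask],
                          model.atom_names[mask]))
    groups = {}
    for (c, r, _), x in zip(labels, xyz):
        groups.setdefault((c, r), []).append(x)
    return {k: np.asarray(v) for k, v in groups.items()}


def contact_count(frame, group_a, group_b, cutoff=CONTACT_CUTOFF,
                  role_map=None):
    """Residue-pair contacts between two groups.

    A residue pair is in contact when any heavy-atom distance is ≤ cutoff.
    Returns ``(count, pairs)`` with ``pairs`` the list of contacting
    ``((chain, res), (chain, res))`` keys.  Groups may be Selections or
    explicit ``(chain, res_id)`` lists; they must be non-empty and disjoint.
    """
    ga = _group_atoms(frame, group_a, role_map=role_map)
    gb = _group_atoms(frame, group_b, role_map=role_map)
    if not ga or not gb:
        raise ValueError("empty selection")
    overlap = set(ga) & set(gb)
    if overlap:
        raise ValueError(f"groups must be disjoint; shared residues {overlap}")
    pairs = []
    for ka, xa in ga.items():
        for kb, xb in gb.items():
            if cdist(xa, xb).min() <= cutoff:
                pairs.append((ka, kb))
    return len(pairs), pairs


def relative_contacts(counts, baseline_count):
    """Contact counts as a percentage of an equilibrium baseline."""
    if baseline_count <= 0:
        raise ValueError("baseline count must be positive")
    return 100.0 * np.asarray(counts, dtype=float) / baseline_count


def block_average(times, values, window_ns):
    """Means over consecutive non-overlapping half-open windows
    ``[start, start + window_ns)`` of the time axis.

    Returns ``(block_end_times, block_means)``; a window is reported only
    when its end does not exceed the last sample time (the trailing partial
    block is dropped).  Used to report contact series as per-interval
    averages (e.g. 30 ns blocks).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window_ns <= 0:
        raise ValueError("window must be positive")
    t0 = times[0]
    ends, means = [], []
    k = 1
    while t0 + k * window_ns <= times[-1] + 1e-12:
        start = t0 + (k - 1) * window_ns
        end = t0 + k * window_ns
        mask = (times >= start - 1e-12) & (times < end - 1e-12)
        if mask.any():
            ends.append(end)
            means.append(values[mask].mean())
        k += 1
    return np.asarray(ends), np.asarray(means)


# ---------------------------------------------------------------------------
# angles

def bending_angle(frame, triplet=(21, 38, 45), chain=None):
    """Interior angle (degrees, [0, 180]) at the middle Cα of a triplet."""
    cid = _chain_of(frame, chain)
    p = [_atom(frame, cid, r, "CA") for r in triplet]
    v1 = p[0] - p[1]
    v2 = p[2] - p[1]
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise ValueError("coincident points in bending-angle triplet")
    cosang = np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def chi1_dihedral(frame, res_id, chain=None):
    """χ1 (N–Cα–Cβ–Xγ) of one residue, degrees in [0, 360)."""
    cid = _chain_of(frame, chain)
    mask = (frame.chain_ids == cid) & (frame.res_ids == res_id)
    if not mask.any():
        raise MissingResidueError([(cid, res_id)])
    res_name = frame.res_names[mask][0]
    gamma = CHI1_GAMMA_ATOM.get(res_name)
    if gamma is None:
        raise ValueError(f"residue {res_name} {cid}/{res_id} has no chi1")
    pts = [_atom(frame, cid, res_id, name)
           for name in ("N", "CA", "CB", gamma)]
    return dihedral(*pts) % 360.0


def chi1_state(chi1_series, centers=(200.0, 300.0), half_width=40.0):
    """Two-state rotamer assignment of a χ1 series.

    Each angle maps to ``"state200"`` / ``"state300"`` when within
    ``half_width`` (circular distance) of the respective center, otherwise
    ``"unassigned"``.  The partition is exhaustive and, with the default
    windows, mutually exclusive.
    """
    chi = np.asarray(chi1_series, dtype=float)
    labels = [f"state{int(round(c))}" for c in centers]

    def circ_dist(x, c):
        d = (x - c) % 360.0
        return np.minimum(d, 360.0 - d)

    out = np.full(chi.shape, "unassigned", dtype="U12")
    for c, lab in sorted(zip(centers, labels)):
        out = np.where(circ_dist(chi, c) <= half_width, lab, out)
    return out if out.ndim else str(out)


def min_distance(frame, residue_a, residue_b):
    """Minimum heavy-atom distance (Å) between two distinct residues.

    Residues are given as ``(chain_id, res_id)`` tuples.
    """
    if tuple(residue_a) == tuple(residue_b):
        raise ValueError("residues must differ")
    ga = _group_atoms(frame, [tuple(residue_a)])
    gb = _group_atoms(frame, [tuple(residue_b)])
    xa = next(iter(ga.values()))
    xb = next(iter(gb.values()))
    return float(cdist(xa, xb).min())
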