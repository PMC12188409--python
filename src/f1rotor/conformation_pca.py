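"""Conformational landscape of αβ catalytic pairs.

Each F1 head contributes three αβ pairs; their Cα coordinates over fixed
residue subsets, superposed by an iterate-to-mean rigid alignment, feed a
covariance PCA.  On the crystallographic ensemble the top mode (PC1) is the
opening/closing of β and the second (PC2) the loosening/tightening of the
αβ interface; together they capture ~97% of the variance.  The PC2-based
progress statistic expresses how far a trajectory has moved from a start
conformation toward a target conformation, in percent.

Units: PCA operates in nm; structure coordinates arrive in Å and are
converted on extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import json
import numpy as np
from scipy.spatial.transform import Rotation

from f1rotor._units import ANGSTROM_PER_NM
from f1rotor import structure_io
from f1rotor.structure_io import Selection

__all__ = [
    "AlphaBetaPair",
    "PCAModel",
    "Projection",
    "extract_pairs",
    "superpose_pairs",
    "fit_pca",
    "project",
    "conformational_progress",
]


@dataclass
class AlphaBetaPair:
    """Flattened Cα coordinate vector (nm) of one αβ catalytic pair."""

    source_id: str
    pair_role: str  # "E" | "TP" | "DP" (or "1"/"2"/"3" after renaming)
    inhibitor_bound: bool
    coords: np.ndarray  # (3N,) nm

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).ravel()

    @property
    def n_atoms(self):
        return len(self.coords) // 3

    def as_points(self):
        return self.coords.reshape(-1, 3)


@dataclass
class PCAModel:
    """Mean, orthonormal modes, eigenvalues (nm²) and explained fractions."""

    mean: np.ndarray  # (3N,)
    eigenvectors: np.ndarray  # (K, 3N), rows orthonormal
    eigenvalues: np.ndarray  # (K,), descending, >= 0
    explained_fraction: np.ndarray  # (K,), sums to 1

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.explained_fraction = np.asarray(self.explained_fraction, dtype=float)

    def transform(self, coords):
        """Score vector (projections on all retained modes) for one pair."""
        coords = np.asarray(coords, dtype=float).ravel()
        if coords.shape != self.mean.shape:
            raise ValueError(
                f"coordinate length {coords.size} does not match model "
                f"dimension {self.mean.size}"
            )
        return self.eigenvectors @ (coords - self.mean)

    def to_json(self, path, n_modes=None):
        """Archive mean, eigenvalues and the top modes as plain JSON."""
        k = len(self.eigenvalues) if n_modes is None else int(n_modes)
        payload = {
            "mean_nm": self.mean.tolist(),
            "eigenvalues_nm2": self.eigenvalues[:k].tolist(),
            "explained_fraction": self.explained_fraction[:k].tolist(),
            "eigenvectors": self.eigenvectors[:k].tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=d["mean_nm"],
            eigenvectors=d["eigenvectors"],
            eigenvalues=d["eigenvalues_nm2"],
            explained_fraction=d["explained_fraction"],
        )


@dataclass(frozen=True)
class Projection:
    """(PC1, PC2) coordinates of one pair, in nm."""

    pc1: float
    pc2: float
    source_id: str = ""
    pair_role: str = ""


# ---------------------------------------------------------------------------
# pair extraction

def extract_pairs(structures, alpha_sel: Selection, beta_sel: Selection,
                  role_map=None, source_ids=None, pair_roles=None,
                  inhibitor_bound=None):
    """Build 3 αβ pairs per structure.

    α and β chains (three of each, resolved via the role map) are paired in
    ascending chain-id order; ``pair_roles`` can supply per-structure labels
    (e.g. from a rotary-angle classification), otherwise pairs are labeled
    "1", "2", "3" in chain order.  Coordinates are Cα over the fixed subsets,
    flattened and converted to nm.  Missing residues raise unless the
    selections were pre-intersected (see
    :func:`f1rotor.structure_io.intersect_selection`).
    """
    pairs = []
    for si, model in enumerate(structures):
        rmap = role_map or model.role_map or structure_io.assign_chain_roles(model)
        for role in ("alpha", "beta"):
            if len(rmap.get(role, ())) != 3:
                raise structure_io.ChainRoleError(
                    f"structure {si}: expected 3 {role} chains, "
                    f"got {len(rmap.get(role, ()))}"
                )
        alphas = sorted(rmap["alpha"])
        betas = sorted(rmap["beta"])
        sid = source_ids[si] if source_ids is not None else str(si)
        bound = (inhibitor_bound[si] if inhibitor_bound is not None
                 else "inhibitor" in rmap)
        labels = (pair_roles[si] if pair_roles is not None
                  else ("1", "2", "3"))
        for k, (ca, cb) in enumerate(zip(alphas, betas)):
            xa, _ = structure_io.select(model, alpha_sel, chains=[ca])
            xb, _ = structure_io.select(model, beta_sel, chains=[cb])
            coords = np.concatenate([xa, xb]).ravel() / ANGSTROM_PER_NM
            pairs.append(AlphaBetaPair(
                source_id=sid, pair_role=labels[k],
                inhibitor_bound=bool(bound), coords=coords,
            ))
    lengths = {p.coords.size for p in pairs}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent pair vector lengths: {sorted(lengths)}")
    return pairs


# ---------------------------------------------------------------------------
# superposition

def _kabsch(mobile, target):
    """Optimal proper rotation + translation mapping mobile onto target.

    Returns the transformed copy of ``mobile`` (N, 3).
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return (mobile - mc) @ rot.as_matrix().T + tc


def superpose_pairs(pairs, tol=1e-6, max_iter=20, reference=None):
    """Iterate-to-mean rigid superposition of equal-length pairs.

    All pairs are first aligned to ``reference`` (default: the first pair),
    then repeatedly re-aligned to the running mean until the mean shifts by
    less than ``tol`` nm RMS (at most ``max_iter`` sweeps).  Returns
    ``(aligned_pairs, mean_vector)``.  Proper rotations only.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to superpose")
    pts = [p.as_points() for p in pairs]
    for x in pts:
        centered = x - x.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise ValueError("degenerate (collinear) coordinates")
    ref = (reference.as_points() if reference is not None else pts[0])
    pts = [_kabsch(x, ref) for x in pts]
    mean = np.mean(pts, axis=0)
    for _ in range(max_iter):
        pts = [_kabsch(x, mean) for x in pts]
        new_mean = np.mean(pts, axis=0)
        shift = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if shift < tol:
            break
    aligned = [replace(p, coords=x.ravel()) for p, x in zip(pairs, pts)]
    return aligned, mean.ravel()


# ---------------------------------------------------------------------------
# PCA

def fit_pca(aligned_pairs):
    """Covariance PCA over M aligned pairs (1/M normalization).

    The covariance matrix of the flattened Cα coordinates is diagonalized
    via SVD of the centered data matrix; modes are sorted by eigenvalue and
    sign-fixed so each mode's largest-magnitude component is positive.
    """
    if len(aligned_pairs) < 2:
        raise ValueError("need at least 2 pairs to fit a PCA")
    x = np.stack([p.coords for p in aligned_pairs])  # (M, 3N)
    mean = x.mean(axis=0)
    centered = x - mean
    # SVD route: eigenvalues of (1/M) XᵀX are s²/M, eigenvectors rows of Vt
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / len(aligned_pairs)
    # deterministic sign: largest-|component| positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] = -vt[k]
    total = eigenvalues.sum()
    if total <= 0:
        raise ValueError("zero total variance: all pairs identical")
    return PCAModel(
        mean=mean,
        eigenvectors=vt,
        eigenvalues=eigenvalues,
        explained_fraction=eigenvalues / total,
    )


def project(pair, model: PCAModel) -> Projection:
    """(PC1, PC2) projection of one pair on a fitted model."""
    scores = model.transform(pair.coords)
    pc2 = float(scores[1]) if len(scores) > 1 else 0.0
    return Projection(pc1=float(scores[0]), pc2=pc2,
                      source_id=pair.source_id, pair_role=pair.pair_role)


def conformational_progress(pc2_t, pc2_start, pc2_target):
    """Percent of the start→target conformational change accomplished.

    ``100 * (pc2_t - pc2_start) / (pc2_target - pc2_start)``, unclipped
    (values outside [0, 100] indicate under/overshoot).
    """
    denom = pc2_target - pc2_start
    if denom == 0:
        raise ValueError("pc2_start and pc2_target must differ")
    return 100.0 * (np.asarray(pc2_t, dtype=float) - pc2_start) / denom
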