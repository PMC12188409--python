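"""Stator frame construction and the γ rotary angle.

The stator frame is built from the three β N-terminal domains (Cα of
residues 10–82): their centers of mass define the origin (centroid) and the
z axis (plane normal, oriented so the γ C-terminal protrusion points to
+z); a final rotation about z puts the β_DP N-domain center on the +x axis.

The rotary angle of γ in a frame-aligned model, relative to a frame-aligned
reference, is the planar rotation of the x axis under the optimal proper
rotation that best fits the model's γ subset (Cα of residues 1–30 and
221–270) onto the reference's.  Sign convention: counterclockwise
(hydrolysis direction) positive; a negative angle is toward synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from f1rotor import structure_io, datasets
from f1rotor._units import wrap_angle_deg

__all__ = ["RotaryFrame", "RotaryAngle", "build_frame", "gamma_angle"]


@dataclass(frozen=True)
class RotaryFrame:
    """Right-handed orthonormal frame (origin in Å, unit axes)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        axes = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-10):
            raise ValueError("axes not orthonormal")
        if not np.allclose(np.cross(self.x_axis, self.y_axis), self.z_axis,
                           atol=1e-10):
            raise ValueError("axes not right-handed")

    @property
    def rotation(self):
        """World→frame rotation matrix (rows are the axes)."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])


@dataclass(frozen=True)
class RotaryAngle:
    """Signed rotary angle in degrees, hydrolysis (CCW) positive."""

    degrees: float

    def __post_init__(self):
        object.__setattr__(self, "degrees", float(wrap_angle_deg(self.degrees)))


def _ndom_centers(model, role_map=None):
    """Per-β-chain center of mass (plain Cα mean) of the N-domain, (3, 3)."""
    rmap = role_map or model.role_map or structure_io.assign_chain_roles(model)
    betas = sorted(rmap["beta"])
    if len(betas) != 3:
        raise structure_io.ChainRoleError(
            f"expected 3 beta chains, got {len(betas)}")
    centers = []
    for cid in betas:
        xyz, _ = structure_io.select(model, datasets.BETA_NDOM_CA, chains=[cid])
        centers.append(xyz.mean(axis=0))
    return np.stack(centers), betas


def build_frame(model, dp_chain, role_map=None,
                ndom_sel=datasets.BETA_NDOM_CA):
    """Construct the stator frame and return ``(frame, aligned_model)``.

    ``dp_chain`` names the β chain of the DP interface (role assignment is
    an input, e.g. from a landscape classification); its N-domain center is
    placed on the +x axis.  z-orientation is disambiguated by the γ
    C-terminal protrusion: the mean of the γ C-terminal half must have
    positive z in the frame.
    """
    rmap = role_map or model.role_map or structure_io.assign_chain_roles(model)
    centers, betas = _ndom_centers(model, role_map=rmap)
    if dp_chain not in betas:
        raise structure_io.ChainRoleError(
            f"dp_chain {dp_chain!r} is not one of the beta chains {betas}")
    origin = centers.mean(axis=0)

    # plane normal through the three centers
    normal = np.cross(centers[1] - centers[0], centers[2] - centers[0])
    nrm = np.linalg.norm(normal)
    if nrm < 1e-9:
        raise ValueError("beta N-domain centers are collinear")
    z = normal / nrm

    # orient z toward the protruding C-terminal half of gamma
    gchain = rmap["gamma"][0]
    gres = model.residue_numbers(gchain)
    half = gres[len(gres) // 2:]
    gsel = structure_io.Selection("gamma", structure_io._runs(half.tolist()), "CA")
    gxyz, _ = structure_io.select(model, gsel, chains=[gchain])
    if np.dot(gxyz.mean(axis=0) - origin, z) < 0:
        z = -z

    # x toward the DP N-domain center, orthogonalized against z
    dp_center = centers[betas.index(dp_chain)]
    x = dp_center - origin
    x = x - np.dot(x, z) * z
    xn = np.linalg.norm(x)
    if xn < 1e-9:
        raise ValueError("DP center lies on the z axis")
    x = x / xn
    y = np.cross(z, x)
    frame = RotaryFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)
    aligned = model.transformed(rotation=frame.rotation,
                                translation=None)
    # translate after rotation: R (p - origin) = R p - R origin
    aligned = aligned.transformed(translation=-frame.rotation @ origin)
    return frame, aligned


def gamma_angle(model, reference, role_map=None, ref_role_map=None,
                fit_sel=datasets.GAMMA_FIT_CA, sign=+1.0) -> RotaryAngle:
    """Rotary angle of ``model``'s γ relative to ``reference``'s γ.

    Both models must already be frame-aligned (see :func:`build_frame`).
    The optimal proper rotation (translation + rotation least-squares fit)
    mapping the model's γ subset onto the reference's is applied to the unit
    x axis; the returned angle is ``atan2(y', x')`` of the rotated axis
    projected on the xy plane, in degrees, CCW/hydrolysis positive.
    ``sign=-1`` flips the convention.
    """
    rmap = role_map or model.role_map or structure_io.assign_chain_roles(model)
    ref_rmap = (ref_role_map or reference.role_map
                or structure_io.assign_chain_roles(reference))
    xyz_mod, lab_mod = structure_io.select(model, fit_sel,
                                           chains=rmap["gamma"])
    xyz_ref, lab_ref = structure_io.select(reference, fit_sel,
                                           chains=ref_rmap["gamma"])
    if [l[1:] for l in lab_mod] != [l[1:] for l in lab_ref]:
        raise ValueError("gamma subset mismatch between model and reference")
    # rotation taking the model subset onto the reference subset
    rot, _ = Rotation.align_vectors(xyz_ref - xyz_ref.mean(axis=0),
                                    xyz_mod - xyz_mod.mean(axis=0))
    # the model's gamma is the reference's gamma rotated by the inverse
    x_rot = rot.inv().as_matrix() @ np.array([1.0, 0.0, 0.0])
    angle = np.degrees(np.arctan2(x_rot[1], x_rot[0]))
    return RotaryAngle(degrees=sign * angle)
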