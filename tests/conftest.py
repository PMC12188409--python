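"""Shared fixtures: synthetic F1-like structures with realistic chain/residue
layout (three ~510-residue α chains, three ~480-residue β chains, a
272-residue γ, an optional 60-residue inhibitor), built deterministically
from a seed."""

import numpy as np
import pytest

from f1rotor.structure_io import StructureModel

F1_ROLE_MAP = {
    "alpha": ("A", "B", "C"),
    "beta": ("D", "E", "F"),
    "gamma": ("G",),
    "inhibitor": ("I",),
}


def _spiral(n, radius, z0, z1, phase, wobble=0.0, rng=None):
    """Non-degenerate deterministic 3-D curve for chain coordinates."""
    t = np.linspace(0.0, 6.0 * np.pi, n)
    xyz = np.stack([
        radius * np.cos(t + phase),
        radius * np.sin(t + phase),
        np.linspace(z0, z1, n),
    ], axis=1)
    if wobble and rng is not None:
        xyz += rng.normal(0.0, wobble, xyz.shape)
    return xyz


def make_synthetic_f1(seed=0, gamma_rotation_deg=0.0, noise_sigma=0.0,
                      inhibitor=True, noise_seed=None):
    """CA-only synthetic F1 head.

    The base geometry is a deterministic function of ``seed``; the γ chain
    can be rigidly rotated about z by ``gamma_rotation_deg`` and isotropic
    Gaussian noise of ``noise_sigma`` Å can be added (stream from
    ``noise_seed``, default = seed + 1000).
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    chains, resids, coords = [], [], []

    def add_chain(cid, n_res, xyz):
        chains.extend([cid] * n_res)
        resids.extend(range(1, n_res + 1))
        coords.append(xyz)

    # alpha / beta rings: N-domain residues clustered near a ring center,
    # the rest wandering outward (deterministic wobble per chain)
    for k, cid in enumerate("ABC"):  # alpha, azimuth 60 + 120k
        phi = np.deg2rad(60.0 + 120.0 * k)
        center = 25.0 * np.array([np.cos(phi), np.sin(phi), 0.0])
        xyz = _spiral(510, 6.0, -10.0, 35.0, phase=phi, wobble=0.3,
                      rng=rng) + center
        add_chain(cid, 510, xyz)
    for k, cid in enumerate("DEF"):  # beta, azimuth 120k
        phi = np.deg2rad(120.0 * k)
        center = 25.0 * np.array([np.cos(phi), np.sin(phi), 0.0])
        xyz = _spiral(480, 6.0, -10.0, 33.0, phase=phi, wobble=0.3,
                      rng=rng) + center
        # keep the N-domain (residues 10-82) tight around the center
        xyz[9:82] = center + _spiral(73, 3.0, -4.0, 4.0, phase=phi,
                                     wobble=0.2, rng=rng)
        add_chain(cid, 480, xyz)

    # gamma: coiled shaft along z, C-terminal half protruding to +z
    gxyz = _spiral(272, 7.0, -18.0, 40.0, phase=0.7, wobble=0.25, rng=rng)
    if gamma_rotation_deg:
        a = np.deg2rad(gamma_rotation_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]])
        gxyz = gxyz @ rot.T
    add_chain("G", 272, gxyz)

    if inhibitor:
        ixyz = _spiral(60, 3.0, -16.0, -2.0, phase=2.1, wobble=0.2, rng=rng)
        ixyz += np.array([10.0, 4.0, 0.0])
        add_chain("I", 60, ixyz)

    xyz = np.concatenate(coords)
    if noise_sigma:
        nrng = np.random.default_rng(
            np.random.SeedSequence(int(noise_seed if noise_seed is not None
                                       else seed + 1000)))
        xyz = xyz + nrng.normal(0.0, noise_sigma, xyz.shape)

    n = len(xyz)
    return StructureModel(
        chain_ids=np.array(chains, dtype="U4"),
        res_ids=np.array(resids, dtype=int),
        res_names=np.full(n, "ALA", dtype="U3"),
        atom_names=np.full(n, "CA", dtype="U4"),
        elements=np.full(n, "C", dtype="U2"),
        coords=xyz,
        hetero=np.zeros(n, dtype=bool),
        role_map=dict(F1_ROLE_MAP),
    )


@pytest.fixture(scope="session")
def f1_model():
    return make_synthetic_f1(seed=0)


@pytest.fixture(scope="session")
def f1_factory():
    return make_synthetic_f1


def rigid_motion(seed):
    """A seeded random proper rotation + translation."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.normal(0.0, 20.0, 3)
    return rot, shift
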