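"""Physical constants and unit conversions used across the package.

Conventions: coordinates in Å, PCA in nm, time in ns, angles in degrees at
user interfaces and radians internally, energies in kcal/mol, torques in
kcal mol⁻¹ rad⁻¹ or pN·nm rad⁻¹.
"""

import numpy as np

#: 1 kcal/mol expressed as pN·nm per molecule (4184 J / N_A / 1e-21 J).
KCAL_PER_MOL_AS_PN_NM = 6.9477

#: Exact SI elementary charge, C.
ELEMENTARY_CHARGE = 1.602176634e-19

#: 1 pN·nm in joule.
PN_NM_AS_J = 1e-21

#: Å per nm.
ANGSTROM_PER_NM = 10.0


def deg2rad(x):
    return np.deg2rad(x)


def rad2deg(x):
    return np.rad2deg(x)


def wrap_angle_deg(x):
    """Wrap an angle in degrees to (-180, 180]."""
    w = np.asarray(x, dtype=float) % 360.0
    w = np.where(w > 180.0, w - 360.0, w)
    return w if w.ndim else float(w)


def wrap_angle_rad(x):
    """Wrap an angle in radians to (-pi, pi]."""
    w = np.asarray(x, dtype=float) % (2.0 * np.pi)
    w = np.where(w > np.pi, w - 2.0 * np.pi, w)
    return w if w.ndim else float(w)
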