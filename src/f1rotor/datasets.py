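"""Canonical residue subsets and the bovine-MF1 structure manifest.

The residue subsets are the analysis selections used throughout the package:
they cover the α/β regions resolved in all crystallographic entries (for the
conformational PCA), the β N-terminal domain (stator frame), the γ core and
γ fitting subsets (rotary angle, flexible-rotor split), and the IF1 helix
segments (trajectory metrics).

``BMF1_STRUCTURES`` lists one row per analyzed F1 copy.  Several crystal
forms carry more than one F1 complex per asymmetric unit (most prominently
the 1ohh form, in which an IF1 dimer bridges two F1 molecules), so the 23
deposited entry codes yield 26 analyzed structures and, at three catalytic
interfaces each, 78 αβ pairs.
"""

from f1rotor.structure_io import Selection, parse_ranges

#: α-subunit Cα subset resolved in all entries.
ALPHA_RANGES = parse_ranges("24-401,413-483,494-509")
#: β-subunit Cα subset resolved in all entries.
BETA_RANGES = parse_ranges("10-126,129-310,312-387,396-464")
#: β N-terminal domain used for the stator frame.
BETA_NDOM_RANGES = parse_ranges("10-82")
#: γ subset used for the best-fit rotary angle.
GAMMA_FIT_RANGES = parse_ranges("1-30,221-270")
#: γ coiled-coil core (buried) vs protruded split used for rotor biasing.
GAMMA_CORE_RANGES = parse_ranges("1-26,228-272")
GAMMA_PROTRUDED_RANGES = parse_ranges("27-227")

ALPHA_CA = Selection("alpha", ALPHA_RANGES, "CA")
BETA_CA = Selection("beta", BETA_RANGES, "CA")
BETA_NDOM_CA = Selection("beta", BETA_NDOM_RANGES, "CA")
GAMMA_FIT_CA = Selection("gamma", GAMMA_FIT_RANGES, "CA")
GAMMA_CORE_CA = Selection("gamma", GAMMA_CORE_RANGES, "CA")
GAMMA_PROTRUDED_CA = Selection("gamma", GAMMA_PROTRUDED_RANGES, "CA")

#: IF1 segments: short helix, long helix and its three sub-segments,
#: and the Cα triplet defining the long-helix bending angle.
IF1_SEGMENTS = {
    "short_helix": (14, 18),
    "long_helix": (21, 45),
    "long_sub1": (21, 30),
    "long_sub2": (31, 37),
    "long_sub3": (38, 45),
}
IF1_BEND_TRIPLET = (21, 38, 45)

#: Entries whose deposited structure carries a bound inhibitor chain.
IF1_BOUND_IDS = frozenset({"1ohh", "2v7q", "4tsf", "4tt3", "4z1m"})

#: One row per analyzed F1 copy: (pdb_id, copy_index, inhibitor_bound).
BMF1_STRUCTURES = tuple(
    (pdb_id, copy, pdb_id in IF1_BOUND_IDS)
    for pdb_id, copies in (
        ("1bmf", 1), ("1cow", 1), ("1e1q", 1), ("1e1r", 1), ("1e79", 1),
        ("1efr", 1), ("1h8e", 1), ("1h8h", 1), ("1nbm", 1), ("1ohh", 2),
        ("1w0j", 1), ("1w0k", 1), ("2ck3", 1), ("2jdi", 1), ("2jiz", 2),
        ("2jj1", 2), ("2jj2", 1), ("2v7q", 1), ("4asu", 1), ("4tsf", 1),
        ("4tt3", 1), ("4yxw", 1), ("4z1m", 1),
    )
    for copy in range(1, copies + 1)
)

#: αβ pairs contributed per F1 structure (three catalytic interfaces).
PAIRS_PER_STRUCTURE = 3


def expected_pair_count(manifest=BMF1_STRUCTURES):
    """Number of αβ pairs a landscape analysis over ``manifest`` yields."""
    return PAIRS_PER_STRUCTURE * len(manifest)
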