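"""Structure and trajectory bookkeeping.

Reads and writes (multi-model) PDB files through biotite, resolves residue
selections given as chain *roles* (alpha, beta, gamma, inhibitor) plus
inclusive residue ranges, and provides the canonical atom ordering contract
used by every downstream module: atoms are sorted by ascending
``(chain_id, residue_number, atom_name)``.

Chain roles are assigned either by an explicit user-supplied map or by a
size heuristic appropriate for mitochondrial F1 entries: the three largest
(~510-residue) chains are α, the next three (~480) are β, a ~270-residue
chain is γ, and a chain of at most 60 residues is the inhibitor.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "StructureModel",
    "Selection",
    "Trajectory",
    "ChainRoleError",
    "MissingResidueError",
    "PDBParseError",
    "FieldWidthError",
    "read_pdb",
    "select",
    "write_multimodel_pdb",
    "assign_chain_roles",
    "parse_ranges",
    "intersect_selection",
]

ROLES = ("alpha", "beta", "gamma", "inhibitor")

# PDB %8.3f coordinate field limits
_COORD_MAX = 9999.999
_COORD_MIN = -999.999


class PDBParseError(ValueError):
    """Unreadable PDB record; carries the 1-based line number."""

    def __init__(self, message, line_number=None):
        self.line_number = line_number
        super().__init__(
            message if line_number is None else f"line {line_number}: {message}"
        )


class MissingResidueError(KeyError):
    """A requested residue (or atom within it) is absent from the model."""

    def __init__(self, gaps):
        #: list of (chain_id, residue_number) tuples
        self.gaps = list(gaps)
        desc = ", ".join(f"{c}/{r}" for c, r in self.gaps)
        super().__init__(f"missing residues/atoms: {desc}")


class ChainRoleError(ValueError):
    """Chain-role assignment failed or was ambiguous."""


class FieldWidthError(ValueError):
    """A coordinate does not fit the fixed-width PDB field."""


@dataclass
class StructureModel:
    """Labeled atomic coordinates for one model.

    All label arrays are parallel to ``coords`` (N atoms).  ``hetero`` flags
    HETATM records (waters, ligands), which are retained but never matched by
    role selections.
    """

    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray  # (N, 3) Å
    hetero: np.ndarray
    title: str = ""
    model_index: int = 1
    role_map: dict = field(default_factory=dict)  # role -> tuple of chain ids

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for name in ("chain_ids", "res_ids", "res_names", "atom_names",
                     "elements", "hetero"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_ids.tolist(), self.res_ids.tolist(),
                        self.atom_names.tolist()))
        if len(set(keys)) != n:
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom {dup} within one model")

    def __len__(self):
        return len(self.coords)

    def sorted(self) -> "StructureModel":
        """Return a copy in canonical (chain, residue, atom-name) order."""
        order = np.lexsort((self.atom_names, self.res_ids, self.chain_ids))
        return replace(
            self,
            chain_ids=self.chain_ids[order],
            res_ids=self.res_ids[order],
            res_names=self.res_names[order],
            atom_names=self.atom_names[order],
            elements=self.elements[order],
            coords=self.coords[order],
            hetero=self.hetero[order],
        )

    def chains(self):
        """Chain ids in order of first appearance."""
        _, idx = np.unique(self.chain_ids, return_index=True)
        return [self.chain_ids[i] for i in np.sort(idx)]

    def residue_numbers(self, chain_id):
        mask = (self.chain_ids == chain_id) & ~self.hetero
        return np.unique(self.res_ids[mask])

    def transformed(self, rotation=None, translation=None) -> "StructureModel":
        """Apply ``x -> R x + t`` to all coordinates."""
        xyz = self.coords
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, dtype=float)
        return replace(self, coords=xyz)


@dataclass(frozen=True)
class Selection:
    """A chain role plus sorted, non-overlapping inclusive residue ranges."""

    chain_role: str
    residue_ranges: tuple  # of (start, stop) inclusive
    atom_filter: str = "CA"  # one of {"CA", "heavy", "all"}

    def __post_init__(self):
        if self.chain_role not in ROLES:
            raise ValueError(f"unknown chain role {self.chain_role!r}")
        if self.atom_filter not in ("CA", "heavy", "all"):
            raise ValueError(f"unknown atom filter {self.atom_filter!r}")
        rr = tuple((int(a), int(b)) for a, b in self.residue_ranges)
        for a, b in rr:
            if a > b:
                raise ValueError(f"empty interval {a}-{b}")
        for (a1, b1), (a2, b2) in zip(rr, rr[1:]):
            if a2 <= b1:
                raise ValueError("residue ranges must be sorted and disjoint")
        object.__setattr__(self, "residue_ranges", rr)

    @property
    def residues(self):
        """All residue numbers covered, ascending."""
        out = []
        for a, b in self.residue_ranges:
            out.extend(range(a, b + 1))
        return out

    def __len__(self):
        return sum(b - a + 1 for a, b in self.residue_ranges)


def parse_ranges(text: str):
    """Parse a range string like ``"1-26,228-272"`` into interval tuples."""
    ranges = []
    for token in str(text).split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token[1:]:
            cut = token.index("-", 1)
            a, b = int(token[:cut]), int(token[cut + 1:])
        else:
            a = b = int(token)
        ranges.append((a, b))
    ranges.sort()
    return tuple(ranges)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, with per-frame metadata."""

    frames: list  # of StructureModel
    times: np.ndarray  # ns
    metadata: dict = field(default_factory=dict)  # key -> array over frames

    def __post_init__(self):
        if not self.frames:
            raise ValueError("empty trajectory")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if (len(f) != len(ref)
                    or not np.array_equal(f.chain_ids, ref.chain_ids)
                    or not np.array_equal(f.res_ids, ref.res_ids)
                    or not np.array_equal(f.atom_names, ref.atom_names)):
                raise ValueError("all frames must share one atom ordering")
        for key, vals in self.metadata.items():
            vals = np.asarray(vals, dtype=float)
            if len(vals) != len(self.frames):
                raise ValueError(f"metadata {key!r} length mismatch")
            self.metadata[key] = vals

    def __len__(self):
        return len(self.frames)


# ---------------------------------------------------------------------------
# chain-role assignment

def assign_chain_roles(model: StructureModel) -> dict:
    """Map chain roles by residue count.

    Three largest chains → alpha, next three → beta, a 150–350-residue chain
    → gamma, a ≤60-residue chain → inhibitor.  Chains that fit no slot (δ, ε,
    waters) are left unassigned.  Returns ``{role: (chain_id, ...)}``.
    """
    counts = {c: len(model.residue_numbers(c)) for c in model.chains()}
    counts = {c: n for c, n in counts.items() if n > 0}
    if len(counts) < 7:
        raise ChainRoleError(
            f"expected >= 7 polymer chains for auto-assignment, got {len(counts)}"
        )
    # stable sort: count descending, chain id ascending
    ranked = sorted(counts, key=lambda c: (-counts[c], c))
    roles = {"alpha": tuple(sorted(ranked[:3])),
             "beta": tuple(sorted(ranked[3:6]))}
    rest = ranked[6:]
    gamma = [c for c in rest if 150 <= counts[c] <= 350]
    if not gamma:
        raise ChainRoleError("no candidate gamma chain (150-350 residues)")
    roles["gamma"] = (gamma[0],)
    inh = [c for c in rest if c not in gamma and 10 <= counts[c] <= 60]
    if inh:
        roles["inhibitor"] = (max(inh, key=lambda c: counts[c]),)
    return roles


def _resolve_chains(model, sel, role_map=None, chains=None):
    if chains is not None:
        return list(chains)
    rmap = role_map or model.role_map
    if not rmap:
        rmap = assign_chain_roles(model)
    if sel.chain_role not in rmap:
        raise ChainRoleError(f"role {sel.chain_role!r} not present in role map")
    return list(rmap[sel.chain_role])


# ---------------------------------------------------------------------------
# reading

def _find_bad_line(text):
    for i, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                [float(line[c:c + 8]) for c in (30, 38, 46)]
                int(line[22:26])
            except (ValueError, IndexError):
                return i, line.rstrip()
    return None, None


def read_pdb(path, model_policy="first", role_map=None, altloc="occupancy"):
    """Read a PDB file into a :class:`StructureModel` or :class:`Trajectory`.

    ``model_policy="first"`` returns the first MODEL as a StructureModel;
    ``"all"`` returns a Trajectory over every MODEL block (times default to
    the frame index in ns).  Waters/heteroatoms are kept with ``hetero=True``.
    Alternate locations collapse to one conformer by occupancy.
    """
    if model_policy not in ("first", "all"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    with open(path) as fh:
        text = fh.read()
    try:
        pfile = pdb.PDBFile.read(io.StringIO(text))
        n_models = pfile.get_model_count()
        models = []
        for i in range(1, n_models + 1):
            arr = pfile.get_structure(model=i, altloc=altloc)
            models.append(_from_atom_array(arr, model_index=i, role_map=role_map))
            if model_policy == "first":
                break
    except PDBParseError:
        raise
    except Exception as exc:  # biotite raises various error types
        line_no, line = _find_bad_line(text)
        if line_no is not None:
            raise PDBParseError(f"unreadable record {line!r}", line_no) from exc
        raise PDBParseError(str(exc)) from exc
    if model_policy == "first":
        return models[0]
    times = np.arange(len(models), dtype=float)
    return Trajectory(frames=models, times=times)


def _from_atom_array(arr, model_index=1, role_map=None):
    model = StructureModel(
        chain_ids=arr.chain_id.astype("U4"),
        res_ids=arr.res_id.astype(int),
        res_names=arr.res_name.astype("U3"),
        atom_names=arr.atom_name.astype("U4"),
        elements=arr.element.astype("U2"),
        coords=np.asarray(arr.coord, dtype=float),
        hetero=np.asarray(arr.hetero, dtype=bool),
        model_index=model_index,
    ).sorted()
    if role_map:
        model.role_map = dict(role_map)
    return model


def _to_atom_array(model: StructureModel):
    n = len(model)
    arr = struc.AtomArray(n)
    arr.chain_id = model.chain_ids.astype("U4")
    arr.res_id = model.res_ids.astype(int)
    arr.res_name = model.res_names.astype("U5")
    arr.atom_name = model.atom_names.astype("U6")
    arr.element = model.elements.astype("U2")
    arr.hetero = model.hetero.astype(bool)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    return arr


# ---------------------------------------------------------------------------
# selection

def select(model, sel, role_map=None, chains=None):
    """Extract coordinates for a :class:`Selection`.

    Returns ``(coords, labels)`` where ``coords`` is (N, 3) Å in ascending
    (chain, residue, atom-name) order and ``labels`` is the parallel list of
    ``(chain_id, residue_number, atom_name)`` tuples.  Any residue in the
    requested ranges that is absent (or lacks the requested atoms) raises
    :class:`MissingResidueError` listing every gap.
    """
    chain_list = _resolve_chains(model, sel, role_map=role_map, chains=chains)
    wanted = sel.residues
    m = model.sorted()
    res_mask = np.zeros(len(m), dtype=bool)
    for a, b in sel.residue_ranges:
        res_mask |= (m.res_ids >= a) & (m.res_ids <= b)
    if sel.atom_filter == "CA":
        atom_mask = m.atom_names == "CA"
    elif sel.atom_filter == "heavy":
        atom_mask = m.elements != "H"
    else:
        atom_mask = np.ones(len(m), dtype=bool)
    gaps = []
    take = np.zeros(len(m), dtype=bool)
    for cid in sorted(chain_list):
        cmask = (m.chain_ids == cid) & ~m.hetero
        present = set(m.res_ids[cmask & res_mask & atom_mask].tolist())
        gaps.extend((cid, r) for r in wanted if r not in present)
        take |= cmask & res_mask & atom_mask
    if gaps:
        raise MissingResidueError(gaps)
    labels = list(zip(m.chain_ids[take].tolist(), m.res_ids[take].tolist(),
                      m.atom_names[take].tolist()))
    return m.coords[take].copy(), labels


def intersect_selection(models, sel, role_map=None):
    """Restrict ``sel`` to residues resolved in *all* models.

    Used when residue ranges must hold across a heterogeneous batch of
    entries (landscape analyses pick ranges "resolved in all structures").
    The intersection is computed per residue number across every chain of the
    role in every model; the returned Selection covers only residues present
    (with the requested atoms) everywhere.
    """
    common = set(sel.residues)
    for model in models:
        m = model.sorted()
        chain_list = _resolve_chains(model, sel, role_map=role_map)
        if sel.atom_filter == "CA":
            atom_mask = m.atom_names == "CA"
        elif sel.atom_filter == "heavy":
            atom_mask = m.elements != "H"
        else:
            atom_mask = np.ones(len(m), dtype=bool)
        for cid in chain_list:
            cmask = (m.chain_ids == cid) & ~m.hetero & atom_mask
            common &= set(m.res_ids[cmask].tolist())
    ranges = _runs(sorted(common))
    return replace(sel, residue_ranges=ranges)


def _runs(numbers):
    """Collapse a sorted integer list into inclusive (start, stop) runs."""
    runs = []
    for n in numbers:
        if runs and n == runs[-1][1] + 1:
            runs[-1][1] = n
        else:
            runs.append([n, n])
    return tuple((a, b) for a, b in runs)


# ---------------------------------------------------------------------------
# writing

def write_multimodel_pdb(traj, path):
    """Write a Trajectory (or single StructureModel) as a multi-model PDB.

    Coordinates outside the fixed-width %8.3f field raise
    :class:`FieldWidthError` instead of being truncated.  Round-trip
    guarantee: ``read_pdb(write(traj), model_policy="all")`` reproduces
    coordinates to 3 decimals and labels exactly.
    """
    if isinstance(traj, StructureModel):
        traj = Trajectory(frames=[traj], times=[0.0])
    for k, frame in enumerate(traj.frames):
        lo, hi = frame.coords.min(), frame.coords.max()
        if hi > _COORD_MAX or lo < _COORD_MIN:
            raise FieldWidthError(
                f"frame {k}: coordinate range [{lo:.3f}, {hi:.3f}] exceeds the "
                f"PDB field width [{_COORD_MIN}, {_COORD_MAX}]"
            )
    pfile = pdb.PDBFile()
    if len(traj) == 1:
        pfile.set_structure(_to_atom_array(traj.frames[0]))
    else:
        stack = struc.stack([_to_atom_array(f) for f in traj.frames])
        pfile.set_structure(stack)
    pfile.write(str(path))
    return path
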