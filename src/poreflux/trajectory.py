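"""Frame model: topology, trajectory, channel sections and atom selections.

Trajectories are held fully in memory as numpy arrays in Å/ns regardless of
the on-disk dialect (nm-based formats are converted on load).  Only
orthorhombic boxes are supported.  A :class:`ChannelSection` pins down one
monomer's pore: its axis is parallel to z by package convention (+z =
extracellular); files with the protein inverted must be flipped before
analysis (``flip_z``).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import PorefluxError

__all__ = [
    "Topology",
    "Trajectory",
    "ChannelSection",
    "load",
    "write",
    "select",
    "unwrap_z",
]

_ION_ELEMENTS = {
    "NA": "NA", "SOD": "NA", "K": "K", "POT": "K", "CL": "CL", "CLA": "CL",
    "MG": "MG", "CA2": "CA", "ZN": "ZN",
}


def guess_element(name: str, resname: str = "") -> str:
    """Guess the chemical element from an atom name.

    Monatomic-ion residue names take precedence (``NA`` in resname ``NA`` is
    sodium, while ``NA`` in an amino acid would be nitrogen).
    """
    rn = resname.strip().upper()
    if rn in _ION_ELEMENTS:
        return _ION_ELEMENTS[rn]
    m = re.search(r"[A-Za-z]", name)
    if not m:
        return "X"
    return m.group(0).upper()


@dataclass
class Topology:
    """Static atom attributes: names, residues, chains, optional charges.

    Atom indices are implicit and contiguous from 0.
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    chainids: np.ndarray
    elements: np.ndarray | None = None
    charges: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("resnames", "resids", "chainids"):
            if len(getattr(self, attr)) != n:
                raise PorefluxError(f"topology field {attr!r} length mismatch")
        if any(str(c) == "" for c in self.chainids):
            raise PorefluxError("chain ids must be non-empty")
        if self.elements is None:
            self.elements = np.array(
                [guess_element(a, r) for a, r in zip(self.names, self.resnames)]
            )

    @property
    def n_atoms(self) -> int:
        return len(self.names)


@dataclass
class Trajectory:
    """Coordinates (frames × atoms × 3, Å), per-frame orthorhombic box (Å)
    and strictly increasing time stamps (ns), bound to a :class:`Topology`."""

    coords: np.ndarray
    box: np.ndarray
    times: np.ndarray
    topology: Topology

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise PorefluxError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise PorefluxError(
                f"atom-count mismatch: topology has {self.topology.n_atoms} "
                f"atoms, trajectory has {self.coords.shape[1]}"
            )
        if len(self.times) != self.n_frames or len(self.box) != self.n_frames:
            raise PorefluxError("times/box length must equal frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise PorefluxError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dt_ns(self) -> float:
        """Mean frame spacing in ns."""
        if self.n_frames < 2:
            return 0.0
        return float((self.times[-1] - self.times[0]) / (self.n_frames - 1))


@dataclass
class ChannelSection:
    """One monomer's transmembrane section: a cylinder of given length
    centred at ``z_center`` on the axis through ``axis_xy``, with the ar/R
    constriction at ``arR_z``."""

    chain_id: str
    axis_xy: tuple[float, float] = (0.0, 0.0)
    z_center: float = 0.0
    length: float = 30.0
    arR_z: float = 7.5
    pore_radius: float = 6.0
    vestibule: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise PorefluxError("section length must be positive")
        if not (self.z_lo <= self.arR_z <= self.z_hi):
            raise PorefluxError("arR_z must lie inside the section")

    @property
    def z_lo(self) -> float:
        return self.z_center - self.length / 2.0

    @property
    def z_hi(self) -> float:
        return self.z_center + self.length / 2.0

    def lateral_mask(self, coords_xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points within the pore cylinder radius."""
        d2 = (coords_xy[..., 0] - self.axis_xy[0]) ** 2 + (
            coords_xy[..., 1] - self.axis_xy[1]
        ) ** 2
        return d2 <= self.pore_radius**2


# ---------------------------------------------------------------------------
# File I/O (via MDAnalysis readers/writers)
# ---------------------------------------------------------------------------

def _check_orthorhombic(dims: np.ndarray) -> None:
    if dims is None or np.any(dims[:3] <= 0):
        raise PorefluxError("zero or missing box dimension")
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise PorefluxError("triclinic boxes are unsupported")


def load(topology_path, trajectory_path=None) -> tuple[Topology, Trajectory]:
    """Read a PDB/GRO topology plus an XTC/DCD/TRR trajectory.

    All coordinates are normalised to Å and times to ns.  An atom-count
    mismatch between the two files is a hard error naming both counts.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        top_u = mda.Universe(str(topology_path))
        n_top = top_u.atoms.n_atoms
        if trajectory_path is not None:
            try:
                u = mda.Universe(str(topology_path), str(trajectory_path))
            except Exception as exc:  # count mismatch raised by the reader
                n_traj = _trajectory_n_atoms(str(trajectory_path))
                if n_traj is not None and n_traj != n_top:
                    raise PorefluxError(
                        f"atom-count mismatch: topology has {n_top} atoms, "
                        f"trajectory has {n_traj}"
                    ) from exc
                raise
        else:
            u = top_u

    ag = u.atoms
    chain = _chain_ids(ag)
    charges = None
    if hasattr(ag, "charges"):
        charges = np.asarray(ag.charges, dtype=float)
    top = Topology(
        names=np.asarray(ag.names, dtype=object),
        resnames=np.asarray(ag.resnames, dtype=object),
        resids=np.asarray(ag.resids, dtype=int),
        chainids=chain,
        charges=charges,
    )

    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, n_top, 3), dtype=np.float32)
    box = np.empty((n_frames, 3), dtype=float)
    times = np.empty(n_frames, dtype=float)
    for i, ts in enumerate(u.trajectory):
        _check_orthorhombic(ts.dimensions)
        coords[i] = ag.positions  # MDAnalysis frames are already in Å
        box[i] = ts.dimensions[:3]
        times[i] = ts.time / 1000.0  # ps -> ns
    if n_frames > 1 and np.allclose(np.diff(times), 0):
        # formats without time stamps: fall back to frame index in ns
        times = np.arange(n_frames, dtype=float)
    return top, Trajectory(coords=coords, box=box, times=times, topology=top)


def _chain_ids(ag) -> np.ndarray:
    for attr in ("chainIDs", "segids"):
        if hasattr(ag, attr):
            vals = np.asarray(getattr(ag, attr), dtype=object)
            vals = np.array([str(v).strip() or "X" for v in vals], dtype=object)
            return vals
    return np.array(["X"] * ag.n_atoms, dtype=object)


def _trajectory_n_atoms(path: str):
    import MDAnalysis as mda

    try:
        reader = mda.coordinates.core.reader(path)
        return reader.n_atoms
    except Exception:
        return None


def _mda_universe(top: Topology, traj: Trajectory):
    """Build an in-memory MDAnalysis Universe mirroring our frame model."""
    import MDAnalysis as mda

    # residues are runs of identical (chainid, resid)
    keys = list(zip(top.chainids, top.resids))
    resindex = np.zeros(top.n_atoms, dtype=int)
    res_keys = [keys[0]]
    for i in range(1, top.n_atoms):
        if keys[i] != keys[i - 1]:
            res_keys.append(keys[i])
        resindex[i] = len(res_keys) - 1
    n_res = len(res_keys)
    first_atom = np.searchsorted(resindex, np.arange(n_res))

    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=n_res,
        n_segments=n_res,
        atom_resindex=resindex,
        residue_segindex=np.arange(n_res),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in top.names])
    u.add_TopologyAttr("resnames", [str(top.resnames[i]) for i in first_atom])
    u.add_TopologyAttr("resids", [int(top.resids[i]) for i in first_atom])
    u.add_TopologyAttr("chainIDs", [str(x)[:1] for x in top.chainids])
    u.add_TopologyAttr("elements", [str(x) for x in top.elements])
    u.add_TopologyAttr("segids", [str(top.chainids[i])[:4] for i in first_atom])
    if top.charges is not None:
        u.add_TopologyAttr("charges", [float(q) for q in top.charges])
    u.load_new(
        np.ascontiguousarray(traj.coords, dtype=np.float32),
        format="memory",
        dimensions=np.column_stack(
            [traj.box, np.full((traj.n_frames, 3), 90.0)]
        ),
    )
    for ts, t_ns in zip(u.trajectory, traj.times):
        ts.time = t_ns * 1000.0
    return u


def write(top: Topology, traj: Trajectory, topology_path, trajectory_path=None):
    """Write the topology as PDB (first frame) and the trajectory as
    XTC/DCD/TRR according to the file extension."""
    import MDAnalysis as mda

    u = _mda_universe(top, traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.trajectory[0]
        u.atoms.write(str(topology_path))
        if trajectory_path is not None:
            with mda.Writer(
                str(trajectory_path), u.atoms.n_atoms,
                dt=traj.dt_ns * 1000.0 or 1.0,
            ) as w:
                for ts in u.trajectory:
                    ts.time = traj.times[ts.frame] * 1000.0
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------
#
#   expr     := or_expr
#   or_expr  := and_expr ('or' and_expr)*
#   and_expr := unary ('and' unary)*
#   unary    := 'not' unary | '(' expr ')' | clause
#   clause   := ('name'|'resname'|'resid'|'chain'|'element') value+
#
# A clause with several values matches any of them; ``resid`` accepts integer
# ranges written a:b (inclusive).

_KEYWORDS = {"name", "resname", "resid", "chain", "element"}
_OPS = {"and", "or", "not", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _Parser:
    def __init__(self, tokens: list[str], top: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = top

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise PorefluxError(f"unexpected token {self.peek()!r} in selection")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            if self.next() != ")":
                raise PorefluxError("unbalanced parenthesis in selection")
            return mask
        return self.clause()

    def clause(self) -> np.ndarray:
        key = self.next()
        if key not in _KEYWORDS:
            raise PorefluxError(f"unknown selection keyword {key!r}")
        values = []
        while self.peek() is not None and self.peek() not in _KEYWORDS | _OPS:
            values.append(self.next())
        if not values:
            raise PorefluxError(f"selection keyword {key!r} needs a value")
        top = self.top
        if key == "resid":
            mask = np.zeros(top.n_atoms, dtype=bool)
            for v in values:
                if ":" in v:
                    lo, hi = (int(x) for x in v.split(":"))
                    mask |= (top.resids >= lo) & (top.resids <= hi)
                else:
                    mask |= top.resids == int(v)
            return mask
        column = {
            "name": top.names,
            "resname": top.resnames,
            "chain": top.chainids,
            "element": top.elements,
        }[key]
        column = np.array([str(x).upper() for x in column])
        wanted = {v.upper() for v in values}
        return np.isin(column, list(wanted))


def select(top: Topology, expression: str) -> np.ndarray:
    """Resolve a selection expression to a sorted array of atom indices.

    Example: ``"resid 106 111 115 199 200 and name OE1 OE2 OD1 OD2"``.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise PorefluxError("empty selection expression")
    mask = _Parser(tokens, top).parse()
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Unwrapping
# ---------------------------------------------------------------------------

def unwrap_z(traj: Trajectory, atoms: np.ndarray) -> np.ndarray:
    """Continuous (unwrapped) z series for the given atoms.

    Per-frame jumps larger than half the box height are treated as periodic
    wraps and corrected by whole multiples of box_z; the wrapped coordinates
    in the trajectory are left untouched.

    Returns an array of shape (n_frames, n_atoms).
    """
    atoms = np.asarray(atoms, dtype=int)
    z = traj.coords[:, atoms, 2].astype(float)
    box_z = traj.box[:, 2]
    if np.any(box_z <= 0):
        raise PorefluxError("zero box dimension")
    dz = np.diff(z, axis=0)
    dz -= box_z[1:, None] * np.round(dz / box_z[1:, None])
    out = np.empty_like(z)
    out[0] = z[0]
    np.cumsum(dz, axis=0, out=out[1:])
    out[1:] += z[0]
    return out


def flip_z(traj: Trajectory) -> Trajectory:
    """Return a copy with the z axis inverted (for inverted input systems)."""
    coords = traj.coords.copy()
    coords[:, :, 2] *= -1
    return Trajectory(coords=coords, box=traj.box.copy(), times=traj.times.copy(),
                      topology=traj.topology)
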