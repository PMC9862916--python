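"""Synthetic single-file-channel trajectory generator.

Emulates the statistical structure of an MD trajectory of a tetrameric
water channel: four pores parallel to z, each holding a column of waters
that diffuse by overdamped (Euler--Maruyama) Langevin dynamics on an
imposed axial free-energy profile U(z) (a sum of Gaussian bumps, with the
main barrier at the ar/R constriction), flanked by reservoir segments with
reflecting outer walls.  The generator also places a crude protein
scaffold (labelled loop residues, ar/R arginine, surface carboxylates,
pore-lining rings), compartmentalised ions and an optional
schedule-driven ligand, so that every downstream selection and metric of
the analysis modules can run on its output.

It is a statistical emulator, not a physical simulation: there are no
force fields, no explicit electrostatics in the dynamics, and ligand
binding is imposed by a schedule rather than sampled.  Its purpose is to
provide exact ground truth (imposed U(z), analytic collective diffusion,
true permeation events, true binding intervals) for validating the
estimators.

Every run is fully determined by ``spec.seed``; each chain draws from its
own RNG stream split from the master seed, so per-chain results are
order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import PorefluxError, V_WATER_CM3
from .trajectory import ChannelSection, Topology, Trajectory

__all__ = [
    "GaussianBump",
    "LigandEvent",
    "SyntheticSpec",
    "GroundTruth",
    "generate",
    "analytic_dn",
    "analytic_pf",
    "default_sections",
    "write_system",
]

CHAIN_IDS = "ABCDEFGH"


@dataclass(frozen=True)
class GaussianBump:
    """One Gaussian feature of the imposed axial profile, U in kT."""

    center: float  # Å
    width: float   # Å (Gaussian sigma)
    height: float  # kT; negative for a well


@dataclass(frozen=True)
class LigandEvent:
    """Schedule entry: a ligand bound to ``chain`` between two frames adds a
    Gaussian barrier increment at the ar/R position of that chain."""

    chain: str
    bind_frame: int
    unbind_frame: int
    barrier_increment: float  # kT
    width: float = 2.0        # Å


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic system.

    Waters per chain are split between the channel section
    (``n_waters_per_chain``) and the two reservoirs
    (``n_reservoir_waters``, half per side).  With the default reservoir
    depth equal to half the section length, equal counts give matched
    densities, so the flat-profile equilibrium section occupancy stays at
    ``n_waters_per_chain``.
    """

    n_chains: int = 4
    n_waters_per_chain: int = 10
    n_reservoir_waters: int = 10
    diffusion_const: float = 50.0       # Å²/ns
    pmf: tuple[GaussianBump, ...] = ()
    arR_z: float = 7.5                  # Å
    section_length: float = 30.0        # Å
    reservoir_depth: float = 15.0       # Å per side
    box_xy: float = 40.0                # Å
    dt: float = 0.01                    # ns per frame
    n_frames: int = 20000
    temperature: float = 310.15         # K
    seed: int = 0
    ligand_schedule: tuple[LigandEvent, ...] = ()
    ion_counts: dict = field(
        default_factory=lambda: {"NA": (0, 6), "CL": (3, 3), "K": (6, 0)}
    )
    pore_radius: float = 6.0
    ion_diffusion_const: float = 100.0  # Å²/ns

    @property
    def half_height(self) -> float:
        return self.section_length / 2.0 + self.reservoir_depth

    @property
    def box_z(self) -> float:
        return 2.0 * self.half_height + 4.0

    def chain_axes(self) -> list[tuple[float, float]]:
        d = self.box_xy / 4.0
        offsets = [(-d, -d), (-d, d), (d, -d), (d, d)]
        if self.n_chains > len(offsets):
            raise PorefluxError("at most 4 chains supported")
        return offsets[: self.n_chains]

    def validate(self) -> None:
        if self.diffusion_const <= 0:
            raise PorefluxError("diffusion_const must be positive")
        if self.n_frames < 2:
            raise PorefluxError("n_frames must be at least 2")
        if self.dt <= 0:
            raise PorefluxError("dt must be positive")
        half = self.section_length / 2.0
        widths = [b.width for b in self.pmf]
        for ev in self.ligand_schedule:
            widths.append(ev.width)
            if ev.chain not in CHAIN_IDS[: self.n_chains]:
                raise PorefluxError(f"ligand chain {ev.chain!r} not in system")
            if not (0 <= ev.bind_frame < ev.unbind_frame):
                raise PorefluxError("ligand schedule frames out of order")
        for b in self.pmf:
            if not (-half <= b.center <= half):
                raise PorefluxError("PMF feature centres must lie in the section")
            if b.width <= 0:
                raise PorefluxError("PMF feature width must be positive")
        if not (-half <= self.arR_z <= half):
            raise PorefluxError("arR_z must lie inside the section")
        if widths:
            step = np.sqrt(2.0 * self.diffusion_const * self.dt)
            if step > 0.2 * min(widths):
                raise PorefluxError(
                    "dt too coarse for the narrowest PMF feature: require "
                    "sqrt(2 D dt) <= 0.2 * min width"
                )
        # reject non-finite profiles
        zgrid = np.linspace(-half, half, 601)
        if not np.all(np.isfinite(self.potential(zgrid))):
            raise PorefluxError("non-finite U(z) inside the section")

    # -- imposed profile -------------------------------------------------
    def potential(self, z: np.ndarray, extra: tuple[GaussianBump, ...] = ()):
        """U(z) in kT for the base profile plus optional extra bumps."""
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for b in tuple(self.pmf) + tuple(extra):
            u += b.height * np.exp(-((z - b.center) ** 2) / (2.0 * b.width**2))
        return u

    def force(self, z: np.ndarray, extra: tuple[GaussianBump, ...] = ()):
        """-dU/dz in kT/Å."""
        z = np.asarray(z, dtype=float)
        f = np.zeros_like(z)
        for b in tuple(self.pmf) + tuple(extra):
            f += (
                b.height
                * (z - b.center)
                / b.width**2
                * np.exp(-((z - b.center) ** 2) / (2.0 * b.width**2))
            )
        return f


@dataclass
class GroundTruth:
    """What the generator actually imposed, for validating estimators."""

    spec: dict
    d_n_per_ns: float | None          # analytic, flat profile only
    pf_cm3_s: float | None            # analytic, flat profile only
    events: list                      # dicts: water_index, chain_id, entry/exit frame, direction
    binding_intervals: list           # dicts: chain_id, bind/unbind frame, barrier_increment
    chain_profiles: dict              # chain_id -> list of bump dicts (base profile)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def analytic_dn(spec: SyntheticSpec) -> float:
    """Collective diffusion coefficient D_n = N*D/L² (ns⁻¹) for a flat profile."""
    if spec.pmf or spec.ligand_schedule:
        raise PorefluxError("analytic D_n requires a flat profile")
    return (
        spec.n_waters_per_chain
        * spec.diffusion_const
        / spec.section_length**2
    )


def analytic_pf(spec: SyntheticSpec) -> float:
    """Closed-form single-channel pf = v_w * N * D / L² in cm³/s (flat profile)."""
    return V_WATER_CM3 * analytic_dn(spec) * 1e9


def default_sections(spec: SyntheticSpec) -> list[ChannelSection]:
    """Channel sections matching the generated geometry, one per chain."""
    return [
        ChannelSection(
            chain_id=CHAIN_IDS[c],
            axis_xy=axy,
            z_center=0.0,
            length=spec.section_length,
            arR_z=spec.arR_z,
            pore_radius=spec.pore_radius,
            vestibule=(spec.section_length / 2.0, spec.half_height),
        )
        for c, axy in enumerate(spec.chain_axes())
    ]


# ---------------------------------------------------------------------------
# Protein scaffold layout (static positions + per-frame jitter)
# ---------------------------------------------------------------------------
# Residues carry the loop labels used by the interaction metrics: C-loop
# (A117, V118, N119), E-loop salt-bridge partners and surface carboxylates
# (E106, D111, R113, D115, D199, D200), the ar/R pair (R187, H177) and the
# C-loop anchor trio (K197, F198, D199).

_SIDE_ATOMS = {
    "GLU": [("OE1", "O", -0.5), ("OE2", "O", -0.5)],
    "ASP": [("OD1", "O", -0.5), ("OD2", "O", -0.5)],
    "ASN": [("OD1", "O", 0.0), ("ND2", "N", 0.0)],
    "ARG": [("NE", "N", 0.3), ("NH1", "N", 0.35), ("NH2", "N", 0.35)],
    "LYS": [("NZ", "N", 1.0)],
    "HIS": [("NE2", "N", 0.0)],
}

_SCAFFOLD_RESIDUES = [
    # (resid, resname, radius Å, z Å)
    (106, "GLU", 9.0, 16.0),
    (111, "ASP", 9.5, 17.0),
    (113, "ARG", 8.5, 15.0),
    (115, "ASP", 9.0, 14.0),
    (117, "ALA", 7.0, 12.0),
    (118, "VAL", 7.0, 11.0),
    (119, "ASN", 7.0, 10.0),
    (177, "HIS", 5.0, 7.5),
    (187, "ARG", 5.0, 7.5),
    (197, "LYS", 8.0, 13.0),
    (198, "PHE", 8.0, 12.0),
    (199, "ASP", 8.0, 11.0),
    (200, "ASP", 8.5, 16.5),
]

_RING_LEVELS = [(-12.0, 4.0), (-6.0, 4.0), (0.0, 3.8), (6.0, 3.6), (7.5, 3.2), (12.0, 4.2)]


def _scaffold_atoms(spec: SyntheticSpec, axis_xy, chain_id):
    """Static base coordinates and attributes of one chain's scaffold."""
    names, resnames, resids, elements, charges, xyz = [], [], [], [], [], []
    x0, y0 = axis_xy

    for k, (resid, resname, radius, z) in enumerate(_SCAFFOLD_RESIDUES):
        theta = 2.0 * np.pi * (k / len(_SCAFFOLD_RESIDUES)) + 0.3
        cx = x0 + radius * np.cos(theta)
        cy = y0 + radius * np.sin(theta)
        backbone = [
            ("N", "N", -0.47, (cx - 0.8, cy, z - 0.6)),
            ("CA", "C", 0.07, (cx, cy, z)),
            ("C", "C", 0.51, (cx + 1.2, cy, z + 0.2)),
            # carbonyl O offset along +z: oxygens orientated extracellular
            ("O", "O", -0.51, (cx + 1.2, cy, z + 1.2)),
        ]
        for name, elem, q, pos in backbone:
            names.append(name)
            resnames.append(resname)
            resids.append(resid)
            elements.append(elem)
            charges.append(q)
            xyz.append(pos)
        for j, (name, elem, q) in enumerate(_SIDE_ATOMS.get(resname, [])):
            # side-chain atoms fan out toward the pore axis
            frac = 0.6 + 0.15 * j
            pos = (x0 + (cx - x0) * frac, y0 + (cy - y0) * frac, z + 0.3 * j)
            names.append(name)
            resnames.append(resname)
            resids.append(resid)
            elements.append(elem)
            charges.append(q)
            xyz.append(pos)

    # pore-lining rings (for the radius profile); inert carbon atoms
    resid = 900
    for z, radius in _RING_LEVELS:
        for j in range(6):
            theta = np.pi * j / 3.0
            names.append(f"C{j + 1}")
            resnames.append("POR")
            resids.append(resid)
            elements.append("C")
            charges.append(0.0)
            xyz.append((x0 + radius * np.cos(theta), y0 + radius * np.sin(theta), z))
        resid += 1

    n = len(names)
    return (
        names,
        resnames,
        resids,
        [chain_id] * n,
        elements,
        charges,
        np.array(xyz, dtype=float),
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _reflect(z, lo, hi):
    """Reflect positions into [lo, hi] (in place, vectorised)."""
    span = hi - lo
    z -= lo
    z = np.abs(z)
    z = np.mod(z, 2.0 * span)
    np.minimum(z, 2.0 * span - z, out=z)
    return z + lo


def _crossing_events(comp: np.ndarray):
    """Events below→inside→above (+1) or above→inside→below (−1) in a
    compartment series coded 0=below, 1=inside, 2=above."""
    out = []
    idx = np.flatnonzero(comp != 1)
    if idx.size < 2:
        return out
    sides = comp[idx]
    change = (sides[1:] != sides[:-1]) & (np.diff(idx) > 1)
    for k in np.flatnonzero(change):
        direction = 1 if sides[k + 1] == 2 else -1
        out.append((int(idx[k] + 1), int(idx[k + 1]), direction))
    return out


def generate(spec: SyntheticSpec):
    """Run the generator.

    Returns ``(topology, trajectory, ground_truth)``.  The trajectory
    contains, per chain: the water column, the protein scaffold; plus the
    shared ions and any scheduled ligand.
    """
    spec.validate()
    rng_streams = np.random.SeedSequence(spec.seed).spawn(spec.n_chains + 2)
    chain_rngs = [np.random.default_rng(s) for s in rng_streams[: spec.n_chains]]
    misc_rng = np.random.default_rng(rng_streams[spec.n_chains])
    ion_rng = np.random.default_rng(rng_streams[spec.n_chains + 1])

    F = spec.n_frames
    half = spec.section_length / 2.0
    H = spec.half_height
    D = spec.diffusion_const
    axes = spec.chain_axes()
    n_w = spec.n_waters_per_chain + spec.n_reservoir_waters

    # --- water dynamics, one RNG stream per chain -----------------------
    z_all = np.empty((spec.n_chains, F, n_w), dtype=np.float32)
    schedule_by_chain = {
        c: [ev for ev in spec.ligand_schedule if ev.chain == CHAIN_IDS[c]]
        for c in range(spec.n_chains)
    }
    for c in range(spec.n_chains):
        rng = chain_rngs[c]
        z = np.empty(n_w)
        z[: spec.n_waters_per_chain] = rng.uniform(-half, half, spec.n_waters_per_chain)
        n_res = spec.n_reservoir_waters
        lo_res = rng.uniform(-H, -half, n_res // 2)
        hi_res = rng.uniform(half, H, n_res - n_res // 2)
        z[spec.n_waters_per_chain:] = np.concatenate([lo_res, hi_res])
        z_all[c, 0] = z
        sigma = np.sqrt(2.0 * D * spec.dt)
        noise = rng.standard_normal((F - 1, n_w))
        events = schedule_by_chain[c]
        for t in range(1, F):
            extra = tuple(
                GaussianBump(spec.arR_z, ev.width, ev.barrier_increment)
                for ev in events
                if ev.bind_frame <= t - 1 < ev.unbind_frame
            )
            z = z + D * spec.force(z, extra) * spec.dt + sigma * noise[t - 1]
            z = _reflect(z, -H, H)
            z_all[c, t] = z

    # --- assemble topology + coordinates --------------------------------
    names, resnames, resids, chainids, elements, charges = [], [], [], [], [], []
    blocks = []  # (F, n, 3) coordinate blocks in atom order

    for c in range(spec.n_chains):
        cid = CHAIN_IDS[c]
        (nm, rn, ri, ch, el, q, base) = _scaffold_atoms(spec, axes[c], cid)
        names += nm
        resnames += rn
        resids += ri
        chainids += ch
        elements += el
        charges += q
        jitter = misc_rng.normal(0.0, 0.2, size=(F, len(nm), 3))
        blocks.append(base[None, :, :] + jitter)

        # waters of this chain: oxygen-only TIP3-like sites
        x0, y0 = axes[c]
        zc = z_all[c]  # (F, n_w)
        inside = np.abs(zc) <= half
        # lateral jitter: tight inside the pore, looser in the reservoirs
        r_in = np.minimum(np.abs(misc_rng.normal(0.0, 0.8, size=zc.shape)),
                          spec.pore_radius - 1.0)
        r_out = np.minimum(np.abs(misc_rng.normal(0.0, 2.0, size=zc.shape)),
                           spec.pore_radius - 1.0)
        r = np.where(inside, r_in, r_out)
        phi = misc_rng.uniform(0.0, 2.0 * np.pi, size=zc.shape)
        wx = x0 + r * np.cos(phi)
        wy = y0 + r * np.sin(phi)
        wblock = np.stack([wx, wy, zc.astype(float)], axis=-1)
        blocks.append(wblock)
        for w in range(n_w):
            names.append("O")
            resnames.append("HOH")
            resids.append(1000 + c * n_w + w)
            chainids.append("W")
            elements.append("O")
            charges.append(0.0)

    # --- ions: 3D diffusion confined to their compartment ---------------
    ion_charge = {"NA": 1.0, "K": 1.0, "CL": -1.0, "MG": 2.0}
    resid_ion = 5000
    for species, (n_intra, n_extra) in sorted(spec.ion_counts.items()):
        for n_ions, (zlo, zhi) in (
            (n_intra, (-H, -half)),
            (n_extra, (half, H)),
        ):
            if n_ions == 0:
                continue
            pos = np.empty((F, n_ions, 3))
            pos[0, :, 0] = ion_rng.uniform(-spec.box_xy / 2, spec.box_xy / 2, n_ions)
            pos[0, :, 1] = ion_rng.uniform(-spec.box_xy / 2, spec.box_xy / 2, n_ions)
            pos[0, :, 2] = ion_rng.uniform(zlo, zhi, n_ions)
            sig = np.sqrt(2.0 * spec.ion_diffusion_const * spec.dt)
            steps = ion_rng.normal(0.0, sig, size=(F - 1, n_ions, 3))
            xy = np.cumsum(np.concatenate([pos[:1, :, :2], steps[:, :, :2]]), axis=0)
            pos[:, :, 0] = _reflect(xy[:, :, 0], -spec.box_xy / 2, spec.box_xy / 2)
            pos[:, :, 1] = _reflect(xy[:, :, 1], -spec.box_xy / 2, spec.box_xy / 2)
            zz = np.cumsum(np.concatenate([pos[:1, :, 2], steps[:, :, 2]]), axis=0)
            pos[:, :, 2] = _reflect(zz, zlo, zhi)
            blocks.append(pos)
            for i in range(n_ions):
                names.append(species)
                resnames.append(species)
                resids.append(resid_ion)
                chainids.append("I")
                elements.append(species)
                charges.append(ion_charge.get(species, 0.0))
                resid_ion += 1

    # --- scheduled ligand(s): parked far away unless bound ---------------
    binding_intervals = []
    if spec.ligand_schedule:
        lig_atoms = [("C1", "C", 0.0), ("C2", "C", 0.0), ("C3", "C", 0.0),
                     ("C4", "C", 0.0), ("O1", "O", -0.3)]
        offsets = np.array(
            [[0, 0, 0], [1.4, 0, 0], [0, 1.4, 0], [-1.4, 0, 0.5], [0, 0, 1.3]]
        )
        for li, ev in enumerate(spec.ligand_schedule):
            c = CHAIN_IDS.index(ev.chain)
            x0, y0 = axes[c]
            bound_center = np.array([x0, y0, half + 2.5])
            parked = np.array(
                [spec.box_xy / 2 - 3.0, -spec.box_xy / 2 + 3.0 + 4.0 * li, H - 2.0]
            )
            centers = np.where(
                (
                    (np.arange(F) >= ev.bind_frame)
                    & (np.arange(F) < ev.unbind_frame)
                )[:, None],
                bound_center[None, :],
                parked[None, :],
            )
            jitter = misc_rng.normal(0.0, 0.15, size=(F, len(lig_atoms), 3))
            blocks.append(centers[:, None, :] + offsets[None, :, :] + jitter)
            for name, elem, q in lig_atoms:
                names.append(name)
                resnames.append("COR")
                resids.append(8000 + li)
                chainids.append("L")
                elements.append(elem)
                charges.append(q)
            binding_intervals.append(
                {
                    "chain_id": ev.chain,
                    "bind_frame": ev.bind_frame,
                    "unbind_frame": ev.unbind_frame,
                    "barrier_increment": ev.barrier_increment,
                }
            )

    coords = np.concatenate(blocks, axis=1).astype(np.float32)
    top = Topology(
        names=np.array(names, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        chainids=np.array(chainids, dtype=object),
        elements=np.array(elements, dtype=object),
        charges=np.array(charges, dtype=float),
    )
    box = np.tile([spec.box_xy, spec.box_xy, spec.box_z], (F, 1)).astype(float)
    times = np.arange(F, dtype=float) * spec.dt
    traj = Trajectory(coords=coords, box=box, times=times, topology=top)

    # --- ground truth -----------------------------------------------------
    events = []
    for c in range(spec.n_chains):
        # classify from the float32 coordinates actually written out
        zc = z_all[c]
        comp = np.where(zc < -half, 0, np.where(zc > half, 2, 1)).astype(np.int8)
        water_base = 1000 + c * n_w
        for w in range(n_w):
            for entry, exit_, direction in _crossing_events(comp[:, w]):
                events.append(
                    {
                        "water_resid": water_base + w,
                        "chain_id": CHAIN_IDS[c],
                        "entry_frame": entry,
                        "exit_frame": exit_,
                        "direction": direction,
                    }
                )

    flat = not spec.pmf and not spec.ligand_schedule
    gt = GroundTruth(
        spec={
            k: v
            for k, v in asdict(spec).items()
            if k not in ("pmf", "ligand_schedule")
        },
        d_n_per_ns=analytic_dn(spec) if flat else None,
        pf_cm3_s=analytic_pf(spec) if flat else None,
        events=sorted(events, key=lambda e: (e["chain_id"], e["exit_frame"])),
        binding_intervals=binding_intervals,
        chain_profiles={
            CHAIN_IDS[c]: [asdict(b) for b in spec.pmf]
            for c in range(spec.n_chains)
        },
    )
    return top, traj, gt


def write_system(top, traj, gt, directory, traj_format="xtc"):
    """Write topology (PDB), trajectory (XTC/DCD) and ground truth (JSON)."""
    from pathlib import Path

    from . import trajectory as tm

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    top_path = directory / "system.pdb"
    traj_path = directory / f"trajectory.{traj_format}"
    tm.write(top, traj, top_path, traj_path)
    gt.to_json(directory / "ground_truth.json")
    return top_path, traj_path
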