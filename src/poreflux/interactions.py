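"""Interaction metrics: hydrogen bonds, group distances, backbone C–O
orientation angles and ion radial distribution functions.

All metrics are returned as :class:`MetricSeries` (one value per analysed
frame, units recorded) and convert to tidy pandas frames for output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import PorefluxError
from .trajectory import Trajectory

__all__ = [
    "HBondCriteria",
    "MetricSeries",
    "find_donor_hydrogens",
    "hydrogen_bonds",
    "mean_group_distance",
    "min_group_distance",
    "backbone_co_angle",
    "rdf",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition: donor–acceptor distance cutoff
    and maximum deviation of the D–H···A angle from linearity."""

    distance: float = 3.5        # Å
    angle_deviation: float = 30.0  # degrees

    def __post_init__(self):
        if self.distance <= 0 or self.angle_deviation <= 0:
            raise PorefluxError("hydrogen-bond cutoffs must be positive")


@dataclass
class MetricSeries:
    name: str
    chain: str
    times: np.ndarray
    values: np.ndarray
    units: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": self.name,
                "chain": self.chain,
                "time_ns": self.times,
                "value": self.values,
                "units": self.units,
            }
        )


def find_donor_hydrogens(
    traj: Trajectory, donors, frame: int = 0, bond_cutoff: float = 1.25
) -> list[tuple[int, int]]:
    """Pair each donor heavy atom with its covalently bonded hydrogens
    (any H within ``bond_cutoff`` Å in the reference frame)."""
    top = traj.topology
    donors = np.asarray(donors, dtype=int)
    hyd = np.flatnonzero(np.char.upper(top.elements.astype(str)) == "H")
    pairs = []
    if hyd.size == 0:
        return pairs
    pos = traj.coords[frame].astype(float)
    d = cdist(pos[donors], pos[hyd])
    for i, dn in enumerate(donors):
        for j in np.flatnonzero(d[i] <= bond_cutoff):
            pairs.append((int(dn), int(hyd[j])))
    return pairs


def hydrogen_bonds(
    traj: Trajectory,
    donors,
    acceptors,
    criteria: HBondCriteria = HBondCriteria(),
    heavy_only: bool = False,
    chain: str = "",
    name: str = "hbonds",
) -> MetricSeries:
    """Per-frame count of donor–H···acceptor triples meeting both the
    distance and the angle criterion (purely geometric, no energy term).

    ``donors`` is a list of donor heavy-atom indices (hydrogens resolved
    from the first frame) or explicit ``(donor, hydrogen)`` pairs.  With
    ``heavy_only`` the angle criterion is dropped and only the
    donor–acceptor distance is applied (for hydrogen-free topologies).
    """
    acceptors = np.asarray(acceptors, dtype=int)
    if acceptors.size == 0:
        raise PorefluxError("no acceptor atoms selected")
    donors = list(donors)
    explicit = len(donors) > 0 and isinstance(donors[0], (tuple, list))
    if heavy_only:
        d_idx = np.asarray(
            [d[0] for d in donors] if explicit else donors, dtype=int
        )
        h_idx = None
    else:
        pairs = (
            [(int(a), int(b)) for a, b in donors]
            if explicit
            else find_donor_hydrogens(traj, donors)
        )
        if not pairs:
            raise PorefluxError(
                "donors carry no bonded hydrogens; pass heavy_only=True "
                "for a distance-only criterion"
            )
        d_idx = np.asarray([p[0] for p in pairs], dtype=int)
        h_idx = np.asarray([p[1] for p in pairs], dtype=int)

    counts = np.zeros(traj.n_frames, dtype=int)
    cos_min = np.cos(np.deg2rad(criteria.angle_deviation))
    for f in range(traj.n_frames):
        pos = traj.coords[f].astype(float)
        dda = cdist(pos[d_idx], pos[acceptors])
        ok = dda <= criteria.distance
        # a donor is never its own acceptor
        same = d_idx[:, None] == acceptors[None, :]
        ok &= ~same
        if h_idx is not None:
            dh = pos[h_idx] - pos[d_idx]          # D->H
            for k in np.flatnonzero(ok.any(axis=1)):
                ha = pos[acceptors[ok[k]]] - pos[h_idx[k]]  # H->A
                # linear D-H...A means D->H parallel to H->A; the angle
                # between them is the deviation from linearity
                cosang = (ha @ dh[k]) / (
                    np.linalg.norm(ha, axis=1) * np.linalg.norm(dh[k]) + 1e-12
                )
                counts[f] += int(np.sum(cosang >= cos_min))
        else:
            counts[f] = int(ok.sum())
    return MetricSeries(
        name=name, chain=chain, times=traj.times.copy(), values=counts,
        units="count",
    )


def _group_distance(traj, group_a, group_b, reduce, mode="pairwise"):
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise PorefluxError("distance groups must be non-empty")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        pos = traj.coords[f].astype(float)
        if mode == "centroid":
            out[f] = np.linalg.norm(pos[a].mean(axis=0) - pos[b].mean(axis=0))
        else:
            out[f] = reduce(cdist(pos[a], pos[b]))
    return out


def mean_group_distance(
    traj: Trajectory, group_a, group_b, mode: str = "pairwise",
    chain: str = "", name: str = "mean_distance",
) -> MetricSeries:
    """Per-frame mean over all inter-group atom-pair distances
    (``mode='centroid'`` measures the centroid–centroid distance instead;
    the convention used is recorded in the series name)."""
    vals = _group_distance(traj, group_a, group_b, np.mean, mode=mode)
    return MetricSeries(
        name=f"{name}[{mode}]", chain=chain, times=traj.times.copy(),
        values=vals, units="angstrom",
    )


def min_group_distance(
    traj: Trajectory, group_a, group_b, chain: str = "",
    name: str = "min_distance",
) -> MetricSeries:
    """Per-frame smallest inter-group atom-pair distance."""
    vals = _group_distance(traj, group_a, group_b, np.min)
    return MetricSeries(
        name=name, chain=chain, times=traj.times.copy(), values=vals,
        units="angstrom",
    )


def backbone_co_angle(
    traj: Trajectory, resids, chain: str | None = None
) -> list[MetricSeries]:
    """Signed angle between each residue's backbone C→O vector and the
    membrane plane: θ = arcsin(v_z/|v|) ∈ [−90°, +90°], positive when the
    carbonyl oxygen points toward the extracellular (+z) side."""
    top = traj.topology
    series = []
    for resid in resids:
        sel = top.resids == resid
        if chain is not None:
            sel &= top.chainids == chain
        c_idx = np.flatnonzero(sel & (top.names == "C"))
        o_idx = np.flatnonzero(sel & (top.names == "O"))
        if c_idx.size != 1 or o_idx.size != 1:
            raise PorefluxError(
                f"residue {resid} needs exactly one backbone C and one O"
            )
        v = traj.coords[:, o_idx[0], :].astype(float) - traj.coords[
            :, c_idx[0], :
        ].astype(float)
        theta = np.degrees(np.arcsin(v[:, 2] / np.linalg.norm(v, axis=1)))
        series.append(
            MetricSeries(
                name=f"co_angle_res{resid}",
                chain=chain or "",
                times=traj.times.copy(),
                values=theta,
                units="degrees",
            )
        )
    return series


def rdf(
    traj: Trajectory,
    ions,
    reference_atoms,
    dr: float = 0.1,
    r_max: float = 10.0,
):
    """Radial distribution function g(r) of ions around reference atoms.

    Minimum-image distances (orthorhombic box); the superposed per-
    reference histograms are normalised by the ideal-gas expectation at
    the ions' mean number density.  Returns ``(r_centers, g)``.
    """
    ions = np.asarray(ions, dtype=int)
    refs = np.asarray(reference_atoms, dtype=int)
    if ions.size == 0:
        raise PorefluxError("no ions selected")
    if refs.size == 0:
        raise PorefluxError("no reference atoms selected")
    if np.any(r_max > traj.box.min(axis=0) / 2):
        raise PorefluxError("r_max exceeds half the smallest box dimension")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    hist = np.zeros(len(edges) - 1)
    rho_sum = 0.0
    for f in range(traj.n_frames):
        pos = traj.coords[f].astype(float)
        box = traj.box[f]
        delta = pos[ions][None, :, :] - pos[refs][:, None, :]
        delta -= box[None, None, :] * np.round(delta / box[None, None, :])
        d = np.linalg.norm(delta, axis=2)
        h, _ = np.histogram(d, bins=edges)
        hist += h
        rho_sum += ions.size / np.prod(box)
    rho = rho_sum / traj.n_frames
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = traj.n_frames * refs.size * rho * shell
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist / norm
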