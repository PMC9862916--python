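"""Pore radius/diameter profiles and axial electrostatic potential.

The radius profile uses a largest-free-sphere construction restricted to
each z-plane: starting from the axis point the sphere centre is optimised
in the plane (coarse grid, then downhill refinement), and the pore radius
is the smallest centre-to-atom distance minus that atom's van der Waals
radius.  The electrostatic profile is a direct softened Coulomb sum over
partial charges with a uniform relative dielectric — a comparative
profile, not an absolute Poisson–Boltzmann potential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .constants import COULOMB_KCAL_A, PorefluxError, kT_kcal
from .trajectory import ChannelSection, Trajectory

__all__ = ["PoreProfile", "PotentialProfile", "radius_profile", "potential_profile",
           "VDW_RADII"]

# Bondi-style van der Waals radii (Å) by element.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "NA": 2.27, "K": 2.75, "MG": 1.73,
    "CA": 2.31, "ZN": 1.39,
}
_DEFAULT_VDW = 1.70


def _vdw_for(elements) -> np.ndarray:
    radii = np.empty(len(elements))
    unknown = set()
    for i, e in enumerate(elements):
        e = str(e).upper()
        if e not in VDW_RADII:
            unknown.add(e)
        radii[i] = VDW_RADII.get(e, _DEFAULT_VDW)
    if unknown:
        warnings.warn(
            f"unknown elements {sorted(unknown)}: using vdW radius {_DEFAULT_VDW} Å"
        )
    return radii


@dataclass
class PoreProfile:
    z: np.ndarray
    diameter: np.ndarray          # Å; NaN where masked (open plane)
    limiting_resid: np.ndarray    # resid of the nearest-contact atom; -1 masked

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.diameter)


@dataclass
class PotentialProfile:
    z: np.ndarray
    potential_kt_e: np.ndarray
    probe_xy: tuple[float, float]


def _free_radius(center_xy, z, pos, radii):
    d = np.sqrt(
        (pos[:, 0] - center_xy[0]) ** 2
        + (pos[:, 1] - center_xy[1]) ** 2
        + (pos[:, 2] - z) ** 2
    )
    i = int(np.argmin(d - radii))
    return d[i] - radii[i], i


def radius_profile(
    traj: Trajectory,
    pore_atoms,
    section: ChannelSection,
    z_step: float = 0.5,
    frames=0,
    search_radius: float = 5.0,
    grid_step: float = 0.5,
    max_radius: float = 10.0,
) -> PoreProfile:
    """Largest-free-sphere pore diameter along the section axis.

    ``frames`` may be one frame index (snapshot) or a sequence (the
    diameters are averaged).  Planes where the optimised free radius
    exceeds ``max_radius`` are masked as open.
    """
    idx = np.asarray(pore_atoms, dtype=int)
    if idx.size == 0:
        raise PorefluxError("no pore atoms selected")
    radii = _vdw_for(traj.topology.elements[idx])
    frame_list = [frames] if np.isscalar(frames) else list(frames)
    zgrid = np.arange(section.z_lo, section.z_hi + z_step / 2, z_step)

    gx = np.arange(-search_radius, search_radius + grid_step / 2, grid_step)
    gxx, gyy = np.meshgrid(gx, gx)
    in_circle = gxx**2 + gyy**2 <= search_radius**2
    offsets = np.column_stack([gxx[in_circle], gyy[in_circle]])

    diam = np.zeros((len(frame_list), len(zgrid)))
    limit = np.full((len(frame_list), len(zgrid)), -1, dtype=int)
    axis = np.asarray(section.axis_xy)
    centers_xy = axis[None, :] + offsets
    for fi, f in enumerate(frame_list):
        pos = traj.coords[f, idx, :].astype(float)
        for zi, z in enumerate(zgrid):
            # vectorised coarse grid, then downhill refinement from the
            # best few seeds (the free-radius landscape is multimodal)
            d = np.sqrt(
                (centers_xy[:, 0, None] - pos[None, :, 0]) ** 2
                + (centers_xy[:, 1, None] - pos[None, :, 1]) ** 2
                + (z - pos[None, :, 2]) ** 2
            )
            grid_r = (d - radii[None, :]).min(axis=1)
            order = np.argsort(grid_r)[-3:]
            r_opt, c_opt = grid_r[order[-1]], centers_xy[order[-1]]

            def objective(c):
                # keep the centre inside the search disc around the axis
                if (c[0] - axis[0]) ** 2 + (c[1] - axis[1]) ** 2 > search_radius**2:
                    return 1e6
                return -_free_radius(c, z, pos, radii)[0]

            for seed in centers_xy[order]:
                res = minimize(
                    objective,
                    seed,
                    method="Nelder-Mead",
                    options={"xatol": 1e-4, "fatol": 1e-5, "maxiter": 300},
                )
                if -res.fun > r_opt:
                    r_opt, c_opt = -res.fun, res.x
            r_opt, i_near = _free_radius(c_opt, z, pos, radii)
            if r_opt > max_radius or not np.isfinite(r_opt):
                diam[fi, zi] = np.nan
            else:
                diam[fi, zi] = max(0.0, 2.0 * r_opt)
                limit[fi, zi] = int(traj.topology.resids[idx[i_near]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_diam = np.nanmean(diam, axis=0) if len(frame_list) > 1 else diam[0]
        all_masked = np.all(np.isnan(diam), axis=0)
    mean_diam = np.where(all_masked, np.nan, mean_diam)
    return PoreProfile(z=zgrid, diameter=mean_diam, limiting_resid=limit[0])


def potential_profile(
    traj: Trajectory,
    charged_atoms,
    section: ChannelSection,
    z_step: float = 0.5,
    dielectric: float = 10.0,
    frames=0,
    softening: float = 1.0,
    temperature: float = 310.15,
) -> PotentialProfile:
    """Direct Coulomb potential at on-axis probe points, in k_B·T/e.

    Atoms closer to a probe than ``softening`` Å contribute at the
    softening radius.  V(p) = Σ q_i·k_e/(ε_r·max(|p−r_i|, s)).
    """
    idx = np.asarray(charged_atoms, dtype=int)
    if idx.size == 0:
        raise PorefluxError("no charged atoms selected")
    charges = traj.topology.charges
    if charges is None:
        raise PorefluxError("topology carries no partial charges")
    q = np.asarray(charges, dtype=float)[idx]
    if np.isnan(q).any():
        bad = idx[np.isnan(q)][:10]
        raise PorefluxError(f"missing charges on atoms {bad.tolist()}")
    frame_list = [frames] if np.isscalar(frames) else list(frames)
    zgrid = np.arange(section.z_lo, section.z_hi + z_step / 2, z_step)
    probes = np.column_stack(
        [
            np.full(len(zgrid), section.axis_xy[0]),
            np.full(len(zgrid), section.axis_xy[1]),
            zgrid,
        ]
    )
    kt = kT_kcal(temperature)
    v = np.zeros(len(zgrid))
    for f in frame_list:
        pos = traj.coords[f, idx, :].astype(float)
        d = np.linalg.norm(probes[:, None, :] - pos[None, :, :], axis=2)
        np.maximum(d, softening, out=d)
        v += (COULOMB_KCAL_A / dielectric) * (q[None, :] / d).sum(axis=1) / kt
    v /= len(frame_list)
    return PotentialProfile(z=zgrid, potential_kt_e=v, probe_xy=section.axis_xy)
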