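"""Shared fixtures: in-memory toy trajectories and a cached synthetic run."""

import numpy as np
import pytest

import poreflux as pf
from poreflux.trajectory import Topology, Trajectory


def make_water_trajectory(z_paths, xy_paths=None, box=(40.0, 40.0, 200.0),
                          dt=0.01):
    """Build a minimal waters-only trajectory from per-water z series.

    ``z_paths`` has shape (n_frames, n_waters); waters sit on the z axis
    unless ``xy_paths`` (n_frames, n_waters, 2) is given.
    """
    z = np.asarray(z_paths, dtype=float)
    n_frames, n_w = z.shape
    coords = np.zeros((n_frames, n_w, 3), dtype=np.float32)
    if xy_paths is not None:
        coords[:, :, :2] = xy_paths
    coords[:, :, 2] = z
    top = Topology(
        names=np.array(["O"] * n_w, dtype=object),
        resnames=np.array(["HOH"] * n_w, dtype=object),
        resids=np.arange(1, n_w + 1),
        chainids=np.array(["W"] * n_w, dtype=object),
    )
    return Trajectory(
        coords=coords,
        box=np.tile(box, (n_frames, 1)),
        times=np.arange(n_frames) * dt,
        topology=top,
    )


def oracle_permeation_events(comp):
    """Brute-force oracle: enumerate every maximal inside-interval of a
    compartment series (0 below, 1 inside, 2 above, 3 excluded) and check
    its flanking compartments.  Independent of the state-machine path."""
    events = []
    F = len(comp)
    t = 0
    while t < F:
        if comp[t] == 1:
            s = t
            while t < F and comp[t] == 1:
                t += 1
            e = t
            if (
                s > 0
                and e < F
                and comp[s - 1] in (0, 2)
                and comp[e] in (0, 2)
                and comp[s - 1] != comp[e]
            ):
                events.append((s, e, 1 if comp[e] == 2 else -1))
        else:
            t += 1
    return events


def oracle_compartments(z, x, y, section):
    comp = np.where(z < section.z_lo, 0, np.where(z > section.z_hi, 2, 1))
    lat = (x - section.axis_xy[0]) ** 2 + (y - section.axis_xy[1]) ** 2
    comp = np.where((comp == 1) & (lat > section.pore_radius**2), 3, comp)
    return comp


@pytest.fixture(scope="session")
def flat_run():
    """One-chain flat-profile synthetic run used by several test modules."""
    spec = pf.SyntheticSpec(n_chains=1, n_frames=5000, seed=42)
    top, traj, gt = pf.generate(spec)
    return spec, top, traj, gt


@pytest.fixture(scope="session")
def flat_section(flat_run):
    spec = flat_run[0]
    return pf.default_sections(spec)[0]
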