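"""Permeation counting and collective-coordinate osmotic permeability.

A full permeation event is a water whose compartment history reads
below → inside → above (direction +1, toward the extracellular side) or
above → inside → below (−1), where "inside" requires both the axial
interval of the :class:`~poreflux.trajectory.ChannelSection` and the
lateral pore cylinder.  Excursions that return to the starting side count
nothing; one water may produce several events.

The osmotic single-channel permeability pf is estimated with the
collective coordinate n(t): per frame pair each water advances n by its
z displacement clipped to the section, divided by the section length L
(so a water crossing a boundary mid-step contributes only the in-section
fraction of its step).  n(t) performs a random walk whose diffusion
coefficient D_n (slope of its mean-squared displacement over lag time,
halved) gives pf = v_w · D_n with v_w = 3.0e-23 cm³ the volume of one
water molecule.

The Dk correction accentuates the ar/R barrier's contribution:
Dk = (2·E0 − EarR)/E0 with E0 the highest free-energy barrier in the
section and EarR the barrier at the ar/R constriction, both in kT from
the Boltzmann-inverted profile; pf_corrected = pf · Dk.  Note this is the
dimensionless reading of the correction (the alternative parse
2·E0 − EarR/E0 would carry units of energy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PorefluxError, V_WATER_CM3
from .trajectory import ChannelSection, Trajectory

__all__ = [
    "PermeationRecord",
    "BarrierSummary",
    "PfResult",
    "count_permeations",
    "cumulative_counts",
    "counts_summary",
    "collective_pf",
    "dk",
]

_BELOW, _INSIDE, _ABOVE, _EXCLUDED = 0, 1, 2, 3


@dataclass(frozen=True)
class PermeationRecord:
    water_index: int      # atom index of the water oxygen
    chain_id: str
    entry_frame: int      # first frame inside the section
    exit_frame: int       # first frame on the far side
    direction: int        # +1 toward extracellular, -1 inward

    def __post_init__(self):
        if self.exit_frame <= self.entry_frame:
            raise PorefluxError("exit frame must follow entry frame")


@dataclass(frozen=True)
class BarrierSummary:
    """Barrier heights feeding the Dk correction, in kT relative to bulk."""

    E0: float
    EarR: float

    @property
    def dk(self) -> float:
        return dk(self.E0, self.EarR)


@dataclass
class PfResult:
    pf_cm3_s: float
    d_n_per_ns: float
    n_t: np.ndarray          # collective coordinate series
    lag_ns: np.ndarray
    msd: np.ndarray
    v_water_cm3: float = V_WATER_CM3


def compartments(
    traj: Trajectory, section: ChannelSection, water_oxygens
) -> np.ndarray:
    """Compartment code per (frame, water): 0 below, 1 inside, 2 above,
    3 axially inside but outside the pore cylinder."""
    idx = np.asarray(water_oxygens, dtype=int)
    xyz = traj.coords[:, idx, :]
    if np.isnan(xyz).any():
        bad = int(np.argwhere(np.isnan(xyz))[0, 0])
        raise PorefluxError(f"missing water coordinates at frame {bad}")
    z = xyz[:, :, 2]
    comp = np.where(
        z < section.z_lo, _BELOW, np.where(z > section.z_hi, _ABOVE, _INSIDE)
    ).astype(np.int8)
    lateral = section.lateral_mask(xyz[:, :, :2])
    comp[(comp == _INSIDE) & ~lateral] = _EXCLUDED
    return comp


def count_permeations(
    traj: Trajectory, section: ChannelSection, water_oxygens
) -> list[PermeationRecord]:
    """Run the three-compartment state machine over every water.

    Returns records sorted by exit frame.  Waters whose path touches the
    lateral exclusion zone abort any pending crossing.
    """
    idx = np.asarray(water_oxygens, dtype=int)
    comp = compartments(traj, section, idx)
    records: list[PermeationRecord] = []
    for w in range(comp.shape[1]):
        seq = comp[:, w]
        origin = seq[0] if seq[0] in (_BELOW, _ABOVE) else None
        entry = None
        for t in range(1, len(seq)):
            c = seq[t]
            if c == _INSIDE:
                if origin is not None and entry is None:
                    entry = t
            elif c == _EXCLUDED:
                origin = None
                entry = None
            else:  # below or above
                if entry is not None and origin is not None and c != origin:
                    records.append(
                        PermeationRecord(
                            water_index=int(idx[w]),
                            chain_id=section.chain_id,
                            entry_frame=entry,
                            exit_frame=t,
                            direction=1 if c == _ABOVE else -1,
                        )
                    )
                origin = c
                entry = None
    records.sort(key=lambda r: (r.exit_frame, r.water_index))
    return records


def cumulative_counts(
    records: list[PermeationRecord], times: np.ndarray, directed: bool = False
) -> np.ndarray:
    """Cumulative crossing count evaluated on the frame time grid.

    ``directed=False`` counts every event (total crossings); ``True``
    accumulates +1/−1 by direction (net transport).  Events are dated by
    their exit frame.
    """
    times = np.asarray(times)
    out = np.zeros(len(times))
    for r in records:
        out[r.exit_frame:] += r.direction if directed else 1
    return out


def counts_summary(records: list[PermeationRecord]) -> dict:
    up = sum(1 for r in records if r.direction == 1)
    down = len(records) - up
    return {"total": len(records), "outward": up, "inward": down, "net": up - down}


def collective_pf(
    traj: Trajectory,
    section: ChannelSection,
    water_oxygens,
    temperature: float = 310.15,
    fit_window: tuple[float, float] = (0.0001, 0.002),
    max_lag_points: int = 60,
) -> PfResult:
    """Collective-coordinate pf estimate for one channel section.

    ``fit_window`` is the MSD fit range as fractions of the trajectory
    length.  The default keeps the fit in the short-lag diffusive regime,
    well below the channel/reservoir relaxation time: in a finite
    simulation box the collective coordinate is weakly mean-reverting at
    longer lags, which would bias the slope downward.  The fit is weighted
    least squares through the origin with inverse-variance weights
    (var MSD ~ lag³ for a Brownian n(t)), so the shortest lags dominate.
    """
    if traj.n_frames < 100:
        raise PorefluxError("collective pf needs at least 100 frames")
    idx = np.asarray(water_oxygens, dtype=int)
    xyz = traj.coords[:, idx, :]
    z = xyz[:, :, 2].astype(float)
    # minimum-image step displacements, then clip endpoints to the section
    box_z = traj.box[:, 2]
    dz = np.diff(z, axis=0)
    dz -= box_z[1:, None] * np.round(dz / box_z[1:, None])
    z1 = z[:-1]
    z2 = z1 + dz
    zc1 = np.clip(z1, section.z_lo, section.z_hi)
    zc2 = np.clip(z2, section.z_lo, section.z_hi)
    lateral = section.lateral_mask(xyz[:, :, :2])
    gate = lateral[:-1] | lateral[1:]
    contrib = np.where(gate, zc2 - zc1, 0.0)
    if not np.any(contrib != 0.0) and not np.any(
        lateral & (z >= section.z_lo) & (z <= section.z_hi)
    ):
        raise PorefluxError("empty channel")
    dn = contrib.sum(axis=1) / section.length
    n_t = np.concatenate([[0.0], np.cumsum(dn)])

    F = len(n_t)
    lag_lo = max(1, int(round(fit_window[0] * F)))
    lag_hi = max(lag_lo + 1, int(round(fit_window[1] * F)))
    lags = np.unique(np.linspace(lag_lo, lag_hi, max_lag_points).astype(int))
    msd = np.array([np.mean((n_t[lag:] - n_t[:-lag]) ** 2) for lag in lags])
    w = 1.0 / lags.astype(float) ** 3
    slope = np.sum(w * lags * msd) / np.sum(w * lags.astype(float) ** 2)
    dt = traj.dt_ns
    d_n = slope / (2.0 * dt)  # ns^-1
    return PfResult(
        pf_cm3_s=V_WATER_CM3 * d_n * 1e9,
        d_n_per_ns=d_n,
        n_t=n_t,
        lag_ns=lags * dt,
        msd=msd,
    )


def dk(E0: float, EarR: float) -> float:
    """Dimensionless barrier correction (2·E0 − EarR)/E0.

    Equals 1 when the ar/R barrier is the global one and approaches 2 as
    the ar/R contribution vanishes.  Undefined without a barrier.
    """
    if E0 <= 0:
        raise PorefluxError("Dk undefined: profile has no barrier (E0 <= 0)")
    if EarR < 0:
        raise PorefluxError("EarR must be non-negative")
    return 2.0 - EarR / E0


def records_frame(records: list[PermeationRecord], times) -> pd.DataFrame:
    """Tidy one-row-per-event table (chain, water, frames, times, direction)."""
    times = np.asarray(times)
    return pd.DataFrame(
        {
            "chain": [r.chain_id for r in records],
            "water_index": [r.water_index for r in records],
            "entry_frame": [r.entry_frame for r in records],
            "exit_frame": [r.exit_frame for r in records],
            "entry_time_ns": [times[r.entry_frame] for r in records],
            "exit_time_ns": [times[r.exit_frame] for r in records],
            "direction": [r.direction for r in records],
        }
    )
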