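"""Axial water-density profiles and Boltzmann-inverted free energy.

The channel is sliced along z (0.5 Å by default); the mean water-oxygen
occupancy per slice, gated to the pore cylinder, gives ρ(z).  Boltzmann
inversion then yields G(z) = −kT·ln(ρ(z)/ρ_bulk), with ρ_bulk averaged
over a reservoir region just outside the section (5 Å on each side by
default, the profile's zero).  Bins sampled below a minimum occupancy are
masked rather than mapped to spuriously large G; G is reported in kT
internally and convertible to kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import GAS_CONSTANT_KCAL, PorefluxError
from .permeation import BarrierSummary
from .trajectory import ChannelSection, Trajectory

__all__ = [
    "DensityProfile",
    "FreeEnergyProfile",
    "density_profile",
    "bulk_region",
    "boltzmann_invert",
    "barrier_summary",
]


@dataclass
class DensityProfile:
    edges: np.ndarray       # bin edges, Å
    occupancy: np.ndarray   # mean waters per bin per frame
    n_frames: int

    def __post_init__(self):
        widths = np.diff(self.edges)
        if not np.allclose(widths, widths[0]):
            raise PorefluxError("bin width must be uniform")
        if np.any(self.occupancy < 0):
            raise PorefluxError("occupancies must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class FreeEnergyProfile:
    centers: np.ndarray
    g_kt: np.ndarray        # masked entries are NaN
    mask: np.ndarray        # True where undersampled
    rho_bulk: float
    temperature: float

    def g_kcal(self) -> np.ndarray:
        return self.g_kt * GAS_CONSTANT_KCAL * self.temperature


def density_profile(
    traj: Trajectory,
    section: ChannelSection,
    water_oxygens,
    bin_width: float = 0.5,
    margin: float = 5.0,
) -> DensityProfile:
    """Mean per-slice water occupancy over the section plus ``margin`` Å of
    reservoir on each side, lateral pore-cylinder gate applied throughout."""
    if bin_width <= 0:
        raise PorefluxError("bin width must be positive")
    if traj.n_frames < 100:
        raise PorefluxError("density profile needs at least 100 frames")
    idx = np.asarray(water_oxygens, dtype=int)
    xyz = traj.coords[:, idx, :]
    z = xyz[:, :, 2]
    lo = section.z_lo - margin
    hi = section.z_hi + margin
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    sel = section.lateral_mask(xyz[:, :, :2])
    counts, _ = np.histogram(z[sel], bins=edges)
    return DensityProfile(
        edges=edges, occupancy=counts / traj.n_frames, n_frames=traj.n_frames
    )


def bulk_region(section: ChannelSection, margin: float = 5.0):
    """Default bulk reference: ``margin`` Å of reservoir beyond each end."""
    return [
        (section.z_lo - margin, section.z_lo),
        (section.z_hi, section.z_hi + margin),
    ]


def boltzmann_invert(
    dens: DensityProfile,
    bulk,
    temperature: float = 310.15,
    min_occupancy: float = 1e-3,
) -> FreeEnergyProfile:
    """Invert ρ(z) to G(z) = −kT·ln(ρ/ρ_bulk) in kT.

    ``bulk`` is a list of (lo, hi) z-intervals; ρ_bulk is the mean
    occupancy of the bins whose centres fall inside them.  Bins with mean
    occupancy below ``min_occupancy`` per frame are masked (NaN), never a
    silent zero.
    """
    centers = dens.centers
    in_bulk = np.zeros(len(centers), dtype=bool)
    for lo, hi in bulk:
        in_bulk |= (centers >= lo) & (centers <= hi)
    if not in_bulk.any():
        raise PorefluxError("bulk region contains no bins")
    rho_bulk = float(dens.occupancy[in_bulk].mean())
    if rho_bulk <= 0:
        raise PorefluxError("empty bulk region")
    mask = dens.occupancy < min_occupancy
    g = np.full(len(centers), np.nan)
    ok = ~mask
    g[ok] = -np.log(dens.occupancy[ok] / rho_bulk)
    return FreeEnergyProfile(
        centers=centers,
        g_kt=g,
        mask=mask,
        rho_bulk=rho_bulk,
        temperature=temperature,
    )


def barrier_summary(
    profile: FreeEnergyProfile,
    section: ChannelSection,
    arR_window: float = 1.5,
) -> BarrierSummary:
    """E0 = max G over the section; EarR = max G within ±``arR_window`` Å of
    the ar/R position; both in kT relative to the bulk reference."""
    c = profile.centers
    in_section = (c >= section.z_lo) & (c <= section.z_hi)
    g_section = profile.g_kt[in_section]
    if np.all(np.isnan(g_section)):
        raise PorefluxError("entire section is masked")
    in_window = in_section & (np.abs(c - section.arR_z) <= arR_window)
    g_window = profile.g_kt[in_window]
    if len(g_window) == 0 or np.all(np.isnan(g_window)):
        raise PorefluxError("ar/R window is entirely masked")
    return BarrierSummary(
        E0=float(np.nanmax(g_section)), EarR=float(np.nanmax(g_window))
    )
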