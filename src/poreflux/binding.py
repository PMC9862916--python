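"""Contact-based empirical ligand binding free energy and K_D.

Per sampled frame (one frame per nanosecond by default) every
protein–ligand atom pair within a cutoff (10.5 Å by default) is counted
into an element-pair bucket (C–C, C–N, C–O, N–N, N–O, O–O, plus
X–polar/X–apolar buckets for other elements); the binding free energy is
a linear function of the bucket counts,

    ΔG = intercept + Σ_b coef_b · count_b   [kcal/mol],

and the dissociation constant follows from the mean ΔG as
K_D = exp(ΔG/(R·T)) at the 1 M reference state.

The coefficients are data, not code: the package ships
``DEFAULT_COEFFICIENTS`` — a synthetic, clearly non-published default set
so the machinery is runnable out of the box — and any published
empirical set can be dropped in as a dict or JSON file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import DEFAULT_TEMPERATURE, GAS_CONSTANT_KCAL, PorefluxError
from .trajectory import Trajectory

__all__ = [
    "BUCKETS",
    "DEFAULT_COEFFICIENTS",
    "ContactCounts",
    "BindingSeries",
    "classify_contacts",
    "binding_energy",
    "binding_series",
    "kd_from_dg",
    "dg_from_kd",
    "interaction_rate",
    "load_coefficients",
]

BUCKETS = ("CC", "CN", "CO", "NN", "NO", "OO", "XPOL", "XAPOL")
_POLAR = {"N", "O"}

# Synthetic default coefficient set (NOT the published empirical
# coefficients of any scoring program): favourable polar contacts, mildly
# favourable apolar ones, zero intercept.
DEFAULT_COEFFICIENTS = {
    "intercept": 0.0,
    "CC": -0.020,
    "CN": -0.035,
    "CO": -0.040,
    "NN": -0.045,
    "NO": -0.050,
    "OO": -0.045,
    "XPOL": -0.030,
    "XAPOL": -0.015,
}


@dataclass
class ContactCounts:
    counts: dict = field(default_factory=lambda: {b: 0 for b in BUCKETS})

    def __post_init__(self):
        for b in BUCKETS:
            self.counts.setdefault(b, 0)
        if any(v < 0 for v in self.counts.values()):
            raise PorefluxError("contact counts must be non-negative")

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class BindingSeries:
    times: np.ndarray        # ns
    dg: np.ndarray           # kcal/mol per sample
    mean_dg: float
    kd_M: float
    temperature: float

    @property
    def kd_nM(self) -> float:
        return self.kd_M * 1e9

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "dg_kcal_mol": self.dg})


def _bucket(e1: str, e2: str) -> str:
    e1, e2 = str(e1).upper(), str(e2).upper()
    std1, std2 = e1 in ("C", "N", "O"), e2 in ("C", "N", "O")
    if std1 and std2:
        return "".join(sorted((e1, e2)))
    other = e2 if std1 else e1
    partner = e1 if std1 else e2
    # hydrogens and exotic elements bucket by their partner's polarity;
    # a pair of two non-CNO atoms counts as apolar
    if std1 != std2 and partner in _POLAR:
        return "XPOL"
    return "XAPOL"


def classify_contacts(
    traj: Trajectory,
    frame: int,
    protein_atoms,
    ligand_atoms,
    cutoff: float = 10.5,
) -> ContactCounts:
    """Count intermolecular atom pairs within ``cutoff`` into element-pair
    buckets (minimum-image distances, orthorhombic box)."""
    p = np.asarray(protein_atoms, dtype=int)
    l = np.asarray(ligand_atoms, dtype=int)
    if l.size == 0:
        raise PorefluxError("ligand selection is empty")
    if p.size == 0:
        raise PorefluxError("protein selection is empty")
    pos = traj.coords[frame].astype(float)
    box = traj.box[frame]
    delta = pos[p][:, None, :] - pos[l][None, :, :]
    delta -= box[None, None, :] * np.round(delta / box[None, None, :])
    d = np.linalg.norm(delta, axis=2)
    counts = {b: 0 for b in BUCKETS}
    ep = traj.topology.elements[p]
    el = traj.topology.elements[l]
    for i, j in zip(*np.nonzero(d <= cutoff)):
        counts[_bucket(ep[i], el[j])] += 1
    return ContactCounts(counts=counts)


def binding_energy(counts: ContactCounts, coefficients=None) -> float:
    """ΔG = intercept + Σ coef_b · count_b, kcal/mol."""
    coef = DEFAULT_COEFFICIENTS if coefficients is None else coefficients
    missing = [b for b in list(BUCKETS) + ["intercept"] if b not in coef]
    if missing:
        raise PorefluxError(f"coefficient set lacks entries for {missing}")
    return float(
        coef["intercept"]
        + sum(coef[b] * counts.counts[b] for b in BUCKETS)
    )


def binding_series(
    traj: Trajectory,
    protein_atoms,
    ligand_atoms,
    every_ns: float = 1.0,
    cutoff: float = 10.5,
    coefficients=None,
    temperature: float = DEFAULT_TEMPERATURE,
) -> BindingSeries:
    """Sample ΔG along the trajectory (default cadence 1 frame/ns),
    aggregate to a mean ΔG and convert it to K_D."""
    times = traj.times
    stride = max(1, int(round(every_ns / traj.dt_ns))) if traj.dt_ns > 0 else 1
    frames = np.arange(0, traj.n_frames, stride)
    dg = np.array(
        [
            binding_energy(
                classify_contacts(traj, f, protein_atoms, ligand_atoms, cutoff),
                coefficients,
            )
            for f in frames
        ]
    )
    mean_dg = float(dg.mean())
    return BindingSeries(
        times=times[frames],
        dg=dg,
        mean_dg=mean_dg,
        kd_M=kd_from_dg(mean_dg, temperature),
        temperature=temperature,
    )


def kd_from_dg(
    dg_kcal_mol: float,
    temperature: float = DEFAULT_TEMPERATURE,
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> float:
    """Dissociation constant in mol/L from a binding free energy.

    K_D = exp(ΔG/(R·T)) at the 1 M reference state, so a favourable
    (negative) ΔG maps to K_D < 1 M.  R defaults to 8.314 J·mol⁻¹·K⁻¹
    expressed in kcal.
    """
    if temperature <= 0:
        raise PorefluxError("temperature must be positive")
    return math.exp(dg_kcal_mol / (gas_constant * temperature))


def dg_from_kd(
    kd_M: float,
    temperature: float = DEFAULT_TEMPERATURE,
    gas_constant: float = GAS_CONSTANT_KCAL,
) -> float:
    """Inverse of :func:`kd_from_dg` (kcal/mol)."""
    if kd_M <= 0:
        raise PorefluxError("K_D must be positive")
    return gas_constant * temperature * math.log(kd_M)


def interaction_rate(n_events: int, duration_ns: float) -> float:
    """Events per second from a count over a trajectory duration in ns
    (e.g. spontaneous ligand encounters per simulated second)."""
    if duration_ns <= 0:
        raise PorefluxError("duration must be positive")
    return n_events / (duration_ns * 1e-9)


def load_coefficients(path) -> dict:
    """Read a coefficient set from JSON ({bucket: kcal/mol, 'intercept': ...})."""
    with open(path) as fh:
        coef = json.load(fh)
    return {str(k): float(v) for k, v in coef.items()}
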