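"""Hydrogen bonds, group distances, C–O angles, ion RDFs."""

import numpy as np
import pytest

import poreflux as pf
from poreflux.constants import PorefluxError
from poreflux.interactions import (
    HBondCriteria,
    backbone_co_angle,
    find_donor_hydrogens,
    hydrogen_bonds,
    mean_group_distance,
    min_group_distance,
    rdf,
)
from poreflux.trajectory import Topology, Trajectory


def make_system(positions, names=None, elements=None, box=(50.0, 50.0, 50.0),
                n_frames=1):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if names is None:
        names = [f"A{i}" for i in range(n)]
    if elements is None:
        elements = ["O"] * n
    top = Topology(
        names=np.array(names, dtype=object),
        resnames=np.array(["XXX"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        chainids=np.array(["A"] * n, dtype=object),
        elements=np.array(elements, dtype=object),
    )
    coords = np.tile(positions[None, :, :], (n_frames, 1, 1)).astype(np.float32)
    traj = Trajectory(
        coords=coords,
        box=np.tile(box, (n_frames, 1)),
        times=np.arange(n_frames, dtype=float),
        topology=top,
    )
    return top, traj


class TestHydrogenBonds:
    def linear_ohO(self, d_oo):
        # donor O at origin, H on the O-O axis, acceptor O at d_oo
        return [[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [d_oo, 0.0, 0.0]]

    def test_ideal_linear_bond_counts_one(self):
        top, traj = make_system(self.linear_ohO(2.8), elements=["O", "H", "O"])
        s = hydrogen_bonds(traj, [0], [2])
        assert s.values[0] == 1

    def test_beyond_distance_cutoff(self):
        top, traj = make_system(self.linear_ohO(4.0), elements=["O", "H", "O"])
        s = hydrogen_bonds(traj, [0], [2])
        assert s.values[0] == 0

    def test_bent_geometry_rejected(self):
        # acceptor within range but 69° off the O-H axis: deviation > 30°
        pos = [[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [1.56, 1.56, 0.0]]
        top, traj = make_system(pos, elements=["O", "H", "O"])
        assert hydrogen_bonds(traj, [0], [2]).values[0] == 0

    def test_monotone_in_cutoffs(self):
        rng = np.random.default_rng(7)
        n_d, n_a = 6, 8
        donors = rng.uniform(0, 8, (n_d, 3))
        hydrogens = donors + [0.96, 0.0, 0.0]
        acceptors = rng.uniform(0, 8, (n_a, 3))
        pos = np.vstack([donors, hydrogens, acceptors])
        elements = ["O"] * n_d + ["H"] * n_d + ["O"] * n_a
        top, traj = make_system(pos, elements=elements)
        pairs = [(i, n_d + i) for i in range(n_d)]
        acc = np.arange(2 * n_d, 2 * n_d + n_a)
        loose = hydrogen_bonds(traj, pairs, acc,
                               HBondCriteria(4.5, 60.0)).values[0]
        tight = hydrogen_bonds(traj, pairs, acc,
                               HBondCriteria(3.0, 20.0)).values[0]
        assert loose >= tight > 0 or loose >= tight

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_triples_oracle(self, seed):
        # random O/H soup vs explicit enumeration of every D-H...A triple
        rng = np.random.default_rng(seed)
        n_d, n_a = 8, 10
        donors = rng.uniform(0, 10, (n_d, 3))
        hydrogens = donors + rng.normal(0, 0.5, (n_d, 3)) * 0.4
        acceptors = rng.uniform(0, 10, (n_a, 3))
        pos = np.vstack([donors, hydrogens, acceptors])
        elements = ["N"] * n_d + ["H"] * n_d + ["O"] * n_a
        top, traj = make_system(pos, elements=elements)
        pairs = [(i, n_d + i) for i in range(n_d)]
        crit = HBondCriteria(3.5, 30.0)
        got = hydrogen_bonds(traj, pairs, np.arange(2 * n_d, 2 * n_d + n_a),
                             crit).values[0]
        expected = 0
        for d, h in pairs:
            for a in range(2 * n_d, 2 * n_d + n_a):
                r_da = np.linalg.norm(pos[a] - pos[d])
                u = pos[h] - pos[d]
                v = pos[a] - pos[h]
                dev = np.degrees(
                    np.arccos(
                        np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)),
                                -1, 1)
                    )
                )
                if r_da <= crit.distance and dev <= crit.angle_deviation:
                    expected += 1
        assert got == expected

    def test_strict_mode_needs_hydrogens(self):
        top, traj = make_system([[0, 0, 0], [3, 0, 0]], elements=["O", "O"])
        with pytest.raises(PorefluxError, match="hydrogen"):
            hydrogen_bonds(traj, [0], [1])
        s = hydrogen_bonds(traj, [0], [1], heavy_only=True)
        assert s.values[0] == 1

    def test_find_donor_hydrogens(self):
        pos = [[0, 0, 0], [0.96, 0, 0], [5, 5, 5]]
        top, traj = make_system(pos, elements=["O", "H", "H"])
        assert find_donor_hydrogens(traj, [0]) == [(0, 1)]


class TestGroupDistances:
    def test_two_single_atoms(self):
        top, traj = make_system([[0, 0, 0], [3, 4, 0]])
        s = mean_group_distance(traj, [0], [1])
        assert s.values[0] == pytest.approx(5.0)
        assert s.units == "angstrom"

    def test_two_by_two_hand_computation(self):
        pos = [[0, 0, 0], [1, 0, 0], [0, 3, 0], [1, 3, 0]]
        top, traj = make_system(pos)
        s = mean_group_distance(traj, [0, 1], [2, 3])
        d = [3.0, np.sqrt(10), np.sqrt(10), 3.0]
        assert s.values[0] == pytest.approx(np.mean(d))
        m = min_group_distance(traj, [0, 1], [2, 3])
        assert m.values[0] == pytest.approx(3.0)

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 10, (6, 3))
        top1, t1 = make_system(pos)
        top2, t2 = make_system(pos + [3.0, -2.0, 5.0])
        a = mean_group_distance(t1, [0, 1, 2], [3, 4, 5]).values
        b = mean_group_distance(t2, [0, 1, 2], [3, 4, 5]).values
        assert np.allclose(a, b)

    def test_single_pair_mean_equals_min(self):
        top, traj = make_system([[0, 0, 0], [2, 2, 1]])
        assert mean_group_distance(traj, [0], [1]).values[0] == pytest.approx(
            min_group_distance(traj, [0], [1]).values[0]
        )

    def test_identical_groups_min_zero(self):
        top, traj = make_system([[0, 0, 0], [2, 2, 1]])
        assert min_group_distance(traj, [0, 1], [0, 1]).values[0] == 0.0

    def test_centroid_mode_differs_from_pairwise(self):
        pos = [[0, 0, 0], [2, 0, 0], [1, 5, 0], [1, -5, 0]]
        top, traj = make_system(pos)
        pair = mean_group_distance(traj, [0, 1], [2, 3]).values[0]
        cent = mean_group_distance(traj, [0, 1], [2, 3], mode="centroid").values[0]
        # both centroids sit at (1,0,0): centroid distance vanishes while
        # the pairwise mean stays ~sqrt(26)
        assert cent == pytest.approx(0.0, abs=1e-6)
        assert pair == pytest.approx(np.mean([np.sqrt(26)] * 4))

    def test_empty_group_errors(self):
        top, traj = make_system([[0, 0, 0]])
        with pytest.raises(PorefluxError):
            mean_group_distance(traj, [], [0])


class TestBackboneCOAngle:
    def co_system(self, o_offset):
        pos = [[0.0, 0.0, 0.0], o_offset]
        top = Topology(
            names=np.array(["C", "O"], dtype=object),
            resnames=np.array(["GLY", "GLY"], dtype=object),
            resids=np.array([7, 7]),
            chainids=np.array(["A", "A"], dtype=object),
        )
        traj = Trajectory(
            coords=np.asarray(pos, dtype=np.float32)[None, :, :],
            box=np.array([[50.0, 50.0, 50.0]]),
            times=np.array([0.0]),
            topology=top,
        )
        return traj

    @pytest.mark.parametrize(
        "offset,expected",
        [
            ([0.0, 0.0, 1.0], 90.0),     # O straight extracellular
            ([1.0, 0.0, 0.0], 0.0),      # O in the membrane plane
            ([1.0, 0.0, -1.0], -45.0),   # O tilted intracellular
        ],
    )
    def test_signed_angles(self, offset, expected):
        series = backbone_co_angle(self.co_system(offset), [7])
        assert series[0].values[0] == pytest.approx(expected, abs=1e-4)

    def test_missing_backbone_errors(self):
        top, traj = make_system([[0, 0, 0]], names=["CA"])
        with pytest.raises(PorefluxError, match="backbone"):
            backbone_co_angle(traj, [1])


class TestRDF:
    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(11)
        box = 30.0
        n_ions, n_frames = 400, 150
        pos = rng.uniform(0, box, (n_frames, n_ions + 1, 3))
        pos[:, 0] = box / 2  # fixed reference point
        top = Topology(
            names=np.array(["P"] + ["NA"] * n_ions, dtype=object),
            resnames=np.array(["REF"] + ["NA"] * n_ions, dtype=object),
            resids=np.arange(n_ions + 1),
            chainids=np.array(["A"] * (n_ions + 1), dtype=object),
        )
        traj = Trajectory(
            coords=pos.astype(np.float32),
            box=np.tile([box] * 3, (n_frames, 1)),
            times=np.arange(n_frames, dtype=float),
            topology=top,
        )
        r, g = rdf(traj, np.arange(1, n_ions + 1), [0], dr=0.5, r_max=12.0)
        sel = r > 2.0
        assert abs(g[sel].mean() - 1.0) < 0.02
        assert np.allclose(g[sel], 1.0, atol=0.25)  # shot noise in thin shells

    def test_shell_spike_normalization(self):
        # all ions at exactly r0: one spike whose shell integral returns
        # the ion count
        box, r0, n_ions = 40.0, 5.0, 30
        rng = np.random.default_rng(3)
        u = rng.normal(size=(n_ions, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        pos = np.vstack([[box / 2] * 3, box / 2 + r0 * u])
        top = Topology(
            names=np.array(["P"] + ["NA"] * n_ions, dtype=object),
            resnames=np.array(["REF"] + ["NA"] * n_ions, dtype=object),
            resids=np.arange(n_ions + 1),
            chainids=np.array(["A"] * (n_ions + 1), dtype=object),
        )
        traj = Trajectory(
            coords=pos[None].astype(np.float32),
            box=np.array([[box] * 3]),
            times=np.array([0.0]),
            topology=top,
        )
        dr = 0.2
        r, g = rdf(traj, np.arange(1, n_ions + 1), [0], dr=dr, r_max=10.0)
        spike = np.argmax(g)
        assert abs(r[spike] - r0) <= dr
        rho = n_ions / box**3
        shell = 4 / 3 * np.pi * ((r + dr / 2) ** 3 - (r - dr / 2) ** 3)
        assert np.sum(g * rho * shell) == pytest.approx(n_ions, rel=0.01)

    def test_closure_integral(self):
        # integral of g * 4 pi r^2 rho over [0, r_max] recovers the mean
        # ion count within r_max
        rng = np.random.default_rng(9)
        box, n_ions, n_frames = 24.0, 150, 25
        pos = rng.uniform(0, box, (n_frames, n_ions + 1, 3))
        top = Topology(
            names=np.array(["P"] + ["NA"] * n_ions, dtype=object),
            resnames=np.array(["REF"] + ["NA"] * n_ions, dtype=object),
            resids=np.arange(n_ions + 1),
            chainids=np.array(["A"] * (n_ions + 1), dtype=object),
        )
        traj = Trajectory(
            coords=pos.astype(np.float32),
            box=np.tile([box] * 3, (n_frames, 1)),
            times=np.arange(n_frames, dtype=float),
            topology=top,
        )
        r_max, dr = 10.0, 0.25
        r, g = rdf(traj, np.arange(1, n_ions + 1), [0], dr=dr, r_max=r_max)
        rho = n_ions / box**3
        shell = 4 / 3 * np.pi * ((r + dr / 2) ** 3 - (r - dr / 2) ** 3)
        integral = np.sum(g * rho * shell)
        # direct count oracle
        counts = []
        for f in range(n_frames):
            delta = pos[f, 1:] - pos[f, 0]
            delta -= box * np.round(delta / box)
            counts.append(np.sum(np.linalg.norm(delta, axis=1) <= r_max))
        assert integral == pytest.approx(np.mean(counts), rel=0.02)

    def test_errors(self):
        top, traj = make_system([[0, 0, 0], [5, 5, 5]], box=(30.0, 30.0, 30.0))
        with pytest.raises(PorefluxError, match="no ions"):
            rdf(traj, [], [0])
        with pytest.raises(PorefluxError, match="r_max"):
            rdf(traj, [1], [0], r_max=20.0)

    def test_generated_system_selects_sodium_and_carboxylates(self):
        spec = pf.SyntheticSpec(n_chains=1, n_frames=200, seed=13)
        top, traj, _ = pf.generate(spec)
        na = pf.select(top, "resname NA")
        carbox = pf.select(
            top, "resid 106 111 115 199 200 and name OE1 OE2 OD1 OD2"
        )
        r, g = rdf(traj, na, carbox, dr=0.5, r_max=12.0)
        assert np.isfinite(g).all()
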