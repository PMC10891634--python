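"""Geometric hydrogen-bond detection, motif census and water partition,
validated against brute-force O(N²)/O(N·M) oracles."""

import numpy as np
import pytest

from poresel.frames import Frame, Trajectory, min_image_vec
from poresel.hbonds import (
    HBondCriteria,
    detect_hbonds,
    hbond_summary,
    mean_hbonds,
    motif_census,
    partition_water,
)
from poresel.synth import gen_motif_fixture

from conftest import random_water_frame

CRIT = HBondCriteria()


# ---------------------------------------------------------------------------
# independent brute-force oracles (no neighbor lists, plain loops)
# ---------------------------------------------------------------------------

def oracle_bonds(frame: Frame, crit: HBondCriteria = CRIT):
    """All-pairs H-bond detection; nearest eligible acceptor per donor H."""
    n = frame.n_waters
    O = frame.water_O
    H = (frame.water_H1, frame.water_H2)
    cosmax = np.cos(np.deg2rad(crit.angle_OOH_max))
    bonds = set()
    for d in range(n):
        for h in (0, 1):
            best = None
            for a in range(n):
                if a == d:
                    continue
                oo = min_image_vec(O[a] - O[d], frame.box)
                r = np.linalg.norm(oo)
                if r >= crit.r_OO_max:
                    continue
                oh = min_image_vec(H[h][d] - O[d], frame.box)
                cos = oo @ oh / (r * np.linalg.norm(oh))
                if cos <= cosmax:
                    continue
                if best is None or r < best[0]:
                    best = (r, a)
            if best is not None:
                bonds.add((d, h, best[1]))
    return bonds


def oracle_partition(frame: Frame, cutoff: float) -> np.ndarray:
    sol = frame.solute_positions()
    mask = np.zeros(frame.n_waters, dtype=bool)
    for w in range(frame.n_waters):
        for s in sol:
            dv = min_image_vec(frame.water_O[w] - s, frame.box)
            if np.linalg.norm(dv) <= cutoff:
                mask[w] = True
                break
    return mask


# ---------------------------------------------------------------------------

def _dimer(r_oo: float, tilt_deg: float = 5.0) -> Frame:
    """Linear water dimer: donor at origin aiming one H at the acceptor."""
    from poresel.synth import _make_water
    box = np.array([20.0, 20.0, 20.0])
    c = box / 2
    tilt = np.deg2rad(tilt_deg)
    aim = np.array([np.cos(tilt), np.sin(tilt), 0.0])
    dO, dH1, dH2 = _make_water(c, aim, np.array([0.0, 0.3, 1.0]))
    aO, aH1, aH2 = _make_water(c + np.array([r_oo, 0, 0]),
                               np.array([1.0, 0.4, 0.0]),
                               np.array([1.0, -0.4, 0.0]))
    return Frame(box=box, water_O=[dO, aO], water_H1=[dH1, aH1],
                 water_H2=[dH2, aH2])


class TestDetectHbonds:
    def test_ideal_dimer_one_bond(self):
        bonds = detect_hbonds(_dimer(2.8), CRIT)
        assert len(bonds) == 1
        d, _, a = bonds[0]
        assert (d, a) == (0, 1)

    def test_distance_cut(self):
        assert detect_hbonds(_dimer(3.6), CRIT) == []

    def test_angle_cut(self):
        assert detect_hbonds(_dimer(2.8, tilt_deg=40.0), CRIT) == []

    def test_matches_oracle_on_random_frames(self, rng):
        for _ in range(5):
            frame = random_water_frame(rng, n=50)
            assert set(detect_hbonds(frame, CRIT)) == oracle_bonds(frame)

    def test_box_too_small_rejected(self):
        f = _dimer(2.8)
        f.box = np.array([6.0, 20.0, 20.0])
        with pytest.raises(ValueError):
            detect_hbonds(f, CRIT)


class TestMotifCensus:
    @pytest.mark.parametrize("label,expected", [
        ("DDAA", (2, 2)), ("DDA", (2, 1)), ("DAA", (1, 2)), ("DA", (1, 1)),
    ])
    def test_fixture_center_classifies(self, label, expected):
        frame = gen_motif_fixture(label)
        counts = motif_census(frame, CRIT)
        assert counts[label] >= 1
        # water 0 is the centre: verify its (donated, accepted) pair
        bonds = detect_hbonds(frame, CRIT)
        donated = sum(1 for d, _, _ in bonds if d == 0)
        accepted = sum(1 for _, _, a in bonds if a == 0)
        assert (donated, accepted) == expected

    def test_trimer_ring_all_DA(self):
        frame = gen_motif_fixture("trimer-ring")
        counts = motif_census(frame, CRIT)
        assert counts["DA"] == 3
        assert counts.n_HB_mean == pytest.approx(2.0)

    def test_counts_sum_and_match_oracle(self, rng):
        for _ in range(5):
            frame = random_water_frame(rng, n=60)
            m = motif_census(frame, CRIT)
            assert sum(m.counts.values()) == frame.n_waters
            bonds = oracle_bonds(frame)
            donated = np.zeros(frame.n_waters, int)
            accepted = np.zeros(frame.n_waters, int)
            for d, _, a in bonds:
                donated[d] += 1
                accepted[a] += 1
            labels = {(2, 2): "DDAA", (2, 1): "DDA", (1, 2): "DAA",
                      (1, 1): "DA"}
            expect = {"DDAA": 0, "DDA": 0, "DAA": 0, "DA": 0, "other": 0}
            for da in zip(donated, accepted):
                expect[labels.get(tuple(da), "other")] += 1
            assert m.counts == expect
            assert m.n_HB_mean == pytest.approx(
                2 * len(bonds) / frame.n_waters)


class TestPartition:
    def test_no_solute_all_bulk(self, rng):
        frame = random_water_frame(rng, n=20)
        with pytest.warns(UserWarning):
            p = partition_water(frame, shell_cutoff=3.5)
        assert p.interfacial_count == 0
        assert p.bulk_count == 20

    def test_single_ion_single_shell_water(self):
        box = np.array([20.0, 20.0, 20.0])
        from poresel.synth import _make_water
        O, H1, H2 = _make_water(np.array([10.0, 10.0, 13.0]),
                                np.array([0, 0, 1.0]), np.array([0, 1.0, 0.3]))
        frame = Frame(box=box, water_O=[O], water_H1=[H1], water_H2=[H2],
                      ion_labels=["K"], ion_pos=[[10.0, 10.0, 10.0]])
        p = partition_water(frame, shell_cutoff=3.5)
        assert p.interfacial_count == 1  # O at 3.0 Å from the ion

    def test_matches_oracle_and_totals(self, rng):
        for _ in range(5):
            frame = random_water_frame(rng, n=40)
            frame.ion_labels = ["K", "CL"]
            frame.ion_pos = rng.uniform(0, 14, size=(2, 3))
            frame.ion_charges = np.array([1.0, -1.0])
            p = partition_water(frame, shell_cutoff=3.5)
            np.testing.assert_array_equal(p.interfacial,
                                          oracle_partition(frame, 3.5))
            assert p.interfacial_count + p.bulk_count == frame.n_waters


class TestMeanHbonds:
    def test_isolated_dimer(self):
        traj = Trajectory([_dimer(2.8)] * 3)
        assert mean_hbonds(traj) == pytest.approx(1.0)

    def test_per_frame_oracle_agreement(self, rng):
        frames = [random_water_frame(rng, n=40) for _ in range(3)]
        traj = Trajectory(frames)
        got = mean_hbonds(traj, subset="all")
        per_frame = []
        for f in frames:
            counts = np.zeros(f.n_waters)
            for d, _, a in oracle_bonds(f):
                counts[d] += 1
                counts[a] += 1
            per_frame.append(counts.mean())
        assert got == pytest.approx(np.mean(per_frame), abs=1e-12)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            mean_hbonds(Trajectory([]))

    def test_summary_flag_undefined_without_solutes(self):
        traj = Trajectory([_dimer(2.8)])
        with pytest.warns(UserWarning):
            s = hbond_summary(traj)
        assert s["n_HB_all"] == pytest.approx(1.0)
        assert s["interfacial_below_bulk"] is None


class TestInvariances:
    def test_rigid_translation(self, rng):
        frame = random_water_frame(rng, n=40)
        shift = np.array([3.1, -2.2, 7.9])
        moved = Frame(box=frame.box, water_O=frame.water_O + shift,
                      water_H1=frame.water_H1 + shift,
                      water_H2=frame.water_H2 + shift)
        assert set(detect_hbonds(moved, CRIT)) == set(
            detect_hbonds(frame, CRIT))

    def test_water_relabeling(self, rng):
        frame = random_water_frame(rng, n=40)
        perm = rng.permutation(frame.n_waters)
        shuffled = Frame(box=frame.box, water_O=frame.water_O[perm],
                         water_H1=frame.water_H1[perm],
                         water_H2=frame.water_H2[perm])
        m1 = motif_census(frame, CRIT)
        m2 = motif_census(shuffled, CRIT)
        assert m1.counts == m2.counts
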