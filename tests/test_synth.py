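"""Synthetic-system generators: density arithmetic, determinism, sheet
geometry, motif fixtures, analytic landscapes and simulability."""

import numpy as np
import pytest

from poresel.constants import M_WATER, N_AVOGADRO
from poresel.frames import min_image_dist
from poresel.hbonds import HBondCriteria, detect_hbonds
from poresel.synth import (
    PackingError,
    SystemSpec,
    gen_graphene_pore,
    gen_ion_in_water,
    gen_motif_fixture,
    gen_pore_system,
    gen_solution,
    gen_toy_landscape,
    gen_water_box,
    waters_for_density,
)


class TestWaterBox:
    def test_count_matches_density_arithmetic(self):
        # ρ·V·N_A / M for the 40×40×60 Å study box at 1 g/cm³
        expected = round(1.0 * (40 * 40 * 60 * 1e-24) * N_AVOGADRO / M_WATER)
        assert waters_for_density((40, 40, 60), 1.0) == expected
        assert expected == pytest.approx(3209, abs=20)  # ± rounding

    def test_zero_waters_valid_empty_frame(self):
        frame = gen_water_box(SystemSpec(box=(10, 10, 10), n_waters=0))
        assert frame.n_waters == 0 and frame.n_atoms == 0

    def test_same_seed_identical(self):
        spec = SystemSpec(box=(15, 15, 15), density=1.0, seed=77)
        f1, f2 = gen_water_box(spec), gen_water_box(spec)
        np.testing.assert_array_equal(f1.positions(), f2.positions())

    def test_different_seed_differs(self):
        f1 = gen_water_box(SystemSpec(box=(15, 15, 15), seed=1))
        f2 = gen_water_box(SystemSpec(box=(15, 15, 15), seed=2))
        assert not np.allclose(f1.positions(), f2.positions())

    def test_no_overlaps_and_valid_geometry(self):
        frame = gen_water_box(SystemSpec(box=(16, 16, 16), seed=3))
        frame.validate_geometry()
        O = frame.water_O
        for i in range(frame.n_waters):
            d = min_image_dist(O, O[i], frame.box)
            d[i] = np.inf
            assert d.min() > 2.2

    def test_unphysical_density_rejected(self):
        with pytest.raises(ValueError):
            SystemSpec(box=(10, 10, 10), density=2.0)

    def test_unreachable_packing_errors(self):
        with pytest.raises(PackingError):
            gen_water_box(SystemSpec(box=(6, 6, 6), n_waters=60))


class TestGraphenePore:
    def test_intact_sheet_atom_count(self):
        pos, info = gen_graphene_pore((17.04, 17.04, 20.0), 0.0)
        # 4 atoms per rectangular cell, nx*ny cells
        nx = round(17.04 / (3 * 1.42))
        ny = round(17.04 / (np.sqrt(3) * 1.42))
        assert info["n_atoms"] == 4 * nx * ny
        assert info["n_removed"] == 0

    def test_removed_set_matches_distance_filter(self):
        box = (16.0, 16.0, 20.0)
        full, _ = gen_graphene_pore(box, 0.0)
        cut, info = gen_graphene_pore(box, 3.7)
        center = np.array([8.0, 8.0])
        d = np.hypot(*(full[:, :2] - center).T)
        assert info["n_removed"] == int((d < 3.7).sum())
        assert np.hypot(*(cut[:, :2] - center).T).min() >= 3.7

    def test_monotone_removal(self):
        box = (16.0, 16.0, 20.0)
        n37 = gen_graphene_pore(box, 3.7)[1]["n_removed"]
        n56 = gen_graphene_pore(box, 5.6)[1]["n_removed"]
        assert n56 > n37 > 0

    def test_accessible_radius_reported(self):
        _, info = gen_graphene_pore((16, 16, 20), 3.7)
        assert info["accessible_radius"] < info["nominal_radius"]

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ValueError):
            gen_graphene_pore((16, 16, 20), 8.5)


class TestComposedSystems:
    def test_ion_in_water_centered(self):
        frame = gen_ion_in_water(SystemSpec(box=(15, 15, 15), seed=5), "NA")
        assert frame.ion_labels == ["NA"]
        np.testing.assert_allclose(frame.ion_pos[0], [7.5, 7.5, 7.5])
        d = min_image_dist(frame.water_O, frame.ion_pos[0], frame.box)
        assert d.min() > 2.2

    def test_pore_system_layout(self):
        frame = gen_pore_system(SystemSpec(box=(16, 16, 24), pore_radius=3.7,
                                           seed=6), ion="K", ion_cv=6.0)
        z0 = frame.wall_pos[0, 2]
        assert frame.ion_pos[0, 2] == pytest.approx(z0 + 6.0)
        # waters keep clear of the wall atoms
        for w in frame.wall_pos[:10]:
            assert min_image_dist(frame.water_O, w, frame.box).min() > 2.4

    def test_solution_charge_bookkeeping(self):
        spec = SystemSpec(box=(20, 20, 24), ions={"K": 10, "NA": 10,
                                                  "CL": 20}, seed=7)
        frame = gen_solution(spec, with_sheet=False)
        assert frame.total_charge() == 0.0
        assert sorted(frame.ion_labels).count("CL") == 20

    def test_generated_box_simulates_stably(self, small_ff):
        """10⁴ Langevin steps without constraint failures."""
        from poresel.integrate import IntegratorConfig, integrate
        frame = gen_water_box(SystemSpec(box=(12.5, 12.5, 12.5), seed=8))
        traj = integrate(frame, small_ff,
                         IntegratorConfig(seed=8, friction=5.0), 10_000)
        traj[-1].validate_geometry()


class TestMotifFixtures:
    @pytest.mark.parametrize("label", ["DDAA", "DDA", "DAA", "DA"])
    def test_center_water_motif(self, label):
        frame = gen_motif_fixture(label)
        bonds = detect_hbonds(frame, HBondCriteria())
        donated = sum(1 for d, _, _ in bonds if d == 0)
        accepted = sum(1 for _, _, a in bonds if a == 0)
        want = {"DDAA": (2, 2), "DDA": (2, 1), "DAA": (1, 2), "DA": (1, 1)}
        assert (donated, accepted) == want[label]

    def test_dimer_single_bond(self):
        frame = gen_motif_fixture("dimer")
        assert len(detect_hbonds(frame, HBondCriteria())) == 1

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            gen_motif_fixture("pentamer")

    def test_fixtures_roundtrip_xyz(self, tmp_path):
        from poresel.io import read_xyz, write_xyz
        for label in ("DDAA", "dimer", "trimer-ring"):
            frame = gen_motif_fixture(label)
            p = tmp_path / f"{label}.xyz"
            write_xyz(frame, p)
            back = read_xyz(p)[0]
            np.testing.assert_allclose(back.positions(), frame.positions(),
                                       atol=1e-6)
            assert set(detect_hbonds(back, HBondCriteria())) == set(
                detect_hbonds(frame, HBondCriteria()))


class TestToyLandscapes:
    def test_flat_zero_everywhere(self):
        lc = gen_toy_landscape("flat")
        x = np.linspace(-3, 3, 7)
        assert not lc.potential(x).any() and not lc.gradient(x).any()

    def test_harmonic_closed_form(self):
        lc = gen_toy_landscape("harmonic", k=1.0, x0=0.0)
        assert lc.pmf(2.0) == pytest.approx(2.0)
        assert lc.pmf(0.0) == 0.0

    def test_gradients_match_numerical_derivative(self):
        for form, kw in [("harmonic", {"k": 7.0, "x0": 0.3}),
                         ("double-well", {"a": 1.4, "h": 5.0})]:
            lc = gen_toy_landscape(form, **kw)
            x = np.linspace(-2, 2, 41)
            h = 1e-6
            num = (lc.potential(x + h) - lc.potential(x - h)) / (2 * h)
            np.testing.assert_allclose(lc.gradient(x), num, atol=1e-5)

    def test_double_well_barrier_by_quadrature(self):
        lc = gen_toy_landscape("double-well", a=1.5, h=4.0)
        x = np.linspace(-3, 3, 60001)
        u = lc.potential(x)
        barrier = u[np.abs(x) < 0.75].max() - u.min()
        assert barrier == pytest.approx(4.0, rel=1e-6)
        assert lc.potential(1.5) == pytest.approx(0.0, abs=1e-12)
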