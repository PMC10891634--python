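"""Analytic hydration/selectivity model: closed forms, critical points,
barrier monotonicity and the κ/unit scaling laws."""

import numpy as np
import pytest
from scipy.optimize import bisect

from poresel.thermo import (
    IonPoreGeometry,
    NoCriticalPointError,
    SingularParameterError,
    WaterThermoParams,
    barrier_height,
    circle_measure,
    classify_regime,
    critical_contact,
    critical_radius,
    default_kappa,
    hydration_free_energy,
    ion_filter_energy,
    membrane_measure,
    pair_critical_distance,
    relative_selectivity,
    selectivity_map,
    solve_critical_contact_distance,
)

P = WaterThermoParams()  # ambient defaults


class TestHydrationFreeEnergy:
    def test_bulk_asymptote(self):
        # interfacial term vanishes for a macroscopic solute
        assert hydration_free_energy(1e9, P) == pytest.approx(
            P.dG_water_water, abs=1e-6)

    def test_equal_terms_at_critical_radius(self):
        Rc = critical_radius(P)
        assert hydration_free_energy(Rc, P) == pytest.approx(
            2.0 * P.dG_water_water, rel=1e-12)

    def test_hand_evaluated_value(self):
        # -4.58 + 8*(-2.66)*1.4/3.25
        assert hydration_free_energy(3.25, P) == pytest.approx(-13.7468,
                                                               abs=1e-3)

    def test_strictly_increasing_and_bounded(self):
        R = np.linspace(0.5, 50, 200)
        vals = np.array([hydration_free_energy(r, P) for r in R])
        assert (np.diff(vals) > 0).all()
        assert (vals < P.dG_water_water).all()

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            hydration_free_energy(0.0, P)


class TestCriticalRadius:
    def test_ambient_value(self):
        # 6.5 Å at 293 K / 0.1 MPa
        assert critical_radius(P) == pytest.approx(6.5, abs=0.05)

    def test_linearity_in_dG_DDAA(self):
        p2 = WaterThermoParams(dG_DDAA=P.dG_DDAA / 2)
        assert critical_radius(p2) == pytest.approx(critical_radius(P) / 2)

    def test_matches_bisection_root(self, rng):
        # R_c is where the interfacial term equals the bulk term
        for _ in range(20):
            p = WaterThermoParams(
                dG_DDAA=-float(rng.uniform(0.5, 5)),
                r_H2O=float(rng.uniform(1.0, 2.0)),
                dG_water_water=-float(rng.uniform(1, 10)),
            )
            f = lambda R: (hydration_free_energy(R, p) - p.dG_water_water
                           ) - p.dG_water_water
            root = bisect(f, 1e-3, 1e5, xtol=1e-12)
            assert critical_radius(p) == pytest.approx(root, rel=1e-9)

    def test_singular_parameters(self):
        with pytest.raises(SingularParameterError):
            critical_radius(WaterThermoParams(dG_water_water=0.0))


class TestRegimesAndPairDistance:
    @pytest.mark.parametrize("R,expected", [(5.0, "initial"),
                                            (8.0, "hydrophobic")])
    def test_classification(self, R, expected):
        assert classify_regime(R, P) == expected

    def test_boundary_is_critical(self):
        assert classify_regime(critical_radius(P), P) == "critical"

    def test_pair_distance_is_half_single(self):
        assert pair_critical_distance(P) == pytest.approx(3.25, abs=0.05)
        p2 = WaterThermoParams(dG_DDAA=2 * P.dG_DDAA)
        assert pair_critical_distance(p2) == pytest.approx(
            critical_radius(p2) / 2, rel=1e-15)


class TestInterfacialMeasures:
    def test_membrane_contact_value(self):
        assert membrane_measure(0.0, 7.0) == pytest.approx(np.pi * 7.0)

    def test_membrane_345_triangle(self):
        assert membrane_measure(15.0, 20.0) == pytest.approx(np.pi * 10.0)

    def test_membrane_decreasing_to_zero(self):
        d = np.linspace(0, 500, 400)
        vals = np.array([membrane_measure(x, 20.0) for x in d])
        assert (np.diff(vals) < 0).all()
        assert vals[-1] < 3.0

    def test_membrane_far_field_series(self):
        # π(√(w²+d²) − d) = π w²/(2d) + O(d⁻³)
        for w in (5.0, 20.0):
            d = 150.0 * w
            series = np.pi * (w ** 2 / (2 * d) - w ** 4 / (8 * d ** 3))
            assert membrane_measure(d, w) == pytest.approx(series, rel=1e-6)

    def test_membrane_domain_errors(self):
        with pytest.raises(ValueError):
            membrane_measure(-1.0, 5.0)
        with pytest.raises(ValueError):
            membrane_measure(1.0, 0.0)

    def test_circle_measure(self):
        g = IonPoreGeometry(r_ion=1.3, R_pore=3.7, sep=0.0)
        assert circle_measure(g) == pytest.approx(0.2)
        g2 = IonPoreGeometry(r_ion=2.6, R_pore=7.4, sep=0.0)
        assert circle_measure(g2) == pytest.approx(0.1)
        far = IonPoreGeometry(r_ion=1.3, R_pore=3.7, sep=1e9)
        assert circle_measure(far) == pytest.approx(0.0, abs=1e-8)


class TestIonFilterDecomposition:
    def test_identity_and_degenerate_pore(self, rng):
        for _ in range(10):
            g = IonPoreGeometry(r_ion=float(rng.uniform(0.5, 3)),
                                R_pore=float(rng.uniform(0.1, 8)),
                                w_membrane=float(rng.uniform(5, 30)),
                                d_axial=float(rng.uniform(0, 20)),
                                sep=float(rng.uniform(0, 5)))
            dec = ion_filter_energy(g, P)
            assert dec.dG_ion_filter == pytest.approx(
                dec.dG_ion_membrane - dec.dG_ion_circle, rel=1e-12)

    def test_linear_in_kappa(self):
        g = IonPoreGeometry(r_ion=1.33, R_pore=3.7, d_axial=5.0)
        k = default_kappa(P)
        d1 = ion_filter_energy(g, P, kappa=k)
        d2 = ion_filter_energy(g, P, kappa=2 * k)
        for attr in ("dG_ion_membrane", "dG_ion_circle", "dG_ion_filter"):
            assert getattr(d2, attr) == pytest.approx(
                2 * getattr(d1, attr), rel=1e-12)


class TestCriticalContact:
    def test_residual_below_tolerance(self):
        crit = critical_contact(P, r_ion=1.33)
        resid = (default_kappa(P)
                 * (membrane_measure(crit.d_c, 20.0) - 1.0 / crit.d_c)
                 - P.dG_water_water)
        assert abs(resid) < 1e-9 * abs(P.dG_water_water)

    def test_round_trip_recovery(self):
        crit = critical_contact(P, r_ion=1.33)
        back = critical_contact(P, R_pore=crit.R_pore_c)
        assert back.r_ion_c == pytest.approx(1.33, abs=1e-6)

    def test_matches_grid_scan(self):
        crit = critical_contact(P, r_ion=1.0, w_membrane=1.2)
        k = default_kappa(P)
        f = lambda d: k * (membrane_measure(d, 1.2) - 1.0 / d) \
            - P.dG_water_water
        # brute-force: last sign change on a dense grid
        d = np.linspace(1e-3, 100, 200001)
        vals = k * (np.pi * (np.hypot(1.2, d) - d) - 1.0 / d) \
            - P.dG_water_water
        idx = np.nonzero(np.diff(np.sign(vals)))[0][-1]
        assert d[idx] <= crit.d_c <= d[idx + 1]
        assert abs(f(crit.d_c)) < 1e-9

    def test_no_root_reported(self):
        # dG_water_water far below anything the measures can balance
        weak = WaterThermoParams(dG_DDAA=-1e-6, dG_water_water=-50.0)
        with pytest.raises(NoCriticalPointError):
            critical_contact(weak, r_ion=1.0, w_membrane=1.0, d_max=1e3)


class TestBarrierHeight:
    def setup_method(self):
        self.crit = critical_contact(P, r_ion=1.33, w_membrane=1.2)

    def test_zero_at_critical_combination(self):
        d_c = self.crit.d_c
        g = IonPoreGeometry(r_ion=d_c / 2, R_pore=d_c / 2, w_membrane=1.2)
        b, regime = barrier_height(g, P, self.crit)
        assert b == 0.0
        assert regime == "critical"

    def test_larger_ion_lower_barrier(self):
        # K+-like (1.33 Å) sees a lower barrier than Na+-like (0.95 Å)
        bK, _ = barrier_height(IonPoreGeometry(1.33, 3.7), P, self.crit)
        bNa, _ = barrier_height(IonPoreGeometry(0.95, 3.7), P, self.crit)
        assert bNa > bK > 0

    def test_wider_pore_lower_barrier(self):
        bs = [barrier_height(IonPoreGeometry(1.33, rp), P, self.crit)[0]
              for rp in (1.8, 3.7, 5.6)]
        assert bs[0] > bs[1] > bs[2] >= 0

    def test_clamped_beyond_critical(self):
        g = IonPoreGeometry(r_ion=self.crit.d_c, R_pore=self.crit.d_c)
        b, regime = barrier_height(g, P, self.crit)
        assert b == 0.0
        assert regime == "hydrophobic"

    def test_monotone_nonincreasing_partial_differences(self):
        grid = np.linspace(0.3, 8.0, 25)
        for r_fixed in (0.95, 1.33):
            bs = [barrier_height(IonPoreGeometry(r_fixed, rp), P,
                                 self.crit)[0] for rp in grid]
            assert (np.diff(bs) <= 1e-12).all()
        for rp_fixed in (1.8, 3.7):
            bs = [barrier_height(IonPoreGeometry(ri, rp_fixed), P,
                                 self.crit)[0] for ri in grid]
            assert (np.diff(bs) <= 1e-12).all()


class TestSelectivityMap:
    def test_single_cell_matches_barrier(self):
        df = selectivity_map([1.33], [3.7], P, w_membrane=1.2)
        crit = critical_contact(P, r_ion=1.33, w_membrane=1.2)
        b, _ = barrier_height(IonPoreGeometry(1.33, 3.7, w_membrane=1.2),
                              P, crit)
        row = df.iloc[0]
        assert row.label == "barrier"
        assert row.barrier_kJmol == pytest.approx(b, rel=1e-9)

    def test_monotone_labels_along_pore_radius(self):
        ri = [0.6, 1.0, 1.6]
        rp = list(np.linspace(0.5, 12.0, 30))
        df = selectivity_map(ri, rp, P, w_membrane=1.2)
        rank = {"barrier": 0, "forbidden": 1, "free-pass": 2}
        for r in ri:
            labels = df[df.r_ion == r].sort_values("R_pore").label
            ranks = [rank[l] for l in labels]
            # never returns from free-pass to barrier as the pore widens
            seen_free = False
            for v in ranks:
                if v == 2:
                    seen_free = True
                assert not (seen_free and v == 0)

    def test_boundary_matches_critical_contact(self):
        d_c = solve_critical_contact_distance(P, w_membrane=1.2)
        rp = np.linspace(0.5, 12.0, 200)
        df = selectivity_map([1.0], rp, P, w_membrane=1.2)
        sub = df.sort_values("R_pore")
        transition = sub[sub.label != "barrier"].R_pore.min()
        # first non-barrier pore radius sits at the critical locus
        assert transition == pytest.approx(d_c - 1.0, abs=np.diff(rp)[0])


class TestRelativeSelectivity:
    def test_no_preference_when_equal(self):
        r = relative_selectivity(-5, -5, -5, -5)
        assert r.ddG == 0
        assert r.preferred_ion == "none"

    def test_bulk_difference_drives_sign(self):
        r = relative_selectivity(-5, -8, -5, -6)
        assert r.ddG > 0
        assert r.preferred_ion == "b"

    def test_antisymmetry(self):
        a = relative_selectivity(-5.0, -7.0, -4.0, -6.5)
        b = relative_selectivity(-4.0, -6.5, -5.0, -7.0)
        assert a.ddG == pytest.approx(-b.ddG)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            relative_selectivity(np.nan, 0, 0, 0)


def test_unit_conversion_is_pure_factor():
    """Expressing all energies in kcal/mol scales every output by 1/4.184."""
    F = 4.184
    p_kcal = WaterThermoParams(dG_DDAA=P.dG_DDAA / F,
                               dG_water_water=P.dG_water_water / F)
    # lengths unchanged
    assert critical_radius(p_kcal) == pytest.approx(critical_radius(P))
    crit = critical_contact(P, r_ion=1.0, w_membrane=1.2)
    crit_k = critical_contact(p_kcal, r_ion=1.0, w_membrane=1.2)
    assert crit_k.d_c == pytest.approx(crit.d_c, rel=1e-9)
    g = IonPoreGeometry(1.0, 2.0, w_membrane=1.2)
    b = barrier_height(g, P, crit)[0]
    b_k = barrier_height(g, p_kcal, crit_k)[0]
    assert b_k == pytest.approx(b / F, rel=1e-9)
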