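# Methods

`poresel` implements a thermodynamic model of ion selectivity in nanopores
together with the water-structure analyses and a minimal molecular simulator
that probe the same physics at desk scale. This note records the model, its
assumptions, the numerical choices, and what the synthetic systems do and do
not establish about real ones.

## The hydration free-energy model

Inserting a spherical solute of radius R into water creates an interfacial
water layer that has lost its tetrahedral (DDAA, double donor–double
acceptor) hydrogen bonds. With ΔG_DDAA the Gibbs energy of a DDAA hydrogen
bond (−2.66 kJ/mol at ambient conditions), r_H2O the mean water radius and
ΔG_ww the per-molecule Gibbs energy of bulk water, the model writes

    ΔG_hydration(R) = ΔG_ww + 8 · ΔG_DDAA · r_H2O / R .

Both terms are negative (stabilising). The interfacial term decays as 1/R
(surface-to-volume ratio), so the two terms cross at the critical radius

    R_c = 8 · ΔG_DDAA · r_H2O / ΔG_ww ,

which separates an "initial" regime (R < R_c, interfacial term dominates,
solutes disperse — effective repulsion) from a "hydrophobic" regime
(R > R_c, bulk term dominates, solutes aggregate — effective attraction).
For two identical spheres the interfacial term scales with the inverse
inter-solute distance, putting the pair critical distance at R_c/2.

**Calibrated constants.** ΔG_DDAA = −2.66 kJ/mol is a stated input. r_H2O
and ΔG_ww are not; the defaults r_H2O = 1.4 Å (conventional mean molecular
radius of water) and ΔG_ww = −4.58 kJ/mol are calibrated so that R_c = 6.5 Å
at 293 K / 0.1 MPa, the ambient value the model targets. Both are
config-overridable and must be read as calibrated stand-ins, not measured
quantities.

**Ion–pore decomposition.** For an ion approaching a membrane pierced by a
circular pore, the interfacial Gibbs energy splits as
ΔG_ion-filter = ΔG_ion-membrane − ΔG_ion-circle, the circle being the
material that would fill the pore. Each term is a geometric measure times a
single interfacial coefficient κ:

* membrane (disc of radius w, on-axis distance d): measure
  π·(√(w²+d²) − d), i.e. π·w at contact, ~π·w²/(2d) far away;
* circle (treated as a sphere of radius R_pore): measure
  1/(R_pore + r_ion + sep).

The two measures are not dimensionally commensurate (one is a length, the
other an inverse length); the model treats both as abstract interfacial
measures under one κ, and we follow it. κ defaults to 8·ΔG_DDAA·r_H2O
(−29.792 kJ·Å/mol) so that κ/R reproduces the isolated-sphere interfacial
term; all barrier outputs scale linearly in κ, and unit changes
(kJ ↔ kcal) are a pure factor 4.184.

The critical contact distance d_c solves
ΔG_ion-membrane(d_c) − ΔG_ion-circle(d_c) = ΔG_ww at sep = 0, with
d_c = R_pore,c + r_ion,c. The balance can cross zero twice; we return the
root on the decreasing branch, the one where the regime flips from initial
(d < d_c, barrier) to hydrophobic (d > d_c) — the physically meaningful
crossing. Because the membrane measure carries its dimensional
inconsistency, the absolute magnitude of d_c depends strongly on w; the
*structure* of the predictions (barrier ordering in ion size and pore
radius, the existence of a critical combination) does not.

The entry barrier in the initial regime is

    ΔG_barrier = |κ| · [ 1/(R_pore + r_ion) − 1/d_c ] ,

zero at the critical combination, clamped to zero beyond it, and reported as
a positive magnitude. Selectivity maps label each (r_ion, R_pore) cell
barrier / free-pass / forbidden; in the hydrophobic regime an ion passes
freely when it fits the aperture (r_ion ≤ R_pore) and is sterically
forbidden otherwise. Relative site selectivity uses
ΔΔG_a→b = (ΔG_site,a − ΔG_site,b) − (ΔG_bulk,a − ΔG_bulk,b); ΔΔG < 0 means
the site prefers ion a.

## Hydrogen-bond and hydration-shell analysis

A hydrogen bond between two waters requires O–O distance < 3.5 Å and the
angle at the donor oxygen between the O→O vector and the donor O–H bond
< 30° — the standard geometric criterion, applied under the minimum-image
convention. Each donor hydrogen binds at most one acceptor (the nearest
eligible one), so donated counts are ≤ 2 and the (donated, accepted) pair
classifies the motif: (2,2) DDAA, (2,1) DDA, (1,2) DAA, (1,1) DA, all else
"other" (accepted counts are not capped; over-coordinated waters land in
"other"). Detection uses a periodic k-d tree neighbor list and is
regression-tested against an all-pairs oracle.

Interfacial water is water whose oxygen lies within a shell cutoff (default
3.5 Å, the same as the O–O cutoff) of any solute or wall atom; everything
else is bulk. The cutoff is a design choice — the underlying notion, "the
topmost water layer at the interface", fixes no number — and is
config-overridable.

RDFs are shell-normalised pair histograms (bin width 0.05 Å); the running
coordination number n(r) is accumulated by direct counting, so n(r_max) is
exactly the mean neighbor count. The first hydration-shell boundary is the
first local minimum after the first maximum of the 5-bin moving-average
smoothed g(r). For the shallow K⁺–O minimum this estimator has a few tenths
of an Å of sampling scatter, which propagates to a few tenths of a water in
the coordination number; the sampling lengths below keep that scatter inside
the stated tolerances.

## The minimal simulator

Rigid 3-site waters (TIP3P-like geometry: O–H 0.9572 Å, H–O–H 104.52°,
charges −0.834/+0.417 e) with standard CHARMM-compatible Lennard-Jones
parameters for Na⁺, K⁺, Cl⁻ and a neutral aromatic carbon for the wall;
the parameter table is versioned in `forcefield.py`. Lennard-Jones
interactions are switched to zero with the C1-continuous CHARMM switching
function; electrostatics use a Barker–Watts reaction field (ε_RF = 78)
truncated with the LJ cutoff. Reaction field replaces Ewald summation
deliberately: it keeps the force loop local and desk-sized, at the cost of
mean-field treatment of long-range polarisation. Box sizes set the cutoffs:
the minimum image demands r_off < box/2, so desk boxes use scaled switching
ranges (7–9 Å for a ~21 Å box, 5.8–7.5 Å for a 16 Å box) in place of the
10–12 Å convention that a 40 Å box supports.

Dynamics are BAOAB-split Langevin at 300 K (2 fs default timestep), which
reduces to velocity Verlet at zero friction — the NVE energy-drift test
exercises exactly that limit on an uncharged LJ fluid, where the potential
is C1 everywhere (the reaction-field force has a small, physical
discontinuity at the cutoff that would contaminate a drift measurement).
Water rigidity is enforced by iterative SHAKE after each drift substep
(tolerance 1e-8 on squared bond lengths, with the matching velocity
correction) and an exact 3×3 velocity projection (RATTLE) after each kick —
for a rigid triatomic the velocity constraints are linear, so no iteration
is needed. Wall atoms are frozen: they exert forces but never move, and
wall–wall pairs are excluded. Forces run through a numba-compiled Verlet
pair list (skin 1 Å, rebuilt when any atom has moved half the skin) that is
regression-tested against the direct O(N²) kernel. Every stochastic run
takes a mandatory seed, carries it in its output metadata, and is
bit-reproducible single-threaded.

## ABF

The collective variable is the axial ion–pore distance; the ion is held on
the pore axis by a stiff transverse harmonic (100 kJ/mol/Å², orthogonal to
the CV, so it does not bias the profile). The CV range splits into
consecutive windows (2.6 Å wide, 0.4 Å overlap) confined by half-harmonic
walls and visited from the largest CV inward; the instantaneous systematic
force on the ion along z is accumulated per 0.2 Å bin (0.1 Å on analytic
landscapes), and the opposing running-mean force is applied after a linear
ramp-up (full bias beyond the per-bin sample threshold), clamped at
400 kJ/mol/Å for stability against the steep wall repulsion of the
narrowest pore. Samples taken while a window wall is active are discarded.
All windows pool into one global bin grid, which stitches overlaps by
count-weighted averaging of the mean force; the PMF is the negative
integral of the mean force (trapezoid), anchored to zero at the largest CV,
with under-sampled bins flagged unconverged. The estimator is validated
against closed-form PMFs: harmonic (RMS < 0.1 kT) and double well (barrier
within 5%).

The voltage experiment adds a constant force q·E·ẑ to every charged
particle (E in kcal·mol⁻¹·Å⁻¹·e⁻¹) and counts signed crossings of the
membrane plane — and its periodic images, since coordinates are unwrapped —
gated on the transverse distance to the pore axis at the crossing step.

## Synthetic systems

Water boxes place molecules on a body-centred candidate lattice
(site spacing ≥ 2.6 Å) with ±0.1 Å jitter and random rigid orientations,
drawing sites with the seeded generator; the water count follows
ρ·V·N_A/M. Overlap-free placement plus a short strong-friction Langevin
segment replaces energy minimisation — a constrained minimiser would
duplicate machinery the integrator already provides, and the generated
boxes integrate stably for ≥10⁴ steps out of the box. The graphene-like
sheet is a hexagonal lattice (C–C 1.42 Å) slightly strained to close the
periodic box, with atoms inside the nominal pore radius removed; the
accessible radius (axis-to-carbon minus the carbon LJ radius) is reported
alongside, since a pore-radius convention is otherwise ambiguous. Ionic
solutions substitute ions onto lattice sites (10 KCl + 10 NaCl → 20 Cl⁻
keeps neutrality in the full-scale voltage analogue). Motif fixtures are
hand-placed geometries guaranteed to classify as DDAA/DDA/DAA/DA, a dimer
or a cyclic trimer; analytic landscapes (flat, harmonic, double-well) ship
exact gradients and closed-form PMFs.

## Problem sizes and what the desk scale shows

The package's standard experiments, chosen to run in minutes on one core:

* **Coordination numbers** — one ion in ~300 waters (~21 Å box), 10 ps
  strong-friction equilibration, 100 ps production, RDF first-minimum
  shell boundary. Scaled-down in-suite versions use 150 waters / 90 ps
  (sampling length set where the first-minimum estimate stops drifting).
* **Ion–pore barriers** — ~120–160 waters around a 15–16 Å sheet, windowed
  ABF sweeps of 15–40 k steps, three seeds; compared at sign level only
  (orderings across pore radii 1.8/3.7/5.6 Å and across Na⁺/K⁺ at 3.7 Å).

Desk-scale ABF PMFs are not converged free energies: absolute barrier
magnitudes drift with protocol length and the positions of PMF minima are
not meaningful at these sampling depths. The orderings — narrower pore ⇒
higher barrier, smaller (more tightly hydrated) ion ⇒ higher barrier — are
the claims the toy systems test, and they are assessed per seed. Likewise
the jittered-lattice water and reaction-field electrostatics reproduce bulk
water's structure only approximately (n_HB ≈ 3.3 against the geometric
criterion, first-shell positions within ~0.1 Å of full-scale values);
passing tests show the machinery is self-consistent and the physics
qualitatively right at this scale, not that the force field is
quantitatively faithful for real channels.

## Known limitations

* No Ewald/PME electrostatics, no polarisability, no protein force field:
  the simulator is a desk-scale analogue, not a production MD engine.
* The Eq.-level dimensional mismatch of the membrane measure is inherited
  from the model; d_c magnitudes depend on the membrane radius w.
* First-minimum detection on shallow RDF minima carries a few tenths of an
  Å of scatter at short sampling.
* The parameter set has its own hydration structure: Na⁺ holds ~5.6–5.9
  first-shell waters, but K⁺ holds ~7 (shell boundary 3.5–3.7 Å) — smaller
  than the ~8 reported for Ewald-based CHARMM setups, because the shallow
  K–O minimum sits earlier here. Comparisons against literature potassium
  coordination numbers should expect that offset.
* H-bond lifetimes, energetic/topological bond definitions and spectral
  reconstructions are out of scope.
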