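# poresel

Thermodynamics of ion selectivity in nanopores: why does a narrow channel
let K⁺ through while turning away the smaller Na⁺? `poresel` implements a
hydration free-energy model of that selectivity, the water-structure
analyses that support it, and a minimal molecular simulator that reproduces
its qualitative predictions on synthetic ion–nanopore systems. It is aimed
at molecular modellers and biophysicists who want a small, fully
inspectable implementation of the model and its desk-scale tests.

## The model

Inserting a sphere of radius R into water costs interfacial hydrogen-bond
structure. With ΔG_DDAA the Gibbs energy of a tetrahedral (DDAA) hydrogen
bond and ΔG_ww the per-molecule Gibbs energy of bulk water,

    ΔG_hydration(R) = ΔG_ww + 8·ΔG_DDAA·r_H2O / R,
    R_c = 8·ΔG_DDAA·r_H2O / ΔG_ww  (≈ 6.5 Å at ambient conditions),

and solutes below/above R_c sit in the "initial" (dispersive) or
"hydrophobic" (aggregative) regime. For an ion of radius r_ion entering a
pore of radius R_pore the interfacial energy decomposes into
ion–membrane minus ion–circle terms, giving an entry barrier

    ΔG_barrier ∝ 1/(R_pore + r_ion) − 1/(R_pore,c + r_ion,c)

in the initial regime: narrower pores and smaller, more tightly hydrated
ions face higher barriers — the thermodynamic reading of K⁺/Na⁺
selectivity. The package evaluates the model in closed form
(`poresel.thermo`), measures water structure in trajectories — geometric
hydrogen bonds (O–O < 3.5 Å, donor angle < 30°), DDAA/DDA/DAA/DA motif
census, interfacial/bulk partition, RDFs and first-shell coordination
numbers (`poresel.hbonds`, `poresel.rdf`) — and checks the barrier
phenomenology with a rigid-water Langevin simulator plus adaptive-biasing-
force (ABF) PMF estimation on graphene-like pores of radius 1.8/3.7/5.6 Å
(`poresel.forcefield`, `poresel.integrate`, `poresel.abf`,
`poresel.protocols`). All inputs are generated synthetically
(`poresel.synth`); nothing is downloaded.

## Worked example

```sh
python examples/01_hydration_model.py
```

prints

```
critical solute radius R_c        : 6.50 Å
two-sphere critical distance      : 3.25 Å
hydration free energy, R = 3.25 Å : -13.75 kJ/mol

entry barrier vs pore radius (K+-sized ion, κ-scaled kJ/mol):
  R_pore = 1.8 Å ->   9.51  [initial]
  R_pore = 3.7 Å ->   5.92  [initial]
  R_pore = 5.6 Å ->   4.29  [initial]
a narrower pore raises the barrier; a smaller ion (0.95 Å) raises it further:
  Na+-sized 6.40 vs K+-sized 5.92 at R_pore = 3.7 Å

ΔΔG(a→b) = -31.0 kJ/mol -> site prefers ion 'a'
```

R_c = 6.5 Å is the solute size at which the interfacial and bulk water
terms balance; the barrier column shows the model's core prediction — the
1.8 Å pore resists a K⁺-sized ion twice as hard as the 3.7 Å pore, and at
fixed pore the smaller Na⁺-sized ion always faces the higher barrier. The
negative ΔΔG in the last line means the binding site prefers ion *a* once
site and bulk solvation are both accounted for.

A scaled-down simulation counterpart:

```sh
python examples/03_hydration_shell.py
```

```
ion                     : NA+
shell boundary (RDF min): 3.23 Å
coordination number     : 5.80 waters
```

i.e. Na⁺ in a ~100-water box keeps ~5.8 waters inside its RDF first
minimum. The other examples cover the hydrogen-bond census, ABF validation
on an analytic double well, and voltage-driven pore crossings. A thin CLI
(`poresel thermo|hbond|rdf|sim|gen`) wraps the same calls for shell use and
writes a JSON manifest per run.

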