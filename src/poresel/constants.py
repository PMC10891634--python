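"""Physical constants and unit conversions.

Internal units throughout the package: length Å, energy kJ/mol, time ps,
mass g/mol (= amu), charge e, temperature K.  In these units velocities come
out in Å/ps and the thermal energy k_B*T in kJ/mol.
"""

#: Boltzmann constant, kJ/(mol·K)
KB = 0.008314462618

#: Coulomb prefactor e²/(4πε₀), in kJ·Å/mol — V(r) = KE·q1·q2/r
KE = 1389.35457644382

#: kcal → kJ
KCAL = 4.184

#: molar masses, g/mol
MASSES = {
    "OW": 15.9994,
    "HW": 1.008,
    "NA": 22.98977,
    "K": 39.0983,
    "CL": 35.453,
    "C": 12.011,
}

#: average molar mass of water, g/mol
M_WATER = 18.01528

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23
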