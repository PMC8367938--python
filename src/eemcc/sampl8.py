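"""Reference dataset: CB8 host-guest binding in the SAMPL8 "Drugs of
Abuse" challenge.

Seven drug-like guests (G1-G7) bind the cucurbit[8]uril (CB8) host in
water. Bundled here are the published per-guest thermodynamic
components from this method's triplicate 100-ns GROMACS runs
(``CALC``), the isothermal-titration-calorimetry experimental values
(``EXPT``), the unbound-host entropy-component column, and the mean
first-shell/released water counts. They serve as worked-example inputs
for the assembly, bookkeeping and error-statistics machinery — desk
machines cannot regenerate the underlying 2.8 us of force-bearing
trajectories.

Units: kcal mol^-1 for dG/dH/TdS, J K^-1 mol^-1 for entropy components,
water counts are trajectory means (fractional).
"""

GUESTS = ("G1", "G2", "G3", "G4", "G5", "G6", "G7")

#: CB8 has an 8-fold and a 2-fold rotational axis
CB8_SYMMETRY_NUMBER = 16

# guest -> (dG, dH, TdS), kcal mol^-1
CALC = {
    "G1": (-6.3, -7.6, -1.3),
    "G2": (-9.6, -5.0, 4.6),
    "G3": (-10.2, -11.9, -1.7),
    "G4": (-12.6, -11.7, 1.0),
    "G5": (-12.2, -14.0, -1.7),
    "G6": (-15.3, -14.4, 1.0),
    "G7": (-9.0, -11.5, -2.5),
}

EXPT = {
    "G1": (-7.1, -7.8, -0.8),
    "G2": (-9.9, -10.8, -0.9),
    "G3": (-11.6, -13.6, -2.0),
    "G4": (-11.2, -15.8, -4.6),
    "G5": (-12.3, -17.3, -5.0),
    "G6": (-14.1, -14.9, -0.8),
    "G7": (-7.9, -8.3, -0.3),
}

# replicate SEMs of dG, kcal mol^-1
CALC_DG_SEM = {
    "G1": 1.4, "G2": 0.6, "G3": 1.9, "G4": 1.8, "G5": 1.4, "G6": 1.0, "G7": 0.4,
}

#: entropy components of the unbound host system (host column),
#: J K^-1 mol^-1
HOST_UNBOUND = {
    "S_M^transvib": 70.0,
    "S_M^rovib": 74.0,
    "S_UA^transvib": 662.0,
    "S_UA^rovib": 159.0,
    "S^conf": 0.0,
    "S_WS^transvib": 4079.0,
    "S_WS^rovib": 1515.0,
    "S_WS^or": 251.0,
}

#: mean first-shell water count of the unbound host
N_WS_HOST = 87.4

#: complex-shell water count on the host side, per guest
N_WS_COMPLEX_HOST = {
    "G1": 76.4, "G2": 73.7, "G3": 75.2, "G4": 75.4,
    "G5": 76.9, "G6": 76.2, "G7": 75.3,
}

#: waters released from the host shell on binding, per guest
N_WB_HOST = {
    "G1": 11.0, "G2": 13.7, "G3": 12.2, "G4": 12.0,
    "G5": 10.5, "G6": 11.2, "G7": 12.1,
}

#: mean first-shell water count of each unbound guest
N_WS_GUEST = {
    "G1": 24.3, "G2": 37.9, "G3": 30.9, "G4": 31.1,
    "G5": 28.4, "G6": 31.7, "G7": 35.4,
}

#: complex-shell water count on the guest side, per guest
N_WS_COMPLEX_GUEST = {
    "G1": 2.4, "G2": 8.3, "G3": 4.7, "G4": 4.6,
    "G5": 2.9, "G6": 5.3, "G7": 10.1,
}

#: waters released from the guest shell on binding, per guest
N_WB_GUEST = {
    "G1": 21.9, "G2": 29.6, "G3": 26.3, "G4": 26.5,
    "G5": 25.5, "G6": 26.4, "G7": 25.3,
}

#: bulk-released water entropy totals of the host system for G1
#: (per-water values are common to all guests: one bulk simulation)
WB_TOTALS_HOST_G1 = {"transvib": 516.0, "rovib": 190.0, "or": 123.0}
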