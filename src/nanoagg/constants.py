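"""Physical constants and reference parameterizations.

Internal unit system (consistent, GROMACS-style): length nm, time ps,
energy kJ/mol, mass u (unified atomic mass units).  In these units
1 u nm^2 ps^-2 == 1 kJ/mol, so the integrator needs no conversion factors.
SI quantities (Hamaker constants in J, viscosities in Pa s) are converted
at the API boundary.
"""

# Boltzmann constant, kJ mol^-1 K^-1 (internal unit system)
KB_KJ_MOL_K = 0.0083144621

# Boltzmann constant, J K^-1 (SI, used where formulas are evaluated in SI)
KB_J = 1.380649e-23

# Avogadro's number, mol^-1
AVOGADRO = 6.02214076e23

# Unified atomic mass unit, kg
AMU_KG = 1.66054e-27

# Dynamic viscosity of water at 310 K, Pa s (default solvent)
WATER_VISCOSITY_310K = 6.913e-4

# Hamaker constant for titania-titania across water, J
HAMAKER_TIO2_WATER = 6.0e-20

# Standard atomic masses, u
MASS_TI = 47.867
MASS_O = 15.999

# Reference anatase TiO2 nanoparticle models: radius (nm) -> (n_Ti, n_O)
ANATASE_STOICHIOMETRY = {
    0.78: (111, 222),
    1.50: (417, 834),
    2.00: (985, 1970),
}

# Aggregation free energy wells of the anatase NP pair PMFs in water:
# radius (nm) -> (well depth AFE, kJ/mol; well position above contact
# d_AFE - 2R, nm).  Used to parameterize synthetic PMF curves.
ANATASE_PMF_WELLS = {
    0.78: (44.18, 0.23),
    1.50: (54.35, 0.35),
    2.00: (75.56, 0.46),
}

# Best-fit coefficients (n2, n3) of the size-aware discretized aggregation
# model for the anatase systems: (radius nm, volume fraction) -> (n2, n3).
ANATASE_KINETIC_COEFFS = {
    (0.78, 0.008): (0.101, 0.221),
    (0.78, 0.018): (0.101, 0.362),
    (0.78, 0.035): (0.134, 0.221),
    (0.78, 0.070): (0.148, 0.101),
    (1.50, 0.008): (0.141, 0.181),
    (1.50, 0.018): (0.134, 0.161),
    (1.50, 0.035): (0.268, 0.027),
    (1.50, 0.070): (0.027, 0.094),
    (2.00, 0.008): (0.0, 0.698),
    (2.00, 0.018): (0.162, 0.114),
    (2.00, 0.035): (0.169, 0.067),
    (2.00, 0.070): (0.040, 0.034),
}


def nanoparticle_mass(radius_nm: float) -> float:
    """Stoichiometric mass (u) of a reference anatase NP of given radius."""
    try:
        n_ti, n_o = ANATASE_STOICHIOMETRY[round(radius_nm, 2)]
    except KeyError:
        raise KeyError(
            f"no reference stoichiometry for R = {radius_nm} nm; "
            f"known radii: {sorted(ANATASE_STOICHIOMETRY)}"
        ) from None
    return n_ti * MASS_TI + n_o * MASS_O
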