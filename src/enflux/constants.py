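"""Physical constants for energy bookkeeping.

All whole-body fluxes are carried in μmol/day and converted into kcal/day
through the triglyceride (TG) energy equivalent: one TG yields 21.4
acetyl-CoA (ACoA) on complete β-oxidation, TG has a molar mass of 853 u,
and fat carries 9 kcal/g.  Every respired ACoA is converted to energy with
this single TG-based factor, irrespective of the substrate it came from;
substrate-specific caloric densities are used only on the *intake* side of
the ledger.
"""

#: mol ACoA produced per mol TG on complete β-oxidation (and consumed per
#: mol TG on de novo lipogenesis; the stoichiometry is applied symmetrically)
ACOA_PER_TG = 21.4

#: molar mass of an average triglyceride [g/mol]
TG_MOLAR_MASS = 853.0

#: caloric density of fat [kcal/g]
KCAL_PER_G_FAT = 9.0

#: energy equivalent of one μmol TG [kcal/μmol]
KCAL_PER_UMOL_TG = TG_MOLAR_MASS * 1e-6 * KCAL_PER_G_FAT

#: energy equivalent of one μmol respired ACoA [kcal/μmol]
KCAL_PER_UMOL_ACOA = KCAL_PER_UMOL_TG / ACOA_PER_TG

# --- dietary (intake-side) energy densities -------------------------------
GLUCOSE_MOLAR_MASS = 180.16   # g/mol
KCAL_PER_G_CARB = 4.0
#: kcal per μmol dietary glucose equivalent
KCAL_PER_UMOL_GLUCOSE = GLUCOSE_MOLAR_MASS * 1e-6 * KCAL_PER_G_CARB

AMINO_ACID_MOLAR_MASS = 110.0  # g/mol, average residue
KCAL_PER_G_PROTEIN = 4.0
#: kcal per μmol dietary amino-acid equivalent
KCAL_PER_UMOL_AA = AMINO_ACID_MOLAR_MASS * 1e-6 * KCAL_PER_G_PROTEIN

#: nominal plasma volume [mL] used to interconvert plasma pool sizes (μmol)
#: and concentrations (mM); 1 mL is a convenient murine default under which
#: 1 μmol corresponds to 1 mM.
PLASMA_VOLUME_ML = 1.0

#: a pool below this size [μmol] counts as depleted
DEPLETION_FLOOR = 1e-6
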