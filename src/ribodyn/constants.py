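"""Physical constants and package-wide defaults.

Units follow the conventions of the nearest-neighbour RNA literature:
energies in kcal/mol, temperatures in kelvin, concentrations in uM,
first-order rates in 1/s and second-order rates in 1/(uM*s).
"""

from __future__ import annotations

import os
import sys

#: Boltzmann constant in kcal/(mol*K) (i.e. the molar gas constant R).
KB_KCAL = 0.0019872

#: Default simulation temperature in kelvin (42 C, the induction temperature
#: of the coat-hairpin expression experiments this package models).
DEFAULT_TEMPERATURE = 315.0

#: S1-mediated 30S interaction energy, -RT*ln(Ka) with Ka = 3e6 1/M at 310 K.
DG_S1 = -9.19

#: Interaction energy of the 16S anti-SD tail with a fully complementary
#: Shine-Dalgarno sequence.
DG_SD = -12.1

#: anti-Shine-Dalgarno sequence of the 16S rRNA 3' tail, written 5'->3'.
ANTI_SD = "UCCUCCA"

#: Best-fit kinetic parameters for 30S:PIC binding to mRNA via protein S1.
K1B = 30.0     # uM^-1 s^-1
K_M1B = 10.0   # s^-1

#: Free 30S:PIC concentration at a growth rate of 0.7 doublings/h, in uM.
CONC_30S = 0.65

#: Effective hairpin folding rate (fitted from relative coat-protein
#: expression of hairpin mutants), in 1/s.
K_F_HAIRPIN = 1.36e6

#: Ribosome geometry: footprint length and P-site offset from the 5' edge,
#: both in nucleotides.
FOOTPRINT = 30
PSITE_OFFSET = 12

#: Bulge / internal-loop tolerance (nt per side) when merging stacked pairs
#: into one coarse-grained helix node.
HELIX_MERGE_TOL = 4

#: Default number of folding windows constructed per tree node.
N_WINDOWS = 4

#: Elementary-move prefactor for single base-pair kinetics, in 1/s.
#: Calibrated so that the exact first-passage time for complete unfolding
#: of the surrogate wild-type coat hairpin at 315 K lands on the
#: experimentally fitted 0.18-0.23 s scale (see docs/methods.md).
K0_ELEMENTARY = 9.0e7

START_CODONS = ("AUG", "GUG", "CUG", "UUG", "AUA", "AUC", "AUU")
STOP_CODONS = ("UAA", "UAG", "UGA")

#: Concentration of a single molecule in an E. coli-scale volume, in uM.
MOLECULE_CONC_UM = 1.5e-3


def turner99_parameter_file() -> str:
    """Locate the Turner-99 nearest-neighbour parameter file shipped with
    ViennaRNA. Raises FileNotFoundError if the file cannot be found."""
    candidates = [
        os.path.join(sys.prefix, "share", "ViennaRNA", "rna_turner1999.par"),
        os.path.join(sys.exec_prefix, "share", "ViennaRNA", "rna_turner1999.par"),
    ]
    for path in candidates:
        if os.path.isfile(path):
            return path
    raise FileNotFoundError(
        "rna_turner1999.par not found; install ViennaRNA with its data files"
    )
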