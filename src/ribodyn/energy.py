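"""Nearest-neighbour (Turner 99) free energies at configurable temperature.

The evaluator is backed by ViennaRNA with the published Turner-99 parameter
set loaded from the file shipped with the library; the temperature enters
through the usual dG(T) = dH - T*dS rescaling of the tabulated terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import RNA

from .constants import DEFAULT_TEMPERATURE, KB_KCAL, turner99_parameter_file

__all__ = ["EnergyParams", "beta", "free_energy", "delta_G", "fold_compound_for"]

_loaded_param_file: str | None = None


def _ensure_parameters(param_file: str) -> None:
    global _loaded_param_file
    if _loaded_param_file != param_file:
        RNA.read_parameter_file(param_file)
        _loaded_param_file = param_file
        _fc_cache.cache_clear()


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B*T) in mol/kcal.

    beta(315) = 1.5975 mol/kcal (printed as 1.59 in the source literature).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return 1.0 / (KB_KCAL * temperature)


@dataclass(frozen=True)
class EnergyParams:
    """Energy-model configuration.

    Parameters
    ----------
    temperature : float
        Temperature in kelvin. Default 315 K (42 C).
    dangles : int
        Dangling-end model; 2 is the standard "d2" treatment applied to
        every helix end. The source of the tabulated parameters does not
        pin this down, so it is configurable.
    param_file : str
        Path to a ViennaRNA parameter file. Defaults to the shipped
        Turner-99 set.
    """

    temperature: float = DEFAULT_TEMPERATURE
    dangles: int = 2
    param_file: str = field(default_factory=turner99_parameter_file)

    @property
    def beta(self) -> float:
        return beta(self.temperature)

    def model_details(self) -> "RNA.md":
        md = RNA.md()
        md.temperature = self.temperature - 273.15
        md.dangles = self.dangles
        return md


@lru_cache(maxsize=4096)
def _fc_cache(sequence: str, temperature: float, dangles: int, noLP: int):
    md = RNA.md()
    md.temperature = temperature - 273.15
    md.dangles = dangles
    md.noLP = noLP
    return RNA.fold_compound(sequence, md)


def fold_compound_for(sequence: str, params: EnergyParams, noLP: bool = False):
    """A (cached) ViennaRNA fold compound for `sequence` under `params`."""
    _ensure_parameters(params.param_file)
    return _fc_cache(sequence, params.temperature, params.dangles, int(noLP))


def free_energy(ss, params: EnergyParams | None = None) -> float:
    """Free energy of formation of a secondary structure, in kcal/mol.

    `ss` is a SecondaryStructure (anything with .sequence and .dotbracket()).
    The open chain scores exactly 0.
    """
    params = params or EnergyParams()
    db = ss.dotbracket()
    if "(" not in db:
        return 0.0
    fc = fold_compound_for(ss.sequence, params)
    return float(fc.eval_structure(db))


def delta_G(ss_from, ss_to, params: EnergyParams | None = None) -> float:
    """Free-energy difference free_energy(to) - free_energy(from).

    Antisymmetric by construction; raises if the two structures are not on
    the same sequence.
    """
    if ss_from.sequence != ss_to.sequence:
        raise ValueError("delta_G requires structures on the same sequence")
    params = params or EnergyParams()
    return free_energy(ss_to, params) - free_energy(ss_from, params)
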