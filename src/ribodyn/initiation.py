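"""Translation initiation regions and 30S standby-site binding kinetics.

TIR candidates are start codons (canonical and near-cognate) scored by a
30S interaction energy dG_30S:mRNA composed of the Shine-Dalgarno:anti-SD
hybridisation energy, a spacing penalty, and a start-codon term, anchored
between the S1-only interaction (dG_S1 = -9.19 kcal/mol, from the measured
association constant Ka = 3e6 1/M) and the full-SD interaction
(dG_SD = -12.1 kcal/mol). Apparent on-rates follow the standby-site mean
first passage time:

    k_ons = k1B / (1 + tau_u * (k1B*[30S] + k_-1B))

where tau_u is the unfolding time of the structure sequestering the start
codon; apparent off-rates are an exponential in the binding energy,
two-point calibrated to the measured extremes 0.001 1/s (full SD) and
4 1/s (no SD) and clipped to [0.001, 10].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import RNA

from .constants import (ANTI_SD, CONC_30S, DG_S1, DG_SD, K1B, K_M1B,
                        START_CODONS)
from .energy import EnergyParams
from .structure import SecondaryStructure, StructureTree

__all__ = [
    "TIR",
    "InitiationKinetics",
    "scan_tirs",
    "weakly_structured",
    "kons_apparent",
    "tau_ons",
    "koff_apparent",
    "sd_hybridisation",
]

KOFF_MIN, KOFF_MAX = 0.001, 10.0
#: off-rate at the S1-only anchor (no SD present), 1/s
KOFF_NO_SD = 4.0
#: two-point calibrated exponent scale: ln(4 / 0.001) / (dG_S1 - dG_SD)
KOFF_SCALE = math.log(KOFF_NO_SD / KOFF_MIN) / (DG_S1 - DG_SD)

#: default start-codon penalties in kcal/mol (AUG free; near-cognate codons
#: are supported but initiation there is flagged low-confidence)
START_PENALTY = {
    "AUG": 0.0, "GUG": 0.5, "UUG": 1.0, "CUG": 1.5,
    "AUA": 2.0, "AUC": 2.0, "AUU": 2.0,
}

#: optimal SD-to-start spacing window (nt between SD 3' end and start codon)
SPACING_OPT = (5, 9)
SPACING_COEF = 0.25  # kcal/mol per nt^2 outside the optimal window

_SD_SEARCH_5 = 20   # how far upstream of the start codon to look for an SD


@dataclass
class TIR:
    """A candidate translation initiation region."""

    start: int                    # 1-based position of the start codon
    codon: str
    sd_span: tuple[int, int] | None
    dG_sd: float                  # scaled SD:anti-SD hybridisation term
    dG_30S: float                 # total 30S:mRNA interaction energy
    spacing: int | None = None
    canonical: bool = True
    low_confidence: bool = False
    standby: tuple[int, int] | None = None
    exposed: bool = True

    @property
    def span(self) -> tuple[int, int]:
        lo = self.sd_span[0] if self.sd_span else max(1, self.start - 12)
        return (lo, self.start + 2)


@dataclass
class InitiationKinetics:
    """Kinetic parameters of the standby-site 30S binding scheme."""

    k1B: float = K1B          # uM^-1 s^-1
    k_m1B: float = K_M1B      # s^-1
    conc_30S: float = CONC_30S  # uM
    tau_u: float = 0.0        # s

    @property
    def r_f(self) -> float:
        return self.k1B * self.conc_30S

    @property
    def k_mF(self) -> float:
        return math.inf if self.tau_u == 0 else 1.0 / self.tau_u


def kons_apparent(kin: InitiationKinetics) -> float:
    """Apparent 30S binding rate in uM^-1 s^-1.

    k_ons = k1B / (1 + tau_u*(k1B*[30S] + k_-1B)); collapses to k1B for an
    unstructured TIR (tau_u = 0), and becomes unfolding-limited for large
    tau_u. Strictly decreasing in tau_u and in [30S].
    """
    if kin.tau_u < 0 or kin.k1B <= 0 or kin.k_m1B < 0 or kin.conc_30S < 0:
        raise ValueError("negative kinetic inputs")
    return kin.k1B / (1.0 + kin.tau_u * (kin.r_f + kin.k_m1B))


def tau_ons(kin: InitiationKinetics) -> float:
    """Mean first passage time for 30S binding to the start codon via the
    standby pathway: (k_-F + k_-1B + r_f) / (r_f * k_-F).

    Satisfies k_ons * [30S] * tau_ons = 1 exactly.
    """
    r_f = kin.r_f
    if r_f <= 0:
        return math.inf
    if kin.tau_u == 0:
        return 1.0 / r_f
    k_mF = 1.0 / kin.tau_u
    return (k_mF + kin.k_m1B + r_f) / (r_f * k_mF)


def koff_apparent(dG_bind: float) -> float:
    """Apparent 30S off-rate in 1/s, monotone increasing in dG_bind.

    Exponential in the binding energy, anchored at the two measured
    extremes (full SD -> 0.001 1/s at dG_SD; no SD -> 4 1/s at dG_S1) and
    clipped to [0.001, 10.0].
    """
    k = KOFF_NO_SD * math.exp(KOFF_SCALE * (dG_bind - DG_S1))
    return min(KOFF_MAX, max(KOFF_MIN, k))


# -- SD scoring ---------------------------------------------------------------

_full_sd_energy_cache: dict[float, float] = {}


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGU", "UGCA"))[::-1]


def sd_hybridisation(upstream: str, params: EnergyParams) -> tuple[float, int] | None:
    """Best hybridisation of the anti-SD tail against `upstream`.

    Returns (duplex energy in kcal/mol, 0-based offset of the paired
    region's 3' end within `upstream`), or None if no favourable duplex.
    """
    if len(upstream) < 3:
        return None
    RNA.cvar.temperature = params.temperature - 273.15
    duplex = RNA.duplexfold(upstream, ANTI_SD)
    if duplex.energy >= 0.0:
        return None
    # duplex.i is the 3' end (1-based) of the paired region in sequence 1
    return float(duplex.energy), int(duplex.i)


def _full_sd_energy(params: EnergyParams) -> float:
    key = params.temperature
    if key not in _full_sd_energy_cache:
        RNA.cvar.temperature = params.temperature - 273.15
        duplex = RNA.duplexfold(_revcomp(ANTI_SD), ANTI_SD)
        _full_sd_energy_cache[key] = float(duplex.energy)
    return _full_sd_energy_cache[key]


def score_start(sequence: str, start: int, params: EnergyParams) -> TIR:
    """Score one candidate start codon into a TIR record."""
    codon = sequence[start - 1:start + 2]
    lo = max(1, start - _SD_SEARCH_5)
    upstream = sequence[lo - 1:start - 1]
    bonus = 0.0
    sd_span = None
    spacing = None
    hyb = sd_hybridisation(upstream, params) if upstream else None
    if hyb is not None:
        energy, end3 = hyb
        sd_end = lo + end3 - 1          # 1-based position of SD 3' end
        spacing = start - sd_end - 1
        full = _full_sd_energy(params)
        scaled = (DG_SD - DG_S1) * min(1.0, energy / full)
        low, high = SPACING_OPT
        dev = max(0, low - spacing, spacing - high)
        penalty = SPACING_COEF * dev * dev
        bonus = min(0.0, scaled + penalty)
        bonus = max(bonus, DG_SD - DG_S1)
        sd_span = (max(lo, sd_end - 5), sd_end)
    bonus += START_PENALTY.get(codon, 2.0)
    bonus = min(0.0, max(bonus, DG_SD - DG_S1))
    return TIR(
        start=start, codon=codon, sd_span=sd_span,
        dG_sd=bonus, dG_30S=DG_S1 + bonus, spacing=spacing,
        canonical=(codon == "AUG"),
        low_confidence=(codon != "AUG"),
    )


def scan_tirs(sequence: str, ss: SecondaryStructure | None = None,
              params: EnergyParams | None = None,
              starts: list[int] | None = None) -> list[TIR]:
    """Scan an mRNA for candidate TIRs.

    Every candidate start codon (AUG, GUG, CUG, UUG, AUA, AUC, AUU; or the
    fixed `starts` list if given) is scored; overlapping candidates are
    pruned keeping the lowest dG_30S:mRNA, ties broken 5'-most. The result
    is independent of discovery order.
    """
    params = params or EnergyParams()
    sequence = sequence.upper().replace("T", "U")
    if starts is None:
        starts = [i for i in range(1, len(sequence) - 1)
                  if sequence[i - 1:i + 2] in START_CODONS]
    tirs = [score_start(sequence, s, params) for s in sorted(starts)]
    tirs.sort(key=lambda t: (t.dG_30S, t.start))
    kept: list[TIR] = []
    for tir in tirs:
        lo, hi = tir.span
        if any(lo <= k.span[1] and k.span[0] <= hi for k in kept):
            continue
        kept.append(tir)
    kept.sort(key=lambda t: t.start)
    return kept


def weakly_structured(tree: StructureTree, tir: TIR,
                      min_unpaired: int = 20) -> bool:
    """True iff the region holding the TIR is weakly structured.

    The region must be a hairpin-only stretch of a loop (bounded by at most
    two flanking multi-loop helices, the loop boundary, or a ribosome or
    protein node) containing at least `min_unpaired` single-stranded
    nucleotides, none under a footprint.
    """
    ss = tree.ss
    pos = tir.start
    node = tree.find_enclosing_loop(pos)
    if node.kind == "hairpin":
        # start codon within a hairpin (stem or loop): the region is the
        # enclosing loop, with the hairpin as one of its elements
        loop = node.rootlink
        ref_lo, ref_hi = node.span
    elif node.kind == "multiloop-helix":
        ii, jj = node.inner_span
        if not (ii <= pos <= jj):
            return False  # start codon inside a multi-loop helix stem
        loop = node
        ref_lo = ref_hi = pos
    else:
        loop = node
        ref_lo = ref_hi = pos
    lo, hi = loop.inner_span if loop.is_helix() else loop.span
    blockers = sorted(
        [c for c in tree.loop_children(loop)
         if c.kind in ("multiloop-helix", "ribosome", "protein")
         or (c.kind == "hairpin"
             and any(p.bound_helix is c for p in tree.protein_nodes()))],
        key=lambda nd: nd.span[0])
    left, right = lo, hi
    for b in blockers:
        if b.span[1] < ref_lo:
            left = max(left, b.span[1] + 1)
        elif b.span[0] > ref_hi:
            right = min(right, b.span[0] - 1)
        else:
            return False
    footprints = [r.span for r in tree.ribosome_nodes()] + \
                 [p.span for p in tree.protein_nodes()]
    n_ss = 0
    for k in range(left, right + 1):
        if ss.pairs[k] == 0 and not any(a <= k <= b for a, b in footprints):
            n_ss += 1
    return n_ss >= min_unpaired
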