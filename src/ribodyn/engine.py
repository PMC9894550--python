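"""Gillespie simulation of ribosome kinetics on a dynamic mRNA.

The reaction set at any instant comprises 30S binding at exposed TIRs
(apparent rates from the standby-site model, recomputed whenever the
structure changes), 50S joining, per-codon elongation with stochastic
melting of structure ahead of the footprint, termination, window-level
folding transitions, and protein binding/unbinding at motif hairpins
(translational repression with optional feedback from synthesised
protein). Reaction selection uses a complete-binary-tree propensity index
with O(log2 R) update and prefix sampling; a linear-scan mode over the
identical reaction ordering and RNG stream is provided as a reference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .constants import (CONC_30S, FOOTPRINT, K1B, K_F_HAIRPIN, K_M1B,
                        MOLECULE_CONC_UM, N_WINDOWS, PSITE_OFFSET,
                        STOP_CODONS, DEFAULT_TEMPERATURE)
from .energy import EnergyParams, free_energy
from .initiation import TIR, InitiationKinetics, kons_apparent, scan_tirs, weakly_structured
from .kinetics import RateModel
from .proteins import BindingRule, find_sites
from .structure import (SecondaryStructure, StructureTree, build_tree,
                        place_protein, place_ribosome)
from .windows import propose_transitions

__all__ = ["SimConfig", "Ribosome", "Gene", "SimState", "PropensityIndex",
           "Trajectory", "simulate", "step", "build_mrna_state"]


class PropensityIndex:
    """Complete binary tree over reaction propensities.

    Sampling with a uniform variate u in [0, total) selects reaction r with
    probability a_r / sum(a); update and select cost O(log2 R).
    """

    def __init__(self, rates):
        rates = np.asarray(rates, dtype=float)
        n = max(1, len(rates))
        size = 1
        while size < n:
            size *= 2
        self.n_leaves = size
        self.tree = np.zeros(2 * size)
        self.tree[size:size + len(rates)] = rates
        for i in range(size - 1, 0, -1):
            self.tree[i] = self.tree[2 * i] + self.tree[2 * i + 1]

    @property
    def total(self) -> float:
        return float(self.tree[1])

    def update(self, idx: int, value: float) -> None:
        i = self.n_leaves + idx
        self.tree[i] = value
        i //= 2
        while i >= 1:
            self.tree[i] = self.tree[2 * i] + self.tree[2 * i + 1]
            i //= 2

    def sample(self, u: float) -> int:
        node = 1
        while node < self.n_leaves:
            left = 2 * node
            if u < self.tree[left]:
                node = left
            else:
                u -= self.tree[left]
                node = left + 1
        return node - self.n_leaves


@dataclass
class SimConfig:
    temperature: float = DEFAULT_TEMPERATURE
    conc_30S: float = CONC_30S      # uM
    k1B: float = K1B                # uM^-1 s^-1
    k_m1B: float = K_M1B            # s^-1
    footprint: int = FOOTPRINT
    psite_offset: int = PSITE_OFFSET
    n_w: int = N_WINDOWS
    k_F: float = K_F_HAIRPIN        # 1/s, closed-form helix unfolding scale
    k_elong: float = 15.0           # 1/s effective per-codon rate
    k_50S: float = 1.0              # 1/s, 50S joining
    k_term: float = 2.0             # 1/s
    duration: float = 1800.0        # s
    max_events: int = 2_000_000
    rate_model: RateModel = field(default_factory=RateModel)
    use_tree_index: bool = True
    folding: bool = True
    tau_u_override: dict[int, float] = field(default_factory=dict)
    fixed_starts: list[int] | None = None
    disabled_tirs: frozenset[int] = frozenset()
    binding_rules: list[BindingRule] = field(default_factory=list)
    feedback_gene: int | None = None   # start position of the repressor gene
    repressor_pool: int = 0            # pre-existing free repressor molecules
    molecule_conc: float = MOLECULE_CONC_UM

    def energy_params(self) -> EnergyParams:
        return EnergyParams(temperature=self.temperature)


@dataclass
class Ribosome:
    id: int
    phase: str          # "IC" | "elongating"
    p_site: int
    gene: "Gene"

    def footprint_interval(self, cfg: SimConfig, n: int) -> tuple[int, int]:
        lo = max(1, self.p_site - cfg.psite_offset)
        return lo, min(n, lo + cfg.footprint - 1)


@dataclass
class Gene:
    tir: TIR
    start: int
    stop: int           # first position of the stop codon
    name: str


@dataclass
class Trajectory:
    events: list
    protein_counts: dict[str, int]
    times: dict[str, list[float]]
    final_structure: str
    t_end: float
    truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events,
                            columns=["time", "event", "position", "gene"])

    def synthesis_times(self, name: str) -> list[float]:
        return self.times.get(name, [])


class SimState:
    """World state of the Gillespie engine on one dynamic mRNA."""

    def __init__(self, ss: SecondaryStructure, cfg: SimConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.ss = ss
        self.params = cfg.energy_params()
        self.tree = build_tree(ss)
        self.rng = rng
        self.t = 0.0
        self.ribosomes: list[Ribosome] = []
        self._next_rib = 1
        self.bound_sites: list[tuple[tuple[int, int], BindingRule]] = []
        self.tirs: list[TIR] = scan_tirs(ss.sequence, ss, self.params,
                                         starts=cfg.fixed_starts)
        self.tirs = [t for t in self.tirs if t.start not in cfg.disabled_tirs]
        self.genes: list[Gene] = [self._make_gene(t) for t in self.tirs]
        self.protein_counts: dict[str, int] = {g.name: 0 for g in self.genes}
        self.free_repressor = cfg.repressor_pool
        self.events: list = []
        self.times: dict[str, list[float]] = {g.name: [] for g in self.genes}
        self._tau_cache: dict = {}
        self._window_cache: dict = {}
        self._fe_cache: dict = {}

    # -- construction ---------------------------------------------------------

    def _make_gene(self, tir: TIR) -> Gene:
        seq = self.ss.sequence
        stop = None
        for pos in range(tir.start + 3, len(seq) - 1, 3):
            if seq[pos - 1:pos + 2] in STOP_CODONS:
                stop = pos
                break
        if stop is None:
            warnings.warn(f"open reading frame at {tir.start} has no stop codon; "
                          "terminating at the 3' end", stacklevel=2)
            stop = len(seq) - 2
        return Gene(tir, tir.start, stop, f"gene@{tir.start}")

    # -- helpers --------------------------------------------------------------

    def _free_energy(self, ss: SecondaryStructure) -> float:
        key = ss.pair_set()
        if key not in self._fe_cache:
            self._fe_cache[key] = free_energy(ss, self.params)
        return self._fe_cache[key]

    def _rebuild_tree(self) -> None:
        self.tree = build_tree(self.ss)
        n = len(self.ss)
        for rib in self.ribosomes:
            lo, hi = rib.footprint_interval(self.cfg, n)
            place_ribosome(self.tree, rib.p_site, footprint=hi - lo + 1,
                           offset=rib.p_site - lo)
        for span, rule in self.bound_sites:
            helix = next((nd for nd in self.tree.helix_nodes()
                          if nd.span == span), None)
            if helix is None:
                raise AssertionError(
                    f"protein-bound helix {span} vanished from the structure")
            place_protein(self.tree, helix.id)

    def _remove_pairs(self, positions: set[int]) -> None:
        """Unpair every pair with a partner in `positions` and rebuild."""
        table = list(self.ss.pairs)
        for i in sorted(positions):
            j = table[i]
            if j:
                table[i], table[j] = 0, 0
        self.ss = SecondaryStructure(self.ss.sequence, table, validate=False)
        self._rebuild_tree()

    def tau_u_for(self, tir: TIR) -> float:
        """Current unfolding time of the structure sequestering a TIR.

        Zero when the SD/start region is unpaired; otherwise the
        closed-form unfolding time exp(-beta*dG_F)/k_F of the sequestering
        pairs, with dG_F the energy gained by forming them.
        """
        if tir.start in self.cfg.tau_u_override:
            return self.cfg.tau_u_override[tir.start]
        lo, hi = tir.span
        touched = {i for i in range(lo, hi + 1) if self.ss.pairs[i]}
        if not touched:
            return 0.0
        key = (self.ss.pair_set(), tir.start)
        if key not in self._tau_cache:
            table = list(self.ss.pairs)
            for i in list(touched):
                j = table[i]
                if j:
                    table[i], table[j] = 0, 0
            opened = SecondaryStructure(self.ss.sequence, table, validate=False)
            dG_F = self._free_energy(self.ss) - self._free_energy(opened)
            beta = self.params.beta
            self._tau_cache[key] = math.exp(-beta * min(0.0, dG_F)) / self.cfg.k_F
        return self._tau_cache[key]

    def _footprints(self) -> list[tuple[int, int]]:
        n = len(self.ss)
        return [r.footprint_interval(self.cfg, n) for r in self.ribosomes]

    def _overlaps_bound(self, lo: int, hi: int) -> bool:
        return any(lo <= b and a <= hi for (a, b), _ in self.bound_sites)

    def _overlaps_ribosome(self, lo: int, hi: int,
                           exclude: Ribosome | None = None) -> bool:
        n = len(self.ss)
        for rib in self.ribosomes:
            if rib is exclude:
                continue
            rlo, rhi = rib.footprint_interval(self.cfg, n)
            if lo <= rhi and rlo <= hi:
                return True
        return False

    # -- reaction construction ------------------------------------------------

    def build_reactions(self) -> list[tuple[float, str, Callable[[], None], tuple]]:
        cfg = self.cfg
        n = len(self.ss)
        reactions: list[tuple[float, str, Callable[[], None], tuple]] = []

        # 30S binding at TIRs
        for tir, gene in zip(self.tirs, self.genes):
            lo = max(1, tir.start - cfg.psite_offset)
            hi = min(n, lo + cfg.footprint - 1)
            rate = 0.0
            if (not self._overlaps_ribosome(lo, hi)
                    and not self._overlaps_bound(lo, hi)
                    and weakly_structured(self.tree, tir)):
                kin = InitiationKinetics(cfg.k1B, cfg.k_m1B, cfg.conc_30S,
                                         self.tau_u_for(tir))
                rate = kons_apparent(kin) * cfg.conc_30S
            reactions.append((rate, "initiation",
                              self._fire_initiation(tir, gene),
                              (tir.start, gene.name)))

        for rib in self.ribosomes:
            if rib.phase == "IC":
                reactions.append((cfg.k_50S, "50S_join",
                                  self._fire_50S(rib), (rib.p_site, rib.gene.name)))
                continue
            if rib.p_site >= rib.gene.stop:
                reactions.append((cfg.k_term, "termination",
                                  self._fire_termination(rib),
                                  (rib.p_site, rib.gene.name)))
                continue
            new_p = rib.p_site + 3
            lo, hi = rib.footprint_interval(self.cfg, n)
            new_hi = min(n, hi + 3)
            if new_p > n - 1:
                raise RuntimeError("ribosome ran past the 3' end without a stop")
            if self._overlaps_ribosome(min(lo + 3, n), new_hi, exclude=rib):
                rate, kind, fire = 0.0, "elongation", self._fire_advance(rib)
            else:
                lead = [k for k in range(hi + 1, new_hi + 1)]
                blocked = {k for k in lead if self.ss.pairs[k]}
                stalled = any(
                    self._overlaps_bound(min(k, self.ss.pairs[k]),
                                         max(k, self.ss.pairs[k]))
                    for k in blocked)
                if stalled:
                    # a bound protein protects the helix: the ribosome
                    # waits for unbinding
                    rate, kind, fire = 0.0, "elongation", self._fire_advance(rib)
                elif not blocked:
                    rate, kind, fire = cfg.k_elong, "elongation", self._fire_advance(rib)
                else:
                    # helix opening and translocation as one event: the
                    # ribosome waits out the unfolding of the pairs in its
                    # path, then steps; sequential waiting times add
                    tau = self._melt_tau(blocked) + 1.0 / cfg.k_elong
                    rate, kind = 1.0 / tau, "melt"
                    fire = self._fire_melt_advance(blocked, rib)
            reactions.append((rate, kind, fire, (rib.p_site, rib.gene.name)))

        # folding transitions
        if cfg.folding:
            for tr in propose_transitions(self.tree, self.ss, self.params,
                                          cfg.n_w, cfg.rate_model,
                                          _cache=self._window_cache):
                reactions.append((tr.k_fwd, "fold",
                                  self._fire_fold(tr), tr.window.interval))

        # protein binding / unbinding
        if cfg.binding_rules:
            bound_spans = {span for span, _ in self.bound_sites}
            conc = self.free_repressor * cfg.molecule_conc
            for node_id, rule, adj in find_sites(self.tree, self.ss,
                                                 cfg.binding_rules):
                node = self.tree.nodes[node_id]
                if node.span in bound_spans:
                    continue
                reactions.append((rule.k_on * adj * conc, "bind",
                                  self._fire_bind(node.span, rule), node.span))
            for span, rule in self.bound_sites:
                reactions.append((rule.k_off, "unbind",
                                  self._fire_unbind(span), span))
        return reactions

    # -- reaction effects -----------------------------------------------------

    def _fire_initiation(self, tir: TIR, gene: Gene):
        def fire():
            cfg = self.cfg
            n = len(self.ss)
            lo = max(1, tir.start - cfg.psite_offset)
            hi = min(n, lo + cfg.footprint - 1)
            melted = {k for k in range(lo, hi + 1) if self.ss.pairs[k]}
            if melted:
                self._remove_pairs(melted)
            rib = Ribosome(self._next_rib, "IC", tir.start, gene)
            self._next_rib += 1
            self.ribosomes.append(rib)
            self._rebuild_tree()
        return fire

    def _fire_50S(self, rib: Ribosome):
        def fire():
            rib.phase = "elongating"
        return fire

    def _fire_advance(self, rib: Ribosome):
        def fire():
            rib.p_site += 3
            self._rebuild_tree()
        return fire

    def _melt_tau(self, blocked: set[int]) -> float:
        key = (self.ss.pair_set(), frozenset(blocked), "melt")
        if key not in self._tau_cache:
            table = list(self.ss.pairs)
            for i in list(blocked):
                j = table[i]
                if j:
                    table[i], table[j] = 0, 0
            opened = SecondaryStructure(self.ss.sequence, table, validate=False)
            dG_F = self._free_energy(self.ss) - self._free_energy(opened)
            beta = self.params.beta
            self._tau_cache[key] = (math.exp(-beta * min(0.0, dG_F))
                                    / self.cfg.k_F)
        return self._tau_cache[key]

    def _fire_melt_advance(self, blocked: set[int], rib: Ribosome):
        def fire():
            table = list(self.ss.pairs)
            for i in sorted(blocked):
                j = table[i]
                if j:
                    table[i], table[j] = 0, 0
            self.ss = SecondaryStructure(self.ss.sequence, table, validate=False)
            rib.p_site += 3
            self._rebuild_tree()
        return fire

    def _fire_termination(self, rib: Ribosome):
        def fire():
            gene = rib.gene
            self.protein_counts[gene.name] += 1
            self.times[gene.name].append(self.t)
            if self.cfg.feedback_gene == gene.start:
                self.free_repressor += 1
            self.ribosomes.remove(rib)
            self._rebuild_tree()
        return fire

    def _fire_fold(self, tr):
        def fire():
            self.ss = tr.ss_to
            self._rebuild_tree()
        return fire

    def _fire_bind(self, span: tuple[int, int], rule: BindingRule):
        def fire():
            self.bound_sites.append((span, rule))
            self.free_repressor -= 1
            self._rebuild_tree()
        return fire

    def _fire_unbind(self, span: tuple[int, int]):
        def fire():
            for k, (s, rule) in enumerate(self.bound_sites):
                if s == span:
                    del self.bound_sites[k]
                    break
            self.free_repressor += 1
            self._rebuild_tree()
        return fire

    def check_invariants(self) -> None:
        """Footprint/pair exclusion and propensity-sum consistency."""
        n = len(self.ss)
        fps = self._footprints()
        for (a, b) in fps:
            for k in range(a, b + 1):
                assert self.ss.pairs[k] == 0, f"paired base {k} under footprint"
        for i, (a, b) in enumerate(fps):
            for (c, d) in fps[i + 1:]:
                assert b < c or d < a, "overlapping footprints"


def step(state: SimState) -> bool:
    """Advance the simulation by one Gillespie event.

    Returns False on clean halt (zero total propensity), True otherwise.
    Time may overrun the configured duration by the last increment; the
    caller truncates.
    """
    reactions = state.build_reactions()
    rates = [r[0] for r in reactions]
    cfg = state.cfg
    if cfg.use_tree_index:
        index = PropensityIndex(rates)
        total = index.total
    else:
        total = math.fsum(rates)
    if total <= 0.0:
        return False
    dt = state.rng.exponential() / total
    u = state.rng.random() * total
    if cfg.use_tree_index:
        idx = index.sample(u)
        while rates[idx] == 0.0:   # guard against fp-edge selection
            idx = (idx + 1) % len(rates)
    else:
        acc = 0.0
        idx = len(rates) - 1
        for k, r in enumerate(rates):
            acc += r
            if u < acc:
                idx = k
                break
        while rates[idx] == 0.0:
            idx = (idx + 1) % len(rates)
    state.t += dt
    if state.t > cfg.duration:
        return False
    rate, kind, fire, payload = reactions[idx]
    fire()
    state.events.append((state.t, kind, payload[0] if payload else 0,
                         payload[1] if len(payload) > 1 else ""))
    return True


def build_mrna_state(sequence: str, structure: str | SecondaryStructure,
                     cfg: SimConfig, seed: int) -> SimState:
    from .structure import parse_dotbracket
    if isinstance(structure, str):
        ss = parse_dotbracket(sequence, structure)
    else:
        ss = structure
    rng = np.random.default_rng(seed)
    return SimState(ss, cfg, rng)


def simulate(sequence: str, structure: str | SecondaryStructure,
             cfg: SimConfig | None = None, duration: float | None = None,
             seed: int = 0) -> Trajectory:
    """Simulate `duration` seconds of protein synthesis on one mRNA.

    Reproducible per seed; returns a Trajectory with the event log, final
    protein counts and per-gene synthesis time stamps.
    """
    cfg = cfg or SimConfig()
    if duration is not None:
        cfg.duration = duration
    state = build_mrna_state(sequence, structure, cfg, seed)
    truncated = False
    for _ in range(cfg.max_events):
        if not step(state):
            break
    else:
        truncated = True
        warnings.warn("event cap reached before configured duration", stacklevel=2)
    return Trajectory(state.events, dict(state.protein_counts),
                      {k: list(v) for k, v in state.times.items()},
                      state.ss.dotbracket(), min(state.t, cfg.duration),
                      truncated)
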