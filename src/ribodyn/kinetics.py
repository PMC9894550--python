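"""Kinetics of RNA secondary-structure rearrangement.

Elementary moves open or close a single base pair; rates follow a
Kawasaki-symmetric rule k = k0 * exp(-beta*ddG/2), which satisfies detailed
balance for any prefactor. On top of the elementary moves the module
provides:

* `greedy_path` -- direct transition path taking the lowest-energy
  distance-reducing move at each step;
* `find_path_bfs` -- beam search over direct paths keeping the candidates
  with the lowest energy barrier;
* `find_path_mfp` -- the same beam search but ranking candidates by mean
  first passage time along the partial path;
* `path_mfpt` -- exact MFPT of the 1-D birth-death chain along a path;
* `kmc_simulate` -- exact stochastic simulation over elementary moves
  (a KFOLD-style kinetic Monte Carlo), the stochastic oracle for the
  coarse-grained transition rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import K0_ELEMENTARY
from .energy import EnergyParams, fold_compound_for
from .structure import SecondaryStructure, parse_dotbracket, _is_canonical

__all__ = [
    "RateModel",
    "TransitionPath",
    "elementary_moves",
    "greedy_path",
    "find_path_bfs",
    "find_path_mfp",
    "path_mfpt",
    "aggregated_path_rates",
    "exact_mfpt",
    "kmc_simulate",
    "KMCResult",
]

MIN_HAIRPIN_LOOP = 3


@dataclass(frozen=True)
class RateModel:
    """Elementary-move rate rule.

    `kawasaki` (default): k = k0*exp(-beta*ddG/2) in both directions.
    `metropolis`: k = k0*min(1, exp(-beta*ddG)).
    Both satisfy detailed balance k+/k- = exp(-beta*ddG) exactly.
    """

    k0: float = K0_ELEMENTARY
    rule: str = "kawasaki"

    def rate(self, ddG: float, beta: float) -> float:
        if self.rule == "kawasaki":
            return self.k0 * math.exp(-beta * ddG / 2.0)
        if self.rule == "metropolis":
            return self.k0 * min(1.0, math.exp(-beta * ddG))
        raise ValueError(f"unknown rate rule {self.rule!r}")


def _pairs_of(db: str) -> list[tuple[int, int]]:
    stack, out = [], []
    for pos, c in enumerate(db, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            out.append((stack.pop(), pos))
    return sorted(out)


def _can_close(db: str, seq: str, i: int, j: int,
               pt: dict[int, int]) -> bool:
    if j - i <= MIN_HAIRPIN_LOOP:
        return False
    if db[i - 1] != "." or db[j - 1] != ".":
        return False
    if not _is_canonical(seq[i - 1], seq[j - 1]):
        return False
    for k in range(i + 1, j):
        p = pt.get(k, 0)
        if p and not (i < p < j):
            return False
    return True


def elementary_moves(seq: str, db: str,
                     mask: frozenset[int] = frozenset()) -> list[tuple[int, int]]:
    """All single base-pair moves from `db`.

    A move (i, j) with i > 0 closes the pair, (-i, -j) opens it. Positions
    in `mask` (1-based) may not pair. Pseudoknot-free, canonical pairs only,
    hairpin loops of at least 3 nt.
    """
    pairs = _pairs_of(db)
    pt = {i: j for i, j in pairs}
    pt.update({j: i for i, j in pairs})
    moves: list[tuple[int, int]] = [(-i, -j) for i, j in pairs]
    n = len(seq)
    for i in range(1, n + 1):
        if db[i - 1] != "." or i in mask:
            continue
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n + 1):
            if j in mask:
                continue
            if _can_close(db, seq, i, j, pt):
                moves.append((i, j))
    return moves


def apply_move(db: str, move: tuple[int, int]) -> str:
    i, j = move
    chars = list(db)
    if i > 0:
        chars[i - 1], chars[j - 1] = "(", ")"
    else:
        chars[-i - 1], chars[-j - 1] = ".", "."
    return "".join(chars)


class _Landscape:
    """Cached view of the single-move energy landscape of one sequence.

    Per visited structure the neighbour list and the energy change of each
    move are computed once (ViennaRNA `eval_move`) and shared across
    trajectories and path searches.
    """

    def __init__(self, seq: str, params: EnergyParams,
                 mask: frozenset[int] = frozenset()):
        self.seq = seq
        self.params = params
        self.mask = mask
        self.fc = fold_compound_for(seq, params)
        self._nbrs: dict[str, tuple[list[tuple[int, int]], np.ndarray]] = {}

    def neighbours(self, db: str):
        hit = self._nbrs.get(db)
        if hit is None:
            moves = elementary_moves(self.seq, db, self.mask)
            ddG = np.array([self.fc.eval_move(db, i, j) for i, j in moves])
            hit = (moves, ddG)
            self._nbrs[db] = hit
        return hit

    def energy(self, db: str) -> float:
        if "(" not in db:
            return 0.0
        return float(self.fc.eval_structure(db))


@dataclass
class TransitionPath:
    """Ordered sequence of structures differing by one base pair each,
    with forward/backward rates per step and the energy barrier relative
    to the initial state."""

    states: list[str]
    energies: list[float]
    k_fwd: list[float] = field(default_factory=list)
    k_bwd: list[float] = field(default_factory=list)

    @property
    def barrier(self) -> float:
        return max(self.energies) - self.energies[0]

    def with_rates(self, beta: float, model: RateModel) -> "TransitionPath":
        kf, kb = [], []
        for a, b in zip(self.energies, self.energies[1:]):
            ddG = b - a
            kf.append(model.rate(ddG, beta))
            kb.append(model.rate(-ddG, beta))
        return TransitionPath(self.states, self.energies, kf, kb)

    def mfpt(self) -> float:
        return path_mfpt(self)

    def to_frame(self):
        """Path as a tidy table (state, energy, step rates) for TSV dumps."""
        import pandas as pd
        n = len(self.states)
        return pd.DataFrame({
            "state": self.states,
            "energy_kcal": self.energies,
            "k_fwd": list(self.k_fwd) + [float("nan")] * (n - len(self.k_fwd)),
            "k_bwd": list(self.k_bwd) + [float("nan")] * (n - len(self.k_bwd)),
        })


def path_mfpt(path: TransitionPath) -> float:
    """Mean first passage time from the first to the last state of the
    1-D birth-death chain along `path`, with the first state reflecting.

    Uses the forward recurrence t_i = (1 + k_i^- * t_{i-1}) / k_i^+ for the
    expected i -> i+1 passage time; the MFPT is the sum of the t_i.
    """
    n = len(path.states)
    if n == 1:
        return 0.0
    if not path.k_fwd:
        raise ValueError("path has no rates; call with_rates() first")
    if any(k <= 0 for k in path.k_fwd) or any(k < 0 for k in path.k_bwd):
        raise ValueError("rates must be positive")
    total = 0.0
    t_prev = 0.0
    for step in range(n - 1):
        k_plus = path.k_fwd[step]
        k_minus = path.k_bwd[step - 1] if step > 0 else 0.0
        t_prev = (1.0 + k_minus * t_prev) / k_plus
        total += t_prev
    return total


def _direct_moves(db: str, target_pairs: set[tuple[int, int]],
                  seq: str) -> list[tuple[int, int]]:
    """Distance-reducing moves: remove pairs absent from the target, add
    addable target pairs."""
    cur = set(_pairs_of(db))
    pt = {}
    for i, j in cur:
        pt[i], pt[j] = j, i
    moves = [(-i, -j) for i, j in cur - target_pairs]
    for i, j in sorted(target_pairs - cur):
        if _can_close(db, seq, i, j, pt) and j - i > MIN_HAIRPIN_LOOP:
            moves.append((i, j))
    return moves


def _as_db(s, seq: str) -> str:
    if isinstance(s, SecondaryStructure):
        return s.dotbracket()
    parse_dotbracket(seq, s)  # validation
    return s


def greedy_path(seq: str, s1, s2, params: EnergyParams | None = None,
                model: RateModel | None = None) -> TransitionPath:
    """Direct path from s1 to s2 taking, at every step, the admissible
    distance-reducing move with the lowest resulting energy (ties broken
    5'-first)."""
    params = params or EnergyParams()
    model = model or RateModel()
    db1, db2 = _as_db(s1, seq), _as_db(s2, seq)
    land = _Landscape(seq, params)
    target = set(_pairs_of(db2))
    states = [db1]
    energies = [land.energy(db1)]
    db = db1
    while db != db2:
        moves = _direct_moves(db, target, seq)
        best = None
        for mv in moves:
            ddG = float(land.fc.eval_move(db, *mv))
            key = (energies[-1] + ddG, abs(mv[0]), abs(mv[1]))
            if best is None or key < best[0]:
                best = (key, mv)
        (e_new, _, _), mv = best
        db = apply_move(db, mv)
        states.append(db)
        energies.append(e_new)
    return TransitionPath(states, energies).with_rates(params.beta, model)


def _bp_distance(db1: str, db2: str) -> int:
    return len(set(_pairs_of(db1)) ^ set(_pairs_of(db2)))


def _beam_search(seq: str, db1: str, db2: str, params: EnergyParams,
                 model: RateModel, width: int, rank: str,
                 slack: int = 0) -> TransitionPath:
    """Beam search over single-move paths from db1 to db2.

    With `slack` = 0 only direct (distance-reducing) paths are explored;
    a positive slack admits indirect detours of up to `slack` extra moves,
    which can lower the barrier past the best direct path.
    """
    land = _Landscape(seq, params)
    target = set(_pairs_of(db2))
    e1 = land.energy(db1)
    d0 = _bp_distance(db1, db2)
    budget = d0 + slack
    beam = [([db1], [e1])]
    finished: list[tuple[list[str], list[float]]] = []
    for level in range(budget):
        candidates = []
        for states, energies in beam:
            db = states[-1]
            seen = set(states)
            if slack == 0:
                moves = _direct_moves(db, target, seq)
            else:
                moves, _ = land.neighbours(db)
            for mv in moves:
                nxt = apply_move(db, mv)
                if nxt in seen:
                    continue
                if level + 1 + _bp_distance(nxt, db2) > budget:
                    continue
                e_new = energies[-1] + float(land.fc.eval_move(db, *mv))
                cand = (states + [nxt], energies + [e_new])
                if nxt == db2:
                    finished.append(cand)
                else:
                    candidates.append(cand)
        if not candidates:
            break

        def score(c):
            states, energies = c
            if rank == "mfpt":
                return (TransitionPath(states, energies)
                        .with_rates(params.beta, model).mfpt(),
                        _bp_distance(states[-1], db2))
            return (max(energies) - energies[0],
                    _bp_distance(states[-1], db2), energies[-1])
        candidates.sort(key=score)
        best_by_end: dict[str, tuple] = {}
        for c in candidates:
            end = c[0][-1]
            if end not in best_by_end:
                best_by_end[end] = c
        beam = list(best_by_end.values())[:width]
    if not finished:
        raise RuntimeError("beam search exhausted without reaching target")
    paths = [TransitionPath(s, e).with_rates(params.beta, model)
             for s, e in finished]
    if rank == "mfpt":
        return min(paths, key=lambda p: p.mfpt())
    return min(paths, key=lambda p: p.barrier)


def find_path_bfs(seq: str, s1, s2, params: EnergyParams | None = None,
                  model: RateModel | None = None, width: int = 10,
                  slack: int = 4) -> TransitionPath:
    """Beam search for the transition path with the lowest energy barrier
    (findpath-style breadth-first search).

    `slack` extra moves beyond the base-pair distance admit indirect
    detours (slack=0 restricts to direct paths). The returned barrier
    never exceeds the greedy path's barrier; for sufficient width and
    slack it matches the exhaustive minimum on small instances.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    params = params or EnergyParams()
    model = model or RateModel()
    db1, db2 = _as_db(s1, seq), _as_db(s2, seq)
    if db1 == db2:
        land = _Landscape(seq, params)
        return TransitionPath([db1], [land.energy(db1)]).with_rates(params.beta, model)
    best = _beam_search(seq, db1, db2, params, model, width, rank="barrier",
                        slack=slack)
    greedy = greedy_path(seq, s1, s2, params, model)
    return best if best.barrier <= greedy.barrier else greedy


def find_path_mfp(seq: str, s1, s2, params: EnergyParams | None = None,
                  model: RateModel | None = None, width: int = 10,
                  aggregate: bool = True) -> TransitionPath:
    """Beam search keeping candidate paths with the lowest mean first
    passage time rather than the lowest barrier.

    With `aggregate` (the default) the returned path carries
    distance-coordinate projected rates (see `aggregated_path_rates`),
    which correct the single-path MFPT for the multiplicity of parallel
    re-orderings of the same moves and track full-chain first passage
    times closely; with `aggregate=False` the per-step single-move rates
    are returned.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    params = params or EnergyParams()
    model = model or RateModel()
    db1, db2 = _as_db(s1, seq), _as_db(s2, seq)
    if db1 == db2:
        land = _Landscape(seq, params)
        return TransitionPath([db1], [land.energy(db1)]).with_rates(params.beta, model)
    best = _beam_search(seq, db1, db2, params, model, width, rank="mfpt")
    greedy = greedy_path(seq, s1, s2, params, model)
    if best.mfpt() > greedy.mfpt():
        best = greedy
    if aggregate:
        best = aggregated_path_rates(seq, best, params, model)
    return best


def aggregated_path_rates(seq: str, path: TransitionPath,
                          params: EnergyParams | None = None,
                          model: RateModel | None = None) -> TransitionPath:
    """Project the elementary-move dynamics onto the path's base-pair
    distance coordinate.

    The forward rate out of path state S_i sums the rates of *every*
    distance-reducing elementary move available there (not only the move
    the path happens to take), and the backward rate out of S_{i+1} sums
    every distance-increasing move. Both are restricted to the path's
    corridor -- moves touching pairs in the symmetric difference of the
    two endpoint structures -- so that unrelated breathing elsewhere in
    the molecule is not misread as backflow. This local-equilibrium
    projection accounts for the many parallel orderings of the same
    rearrangement; on hairpin unfolding it tracks the exact chain MFPT
    to within ~10%, where the literal single-move path overestimates
    severalfold.
    """
    params = params or EnergyParams()
    model = model or RateModel()
    if len(path.states) == 1:
        return path
    land = _Landscape(seq, params)
    beta = params.beta
    target = set(_pairs_of(path.states[-1]))
    corridor = set(_pairs_of(path.states[0])) ^ target
    corridor_pos = {p for ij in corridor for p in ij}
    kf, kb = [], []
    for a, b in zip(path.states, path.states[1:]):
        moves, ddg = land.neighbours(a)
        f = 0.0
        for mv, dg in zip(moves, ddg):
            if _move_pair(mv) in corridor and _reduces_distance(mv, target):
                f += model.rate(float(dg), beta)
        kf.append(f)
        moves_b, ddg_b = land.neighbours(b)
        g = 0.0
        for mv, dg in zip(moves_b, ddg_b):
            i, j = _move_pair(mv)
            if ((i in corridor_pos or j in corridor_pos)
                    and not _reduces_distance(mv, target)):
                g += model.rate(float(dg), beta)
        kb.append(g)
    return TransitionPath(path.states, path.energies, kf, kb)


def _move_pair(mv: tuple[int, int]) -> tuple[int, int]:
    return (mv[0], mv[1]) if mv[0] > 0 else (-mv[0], -mv[1])


def _reduces_distance(mv: tuple[int, int], target: set[tuple[int, int]]) -> bool:
    if mv[0] > 0:
        return (mv[0], mv[1]) in target
    return (-mv[0], -mv[1]) not in target


def exact_mfpt(seq: str, start, absorbing, params: EnergyParams | None = None,
               model: RateModel | None = None, energy_cap: float = 12.0,
               max_states: int = 300_000,
               mask: frozenset[int] = frozenset(),
               full_output: bool = False):
    """Exact mean first passage time by first-step analysis.

    Explores the single base-pair move graph reachable from `start`
    keeping states whose free energy does not exceed `energy_cap`
    kcal/mol (absolute, open chain = 0), then solves the sparse linear
    system Q*tau = -1 over transient states. This is the exact
    infinite-trajectory limit of the kinetic Monte Carlo estimate; the
    cap discards states far above every relevant saddle (raise it to
    check convergence).
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla
    from collections import deque

    params = params or EnergyParams()
    model = model or RateModel()
    db0 = _as_db(start, seq)
    land = _Landscape(seq, params, mask)
    beta = params.beta
    e0 = land.energy(db0)
    if e0 > energy_cap:
        raise ValueError("starting state lies above the energy cap")
    seen = {db0: 0}
    order = [db0]
    energies = [e0]
    edges: list[tuple[int, int, float]] = []
    queue = deque([db0])
    while queue:
        s = queue.popleft()
        si = seen[s]
        moves, ddg = land.neighbours(s)
        for mv, dg in zip(moves, ddg):
            e_new = energies[si] + float(dg)
            if e_new > energy_cap:
                continue
            ns = apply_move(s, mv)
            if ns not in seen:
                if len(order) >= max_states:
                    raise RuntimeError(
                        "state space exceeds max_states; raise the cap "
                        "ceiling or max_states")
                seen[ns] = len(order)
                order.append(ns)
                energies.append(e_new)
                queue.append(ns)
            edges.append((si, seen[ns], float(dg)))
    is_abs = np.array([bool(absorbing(s)) for s in order])
    if not is_abs.any():
        raise RuntimeError("absorbing set unreachable within the energy cap")
    n = len(order)
    diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for i, j, dg in edges:
        if is_abs[i]:
            continue
        r = model.rate(dg, beta)
        diag[i] -= r
        if not is_abs[j]:
            rows.append(i)
            cols.append(j)
            vals.append(r)
    trans = np.where(~is_abs)[0]
    remap = -np.ones(n, dtype=int)
    remap[trans] = np.arange(len(trans))
    Q = sp.csr_matrix((vals, (remap[rows], remap[cols])),
                      shape=(len(trans), len(trans))) + sp.diags(diag[trans])
    tau = spla.spsolve(Q.tocsc(), -np.ones(len(trans)))
    result = float(tau[remap[seen[db0]]])
    if full_output:
        return result, len(order)
    return result


@dataclass
class KMCResult:
    mean: float
    se: float
    times: np.ndarray
    n_events: int
    truncated: int

    def __repr__(self):
        return (f"KMCResult(mean={self.mean:.4g} s, se={self.se:.2g}, "
                f"n={len(self.times)}, truncated={self.truncated})")


def kmc_simulate(seq: str, start, absorbing, params: EnergyParams | None = None,
                 model: RateModel | None = None, n_traj: int = 1000,
                 seed: int = 0, step_cap: int = 10**9,
                 mask: frozenset[int] = frozenset()) -> KMCResult:
    """Kinetic Monte Carlo over single base-pair moves.

    Simulates `n_traj` trajectories from `start` until `absorbing(db)` is
    true (or a step cap is hit, which is counted and reported, never
    silent) and returns the mean first passage time with its standard
    error. Fully reproducible for a given seed.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    params = params or EnergyParams()
    model = model or RateModel()
    db0 = _as_db(start, seq)
    land = _Landscape(seq, params, mask)
    beta = params.beta
    rate_cache: dict[str, tuple[list[tuple[int, int]], np.ndarray, float]] = {}

    def rates_for(db: str):
        hit = rate_cache.get(db)
        if hit is None:
            moves, ddG = land.neighbours(db)
            if model.rule == "kawasaki":
                rates = model.k0 * np.exp(-beta * ddG / 2.0)
            else:
                rates = model.k0 * np.minimum(1.0, np.exp(-beta * ddG))
            hit = (moves, np.cumsum(rates), float(rates.sum()))
            rate_cache[db] = hit
        return hit

    rng = np.random.default_rng(seed)
    times = []
    truncated = 0
    total_events = 0
    for _ in range(n_traj):
        db = db0
        t = 0.0
        for _step in range(step_cap):
            if absorbing(db):
                times.append(t)
                break
            moves, cum, total = rates_for(db)
            if total <= 0.0:
                raise RuntimeError(f"absorbing set unreachable: stuck at {db}")
            t += rng.exponential(1.0 / total)
            idx = int(np.searchsorted(cum, rng.random() * total, side="right"))
            idx = min(idx, len(moves) - 1)
            db = apply_move(db, moves[idx])
            total_events += 1
        else:
            truncated += 1
    if not times:
        raise RuntimeError("no trajectory reached the absorbing set within the step cap")
    arr = np.asarray(times)
    se = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else float("nan")
    return KMCResult(float(arr.mean()), float(se), arr, total_events, truncated)
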