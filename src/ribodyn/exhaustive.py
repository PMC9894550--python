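"""Brute-force reference computations on small RNAs.

These enumerate the complete secondary-structure space of a short sequence
(canonical pairs, hairpin loops >= 3 nt, no pseudoknots) and compute exact
quantities by exhaustion: the global minimum free energy structure, and the
minimum achievable energy barrier between two structures over *all*
single-move paths (a minimax shortest path on the full move graph).

They are deliberately independent of the dynamic-programming and beam
search code and serve as oracles; complexity is exponential, so keep
sequences at or below ~20 nt.
"""

from __future__ import annotations

import heapq

from .energy import EnergyParams, fold_compound_for
from .kinetics import MIN_HAIRPIN_LOOP, _pairs_of, apply_move
from .structure import _is_canonical

__all__ = ["enumerate_structures", "exhaustive_mfe", "exhaustive_min_barrier"]


def _compatible_pairs(seq: str) -> list[tuple[int, int]]:
    n = len(seq)
    return [(i, j) for i in range(1, n + 1)
            for j in range(i + MIN_HAIRPIN_LOOP + 1, n + 1)
            if _is_canonical(seq[i - 1], seq[j - 1])]


def enumerate_structures(seq: str) -> list[str]:
    """All pseudoknot-free structures of `seq` as dot-bracket strings."""
    n = len(seq)
    pairable = _compatible_pairs(seq)
    results: list[str] = []

    def rec(chosen: list[tuple[int, int]], remaining: list[tuple[int, int]]):
        results.append(_to_db(chosen, n))
        for idx, (i, j) in enumerate(remaining):
            nxt = [(p, q) for p, q in remaining[idx + 1:]
                   if _nests(i, j, p, q)]
            rec(chosen + [(i, j)], nxt)

    def _nests(i, j, p, q):
        if p > j or q < i:
            return True  # disjoint
        if i < p and q < j:
            return True  # nested inside
        if p < i and j < q:
            return True
        return False

    # duplicates cannot arise: extensions only use pairs later in the list
    rec([], pairable)
    return sorted(set(results))


def _to_db(pairs, n: int) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i - 1], chars[j - 1] = "(", ")"
    return "".join(chars)


def exhaustive_mfe(seq: str, params: EnergyParams | None = None,
                   mask: frozenset[int] = frozenset()) -> tuple[str, float]:
    """Globally minimal-energy structure by full enumeration."""
    params = params or EnergyParams()
    fc = fold_compound_for(seq, params)
    best_db, best_e = "." * len(seq), 0.0
    for db in enumerate_structures(seq):
        if mask and any(db[i - 1] != "." for i in mask):
            continue
        e = fc.eval_structure(db) if "(" in db else 0.0
        if e < best_e - 1e-9 or (abs(e - best_e) <= 1e-9 and db < best_db):
            best_db, best_e = db, float(e)
    return best_db, best_e


def exhaustive_min_barrier(seq: str, db1: str, db2: str,
                           params: EnergyParams | None = None) -> float:
    """Minimum energy barrier between db1 and db2 over all single base-pair
    move paths, relative to the energy of db1.

    Dijkstra on the full move graph with the path maximum energy as the
    (minimax) objective.
    """
    params = params or EnergyParams()
    fc = fold_compound_for(seq, params)

    def energy(db: str) -> float:
        return float(fc.eval_structure(db)) if "(" in db else 0.0

    e1 = energy(db1)
    best: dict[str, float] = {db1: e1}
    heap = [(e1, db1)]
    while heap:
        emax, db = heapq.heappop(heap)
        if db == db2:
            return emax - e1
        if emax > best.get(db, float("inf")):
            continue
        pairs = _pairs_of(db)
        pt: dict[int, int] = {}
        for i, j in pairs:
            pt[i], pt[j] = j, i
        moves = [(-i, -j) for i, j in pairs]
        n = len(seq)
        for i in range(1, n + 1):
            if db[i - 1] != ".":
                continue
            for j in range(i + MIN_HAIRPIN_LOOP + 1, n + 1):
                if db[j - 1] != "." or not _is_canonical(seq[i - 1], seq[j - 1]):
                    continue
                if all(i < pt[k] < j for k in range(i + 1, j) if pt.get(k)):
                    moves.append((i, j))
        for mv in moves:
            nxt = apply_move(db, mv)
            cand = max(emax, energy(nxt))
            if cand < best.get(nxt, float("inf")):
                best[nxt] = cand
                heapq.heappush(heap, (cand, nxt))
    raise RuntimeError("target unreachable in move graph")
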