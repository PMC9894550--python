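"""Folding windows and candidate folding transitions.

Windows are local fragments of loop regions of the structure tree inside
which alternative locally optimal refolds are proposed. A window is a
contiguous run of loop elements (hairpin children plus the unpaired gaps
flanking them); runs containing a multi-loop helix, a ribosome, or a
protein-bound helix are discarded. For a helix anchor the run grows
symmetrically around the anchor (5' side first on ties); for the loop node
itself it grows from the loop's 5' boundary. With the default N_w = 4 on a
three-hairpin exterior loop this generates every contiguous fragment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import RNA

from .constants import N_WINDOWS
from .energy import EnergyParams, fold_compound_for
from .kinetics import RateModel, find_path_mfp
from .structure import HelixNode, SecondaryStructure, StructureTree, parse_dotbracket

__all__ = [
    "FoldingWindow",
    "FoldingTransition",
    "enumerate_windows",
    "fragment_mfe",
    "propose_transitions",
]


@dataclass(frozen=True)
class FoldingWindow:
    anchor_id: int
    index: int                    # window index w in [1, N_w]
    interval: tuple[int, int]     # 1-based closed interval on the mRNA
    mask: frozenset[int] = frozenset()  # footprinted positions (no pairing)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0] + 1


@dataclass
class FoldingTransition:
    """A local rearrangement between two full-mRNA structures.

    The two structures differ only inside `window`. Rates satisfy
    k_fwd / k_rev = exp(-beta * ddG) (detailed balance), with k_fwd taken
    as the inverse mean first passage time of the minimum-MFPT path on the
    window fragment.
    """

    ss_from: SecondaryStructure
    ss_to: SecondaryStructure
    window: FoldingWindow
    k_fwd: float
    k_rev: float
    ddG: float


def windows_frame(windows: list[FoldingWindow]):
    """Window diagnostics as a tidy table for TSV dumps."""
    import pandas as pd
    return pd.DataFrame(
        [{"anchor": w.anchor_id, "index": w.index,
          "start": w.interval[0], "end": w.interval[1],
          "masked": len([p for p in w.mask
                         if w.interval[0] <= p <= w.interval[1]])}
         for w in windows])


def _loop_items(tree: StructureTree, node: HelixNode):
    """Children of `node`'s loop in 5'->3' order plus the loop boundary."""
    lo, hi = node.inner_span
    kids = tree.loop_children(node)
    return lo, hi, kids


def _run_interval(lo: int, hi: int, kids: list[HelixNode],
                  first: int, last: int) -> tuple[int, int]:
    """Interval covering children[first..last] plus flanking gaps, bounded
    by the neighbouring children outside the run (or the loop boundary)."""
    left = lo if first == 0 else kids[first - 1].span[1] + 1
    right = hi if last == len(kids) - 1 else kids[last + 1].span[0] - 1
    return (left, right)


def enumerate_windows(tree: StructureTree, n_w: int = N_WINDOWS) -> list[FoldingWindow]:
    """Folding windows for every loop region of the tree.

    Up to `n_w` windows per anchor node; empty or invalid windows (those
    that would contain a multi-loop helix, ribosome, or protein-bound
    structure) are omitted; duplicates are dropped 5'-first.
    """
    if n_w < 1:
        raise ValueError("N_w must be >= 1")
    bound_spans = {p.bound_helix.span for p in tree.protein_nodes()}
    mask = frozenset(pos for rib in tree.ribosome_nodes()
                     for pos in range(rib.span[0], rib.span[1] + 1))
    windows: list[FoldingWindow] = []
    seen: set[tuple[int, int]] = set()

    def blocker(child: HelixNode) -> bool:
        return child.kind != "hairpin" or child.span in bound_spans

    loop_nodes = [tree.root] + [nd for nd in tree.helix_nodes()]
    for node in loop_nodes:
        if node.kind == "hairpin" and node.children:
            continue
        loop_lo, loop_hi, kids = _loop_items(tree, node)
        if loop_hi < loop_lo:
            continue
        # split the loop into segments of hairpin children separated by
        # blockers (multi-loop helices, ribosomes, protein-bound hairpins);
        # windows never cross a blocker but are bounded by its edge
        segments: list[tuple[int, int, list[HelixNode]]] = []
        seg_lo, seg_kids = loop_lo, []
        for child in kids:
            if blocker(child):
                segments.append((seg_lo, child.span[0] - 1, seg_kids))
                seg_lo, seg_kids = child.span[1] + 1, []
            else:
                seg_kids.append(child)
        segments.append((seg_lo, loop_hi, seg_kids))

        for lo, hi, skids in segments:
            if hi < lo:
                continue

            def add(anchor, w, first, last):
                if first < 0 or last > len(skids) - 1:
                    return
                iv = _run_interval(lo, hi, skids, first, last)
                if iv[1] < iv[0] or iv in seen:
                    return
                seen.add(iv)
                windows.append(FoldingWindow(anchor.id, w, iv, mask))

            if not skids:
                # bare segment: one window over the unpaired stretch
                if (lo, hi) not in seen:
                    seen.add((lo, hi))
                    windows.append(FoldingWindow(node.id, 1, (lo, hi), mask))
                continue
            # loop-node anchor: runs growing from the segment 5' boundary
            for w in range(1, n_w + 1):
                add(node, w, 0, w - 1)
            # helix anchors: runs of w children grown symmetrically, 5'-first
            for k, child in enumerate(skids):
                for w in range(1, n_w + 1):
                    extra = w - 1
                    left = k - (extra + 1) // 2
                    right = k + extra // 2
                    if left < 0:
                        right = min(len(skids) - 1, right - left)
                        left = 0
                    if right > len(skids) - 1:
                        left = max(0, left - (right - (len(skids) - 1)))
                        right = len(skids) - 1
                    add(child, w, left, right)
    return windows


def fragment_mfe(fragment: str, params: EnergyParams | None = None,
                 mask: frozenset[int] = frozenset(),
                 no_lonely_pairs: bool = False) -> SecondaryStructure:
    """Minimum-free-energy pseudoknot-free fold of a fragment.

    `mask` holds 1-based fragment positions forced to stay unpaired.
    Standard O(n^3) dynamic programming via ViennaRNA; with
    `no_lonely_pairs` helices of a single pair are disallowed (used for
    transition proposals, where the minimum helix length is 2 bp).
    """
    if len(fragment) < 1:
        raise ValueError("fragment must be non-empty")
    params = params or EnergyParams()
    fc = fold_compound_for(fragment, params, noLP=no_lonely_pairs)
    if mask:
        # fresh compound: hard constraints are stateful
        md = params.model_details()
        md.noLP = int(no_lonely_pairs)
        fc = RNA.fold_compound(fragment, md)
        for pos in sorted(mask):
            fc.hc_add_up(pos)
    db, _ = fc.mfe()
    return parse_dotbracket(fragment, db)


def _local_db(ss: SecondaryStructure, interval: tuple[int, int]) -> str:
    lo, hi = interval
    return ss.dotbracket()[lo - 1:hi - 1 + 1]


def propose_transitions(tree: StructureTree, ss: SecondaryStructure,
                        params: EnergyParams | None = None,
                        n_w: int = N_WINDOWS,
                        model: RateModel | None = None,
                        path_width: int = 5,
                        _cache: dict | None = None) -> list[FoldingTransition]:
    """Candidate folding transitions: one per window whose MFE refold
    differs from the current local structure.

    Forward rates are inverse mean first passage times of the lowest-MFPT
    direct path on the window fragment; reverse rates follow from detailed
    balance. Transitions never touch ribosome or protein footprints.
    """
    params = params or EnergyParams()
    model = model or RateModel()
    out: list[FoldingTransition] = []
    for win in enumerate_windows(tree, n_w):
        lo, hi = win.interval
        frag = ss.sequence[lo - 1:hi]
        local_mask = frozenset(p - lo + 1 for p in win.mask if lo <= p <= hi)
        cur_local = _local_db(ss, win.interval)
        key = (frag, cur_local, local_mask)
        if _cache is not None and key in _cache:
            cached = _cache[key]
            if cached is None:
                continue
            new_local, kf, ddG = cached
        else:
            refold = fragment_mfe(frag, params, local_mask, no_lonely_pairs=True)
            new_local = refold.dotbracket()
            if new_local == cur_local:
                if _cache is not None:
                    _cache[key] = None
                continue
            path = find_path_mfp(frag, cur_local, new_local, params, model,
                                 width=path_width)
            tau = path.mfpt()
            if tau <= 0:
                continue
            kf = 1.0 / tau
            ddG = path.energies[-1] - path.energies[0]
            if _cache is not None:
                _cache[key] = (new_local, kf, ddG)
        db_full = ss.dotbracket()
        new_full = db_full[:lo - 1] + new_local + db_full[hi:]
        ss_to = parse_dotbracket(ss.sequence, new_full)
        k_rev = kf * math.exp(params.beta * ddG)
        out.append(FoldingTransition(ss, ss_to, win, kf, k_rev, ddG))
    return out
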