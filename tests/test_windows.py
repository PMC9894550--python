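"""Folding windows, fragment MFE, and transition proposals."""

import random

import pytest

from conftest import random_sequence
from ribodyn.energy import free_energy
from ribodyn.exhaustive import enumerate_structures, exhaustive_mfe
from ribodyn.kinetics import RateModel
from ribodyn.structure import build_tree, parse_dotbracket, place_ribosome
from ribodyn.windows import enumerate_windows, fragment_mfe, propose_transitions

THREE_HAIRPINS = (
    "GGGAAACCC" + "AAAA" + "GGCAAAGCC" + "AAAA" + "GCGAAACGC",
    "(((...)))" + "...." + "(((...)))" + "...." + "(((...)))",
)


class TestEnumerateWindows:
    def test_two_windows_per_anchor_on_three_hairpins(self):
        tree = build_tree(parse_dotbracket(*THREE_HAIRPINS))
        wins = enumerate_windows(tree, n_w=2)
        by_anchor = {}
        for w in wins:
            by_anchor.setdefault(w.anchor_id, []).append(w)
        # every anchor contributes windows; duplicates collapse 5'-first,
        # and each hairpin anchor may add its own bare-loop window
        assert set(by_anchor) >= {0, 1, 2, 3}
        assert all(len(v) <= 2 + 1 for v in by_anchor.values())

    def test_nw4_covers_every_contiguous_fragment(self):
        tree = build_tree(parse_dotbracket(*THREE_HAIRPINS))
        wins = enumerate_windows(tree, n_w=4)
        intervals = {w.interval for w in wins}
        # runs of 1, 2 and 3 hairpin subtrees with their flanking gaps
        assert {(1, 13), (10, 26), (23, 35), (1, 26), (10, 35), (1, 35)} <= intervals

    def test_multiloop_containing_window_absent(self):
        # exterior loop: hairpin + multiloop; no window may span the multiloop
        seq = ("GGGAAACCC" + "AAAA"
               + "GGGAA" + "GGGAAACCC" + "A" + "GGGAAUCCC" + "AACCC")
        db = ("(((...)))" + "...."
              + "(((.." + "(((...)))" + "." + "(((...)))" + "..)))")
        tree = build_tree(parse_dotbracket(seq, db))
        ml = next(nd for nd in tree.helix_nodes() if nd.kind == "multiloop-helix")
        lo, hi = ml.span
        for w in enumerate_windows(tree, n_w=4):
            a, b = w.interval
            assert not (a <= lo and hi <= b), "window swallowed a multi-loop"

    def test_ribosome_bounded_windows(self):
        seq, db = THREE_HAIRPINS
        seq += "A" * 40
        db += "." * 40
        tree = build_tree(parse_dotbracket(seq, db))
        rib = place_ribosome(tree, p_site=50)
        lo, hi = rib.span
        for w in enumerate_windows(tree, n_w=4):
            a, b = w.interval
            assert b < lo or hi < a or not (a <= lo and hi <= b)

    def test_invalid_nw_rejected(self):
        tree = build_tree(parse_dotbracket("AAAA", "...."))
        with pytest.raises(ValueError):
            enumerate_windows(tree, n_w=0)


class TestFragmentMfe:
    def test_polyA_folds_open(self, params):
        ss = fragment_mfe("A" * 20, params)
        assert ss.pair_list() == []
        assert free_energy(ss, params) == 0.0

    def test_gquad_free_tetraloop_hairpin(self, params):
        ss = fragment_mfe("GGGGAAAACCCC", params)
        assert ss.dotbracket() == "((((....))))"

    def test_mask_forces_positions_open(self, params):
        ss = fragment_mfe("GGGGAAAACCCC", params, mask=frozenset(range(1, 5)))
        assert all(ss.pairs[i] == 0 for i in range(1, 5))

    def test_matches_exhaustive_minimum_on_short_fragments(self, params):
        rng = random.Random(77)
        for _ in range(12):
            seq = random_sequence(rng, rng.randrange(10, 17))
            dp = fragment_mfe(seq, params)
            _, e_brute = exhaustive_mfe(seq, params)
            assert free_energy(dp, params) == pytest.approx(e_brute, abs=1e-6)


class TestProposeTransitions:
    def test_stable_hairpin_proposes_nothing(self, params):
        seq, db = "GGGGAAAACCCC", "((((....))))"
        tree = build_tree(parse_dotbracket(seq, db))
        ss = parse_dotbracket(seq, db)
        assert propose_transitions(tree, ss, params) == []

    def test_stem_extension_proposed(self, params):
        # hairpin with an unpaired flank that can extend the stem
        seq = "GGGGGAAAACCCCC"
        db = ".((((....))))."
        tree = build_tree(parse_dotbracket(seq, db))
        ss = parse_dotbracket(seq, db)
        trans = propose_transitions(tree, ss, params)
        assert any(t.ss_to.dotbracket() == "(((((....)))))" for t in trans)

    def test_footprint_blocks_refolding(self, params):
        seq = "GGGGAAAACCCC" + "A" * 40
        db = "." * len(seq)
        ss = parse_dotbracket(seq, db)
        tree = build_tree(ss)
        place_ribosome(tree, p_site=13, footprint=30, offset=6)  # covers hairpin
        trans = propose_transitions(tree, ss, params)
        assert all("(" not in t.ss_to.dotbracket()[:12] for t in trans)

    def test_transitions_are_local_and_reversible(self, params):
        seq = "GGGGGAAAACCCCC" + "AAAA" + "GGCGAAAACGCC"
        db = ".((((....))))." + "...." + "............"
        ss = parse_dotbracket(seq, db)
        tree = build_tree(ss)
        for t in propose_transitions(tree, ss, params):
            lo, hi = t.window.interval
            before, after = t.ss_from.dotbracket(), t.ss_to.dotbracket()
            assert before[:lo - 1] == after[:lo - 1]
            assert before[hi:] == after[hi:]
            # detailed balance at the transition level
            import math
            assert t.k_fwd / t.k_rev == pytest.approx(
                math.exp(-params.beta * t.ddG), rel=1e-9)

    def test_reachable_set_contains_global_mfe(self, params):
        # iterate proposals from the open chain; the global MFE structure
        # must be reachable for a short RNA with generous windows
        seq = "GGGAAACCCAAAGGGAAACCC"
        ss = parse_dotbracket(seq, "." * len(seq))
        tree = build_tree(ss)
        model = RateModel()
        seen = {ss.dotbracket()}
        frontier = [ss]
        for _ in range(4):
            nxt = []
            for cur in frontier:
                for t in propose_transitions(build_tree(cur), cur, params,
                                             n_w=4, model=model):
                    db2 = t.ss_to.dotbracket()
                    if db2 not in seen:
                        seen.add(db2)
                        nxt.append(t.ss_to)
            frontier = nxt
            if not frontier:
                break
        mfe_db, _ = exhaustive_mfe(seq, params)
        assert mfe_db in seen
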