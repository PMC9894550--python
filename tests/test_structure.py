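"""Secondary-structure parsing and the coarse-grained helix tree."""

import io
import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_sequence, random_structure
from ribodyn.structure import (SecondaryStructure, build_tree, parse_dotbracket,
                               place_ribosome, read_ct, remove_node, write_ct)


class TestParseDotbracket:
    def test_simple_hairpin_pairs(self):
        ss = parse_dotbracket("GGGAAACCC", "(((...)))")
        assert ss.pair_list() == [(1, 9), (2, 8), (3, 7)]

    def test_open_chain_has_no_pairs(self):
        ss = parse_dotbracket("AAAA", "....")
        assert ss.pair_list() == []
        assert ss.dotbracket() == "...."

    @pytest.mark.parametrize("seq,db,msg", [
        ("GGGA", "((..", "unbalanced"),
        ("GGGA", "()..", "non-canonical|unbalanced|hairpin|pair"),
        ("GGG", "(((...)))", "length mismatch"),
        ("AAAAAAAAA", "(((...)))", "non-canonical"),
    ])
    def test_errors_are_reported(self, seq, db, msg):
        with pytest.raises(ValueError):
            parse_dotbracket(seq, db)

    def test_roundtrip_dotbracket(self):
        db = "((((...))))..((...))"
        seq = "GGGGAAACCCCAAGGAAACC"
        assert parse_dotbracket(seq, db).dotbracket() == db

    def test_gu_pairs_are_canonical(self):
        parse_dotbracket("GGGAAAUUU", "(((...)))")  # GU closing pairs


class TestBuildTree:
    def test_single_hairpin(self):
        tree = build_tree(parse_dotbracket("GGGAAACCC", "(((...)))"))
        helices = tree.helix_nodes()
        assert len(helices) == 1
        assert helices[0].kind == "hairpin"
        assert tree.root.children == helices

    def test_three_hairpins_linked_5to3(self):
        seq = "GGGAAACCC" + "AAAA" + "GGCAAAGCC" + "AAAA" + "GCGAAACGC"
        db = "(((...)))" + "...." + "(((...)))" + "...." + "(((...)))"
        tree = build_tree(parse_dotbracket(seq, db))
        kids = tree.root.children
        assert len(kids) == 3
        assert [k.span[0] for k in kids] == sorted(k.span[0] for k in kids)
        # in-order neighbour traversal visits root + 3 nodes exactly once
        visited = list(tree.in_order())
        assert len(visited) == 4 == len(set(id(v) for v in visited))
        assert tree.root.leaf is kids[0]
        assert all(k.rootlink is tree.root for k in kids)

    def test_bulge_absorbed_into_one_helix(self):
        # 1-nt bulge within merge tolerance: a single coarse-grained helix
        seq = "GGAGGAAAACCCC"
        db = "((.((....))))"
        tree = build_tree(parse_dotbracket(seq, db))
        assert len(tree.helix_nodes()) == 1
        assert len(tree.helix_nodes()[0].pairs) == 4

    def test_large_interior_loop_splits_helices(self):
        # 6-nt interior loop on each side exceeds the 4-nt tolerance
        seq = "GGG" + "AACAAA" + "GGG" + "AAAA" + "CCC" + "AAACAA" + "CCC"
        db = "(((" + "......" + "(((" + "...." + ")))" + "......" + ")))"
        tree = build_tree(parse_dotbracket(seq, db))
        assert len(tree.helix_nodes()) == 2

    def test_multiloop_kinds_and_leaf_links(self):
        seq = "GGGAA" + "GGGAAACCC" + "A" + "GGGAAACCC" + "AACCC"
        db = "(((.." + "(((...)))" + "." + "(((...)))" + "..)))"
        tree = build_tree(parse_dotbracket(seq, db))
        kinds = sorted(nd.kind for nd in tree.helix_nodes())
        assert kinds == ["hairpin", "hairpin", "multiloop-helix"]
        ml = next(nd for nd in tree.helix_nodes() if nd.kind == "multiloop-helix")
        assert ml.leaf is tree.loop_children(ml)[0]

    def test_roundtrip_random_structures(self):
        rng = random.Random(42)
        for _ in range(200):
            seq = random_sequence(rng, rng.randrange(20, 60))
            db = random_structure(seq, rng)
            ss = parse_dotbracket(seq, db)
            tree = build_tree(ss)
            assert tree.to_pairs().pair_set() == ss.pair_set()
            # node count equals number of coarse-grained helices
            assert len(list(tree.in_order())) == len(tree.helix_nodes()) + 1

    def test_pseudoknot_rejected(self):
        with pytest.raises(ValueError, match="pseudoknot|involution"):
            SecondaryStructure.from_pairs("GAAGAACAACAA", [(1, 7), (4, 10)])


class TestRibosomeNodes:
    def _tree(self):
        seq = "GGGAAACCC" + "A" * 35 + "GGGAAACCC"
        db = "(((...)))" + "." * 35 + "(((...)))"
        return build_tree(parse_dotbracket(seq, db))

    def test_place_splices_between_flanking_helices(self):
        tree = self._tree()
        node = place_ribosome(tree, p_site=25)
        order = [nd.id for nd in tree.in_order()]
        helix_ids = [nd.id for nd in tree.helix_nodes()]
        assert order.index(helix_ids[0]) < order.index(node.id) < order.index(helix_ids[1])
        assert node.kind == "ribosome" and node.p_site == 25

    def test_overlapping_ribosome_rejected(self):
        tree = self._tree()
        place_ribosome(tree, p_site=25)
        with pytest.raises(ValueError, match="overlap"):
            place_ribosome(tree, p_site=30)

    def test_footprint_on_paired_bases_rejected(self):
        tree = self._tree()
        with pytest.raises(ValueError, match="paired"):
            place_ribosome(tree, p_site=5)

    def test_place_then_remove_is_identity(self):
        tree = self._tree()
        before = tree.to_pairs().pair_set()
        node = place_ribosome(tree, p_site=25)
        assert tree.to_pairs().pair_set() == before  # structure untouched
        remove_node(tree, node.id)
        assert tree.to_pairs().pair_set() == before
        assert len(list(tree.in_order())) == 3

    def test_remove_root_or_unknown_errors(self):
        tree = self._tree()
        with pytest.raises(ValueError):
            remove_node(tree, 0)
        with pytest.raises(KeyError):
            remove_node(tree, 999)

    def test_random_insert_remove_leaves_pairs_unchanged(self):
        rng = random.Random(7)
        seq = "GGGAAACCC" + "A" * 80 + "GGGAAACCC"
        db = "(((...)))" + "." * 80 + "(((...)))"
        tree = build_tree(parse_dotbracket(seq, db))
        ref = tree.to_pairs().pair_set()
        live = []
        for _ in range(40):
            if live and rng.random() < 0.5:
                remove_node(tree, live.pop(rng.randrange(len(live))))
            else:
                p = rng.randrange(22, 80)
                try:
                    live.append(place_ribosome(tree, p_site=p, footprint=10,
                                               offset=4).id)
                except ValueError:
                    pass
            assert tree.to_pairs().pair_set() == ref


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_tree_flattening_inverts_building(seed):
    """For arbitrary valid structures, build_tree followed by flattening
    to a pair table is the identity; dot-bracket print/parse round-trips."""
    rng = random.Random(seed)
    seq = random_sequence(rng, rng.randrange(15, 50))
    db = random_structure(seq, rng)
    ss = parse_dotbracket(seq, db)
    assert parse_dotbracket(seq, ss.dotbracket()) == ss
    assert build_tree(ss).to_pairs().pair_set() == ss.pair_set()


def test_ct_roundtrip():
    ss = parse_dotbracket("GGGAAACCCAA", "(((...)))..")
    buf = io.StringIO()
    write_ct(ss, buf)
    buf.seek(0)
    back = read_ct(buf)
    assert back.sequence == ss.sequence
    assert back.pair_set() == ss.pair_set()
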