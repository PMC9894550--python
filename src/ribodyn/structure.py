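"""Single-nucleotide secondary structure and the coarse-grained helix tree.

A `SecondaryStructure` stores the sequence and a 1-based pair table; it is
the ground truth that the `StructureTree` coarse-grains. Tree nodes are
helix elements (a maximal run of stacked pairs, allowing small interior
loops/bulges), the exterior loop (node 0), and -- during simulation --
bound ribosomes and proteins. Nodes carry 5'/3' neighbour links forming a
single in-order linked list over the whole molecule, a `leaf` link to the
5'-most helix inside their loop and a `rootlink` to the enclosing helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .constants import FOOTPRINT, HELIX_MERGE_TOL, PSITE_OFFSET

__all__ = [
    "SecondaryStructure",
    "HelixNode",
    "StructureTree",
    "parse_dotbracket",
    "build_tree",
    "place_ribosome",
    "place_protein",
    "remove_node",
    "read_ct",
    "write_ct",
]

_CANONICAL = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


def _is_canonical(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


class SecondaryStructure:
    """RNA sequence plus pair table at single-nucleotide resolution.

    `pairs[i]` (1-based) is the partner of position i, or 0 if unpaired.
    Pairing is an involution, pseudoknot-free, and restricted to
    Watson-Crick and GU pairs.
    """

    __slots__ = ("sequence", "pairs")

    def __init__(self, sequence: str, pairs: Iterable[int], validate: bool = True):
        self.sequence = sequence.upper().replace("T", "U")
        self.pairs = list(pairs)
        if len(self.pairs) != len(self.sequence) + 1:
            # accept 0-padded or plain lists
            if len(self.pairs) == len(self.sequence):
                self.pairs = [0] + self.pairs
            else:
                raise ValueError("pair table length mismatch")
        if validate:
            self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_pairs(cls, sequence: str, pair_list: Iterable[tuple[int, int]],
                   validate: bool = True) -> "SecondaryStructure":
        table = [0] * (len(sequence) + 1)
        for i, j in pair_list:
            table[i], table[j] = j, i
        return cls(sequence, table, validate=validate)

    def _validate(self) -> None:
        n = len(self.sequence)
        for i in range(1, n + 1):
            j = self.pairs[i]
            if j == 0:
                continue
            if not (1 <= j <= n) or self.pairs[j] != i or j == i:
                raise ValueError(f"pair table is not an involution at position {i}")
            if i < j and not _is_canonical(self.sequence[i - 1], self.sequence[j - 1]):
                raise ValueError(
                    f"non-canonical pair {self.sequence[i-1]}{self.sequence[j-1]} "
                    f"at positions ({i},{j})"
                )
        # pseudoknot check via bracket matching
        stack: list[int] = []
        for i in range(1, n + 1):
            j = self.pairs[i]
            if j > i:
                stack.append(j)
            elif 0 < j < i:
                if not stack or stack[-1] != i:
                    raise ValueError(f"pseudoknotted pair table at position {i}")
                stack.pop()

    # -- queries --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    def pair_list(self) -> list[tuple[int, int]]:
        return [(i, self.pairs[i]) for i in range(1, len(self) + 1)
                if self.pairs[i] > i]

    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(self.pair_list())

    def dotbracket(self) -> str:
        out = []
        for i in range(1, len(self) + 1):
            j = self.pairs[i]
            out.append("." if j == 0 else ("(" if j > i else ")"))
        return "".join(out)

    def is_unpaired(self, i: int, j: int | None = None) -> bool:
        """True iff positions i..j (inclusive, 1-based) are all unpaired."""
        j = i if j is None else j
        return all(self.pairs[k] == 0 for k in range(i, j + 1))

    def copy(self) -> "SecondaryStructure":
        return SecondaryStructure(self.sequence, list(self.pairs), validate=False)

    def __eq__(self, other) -> bool:
        return (isinstance(other, SecondaryStructure)
                and self.sequence == other.sequence
                and self.pairs == other.pairs)

    def __hash__(self):
        return hash((self.sequence, tuple(self.pairs)))

    def __repr__(self) -> str:
        return f"SecondaryStructure({self.sequence!r}, {self.dotbracket()!r})"


def parse_dotbracket(sequence: str, db: str) -> SecondaryStructure:
    """Parse a dot-bracket string against `sequence`.

    Raises ValueError on length mismatch, unbalanced brackets, or a
    non-canonical pair (reported with its position).
    """
    sequence = sequence.upper().replace("T", "U")
    if len(sequence) != len(db):
        raise ValueError(
            f"length mismatch: sequence {len(sequence)} nt vs structure {len(db)}"
        )
    table = [0] * (len(sequence) + 1)
    stack: list[int] = []
    for pos, c in enumerate(db, start=1):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced brackets: unmatched ')' at position {pos}")
            i = stack.pop()
            table[i], table[pos] = pos, i
        elif c != ".":
            raise ValueError(f"invalid character {c!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced brackets: unmatched '(' at position {stack[-1]}")
    return SecondaryStructure(sequence, table)


# -- coarse-grained tree ------------------------------------------------------

@dataclass(eq=False)
class HelixNode:
    """One node of the coarse-grained structure tree.

    For helix kinds (`hairpin`, `multiloop-helix`) `pairs` lists the base
    pairs of the helix outermost-first and `span` is the closed interval
    from the outermost 5' to the outermost 3' nucleotide. Ribosome nodes
    carry a `footprint` interval and a `p_site`; protein nodes reference
    the helix node they occupy.
    """

    id: int
    kind: str  # exterior | hairpin | multiloop-helix | ribosome | protein
    span: tuple[int, int]
    pairs: list[tuple[int, int]] = field(default_factory=list)
    neighbour5: "HelixNode | None" = None
    neighbour3: "HelixNode | None" = None
    leaf: "HelixNode | None" = None
    rootlink: "HelixNode | None" = None
    children: list["HelixNode"] = field(default_factory=list)
    # ribosome extras
    p_site: int | None = None
    footprint: tuple[int, int] | None = None
    # protein extras
    bound_helix: "HelixNode | None" = None

    @property
    def inner_span(self) -> tuple[int, int]:
        """Loop interval enclosed by the innermost pair of a helix."""
        if self.kind == "exterior":
            return self.span
        i, j = self.pairs[-1]
        return (i + 1, j - 1)

    def is_helix(self) -> bool:
        return self.kind in ("hairpin", "multiloop-helix")

    def __repr__(self) -> str:
        return f"<{self.kind} {self.id} span={self.span}>"


class StructureTree:
    """Rooted tree of helix elements with global 5'->3' neighbour links."""

    def __init__(self, ss: SecondaryStructure):
        self.ss = ss
        self.root = HelixNode(0, "exterior", (1, len(ss)))
        self.nodes: dict[int, HelixNode] = {0: self.root}
        self._next_id = 1

    # -- linked-list helpers --------------------------------------------------

    def in_order(self) -> Iterator[HelixNode]:
        node: HelixNode | None = self.root
        while node is not None:
            yield node
            node = node.neighbour3

    def _relink(self) -> None:
        """Rebuild neighbour5/neighbour3 as the in-order (5' start) list."""
        ordered = sorted(self.nodes.values(),
                         key=lambda nd: (nd.span[0], -nd.span[1], nd.id != 0))
        for a, b in zip(ordered, ordered[1:]):
            a.neighbour3 = b
            b.neighbour5 = a
        if ordered:
            ordered[0].neighbour5 = None
            ordered[-1].neighbour3 = None

    def helix_nodes(self) -> list[HelixNode]:
        return [nd for nd in self.nodes.values() if nd.is_helix()]

    def ribosome_nodes(self) -> list[HelixNode]:
        return [nd for nd in self.nodes.values() if nd.kind == "ribosome"]

    def protein_nodes(self) -> list[HelixNode]:
        return [nd for nd in self.nodes.values() if nd.kind == "protein"]

    def to_pairs(self) -> SecondaryStructure:
        """Flatten the helix nodes back to a pair table."""
        pair_list = [p for nd in self.helix_nodes() for p in nd.pairs]
        return SecondaryStructure.from_pairs(self.ss.sequence, pair_list)

    def loop_children(self, node: HelixNode) -> list[HelixNode]:
        """Direct children of `node`'s loop, in 5'->3' order (includes
        ribosome/protein nodes located in the loop)."""
        return sorted(node.children, key=lambda nd: nd.span[0])

    def find_enclosing_loop(self, pos: int) -> HelixNode:
        """Innermost loop node whose loop region contains position `pos`.

        If `pos` lies within a helix stem the helix node itself is returned.
        """
        node = self.root
        while True:
            for child in node.children:
                if not child.is_helix():
                    continue
                lo, hi = child.span
                if lo <= pos <= hi:
                    ii, jj = child.inner_span
                    if ii <= pos <= jj:
                        node = child
                        break
                    return child  # inside the stem itself
            else:
                return node
            continue

    def copy(self) -> "StructureTree":
        tree = build_tree(self.ss.copy())
        for rib in self.ribosome_nodes():
            place_ribosome(tree, rib.p_site,
                           footprint=rib.footprint[1] - rib.footprint[0] + 1,
                           offset=rib.p_site - rib.footprint[0])
        for prot in self.protein_nodes():
            target = next(nd for nd in tree.helix_nodes()
                          if nd.span == prot.bound_helix.span)
            place_protein(tree, target.id)
        return tree


def _group_helices(ss: SecondaryStructure, tol: int) -> list[list[tuple[int, int]]]:
    """Partition the pair list into coarse-grained helices.

    Consecutive pairs are merged into one helix while the structure nests
    directly (a single branch) and the interior gap is at most `tol`
    nucleotides on each side; larger interior loops and multiloops start a
    new helix.
    """
    pt = ss.pairs
    helices: list[list[tuple[int, int]]] = []
    seen: set[tuple[int, int]] = set()
    for i, j in ss.pair_list():
        if (i, j) in seen:
            continue
        helix = [(i, j)]
        seen.add((i, j))
        while True:
            a, b = helix[-1]
            # direct children of the loop closed by (a, b)
            kids = []
            k = a + 1
            while k < b:
                if pt[k] > k:
                    kids.append((k, pt[k]))
                    k = pt[k] + 1
                else:
                    k += 1
            if len(kids) != 1:
                break
            (p, q) = kids[0]
            if (p - a - 1) <= tol and (b - q - 1) <= tol:
                helix.append((p, q))
                seen.add((p, q))
            else:
                break
        helices.append(helix)
    return helices


def build_tree(ss: SecondaryStructure, merge_tol: int = HELIX_MERGE_TOL) -> StructureTree:
    """Build the coarse-grained helix tree of a pseudoknot-free structure.

    One node per maximal stack of pairs (interior loops/bulges up to
    `merge_tol` nt per side are absorbed); neighbour, leaf and root links
    populated. Round trip `tree.to_pairs()` reproduces `ss` exactly.
    """
    tree = StructureTree(ss)
    helices = _group_helices(ss, merge_tol)
    # create nodes, sorted by 5' start so ids are 5'->3'
    helices.sort(key=lambda h: h[0][0])
    nodes: list[HelixNode] = []
    for pairs in helices:
        i, j = pairs[0]
        node = HelixNode(tree._next_id, "hairpin", (i, j), pairs=list(pairs))
        tree._next_id += 1
        tree.nodes[node.id] = node
        nodes.append(node)
    # assign parents by nesting (smallest enclosing helix)
    for node in nodes:
        parent = tree.root
        for cand in nodes:
            if cand is node:
                continue
            ci, cj = cand.inner_span
            if ci <= node.span[0] and node.span[1] <= cj:
                if parent is tree.root or (
                        cand.span[0] >= parent.span[0] and cand.span[1] <= parent.span[1]):
                    parent = cand
        node.rootlink = parent
        parent.children.append(node)
    for node in [tree.root] + nodes:
        node.children.sort(key=lambda nd: nd.span[0])
        helix_kids = [c for c in node.children if c.is_helix()]
        node.leaf = helix_kids[0] if helix_kids else None
        if node.is_helix():
            node.kind = "multiloop-helix" if helix_kids else "hairpin"
    tree._relink()
    return tree


def place_ribosome(tree: StructureTree, p_site: int,
                   footprint: int = FOOTPRINT,
                   offset: int = PSITE_OFFSET) -> HelixNode:
    """Splice a ribosome node into the tree at the given P-site.

    The footprint interval is [p_site - offset, p_site - offset + footprint - 1]
    clipped to the molecule; it must contain no paired nucleotide and must
    not overlap an existing ribosome or protein footprint.
    """
    n = len(tree.ss)
    lo = max(1, p_site - offset)
    hi = min(n, lo + footprint - 1)
    if not tree.ss.is_unpaired(lo, hi):
        raise ValueError(f"ribosome footprint [{lo},{hi}] overlaps paired bases")
    for other in tree.ribosome_nodes() + tree.protein_nodes():
        olo, ohi = other.span
        if lo <= ohi and olo <= hi:
            raise ValueError(
                f"ribosome footprint [{lo},{hi}] overlaps node {other.id}")
    node = HelixNode(tree._next_id, "ribosome", (lo, hi),
                     p_site=p_site, footprint=(lo, hi))
    tree._next_id += 1
    tree.nodes[node.id] = node
    parent = tree.find_enclosing_loop(lo)
    if not parent.is_helix() and parent.kind != "exterior":
        parent = tree.root
    node.rootlink = parent
    parent.children.append(node)
    parent.children.sort(key=lambda nd: nd.span[0])
    tree._relink()
    return node


def place_protein(tree: StructureTree, helix_id: int) -> HelixNode:
    """Attach a protein node to a helix (hairpin) node."""
    helix = tree.nodes.get(helix_id)
    if helix is None or not helix.is_helix():
        raise ValueError(f"no helix node with id {helix_id}")
    if any(p.bound_helix is helix for p in tree.protein_nodes()):
        raise ValueError(f"helix {helix_id} already protein-bound")
    node = HelixNode(tree._next_id, "protein", helix.span, bound_helix=helix)
    tree._next_id += 1
    tree.nodes[node.id] = node
    node.rootlink = helix.rootlink
    tree._relink()
    return node


def remove_node(tree: StructureTree, node_id: int) -> None:
    """Remove a ribosome or protein node, re-splicing the neighbour links.

    Removing the exterior node (id 0) or an unknown id is an error; helix
    nodes are managed by structure updates, not by this call.
    """
    if node_id == 0:
        raise ValueError("cannot remove the exterior-loop node")
    node = tree.nodes.get(node_id)
    if node is None:
        raise KeyError(f"no node with id {node_id}")
    if node.is_helix():
        raise ValueError("helix nodes are removed via structure updates")
    if node.rootlink is not None and node in node.rootlink.children:
        node.rootlink.children.remove(node)
    del tree.nodes[node_id]
    tree._relink()


# -- CT file round trip -------------------------------------------------------

def write_ct(ss: SecondaryStructure, handle, title: str = "ribodyn") -> None:
    """Write a structure in connectivity-table (CT) format."""
    n = len(ss)
    handle.write(f"{n} {title}\n")
    for i in range(1, n + 1):
        nxt = i + 1 if i < n else 0
        handle.write(
            f"{i} {ss.sequence[i-1]} {i-1} {nxt} {ss.pairs[i]} {i}\n")


def read_ct(handle) -> SecondaryStructure:
    """Read a single structure from a CT-format file."""
    header = handle.readline().split()
    n = int(header[0])
    seq = []
    table = [0] * (n + 1)
    for _ in range(n):
        fields = handle.readline().split()
        idx = int(fields[0])
        seq.append(fields[1])
        table[idx] = int(fields[4])
    return SecondaryStructure("".join(seq), table)
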