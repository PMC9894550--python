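"""Sequence/structure motif detection for protein-binding hairpins.

Binding rules describe a family of RNA stem-loops recognised by an
RNA-binding protein: loop length, required loop nucleotides with IUPAC
degeneracy codes, minimum stem length, and an optional bulged nucleotide
in the 5' strand (the architecture of the phage MS2 coat-protein operator
family). Affinity defaults are order-of-magnitude placeholders and are
meant to be overridden from config; they are not literature values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure import HelixNode, SecondaryStructure, StructureTree

__all__ = ["BindingRule", "TR_RULE", "find_sites"]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC", "B": "CGU", "D": "AGU",
    "H": "ACU", "V": "ACG", "N": "ACGU",
}


def _matches(pattern: str, s: str) -> bool:
    return len(pattern) == len(s) and all(
        c in _IUPAC[p] for p, c in zip(pattern, s))


@dataclass(frozen=True)
class BindingRule:
    """A hairpin-binding motif with base affinities.

    `loop_pattern` uses IUPAC degeneracy codes; `bulge` optionally requires
    a single bulged nucleotide of the given identity in the 5' strand
    within `bulge_max_dist` nt of the loop.
    """

    name: str
    loop_pattern: str
    min_stem: int = 5
    bulge: str | None = None
    bulge_max_dist: int = 3
    k_on: float = 1.0      # uM^-1 s^-1 (placeholder scale)
    k_off: float = 1e-4    # s^-1 (placeholder; near-irreversible, nM-scale Kd)
    affinity_adjust: dict[str, float] = field(default_factory=dict)

    def match(self, ss: SecondaryStructure, node: HelixNode) -> float | None:
        """Return an affinity multiplier if the hairpin matches, else None."""
        if node.kind != "hairpin":
            return None
        if len(node.pairs) < self.min_stem:
            return None
        li, lj = node.inner_span
        loop_seq = ss.sequence[li - 1:lj]
        if not _matches(self.loop_pattern, loop_seq):
            return None
        if self.bulge is not None and not self._has_bulge(ss, node):
            return None
        return self.affinity_adjust.get(loop_seq, 1.0)

    def _has_bulge(self, ss: SecondaryStructure, node: HelixNode) -> bool:
        li = node.inner_span[0]
        for pos in range(max(node.span[0], li - 1 - self.bulge_max_dist - 1), li - 1):
            if ss.pairs[pos] == 0 and ss.sequence[pos - 1] in _IUPAC[self.bulge]:
                return True
        return False


#: Default operator-family rule: 4-nt A-N-Y-A loop on a stem of >= 5 pairs
#: with a bulged adenine in the 5' strand near the loop (the consensus
#: architecture of the coat-protein operator hairpin family).
TR_RULE = BindingRule(name="TR", loop_pattern="ANYA", min_stem=5, bulge="A")


def find_sites(tree: StructureTree, ss: SecondaryStructure,
               rules: list[BindingRule]) -> list[tuple[int, BindingRule, float]]:
    """Every hairpin node matching any rule, with its adjusted affinity.

    Returns (node id, rule, affinity multiplier) triples; a hairpin
    matching several rules is listed once per rule.
    """
    out = []
    for node in sorted(tree.helix_nodes(), key=lambda nd: nd.span[0]):
        for rule in rules:
            adj = rule.match(ss, node)
            if adj is not None:
                out.append((node.id, rule, adj))
    return out
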