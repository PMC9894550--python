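"""Synthetic mRNA constructs for exercising the simulator.

Everything here is generated or designed in silico:

* a surrogate of the coat-gene start hairpin (SD fragment and start codon
  sequestered in a stem, free energy placed at the wild-type -7.93
  kcal/mol at 315 K) for unfolding-kinetics work;
* series of designed start-codon hairpins spanning a free-energy range
  (the in-silico analogue of a hairpin-mutant panel);
* structure-free single-gene mRNAs for validating the Gillespie engine
  against closed-form counting statistics;
* two-gene constructs with the translational-coupling topology (the
  downstream TIR sequestered by long-distance pairs into the upstream
  coding region) and with a repressor-bindable TR-motif hairpin on the
  downstream start codon.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from Bio import SeqIO

from .energy import EnergyParams, free_energy
from .structure import SecondaryStructure, parse_dotbracket

__all__ = [
    "SYNTHETIC_COAT_HAIRPIN", "SYNTHETIC_COAT_HAIRPIN_DB",
    "TR_HAIRPIN", "TR_HAIRPIN_DB",
    "make_hairpin_series", "make_toy_gene", "make_coupled_construct",
    "make_repression_construct", "read_fasta", "write_fasta",
    "read_dotbracket_file", "write_dotbracket_file", "ToySpec",
]

#: Synthetic surrogate of the 27-nt coat-gene start hairpin: a designed
#: stem-loop with the GGAG Shine-Dalgarno fragment on the 5' arm and the
#: AUG start codon on the 3' arm, whose Turner-99 free energy at 315 K is
#: the wild-type value of -7.93 kcal/mol. (The authentic phage sequence is
#: not bundled; this synthetic analogue shares its architecture and
#: stability.)
SYNTHETIC_COAT_HAIRPIN = "GGAGUAUCCCCCCAUACACGAUGCUCC"
SYNTHETIC_COAT_HAIRPIN_DB = "((((((((...........))))))))"

#: Designed TR-family operator hairpin (A-N-Y-A tetraloop, bulged A in the
#: 5' strand, start codon in the 3' arm), dG_F = -4.25 kcal/mol at 315 K.
TR_HAIRPIN = "GACAUAGCAUCAGCAUGUC"
TR_HAIRPIN_DB = "(((((.((....)))))))"


def _verify(seq: str, db: str) -> SecondaryStructure:
    return parse_dotbracket(seq, db)


_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def make_hairpin_series(n: int, dG_range: tuple[float, float] = (-13.0, -6.0),
                        seed: int = 0,
                        params: EnergyParams | None = None,
                        tolerance: float = 0.5,
                        max_tries: int = 200_000
                        ) -> list[tuple[str, str, float]]:
    """Designed start-codon hairpins with free energies spanning `dG_range`.

    Each hairpin carries a GGAG SD fragment on the 5' arm and an AUG on
    the 3' arm, mirroring the coat-hairpin architecture; `n` targets are
    placed evenly across the range and each emitted hairpin's verified
    dG_F lies within `tolerance` of its target. Deterministic per seed.
    """
    if n == 0:
        return []
    params = params or EnergyParams()
    rng = random.Random(seed)
    lo, hi = min(dG_range), max(dG_range)
    targets = [lo + (hi - lo) * k / max(1, n - 1) for k in range(n)]
    out: list[tuple[str, str, float]] = []
    for target in targets:
        found = None
        for _ in range(max_tries):
            stem = rng.choice([7, 8, 9, 10])
            loop_len = 27 - 2 * stem
            if loop_len < 3:
                continue
            arm3 = ["N"] * stem
            if stem < 7:
                continue
            pos_aug = rng.randrange(0, stem - 6)
            arm3[pos_aug:pos_aug + 3] = "AUG"
            pos_sd = rng.randrange(pos_aug + 3, stem - 3)
            arm3[pos_sd:pos_sd + 4] = "CUCC"
            for k, c in enumerate(arm3):
                if c == "N":
                    arm3[k] = rng.choice("ACGU")
            arm3 = "".join(arm3)
            arm5 = list(_revcomp(arm3))
            for k in range(stem):
                if rng.random() < 0.25:
                    j = stem - 1 - k
                    if arm3[j] == "G" and arm5[k] == "C":
                        arm5[k] = "U"
                    elif arm3[j] == "U" and arm5[k] == "A":
                        arm5[k] = "G"
            arm5 = "".join(arm5)
            if "GGAG" not in arm5:
                continue
            loop = "".join(rng.choice("ACU") for _ in range(loop_len))
            seq = arm5 + loop + arm3
            db = "(" * stem + "." * loop_len + ")" * stem
            dG = free_energy(_verify(seq, db), params)
            if abs(dG - target) <= tolerance:
                found = (seq, db, dG)
                break
        if found is None:
            raise RuntimeError(f"no hairpin found near {target} kcal/mol")
        out.append(found)
    return out


def make_toy_gene(n_codons: int = 50, leader: int = 25, trailer: int = 10
                  ) -> tuple[str, str]:
    """Structure-free single-gene mRNA: poly-A leader, AUG, poly-Lys
    codons, UAA stop, poly-A trailer.

    The alphabet keeps canonical pairing essentially impossible (no C, a
    single G), so the minimum-free-energy fold of every fragment is the
    open chain and initiation kinetics can be validated against counting
    statistics. Start codon at position leader+1.
    """
    seq = "A" * leader + "AUG" + "AAA" * (n_codons - 2) + "UAA" + "A" * trailer
    return seq, "." * len(seq)


@dataclass
class ToySpec:
    """Layout for the two-gene coupling construct."""

    gene1_codons: int = 24          # poly-Lys codons before the pairing block
    gene2_codons: int = 15
    leader: int = 25
    spacer: int = 6                 # unpaired nt flanking the 3' UTR hairpin
    sd2: str = "GGAGG"
    spacer2: str = "AACAA"          # SD2-to-start spacing (5 nt, optimal)
    utr_hairpin: str = "GGCGCUUCGGCGCC"
    utr_hairpin_db: str = "(((((....)))))"


def make_coupled_construct(spec: ToySpec | None = None, seed: int = 0
                           ) -> tuple[str, str, int, int]:
    """Two-gene mRNA with the translational-coupling topology.

    The downstream TIR (SD2 + spacer + AUG2) is base-paired, via a
    long-distance helix, to a complementary block inside the upstream
    coding region; a small stable hairpin sits inside the enclosed loop so
    the sequestering helix is a multi-loop helix. Translation of gene 1
    melts the helix codon by codon, transiently exposing the downstream
    TIR; refolding after ribosome passage re-sequesters it.

    Returns (sequence, initial dot-bracket, start1, start2).
    Deterministic; `seed` is accepted for interface uniformity but the
    default layout is fixed.
    """
    spec = spec or ToySpec()
    tir2_block = spec.sd2 + spec.spacer2 + "AUG"       # 13 nt
    pair_block = _revcomp(tir2_block)                  # 13 nt, in gene 1
    # keep the pairing block in frame and stop-free
    assert all(pair_block[i:i + 3] not in ("UAA", "UAG", "UGA")
               for i in range(0, len(pair_block), 3))
    parts = []
    parts.append("A" * spec.leader)                    # leader
    g1_start = len("".join(parts)) + 1
    parts.append("AUG" + "AAA" * spec.gene1_codons)
    x_start = len("".join(parts)) + 1
    parts.append(pair_block + "AA")                    # block + frame pad
    parts.append("AAA" * 2 + "UAA")                    # tail codons + stop
    parts.append("A" * spec.spacer)
    h_start = len("".join(parts)) + 1
    parts.append(spec.utr_hairpin)
    parts.append("A" * spec.spacer)
    t2_start = len("".join(parts)) + 1
    parts.append(tir2_block)                           # SD2 ... AUG2
    g2_start = t2_start + len(tir2_block) - 3
    parts.append("AAA" * spec.gene2_codons + "UAA" + "A" * 10)
    seq = "".join(parts)
    pairs = []
    # long-distance helix: pair_block[k] with tir2_block[-1-k]
    L = len(tir2_block)
    for k in range(L):
        pairs.append((x_start + k, t2_start + L - 1 - k))
    hp = parse_dotbracket(spec.utr_hairpin, spec.utr_hairpin_db)
    for i, j in hp.pair_list():
        pairs.append((h_start + i - 1, h_start + j - 1))
    ss = SecondaryStructure.from_pairs(seq, pairs)
    return seq, ss.dotbracket(), g1_start, g2_start


def make_repression_construct(gene1_codons: int = 28, gene2_codons: int = 15,
                              leader: int = 25, spacer: int = 12
                              ) -> tuple[str, str, int, int]:
    """Two-gene mRNA whose downstream start codon sits in a TR-motif
    hairpin bindable by the protein product of gene 1.

    Returns (sequence, initial dot-bracket, start1, start2).
    """
    parts = ["A" * leader]
    start1 = leader + 1
    parts.append("AUG" + "AAA" * gene1_codons + "UAA")
    parts.append("A" * spacer)
    tr_start = len("".join(parts)) + 1
    parts.append(TR_HAIRPIN)
    start2 = tr_start + TR_HAIRPIN.index("AUGUC")
    parts.append("A" + "AAA" * gene2_codons + "UAA" + "A" * 10)
    seq = "".join(parts)
    db = ["."] * len(seq)
    db[tr_start - 1:tr_start - 1 + len(TR_HAIRPIN)] = list(TR_HAIRPIN_DB)
    db = "".join(db)
    parse_dotbracket(seq, db)  # validate
    return seq, db, start1, start2


# -- plain-text I/O -----------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read sequences from a FASTA file (DNA alphabets converted to RNA)."""
    return {rec.id: str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")


def read_dotbracket_file(path) -> dict[str, tuple[str, str]]:
    """Read a dot-bracket sidecar file: records of '>name', sequence line,
    structure line."""
    out = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    k = 0
    while k < len(lines):
        if not lines[k].startswith(">"):
            raise ValueError(f"malformed dot-bracket file near {lines[k]!r}")
        name = lines[k][1:]
        seq, db = lines[k + 1], lines[k + 2]
        parse_dotbracket(seq, db)
        out[name] = (seq, db)
        k += 3
    return out


def write_dotbracket_file(path, records: dict[str, tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, (seq, db) in records.items():
            fh.write(f">{name}\n{seq}\n{db}\n")
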