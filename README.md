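# ribodyn

Stochastic simulation of ribosome kinetics on dynamic, co-translationally
folding mRNAs.

Bacteria and positive-sense ssRNA phages regulate protein synthesis at the
translational level: secondary structure around a translation initiation
region (TIR) throttles 30S subunit loading, ribosome transit through an
upstream gene melts long-distance base pairs that hide a downstream TIR
(translational coupling), and accumulating protein can bind an operator
stem-loop and silence a gene (translational repression). `ribodyn` models
all three on a single mRNA whose secondary structure is explicit at
single-nucleotide resolution and changes in response to ribosome movement,
protein binding and thermal folding kinetics. It is aimed at people
studying polycistronic mRNAs and phage-style regulatory circuits who want
a mechanistic, kinetic alternative to purely thermodynamic RBS
calculators.

## The model

* **Structure.** The mRNA carries a pseudoknot-free pair table (Turner-99
  nearest-neighbour energies, temperature-rescaled; evaluated through
  ViennaRNA). A coarse-grained rooted tree of helix elements — hairpins,
  multi-loop helices, bound ribosomes and proteins — supports fast local
  queries; the full pair table remains the ground truth.
* **Folding moves.** Around every tree node, up to `N_w` folding windows
  are built from contiguous runs of loop elements. Each window's fragment
  is refolded to its minimum-free-energy structure; a differing refold
  becomes a candidate transition whose forward rate is the inverse mean
  first passage time of the best single base-pair-move path
  (Kawasaki rule `k = k0 exp(-beta*dG/2)`, detailed balance exact), with
  rates projected onto the path's base-pair-distance coordinate.
* **Initiation.** Start codons (AUG and near-cognates) are scored by
  SD:anti-SD hybridisation plus spacing and start-codon terms, bounded
  between the S1-only interaction (ΔG_S1 = −9.19 kcal/mol) and the full-SD
  interaction (ΔG_SD = −12.1 kcal/mol). A 30S particle parks at a weakly
  structured standby region and waits for the TIR to unfold; the apparent
  binding rate is

      k_ons = k1B / (1 + tau_u (k1B[30S] + k-1B)),

  with `k1B = 30 /uM/s`, `k-1B = 10 /s`, free `[30S] = 0.65 uM`, and
  `tau_u` the current TIR unfolding time.
* **Expression.** For a gene whose start codon sits in a hairpin of free
  energy ΔG_F, the synthesis rate follows

      E = A / (1 + tau_u B),      tau_u = exp(-beta*ΔG_F) / k_F,

  with fitted constants `A = 28.8 /min`, `B = 1.40 /s`,
  `k_F = 1.36e6 /s` at 315 K.
* **Engine.** A Gillespie simulation over initiation, 50S joining,
  codon-wise elongation (with stochastic melting of helices in the
  ribosome's path), termination, folding transitions and protein
  binding/unbinding, with a binary-tree propensity index (O(log R) update
  and selection) and a linear-scan reference mode that replays the same
  RNG stream event for event.

## Worked example

Closed-form expression table for the coat-hairpin mutant panel
(`ribodyn table1`, or `table1_report()` from Python):

```
mutant   dG_F   tau_u       E  E_R_measured  E_R_theory
    18  -6.63 0.02926   27.67           0.8      0.9606
    wt  -7.93  0.2335    21.7             1      0.7536
    11  -9.49   2.822   5.817           0.2       0.202
     5 -10.27   9.812   1.954          0.04     0.06786
    17  -10.5   14.17   1.382          0.03     0.04799
    20 -10.52   14.63   1.341          0.06     0.04655
    22 -11.81   114.9   0.178         0.003     0.00618
    23  -12.2   214.2 0.09573         0.002    0.003324
    15 -12.85     605 0.03396         0.001    0.001179
```

Each row: hairpin free energy at 315 K, unfolding time `tau_u` in
seconds, absolute synthesis rate `E` in proteins/min, and relative
expression `E_R = E/A` against the measured value. A hairpin only ~5
kcal/mol more stable than wild type already silences the gene
thousand-fold — the core of hairpin-mediated translational control.

Unfolding kinetics of the bundled synthetic coat-hairpin surrogate
(ΔG_F = −7.93 kcal/mol, 315 K):

```
$ ribodyn fold-kinetics --method path
mfpt_s  0.200464
barrier_kcal    11.810
```

i.e. a ~0.2 s unfolding time over an 11.8 kcal/mol barrier, matching the
0.18–0.23 s scale inferred from expression data.

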