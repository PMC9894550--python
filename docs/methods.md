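# Methods

## Scope and state representation

`ribodyn` simulates translation on one "dynamic" mRNA whose secondary
structure is explicit and mutable. The rest of the cell enters only
through fixed free concentrations (free 30S pre-initiation complex,
effective elongation resources); there is no per-tRNA bookkeeping, no
ribosome drop-off or misreading, and no re-initiation/scanning — only
de novo 30S binding. Pseudoknots are excluded throughout.

Two coupled representations are kept consistent at all times:

1. a 1-based pair table over the sequence (ground truth), restricted to
   Watson–Crick and GU pairs, pseudoknot-free;
2. a rooted tree of coarse-grained helix elements. A helix node is a
   maximal run of stacked pairs absorbing interior loops/bulges of up to
   4 nt per side (configurable); larger interior loops split the run into
   two nodes. The exterior loop is node 0. Bound ribosomes (footprint
   30 nt, P-site 12 nt from the 5' edge; both configurable) and bound
   proteins appear as additional nodes. Nodes carry 5'/3' neighbour links
   (a single in-order list over the molecule), a `leaf` link to the
   5'-most helix of their loop and a `rootlink` to the enclosing helix.

The tree is rebuilt from the pair table after structure-changing events
(O(m) in the number of helices); the logarithmic-time data structure of
the engine is the propensity index (below), not the tree rebuild. At the
toy scales this package targets (mRNAs of a few hundred nt) the rebuild
is far from rate-limiting.

## Energies

Free energies are Turner-99 nearest-neighbour values evaluated through
ViennaRNA with the `rna_turner1999.par` parameter file, temperature set
on the model details (default 315 K, i.e. the 42 °C induction temperature
of the expression experiments the defaults mirror), dangling ends in the
standard "d2" treatment (configurable). β = 1/(k_B T) is computed from
physical constants (1.5975 mol/kcal at 315 K); the widely quoted 1.59 is
that value rounded. The open chain scores exactly zero.

Lonely pairs are permitted in kinetics (they are unavoidable as path
intermediates) but refold proposals require helices of at least 2 bp
(`noLP` folding), so transient single pairs never become coarse states.

## Folding windows and transitions

For every loop region, the children are split into segments separated by
"blockers" — multi-loop helices, ribosomes, and protein-bound hairpins;
folding windows never contain a blocker but are bounded by its edge.
Within a segment, a window is a contiguous run of hairpin children plus
the flanking unpaired gaps: for a helix anchor the run grows symmetrically
around the anchor (5' side first on ties) up to `N_w` children; for the
loop anchor it grows from the segment's 5' boundary; childless segments
contribute one bare window. With the default `N_w = 4`, a three-hairpin
exterior loop generates every contiguous fragment. Duplicate intervals
are dropped 5'-first. Positions under footprints are additionally masked
(forced unpaired) inside any window that borders them.

A window whose fragment MFE differs from the current local structure
yields one candidate transition to that refold. Transitions are strictly
local (positions outside the window are untouched) and are re-derived
after every event from the current structure; results are cached by
(fragment sequence, local structure, mask), which makes the per-event
cost a dictionary lookup after warm-up.

Because proposals always point toward the local MFE, a structure sitting
at its local MFE emits no spontaneous unfolding transition; escape from
stable basins is carried by the explicit TIR-unfolding kinetics (standby
model) and by ribosome-driven melting. This matches the coarse-grained
"finite set of folding transitions" picture and keeps the reachable state
set small.

## Elementary-move kinetics and transition rates

Elementary moves open or close one base pair (hairpin loops ≥ 3 nt).
Rates follow the Kawasaki symmetric rule `k = k0 exp(-β ΔΔG / 2)`
(Metropolis available), which satisfies detailed balance exactly for any
prefactor `k0`.

Transition paths between two structures are searched three ways:

* `greedy_path` — always take the lowest-energy distance-reducing move;
* `find_path_bfs` — beam search ranked by barrier; a `slack` parameter
  admits indirect detours of up to that many extra moves (slack 0 is the
  classic direct-path search). On 16-nt instances with width 50 and
  slack 10 the result matches an exhaustive minimax search over the full
  move graph.
* `find_path_mfp` — the same beam ranked by the 1-D mean first passage
  time along the partial path.

The MFPT of a path uses the standard birth–death recurrence
`t_i = (1 + k_i^- t_{i-1}) / k_i^+` with the initial state reflecting.
For rate estimation the per-step rates are *aggregated*: the forward rate
out of path state `S_i` sums every distance-reducing elementary move
available there, and the backward rate sums every distance-increasing
move, both restricted to the path's corridor (moves touching pairs in the
symmetric difference of the endpoints, by position). This
local-equilibrium projection onto the base-pair-distance coordinate
corrects the severalfold overestimate of the literal single-move path
(which ignores the many parallel orderings of the same rearrangement)
while excluding unrelated breathing elsewhere in the molecule; on hairpin
unfolding it tracks the exact chain MFPT to within ~10%. A window
transition's forward rate is the inverse aggregated MFPT; the reverse
rate follows from detailed balance at the transition level.

Two reference routes exist for validation: `kmc_simulate`, an exact
stochastic simulation over elementary moves (KFOLD-style), and
`exact_mfpt`, first-step analysis (sparse solve of `Q τ = −1`) over the
reachable move graph with an absolute energy cap (default 12 kcal/mol
above the open chain; the result changes by <1% between caps 10 and 12
for the 27-nt hairpin). `exact_mfpt` is the infinite-trajectory limit of
the KMC estimate and is used where full sampling would be wasteful.

### Prefactor calibration

The elementary-move prefactor is not identifiable from equilibrium data;
it is calibrated once so that the exact unfolding MFPT of the surrogate
wild-type coat hairpin (ΔG_F = −7.93 kcal/mol) at 315 K lands on the
0.18–0.23 s scale inferred from expression measurements and hairpin
unfolding simulations. With `k0 = 9e7 s⁻¹` the exact chain MFPT is
0.185 s and the aggregated-path estimate 0.200 s. `k0` is configurable.

## Initiation

Candidate starts are the codons AUG, GUG, CUG, UUG, AUA, AUC, AUU
(non-AUG flagged low-confidence). The 30S interaction energy is

    ΔG_30S = ΔG_S1 + clip(scaled SD hybridisation + spacing penalty
                          + start-codon penalty, ΔG_SD − ΔG_S1, 0)

with ΔG_S1 = −RT ln(K_a), K_a = 3×10⁶ M⁻¹ at 310 K (−9.19 kcal/mol) as
the non-specific S1 floor and ΔG_SD = −12.1 kcal/mol as the full-SD
ceiling. SD hybridisation is the best duplex of the anti-SD tail
(5'-UCCUCCA) against the 20 nt upstream, scaled so a perfect complement
reaches the ceiling; the spacing penalty is quadratic outside a 5–9 nt
SD-to-start gap (0.25 kcal/mol/nt²); start-codon penalties are 0 (AUG)
to 2 kcal/mol (AUA/AUC/AUU). Overlapping candidates are pruned keeping
the lowest ΔG_30S (ties 5'-most). Apparent off-rates are exponential in
ΔG_30S, two-point calibrated to the measured extremes (0.001 s⁻¹ with a
full SD, 4 s⁻¹ without), clipped to [0.001, 10] s⁻¹.

A TIR is *available* when its region is weakly structured: a hairpin-only
stretch of one loop, bounded by at most two multi-loop helices (or
ribosome/protein nodes), with ≥ 20 single-stranded nucleotides free of
footprints. The apparent on-rate follows the standby mean-first-passage
formula quoted in the README; `tau_u` is zero for an unpaired start
region and otherwise the closed-form unfolding time
`exp(-β ΔG_seq)/k_F` of the sequestering pairs (ΔG_seq: energy gained by
forming them; `k_F = 1.36e6 s⁻¹`). The standby dwell is folded into the
apparent rate, so firing an initiation places the 30S directly at the
start codon and opens any pairs under the incoming footprint (their
melting time is what `tau_u` accounted for).

## The Gillespie engine

Reactions: initiation per exposed TIR; 50S joining (effective single
rate, default 1 s⁻¹); elongation in 3-nt steps at an effective per-codon
rate (default 15–50 s⁻¹ in the bundled configurations); termination;
window folding transitions; protein binding (mass action on the free
repressor count, 1 molecule ≈ 1.5 nM) and unbinding. When the codon
ahead of the footprint is paired, helix opening and translocation form
one event whose waiting time is the closed-form unfolding time of the
blocking pairs plus one elongation step — the ribosome waits, then steps.
Keeping them as separate events invites an unproductive race in which
marginal pairs re-form at the leading edge faster than the ribosome can
move; fusing them preserves the mean waiting time while bounding the
event count. A ribosome whose blocking helix is protein-bound stalls
until unbinding. Elongation into another footprint is blocked (queuing);
footprints never overlap and never cover paired bases (asserted in debug
checks after every event in the test suite).

Selection uses a complete binary tree over propensities (update and
prefix-sampling in O(log₂ R)); a linear-scan mode shares the identical
reaction ordering and RNG draws and replays trajectories event for
event. The reaction list itself is rebuilt per event — at toy scale the
caches make this cheap, and it guarantees every propensity reflects the
current structure (initiation rates are "dynamic" in exactly the sense
the standby model requires). Sub-linear per-event scaling in the
reaction count is therefore not claimed.

## Synthetic constructs

The generators emit the study conditions; they are code, not data files.

* **Surrogate coat hairpin** (`SYNTHETIC_COAT_HAIRPIN`): designed 27-nt
  stem-loop with the GGAG SD fragment on the 5' arm and the AUG on the 3'
  arm, Turner-99 ΔG_F = −7.93 kcal/mol at 315 K — the wild-type stability.
  The authentic phage sequence is not bundled; the surrogate shares its
  architecture and free energy, which are the quantities the kinetics
  depend on.
* **Hairpin series**: seeded search for 27-nt hairpins of the same
  architecture at evenly spaced target energies (default −13…−6
  kcal/mol, ±0.5 verified on emission) — the in-silico analogue of a
  hairpin-mutant panel.
* **Structure-free toy gene**: poly-A leader (25 nt standby region), AUG,
  poly-AAA codons, UAA. The alphabet admits essentially no canonical
  pairs, so initiation is the only rate-limiting step and protein counts
  can be checked against Poisson statistics.
* **Coupling construct**: two genes; the downstream TIR (GGAGG SD, 5-nt
  spacer, AUG) is base-paired via a 13-bp long-distance helix to a
  complementary, stop-free, in-frame block inside the upstream coding
  region; a stable hairpin inside the enclosed loop makes the
  sequestering helix a multi-loop helix (so the downstream TIR is not
  weakly structured at rest). Ribosome transit melts the helix codon by
  codon, transiently exposing the TIR; after passage, a folding window
  re-forms the helix.
* **Repression construct**: the downstream start codon sits in a
  TR-family operator hairpin (A-N-Y-A tetraloop, bulged A, ≥5-bp stem;
  ΔG_F = −4.25 kcal/mol — weak enough not to throttle initiation).
  Gene 1's product feeds the free-repressor pool; binding converts the
  hairpin into a protein node, removing it from folding windows and
  zeroing the TIR's initiation propensity.

What the toys do not emulate: real coding-sequence composition and codon
bias, competing cellular mRNAs, tRNA dynamics, and genome-scale folds.
Passing tests therefore demonstrate the mechanisms (hairpin-controlled
initiation, coupling, repression, SSA correctness), not quantitative
predictions for any natural mRNA.

## Parameters

| parameter | default | units | provenance |
|---|---|---|---|
| temperature | 315 | K | induction temperature of the expression data |
| k1B / k−1B | 30 / 10 | µM⁻¹s⁻¹ / s⁻¹ | best-fit S1-mediated 30S binding |
| [30S] free | 0.65 | µM | cell model at µ = 0.7 dbl/h (0.69 also reported; configurable) |
| ΔG_S1 / ΔG_SD | −9.19 / −12.1 | kcal/mol | measured association constants |
| k_off range | [0.001, 10] | s⁻¹ | measured extremes, exponential interpolation |
| A / B / k_F | 28.8 / 1.40 / 1.36×10⁶ | min⁻¹ / s⁻¹ / s⁻¹ | fitted expression constants |
| k0 (elementary moves) | 9×10⁷ | s⁻¹ | calibrated (see above) |
| N_w | 4 | — | windows per node |
| footprint / P-site offset | 30 / 12 | nt | standard ribosome geometry |
| helix merge tolerance | 4 | nt/side | coarse-graining rule |
| k_elong / k_50S / k_term | 15 / 1 / 2 | s⁻¹ | effective single-step defaults |
| protein k_on / k_off | 1 / 10⁻⁴ | µM⁻¹s⁻¹ / s⁻¹ | order-of-magnitude placeholders, not literature values |

## Numerical choices and edge cases

* Energies are ViennaRNA-rounded to 0.01 kcal/mol; tests compare at that
  precision or looser.
* Beam-search ties break 5'-first; candidate paths are deduplicated by
  endpoint keeping the better partial score.
* `exact_mfpt` raises if the absorbing set is unreachable under the cap;
  `kmc_simulate` reports (never silences) trajectories truncated by the
  step cap.
* Degenerate inputs: empty reaction sets halt the simulation cleanly at
  the current time; ORFs without an in-frame stop terminate at the 3'
  end with a warning; removing node 0 or placing overlapping footprints
  raises.
* The multiloop linear energy model can score spurious lonely branches
  inside very large loops as marginally favourable; the 2-bp minimum
  helix rule in proposals and the corridor restriction in rate
  aggregation keep these breathing pairs out of the coarse state space.

## Known limitations

* Fragment-level refold energetics ignore small boundary terms (dangles
  across window edges), so transition ΔΔG is local, not global;
  detailed balance holds within each transition.
* The engine's in-line helix-melting times use the closed-form
  `exp(-β ΔG)/k_F` rather than a per-event path search (the window
  transitions do use path MFPTs); this trades per-event accuracy for
  bounded cost and is exact in the same limit the closed form assumes.
* Spontaneous basin escape is not represented beyond TIR unfolding and
  ribosome melting (see Folding windows above).
* One dynamic mRNA per simulation; the shared-pool/multi-copy mode is
  limited to fixed concentrations.
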