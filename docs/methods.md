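# Methods

This note documents the models, statistics and numerical choices behind
`coremature`, and what its synthetic data do and do not establish.

## Coordinate system and region scheme

Propeptide residues of the bacterial proteasome β subunit are numbered
with negative integers; residue −1 is immediately N-terminal of the
cleavage site and the catalytic threonine of the mature chain is +1
(Thr1). The default region scheme partitions the 65-residue propeptide
(R. erythropolis Prcβ1 numbering) into closed intervals

| region | interval   | width | character |
|--------|------------|-------|-----------|
| I      | −65..−43   | 23    | N-terminal, weakly conserved |
| II     | −42..−27   | 16    | structured "central box", α-contacting |
| III    | −26..−1    | 26    | glycine-rich flexible linker |

Alignment columns receive coordinates from the designated reference row
only: successive non-gap reference columns are labelled −L..−1 and
reference-gap columns carry no coordinate. Region membership of a column
is decided purely by this mapping; other rows are never re-annotated, and
gaps are excluded from all counts and length statistics. Per-sequence
region lengths are therefore ungapped lengths, which is why they can fall
below the reference interval widths.

## Enrichment statistic

Glycine enrichment in a region is tested with an upper-tail
hypergeometric law: with `N` residues in all regions combined, `K` of
them glycine, and a region containing `n` residues of which `k` are
glycine, the p-value is `P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`. The
background population is the full propeptide set of the alignment itself;
this makes the test symmetric across regions without importing an
external composition. A one-sided binomial variant against a fixed
background frequency (e.g. the ~8% glycine average of globular proteins)
is provided for when an external null is preferred. Fold enrichment is
`(k/n)/(K/N)`. The implementation is validated against exhaustive
enumeration of all `n`-subsets for populations up to N = 20, where the
comparison is exact.

## Active-site geometry and loop span feasibility

The CP carries 14 catalytic threonines, seven per β ring. The reference
atom for "active-site position" is the Thr1 Cα (robust to side-chain
modelling; the Oγ nucleophile is selectable). The last structured
propeptide residue — the arginine at −24 — serves as the anchor from
which the flexible region III linker must reach a neighbouring site for
cross-cutting. For a central subunit and a neighbour:

    l1      = |Thr1_central − Thr1_neighbor|
    l2      = |Thr1_neighbor − anchor_central|
    l_total = l1 + l2

A linker of `n` flexible residues is assumed able to span at most
`(n − occlusion) × 3.63 Å`; 3.63 Å is the trans-peptide Cα–Cα virtual
bond (fully extended contour length), and `occlusion = 4` residues
(the P4–P1 stretch) are treated as buried in the neighbour's substrate
groove and unavailable for spanning. Both constants are configurable;
the defaults are deliberately generous upper bounds — a verdict of
"infeasible" is therefore strong, "feasible" is merely necessary.
Feasibility is `max_reach ≥ l_total`, with ties feasible.

Ring membership and azimuthal indices of loaded structures are assigned
geometrically (split of the 14 points along the principal axis with the
cleanest 7/7 separation, then azimuthal sort), so any PDB-format file
with 14 matching catalytic residues works regardless of chain naming.
The azimuthal origin is arbitrary, so site labels are canonical only up
to ring rotation; all distance-based outputs are invariant to that.

Neighbour classification: intra-ring adjacent = ring index ±1 (mod 7);
inter-ring nearest = the minimum-distance partner on the opposite ring.
Which inter-ring pairs count as cutting partners is exposed as
configuration (`feasible_cross_edges` derives them from span
feasibility), since the set is not independently established.

Because no crystal structure is bundled, structure-level checks run on
the synthetic idealized geometry (ring radius 28 Å, plane separation
30 Å, half-step twist 360/14°), whose scale was chosen to match the CP
interior: adjacent catalytic sites then sit 2·28·sin(π/7) ≈ 24.3 Å
apart, consistent with the >24 Å spacing that rules out cross-cutting at
the Thr1 bond itself. The geometry module accepts any real CP structure
in PDB format via configurable selectors.

## Mass mapping

All masses are average (isotope-abundance-weighted) masses — the
quantity a linear-mode MALDI-TOF reports for ~25 kDa proteins — computed
with `pyteomics` (sum of average residue masses plus one water; no
modification chemistry, no Met excision; construct sequences are taken
verbatim). Candidate cleavage hypotheses are enumerated per inter-residue
boundary in a window (default region III) plus the canonical Thr1 cut;
the C-terminal fragment mass is strictly decreasing in cut position,
which makes the peak→site assignment well posed. Matching is greedy by
ascending absolute error with unique use of peaks and hypotheses,
tolerance 10 Da (~400 ppm at 25 kDa) by default; with ladder spacings of
one residue or more (≥57 Da) this is equivalent to nearest-mass matching,
which the tests verify. Ladder detection reports maximal chains of peaks
whose consecutive spacings lie in a residue-step window (default two
residues, 114.1–372.4 Da); spacings are converted to residue steps by
rounding against a 111.13 Da mean residue mass.

## Maturation simulator

States. An HP is seven β subunits; a CP is two HPs plus an adjacency
over the 14 sites. Each subunit's propeptide is `intact`, `cross_cut` or
`processed`; transitions are strictly forward. Autocatalysis requires a
catalytically competent subunit; a TtoA (Thr1→Ala) subunit can be
cross-cut but is then terminal — it never reaches `processed`, matching
the persistence of partially processed subunits after extended
incubation. Cross-cutting acts only on `intact` subunits and requires at
least one adjacent `processed`, competent subunit.

Models. `independent`: every competent subunit processes at a single
rate `k_auto` (`k_cross = 0`), so pre-formed CPs have processed counts
`Binomial(14, 1 − e^{−kt})`. `cooperative`: intact subunits process
slowly (`k_auto_slow`), cross-cut ones quickly (`k_auto_fast ≥
k_auto_slow`), and processed neighbours cross-cut intact ones at
`k_cross` per neighbour. The observable separating the two is the
intermediate fraction — the probability mass on CPs with 1–13 of 14
subunits processed — evaluated at the time of 50% mean maturation:
independent activation leaves ≈ 0.99988 of CPs in intermediate states,
whereas cooperative activation drains the middle of the distribution
toward all-or-none. Neither model is asserted as the in vivo truth; they
are competing hypotheses the simulator makes comparable.

Rates and variants. Dimerization is mass-action over HP pairs with rate
`k_dimer0 × temperature_scale × f_trunc(A) × f_trunc(B) × f_loop(A, B)`,
where `f_trunc` is the mean region I truncation multiplier over a ring
(truncations accelerate dimerization and slow the first autocatalytic
step, via `trunc_factors`), and `f_loop` penalises loop-variant clashes:
`el_penalty^min(nA_el, nB_el)` for extended loops and
`sl_penalty^min(nA_sl, nB_sl)` for shortened loops. Both penalties are
two-sided by design: a single extended loop meeting a normal partner is
accommodated (preformed extended-loop HPs form active CP with
truncated-dead-subunit HPs), and shortened-loop HPs likewise dimerize
with normal-loop partners while failing against themselves — a one-sided
per-subunit penalty would contradict both observations. The interaction
is pluggable (`RateParameters.loop_interaction`) for exploring other
forms. Temperature enters as a multiplier on dimerization only, since
cold arrests dimerization but not processing; time units are nominal
minutes and only rate ratios are meaningful.

Default rate constants (`k_dimer0 = 0.5`, `k_auto_slow = 0.05`,
`k_auto_fast = k_cross = 5`, el/sl penalties 0.01/0.2, truncation
multipliers ×2–5 on dimerization and ×0.08–0.5 on slow autocatalysis)
are order-of-magnitude choices that reproduce the qualitative
phenomenology — wild-type CP within ~30 min with few visible
intermediates, truncation mutants exposing a pre-holo CP pool,
loop-mutant self-dimerization failure below 5% of wild-type yield. No
quantitative kinetic data exist to fit them to; they are not fitted.

Algorithm. Exact stochastic simulation (Gillespie direct method) from a
single seeded generator. Dimerization propensities do not depend on
internal propeptide states, so the association stage is simulated first
(HPs grouped by composition signature, pair propensity
`rate / n_initial`, i.e. unit total initial HP concentration) and each
CP's internal jump process is then simulated from its formation time;
this staging is statistically exact, not an approximation. Populations
are well mixed; there is no spatial structure.

## Master-equation oracle

With the intra-ring-only topology the two rings of a CP evolve
independently, so the cooperative model on one 7-ring (3^7 = 2187
configurations) is integrated exactly via the sparse generator and
`expm_multiply`; the CP distribution is the convolution of two ring
marginals. The time of 50% mean maturation is found by bisection
(`brentq`, tolerance 1e-10). This provides the reference value for the
intermediate fraction and a second, simulation-free route to the full
processed-count distribution; simulator and oracle are compared by total
variation distance. The oracle is restricted to all-competent rings and
the intra-ring topology — exactly the regime in which it is used.

## Synthetic data: what it emulates and what it does not

* Alignments: region-structured rows around a 65-residue synthetic
  reference whose per-region composition matches the curated-set
  conditions (~9% / ~0% / ~19% glycine in I/II/III; the alignment-wide
  region III glycine fraction across 256 generated sequences is ~18.5%
  in expectation). Columns are i.i.d. given the region and a Bernoulli
  conservation mask (default 0.3) shared by all rows; because a
  conserved column is identical in every row, whether the reference's
  glycine columns land in the conserved set moves per-region frequencies
  by a few percentage points from seed to seed.
  There is no phylogenetic correlation between rows, no
  indel structure beyond a uniform gap rate in non-reference rows, and
  the reference is invented. Recovering the planted composition
  therefore validates the counting and the statistic, not any
  evolutionary claim.
* Geometry: ideal rings with exact 7-fold symmetry and a fixed anchor
  offset; real CP sites deviate from planarity and the propeptide anchor
  geometry varies per subunit. Closed-form distances make the geometry
  code exactly checkable; conclusions about a real structure require
  loading that structure.
* Peak lists: one Gaussian-perturbed peak per planted cut plus uniform
  decoys over [min true − 2 kDa, max true + 2 kDa]; no isotope
  envelopes, adducts, baseline or intensity physics. Recovery rates
  measure the matcher, not instrument performance.
* HP pools: binomial composition at the input ratio, i.e. equal
  incorporation efficiency of the two species, with no within-ring
  position preference.

All generators are pure functions of an explicit seed; no global random
state is used anywhere.

## Numerical choices and degenerate inputs

Ties in span feasibility are feasible; `match_peaks` breaks error ties
deterministically by peak then hypothesis order; empty CP populations
yield a flagged empty distribution rather than an error; an all-gap
region gives length 0 and a region with zero residues is a statistics
error; unknown residue characters are a strict error by default
(`skip` optional). Hypergeometric tail probabilities come from
`scipy.stats.hypergeom.sf`, which is exact to double precision over the
sizes used. Problem sizes in the validation suite (10,000–20,000 CPs for
distribution comparisons, 200 trials for recovery rates, 256-sequence
alignments) were chosen so that Monte Carlo error is well below the
tolerances being asserted.

## Known limitations

* The simulator's topology is a graph abstraction; it does not model
  the dimerization interface structurally, α-ring gating, or any
  conformational-switch mechanism for cooperativity other than
  cross-cut-then-fast-autocatalysis.
* Rate constants are qualitative; absolute time courses are not
  predictions.
* Absolute masses of published constructs cannot be reproduced without
  their exact tag sequences; only the mapping procedure is implemented.
* The bundled geometry is a synthetic stand-in; distance tables for a
  real CP require the corresponding PDB file as input.
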