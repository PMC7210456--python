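# coremature

Tools for dissecting the maturation of the bacterial proteasome **core
particle (CP)** — the α₇β₇β₇α₇ protease barrel whose assembly proceeds
through dimerization of two **half proteasomes (HPs, α₇β₇)** followed by
removal of the β-subunit propeptides that mask the 14 catalytic
threonines (Thr1). The package is aimed at structural bioinformaticians
and modellers studying actinobacterial proteasome assembly (e.g. the
*Rhodococcus erythropolis* reconstitution system and its *M.
tuberculosis* relatives).

It implements four connected analyses:

1. **Propeptide region statistics** (`coremature.regions`) — maps
   alignment columns onto the negative propeptide coordinate system
   (−65..−1, Thr1 = +1), segments the propeptide into regions
   I (−65..−43), II (−42..−27, the structured "central box") and
   III (−26..−1, the glycine-rich flexible linker), and quantifies
   composition. Glycine enrichment in a region is tested with an
   upper-tail hypergeometric law: for a region with *k* glycines among
   *n* residues, drawn from a propeptide population of *N* residues with
   *K* glycines, *p* = P(X ≥ k), X ~ Hypergeom(N, K, n).
2. **Active-site geometry** (`coremature.geometry`) — extracts the 14
   Thr1 reference atoms and the region II anchor (Arg −24) from a
   PDB-format structure, classifies neighbour pairs, and asks whether a
   flexible linker of *n* residues can physically span
   l_total = l₁ + l₂ (central Thr1 → neighbour Thr1 → central anchor)
   given a fully extended reach of (n − occluded) × 3.63 Å.
3. **Cleavage-site mass mapping** (`coremature.masses`) — matches
   intact-protein average masses (linear-mode MALDI-TOF peak lists) to
   the theoretical masses of C-terminal fragments for every candidate
   cut in the propeptide, and detects truncation ladders of peaks spaced
   by ~2 residue masses, the signature of distributive trimming of a
   neighbour's propeptide within region III.
4. **Stochastic maturation simulator** (`coremature.simulate`,
   `coremature.scenarios`) — exact (Gillespie) simulation of HP
   dimerization and per-subunit propeptide processing
   (intact → cross-cut → processed) on a configurable 14-site topology,
   contrasting **independent** activation (every subunit self-cleaves at
   one rate; processed counts are Binomial(14, 1 − e^(−kt))) with
   **cooperative** activation (a slow first autocatalysis unlocks fast
   cross-cutting by active neighbours, driving all-or-none maturation).
   An exact master-equation solver (`coremature.master_equation`, 3⁷
   ring states) provides an independent oracle for the cooperative
   model. A scenario library encodes the characteristic reconstitution
   set-ups (loop-length mutants, region I truncations, TtoA dead-subunit
   mixtures, cold-arrested two-step premixes).

Synthetic inputs for all four stages — region-structured alignments,
idealized two-ring site geometry, planted-cleavage peak lists, binomial
HP mixtures — are generated by `coremature.synth`; every generator is a
pure function of its seed.

## Worked example

Generate a 256-sequence synthetic alignment and analyse it:

```text
$ coremature synth alignment --seed 11 --out aln.fasta
wrote 256 aligned sequences to aln.fasta
$ coremature regions --alignment aln.fasta --reference "ref|synthetic_Re_like"
Glycine frequency per region:
  I: 0.1442
  II: 0.0020
  III: 0.2227
Gly enrichment in region III: k=1482/6656, fold=1.58, p=7.299e-134
        mean   sd  min  max
region
I       23.0  0.0   23   23
II      16.0  0.0   16   16
III     26.0  0.0   26   26
```

Region III carries 22% glycine in this draw versus 0.2% in the central
box, and the hypergeometric tail probability (~10⁻¹³⁴) says such an
excess essentially cannot arise by chance from a homogeneous propeptide
— the flexible-linker composition is a real, region-specific property.
(Per-region frequencies move by a few points from seed to seed; see
`docs/methods.md`.)

Simulate a region I truncation mutant, which dimerizes fast but makes
the first autocatalytic cut slowly, exposing the otherwise invisible
pre-holo CP (all 14 propeptides intact):

```text
$ coremature simulate --scenario delta23 --n-hp 200 --seed 7
scenario delta23: region I truncation (23 aa): pre-holo CP pool becomes visible [cooperative model]
      time  free_hp  cp_total  cp_preholo  cp_active  cp_fully_matured  mean_processed ...
  0.000000      200         0           0          0                 0             NaN
 12.244898        4        98          42         56                50        7.367347
 24.489796        0       100          23         77                77       10.780000
 48.979592        0       100           3         97                96       13.570000
 73.469388        0       100           0        100               100       14.000000
```

Half the pool has dimerized within ~12 minutes (nominal units) while 42
of 98 CPs still carry all 14 propeptides — the pre-holo intermediate —
and the population then converts to fully matured CPs with almost no
partially processed particles at late times: under cooperative
activation CPs are either all-propeptide or all-processed. Note
`cp_fully_matured` tracks `cp_active` closely at every time point —
the all-or-none signature; an independent model run
(`--model independent`) instead fills the intermediate counts.

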