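# ploopmsm

Markov state model analysis of P-loop conformational distributions in
myosin motor domains.

Myosin motors share one mechanochemical cycle yet differ enormously in duty
ratio (the fraction of the cycle spent bound to actin) and ADP release rate
(which sets sliding speed), and crystal structures of biochemically distinct
motors are often nearly indistinguishable. The working hypothesis behind
this package is that the *distribution* of conformations an isolated motor
domain explores — in particular of its P-loop (Walker A motif), the
conserved GESGAG element that wraps the nucleotide phosphates — encodes
these biochemical differences. `ploopmsm` implements the analysis pipeline
that tests that hypothesis on trajectory-style conformational data:

* **featurize** — 36 backbone N(i)/O(j) pairwise distances of the 6-residue
  P-loop (nm), optimal-superposition backbone RMSD (Å), carbonyl bond-vector
  angles, per-residue side-chain solvent-accessible surface area, contact
  fractions at a 0.35 nm cutoff;
* **cluster** — k-hybrid microstates (k-centers to a radius plus k-medoids
  refinement), Ward agglomeration of microstate representatives in a 4-D
  PCA space into five coarse P-loop states A–E, and k-NN (k = 5) assignment
  of other motors' conformations to those states;
* **msm** — transition counting with a uniform 1/n pseudocount and row
  normalization; equilibrium distributions, implied timescales
  t_i = −τ/ln λ_{i+1}, mean first-passage times, and leave-one-trajectory-out
  jackknife errors;
* **landscape** — PCA (full SVD, no whitening) of microstate feature
  vectors and the weighted free-energy surface −ln p in the PC1/PC3 plane
  (50 bins, Gaussian smoothing of variance 0.3 grid cells, six level sets);
* **crystal** — nucleotide-occupancy classification by a 14-entry residue-name
  list, RMSD partitioning at 0.6 Å, and enrichment statistics with an
  in-package two-sided Fisher exact test plus bootstrap intervals;
* **predict** — the two mechanochemical predictors: ΔG_AB = −ln(π_A/π_B) in
  kT (duty-ratio proxy; negative = nucleotide-favorable A state preferred)
  and P(A→B) = T₅[A,B] (ADP-release proxy), evaluated against a motor panel;
* **synthetic** — generators with known ground truth (metastable 5-state
  chains with Gaussian emissions in the 36-D feature space, toy 6-residue
  loop structures exhibiting the serine-carbonyl flip, crystal sets, motor
  panels), so every stage is testable by parameter recovery.

## Worked example

`examples/04_motor_panel_predictors.py` simulates an 8-motor panel whose
chains span A-favoring to B-favoring thermodynamics, runs the full pipeline
(clustering, PCA/Ward state definition on a reference motor, k-NN
assignment of the rest, coarse MSMs) and prints:

```
   motor   dG_AB (kT)    P(A->B)  duty  ADP (1/s)  class
 motor00   -2.08 ± 0.06   0.015    0.85       24.9  high
 ...
 motor07    2.02 ± 0.05   0.168    0.16      287.7  low

Spearman(-dG_AB, duty ratio)    = 0.976
Spearman(P(A->B), ADP release)  = 1.000
```

A negative recovered ΔG_AB means the motor prefers the nucleotide-favorable
A state — the signature of a high duty ratio — and a larger P(A→B) marks a
faster ADP releaser; the rank correlations quantify how well the pipeline
recovers the generating relationships. `examples/01`–`03` demonstrate MSM
parameter recovery, the free-energy surface, and the crystal-ensemble
enrichment analysis (including the published contingency tables: odds ratio
0.03 for nucleotide depletion beyond 0.6 Å, p < 0.034 for the unliganded
duty-ratio split).

There is also a thin CLI (`ploopmsm simulate|cluster|fit-msm|timescales|
landscape|coarse-grain|crystal-test|predict|run-all`) over the same library
calls.

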