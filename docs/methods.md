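# Methods

## The refolding evaluation model

A design is evaluated by superposing the Cα trace of its refolded model onto
the intended target.  The rigid transform minimising the least-squares
deviation is computed with the Kabsch algorithm: both point sets are centred,
the 3×3 covariance is decomposed by SVD, and the rotation is assembled with
the sign of the smallest singular vector flipped whenever the determinant
would be −1 (proteins are chiral; reflections are never acceptable).  The
per-residue deviation vector under that transform yields two aggregates:
`rmsd_mean`, the classical root-mean-square, and `rmsd_median`, the plain
median of per-residue deviations.  "scRMSD" with no qualifier means the
root-mean-square over all residues.

A design is designable when mean pLDDT ≥ 70 **and** scRMSD ≤ 2.0 Å, both
comparisons inclusive.  pLDDT is stored on the 0–100 scale; files carrying
confidences in [0, 1] are auto-scaled ×100 on ingest.

## The outlier-corrected scRMSD

Flexible or disordered termini have no single conformation; a refolded model
places them differently from the target, and because the Kabsch fit is a
global least-squares, a 10–20-residue divergent tail drags the whole
superposition and inflates the deviation of a perfectly-predicted core.  The
correction is deliberately simple and runs in four fixed steps:

1. plain Kabsch fit over all residues → per-residue deviations `d`;
2. outliers = residues with `d > median(d) + 1.5 × MAD(d)`, where
   `MAD(d) = median(|d − median(d)|)` (unscaled; a MAD of exactly zero flags
   nothing); the inequality is strict;
3. re-fit using only non-outlier residues;
4. report the aggregate — median by default — of the per-residue deviations
   of the **full** chain (outliers included) under the re-fit transform.

If fewer than three non-outliers remain the plain fit is returned with a
fallback flag.  An iterative variant repeats steps 2–3 from the current
transform until the outlier set stabilises or `max_iter` is reached;
`max_iter=1` is exactly the single-round correction.

### Known limitation: single-round rejection at high tail mass

The outlier threshold is computed from the *initial* global fit.  When the
divergent region carries a large share of the chain (the synthetic study
conditions use 20 of 100 residues, hinged 90°), the initial fit is itself so
distorted that core deviations reach ~10 Å and near-hinge tail residues
(deviating only ~5 Å) cannot be flagged; the re-fit then retains a few truly
divergent residues and the corrected median lands above 2 Å in roughly one
pair in ten.  The iterative variant converges to the clean core fit and
rescues essentially all such pairs.  Real campaigns, where flexible tails are
usually well under 20 % of the chain, sit in the regime where one round
suffices; at 20 % tail mass the single-round rescue rate is ~90 % and
sensitive to the tail's conformational ensemble.  This is a property of the
procedure, not of its implementation, and is the main caveat when applying
the single-round correction to heavily tailed chains.

## Synthetic data: what it emulates, what it does not

The generators stand in for GPU folding models so that every pipeline stage
is exercised end to end.

**Ideal backbones.**  N/Cα/C/O coordinates are built residue-by-residue from
internal coordinates (bond lengths N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å; angles N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°; ω = 180°)
via natural-extension-of-reference-frame placement.  Dihedrals per state:
helix (φ, ψ) = (−57°, −47°); strand (−119°, 113°); coil drawn per residue
from a 3-basin Ramachandran mixture (45 % extended/PP-II
φ ∈ [−160°, −60°], ψ ∈ [90°, 180°]; 40 % α-basin φ ∈ [−100°, −50°],
ψ ∈ [−60°, 0°]; 15 % left-handed α), which yields semi-compact random-coil
geometry rather than a straight rod.  The carbonyl O sits in the peptide
plane bisecting Cα–C–N(next).  Consecutive Cα–Cα distances come out at the
trans-peptide 3.80 Å.  Chains are *not* folded into compact globules and
self-intersection is not prevented — superposition arithmetic is indifferent
to packing, and the secondary-structure tests rely only on local geometry.

**Predicted-model analogs.**  The core is displaced by one isotropic
Gaussian offset per residue (σ per coordinate, default 0.5 Å — note the
resulting per-residue displacement has RMS √3·σ ≈ 0.87 Å, so even a perfect
core fit reports a median deviation of ≈ 0.77 Å; sub-0.5 Å corrected medians
are impossible under this noise model).  Tails are re-posed, not noised:
`hinge` rigidly rotates each tail about its junction Cα by a fixed angle
(default 90°) around an axis drawn uniformly on the sphere; `random-walk`
rebuilds tail Cα positions as a 3.8 Å-step random walk.  pLDDT is Gaussian
per region (core mean 90, tail mean 60, sd 5, clipped to [0, 100]) — a
threshold-behaviour model, not a mechanistic one.  Nothing here emulates
folding-model error modes, recycling effects or sequence-dependent accuracy;
passing tests demonstrate the *evaluation layer* is correct, not that any
folding model behaves this way.

**Mutagenesis degradation surrogate.**  The pipeline-level mutagenesis
experiment replaces the folding oracle with a surrogate in which mean pLDDT
falls and scRMSD grows linearly with mutation load
(pLDDT ~ N(92 − 55·f, 4), scRMSD ~ |N(0.55 + 4.5·f, 0.4)|): at f = 0 a
confidently-refolded parent, by f = 0.6 a failed refold.  Only the monotone
coupling matters to what the experiment tests (threshold ordering and
monotone designability decay).

**MSAs.**  Homolog rows are the query with Binomial(L, divergence)
substitutions and Binomial(L, gap_rate) gaps, independently seeded — enough
structure for weighting/Neff arithmetic, with none of the phylogenetic
correlation of real alignments.

**Outcomes.**  Binary success labels are Bernoulli with
logit = β₀ + β_pLDDT·pLDDT + β_scRMSD·scRMSD.  The accompanying metric
generator draws pLDDT from a clipped N(80, 10) and scRMSD from a lognormal
(median 1.5 Å, log-sd 1.0), matching the long-tailed scRMSD histograms of
real campaigns; with β = (+0.2 / pLDDT unit, −1.0 / Å) both single-metric
ROC AUCs exceed 0.75 at n = 2000.

## Statistical conventions

* **ROC AUC** uses the Mann–Whitney pair convention — P(score_pos >
  score_neg) + ½·P(tie) — computed from midranks; it is exact under ties and
  independent of sample order.  `higher_is_better=False` negates scores
  (used for scRMSD).
* **Threshold grid**: predicted-positive iff pLDDT ≥ p and scRMSD ≤ r
  (inclusive, matching the designability predicate); default axes pLDDT
  50–100 step 5, scRMSD 0–5 step 0.5 Å (11 × 11 cells).  Precision is 0 and
  flagged where no positives are predicted; F1 is 0 where precision + recall
  is 0.  Optimum selection breaks ties toward stringency: highest pLDDT
  threshold first, then lowest scRMSD threshold.
* **Fisher's exact test** (two-sided) sums hypergeometric probabilities of
  all same-margin tables no more probable than the observed one (delegated
  to scipy; verified in-suite against exhaustive enumeration for all tables
  with margins ≤ 10).
* **Neff**: sequence weights are 1 / (number of rows, self included, within
  0.8 fractional identity over mutually non-gap columns); per-position Neff
  sums the weights of rows with a residue at that position (query included,
  so a single-sequence alignment scores 1.0, not 0); the reported value is
  the median over query positions.  The 0.8 threshold is the convention
  associated with the standard weighting scheme and is configurable.
* **Secondary structure**: amide H placed on N, 1.01 Å opposite the
  preceding C=O; hydrogen bond when the Kabsch–Sander energy
  0.084·(1/d_ON + 1/d_CH − 1/d_OH − 1/d_CN)·332 kcal/mol < −0.5; two
  consecutive i→i+4 turns mark helix (minimum run length 4), parallel or
  antiparallel bridge patterns (|i−j| ≥ 3) mark strand, all else coil.
  3₁₀/π helices collapse to coil, isolated bridges to strand; chains split
  at Cα–Cα breaks > 4.5 Å; segments under 5 residues are coil.  On real
  proteins this simplified assigner can differ from full 8-state
  implementations by a few percent of residues; tests therefore rely on
  constructed geometries.

## Numerical and design choices

* Collinear fit sets (rank < 2 after centring) raise rather than return an
  under-determined rotation; < 3 fit points likewise.
* A MAD below 1e-9 Å is treated as exactly zero so that byte-identical or
  uniformly-shifted structures never produce spurious outliers.
* Mutation counts are `round(f·L)` (half away from zero), minimum 1 for
  f > 0; substitutions exclude the parent residue so nominal and realized
  loads coincide exactly.  Per-replicate RNG seeds derive from a SHA-256
  hash of (master seed, parent id, fraction, replicate) — stable across
  processes and Python versions.
* Column masking leaves the query row intact by default (structure
  predictors require row 1 to equal the input sequence); `mask_query=True`
  masks it too.
* Truncation to a reference sequence requires a unique exact substring
  match by default; a mismatch-tolerant sliding-window mode exists but is
  off by default.  Eligibility for truncation analyses uses strict bounds
  5 < Δlength < 50.
* Uniform-length subsets take k = (smallest per-bin availability) records
  from every bin — the largest count that still guarantees a flat
  histogram; length-matched control subsets use the analogous integer
  pool/case ratio.
* All generators and experiments are deterministic given their seeds; reruns
  produce byte-identical CSV output.
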