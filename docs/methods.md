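# Methods

This note documents the models, scores and numerical conventions behind
`xlscreen`, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the design choices made where the
underlying procedure was genuinely open.

## Crosslink restraints

A crosslinked residue pair is treated as a Cα–Cα distance restraint.  For a
lysine-reactive crosslinker of the DSSO class, spacer plus side-chain
geometry makes ~30 Å the accepted upper bound, so the default satisfaction
threshold is 30 Å and it is **inclusive** (distance ≤ 30 Å counts as
satisfied).  Boundary cases are rare in practice; the threshold and its
sense are explicit arguments throughout.

Mapping a restraint onto a model uses the **minimum-distance rule**: each
end is assigned to a chain carrying its accession, and when the accession
occurs on several chains (homo-oligomers; both orders of a self link) the
assignment with the smallest Cα–Cα distance is chosen.  This is the standard
convention for ambiguous crosslinks in homo-oligomers.  Restraints whose
accession is absent from the model, or whose residue index falls on an
unresolved position, are *unmappable*: a state, not an error.  They are
excluded from every violation denominator and counted separately, so
violation percentages are always over mapped links only.

Violation is summarised per PPI — heteromeric and self links tallied
separately, since self links confound intra-chain conformation with the
interface — and then aggregated per ipTM bin by median and quartiles of the
per-PPI percentages (not pooled counts), which matches how
violation-vs-confidence boxplots are constructed.  PPIs with zero mapped
heteromeric links have an undefined percentage; they are excluded from the
bins and surfaced in a side count.  Default bin edges are
(0, 0.55, 0.75, 0.85, 1.0]: the random-like / gray / high-confidence ranges,
with the gray zone split at 0.75 because restraint agreement differs
markedly between its halves.

## Confidence tiering and the target–decoy noise model

Per predicted pair the representative model is the one with maximum ipTM
(ties break to the lower model index).  Tiers:

| tier            | rule                |
|-----------------|---------------------|
| high_confidence | best ipTM > 0.85    |
| gray_zone       | 0.55 < best ≤ 0.85  |
| random_like     | best ≤ 0.55         |

The boundary convention (strict at the top, inclusive at 0.85 for gray,
inclusive at 0.55 for random-like) makes the tiers a partition for any pair
of cutoffs; both cutoffs are arguments.

The noise model draws `n_reps` (default 10) subsamples of `n_subsample`
(default 300) target records **without replacement** — a subsample of PPIs
means distinct PPIs — histograms best-ipTM on 0.1-wide bins, and reports the
per-bin median and standard deviation of the subsample frequencies next to
the frequencies of the full decoy set.  The count of decoys above the high
cut is the empirical false-positive check; a decoy-free region above 0.85 is
what justifies the high-confidence tier.  Decoy generation itself (predicting
shuffled pairs) is external; the module consumes decoy score tables, and the
synthetic generator emulates them.

Homology filtering consumes standard 12-column tabular alignment output.  A
hit passes with identity ≥ 30% and E-value < 10⁻³ (E-values of 0 are floored
to 10⁻²⁰⁰).  A *pair* is considered structurally represented in the PDB when
a passing hit is keyed by the pair itself, or when both members have passing
hits to chains of the same PDB entry — the latter is the package's
interpretation of "the complex has a homolog", chosen because per-protein
hits alone say nothing about the interface.  Paralogs hitting the same chain
are judged independently.  STRING annotation uses combined score > 0.4;
`novel_interaction` means absent from both the curated database and STRING,
`novel_interface` means no PDB homolog flag.

## Co-fractionation analysis

Abundance filter: a protein enters the analysis iff it has ≥ 3 identified
peptides and ≥ 9.5×10⁶ iBAQ in **all** replicates of at least one condition;
ribosomal proteins are removed when a ribosome set is supplied (SEC lysis
conditions are not selected for ribosome stability).

Profiles are max-normalized per protein/replicate, averaged over replicates
and group members, and smoothed with a Gaussian of σ = 1 fraction.  The
**co-elution score is a documented stand-in**: max(0, Pearson r) of the
smoothed, max-normalized profiles per replicate.  The original analysis used
an external complex-centric score (PCprophet's pre-GO-enrichment score);
that score is not re-derived here, but pre-computed score tables can be
replayed through the same filter chain, which is what the exact
candidate-count checks require.  Zero-variance profiles score 0 and are
flagged rather than propagating undefined correlations.

The candidate filter chain: complexes with more than 10 members or peak
elution ≥ 19.5 ml are removed (poorly resolved late fractions and the void),
a pair passes in a condition if its score reaches 0.8 in at least 2 of 3
replicates, the union over the crosslinked and untreated conditions is
taken, and groups are expanded all-against-all into binary pairs.  The peak
elution of a complex is the fraction of maximum of the group-averaged
normalized profile, mapped by the affine fraction→volume map
(fraction *i* → 10.5 + (*i* − 0.5)·0.2 ml for the default 50×200 µl
geometry); the peak estimator was not prescribed, so the simplest robust
choice was taken and is configurable through the smoothing σ.

Condition comparison uses the median replicate score per condition (robust
to one noisy replicate; mean vs median was not prescribed) and a symmetric
similarity band of ±0.1 by default — the band is a calibration parameter,
not a constant, and is always reported.  ROC curves sweep cutoffs 0.0–1.0 in
0.1 steps with equally sized known and random pair sets; pairs missing from
the records score 0, so the cutoff-0 point is always (FPR 1, TPR 1).

## Assembly inference

The interaction graph has an edge where best ipTM **strictly** exceeds the
threshold (default 0.65).  Candidate higher-order complexes are connected
components with ≥ 3 proteins; components of exactly 3 are candidate 1:1:1
trimers regardless of whether they are a path or a triangle — an indirect
A–B–C path is still a hypothesis worth one trimer prediction.  Isolated
binary components are reported separately.

Superposition is the Kabsch algorithm via SVD with the determinant guard, so
degenerate (e.g. colinear) point sets still yield a proper rotation.  Merging
two models on a shared accession superposes the incoming model's copy of the
shared chain onto the reference's copy over their common resolved residues
(residue-index correspondence over the full-length sequence; ≥ 3 common
residues required), applies the transform to the whole incoming model, drops
the incoming shared chain, and appends the partner chains.  When an
accession appears on several chains, the chain pair minimising superposition
RMSD is used, mirroring the minimum-distance convention in restraint
mapping.  Each merge step records the superposition RMSD (a conformational
consistency diagnostic — a large value means the shared chain changes
conformation between the two predictions) and the count of inter-source Cα
pairs closer than 3 Å (steric clashes).  No refinement is applied: the
assembly is exactly the union of rigidly placed binary models.

## Synthetic data

The generator provides every input with ground truth attached, under the
conditions the downstream stages assume:

- **Toy chains** are ideal α-helices (radius 2.3 Å, twist 100°, rise 1.5 Å
  per residue) in a random orientation with small Gaussian jitter and a
  rejection check, giving 3.8 ± 0.1 Å consecutive Cα spacing and ≥ 3.5 Å
  non-adjacent separation by construction.  Complex chains are placed so a
  designated interface residue pair sits at 8 Å, guaranteeing satisfiable
  crosslinks; placement orientation is re-randomised until no inter-chain
  contact falls below 3.5 Å.
- **Crosslinks**: `n_true` records sampled from residue pairs within the
  crosslinker bound (default 28 Å, so they are satisfied with margin at the
  30 Å threshold) and `n_random` uniform over all pairs; every record carries
  its true distance, so violation calls are scored exactly.
- **Score tables**: targets draw best ipTM from a two-component truncated
  normal mixture (0.45·N(0.30, 0.12) + 0.55·N(0.90, 0.04), clipped to
  [0, 1]) — bimodal, as real candidate screens produce; decoys from
  0.85·Beta(1.2, 5) — one-tailed with zero mass above 0.85 by default, the
  behaviour the tiering cut relies on.  Both mixtures are configurable.
- **Elution matrices**: 50 fractions × 3 replicates × 2 conditions.  Complex
  members share a Gaussian peak (σ = 1.5 fractions) at an early fraction;
  monomers and labile members peak ≥ 5 fractions later.  In the crosslinked
  condition a labile member's profile shifts to the complex peak with weight
  min(1, stabilization_gain); gain 0 makes the two conditions identically
  distributed.  Replicate noise is multiplicative log-normal (σ = 0.25),
  because MS intensity noise is multiplicative.  Abundance records
  (peptides/iBAQ) carry a planted pass/fail ledger.

What the generator does **not** emulate: peptide-level identification and
missing values, elution peak tailing and column-to-column drift, correlated
(batch) replicate noise, shared subunits between complexes, and any
sequence-level realism (chains are Cα-only poly-alanine).  Tests passing on
this data therefore demonstrate algorithmic correctness — exact restraint
geometry, filter logic, score calibration behaviour — not robustness to the
messiness of real LC-MS data.

## Problem sizes and numerical conventions

The self-contained acceptance battery uses 1,000 synthetic restraints for
the distance oracle (tolerance 10⁻⁶ Å), 100 random graphs for the
connected-component oracle, 100 generator seeds for the co-elution AUROC,
20 seeds × 10 histogram bins for the noise-model agreement check, and
2,000 decoys for the truncation check — sizes at which the stochastic checks
are stable across seeds while the whole battery completes in seconds.
Distances and coordinates are Å throughout; residue numbering is 1-based
over the full protein sequence (the crosslinking-MS convention); pair keys
are lexicographically sorted accession tuples, and canonicalization is
idempotent.  Determinism: every stochastic routine takes an explicit seed
and a fixed seed reproduces outputs bit-for-bit.

## Known limitations

- The co-elution stand-in is intentionally simple; absolute candidate counts
  from it are not comparable to complex-centric tools, only the filter chain
  downstream of the score is.
- Violation analysis is Cα-distance only; no solvent-accessible surface
  distance and no accessible-volume (rotational search) analysis.
- Assembly merging reports clashes but does not resolve them; stoichiometry
  beyond 1:1:1 trimer listing is out of scope.
- PAE matrices are parsed and carried but not used by any decision rule.
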