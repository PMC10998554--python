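# Methods

## Model and procedure

`nanotcr` analyses a sorted single-cell experiment in which each T cell is
bound to one nanovial carrying (i) a pMHC species whose identity is encoded by
an oligonucleotide feature barcode and (ii) capture antibodies that accumulate
secreted granzyme B, read out as a second, oligo-tagged barcode. Sequencing
yields, per cell barcode, a set of assembled TCR contigs and an integer count
vector over the feature registry. The pipeline assumes:

- **Clonotype identity** is the equality of retained chain-key sets, where a
  chain key is (locus, V gene, J gene, CDR3 nucleotide sequence). Nucleotide
  keys mirror Cell Ranger clonotype semantics; amino-acid keys are an option
  (`key_level="aa"`). At most 2 chains per locus are retained per cell, ranked
  by UMI count with deterministic ties (reads, then contig id); cells over the
  cap are truncated by default rather than discarded (`discard_excess=True`
  inverts this).
- **Epitope dominance**: the pMHC barcode counts of a cell are a mixture of
  the cognate nanovial's barcode and a small ambient background. The call
  assigns epitope *e* iff count(*e*)/Σ pMHC counts > `threshold` (default
  0.90, strict, read literally from the ">90%" rule). Secretion-class
  features are excluded from the denominator because the two barcode classes
  measure different quantities. No depth gate by default (`min_total_umis=1`).
  Clonotype-level calls default to pooled member counts (lower variance than
  per-cell majority voting, which is also provided).
- **Secretion tiers**: High iff level ≥ `high_min` (2,000), Medium on
  [`medium_min`, `high_min`) = [500, 2,000), Low below. The closed High bound
  follows the normative text statement; an open-bound variant
  (`high_inclusive=False`) covers the alternative convention that appears in
  one figure caption. Clonotype secretion aggregates member cells by **max**
  (a clonotype is High if any sorted member crossed the bound); mean is an
  option.
- **Gated-population comparison** uses a two-sided Mann–Whitney U test.
  Barcode levels are strongly right-skewed (the positive gate's SD, 1,286,
  exceeds its mean, 1,022), so a rank test is the defensible default; Welch's
  t-test is available.
- **Quadrant gating** for two-cytokine profiling: Q1 = A only, Q2 = both
  (polyfunctional), Q3 = B only, Q4 = nonsecretor, with events exactly at a
  threshold assigned to the lower class (consistent with strict ">" gating).
- **Percentages** are rounded half-up to one decimal, in exact decimal
  arithmetic. Note 9/68 = 13.235…% therefore reports 13.2%, although the
  source figure prints 13.3% alongside 58.8% and 27.9% — the printed trio is
  internally inconsistent at one decimal; the computed value is asserted in
  the tests and reported as 13.2.
- **Venn regions** across 2–3 isolation methods are reported both as
  exclusive partitions (disjoint, summing to the union) and as inclusive
  intersection cardinalities, since published overlap counts are ambiguous
  between the two conventions. Pair identity for cross-method comparison is
  joint CDR3α+CDR3β at the amino-acid level (a β-only mode exists for
  reference matching).

## Synthetic-data generator

`sim_data.simulate_repertoire` emulates the statistical structure the
analysis relies on; defaults encode the granzyme-B screening conditions.

| parameter | default | meaning |
|---|---|---|
| `n_cells`, `n_clonotypes` | 5,000, 300 | cohort size; clone identity per cell drawn from a zipf-weighted pmf (exponent 1.5) over clone ranks, so realised clonal sizes follow a truncated-zipf law |
| `multi_alpha_rate`, `multi_beta_rate` | 0.10, 0.05 | probability a clone carries 2 α (resp. β) chains — "a few clonotypes contain multiple chains" |
| `productive_rate` | 0.9 | per-contig probability of an in-frame junction; nonproductive contigs get a frameshifted CDR3 and drop out at filtering (matches the ~90% productive-pair fraction) |
| `pmhc_total_mean/dispersion` | 200, 10 | negative-binomial pMHC UMI totals per cell |
| `dominant_fraction_alpha/beta` | 97, 3 | Beta law of the cognate-epitope share, mean 0.97, concentration 100; `beta=0` degenerates to a point mass at 1 for noiseless checks |
| `ambient_noise` | 0.01 | share of pMHC mass spread uniformly over non-cognate epitopes; measured inter-nanovial crosstalk is < 0.04%, justifying small, unstructured contamination |
| `secretion_pos/neg mean, sd` | 1,022/1,286 and 288/149 | log-normal laws moment-matched to the printed gate moments (σ² = ln(1+SD²/mean²)); only moments are published, and a log-normal is the natural positive, heavy-right-tailed choice |
| `tier_proportions` | (9, 40, 19)/68 | tier mix of positive-gate cells; levels are drawn from the positive law *truncated to the tier's interval* (inverse-CDF), so truth tiers are consistent with the emitted counts by construction |
| `positive_gate_fraction` | 87/657 | share of sequenced cells from the positive sort, from the published sequencing summary (87 positive vs 570 negative cells) |
| `gate_false_positive_rate` | 0.0004 | the crosstalk rate, carried in the config for completeness |

CDR3s are random in-frame non-stop codon strings of 12–20 aa (translated with
Biopython); V/J names come from a small bundled human TRAV/TRAJ/TRBV/TRBJ
name list (names only). Chain keys are enforced unique across clones so
truth-partition recovery is exact when dropout is disabled. Cell barcodes are
deterministic base-4 encodings of the cell index, 16 nt plus the `-1` suffix.
Everything derives from one `numpy` generator seeded by `SimulationConfig.seed`;
fixed seed ⇒ byte-identical output files.

`simulate_loading` models nanovial occupancy as binomial thinning (capture
probability *p*) of Poisson(λ) arrivals, i.e. Poisson(λ·p) occupancy. The
empirically reported loading optimum near 1.6 seeded cells per nanovial is
deliberately *not* hard-coded as Poisson-optimal (pure Poisson single
occupancy peaks at λ=1); *p* is free so users can reproduce an effective
optimum.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: doublet cell barcodes, cross-cell barcode swapping or
index hopping, depth variation between gates, clone-level correlation between
secretion and frequency, sequence-realistic V(D)J junctions, and transcriptome
counts. Parameter-recovery results certify the pipeline's arithmetic and
decision rules under the stated noise model, not performance on arbitrary
datasets.

## Numerical and design choices

- Strict inequalities at every published boundary (">90%", ">" gating);
  closed lower tier bounds per the normative text. Boundary behaviour is
  pinned by tests at 499/500/1999/2000 and at a 0.90 dominant fraction.
- Argmax ties in the epitope call return no call; unreachable at the default
  threshold but defined for configurable thresholds ≤ 0.5.
- Degenerate gated comparison (every observation identical in both groups)
  returns p = 1.0 rather than propagating a 0/0 from the rank test.
- `recovery_rate` reports rate 0 with an `undefined` flag for tiers with no
  tested candidate.
- Frequency cutoffs are applied at the clonotype level **before** pair
  expansion, matching the way published pair counts arise from clonotype
  counts.
- Readers keep cell barcodes opaque (no `-1` suffix normalisation) to avoid
  silent collisions; unknown contig-table columns warn and are ignored.
- The worked-example and simulation problem sizes (5,000-cell default cohort,
  10⁵ nanovials for loading, 10⁴ draws for law moments) were chosen so all
  statistical assertions sit at ≥3-SE separation while the whole suite runs
  in seconds.

## Known limitations

- Ambient contamination is uniform and small; no EM-style demultiplexing or
  crosstalk correction is attempted (out of scope by design).
- "Barcode level" integers are taken as given; whether they are raw or
  corrected UMI counts is not modelled.
- The AIRR dialect covers the fields this pipeline uses, not the full
  Rearrangement schema.
- Venn reporting supports at most three methods.
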