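# Methods

## The classification model

Each missense variant carries up to three predictor scores. The three are
deliberately heterogeneous: the SVM probability aggregates sequence- and
structure-derived features of the substitution, FoldX ΔΔG measures only the
predicted change in folding free energy of the mutant protein, and
PolyPhen-2 is predominantly conservation-driven. The consensus is a plain
vote — no weighting, no calibration — because the point of the category is
interpretability for a clinical audience: "all predictors agree" and "the
predictors disagree" are the meaningful distinctions.

Per-predictor decision rules, all inclusive at the boundary:

| predictor | deleterious when | default |
|---|---|---|
| SVM | *p* ≥ `svm_cut` | 0.5 |
| FoldX | round(ΔΔG, 1) ≥ `foldx_cut` | 1.0 kcal/mol |
| PolyPhen-2 | *p* ≥ `pp2_vote_cut` | 0.5 |

**Why FoldX rounds before comparing.** ΔΔG values are reported at
one-decimal precision, and the reference analysis treats 0.99 kcal/mol as
crossing the 1 kcal/mol destabilisation threshold while 0.72 does not. A
strict `ΔΔG > 1` rule cannot produce that pair of calls; comparing after
rounding to the reporting precision (equivalently ΔΔG ≥ 0.95) reproduces
every published call. The rounding is configurable
(`foldx_round_decimals=None` restores the strict rule).

**Why PolyPhen-2 votes at 0.5.** PolyPhen-2's conventional ternary bands
(benign ≤ 0.15 < possibly damaging < 0.85 ≤ probably damaging) are reported
as a descriptive annotation, but the vote is binary at 0.5. The published
per-variant calls (e.g. a 0.648 scored as a deleterious vote, a 0.311 as
benign) are jointly consistent only with a 0.5 cut; using the ternary lower
bound as the vote boundary would flip several categories.

**Missing scores.** A predictor without a score (FoldX cannot evaluate
residues absent from the structure, such as signal-peptide positions) drops
out of the vote denominator. The count-to-label map is unchanged: with two
available predictors, one deleterious vote still maps to "possibly neutral".
Such variants are flagged `reduced_evidence` in all outputs. The map is a
pure function of the deleterious count — which predictors voted never
matters.

## Neutral-benchmark construction

Substitutions tolerated in a close ortholog are treated as neutral in the
human protein, provided the local context is preserved. Given pairwise
alignments of the human query against each ortholog:

1. every column where both rows hold residues and they differ is a
   candidate (insertions/deletions are not substitutions);
2. **flank filter** — the two columns on each side must hold identical
   residues in both rows (a gap or the alignment end fails);
3. **gap filter** — no gap in either row within ±3 columns;
4. **contact filter** — every residue with at least one atom pair < 5 Å
   from the candidate residue in the reference structure must align to an
   identical ortholog residue (aligned-to-gap counts as different; an
   unresolved candidate position is rejected with the reason recorded);
5. **identity filter** — the source alignment must exceed 90% identity,
   computed as identical pairs over residue–residue columns (gap columns
   excluded from the denominator; the denominator convention is not
   standardised, so it is documented here and configurable);
6. **deduplication** — each distinct (ref, position, alt) keeps exactly one
   record, from the highest-identity alignment (closest ortholog first);
   equal identities tie-break on the lexicographically smaller subject id.

The comparisons are strict where the definitions say strict: a 5.0 Å atom
pair is not a contact and a 90.0%-identity alignment is excluded.

Contact maps are computed from the first model of a PDB file, one chain
(first polymer chain unless configured), all atoms of standard amino-acid
residues including backbone; waters and hetero residues are excluded and
alternate locations collapse to the highest-occupancy atom per atom name.
Sequence neighbours *i* ± 1 are not excluded — the definition is purely
geometric. Atom pairs are found with a k-d tree and re-checked against the
strict cutoff, so the result is identical to an all-pairs scan. When author
residue numbering disagrees with query numbering (fewer than 90% of numbered
residues match), the structure-derived sequence is globally aligned to the
query and positions mapped through that alignment.

Homolog acquisition (e.g. an iterative profile search against a sequence
database) is out of scope: the builder consumes user-supplied sequences or
alignments. Unaligned homologs are aligned with a global affine-gap aligner
(BLOSUM62, open −11, extend −1) — the filters are defined on alignment
columns, not on any particular search tool.

## Benchmark statistics

Pathogenic is the positive truth class, a deleterious call the positive
prediction. TPR, TNR, PPV, NPV, ACC and BACC = (TPR + TNR)/2 follow the
standard formulas. A zero denominator leaves that single statistic
undefined (`None`/`NA`) instead of raising: the benchmark subsets here are
small, and a partially filled report is more useful than none. Values are
kept at full precision; displayed values round half-away-from-zero to three
decimals (so a BACC of 0.9125 displays as 0.913).

The report also summarises the raw sign of ΔΔG per subset (fraction with
ΔΔG > 0, i.e. any predicted destabilisation). This is intentionally
distinct from FoldX's 1 kcal/mol classification threshold: the two answer
different questions ("does FoldX predict any destabilisation?" vs "does
FoldX call this variant deleterious?"), and on the packaged benchmark they
give visibly different counts (16/17 pathogenic variants have ΔΔG > 0 but
only 15/17 cross the classification threshold).

**Known discrepancy.** For the packaged 57-variant benchmark, the
recomputed SVM PPV (17/24 ≈ 0.708) and ACC (50/57 ≈ 0.877) and the
PolyPhen-2 TPR/PPV/ACC/BACC (≈ 0.941 / 0.842 / 0.930 / 0.933) differ in the
third decimal (or second, for PPV) from some previously published summary
cells (0.720, 0.879, 0.944, 0.85, 0.931, 0.935). Those cells are not
derivable from the per-variant scores under any consistent thresholding we
could find; this package always reports the values recomputed from the
per-variant data. The SVM TPR/TNR/NPV/BACC and PolyPhen-2 TNR/NPV cells
agree exactly at display precision.

## Variant numbering

AAT positions are quoted in mature numbering (secreted protein) unless
stated; precursor numbering includes the 24-residue signal peptide, so
precursor = mature + 24. Conversion is exact and invertible for mature
positions; a precursor position ≤ 24 has no mature equivalent and the
conversion refuses rather than guessing. The signal-peptide length is a
configurable constant (`signal_peptide_len`) so the machinery applies to
other secreted proteins. Stop gains (`Q156X`) parse but are excluded from
classification, which covers missense substitutions only.

## Synthetic data: what it emulates and what it does not

The full-scale inputs of the benchmark builder — an ortholog set from a
database search and a crystal structure — are external, so correctness is
established on synthetic inputs whose right answer is planted:

* **Homolog pairs** (`gen_homolog_pair`): a random query of configurable
  length; planted substitutions whose three filter outcomes are realised by
  construction (a helper substitution at *s*+1 breaks the flank; a subject
  gap at *s*+3 sits inside the gap window but outside the flank window; a
  substitution at the designated 3D contact partner breaks contact
  conservation). The toy structure spaces residues 8 Å apart on a line —
  no incidental contacts — and places each planted substitution's partner
  4 Å away, so every contact is explicit and every non-failing planted
  substitution's conservation check is exercised non-vacuously. Isolated
  background substitutions tune the realised identity to within one
  percentage point of the target (validated at generation; an incompatible
  identity/substitution combination raises rather than silently drifting).
  Defaults (length 120, 95% identity) mirror the close-primate regime the
  real benchmark draws from.
* **Toy structures** (`gen_toy_structure`): single-atom residues at
  controlled distances keep the expected contact map analytic; the
  three-atom mode with bounded jitter exercises the min-over-atom-pairs
  rule. The expected map is computed by direct all-pairs arithmetic from
  the generated coordinates.
* **Score tables** (`gen_score_table`): scores are drawn from ranges that
  straddle the thresholds with a safety margin (deleterious SVM/PolyPhen-2
  in [0.55, 1], ΔΔG in [1.5, 6]; neutral in [0, 0.45] and [−2, 0.5]), so
  the thresholded calls reproduce the planted confusion matrix exactly.

What passing these tests shows: the filters, the contact geometry, the
deduplication logic and the metric arithmetic are implemented correctly.
What it does not show: anything about real evolutionary sequence
divergence (no rate variation, no indel clustering, no realistic gap
patterns), real protein geometry (no packing, no secondary structure), or
realistic predictor score distributions. Claims about predictor accuracy
rest on the packaged labelled benchmark, not on synthetic data. For the
same reason the curated 35-variant primate set is shipped as data rather
than regenerated: regenerating it would require a specific ortholog
database snapshot and search configuration, and the result is
database-version dependent.

## Numerical and engineering choices

* All residue indexing is 1-based, matching biological numbering; alignment
  columns are 0-based internally.
* Rounding is decimal half-away-from-zero (via `decimal`), both for the
  FoldX pre-comparison rounding and for display; binary-float `round()`
  half-even would misclassify boundary values.
* Contact-pair candidates from `scipy.spatial.cKDTree.query_pairs` (which
  is ≤-inclusive) are re-checked with a strict `<` comparison.
* Determinism: all generators take explicit seeds
  (`numpy.random.default_rng`); reports preserve input row order and use
  fixed number formatting, so identical inputs and configuration give
  byte-identical outputs. Packaged tables are SHA-256-verified at load.
* Property sizes in the test suite (100 random homolog specs, 100 random
  toy structures of ≤ 20 residues, 1000 random labelings) were chosen to
  cover the combinatorics of the planted-outcome space many times over
  while keeping the default suite fast.

## Limitations

* The builder evaluates pairwise alignments independently; it does not
  build or use a multiple sequence alignment, and percent identity is
  sensitive to the aligner's gap placement for distant homologs.
* Only single-residue missense substitutions are classified. Splice,
  frameshift and nucleotide-level notations are rejected at parse time by
  design; stop gains parse but carry no scores.
* The consensus vote treats predictors as exchangeable and independent,
  which they are not (PolyPhen-2 and the SVM share conservation signal);
  the category is a communication device, not a calibrated probability.
* With two available predictors and two deleterious votes the label is
  "possibly deleterious" on reduced evidence; the `reduced_evidence` flag
  should accompany any downstream use.
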