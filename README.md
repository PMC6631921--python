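# serpinvar

Consensus pathogenicity assessment for protein missense variants, built
around the rare-variant analysis of alpha-1 antitrypsin (AAT, the *SERPINA1*
gene product). Clinical laboratories sequencing *SERPINA1* in patients with
suspected alpha-1 antitrypsin deficiency routinely find rare or novel
missense variants with no reported phenotype; `serpinvar` implements the
computational side of triaging them.

The package does four things:

1. **Per-predictor calls.** Each variant carries up to three scores: an SVM
   pathogenicity probability *p*<sub>SVM</sub> ∈ [0, 1], a FoldX folding
   free-energy change ΔΔG (kcal/mol, positive = destabilising), and a
   PolyPhen-2 damage probability *p*<sub>PP2</sub> ∈ [0, 1]. A predictor
   votes *deleterious* when *p*<sub>SVM</sub> ≥ 0.5, ΔΔG ≥ 1.0 kcal/mol
   after rounding to the one-decimal reporting precision (equivalently
   ΔΔG ≥ 0.95), or *p*<sub>PP2</sub> ≥ 0.5.
2. **Consensus category.** With *d* deleterious votes among the available
   predictors: *d* = 3 → probably deleterious, 2 → possibly deleterious,
   1 → possibly neutral, 0 → probably neutral. A missing score (e.g. no ΔΔG
   for a residue absent from the structure) shrinks the denominator rather
   than counting as a neutral vote.
3. **Ortholog neutral benchmarks.** Substitutions observed in close
   orthologs (> 90% pairwise identity) are collected as presumed-neutral
   variants, keeping only those flanked by ±2 conserved alignment columns,
   at least 3 columns from any gap, and whose 3D contact residues (any atom
   pair < 5 Å in a reference structure) are all conserved; each distinct
   substitution is taken from its closest ortholog.
4. **Benchmark statistics.** TPR = TP/(TP+FN), TNR = TN/(TN+FP),
   PPV = TP/(TP+FP), NPV = TN/(TN+FN), ACC = (TP+TN)/(P+N),
   BACC = (TPR+TNR)/2, computed per predictor from a labelled score table.

Two curated score tables ship with the package: the 16 rare/novel *SERPINA1*
missense variants with their predictor scores (`table2`), and a 57-variant
labelled benchmark — 17 ClinVar-pathogenic, 5 ClinVar-benign, and 35
primate-ortholog neutral variants (`table3`). Variant positions use mature
AAT numbering (precursor numbering, which includes the 24-residue signal
peptide, is converted with `convert_numbering`).

## Worked example

Classify the packaged 16-variant table:

```sh
$ serpinvar classify --scores table2 --log-level WARNING
probably_deleterious	8
possibly_deleterious	2
possibly_neutral	4
probably_neutral	2
```

Eight variants (P289S, I50N, D341V, M221T, V210E, P28L, P369H, A142D) get
three deleterious votes, two (M385T, V333M) get two, four (I9N, Q40R, K174E,
H262Y) one, and two (E204K, A325P) none. Note D341V: its ΔΔG of 0.99
kcal/mol rounds to 1.0 at the reported precision and therefore votes
deleterious; and I9N, which lies in the cleaved signal peptide and has no
structural coordinates, is categorised from the two available scores.

Benchmark the three predictors on the labelled 57-variant table
(columns are TPR, TNR, PPV, NPV, ACC, BACC):

```sh
$ serpinvar benchmark-score --scores table3 --log-level WARNING
svm	1.000	0.825	0.708	1.000	0.877	0.913
foldx	0.882	0.775	0.625	0.939	0.807	0.829
polyphen2	0.941	0.925	0.842	0.974	0.930	0.933
```

The SVM calls all 17 pathogenic variants deleterious (TPR 1.000, NPV 1.000)
and 33 of the 40 benign/neutral variants benign (TNR 0.825), for a balanced
accuracy of 0.913; 28/35 of the primate neutral set is called benign. The
JSON report written with `--out` additionally summarises raw ΔΔG signs per
subset: 16/17 pathogenic variants have ΔΔG > 0 (destabilising) and 4/5
ClinVar-benign variants have ΔΔG < 0.

From Python:

```python
import serpinvar as sv

rows = sv.load_table2()
result = sv.classify_table([(r.variant, r.scores) for r in rows])
print({k.value: v for k, v in result.summary.items()})
# {'probably_deleterious': 8, 'possibly_deleterious': 2,
#  'possibly_neutral': 4, 'probably_neutral': 2}
```

Building a neutral benchmark from your own homologs:

```sh
serpinvar benchmark-build --query query.fa --homologs orthologs.fa \
    --structure reference.pdb --out out/
```

Unaligned homologs are aligned internally (global, BLOSUM62, affine gaps);
pass `--aligned` if the FASTA already holds pairwise rows aligned to a
gapped query record. `serpinvar simulate --seed N --out DIR` writes
synthetic fixtures (alignment, structure, score table) together with their
ground truth, byte-identical for a given seed.

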