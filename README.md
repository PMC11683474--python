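# pepatlas

Analysis toolkit for endogenous-peptide tissue atlases, built around the
maize (B73) setting: thousands of naturally occurring 2–100 aa peptides
identified by mass spectrometry across 13 tissues spanning the vegetative
and reproductive phases.

Given canonical CDS sequences (FASTA + GFF3), a nonredundant peptide table
with per-tissue label-free abundances (TSV), and a matched protein
abundance matrix, the package answers the questions such an atlas raises:

* **Peptidogenomics** — where does each peptide come from?  Each peptide is
  matched exactly against the three forward-frame translations of every
  canonical CDS (Aho–Corasick multi-pattern search, linear in total
  proteome length).  A frame-0 match makes a peptide *in-frame*, otherwise
  *out-of-frame*; matches are lifted through the spliced CDS segments to
  genomic coordinates (BED12 blocks), and the CDS codon covering the first
  residue gives the AUG / non-AUG start-codon class.
* **Tissue specificity** — each abundance row is classified as
  tissue-specific (single-tissue detection, or top ≥ 5× second),
  tissue-enhanced (top ≥ 5× mean of the other detected tissues) or mixed;
  the rules are monotone and scale-invariant.
* **Genomic landscape** — per-chromosome shares, fixed-width window
  densities with peptide-rich-region calls (count ≥ mean + 2 sd over all
  windows genome-wide), adjacent-peptide distances, distance to the
  canonical translation start, and telomere-proximity fractions.
* **Family enrichment** — exact hypergeometric upper-tail tests of, e.g.,
  TF-family-derived peptides per tissue, Benjamini–Hochberg corrected
  across the whole family × tissue grid, plus clustered row-normalized
  family profiles.
* **Coexpression modules** — a weighted network a\_ij = |cor(x\_i, x\_j)|^β
  on log2 abundances, with β chosen for scale-free topology fit (R² > 0.80,
  mean connectivity < 100), topological-overlap clustering with a
  deterministic static tree cut, module eigengenes (first principal
  components), and eigengene–tissue correlation.
* **Peptide–protein correlation** — tissue-wise Spearman ρ and per-pair
  Pearson r between peptides and their source (or nearest neighboring)
  proteins, a Wilcoxon signed-rank comparison against a shuffled pairing,
  extraction of strongly coexpressed pairs (r > 0.70) with set enrichment,
  and correlation decay in 50-kb genomic-distance bins.

Because real atlas data cannot ship with the package, `pepatlas.synthetic`
generates a miniature maize-like dataset with *planted ground truth* —
frame classes, specificity labels, module memberships, pair correlations,
and terminal gene-density excess — so every stage is tested against known
answers.

## Worked example

```sh
python examples/03_tissue_specificity.py
```

```
category counts: {'tissue_enhanced': 710, 'tissue_specific': 692, 'mixed': 598}
planted-label recovery: 98.45% (>=95% expected at the default 8x effect size and 0.2 log-noise)
tissue with most specific peptides: EP (72 peptides; 1562 identified there in total)
```

The classifier recovers 98.45% of the labels the generator planted; the
remaining ~1.5% are rows whose multiplicative noise pushed them across a
fold threshold.  The other scripts in `examples/` walk through simulation,
peptidogenomic mapping, the genomic landscape, module detection (adjusted
Rand index 1.000 against the planted 6-module truth at seed 1) and
peptide–protein correlation, each printing the quantities it computes.

The same pipeline is available from the shell:

```sh
pepatlas simulate --seed 1 --outdir atlas/
pepatlas all --indir atlas/ --outdir results/
```

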