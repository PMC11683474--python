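# Methods

## Peptidogenomic mapping

Peptides are matched against the three forward-frame translations of each
canonical CDS only — not a whole-genome six-frame translation — because
endogenous peptides in this setting derive from annotated coding space.
Translation uses the standard codon table; stop codons become `*`, any
codon containing `N` becomes `X` (even when the ambiguity could be
resolved), and trailing 1–2 nt of a frame are dropped.  Matching is exact
substring search with an Aho–Corasick automaton, so the cost is one pass
over each frame string regardless of peptide count; peptide sequences are
pure amino-acid strings, so a match can never span a stop or ambiguous
position.  Isoleucine and leucine are treated as distinct residues: the
input peptide table lists literal sequences, and conflating I/L is left to
the caller's preprocessing if their identifications warrant it.

A peptide with any frame-0 match is **in-frame**; in-frame takes priority
over alternative-frame matches.  Peptides matching several genes keep all
matches, but counting and coordinates use a deterministic **primary
gene**: the lexicographically smallest gene id within the winning frame
class, and the smallest amino-acid offset within that gene.  This
convention (recorded in output metadata) makes unique-gene counts
reproducible; other tie rules would change those counts slightly.

Coordinates are 0-based half-open internally, 1-based inclusive at GFF3
boundaries, BED for exports.  An amino-acid offset maps to a spliced-CDS
nucleotide interval (`frame + 3*offset`, length `3*peptide length`) and
then through the CDS segments to genomic blocks, reversing orientation on
the minus strand; block lengths always sum to three times the peptide
length.  The canonical translation start site is the first base of the
first codon (the 3′-most genomic coordinate for minus-strand genes), and
TSS distance is measured from the peptide's 5′-most mapped base.

Molecular weights use **average** residue masses (a fixed, documented
table) plus one water, 18.0153 Da — the convention of label-free atlas
reporting; monoisotopic masses would run ~0.06% lower.

## Tissue-specificity classification

With `x` a peptide's abundance row (0 = not detected):

* *tissue_specific*: detected in exactly one tissue, or
  `max(x) >= fold_specific * second_max(x)`;
* *tissue_enhanced*: `max(x) >= fold_enhanced * mean(other detected)`;
* *mixed*: everything else; all-zero rows get an `undetected` sentinel.

Both folds default to 5 and are configurable.  The rules are deliberately
monotone (raising `fold_specific` can only shrink the specific class) and
scale-invariant (categories ignore the absolute intensity scale, which the
upstream normalization does not fix).  Phase trajectories divide each row
by its maximum before averaging, so every detected row peaks at exactly 1.

## Genomic landscape

Windows tile each chromosome half-open; a peptide belongs to the window
containing its interval start (unambiguous for boundary-straddling
peptides), and the last partial window is kept.  **Peptide-rich regions**
are windows with count ≥ mean + 2 sd, where mean and sd are computed over
all windows genome-wide; adjacent rich windows merge.  This z-threshold is
this package's definition — parameter-light and scale-free — and both the
window size (default 6 Mb, matched to full-size maize chromosomes; 500 kb
suits the miniature synthetic genome) and the z cutoff are configurable.
"Near the telomeres" means the terminal 10% of either chromosome end,
also configurable.  Zero-variance tracks yield no calls, with a warning.

## Family enrichment

One hypergeometric upper-tail test per (family, tissue) cell, with the
universe restricted to annotated peptides (configurable to the whole
atlas), and a single Benjamini–Hochberg pass across the entire grid; the
correction scope matters when families are few, and one global pass is the
conservative choice.  Family profiles sum member abundances per tissue,
normalize rows by their maxima, and order rows by average-linkage
clustering of Euclidean distances.

## Coexpression network

Rows detected in ≥ 6 of 13 tissues enter the network on the log2(x+1)
scale; this detection filter stands in for whatever filter reduces a full
atlas to its broadly quantified core, and is configurable.  The network is
**unsigned**, `a_ij = |r_ij|^beta` with Pearson r.  The soft power is the
smallest candidate in 1..20 whose scale-free topology fit R² exceeds 0.80
with mean connectivity below 100; R² is the squared correlation of
log10 p(k) against log10 k over 10 equal-count connectivity bins, zeroed
for positive slopes.  When no candidate qualifies — typical for strongly
modular planted data, whose degree distribution is not scale-free — the
best-fit power is used and the result flagged.

Topological overlap is the standard
`w_ij = (L_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)`; modules come from
average-linkage clustering of `1 - w` with a **static tree cut**: the cut
height (among the merge heights) is chosen to maximize the number of
clusters ≥ `min_module_size` (default 30), ties resolved by the fewest
leftover nodes and then the lower height.  Sub-threshold clusters become
"grey".  The static cut replaces the dynamic hybrid tree cut of the
canonical WGCNA workflow: it is fully deterministic and recovers planted
block structure exactly, but it will not reproduce the finer module splits
the dynamic cut finds on real data.  Module labels follow the
conventional color order by descending size, ties broken by smallest
member id.  Eigengenes are first principal components of row-standardized
member submatrices, unit-norm and sign-oriented to correlate positively
with the module mean profile.

## Peptide-protein correlation

All correlations run on log2(x+1) abundances with zeros retained — a
non-detection is informative in label-free data, and dropping it would
bias pair correlations upward.  Per-pair Pearson requires ≥ 3 detected
tissues in both profiles; excluded pairs are counted and logged so that
excluded + reported always equals the total.  Membership in the
high-correlation set uses strict `r > 0.70`.  The Wilcoxon signed-rank
comparison is defined here as: per-pair r of true peptide–protein pairs
versus the r of a shuffled partner assignment, paired by peptide — a
convention this package fixes because "true versus background pairing" can
be formalized several ways.  The signed-rank null is enumerated exactly
(dynamic programming over sign patterns, average ranks doubled to stay
integral under ties) up to 25 nonzero differences, and approximated by a
continuity-corrected normal with tie correction beyond.  Distance decay
uses half-open 50-kb bins over 0–200 kb plus a final open bin.

## Synthetic data generator

The generator emulates the study conditions: a 10 × 5 Mb genome, 400
spliced gene models (1–5 CDS segments, both strands, back-translated from
stop-free random proteins that start with M), 2000 nonredundant peptides
(91% in-frame, ~94% shorter than 23 aa, lengths 8–60 aa — MS rarely
identifies shorter peptides, and longer minimum lengths also make chance
frame-0 matches of planted out-of-frame peptides negligible), 13 tissues
with the maize panel names, and a 0.35/0.35/0.30 specific/enhanced/mixed
mix.  A 2.43% fraction of peptides is planted at protein N-termini so the
AUG start-codon share is controlled; note that *any* peptide whose first
residue is M has an ATG start codon, so the measured AUG share is the
methionine-start share, with the planted N-terminal peptides as a floor.

Abundances are log-normal (natural-log base N(10, 1), multiplicative
noise sd 0.2) with zero meaning not detected:

* **specific** rows: top tissue at 8× base; each other tissue detected
  with probability 0.3 at 1/(2·8) of the top value (an infinite effect
  fold collapses to single-tissue detection);
* **enhanced** rows: one secondary tissue at 4× baseline and the top
  tissue at 8× the mean of the others, everything detected — the planted
  pattern clears both classifier inequalities with ~ln 2 log-margin on
  each side;
* **mixed** rows: baseline everywhere plus a module latent profile
  (orthonormalized random tissue programs, amplitude 0.5 in log space)
  and a chromosome-wise Ornstein–Uhlenbeck tissue-profile field
  (amplitude 0.3, correlation length 100 kb) that makes neighboring
  peptides' profiles decay in similarity with genomic distance.

Gene starts fall in the terminal 10% of each chromosome end with 2× the
interior density, planting the telomere-proximity and rich-region
signals.  The protein matrix has one row per gene; for each gene one
fully detected peptide is designated and its protein profile is mixed as
`z = r·x̃ + sqrt(1-r²)·e` from the standardized peptide profile, hitting
the planted Pearson r in expectation (default levels −0.2, 0, 0.2, 0.45,
0.7 cycled across genes).

Three reduced presets fix the problem sizes of the recovery benchmarks:
`module_benchmark_config` (1 Mb chromosomes, 800 peptides, spatial
amplitude 0.15) for seed-averaged module ARI; `decay_benchmark_config`
(600 all-mixed peptides, spatial amplitude 0.55, no module structure),
which isolates the planted distance-decay mechanism — in the default mix
the decay signal is diluted by specific/enhanced pairs whose correlation
is distance-independent; and `pair_benchmark_config` (700 genes, one
planted correlation level) so that ≥ 500 planted pairs are measurable.

**What passing these tests does and does not show.**  The generator
plants clean, margin-separated structure: real label-free data have
missing-value mechanisms, batch effects, correlated noise and overlapping
expression programs that it deliberately omits (simulating mass spectra
and chimeric identifications is out of scope).  Recovery of planted truth
therefore validates the *implementations* — the classifiers recover what
their defining inequalities plant, the network code recovers planted
blocks — not the biological fidelity of any particular threshold on real
atlases.  Quantities that depend on the real data and unpublished
parameter choices (exact module counts, per-tissue category ranges,
rich-region counts) are qualitative context only.

## Numerical choices and degenerate inputs

Constant rows are removed (with a warning) before correlation; an
all-constant matrix is an error.  Correlations are clipped to [−1, 1]
before powering; TOM entries are clipped to [0, 1] and NaNs from isolated
nodes set to 0.  Rich-region statistics accumulate counts in canonical
chromosome order so calls are bit-identical under input reordering.  Ties
in argmax (specificity top tissue) take the first tissue in panel order;
neighbor-gene ties take the smaller gene id.  All generator randomness
derives from one seed through fixed per-stage streams, so identical
configurations give byte-identical outputs; no stage reads the clock or
filesystem order.
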