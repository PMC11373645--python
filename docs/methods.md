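# Methods

This note documents the models, conventions and numerical choices behind
`spokenpheno`, and what the synthetic study does and does not establish.

## Transcript model and parsing

One observation per line, `"<name>, <row>. <text>"`. The row number strips
`,` and `_` separators (transcriptions render "1,641"). Parsing is strict by
default (errors carry the file line number); a skip-and-count mode exists
for noisy archives. Duplicate observations for the same row and participant
are kept — repeated passes over the field are real data, and the adjusted-
means models are what averages them.

Synonym detection for positive-control rows counts an observation as a hit
if it contains at least one synonym, matched case-insensitively as whole
words on Unicode `\w+` token boundaries; multiword synonyms must appear as
contiguous token runs. No stemming or spelling correction is applied: the
whole-word rule is the simplest auditable choice, and morphology-aware
matching would only raise proportions (the statistic is monotone in the
synonym set).

## Semantic similarity

`similarity(text, query)` is the cosine of the two embeddings, clipped to
[0, 1] (a negative cosine reports 0 — scores are defined on [0, 1] and
clipping is the minimal map). The embedding backend is a contract
(`embed(text) -> fixed-length vector`, deterministic); the shipped default
is a hashed bag-of-words vectorizer (scikit-learn `HashingVectorizer`,
2^18 features, no sign alternation, lowercase `\w+` tokens). Scores are
scale-invariant in the backend. A pretrained sentence encoder can be plugged
in through the same contract; nothing downstream changes.

Bag-of-words similarity is coarse: it sees token overlap, not meaning, so
"very tall plants" can score *below* a bare "tall" against the query "tall"
(extra tokens dilute the cosine), and negation is invisible. The default
lexicon wording was chosen once so the tall-token gradient is broadly
monotone over bins 5–7 under this backend; with a true sentence encoder the
ordering would be smoother. Downstream analyses use the "tall" query column;
"tall plant" and "tall height" are computed alongside for inspection.

## Phrase binning

The lexicon maps curated phrases to ordinal bins 0–7 (0: no growth,
1: very short, 2: short, 3: short–medium, 4: medium, 5: medium–tall,
6: tall, 7: very tall plants). Phrases are token-normalized (lowercase,
`\w+`), so hyphenation and case never matter. All phrases occurring in an
observation as contiguous token runs are collected; the assignment is the
bin of the longest match (token count), with ties resolved by the mean of
the tied bins rounded half away from zero. Longest-match-first encodes that
a more specific phrase ("very tall") overrides its substring ("tall"). The
shipped lexicon is a TSV config, not a constant — a real campaign would
curate hundreds of phrases; the default covers the eight bin semantics plus
common modifiers.

## Adjusted means

* **BLUE** — ordinary least squares of `value ~ taxon + replicate`
  (treatment coding); the per-taxon value is the estimated marginal mean:
  taxon effect plus the unweighted average of replicate effects, invariant
  to coding. On a balanced complete design this equals the raw taxon mean.
  A design where taxon aliases replicate (not connected) is rejected with
  the confounded factors named.
* **BLUP** — REML for `value = μ + taxon + replicate + row + ε` with all
  three factors random and crossed. The solver works on Henderson's
  mixed-model equations with the residual variance profiled out: with
  variance ratios γ_f = σ²_f/σ²_e and MME matrix M,
  `−2 lR = (n−1)·log(y'Py) + log|M| + Σ_f q_f log γ_f + const`,
  optimized by Nelder–Mead on log γ (bounds e^±12, tolerance 1e-8,
  iteration cap 200 per dimension; non-convergence raises with the last
  components attached). This is dramatically faster than a generic
  mixed-model fitter at field-trial size (one dense Cholesky of a
  ~1200-dim matrix per evaluation) and allows fixing ratios, which the
  closed-form shrinkage tests use. statsmodels' MixedLM serves as the
  independent cross-check in the test suite, not as the implementation.
  The per-taxon phenotype is the grand mean plus the taxon BLUP
  (conditional mode) — the standard reading of "BLUP-corrected means";
  deviations therefore shrink toward zero relative to raw means whenever
  residual variance is positive.
* **Multinomial expected bin** — multinomial logit of the bin on taxon and
  replicate (one-hot design, L2 ridge 1e-4 on coefficients — with one
  parameter per taxon the unpenalized MLE separates), predictions averaged
  over replicate levels, collapsed to `Σ_b b·P̂(b|taxon)` ∈ [0, 7]. The
  scan needs a scalar per taxon; the expected bin is the natural one, and a
  modal-class mode is available behind a flag. A single observed bin is a
  degenerate fit and returns that bin for every taxon with a warning.

## Association scan

Population structure: top-k (default 3) principal components of the dosage
matrix, missing dosages imputed to the marker mean, markers centered at 2p̂
and scaled by √(2p̂(1−p̂)); component signs are fixed (largest-magnitude
loading positive) so scores are deterministic.

The scan fits `value = μ + PCs + β·dosage` per marker by OLS and tests β
with a two-sided t-test. Implementation residualizes y and each dosage on
an orthonormal basis of the covariate column space (SVD-based, so redundant
covariate columns are harmless) — algebraically identical to the full
regression, verified against statsmodels OLS to 1e-8 relative. Missing
dosages are handled by case-wise deletion per marker; markers monomorphic
among analyzed taxa or missing in >50% of them are flagged `skipped`, never
given p-values. p-values are floored at 1e-300. The Bonferroni line is
`−log10(α/m)` with m the count of markers actually tested; when chromosomes
are scanned individually the pipeline recomputes one genome-wide line from
the summed tested count, so the per-chromosome route and the single-pass
route flag the same markers.

This scan is a deliberate substitute for FarmCPU/MLM multi-locus machinery:
the package's contribution is the phenotype derivation, and a transparent
single-marker model keeps the scan auditable against a brute-force oracle.
Kinship-based mixed models would lower the false-positive rate in strongly
structured panels; that is a known limitation.

LD decay: r² is the squared Pearson correlation of dosage vectors
(pairwise-complete) for same-chromosome pairs within 1 Mb, averaged in
50 kb distance bins. The candidate-window halfwidth is the smallest bin
midpoint with mean r² < 0.2, rounded up to 50 kb, with a ±300 kb fallback
when the curve never crosses; the pipeline's default window is ±300 kb.

## Candidate regions and annotation

Coordinates are 1-based inclusive (GFF3); windows clip at position 1. A gene
belongs to a region iff its span intersects the ±window by ≥1 bp. Regions
are never merged — each significant marker keeps its own row, and overlap
is handled at comparison time (two regions are "shared" iff same chromosome
and overlapping windows; "same marker" iff identical position; reciprocal-
overlap fractions are not required). Literature flags match on gene-model
IDs only; symbol-level matching is out of scope. Hormone-keyword GO counts
are distinct (gene, GO term) pairs whose term name contains the keyword as
a case-insensitive substring — the counting unit is recorded here because
"appearances" could also mean distinct terms or distinct genes; pairs are
the only choice that is additive over disjoint region sets. GO IDs with no
known term name count as unannotated; no GO-graph ancestor propagation is
performed.

## Synthetic study

The generator emulates the statistical structure of the motivating field
campaign: ~650 taxa in 2 replicates of 720 rows (31 seed-increase rows, 8
experimental-control rows, 25 positive-control rows, 655 panel rows, 1
duplicated panel row), three observation passes per row, and a height
phrase present in roughly 90% of observations (`omit_prob = 0.1`).

* **Genotypes** — evenly spaced biallelic markers; each chromosome is
  partitioned into blocks of `ld_block_len_bp` (default 750 kb); within a
  block all markers share an allele frequency drawn from `maf_range`
  (default 0.1–0.5) and haplotypes follow a two-state Markov chain with
  adjacent-marker correlation exp(−2d/L), giving r² ≈ exp(−4d/L) — the
  curve crosses 0.2 near 300 kb at the default L, which is what motivates
  the ±300 kb window. Blocks are independent; `ld_block_len_bp = 0` gives
  independent markers. A coalescent simulator would give richer haplotype
  structure; block-copy-with-switch is sufficient to produce an r²–distance
  curve for window selection.
* **Trait** — causal markers are sampled among markers with realized
  MAF ≥ 0.2, with equal-magnitude, alternating-sign effects: standard
  power-study practice, so per-locus explained variance is not dominated by
  the allele-frequency lottery. Genetic values are rescaled so the realized
  ratio Var(g)/(Var(g)+σ²_rep+σ²_row+σ²_e) equals h² exactly, and the
  replicate and row effect draws are likewise rescaled to their target
  ddof=1 sample variance. The ddof=1 convention is deliberate: REML
  estimates a component from its q realized effects with q−1 degrees of
  freedom, so this is the convention under which recovery is centered on
  the target even at q = 2 replicates — without it, the replicate component
  is a 1-df draw and no recovery tolerance short of ~2× would be honest.
  Residuals stay pure Gaussian draws (their df is large).
* **Transcripts** — each pass's standardized phenotype z maps to a bin by
  `clamp(round(3.5 + 1.5z), 0, 7)` (the 8-bin scale centered on the trait
  mean; the link between spoken bins and true height is the simulator's
  own convention), a phrase is drawn uniformly from that bin, omitted with
  probability `omit_prob`, and one or two height-unrelated noise sentences
  are appended. Participants are exchangeable — no participant-specific
  vocabulary; real observers differ in wording and diligence, which this
  does not emulate.
* **Annotation stand-ins** — gene models tile the chromosomes (4 kb genes
  every 40 kb), GO assignments are drawn from a small synthetic vocabulary
  containing the hormone terms, and the literature list contains genes
  within 50 kb of causal loci plus random decoys. These are synthetic
  stand-ins for a genome annotation, a GO release, and a curated gene
  list; they exercise the region/annotation code paths, not biology.

All randomness flows from one seed through per-operation child streams;
identical configs give bit-identical outputs.

**What passing tests show** — that the pipeline's statistics are computed
correctly (against closed forms and independent oracles) and that, under an
additive trait faithfully described in a controlled vocabulary, the chain
from text to GWAS recovers the simulated loci. They do not show that real
spoken descriptions carry as much signal: real transcripts have speech-
recognition errors, idiosyncratic vocabulary, non-additive traits, and
population structure correlated with the trait, none of which the generator
reproduces.

## Problem sizes

Default analysis scale (drivers and end-to-end tests): 400 taxa, 2,000
markers on 2 chromosomes of 50 Mb, 5 causal loci, h² = 0.6, variance
components σ²_rep/σ²_row/σ²_e = 1/0.5/1, 2,400 spoken observations. These
sizes give the REML and scan enough data for tight recovery while keeping a
full run in seconds; the marker count stands in for the tens of millions in
a real panel, which is why the Bonferroni utility takes the tested-marker
count as an input rather than assuming a panel size.
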