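# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the decisions taken where more than one reasonable convention
exists.

## Differential proteomics

Abundances are handled on the log2 scale throughout, so a fold-change is
an arithmetic mean difference. Each knockdown condition is compared only
against the non-targeting controls carried in its own multiplexed (TMT)
set; cross-set comparisons are never formed at this stage, which is what
makes the later batch-aware z-scoring necessary and sufficient.

The protein-level test is a two-sided two-sample *t* test with pooled
variance (Student). Pooled rather than Welch is the textbook default for
an unqualified "unpaired two-tailed t test"; the choice is recorded in the
output metadata (`test` attribute) and switchable (`equal_var=False`).
Conventions for degenerate inputs keep null simulations total rather than
erroring: proteins with fewer than two quantified replicates in either
group are reported as missing (NaN, never silently zero), and zero pooled
variance yields p = 1 when the means agree (an information-free
comparison) or p at the floating-point floor when they differ. Reported
p-values are clipped to (0, 1].

RNA-level testing uses Kruskal–Wallis (tie-corrected H, chi-squared
reference) plus Dunn's pairwise z with tie-corrected variance on
log2(TPM+1). With two groups Kruskal–Wallis is equivalent to a Wilcoxon
rank-sum; both the Kruskal–Wallis and the Dunn p are reported and either
can populate the decision column (`p_from`, default Dunn). Per-gene p
values are reported raw; study-wide FDR, where wanted, is applied
separately (Benjamini–Hochberg is available in `overrepresentation` and
`statsmodels` directly). All-tied input returns H = 0, p = 1.

**Transcription independence.** A significant protein change (default
alpha = 0.05, |Log2FC| > 0.2; both thresholds recorded verbatim in the
output) is transcription-independent unless the mapped gene is significant
at the same alpha with |log2fc| above the same threshold *and* the same
sign. The same-sign requirement mirrors the protein-side thresholds
symmetrically; an opposite-sign mRNA change cannot "explain" a protein
change. Proteins with no mapped gene keep their protein-level call and
are counted (`n_unmapped`) rather than dropped — dropping them would
silently bias the screen toward well-annotated proteins.

Regulator counts bin proteins by how many conditions modulate them
(1, 2–4, 5–9, ≥10); proteins never called are excluded from the binned
output. Over-representation of gene sets among hits uses the upper-tail
hypergeometric probability with BH correction across sets, each set being
intersected with the detection universe first.

## IP-MS interaction scoring

Spectral counts are normalised to counts per residue and rescaled to the
median prey length, so preys of different size are compared on a common
count scale while the Poisson machinery still sees count-like magnitudes.
The enrichment probability of a prey for a bait is a Poisson mid-p: with
the control rate λ (mean rescaled control count, floored at
`pseudo_rate = 0.1` so preys never seen in controls are still scorable)
and rescaled bait replicate count k, each replicate contributes
P(X < k) + ½P(X = k), averaged over replicates. The mid-p construction
puts a never-detected prey at ≈ 0.5 rather than ≈ 1, is monotone
non-decreasing in every bait count, and is invariant to replicate order.
This scorer is a deliberately simple, fully reproducible probability
model; where externally computed interaction probabilities exist (e.g.
SAINT output shipped with a deposited dataset), they take precedence via
the `external_scores` column mechanism, and the per-row `score_source`
records which path produced each number.

Filtering keeps pairs with probability ≥ 0.65 (inclusive boundary), and
optionally requires a contaminant frequency ≤ a cutoff (frequency table
supplied by the user, CRAPome-style — no remote lookups, so runs are
deterministic and offline) and a *strictly* greater maximum bait spectral
count than the maximum control count ("consistently higher" reads as
strict; ties are rejected). The bait's own protein is always scored in
its own pull-down — even when undetected — so the self-enrichment check
can flag degraded baits with a concrete low score instead of a missing
row. Networks are directed bait → prey graphs (networkx) with a
functional role per node; endpoints missing from the role table default
to "other" with a logged warning.

## Pairwise similarity

The regulated-protein selection is the union over all conditions of
proteins significantly modulated by at least one knockdown at the calling
thresholds. R² is the squared Pearson correlation — identical to
simple-regression R² — computed pairwise-complete over the selection. The
per-pair count n ("regulated proteins detected in that pairwise
comparison") defaults to proteins quantified in both conditions and
regulated by at least one *of the two* ("either"); the broader union and
stricter intersection readings are selectable (`pair_universe`). The
similarity score is S = R² × n, monotone in both factors.

z-scoring groups: each TMT set's internal pairs form one group; all
cross-set pairs pool into a single extra-batch group. z = (S − group
mean) / group sample SD (ddof = 1), so each group standardises exactly to
mean 0, SD 1. Groups with fewer than two values or zero SD return NaN —
missing, never zero. Self-comparisons (the diagonal) are excluded from
every group.

Interactome similarity applies the same R² to enrichment-probability
vectors over the prey union, with unscored preys entering as 0. With a
universe of fewer than three preys the two-point degeneracy (R² = 1 for
any two distinct points) applies; callers should treat such pairs as
uninformative.

Sequence identity comes from a global Needleman–Wunsch alignment with
match +1, mismatch 0, linear gap −1 (configurable), identity =
matches / alignment length × 100. Plain NW has score ties whose
alignments differ in match count, which would make "identity" an artefact
of traceback order; the DP here optimises (score, matches, diagonal
steps) lexicographically, making identity a well-defined function of the
two sequences. The test suite checks this against an independent
recursive implementation of the same objective and verifies the score
level against Biopython's `PairwiseAligner`.

Layers (proteome z, interactome z, identity) are compared pairwise by
Spearman rank correlation, excluding missing entries; a constant layer
yields NaN, not zero.

## Peroxisomal panel

Panel subsetting restricts a differential table to an annotated
peroxisomal proteome (user-supplied TSV; a peroxin flag marks PEX
biogenesis/import factors) and reports the detected count. Cumulative PEX
Log2FC per condition sums *signed* fold-changes over PEX proteins with
significant transcription-independent calls — ups and downs can cancel,
matching a net-change reading; separate up/down sums and an
all-changes variant (no significance gate) are exposed by flags, since
the net-of-significant-calls definition is a choice, not a necessity.

## Import imaging

Segmentation is a deterministic classical chain: Gaussian smoothing
(sigma 2 px for nuclei, 1 px for puncta), thresholding (Otsu by default;
absolute thresholds for rendered fixtures, where Otsu's bimodality
assumption is unnecessary), 8-connected component labelling, minimum-area
filtering (defaults: 50 px nuclei, 3 px puncta), consecutive relabelling.
Coordinates are 0-based (row, col); areas are pixels internally and µm²
on export. The study this pipeline is modelled on used trained ML
segmenters (StarDist, ilastik); the defined computation downstream — the
overlap classification — is segmenter-agnostic, and externally produced
integer label maps can be fed directly into `classify_peroxisomes` (TIFF
import in the CLI) in place of the built-in operators.

Only PMP70 puncta define peroxisomes. Each PMP70 punctum's overlap
fraction is the fraction of its pixels covered by any PTS1 punctum;
functional iff overlap ≥ 0.1 (default). The fraction-based rule is robust
to single-pixel coincidences; an effectively any-overlap rule is
available by setting the threshold just above zero. PTS1-only puncta
never create calls. Conservation (functional + ghost = total PMP70
puncta) holds by construction. The functional fraction carries a Wilson
95% interval; peroxisomes per cell is total PMP70 puncta divided by
nuclei.

## Synthetic-data generators

The generators emulate the screen designs the pipeline targets, with
defaults fixed at those conditions:

- **TMT**: 16-plex-style sets, 3 knockdown replicates per condition and 4
  in-set controls; per-(batch, protein) offsets drawn once from N(0,
  0.5²) create the intra-/extra-batch structure the z-scoring absorbs;
  replicate noise N(0, 0.3²) log2 units, typical of deep TMT
  quantification after normalisation. Sample value = baseline + batch
  offset + effect + noise, so at zero noise the knockdown-minus-control
  mean difference equals the true effect exactly.
- **Shared targets**: designated condition pairs draw a configurable
  fraction (0.5 in the discrimination benchmarks) of their regulated
  proteins, same sign and magnitude, from reserved disjoint pools;
  private targets are sampled freely and may overlap by chance, as in a
  real screen. This is the minimal mechanism producing graded pairwise R².
- **RNA-seq**: log-normal baseline expression, each protein effect
  mirrored by its gene with probability `mrna_concordance`, multiplicative
  log-normal noise, columns normalised to exactly 10⁶ (TPM). The
  realised mirrored-effect map is returned alongside the matrix so tests
  can score transcription-independence calls against truth. Column
  renormalisation shifts all log fold-changes by a small common offset
  that vanishes as the regulated fraction shrinks.
- **IP-MS**: Poisson counts; true edges at their mean rate only in their
  bait's runs, contaminants in every run, the bait protein itself at a
  high rate (default 50) in its own runs; 3 bait replicates and 10
  controls by default.
- **Imaging**: puncta are isotropic Gaussian spots truncated at 4σ
  (closed-form centroids for oracle tests), nuclei are filled discs;
  noise is background + Gaussian read noise + optional Poisson shot
  noise. `random_scene` enforces a minimum spot separation (12 px
  default) and border margin so zero-noise rendering is exactly
  segmentable — deliberately: exactness tests need scenes where the true
  counts are unambiguous.

Every generator is byte-deterministic given its seed.

**What the generators do not emulate** — and hence what passing tests do
not establish about real data: isobaric ratio compression and reporter-ion
interference, missing-value structure correlated with abundance,
peptide-to-protein roll-up, library-size and gene-length biases in
RNA-seq, correlated contaminant structure across IP-MS runs, realistic
optics (PSF tails, uneven illumination, out-of-focus light) or touching/
overlapping organelles. Results on real data depend on upstream
processing handling those effects.

## Benchmark problem sizes

The shipped checks use: 10⁴ proteins × 10 simulated screens for the null
type-I benchmark; 6 sets × 3 conditions × 400 proteins × 100 screens for
similarity discrimination; 100 rendered 256×256 fields (30 puncta, noise
SD 10% of amplitude) for imaging recovery; 5 baits × 60 preys × 50
simulated experiments for IP-MS recovery; 100 randomised small instances
per statistic for oracle agreement. These sizes make each benchmark's
Monte-Carlo error small relative to its acceptance margin while keeping a
full run in the low minutes on one core.

## Known limitations

- The Poisson mid-p scorer ignores count overdispersion between
  replicates; real IP-MS counts are noisier, and the 0.65 threshold's
  operating point on real data differs from the simulated one.
- Dunn's z uses the normal approximation; at 3 vs 4 replicates the
  discreteness of ranks makes attainable p-values coarse.
- R² on probability vectors treats unscored preys as hard zeros, which
  overweights detection overlap relative to score agreement for sparse
  interactomes.
- The classical segmenters assume roughly uniform background; they are a
  seam for external label maps, not a replacement for trained models on
  real micrographs.
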