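# Methods

This note documents the models and conventions the package implements,
the defaults and why, what the synthetic generator does and does not
emulate, and the known limitations.

## Coordinates and formats

Everything internal is 0-based, half-open, stranded (BED). Genome-browser
literals `chrN:A..B,strand` are 1-based inclusive and converted on
parsing (`start = A−1, end = B`). Unstranded features (CpG islands, ChIP
peaks) match both strands in every intersection. TSV parsing is strict:
`NA`, ragged rows, duplicate ids and inverted coordinates are errors with
the offending line named — silent imputation would corrupt every
downstream statistic. Where the provenance of TSS-cluster coordinates is
ambiguous (some resources export 1-based peaks), the reader defaults to
BED semantics and the literal parser covers the 1-based case.

## Expression

TPM is per-library: `count × 10⁶ / total mapped tags`. Column sums equal
10⁶ exactly only when the table covers the whole library; on gene subsets
they are proportional to the subset's share.

Thresholds are read literally: detection ("over 5 TPM in any sample") and
per-sample expression ("above 1 TPM") are strict inequalities; novelty
("over 500 bp" from every annotated TSS of the gene) is strict; the
annotation vicinities ("within 500 bp") are closed. A gene counts as
expressed in a sample when **any** of its promoters exceeds the cutoff
(union semantics — the natural gene-level reading when promoters are
alternative starts of one gene).

The reference base of a promoter ("center") is `floor((start+end−1)/2)`
of its cluster interval unless a dominant CTSS position is supplied. One
reference point serves the TATA window, the CpG window, the enhancer
distance and the TFBS summation, so the four annotations are mutually
consistent.

## Promoter shape

The sharp/broad rule is a two-window dominance test:

1. trim the per-nucleotide profile to its densest 50-bp genomic window
   (the TSS cluster; signal outside it is reported as a QC fraction);
2. find the densest 5-nt window inside the trimmed profile;
3. **sharp** iff that window's share of the trimmed signal is strictly
   greater than 0.5, else **broad**.

The 0.5 majority threshold quantifies "majority of transcripts from a
single dominant TSS or within 5 nucleotides"; a 1-nt dominant site is
subsumed by the 5-nt window. The threshold is configurable
(`sharp_fraction`). Window arithmetic is in genomic base pairs — gaps
between observed positions count — because "within 5 nucleotides" is a
genomic distance. Candidate window starts are the observed tag positions
(any maximal-sum window can be slid right onto one without losing tags);
ties break to the smallest start. The classification is invariant to
count scaling (raw tags or TPM) and coordinate translation, and pooling
profiles across samples is a position-wise sum.

## Regulatory annotation

* TATA: strand-aware upstream window `[center−500, center)` on +,
  mirrored on −. Unstranded promoters are rejected (no direction).
* CpG: strand-agnostic closed window `center ± 500`; any overlap of an
  island qualifies (edge-distance is a configurable alternative; the
  any-overlap reading is the weaker and therefore safer claim).
* Histone marks: an H3K27ac peak with no H3K4me3 overlap is an
  `active_enhancer`; an H3K4me3 peak is `dual` when the **union** of
  overlapping H3K27ac peaks covers every base of it (containment by a
  fragmented mark still counts), otherwise `active_promoter`. Peaks are
  used as provided; no pre-merging.
* `promoter_context` reports the nearest region of each label by
  edge-to-center distance, signed negative upstream relative to the
  promoter strand; ties break to the smaller start.

## Correlation, linking, multiple testing

Spearman uses tie-averaged ranks (the convention of the analysis
environment the outputs mirror); Pearson p-values are the two-sided tail
of `t = r√((n−2)/(1−r²))` on n−2 df. Constant vectors yield flagged NaN
(a warning is recorded), never a silent zero — silent promoters in
sample subsets make this case routine.

Enhancer candidates pair a promoter with every enhancer whose interval
midpoint lies within 500 kb of the promoter's reference base on the same
chromosome (center-to-midpoint, unsigned; chosen for symmetry and
reported so results are reproducible). All tested pairs across all genes
form one Bonferroni family (`m` = pairs with a defined correlation;
undefined pairs are flagged and excluded from `m`). Negative correlations
are retained and tested two-sided.

**Caveat** — the t reference distribution of the Pearson test is exact
under Gaussian noise but anticonservative on heavy-tailed marginals: with
log-normal expression at n = 450 we observed a family-wise error near
0.3 instead of 0.05 in simulation. This is a property of the published
procedure itself (Pearson on TPM values), not of the implementation; the
calibration tests therefore verify error control in a Gaussian null
world, and practitioners should treat borderline corrected p-values on
heavy-tailed data with suspicion (or rank-transform first).

## TFBS enrichment

Sites with posterior ≥ 0.2 (inclusive) are retained; per promoter and TF
the posteriors of sites whose midpoint lies within the closed ±500-bp
window of the reference base are summed (the expected number of binding
sites). Significance is the empirical tail `rank / N` in a background
population of promoters scored identically, with `rank` = number of
background values ≥ the observed count — maximal rank under ties, and the
promoter itself included (appended when absent), so `rank ≥ 1` and the
statistic is super-uniform under the null by construction. Ranking is
per-TF. The motif-posterior model that produces site lists is an input
contract, not reimplemented. Per-gene TF reports use the stricter
posterior > 0.7 cutoff; the cross-gene intersection flags candidate
shared regulators.

## Synthetic data

The generator states a world and sticks to it; every output is a pure
function of the seed.

* **Expression**: a Gaussian copula plants a target Spearman matrix
  (latent Pearson `2·sin(π·ρs/6)`; non-PSD targets are rejected before
  sampling). Marginals are log-normal (σ = 1.5) — CAGE TPM is
  heavy-tailed — scaled to each promoter's target maximum TPM and
  converted to integer counts against library totals drawn uniformly from
  5–20 million mapped tags (realistic CAGE depth; chosen once). Rank
  targets make the marginal choice immaterial to Spearman recovery up to
  count-rounding ties. Tissue restriction is modeled by zeroing samples
  below a latent quantile (`restricted_fraction`).
* **Profiles**: sharp promoters put 65–85 % of tags at one mode (margin
  ≥ 0.1 above the 0.5 threshold); broad profiles are Dirichlet-jittered
  near-uniform and re-drawn until no 5-nt window exceeds 0.4 of the
  cluster (margin ≥ 0.1 below).
* **Enhancers**: linked expression is `r·z(x) + √(1−r²)·ε` shifted
  non-negative, so the population Pearson correlation equals the target;
  placements include a null (independent) enhancer and one beyond the
  500-kb window as negative controls.
* **TFBS**: per-TF backgrounds are exponential with mean 0.3; a planted
  excess of +2.0 then clears the 1 % empirical tail with analytic margin
  (`P(X ≥ 2.0) = e^(−2/0.3) ≈ 1.3·10⁻³`). Every focal promoter also
  receives a sub-cutoff site (posterior 0.1) and an out-of-window
  high-posterior site; neither may leak into any count.

The default six-promoter world mirrors the published three-gene
promoterome: its planted Spearman matrix is the printed six-promoter
table, maximum TPM values are at the published scale, shapes and
TATA/CpG statuses follow the published annotation table, and the
enhancer distances/correlations (7 kb/0.78, 53 kb/0.43, 408 kb/0.55,
245 kb/0.20) match the reported links.

What a green test does **not** establish: the generator does not simulate
read-level CAGE, mapping artifacts, batch structure, inter-sample
dependence, or genome-scale annotation density, so recovery on synthetic
data validates the statistics and plumbing, not robustness to those
real-data features. Genome-scale outputs (promoter counts per gene,
enhancer tallies, published tail probabilities) depend on external
resources and are deliberately out of numeric scope.

## Numerical and procedural choices

* Monte-Carlo acceptance checks estimate planted correlations by the
  mean over 20 seeded replicates (standard error ≈ 0.01 at n = 450),
  so the ±0.05 recovery tolerance is a >3σ bound rather than a coin
  flip on a single draw; family-wise error is tested one-sided at the
  0.999 binomial level over 500 replicates.
* Promoter naming ties (equal maximum TPM) break by (chrom, start);
  naming is a bijection and stable under row permutation.
* The pipeline driver records SHA-256 digests of all inputs and the
  config in `manifest.json`; a rerun with identical digests reuses
  existing outputs, any change recomputes everything (whole-run
  resumption — conservative by design).
* Discarded rows (detection filter, undefined correlations, profile-less
  promoters) are counted and logged, never dropped silently.

## Limitations

* No probabilistic shape indices (entropy scores) or multi-peak
  decomposition; the two-window rule is deliberately simple.
* No p-values for Spearman coefficients (matrix outputs mirror the
  published table, which reports coefficients only).
* Enhancer calling, motif discovery and peak calling are upstream of the
  package's contracts.
* The published per-sample supplement is a binary spreadsheet and is not
  packaged; the table-reproduction pathway is validated against an
  independent R oracle on a synthetic stand-in and against the planted
  copula world instead.
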