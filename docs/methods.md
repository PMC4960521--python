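# Methods

`chromcobind` implements an integrative analysis of nucleosome-resolution
H3K4me2 chromatin dynamics and transcription-factor (TF) co-occupancy
between two cell states, here called *imm* (immature) and *mat* (mature)
after the megakaryocyte maturation setting the method was designed for.
This note describes the models, the parameters that matter, the
synthetic-data generator, and the numerical choices.

## The enhancer model: paired nucleosomes around a depleted trough

Active cis-regulatory elements are modelled as **nucleosome pairs**: two
H3K4me2-marked nucleosomes whose dyads sit 250–450 bp apart, flanking a
trough of depleted signal where TFs bind. Detection has three steps:

1. **Nucleosome calling** (`call_nucleosomes`). The raw coverage track is
   smoothed with a 30-base moving average; local maxima at least
   `min_peak_height` high become candidate dyads, and candidates closer
   than `min_spacing` (default 147 bases, one core-particle footprint)
   are greedily suppressed keeping the higher (ties: leftmost). This is a
   deliberately simple, fully specified caller — it does not attempt the
   Poisson-significance machinery of dedicated nucleosome-positioning
   tools, and its parameters are exposed so an alternative caller can be
   swapped in upstream.
2. **Pair detection** (`detect_pairs`). Adjacent dyads with separation in
   `[sep_min, sep_max]` (defaults 250/450 bp) qualify when the mean
   smoothed signal over the **central third** of the inter-dyad span is
   below `trough_fraction` (default 0.5) of the lower flanking dyad
   height. The central third avoids shoulder contamination from the
   flanking nucleosomes. Pairing is greedy left-to-right and
   non-overlapping, so a nucleosome belongs to at most one pair.
3. **Locale classification** (`classify_pairs`). Pairs centered strictly
   within 2 kb of the nearest TSS are *promoter*, all others *distal*;
   chromosomes without annotated genes yield distal pairs.

## NSD: the differential-marking score

Per pair, with `S_c` the per-million-normalised count of condition-*c*
fragment centers in the two nucleosome windows (each dyad ±73 bases):

```
nsd = (S_mat − S_imm) / (S_mat + S_imm + ε),   ε = 1 per million
```

Fragment centers are stranded 5′ tag positions shifted 3′-ward by half
the fragment length (default 150 bases). The score is bounded in (−1, 1),
zero for equal marking, antisymmetric in the conditions up to ε, and
monotone in the mat:imm signal ratio of the pair when the rest of the
libraries are held fixed. The ε term regularises low-coverage pairs
toward zero instead of ±1. The published upstream tools that inspired the
score do not expose a closed-form definition; the formula above is this
package's own, chosen for boundedness and antisymmetry, and is
parameterised (`shift`, `eps`) so variants can be explored. Ranked pairs
are split into consecutive bins (`rank_and_bin`, default 1,000 pairs per
bin, descending for mature-selective ranking) with coordinate tie-breaks
so the ordering is deterministic.

Note one library-composition subtlety: because `S_c` is normalised per
million tags *within each condition*, enhancers marked equally in both
conditions score slightly negative when the immature library is smaller
overall (each immature tag then carries more weight). This mirrors what
happens with real sequencing libraries and is why NSD comparisons are
made by rank rather than absolute value.

## Fragment-shift estimation and composite profiles

ChIP tags mark fragment ends. The fragment length is estimated by the
strand cross-correlation of per-base 5′-end counts (`estimate_shift`):
the Pearson correlation between the plus-strand and minus-strand count
vectors is evaluated at every lag in [1, 600], and the fragment length is
the argmax (ties: smallest lag). Dialect: a fragment of length L spanning
[s, s+L) records its minus-strand 5′ end at s+L−1, and lag ℓ compares
`plus[x]` against `minus[x+ℓ−1]`, so a fixed-length library yields the
exact length. With positional jitter in fragment placement the
correlation peak is broad and the argmax can move a base or two — the
recovery contract is therefore ±5 bases on the shift (= half length,
rounded down), and a default shift of 150 bases is used when estimation
fails (single-stranded or degenerate input).

Composite profiles (`composite_profile`) tally shifted tags in
non-overlapping 10-bp windows over ±1.5 kb around a set of anchors
(summits or pair centers) and normalise to RPKM over the anchor set:
`counts × 10⁹ / (n_anchors × bin_size × total_tags)`. Mass is conserved
exactly: summing bins undoes the normalisation to the in-window tag
count. `signal_matrix` produces the per-site analogue (1-kb window, 100
bins per TF, concatenated in fixed TF order) for clustering.
Deduplication is exact-position (chrom, pos5, strand) and off by default
in the synthetic setting, where duplicate positions are legitimate.

## Co-occupancy, regulation maps, clustering, enrichment

- **Summit distances** are unsigned TSS-to-summit distances on the same
  chromosome, ignoring intervening genes and gene strand. The nearest-
  distance routine is exact (verified against an all-pairs oracle).
- **Co-occupancy merging** pools all TFs' summits and single-links
  summits strictly closer than 300 bases — the empirical inflection of
  the cross-TF summit-distance histogram. Chains of sub-threshold links
  can span more than 300 bases end to end; this is the simplest closure
  of the pairwise criterion and is what the tests pin down. The
  inflection detector histograms nearest-cross-TF-neighbor distances in
  20-bp bins, smooths with a 3-bin moving average, and reports the left
  edge of the first post-mode bin where the slope flattens to ≥
  −peak/100. With fewer than 30 distances (or no flattening) it falls
  back to the 300-base default with a warning; the threshold is always
  overridable.
- **Gene combination labels** are the union of TF combinations over loci
  whose nearest member summit lies within 20 kb of the TSS (50 kb as a
  secondary cutoff in the binding-fraction summaries).
- **Clustering** (`kmeans_sites`) standardises matrix columns, drops
  constant ones, runs k-means (k = 3 by default, ≥10 restarts, fixed
  seed) and relabels clusters 1..k by decreasing mean FLI1+RUNX1 signal,
  so cluster 1 is always the most co-occupied class. An all-constant
  matrix degenerates to a single cluster with a warning.
- **Enrichment** uses Fisher's exact test on 2×2 gene contingencies. The
  odds ratio is a·d/(b·c) with a Haldane–Anscombe +0.5 on all cells only
  when a cell is zero. Both sidedness conventions are exposed: the
  default is two-sided; the package's reproduction of the published
  megakaryocyte contingency ([[270, 422], [60, 348]]) uses the one-sided
  (greater) alternative, which is the convention that yields the printed
  p = 1.3 × 10⁻¹⁸ (the two-sided value is 2.1 × 10⁻¹⁸).

## The synthetic-data generator

The generator (`simulate`) emulates the statistical structure the
analysis assumes, with explicit ground truth so recall, sign correctness
and label recovery are exactly computable:

- **Genes** fall into three expression classes — mat-selective
  (mat/imm ≥ 1.5, FDR < 0.05), imm-selective (reverse), invariant
  (ratio < 1.5) — with configurable fractions (defaults 0.3/0.2,
  echoing a study design in which more genes rise than fall on
  maturation). Expression baselines are log-normal.
- **Enhancers** are planted as dyad pairs with separations uniform in
  [250, 450] bp, at least 2 kb apart, with a condition bias (mat / imm /
  both) and a TF combination drawn from configurable mixtures. A
  configurable fraction (default 0.8) of condition-biased enhancers is
  linked to a same-class gene and placed 2–20 kb from its TSS; the
  linkage is recorded in the truth table rather than inferred.
- **Tags**: fragment lengths are truncated-normal (mean 300, sd 30,
  floor 50 — the floor keeps the strand modes well separated for the
  cross-correlation test); fragments center on the two dyads (H3K4me2)
  or the planted summit (TFs) with ±20-base placement jitter; each tag
  records its 5′ end on a uniformly chosen strand. Biased enhancers
  keep a residual 10% of full depth in the off condition, so
  differential scoring faces partial rather than binary contrasts.
  Background tags land uniformly at 0.5 tags/kb. Tag counts are
  conserved exactly (boundary tags are clamped, not dropped).
- All randomness flows from one integer seed; identical seeds give
  byte-identical datasets.

What the generator does **not** model: mappability, GC bias, duplicate
reads, diploidy, chromatin domains, or realistic signal-to-noise (the
background rate is chosen for testability — the real libraries' noise
level is unknown). Passing tests therefore demonstrate correctness of
the algorithms under the stated generative model, not performance on
real ChIP-seq libraries.

## Default constants

| parameter | default | meaning |
|---|---|---|
| `sep_min`/`sep_max` | 250/450 bp | accepted inter-dyad separation |
| `trough_fraction` | 0.5 | trough depletion vs lower flank |
| `promoter_cutoff` | 2 kb | promoter vs distal |
| `enhancer_cutoff` | 20 kb | gene-to-binding imputation distance |
| `secondary_cutoff` | 50 kb | wider binding fraction |
| `cooccupancy_threshold` | 300 bp | summit merge distance |
| `bin_size` | 10 bp | profile window width |
| `pair_bin` | 1,000 | pairs per NSD bin |
| `gene_bin` | 50 | genes per expression bin |
| `fc_threshold`/`fdr_threshold` | 1.5 / 0.05 | differential class |
| `ko_fc_threshold` | 2.0 | knockout response class |
| `k` | 3 | k-means clusters |
| `shift_default` | 150 bp | fallback half-fragment shift |

## Problem sizes and numerical choices

The default synthetic study is one 2-Mb chromosome, 200 genes, 160
enhancers, 500 H3K4me2 tags per enhancer (250 per TF), chosen so the
whole pipeline and its verification run in seconds while every
statistical contrast (NSD sign, KS separation, bin enrichment,
clustering) is decisively resolved. At this scale NSD ranking bins use
25–40 pairs per bin rather than the 1,000-pair production default. The
flatness check for composite profiles uses disjoint anchor windows so
per-bin counts are independent Poisson draws. Coordinates are 0-based
half-open everywhere internally; chromosome names match by exact string
equality; all ties (equal peak heights, equal NSD, equal correlation)
break deterministically by coordinate or smallest value.

## Known limitations

- The nucleosome caller and NSD formula are simplified, fully specified
  stand-ins for richer published tools; absolute values are not
  comparable across tools, ranks are.
- Single-linkage co-occupancy loci can chain beyond the threshold.
- The inflection detector is a heuristic; 300 bp is the operational
  default and always available as an override.
- Motif enrichment, GO analysis and genome-browser rendering are out of
  scope.
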