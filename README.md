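# chromcobind

Nucleosome-resolution chromatin dynamics and transcription-factor (TF)
co-occupancy analysis for two-state differentiation systems.

Active enhancers leave a characteristic footprint in H3K4me2 MNase-ChIP
data: two marked nucleosomes flanking a 250–450 bp depleted trough where
transcription factors bind. `chromcobind` detects these **nucleosome
pairs**, scores how their marking changes between an immature and a
mature cell state with a signed **NSD (nucleosome
stabilization–destabilization) score**

```
nsd = (S_mat − S_imm) / (S_mat + S_imm + ε),   ε = 1 tag per million,
```

where `S_c` is the per-million-normalised H3K4me2 fragment count in the
two nucleosome windows (dyad ± 73 bp), and integrates the result with TF
binding summits: strand cross-correlation fragment-shift estimation,
10-bp RPKM composite profiles, TSS-to-summit regulation maps with
two-sample KS tests, 300-bp single-linkage summit co-occupancy with TF
combination labels, k-means (k = 3) classification of binding sites by
co-factor signal, and Fisher exact enrichment of gene classes.

Because the genome-scale inputs are large and external, the package
ships a seeded **synthetic-data generator** that emulates the
statistical structure of such a study — differential gene classes
(fold change ≥ 1.5, FDR < 0.05), planted paired-nucleosome enhancers
with condition bias and known TF combinations, stranded read tags with a
configurable fragment-length distribution — so the entire pipeline runs
and is verified against exact ground truth without downloading anything.

Audience: computational biologists analysing nucleosome-resolution
histone-mark ChIP-seq together with TF binding maps, and anyone needing
a fully specified, testable reference for paired-nucleosome enhancer
detection and co-occupancy statistics.

## Worked example

```python
import chromcobind as cb
from chromcobind.simulate import coverage_track, true_summits

genome = cb.generate_genome(n_chroms=1, chrom_length=2_000_000, n_genes=200,
                            frac_mat_selective=0.3, frac_imm_selective=0.2,
                            seed=7)
truth = cb.plant_enhancers(genome, n_enhancers=160, seed=8)
tagsets = cb.synthesize_all_tags(genome, truth, depth=500, seed=9)

tracks = {c: coverage_track(tagsets[c]["H3K4me2"], genome.chrom_lengths, 10)
          for c in cb.CONDITIONS}
merged = cb.SignalTrack({ch: tracks["imm"].values[ch] + tracks["mat"].values[ch]
                         for ch in tracks["imm"].values}, 10)
pairs = cb.detect_pairs(cb.call_nucleosomes(merged, min_peak_height=2.0), merged)
cb.classify_pairs(pairs, genome.genes)
cb.nsd_scores(pairs, tagsets["imm"]["H3K4me2"], tagsets["mat"]["H3K4me2"],
              shift=150)
print(f"{len(pairs)} nucleosome pairs "
      f"({sum(p.locale == 'distal' for p in pairs)} distal)")
top = max(pairs, key=lambda p: p.nsd)
print(f"most mature-selective pair: {top.chrom}:{top.left.dyad}-{top.right.dyad} "
      f"nsd={top.nsd:.3f} (imm {top.signal_imm:.1f}, mat {top.signal_mat:.1f} tags/M)")

loci = cb.merge_cooccupancy({tf: true_summits(truth, tf) for tf in cb.TF_NAMES})
print(f"{len(loci)} co-occupancy loci, "
      f"{sum(len(l.tf_combination) == 3 for l in loci)} bound by all three TFs")

res = cb.fisher_enrichment([[270, 422], [60, 348]], alternative="greater")
print(f"published contingency: OR={res.odds_ratio:.2f}, p={res.p_value:.1e}")
```

prints

```
160 nucleosome pairs (114 distal)
most mature-selective pair: chr1:1207005-1207315 nsd=0.793 (imm 952.4, mat 8258.7 tags/M)
160 co-occupancy loci, 43 bound by all three TFs
published contingency: OR=3.71, p=1.3e-18
```

All 160 planted enhancers are recovered as pairs with separations inside
the 250–450 bp window; the top-ranked pair's NSD of 0.79 reflects an
~8.7-fold mature-biased H3K4me2 signal. The final line reproduces the
published megakaryocyte gene-class contingency (270 of 692
mature-selective vs 60 of 408 immature-selective genes bound within
20 kb): odds ratio 3.71 and a one-sided Fisher exact p of 1.3 × 10⁻¹⁸.

## Command line

The same stages are scriptable through one CLI with one YAML config
(defaults are the study's printed constants):

```bash
chromcobind run --seed 5 --out results_dir          # all eight stages
chromcobind simulate --seed 5 --out results_dir     # any single stage
```

Stages: `simulate → pairs → profiles → map → cooccupy → cluster →
enrich → report`; every run writes a `manifest.json` with the config
hash, row counts and content hashes, and reruns with the same seed are
hash-identical.

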