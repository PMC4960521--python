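"""Cross-dataset statistics: regulation maps, co-occupancy, clustering,
and enrichment.

Distances between genes and TF binding sites are measured from the TSS to
the nearest peak summit on the same chromosome, upstream or downstream,
ignoring intervening genes and gene strand.  Summits of different TFs
closer than the co-occupancy threshold (default 300 bases, the empirical
inflection in the cross-TF summit-distance distribution) merge into
co-occupancy loci by single linkage, each labeled with its TF combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .core import (
    CooccupancyLocus,
    EnrichmentResult,
    GeneRecord,
    GenomicInterval,
    NucleosomePair,
    ParameterError,
    PeakSummit,
    RegulationEntry,
)
from .nucleosomes import NUCLEOSOME_HALF, RankedBins
from .profiles import SignalMatrix


# ---------------------------------------------------------------------------
# regulation maps
# ---------------------------------------------------------------------------

def nearest_summit_distance(
    genes: Sequence[GeneRecord],
    summits: Sequence[PeakSummit],
    knockout_classes: Mapping[str, str] | None = None,
) -> list[RegulationEntry]:
    """Distance from each gene's TSS to the nearest summit on its chromosome.

    Genes on chromosomes without summits get an undefined (None) distance.
    log2 fold change uses a pseudocount equal to the smallest positive
    expression value in the table, keeping the ratio finite at zero.
    """
    by_chrom: dict[str, list[PeakSummit]] = {}
    for s in summits:
        by_chrom.setdefault(s.chrom, []).append(s)
    sorted_by_chrom = {
        c: sorted(v, key=lambda s: s.summit) for c, v in by_chrom.items()
    }
    pos_by_chrom = {
        c: np.array([s.summit for s in v]) for c, v in sorted_by_chrom.items()
    }
    positive = [
        v for g in genes for v in (g.expr_imm, g.expr_mat) if v > 0
    ]
    delta = min(positive) if positive else 1.0
    ko = knockout_classes or {}
    entries: list[RegulationEntry] = []
    for g in genes:
        log2_fc = float(np.log2((g.expr_mat + delta) / (g.expr_imm + delta)))
        pos = pos_by_chrom.get(g.chrom)
        if pos is None or pos.size == 0:
            entries.append(
                RegulationEntry(g.gene_id, None, log2_fc,
                                knockout_class=ko.get(g.gene_id, "unknown"))
            )
            continue
        i = int(np.searchsorted(pos, g.tss))
        best = None
        for j in (i - 1, i):
            if 0 <= j < pos.size:
                d = abs(int(pos[j]) - g.tss)
                if best is None or d < best[0]:
                    best = (d, sorted_by_chrom[g.chrom][j])
        entries.append(
            RegulationEntry(g.gene_id, best[0], log2_fc, nearest_summit=best[1],
                            knockout_class=ko.get(g.gene_id, "unknown"))
        )
    return entries


@dataclass
class DistanceCdfResult:
    """Two-sample empirical CDFs on pooled distances plus a KS test."""

    grid: np.ndarray
    cdf_a: np.ndarray
    cdf_b: np.ndarray
    ks_statistic: float
    p_value: float
    n_a: int = 0
    n_b: int = 0


def distance_cdf_test(
    entries: Sequence[RegulationEntry],
    class_a: Callable[[RegulationEntry], bool],
    class_b: Callable[[RegulationEntry], bool],
) -> DistanceCdfResult:
    """Two-sided two-sample KS test between two gene classes' distances.

    Undefined distances are dropped before classification; both classes
    must be nonempty afterwards.
    """
    defined = [e for e in entries if e.distance is not None]
    a = np.array([e.distance for e in defined if class_a(e)], dtype=float)
    b = np.array([e.distance for e in defined if class_b(e)], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both gene classes must be nonempty")
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    grid = np.sort(np.concatenate([a, b]))
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return DistanceCdfResult(
        grid=grid, cdf_a=cdf_a, cdf_b=cdf_b,
        ks_statistic=float(ks.statistic), p_value=float(ks.pvalue),
        n_a=int(a.size), n_b=int(b.size),
    )


# ---------------------------------------------------------------------------
# NSD-bin binding frequency / expression-bin pair counts
# ---------------------------------------------------------------------------

def binding_frequency_by_bin(
    bins: RankedBins,
    summits: Sequence[PeakSummit],
) -> np.ndarray:
    """Per NSD bin, the number of pairs with a summit inside their span.

    A pair's span runs from 73 bases outside the left dyad to 73 bases
    outside the right dyad (the full two-nucleosome footprint).
    """
    pos_by_chrom: dict[str, np.ndarray] = {}
    for s in summits:
        pos_by_chrom.setdefault(s.chrom, []).append(s.summit)
    pos_by_chrom = {c: np.sort(np.asarray(v)) for c, v in pos_by_chrom.items()}
    counts = np.zeros(len(bins.bins), dtype=int)
    for b, pair_bin in enumerate(bins.bins):
        for pair in pair_bin:
            pos = pos_by_chrom.get(pair.chrom)
            if pos is None:
                continue
            lo = pair.left.dyad - NUCLEOSOME_HALF
            hi = pair.right.dyad + NUCLEOSOME_HALF
            if np.searchsorted(pos, hi, side="right") > np.searchsorted(pos, lo):
                counts[b] += 1
    return counts


@dataclass
class ExpressionBinResult:
    """Mean nearby-pair count per expression-ranked gene bin."""

    means: np.ndarray
    bin_gene_ids: list[list[str]]
    partial_last: bool


def pair_count_by_expression_bin(
    genes: Sequence[GeneRecord],
    pairs: Sequence[NucleosomePair],
    gene_bin: int = 50,
    dist_min: int = 2_000,
    dist_max: int = 20_000,
) -> ExpressionBinResult:
    """Average pair count 2-20 kb from the TSS, per fold-change gene bin.

    Genes are ordered by log2 fold change (mat over imm, descending) and
    split into consecutive bins of ``gene_bin``; per gene, pairs whose
    center c satisfies dist_min <= |c - tss| < dist_max on the same
    chromosome are counted.
    """
    if gene_bin < 1:
        raise ParameterError("gene_bin must be >= 1")
    centers_by_chrom: dict[str, np.ndarray] = {}
    for p in pairs:
        centers_by_chrom.setdefault(p.chrom, []).append(p.center)
    centers_by_chrom = {c: np.sort(np.asarray(v)) for c, v in centers_by_chrom.items()}

    eps = 1e-12
    ordered = sorted(
        genes,
        key=lambda g: (-np.log2((g.expr_mat + eps) / (g.expr_imm + eps)), g.gene_id),
    )
    per_gene = np.zeros(len(ordered))
    for i, g in enumerate(ordered):
        centers = centers_by_chrom.get(g.chrom)
        if centers is None:
            continue
        # dist_min <= |c - tss| < dist_max splits into two half-open bands
        left = (
            np.searchsorted(centers, g.tss - dist_min, side="right")
            - np.searchsorted(centers, g.tss - dist_max, side="right")
        )
        right = (
            np.searchsorted(centers, g.tss + dist_max, side="left")
            - np.searchsorted(centers, g.tss + dist_min, side="left")
        )
        per_gene[i] = left + right
    means = []
    bin_ids = []
    for i in range(0, len(ordered), gene_bin):
        chunk = per_gene[i: i + gene_bin]
        means.append(float(chunk.mean()))
        bin_ids.append([g.gene_id for g in ordered[i: i + gene_bin]])
    partial = len(ordered) % gene_bin != 0
    return ExpressionBinResult(np.asarray(means), bin_ids, partial)


# ---------------------------------------------------------------------------
# co-occupancy
# ---------------------------------------------------------------------------

@dataclass
class SummitDistanceHistogram:
    """Cross-TF nearest-neighbor summit distances plus inflection point."""

    edges: np.ndarray         # bin left edges
    counts: np.ndarray
    smoothed: np.ndarray
    inflection: int
    used_default: bool


def summit_distance_histogram(
    summits_by_tf: Mapping[str, Sequence[PeakSummit]],
    bin_width: int = 20,
    max_distance: int = 1_000,
    default_inflection: int = 300,
) -> SummitDistanceHistogram:
    """Histogram cross-TF nearest-neighbor summit distances, find the knee.

    For every summit the distance to its nearest summit of any *other* TF
    on the same chromosome is tallied (each summit contributes once).  The
    histogram is smoothed with a 3-bin moving average and the inflection
    is the left edge of the first bin after the global mode where the
    smoothed slope flattens (first difference >= -peak/100).  When
    detection is ambiguous the default threshold is reported with a
    warning.
    """
    tfs = [tf for tf, s in summits_by_tf.items() if len(s) > 0]
    if len(tfs) < 2:
        raise ParameterError("need summits from at least two TFs")
    pos = {
        tf: {} for tf in tfs
    }
    for tf in tfs:
        for s in summits_by_tf[tf]:
            pos[tf].setdefault(s.chrom, []).append(s.summit)
        pos[tf] = {c: np.sort(np.asarray(v)) for c, v in pos[tf].items()}

    distances: list[int] = []
    for tf in tfs:
        others: dict[str, np.ndarray] = {}
        for other in tfs:
            if other == tf:
                continue
            for c, arr in pos[other].items():
                others.setdefault(c, []).append(arr)
        others = {c: np.sort(np.concatenate(v)) for c, v in others.items()}
        for c, arr in pos[tf].items():
            oarr = others.get(c)
            if oarr is None or oarr.size == 0:
                continue
            idx = np.searchsorted(oarr, arr)
            for p, i in zip(arr, idx):
                best = min(
                    abs(int(oarr[j]) - int(p))
                    for j in (i - 1, i) if 0 <= j < oarr.size
                )
                if best <= max_distance:
                    distances.append(best)

    n_bins = max_distance // bin_width + (1 if max_distance % bin_width else 0)
    edges = np.arange(n_bins) * bin_width
    counts = np.zeros(n_bins, dtype=int)
    for d in distances:
        counts[min(d // bin_width, n_bins - 1)] += 1
    smoothed = np.convolve(counts, np.ones(3) / 3.0, mode="same")

    if len(distances) < 30:
        # too few cross-TF neighbor distances to place a knee
        inflection, used_default = default_inflection, True
    else:
        inflection, used_default = _detect_inflection(
            edges, smoothed, bin_width, default_inflection
        )
    if used_default:
        warnings.warn(
            "summit-distance inflection ambiguous; "
            f"using default {default_inflection} bases",
            stacklevel=2,
        )
    return SummitDistanceHistogram(edges, counts, smoothed, inflection, used_default)


def _detect_inflection(edges: np.ndarray, smoothed: np.ndarray, bin_width: int,
                       default: int) -> tuple[int, bool]:
    if smoothed.size < 3 or smoothed.max() <= 0 or np.count_nonzero(smoothed) < 3:
        return default, True
    mode = int(np.argmax(smoothed))
    peak = float(smoothed[mode])
    diff = np.diff(smoothed)
    for i in range(mode, diff.size):
        if diff[i] >= -peak / 100.0:
            return int(edges[i + 1]), False
    return default, True


def merge_cooccupancy(
    summits_by_tf: Mapping[str, Sequence[PeakSummit]],
    threshold: int = 300,
) -> list[CooccupancyLocus]:
    """Single-linkage merge of all summits at pairwise distance < threshold.

    All TFs' summits are pooled and sorted; consecutive summits on the
    same chromosome link when strictly closer than ``threshold``, so a
    chain of sub-threshold gaps can span more than the threshold end to
    end.  A distance of exactly ``threshold`` does not link.  Each locus
    is labeled with the set of member TF names.  The result is
    independent of input order.
    """
    pooled = sorted(
        (s for summits in summits_by_tf.values() for s in summits),
        key=lambda s: (s.chrom, s.summit, s.tf_name),
    )
    loci: list[CooccupancyLocus] = []
    current: list[PeakSummit] = []
    for s in pooled:
        if current and (
            s.chrom != current[-1].chrom
            or s.summit - current[-1].summit >= threshold
        ):
            loci.append(_make_locus(current))
            current = []
        current.append(s)
    if current:
        loci.append(_make_locus(current))
    return loci


def _make_locus(members: list[PeakSummit]) -> CooccupancyLocus:
    lo = min(s.summit for s in members)
    hi = max(s.summit for s in members)
    return CooccupancyLocus(
        chrom=members[0].chrom,
        span=GenomicInterval(members[0].chrom, lo, hi + 1),
        members=list(members),
    )


def gene_combination_assignment(
    genes: Sequence[GeneRecord],
    loci: Sequence[CooccupancyLocus],
    cutoff: int = 20_000,
) -> dict[str, frozenset[str]]:
    """Per gene, the union of TF combinations of loci within the cutoff.

    A locus is in range when its nearest member summit lies within
    ``cutoff`` bases of the TSS.  Genes with no locus in range map to the
    empty set (reported downstream as "none").
    """
    summit_arrays: dict[str, tuple[np.ndarray, list[CooccupancyLocus]]] = {}
    by_chrom: dict[str, list[tuple[int, CooccupancyLocus]]] = {}
    for locus in loci:
        for s in locus.members:
            by_chrom.setdefault(locus.chrom, []).append((s.summit, locus))
    for c, items in by_chrom.items():
        items.sort(key=lambda t: t[0])
        summit_arrays[c] = (
            np.array([t[0] for t in items]),
            [t[1] for t in items],
        )
    out: dict[str, frozenset[str]] = {}
    for g in genes:
        label: set[str] = set()
        entry = summit_arrays.get(g.chrom)
        if entry is not None:
            pos, locus_refs = entry
            lo = int(np.searchsorted(pos, g.tss - cutoff, side="left"))
            hi = int(np.searchsorted(pos, g.tss + cutoff, side="right"))
            for j in range(lo, hi):
                label |= locus_refs[j].tf_combination
        out[g.gene_id] = frozenset(label)
    return out


def fraction_bound_within(
    genes: Sequence[GeneRecord],
    summits_by_tf: Mapping[str, Sequence[PeakSummit]],
    cutoffs: Sequence[int] = (20_000, 50_000),
) -> dict[str, dict[int, float]]:
    """Fraction of genes whose nearest same-TF summit is within each cutoff."""
    if not genes:
        raise ParameterError("gene subset is empty")
    out: dict[str, dict[int, float]] = {}
    for tf, summits in summits_by_tf.items():
        entries = nearest_summit_distance(genes, summits)
        out[tf] = {}
        for cutoff in cutoffs:
            bound = sum(
                1 for e in entries if e.distance is not None and e.distance <= cutoff
            )
            out[tf][cutoff] = bound / len(genes)
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """1-based cluster labels ordered by decreasing co-factor signal."""

    labels: np.ndarray
    k: int
    cluster_order_statistic: np.ndarray  # mean co-factor signal per cluster, by label
    degenerate: bool = False


def kmeans_sites(
    matrix: SignalMatrix,
    k: int = 3,
    seed: int = 0,
    cofactor_tfs: Sequence[str] = ("FLI1", "RUNX1"),
    n_restarts: int = 10,
) -> ClusterAssignment:
    """k-means over standardized binding-site signal rows.

    Columns are standardized to zero mean / unit variance (constant
    columns dropped); clusters are relabeled 1..k by decreasing mean
    signal over the co-factor feature blocks so label 1 always marks the
    most co-occupied class.
    """
    X = matrix.matrix
    if X.shape[0] < k:
        raise ParameterError(f"k={k} exceeds number of rows {X.shape[0]}")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        warnings.warn("all features constant; single effective cluster", stacklevel=2)
        labels = np.ones(X.shape[0], dtype=int)
        return ClusterAssignment(labels, k, np.zeros(1), degenerate=True)
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(Z)

    cof = [tf for tf in cofactor_tfs if tf in matrix.tf_order]
    if cof:
        cof_signal = np.column_stack([matrix.tf_block(tf) for tf in cof]).mean(axis=1)
    else:
        cof_signal = X.mean(axis=1)
    means = np.array([
        cof_signal[raw == c].mean() if (raw == c).any() else -np.inf
        for c in range(k)
    ])
    order = np.argsort(-means)  # cluster with highest co-factor signal first
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = np.array([relabel[int(c)] for c in raw])
    stats_by_label = np.array([
        cof_signal[labels == lab].mean() if (labels == lab).any() else np.nan
        for lab in range(1, k + 1)
    ])
    return ClusterAssignment(labels, k, stats_by_label)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(table: np.ndarray | Sequence[Sequence[int]],
                      alternative: str = "two-sided") -> EnrichmentResult:
    """Fisher's exact test plus the sample odds ratio on a 2x2 table.

    The odds ratio is a*d / (b*c), with a Haldane-Anscombe +0.5 applied to
    every cell only when any cell is zero.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ParameterError("contingency must be a nonnegative 2x2 table")
    p = float(stats.fisher_exact(t, alternative=alternative).pvalue)
    a, b, c, d = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = float((a * d) / (b * c))
    method = {"two-sided": "fisher_two_sided", "greater": "fisher_greater",
              "less": "fisher_less"}[alternative]
    return EnrichmentResult(contingency=t, odds_ratio=odds, p_value=p, method=method)


def enrichment_test(
    gene_label: Mapping[str, object],
    target_class: object,
    group: Callable[[str], bool],
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Association between group membership and carrying the target label.

    Contingency rows are the in-group / out-group gene sets, columns the
    target vs non-target labels; the test is Fisher's exact.
    """
    gene_ids = list(gene_label)
    in_group = [g for g in gene_ids if group(g)]
    out_group = [g for g in gene_ids if not group(g)]
    if not in_group or not out_group:
        raise ParameterError("group must be a proper nonempty subset of genes")
    a = sum(1 for g in in_group if gene_label[g] == target_class)
    b = len(in_group) - a
    c = sum(1 for g in out_group if gene_label[g] == target_class)
    d = len(out_group) - c
    return fisher_enrichment([[a, b], [c, d]], alternative=alternative)
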