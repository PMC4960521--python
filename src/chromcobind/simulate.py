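"""Seeded synthetic-data generator with ground-truth annotation.

Emulates the statistical structure of a two-state megakaryocyte maturation
study: genes with two-condition expression (a >=1.5-fold / FDR<0.05
differential class), enhancers realized as two H3K4me2-marked nucleosomes
flanking a 250-450 bp depleted trough with condition-biased marking, TF
summits placed inside the troughs with controlled combination structure,
and stranded read tags with a configurable fragment-length distribution.

Every dataset is fully determined by one integer seed; gene-enhancer
linkage is recorded explicitly in the truth table so recall and precision
of downstream detection are exactly computable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .core import (
    CONDITIONS,
    H3K4ME2,
    TF_NAMES,
    GeneRecord,
    GenomicInterval,
    ParameterError,
    PeakSummit,
    PlacementError,
    ReadTagSet,
    SignalTrack,
)

NUCLEOSOME_HALF = 73  # half the 147-bp core-particle footprint


@dataclass
class GenomeModel:
    """A small synthetic genome: chromosome sizes plus annotated genes."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if any(length <= 0 for length in lengths.values()):
            raise ParameterError("chromosome lengths must be positive")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ParameterError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in lengths or g.tss >= lengths[g.chrom]:
                raise ParameterError(f"{g.gene_id}: TSS outside its chromosome")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass
class EnhancerTruth:
    """Ground truth for one planted paired-nucleosome enhancer."""

    chrom: str
    left_dyad: int
    right_dyad: int
    condition_bias: str  # imm | mat | both
    tf_set: frozenset[str]
    summit_offsets: dict[str, int] = field(default_factory=dict)
    linked_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.condition_bias not in ("imm", "mat", "both"):
            raise ParameterError(f"bad condition_bias {self.condition_bias!r}")
        for tf, off in self.summit_offsets.items():
            if abs(off) >= self.separation / 2:
                raise ParameterError(
                    f"summit offset {off} for {tf} reaches a flanking dyad"
                )

    @property
    def separation(self) -> int:
        return self.right_dyad - self.left_dyad

    @property
    def trough_center(self) -> int:
        return (self.left_dyad + self.right_dyad) // 2

    def summit_position(self, tf: str) -> int:
        return self.trough_center + self.summit_offsets.get(tf, 0)


def expression_class(g: GeneRecord, fc_threshold: float = 1.5,
                     fdr_threshold: float = 0.05) -> str:
    """Classify a gene as mat-selective, imm-selective, or invariant."""
    eps = 1e-12
    ratio_mat = (g.expr_mat + eps) / (g.expr_imm + eps)
    if g.fdr < fdr_threshold:
        if ratio_mat >= fc_threshold:
            return "mat"
        if 1.0 / ratio_mat >= fc_threshold:
            return "imm"
    return "invariant"


# ---------------------------------------------------------------------------
# genome + genes
# ---------------------------------------------------------------------------

def generate_genome(
    n_chroms: int = 1,
    chrom_length: int = 2_000_000,
    n_genes: int = 200,
    frac_mat_selective: float = 0.3,
    frac_imm_selective: float = 0.2,
    seed: int = 0,
) -> GenomeModel:
    """Generate a genome whose genes fall into three expression classes.

    Designated mat-selective genes satisfy expr_mat/expr_imm >= 1.5 with
    FDR < 0.05 (imm-selective genes the reverse); the rest have a
    fold-change ratio strictly below 1.5 in both directions.
    """
    if n_chroms < 1 or chrom_length <= 0 or n_genes < 1:
        raise ParameterError("counts and lengths must be positive")
    if frac_mat_selective < 0 or frac_imm_selective < 0 or \
            frac_mat_selective + frac_imm_selective > 1:
        raise ParameterError("class fractions must be nonnegative and sum to <= 1")
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i + 1}", chrom_length) for i in range(n_chroms)]

    n_mat = int(round(frac_mat_selective * n_genes))
    n_imm = int(round(frac_imm_selective * n_genes))
    classes = ["mat"] * n_mat + ["imm"] * n_imm + ["invariant"] * (n_genes - n_mat - n_imm)
    rng.shuffle(classes)

    margin = 50_000 if chrom_length > 200_000 else chrom_length // 10
    genes: list[GeneRecord] = []
    for i, cls in enumerate(classes):
        chrom = chromosomes[rng.integers(n_chroms)][0]
        tss = int(rng.integers(margin, chrom_length - margin))
        base = float(rng.lognormal(mean=5.0, sigma=1.0))
        if cls == "mat":
            ratio = float(rng.uniform(1.5, 6.0))
            expr_imm, expr_mat = base, base * ratio
            fdr = float(rng.uniform(0.0, 0.05))
        elif cls == "imm":
            ratio = float(rng.uniform(1.5, 6.0))
            expr_imm, expr_mat = base * ratio, base
            fdr = float(rng.uniform(0.0, 0.05))
        else:
            ratio = float(rng.uniform(1.0 / 1.45, 1.45))
            expr_imm, expr_mat = base, base * ratio
            fdr = float(rng.uniform(0.0, 1.0))
        genes.append(
            GeneRecord(
                gene_id=f"gene_{i + 1:05d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                tss=tss,
                expr_imm=round(expr_imm, 4),
                expr_mat=round(expr_mat, 4),
                fdr=round(fdr, 6),
            )
        )
    return GenomeModel(chromosomes=chromosomes, genes=genes)


# ---------------------------------------------------------------------------
# enhancer planting
# ---------------------------------------------------------------------------

def _normalize_mix(mix: Mapping, what: str) -> list[tuple[object, float]]:
    items = list(mix.items())
    total = sum(p for _, p in items)
    if not items or abs(total - 1.0) > 1e-9:
        raise ParameterError(f"{what} probabilities must sum to 1 (got {total})")
    if any(p < 0 for _, p in items):
        raise ParameterError(f"{what} probabilities must be nonnegative")
    return items


DEFAULT_TF_MIX: dict[frozenset[str], float] = {
    frozenset({"NFE2", "FLI1", "RUNX1"}): 0.25,
    frozenset({"NFE2", "FLI1"}): 0.15,
    frozenset({"FLI1", "RUNX1"}): 0.15,
    frozenset({"NFE2", "RUNX1"}): 0.05,
    frozenset({"NFE2"}): 0.10,
    frozenset({"FLI1"}): 0.20,
    frozenset({"RUNX1"}): 0.10,
}
DEFAULT_BIAS_MIX = {"mat": 0.45, "imm": 0.25, "both": 0.30}


@dataclass
class LinkRule:
    """How condition-biased enhancers attach to same-class genes."""

    link_fraction: float = 0.8      # fraction of mat/imm enhancers linked to a gene
    min_distance: int = 2_000       # linked enhancers sit 2-20 kb from the TSS
    max_distance: int = 20_000


def plant_enhancers(
    genome: GenomeModel,
    n_enhancers: int = 200,
    tf_mix: Mapping[frozenset, float] | None = None,
    bias_mix: Mapping[str, float] | None = None,
    link_rule: LinkRule | None = None,
    sep_range: tuple[int, int] = (250, 450),
    summit_offset_max: int = 100,
    min_gap: int = 2_000,
    seed: int = 0,
) -> list[EnhancerTruth]:
    """Place paired-nucleosome enhancers with controlled TF combinations.

    Condition-biased enhancers are preferentially linked to a same-class
    differential gene and placed 2-20 kb from its TSS (the linkage is
    recorded); the remainder land uniformly.  No two enhancers come within
    ``min_gap`` of each other.
    """
    tf_items = _normalize_mix(tf_mix or DEFAULT_TF_MIX, "tf_mix")
    bias_items = _normalize_mix(bias_mix or DEFAULT_BIAS_MIX, "bias_mix")
    rule = link_rule or LinkRule()
    rng = np.random.default_rng(seed)
    lengths = genome.chrom_lengths

    genes_by_class: dict[str, list[GeneRecord]] = {"mat": [], "imm": []}
    for g in genome.genes:
        cls = expression_class(g)
        if cls in genes_by_class:
            genes_by_class[cls].append(g)

    occupied: dict[str, list[int]] = {c: [] for c in lengths}

    def _free(chrom: str, center: int, sep: int) -> bool:
        half = sep // 2 + NUCLEOSOME_HALF
        if center - half < 0 or center + half >= lengths[chrom]:
            return False
        return all(abs(center - o) >= min_gap + sep for o in occupied[chrom])

    truths: list[EnhancerTruth] = []
    tf_probs = np.array([p for _, p in tf_items])
    bias_probs = np.array([p for _, p in bias_items])
    for _ in range(n_enhancers):
        tf_set = frozenset(tf_items[rng.choice(len(tf_items), p=tf_probs)][0])
        bias = bias_items[rng.choice(len(bias_items), p=bias_probs)][0]
        sep = int(rng.integers(sep_range[0], sep_range[1] + 1))

        linked: Optional[GeneRecord] = None
        candidates = genes_by_class.get(bias, [])
        if candidates and rng.random() < rule.link_fraction:
            linked = candidates[rng.integers(len(candidates))]

        placed = False
        for _attempt in range(200):
            if linked is not None:
                dist = int(rng.integers(rule.min_distance, rule.max_distance + 1))
                side = 1 if rng.random() < 0.5 else -1
                chrom = linked.chrom
                center = linked.tss + side * dist
            else:
                chrom = genome.chromosomes[rng.integers(len(genome.chromosomes))][0]
                center = int(rng.integers(0, lengths[chrom]))
            if _free(chrom, center, sep):
                placed = True
                break
        if not placed:
            raise PlacementError(
                "could not place an enhancer after 200 retries; "
                "genome too small for the requested count and spacing"
            )
        occupied[chrom].append(center)
        max_off = min(summit_offset_max, sep // 2 - 1)
        offsets = {
            tf: int(rng.integers(-max_off, max_off + 1)) for tf in sorted(tf_set)
        }
        left = center - sep // 2
        truths.append(
            EnhancerTruth(
                chrom=chrom,
                left_dyad=left,
                right_dyad=left + sep,
                condition_bias=bias,
                tf_set=tf_set,
                summit_offsets=offsets,
                linked_gene=linked.gene_id if linked is not None else None,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# read-tag synthesis
# ---------------------------------------------------------------------------

def _draw_fragment_lengths(rng: np.random.Generator, n: int, mean: float,
                           sd: float, min_length: int = 50) -> np.ndarray:
    """Truncated-normal fragment lengths (hard floor at ``min_length``)."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    if sd <= 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    lengths = rng.normal(mean, sd, size=n)
    lengths = np.clip(np.rint(lengths), min_length, None)
    return lengths.astype(np.int64)


def _tags_from_centers(rng: np.random.Generator, chroms: np.ndarray,
                       centers: np.ndarray, lengths: np.ndarray,
                       chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Turn fragment centers into stranded 5'-end tags.

    A fragment of length L centered at c spans [c - L//2, c - L//2 + L);
    the recorded tag is the fragment's 5' end on a uniformly chosen strand
    (for minus-strand tags, the rightmost base).
    """
    strands = np.where(rng.random(len(centers)) < 0.5, "+", "-")
    starts = centers - lengths // 2
    ends = starts + lengths - 1
    pos5 = np.where(strands == "+", starts, ends)
    df = pd.DataFrame({"chrom": chroms, "pos5": pos5, "strand": strands})
    # clamp to chromosome bounds so the tag count is conserved exactly
    limits = df["chrom"].map(chrom_lengths).to_numpy(dtype=np.int64)
    df["pos5"] = np.clip(df["pos5"].to_numpy(), 0, limits - 1)
    return df


def synthesize_tags(
    genome: GenomeModel,
    truth: Sequence[EnhancerTruth],
    condition: str,
    mark: str = H3K4ME2,
    depth: int = 500,
    fragment_length_mean: float = 300.0,
    fragment_length_sd: float = 30.0,
    background_rate: float = 0.5,
    residual_fraction: float = 0.1,
    center_jitter_sd: float = 20.0,
    seed: int = 0,
) -> ReadTagSet:
    """Simulate one stranded tag library for one mark/TF in one condition.

    H3K4me2 fragments center on the two flanking dyads of each enhancer
    active in ``condition``; TF fragments center on that TF's planted summit.
    Enhancers biased toward the other condition still contribute
    ``residual_fraction`` of the full depth, so differential scores face
    partial rather than binary contrasts.  Background tags land uniformly
    at ``background_rate`` tags per kb.
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"condition must be one of {CONDITIONS}")
    if depth < 0 or background_rate < 0 or residual_fraction < 0:
        raise ParameterError("depth and rates must be nonnegative")
    rng = np.random.default_rng(seed)
    chrom_lengths = genome.chrom_lengths

    chroms: list[str] = []
    centers: list[int] = []
    for enh in truth:
        if mark == H3K4ME2:
            anchors = [enh.left_dyad, enh.right_dyad]
        elif mark in enh.tf_set:
            anchors = [enh.summit_position(mark)]
        else:
            continue
        if enh.condition_bias in ("both", condition):
            n = depth
        else:
            n = int(round(depth * residual_fraction))
        if n == 0:
            continue
        which = rng.integers(len(anchors), size=n)
        jitter = (
            np.rint(rng.normal(0.0, center_jitter_sd, size=n)).astype(np.int64)
            if center_jitter_sd > 0
            else np.zeros(n, dtype=np.int64)
        )
        for a, j in zip(which, jitter):
            chroms.append(enh.chrom)
            centers.append(anchors[a] + int(j))

    n_signal = len(centers)
    # uniform background over the whole genome
    n_bg = int(round(background_rate * genome.total_length / 1000.0))
    for _ in range(n_bg):
        chrom, length = genome.chromosomes[rng.integers(len(genome.chromosomes))]
        chroms.append(chrom)
        centers.append(int(rng.integers(0, length)))

    chrom_arr = np.array(chroms, dtype=object)
    center_arr = np.array(centers, dtype=np.int64)
    lengths = _draw_fragment_lengths(
        rng, len(center_arr), fragment_length_mean, fragment_length_sd
    )
    df = _tags_from_centers(rng, chrom_arr, center_arr, lengths, chrom_lengths)
    df.attrs["n_signal"] = n_signal
    df.attrs["n_background"] = n_bg
    return ReadTagSet(tags=df, fragment_length_mean=fragment_length_mean)


def synthesize_all_tags(
    genome: GenomeModel,
    truth: Sequence[EnhancerTruth],
    depth: int = 500,
    tf_depth: int | None = None,
    fragment_length_mean: float = 300.0,
    fragment_length_sd: float = 30.0,
    background_rate: float = 0.5,
    residual_fraction: float = 0.1,
    seed: int = 0,
) -> dict[str, dict[str, ReadTagSet]]:
    """All libraries for both conditions: H3K4me2 plus each TF.

    Returns ``{condition: {mark: ReadTagSet}}``; each library gets an
    independent stream derived from ``seed``.
    """
    out: dict[str, dict[str, ReadTagSet]] = {}
    marks = (H3K4ME2,) + TF_NAMES
    for ci, condition in enumerate(CONDITIONS):
        out[condition] = {}
        for mi, mark in enumerate(marks):
            sub_seed = (seed * 1_000 + ci * 100 + mi) % (2**31 - 1)
            out[condition][mark] = synthesize_tags(
                genome, truth, condition, mark,
                depth=depth if mark == H3K4ME2 else (tf_depth or depth // 2),
                fragment_length_mean=fragment_length_mean,
                fragment_length_sd=fragment_length_sd,
                background_rate=background_rate,
                residual_fraction=residual_fraction,
                seed=sub_seed,
            )
    return out


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def coverage_track(tags: ReadTagSet, chrom_lengths: dict[str, int],
                   bin_size: int = 10, shift: int | None = None) -> SignalTrack:
    """Binned counts of estimated fragment centers (raw coverage proxy)."""
    if shift is None:
        shift = int(tags.fragment_length_mean) // 2
    values = {}
    for chrom, length in chrom_lengths.items():
        n_bins = (length - 1) // bin_size + 1
        arr = np.zeros(n_bins)
        pos = tags.shifted_positions(shift).get(chrom)
        if pos is not None and pos.size:
            pos = pos[pos < length]
            np.add.at(arr, pos // bin_size, 1.0)
        values[chrom] = arr
    return SignalTrack(values=values, bin_size=bin_size, normalization="raw")


def truth_table(truth: Sequence[EnhancerTruth]) -> pd.DataFrame:
    rows = []
    for i, e in enumerate(truth):
        rows.append(
            {
                "enhancer_id": f"enh_{i + 1:05d}",
                "chrom": e.chrom,
                "left_dyad": e.left_dyad,
                "right_dyad": e.right_dyad,
                "separation": e.separation,
                "condition_bias": e.condition_bias,
                "tf_set": "+".join(sorted(e.tf_set)),
                "summit_offsets": ";".join(
                    f"{tf}:{off}" for tf, off in sorted(e.summit_offsets.items())
                ),
                "linked_gene": e.linked_gene or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "enhancer_id", "chrom", "left_dyad", "right_dyad", "separation",
            "condition_bias", "tf_set", "summit_offsets", "linked_gene",
        ],
    )


def true_summits(truth: Sequence[EnhancerTruth], tf: str) -> list[PeakSummit]:
    """Planted summit records for one TF, as narrowPeak-style summits."""
    out = []
    for i, e in enumerate(truth):
        if tf not in e.tf_set:
            continue
        pos = e.summit_position(tf)
        iv = GenomicInterval(e.chrom, max(0, pos - 150), pos + 150)
        out.append(PeakSummit(interval=iv, summit=pos, score=100.0, tf_name=tf,
                              name=f"{tf}_enh_{i + 1:05d}"))
    return out


def write_dataset(
    genome: GenomeModel,
    truth: Sequence[EnhancerTruth],
    tagsets: Mapping[str, Mapping[str, ReadTagSet]],
    out_dir: str | Path,
    bin_size: int = 10,
) -> dict:
    """Write the full synthetic dataset; returns a manifest dict.

    Emits the gene table, expression table, enhancer truth table, per-TF
    narrowPeak files of planted summits, per-condition H3K4me2 bedGraph
    coverage, and one tag-table TSV per library.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {"files": {}}

    def record(name: str, rows: int) -> None:
        manifest["files"][name] = {"rows": rows}

    record("genes.tsv", io_formats.write_gene_table(genome.genes, out_dir / "genes.tsv"))

    expr = pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "expr_imm": g.expr_imm,
                "expr_mat": g.expr_mat,
                "log2_fc": float(np.log2((g.expr_mat + 1e-9) / (g.expr_imm + 1e-9))),
                "fdr": g.fdr,
                "class": expression_class(g),
            }
            for g in genome.genes
        ]
    )
    record("expression.tsv", io_formats.write_tsv(expr, out_dir / "expression.tsv"))
    record("truth.tsv", io_formats.write_tsv(truth_table(truth), out_dir / "truth.tsv"))

    chrom_sizes = pd.DataFrame(genome.chromosomes, columns=["chrom", "length"])
    record("chrom_sizes.tsv", io_formats.write_tsv(chrom_sizes, out_dir / "chrom_sizes.tsv"))

    for tf in TF_NAMES:
        name = f"summits_{tf}.narrowPeak"
        record(name, io_formats.write_narrowpeak(true_summits(truth, tf), out_dir / name))

    for condition, marks in tagsets.items():
        for mark, tags in marks.items():
            name = f"tags_{mark}_{condition}.tsv"
            record(name, io_formats.write_tag_table(tags, out_dir / name))
        if H3K4ME2 in marks:
            track = coverage_track(marks[H3K4ME2], genome.chrom_lengths, bin_size)
            name = f"H3K4me2_{condition}.bedGraph"
            record(name, io_formats.write_bedgraph(track, out_dir / name))

    with open(out_dir / "dataset_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
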