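"""Stage orchestration: simulate -> pairs -> profiles -> map -> cooccupy
-> cluster -> enrich -> report.

Each stage reads its inputs from and writes its outputs to the configured
output directory, so stages can be re-run individually; ``run_pipeline``
executes a requested subset in dependency order and returns a manifest
with row counts and content hashes.  Runs are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import integration, io_formats, nucleosomes, profiles, simulate
from .config import PipelineConfig
from .core import (
    CONDITIONS,
    H3K4ME2,
    TF_NAMES,
    DependencyError,
    EstimationError,
    ParameterError,
    SignalTrack,
)
from .simulate import expression_class

log = logging.getLogger("chromcobind")

STAGES = ("simulate", "pairs", "profiles", "map", "cooccupy", "cluster",
          "enrich", "report")


def _require(out_dir: Path, names: Sequence[str], stage: str) -> None:
    missing = [n for n in names if not (out_dir / n).exists()]
    if missing:
        raise DependencyError(
            f"stage {stage!r} needs outputs of an earlier stage; "
            f"missing files: {missing}"
        )


def _load_genome_inputs(out_dir: Path, stage: str):
    _require(out_dir, ["genes.tsv", "chrom_sizes.tsv"], stage)
    genes = io_formats.read_gene_table(out_dir / "genes.tsv")
    sizes = pd.read_csv(out_dir / "chrom_sizes.tsv", sep="\t")
    chrom_lengths = dict(zip(sizes["chrom"], sizes["length"].astype(int)))
    return genes, chrom_lengths


def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> dict:
    genome = simulate.generate_genome(
        n_chroms=cfg.n_chroms,
        chrom_length=cfg.chrom_length,
        n_genes=cfg.n_genes,
        frac_mat_selective=cfg.frac_mat_selective,
        frac_imm_selective=cfg.frac_imm_selective,
        seed=cfg.seed,
    )
    truth = simulate.plant_enhancers(
        genome,
        n_enhancers=cfg.n_enhancers,
        sep_range=(cfg.sep_min, cfg.sep_max),
        seed=cfg.seed + 1,
    )
    tagsets = simulate.synthesize_all_tags(
        genome, truth,
        depth=cfg.depth,
        tf_depth=cfg.tf_depth,
        fragment_length_mean=cfg.fragment_length_mean,
        fragment_length_sd=cfg.fragment_length_sd,
        background_rate=cfg.background_rate,
        residual_fraction=cfg.residual_fraction,
        seed=cfg.seed + 2,
    )
    manifest = simulate.write_dataset(genome, truth, tagsets, out_dir,
                                      bin_size=cfg.bin_size)
    return manifest["files"]


def stage_pairs(cfg: PipelineConfig, out_dir: Path) -> dict:
    genes, chrom_lengths = _load_genome_inputs(out_dir, "pairs")
    _require(
        out_dir,
        [f"H3K4me2_{c}.bedGraph" for c in CONDITIONS]
        + [f"tags_{H3K4ME2}_{c}.tsv" for c in CONDITIONS],
        "pairs",
    )
    tracks = {
        c: io_formats.read_bedgraph(out_dir / f"H3K4me2_{c}.bedGraph", cfg.bin_size)
        for c in CONDITIONS
    }
    # nucleosomes are called on the condition-merged coverage
    merged_values: dict[str, np.ndarray] = {}
    for c in CONDITIONS:
        for chrom, arr in tracks[c].values.items():
            if chrom in merged_values:
                a, b = merged_values[chrom], arr
                if a.size < b.size:
                    a, b = b, a
                a = a.copy()
                a[: b.size] += b
                merged_values[chrom] = a
            else:
                merged_values[chrom] = arr.copy()
    merged = SignalTrack(values=merged_values, bin_size=cfg.bin_size)
    nucs = nucleosomes.call_nucleosomes(
        merged, min_peak_height=cfg.min_peak_height, min_spacing=cfg.min_spacing
    )
    pairs = nucleosomes.detect_pairs(
        nucs, merged, sep_min=cfg.sep_min, sep_max=cfg.sep_max,
        trough_fraction=cfg.trough_fraction,
    )
    nucleosomes.classify_pairs(pairs, genes, promoter_cutoff=cfg.promoter_cutoff)

    tags = {
        c: io_formats.read_tag_table(out_dir / f"tags_{H3K4ME2}_{c}.tsv",
                                     cfg.fragment_length_mean)
        for c in CONDITIONS
    }
    shift = _estimated_or_default(tags["mat"], chrom_lengths, cfg)
    nucleosomes.nsd_scores(pairs, tags["imm"], tags["mat"], shift=shift)

    table = pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "left_dyad": p.left.dyad,
                "right_dyad": p.right.dyad,
                "separation": p.separation,
                "locale": p.locale,
                "signal_imm": p.signal_imm,
                "signal_mat": p.signal_mat,
                "nsd": p.nsd,
            }
            for p in pairs
        ],
        columns=["chrom", "left_dyad", "right_dyad", "separation", "locale",
                 "signal_imm", "signal_mat", "nsd"],
    )
    files = {}
    files["pairs.tsv"] = {"rows": io_formats.write_tsv(table, out_dir / "pairs.tsv")}
    files["troughs.bed"] = {
        "rows": io_formats.write_bed(
            [p.trough for p in pairs], out_dir / "troughs.bed",
            names=[f"pair_{i + 1}" for i in range(len(pairs))],
        )
    }
    return files


def _estimated_or_default(tags, chrom_lengths, cfg: PipelineConfig) -> int:
    try:
        return profiles.estimate_shift(tags, chrom_lengths).shift
    except EstimationError:
        log.warning("fragment-shift estimation failed; using default %d",
                    cfg.shift_default)
        return cfg.shift_default


def _read_pairs_table(out_dir: Path, stage: str) -> pd.DataFrame:
    _require(out_dir, ["pairs.tsv"], stage)
    return pd.read_csv(out_dir / "pairs.tsv", sep="\t")


def _pairs_from_table(df: pd.DataFrame) -> list[nucleosomes.NucleosomePair]:
    out = []
    for row in df.itertuples(index=False):
        pair = nucleosomes.NucleosomePair(
            chrom=row.chrom,
            left=nucleosomes.Nucleosome(row.chrom, int(row.left_dyad), 0.0),
            right=nucleosomes.Nucleosome(row.chrom, int(row.right_dyad), 0.0),
            signal_imm=float(row.signal_imm),
            signal_mat=float(row.signal_mat),
            nsd=float(row.nsd),
            locale=str(row.locale),
        )
        out.append(pair)
    return out


def stage_profiles(cfg: PipelineConfig, out_dir: Path) -> dict:
    genes, chrom_lengths = _load_genome_inputs(out_dir, "profiles")
    df = _read_pairs_table(out_dir, "profiles")
    pairs = _pairs_from_table(df)
    anchors = [(p.chrom, p.center) for p in pairs]
    files: dict[str, dict] = {}
    shifts: dict[str, dict[str, int]] = {}
    for c in CONDITIONS:
        name = f"tags_{H3K4ME2}_{c}.tsv"
        _require(out_dir, [name], "profiles")
        tags = io_formats.read_tag_table(out_dir / name, cfg.fragment_length_mean)
        shift = _estimated_or_default(tags, chrom_lengths, cfg)
        shifts.setdefault(H3K4ME2, {})[c] = shift
        if anchors:
            prof = profiles.composite_profile(
                anchors, tags, shift, half_width=cfg.half_width,
                bin_size=cfg.bin_size, anchor_kind="pair_center",
            )
            table = pd.DataFrame({"offset": prof.offsets, "rpkm": prof.values})
            fname = f"profile_{H3K4ME2}_{c}.tsv"
            files[fname] = {"rows": io_formats.write_tsv(table, out_dir / fname)}
    with open(out_dir / "shifts.json", "w") as fh:
        json.dump(shifts, fh, indent=2, sort_keys=True)
    files["shifts.json"] = {"rows": sum(len(v) for v in shifts.values())}
    return files


def stage_map(cfg: PipelineConfig, out_dir: Path) -> dict:
    genes, _ = _load_genome_inputs(out_dir, "map")
    _require(out_dir, ["summits_NFE2.narrowPeak"], "map")
    summits = io_formats.read_narrowpeak(out_dir / "summits_NFE2.narrowPeak", "NFE2")
    entries = integration.nearest_summit_distance(genes, summits)
    table = pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "distance": -1 if e.distance is None else e.distance,
                "log2_fc": e.log2_fc,
                "knockout_class": e.knockout_class,
            }
            for e in entries
        ]
    )
    return {
        "regulation_map.tsv": {
            "rows": io_formats.write_tsv(table, out_dir / "regulation_map.tsv")
        }
    }


def _summits_by_tf(out_dir: Path, stage: str):
    names = [f"summits_{tf}.narrowPeak" for tf in TF_NAMES]
    _require(out_dir, names, stage)
    return {
        tf: io_formats.read_narrowpeak(out_dir / f"summits_{tf}.narrowPeak", tf)
        for tf in TF_NAMES
    }


def stage_cooccupy(cfg: PipelineConfig, out_dir: Path) -> dict:
    genes, _ = _load_genome_inputs(out_dir, "cooccupy")
    summits_by_tf = _summits_by_tf(out_dir, "cooccupy")
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        hist = integration.summit_distance_histogram(summits_by_tf)
    loci = integration.merge_cooccupancy(
        summits_by_tf, threshold=cfg.cooccupancy_threshold
    )
    labels = integration.gene_combination_assignment(
        genes, loci, cutoff=cfg.enhancer_cutoff
    )
    files = {}
    hist_table = pd.DataFrame(
        {"bin_left": hist.edges, "count": hist.counts, "smoothed": hist.smoothed}
    )
    files["summit_distance_histogram.tsv"] = {
        "rows": io_formats.write_tsv(hist_table, out_dir / "summit_distance_histogram.tsv")
    }
    files["cooccupancy_loci.bed"] = {
        "rows": io_formats.write_bed(
            [l.span for l in loci], out_dir / "cooccupancy_loci.bed",
            names=["+".join(sorted(l.tf_combination)) for l in loci],
        )
    }
    combo_table = pd.DataFrame(
        [
            {"gene_id": g, "combination": "+".join(sorted(lab)) if lab else "none"}
            for g, lab in sorted(labels.items())
        ]
    )
    files["gene_combinations.tsv"] = {
        "rows": io_formats.write_tsv(combo_table, out_dir / "gene_combinations.tsv")
    }
    with open(out_dir / "inflection.json", "w") as fh:
        json.dump({"inflection": hist.inflection, "used_default": hist.used_default},
                  fh, indent=2, sort_keys=True)
    files["inflection.json"] = {"rows": 1}
    return files


def stage_cluster(cfg: PipelineConfig, out_dir: Path) -> dict:
    genes, chrom_lengths = _load_genome_inputs(out_dir, "cluster")
    summits = io_formats.read_narrowpeak(out_dir / "summits_NFE2.narrowPeak", "NFE2")
    tag_names = [f"tags_{tf}_mat.tsv" for tf in TF_NAMES]
    _require(out_dir, tag_names, "cluster")
    tracks = {
        tf: io_formats.read_tag_table(out_dir / f"tags_{tf}_mat.tsv",
                                      cfg.fragment_length_mean)
        for tf in TF_NAMES
    }
    shifts = {
        tf: _estimated_or_default(tracks[tf], chrom_lengths, cfg)
        for tf in TF_NAMES
    }
    matrix = profiles.signal_matrix(
        summits, tracks, shifts, window=cfg.cluster_window,
        bin_size=cfg.bin_size, tf_order=TF_NAMES,
    )
    assignment = integration.kmeans_sites(matrix, k=cfg.k, seed=cfg.seed)
    table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in summits],
            "summit": [s.summit for s in summits],
            "name": [s.name for s in summits],
            "cluster": assignment.labels,
        }
    )
    return {
        "clusters.tsv": {
            "rows": io_formats.write_tsv(table, out_dir / "clusters.tsv")
        }
    }


def stage_enrich(cfg: PipelineConfig, out_dir: Path) -> dict:
    genes, _ = _load_genome_inputs(out_dir, "enrich")
    summits = io_formats.read_narrowpeak(out_dir / "summits_NFE2.narrowPeak", "NFE2")
    entries = integration.nearest_summit_distance(genes, summits)
    bound = {
        e.gene_id: (e.distance is not None and e.distance <= cfg.enhancer_cutoff)
        for e in entries
    }
    classes = {g.gene_id: expression_class(g, cfg.fc_threshold, cfg.fdr_threshold)
               for g in genes}
    mat_ids = {g for g, c in classes.items() if c == "mat"}
    imm_ids = {g for g, c in classes.items() if c == "imm"}
    rows = []
    if mat_ids and imm_ids:
        # mat-selective vs imm-selective genes, bound within the cutoff or not
        universe = sorted(mat_ids | imm_ids)
        label = {g: bound[g] for g in universe}
        result = integration.enrichment_test(
            label, True, lambda g: g in mat_ids
        )
        a, b = result.contingency[0]
        c, d = result.contingency[1]
        rows.append(
            {
                "comparison": "mat_vs_imm_bound_within_cutoff",
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": result.odds_ratio,
                "p_value": result.p_value,
                "method": result.method,
            }
        )
    table = pd.DataFrame(
        rows, columns=["comparison", "a", "b", "c", "d", "odds_ratio",
                       "p_value", "method"],
    )
    return {
        "enrichment.tsv": {
            "rows": io_formats.write_tsv(table, out_dir / "enrichment.tsv")
        }
    }


def stage_report(cfg: PipelineConfig, out_dir: Path) -> dict:
    files = {}
    for path in sorted(out_dir.iterdir()):
        if path.name in ("manifest.json",) or path.is_dir():
            continue
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        files[path.name] = {"sha256": digest, "bytes": path.stat().st_size}
    return files


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "pairs": stage_pairs,
    "profiles": stage_profiles,
    "map": stage_map,
    "cooccupy": stage_cooccupy,
    "cluster": stage_cluster,
    "enrich": stage_enrich,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages in dependency order; return the manifest.

    The manifest records the config hash and, per stage, every output
    file with its row count (and, for the report stage, content hashes).
    Rerunning with an identical config and seed reproduces identical
    outputs.
    """
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ParameterError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in requested]
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.hash(), "stages": {}}
    for stage in ordered:
        log.info("running stage %s", stage)
        manifest["stages"][stage] = _STAGE_FUNCS[stage](cfg, out_dir)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
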