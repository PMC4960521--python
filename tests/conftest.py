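"""Shared fixtures: one small synthetic study reused across the suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import chromcobind as cb
from chromcobind.simulate import coverage_track


@pytest.fixture(scope="session")
def genome():
    return cb.generate_genome(
        n_chroms=1, chrom_length=2_000_000, n_genes=200,
        frac_mat_selective=0.3, frac_imm_selective=0.2, seed=7,
    )


@pytest.fixture(scope="session")
def truth(genome):
    return cb.plant_enhancers(genome, n_enhancers=160, seed=8)


@pytest.fixture(scope="session")
def tagsets(genome, truth):
    return cb.synthesize_all_tags(genome, truth, depth=500, seed=9)


@pytest.fixture(scope="session")
def merged_track(genome, tagsets):
    tracks = {
        c: coverage_track(tagsets[c]["H3K4me2"], genome.chrom_lengths, bin_size=10)
        for c in cb.CONDITIONS
    }
    values = {
        chrom: tracks["imm"].values[chrom] + tracks["mat"].values[chrom]
        for chrom in tracks["imm"].values
    }
    return cb.SignalTrack(values=values, bin_size=10)


@pytest.fixture(scope="session")
def scored_pairs(genome, truth, tagsets, merged_track):
    nucs = cb.call_nucleosomes(merged_track, min_peak_height=2.0)
    pairs = cb.detect_pairs(nucs, merged_track)
    cb.classify_pairs(pairs, genome.genes)
    cb.nsd_scores(pairs, tagsets["imm"]["H3K4me2"], tagsets["mat"]["H3K4me2"],
                  shift=150)
    return pairs


def match_truth(pair, truth, tolerance=60):
    """The planted enhancer a detected pair corresponds to, if any."""
    for e in truth:
        if (
            pair.chrom == e.chrom
            and abs(pair.left.dyad - e.left_dyad) <= tolerance
            and abs(pair.right.dyad - e.right_dyad) <= tolerance
        ):
            return e
    return None


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """Two full pipeline runs with the same seed, for determinism checks."""
    from chromcobind.config import validate_config
    from chromcobind.pipeline import run_pipeline

    manifests = []
    for name in ("run_a", "run_b"):
        out = tmp_path_factory.mktemp(name)
        cfg = validate_config({"out_dir": str(out), "seed": 5})
        manifests.append((out, run_pipeline(cfg)))
    return manifests
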