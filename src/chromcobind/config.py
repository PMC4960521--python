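"""Pipeline configuration: one flat document, defaults = the study's
printed operating constants.

Every threshold the analysis uses lives here so a run is fully described
by one YAML document plus one integer seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

from .core import ParameterError


@dataclass
class PipelineConfig:
    # analysis thresholds (defaults are the study's printed values)
    promoter_cutoff: int = 2_000        # promoter vs distal pair boundary, bases
    enhancer_cutoff: int = 20_000       # distance to impute an enhancer to a gene
    secondary_cutoff: int = 50_000      # wider binding-fraction cutoff
    cooccupancy_threshold: int = 300    # summit merge distance, bases
    sep_min: int = 250                  # minimum inter-dyad separation, bases
    sep_max: int = 450                  # maximum inter-dyad separation, bases
    trough_fraction: float = 0.5        # trough depletion vs flank signal
    bin_size: int = 10                  # profile window width, bases
    pair_bin: int = 1_000               # pairs per NSD ranking bin
    gene_bin: int = 50                  # genes per expression bin
    fc_threshold: float = 1.5           # differential expression fold change
    fdr_threshold: float = 0.05
    ko_fc_threshold: float = 2.0        # knockout response fold change
    k: int = 3                          # k-means cluster count
    shift_default: int = 150            # fallback fragment half-length, bases
    min_peak_height: float = 2.0        # nucleosome caller height floor
    min_spacing: int = 147              # nucleosome caller suppression, bases
    half_width: int = 1_500             # composite profile half-window, bases
    cluster_window: int = 1_000         # signal-matrix window, bases

    # synthetic dataset
    n_chroms: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 200
    frac_mat_selective: float = 0.3
    frac_imm_selective: float = 0.2
    n_enhancers: int = 160
    depth: int = 500                    # H3K4me2 tags per enhancer
    tf_depth: int = 250                 # TF tags per bound enhancer
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 30.0
    background_rate: float = 0.5        # tags per kb
    residual_fraction: float = 0.1      # off-condition signal fraction

    seed: int = 0
    out_dir: str = "chromcobind_out"

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


_POSITIVE = {
    "promoter_cutoff", "enhancer_cutoff", "secondary_cutoff",
    "cooccupancy_threshold", "sep_min", "sep_max", "trough_fraction",
    "bin_size", "pair_bin", "gene_bin", "fc_threshold", "fdr_threshold",
    "ko_fc_threshold", "k", "shift_default", "min_spacing", "half_width",
    "cluster_window", "n_chroms", "chrom_length", "n_genes", "n_enhancers",
    "fragment_length_mean",
}


def validate_config(raw: Mapping[str, Any] | None) -> PipelineConfig:
    """Build a PipelineConfig from a raw mapping.

    Unknown keys are an error; missing keys take the defaults; simple
    cross-field constraints (sep_min < sep_max) are enforced.
    """
    raw = dict(raw or {})
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for name, value in raw.items():
        ftype = fields[name].type
        try:
            if ftype == "int":
                if isinstance(value, float) and not value.is_integer():
                    raise ValueError("not an integer")
                kwargs[name] = int(value)
            elif ftype == "float":
                kwargs[name] = float(value)
            else:
                kwargs[name] = str(value)
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"config key {name!r}: {exc}") from exc
    cfg = PipelineConfig(**kwargs)
    for name in _POSITIVE:
        if getattr(cfg, name) <= 0:
            raise ParameterError(f"config key {name!r} must be positive")
    if cfg.sep_min > cfg.sep_max:
        raise ParameterError("sep_min must not exceed sep_max")
    for name in ("frac_mat_selective", "frac_imm_selective", "residual_fraction",
                 "fdr_threshold"):
        if not (0 <= getattr(cfg, name) <= 1):
            raise ParameterError(f"config key {name!r} must lie in [0, 1]")
    if cfg.depth < 0 or cfg.tf_depth < 0 or cfg.background_rate < 0:
        raise ParameterError("depths and rates must be nonnegative")
    return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config file (None -> all defaults)."""
    if path is None:
        return validate_config({})
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ParameterError("config document must be a mapping")
    return validate_config(raw)
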