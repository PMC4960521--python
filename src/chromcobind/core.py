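"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open throughout the package; any
1-based source format is converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


class ChromcobindError(Exception):
    """Base class for package errors."""


class ParameterError(ChromcobindError, ValueError):
    """Invalid parameter value."""


class FormatError(ChromcobindError, ValueError):
    """Malformed input file."""


class ValidationError(ChromcobindError, ValueError):
    """Well-formed input violating a semantic constraint."""


class PlacementError(ChromcobindError, RuntimeError):
    """Synthetic element placement failed after bounded retries."""


class EstimationError(ChromcobindError, RuntimeError):
    """A statistical estimate could not be computed from the input."""


class DependencyError(ChromcobindError, RuntimeError):
    """A pipeline stage's required input is missing."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakSummit:
    """A TF binding site reduced to its single-base summit coordinate."""

    interval: GenomicInterval
    summit: int
    score: float
    tf_name: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValidationError("negative peak score")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its TSS and two-condition expression indices."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    expr_imm: float
    expr_mat: float
    fdr: float

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"{self.gene_id}: negative TSS")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValidationError(f"{self.gene_id}: fdr {self.fdr} outside [0, 1]")
        if self.expr_imm < 0 or self.expr_mat < 0:
            raise ValidationError(f"{self.gene_id}: negative expression")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: invalid strand {self.strand!r}")


@dataclass
class SignalTrack:
    """Binned nonnegative coverage for one mark/TF in one condition.

    ``values`` maps chromosome name to a dense per-bin array; bin i covers
    bases [i * bin_size, (i + 1) * bin_size).
    """

    values: dict[str, np.ndarray]
    bin_size: int = 1
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ParameterError("bin_size must be >= 1")
        if self.normalization not in ("raw", "RPKM"):
            raise ParameterError(f"unknown normalization {self.normalization!r}")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size and arr.min() < 0:
                raise ValidationError(f"negative signal on {chrom}")
            self.values[chrom] = arr


@dataclass
class ReadTagSet:
    """Stranded sequencing tags: 5' end positions plus strand per tag.

    For minus-strand tags ``pos5`` records the rightmost base of the read
    (the 5' end on the minus strand).
    """

    tags: pd.DataFrame  # columns: chrom (str), pos5 (int), strand (+/-)
    fragment_length_mean: float = 300.0

    REQUIRED = ("chrom", "pos5", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.tags.columns]
        if missing:
            raise ValidationError(f"tag table missing columns {missing}")
        bad = ~self.tags["strand"].isin(["+", "-"])
        if bad.any():
            raise ValidationError("tag strands must be '+' or '-'")

    @property
    def total_count(self) -> int:
        return len(self.tags)

    def shifted_positions(self, shift: int) -> dict[str, np.ndarray]:
        """Per-chromosome sorted fragment-center estimates.

        Plus-strand tags move ``shift`` bases rightward, minus-strand tags
        ``shift`` bases leftward; positions shifted below zero are dropped.
        """
        plus = self.tags["strand"].to_numpy() == "+"
        pos = self.tags["pos5"].to_numpy(dtype=np.int64).copy()
        pos[plus] += shift
        pos[~plus] -= shift
        out: dict[str, np.ndarray] = {}
        chroms = self.tags["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            p = pos[chroms == chrom]
            p = p[p >= 0]
            out[chrom] = np.sort(p)
        return out

    def strand_start_vectors(self, chrom_lengths: dict[str, int]
                             ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-base 5'-end count vectors (plus, minus) per chromosome."""
        out = {}
        for chrom, length in chrom_lengths.items():
            sub = self.tags[self.tags["chrom"] == chrom]
            plus = np.bincount(
                sub.loc[sub["strand"] == "+", "pos5"].to_numpy(), minlength=length
            )[:length]
            minus = np.bincount(
                sub.loc[sub["strand"] == "-", "pos5"].to_numpy(), minlength=length
            )[:length]
            out[chrom] = (plus.astype(float), minus.astype(float))
        return out


@dataclass
class Nucleosome:
    """A called nucleosome position (dyad) with its signal height."""

    chrom: str
    dyad: int
    occupancy: float


@dataclass
class NucleosomePair:
    """Two H3K4me2-marked nucleosomes flanking a depleted trough.

    The operational unit of an active cis-regulatory element: paired
    nucleosomes 250-450 bp apart with H3K4me2-depleted chromatin between
    them.  ``nsd`` is the signed stabilization-destabilization score
    contrasting mature vs immature signal.
    """

    chrom: str
    left: Nucleosome
    right: Nucleosome
    signal_imm: float = 0.0
    signal_mat: float = 0.0
    nsd: float = 0.0
    locale: str = ""  # "promoter" | "distal"

    @property
    def separation(self) -> int:
        return self.right.dyad - self.left.dyad

    @property
    def center(self) -> int:
        return (self.left.dyad + self.right.dyad) // 2

    @property
    def trough(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.left.dyad, self.right.dyad)


@dataclass
class RegulationEntry:
    """One gene's distance to its nearest TF summit plus expression change."""

    gene_id: str
    distance: Optional[int]  # None when no summit on the gene's chromosome
    log2_fc: float
    nearest_summit: Optional[PeakSummit] = None
    knockout_class: str = "unknown"  # down | up | unchanged | unknown


@dataclass
class CooccupancyLocus:
    """Summits merged by single linkage at the co-occupancy threshold."""

    chrom: str
    span: GenomicInterval
    members: list[PeakSummit] = field(default_factory=list)

    @property
    def tf_combination(self) -> frozenset[str]:
        return frozenset(s.tf_name for s in self.members)


@dataclass
class EnrichmentResult:
    """2x2 contingency with Fisher exact p and odds ratio."""

    contingency: np.ndarray
    odds_ratio: float
    p_value: float
    method: str = "fisher_two_sided"


TF_NAMES = ("NFE2", "FLI1", "RUNX1")
H3K4ME2 = "H3K4me2"
CONDITIONS = ("imm", "mat")
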