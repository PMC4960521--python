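"""Nucleosome calling, paired-enhancer detection, and NSD scoring.

The enhancer unit here is a pair of H3K4me2-marked nucleosomes flanking a
250-450 bp trough of depleted signal.  The nucleosome stabilization-
destabilization (NSD) score quantifies, per pair, the difference in
H3K4me2 signal between the mature and immature conditions:

    nsd = (S_mat - S_imm) / (S_mat + S_imm + eps),  eps = 1 per million,

where S_c is the per-million-normalised count of condition-c fragment
centers falling in the two nucleosome windows (each dyad +/- 73 bases).
The score is bounded in (-1, 1), zero when the two conditions match, and
antisymmetric in the two conditions up to the eps regularisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .core import (
    GeneRecord,
    Nucleosome,
    NucleosomePair,
    ParameterError,
    ReadTagSet,
    SignalTrack,
)

NUCLEOSOME_HALF = 73  # half the 147-bp core particle
SMOOTH_WINDOW = 30    # moving-average window in bases for peak calling


def _smoothed(track: SignalTrack, chrom: str) -> np.ndarray:
    arr = track.values[chrom]
    win = max(1, int(round(SMOOTH_WINDOW / track.bin_size)))
    if win <= 1 or arr.size == 0:
        return arr.astype(float)
    return uniform_filter1d(arr.astype(float), size=win, mode="nearest")


def call_nucleosomes(
    track: SignalTrack,
    min_peak_height: float = 1.0,
    min_spacing: int = 147,
) -> list[Nucleosome]:
    """Call nucleosome dyads as spaced local maxima of smoothed coverage.

    The raw track is smoothed with a 30-base moving average; local maxima
    at least ``min_peak_height`` high become candidates, and maxima closer
    than ``min_spacing`` bases are greedily suppressed keeping the higher
    (ties: the leftmost).  Returned sorted by (chrom, dyad).
    """
    if track.normalization != "raw":
        raise ParameterError("nucleosome calling requires a raw coverage track")
    if min_spacing < 1:
        raise ParameterError("min_spacing must be >= 1")
    out: list[Nucleosome] = []
    for chrom in sorted(track.values):
        s = _smoothed(track, chrom)
        if s.size == 0:
            continue
        idx, props = find_peaks(s, height=min_peak_height, plateau_size=1)
        # plateau candidates: use the plateau midpoint
        left = props.get("left_edges", idx)
        right = props.get("right_edges", idx)
        idx = (left + right) // 2
        heights = s[idx]
        order = np.lexsort((idx, -heights))  # height desc, then position asc
        kept_pos: list[int] = []
        kept: list[tuple[int, float]] = []
        spacing_bins = min_spacing / track.bin_size
        for j in order:
            if all(abs(idx[j] - p) >= spacing_bins for p in kept_pos):
                kept_pos.append(idx[j])
                kept.append((idx[j], heights[j]))
        for pos_bin, height in sorted(kept):
            dyad = pos_bin * track.bin_size + track.bin_size // 2
            out.append(Nucleosome(chrom=chrom, dyad=int(dyad), occupancy=float(height)))
    return out


def detect_pairs(
    nucleosomes: list[Nucleosome],
    track: SignalTrack,
    sep_min: int = 250,
    sep_max: int = 450,
    trough_fraction: float = 0.5,
) -> list[NucleosomePair]:
    """Detect paired nucleosomes flanking a depleted trough.

    Adjacent dyads ``sep_min``-``sep_max`` bases apart qualify when the
    mean smoothed signal over the central third of the inter-dyad span is
    below ``trough_fraction`` times the lower of the two dyad heights.
    Pairing is greedy left-to-right and non-overlapping: each nucleosome
    joins at most one pair.
    """
    if sep_min < 1 or sep_max < sep_min:
        raise ParameterError("need 1 <= sep_min <= sep_max")
    by_chrom: dict[str, list[Nucleosome]] = {}
    for n in nucleosomes:
        by_chrom.setdefault(n.chrom, []).append(n)
    pairs: list[NucleosomePair] = []
    for chrom in sorted(by_chrom):
        nucs = sorted(by_chrom[chrom], key=lambda n: n.dyad)
        s = _smoothed(track, chrom) if chrom in track.values else np.zeros(0)
        i = 0
        while i + 1 < len(nucs):
            left, right = nucs[i], nucs[i + 1]
            sep = right.dyad - left.dyad
            if sep_min <= sep <= sep_max and _trough_depleted(
                s, track.bin_size, left, right, trough_fraction
            ):
                pairs.append(NucleosomePair(chrom=chrom, left=left, right=right))
                i += 2
            else:
                i += 1
    return pairs


def _trough_depleted(s: np.ndarray, bin_size: int, left: Nucleosome,
                     right: Nucleosome, trough_fraction: float) -> bool:
    sep = right.dyad - left.dyad
    lo = left.dyad + sep // 3
    hi = right.dyad - sep // 3
    b0, b1 = lo // bin_size, max(lo // bin_size + 1, hi // bin_size + 1)
    if s.size == 0:
        return True
    window = s[min(b0, s.size - 1): min(b1, s.size)]
    if window.size == 0:
        return True
    flank = min(left.occupancy, right.occupancy)
    return float(window.mean()) < trough_fraction * flank


def classify_pairs(
    pairs: list[NucleosomePair],
    genes: list[GeneRecord],
    promoter_cutoff: int = 2_000,
) -> list[NucleosomePair]:
    """Label each pair promoter (< cutoff from the nearest TSS) or distal.

    Chromosomes without annotated genes yield distal pairs.  The cutoff is
    strict: a pair centered exactly at the cutoff distance is distal.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    for pair in pairs:
        tss = tss_by_chrom.get(pair.chrom)
        if tss is None or tss.size == 0:
            pair.locale = "distal"
            continue
        i = np.searchsorted(tss, pair.center)
        dists = [abs(int(tss[j]) - pair.center) for j in (i - 1, i) if 0 <= j < tss.size]
        pair.locale = "promoter" if min(dists) < promoter_cutoff else "distal"
    return pairs


def nsd_score(
    pair: NucleosomePair,
    tags_imm: ReadTagSet,
    tags_mat: ReadTagSet,
    shift: int = 150,
    eps: float = 1.0,
) -> float:
    """Score one pair; see the module docstring for the formula.

    ``shift`` converts stranded 5' tag positions into fragment-center
    estimates before counting (default 150, half a typical fragment).
    Also stores ``signal_imm``/``signal_mat`` on the pair.
    """
    return nsd_scores([pair], tags_imm, tags_mat, shift=shift, eps=eps)[0]


def nsd_scores(
    pairs: list[NucleosomePair],
    tags_imm: ReadTagSet,
    tags_mat: ReadTagSet,
    shift: int = 150,
    eps: float = 1.0,
) -> np.ndarray:
    """Vectorised NSD scoring of many pairs against two tag libraries."""
    if tags_imm.total_count == 0 or tags_mat.total_count == 0:
        raise ParameterError("both tag libraries must be nonempty")
    pos_imm = tags_imm.shifted_positions(shift)
    pos_mat = tags_mat.shifted_positions(shift)
    scale_imm = 1e6 / tags_imm.total_count
    scale_mat = 1e6 / tags_mat.total_count
    scores = np.zeros(len(pairs))
    for k, pair in enumerate(pairs):
        s_imm = _window_count(pos_imm.get(pair.chrom), pair) * scale_imm
        s_mat = _window_count(pos_mat.get(pair.chrom), pair) * scale_mat
        pair.signal_imm = float(s_imm)
        pair.signal_mat = float(s_mat)
        pair.nsd = float((s_mat - s_imm) / (s_mat + s_imm + eps))
        scores[k] = pair.nsd
    return scores


def _window_count(pos: np.ndarray | None, pair: NucleosomePair) -> int:
    """Fragment centers in the two nucleosome windows (dyad +/- 73)."""
    if pos is None or pos.size == 0:
        return 0
    total = 0
    for dyad in (pair.left.dyad, pair.right.dyad):
        lo, hi = dyad - NUCLEOSOME_HALF, dyad + NUCLEOSOME_HALF + 1
        total += int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))
    return total


@dataclass
class RankedBins:
    """Pairs partitioned into consecutive bins along the NSD ranking."""

    bins: list[list[NucleosomePair]] = field(default_factory=list)
    direction: str = "mat_selective"
    partial_last: bool = False

    def __len__(self) -> int:
        return len(self.bins)


def rank_and_bin(
    pairs: list[NucleosomePair],
    direction: str = "mat_selective",
    bin_size: int = 1_000,
) -> RankedBins:
    """Rank pairs by NSD and split into consecutive bins of ``bin_size``.

    ``mat_selective`` ranks descending (most mature-gained first),
    ``imm_selective`` ascending.  Ties break by (chrom, left dyad) so the
    ordering is deterministic.  A final partial bin is kept and flagged.
    """
    if bin_size < 1:
        raise ParameterError("bin_size must be >= 1")
    if direction not in ("mat_selective", "imm_selective"):
        raise ParameterError(f"unknown direction {direction!r}")
    sign = -1.0 if direction == "mat_selective" else 1.0
    ordered = sorted(pairs, key=lambda p: (sign * p.nsd, p.chrom, p.left.dyad))
    bins = [ordered[i: i + bin_size] for i in range(0, len(ordered), bin_size)]
    partial = bool(bins) and len(bins[-1]) < bin_size
    return RankedBins(bins=bins, direction=direction, partial_last=partial)
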