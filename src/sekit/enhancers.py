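"""Typical/super-enhancer identification from H3K27ac peaks and signal.

The procedure is the stitched-enhancer (ROSE) lineage: drop promoter-proximal
peaks, merge neighbouring distal peaks whose gap is under the stitching
threshold (12.5 kb by default) into enhancer units, rank the units by total
H3K27ac signal, and split the ranked curve at the point where a slope-1 line
is tangent to the curve after both axes are scaled to the unit square.
Enhancers above the tangency point are super-enhancers (SEs); the rest are
typical enhancers (TEs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import (
    Gene,
    GenomicInterval,
    Peak,
    PipelineParams,
    SignalTrack,
    ValidationError,
)

__all__ = [
    "StitchedEnhancer",
    "SeCutoff",
    "filter_distal",
    "stitch",
    "quantify",
    "find_se_cutoff",
    "call_enhancers",
    "profile_matrix",
]


@dataclass(frozen=True)
class StitchedEnhancer:
    """A merged cluster of distal peaks with its total signal and rank.

    ``rank`` is 1-based ascending by total signal (1 = weakest); within one
    result set ``is_super`` is true exactly for a contiguous top block of
    ranks.
    """

    region: GenomicInterval
    constituent_peaks: Tuple[Peak, ...]
    total_signal: float = 0.0
    rank: int = 0
    is_super: bool = False

    def __post_init__(self) -> None:
        if not self.constituent_peaks:
            raise ValidationError("stitched enhancer needs >=1 constituent peak")
        lo = min(p.start for p in self.constituent_peaks)
        hi = max(p.end for p in self.constituent_peaks)
        if (self.region.start, self.region.end) != (lo, hi):
            raise ValidationError("region must span exactly its constituents")
        if self.total_signal < 0:
            raise ValidationError("total_signal must be non-negative")


@dataclass(frozen=True)
class SeCutoff:
    """The tangency point splitting super from typical enhancers."""

    tangency_rank: int  # 1-based rank of the tangency point
    tangency_signal: float
    n_super: int
    n_typical: int


def _nearest_tss_distance(positions: np.ndarray, tss: np.ndarray) -> np.ndarray:
    """Distance from each query position to its nearest TSS (both sorted-free)."""
    order = np.argsort(tss)
    sorted_tss = tss[order]
    idx = np.searchsorted(sorted_tss, positions)
    best = np.full(positions.shape, np.iinfo(np.int64).max, dtype=np.int64)
    left = idx - 1
    ok = left >= 0
    best[ok] = np.abs(positions[ok] - sorted_tss[left[ok]])
    ok = idx < len(sorted_tss)
    best[ok] = np.minimum(best[ok], np.abs(positions[ok] - sorted_tss[idx[ok]]))
    return best


def filter_distal(
    peaks: Sequence[Peak], genes: Sequence[Gene], params: PipelineParams | None = None
) -> List[Peak]:
    """Keep distal peaks: boundary >= 1.5 kb from the nearest TSS, or peak
    center >= 3 kb from the nearest TSS (the two clauses are alternative
    sufficiency criteria; set ``params.distal_conjunction`` to require both).

    A TSS inside a peak gives both distances 0, so such peaks are always
    promoter-proximal. Input order is preserved.
    """
    if not genes:
        raise ValidationError("distal filtering needs a non-empty gene annotation")
    params = params or PipelineParams()
    tss_by_chrom: Dict[str, List[int]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss_pos)
    kept: List[Peak] = []
    for p in peaks:
        tss_list = tss_by_chrom.get(p.chrom)
        if tss_list is None:
            kept.append(p)  # no TSS on this chromosome: trivially distal
            continue
        tss = np.asarray(tss_list, dtype=np.int64)
        # distance from the nearest peak boundary to the nearest TSS
        # (0 for a TSS inside the peak)
        d = np.where(tss < p.start, p.start - tss, np.maximum(tss - p.end, 0))
        edge_dist = int(d.min())
        center_dist = int(
            _nearest_tss_distance(
                np.asarray([p.interval.midpoint], dtype=np.int64), tss
            )[0]
        )
        boundary_ok = edge_dist >= params.distal_boundary
        center_ok = center_dist >= params.distal_center
        if params.distal_conjunction:
            distal = boundary_ok and center_ok
        else:
            distal = boundary_ok or center_ok
        if distal:
            kept.append(p)
    return kept


def stitch(peaks: Sequence[Peak], stitch_gap: int = 12_500) -> List[StitchedEnhancer]:
    """Single-linkage merge of peaks whose gap is strictly under ``stitch_gap``.

    The gap between two peaks is end-of-one to start-of-next (0 when they
    overlap or touch). Every input peak lands in exactly one output enhancer;
    output is sorted by position.
    """
    by_chrom: Dict[str, List[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: List[StitchedEnhancer] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cluster: List[Peak] = []
        cluster_end = -1
        for p in chrom_peaks:
            gap = max(0, p.start - cluster_end)
            if cluster and gap < stitch_gap:
                cluster.append(p)
                cluster_end = max(cluster_end, p.end)
            else:
                if cluster:
                    out.append(_make_enhancer(chrom, cluster))
                cluster = [p]
                cluster_end = p.end
        if cluster:
            out.append(_make_enhancer(chrom, cluster))
    return out


def _make_enhancer(chrom: str, cluster: List[Peak]) -> StitchedEnhancer:
    lo = min(p.start for p in cluster)
    hi = max(p.end for p in cluster)
    region = GenomicInterval(chrom, lo, hi, f"{chrom}:{lo}-{hi}")
    return StitchedEnhancer(region, tuple(cluster))


def quantify(
    enhancers: Sequence[StitchedEnhancer], track: SignalTrack
) -> List[StitchedEnhancer]:
    """Attach total H3K27ac signal (area over the region) and ascending ranks.

    Ties in total signal break by genomic position so ranking is deterministic.
    """
    scored = [
        replace(e, total_signal=track.area(e.region.chrom, e.region.start, e.region.end))
        for e in enhancers
    ]
    order = sorted(
        range(len(scored)),
        key=lambda i: (
            scored[i].total_signal,
            scored[i].region.chrom,
            scored[i].region.start,
        ),
    )
    ranked = list(scored)
    for rank0, i in enumerate(order):
        ranked[i] = replace(scored[i], rank=rank0 + 1)
    return ranked


def find_se_cutoff(ranked_signals: Sequence[float]) -> SeCutoff:
    """Locate the slope-1 tangency point on the ranked-signal curve.

    Both axes are scaled to the unit square (x = rank/(N-1) over 0-based
    ranks, y = signal/max). The tangency point is where a line of slope 1
    supports the scaled curve from below — the index minimizing y - x, which
    for a convex ascending curve is exactly where the discrete slope crosses
    1. Ties resolve to the higher-signal side (fewer super-enhancers).
    Enhancers with signal strictly above the tangency signal are super.

    The labels are invariant under scaling all signals by a positive
    constant, since scaling cancels in y.
    """
    s = np.asarray(ranked_signals, dtype=float)
    if s.size < 3:
        raise ValidationError("need at least 3 enhancers to locate a cutoff")
    if np.any(np.diff(s) < 0):
        s = np.sort(s)
    smax = s[-1]
    if smax <= 0:
        raise ValidationError("degenerate curve: maximum signal is 0")
    n = s.size
    x = np.arange(n, dtype=float) / (n - 1)
    y = s / smax
    d = y - x
    # last index attaining the minimum => ties go to the higher-signal side
    tangency_idx = int(n - 1 - np.argmin(d[::-1]))
    tangency_signal = float(s[tangency_idx])
    n_super = int(np.sum(s > tangency_signal))
    return SeCutoff(
        tangency_rank=tangency_idx + 1,
        tangency_signal=tangency_signal,
        n_super=n_super,
        n_typical=n - n_super,
    )


def call_enhancers(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    track: SignalTrack,
    params: PipelineParams | None = None,
) -> Tuple[List[StitchedEnhancer], SeCutoff | None]:
    """Full enhancer call: distal filter -> stitch -> quantify -> SE cutoff.

    Returns the labelled enhancers sorted by position and the cutoff record,
    or ``(\\[], None)`` when no distal peaks survive. A flat signal curve
    (max == min) yields zero super-enhancers rather than an error: "no
    elbow" is a meaningful empirical outcome.
    """
    params = params or PipelineParams()
    distal = filter_distal(peaks, genes, params)
    if not distal:
        return [], None
    stitched = stitch(distal, params.stitch_gap)
    ranked = quantify(stitched, track)
    signals = np.asarray(sorted(e.total_signal for e in ranked))
    if signals.size < 3 or signals[-1] <= 0 or signals[0] == signals[-1]:
        cutoff = SeCutoff(
            tangency_rank=len(ranked),
            tangency_signal=float(signals[-1]),
            n_super=0,
            n_typical=len(ranked),
        )
    else:
        cutoff = find_se_cutoff(signals)
    labelled = [
        replace(e, is_super=e.total_signal > cutoff.tangency_signal) for e in ranked
    ]
    return labelled, cutoff


def profile_matrix(
    anchors: Sequence[Peak | GenomicInterval | Gene],
    track: SignalTrack,
    flank: int = 2_000,
    nbins: int = 100,
) -> Tuple[np.ndarray, np.ndarray]:
    """Average-signal profile around anchor points (metagene-style).

    The anchor point is the summit for a Peak, the TSS for a Gene, and the
    midpoint for a bare interval. Row r, column b holds the mean signal
    density over the b-th of ``nbins`` equal windows spanning
    ``[anchor - flank, anchor + flank)``; windows clipped at the chromosome
    start contribute 0 for the missing bases. Returns (matrix, column means).
    """
    if flank <= 0 or nbins < 1:
        raise ValidationError("flank must be > 0 and nbins >= 1")
    mat = np.zeros((len(anchors), nbins), dtype=float)
    edges = np.linspace(-flank, flank, nbins + 1)
    for r, anchor in enumerate(anchors):
        if isinstance(anchor, Peak):
            chrom, center = anchor.chrom, anchor.summit
        elif isinstance(anchor, Gene):
            chrom, center = anchor.chrom, anchor.tss_pos
        else:
            chrom, center = anchor.chrom, anchor.midpoint
        for b in range(nbins):
            lo = center + int(edges[b])
            hi = center + int(edges[b + 1])
            width = hi - lo
            lo_clipped = max(lo, 0)
            if lo_clipped >= hi:
                continue
            mat[r, b] = track.area(chrom, lo_clipped, hi) / width
    return mat, mat.mean(axis=0) if len(anchors) else np.zeros(nbins)


def plot_se_curve(signals: Sequence[float], cutoff: SeCutoff, out_path) -> None:
    """Write the ranked hockey-stick curve with the tangency cutoff marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s = np.sort(np.asarray(signals, dtype=float))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(np.arange(1, s.size + 1), s, color="0.3", lw=1.5)
    ax.axvline(cutoff.tangency_rank, color="firebrick", ls="--", lw=1)
    ax.axhline(cutoff.tangency_signal, color="firebrick", ls=":", lw=1)
    ax.set_xlabel("enhancer rank (ascending signal)")
    ax.set_ylabel("total H3K27ac signal")
    ax.set_title(f"{cutoff.n_super} super / {cutoff.n_typical} typical")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
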