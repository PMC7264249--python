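"""Peak-to-gene annotation, target-gene calling and co-binding analysis.

A TF's candidate targets are the genes that are both adjacent to one of its
peaks (nearest-TSS assignment) and differentially expressed upon pathway
stimulation.  Two TF peak sets co-bind a site when their summits lie within
a distance threshold (<200 bp by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np

from .core import Gene, Peak, ValidationError

__all__ = [
    "PeakGeneLink",
    "TargetCall",
    "SetSummary",
    "CobindResult",
    "annotate_peaks",
    "bound_genes",
    "call_targets",
    "summarize_sets",
    "cobinding",
    "novel_vs_reported",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakGeneLink:
    """A peak assigned to its nearest gene.

    ``distance`` is the summit-to-TSS separation signed by the gene strand:
    negative means the summit lies upstream of the TSS in the gene's
    orientation.
    """

    peak: Peak
    gene_id: str
    distance: int


@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    bound: bool
    de_status: str  # up / down / none
    is_target: bool

    def __post_init__(self) -> None:
        if self.de_status not in ("up", "down", "none"):
            raise ValidationError(f"bad de_status {self.de_status!r}")
        if self.is_target != (self.bound and self.de_status != "none"):
            raise ValidationError("is_target must equal bound AND differentially expressed")


@dataclass(frozen=True)
class SetSummary:
    """Venn-diagram counts for two sets."""

    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    n_a_only: int
    n_b_only: int


@dataclass(frozen=True)
class CobindResult:
    """Partition of two peak sets into co-bound pairs and unique peaks."""

    pairs: Tuple[Tuple[Peak, Peak], ...]
    a_only: Tuple[Peak, ...]
    b_only: Tuple[Peak, ...]


def annotate_peaks(peaks: Sequence[Peak], genes: Sequence[Gene]) -> List[PeakGeneLink]:
    """Assign each peak to the gene whose TSS is nearest its summit.

    Ties break by smaller absolute distance, then lexicographic gene_id.
    Assignments and distances are invariant under shifting all coordinates
    by a constant.
    """
    if not genes:
        raise ValidationError("peak annotation needs a non-empty gene annotation")
    by_chrom: Dict[str, List[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    sorted_genes: Dict[str, Tuple[np.ndarray, List[Gene]]] = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.tss_pos, g.gene_id))
        sorted_genes[chrom] = (
            np.asarray([g.tss_pos for g in glist], dtype=np.int64),
            glist,
        )
    links: List[PeakGeneLink] = []
    for p in peaks:
        if p.chrom not in sorted_genes:
            raise ValidationError(f"no TSS on chromosome {p.chrom!r}")
        tss, glist = sorted_genes[p.chrom]
        i = int(np.searchsorted(tss, p.summit))
        candidates = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(glist):
                g = glist[j]
                candidates.append((abs(p.summit - g.tss_pos), g.gene_id, g))
        best = min(candidates)
        g = best[2]
        signed = p.summit - g.tss_pos if g.strand == "+" else g.tss_pos - p.summit
        links.append(PeakGeneLink(p, g.gene_id, signed))
    return links


def bound_genes(links: Iterable[PeakGeneLink]) -> Set[str]:
    """The set of gene ids adjacent to at least one peak."""
    return {link.gene_id for link in links}


def call_targets(
    bound_gene_ids: Set[str],
    deg_table: Dict[str, str],
    annotation_ids: Set[str] | None = None,
) -> List[TargetCall]:
    """Target genes = bound AND differentially expressed; direction carried.

    DEG entries absent from the annotation are warned about but retained,
    so targets are never silently dropped by an annotation mismatch.
    """
    if annotation_ids is not None:
        missing = set(deg_table) - annotation_ids
        if missing:
            logger.warning(
                "%d DEG gene(s) absent from the annotation (retained): %s",
                len(missing), ", ".join(sorted(missing)[:5]),
            )
    all_ids = set(bound_gene_ids) | set(deg_table)
    calls = []
    for gene_id in sorted(all_ids):
        bound = gene_id in bound_gene_ids
        de_status = deg_table.get(gene_id, "none")
        calls.append(
            TargetCall(
                gene_id=gene_id,
                bound=bound,
                de_status=de_status,
                is_target=bound and de_status != "none",
            )
        )
    return calls


def summarize_sets(a: Iterable, b: Iterable) -> SetSummary:
    """Exact Venn counts for two sets (inclusion-exclusion holds by
    construction)."""
    sa, sb = set(a), set(b)
    inter = len(sa & sb)
    return SetSummary(
        n_a=len(sa),
        n_b=len(sb),
        n_intersection=inter,
        n_union=len(sa) + len(sb) - inter,
        n_a_only=len(sa) - inter,
        n_b_only=len(sb) - inter,
    )


def cobinding(
    peaks_a: Sequence[Peak],
    peaks_b: Sequence[Peak],
    max_dist: int = 200,
    use_summit: bool = True,
) -> CobindResult:
    """Partition two TF peak sets into co-bound pairs and unique peaks.

    A pair (one peak from each set, same chromosome) qualifies when its
    summit-to-summit distance is strictly below ``max_dist`` (199 bp merges,
    200 bp does not). Matching is greedy nearest-first with each peak used
    at most once, so the partition is exhaustive and disjoint:
    ``|a_only| + |pairs| == |peaks_a|`` and likewise for b.  With
    ``use_summit=False`` the edge-to-edge gap is used instead.
    """
    if max_dist <= 0:
        raise ValidationError("max_dist must be positive")

    def dist(pa: Peak, pb: Peak) -> int:
        if use_summit:
            return abs(pa.summit - pb.summit)
        if pa.end <= pb.start:
            return pb.start - pa.end
        if pb.end <= pa.start:
            return pa.start - pb.end
        return 0

    candidates: List[Tuple[int, int, int]] = []
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            if pa.chrom != pb.chrom:
                continue
            d = dist(pa, pb)
            if d < max_dist:
                candidates.append((d, i, j))
    candidates.sort()
    used_a: Set[int] = set()
    used_b: Set[int] = set()
    pairs: List[Tuple[Peak, Peak]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((peaks_a[i], peaks_b[j]))
    a_only = tuple(p for i, p in enumerate(peaks_a) if i not in used_a)
    b_only = tuple(p for j, p in enumerate(peaks_b) if j not in used_b)
    return CobindResult(tuple(pairs), a_only, b_only)


def novel_vs_reported(targets: Iterable, reported: Iterable) -> Tuple[int, int]:
    """Split a target-gene set into previously reported vs novel counts."""
    t, r = set(targets), set(reported)
    n_reported = len(t & r)
    return n_reported, len(t) - n_reported
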