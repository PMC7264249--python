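"""Domain types shared across the pipeline.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Peaks are unstranded; strand matters only for motif
scanning (both strands are always scanned) and for orienting peak-to-gene
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Tuple

import numpy as np

__all__ = [
    "ValidationError",
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "Gene",
    "Pwm",
    "PipelineParams",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of the interval midpoint."""
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: an interval plus a summit and a signal value.

    The summit is an absolute base position inside ``[start, end)``; when a
    peak caller did not report one it defaults to the interval midpoint.
    """

    interval: GenomicInterval
    summit: int
    signal: float = 0.0

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError(
                f"summit {self.summit} outside peak "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end}"
            )
        if self.signal < 0:
            raise ValidationError("peak signal must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def name(self) -> str:
        return self.interval.name

    @classmethod
    def from_coords(
        cls,
        chrom: str,
        start: int,
        end: int,
        name: str = ".",
        summit: int | None = None,
        signal: float = 0.0,
    ) -> "Peak":
        iv = GenomicInterval(chrom, start, end, name)
        if summit is None:
            summit = iv.midpoint
        return cls(iv, summit, signal)


class SignalTrack:
    """Piecewise-constant genome-wide signal density.

    Stores, per chromosome, sorted non-overlapping runs ``(start, end, value)``
    with ``value`` the signal density per base.  Queries outside any run
    return 0.  This is the in-memory form of a bedGraph file.
    """

    def __init__(self, runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs = runs

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, int, int, float]], coalesce: bool = True
    ) -> "SignalTrack":
        """Build a track from ``(chrom, start, end, value)`` records.

        Records are sorted per chromosome and validated non-overlapping;
        adjacent runs of equal value are coalesced when ``coalesce`` is set.
        """
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            if start < 0 or end <= start:
                raise ValidationError(
                    f"invalid run {chrom}:{start}-{end}: require 0 <= start < end"
                )
            if value < 0:
                raise ValidationError(
                    f"negative signal value {value} at {chrom}:{start}-{end}"
                )
            by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, items in by_chrom.items():
            items.sort(key=lambda r: (r[0], r[1]))
            merged: List[List[float]] = []
            for start, end, value in items:
                if merged and start < merged[-1][1]:
                    raise ValidationError(
                        f"overlapping runs on {chrom}: "
                        f"[{merged[-1][0]},{merged[-1][1]}) and [{start},{end})"
                    )
                if (
                    coalesce
                    and merged
                    and start == merged[-1][1]
                    and value == merged[-1][2]
                ):
                    merged[-1][1] = end
                else:
                    merged.append([start, end, value])
            arr = np.asarray(merged, dtype=float)
            runs[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(runs)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def records(self) -> Iterable[Tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def total_area(self) -> float:
        """Sum over all runs of value * width (invariant under coalescing)."""
        return float(
            sum(
                np.sum((ends - starts) * values)
                for starts, ends, values in self._runs.values()
            )
        )

    def area(self, chrom: str, start: int, end: int) -> float:
        """Integral of the signal density over ``chrom:[start, end)``."""
        if end <= start:
            return 0.0
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]))

    def mean_density(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base density over the window (uncovered bases count 0)."""
        if end <= start:
            return 0.0
        return self.area(chrom, start, end) / (end - start)

    def value_at(self, chrom: str, pos: int) -> float:
        """Signal density at a single base; 0 outside any run."""
        if chrom not in self._runs:
            return 0.0
        starts, ends, values = self._runs[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0


@dataclass(frozen=True)
class Gene:
    """A gene reduced to its TSS: a width-1 interval plus a strand."""

    gene_id: str
    tss: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.tss.width != 1:
            raise ValidationError(f"gene {self.gene_id}: TSS must have width 1")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss_pos(self) -> int:
        return self.tss.start

    @property
    def chrom(self) -> str:
        return self.tss.chrom


@dataclass(frozen=True)
class Pwm:
    """Position probability matrix over A,C,G,T with a background model.

    ``matrix`` has shape (L, 4); each row sums to 1 and, after the read-time
    pseudocount, every entry is strictly positive so log-odds are finite.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValidationError(f"motif {self.motif_id}: matrix must be L x 4")
        if np.any(m <= 0):
            raise ValidationError(
                f"motif {self.motif_id}: zero probability (apply a pseudocount)"
            )
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValidationError(f"motif {self.motif_id}: rows must sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValidationError(f"motif {self.motif_id}: invalid background")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        """Argmax base per position."""
        return "".join(BASES[i] for i in np.argmax(self.matrix, axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.matrix[::-1, ::-1], self.background[::-1])


@dataclass(frozen=True)
class PipelineParams:
    """Every tunable distance/threshold of the pipeline, with the defaults
    used throughout: 12.5 kb stitching gap, 1.5 kb boundary / 3 kb center
    distal rule, 200 bp summit flanks, <200 bp co-binding rule, 0.05
    enrichment alpha.
    """

    stitch_gap: int = 12_500
    distal_boundary: int = 1_500
    distal_center: int = 3_000
    flank_width: int = 200
    cobind_max_dist: int = 200
    enrich_alpha: float = 0.05
    distal_conjunction: bool = False  # see enhancer module docs

    def __post_init__(self) -> None:
        for attr in (
            "stitch_gap",
            "distal_boundary",
            "distal_center",
            "flank_width",
            "cobind_max_dist",
        ):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{attr} must be positive")
        if not (0.0 < self.enrich_alpha < 1.0):
            raise ValidationError("enrich_alpha must be in (0, 1)")
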