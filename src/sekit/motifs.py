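"""Motif enrichment for co-regulator prediction.

Mirrors the AME average-odds / rank-sum configuration: fixed-width sequences
around TF peak summits are scored against each PWM by the arithmetic mean of
the odds ratio over every window on both strands, and a one-sided
Wilcoxon rank-sum test asks whether condition flanks score higher than
control flanks.  A motif is called a candidate co-regulator when it is
enriched in the condition set and not enriched in the reverse direction
(the "conserved and biased sites" filter between conditions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import BASE_INDEX, Peak, Pwm, ValidationError

__all__ = [
    "FlankSet",
    "MotifEnrichmentResult",
    "CoregulatorCall",
    "extract_flanks",
    "avg_odds_score",
    "score_sequences",
    "ranksum_test",
    "enrich_motifs",
    "predict_coregulators",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# combined sample size at or below which the rank-sum test is enumerated
# exactly (cheap and tie-free exactness); above it, normal approximation
# with tie and continuity corrections
EXACT_RANKSUM_MAX_N = 25


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FlankSet:
    """Uniform-width DNA sequences around the summits of one peak set."""

    label: str
    sequences: Tuple[str, ...]

    def __post_init__(self) -> None:
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValidationError(
                f"flank set {self.label!r}: sequences have mixed widths {widths}"
            )
        for s in self.sequences:
            if set(s) - set("ACGTN"):
                raise ValidationError(
                    f"flank set {self.label!r}: alphabet must be A,C,G,T,N"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def width(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif_id: str
    u_statistic: float
    p_value: float
    n_fg: int
    n_bg: int
    enriched: bool


@dataclass(frozen=True)
class CoregulatorCall:
    motif_id: str
    p_condition: float
    p_control_direction: float
    retained: bool


def extract_flanks(
    peaks: Sequence[Peak], genome: Dict[str, str], width: int = 200, label: str = ""
) -> FlankSet:
    """Extract the ``width`` bp sequence centred on each peak summit.

    Windows that would run past either chromosome end are discarded (and
    logged) so every retained sequence has exactly ``width`` bases.
    """
    if width % 2 != 0:
        raise ValidationError("flank width must be even")
    half = width // 2
    seqs: List[str] = []
    n_dropped = 0
    for p in peaks:
        if p.chrom not in genome:
            raise ValidationError(
                f"chromosome {p.chrom!r} absent from the genome FASTA"
            )
        chrom_seq = genome[p.chrom]
        lo, hi = p.summit - half, p.summit + half
        if lo < 0 or hi > len(chrom_seq):
            n_dropped += 1
            logger.info(
                "discarding clipped flank %s:%d-%d (chromosome length %d)",
                p.chrom, lo, hi, len(chrom_seq),
            )
            continue
        seqs.append(chrom_seq[lo:hi].upper())
    if n_dropped:
        logger.info("%d/%d flanks discarded at chromosome ends", n_dropped, len(peaks))
    return FlankSet(label, tuple(seqs))


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return codes


def _window_log_odds(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Per-window summed log-odds; windows containing N return log(1)=0."""
    L = log_odds.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    # column 4 (N) scores 0 per base; whole windows with any N are neutralised
    padded = np.concatenate([log_odds, np.zeros((L, 1))], axis=1)
    vals = padded[np.arange(L)[None, :], windows]
    sums = vals.sum(axis=1)
    sums[(windows == 4).any(axis=1)] = 0.0
    return sums


def avg_odds_score(seq: str, pwm: Pwm) -> float:
    """AME-style average-odds score of one sequence under one motif.

    For every offset on the forward strand and on the reverse complement,
    the window odds is the product over motif positions of
    p_motif(base)/p_background(base); the score is the arithmetic mean of
    all 2*(len-L+1) window odds. Windows containing N contribute odds 1.
    The score is exactly invariant under reverse-complementing the input.
    """
    L = len(pwm)
    if len(seq) < L:
        raise ValidationError(
            f"sequence length {len(seq)} shorter than motif length {L}"
        )
    codes = _encode(seq.upper())
    fwd = np.log(pwm.matrix / pwm.background)
    rev = np.log(pwm.reverse_complement().matrix / pwm.background)
    lo = np.concatenate(
        [_window_log_odds(codes, fwd), _window_log_odds(codes, rev)]
    )
    return float(np.mean(np.exp(lo)))


def score_sequences(seqs: Sequence[str], pwm: Pwm) -> np.ndarray:
    """Vectorised ``avg_odds_score`` over equal-length sequences."""
    return np.asarray([avg_odds_score(s, pwm) for s in seqs])


def ranksum_test(
    fg_scores: Sequence[float], bg_scores: Sequence[float]
) -> Tuple[float, float]:
    """One-sided Wilcoxon rank-sum (Mann-Whitney U) test, alternative
    "foreground scores are larger".

    Exact enumeration when the combined sample size is at most
    ``EXACT_RANKSUM_MAX_N`` and the pooled scores are tie-free; otherwise the
    normal approximation with tie and continuity corrections. Returns
    ``(U, one_sided_p)`` with U the Mann-Whitney statistic of the foreground.
    """
    fg = np.asarray(fg_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise ValidationError("rank-sum test needs non-empty samples")
    pooled = np.concatenate([fg, bg])
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= EXACT_RANKSUM_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        fg, bg, alternative="greater", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def enrich_motifs(
    fg: FlankSet,
    bg: FlankSet,
    motifs: Sequence[Pwm],
    alpha: float = 0.05,
    correction: str = "none",
) -> List[MotifEnrichmentResult]:
    """Test every motif for enrichment in ``fg`` versus ``bg`` flanks.

    Sequences are scored by ``avg_odds_score`` and compared with the
    one-sided rank-sum test. Results are sorted by ascending p (ties broken
    by motif_id). By default p-values are reported raw, matching the usual
    AME report threshold; ``correction="bonferroni"`` multiplies each p by
    the number of motifs before thresholding.
    """
    if len(fg) == 0 or len(bg) == 0:
        raise ValidationError("enrichment needs non-empty flank sets")
    if correction not in ("none", "bonferroni"):
        raise ValidationError(f"unknown correction {correction!r}")
    results: List[MotifEnrichmentResult] = []
    for pwm in motifs:
        fg_scores = score_sequences(fg.sequences, pwm)
        bg_scores = score_sequences(bg.sequences, pwm)
        u, p = ranksum_test(fg_scores, bg_scores)
        if correction == "bonferroni":
            p = min(1.0, p * len(motifs))
        results.append(
            MotifEnrichmentResult(
                motif_id=pwm.motif_id,
                u_statistic=u,
                p_value=p,
                n_fg=len(fg),
                n_bg=len(bg),
                enriched=p <= alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.motif_id))
    return results


def predict_coregulators(
    cond: FlankSet,
    control: FlankSet,
    motifs: Sequence[Pwm],
    alpha: float = 0.05,
) -> List[CoregulatorCall]:
    """Candidate co-regulators: motifs enriched in the stimulated condition
    versus the control and not enriched in the reverse direction.

    Motifs scoring high in both sets (constitutive / sequence-composition
    bias) fail the forward test; motifs enriched in the control fail the
    reverse filter. Output sorted by the condition-direction p-value.
    """
    calls: List[CoregulatorCall] = []
    for pwm in motifs:
        cond_scores = score_sequences(cond.sequences, pwm)
        ctrl_scores = score_sequences(control.sequences, pwm)
        _, p_fwd = ranksum_test(cond_scores, ctrl_scores)
        _, p_rev = ranksum_test(ctrl_scores, cond_scores)
        calls.append(
            CoregulatorCall(
                motif_id=pwm.motif_id,
                p_condition=p_fwd,
                p_control_direction=p_rev,
                retained=(p_fwd <= alpha) and (p_rev > alpha),
            )
        )
    calls.sort(key=lambda c: (c.p_condition, c.motif_id))
    return calls
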