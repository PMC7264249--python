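"""Seeded synthetic-data generator with ground truth.

Builds a toy genome carrying (a) a long-tailed enhancer landscape with a
small planted high-signal (super-enhancer) class, (b) TF summit sets under
two stimulation conditions plus a control, with an exact motif consensus
planted into a controllable fraction of condition summit flanks, and (c)
per-condition expression tables with planted up/down DEG sets biased toward
the bound genes — everything the pipeline stages consume, with a
machine-readable truth record for scoring recovery.

All randomness flows through one ``numpy`` Generator keyed by a single seed
and a fixed draw order, so identical seeds give byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import io as sio
from .core import Gene, GenomicInterval, Peak, Pwm, SignalTrack, ValidationError
from .motifs import MotifEnrichmentResult, reverse_complement

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "make_motif_library",
    "random_flanks",
    "planted_flank_sets",
    "simulate",
    "truth_metrics",
]

BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Knobs of the synthetic study.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 500 typical + 25 super enhancers with a 50x signal multiplier,
    200 TF peaks per condition, 200 bp flanks with a 30% consensus plant
    rate, and 60 up / 40 down DEGs per condition.
    """

    seed: int = 1
    n_genes: int = 200
    n_typical_enhancers: int = 500
    n_super_enhancers: int = 25
    typical_signal_mean: float = 100.0
    super_signal_multiplier: float = 50.0
    n_peaks_per_condition: int = 200
    flank_width: int = 200
    plant_rate: float = 0.30
    n_deg_up: int = 60
    n_deg_down: int = 40
    n_proximal_peaks: int = 50
    n_decoy_motifs: int = 10
    motif_length: int = 8
    chrom_length: int = 20_000_000
    chrom_name: str = "chr1"
    conditions: Tuple[str, ...] = ("5FU", "Nutlin3a")
    control: str = "DMSO"
    shared_summit_frac: float = 0.5
    gene_spacing: int = 5_000
    enhancer_spacing: int = 24_000
    margin: int = 50_000

    def __post_init__(self) -> None:
        for attr in (
            "n_genes",
            "n_typical_enhancers",
            "n_super_enhancers",
            "n_peaks_per_condition",
            "flank_width",
            "chrom_length",
        ):
            if getattr(self, attr) <= 0:
                raise ValidationError(f"{attr} must be positive")
        if self.super_signal_multiplier <= 1:
            raise ValidationError("super_signal_multiplier must exceed 1")
        if not (0.0 <= self.plant_rate <= 1.0):
            raise ValidationError("plant_rate must lie in [0, 1]")
        if self.n_deg_up + self.n_deg_down > self.n_genes:
            raise ValidationError("more DEGs requested than genes")


@dataclass
class SyntheticTruth:
    """What was planted, for scoring pipeline recovery."""

    super_enhancer_ids: List[str]
    motif_planted: Dict[str, Dict]  # condition -> {motif_id, plant_rate, planted_peaks}
    deg_truth: Dict[str, Dict[str, str]]  # condition -> gene_id -> up/down
    bound_genes: Dict[str, List[str]]  # condition -> planted bound gene ids
    cobound_pairs: List[Tuple[str, str]]  # (condition-1 peak name, control peak name)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=1, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
        raw["cobound_pairs"] = [tuple(p) for p in raw["cobound_pairs"]]
        return cls(**raw)


def _sharp_pwm(motif_id: str, consensus_codes: np.ndarray, p_major: float = 0.97) -> Pwm:
    L = consensus_codes.size
    matrix = np.full((L, 4), (1.0 - p_major) / 3.0)
    matrix[np.arange(L), consensus_codes] = p_major
    return Pwm(motif_id, matrix)


def make_motif_library(
    rng: np.random.Generator,
    n_decoys: int = 10,
    length: int = 8,
    planted_id: str = "planted_motif",
) -> Tuple[Pwm, List[Pwm]]:
    """One sharp planted motif plus ``n_decoys`` decoy PWMs of equal length.

    Decoys have a weaker (0.85) dominant base per position so they score
    informatively but match nothing planted.
    """
    planted = _sharp_pwm(planted_id, rng.integers(0, 4, size=length))
    decoys = [
        _sharp_pwm(f"decoy_{k + 1:02d}", rng.integers(0, 4, size=length), p_major=0.85)
        for k in range(n_decoys)
    ]
    return planted, decoys


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[c] for c in rng.integers(0, 4, size=length))


def random_flanks(rng: np.random.Generator, n: int, width: int = 200) -> List[str]:
    """``n`` i.i.d. uniform-base sequences of ``width`` bp."""
    return [_random_seq(rng, width) for _ in range(n)]


def planted_flank_sets(
    rng: np.random.Generator,
    motif: Pwm,
    n_fg: int = 200,
    n_bg: int = 200,
    width: int = 200,
    plant_rate: float = 0.30,
) -> Tuple[List[str], List[str]]:
    """Foreground/background flank sets with the motif consensus planted
    into a ``plant_rate`` fraction of foreground sequences at a uniform
    offset and strand. Background sequences are untouched."""
    consensus = motif.consensus
    L = len(consensus)
    fg = random_flanks(rng, n_fg, width)
    n_plant = int(round(plant_rate * n_fg))
    planted_idx = rng.choice(n_fg, size=n_plant, replace=False)
    for i in planted_idx:
        offset = int(rng.integers(0, width - L + 1))
        site = consensus if rng.integers(0, 2) == 0 else reverse_complement(consensus)
        fg[i] = fg[i][:offset] + site + fg[i][offset + L:]
    bg = random_flanks(rng, n_bg, width)
    return fg, bg


def _place_clear(
    rng: np.random.Generator,
    lo: int,
    hi: int,
    occupied: List[int],
    min_dist: int,
    max_tries: int = 1000,
) -> int:
    """Draw a position in [lo, hi) at least ``min_dist`` from every occupied
    position (rejection sampling; deterministic given the rng state)."""
    occ = np.asarray(occupied, dtype=np.int64)
    for _ in range(max_tries):
        pos = int(rng.integers(lo, hi))
        if occ.size == 0 or np.min(np.abs(occ - pos)) >= min_dist:
            return pos
    raise ValidationError("could not place a summit clear of existing summits")


def simulate(params: SimParams, out_dir) -> SyntheticTruth:
    """Generate the full bundle into ``out_dir`` and return the truth record.

    Files written: ``genome.fa``, ``tss.bed``, ``h3k27ac_peaks.bed``,
    ``h3k27ac.bedgraph``, ``<cond>_summits.bed`` for each condition and the
    control, ``expression_<cond>.tsv`` per stimulation condition,
    ``motifs.meme`` and ``truth.json``.
    """
    p = params
    out = Path(out_dir)
    rng = np.random.default_rng(p.seed)

    # ---- layout feasibility (checked before anything is written) ----
    n_enh = p.n_typical_enhancers + p.n_super_enhancers
    gene_zone_start = p.margin
    gene_zone_end = gene_zone_start + p.n_genes * p.gene_spacing
    enh_zone_start = gene_zone_end + 20_000
    enh_zone_end = enh_zone_start + n_enh * p.enhancer_spacing
    if enh_zone_end + p.margin > p.chrom_length:
        raise ValidationError(
            f"chrom_length {p.chrom_length} too short for {p.n_genes} genes "
            f"and {n_enh} enhancers (need >= {enh_zone_end + p.margin})"
        )
    out.mkdir(parents=True, exist_ok=True)

    # ---- genome: i.i.d. uniform bases, mutable for motif planting ----
    base_codes = rng.integers(0, 4, size=p.chrom_length, dtype=np.int8)
    genome_arr = np.frombuffer(b"ACGT", dtype=np.uint8)[base_codes].copy()

    # ---- genes ----
    strands = rng.integers(0, 2, size=p.n_genes)
    genes: List[Gene] = []
    for j in range(p.n_genes):
        tss = gene_zone_start + j * p.gene_spacing
        genes.append(
            Gene(
                f"gene_{j + 1:04d}",
                GenomicInterval(p.chrom_name, tss, tss + 1, f"gene_{j + 1:04d}"),
                "+" if strands[j] == 0 else "-",
            )
        )

    # ---- enhancer landscape ----
    slot_order = rng.permutation(n_enh)
    super_slots = set(slot_order[: p.n_super_enhancers].tolist())
    # constituent span must leave an inter-slot gap of at least the 12.5 kb
    # stitch threshold so each planted slot stitches to exactly one enhancer
    k27_peaks: List[Peak] = []
    track_records: List[Tuple[str, int, int, float]] = []
    super_ids: List[str] = []
    pk_counter = 0
    for slot in range(n_enh):
        slot_start = enh_zone_start + slot * p.enhancer_spacing
        is_super = slot in super_slots
        n_const = int(rng.integers(3, 6)) if is_super else int(rng.integers(1, 3))
        widths = rng.integers(500, 1501, size=n_const)
        gaps = rng.integers(200, 801, size=n_const)
        if is_super:
            total = (
                p.super_signal_multiplier
                * p.typical_signal_mean
                * float(rng.uniform(0.8, 1.2))
            )
            shares = rng.uniform(0.5, 1.5, size=n_const)
            signals = total * shares / shares.sum()
        else:
            signals = rng.exponential(p.typical_signal_mean, size=n_const)
        pos = slot_start
        lo = pos
        for c in range(n_const):
            start, end = pos, pos + int(widths[c])
            pk_counter += 1
            k27_peaks.append(
                Peak.from_coords(
                    p.chrom_name, start, end, f"k27_{pk_counter:05d}",
                    signal=float(signals[c]),
                )
            )
            track_records.append(
                (p.chrom_name, start, end, float(signals[c]) / (end - start))
            )
            pos = end + int(gaps[c])
        hi = k27_peaks[-1].end
        if hi - lo > p.enhancer_spacing - 12_500 - 100:
            raise ValidationError("enhancer slot span exceeds its budget")
        if is_super:
            super_ids.append(f"{p.chrom_name}:{lo}-{hi}")

    # promoter-proximal H3K27ac peaks (removed by the distal filter)
    prox_gene_idx = rng.choice(p.n_genes, size=min(p.n_proximal_peaks, p.n_genes), replace=False)
    for j in sorted(prox_gene_idx.tolist()):
        tss = genes[j].tss_pos
        center = tss + int(rng.integers(-400, 401))
        half = int(rng.integers(200, 401))
        start, end = max(0, center - half), center + half
        pk_counter += 1
        sig = float(rng.exponential(p.typical_signal_mean))
        k27_peaks.append(
            Peak.from_coords(p.chrom_name, start, end, f"k27_{pk_counter:05d}", signal=sig)
        )
        track_records.append((p.chrom_name, start, end, sig / (end - start)))

    # ---- TF summit sets ----
    n_pk = p.n_peaks_per_condition
    n_bound = min(n_pk // 2, p.n_genes // 2)
    gene_pool = rng.permutation(p.n_genes)
    overlap = n_bound // 2
    bound_idx: Dict[str, np.ndarray] = {}
    if len(p.conditions) >= 1:
        bound_idx[p.conditions[0]] = gene_pool[:n_bound]
    if len(p.conditions) >= 2:
        bound_idx[p.conditions[1]] = gene_pool[overlap : overlap + n_bound]
    for extra in p.conditions[2:]:
        bound_idx[extra] = rng.choice(p.n_genes, size=n_bound, replace=False)

    all_summits: List[int] = []
    cond_peaks: Dict[str, List[Peak]] = {}
    for cond in p.conditions:
        peaks: List[Peak] = []
        for i, gidx in enumerate(bound_idx[cond]):
            summit = genes[int(gidx)].tss_pos + int(rng.integers(-500, 501))
            peaks.append(
                Peak.from_coords(
                    p.chrom_name, summit - 250, summit + 250,
                    f"{cond}_peak_{i + 1:04d}", summit=summit,
                )
            )
            all_summits.append(summit)
        for i in range(n_bound, n_pk):
            summit = _place_clear(
                rng, enh_zone_start, enh_zone_end, all_summits, 1_000
            )
            peaks.append(
                Peak.from_coords(
                    p.chrom_name, summit - 250, summit + 250,
                    f"{cond}_peak_{i + 1:04d}", summit=summit,
                )
            )
            all_summits.append(summit)
        cond_peaks[cond] = peaks

    # control shares a fraction of condition-1 summits (jitter < 200 bp,
    # giving the planted co-bound pairs); the rest are placed clear of
    # every existing summit so no accidental co-binding arises
    control_peaks: List[Peak] = []
    cobound_pairs: List[Tuple[str, str]] = []
    n_shared = int(round(p.shared_summit_frac * n_pk))
    first_cond = p.conditions[0]
    for i in range(n_pk):
        name = f"{p.control}_peak_{i + 1:04d}"
        if i < n_shared:
            partner = cond_peaks[first_cond][i]
            summit = partner.summit + int(rng.integers(-99, 100))
            cobound_pairs.append((partner.name, name))
        else:
            summit = _place_clear(
                rng, gene_zone_start, enh_zone_end, all_summits, 1_000
            )
        control_peaks.append(
            Peak.from_coords(
                p.chrom_name, summit - 250, summit + 250, name, summit=summit
            )
        )
        all_summits.append(summit)

    # ---- motif library and consensus planting ----
    planted_pwm, decoys = make_motif_library(
        rng, n_decoys=p.n_decoy_motifs, length=p.motif_length
    )
    consensus = planted_pwm.consensus
    L = len(consensus)
    half = p.flank_width // 2
    motif_planted: Dict[str, Dict] = {}
    for cond in p.conditions:
        peaks = cond_peaks[cond]
        n_plant = int(round(p.plant_rate * n_pk))
        # plant preferentially into summits not shared with the control so
        # the control flanks stay motif-free
        if cond == first_cond:
            candidates = list(range(n_shared, n_pk))
        else:
            candidates = list(range(n_pk))
        if n_plant > len(candidates):
            candidates = list(range(n_pk))
        chosen = rng.choice(len(candidates), size=n_plant, replace=False)
        planted_names = []
        for c in sorted(int(candidates[i]) for i in chosen):
            pk = peaks[c]
            offset = int(rng.integers(0, p.flank_width - L + 1))
            site = consensus if rng.integers(0, 2) == 0 else reverse_complement(consensus)
            start = pk.summit - half + offset
            genome_arr[start : start + L] = np.frombuffer(site.encode(), dtype=np.uint8)
            planted_names.append(pk.name)
        motif_planted[cond] = {
            "motif_id": planted_pwm.motif_id,
            "plant_rate": p.plant_rate,
            "planted_peaks": planted_names,
        }

    # ---- DEG tables, biased toward the bound genes ----
    deg_truth: Dict[str, Dict[str, str]] = {}
    n_deg = p.n_deg_up + p.n_deg_down
    for cond in p.conditions:
        bound = [int(i) for i in bound_idx[cond]]
        unbound = [j for j in range(p.n_genes) if j not in set(bound)]
        n_from_bound = min(int(round(0.7 * n_deg)), len(bound))
        pick_bound = rng.choice(len(bound), size=n_from_bound, replace=False)
        pick_unbound = rng.choice(
            len(unbound), size=n_deg - n_from_bound, replace=False
        )
        deg_gene_idx = [bound[int(i)] for i in pick_bound] + [
            unbound[int(i)] for i in pick_unbound
        ]
        directions = ["up"] * p.n_deg_up + ["down"] * p.n_deg_down
        perm = rng.permutation(n_deg)
        deg_truth[cond] = {
            genes[deg_gene_idx[int(k)]].gene_id: directions[int(k)] for k in perm
        }

    # ---- write the bundle ----
    genome = {p.chrom_name: genome_arr.tobytes().decode("ascii")}
    sio.write_fasta(out / "genome.fa", genome)
    sio.write_tss_bed(out / "tss.bed", genes)
    sio.write_bed(out / "h3k27ac_peaks.bed", k27_peaks)
    track = SignalTrack.from_records(track_records)
    sio.write_bedgraph(out / "h3k27ac.bedgraph", track)
    for cond in p.conditions:
        sio.write_bed(out / f"{cond}_summits.bed", cond_peaks[cond])
    sio.write_bed(out / f"{p.control}_summits.bed", control_peaks)
    for cond in p.conditions:
        degs = deg_truth[cond]
        fold = {
            g: (round(float(rng.uniform(1.0, 4.0)), 3) if d == "up"
                else -round(float(rng.uniform(1.0, 4.0)), 3))
            for g, d in degs.items()
        }
        sio.write_deg_table(out / f"expression_{cond}.tsv", degs, fold)
    sio.write_meme_motifs(out / "motifs.meme", [planted_pwm] + decoys)

    truth = SyntheticTruth(
        super_enhancer_ids=super_ids,
        motif_planted=motif_planted,
        deg_truth=deg_truth,
        bound_genes={
            cond: [genes[int(i)].gene_id for i in bound_idx[cond]]
            for cond in p.conditions
        },
        cobound_pairs=cobound_pairs,
    )
    truth.to_json(out / "truth.json")
    return truth


def truth_metrics(
    truth: SyntheticTruth,
    enhancers=None,
    motif_results: Sequence[MotifEnrichmentResult] | None = None,
    condition: str | None = None,
    target_gene_ids: set | None = None,
) -> Dict[str, float]:
    """Score pipeline outputs against the planted truth.

    Any combination of outputs may be supplied; the report contains the
    metrics for whichever were given: sensitivity/specificity of
    super-enhancer labels, 1-based rank of the planted motif, and
    precision/recall of target-gene calls for ``condition``.
    """
    report: Dict[str, float] = {}
    if enhancers is not None:
        called = {e.region.name: e.is_super for e in enhancers}
        missing = [sid for sid in truth.super_enhancer_ids if sid not in called]
        if missing:
            raise ValidationError(
                f"planted super-enhancer ids absent from results: {missing[:3]}"
            )
        planted = set(truth.super_enhancer_ids)
        tp = sum(1 for sid in planted if called[sid])
        fn = len(planted) - tp
        negatives = [n for n in called if n not in planted]
        fp = sum(1 for n in negatives if called[n])
        tn = len(negatives) - fp
        report["se_sensitivity"] = tp / (tp + fn) if (tp + fn) else float("nan")
        report["se_specificity"] = tn / (tn + fp) if (tn + fp) else float("nan")
    if motif_results is not None:
        if condition is None or condition not in truth.motif_planted:
            raise ValidationError("condition required to score motif recovery")
        planted_id = truth.motif_planted[condition]["motif_id"]
        ids = [r.motif_id for r in motif_results]
        if planted_id not in ids:
            raise ValidationError(f"planted motif {planted_id!r} absent from results")
        report["planted_motif_rank"] = float(ids.index(planted_id) + 1)
        report["planted_motif_p"] = float(
            next(r.p_value for r in motif_results if r.motif_id == planted_id)
        )
    if target_gene_ids is not None:
        if condition is None or condition not in truth.deg_truth:
            raise ValidationError("condition required to score target calls")
        truth_targets = set(truth.bound_genes[condition]) & set(
            truth.deg_truth[condition]
        )
        called = set(target_gene_ids)
        tp = len(called & truth_targets)
        report["target_precision"] = tp / len(called) if called else float("nan")
        report["target_recall"] = (
            tp / len(truth_targets) if truth_targets else float("nan")
        )
    return report
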