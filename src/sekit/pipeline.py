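"""End-to-end orchestration: simulate (or ingest) -> call enhancers ->
predict co-regulators -> call targets -> co-binding and profile reports.

Each stage reads and writes plain-text files so any stage can be rerun or
replaced; a JSON manifest records parameters, input digests and per-stage
row counts for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import io as sio
from .core import PipelineParams, ValidationError
from .enhancers import call_enhancers, profile_matrix
from .motifs import extract_flanks, predict_coregulators
from .simulate import SimParams, simulate
from .targets import annotate_peaks, bound_genes, call_targets, cobinding, summarize_sets

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run.

    When ``sim`` is set the input bundle is generated under
    ``out_dir/data`` and the input paths are filled in automatically;
    otherwise every input path must point at an existing file.
    """

    out_dir: str = "sekit_run"
    params: PipelineParams = field(default_factory=PipelineParams)
    sim: Optional[SimParams] = None
    genome: Optional[str] = None
    tss: Optional[str] = None
    k27_peaks: Optional[str] = None
    k27_signal: Optional[str] = None
    motifs: Optional[str] = None
    conditions: List[str] = field(default_factory=lambda: ["5FU", "Nutlin3a"])
    control: str = "DMSO"
    summits: Dict[str, str] = field(default_factory=dict)  # condition -> BED
    expression: Dict[str, str] = field(default_factory=dict)  # condition -> TSV
    summit_dialect: bool = True  # summit offset column present in summit BEDs
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "params" in raw:
            raw["params"] = PipelineParams(**raw["params"])
        if raw.get("sim") is not None:
            raw["sim"] = SimParams(**raw["sim"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    """Context manager: on failure remove this stage's new outputs and
    re-raise with the stage name."""

    class _Ctx:
        def __init__(self) -> None:
            self.outputs: List[Path] = []

        def register(self, *paths) -> None:
            self.outputs.extend(Path(p) for p in paths)

        def __enter__(self):
            logger.info("[stage:%s] start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                for path in self.outputs:
                    path.unlink(missing_ok=True)
                logger.error("[stage:%s] failed: %s", name, exc)
                raise PipelineStageError(name, exc) from exc
            logger.info("[stage:%s] done", name)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order and return the manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "params": asdict(config.params),
        "conditions": list(config.conditions),
        "control": config.control,
        "stages": {},
        "inputs": {},
    }

    if config.sim is not None:
        with _stage(manifest, "simulate"):
            data = out / "data"
            simulate(config.sim, data)
            config.genome = str(data / "genome.fa")
            config.tss = str(data / "tss.bed")
            config.k27_peaks = str(data / "h3k27ac_peaks.bed")
            config.k27_signal = str(data / "h3k27ac.bedgraph")
            config.motifs = str(data / "motifs.meme")
            config.conditions = list(config.sim.conditions)
            config.control = config.sim.control
            config.summits = {
                c: str(data / f"{c}_summits.bed")
                for c in config.conditions + [config.control]
            }
            config.expression = {
                c: str(data / f"expression_{c}.tsv") for c in config.conditions
            }
            manifest["stages"]["simulate"] = {"seed": config.sim.seed}

    required = {
        "genome": config.genome,
        "tss": config.tss,
        "k27_peaks": config.k27_peaks,
        "k27_signal": config.k27_signal,
        "motifs": config.motifs,
    }
    for key, path in required.items():
        if path is None or not Path(path).exists():
            raise PipelineStageError(
                "inputs", ValidationError(f"missing input {key!r}: {path}")
            )
        manifest["inputs"][key] = _sha256(path)
    for cond, path in {**config.summits, **config.expression}.items():
        if not Path(path).exists():
            raise PipelineStageError(
                "inputs", ValidationError(f"missing input for {cond!r}: {path}")
            )
        manifest["inputs"][Path(path).name] = _sha256(path)

    genes = sio.read_tss_bed(config.tss)
    params = config.params

    with _stage(manifest, "call-enhancers") as st:
        peaks = sio.read_bed(config.k27_peaks, has_summit=config.summit_dialect, summit_column=6)
        track = sio.read_bedgraph(config.k27_signal)
        enhancers, cutoff = call_enhancers(peaks, genes, track, params)
        enh_path = out / "enhancers.bed"
        st.register(enh_path, out / "se_cutoff.tsv")
        with open(enh_path, "w", encoding="utf-8") as fh:
            for e in enhancers:
                fh.write(
                    f"{e.region.chrom}\t{e.region.start}\t{e.region.end}\t"
                    f"{e.region.name}\t{e.total_signal!r}\t.\t{e.rank}\t"
                    f"{int(e.is_super)}\n"
                )
        with open(out / "se_cutoff.tsv", "w", encoding="utf-8") as fh:
            fh.write("tangency_rank\ttangency_signal\tn_super\tn_typical\n")
            if cutoff is not None:
                fh.write(
                    f"{cutoff.tangency_rank}\t{cutoff.tangency_signal!r}\t"
                    f"{cutoff.n_super}\t{cutoff.n_typical}\n"
                )
        manifest["stages"]["call-enhancers"] = {
            "n_enhancers": len(enhancers),
            "n_super": cutoff.n_super if cutoff else 0,
        }

    genome = sio.read_fasta(config.genome)
    motifs = sio.read_meme_motifs(config.motifs)
    ctrl_peaks = sio.read_bed(
        config.summits[config.control], has_summit=config.summit_dialect, summit_column=6
    )
    ctrl_flanks = extract_flanks(
        ctrl_peaks, genome, params.flank_width, label=config.control
    )

    with _stage(manifest, "predict-coregulators") as st:
        counts = {}
        for cond in config.conditions:
            cond_peaks = sio.read_bed(
                config.summits[cond], has_summit=config.summit_dialect, summit_column=6
            )
            flanks = extract_flanks(cond_peaks, genome, params.flank_width, label=cond)
            calls = predict_coregulators(
                flanks, ctrl_flanks, motifs, alpha=params.enrich_alpha
            )
            path = out / f"coregulators_{cond}.tsv"
            st.register(path)
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("motif_id\tp_condition\tp_control_direction\tretained\n")
                for c in calls:
                    fh.write(
                        f"{c.motif_id}\t{c.p_condition!r}\t"
                        f"{c.p_control_direction!r}\t{int(c.retained)}\n"
                    )
            counts[cond] = sum(c.retained for c in calls)
        manifest["stages"]["predict-coregulators"] = {"n_retained": counts}

    with _stage(manifest, "call-targets") as st:
        target_sets: Dict[str, set] = {}
        counts = {}
        for cond in config.conditions:
            cond_peaks = sio.read_bed(
                config.summits[cond], has_summit=config.summit_dialect, summit_column=6
            )
            links = annotate_peaks(cond_peaks, genes)
            degs = sio.read_deg_table(config.expression[cond])
            calls = call_targets(
                bound_genes(links), degs, {g.gene_id for g in genes}
            )
            path = out / f"targets_{cond}.tsv"
            st.register(path)
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("gene_id\tbound\tde_status\tis_target\n")
                for t in calls:
                    fh.write(
                        f"{t.gene_id}\t{int(t.bound)}\t{t.de_status}\t{int(t.is_target)}\n"
                    )
            target_sets[cond] = {t.gene_id for t in calls if t.is_target}
            counts[cond] = len(target_sets[cond])
        if len(config.conditions) >= 2:
            a, b = config.conditions[0], config.conditions[1]
            summary = summarize_sets(target_sets[a], target_sets[b])
            path = out / "target_set_summary.tsv"
            st.register(path)
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("n_a\tn_b\tn_intersection\tn_union\tn_a_only\tn_b_only\n")
                fh.write(
                    f"{summary.n_a}\t{summary.n_b}\t{summary.n_intersection}\t"
                    f"{summary.n_union}\t{summary.n_a_only}\t{summary.n_b_only}\n"
                )
        manifest["stages"]["call-targets"] = {"n_targets": counts}

    with _stage(manifest, "cobind") as st:
        cond = config.conditions[0]
        cond_peaks = sio.read_bed(
            config.summits[cond], has_summit=config.summit_dialect, summit_column=6
        )
        result = cobinding(cond_peaks, ctrl_peaks, params.cobind_max_dist)
        path = out / "cobind_pairs.tsv"
        st.register(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("peak_a\tpeak_b\tsummit_a\tsummit_b\tdistance\n")
            for pa, pb in result.pairs:
                fh.write(
                    f"{pa.name}\t{pb.name}\t{pa.summit}\t{pb.summit}\t"
                    f"{abs(pa.summit - pb.summit)}\n"
                )
        manifest["stages"]["cobind"] = {
            "n_pairs": len(result.pairs),
            "n_a_only": len(result.a_only),
            "n_b_only": len(result.b_only),
        }

    with _stage(manifest, "profile") as st:
        cond = config.conditions[0]
        cond_peaks = sio.read_bed(
            config.summits[cond], has_summit=config.summit_dialect, summit_column=6
        )
        track = sio.read_bedgraph(config.k27_signal)
        _, means = profile_matrix(cond_peaks, track, flank=2_000, nbins=100)
        path = out / "profile_means.tsv"
        st.register(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("bin\tmean_signal\n")
            for b, v in enumerate(means):
                fh.write(f"{b}\t{v!r}\n")
        manifest["stages"]["profile"] = {"n_anchors": len(cond_peaks)}

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return manifest
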