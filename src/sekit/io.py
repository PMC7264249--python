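"""Readers and writers for the plain-text formats the pipeline consumes.

BED (peaks and TSS annotations), bedGraph (signal), FASTA (genome),
MEME minimal (motif libraries) and headered TSV (DEG tables).  All BED-side
coordinates are 0-based half-open.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Iterable, List, TextIO

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Gene, GenomicInterval, Peak, Pwm, SignalTrack, ValidationError

__all__ = [
    "ParseError",
    "read_bed",
    "write_bed",
    "read_tss_bed",
    "write_tss_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_deg_table",
    "write_deg_table",
]


class ParseError(ValueError):
    """A malformed record; the message names the offending line number."""


def _open(path, mode="r") -> TextIO:
    return open(path, mode, encoding="utf-8")


def read_bed(path, has_summit: bool = False, summit_column: int = 5) -> List[Peak]:
    """Read a peak BED file.

    Parameters
    ----------
    has_summit
        If set, the 0-based column ``summit_column`` holds the summit as an
        offset from ``start`` (the MACS ``_summits``/narrowPeak dialect);
        otherwise the summit defaults to the floor of the interval midpoint.
    """
    peaks: List[Peak] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] else "."
            signal = 0.0
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    signal = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
            try:
                iv = GenomicInterval(chrom, start, end, name)
                if has_summit:
                    if len(fields) <= summit_column:
                        raise ParseError(
                            f"{path}: line {lineno}: missing summit column "
                            f"{summit_column}"
                        )
                    summit = start + int(fields[summit_column])
                else:
                    summit = iv.midpoint
                peaks.append(Peak(iv, summit, signal))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return peaks


def write_bed(path, peaks: Iterable[Peak], with_summit: bool = True) -> None:
    """Write peaks as BED; summit emitted as an offset-from-start column 6."""
    with _open(path, "w") as fh:
        for p in peaks:
            cols = [p.chrom, str(p.start), str(p.end), p.name, repr(p.signal), "."]
            if with_summit:
                cols.append(str(p.summit - p.start))
            fh.write("\t".join(cols) + "\n")


def read_tss_bed(path) -> List[Gene]:
    """Read a TSS annotation: BED with name (gene_id) and strand columns.

    Each record may be width 1 (the TSS itself) or wider, in which case the
    strand-aware 5' end is taken as the TSS.
    """
    genes: List[Gene] = []
    seen: Dict[str, int] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"{path}: line {lineno}: TSS BED needs chrom/start/end/name"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            gene_id = fields[3]
            strand = fields[5] if len(fields) > 5 else "+"
            if gene_id in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate gene_id {gene_id!r} "
                    f"(first at line {seen[gene_id]})"
                )
            seen[gene_id] = lineno
            if end - start == 1:
                tss = start
            else:
                tss = start if strand == "+" else end - 1
            genes.append(
                Gene(gene_id, GenomicInterval(chrom, tss, tss + 1, gene_id), strand)
            )
    return genes


def write_tss_bed(path, genes: Iterable[Gene]) -> None:
    with _open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.tss_pos}\t{g.tss_pos + 1}\t{g.gene_id}\t.\t{g.strand}\n"
            )


def read_bedgraph(path) -> SignalTrack:
    """Read a bedGraph into a SignalTrack (validated, coalesced)."""
    records = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    try:
        return SignalTrack.from_records(records)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_bedgraph(path, track: SignalTrack) -> None:
    with _open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def read_fasta(path) -> Dict[str, str]:
    """Read a genome FASTA into an uppercased dict chrom -> sequence."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, sequences: Dict[str, str], width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_meme_motifs(path, pseudocount: float = 1e-4) -> List[Pwm]:
    """Parse a MEME minimal-format motif library.

    Each letter-probability row is checked to sum to ~1, then a pseudocount
    is added and the row renormalized, so downstream odds ratios are always
    finite.  The background comes from the file's "Background letter
    frequencies" block when present, else it is uniform.
    """
    background = np.full(4, 0.25)
    motifs: List[Pwm] = []
    with _open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            tokens: List[str] = []
            while i < n and lines[i].strip() and not lines[i].startswith("MOTIF"):
                tokens.extend(lines[i].split())
                i += 1
            freq = {
                tokens[j]: float(tokens[j + 1]) for j in range(0, len(tokens) - 1, 2)
            }
            if set("ACGT") <= set(freq):
                background = np.array([freq[b] for b in "ACGT"])
                background = background / background.sum()
            continue
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            # advance to the letter-probability matrix header
            i += 1
            while i < n and "letter-probability matrix" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    break
                i += 1
            if i >= n or "letter-probability matrix" not in lines[i]:
                raise ParseError(
                    f"{path}: motif {motif_id}: missing letter-probability matrix"
                )
            i += 1
            rows = []
            while i < n:
                stripped = lines[i].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                values = [float(x) for x in stripped.split()]
                if len(values) != 4:
                    raise ParseError(
                        f"{path}: line {i + 1}: expected 4 probabilities"
                    )
                total = sum(values)
                if not (0.9 <= total <= 1.1):
                    raise ValidationError(
                        f"{path}: line {i + 1}: motif {motif_id} row sums to "
                        f"{total:.4f}, outside [0.9, 1.1]"
                    )
                rows.append(values)
                i += 1
            matrix = np.asarray(rows, dtype=float) + pseudocount
            matrix /= matrix.sum(axis=1, keepdims=True)
            motifs.append(Pwm(motif_id, matrix, background))
            continue
        i += 1
    return motifs


def write_meme_motifs(path, motifs: Iterable[Pwm], background=None) -> None:
    """Write motifs in MEME minimal format."""
    motifs = list(motifs)
    if background is None:
        background = motifs[0].background if motifs else np.full(4, 0.25)
    buf = _io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\n")
    buf.write(
        " ".join(f"{b} {freq:.6f}" for b, freq in zip("ACGT", background)) + "\n\n"
    )
    for pwm in motifs:
        buf.write(f"MOTIF {pwm.motif_id}\n")
        buf.write(
            f"letter-probability matrix: alength= 4 w= {len(pwm)} "
            f"nsites= 20 E= 0\n"
        )
        for row in pwm.matrix:
            buf.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_deg_table(path) -> Dict[str, str]:
    """Read a DEG TSV with header; returns gene_id -> direction (up/down).

    Accepts either an explicit ``direction`` column or a ``log2fc`` column
    (sign determines direction; zero rows are dropped).
    """
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: idx for idx, name in enumerate(header)}
        if "gene_id" not in cols:
            raise ParseError(f"{path}: header must contain 'gene_id'")
        has_dir = "direction" in cols
        has_fc = "log2fc" in cols
        if not (has_dir or has_fc):
            raise ParseError(f"{path}: header needs 'direction' or 'log2fc'")
        out: Dict[str, str] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            gene_id = fields[cols["gene_id"]]
            if has_dir:
                direction = fields[cols["direction"]].lower()
            else:
                fc = float(fields[cols["log2fc"]])
                direction = "up" if fc > 0 else ("down" if fc < 0 else "none")
            if direction in ("up", "down"):
                out[gene_id] = direction
            elif direction not in ("none", "ns", ""):
                raise ParseError(
                    f"{path}: line {lineno}: bad direction {direction!r}"
                )
    return out


def write_deg_table(path, degs: Dict[str, str], log2fc: Dict[str, float] | None = None) -> None:
    with _open(path, "w") as fh:
        fh.write("gene_id\tlog2fc\tdirection\n")
        for gene_id in degs:
            direction = degs[gene_id]
            if log2fc is not None and gene_id in log2fc:
                fc = log2fc[gene_id]
            else:
                fc = 1.0 if direction == "up" else -1.0
            fh.write(f"{gene_id}\t{fc!r}\t{direction}\n")
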