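"""Readers/writers for the external formats the pipeline touches.

Covers FASTA/FASTQ ligand libraries, the MEME minimal motif format,
narrowPeak (BED6+4) peak sets, and FASTA+GFF3 genome annotation. All genomic
intervals are 0-based half-open throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._seq import encode_matrix

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


@dataclass
class LigandLibrary:
    """A set of equal-length reads from one SELEX cycle.

    ``methylated`` is a library-level flag: in a Methyl-SELEX library every
    cytosine of every read (both strands) is 5-methylcytosine, so the
    alphabet stays ACGT. ``random_region`` is (start, length) of the
    randomized insert within each read; cycle 0 is the unselected input.
    """

    reads: list[str]
    cycle: int = 0
    methylated: bool = False
    random_region: tuple[int, int] | None = None
    label: str = ""

    def __post_init__(self):
        if self.cycle < 0:
            raise ValueError("cycle must be >= 0")
        if self.reads:
            L = len(self.reads[0])
            for i, r in enumerate(self.reads):
                if len(r) != L:
                    raise ValueError(
                        f"unequal read lengths: read {i} has length {len(r)}, expected {L}"
                    )
        if self.random_region is None:
            L = len(self.reads[0]) if self.reads else 0
            self.random_region = (0, L)
        start, length = self.random_region
        if self.reads and not (0 <= start and start + length <= len(self.reads[0])):
            raise ValueError("random_region outside read bounds")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def read_length(self) -> int:
        return len(self.reads[0]) if self.reads else 0

    def regions(self) -> list[str]:
        """The random-region substring of every read."""
        s, n = self.random_region
        return [r[s : s + n] for r in self.reads]

    def region_codes(self) -> np.ndarray:
        """(n_reads, region_length) uint8 encoding of the random regions."""
        return encode_matrix(self.regions())

    def read_codes(self) -> np.ndarray:
        """(n_reads, read_length) uint8 encoding of the full reads."""
        return encode_matrix(self.reads)

    def replace_reads(self, reads: list[str], cycle: int | None = None) -> "LigandLibrary":
        return LigandLibrary(
            reads=reads,
            cycle=self.cycle if cycle is None else cycle,
            methylated=self.methylated,
            random_region=self.random_region,
            label=self.label,
        )


def read_sequences(
    path,
    format: str = "fasta",
    random_region: tuple[int, int] | None = None,
    methylated: bool = False,
    cycle: int = 0,
    label: str | None = None,
) -> LigandLibrary:
    """Read a FASTA/FASTQ file into a LigandLibrary.

    Reads are uppercased; records containing characters outside ACGTN raise a
    format error naming the record; records containing N are dropped (their
    count is logged); all surviving reads must share one length.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    reads = []
    n_dropped = 0
    length = None
    for rec in SeqIO.parse(str(path), format):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"record {rec.id!r}: characters outside ACGTN: {sorted(bad)}"
            )
        if "N" in seq:
            n_dropped += 1
            continue
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"record {rec.id!r}: read length {len(seq)} differs from {length}"
            )
        reads.append(seq)
    if length is None:
        raise ValueError(f"{path}: no usable records")
    if n_dropped:
        logger.info("%s: dropped %d reads containing N", path, n_dropped)
    return LigandLibrary(
        reads=reads,
        cycle=cycle,
        methylated=methylated,
        random_region=random_region,
        label=label if label is not None else path.stem,
    )


def write_sequences(library: LigandLibrary, path, format: str = "fasta") -> None:
    """Write a LigandLibrary as FASTA or FASTQ (uniform quality 'I')."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    with open(path, "w") as fh:
        for i, read in enumerate(library.reads):
            name = f"{library.label or 'read'}_c{library.cycle}_{i}"
            if format == "fasta":
                fh.write(f">{name}\n{read}\n")
            else:
                fh.write(f"@{name}\n{read}\n+\n{'I' * len(read)}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format

def write_motif_meme(models, path, background=None) -> None:
    """Write PWM models in MEME minimal motif format.

    Every matrix column must sum to 1 within 1e-9. An empty model list
    produces a valid header-only file.
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        "A {:.6f} C {:.6f} G {:.6f} T {:.6f}".format(*bg),
        "",
    ]
    for model in models:
        mat = np.asarray(model.matrix, float)
        colsums = mat.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-9):
            raise ValueError(f"motif {model.name!r}: un-normalized column(s)")
        w = mat.shape[1]
        lines.append(f"MOTIF {model.name}")
        lines.append(f"letter-probability matrix: alength= 4 w= {w} nsites= 20 E= 0")
        for c in range(w):
            lines.append(" ".join(f"{mat[b, c]:.6f}" for b in range(4)))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def read_motif_meme(path) -> list:
    """Read a MEME minimal motif file back into PWMModel objects."""
    from .motifs import PWMModel  # local import to avoid a cycle

    models = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1] if len(line.split()) > 1 else ""
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            mat = np.array(rows).T  # stored row-per-position; PWMModel is 4 x w
            # renormalize away the 1e-6 print rounding
            mat = mat / mat.sum(axis=0, keepdims=True)
            models.append(PWMModel(matrix=mat, seed="", name=name))
            i += 1 + w
        else:
            i += 1
    return models


# ---------------------------------------------------------------------------
# narrowPeak

@dataclass
class PeakSet:
    """Genomic intervals with an intensity (narrowPeak signalValue).

    Intervals are 0-based half-open; ranking is by descending intensity with
    ties broken by (chrom, start).
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    intensity: np.ndarray
    names: np.ndarray | None = None

    def __post_init__(self):
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.starts >= self.ends):
            bad = int(np.nonzero(self.starts >= self.ends)[0][0])
            raise ValueError(f"interval {bad}: start >= end")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.starts)

    def rank_order(self) -> np.ndarray:
        """Indices sorted by descending intensity, ties by (chrom, start)."""
        return np.lexsort((self.starts, self.chroms, -self.intensity))

    def top(self, n: int) -> "PeakSet":
        idx = self.rank_order()[:n]
        return PeakSet(
            self.chroms[idx], self.starts[idx], self.ends[idx], self.intensity[idx],
            None if self.names is None else self.names[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "start": self.starts,
                "end": self.ends,
                "intensity": self.intensity,
            }
        )


def read_narrowpeak(path) -> PeakSet:
    """Read a narrowPeak (BED6+4) file; intensity is column 7 (signalValue)."""
    cols = [
        "chrom", "start", "end", "name", "score",
        "strand", "signalValue", "pValue", "qValue", "peak",
    ]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 7:
        raise ValueError(f"{path}: narrowPeak needs >= 7 columns, got {df.shape[1]}")
    df.columns = cols[: df.shape[1]]
    try:
        intensity = pd.to_numeric(df["signalValue"], errors="raise").to_numpy(float)
        starts = pd.to_numeric(df["start"], errors="raise").to_numpy(np.int64)
        ends = pd.to_numeric(df["end"], errors="raise").to_numpy(np.int64)
    except (ValueError, TypeError) as e:
        raise ValueError(f"{path}: non-numeric coordinate or signalValue: {e}") from e
    return PeakSet(
        chroms=df["chrom"].to_numpy(object),
        starts=starts,
        ends=ends,
        intensity=intensity,
        names=df["name"].to_numpy(object) if "name" in df else None,
    )


def write_narrowpeak(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(peaks)):
            name = peaks.names[i] if peaks.names is not None else f"peak_{i}"
            fh.write(
                f"{peaks.chroms[i]}\t{peaks.starts[i]}\t{peaks.ends[i]}\t{name}\t0\t.\t"
                f"{peaks.intensity[i]:g}\t-1\t-1\t-1\n"
            )


# ---------------------------------------------------------------------------
# Genome annotation

@dataclass
class GenomeAnnotation:
    """Named genome sequences plus TSS records (chrom, pos0, strand, gene_id).

    TSS positions are 0-based; strand is '+' or '-'. The 5' end of a gene
    defines its TSS (start for '+', end-1 for '-').
    """

    sequences: dict
    tss: list = field(default_factory=list)

    def __post_init__(self):
        for chrom, pos, strand, gene in self.tss:
            if chrom not in self.sequences:
                raise ValueError(f"TSS of {gene}: unknown chromosome {chrom!r}")
            if strand not in "+-":
                raise ValueError(f"TSS of {gene}: invalid strand {strand!r}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open substring, clipped to the contig."""
        seq = self.sequences[chrom]
        return str(seq[max(start, 0) : min(end, len(seq))]).upper()

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


def read_genome(fasta_path, gff3_path=None, feature_type: str = "gene") -> GenomeAnnotation:
    """Load a genome FASTA (via pyfaidx) and optional GFF3 gene annotation.

    TSSs come from the strand-aware 5' ends of ``feature_type`` features
    (GFF3 is 1-based inclusive; positions are converted to 0-based).
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    sequences = {name: fa[name] for name in fa.keys()}
    tss = []
    if gff3_path is not None:
        import gffutils

        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        for feat in db.features_of_type(feature_type):
            pos = feat.start - 1 if feat.strand == "+" else feat.end - 1
            tss.append((feat.seqid, pos, feat.strand, feat.id))
    return GenomeAnnotation(sequences=sequences, tss=tss)
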