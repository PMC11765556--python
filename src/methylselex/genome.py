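"""Genomic context statistics: TSS-proximity motif density, promoter target
assignment, and DAP-seq peak statistics (overlap, motif containment,
intensity comparison)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeAnnotation, PeakSet
from .motifs import MotifThreshold, PWMModel, match_motif, score_threshold_for_pvalue

logger = logging.getLogger(__name__)


@dataclass
class DensityProfile:
    """Motif-match density around TSSs, strand-oriented (upstream negative).

    ``density[k]`` is matches per gene per bp at offset ``offsets[k]``; the
    per-offset gene count corrects for genes truncated by contig ends. A
    match is placed at the gene-oriented offset of its 5'-most base.
    """

    offsets: np.ndarray
    density: np.ndarray
    gene_counts: np.ndarray
    name: str = ""


@dataclass
class OverlapTable:
    """Peak-level Venn counts for two peak sets plus a Fisher test.

    ``shared`` is min(#A overlapping B, #B overlapping A), so it is
    symmetric under swapping the sets. The Fisher 2x2 table cross-tabulates
    coverage of genome tiles (width = pooled median peak width) by A and B.
    """

    unique_a: int
    unique_b: int
    shared: int
    table: tuple
    p_value: float
    odds_ratio: float


def _ensure_threshold(model, p, threshold):
    if threshold is None:
        return score_threshold_for_pvalue(model, p=p)
    return threshold


def tss_density(
    genome: GenomeAnnotation,
    models: list[PWMModel],
    W: int = 1000,
    min_mean_ic: float = 0.3,
    p: float = 1e-5,
    thresholds: dict | None = None,
) -> dict[str, DensityProfile]:
    """Motif-match density profiles in [TSS-W, TSS+W] per qualifying model.

    Models with mean IC <= ``min_mean_ic`` are excluded. Matches on both
    strands count; the offset of a match is the strand-oriented position of
    its 5'-most base relative to the TSS (TSS = 0, upstream negative).
    """
    kept = [m for m in models if m.mean_ic > min_mean_ic]
    if not kept:
        logger.warning("no model passes the mean-IC > %.2f filter", min_mean_ic)
        return {}
    offsets = np.arange(-W, W + 1)
    out: dict[str, DensityProfile] = {}
    for model in kept:
        thr = (thresholds or {}).get(model.name) or _ensure_threshold(model, p, None)
        w = model.width
        hist = np.zeros(2 * W + 1)
        gene_counts = np.zeros(2 * W + 1)
        for chrom, tss, strand, _gene in genome.tss:
            clen = genome.chrom_length(chrom)
            lo = max(tss - W - w, 0)
            hi = min(tss + W + w + 1, clen)
            seq = genome.fetch(chrom, lo, hi)
            # offsets covered by the contig (strand-oriented)
            pos = tss + (offsets if strand == "+" else -offsets)
            gene_counts += (pos >= 0) & (pos < clen)
            if len(seq) < w:
                continue
            df = match_motif(model, [seq], thr)
            for _, row in df.iterrows():
                gstart = lo + int(row["offset"])  # genomic start of the match
                gend5 = gstart if strand == "+" else gstart + w - 1
                off = gend5 - tss if strand == "+" else tss - gend5
                if -W <= off <= W:
                    hist[off + W] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            density = np.where(gene_counts > 0, hist / np.maximum(gene_counts, 1), 0.0)
        out[model.name] = DensityProfile(
            offsets=offsets, density=density, gene_counts=gene_counts, name=model.name
        )
    return out


def scan_genome(
    model: PWMModel,
    genome: GenomeAnnotation,
    p: float = 1e-5,
    threshold: MotifThreshold | None = None,
) -> pd.DataFrame:
    """Genome-wide motif matches as (chrom, start, end, strand, score)."""
    thr = _ensure_threshold(model, p, threshold)
    w = model.width
    rows = []
    for chrom in genome.sequences:
        seq = genome.fetch(chrom, 0, genome.chrom_length(chrom))
        df = match_motif(model, [seq], thr)
        for _, r in df.iterrows():
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(r["offset"]),
                    "end": int(r["offset"]) + w,
                    "strand": r["strand"],
                    "score": r["score"],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score"])


def assign_targets(
    matches: pd.DataFrame,
    annotation: GenomeAnnotation,
    upstream: int = 1000,
    downstream: int = 200,
) -> dict[str, int]:
    """Count motif matches per gene promoter.

    A match is assigned to every gene whose strand-oriented promoter window
    [TSS - upstream, TSS + downstream] contains the match midpoint; a match
    between two divergent promoters is assigned to both genes.
    """
    out: dict[str, int] = {}
    if len(matches) == 0:
        return out
    mids = ((matches["start"] + matches["end"]) // 2).to_numpy()
    chroms = matches["chrom"].to_numpy()
    for chrom, tss, strand, gene in annotation.tss:
        if strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        n = int(np.sum((chroms == chrom) & (mids >= lo) & (mids <= hi)))
        if n:
            out[gene] = out.get(gene, 0) + n
    return out


# ---------------------------------------------------------------------------
# Peak statistics

def _overlap_flags(a: PeakSet, b: PeakSet, min_frac: float) -> np.ndarray:
    """For every interval of a: does it overlap (>= 1 bp, and >= min_frac of
    its own length) some interval of b?"""
    flags = np.zeros(len(a), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i in range(len(b)):
        by_chrom.setdefault(b.chroms[i], []).append((int(b.starts[i]), int(b.ends[i])))
    for c in by_chrom:
        by_chrom[c].sort()
    for i in range(len(a)):
        ivs = by_chrom.get(a.chroms[i])
        if not ivs:
            continue
        s, e = int(a.starts[i]), int(a.ends[i])
        need = max(1.0, min_frac * (e - s))
        for bs, be in ivs:
            if bs >= e:
                break
            ov = min(e, be) - max(s, bs)
            if ov >= need:
                flags[i] = True
                break
    return flags


def peak_overlap(a: PeakSet, b: PeakSet, min_frac: float = 1e-9) -> OverlapTable:
    """Peak-level Venn counts and a Fisher test of the overlap.

    Peaks overlap if they share at least one base. For the Fisher 2x2 the
    genome span covered by either set is tiled into non-overlapping bins of
    the pooled median peak width, and bins are cross-tabulated by whether A
    and B cover them; the two-sided p-value is reported.
    """
    chroms_a, chroms_b = set(a.chroms), set(b.chroms)
    if not chroms_a or not chroms_b:
        raise ValueError("empty peak set")
    a_in_b = int(_overlap_flags(a, b, min_frac).sum())
    b_in_a = int(_overlap_flags(b, a, min_frac).sum())
    shared = min(a_in_b, b_in_a)
    widths = np.concatenate([a.ends - a.starts, b.ends - b.starts])
    bin_w = max(1, int(np.median(widths)))
    table = np.zeros((2, 2), dtype=np.int64)
    for chrom in sorted(chroms_a | chroms_b):
        sel_a = a.chroms == chrom
        sel_b = b.chroms == chrom
        hi = max(
            a.ends[sel_a].max() if sel_a.any() else 0,
            b.ends[sel_b].max() if sel_b.any() else 0,
        )
        n_bins = int(np.ceil(hi / bin_w))
        cov_a = np.zeros(n_bins, dtype=bool)
        cov_b = np.zeros(n_bins, dtype=bool)
        for cov, ps, sel in ((cov_a, a, sel_a), (cov_b, b, sel_b)):
            for s, e in zip(ps.starts[sel], ps.ends[sel]):
                cov[s // bin_w : (e - 1) // bin_w + 1] = True
        table[0, 0] += int(np.sum(cov_a & cov_b))
        table[0, 1] += int(np.sum(cov_a & ~cov_b))
        table[1, 0] += int(np.sum(~cov_a & cov_b))
        table[1, 1] += int(np.sum(~cov_a & ~cov_b))
    odds, pval = fisher_2x2(tuple(table.ravel()))
    return OverlapTable(
        unique_a=len(a) - a_in_b,
        unique_b=len(b) - b_in_a,
        shared=shared,
        table=tuple(int(x) for x in table.ravel()),
        p_value=pval,
        odds_ratio=odds,
    )


def fisher_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a flat (a, b, c, d) table."""
    a, b, c, d = table
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _peak_contains(
    peaks: PeakSet, genome: GenomeAnnotation, model: PWMModel, threshold
) -> np.ndarray:
    """Boolean per peak: >= 1 motif match (either strand) within the peak."""
    out = np.zeros(len(peaks), dtype=bool)
    seqs, keep = [], []
    for i in range(len(peaks)):
        seq = genome.fetch(peaks.chroms[i], int(peaks.starts[i]), int(peaks.ends[i]))
        if len(seq) >= model.width:
            seqs.append(seq)
            keep.append(i)
    if not seqs:
        return out
    df = match_motif(model, seqs, threshold)
    for si in df["seq_index"].unique():
        out[keep[int(si)]] = True
    return out


def top_peaks_motif_proportion(
    peaks: PeakSet,
    genome: GenomeAnnotation,
    model: PWMModel,
    top_n: int = 3000,
    bins: int = 10,
    p: float = 1e-5,
    threshold: MotifThreshold | None = None,
) -> tuple[float, np.ndarray]:
    """Fraction of the top-N peaks (by intensity rank) containing the motif.

    Also returns per-bin proportions over ``bins`` rank-contiguous blocks,
    the replicate unit for between-library t-tests on containment.
    """
    if len(peaks) < top_n:
        logger.warning("only %d peaks available; using all", len(peaks))
        top_n = len(peaks)
    thr = _ensure_threshold(model, p, threshold)
    top = peaks.top(top_n)
    contains = _peak_contains(top, genome, model, thr)
    proportion = float(contains.mean()) if top_n else 0.0
    edges = np.linspace(0, top_n, bins + 1).astype(int)
    per_bin = np.array(
        [
            contains[edges[k] : edges[k + 1]].mean() if edges[k + 1] > edges[k] else np.nan
            for k in range(bins)
        ]
    )
    return proportion, per_bin


def welch_t(group_a, group_b) -> tuple[float, float, str]:
    """Two-sided Welch t-test; marker '*' at p <= 0.05, 'ns' above, 'na' when
    a group is too small for the statistic."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan"), "na"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(t):
        return float("nan"), float("nan"), "na"
    return float(t), float(p), ("*" if p <= 0.05 else "ns")


def peak_intensity_by_motif(
    peaks: PeakSet,
    genome: GenomeAnnotation,
    modelA: PWMModel,
    modelB: PWMModel,
    p: float = 1e-5,
    thresholds: tuple | None = None,
) -> dict:
    """Compare intensities of peaks containing motif A only vs B only.

    Peaks containing both or neither motif are excluded. Returns the two
    intensity vectors, their means, and a two-sided Welch t-test with a
    significance marker ('*' at p <= 0.05, else 'ns'; 'na' if a group is
    degenerate).
    """
    thrA = thresholds[0] if thresholds else _ensure_threshold(modelA, p, None)
    thrB = thresholds[1] if thresholds else _ensure_threshold(modelB, p, None)
    hasA = _peak_contains(peaks, genome, modelA, thrA)
    hasB = _peak_contains(peaks, genome, modelB, thrB)
    only_a = peaks.intensity[hasA & ~hasB]
    only_b = peaks.intensity[~hasA & hasB]
    t, pv, marker = welch_t(only_a, only_b)
    return {
        "intensity_a_only": only_a,
        "intensity_b_only": only_b,
        "mean_a": float(only_a.mean()) if len(only_a) else float("nan"),
        "mean_b": float(only_b.mean()) if len(only_b) else float("nan"),
        "t": t,
        "p": pv,
        "marker": marker,
    }
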