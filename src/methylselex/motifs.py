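"""Seed-based PWM construction, matching and enrichment.

The PWM builder follows the seed-driven multinomial convention used by
HT-SELEX motif discovery tools: base counts for column c come from windows
(both strands) that match the IUPAC seed at every position except possibly c.
Match significance uses an exact dynamic-programming distribution of the
log-odds score of a random background sequence, discretized to an integer
lattice, so thresholds correspond to exact tail probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import mismatch_counts, pattern_masks, revcomp_iupac, windows, MATCH_TABLE
from .io import LigandLibrary

logger = logging.getLogger(__name__)

_ROW_ORDER = "ACGT"


@dataclass
class PWMModel:
    """A 4 x w base-probability matrix (rows A, C, G, T).

    ``seed`` is the IUPAC seed the matrix was built from, ``methylated``
    flags the source library, ``enrichment`` is filled by
    :func:`motif_enrichment`. ``ic`` is the per-column information content in
    bits against a uniform background.
    """

    matrix: np.ndarray
    seed: str = ""
    name: str = ""
    methylated: bool = False
    enrichment: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x w")
        colsums = self.matrix.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise ValueError("PWM columns must each sum to 1")
        self.matrix = self.matrix / colsums  # exact normalization

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def ic(self) -> np.ndarray:
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + term.sum(axis=0)

    @property
    def mean_ic(self) -> float:
        return float(self.ic.mean())

    def consensus(self) -> str:
        return "".join(_ROW_ORDER[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self, background=None, prob_floor: float = 1e-9) -> np.ndarray:
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        p = np.maximum(self.matrix, prob_floor)
        return np.log2(p / bg[:, None])


def information_content(model: PWMModel) -> tuple[np.ndarray, float]:
    """Per-column IC (bits, uniform background) and the mean over columns."""
    ic = model.ic
    return ic, float(ic.mean())


# ---------------------------------------------------------------------------
# Seed-based construction

def _seed_column_counts(
    codes: np.ndarray, seed: str, level: int
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial column counts for one library (both strands).

    codes: (n, L) uint8. Returns (counts[4, w], totals[w]) where column c
    counts bases at c over windows whose mismatch count at positions other
    than c is <= level - 1. Reverse-strand windows are read in the seed frame
    (complemented bases), so they contribute complemented counts.
    """
    w = len(seed)
    if codes.shape[1] < w:
        raise ValueError("seed longer than scanned region")
    counts = np.zeros((4, w), dtype=np.int64)
    totals = np.zeros(w, dtype=np.int64)
    win = windows(codes, w).reshape(-1, w)  # (n_windows, w)
    for strand, masks in (("+", pattern_masks(seed)),
                          ("-", pattern_masks(revcomp_iupac(seed)))):
        ok = MATCH_TABLE[masks[None, :], win]  # (n_windows, w)
        mm = (w - ok.sum(axis=1)).astype(np.int32)
        # windows needing attention: mismatches excluding one column <= level-1
        cand = mm <= level
        if not np.any(cand):
            continue
        okc, mmc, winc = ok[cand], mm[cand], win[cand]
        for c in range(w):
            wpos = c if strand == "+" else w - 1 - c
            ok_c = okc[:, wpos]
            sel = (mmc - (~ok_c)) <= level - 1
            if not np.any(sel):
                continue
            bases = winc[sel, wpos]
            if strand == "-":
                bases = 3 - bases
            bc = np.bincount(bases[bases < 4], minlength=4)
            counts[:, c] += bc
            totals[c] += bc.sum()
    return counts, totals


def build_pwm_from_seed(
    library: LigandLibrary,
    seed: str,
    background: LigandLibrary | None = None,
    multinomial_level: int = 1,
    pseudocount: float = 1.0,
    name: str | None = None,
) -> PWMModel:
    """Build a PWM from an IUPAC seed by multinomial counting.

    Column c counts base frequencies over random-region windows (both
    strands) matching the seed at every position except up to
    ``multinomial_level`` positions including c. With a ``background``
    library (typically cycle 0) its expected counts, scaled to equal
    per-column match totals, are subtracted and floored at the pseudocount.
    """
    if multinomial_level < 1:
        raise ValueError("multinomial_level must be >= 1")
    counts, totals = _seed_column_counts(library.region_codes(), seed, multinomial_level)
    if totals.sum() == 0:
        raise ValueError(f"seed {seed!r}: zero matches in library")
    mat = counts.astype(float) + pseudocount
    if background is not None:
        bcounts, btotals = _seed_column_counts(
            background.region_codes(), seed, multinomial_level
        )
        scale = np.where(btotals > 0, totals / np.maximum(btotals, 1), 0.0)
        mat = np.maximum(mat - bcounts * scale[None, :], pseudocount)
    mat = mat / mat.sum(axis=0, keepdims=True)
    return PWMModel(
        matrix=mat,
        seed=seed,
        name=name if name is not None else seed,
        methylated=library.methylated,
    )


def seed_pwm(seed: str, match_prob: float = 0.9, name: str | None = None) -> PWMModel:
    """An idealized PWM encoding an IUPAC seed directly.

    Allowed bases at each position share ``match_prob`` equally and the rest
    share the remainder; N columns are uniform. Useful as a fixed,
    library-independent detector for a seed-defined motif.
    """
    from ._seq import iupac_mask

    w = len(seed)
    mat = np.empty((4, w))
    for c, ch in enumerate(seed.upper()):
        mask = iupac_mask(ch)
        allowed = np.array([bool(mask & (1 << b)) for b in range(4)])
        k = int(allowed.sum())
        if k == 4:
            mat[:, c] = 0.25
        else:
            mat[allowed, c] = match_prob / k
            mat[~allowed, c] = (1 - match_prob) / (4 - k)
    return PWMModel(matrix=mat, seed=seed, name=name if name is not None else seed)


# ---------------------------------------------------------------------------
# Exact score-distribution thresholds

@dataclass
class MotifThreshold:
    """A lattice score threshold with its exact tail probability.

    Scores are discretized as round(log_odds / delta); ``t_int`` is the
    smallest integer lattice score whose tail probability under the
    background model is <= the requested p. ``score`` is t_int * delta on the
    log-odds scale.
    """

    t_int: int
    delta: float
    p_actual: float
    p_requested: float
    s_int: np.ndarray = field(repr=False, default=None)
    background: np.ndarray = field(repr=False, default=None)

    @property
    def score(self) -> float:
        return self.t_int * self.delta


def lattice_scores(model: PWMModel, background=None, n_levels: int = 10_000):
    """Integer lattice log-odds scores (w, 4) and the lattice step delta."""
    lo = model.log_odds(background)  # (4, w)
    span = float((lo.max(axis=0) - lo.min(axis=0)).sum())
    delta = span / n_levels if span > 0 else 1.0
    s_int = np.rint(lo.T / delta).astype(np.int64)  # (w, 4)
    return s_int, delta


def score_distribution(s_int: np.ndarray, background: np.ndarray):
    """Exact pmf of the summed lattice score of a random background w-mer.

    Returns (offset, pmf) with P(score == offset + k) = pmf[k]; computed by
    column-wise convolution.
    """
    w = s_int.shape[0]
    lo_sum = int(s_int.min(axis=1).sum())
    hi_sum = int(s_int.max(axis=1).sum())
    size = hi_sum - lo_sum + 1
    dist = np.zeros(size)
    dist[0] = 1.0
    reach = 0  # current occupied extent, scores relative to running minimum
    base = 0  # running sum of per-column minima
    for pos in range(w):
        col = s_int[pos]
        cmin = int(col.min())
        new = np.zeros(size)
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift : shift + reach + 1] += background[b] * dist[: reach + 1]
        dist = new
        reach += int(col.max()) - cmin
        base += cmin
    assert base == lo_sum
    return lo_sum, dist[: reach + 1]


def score_threshold_for_pvalue(
    model: PWMModel,
    background=None,
    p: float = 1e-5,
    n_levels: int = 10_000,
) -> MotifThreshold:
    """Smallest lattice threshold t with P(score >= t) <= p, plus p_actual.

    The exact distribution of the lattice log-odds score of a random
    background w-mer is computed by dynamic programming. If p is below the
    smallest attainable tail, the maximum score is returned with its actual
    tail probability.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    s_int, delta = lattice_scores(model, bg, n_levels)
    offset, pmf = score_distribution(s_int, bg)
    tail = np.cumsum(pmf[::-1])[::-1]  # tail[k] = P(score >= offset + k)
    ok = np.nonzero(tail <= p)[0]
    if len(ok) == 0:  # p below the minimal attainable tail: use max score
        k = len(pmf) - 1
    else:
        k = int(ok[0])
    return MotifThreshold(
        t_int=offset + k,
        delta=delta,
        p_actual=float(tail[k]),
        p_requested=p,
        s_int=s_int,
        background=bg,
    )


# ---------------------------------------------------------------------------
# Matching

def _as_sequences(sequences):
    if isinstance(sequences, LigandLibrary):
        return sequences.regions()
    if isinstance(sequences, str):
        return [sequences]
    return list(sequences)


def _window_scores(codes: np.ndarray, smat: np.ndarray) -> np.ndarray:
    """Sum scores over sliding windows: codes (n, L), smat (w, 4+pad)."""
    w = smat.shape[0]
    # pad score matrix with a very negative column for unknown bases
    neg = np.full((w, 1), -1e12 if smat.dtype.kind == "f" else np.iinfo(np.int64).min // (2 * w))
    sm = np.concatenate([smat, neg.astype(smat.dtype)], axis=1)
    win = windows(codes, w)  # (n, Wn, w)
    return sm[np.arange(w)[None, None, :], win].sum(axis=-1)


def match_motif(model: PWMModel, sequences, threshold) -> pd.DataFrame:
    """Scan sequences on both strands for windows scoring >= threshold.

    ``threshold`` is either a :class:`MotifThreshold` (matching is done on
    its exact integer lattice) or a float log-odds cutoff. Returns a frame
    with columns (seq_index, offset, strand, score); offsets are 0-based
    starts on the given sequence, and a window counts once per (position,
    strand).
    """
    seqs = _as_sequences(sequences)
    if isinstance(threshold, MotifThreshold):
        smat = threshold.s_int
        cutoff = threshold.t_int
        delta = threshold.delta
    else:
        smat = model.log_odds().T  # (w, 4)
        cutoff = float(threshold)
        delta = 1.0
    w = model.width
    # reverse-complement score frame: rc[p, b] = smat[w-1-p, 3-b]
    smat_rc = smat[::-1, ::-1].copy()

    from ._seq import encode_matrix

    rows = []
    # group by length so libraries vectorize as one matrix
    by_len: dict[int, list[tuple[int, str]]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append((i, s))
    for L, group in by_len.items():
        if L < w:
            continue
        idx = np.array([i for i, _ in group])
        codes = encode_matrix([s for _, s in group])
        for strand, sm in (("+", smat), ("-", smat_rc)):
            sc = _window_scores(codes, sm)
            hit = np.nonzero(sc >= cutoff)
            for gi, off in zip(*hit):
                rows.append(
                    (int(idx[gi]), int(off), strand, float(sc[gi, off] * delta))
                )
    df = pd.DataFrame(rows, columns=["seq_index", "offset", "strand", "score"])
    return df.sort_values(["seq_index", "offset", "strand"]).reset_index(drop=True)


def count_matches(model: PWMModel, sequences, threshold) -> int:
    return len(match_motif(model, sequences, threshold))


def count_seed_matches(sequences, seed: str, max_mismatch: int = 0) -> int:
    """Windows (both strands) matching an IUPAC seed with <= max_mismatch
    mismatches; N positions match everything."""
    from ._seq import encode_matrix

    seqs = _as_sequences(sequences)
    total = 0
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    for L, group in by_len.items():
        if L < len(seed):
            continue
        codes = encode_matrix(group)
        for masks in (pattern_masks(seed), pattern_masks(revcomp_iupac(seed))):
            total += int((mismatch_counts(codes, masks) <= max_mismatch).sum())
    return total


# ---------------------------------------------------------------------------
# Shuffled background and enrichment

def shuffle_library(library: LigandLibrary, seed: int) -> LigandLibrary:
    """Mononucleotide-shuffle each read's random region (flanks untouched).

    Per-read base composition is exactly preserved; reproducible by seed.
    """
    rng = np.random.default_rng(seed)
    s, n = library.random_region
    reads = []
    for read in library.reads:
        region = np.array(list(read[s : s + n]))
        rng.shuffle(region)
        reads.append(read[:s] + "".join(region) + read[s + n :])
    lib = library.replace_reads(reads)
    lib.label = (library.label + "_shuffled").lstrip("_")
    return lib


def motif_enrichment(
    model: PWMModel,
    library: LigandLibrary,
    shuffled: LigandLibrary,
    p: float = 1e-5,
    threshold: MotifThreshold | None = None,
) -> float:
    """Motif hits in the library divided by hits in its shuffled version.

    The shuffled count is pseudocounted (+1). The ratio is stored on
    ``model.enrichment`` and returned.
    """
    if len(library) != len(shuffled) or library.read_length != shuffled.read_length:
        raise ValueError("library and shuffled background must have equal size/length")
    if threshold is None:
        threshold = score_threshold_for_pvalue(model, p=p)
    n_lib = count_matches(model, library, threshold)
    n_shuf = count_matches(model, shuffled, threshold)
    ratio = n_lib / (n_shuf + 1.0)
    model.enrichment = float(ratio)
    return float(ratio)


# ---------------------------------------------------------------------------
# Methyl vs normal positional comparison

@dataclass
class MethylComparison:
    """Per-position comparison of a methylated PWM with its normal version.

    ``call`` is '+' when the C+G probability rises by more than tau upon
    methylation, '-' when it falls by more than tau, and '.' otherwise.
    """

    table: pd.DataFrame
    tau: float

    def calls(self) -> str:
        return "".join(self.table["call"])


def compare_methyl_pwms(
    normal: PWMModel, methyl: PWMModel, tau: float = 0.05
) -> MethylComparison:
    """Position-wise cytosine-affinity calls between matched PWMs.

    Positions are aligned from column 1 of each matrix and compared over the
    narrower width. delta_CG is the change in C+G probability (methyl minus
    normal); the preferred base is the per-column argmax.
    """
    w = min(normal.width, methyl.width)
    rows = []
    for c in range(w):
        pn = normal.matrix[:, c]
        pm = methyl.matrix[:, c]
        delta = float((pm[1] + pm[2]) - (pn[1] + pn[2]))
        call = "+" if delta > tau else ("-" if delta < -tau else ".")
        rows.append(
            {
                "position": c + 1,
                "preferred_base_normal": _ROW_ORDER[int(pn.argmax())],
                "preferred_base_methyl": _ROW_ORDER[int(pm.argmax())],
                "delta_CG": delta,
                "call": call,
            }
        )
    return MethylComparison(table=pd.DataFrame(rows), tau=tau)
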