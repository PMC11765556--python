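"""Low-level sequence utilities: base encoding, reverse complement, IUPAC masks.

Bases are encoded A=0, C=1, G=2, T=3; any other character encodes to 4 and
never matches an IUPAC pattern. IUPAC codes are represented as 4-bit masks
(A=1, C=2, G=4, T=8) so pattern matching is a table lookup.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC code -> bitmask over A=1, C=2, G=4, T=8
IUPAC_MASKS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

# mask -> IUPAC char (for complementing degenerate patterns)
_MASK_TO_IUPAC = {m: c for c, m in IUPAC_MASKS.items()}

# preferred single-base instantiation of each IUPAC code; chosen so that
# consensus(revcomp(code)) == complement(consensus(code)) for R/Y/S/K/M,
# and so Y -> C, R -> G (the methylation-relevant choice).
_IUPAC_CONSENSUS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "G", "Y": "C", "S": "C", "W": "A", "K": "G", "M": "C",
    "B": "C", "D": "A", "H": "A", "V": "A", "N": "A",
}

# match table: rows indexed by mask (0..15), cols by base code 0..4;
# code 4 (unknown) never matches.
MATCH_TABLE = np.zeros((16, 5), dtype=bool)
for _m in range(16):
    for _b in range(4):
        MATCH_TABLE[_m, _b] = bool(_m & (1 << _b))


def encode(seq: str) -> np.ndarray:
    """Encode a sequence to uint8 codes; unknown characters become 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def encode_matrix(seqs) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    if len(seqs) == 0:
        return np.zeros((0, 0), dtype=np.uint8)
    joined = "".join(seqs)
    L = len(seqs[0])
    return encode(joined).reshape(len(seqs), L)


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of a degenerate IUPAC pattern."""
    out = []
    for ch in reversed(pattern.upper()):
        mask = iupac_mask(ch)
        comp = ((mask & 1) << 3) | ((mask & 2) << 1) | ((mask & 4) >> 1) | ((mask & 8) >> 3)
        out.append(_MASK_TO_IUPAC[comp])
    return "".join(out)


def iupac_mask(ch: str) -> int:
    try:
        return IUPAC_MASKS[ch.upper()]
    except KeyError:
        raise ValueError(f"invalid IUPAC symbol: {ch!r}") from None


def pattern_masks(pattern: str) -> np.ndarray:
    """uint8 mask array for a degenerate pattern (validates symbols)."""
    return np.array([iupac_mask(c) for c in pattern], dtype=np.uint8)


def iupac_consensus(pattern: str) -> str:
    """A fixed single-base instantiation of a degenerate pattern (Y->C, R->G)."""
    try:
        return "".join(_IUPAC_CONSENSUS[c.upper()] for c in pattern)
    except KeyError as e:
        raise ValueError(f"invalid IUPAC symbol in {pattern!r}") from e


def windows(codes: np.ndarray, w: int) -> np.ndarray:
    """Sliding windows of width w along the last axis (a view, not a copy)."""
    return np.lib.stride_tricks.sliding_window_view(codes, w, axis=-1)


def mismatch_counts(codes: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Number of pattern mismatches for every window of every row.

    codes: (n, L) uint8; masks: (w,) uint8. Returns (n, L-w+1) int16.
    """
    w = len(masks)
    win = windows(codes, w)  # (n, L-w+1, w)
    ok = MATCH_TABLE[masks[None, None, :], win]
    return (w - ok.sum(axis=-1)).astype(np.int16)
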