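"""Half-site grammar for homodimeric binding sites.

A dimeric cis-regulatory element is two copies of a short half-site (default
``YAATYA``) in one of three relative orientations — direct repeat (DR, both
copies on the same strand), inverted repeat (IR, head-to-head, +/-) and
everted repeat (ER, tail-to-tail, -/+) — separated by a gap of ``spacing``
bases. A configuration is named by orientation plus spacing, e.g. ``ER0``,
``ER1``, ``DR3``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ._seq import (
    encode,
    iupac_consensus,
    mismatch_counts,
    pattern_masks,
    revcomp_iupac,
)

DEFAULT_HALF_SITE = "YAATYA"
ORIENTATIONS = ("DR", "IR", "ER")


@dataclass(frozen=True)
class HalfSiteMatch:
    """One half-site occurrence: 0-based start, strand, mismatch count."""

    start: int
    strand: str  # '+' or '-'
    mismatches: int = 0


@dataclass(frozen=True)
class DimerAssignment:
    """Orientation/spacing call for a sequence or a half-site pair.

    ``orientation`` is one of DR/IR/ER for dimers, or "monomer", "none",
    "overlap". ``spacing`` (gap in bases between the half-site spans) is only
    set for dimers; ``name`` combines the two (e.g. "ER0").
    """

    orientation: str
    spacing: int | None = None
    name: str = ""

    def __post_init__(self):
        if not self.name:
            if self.orientation in ORIENTATIONS and self.spacing is not None:
                object.__setattr__(self, "name", f"{self.orientation}{self.spacing}")
            else:
                object.__setattr__(self, "name", self.orientation)


def scan_half_sites(
    sequence: str,
    half_site: str = DEFAULT_HALF_SITE,
    max_mismatch: int = 0,
) -> list[HalfSiteMatch]:
    """Find half-site occurrences on both strands of ``sequence``.

    Forward matches are windows matching the IUPAC ``half_site`` with at most
    ``max_mismatch`` mismatches; reverse matches are windows matching its
    reverse complement, reported with strand '-'. Coordinates are 0-based
    starts on the given sequence; results are sorted by (start, strand).
    """
    L = len(half_site)
    if len(sequence) < L:
        raise ValueError("sequence shorter than half-site")
    fwd = pattern_masks(half_site)
    rev = pattern_masks(revcomp_iupac(half_site))
    codes = encode(sequence)[None, :]
    out: list[HalfSiteMatch] = []
    for strand, masks in (("+", fwd), ("-", rev)):
        mm = mismatch_counts(codes, masks)[0]
        for i in np.nonzero(mm <= max_mismatch)[0]:
            out.append(HalfSiteMatch(int(i), strand, int(mm[i])))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def classify_pair(m1: HalfSiteMatch, m2: HalfSiteMatch, half_len: int) -> DimerAssignment:
    """Classify an ordered half-site pair (m1.start <= m2.start).

    spacing = m2.start - (m1.start + half_len). Negative spacing (overlapping
    spans) is called "overlap". Strand pairs: (+,+) and (-,-) are direct
    repeats; (+,-) head-to-head inverted repeats; (-,+) tail-to-tail everted
    repeats.
    """
    if m1.start > m2.start:
        raise ValueError("m1 must not start after m2")
    spacing = m2.start - (m1.start + half_len)
    if spacing < 0:
        return DimerAssignment("overlap")
    if m1.strand == m2.strand:
        orient = "DR"
    elif (m1.strand, m2.strand) == ("+", "-"):
        orient = "IR"
    else:
        orient = "ER"
    return DimerAssignment(orient, spacing)


def classify_probe(
    sequence: str,
    half_site: str = DEFAULT_HALF_SITE,
    max_mismatch: int = 0,
    max_spacing: int = 20,
) -> DimerAssignment:
    """Classify a probe sequence by its half-site content.

    No half-site match gives "none"; a single match "monomer". With two or
    more matches the best dimeric pair is reported: fewest total mismatches,
    then smallest spacing, then orientation (DR < ER < IR), then leftmost.
    The orientation key before the positional tie-break keeps the call
    invariant under reverse complementation. Pairs with spacing above
    ``max_spacing`` or with overlapping spans are ignored; if no valid pair
    remains the call is "monomer".
    """
    matches = scan_half_sites(sequence, half_site, max_mismatch)
    if not matches:
        return DimerAssignment("none")
    if len(matches) == 1:
        return DimerAssignment("monomer")
    half_len = len(half_site)
    best_key = None
    best: DimerAssignment | None = None
    for a in range(len(matches)):
        for b in range(a + 1, len(matches)):
            m1, m2 = matches[a], matches[b]
            asn = classify_pair(m1, m2, half_len)
            if asn.orientation not in ORIENTATIONS or asn.spacing > max_spacing:
                continue
            key = (m1.mismatches + m2.mismatches, asn.spacing, asn.orientation, m1.start)
            if best_key is None or key < best_key:
                best_key, best = key, asn
    return best if best is not None else DimerAssignment("monomer")


def enumerate_dimer_seeds(
    half_site: str = DEFAULT_HALF_SITE,
    orientations: Sequence[str] = ORIENTATIONS,
    max_spacing: int = 10,
) -> list[tuple[str, str]]:
    """Gapped IUPAC seeds for every orientation x spacing up to max_spacing.

    DRs = HS + N^s + HS; IRs = HS + N^s + revcomp(HS); ERs = revcomp(HS) +
    N^s + HS. Returns (name, seed) pairs, ordered by orientation then spacing.
    """
    if max_spacing < 0:
        raise ValueError("max_spacing must be >= 0")
    hs = half_site.upper()
    rc = revcomp_iupac(hs)
    out = []
    for orient in orientations:
        if orient not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {orient!r}")
        for s in range(max_spacing + 1):
            gap = "N" * s
            if orient == "DR":
                seed = hs + gap + hs
            elif orient == "IR":
                seed = hs + gap + rc
            else:
                seed = rc + gap + hs
            out.append((f"{orient}{s}", seed))
    return out


def seed_consensus(seed: str) -> str:
    """Fixed single-base instantiation of a degenerate seed (Y->C, R->G, N->A)."""
    return iupac_consensus(seed)


_NAME_RE = re.compile(r"^(DR|IR|ER)(\d+)$")


def parse_name(name: str) -> tuple[str, int]:
    """Split a dimer name like 'ER0' into ('ER', 0)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a dimer configuration name: {name!r}")
    return m.group(1), int(m.group(2))
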