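"""Generative SELEX / Methyl-SELEX model with known ground truth.

A read's affinity is linear in Boltzmann weights: monomeric occupancy sums
exp(energy) over all half-site windows on both strands, and dimeric
occupancy sums gamma(orientation, spacing) * exp(E1 + E2) over ordered
window pairs. Methylation (a library-level flag; every C is 5mC on both
strands) adds position-dependent energy deltas to C/G bases inside the
half-site frame and at its two flanking positions, and may switch the
cooperativity map — the spacing dependence of the methylation effect
reported for this TF family cannot be expressed by position-additive terms
alone (any spacer bonus reachable by the abutting configuration is also
reachable by a spaced one), so the model carries an optional methylated
cooperativity map.

Each selection cycle draws a multinomial sample proportional to affinity and
then resamples with replacement back to the library size (PCR without an
error model), so enrichment of a read class is exponential in its relative
affinity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, encode_matrix, revcomp
from .io import LigandLibrary

ORIENTATIONS = ("DR", "IR", "ER")
_STRAND_ORIENT = {("+", "+"): "DR", ("-", "-"): "DR", ("+", "-"): "IR", ("-", "+"): "ER"}


@dataclass
class BindingModel:
    """Simulator ground truth.

    half_site: IUPAC pattern the energies refer to (positions 0..L-1).
    monomer_energy: (L, 4) log-affinity matrix (columns A, C, G, T);
        consensus bases 0, deviations negative.
    gamma: {(orientation, spacing): cooperativity >= 0} for unmethylated
        libraries; gamma_methylated (optional) replaces it when the library
        is methylated.
    methyl_delta: {position: energy delta} added to a C or G at that
        half-site frame position when the library is methylated; keys -1 and
        L address the two flanking positions.
    monomer_weight: scalar multiplier of the monomeric occupancy term.
    energy_floor: windows below this energy contribute nothing.
    """

    half_site: str = "YAATYA"
    monomer_energy: np.ndarray = None
    gamma: dict = field(default_factory=dict)
    methyl_delta: dict = field(default_factory=dict)
    monomer_weight: float = 1.0
    gamma_methylated: dict | None = None
    energy_floor: float = -10.0

    def __post_init__(self):
        L = len(self.half_site)
        if self.monomer_energy is None:
            self.monomer_energy = np.zeros((L, 4))
        self.monomer_energy = np.asarray(self.monomer_energy, dtype=float)
        if self.monomer_energy.shape != (L, 4):
            raise ValueError("monomer_energy must be (half-site length, 4)")
        for gm in (self.gamma, self.gamma_methylated or {}):
            for (orient, s), g in gm.items():
                if orient not in ORIENTATIONS or s < 0:
                    raise ValueError(f"bad gamma key {(orient, s)}")
                if not np.isfinite(g) or g < 0:
                    raise ValueError(f"gamma{(orient, s)} must be finite and >= 0")
        for p in self.methyl_delta:
            if not -1 <= p <= L:
                raise ValueError(f"methyl_delta key {p} outside half-site + flanks")

    @property
    def max_spacing(self) -> int:
        keys = list(self.gamma) + list(self.gamma_methylated or {})
        return max((s for _, s in keys), default=0)

    def gamma_map(self, methylated: bool) -> dict:
        if methylated and self.gamma_methylated is not None:
            return self.gamma_methylated
        return self.gamma

    def to_json(self, path=None) -> str:
        d = {
            "half_site": self.half_site,
            "monomer_energy": self.monomer_energy.tolist(),
            "gamma": {f"{o}{s}": g for (o, s), g in self.gamma.items()},
            "gamma_methylated": None
            if self.gamma_methylated is None
            else {f"{o}{s}": g for (o, s), g in self.gamma_methylated.items()},
            "methyl_delta": {str(k): v for k, v in self.methyl_delta.items()},
            "monomer_weight": self.monomer_weight,
            "energy_floor": self.energy_floor,
        }
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "BindingModel":
        from .dimers import parse_name

        d = json.loads(text)
        return cls(
            half_site=d["half_site"],
            monomer_energy=np.array(d["monomer_energy"]),
            gamma={parse_name(k): v for k, v in d["gamma"].items()},
            gamma_methylated=None
            if d.get("gamma_methylated") is None
            else {parse_name(k): v for k, v in d["gamma_methylated"].items()},
            methyl_delta={int(k): v for k, v in d["methyl_delta"].items()},
            monomer_weight=d["monomer_weight"],
            energy_floor=d.get("energy_floor", -10.0),
        )


@dataclass
class SimConfig:
    """SELEX simulation settings (defaults emulate the 40N library design)."""

    random_len: int = 40
    library_size: int = 10_000
    cycles: int = 5
    selection_fraction: float = 0.35
    seed: int = 0
    flank5: str = "CGGATCCG"
    flank3: str = "CGGATCCG"
    methylated: bool = False
    label: str = ""
    plant: str | None = None
    plant_frac: float = 0.0

    def __post_init__(self):
        if not 0 < self.selection_fraction < 1:
            raise ValueError("selection_fraction must be in (0, 1)")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.random_len < 1 or self.library_size < 1:
            raise ValueError("random_len and library_size must be positive")
        if self.plant is not None and len(self.plant) > self.random_len:
            raise ValueError("planted sequence longer than the random region")
        if not 0 <= self.plant_frac <= 1:
            raise ValueError("plant_frac must be in [0, 1]")


def default_binding_model() -> BindingModel:
    """The package's reference ground truth.

    Mismatch penalties are soft enough that one-mismatch dimer arrangements
    carry the configurational signal at desk-scale library sizes, yet the
    cooperativity gap between the peak configuration and every other one
    exceeds e^penalty, so a chance exact-consensus arrangement of a
    non-peak configuration cannot outweigh the peak's one-mismatch carriers.
    Cooperativity peaks at ER1 without methylation and at ER0 with it; the
    negative in-site deltas at the two Y positions weaken every
    cytosine-containing site when methylated, which represses the monomeric
    path (C stays the preferred base, with a reduced margin over T).
    """
    # rows = half-site positions of YAATYA, columns = A, C, G, T
    e = np.array(
        [
            [-1.5, 0.0, -1.5, -0.8],  # Y: C preferred, T tolerated
            [0.0, -1.5, -1.5, -1.5],  # A
            [0.0, -1.5, -1.5, -1.5],  # A
            [-1.5, -1.5, -1.5, 0.0],  # T
            [-1.5, 0.0, -1.5, -0.8],  # Y
            [0.0, -1.5, -1.5, -1.5],  # A
        ]
    )
    gamma = {(o, s): 0.05 for o in ORIENTATIONS for s in range(11)}
    gamma.update({("ER", 1): 150.0, ("ER", 0): 25.0,
                  ("DR", 3): 10.0, ("DR", 4): 8.0, ("DR", 5): 6.0,
                  ("IR", 6): 6.0, ("IR", 7): 5.0, ("IR", 8): 4.0})
    gamma_me = {(o, s): 0.05 for o in ORIENTATIONS for s in range(11)}
    gamma_me.update({("ER", 0): 150.0, ("ER", 1): 25.0,
                     ("DR", 3): 8.0, ("DR", 4): 6.0, ("DR", 5): 5.0,
                     ("IR", 6): 5.0, ("IR", 7): 4.0, ("IR", 8): 3.0})
    return BindingModel(
        half_site="YAATYA",
        monomer_energy=e,
        gamma=gamma,
        gamma_methylated=gamma_me,
        methyl_delta={0: -0.3, 4: -0.3},
        monomer_weight=2.0,
    )


# ---------------------------------------------------------------------------
# Affinity

def _window_energies(model: BindingModel, codes: np.ndarray, methylated: bool):
    """Per-window energies on both strands for full-read code matrix.

    Returns (Eplus, Eminus), each (n, n_windows); window i spans read
    positions i..i+L-1. Strand '-' reads the window as a reverse-complement
    half-site occurrence (position p of the half-site frame maps to read
    position i+L-1-p with complemented base). The C/G condition of methyl
    deltas is complement-closed, so both strands test the plus-strand base.
    """
    n, Lr = codes.shape
    L = len(model.half_site)
    if Lr < L:
        raise ValueError("read shorter than half-site")
    me = model.monomer_energy
    me5 = np.concatenate([me, np.full((L, 1), -1e9)], axis=1)  # unknown base kills
    me5_rc = me5[::-1, [3, 2, 1, 0, 4]]  # rc[p, b] = me[L-1-p, 3-b]
    W = Lr - L + 1
    Ep = np.zeros((n, W))
    Em = np.zeros((n, W))
    for p in range(L):
        Ep += me5[p, codes[:, p : p + W]]
        Em += me5_rc[p, codes[:, p : p + W]]
    if methylated and model.methyl_delta:
        is_cg = (codes == 1) | (codes == 2)
        for p, d in model.methyl_delta.items():
            if d == 0:
                continue
            if 0 <= p < L:
                # in-site: plus-strand frame position p; minus-strand frame
                # position p sits at read position i + L-1-p
                Ep += d * is_cg[:, p : p + W]
                Em += d * is_cg[:, L - 1 - p : L - 1 - p + W]
            else:
                # flanking positions: frame -1 maps to read offset -1 on the
                # plus strand and offset L on the minus strand (and vice
                # versa for frame L); out-of-read flanks contribute nothing
                for E, off in ((Ep, -1 if p == -1 else L),
                               (Em, L if p == -1 else -1)):
                    idx = np.arange(W) + off
                    valid = (idx >= 0) & (idx < Lr)
                    E[:, valid] += d * is_cg[:, idx[valid]]
    return Ep, Em


def _pair_term(model: BindingModel, wp: np.ndarray, wm: np.ndarray, methylated: bool):
    """Sum of gamma * exp(E1 + E2) over ordered window pairs."""
    gmap = model.gamma_map(methylated)
    L = len(model.half_site)
    n, W = wp.shape
    out = np.zeros(n)
    strand_w = {"+": wp, "-": wm}
    for (s1, s2), orient in _STRAND_ORIENT.items():
        w1, w2 = strand_w[s1], strand_w[s2]
        for s in range(model.max_spacing + 1):
            g = gmap.get((orient, s), 0.0)
            if g == 0.0:
                continue
            off = L + s
            if off >= W:
                continue
            out += g * np.einsum("ij,ij->i", w1[:, : W - off], w2[:, off:])
    return out


def affinities(model: BindingModel, codes: np.ndarray, methylated: bool) -> np.ndarray:
    """Vectorized ligand affinities for an (n, read_length) code matrix."""
    Ep, Em = _window_energies(model, codes, methylated)
    wp = np.where(Ep >= model.energy_floor, np.exp(np.minimum(Ep, 50.0)), 0.0)
    wm = np.where(Em >= model.energy_floor, np.exp(np.minimum(Em, 50.0)), 0.0)
    mono = model.monomer_weight * (wp.sum(axis=1) + wm.sum(axis=1))
    dimer = _pair_term(model, wp, wm, methylated)
    return mono + dimer + 1e-9


def ligand_affinity(model: BindingModel, read: str, methylated: bool = False) -> float:
    """Occupancy-proportional weight of one read (monomer + dimer paths)."""
    codes = encode_matrix([read.upper()])
    return float(affinities(model, codes, methylated)[0])


# ---------------------------------------------------------------------------
# Selection cycles

def run_selex_cycle(
    library: LigandLibrary,
    model: BindingModel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> LigandLibrary:
    """One selection + amplification cycle.

    Draws round(selection_fraction * N) reads multinomially with probability
    proportional to affinity, then resamples with replacement back to the
    library size (PCR). The cycle index increments and the methylated flag
    propagates.
    """
    if len(library) == 0:
        raise ValueError("empty library")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    codes = library.read_codes()
    uniq, inverse, counts = np.unique(
        codes, axis=0, return_inverse=True, return_counts=True
    )
    w = affinities(model, uniq, library.methylated)
    if np.all(w <= 2e-9):
        raise ValueError("no binders: all ligand weights at the floor")
    mass = w * counts
    n_sel = max(1, round(cfg.selection_fraction * len(library)))
    sel = rng.multinomial(n_sel, mass / mass.sum())
    pcr = rng.multinomial(cfg.library_size, sel / n_sel)
    reads = []
    uniq_reads = ["".join(BASES[c] for c in row) for row in uniq]
    for read, count in zip(uniq_reads, pcr):
        reads.extend([read] * int(count))
    return library.replace_reads(reads, cycle=library.cycle + 1)


def initial_library(cfg: SimConfig, rng: np.random.Generator) -> LigandLibrary:
    """Cycle-0 library: i.i.d. uniform ACGT random regions with fixed flanks.

    With ``cfg.plant`` set, round(plant_frac * library_size) reads carry the
    planted sequence at a random offset inside the random region (overwriting
    the uniform background there).
    """
    region = rng.integers(0, 4, size=(cfg.library_size, cfg.random_len))
    regions = ["".join(BASES[c] for c in row) for row in region]
    if cfg.plant and cfg.plant_frac > 0:
        n_plant = round(cfg.plant_frac * cfg.library_size)
        span = cfg.random_len - len(cfg.plant) + 1
        which = rng.choice(cfg.library_size, size=n_plant, replace=False)
        offs = rng.integers(0, span, size=n_plant)
        for i, off in zip(which, offs):
            r = regions[i]
            regions[i] = r[:off] + cfg.plant + r[off + len(cfg.plant):]
    reads = [cfg.flank5 + r + cfg.flank3 for r in regions]
    return LigandLibrary(
        reads=reads,
        cycle=0,
        methylated=cfg.methylated,
        random_region=(len(cfg.flank5), cfg.random_len),
        label=cfg.label or ("methyl" if cfg.methylated else "normal"),
    )


def simulate_selex(cfg: SimConfig, model: BindingModel) -> list[LigandLibrary]:
    """Simulate cycles 0..cfg.cycles; returns cycles + 1 libraries."""
    rng = np.random.default_rng(cfg.seed)
    libs = [initial_library(cfg, rng)]
    for _ in range(cfg.cycles):
        libs.append(run_selex_cycle(libs[-1], model, cfg, rng))
    return libs


# ---------------------------------------------------------------------------
# Toy genome / annotation / peaks

def _random_seq(rng: np.random.Generator, n: int, exclude=None, max_tries: int = 200) -> str:
    """Random ACGT sequence; with ``exclude`` set, rejection-sampled until the
    predicate is False (used to make genuinely signal-free stretches)."""
    for _ in range(max_tries):
        seq = "".join(BASES[c] for c in rng.integers(0, 4, size=n))
        if exclude is None or not exclude(seq):
            return seq
    raise RuntimeError("could not draw a sequence passing the exclusion filter")


def simulate_genome(
    n_genes: int = 20,
    intergenic: int = 2500,
    plant: str | None = None,
    plant_offset: int = -50,
    seed: int = 0,
    exclude=None,
    minus_strand_every: int = 2,
):
    """A toy single-chromosome genome with evenly spaced genes.

    Genes alternate strands (every ``minus_strand_every``-th gene is on -).
    With ``plant``, the sequence is inserted so its gene-oriented 5'-most
    base sits at ``plant_offset`` relative to each TSS; ``exclude`` is an
    optional predicate used to rejection-sample the background so it stays
    free of spurious sites. Returns a GenomeAnnotation.
    """
    from .io import GenomeAnnotation

    rng = np.random.default_rng(seed)
    w = len(plant) if plant else 0
    chrom_parts: list[str] = []
    tss_list = []
    pos = 0
    for g in range(n_genes):
        chrom_parts.append(_random_seq(rng, intergenic, exclude))
        pos += intergenic
        strand = "-" if (minus_strand_every and g % minus_strand_every == 1) else "+"
        tss = pos
        if plant:
            block = list(_random_seq(rng, 2 * abs(plant_offset) + 2 * w + 20, exclude))
            # genomic start so that the oriented 5'-most base is at plant_offset
            if strand == "+":
                gstart = abs(plant_offset) + plant_offset  # tss-relative
                ins = plant
            else:
                gstart = abs(plant_offset) - plant_offset - (w - 1)
                ins = revcomp(plant)
            tss_rel = abs(plant_offset)
            block[gstart : gstart + w] = list(ins)
            chrom_parts.append("".join(block))
            tss = pos + tss_rel
            pos += len(block)
        else:
            body = _random_seq(rng, 600, exclude)
            chrom_parts.append(body)
            tss = pos if strand == "+" else pos + len(body) - 1
            pos += len(body)
        tss_list.append(("chr1", tss, strand, f"gene{g + 1:03d}"))
    chrom_parts.append(_random_seq(rng, intergenic, exclude))
    return GenomeAnnotation(sequences={"chr1": "".join(chrom_parts)}, tss=tss_list)


def simulate_peaks(
    genome,
    n_peaks: int,
    motif: str | None = None,
    frac_with_motif: float = 0.6,
    width: int = 120,
    seed: int = 0,
    exclude=None,
    chrom: str = "chr1",
    intensity_by_motif: tuple[float, float] | None = None,
):
    """Toy peak calls on a (writable) toy genome.

    The first round(frac_with_motif * n_peaks) peaks in rank order carry the
    ``motif`` sequence at their center (the chromosome is edited in place).
    With an ``exclude`` predicate, every peak's sequence is first replaced by
    a rejection-sampled background passing the predicate, so motif-free
    peaks are genuinely signal-free. Intensities decrease with rank (plus
    noise) unless ``intensity_by_motif`` gives (mean_with, mean_without).
    Returns (PeakSet, edited GenomeAnnotation).
    """
    from .io import GenomeAnnotation, PeakSet

    rng = np.random.default_rng(seed)
    seq = list(str(genome.sequences[chrom]))
    clen = len(seq)
    gap = clen // (n_peaks + 1)
    if gap <= width:
        raise ValueError("chromosome too short for that many peaks")
    n_with = round(frac_with_motif * n_peaks) if motif else 0
    starts, ends, intens = [], [], []
    order = rng.permutation(n_peaks)  # motif peaks scattered along the chrom
    for rank, slot in enumerate(order):
        s = gap * (int(slot) + 1) - width // 2
        e = s + width
        if exclude is not None:
            seq[s:e] = list(_random_seq(rng, width, exclude))
        if motif and rank < n_with:
            mid = s + (width - len(motif)) // 2
            seq[mid : mid + len(motif)] = list(motif)
        starts.append(s)
        ends.append(e)
        if intensity_by_motif is not None:
            mean = intensity_by_motif[0] if (motif and rank < n_with) else intensity_by_motif[1]
            intens.append(max(0.1, rng.normal(mean, 1.0)))
        else:
            intens.append(float(n_peaks - rank) + float(rng.uniform(0, 0.5)))
    edited = GenomeAnnotation(
        sequences={**{c: genome.sequences[c] for c in genome.sequences}, chrom: "".join(seq)},
        tss=genome.tss,
    )
    peaks = PeakSet(
        chroms=np.array([chrom] * n_peaks, dtype=object),
        starts=np.array(starts),
        ends=np.array(ends),
        intensity=np.array(intens),
    )
    return peaks, edited
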