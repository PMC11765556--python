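"""End-to-end orchestration: simulate (or load) SELEX series, run the k-mer,
E-MI, motif, dimer and enrichment stages, and emit a machine-readable
summary naming the top-enriched dimeric configuration per library."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dimers, kmers, motifs
from .io import LigandLibrary, read_sequences, write_motif_meme, write_sequences
from .simulate import BindingModel, SimConfig, default_binding_model, simulate_selex

logger = logging.getLogger(__name__)

REQUIRED_KEYS = ("out_dir", "seed")


def rank_dimer_configs(
    final: LigandLibrary,
    background: LigandLibrary | None = None,
    half_site: str = dimers.DEFAULT_HALF_SITE,
    max_spacing: int = 10,
    max_mismatch: int = 1,
    multinomial_level: int = 2,
    shuffle_seed: int = 0,
    compute_ic: bool = False,
) -> pd.DataFrame:
    """Rank dimeric configurations of a library.

    Each orientation x spacing configuration is detected by its IUPAC seed
    with at most ``max_mismatch`` mismatches, on both strands. The detector
    tolerance is uniform across configurations — every seed has the same
    twelve informative positions — so it is independent of the selected pool
    and a collapsed library cannot leak one configuration's reads into
    another's model. Configurations are ranked by ``hits`` (tolerant match
    count in the final library); ``enrichment`` reports the ratio of hits to
    hits in a shuffled copy of the library (+1) for reference. With
    ``compute_ic`` a PWM is additionally trained per seed (cycle-0
    ``background`` correction) and its mean information content reported
    (NaN when the seed has no counting windows).
    """
    shuffled = motifs.shuffle_library(final, seed=shuffle_seed)
    rows = []
    for name, seed in dimers.enumerate_dimer_seeds(half_site, max_spacing=max_spacing):
        # count on full reads: binding sites may straddle the random-region /
        # flank junction, and selection sees the whole ligand
        n_lib = motifs.count_seed_matches(final.reads, seed, max_mismatch)
        n_shuf = motifs.count_seed_matches(shuffled.reads, seed, max_mismatch)
        mean_ic = np.nan
        if compute_ic:
            try:
                trained = motifs.build_pwm_from_seed(
                    final, seed, background=background,
                    multinomial_level=multinomial_level, name=name,
                )
                mean_ic = trained.mean_ic
            except ValueError:
                pass
        rows.append(
            {"name": name, "seed": seed, "width": len(seed),
             "hits": n_lib, "hits_shuffled": n_shuf,
             "enrichment": n_lib / (n_shuf + 1.0), "mean_ic": mean_ic}
        )
    df = pd.DataFrame(rows).sort_values(
        ["hits", "name"], ascending=[False, True]
    ).reset_index(drop=True)
    return df


def top_dimer_config(final, background, **kwargs) -> str:
    """Name of the top-enriched dimeric configuration of a library."""
    return str(rank_dimer_configs(final, background, **kwargs).iloc[0]["name"])


def _load_series(block: dict) -> list[LigandLibrary]:
    libs = []
    region = tuple(block["random_region"]) if "random_region" in block else None
    for cycle, path in enumerate(block["files"]):
        libs.append(
            read_sequences(
                path,
                format=block.get("format", "fasta"),
                random_region=region,
                methylated=bool(block.get("methylated", False)),
                cycle=cycle,
            )
        )
    return libs


def _simulate_series(config: dict, methylated: bool, model: BindingModel):
    sim = config.get("simulate", {})
    cfg = SimConfig(
        random_len=int(sim.get("random_len", 40)),
        library_size=int(sim.get("library_size", 10_000)),
        cycles=int(sim.get("cycles", 5)),
        selection_fraction=float(sim.get("selection_fraction", 0.25)),
        seed=int(config["seed"]) + (1 if methylated else 0),
        methylated=methylated,
        label="methyl" if methylated else "normal",
    )
    return simulate_selex(cfg, model)


def run_pipeline(config: dict) -> dict:
    """Run the full SELEX analysis described by a flat config mapping.

    The config either names per-cycle input files (``normal:``/``methyl:``
    blocks with a ``files`` list) or requests simulation (``simulate:``
    block; a missing block simulates with defaults). Deterministic given
    config + seed. Writes k-mer tables, E-MI matrices, MEME motifs, the
    dimer ranking and a summary.json under ``out_dir`` and returns the
    summary mapping.
    """
    for key in REQUIRED_KEYS:
        if key not in config:
            raise ValueError(f"missing mandatory config key {key!r}")
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    if "model" in config:
        model = BindingModel.from_json(Path(config["model"]).read_text())
    else:
        model = default_binding_model()

    series: dict[str, list[LigandLibrary]] = {}
    for label, methylated in (("normal", False), ("methyl", True)):
        if label in config and "files" in config[label]:
            libs = _load_series({**config[label], "methylated": methylated})
        else:
            libs = _simulate_series(config, methylated, model)
            if config.get("write_fasta", False):
                for lib in libs:
                    write_sequences(lib, out / f"{label}_cycle{lib.cycle}.fasta")
                model.to_json(out / "ground_truth.json")
        if len(libs) < 2:
            raise ValueError("need >= 2 cycles for enrichment")
        series[label] = libs

    summary: dict = {"seed": seed, "libraries": {}}
    k_traj = int(config.get("k_trajectory", 10))
    top_n = int(config.get("top_n_kmers", 100))
    max_spacing = int(config.get("max_spacing", 10))
    half_site = str(config.get("half_site", dimers.DEFAULT_HALF_SITE))

    tables_by_label = {}
    for label, libs in series.items():
        tables = [kmers.count_kmers(lib, k_traj) for lib in libs]
        tables_by_label[label] = libs
        top_kmers = tables[-1].top(10)
        traj_rows = []
        for km in top_kmers:
            traj = kmers.enrichment_trajectory(tables, km)
            slope, intercept, r2 = kmers.fit_log_linear(traj, pseudo=0.5 / tables[0].total)
            traj_rows.append(
                {"kmer": km, "slope": slope, "r2": r2,
                 **{f"cycle{c}": traj[c] for c in range(len(traj))}}
            )
        pd.DataFrame(traj_rows).to_csv(out / f"{label}_kmer_trajectories.tsv",
                                       sep="\t", index=False)
        tables[-1].to_dataframe().head(1000).to_csv(
            out / f"{label}_kmers_final.tsv", sep="\t", index=False
        )
        emi_mat = kmers.emi(libs[-1])
        emi_df = emi_mat.to_dataframe()
        emi_df.to_csv(out / f"{label}_emi.tsv", sep="\t", index=False)

        ranking = rank_dimer_configs(
            libs[-1], libs[0], half_site=half_site, max_spacing=max_spacing,
            shuffle_seed=seed + 17, compute_ic=True,
        )
        ranking.to_csv(out / f"{label}_dimer_ranking.tsv", sep="\t", index=False)
        summary["libraries"][label] = {
            "methylated": libs[-1].methylated,
            "cycles": len(libs) - 1,
            "reads": len(libs[-1]),
            "top_dimer": str(ranking.iloc[0]["name"]),
            "top_dimer_enrichment": round(float(ranking.iloc[0]["enrichment"]), 4),
            "max_emi": round(float(np.nanmax(emi_mat.values)), 4),
        }

        # motif models (monomer + dimers) to MEME
        built = []
        for name, sd in [("M1", half_site)] + dimers.enumerate_dimer_seeds(
            half_site, max_spacing=max_spacing
        ):
            try:
                built.append(
                    motifs.build_pwm_from_seed(
                        libs[-1], sd, background=libs[0],
                        multinomial_level=2, name=f"{label}_{name}",
                    )
                )
            except ValueError:
                continue
        write_motif_meme(built, out / f"{label}_motifs.meme")

    # cross-library 8-mer / 12-mer comparison
    for k in (8, 12):
        tA = kmers.count_kmers(series["normal"][-1], k)
        tB = kmers.count_kmers(series["methyl"][-1], k)
        bA = kmers.count_kmers(series["normal"][0], k)
        bB = kmers.count_kmers(series["methyl"][0], k)
        df, comp = kmers.compare_libraries(tA, tB, bA, bB, top_n=top_n)
        df.to_csv(out / f"compare_{k}mers.tsv", sep="\t", index=False)
        summary[f"compare_{k}mers"] = comp

    # methyl-vs-normal positional comparison per top configuration
    methyl_cmp = {}
    for name in ("ER0", "ER1"):
        seed_str = dict(dimers.enumerate_dimer_seeds(half_site, max_spacing=max_spacing))[name]
        try:
            mn = motifs.build_pwm_from_seed(
                series["normal"][-1], seed_str, background=series["normal"][0],
                multinomial_level=2, name=name,
            )
            mm = motifs.build_pwm_from_seed(
                series["methyl"][-1], seed_str, background=series["methyl"][0],
                multinomial_level=2, name=name,
            )
        except ValueError:
            continue
        cmp_ = motifs.compare_methyl_pwms(mn, mm)
        cmp_.table.to_csv(out / f"methyl_comparison_{name}.tsv", sep="\t", index=False)
        methyl_cmp[name] = cmp_.calls()
    summary["methyl_calls"] = methyl_cmp

    summary["metadata"] = {
        "emi_definition": "top-10 most frequent 3-mer pairs, pointwise MI, pseudocount 1",
        "enrichment_reference": "cycle 0",
        "kmer_strand": "forward only",
        "half_site": half_site,
    }
    text = json.dumps(summary, indent=2, sort_keys=True)
    (out / "summary.json").write_text(text + "\n")
    return summary
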