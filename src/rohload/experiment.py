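"""Replicate harness tying simulator, ROH caller and load statistics together.

One replicate runs the (optionally rescaled) Soay demographic history under a
chosen DFE, calls ROH on the final-generation genotypes using the standard
detection parameters on cM = bp/1e6 coordinates, and computes the per-class
load statistics.  Across replicates the harness reports the percent contrasts
of medium and short ROH against long ROH that summarize how mutation load
decays with haplotype age.

Desk-scale choices: histories are rescaled by Q (default 10), but the sampled
generation is run at the study census of 200 individuals so that per-replicate
statistics average over the same number of individuals as the study design and
the segregating-site density is sufficient for the 25-SNP windowed caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .load import mutations_in_roh, per_individual_load, summarize_replicate
from .roh import GenotypeMatrix, ROHParams, call_roh, classify_segments
from .wfsim import (DemographyConfig, DFEConfig, GenomeConfig, SimResult,
                    rescale_config, run_simulation, soay_demography)

__all__ = ["headline_configs", "run_replicate", "run_experiment",
           "aggregate_contrasts", "spawn_seeds"]


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent sub-seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def headline_configs(Q: float = 10, mean_s: float = -0.03, shape: float = 0.2,
                     h: float = 0.05, sample_census: int | None = 200):
    """Configs for the headline scenario: Soay history, gamma DFE.

    ``sample_census`` keeps the final (sampled) generation at the study census
    even when the history is rescaled; pass ``None`` to sample the rescaled
    size instead.
    """
    demo, genome, dfe = rescale_config(
        soay_demography(), GenomeConfig(),
        DFEConfig(mean_s=mean_s, shape=shape, h=h), Q)
    if sample_census is not None:
        last = demo.phases[-1]
        assert last[0] == "const"
        demo.phases[-1] = ("const", int(sample_census), 1)
    return demo, genome, dfe


def sim_to_genotype_matrix(res: SimResult) -> GenotypeMatrix:
    """View a simulation sample as a genotype matrix on cM = bp/1e6 coordinates."""
    markers = pd.DataFrame({
        "marker_id": [f"m{i}" for i in res.mutation_table["id"]],
        "chromosome": "1",
        "bp": res.positions,
        "cm": res.positions / 1e6,
    })
    individuals = [f"ind{i}" for i in range(res.n_individuals)]
    return GenotypeMatrix(individuals=individuals, markers=markers,
                          calls=res.genotypes)


def run_replicate(seed: int, replicate: int = 0, Q: float = 10,
                  mean_s: float = -0.03, shape: float = 0.2, h: float = 0.05,
                  roh_params: ROHParams | None = None,
                  sample_census: int | None = 200) -> dict:
    """Simulate one replicate and compute its per-class load summary."""
    demo, genome, dfe = headline_configs(Q, mean_s, shape, h, sample_census)
    res = run_simulation(demo, dfe, genome, seed=seed)
    gm = sim_to_genotype_matrix(res)
    segments = classify_segments(call_roh(gm, roh_params))
    hits = mutations_in_roh(res.genotypes, gm.individuals, segments,
                            res.mutation_table)
    stats = per_individual_load(segments, hits, gm.individuals)
    summary = summarize_replicate(stats, replicate)
    return {"result": res, "segments": segments, "stats": stats,
            "summary": summary}


def run_experiment(n_replicates: int = 20, seed: int = 1, Q: float = 10,
                   mean_s: float = -0.03, shape: float = 0.2, h: float = 0.05,
                   verbose: bool = False) -> pd.DataFrame:
    """Run replicates of the headline scenario; returns stacked summaries."""
    seeds = spawn_seeds(seed, n_replicates)
    out = []
    for r, s in enumerate(seeds):
        rep = run_replicate(s, replicate=r, Q=Q, mean_s=mean_s, shape=shape, h=h)
        out.append(rep["summary"])
        if verbose:
            print(rep["summary"][["replicate", "length_class", "load_per_cm",
                                  "count_per_cm", "mean_allele_frequency"]])
    return pd.concat(out, ignore_index=True)


def aggregate_contrasts(summaries: pd.DataFrame) -> dict:
    """Across-replicate aggregate of the class patterns.

    Grand class means are means over replicates of the per-replicate class
    means; contrasts are ``100 * (1 - mean_class / mean_long)``.  Also reports
    the fraction of replicates in which |load per cM| orders
    long > medium > short, and the mean allele-frequency comparison between
    long and short ROH.
    """
    grand = summaries.groupby("length_class")[
        ["load_per_cm", "count_per_cm", "mean_allele_frequency"]].mean()
    res = {"grand_means": grand}
    for stat in ("load_per_cm", "count_per_cm"):
        base = grand.loc["long", stat]
        for cls in ("medium", "short"):
            res[f"{stat}_{cls}_vs_long_pct"] = float(
                100.0 * (1.0 - grand.loc[cls, stat] / base))
    wide = summaries.pivot(index="replicate", columns="length_class",
                           values="load_per_cm").abs()
    ordered = (wide["long"] > wide["medium"]) & (wide["medium"] > wide["short"])
    res["load_ordering_fraction"] = float(ordered.mean())
    res["freq_long_lt_short"] = bool(
        grand.loc["long", "mean_allele_frequency"]
        < grand.loc["short", "mean_allele_frequency"])
    res["n_replicates"] = int(summaries["replicate"].nunique())
    return res
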