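"""Replicated synthetic-cohort experiments.

These drive the package's headline questions on simulated data with known
ground truth:

* does the slow 16s-like marker predict AAI poorly among closely related
  genomes (AAI above the split threshold) while remaining among the best
  predictors for distant ones?
* do lineage-average conservation ranks predict how well each marker's tree
  reconstructs the AAI tree (less conserved -> more similar trees)?
* does the binned AAI confidence interval broaden as 16s identity rises?

Each replicate simulates a fresh cohort (seed derived from the base seed),
runs the full pipeline, and summarizes the replicate into one row.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import pipeline as pl
from .simulate import SLOW16S, SimulationConfig, generate_dataset
from .stats import spearman
from .errors import MarkerRankError


def run_one_cohort(
    seed: int,
    workdir: str | Path | None = None,
    sim_overrides: dict | None = None,
    pipe_overrides: dict | None = None,
) -> pl.PipelineResult:
    """Simulate one cohort and run the full pipeline on it."""
    sim_kwargs = {"seed": seed}
    sim_kwargs.update(sim_overrides or {})
    cfg = SimulationConfig(**sim_kwargs)
    if workdir is None:
        tmp = tempfile.TemporaryDirectory(prefix="markerrank_")
        workdir = tmp.name
        # keep the handle alive until the result is built
        _keep = tmp
    workdir = Path(workdir)
    data_dir = workdir / "cohort"
    out_dir = workdir / "out"
    generate_dataset(cfg, data_dir)
    pipe_kwargs = dict(
        input_dir=str(data_dir), out_dir=str(out_dir),
        min_homologs=100, seed=seed,
    )
    pipe_kwargs.update(pipe_overrides or {})
    pcfg = pl.PipelineConfig(**pipe_kwargs)
    return pl.run_all(pcfg)


def summarize_replicate(res: pl.PipelineResult, gene_16s: str = SLOW16S) -> dict:
    """One row of headline statistics for a completed pipeline run."""
    corr = res.correlations
    close = corr[(corr["side"] == "close") & corr["rho"].notna()].set_index("gene_label")
    far = corr[(corr["side"] == "far") & corr["rho"].notna()].set_index("gene_label")
    out: dict[str, float] = {}

    others_close = close.drop(index=gene_16s, errors="ignore")
    if gene_16s in close.index and len(others_close):
        r16 = close.loc[gene_16s, "rho"]
        out["frac_markers_beating_16s_close"] = float(
            (others_close["rho"] > r16).mean()
        )
    else:
        # a close-side correlation too degenerate to compute is itself the
        # "16s is uninformative among close relatives" outcome
        out["frac_markers_beating_16s_close"] = 1.0 if len(others_close) else np.nan

    n_markers = len(res.marker_genes)
    if gene_16s in far.index:
        rank16 = 1 + int((far.drop(index=gene_16s)["rho"] > far.loc[gene_16s, "rho"]).sum())
        out["far_rank_16s"] = float(rank16)
        out["far_rank_16s_top_quartile"] = float(rank16 <= math.ceil(n_markers / 4))
    else:
        out["far_rank_16s"] = np.nan
        out["far_rank_16s_top_quartile"] = np.nan

    comb = res.rank_vs_split[res.rank_vs_split["lineage"] == "combined"]
    if len(comb) and np.isfinite(comb["rho"].iloc[0]):
        out["rank_split_rho"] = float(comb["rho"].iloc[0])
        out["rank_split_p"] = float(comb["p"].iloc[0])
    else:
        out["rank_split_rho"] = np.nan
        out["rank_split_p"] = np.nan

    # overall 16s-vs-AAI correlation over all retained pairs
    sub = res.joined[[gene_16s, "aai"]].dropna()
    try:
        out["rho_16s_aai_all"] = spearman(sub[gene_16s], sub["aai"]).rho
    except MarkerRankError:
        out["rho_16s_aai_all"] = np.nan

    # CI broadening: width in the top non-empty bin vs the bottom one
    binned = res.binned[res.binned["flag"] != "empty-bin"]
    binned = binned[np.isfinite(binned["ci_low"])]
    if len(binned) >= 2:
        first, last = binned.iloc[0], binned.iloc[-1]
        out["ci_width_low_bin"] = float(first["ci_high"] - first["ci_low"])
        out["ci_width_high_bin"] = float(last["ci_high"] - last["ci_low"])
    else:
        out["ci_width_low_bin"] = out["ci_width_high_bin"] = np.nan

    out["n_close"] = float((res.joined["aai"] > 95).sum())
    out["n_far"] = float((res.joined["aai"] < 95).sum())
    return out


def headline_replicates(
    base_seed: int,
    n_replicates: int = 20,
    sim_overrides: dict | None = None,
    pipe_overrides: dict | None = None,
) -> pd.DataFrame:
    """Run ``n_replicates`` simulated cohorts and summarize each.

    Replicate seeds are derived deterministically from ``base_seed`` and kept
    below 2**31.
    """
    rows = []
    for i in range(n_replicates):
        seed = (int(base_seed) * 1_000_003 + i) % (2**31 - 1)
        with tempfile.TemporaryDirectory(prefix="markerrank_rep_") as tmp:
            res = run_one_cohort(seed, workdir=tmp, sim_overrides=sim_overrides,
                                 pipe_overrides=pipe_overrides)
            row = summarize_replicate(res)
        row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)


def rate_rank_recovery(
    base_seed: int,
    n_seeds: int = 20,
    n_genomes: int = 6,
    n_markers: int = 8,
    multiplier_range: tuple[float, float] = (0.2, 3.0),
) -> list[float]:
    """Spearman rho between true rate multipliers and lineage-average
    conservation ranks, one value per seed.

    Faster genes should receive higher (less conserved) ranks, so recovery
    of the generative rate ordering means rho close to +1.
    """
    from . import markers as mk
    from .io import load_cohort

    lo, hi = multiplier_range
    mults = {SLOW16S: lo}
    for i, m in enumerate(
        np.exp(np.linspace(np.log(lo), np.log(hi), n_markers))[1:], start=1
    ):
        mults[f"m{i:02d}"] = float(m)
    rhos: list[float] = []
    for i in range(n_seeds):
        seed = (int(base_seed) * 7_000_003 + i) % (2**31 - 1)
        cfg = SimulationConfig(
            n_genomes=n_genomes, n_markers=n_markers, n_background_genes=1,
            marker_length_nt=900, slow16s_length_nt=1200, protein_length_aa=60,
            tree_depth=0.3, n_lineages=1, lineage_sizes=None,
            presence_prob=1.0, rate_jitter_sigma=0.0, seed=seed,
            rate_multipliers={**mults, "p001": 1.0},
        )
        with tempfile.TemporaryDirectory(prefix="markerrank_rr_") as tmp:
            gt = generate_dataset(cfg, tmp)
            genomes = load_cohort(tmp)
            identity = mk.build_identity_table(genomes, cfg.marker_labels)
            ranks = mk.build_rank_table(
                identity, {g: "lin1" for g in gt.lineages}
            )
        mean_ranks = [ranks.lineage_average[("lin1", g)] for g in cfg.marker_labels]
        true = [mults[g] for g in cfg.marker_labels]
        rhos.append(spearman(true, mean_ranks).rho)
    return rhos
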