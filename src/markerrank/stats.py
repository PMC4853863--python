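"""Spearman correlations, the AAI-threshold split analysis and binned,
genome-disjoint resampling confidence intervals.

The split analysis computes, for every marker gene, the Spearman correlation
between that gene's percent identity and AAI separately for distantly related
pairs (AAI below the threshold, default 95%) and closely related pairs (AAI
above it) — the basis for asking which markers best predict genome-wide
similarity among close relatives.

The binned confidence intervals resample genome pairs within 2%-wide bins of
16s-like identity such that no genome is used twice inside one sampling
(guarding against single outlier genomes dominating a bin), compute the mean
AAI per sampling, and report the 2.5th/97.5th percentile interval across
sampling means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidInputError, UndefinedCorrelationError


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the t-distribution p-value.

    Raises :class:`UndefinedCorrelationError` when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("inputs must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant input vector")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(rho):
        raise UndefinedCorrelationError("correlation undefined for these inputs")
    return CorrelationResult(rho=rho, p_value=p, n=int(x.size))


def split_correlations(
    joined: pd.DataFrame,
    genes: list[str],
    threshold: float = 95.0,
    aai_col: str = "aai",
) -> pd.DataFrame:
    """Per-gene Spearman(identity, AAI) on each side of the AAI threshold.

    ``joined`` has one row per genome pair with an ``aai`` column and one
    identity column per gene (NaN where the gene is absent).  Sides with
    fewer than 3 pairs, or with constant values, are reported with NaN rho
    and a reason flag.  Output rows are ordered by decreasing close-side rho.
    """
    if not (0 < threshold < 100):
        raise InvalidInputError("threshold must be in (0, 100)")
    aai = joined[aai_col].to_numpy(dtype=float)
    masks = {"far": aai < threshold, "close": aai > threshold}
    rows = []
    for gene in genes:
        ident = joined[gene].to_numpy(dtype=float)
        for side, side_mask in masks.items():
            mask = side_mask & ~np.isnan(ident)
            flag = ""
            rho = p = np.nan
            n = int(mask.sum())
            if n < 3:
                flag = "insufficient-data"
            else:
                try:
                    res = spearman(ident[mask], aai[mask])
                    rho, p = res.rho, res.p_value
                except UndefinedCorrelationError:
                    flag = "undefined-correlation"
            rows.append((gene, side, rho, p, n, flag))
    out = pd.DataFrame(rows, columns=["gene_label", "side", "rho", "p", "n", "flag"])
    close_order = (
        out[out["side"] == "close"]
        .sort_values("rho", ascending=False, kind="mergesort")["gene_label"]
        .tolist()
    )
    order = {g: i for i, g in enumerate(close_order)}
    out["__o"] = out["gene_label"].map(order)
    out = out.sort_values(["__o", "side"], kind="mergesort").drop(columns="__o")
    return out.reset_index(drop=True)


@dataclass
class BinnedCI:
    bin_low: float
    bin_high: float
    ci_low: float
    ci_high: float
    n_samplings: int
    sample_size: int      # requested
    achieved_size: int    # smallest genome-disjoint sample actually drawn
    n_pairs_in_bin: int
    flag: str = ""        # "" | "short-sample" | "empty-bin"


def _disjoint_sample(
    pairs: list[tuple[str, str, float]],
    sample_size: int,
    rng: np.random.Generator,
) -> list[float]:
    """Greedy genome-disjoint draw: shuffle, accept pairs introducing no
    already-used genome, stop at sample_size."""
    order = rng.permutation(len(pairs))
    used: set[str] = set()
    vals: list[float] = []
    for idx in order:
        a, b, v = pairs[idx]
        if a in used or b in used:
            continue
        used.add(a)
        used.add(b)
        vals.append(v)
        if len(vals) >= sample_size:
            break
    return vals


def binned_ci(
    records: pd.DataFrame,
    bin_width: float = 2.0,
    n_samplings: int = 20,
    sample_size: int = 100,
    seed: int = 0,
    identity_col: str = "identity_16s",
    aai_col: str = "aai",
    lo: float | None = None,
    hi: float = 100.0,
) -> list[BinnedCI]:
    """95% CI of mean AAI per 2%-wide bin of 16s-like identity.

    Bins are half-open [low, high) except the last, which includes ``hi``.
    Per bin: ``n_samplings`` genome-disjoint samplings of up to
    ``sample_size`` pairs; per sampling the mean AAI; the CI is the
    2.5th/97.5th percentile across sampling means.  Bins that cannot supply
    ``sample_size`` disjoint pairs are flagged with the achieved size.
    """
    if bin_width <= 0:
        raise InvalidInputError("bin_width must be positive")
    ident = records[identity_col].to_numpy(dtype=float)
    if lo is None:
        lo = bin_width * np.floor(ident.min() / bin_width)
    edges = np.arange(lo, hi + bin_width, bin_width)
    rng = np.random.default_rng(seed)
    out: list[BinnedCI] = []
    for k in range(len(edges) - 1):
        blo, bhi = float(edges[k]), float(edges[k + 1])
        last = k == len(edges) - 2
        mask = (ident >= blo) & ((ident <= bhi) if last else (ident < bhi))
        sub = records[mask]
        if sub.empty:
            out.append(
                BinnedCI(blo, bhi, np.nan, np.nan, n_samplings, sample_size, 0, 0,
                         flag="empty-bin")
            )
            continue
        pairs = list(
            zip(sub["genome_a"], sub["genome_b"], sub[aai_col].astype(float))
        )
        means = []
        achieved = sample_size
        for _ in range(n_samplings):
            vals = _disjoint_sample(pairs, sample_size, rng)
            achieved = min(achieved, len(vals))
            means.append(float(np.mean(vals)))
        ci_low, ci_high = np.percentile(means, [2.5, 97.5])
        out.append(
            BinnedCI(
                blo, bhi, float(ci_low), float(ci_high), n_samplings, sample_size,
                achieved, len(pairs),
                flag="" if achieved >= sample_size else "short-sample",
            )
        )
    return out


def binned_ci_frame(cis: list[BinnedCI]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.bin_low, c.bin_high, c.ci_low, c.ci_high, c.n_samplings,
             c.sample_size, c.achieved_size, c.n_pairs_in_bin, c.flag)
            for c in cis
        ],
        columns=[
            "bin_low", "bin_high", "ci_low", "ci_high", "n_samplings",
            "sample_size", "achieved_size", "n_pairs_in_bin", "flag",
        ],
    )
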