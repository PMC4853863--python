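"""Marker extraction, per-pair identity tables and conservation ranking.

The conservation rank of a marker within a genome pair orders the M markers
by percent identity: the most similar (most conserved) gene gets rank 1, the
least similar gets rank M, ties share fractional (mean) ranks so every rank
row sums to M(M+1)/2.  Lineage-average ranks are unweighted means over all
within-lineage genome pairs that carry the complete marker set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .alignment import NUCLEOTIDE_SCHEME, ScoringScheme, percent_identity_pairmax
from .errors import IncompletePairError, InsufficientDataError, InvalidInputError
from .io import GenomeRecord

LEN_16S_MIN = 1000
LEN_16S_MAX = 1800


def extract_16s_like(
    genome: GenomeRecord,
    gene_label: str = "slow16s",
    min_len: int = LEN_16S_MIN,
    max_len: int = LEN_16S_MAX,
) -> list[str]:
    """All annotated 16s-like copies of legitimate length (inclusive bounds).

    An empty return flags the genome as excluded from 16s-based analyses.
    """
    if min_len > max_len:
        raise InvalidInputError("min_len must be <= max_len")
    copies = genome.markers.get(gene_label, [])
    return [c for c in copies if min_len <= len(c) <= max_len]


@dataclass
class MarkerIdentityTable:
    """(genome pair x marker gene) percent identities; NaN marks absence.

    ``table`` is indexed by canonical (a, b) pairs with a < b.
    """

    genes: list[str]
    table: pd.DataFrame

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.table.index)

    def row(self, a: str, b: str) -> pd.Series:
        key = (a, b) if a < b else (b, a)
        # index holds tuples, so avoid the (row, col) reading of .loc[tuple]
        return self.table.loc[[key]].iloc[0]

    def to_long(self) -> pd.DataFrame:
        rows = []
        for (a, b), vals in self.table.iterrows():
            for gene in self.genes:
                v = vals[gene]
                if not np.isnan(v):
                    rows.append((a, b, gene, v))
        return pd.DataFrame(rows, columns=["genome_a", "genome_b", "gene_label", "identity"])

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "MarkerIdentityTable":
        genes = sorted(df["gene_label"].unique())
        wide = df.pivot_table(
            index=["genome_a", "genome_b"], columns="gene_label", values="identity"
        )
        wide = wide.reindex(columns=genes)
        wide.index = [tuple(x) for x in wide.index]
        return cls(genes=genes, table=wide)


def build_identity_table(
    genomes: list[GenomeRecord],
    genes: list[str],
    scheme: ScoringScheme = NUCLEOTIDE_SCHEME,
    length_filters: dict[str, tuple[int, int]] | None = None,
) -> MarkerIdentityTable:
    """Global-alignment percent identity for each unordered genome pair and
    each gene present in both genomes (max over copy pairs for multi-copy
    genes); NaN where either genome lacks the gene.

    ``length_filters`` optionally maps gene labels to (min_len, max_len)
    copy-length bounds (the 16s legitimate-length rule); copies outside the
    bounds are ignored.
    """
    if len(genomes) < 2:
        raise InvalidInputError("need at least two genomes")
    length_filters = length_filters or {}
    usable: dict[str, dict[str, list[str]]] = {}
    for rec in genomes:
        usable[rec.genome_id] = {}
        for gene in genes:
            copies = rec.markers.get(gene, [])
            if gene in length_filters:
                lo, hi = length_filters[gene]
                copies = [c for c in copies if lo <= len(c) <= hi]
            if copies:
                usable[rec.genome_id][gene] = copies

    ids = sorted(usable)
    index = []
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            vals = []
            for gene in genes:
                ca = usable[a].get(gene)
                cb = usable[b].get(gene)
                if ca and cb:
                    vals.append(percent_identity_pairmax(ca, cb, scheme))
                else:
                    vals.append(np.nan)
            index.append((a, b))
            rows.append(vals)
    table = pd.DataFrame(rows, index=index, columns=genes)
    return MarkerIdentityTable(genes=list(genes), table=table)


def rank_markers_per_pair(row: dict[str, float] | pd.Series) -> dict[str, float]:
    """Fractional conservation ranks for one genome pair.

    Rank 1 = most similar (highest identity), rank M = least similar.  Pairs
    missing any marker cannot be ranked.
    """
    if isinstance(row, pd.Series):
        row = row.to_dict()
    if len(row) < 2:
        raise InvalidInputError("need at least two genes to rank")
    genes = sorted(row)
    vals = np.array([row[g] for g in genes], dtype=float)
    if np.isnan(vals).any():
        missing = [g for g, v in zip(genes, vals) if np.isnan(v)]
        raise IncompletePairError(f"missing identities for {missing}")
    ranks = rankdata(-vals, method="average")
    return dict(zip(genes, ranks))


@dataclass
class RankTable:
    """Per-pair fractional ranks and lineage-average ranks."""

    per_pair_ranks: pd.DataFrame                     # index (a, b), columns genes
    lineage_average: dict[tuple[str, str], float]    # (lineage, gene) -> mean rank

    def lineage_frame(self) -> pd.DataFrame:
        rows = [(lin, g, r) for (lin, g), r in sorted(self.lineage_average.items())]
        return pd.DataFrame(rows, columns=["lineage", "gene_label", "mean_rank"])


def rank_table(identity: MarkerIdentityTable) -> pd.DataFrame:
    """Per-pair ranks over all pairs carrying the complete marker set."""
    rows, index = [], []
    for key, vals in identity.table.iterrows():
        if vals.isna().any():
            continue  # incomplete pairs are excluded from ranking
        ranks = rank_markers_per_pair(vals)
        index.append(key)
        rows.append([ranks[g] for g in identity.genes])
    return pd.DataFrame(rows, index=index, columns=identity.genes)


def average_rank_by_lineage(
    per_pair_ranks: pd.DataFrame,
    lineages: dict[str, str],
    strict: bool = True,
) -> dict[tuple[str, str], float]:
    """Unweighted mean rank over all complete within-lineage pairs.

    A lineage contributing no complete pair raises when ``strict``; with
    ``strict=False`` it is skipped (and simply absent from the result).
    """
    out: dict[tuple[str, str], float] = {}
    lineage_names = sorted(set(lineages.values()))
    for lin in lineage_names:
        members = {g for g, l in lineages.items() if l == lin}
        mask = [a in members and b in members for a, b in per_pair_ranks.index]
        sub = per_pair_ranks[mask]
        if sub.empty:
            if strict:
                raise InsufficientDataError(
                    f"lineage {lin!r} has no complete within-lineage pair"
                )
            continue
        for gene in per_pair_ranks.columns:
            out[(lin, gene)] = float(sub[gene].mean())
    return out


def build_rank_table(
    identity: MarkerIdentityTable, lineages: dict[str, str], strict: bool = True
) -> RankTable:
    per_pair = rank_table(identity)
    return RankTable(
        per_pair_ranks=per_pair,
        lineage_average=average_rank_by_lineage(per_pair, lineages, strict=strict),
    )
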