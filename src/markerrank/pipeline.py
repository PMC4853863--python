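"""End-to-end analysis pipeline.

Stages, in order (each writes a TSV and is skipped on re-run when its output
exists and the config hash matches; ``force`` recomputes):

1. load cohort (markers/, proteome/, annotations.tsv, lineages.tsv)
2. marker identity table (16s legitimate-length filter, max-over-copies rule,
   Needleman-Wunsch percent identities)            -> marker_identity.tsv
3. 16s-identity prefilter (default >= 80%) of genome pairs
4. reciprocal-best-hit homologs + AAI per passing pair -> aai.tsv
5. binned genome-disjoint CIs of AAI vs 16s identity   -> binned_ci.tsv
6. per-gene Spearman(identity, AAI) split at the AAI threshold
                                                       -> correlations.tsv
7. per lineage: AAI tree, per-marker trees, split distances, conservation
   ranks, Spearman(lineage-average rank, normalized split distance)
                      -> ranks.tsv, lineage_ranks.tsv, split_distances.tsv,
                         rank_vs_splitdist.tsv, trees/*.nwk

Every stage logs ``stage, records_in, records_out, seconds``.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import homology, io as mio, markers as mk, stats as st, trees as tr
from .alignment import ScoringScheme
from .errors import InsufficientDataError, MarkerRankError
from .simulate import SLOW16S

logger = logging.getLogger("markerrank")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "out"
    # scoring
    nt_match: float = 5.0
    nt_mismatch: float = -4.0
    nt_gap_open: float = 10.0
    nt_gap_extend: float = 0.5
    protein_matrix: str = "BLOSUM62"
    aa_gap_open: float = 11.0
    aa_gap_extend: float = 1.0
    # thresholds (defaults follow genome-scale practice)
    min_16s_identity_percent: float = 80.0
    min_homologs: int = 200
    aai_split_threshold_percent: float = 95.0
    ci_bin_width: float = 2.0
    ci_n_samplings: int = 20
    ci_sample_size: int = 100
    # homology search
    prefilter: bool = True
    kmer_ks: list[int] = field(default_factory=lambda: [5, 4])
    max_candidates: int = 4
    # marker handling
    gene_16s: str = SLOW16S
    len_16s_min: int = 1000
    len_16s_max: int = 1800
    lineages: list[str] = field(default_factory=list)  # empty = all
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.min_16s_identity_percent <= 100):
            raise MarkerRankError("min_16s_identity_percent outside [0, 100]")
        if not (0 < self.aai_split_threshold_percent < 100):
            raise MarkerRankError("aai_split_threshold_percent outside (0, 100)")
        if self.min_homologs < 1:
            raise MarkerRankError("min_homologs must be >= 1")

    @property
    def nt_scheme(self) -> ScoringScheme:
        return ScoringScheme(
            kind="nucleotide", match=self.nt_match, mismatch=self.nt_mismatch,
            gap_open=self.nt_gap_open, gap_extend=self.nt_gap_extend,
        )

    @property
    def aa_scheme(self) -> ScoringScheme:
        return ScoringScheme(
            kind="protein", matrix_name=self.protein_matrix,
            gap_open=self.aa_gap_open, gap_extend=self.aa_gap_extend,
        )

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    out_dir: Path
    genomes: list
    marker_genes: list[str]
    identity: mk.MarkerIdentityTable
    aai: pd.DataFrame               # genome_a, genome_b, n_homologs, aai, discarded
    joined: pd.DataFrame            # per-pair identities + aai (retained pairs)
    correlations: pd.DataFrame
    binned: pd.DataFrame
    ranks: mk.RankTable | None
    split_distances: pd.DataFrame
    rank_vs_split: pd.DataFrame
    counts: dict[str, int]


class _StageLogger:
    def __init__(self, out_dir: Path):
        self.rows = []
        self.out_dir = out_dir

    def log(self, stage: str, n_in: int, n_out: int, seconds: float):
        logger.info("stage=%s records_in=%d records_out=%d seconds=%.2f",
                    stage, n_in, n_out, seconds)
        self.rows.append((stage, n_in, n_out, round(seconds, 3)))

    def write(self):
        df = pd.DataFrame(self.rows, columns=["stage", "records_in", "records_out", "seconds"])
        df.to_csv(self.out_dir / "run_log.tsv", sep="\t", index=False)


def _cached(out_path: Path, hash_path: Path, cfg_hash: str, force: bool) -> bool:
    return (
        not force
        and out_path.exists()
        and hash_path.exists()
        and hash_path.read_text().strip() == cfg_hash
    )


def run_all(cfg: PipelineConfig, force: bool = False) -> PipelineResult:
    """Execute the full analysis; returns in-memory results (all stages also
    persisted under ``cfg.out_dir``)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    cfg_hash = cfg.config_hash()
    hash_path = out / "config_hash.txt"
    slog = _StageLogger(out)

    # ---- stage: load ------------------------------------------------------
    t0 = time.perf_counter()
    genomes = mio.load_cohort(cfg.input_dir)
    if cfg.lineages:
        genomes = [g for g in genomes if g.lineage in cfg.lineages]
    lineage_of = {g.genome_id: g.lineage for g in genomes}
    marker_genes = sorted({gene for g in genomes for gene in g.markers})
    slog.log("load", len(genomes), len(genomes), time.perf_counter() - t0)

    # ---- stage: marker identity table ------------------------------------
    t0 = time.perf_counter()
    ident_path = out / "marker_identity.tsv"
    length_filters = {cfg.gene_16s: (cfg.len_16s_min, cfg.len_16s_max)}
    if _cached(ident_path, hash_path, cfg_hash, force):
        identity = mk.MarkerIdentityTable.from_long(mio.read_tsv(ident_path))
    else:
        identity = mk.build_identity_table(
            genomes, marker_genes, cfg.nt_scheme, length_filters
        )
        mio.write_tsv(identity.to_long(), ident_path)
    n_pairs = len(identity.pairs)
    slog.log("marker_identity", len(genomes), n_pairs, time.perf_counter() - t0)

    # ---- stage: 16s prefilter --------------------------------------------
    t0 = time.perf_counter()
    id16 = identity.table[cfg.gene_16s].to_dict()
    pass16 = [
        pair for pair in identity.pairs
        if not np.isnan(id16[pair]) and id16[pair] >= cfg.min_16s_identity_percent
    ]
    n_rejected = n_pairs - len(pass16)
    assert len(pass16) + n_rejected == n_pairs  # filter-count conservation
    slog.log("prefilter_16s", n_pairs, len(pass16), time.perf_counter() - t0)

    # ---- stage: AAI -------------------------------------------------------
    t0 = time.perf_counter()
    aai_path = out / "aai.tsv"
    proteomes = {g.genome_id: g.proteome for g in genomes}
    if _cached(aai_path, hash_path, cfg_hash, force):
        aai = mio.read_tsv(aai_path)
    else:
        rows = []
        for a, b in pass16:
            rec = homology.aai_between(
                proteomes[a], proteomes[b], a, b,
                scheme=cfg.aa_scheme, min_homologs=cfg.min_homologs,
                prefilter=cfg.prefilter, ks=tuple(cfg.kmer_ks),
                max_candidates=cfg.max_candidates,
            )
            rows.append((rec.genome_a, rec.genome_b, rec.n_homologs,
                         np.nan if rec.aai is None else rec.aai, rec.discarded))
        aai = pd.DataFrame(
            rows, columns=["genome_a", "genome_b", "n_homologs", "aai", "discarded"]
        )
        mio.write_tsv(aai, aai_path)
    retained = aai[~aai["discarded"].astype(bool)]
    assert len(retained) + int(aai["discarded"].astype(bool).sum()) == len(aai)
    slog.log("aai", len(pass16), len(retained), time.perf_counter() - t0)

    # ---- joined table (pair x gene identities + aai) ----------------------
    joined = identity.table.copy()
    joined.index = pd.MultiIndex.from_tuples(joined.index, names=["genome_a", "genome_b"])
    joined = joined.reset_index()
    joined = joined.merge(
        retained[["genome_a", "genome_b", "aai"]], on=["genome_a", "genome_b"],
        how="inner",
    )
    joined = joined.rename(columns={cfg.gene_16s: cfg.gene_16s})

    # ---- stage: binned CI -------------------------------------------------
    t0 = time.perf_counter()
    ci_records = joined[["genome_a", "genome_b", cfg.gene_16s, "aai"]].rename(
        columns={cfg.gene_16s: "identity_16s"}
    ).dropna()
    cis = st.binned_ci(
        ci_records, bin_width=cfg.ci_bin_width, n_samplings=cfg.ci_n_samplings,
        sample_size=cfg.ci_sample_size, seed=cfg.seed,
    )
    binned = st.binned_ci_frame(cis)
    mio.write_tsv(binned, out / "binned_ci.tsv")
    slog.log("binned_ci", len(ci_records), len(binned), time.perf_counter() - t0)

    # ---- stage: split correlations ---------------------------------------
    t0 = time.perf_counter()
    correlations = st.split_correlations(
        joined, marker_genes, threshold=cfg.aai_split_threshold_percent
    )
    mio.write_tsv(correlations, out / "correlations.tsv")
    slog.log("split_correlations", len(joined), len(correlations),
             time.perf_counter() - t0)

    # ---- stage: ranks -----------------------------------------------------
    t0 = time.perf_counter()
    ranks: mk.RankTable | None
    try:
        ranks = mk.build_rank_table(identity, lineage_of, strict=False)
        if not ranks.lineage_average:
            raise InsufficientDataError("no lineage has a complete pair")
    except InsufficientDataError as exc:
        logger.warning("ranking skipped: %s", exc)
        ranks = None
    if ranks is not None:
        per_pair = ranks.per_pair_ranks.copy()
        per_pair.index = pd.MultiIndex.from_tuples(
            per_pair.index, names=["genome_a", "genome_b"]
        )
        mio.write_tsv(per_pair.reset_index(), out / "ranks.tsv")
        mio.write_tsv(ranks.lineage_frame(), out / "lineage_ranks.tsv")
    slog.log("ranks", n_pairs,
             0 if ranks is None else len(ranks.per_pair_ranks),
             time.perf_counter() - t0)

    # ---- stage: per-lineage trees + split distances -----------------------
    t0 = time.perf_counter()
    sd_rows = []
    rvs_rows = []
    lineage_names = sorted(set(lineage_of.values()))
    aai_lookup = {
        (r.genome_a, r.genome_b): r.aai for r in retained.itertuples()
    }
    for lin in lineage_names:
        members = sorted(
            g.genome_id for g in genomes
            if g.lineage == lin and _has_complete_markers(g, marker_genes, cfg)
        )
        # keep only members with full AAI coverage among themselves
        members = _largest_aai_complete_subset(members, aai_lookup)
        if len(members) < 4:
            logger.warning("lineage %s: only %d usable genomes, trees skipped",
                           lin, len(members))
            continue
        aai_vals = {
            (a, b): aai_lookup[(a, b)]
            for a, b in itertools.combinations(members, 2)
        }
        aai_tree = tr.upgma(tr.identity_to_distance(aai_vals, members))
        mio.write_newick(aai_tree, out / "trees" / f"{lin}__AAI.nwk")
        for gene in marker_genes:
            gvals = {
                (a, b): identity.row(a, b)[gene]
                for a, b in itertools.combinations(members, 2)
            }
            gtree = tr.upgma(tr.identity_to_distance(gvals, members))
            mio.write_newick(gtree, out / "trees" / f"{lin}__{gene}.nwk")
            raw, norm = tr.split_distance(gtree, aai_tree)
            sd_rows.append((lin, gene, raw, norm))
    split_distances = pd.DataFrame(
        sd_rows, columns=["lineage", "gene_label", "raw_rf", "normalized_rf"]
    )
    mio.write_tsv(split_distances, out / "split_distances.tsv")

    # rank vs split distance (per lineage and combined across lineages)
    if ranks is not None and not split_distances.empty:
        merged = split_distances.merge(
            ranks.lineage_frame(), on=["lineage", "gene_label"], how="inner"
        )
        for lin, sub in merged.groupby("lineage"):
            rvs_rows.append(_rank_vs_split_row(lin, sub))
        rvs_rows.append(_rank_vs_split_row("combined", merged))
    rank_vs_split = pd.DataFrame(
        rvs_rows, columns=["lineage", "rho", "p", "n", "flag"]
    )
    mio.write_tsv(rank_vs_split, out / "rank_vs_splitdist.tsv")
    slog.log("lineage_trees", len(lineage_names), len(split_distances),
             time.perf_counter() - t0)

    slog.write()
    hash_path.write_text(cfg_hash + "\n")

    counts = {
        "n_genomes": len(genomes),
        "pairs_in": n_pairs,
        "pairs_passing_16s_filter": len(pass16),
        "pairs_rejected_16s": n_rejected,
        "aai_retained": len(retained),
        "aai_discarded": int(aai["discarded"].astype(bool).sum()),
    }
    return PipelineResult(
        out_dir=out, genomes=genomes, marker_genes=marker_genes,
        identity=identity, aai=aai, joined=joined, correlations=correlations,
        binned=binned, ranks=ranks, split_distances=split_distances,
        rank_vs_split=rank_vs_split, counts=counts,
    )


def _has_complete_markers(genome, marker_genes, cfg: PipelineConfig) -> bool:
    for gene in marker_genes:
        copies = genome.markers.get(gene, [])
        if gene == cfg.gene_16s:
            copies = [c for c in copies if cfg.len_16s_min <= len(c) <= cfg.len_16s_max]
        if not copies:
            return False
    return True


def _largest_aai_complete_subset(members: list[str], aai_lookup) -> list[str]:
    """Drop genomes (fewest-covered first) until all pairwise AAIs exist."""
    members = list(members)
    while True:
        missing = {
            g: sum(
                1 for h in members
                if h != g and (min(g, h), max(g, h)) not in aai_lookup
            )
            for g in members
        }
        worst = max(missing.values(), default=0)
        if worst == 0:
            return members
        drop = sorted(g for g, m in missing.items() if m == worst)[0]
        members.remove(drop)


def _rank_vs_split_row(label: str, sub: pd.DataFrame):
    try:
        res = st.spearman(sub["mean_rank"], sub["normalized_rf"])
        return (label, res.rho, res.p_value, res.n, "")
    except MarkerRankError as exc:
        return (label, np.nan, np.nan, len(sub), type(exc).__name__)


# ---------------------------------------------------------------------------
# report

def report(out_dir) -> str:
    """Human-readable summary of a completed run directory."""
    out = Path(out_dir)
    needed = ["config.yaml", "marker_identity.tsv", "aai.tsv", "correlations.tsv"]
    for name in needed:
        if not (out / name).exists():
            raise MarkerRankError(f"missing stage output: {name}")
    cfg = PipelineConfig.from_yaml(out / "config.yaml")
    ident = mio.read_tsv(out / "marker_identity.tsv")
    aai = mio.read_tsv(out / "aai.tsv")
    corr = mio.read_tsv(out / "correlations.tsv")
    lines = []
    genomes = sorted(set(ident["genome_a"]) | set(ident["genome_b"]))
    n_pairs = len(ident[["genome_a", "genome_b"]].drop_duplicates())
    retained = aai[~aai["discarded"].astype(bool)]
    lines.append(f"genomes: {len(genomes)}")
    lines.append(f"genome pairs with marker identities: {n_pairs}")
    lines.append(f"pairs with AAI computed (16s >= {cfg.min_16s_identity_percent:g}%): {len(aai)}")
    lines.append(
        f"pairs discarded by min_homologs={cfg.min_homologs}: "
        f"{int(aai['discarded'].astype(bool).sum())}"
    )
    if retained.empty:
        lines.append("zero analyzable pairs: no correlations computed")
        return "\n".join(lines)
    close = corr[(corr["side"] == "close") & corr["rho"].notna()]
    if not close.empty:
        ordered = close.sort_values("rho", ascending=False)["gene_label"].tolist()
        if cfg.gene_16s in ordered:
            pos = ordered.index(cfg.gene_16s) + 1
            lines.append(
                f"close-side (AAI > {cfg.aai_split_threshold_percent:g}%) correlation "
                f"ordering: {cfg.gene_16s} is {pos} of {len(ordered)}"
            )
    rvs_path = out / "rank_vs_splitdist.tsv"
    if rvs_path.exists():
        rvs = mio.read_tsv(rvs_path)
        for row in rvs.itertuples():
            if row.lineage == "combined":
                continue
            lines.append(
                f"lineage {row.lineage}: rank vs split-distance rho = "
                f"{row.rho:.3f} (p = {row.p:.2g}, n = {row.n})"
            )
        comb = rvs[rvs["lineage"] == "combined"]
        if not comb.empty and np.isfinite(comb["rho"].iloc[0]):
            lines.append(
                f"combined: rank vs split-distance rho = {comb['rho'].iloc[0]:.3f} "
                f"(p = {comb['p'].iloc[0]:.2g}, n = {int(comb['n'].iloc[0])})"
            )
    lin_frame = mio.read_tsv(Path(cfg.input_dir) / "lineages.tsv") \
        if (Path(cfg.input_dir) / "lineages.tsv").exists() else None
    if lin_frame is not None:
        lines.append("lineages: " + ", ".join(sorted(lin_frame["lineage"].unique())))
    return "\n".join(lines)
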