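"""Synthetic genome-evolution simulator.

Generates a cohort of related genomes with a known clonal genealogy and known
per-gene evolutionary rates, writing exactly the input files the analysis
pipeline consumes.  Sequences evolve under a K-state Jukes-Cantor process
(uniform exchange, K=4 for marker nucleotide genes, K=20 for background
amino-acid genes) with no indels, so the closed-form identity expectation

    P(identical site) = 1/K + (K-1)/K * exp(-K/(K-1) * d)

at branch-length d (expected substitutions per site) is available as an
exact oracle for every pairwise comparison.

Genealogy model
---------------
``sample_tree`` draws a pure-birth (Yule) tree and rescales branch lengths so
every root-to-leaf path equals ``depth`` (ultrametric).  ``generate_dataset``
builds a three-level cohort genealogy: genomes group into strain clusters
(very shallow, species-like divergences drawn per cluster), clusters group
into lineages at the lineage crown depth, and lineages join through a deep
Yule backbone.  Pairwise divergences therefore span near-identical strains
to deeply diverged lineages, the regime in which the relative usefulness of
slow and fast marker genes differs most.

Seeding: a single master seed deterministically derives independent streams
per (purpose, gene, branch), so adding a gene never perturbs other genes'
sequences and identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .errors import InvalidConfigError

NT = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

SLOW16S = "slow16s"


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``rate_multipliers`` must name every marker and background gene; the rate
    on each branch of a gene's genealogy is the genealogical branch length
    times that gene's multiplier.  ``tree_depth`` is in expected substitutions
    per site at the base rate (multiplier 1).
    """

    n_genomes: int = 15
    n_markers: int = 133  # includes the slow 16s-like marker
    n_background_genes: int = 200
    marker_length_nt: int = 300
    slow16s_length_nt: int = 1200
    protein_length_aa: int = 70
    tree_depth: float = 1.2
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    presence_prob: float = 0.9999
    seed: int = 0
    # cohort structure
    n_lineages: int = 3
    lineage_sizes: tuple[int, ...] | None = (6, 5, 4)
    lineage_crown_frac: float = 0.4
    cluster_size: int = 3
    cluster_depth_range: tuple[float, float] = (0.015, 0.045)
    backbone_span: tuple[float, float] = (0.55, 0.95)
    # relaxed clock: per-(gene, branch) lognormal rate jitter (sigma of the
    # log; 0 disables).  Mean rate is preserved (exp(sigma*z - sigma^2/2)).
    rate_jitter_sigma: float = 0.0
    # multi-copy 16s-like marker
    n_16s_copies: int = 2
    copy_divergence: float = 0.005

    def __post_init__(self):
        if self.n_genomes < 2:
            raise InvalidConfigError("n_genomes must be >= 2")
        if self.n_markers < 1 or self.n_background_genes < 1:
            raise InvalidConfigError("need at least one marker and one background gene")
        if self.marker_length_nt < 300:
            raise InvalidConfigError("marker_length_nt must be >= 300")
        if self.protein_length_aa < 50:
            raise InvalidConfigError("protein_length_aa must be >= 50")
        if self.tree_depth < 0:
            raise InvalidConfigError("tree_depth must be nonnegative")
        if not (0 < self.presence_prob <= 1):
            raise InvalidConfigError("presence_prob must be in (0, 1]")
        if self.n_16s_copies < 1:
            raise InvalidConfigError("n_16s_copies must be >= 1")
        if not (2 <= self.n_lineages <= self.n_genomes // 2) and self.n_lineages != 1:
            raise InvalidConfigError("n_lineages must be 1 or between 2 and n_genomes/2")
        if self.n_lineages >= 2 and self.lineage_crown_frac >= self.backbone_span[0]:
            raise InvalidConfigError(
                "lineage_crown_frac must be below backbone_span[0] so lineage "
                "crowns sit strictly below backbone divergences"
            )
        if self.lineage_sizes is not None:
            self.lineage_sizes = tuple(int(s) for s in self.lineage_sizes)
            if len(self.lineage_sizes) != self.n_lineages:
                raise InvalidConfigError("lineage_sizes length must equal n_lineages")
            if sum(self.lineage_sizes) != self.n_genomes:
                raise InvalidConfigError("lineage_sizes must sum to n_genomes")
            if any(s < 1 for s in self.lineage_sizes):
                raise InvalidConfigError("every lineage needs at least one genome")
        if not self.rate_multipliers:
            self.rate_multipliers = default_rate_multipliers(
                self.n_markers, self.n_background_genes
            )
        missing = [g for g in self.marker_labels + self.background_labels
                   if g not in self.rate_multipliers]
        if missing:
            raise InvalidConfigError(f"rate_multipliers missing entries for {missing[:5]}...")
        bad = {g: m for g, m in self.rate_multipliers.items() if m < 0}
        if bad:
            raise InvalidConfigError(f"negative rate multipliers: {bad}")

    @property
    def marker_labels(self) -> list[str]:
        return [SLOW16S] + [f"m{i:02d}" for i in range(1, self.n_markers)]

    @property
    def background_labels(self) -> list[str]:
        return [f"p{i:03d}" for i in range(1, self.n_background_genes + 1)]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("backbone_span", "cluster_depth_range", "lineage_sizes"):
            if d[key] is not None:
                d[key] = list(d[key])
        d["rate_multipliers"] = {k: float(v) for k, v in sorted(d["rate_multipliers"].items())}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("backbone_span", "cluster_depth_range", "lineage_sizes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def default_rate_multipliers(n_markers: int, n_background: int) -> dict[str, float]:
    """Default per-gene rates: a very slow 16s-like marker, protein-coding
    markers log-spaced from moderately to very fast at the nucleotide level,
    and slowly diverging background amino-acid genes (amino-acid substitutions
    accumulate far more slowly than marker nucleotide substitutions)."""
    mult: dict[str, float] = {SLOW16S: 0.035}
    if n_markers > 1:
        spread = np.exp(np.linspace(np.log(0.6), np.log(10.0), n_markers - 1))
        for i, m in enumerate(spread, start=1):
            mult[f"m{i:02d}"] = float(m)
    bg = np.exp(np.linspace(np.log(0.25), np.log(0.40), n_background))
    for i, m in enumerate(bg, start=1):
        mult[f"p{i:03d}"] = float(m)
    return mult


@dataclass
class GroundTruth:
    """What the generator knows: the genealogy, rates, and path lengths."""

    true_tree: dendropy.Tree
    true_rates: dict[str, float]
    pairwise_path_lengths: pd.DataFrame  # symmetric, zero diagonal
    lineages: dict[str, str]


# ---------------------------------------------------------------------------
# deterministic stream derivation

def _rng(master_seed: int, *keys) -> np.random.Generator:
    token = repr((int(master_seed),) + tuple(keys)).encode()
    digest = hashlib.sha256(token).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


# ---------------------------------------------------------------------------
# trees (lightweight nodes; converted to dendropy at the end)

class _Node:
    __slots__ = ("children", "length", "label", "index", "height")

    def __init__(self, length=0.0, label=None):
        self.children: list[_Node] = []
        self.length = float(length)
        self.label = label
        self.index = -1  # preorder index, set by _index_tree
        self.height = 0.0  # height above the tips (used during construction)


def _index_tree(root: _Node) -> list[_Node]:
    order = []
    stack = [root]
    while stack:
        node = stack.pop()
        node.index = len(order)
        order.append(node)
        stack.extend(reversed(node.children))
    return order


def _yule_topology(n_taxa: int, rng: np.random.Generator) -> _Node:
    """Forward pure-birth simulation; branch lengths in raw time units."""
    root = _Node()
    start = {id(root): 0.0}
    active = [root]
    t = 0.0
    for k in range(1, n_taxa):
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.length = t - start[id(node)]
        for _ in range(2):
            child = _Node()
            start[id(child)] = t
            node.children.append(child)
            active.append(child)
    T = t + rng.exponential(1.0 / n_taxa)
    for node in active:
        node.length = T - start[id(node)]
    return root


def _scale(root: _Node, factor: float) -> None:
    for node in _index_tree(root):
        node.length *= factor


def _leaf_depth(root: _Node) -> float:
    node = root
    d = 0.0
    while node.children:
        node = node.children[0]
        d += node.length
    return d


def _label_leaves(root: _Node, labels: list[str]) -> None:
    leaves = [n for n in _index_tree(root) if not n.children]
    if len(leaves) != len(labels):
        raise InvalidConfigError("label count does not match leaf count")
    for node, lab in zip(leaves, labels):
        node.label = lab


def _to_newick(node: _Node) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.12g}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}):{node.length:.12g}"


def _to_dendropy(root: _Node) -> dendropy.Tree:
    text = f"({','.join(_to_newick(c) for c in root.children)});"
    return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)


def _yule_height_tree(n: int, rng: np.random.Generator) -> _Node:
    """Yule topology with ``height`` set on every node (leaves 0, root 1)."""
    root = _yule_topology(n, rng)
    order = _index_tree(root)
    depth_above = {root.index: 0.0}
    for node in order:
        for c in node.children:
            depth_above[c.index] = depth_above[node.index] + c.length
    total = max(depth_above[n.index] for n in order if not n.children)
    for node in order:
        node.height = 0.0 if not node.children else 1.0 - depth_above[node.index] / total
    return root


def _spread_heights(
    root: _Node, root_height: float, span: tuple[float, float],
    rng: np.random.Generator,
) -> None:
    """Set root.height = root_height and scatter the other internal-node
    heights inside ``span * root_height``, preserving the original height
    order (and therefore parent > child).

    Each node draws uniformly within its own sub-band of the span (with a
    15% margin on both sides), so consecutive node heights are guaranteed to
    be separated by at least 30% of a sub-band — no two divergences collapse
    onto each other.
    """
    order = _index_tree(root)
    internals = [n for n in order if n.children and n is not root]
    root.height = root_height
    if not internals:
        return
    lo, hi = span
    k = len(internals)
    delta = (hi - lo) / k
    by_height = sorted(internals, key=lambda n: (n.height, n.index))
    for i, node in enumerate(by_height):
        frac = lo + (i + 0.15) * delta + rng.uniform(0.0, 0.7 * delta)
        node.height = float(frac * root_height)


def _heights_to_lengths(root: _Node) -> None:
    for node in _index_tree(root):
        for c in node.children:
            c.length = max(0.0, node.height - c.height)


def sample_tree(n_taxa: int, depth: float, seed: int) -> dendropy.Tree:
    """Rooted binary ultrametric Yule tree with all root-to-leaf paths equal
    to ``depth``.  Leaf labels are g001..gNNN in preorder."""
    if n_taxa < 2:
        raise InvalidConfigError("n_taxa must be >= 2")
    if depth < 0:
        raise InvalidConfigError("depth must be nonnegative")
    rng = _rng(seed, "sample_tree", n_taxa)
    root = _yule_topology(n_taxa, rng)
    raw = _leaf_depth(root)
    _scale(root, depth / raw if raw > 0 else 0.0)
    _index_tree(root)
    _label_leaves(root, [f"g{i:03d}" for i in range(1, n_taxa + 1)])
    return _to_dendropy(root)


#: within-cluster internal nodes sit below the cluster root by absolute
#: height gaps drawn from this range (expected substitutions per site):
#: wide enough for the pooled proteome (AAI) to resolve every split, narrow
#: enough that slow markers cannot
_CLUSTER_GAP = (0.0055, 0.0075)
#: within-lineage (between-cluster) internal nodes, fraction of crown depth
_LINEAGE_SPAN = (0.6, 0.9)


def _split_sizes(total: int, part: int) -> list[int]:
    """Split ``total`` into greedily filled parts of at most ``part``
    members (e.g. 5 genomes in clusters of 3 -> [3, 2]; 4 -> [3, 1]), so
    full-size strain clusters are formed whenever possible."""
    sizes = []
    while total > 0:
        take = min(part, total)
        sizes.append(take)
        total -= take
    return sizes


def _stack_heights(
    root: _Node, root_height: float, gap_range: tuple[float, float],
    rng: np.random.Generator,
) -> None:
    """Set root.height = root_height and place the other internal nodes at
    absolute height gaps below their predecessor (deepest first), clamped
    above zero.  Gives direct control over how contested each split is."""
    order = _index_tree(root)
    internals = [n for n in order if n.children and n is not root]
    root.height = root_height
    h = root_height
    for node in sorted(internals, key=lambda n: (-n.height, n.index)):
        h = max(h - rng.uniform(*gap_range), 0.2 * h)
        node.height = float(h)


def _graft(host_leaf: _Node, subtree: _Node) -> None:
    """Replace a pendant leaf of the upper level with a lower-level subtree
    whose root height is already set."""
    host_leaf.children = subtree.children
    host_leaf.label = subtree.label
    host_leaf.height = subtree.height


def _build_cohort_tree(cfg: SimulationConfig) -> tuple[_Node, dict[str, str]]:
    """Three-level genealogy: strain clusters within lineages within a deep
    Yule backbone.  Heights are assigned top-down, then converted to edge
    lengths in one pass."""
    rng = _rng(cfg.seed, "cohort_tree")
    if cfg.lineage_sizes is not None:
        lin_sizes = list(cfg.lineage_sizes)
    else:
        lin_sizes = [cfg.n_genomes // cfg.n_lineages] * cfg.n_lineages
        for i in range(cfg.n_genomes % cfg.n_lineages):
            lin_sizes[i] += 1
    crown_depth = (
        cfg.lineage_crown_frac * cfg.tree_depth
        if cfg.n_lineages > 1
        else cfg.tree_depth
    )
    dlo, dhi = cfg.cluster_depth_range
    lineages: dict[str, str] = {}
    crowns: list[_Node] = []
    for li, size in enumerate(lin_sizes, start=1):
        lin = f"lin{li}"
        labels = [f"{lin}_g{i:02d}" for i in range(1, size + 1)]
        for lab in labels:
            lineages[lab] = lin
        # strain clusters
        csizes = _split_sizes(size, cfg.cluster_size)
        clusters: list[_Node] = []
        pos = 0
        for csize in csizes:
            clabels = labels[pos : pos + csize]
            pos += csize
            cluster_depth = float(
                np.exp(rng.uniform(np.log(dlo), np.log(dhi)))
            )
            if csize == 1:
                clusters.append(_Node(label=clabels[0]))
                continue
            sub = _yule_height_tree(csize, rng)
            _stack_heights(sub, cluster_depth, _CLUSTER_GAP, rng)
            _label_leaves(sub, clabels)
            clusters.append(sub)
        if len(clusters) == 1:
            crown = clusters[0]
        else:
            crown = _yule_height_tree(len(clusters), rng)
            _spread_heights(crown, crown_depth, _LINEAGE_SPAN, rng)
            cleaves = [n for n in _index_tree(crown) if not n.children]
            for leaf, cl in zip(cleaves, clusters):
                _graft(leaf, cl)
        crowns.append(crown)

    if cfg.n_lineages == 1:
        root = crowns[0]
    else:
        root = _yule_height_tree(cfg.n_lineages, rng)
        _spread_heights(root, cfg.tree_depth, cfg.backbone_span, rng)
        bleaves = [n for n in _index_tree(root) if not n.children]
        for leaf, crown in zip(bleaves, crowns):
            _graft(leaf, crown)
    _heights_to_lengths(root)
    _index_tree(root)
    return root, lineages


# ---------------------------------------------------------------------------
# sequence evolution

def evolve_sequence(
    parent: np.ndarray | str,
    branch_subs_per_site: float,
    alphabet_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one sequence along one branch under K-state Jukes-Cantor.

    ``parent`` may be a string over ACGT / 20 amino acids or an integer state
    array; returns an integer state array of the same length.
    """
    if branch_subs_per_site < 0:
        raise InvalidConfigError("negative branch length")
    if alphabet_size not in (4, 20):
        raise InvalidConfigError("alphabet_size must be 4 or 20")
    if isinstance(parent, str):
        if not parent:
            raise InvalidConfigError("empty parent sequence")
        letters = NT if alphabet_size == 4 else AA
        lookup = {c: i for i, c in enumerate(letters)}
        parent = np.array([lookup[c] for c in parent.upper()], dtype=np.int8)
    if parent.size == 0:
        raise InvalidConfigError("empty parent sequence")
    K = alphabet_size
    d = branch_subs_per_site
    p_change = (K - 1) / K * (1.0 - np.exp(-K / (K - 1) * d))
    child = parent.copy()
    hit = rng.random(child.size) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        # uniform among the K-1 other states
        shift = rng.integers(1, K, size=n_hit)
        child[hit] = (child[hit] + shift) % K
    return child


def jc_identity(d: float, alphabet_size: int) -> float:
    """Closed-form expected fraction of identical sites at distance ``d``."""
    K = alphabet_size
    return 1.0 / K + (K - 1.0) / K * np.exp(-K / (K - 1.0) * d)


def states_to_str(states: np.ndarray, alphabet_size: int) -> str:
    letters = NT if alphabet_size == 4 else AA
    return "".join(letters[states])


def _evolve_gene_over_tree(
    root: _Node,
    length: int,
    multiplier: float,
    alphabet_size: int,
    master_seed: int,
    gene: str,
    jitter_sigma: float = 0.0,
) -> dict[str, np.ndarray]:
    """Evolve one gene down the genealogy; returns leaf-label -> state array.

    Streams are keyed by (gene, node preorder index) so every gene and every
    branch has an independent reproducible stream.  ``jitter_sigma`` applies
    a relaxed clock: each (gene, branch) rate is multiplied by an independent
    mean-one lognormal draw, so a gene's realized rate can drift between
    clades while its expected rate stays the multiplier.
    """
    rng_root = _rng(master_seed, "root", gene)
    out: dict[str, np.ndarray] = {}
    root_seq = rng_root.integers(0, alphabet_size, size=length).astype(np.int8)
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if not node.children:
            out[node.label] = seq
            continue
        for child in node.children:
            rng = _rng(master_seed, "branch", gene, child.index)
            rate = multiplier
            if jitter_sigma > 0:
                z = rng.standard_normal()
                rate *= float(np.exp(jitter_sigma * z - jitter_sigma**2 / 2.0))
            child_seq = evolve_sequence(
                seq, child.length * rate, alphabet_size, rng
            )
            stack.append((child, child_seq))
    return out


# ---------------------------------------------------------------------------
# dataset generation

def generate_dataset(cfg: SimulationConfig, out_dir) -> GroundTruth:
    """Simulate the cohort and write the full pipeline input layout.

    Writes markers/<genome>.fna, proteome/<genome>.faa, annotations.tsv,
    lineages.tsv, true_tree.nwk, true_rates.tsv and sim_config.yaml.
    Each gene is independently absent from a genome with probability
    1 - presence_prob; the slow 16s-like marker is always present.
    """
    out_dir = Path(out_dir)
    try:
        (out_dir / "markers").mkdir(parents=True, exist_ok=True)
        (out_dir / "proteome").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out_dir}: {exc}") from exc

    root, lineages = _build_cohort_tree(cfg)
    genome_ids = sorted(lineages)

    # presence masks (gene -> genome -> bool), keyed independently per gene
    presence: dict[str, dict[str, bool]] = {}
    for gene in cfg.marker_labels + cfg.background_labels:
        if gene == SLOW16S:
            presence[gene] = {g: True for g in genome_ids}
        else:
            rng = _rng(cfg.seed, "presence", gene)
            draws = rng.random(len(genome_ids))
            presence[gene] = {
                g: bool(draws[i] < cfg.presence_prob) for i, g in enumerate(genome_ids)
            }

    # evolve genes
    marker_seqs: dict[str, dict[str, list[str]]] = {g: {} for g in genome_ids}
    proteomes: dict[str, dict[str, str]] = {g: {} for g in genome_ids}
    for gene in cfg.marker_labels:
        length = cfg.slow16s_length_nt if gene == SLOW16S else cfg.marker_length_nt
        states = _evolve_gene_over_tree(
            root, length, cfg.rate_multipliers[gene], 4, cfg.seed, gene,
            cfg.rate_jitter_sigma,
        )
        for g in genome_ids:
            if not presence[gene][g]:
                continue
            copies = [states_to_str(states[g], 4)]
            if gene == SLOW16S:
                for ci in range(2, cfg.n_16s_copies + 1):
                    rng = _rng(cfg.seed, "copy", gene, g, ci)
                    extra = evolve_sequence(states[g], cfg.copy_divergence, 4, rng)
                    copies.append(states_to_str(extra, 4))
            marker_seqs[g][gene] = copies
    for gene in cfg.background_labels:
        states = _evolve_gene_over_tree(
            root, cfg.protein_length_aa, cfg.rate_multipliers[gene], 20,
            cfg.seed, gene, cfg.rate_jitter_sigma,
        )
        for g in genome_ids:
            if presence[gene][g]:
                proteomes[g][f"{g}|{gene}|c1"] = states_to_str(states[g], 20)

    # write files
    ann_rows = []
    for g in genome_ids:
        recs = []
        for gene in sorted(marker_seqs[g]):
            for ci, seq in enumerate(marker_seqs[g][gene], start=1):
                sid = f"{g}|{gene}|c{ci}"
                recs.append((sid, seq))
                ann_rows.append((g, gene, f"c{ci}", sid))
        mio.write_fasta(recs, out_dir / "markers" / f"{g}.fna")
        mio.write_fasta(
            sorted(proteomes[g].items()), out_dir / "proteome" / f"{g}.faa"
        )
    ann = pd.DataFrame(ann_rows, columns=["genome_id", "gene_label", "copy_id", "sequence_id"])
    mio.write_tsv(ann, out_dir / "annotations.tsv")
    lin = pd.DataFrame(
        [(g, lineages[g]) for g in genome_ids], columns=["genome_id", "lineage"]
    )
    mio.write_tsv(lin, out_dir / "lineages.tsv")

    tree = _to_dendropy(root)
    mio.write_newick(tree, out_dir / "true_tree.nwk")
    rates = pd.DataFrame(
        sorted(cfg.rate_multipliers.items()), columns=["gene_label", "multiplier"]
    )
    mio.write_tsv(rates, out_dir / "true_rates.tsv")
    cfg.to_yaml(out_dir / "sim_config.yaml")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(genome_ids)
    mat = np.zeros((n, n))
    for i, a in enumerate(genome_ids):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[genome_ids[j]])
            mat[i, j] = mat[j, i] = d
    paths = pd.DataFrame(mat, index=genome_ids, columns=genome_ids)

    return GroundTruth(
        true_tree=tree,
        true_rates=dict(cfg.rate_multipliers),
        pairwise_path_lengths=paths,
        lineages=lineages,
    )
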