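"""Reciprocal-best-hit homology detection and average amino-acid identity.

Homologs between two proteomes are reciprocal best hits (RBH) under local
alignment score, re-aligned with Smith-Waterman to obtain identity and
coverage.  A pair of proteins counts as homologous when it aligns over at
least 70% of the shorter sequence with identity strictly above 30%; the
genome pair's AAI is the unweighted mean identity over homologs, reported
only when at least ``min_homologs`` (200 by default, matching genome-scale
practice) survive the filters.

Instead of an external BLAST dependency, candidate hits are seeded with a
shared k-mer prefilter and scored with exact local alignment, which keeps
the search deterministic and self-contained.  Seeding is adaptive: subjects
sharing a 5-mer with the query are ranked by the number of distinct shared
5-mers; when no subject shares a 5-mer the seed length falls back to 4 (the
BLAST-like word-hit requirement).  The top ``max_candidates`` (4) candidates
are aligned.  Set ``prefilter=False`` to recover the exhaustive all-vs-all
computation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .alignment import (
    PROTEIN_SCHEME,
    ScoringScheme,
    local_identity_coverage,
    local_score,
)
from .errors import InvalidInputError

COVERAGE_MIN = 0.70   # aligned over at least 70% of the shorter sequence
IDENTITY_MIN = 30.0   # identity strictly above 30%
DEFAULT_MIN_HOMOLOGS = 200
KMER_KS = (5, 4)      # adaptive seed lengths, longest first
MAX_CANDIDATES = 4


@dataclass(frozen=True)
class HomologPair:
    protein_id_a: str
    protein_id_b: str
    identity: float            # percent, over aligned columns
    coverage_shorter: float    # in [0, 1]


@dataclass
class AAIRecord:
    genome_a: str
    genome_b: str
    n_homologs: int
    aai: float | None
    discarded: bool


def _kmer_index(proteome: dict[str, str], k: int) -> dict[str, set[str]]:
    index: dict[str, set[str]] = defaultdict(set)
    for pid, seq in proteome.items():
        for i in range(len(seq) - k + 1):
            index[seq[i : i + k]].add(pid)
    return index


def _candidates(
    query: str,
    indexes: dict[int, dict[str, set[str]]],
    ks: tuple[int, ...],
    max_candidates: int,
) -> list[str]:
    for k in ks:
        index = indexes[k]
        counts: dict[str, int] = defaultdict(int)
        seen = set()
        for i in range(len(query) - k + 1):
            kmer = query[i : i + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for pid in index.get(kmer, ()):
                counts[pid] += 1
        if counts:
            ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
            return [pid for pid, _ in ranked[:max_candidates]]
    return []


def best_hits(
    query_proteome: dict[str, str],
    subject_proteome: dict[str, str],
    scheme: ScoringScheme = PROTEIN_SCHEME,
    prefilter: bool = True,
    ks: tuple[int, ...] = KMER_KS,
    max_candidates: int = MAX_CANDIDATES,
) -> dict[str, str]:
    """Best local-alignment hit in the subject proteome for each query.

    Queries without a positive-scoring hit are absent from the map.  Ties are
    broken toward the lexicographically smallest subject id.
    """
    if not query_proteome or not subject_proteome:
        raise InvalidInputError("empty proteome")
    indexes = {k: _kmer_index(subject_proteome, k) for k in ks} if prefilter else None
    hits: dict[str, str] = {}
    all_subjects = sorted(subject_proteome)
    for qid in sorted(query_proteome):
        qseq = query_proteome[qid]
        if prefilter:
            cand = _candidates(qseq, indexes, ks, max_candidates)
        else:
            cand = all_subjects
        best_id, best_score = None, 0.0
        for sid in sorted(cand):
            s = local_score(qseq, subject_proteome[sid], scheme)
            if s > best_score:
                best_id, best_score = sid, s
        if best_id is not None:
            hits[qid] = best_id
    return hits


def reciprocal_best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    scheme: ScoringScheme = PROTEIN_SCHEME,
    prefilter: bool = True,
    ks: tuple[int, ...] = KMER_KS,
    max_candidates: int = MAX_CANDIDATES,
) -> list[HomologPair]:
    """Mutual best hits between two proteomes with SW re-alignment stats."""
    fwd = best_hits(proteome_a, proteome_b, scheme, prefilter, ks, max_candidates)
    rev = best_hits(proteome_b, proteome_a, scheme, prefilter, ks, max_candidates)
    pairs: list[HomologPair] = []
    for qa in sorted(fwd):
        qb = fwd[qa]
        if rev.get(qb) == qa:
            identity, coverage = local_identity_coverage(
                proteome_a[qa], proteome_b[qb], scheme
            )
            pairs.append(HomologPair(qa, qb, identity, coverage))
    return pairs


def filter_homologs(pairs: list[HomologPair]) -> list[HomologPair]:
    """Keep pairs aligned over >= 70% of the shorter sequence with identity
    strictly above 30%."""
    return [
        p
        for p in pairs
        if p.coverage_shorter >= COVERAGE_MIN and p.identity > IDENTITY_MIN
    ]


def compute_aai(
    pairs: list[HomologPair],
    genome_a: str = "a",
    genome_b: str = "b",
    min_homologs: int = DEFAULT_MIN_HOMOLOGS,
) -> AAIRecord:
    """Unweighted mean homolog identity, or a discarded record below the
    homolog-count minimum."""
    if min_homologs < 1:
        raise InvalidInputError("min_homologs must be >= 1")
    n = len(pairs)
    if n < min_homologs:
        return AAIRecord(genome_a, genome_b, n, None, True)
    aai = sum(p.identity for p in pairs) / n
    return AAIRecord(genome_a, genome_b, n, aai, False)


def aai_between(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    genome_a: str = "a",
    genome_b: str = "b",
    scheme: ScoringScheme = PROTEIN_SCHEME,
    min_homologs: int = DEFAULT_MIN_HOMOLOGS,
    prefilter: bool = True,
    ks: tuple[int, ...] = KMER_KS,
    max_candidates: int = MAX_CANDIDATES,
) -> AAIRecord:
    """RBH -> homolog filters -> AAI for one genome pair."""
    pairs = filter_homologs(
        reciprocal_best_hits(proteome_a, proteome_b, scheme, prefilter, ks,
                             max_candidates)
    )
    return compute_aai(pairs, genome_a, genome_b, min_homologs)


def find_markers_by_rbh(
    genome_proteome: dict[str, str],
    reference_markers: dict[str, str],
    scheme: ScoringScheme = PROTEIN_SCHEME,
    prefilter: bool = True,
) -> dict[str, str]:
    """Recognize marker genes in a genome as reciprocal best hits against a
    reference genome's marker proteins (gene label -> protein id, absent
    when no reciprocal hit exists)."""
    if not reference_markers:
        raise InvalidInputError("empty reference marker set")
    if not genome_proteome:
        raise InvalidInputError("empty proteome")
    pairs = reciprocal_best_hits(reference_markers, genome_proteome, scheme, prefilter)
    return {p.protein_id_a: p.protein_id_b for p in pairs}


def marker_presence_filter(
    presence: dict[str, float], threshold: float = 0.90
) -> list[str]:
    """Genes present in strictly more than ``threshold`` of genomes."""
    for gene, frac in presence.items():
        if not (0 <= frac <= 1):
            raise InvalidInputError(f"presence fraction for {gene} outside [0,1]")
    return sorted(g for g, frac in presence.items() if frac > threshold)
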