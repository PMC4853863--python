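"""Pairwise alignment kernels and percent-identity computation.

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment with affine
gap penalties, used for marker-gene nucleotide identities and for protein
homolog detection/re-alignment.  The dynamic programming itself is delegated
to :class:`Bio.Align.PairwiseAligner`; this module fixes the scoring
conventions and the percent-identity definitions used throughout the
pipeline:

* global percent identity = identical columns / total alignment columns
  (gap columns included), the EMBOSS-needle convention;
* local percent identity = identical columns / aligned columns of the local
  alignment;
* ``coverage_shorter`` = residues of the shorter sequence inside the aligned
  region / length of the shorter sequence.

Gap convention: a gap of length k costs ``gap_open + (k - 1) * gap_extend``,
so setting ``gap_extend == gap_open`` gives linear gap costs.  End gaps are
penalized in global mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InvalidInputError, MissingGeneError

NT_ALPHABET = "ACGTN"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"


def _nt_matrix(match: float, mismatch: float):
    """Match/mismatch matrix over ACGTN; N never matches, not even itself."""
    m = substitution_matrices.Array(NT_ALPHABET, dims=2)
    for x in NT_ALPHABET:
        for y in NT_ALPHABET:
            m[x, y] = match if (x == y and x != "N") else mismatch
    return m


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters.

    ``kind`` is "nucleotide" (match/mismatch scores) or "protein"
    (a named substitution matrix, BLOSUM62 by default).  ``gap_open`` and
    ``gap_extend`` are nonnegative penalties with gap_open >= gap_extend.
    """

    kind: str = "nucleotide"
    match: float = 5.0
    mismatch: float = -4.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.kind not in ("nucleotide", "protein"):
            raise InvalidInputError(f"unknown scheme kind {self.kind!r}")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise InvalidInputError(
                f"require gap_open >= gap_extend >= 0, got {self.gap_open}, {self.gap_extend}"
            )

    @property
    def alphabet(self) -> str:
        return NT_ALPHABET if self.kind == "nucleotide" else AA_ALPHABET


#: EMBOSS-needle-like nucleotide defaults.
NUCLEOTIDE_SCHEME = ScoringScheme(kind="nucleotide")
#: BLAST-like protein defaults.
PROTEIN_SCHEME = ScoringScheme(kind="protein", gap_open=11.0, gap_extend=1.0)


@dataclass
class AlignmentResult:
    """One pairwise alignment: gapped sequences, score and identity summary."""

    aligned_a: str
    aligned_b: str
    score: float
    percent_identity: float
    coverage_shorter: float
    n_columns: int = 0
    n_identical: int = 0

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@lru_cache(maxsize=32)
def _make_aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    if scheme.kind == "nucleotide":
        aligner.substitution_matrix = _nt_matrix(scheme.match, scheme.mismatch)
    else:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    aligner.open_gap_score = -(scheme.gap_open)
    aligner.extend_gap_score = -(scheme.gap_extend)
    aligner.mode = mode
    return aligner


def _check_input(seq: str, scheme: ScoringScheme, name: str) -> str:
    if not seq:
        raise InvalidInputError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - set(scheme.alphabet)
    if bad:
        raise InvalidInputError(
            f"{name}: characters {sorted(bad)} outside {scheme.kind} alphabet"
        )
    return seq


def _result_from_alignment(aln, a: str, b: str, keep_strings: bool = True) -> AlignmentResult:
    counts = aln.counts()
    n_columns = aln.length
    n_identical = counts.identities
    # residues of the shorter sequence inside the aligned region
    short_len = min(len(a), len(b))
    # aln.aligned: pairs of (target, query) aligned blocks
    blocks = aln.aligned
    if len(a) <= len(b):
        covered = sum(int(e - s) for s, e in blocks[0])
    else:
        covered = sum(int(e - s) for s, e in blocks[1])
    # building the gapped strings is costly; skip it on the hot paths
    text = (aln[0], aln[1]) if keep_strings else ("", "")
    return AlignmentResult(
        aligned_a=text[0],
        aligned_b=text[1],
        score=float(aln.score),
        percent_identity=100.0 * n_identical / n_columns if n_columns else 0.0,
        coverage_shorter=covered / short_len if short_len else 0.0,
        n_columns=int(n_columns),
        n_identical=int(n_identical),
    )


def global_align(a: str, b: str, scheme: ScoringScheme = NUCLEOTIDE_SCHEME) -> AlignmentResult:
    """Optimal global alignment of ``a`` and ``b`` under ``scheme``.

    Percent identity uses all alignment columns (gaps included) as the
    denominator.  Tie-breaking among co-optimal alignments is the aligner's
    deterministic canonical order.
    """
    a = _check_input(a, scheme, "a")
    b = _check_input(b, scheme, "b")
    aligner = _make_aligner(scheme, "global")
    aln = aligner.align(a, b)[0]
    res = _result_from_alignment(aln, a, b)
    # for global alignments the denominator is all columns, which
    # _result_from_alignment already uses (aln.length includes gap columns)
    return res


def local_align(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> AlignmentResult:
    """Optimal local alignment; empty result if nothing scores positively."""
    a = _check_input(a, scheme, "a")
    b = _check_input(b, scheme, "b")
    aligner = _make_aligner(scheme, "local")
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments[0].score <= 0:
        return AlignmentResult("", "", 0.0, 0.0, 0.0, 0, 0)
    return _result_from_alignment(alignments[0], a, b)


def local_score(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> float:
    """Local alignment score only (no traceback); floors at 0."""
    a = _check_input(a, scheme, "a")
    b = _check_input(b, scheme, "b")
    aligner = _make_aligner(scheme, "local")
    return max(0.0, float(aligner.score(a, b)))


def _ungapped_score(a: str, b: str, scheme: ScoringScheme) -> float:
    if scheme.kind == "nucleotide":
        return sum(
            scheme.match if (x == y and x != "N") else scheme.mismatch
            for x, y in zip(a, b)
        )
    matrix = substitution_matrices.load(scheme.matrix_name)
    return sum(float(matrix[x, y]) for x, y in zip(a, b))


def global_percent_identity(a: str, b: str, scheme: ScoringScheme = NUCLEOTIDE_SCHEME) -> float:
    """Global-alignment percent identity (identical columns / all columns).

    For equal-length sequences the ungapped alignment is tried first: when
    it reaches the optimal score (checked against the score-only DP) it is
    taken as the preferred co-optimal alignment — the diagonal-first
    tie-break — which avoids the full traceback on colinear inputs.
    """
    a = _check_input(a, scheme, "a")
    b = _check_input(b, scheme, "b")
    aligner = _make_aligner(scheme, "global")
    if len(a) == len(b):
        optimal = float(aligner.score(a, b))
        if abs(_ungapped_score(a, b, scheme) - optimal) < 1e-6:
            return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)
    aln = aligner.align(a, b)[0]
    n_columns = aln.length
    return 100.0 * aln.counts().identities / n_columns if n_columns else 0.0


def local_identity_coverage(a: str, b: str, scheme: ScoringScheme = PROTEIN_SCHEME) -> tuple[float, float]:
    """(percent identity, coverage of the shorter sequence) of the optimal
    local alignment, without gapped-string construction."""
    a = _check_input(a, scheme, "a")
    b = _check_input(b, scheme, "b")
    aligner = _make_aligner(scheme, "local")
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments[0].score <= 0:
        return 0.0, 0.0
    res = _result_from_alignment(alignments[0], a, b, keep_strings=False)
    return res.percent_identity, res.coverage_shorter


def percent_identity_pairmax(
    copies_a: list[str], copies_b: list[str], scheme: ScoringScheme = NUCLEOTIDE_SCHEME
) -> float:
    """Maximal global-alignment percent identity over all copy pairs.

    Mirrors the multi-copy rule for rRNA-like genes: when either genome
    carries several copies, the best-matching pair defines the identity.
    """
    if not copies_a or not copies_b:
        raise MissingGeneError("empty copy list for one genome")
    return max(
        global_percent_identity(x, y, scheme) for x in copies_a for y in copies_b
    )
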