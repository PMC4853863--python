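"""Readers and writers for every file the pipeline touches.

Cohort layout (produced by :mod:`markerrank.simulate`, consumable from any
source that follows it)::

    <dir>/
      markers/<genome_id>.fna    nucleotide FASTA, headers <genome>|<gene>|<copy>
      proteome/<genome_id>.faa   amino-acid FASTA, same header convention
      annotations.tsv            genome_id  gene_label  copy_id  sequence_id
      lineages.tsv               genome_id  lineage

Sequences are whole-gene units on the coding strand; no genomic coordinates
or reverse-complement handling (a documented limitation for real data).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from .errors import LayoutError, ParseError

logger = logging.getLogger("markerrank")

_NT_OK = set("ACGTN")
_AA_OK = set("ACDEFGHIKLMNPQRSTVWYX")
_LABEL_RE = re.compile(r"^[A-Za-z0-9_.|-]+$")


@dataclass
class GenomeRecord:
    """One genome: marker nucleotide sequences (multi-copy) and its proteome."""

    genome_id: str
    markers: dict[str, list[str]] = field(default_factory=dict)
    proteome: dict[str, str] = field(default_factory=dict)
    lineage: str = ""

    def has_all(self, genes: list[str]) -> bool:
        return all(g in self.markers for g in genes)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Strict FASTA reader: (id, uppercased sequence) in file order.

    The id is the header token up to the first whitespace.  Malformed records
    (sequence before any header, empty sequence) raise :class:`ParseError`
    with the offending line number.
    """
    records: list[tuple[str, str]] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush():
        if header is not None:
            if not chunks:
                raise ParseError("record has no sequence", path, header_line)
            records.append((header, "".join(chunks).upper()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if len(line) > 1 else ""
                if not header:
                    raise ParseError("empty FASTA header", path, lineno)
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError("sequence data before first header", path, lineno)
                chunks.append(line)
    flush()
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def validate_alphabet(seq: str, kind: str, name: str, path=None) -> None:
    ok = _NT_OK if kind == "nucleotide" else _AA_OK
    bad = set(seq) - ok
    if bad:
        raise ParseError(f"{name}: invalid {kind} characters {sorted(bad)}", path)


# ---------------------------------------------------------------------------
# Cohort

def load_cohort(directory) -> list[GenomeRecord]:
    """Load a cohort directory into :class:`GenomeRecord` objects.

    Annotated-but-missing sequences are errors; unannotated FASTA records are
    logged as warnings and ignored.
    """
    directory = Path(directory)
    ann_path = directory / "annotations.tsv"
    lin_path = directory / "lineages.tsv"
    markers_dir = directory / "markers"
    proteome_dir = directory / "proteome"
    for p in (ann_path, lin_path, markers_dir, proteome_dir):
        if not p.exists():
            raise LayoutError(f"missing mandatory cohort entry: {p}")

    ann = pd.read_csv(ann_path, sep="\t", dtype=str)
    required = {"genome_id", "gene_label", "copy_id", "sequence_id"}
    if set(ann.columns) < required:
        raise LayoutError(f"annotations.tsv missing columns {required - set(ann.columns)}")
    lin = pd.read_csv(lin_path, sep="\t", dtype=str)
    lineage_of = dict(zip(lin["genome_id"], lin["lineage"]))

    genomes: dict[str, GenomeRecord] = {}
    for gid in sorted(lineage_of):
        rec = GenomeRecord(genome_id=gid, lineage=lineage_of[gid])
        marker_fa = markers_dir / f"{gid}.fna"
        prot_fa = proteome_dir / f"{gid}.faa"
        marker_seqs = dict(read_fasta(marker_fa)) if marker_fa.exists() else {}
        for sid, seq in marker_seqs.items():
            validate_alphabet(seq, "nucleotide", sid, marker_fa)
        if prot_fa.exists():
            for sid, seq in read_fasta(prot_fa):
                validate_alphabet(seq, "protein", sid, prot_fa)
                rec.proteome[sid] = seq
        rows = ann[ann["genome_id"] == gid]
        annotated_ids = set()
        for _, row in rows.iterrows():
            sid = row["sequence_id"]
            annotated_ids.add(sid)
            if sid not in marker_seqs:
                raise LayoutError(
                    f"annotation names sequence {sid!r} absent from {marker_fa}"
                )
            rec.markers.setdefault(row["gene_label"], []).append(marker_seqs[sid])
        extra = set(marker_seqs) - annotated_ids
        for sid in sorted(extra):
            logger.warning("unannotated marker record %s in %s ignored", sid, marker_fa)
        genomes[gid] = rec
    return [genomes[g] for g in sorted(genomes)]


# ---------------------------------------------------------------------------
# Newick

def check_label(label: str) -> str:
    if not _LABEL_RE.match(label):
        raise ParseError(
            f"label {label!r} contains characters outside [A-Za-z0-9_.|-]; "
            "quoted Newick labels are not supported"
        )
    return label


def write_newick(tree: dendropy.Tree, path) -> None:
    """Serialize with >=10 significant digits on branch lengths."""
    for leaf in tree.leaf_node_iter():
        check_label(leaf.taxon.label)
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    )
    with open(path, "w") as fh:
        fh.write(text)


def read_newick(path) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises various parse error types
        raise ParseError(f"malformed Newick: {exc}", path) from exc
    return tree


def newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", suppress_rooting=True, real_value_format_specifier=".12g"
    ).strip()


# ---------------------------------------------------------------------------
# TSV helpers (fixed column order, header row, %.12g reals)

def write_tsv(df: pd.DataFrame, path, columns: list[str] | None = None) -> None:
    if columns is not None:
        df = df[columns]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
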