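"""Readers and writers for every external file format the pipeline touches.

All tabular formats are plain TSV with a header row; FASTA goes through
Bio.SeqIO with a strict validation layer on top (unique ids, non-empty,
alphabet-checked sequences). Coordinates are 1-based inclusive (GFF3
convention). Parsers never silently drop rows: skipped rows (e.g. non-CDS
GFF features) are logged with a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from magscreen._util import FormatError
from magscreen.taxonomy import normalize_lineage_string

logger = logging.getLogger(__name__)

# IUPAC alphabets; ambiguity codes and X/N placeholders are legal residues.
NT_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO")

LOCALIZATIONS = (
    "extracellular",
    "outer_membrane",
    "periplasmic",
    "cytoplasmic",
    "inner_membrane",
    "unknown",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    gene_index: int  # 0-based rank of the gene on its contig by start
    mag_id: str


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    labels: frozenset[str] = frozenset()


@dataclass(frozen=True)
class HomologyHit:
    query_gene_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    query_coverage: float
    subject_coverage: float


@dataclass(frozen=True)
class CoverageRecord:
    contig_id: str
    sample_id: str
    mean_depth: float
    mapped_reads: int
    contig_length: int


@dataclass
class OTUTable:
    """Sample x OTU count matrix with lineage strings and optional rep seqs."""

    counts: pd.DataFrame  # rows = samples, columns = OTU ids, integer counts
    lineages: dict[str, str]  # OTU id -> normalized rank-prefixed lineage
    rep_seqs: dict[str, SequenceRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [otu for otu in self.counts.columns if otu not in self.lineages]
        if missing:
            raise FormatError(f"OTUs without a lineage entry: {missing[:5]}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("OTU counts must be non-negative")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _check_alphabet(rec_id: str, seq: str, alphabet: str) -> None:
    allowed = NT_ALPHABET if alphabet == "nt" else AA_ALPHABET
    for pos, residue in enumerate(seq, start=1):
        if residue not in allowed:
            raise FormatError(
                f"illegal {alphabet} residue {residue!r} at position {pos} of record {rec_id!r}"
            )


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated, upper-cased records.

    ``alphabet`` is ``"nt"`` or ``"aa"``; duplicate ids, empty sequences and
    residues outside the IUPAC alphabet raise :class:`FormatError`.
    """
    if alphabet not in ("nt", "aa"):
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if not bio.id:
            raise FormatError(f"record without an id in {path}")
        if bio.id in seen:
            raise FormatError(f"duplicate sequence id {bio.id!r} in {path}")
        seen.add(bio.id)
        seq = str(bio.seq).replace(" ", "").replace("\t", "").upper()
        if not seq:
            raise FormatError(f"empty sequence for record {bio.id!r} in {path}")
        _check_alphabet(bio.id, seq, alphabet)
        desc = bio.description[len(bio.id):].strip() if bio.description.startswith(bio.id) else bio.description
        records.append(SequenceRecord(id=bio.id, seq=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio_records = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio_records)


# ---------------------------------------------------------------------------
# Gene calls (GFF3 subset, CDS rows only)
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gene_calls(path: str | Path, mag_assignment: Mapping[str, str]) -> list[GeneCall]:
    """Read CDS rows from a GFF3-subset file and assign per-contig gene ranks.

    Only ``CDS`` features are consumed (others are logged and skipped);
    ``gene_index`` is the 0-based rank by ascending start, ties broken by
    ascending end then lexicographic gene id.
    """
    raw: list[tuple[str, str, int, int, str]] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols
            if ftype != "CDS":
                n_skipped += 1
                logger.debug("%s:%d: skipping non-CDS feature %r", path, lineno, ftype)
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 1 or start > end:
                raise FormatError(f"{path}:{lineno}: invalid coordinates start={start} end={end}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
            gene_id = _parse_gff_attributes(attrs).get("ID")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: CDS row without an ID attribute")
            if contig not in mag_assignment:
                raise FormatError(f"{path}:{lineno}: contig {contig!r} has no MAG assignment")
            raw.append((contig, gene_id, start, end, strand))
    if n_skipped:
        logger.info("read_gene_calls(%s): skipped %d non-CDS rows", path, n_skipped)

    calls: list[GeneCall] = []
    seen_per_mag: dict[str, set[str]] = {}
    by_contig: dict[str, list[tuple[str, str, int, int, str]]] = {}
    for row in raw:
        by_contig.setdefault(row[0], []).append(row)
    for contig in sorted(by_contig):
        rows = sorted(by_contig[contig], key=lambda r: (r[2], r[3], r[1]))
        mag = mag_assignment[contig]
        seen = seen_per_mag.setdefault(mag, set())
        for idx, (contig_id, gene_id, start, end, strand) in enumerate(rows):
            if gene_id in seen:
                raise FormatError(f"duplicate gene id {gene_id!r} within MAG {mag!r}")
            seen.add(gene_id)
            calls.append(GeneCall(gene_id, contig_id, start, end, strand, idx, mag))
    return calls


def write_gene_calls(calls: Iterable[GeneCall], path: str | Path, source: str = "magscreen") -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for c in sorted(calls, key=lambda c: (c.contig_id, c.start, c.end, c.gene_id)):
            fh.write(
                f"{c.contig_id}\t{source}\tCDS\t{c.start}\t{c.end}\t.\t{c.strand}\t0\tID={c.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Annotations (gene_id -> namespaced function labels)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a TSV annotation table (gene_id, comma-joined namespaced labels)."""
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "labels"]:
            raise FormatError(f"{path}: expected header 'gene_id\\tlabels'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            gene_id, labels_s = cols
            labels = set()
            for label in labels_s.split(","):
                label = label.strip()
                if not label:
                    continue
                if ":" not in label:
                    raise FormatError(
                        f"{path}:{lineno}: label {label!r} lacks a namespace prefix (e.g. 'KO:')"
                    )
                labels.add(label)
            records.append(AnnotationRecord(gene_id=gene_id, labels=frozenset(labels)))
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tlabels\n")
        for rec in sorted(records, key=lambda r: r.gene_id):
            fh.write(f"{rec.gene_id}\t{','.join(sorted(rec.labels))}\n")


def annotation_map(records: Iterable[AnnotationRecord]) -> dict[str, frozenset[str]]:
    return {rec.gene_id: rec.labels for rec in records}


# ---------------------------------------------------------------------------
# Localization labels
# ---------------------------------------------------------------------------

def read_localization(path: str | Path) -> dict[str, str]:
    """Read a TSV of per-gene subcellular localization labels."""
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["gene_id", "localization"]:
            raise FormatError(f"{path}: expected header 'gene_id\\tlocalization'")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, label = line.split("\t")[:2]
            if label not in LOCALIZATIONS:
                raise FormatError(
                    f"{path}:{lineno}: unknown localization {label!r}; allowed: {', '.join(LOCALIZATIONS)}"
                )
            out[gene_id] = label
    return out


def write_localization(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tlocalization\n")
        for gene_id in sorted(labels):
            fh.write(f"{gene_id}\t{labels[gene_id]}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (12-column outfmt 6)
# ---------------------------------------------------------------------------

def read_blast_tab(
    path: str | Path,
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
) -> list[HomologyHit]:
    """Read 12-column tabular homology hits and compute coverages.

    Query/subject coverage is ``100 * aligned_span / sequence_length`` with
    coordinates normalized so start <= end. Extra trailing columns are
    ignored with a warning; unknown ids in the length maps are errors.
    """
    hits: list[HomologyHit] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            if len(cols) > 12 and not warned_extra:
                logger.warning("%s: more than 12 columns; extras ignored", path)
                warned_extra = True
            query, subject = cols[0], cols[1]
            try:
                pident = float(cols[2])
                length = int(cols[3])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            if query not in query_lengths:
                raise FormatError(f"{path}:{lineno}: unknown query id {query!r}")
            if subject not in subject_lengths:
                raise FormatError(f"{path}:{lineno}: unknown subject id {subject!r}")
            if not (0.0 <= pident <= 100.0) or evalue < 0:
                raise FormatError(f"{path}:{lineno}: field out of range")
            qlo, qhi = min(qstart, qend), max(qstart, qend)
            slo, shi = min(sstart, send), max(sstart, send)
            qcov = 100.0 * (qhi - qlo + 1) / query_lengths[query]
            scov = 100.0 * (shi - slo + 1) / subject_lengths[subject]
            hits.append(
                HomologyHit(
                    query_gene_id=query,
                    subject_id=subject,
                    percent_identity=pident,
                    alignment_length=length,
                    evalue=evalue,
                    bitscore=bitscore,
                    query_coverage=qcov,
                    subject_coverage=scov,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Coverage table
# ---------------------------------------------------------------------------

_COVERAGE_COLS = ["contig_id", "sample_id", "mean_depth", "mapped_reads", "contig_length"]


def read_coverage(path: str | Path) -> list[CoverageRecord]:
    """Read the per-contig per-sample coverage table."""
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "sample_id": str})
    if list(df.columns)[: len(_COVERAGE_COLS)] != _COVERAGE_COLS:
        raise FormatError(f"{path}: expected columns {_COVERAGE_COLS}")
    records = []
    for row in df.itertuples(index=False):
        if row.contig_length <= 0:
            raise FormatError(f"{path}: contig {row.contig_id!r} has non-positive length")
        if row.mean_depth < 0 or row.mapped_reads < 0:
            raise FormatError(f"{path}: negative coverage for contig {row.contig_id!r}")
        records.append(
            CoverageRecord(
                contig_id=str(row.contig_id),
                sample_id=str(row.sample_id),
                mean_depth=float(row.mean_depth),
                mapped_reads=int(row.mapped_reads),
                contig_length=int(row.contig_length),
            )
        )
    return records


def write_coverage(records: Iterable[CoverageRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_COVERAGE_COLS) + "\n")
        for r in sorted(records, key=lambda r: (r.sample_id, r.contig_id)):
            fh.write(f"{r.contig_id}\t{r.sample_id}\t{r.mean_depth!r}\t{r.mapped_reads}\t{r.contig_length}\n")


# ---------------------------------------------------------------------------
# OTU table
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, lineage_column: str = "taxonomy") -> OTUTable:
    """Read a TSV OTU table: first column OTU ids, one column per sample,
    plus a lineage column normalized to six rank prefixes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if lineage_column not in df.columns:
        raise FormatError(f"{path}: missing lineage column {lineage_column!r}")
    otu_col = df.columns[0]
    sample_cols = [c for c in df.columns if c not in (otu_col, lineage_column)]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    lineages: dict[str, str] = {}
    data: dict[str, list[int]] = {}
    otu_ids = list(df[otu_col])
    if len(set(otu_ids)) != len(otu_ids):
        raise FormatError(f"{path}: duplicate OTU ids")
    for _, row in df.iterrows():
        otu = row[otu_col]
        lineages[otu] = normalize_lineage_string(row[lineage_column] or "")
        counts = []
        for c in sample_cols:
            raw = row[c]
            try:
                val = float(raw)
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: non-numeric count {raw!r} for OTU {otu!r}") from exc
            if val < 0 or val != int(val):
                raise FormatError(f"{path}: count {raw!r} for OTU {otu!r} is negative or fractional")
            counts.append(int(val))
        data[otu] = counts
    counts_df = pd.DataFrame(data, index=sample_cols).astype(int)
    counts_df.index.name = "sample_id"
    return OTUTable(counts=counts_df, lineages=lineages)


def write_otu_table(table: OTUTable, path: str | Path, lineage_column: str = "taxonomy") -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("otu_id\t" + "\t".join(table.sample_ids) + f"\t{lineage_column}\n")
        for otu in table.otu_ids:
            counts = "\t".join(str(int(table.counts.at[s, otu])) for s in table.sample_ids)
            fh.write(f"{otu}\t{counts}\t{table.lineages[otu]}\n")
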