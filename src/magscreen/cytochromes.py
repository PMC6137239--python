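"""Multiheme c-type cytochrome detection by heme-binding motif counting.

c-type cytochromes bind heme covalently at CXXCH motifs. A protein is
called multiheme when it carries at least ``min_hemes_multiheme`` such
motifs (default 3, which excludes mono- and di-heme housekeeping
cytochromes). The subcellular localization label is consumed as input from
an upstream predictor, never inferred here; extracellular and periplasmic
multiheme cytochromes are the ones that matter for porin-cytochrome EET
conduits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from magscreen.io_formats import AA_ALPHABET, LOCALIZATIONS, GeneCall, SequenceRecord


@dataclass(frozen=True)
class MotifSpec:
    """Heme-binding motif definition: C x{gap} C H.

    The canonical motif has exactly two intervening residues; CX3CH/CX4CH
    variants can be enabled by widening ``gap_max``.
    """

    gap_min: int = 2
    gap_max: int = 2
    min_hemes_multiheme: int = 3

    def __post_init__(self) -> None:
        if self.gap_min < 0 or self.gap_min > self.gap_max:
            raise ValueError(f"invalid gap range [{self.gap_min}, {self.gap_max}]")
        if self.min_hemes_multiheme < 1:
            raise ValueError("min_hemes_multiheme must be >= 1")


DEFAULT_MOTIF_SPEC = MotifSpec()


@dataclass(frozen=True)
class CytochromeRecord:
    gene_id: str
    heme_count: int
    is_multiheme: bool
    localization: str


def count_heme_motifs(seq: str, spec: MotifSpec = DEFAULT_MOTIF_SPEC) -> int:
    """Number of distinct start positions matching C,x{gap},C,H.

    Overlapping matches are all counted; a start position matching at more
    than one gap width within the configured range counts once.
    """
    if not seq:
        raise ValueError("empty amino-acid sequence")
    seq = seq.upper()
    for pos, residue in enumerate(seq, start=1):
        if residue not in AA_ALPHABET:
            raise ValueError(f"illegal amino-acid residue {residue!r} at position {pos}")
    count = 0
    n = len(seq)
    for i in range(n):
        if seq[i] != "C":
            continue
        for gap in range(spec.gap_min, spec.gap_max + 1):
            j = i + 1 + gap  # second cysteine
            if j + 1 < n and seq[j] == "C" and seq[j + 1] == "H":
                count += 1
                break
    return count


def classify_cytochrome(
    gene: GeneCall,
    seq: SequenceRecord,
    localization_label: str,
    spec: MotifSpec = DEFAULT_MOTIF_SPEC,
) -> CytochromeRecord:
    """Attach heme count, multiheme flag and localization to a gene."""
    if gene.gene_id != seq.id:
        raise ValueError(f"sequence {seq.id!r} does not correspond to gene {gene.gene_id!r}")
    if localization_label not in LOCALIZATIONS:
        raise ValueError(
            f"unknown localization {localization_label!r}; allowed: {', '.join(LOCALIZATIONS)}"
        )
    hemes = count_heme_motifs(seq.seq, spec)
    return CytochromeRecord(
        gene_id=gene.gene_id,
        heme_count=hemes,
        is_multiheme=hemes >= spec.min_hemes_multiheme,
        localization=localization_label,
    )


def scan_cytochromes(
    genes: Iterable[GeneCall],
    proteins: Mapping[str, SequenceRecord],
    localizations: Mapping[str, str],
    spec: MotifSpec = DEFAULT_MOTIF_SPEC,
) -> list[CytochromeRecord]:
    """Classify every gene that has a protein sequence.

    Genes without a localization label are treated as "unknown".
    """
    records = []
    for gene in genes:
        seq = proteins.get(gene.gene_id)
        if seq is None:
            continue
        label = localizations.get(gene.gene_id, "unknown")
        records.append(classify_cytochrome(gene, seq, label, spec))
    return records


def write_cytochromes(records: Iterable[CytochromeRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\theme_count\tis_multiheme\tlocalization\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            fh.write(f"{r.gene_id}\t{r.heme_count}\t{str(r.is_multiheme).lower()}\t{r.localization}\n")
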