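"""Synthetic microbial community generator with planted ground truth.

Generates a complete input dataset for the screening pipeline — contigs,
proteins, gene calls, functional annotations, localization labels, homology
hits, per-contig per-sample coverage, MAG 16S genes, and an amplicon OTU
table — together with a truth manifest stating, for every MAG, the EET
category, pathway statuses, phototrophy class, per-sample abundant flag,
lineage, and OTU link the pipeline is expected to recover.

What the generator emulates: the statistical structure the screen assumes —
porin-cytochrome gene clusters at operon scale, heme-motif-bearing
multiheme cytochromes with localization labels, complete/partial pathway
gene complements, log-normally noisy coverage, and 16S representatives
diverged from the genomic copy by independent per-site substitutions
(Jukes-Cantor style, so the expected identity is analytic: 1 - rate).
What it does not emulate: real gene sequences (protein backgrounds are
random with cysteine down-weighted), assembly/binning artifacts, chimeras,
or strain heterogeneity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from magscreen import io_formats
from magscreen.carbon_fixation import load_pathway_definitions
from magscreen.cytochromes import DEFAULT_MOTIF_SPEC, MotifSpec, count_heme_motifs
from magscreen.io_formats import (
    AnnotationRecord,
    CoverageRecord,
    GeneCall,
    OTUTable,
    SequenceRecord,
)
from magscreen.taxonomy import normalize_lineage_string

EET_PLANTS = (
    "none",
    "geobacter_pcc",
    "geobacter_pcc_partial",
    "pcc_like",
    "mto_like",
    "model_feob_homolog",
)
PHOTOTROPHY_PLANTS = ("none", "oxygenic", "anoxygenic_typeI", "anoxygenic_typeII")

# Amino-acid background: uniform with C down-weighted so spurious CXXCH
# motifs are rare but present; H kept at normal weight.
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_WEIGHTS = np.ones(20)
_AA_WEIGHTS[list("ACDEFGHIKLMNPQRSTVWY").index("C")] = 0.3
_AA_WEIGHTS /= _AA_WEIGHTS.sum()
_NT = np.array(list("ACGT"))

#: The key-marker role dropped from each pathway to make a "partial" plant.
#: For rTCA the whole citrate-cleavage slot is dropped, exercising the
#: conservative rule (no aclAB and no citryl-CoA route).
PARTIAL_DROP_ROLES = {
    "CBB": ("prk",),
    "rTCA": ("aclA", "aclB", "ccs", "ccl"),
    "WL": ("codh",),
    "3HP": ("mcr",),
}

_PHOTO_PLANT_ROLES = {
    "oxygenic": ("psII", "psI"),
    "anoxygenic_typeII": ("pufL", "pufM", "puhA"),
    "anoxygenic_typeI": ("typeI_rc",),
}

PORIN_LABEL = "product:outer membrane porin"


@dataclass
class MagPlant:
    """What to plant in one synthetic MAG."""

    mag_id: str
    eet: str = "none"
    pathways: dict[str, str] = field(default_factory=dict)  # name -> complete|partial
    phototrophy: str = "none"
    coverage_levels: tuple[float, ...] = (10.0,)
    has_16s: bool = False
    lineage: str = ""
    n_filler_genes: int = 25
    decoy_orphan_porin: bool = False
    decoy_cytoplasmic_ccyt: bool = False
    decoy_subthreshold_ccyt: bool = False  # periplasmic 2-heme protein near a porin


@dataclass
class CommunityConfig:
    n_mags: int
    n_samples: int
    seed: int
    plants: list[MagPlant]
    mutation_rate: float = 0.0
    n_background_otus: int = 10
    coverage_sigma: float = 0.0  # log-normal sigma on contig depths
    window: int = 5
    read_length: int = 100
    gene_length_nt: int = 300
    gene_gap_nt: int = 50
    rrna_length: int = 1200
    motif_spec: MotifSpec = field(default_factory=lambda: DEFAULT_MOTIF_SPEC)

    def validate(self) -> None:
        if len(self.plants) != self.n_mags:
            raise ValueError(f"plant spec list length {len(self.plants)} != n_mags {self.n_mags}")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError(f"mutation rate must be in [0, 1], got {self.mutation_rate}")
        ids = [p.mag_id for p in self.plants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate mag_id in plant specs")
        for plant in self.plants:
            if plant.eet not in EET_PLANTS:
                raise ValueError(f"unknown eet plant {plant.eet!r}")
            if plant.phototrophy not in PHOTOTROPHY_PLANTS:
                raise ValueError(f"unknown phototrophy plant {plant.phototrophy!r}")
            if len(plant.coverage_levels) != self.n_samples:
                raise ValueError(
                    f"{plant.mag_id}: {len(plant.coverage_levels)} coverage levels for "
                    f"{self.n_samples} samples"
                )
            if any(level <= 0 for level in plant.coverage_levels):
                raise ValueError(f"{plant.mag_id}: coverage levels must be positive")
            for name, status in plant.pathways.items():
                if name not in PARTIAL_DROP_ROLES:
                    raise ValueError(f"{plant.mag_id}: unknown pathway {name!r}")
                if status not in ("complete", "partial"):
                    raise ValueError(f"{plant.mag_id}: pathway status {status!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class TruthManifest:
    """Expected downstream calls, derivable deterministically from the config."""

    mags: dict[str, dict]
    background_otus: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {"mags": self.mags, "background_otus": self.background_otus},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        raw = json.loads(text)
        return cls(mags=raw["mags"], background_otus=raw["background_otus"])


# ---------------------------------------------------------------------------
# Sequence construction helpers
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_WEIGHTS))


def _scrub_motifs(seq: str, spec: MotifSpec, keep: int = 1) -> str:
    """Break heme motifs beyond ``keep`` by swapping the terminal H for K."""
    chars = list(seq)
    found = 0
    n = len(chars)
    for i in range(n):
        if chars[i] != "C":
            continue
        for gap in range(spec.gap_min, spec.gap_max + 1):
            j = i + 1 + gap
            if j + 1 < n and chars[j] == "C" and chars[j + 1] == "H":
                found += 1
                if found > keep:
                    chars[j + 1] = "K"
                break
    return "".join(chars)


def _protein_with_motifs(rng: np.random.Generator, length: int, n_motifs: int, spec: MotifSpec) -> str:
    """A protein carrying exactly ``n_motifs`` heme-binding motifs."""
    seq = list(_scrub_motifs(_random_protein(rng, length), spec, keep=0))
    if n_motifs:
        positions = np.linspace(3, length - 8, n_motifs).astype(int)
        gap = spec.gap_min
        for p in positions:
            seq[p] = "C"
            for k in range(1, gap + 1):
                if seq[p + k] in ("C", "H"):
                    seq[p + k] = "A"
            seq[p + gap + 1] = "C"
            seq[p + gap + 2] = "H"
            if p + gap + 3 < length and seq[p + gap + 3] == "H":
                seq[p + gap + 3] = "A"  # avoid accidental extra motif endings
    out = "".join(seq)
    got = count_heme_motifs(out, spec)
    if got != n_motifs:  # insertion collisions are possible in principle
        out = _scrub_motifs(out, spec, keep=n_motifs)
        got = count_heme_motifs(out, spec)
    assert got == n_motifs, f"motif planting failed: wanted {n_motifs}, got {got}"
    return out


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def _mutate_jc(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Independent per-site substitution; a hit site changes to another base."""
    if rate == 0.0:
        return seq
    chars = np.array(list(seq))
    hits = rng.random(len(chars)) < rate
    for i in np.flatnonzero(hits):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Per-MAG gene content
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    gene_id: str
    protein: str
    labels: set[str] = field(default_factory=set)
    localization: str = "cytoplasmic"


def _pathway_labels(name: str, status: str) -> list[set[str]]:
    """One label set per planted gene for a pathway with the given status."""
    definitions, _ = load_pathway_definitions()
    definition = definitions[name]
    drop = set(PARTIAL_DROP_ROLES[name]) if status == "partial" else set()
    label_sets = []
    for role in definition.roles:
        if role.role_id in drop:
            continue
        # rTCA: plant only the aclAB citrate-cleavage route, not both.
        if name == "rTCA" and role.role_id in ("ccs", "ccl"):
            continue
        label_sets.append({sorted(role.labels)[0]})
    return label_sets


def _photo_labels(phototrophy: str) -> list[set[str]]:
    if phototrophy == "none":
        return []
    _, photo = load_pathway_definitions()
    return [{sorted(photo.role_labels[r])[0]} for r in _PHOTO_PLANT_ROLES[phototrophy]]


def _build_mag_genes(
    plant: MagPlant, config: CommunityConfig, rng: np.random.Generator
) -> tuple[list[_Gene], list[_Gene], list[tuple[str, str]]]:
    """Gene lists for the MAG's main contig and decoy contig, plus BLAST rows.

    Returns (main contig genes in order, decoy contig genes, homology rows
    as (gene_id, subject_component_id)).
    """
    spec = config.motif_spec
    mid = plant.mag_id
    genes: list[_Gene] = []
    blast_rows: list[tuple[str, str]] = []
    n = 0

    def new_gene(protein: str, labels: set[str] | None = None, loc: str = "cytoplasmic") -> _Gene:
        nonlocal n
        n += 1
        return _Gene(f"{mid}_g{n:03d}", protein, labels or set(), loc)

    def filler() -> _Gene:
        return new_gene(_scrub_motifs(_random_protein(rng, int(rng.integers(150, 260))), spec, keep=1))

    multi = spec.min_hemes_multiheme

    # Leading filler so planted clusters are not at the contig edge.
    genes.extend(filler() for _ in range(3))

    if plant.eet in ("pcc_like", "mto_like"):
        porin = new_gene(_scrub_motifs(_random_protein(rng, 300), spec, keep=0),
                         {PORIN_LABEL}, "outer_membrane")
        peri = new_gene(_protein_with_motifs(rng, 280, multi + 5, spec), set(), "periplasmic")
        genes.extend([porin, filler(), peri])
        if plant.eet == "pcc_like":
            extra = new_gene(_protein_with_motifs(rng, 330, multi + 7, spec), set(), "extracellular")
            genes.append(extra)
    elif plant.eet in ("geobacter_pcc", "geobacter_pcc_partial"):
        porin = new_gene(_scrub_motifs(_random_protein(rng, 320), spec, keep=0),
                         {PORIN_LABEL}, "outer_membrane")
        peri = new_gene(_protein_with_motifs(rng, 280, multi + 5, spec), set(), "periplasmic")
        extra = new_gene(_protein_with_motifs(rng, 350, multi + 9, spec), set(), "extracellular")
        genes.extend([porin, peri, extra])
        blast_rows += [
            (porin.gene_id, "gpcc_porin_ombB"),
            (peri.gene_id, "gpcc_periplasmic_omaB"),
            (extra.gene_id, "gpcc_extracellular_omcB"),
        ]
        if plant.eet == "geobacter_pcc":
            gsu = new_gene(_protein_with_motifs(rng, 240, multi + 2, spec), set(), "periplasmic")
            genes.append(gsu)
            blast_rows.append((gsu.gene_id, "gpcc_periplasmic_gsu1999"))
    elif plant.eet == "model_feob_homolog":
        fused = new_gene(_protein_with_motifs(rng, 290, 1, spec), set(), "outer_membrane")
        genes.append(fused)
        blast_rows.append((fused.gene_id, "cyc2_fused"))

    genes.append(filler())

    for name in sorted(plant.pathways):
        for labels in _pathway_labels(name, plant.pathways[name]):
            genes.append(new_gene(_scrub_motifs(_random_protein(rng, 200), spec, keep=0), labels))
    for labels in _photo_labels(plant.phototrophy):
        genes.append(new_gene(_scrub_motifs(_random_protein(rng, 200), spec, keep=0), labels))

    if plant.decoy_subthreshold_ccyt:
        # Near-boundary negative: a porin next to a BELOW-threshold cytochrome.
        porin = new_gene(_scrub_motifs(_random_protein(rng, 300), spec, keep=0),
                         {PORIN_LABEL}, "outer_membrane")
        weak = new_gene(_protein_with_motifs(rng, 250, multi - 1, spec), set(), "periplasmic")
        genes.extend([porin, weak])

    while len(genes) < plant.n_filler_genes:
        genes.append(filler())

    # Decoys live on a separate contig so they can never join a real cluster.
    decoy_genes: list[_Gene] = []
    if plant.decoy_orphan_porin:
        decoy_genes.append(
            new_gene(_scrub_motifs(_random_protein(rng, 310), spec, keep=0),
                     {PORIN_LABEL}, "outer_membrane")
        )
        decoy_genes.append(filler())
    if plant.decoy_cytoplasmic_ccyt:
        decoy_genes.append(new_gene(_protein_with_motifs(rng, 260, multi + 4, spec), set(), "cytoplasmic"))
        decoy_genes.append(filler())

    return genes, decoy_genes, blast_rows


# ---------------------------------------------------------------------------
# Expected calls (the planted truth)
# ---------------------------------------------------------------------------

_EXPECTED_EET = {
    "none": ("none", None),
    "geobacter_pcc": ("geobacter_pcc", "complete"),
    "geobacter_pcc_partial": ("geobacter_pcc", "partial"),
    "pcc_like": ("pcc_like", "complete"),
    "mto_like": ("mto_like", "partial"),
    "model_feob_homolog": ("cyc2_homolog", "complete"),
}


def _expected_trophic(plant: MagPlant) -> str:
    has_eet = plant.eet != "none"
    has_cfix = any(s == "complete" for s in plant.pathways.values())
    if has_eet and has_cfix:
        return "eet_and_cfix"
    if has_eet:
        return "eet_only"
    if has_cfix and plant.phototrophy != "none":
        return "phototroph_cfix"
    if has_cfix:
        return "cfix_only"
    return "none"


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_otu_table(
    config: CommunityConfig,
    mag_16s: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[OTUTable, list[str]]:
    """OTU table + representative sequences from the MAG 16S genes.

    MAGs with a 16S gene get an OTU whose representative is the genomic copy
    diverged by the configured per-site substitution rate; background OTUs
    (random sequences, unrelated lineages) fill out the table. Counts are
    Poisson around the MAG's mean coverage level (x20 reads), background
    OTUs around 30.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if mag_16s is None:
        mag_16s = {
            p.mag_id: _random_nt(rng, config.rrna_length)
            for p in config.plants
            if p.has_16s
        }
    otu_counts: dict[str, list[int]] = {}
    lineages: dict[str, str] = {}
    rep_seqs: dict[str, SequenceRecord] = {}
    level_by_mag = {p.mag_id: p.coverage_levels for p in config.plants}
    for mag_id in sorted(mag_16s):
        otu = f"OTU_{mag_id}"
        rep = _mutate_jc(rng, mag_16s[mag_id], config.mutation_rate)
        rep_seqs[otu] = SequenceRecord(id=otu, seq=rep)
        plant = next(p for p in config.plants if p.mag_id == mag_id)
        lineages[otu] = plant.lineage or "k__Bacteria"
        otu_counts[otu] = [
            int(rng.poisson(20.0 * level)) + 1 for level in level_by_mag[mag_id]
        ]
    background = []
    for i in range(config.n_background_otus):
        otu = f"OTU_bg{i:03d}"
        background.append(otu)
        rep_seqs[otu] = SequenceRecord(id=otu, seq=_random_nt(rng, config.rrna_length))
        lineages[otu] = f"k__Bacteria;p__bgp{i:03d};c__bgc{i:03d};o__bgo{i:03d};f__bgf{i:03d}"
        otu_counts[otu] = [int(rng.poisson(30.0)) + 1 for _ in range(config.n_samples)]

    counts = pd.DataFrame(otu_counts, index=config.sample_ids).astype(int)
    counts.index.name = "sample_id"
    table = OTUTable(
        counts=counts,
        lineages={k: normalize_lineage_string(v) for k, v in lineages.items()},
        rep_seqs=rep_seqs,
    )
    return table, background


def generate_community(config: CommunityConfig, outdir: str | Path) -> TruthManifest:
    """Write the full synthetic dataset to ``outdir`` and return the manifest.

    The same config and seed produce byte-identical files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    contigs: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    gene_calls: list[GeneCall] = []
    annotations: list[AnnotationRecord] = []
    localizations: dict[str, str] = {}
    contig2mag: dict[str, str] = {}
    coverage: list[CoverageRecord] = []
    blast_lines: list[str] = []
    mag_16s: dict[str, str] = {}
    gene_lineages: list[tuple[str, str, str]] = []
    placements: list[tuple[str, str]] = []
    manifest_mags: dict[str, dict] = {}

    subject_lengths = _reference_lengths()

    for plant in config.plants:
        main_genes, decoy_genes, blast_rows = _build_mag_genes(plant, config, rng)
        contig_specs = [(f"{plant.mag_id}_c1", main_genes)]
        if decoy_genes:
            contig_specs.append((f"{plant.mag_id}_c2", decoy_genes))

        for contig_id, genes in contig_specs:
            contig2mag[contig_id] = plant.mag_id
            contig_len = len(genes) * (config.gene_length_nt + config.gene_gap_nt)
            contigs.append(SequenceRecord(id=contig_id, seq=_random_nt(rng, contig_len)))
            for idx, gene in enumerate(genes):
                start = idx * (config.gene_length_nt + config.gene_gap_nt) + 1
                end = start + config.gene_length_nt - 1
                gene_calls.append(
                    GeneCall(gene.gene_id, contig_id, start, end, "+", idx, plant.mag_id)
                )
                proteins.append(SequenceRecord(id=gene.gene_id, seq=gene.protein))
                annotations.append(AnnotationRecord(gene.gene_id, frozenset(gene.labels)))
                localizations[gene.gene_id] = gene.localization
            for sample_i, sample in enumerate(config.sample_ids):
                level = plant.coverage_levels[sample_i]
                depth = level
                if config.coverage_sigma > 0:
                    depth = level * float(
                        np.exp(rng.normal(0.0, config.coverage_sigma))
                    )
                reads = max(1, round(depth * contig_len / config.read_length))
                coverage.append(CoverageRecord(contig_id, sample, depth, reads, contig_len))

        for gene_id, subject in blast_rows:
            qlen = len(next(p.seq for p in proteins if p.id == gene_id))
            slen = subject_lengths[subject]
            alen = min(qlen, slen)
            blast_lines.append(
                f"{gene_id}\t{subject}\t65.0\t{alen}\t{alen // 3}\t0\t1\t{qlen}\t1\t{alen}\t1e-80\t420.0"
            )

        lineage = plant.lineage or f"k__Bacteria;p__Px;c__Cx;o__Ox;f__F_{plant.mag_id}"
        n_marker_genes = 20
        for k in range(n_marker_genes):
            gene_lineages.append((plant.mag_id, f"{plant.mag_id}_hk{k:02d}", lineage))
        placements.append((plant.mag_id, lineage))

        if plant.has_16s:
            mag_16s[plant.mag_id] = _random_nt(rng, config.rrna_length)

        category, completeness = _EXPECTED_EET[plant.eet]
        pathways = {
            name: plant.pathways.get(name, "absent")
            for name in ("CBB", "rTCA", "WL", "3HP")
        }
        manifest_mags[plant.mag_id] = {
            "eet_category": category,
            "eet_completeness": completeness,
            "pathways": pathways,
            "phototrophy": plant.phototrophy,
            "trophic": _expected_trophic(plant),
            "lineage": lineage,
            "has_16s": plant.has_16s,
            "otu": f"OTU_{plant.mag_id}" if plant.has_16s else None,
        }

    # Expected abundant flags from the generated coverage values themselves
    # (plain arithmetic on the emitted records, independent of the pipeline).
    totals: dict[str, int] = {}
    for rec in coverage:
        totals[rec.sample_id] = totals.get(rec.sample_id, 0) + rec.mapped_reads
    min_total = min(totals.values())
    norm: dict[tuple[str, str], float] = {}
    for plant in config.plants:
        for sample in config.sample_ids:
            recs = [
                r
                for r in coverage
                if r.sample_id == sample and contig2mag[r.contig_id] == plant.mag_id
            ]
            raw = sum(r.mean_depth * r.contig_length for r in recs) / sum(
                r.contig_length for r in recs
            )
            norm[(plant.mag_id, sample)] = raw * (min_total / totals[sample])
    for plant in config.plants:
        flags = {}
        for sample in config.sample_ids:
            mean = sum(norm[(p.mag_id, sample)] for p in config.plants) / config.n_mags
            flags[sample] = norm[(plant.mag_id, sample)] > mean
        manifest_mags[plant.mag_id]["abundant"] = flags

    otu_table, background = generate_otu_table(config, mag_16s, rng)
    manifest = TruthManifest(mags=manifest_mags, background_otus=background)

    io_formats.write_fasta(contigs, outdir / "contigs.fna")
    io_formats.write_fasta(proteins, outdir / "proteins.faa")
    io_formats.write_gene_calls(gene_calls, outdir / "genes.gff")
    io_formats.write_annotations(annotations, outdir / "annotations.tsv")
    io_formats.write_localization(localizations, outdir / "localization.tsv")
    io_formats.write_coverage(coverage, outdir / "coverage.tsv")
    with open(outdir / "contig2mag.tsv", "w", newline="\n") as fh:
        fh.write("contig_id\tmag_id\n")
        for contig in sorted(contig2mag):
            fh.write(f"{contig}\t{contig2mag[contig]}\n")
    with open(outdir / "blast_hits.tsv", "w", newline="\n") as fh:
        for line in blast_lines:
            fh.write(line + "\n")
    with open(outdir / "gene_lineages.tsv", "w", newline="\n") as fh:
        fh.write("mag_id\tgene_id\tlineage\n")
        for mag_id, gene_id, lineage in gene_lineages:
            fh.write(f"{mag_id}\t{gene_id}\t{lineage}\n")
    with open(outdir / "placements.tsv", "w", newline="\n") as fh:
        fh.write("mag_id\tlineage\n")
        for mag_id, lineage in placements:
            fh.write(f"{mag_id}\t{lineage}\n")
    io_formats.write_fasta(
        [SequenceRecord(id=m, seq=s) for m, s in sorted(mag_16s.items())],
        outdir / "mag_16s.fna",
    )
    io_formats.write_otu_table(otu_table, outdir / "otu_table.tsv")
    io_formats.write_fasta(
        [otu_table.rep_seqs[o] for o in sorted(otu_table.rep_seqs)],
        outdir / "otu_reps.fna",
    )
    with open(outdir / "manifest.json", "w", newline="\n") as fh:
        fh.write(manifest.to_json() + "\n")
    with open(outdir / "config.yaml", "w", newline="\n") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)
    return manifest


def _config_to_dict(config: CommunityConfig) -> dict:
    d = asdict(config)
    d["motif_spec"] = asdict(config.motif_spec)
    return d


def _reference_lengths() -> dict[str, int]:
    from magscreen.eet import reference_component_lengths

    return reference_component_lengths()


def load_manifest(path: str | Path) -> TruthManifest:
    return TruthManifest.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# The default study-conditions community
# ---------------------------------------------------------------------------

def default_community(seed: int = 20180907, mutation_rate: float = 0.0,
                      coverage_sigma: float = 0.0) -> CommunityConfig:
    """A 20-MAG, 3-sample community mirroring an Fe-cycling hot-spring screen.

    The composition covers every planted condition: complete and
    gsu1999-partial Geobacter-type conduits, pcc-like and mto-like clusters,
    a cyc2-type Fe(II)-oxidizer homolog, complete WL/CBB/rTCA and partial
    rTCA/3HP pathway complements, oxygenic and both anoxygenic phototroph
    classes, orphan-porin and cytoplasmic-cytochrome decoys, a sub-threshold
    near-boundary cytochrome, and a spread of coverage levels around the
    per-sample means.
    """
    P = MagPlant
    plants = [
        P("MAG01", eet="geobacter_pcc", coverage_levels=(42.0, 12.0, 6.0), has_16s=True,
          lineage="k__Bacteria;p__Chlorobi;c__Ignavibacteria;o__Ignavibacteriales;f__Ignavibacteriaceae"),
        P("MAG02", eet="geobacter_pcc_partial", coverage_levels=(25.0, 8.0, 5.0),
          lineage="k__Bacteria;p__Chlorobi;c__Ignavibacteria;o__Ignavibacteriales;f__Melioribacteraceae"),
        P("MAG03", eet="geobacter_pcc", pathways={"WL": "complete"}, coverage_levels=(18.0, 6.0, 30.0),
          lineage="k__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__Deferrisomatales;f__Deferrisomataceae"),
        P("MAG04", eet="pcc_like", pathways={"rTCA": "complete"}, coverage_levels=(9.0, 28.0, 7.0),
          lineage="k__Bacteria;p__Nitrospirae;c__Nitrospira;o__Nitrospirales;f__Nitrospiraceae"),
        P("MAG05", eet="pcc_like", coverage_levels=(20.0, 5.0, 4.0),
          lineage="k__Bacteria;p__Acidobacteria;c__Holophagae;o__Holophagales;f__Holophagaceae"),
        P("MAG06", eet="pcc_like", coverage_levels=(4.0, 6.0, 40.0), has_16s=True,
          lineage="k__Bacteria;p__Calditrichaeota;c__Calditrichae;o__Calditrichales;f__Calditrichaceae"),
        P("MAG07", eet="pcc_like", pathways={"WL": "complete"}, coverage_levels=(6.0, 14.0, 5.0),
          lineage="k__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__Desulfarculales;f__Desulfarculaceae"),
        P("MAG08", eet="mto_like", coverage_levels=(5.0, 16.0, 6.0),
          lineage="k__Bacteria;p__Gemmatimonadetes;c__Gemmatimonadetes;o__Gemmatimonadales;f__Gemmatimonadaceae"),
        P("MAG09", eet="mto_like", pathways={"WL": "complete"}, coverage_levels=(30.0, 9.0, 4.0),
          has_16s=True,
          lineage="k__Bacteria;p__Nitrospirae;c__Nitrospira;o__Nitrospirales;f__Thermodesulfovibrionaceae"),
        P("MAG10", eet="model_feob_homolog", pathways={"CBB": "complete"},
          coverage_levels=(7.0, 22.0, 8.0), has_16s=True,
          lineage="k__Bacteria;p__Proteobacteria;c__Betaproteobacteria;o__Gallionellales;f__Gallionellaceae"),
        P("MAG11", pathways={"CBB": "complete"}, phototrophy="oxygenic",
          coverage_levels=(12.0, 7.0, 26.0), has_16s=True,
          lineage="k__Bacteria;p__Cyanobacteria;c__Cyanophyceae;o__Pseudanabaenales;f__Pseudanabaenaceae"),
        P("MAG12", pathways={"rTCA": "partial"}, phototrophy="anoxygenic_typeI",
          coverage_levels=(8.0, 5.0, 14.0), has_16s=True,
          lineage="k__Bacteria;p__Chlorobi;c__Chlorobia;o__Chlorobiales;f__Chlorobiaceae"),
        P("MAG13", pathways={"rTCA": "partial"}, phototrophy="anoxygenic_typeI",
          coverage_levels=(3.0, 4.0, 9.0),
          lineage="k__Bacteria;p__Chlorobi;c__Chlorobia;o__Chloroherpetales;f__Chloroherpetaceae"),
        P("MAG14", pathways={"3HP": "partial"}, phototrophy="anoxygenic_typeII",
          coverage_levels=(6.0, 10.0, 5.0), has_16s=True,
          lineage="k__Bacteria;p__Chloroflexi;c__Chloroflexia;o__Chloroflexales;f__Roseiflexaceae"),
        P("MAG15", pathways={"3HP": "partial"}, coverage_levels=(4.0, 3.0, 12.0),
          lineage="k__Bacteria;p__Chloroflexi;c__Dehalococcoidia;o__Dehalococcoidales;f__Dehalococcoidaceae"),
        P("MAG16", coverage_levels=(16.0, 11.0, 3.0), has_16s=True,
          lineage="k__Archaea;p__Crenarchaeota;c__Thermoprotei;o__Thermoproteales;f__Thermoproteaceae"),
        P("MAG17", decoy_orphan_porin=True, coverage_levels=(5.0, 4.0, 6.0), has_16s=True,
          lineage="k__Bacteria;p__Armatimonadetes;c__Chthonomonadetes;o__Chthonomonadales;f__Chthonomonadaceae"),
        P("MAG18", decoy_cytoplasmic_ccyt=True, coverage_levels=(3.0, 7.0, 5.0),
          lineage="k__Bacteria;p__Acidobacteria;c__Acidobacteriia;o__Acidobacteriales;f__Acidobacteriaceae"),
        P("MAG19", decoy_subthreshold_ccyt=True, coverage_levels=(4.0, 5.0, 3.0),
          lineage="k__Bacteria;p__Planctomycetes;c__Phycisphaerae;o__Phycisphaerales;f__Phycisphaeraceae"),
        P("MAG20", coverage_levels=(2.0, 3.0, 2.0),
          lineage="k__Bacteria;p__Bacteroidetes;c__Rhodothermia;o__Rhodothermales;f__Rhodothermaceae"),
    ]
    return CommunityConfig(
        n_mags=len(plants),
        n_samples=3,
        seed=seed,
        plants=plants,
        mutation_rate=mutation_rate,
        coverage_sigma=coverage_sigma,
        n_background_otus=10,
    )
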