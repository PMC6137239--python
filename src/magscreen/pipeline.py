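"""Pipeline orchestration: run every screening stage over one dataset.

The stages run in a fixed order — cytochrome scan, EET typing, CO2-fixation
and phototrophy screens, consensus taxonomy, abundance profiling and OTU
summarization, and 16S-OTU linking — each writing a TSV under the output
directory. A MANIFEST file lists the stages that completed, so a failed run
retains its partial outputs. Every number in the report files is
reproducible from the per-stage TSVs; fixed inputs and config give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from magscreen import abundance, carbon_fixation, cytochromes, eet, io_formats, linking, taxonomy
from magscreen._util import FormatError

logger = logging.getLogger(__name__)

DATASET_FILES = {
    "proteins": "proteins.faa",
    "genes": "genes.gff",
    "contig2mag": "contig2mag.tsv",
    "annotations": "annotations.tsv",
    "localization": "localization.tsv",
    "blast_hits": "blast_hits.tsv",
    "coverage": "coverage.tsv",
    "mag_16s": "mag_16s.fna",
    "otu_table": "otu_table.tsv",
    "otu_reps": "otu_reps.fna",
    "gene_lineages": "gene_lineages.tsv",
    "placements": "placements.tsv",
}


@dataclass
class PipelineConfig:
    dataset_dir: str
    outdir: str
    motif_gap_min: int = 2
    motif_gap_max: int = 2
    min_hemes_multiheme: int = 3
    max_evalue: float = 1e-5
    min_identity: float = 30.0
    min_query_coverage: float = 50.0
    window: int = 5
    min_support: float = 0.5
    link_threshold: float = 97.0
    link_min_length: int = 200
    otu_rank: str = "family"
    otu_threshold_percent: float = 1.0
    rank_top_n: int = 20
    reference_systems_path: str | None = None
    pathway_definitions_path: str | None = None

    def motif_spec(self) -> cytochromes.MotifSpec:
        return cytochromes.MotifSpec(self.motif_gap_min, self.motif_gap_max, self.min_hemes_multiheme)

    def hit_thresholds(self) -> eet.HitThresholds:
        return eet.HitThresholds(self.max_evalue, self.min_identity, self.min_query_coverage)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: pipeline config must be a key-value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "dataset_dir" not in raw or "outdir" not in raw:
            raise FormatError(f"{path}: config requires dataset_dir and outdir")
        return cls(**raw)


@dataclass
class PipelineResult:
    cytochrome_records: dict[str, list[cytochromes.CytochromeRecord]]
    eet_calls: dict[str, eet.EETCall]
    pathway_calls: dict[str, dict[str, carbon_fixation.PathwayCall]]
    photo_calls: dict[str, carbon_fixation.PhototrophyCall]
    trophic: dict[str, str]
    taxonomy: dict[str, taxonomy.ConsensusReport]
    profiles: list[abundance.AbundanceProfile]
    breakdowns: list[abundance.CategoryBreakdown]
    otu_summary: abundance.OTUSummary
    links: list[linking.LinkRecord]
    completed_stages: list[str] = field(default_factory=list)


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    return path


def _read_two_column(path: Path, expected_header: list[str]) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(expected_header)] != expected_header:
            raise FormatError(f"{path}: expected header {expected_header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            out[cols[0]] = cols[1]
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; writes per-stage TSVs, MANIFEST and run.log."""
    dataset = Path(config.dataset_dir)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    log_lines: list[str] = []
    with open(outdir / "MANIFEST", "w", newline="\n") as fh:
        fh.write("")

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def finish_stage(name: str) -> None:
        completed.append(name)
        with open(outdir / "MANIFEST", "w", newline="\n") as fh:
            fh.write("\n".join(completed) + "\n")

    try:
        # ---- load inputs -------------------------------------------------
        paths = {k: _require(dataset / v) for k, v in DATASET_FILES.items()}
        proteins = {r.id: r for r in io_formats.read_fasta(paths["proteins"], "aa")}
        contig2mag = _read_two_column(paths["contig2mag"], ["contig_id", "mag_id"])
        genes = io_formats.read_gene_calls(paths["genes"], contig2mag)
        annotations = io_formats.annotation_map(io_formats.read_annotations(paths["annotations"]))
        localizations = io_formats.read_localization(paths["localization"])
        coverage = io_formats.read_coverage(paths["coverage"])
        query_lengths = {gid: len(rec.seq) for gid, rec in proteins.items()}
        subject_lengths = eet.reference_component_lengths()
        hits = io_formats.read_blast_tab(paths["blast_hits"], query_lengths, subject_lengths)
        systems = eet.load_reference_systems(config.reference_systems_path)
        definitions, photo_def = carbon_fixation.load_pathway_definitions(
            config.pathway_definitions_path
        )
        mag_16s = io_formats.read_fasta(paths["mag_16s"], "nt")
        otu_table = io_formats.read_otu_table(paths["otu_table"])
        otu_reps = io_formats.read_fasta(paths["otu_reps"], "nt")
        log(f"loaded {len(genes)} genes in {len(set(contig2mag.values()))} MAGs, "
            f"{len(hits)} homology hits, {len(coverage)} coverage rows")
        finish_stage("load")

        genes_by_mag: dict[str, list[io_formats.GeneCall]] = {}
        for g in genes:
            genes_by_mag.setdefault(g.mag_id, []).append(g)
        mag_ids = sorted(genes_by_mag)

        # ---- cytochromes -------------------------------------------------
        spec = config.motif_spec()
        cyt_records = {
            mag: cytochromes.scan_cytochromes(genes_by_mag[mag], proteins, localizations, spec)
            for mag in mag_ids
        }
        cytochromes.write_cytochromes(
            [r for recs in cyt_records.values() for r in recs], outdir / "cytochromes.tsv"
        )
        n_multi = sum(r.is_multiheme for recs in cyt_records.values() for r in recs)
        log(f"cytochromes: {n_multi} multiheme c-type cytochromes")
        finish_stage("cytochromes")

        # ---- EET screening ----------------------------------------------
        filtered = eet.filter_homology_hits(hits, config.hit_thresholds())
        log(f"eet: {len(filtered)}/{len(hits)} homology hits pass thresholds")
        hits_by_mag: dict[str, list] = {mag: [] for mag in mag_ids}
        gene_to_mag = {g.gene_id: g.mag_id for g in genes}
        for hit in filtered:
            mag = gene_to_mag.get(hit.query_gene_id)
            if mag is not None:
                hits_by_mag[mag].append(hit)
        eet_calls: dict[str, eet.EETCall] = {}
        for mag in mag_ids:
            porins = eet.find_porin_genes(
                {g.gene_id: annotations.get(g.gene_id, frozenset()) for g in genes_by_mag[mag]},
                hits_by_mag[mag],
                systems,
            )
            clusters = eet.find_porin_cytochrome_clusters(
                genes_by_mag[mag], cyt_records[mag], porins, config.window
            )
            eet_calls[mag] = eet.classify_eet_system(
                mag, genes_by_mag[mag], clusters, hits_by_mag[mag], systems, config.window
            )
        eet.write_eet_calls(eet_calls.values(), outdir / "eet_calls.tsv")
        n_eet = sum(1 for c in eet_calls.values() if c.category != "none")
        log(f"eet: {n_eet}/{len(mag_ids)} MAGs with a putative EET system")
        finish_stage("eet")

        # ---- carbon fixation + phototrophy -------------------------------
        labels_by_mag = {
            mag: frozenset(
                label
                for g in genes_by_mag[mag]
                for label in annotations.get(g.gene_id, frozenset())
            )
            for mag in mag_ids
        }
        pathway_calls = {
            mag: carbon_fixation.screen_pathways(mag, labels_by_mag[mag], definitions)
            for mag in mag_ids
        }
        photo_calls = {
            mag: carbon_fixation.screen_phototrophy(mag, labels_by_mag[mag], photo_def)
            for mag in mag_ids
        }
        trophic = {
            mag: carbon_fixation.infer_trophic_category(
                eet_calls[mag], pathway_calls[mag].values(), photo_calls[mag]
            )
            for mag in mag_ids
        }
        carbon_fixation.write_pathway_calls(
            [c for calls in pathway_calls.values() for c in calls.values()],
            outdir / "pathway_calls.tsv",
        )
        carbon_fixation.write_phototrophy_calls(photo_calls.values(), outdir / "phototrophy.tsv")
        with open(outdir / "trophic.tsv", "w", newline="\n") as fh:
            fh.write("mag_id\ttrophic_category\n")
            for mag in mag_ids:
                fh.write(f"{mag}\t{trophic[mag]}\n")
        n_cfix = sum(
            1 for calls in pathway_calls.values() if any(c.status == "complete" for c in calls.values())
        )
        log(f"cfix: {n_cfix}/{len(mag_ids)} MAGs with a complete CO2-fixation pathway")
        finish_stage("carbon_fixation")

        # ---- consensus taxonomy ------------------------------------------
        lineage_rows: dict[str, list[taxonomy.Lineage]] = {}
        with open(paths["gene_lineages"]) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["mag_id", "gene_id", "lineage"]:
                raise FormatError(f"{paths['gene_lineages']}: expected mag_id/gene_id/lineage header")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                mag, _gene, lineage = line.split("\t")[:3]
                lineage_rows.setdefault(mag, []).append(taxonomy.Lineage.from_string(lineage))
        placements = {
            mag: taxonomy.Lineage.from_string(lin)
            for mag, lin in _read_two_column(paths["placements"], ["mag_id", "lineage"]).items()
        }
        tax_reports = {
            mag: taxonomy.consensus_taxonomy(
                lineage_rows.get(mag, [taxonomy.ROOT]),
                placements.get(mag, taxonomy.ROOT),
                config.min_support,
            )
            for mag in mag_ids
        }
        with open(outdir / "taxonomy.tsv", "w", newline="\n") as fh:
            fh.write("mag_id\tlineage\t" + "\t".join(f"support_{r}" for r in taxonomy.RANKS) + "\n")
            for mag in mag_ids:
                rep = tax_reports[mag]
                sup = "\t".join(f"{s:.3f}" for s in rep.support)
                fh.write(f"{mag}\t{rep.lineage.to_string()}\t{sup}\n")
        finish_stage("taxonomy")

        # ---- abundance ----------------------------------------------------
        profiles = abundance.flag_abundant(abundance.normalize_coverage(coverage, contig2mag))
        pathway_lists = {mag: list(calls.values()) for mag, calls in pathway_calls.items()}
        breakdowns = abundance.aggregate_category_fractions(
            profiles, eet_calls, pathway_lists, photo_calls
        )
        abundance.write_profiles(profiles, outdir / "abundance.tsv")
        abundance.write_breakdowns(breakdowns, outdir / "category_breakdown.tsv")
        samples = sorted({p.sample_id for p in profiles})
        for sample in samples:
            table = abundance.rank_abundance(
                [p for p in profiles if p.sample_id == sample],
                config.rank_top_n,
                eet_calls,
                pathway_lists,
            )
            with open(outdir / f"rank_abundance_{sample}.tsv", "w", newline="\n") as fh:
                fh.write(f"# mean_coverage\t{table.attrs['mean_coverage']:.6f}\n")
                table.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        n_abundant = sum(1 for p in profiles if p.abundant)
        log(f"abundance: {n_abundant} abundant MAG-sample pairs across {len(samples)} samples")
        finish_stage("abundance")

        # ---- OTU summary ----------------------------------------------------
        summary = abundance.summarize_otu_table(
            otu_table, config.otu_rank, config.otu_threshold_percent
        )
        with open(outdir / "otu_summary.tsv", "w", newline="\n") as fh:
            fh.write(
                f"# rank={summary.rank} threshold>{summary.threshold_percent}% "
                f"retained={summary.retained_count}/{summary.n_collapsed} "
                f"cumulative={summary.cumulative_percent}\n"
            )
            summary.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        log(
            f"otu: {summary.retained_count}/{summary.n_collapsed} taxa above "
            f"{summary.threshold_percent}%, cumulative {summary.cumulative_percent}%"
        )
        finish_stage("otu_summary")

        # ---- 16S linking ----------------------------------------------------
        links = linking.link_otus_to_mags(
            mag_16s, otu_reps, config.link_threshold, config.link_min_length
        )
        linking.write_links(links, outdir / "links.tsv")
        n_accepted = sum(1 for l in links if l.accepted)
        log(f"linking: {n_accepted} accepted OTU-MAG links")
        finish_stage("linking")
    finally:
        with open(outdir / "run.log", "w", newline="\n") as fh:
            fh.write("\n".join(log_lines) + "\n")

    return PipelineResult(
        cytochrome_records=cyt_records,
        eet_calls=eet_calls,
        pathway_calls=pathway_calls,
        photo_calls=photo_calls,
        trophic=trophic,
        taxonomy=tax_reports,
        profiles=profiles,
        breakdowns=breakdowns,
        otu_summary=summary,
        links=links,
        completed_stages=completed,
    )
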