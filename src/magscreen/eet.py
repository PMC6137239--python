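"""Typing of putative extracellular electron transfer (EET) systems per MAG.

Two routes of evidence are combined:

* homology to reference porin-cytochrome systems of model Fe(III) reducers
  (Geobacter pcc, Shewanella mtrABC) and Fe(II) oxidizers (Acidithiobacillus
  cyc2, Sideroxydans mtoABCD, Rhodobacter foxEZY, Rhodopseudomonas pioABC),
  from filtered protein homology hits whose genes co-locate in the genome;

* non-homologous porin-cytochrome gene clusters: an outer-membrane porin
  gene lying within a small gene-index window of multiheme c-type
  cytochromes. A cluster with both periplasmic and extracellular multiheme
  cytochromes is called "pcc-like"; one with periplasmic but no
  extracellular multiheme cytochrome is called "mto-like".

"mto-like" is explicitly a negative-evidence label: it records the absence
of an identified extracellular c-type cytochrome near the porin and may
simply represent an incomplete EET system (e.g. the extracellular
cytochrome failed to assemble or bin), not a distinct physiology.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from magscreen.cytochromes import CytochromeRecord
from magscreen.io_formats import GeneCall, HomologyHit, read_fasta

COMPONENT_ROLES = (
    "porin",
    "periplasmic_ccyt",
    "extracellular_ccyt",
    "inner_membrane_ccyt",
    "fused_cytochrome_porin",
)

#: Curated vocabulary of annotation labels that identify a putative
#: outer-membrane porin. Editable via `find_porin_genes(porin_labels=...)`.
DEFAULT_PORIN_LABELS = frozenset(
    {
        "product:outer membrane porin",
        "product:porin-cytochrome conduit porin",
        "pfam:PF13505",
    }
)

# Category ranks: homologous systems outrank the cluster-only categories.
_HOMOLOGOUS_CATEGORIES = (
    "geobacter_pcc",
    "shewanella_mtr",
    "cyc2_homolog",
    "mto_homolog",
    "fox_homolog",
    "pio_homolog",
)
CATEGORY_RANK: dict[str, int] = {"none": 0, "mto_like": 1, "pcc_like": 2}
CATEGORY_RANK.update({c: 3 for c in _HOMOLOGOUS_CATEGORIES})

_SYSTEM_CATEGORY = {
    "geobacter_pcc": "geobacter_pcc",
    "shewanella_mtr": "shewanella_mtr",
    "cyc2": "cyc2_homolog",
    "mto": "mto_homolog",
    "fox": "fox_homolog",
    "pio": "pio_homolog",
}


@dataclass(frozen=True)
class ReferenceComponent:
    component_id: str
    role: str
    required: bool = True


@dataclass(frozen=True)
class ReferenceSystem:
    name: str
    components: tuple[ReferenceComponent, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not any(c.required for c in self.components):
            raise ValueError(f"system {self.name!r} has no required component")


@dataclass(frozen=True)
class HitThresholds:
    max_evalue: float = 1e-5
    min_identity: float = 30.0
    min_query_coverage: float = 50.0

    def __post_init__(self) -> None:
        if self.max_evalue < 0 or not (0 <= self.min_identity <= 100) or not (
            0 <= self.min_query_coverage <= 100
        ):
            raise ValueError("hit thresholds out of range")


@dataclass(frozen=True)
class GeneCluster:
    mag_id: str
    contig_id: str
    porin_gene_id: str
    cytochromes: tuple[CytochromeRecord, ...]
    gene_ids: tuple[str, ...]
    span: int  # max pairwise gene_index gap among members


@dataclass(frozen=True)
class Evidence:
    gene_id: str
    role: str
    basis: str  # "homology" or "cluster"
    detail: str = ""


@dataclass(frozen=True)
class EETCall:
    mag_id: str
    category: str
    completeness: str | None  # "complete" | "partial"; None iff category == "none"
    evidence: tuple[Evidence, ...] = ()

    def __post_init__(self) -> None:
        if (self.category == "none") != (len(self.evidence) == 0):
            raise ValueError("category 'none' iff evidence empty")
        if (self.category == "none") != (self.completeness is None):
            raise ValueError("completeness defined exactly when category != 'none'")

    @property
    def rank(self) -> int:
        return CATEGORY_RANK[self.category]


def load_reference_systems(path: str | Path | None = None) -> list[ReferenceSystem]:
    """Load reference EET system definitions from structured text (YAML).

    The packaged default ships curated component lists; component ids are
    unique across systems.
    """
    if path is None:
        text = resources.files("magscreen").joinpath("data/eet_reference_systems.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    systems = []
    seen_ids: set[str] = set()
    for entry in raw["systems"]:
        comps = []
        for c in entry["components"]:
            if c["role"] not in COMPONENT_ROLES:
                raise ValueError(f"unknown component role {c['role']!r}")
            if c["component_id"] in seen_ids:
                raise ValueError(f"component id {c['component_id']!r} duplicated across systems")
            seen_ids.add(c["component_id"])
            comps.append(
                ReferenceComponent(
                    component_id=c["component_id"],
                    role=c["role"],
                    required=bool(c.get("required", True)),
                )
            )
        systems.append(
            ReferenceSystem(name=entry["name"], components=tuple(comps), source=entry.get("source", ""))
        )
    return systems


def reference_component_lengths(path: str | Path | None = None) -> dict[str, int]:
    """Lengths of the packaged reference component proteins (synthetic stand-ins)."""
    if path is None:
        with resources.as_file(
            resources.files("magscreen").joinpath("data/eet_reference_components_synthetic.faa")
        ) as p:
            records = read_fasta(p, "aa")
    else:
        records = read_fasta(path, "aa")
    return {r.id: len(r.seq) for r in records}


def filter_homology_hits(
    hits: Iterable[HomologyHit], thresholds: HitThresholds = HitThresholds()
) -> list[HomologyHit]:
    """Keep hits passing all thresholds, best hit per (query, subject).

    Best = higher bitscore, then lower e-value, then input order.
    """
    best: dict[tuple[str, str], tuple[float, float, int, HomologyHit]] = {}
    for order, hit in enumerate(hits):
        if hit.evalue > thresholds.max_evalue:
            continue
        if hit.percent_identity < thresholds.min_identity:
            continue
        if hit.query_coverage < thresholds.min_query_coverage:
            continue
        key = (hit.query_gene_id, hit.subject_id)
        rank = (-hit.bitscore, hit.evalue, order)
        if key not in best or rank < best[key][:3]:
            best[key] = (*rank, hit)
    kept = sorted(best.values(), key=lambda v: v[2])  # restore input order
    return [v[3] for v in kept]


def find_porin_genes(
    annotations: Mapping[str, frozenset[str]],
    filtered_hits: Iterable[HomologyHit],
    systems: Sequence[ReferenceSystem],
    porin_labels: frozenset[str] = DEFAULT_PORIN_LABELS,
) -> set[str]:
    """Genes identified as putative outer-membrane porins.

    A gene qualifies by annotation label (configurable vocabulary) or by a
    passing hit to any reference porin component.
    """
    porin_components = {
        c.component_id
        for s in systems
        for c in s.components
        if c.role in ("porin", "fused_cytochrome_porin")
    }
    porins = {g for g, labels in annotations.items() if labels & porin_labels}
    porins.update(h.query_gene_id for h in filtered_hits if h.subject_id in porin_components)
    return porins


def find_porin_cytochrome_clusters(
    genes: Sequence[GeneCall],
    cytochromes: Sequence[CytochromeRecord],
    porin_genes: Iterable[str],
    window: int = 5,
) -> list[GeneCluster]:
    """One cluster per porin with >= 1 multiheme cytochrome within ``window``.

    Distances are measured in gene-index units on the same contig; clusters
    are reported in (contig, gene_index) order.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    by_id = {g.gene_id: g for g in genes}
    if not by_id:
        return []
    mag_ids = {g.mag_id for g in genes}
    if len(mag_ids) != 1:
        raise ValueError(f"genes from more than one MAG: {sorted(mag_ids)}")
    mag_id = mag_ids.pop()
    cyt_by_id = {c.gene_id: c for c in cytochromes}
    for gid in cyt_by_id:
        if gid not in by_id:
            raise ValueError(f"cytochrome gene {gid!r} absent from MAG {mag_id!r}")
    porin_list = sorted(porin_genes)
    for gid in porin_list:
        if gid not in by_id:
            raise ValueError(f"porin gene {gid!r} absent from MAG {mag_id!r}")

    clusters = []
    for porin_id in porin_list:
        porin = by_id[porin_id]
        members = []
        for cyt in cytochromes:
            if not cyt.is_multiheme:
                continue
            g = by_id[cyt.gene_id]
            if g.contig_id != porin.contig_id or g.gene_id == porin_id:
                continue
            if abs(g.gene_index - porin.gene_index) <= window:
                members.append(cyt)
        if not members:
            continue
        members.sort(key=lambda c: by_id[c.gene_id].gene_index)
        indices = [porin.gene_index] + [by_id[c.gene_id].gene_index for c in members]
        clusters.append(
            GeneCluster(
                mag_id=mag_id,
                contig_id=porin.contig_id,
                porin_gene_id=porin_id,
                cytochromes=tuple(members),
                gene_ids=tuple([porin_id] + [c.gene_id for c in members]),
                span=max(indices) - min(indices),
            )
        )
    clusters.sort(key=lambda c: (c.contig_id, by_id[c.porin_gene_id].gene_index))
    return clusters


def _colocated(genes: Sequence[GeneCall], window: int) -> bool:
    if len(genes) <= 1:
        return True
    contigs = {g.contig_id for g in genes}
    if len(contigs) != 1:
        return False
    idx = [g.gene_index for g in genes]
    return max(idx) - min(idx) <= window


def _match_system(
    system: ReferenceSystem,
    filtered_hits: Sequence[HomologyHit],
    gene_by_id: Mapping[str, GeneCall],
    window: int,
) -> tuple[str, dict[str, tuple[str, HomologyHit]]] | None:
    """Try to satisfy a reference system from filtered hits.

    Returns (completeness, component -> (gene_id, hit)) or None. Required
    components must all be hit by genes that co-locate within the window;
    completeness is "complete" when the optional components are also
    present (co-locating), "partial" otherwise.
    """
    candidates: dict[str, list[HomologyHit]] = {c.component_id: [] for c in system.components}
    for hit in filtered_hits:
        if hit.subject_id in candidates and hit.query_gene_id in gene_by_id:
            candidates[hit.subject_id].append(hit)

    required = [c for c in system.components if c.required]
    optional = [c for c in system.components if not c.required]
    if any(not candidates[c.component_id] for c in required):
        return None

    # Search gene choices for the required components (candidate lists are
    # tiny in practice; cap the product to stay safe on adversarial input).
    req_lists = [candidates[c.component_id][:8] for c in required]
    for combo in itertools.islice(itertools.product(*req_lists), 4096):
        genes = [gene_by_id[h.query_gene_id] for h in combo]
        if not _colocated(genes, window):
            continue
        assignment = {
            c.component_id: (h.query_gene_id, h) for c, h in zip(required, combo)
        }
        completeness = "complete"
        for comp in optional:
            placed = None
            for hit in candidates[comp.component_id]:
                if _colocated(genes + [gene_by_id[hit.query_gene_id]], window):
                    placed = hit
                    break
            if placed is not None:
                assignment[comp.component_id] = (placed.query_gene_id, placed)
                genes.append(gene_by_id[placed.query_gene_id])
            else:
                completeness = "partial"
        return completeness, assignment
    return None


def classify_eet_system(
    mag_id: str,
    genes: Sequence[GeneCall],
    clusters: Sequence[GeneCluster],
    filtered_hits: Sequence[HomologyHit],
    systems: Sequence[ReferenceSystem],
    window: int = 5,
) -> EETCall:
    """Decision ladder for one MAG: homologous system > pcc-like > mto-like > none.

    1. A reference system whose required components all have passing,
       co-locating hits gives the system's category ("complete" if the
       optional/accessory components are hit too, else "partial").
    2. Otherwise a porin cluster with >= 1 periplasmic and >= 1
       extracellular multiheme c-type cytochrome is "pcc_like".
    3. Otherwise a porin cluster with >= 1 periplasmic multiheme
       cytochrome and no extracellular one in that cluster is "mto_like".
    4. Otherwise "none". Genes localized "unknown" count for neither the
       periplasmic nor the extracellular requirement.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    role_by_component = {
        c.component_id: c.role for s in systems for c in s.components
    }

    for system in systems:
        match = _match_system(system, filtered_hits, gene_by_id, window)
        if match is None:
            continue
        completeness, assignment = match
        evidence = tuple(
            Evidence(
                gene_id=gene_id,
                role=role_by_component[comp],
                basis="homology",
                detail=f"{comp} (bitscore {hit.bitscore:g}, evalue {hit.evalue:g})",
            )
            for comp, (gene_id, hit) in sorted(assignment.items())
        )
        return EETCall(
            mag_id=mag_id,
            category=_SYSTEM_CATEGORY[system.name],
            completeness=completeness,
            evidence=evidence,
        )

    def cluster_evidence(cluster: GeneCluster) -> tuple[Evidence, ...]:
        ev = [Evidence(cluster.porin_gene_id, "porin", "cluster", f"span {cluster.span}")]
        ev.extend(
            Evidence(c.gene_id, c.localization + "_ccyt", "cluster", f"{c.heme_count} hemes")
            for c in cluster.cytochromes
        )
        return tuple(ev)

    for cluster in clusters:
        locs = {c.localization for c in cluster.cytochromes}
        if "periplasmic" in locs and "extracellular" in locs:
            return EETCall(mag_id, "pcc_like", "complete", cluster_evidence(cluster))
    for cluster in clusters:
        locs = {c.localization for c in cluster.cytochromes}
        if "periplasmic" in locs and "extracellular" not in locs:
            return EETCall(mag_id, "mto_like", "partial", cluster_evidence(cluster))
    return EETCall(mag_id, "none", None, ())


def write_eet_calls(calls: Iterable[EETCall], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("mag_id\tcategory\tcompleteness\tn_evidence_genes\n")
        for c in sorted(calls, key=lambda c: c.mag_id):
            comp = c.completeness or ""
            fh.write(f"{c.mag_id}\t{c.category}\t{comp}\t{len(c.evidence)}\n")
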