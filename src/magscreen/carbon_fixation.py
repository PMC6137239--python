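"""CO2-fixation pathway completeness calls and the phototrophy gene screen.

A pathway is called ``complete`` only when every role in its definition is
evidenced by an annotation label, ``absent`` when no role at all is
present, and ``partial`` otherwise. Roles wired into an alternative-marker
slot (e.g. the rTCA citrate-cleavage step, satisfiable by ATP-citrate
lyase OR citryl-CoA synthetase + citryl-CoA lyase) are evaluated slot-wise:
any one fully-present group satisfies the slot.

A complete Wood-Ljungdahl call carries a directionality caveat: the same
gene complement can run oxidatively for acetate assimilation (oxidative
acetyl-CoA pathway), so completeness does not by itself imply autotrophy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from magscreen.eet import EETCall

PATHWAY_STATUS_ORDER = ("absent", "partial", "complete")

#: Caveat attached to complete WL calls (see module docstring).
WL_DIRECTIONALITY_CAVEAT = (
    "gene complement also supports the oxidative acetyl-CoA route; "
    "completeness does not imply net CO2 fixation"
)


@dataclass(frozen=True)
class PathwayRole:
    role_id: str
    labels: frozenset[str]
    key_marker: bool = False


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    roles: tuple[PathwayRole, ...]
    # Each slot is a tuple of alternative role-id groups; any one group
    # fully present satisfies the slot. Roles in a slot are exempt from the
    # individual all-roles requirement.
    alternative_marker_groups: tuple[tuple[tuple[str, ...], ...], ...] = ()

    def __post_init__(self) -> None:
        ids = [r.role_id for r in self.roles]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate role ids in pathway {self.name!r}")
        if not any(r.key_marker for r in self.roles):
            raise ValueError(f"pathway {self.name!r} has no key marker")
        known = set(ids)
        for slot in self.alternative_marker_groups:
            for group in slot:
                unknown = set(group) - known
                if unknown:
                    raise ValueError(f"unknown role ids in marker group: {sorted(unknown)}")

    @property
    def grouped_roles(self) -> frozenset[str]:
        return frozenset(r for slot in self.alternative_marker_groups for grp in slot for r in grp)


@dataclass(frozen=True)
class PathwayCall:
    mag_id: str
    pathway: str
    status: str  # absent | partial | complete
    present_roles: tuple[str, ...]
    missing_roles: tuple[str, ...]
    markers_satisfied: bool
    caveat: str = ""


@dataclass(frozen=True)
class PhototrophyCall:
    mag_id: str
    phototrophy: str  # none | oxygenic | anoxygenic_typeII | anoxygenic_typeI
    evidence_labels: tuple[str, ...] = ()


@dataclass(frozen=True)
class PhotoDefinition:
    role_labels: Mapping[str, frozenset[str]]  # psII, psI, pufL, pufM, puhA, typeI_rc


def load_pathway_definitions(
    path: str | Path | None = None,
) -> tuple[dict[str, PathwayDefinition], PhotoDefinition]:
    """Load pathway role tables and the phototrophy screen from YAML."""
    if path is None:
        text = resources.files("magscreen").joinpath("data/pathway_definitions.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    pathways: dict[str, PathwayDefinition] = {}
    for entry in raw["pathways"]:
        roles = tuple(
            PathwayRole(
                role_id=r["role_id"],
                labels=frozenset(r["labels"]),
                key_marker=bool(r.get("key_marker", False)),
            )
            for r in entry["roles"]
        )
        slots = tuple(
            tuple(tuple(group) for group in slot)
            for slot in entry.get("alternative_marker_groups", [])
        )
        pathways[entry["name"]] = PathwayDefinition(
            name=entry["name"], roles=roles, alternative_marker_groups=slots
        )
    photo = PhotoDefinition(
        role_labels={k: frozenset(v) for k, v in raw["phototrophy"].items()}
    )
    return pathways, photo


DEFAULT_SCREEN = ("CBB", "rTCA", "WL", "3HP")


def evaluate_pathway(
    mag_id: str,
    annotations: Iterable[str],
    definition: PathwayDefinition,
) -> PathwayCall:
    """Score one pathway against a MAG's pooled annotation label set."""
    labels = set(annotations)
    present = {r.role_id for r in definition.roles if labels & r.labels}
    grouped = definition.grouped_roles

    slots_ok = all(
        any(all(r in present for r in group) for group in slot)
        for slot in definition.alternative_marker_groups
    )
    ungrouped = [r for r in definition.roles if r.role_id not in grouped]
    ungrouped_ok = all(r.role_id in present for r in ungrouped)
    markers_ok = slots_ok and all(
        r.role_id in present for r in ungrouped if r.key_marker
    )

    missing = [r.role_id for r in ungrouped if r.role_id not in present]
    if not slots_ok:
        missing.extend(sorted(grouped - present))

    if ungrouped_ok and slots_ok:
        status = "complete"
    elif not present:
        status = "absent"
    else:
        status = "partial"
    caveat = WL_DIRECTIONALITY_CAVEAT if (definition.name == "WL" and status == "complete") else ""
    return PathwayCall(
        mag_id=mag_id,
        pathway=definition.name,
        status=status,
        present_roles=tuple(sorted(present)),
        missing_roles=tuple(missing),
        markers_satisfied=markers_ok,
        caveat=caveat,
    )


def screen_pathways(
    mag_id: str,
    annotations: Iterable[str],
    definitions: Mapping[str, PathwayDefinition] | None = None,
    names: Sequence[str] = DEFAULT_SCREEN,
) -> dict[str, PathwayCall]:
    if definitions is None:
        definitions, _ = load_pathway_definitions()
    labels = set(annotations)
    return {name: evaluate_pathway(mag_id, labels, definitions[name]) for name in names}


def screen_phototrophy(
    mag_id: str,
    annotations: Iterable[str],
    photo_definition: PhotoDefinition | None = None,
) -> PhototrophyCall:
    """Class a MAG's phototrophy from reaction-center gene hits.

    Oxygenic requires both photosystem II and I; pufL+pufM+puhA indicate a
    type-II anoxygenic reaction center; a type-I reaction center without
    PS-II indicates type-I anoxygenic phototrophy.
    """
    if photo_definition is None:
        _, photo_definition = load_pathway_definitions()
    labels = set(annotations)
    hit = {
        role: frozenset(labels & role_labels)
        for role, role_labels in photo_definition.role_labels.items()
    }
    evidence = tuple(sorted(l for ls in hit.values() for l in ls))
    if hit["psII"] and hit["psI"]:
        cls = "oxygenic"
    elif hit["pufL"] and hit["pufM"] and hit["puhA"]:
        cls = "anoxygenic_typeII"
    elif hit["typeI_rc"] and not hit["psII"]:
        cls = "anoxygenic_typeI"
    else:
        cls = "none"
    return PhototrophyCall(mag_id=mag_id, phototrophy=cls, evidence_labels=evidence if cls != "none" else ())


TROPHIC_CATEGORIES = ("eet_only", "cfix_only", "eet_and_cfix", "phototroph_cfix", "none")


def infer_trophic_category(
    eet: EETCall,
    pathways: Iterable[PathwayCall],
    photo: PhototrophyCall,
) -> str:
    """Cross-tabulate EET presence, CO2-fixation completeness and phototrophy."""
    pathways = list(pathways)
    mag_ids = {eet.mag_id, photo.mag_id, *(p.mag_id for p in pathways)}
    if len(mag_ids) != 1:
        raise ValueError(f"calls from different MAGs: {sorted(mag_ids)}")
    has_eet = eet.category != "none"
    has_cfix = any(p.status == "complete" for p in pathways)
    if has_eet and has_cfix:
        return "eet_and_cfix"
    if has_eet:
        return "eet_only"
    if has_cfix and photo.phototrophy != "none":
        return "phototroph_cfix"
    if has_cfix:
        return "cfix_only"
    return "none"


def write_pathway_calls(calls: Iterable[PathwayCall], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("mag_id\tpathway\tstatus\tmarkers_satisfied\tmissing_roles\tcaveat\n")
        for c in sorted(calls, key=lambda c: (c.mag_id, c.pathway)):
            fh.write(
                f"{c.mag_id}\t{c.pathway}\t{c.status}\t{str(c.markers_satisfied).lower()}\t"
                f"{','.join(c.missing_roles)}\t{c.caveat}\n"
            )


def write_phototrophy_calls(calls: Iterable[PhototrophyCall], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("mag_id\tphototrophy\tevidence\n")
        for c in sorted(calls, key=lambda c: c.mag_id):
            fh.write(f"{c.mag_id}\t{c.phototrophy}\t{','.join(c.evidence_labels)}\n")
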