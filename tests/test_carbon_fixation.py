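"""Pathway completeness scoring, phototrophy screen, trophic categories."""

from __future__ import annotations

import random

import pytest

from magscreen.carbon_fixation import (
    PATHWAY_STATUS_ORDER,
    evaluate_pathway,
    infer_trophic_category,
    load_pathway_definitions,
    screen_pathways,
    screen_phototrophy,
)
from magscreen.eet import EETCall, Evidence

DEFINITIONS, PHOTO = load_pathway_definitions()


def _labels_for(pathway: str, drop: set[str] = frozenset()) -> set[str]:
    """One accepted label per role, minus dropped roles."""
    return {
        sorted(role.labels)[0]
        for role in DEFINITIONS[pathway].roles
        if role.role_id not in drop
    }


def test_3hp_without_malonyl_coa_reductase_is_partial():
    call = evaluate_pathway("m1", _labels_for("3HP", drop={"mcr"}), DEFINITIONS["3HP"])
    assert call.status == "partial"
    assert "mcr" in call.missing_roles and not call.markers_satisfied


def test_archaeal_cbb_without_sbp_is_partial():
    labels = _labels_for("CBB_archaeal", drop={"sbp"})
    call = evaluate_pathway("m1", labels, DEFINITIONS["CBB_archaeal"])
    assert call.status == "partial"
    assert "sbp" in call.missing_roles
    # thiazole-adenylate synthase route is present, so only sbp is missing
    assert call.missing_roles == ("sbp",)


def test_empty_annotations_are_absent_for_every_pathway():
    calls = screen_pathways("m1", set(), DEFINITIONS)
    assert {c.status for c in calls.values()} == {"absent"}


def test_complete_pathways():
    for name in ("CBB", "WL", "3HP"):
        call = evaluate_pathway("m1", _labels_for(name), DEFINITIONS[name])
        assert call.status == "complete", name
        assert call.markers_satisfied


def test_wl_completeness_carries_directionality_caveat():
    complete = evaluate_pathway("m1", _labels_for("WL"), DEFINITIONS["WL"])
    assert "oxidative" in complete.caveat
    partial = evaluate_pathway("m1", _labels_for("WL", drop={"codh"}), DEFINITIONS["WL"])
    assert partial.status == "partial" and partial.caveat == ""


class TestRTCAConservativeRule:
    def test_complete_via_acl_route(self):
        labels = _labels_for("rTCA", drop={"ccs", "ccl"})
        assert evaluate_pathway("m1", labels, DEFINITIONS["rTCA"]).status == "complete"

    def test_complete_via_citryl_coa_route(self):
        labels = _labels_for("rTCA", drop={"aclA", "aclB"})
        assert evaluate_pathway("m1", labels, DEFINITIONS["rTCA"]).status == "complete"

    def test_acl_alone_is_not_enough(self):
        """A citrate-cleavage route without the rest of the cycle stays partial."""
        labels = {sorted(DEFINITIONS["rTCA"].roles[0].labels)[0],
                  sorted(DEFINITIONS["rTCA"].roles[1].labels)[0]}  # aclA + aclB only
        assert evaluate_pathway("m1", labels, DEFINITIONS["rTCA"]).status == "partial"

    def test_no_cleavage_route_is_partial_even_with_everything_else(self):
        labels = _labels_for("rTCA", drop={"aclA", "aclB", "ccs", "ccl"})
        call = evaluate_pathway("m1", labels, DEFINITIONS["rTCA"])
        assert call.status == "partial" and not call.markers_satisfied

    def test_incomplete_cleavage_group_does_not_satisfy_slot(self):
        labels = _labels_for("rTCA", drop={"aclB", "ccs", "ccl"})  # aclA alone
        assert evaluate_pathway("m1", labels, DEFINITIONS["rTCA"]).status == "partial"


def _oracle_status(labels: set[str], definition) -> str:
    """Independent set-cover check over the definition's role table."""
    present = {r.role_id for r in definition.roles if labels & r.labels}
    grouped = set(definition.grouped_roles)
    ok = all(r.role_id in present for r in definition.roles if r.role_id not in grouped)
    for slot in definition.alternative_marker_groups:
        ok = ok and any(set(g) <= present for g in slot)
    if ok:
        return "complete"
    return "absent" if not present else "partial"


def test_random_annotation_subsets_match_set_cover_oracle():
    rng = random.Random(41)
    all_labels = sorted({l for d in DEFINITIONS.values() for r in d.roles for l in r.labels})
    for _ in range(1000):
        labels = {l for l in all_labels if rng.random() < rng.choice([0.1, 0.5, 0.9])}
        name = rng.choice(list(DEFINITIONS))
        call = evaluate_pathway("m1", labels, DEFINITIONS[name])
        assert call.status == _oracle_status(labels, DEFINITIONS[name])


def test_adding_labels_never_lowers_status():
    rng = random.Random(43)
    all_labels = sorted({l for r in DEFINITIONS["rTCA"].roles for l in r.labels})
    for _ in range(200):
        base = {l for l in all_labels if rng.random() < 0.4}
        extra = base | {rng.choice(all_labels)}
        s0 = PATHWAY_STATUS_ORDER.index(evaluate_pathway("m1", base, DEFINITIONS["rTCA"]).status)
        s1 = PATHWAY_STATUS_ORDER.index(evaluate_pathway("m1", extra, DEFINITIONS["rTCA"]).status)
        assert s1 >= s0


def test_pathway_calls_are_independent():
    wl_and_cbb = _labels_for("WL") | _labels_for("CBB")
    cbb_only = _labels_for("CBB")
    assert (
        evaluate_pathway("m1", wl_and_cbb, DEFINITIONS["CBB"]).status
        == evaluate_pathway("m1", cbb_only, DEFINITIONS["CBB"]).status
    )


@pytest.mark.parametrize(
    "roles,expected",
    [
        (("psII", "psI"), "oxygenic"),
        (("pufL", "pufM", "puhA"), "anoxygenic_typeII"),
        (("typeI_rc",), "anoxygenic_typeI"),
        ((), "none"),
        (("pufL", "pufM"), "none"),  # type-II needs puhA too
    ],
)
def test_phototrophy_rules(roles, expected):
    labels = {sorted(PHOTO.role_labels[r])[0] for r in roles}
    assert screen_phototrophy("m1", labels, PHOTO).phototrophy == expected


def _eet(category):
    if category == "none":
        return EETCall("m1", "none", None, ())
    return EETCall("m1", category, "complete", (Evidence("g1", "porin", "cluster"),))


def _pathway_calls(complete: bool):
    labels = _labels_for("WL") if complete else set()
    return list(screen_pathways("m1", labels, DEFINITIONS).values())


def test_trophic_categories():
    oxy = screen_phototrophy("m1", {sorted(PHOTO.role_labels["psII"])[0],
                                    sorted(PHOTO.role_labels["psI"])[0]}, PHOTO)
    none_photo = screen_phototrophy("m1", set(), PHOTO)
    assert infer_trophic_category(_eet("pcc_like"), _pathway_calls(True), none_photo) == "eet_and_cfix"
    assert infer_trophic_category(_eet("none"), _pathway_calls(True), oxy) == "phototroph_cfix"
    assert infer_trophic_category(_eet("none"), _pathway_calls(False), none_photo) == "none"
    assert infer_trophic_category(_eet("mto_like"), _pathway_calls(False), none_photo) == "eet_only"
    assert infer_trophic_category(_eet("none"), _pathway_calls(True), none_photo) == "cfix_only"


def test_trophic_rejects_mismatched_mags():
    other = screen_phototrophy("mX", set(), PHOTO)
    with pytest.raises(ValueError, match="different MAGs"):
        infer_trophic_category(_eet("none"), _pathway_calls(False), other)
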