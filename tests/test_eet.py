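"""EET typing: hit filtering, porin-cytochrome clusters, the decision ladder."""

from __future__ import annotations

import random

import pytest

from magscreen.cytochromes import CytochromeRecord
from magscreen.eet import (
    CATEGORY_RANK,
    EETCall,
    HitThresholds,
    classify_eet_system,
    filter_homology_hits,
    find_porin_cytochrome_clusters,
    find_porin_genes,
    load_reference_systems,
)
from magscreen.io_formats import GeneCall, HomologyHit

SYSTEMS = load_reference_systems()


def _hit(q="g1", s="gpcc_porin_ombB", evalue=1e-10, pident=40.0, qcov=60.0, bitscore=100.0):
    return HomologyHit(q, s, pident, 100, evalue, bitscore, qcov, 80.0)


def test_filter_keeps_passing_and_drops_failing_hits():
    assert filter_homology_hits([_hit()]) == [_hit()]
    assert filter_homology_hits([_hit(evalue=1e-3, pident=90.0, qcov=90.0)]) == []
    assert filter_homology_hits([_hit(pident=20.0)]) == []
    assert filter_homology_hits([_hit(qcov=40.0)]) == []


def test_filter_random_hits_match_brute_force_oracle():
    rng = random.Random(17)
    hits = [
        _hit(
            q=f"g{rng.randint(0, 20)}",
            s=rng.choice(["A", "B", "C"]) + "_comp",
            evalue=10 ** rng.uniform(-30, 0),
            pident=rng.uniform(0, 100),
            qcov=rng.uniform(0, 100),
            bitscore=rng.choice([50.0, 100.0, 100.0, 200.0]),  # ties on purpose
        )
        for _ in range(500)
    ]
    thresholds = HitThresholds()

    # Brute-force oracle: filter, then per-key argmax by the documented order.
    passing = [
        (i, h)
        for i, h in enumerate(hits)
        if h.evalue <= thresholds.max_evalue
        and h.percent_identity >= thresholds.min_identity
        and h.query_coverage >= thresholds.min_query_coverage
    ]
    expected = {}
    for i, h in passing:
        key = (h.query_gene_id, h.subject_id)
        if key not in expected or (-h.bitscore, h.evalue, i) < expected[key][0]:
            expected[key] = ((-h.bitscore, h.evalue, i), h)
    got = filter_homology_hits(hits, thresholds)
    assert sorted(got, key=lambda h: (h.query_gene_id, h.subject_id)) == sorted(
        (v[1] for v in expected.values()), key=lambda h: (h.query_gene_id, h.subject_id)
    )


def _genes(layout: dict[str, int], contig="c1", mag="m1"):
    """GeneCalls at the given gene indices."""
    return [
        GeneCall(gid, contig, idx * 100 + 1, idx * 100 + 90, "+", idx, mag)
        for gid, idx in layout.items()
    ]


def _cyt(gene_id, hemes=10, loc="periplasmic"):
    return CytochromeRecord(gene_id, hemes, hemes >= 3, loc)


def test_cluster_within_window():
    genes = _genes({"porin": 10, "cytA": 12, "cytB": 13, "far": 20})
    cyts = [_cyt("cytA"), _cyt("cytB", loc="extracellular"), _cyt("far")]
    clusters = find_porin_cytochrome_clusters(genes, cyts, ["porin"], window=5)
    assert len(clusters) == 1
    assert set(clusters[0].gene_ids) == {"porin", "cytA", "cytB"}
    assert clusters[0].span == 3


def test_cluster_requires_same_contig():
    genes = _genes({"porin": 0}) + _genes({"cyt": 1}, contig="c2")
    clusters = find_porin_cytochrome_clusters(genes, [_cyt("cyt")], ["porin"], window=5)
    assert clusters == []


def test_cluster_ignores_sub_threshold_cytochromes():
    genes = _genes({"porin": 0, "weak": 1})
    clusters = find_porin_cytochrome_clusters(genes, [_cyt("weak", hemes=2)], ["porin"], window=5)
    assert clusters == []


def test_cluster_random_layouts_match_all_pairs_oracle():
    rng = random.Random(23)
    for trial in range(20):
        n = 200
        window = rng.choice([1, 3, 5, 8])
        contigs = [f"c{rng.randint(0, 3)}" for _ in range(n)]
        per_contig_counter: dict[str, int] = {}
        genes, cyts, porins = [], [], []
        meta = {}
        for i in range(n):
            contig = contigs[i]
            idx = per_contig_counter.get(contig, 0)
            per_contig_counter[contig] = idx + 1
            gid = f"t{trial}_g{i}"
            genes.append(GeneCall(gid, contig, idx * 100 + 1, idx * 100 + 90, "+", idx, "m1"))
            kind = rng.random()
            if kind < 0.1:
                porins.append(gid)
            elif kind < 0.4:
                hemes = rng.choice([1, 2, 3, 5, 10])
                loc = rng.choice(["periplasmic", "extracellular", "cytoplasmic", "unknown"])
                cyts.append(_cyt(gid, hemes=hemes, loc=loc))
            meta[gid] = (contig, idx)

        clusters = find_porin_cytochrome_clusters(genes, cyts, porins, window)

        # Oracle: all-pairs windowing over porins x multiheme cytochromes.
        expected = {}
        for porin in porins:
            pc, pi = meta[porin]
            members = {
                c.gene_id
                for c in cyts
                if c.is_multiheme
                and meta[c.gene_id][0] == pc
                and abs(meta[c.gene_id][1] - pi) <= window
            }
            if members:
                expected[porin] = members
        got = {c.porin_gene_id: set(c.gene_ids) - {c.porin_gene_id} for c in clusters}
        assert got == expected


def _call(eet_plant: str, window=5) -> EETCall:
    """Build a MAG matching one of the spec'd scenarios and classify it."""
    if eet_plant == "pcc_like":
        genes = _genes({"porin": 0, "peri": 1, "extra": 2})
        cyts = [_cyt("peri", 10, "periplasmic"), _cyt("extra", 12, "extracellular")]
        porins = ["porin"]
        hits = []
    elif eet_plant == "mto_like":
        genes = _genes({"porin": 0, "peri": 1})
        cyts = [_cyt("peri", 10, "periplasmic")]
        porins = ["porin"]
        hits = []
    elif eet_plant == "geobacter_partial":
        genes = _genes({"porin": 0, "peri": 1, "extra": 2})
        cyts = []
        porins = []
        hits = [
            _hit("porin", "gpcc_porin_ombB"),
            _hit("peri", "gpcc_periplasmic_omaB"),
            _hit("extra", "gpcc_extracellular_omcB"),
        ]
    elif eet_plant == "no_porin":
        genes = _genes({"peri": 0})
        cyts = [_cyt("peri", 10, "periplasmic")]
        porins = []
        hits = []
    clusters = find_porin_cytochrome_clusters(genes, cyts, porins, window)
    return classify_eet_system("m1", genes, clusters, hits, SYSTEMS, window)


def test_ladder_pcc_like_and_mto_like():
    call = _call("pcc_like")
    assert (call.category, call.completeness) == ("pcc_like", "complete")
    call = _call("mto_like")
    assert (call.category, call.completeness) == ("mto_like", "partial")


def test_ladder_geobacter_partial_without_gsu1999_analog():
    call = _call("geobacter_partial")
    assert (call.category, call.completeness) == ("geobacter_pcc", "partial")


def test_ladder_bottom_without_porin():
    call = _call("no_porin")
    assert call.category == "none" and call.completeness is None and call.evidence == ()


def test_unknown_localization_counts_for_neither_requirement():
    genes = _genes({"porin": 0, "mystery": 1})
    cyts = [_cyt("mystery", 10, "unknown")]
    clusters = find_porin_cytochrome_clusters(genes, cyts, ["porin"], 5)
    call = classify_eet_system("m1", genes, clusters, [], SYSTEMS, 5)
    assert call.category == "none"


def test_adding_evidence_never_lowers_category_rank():
    """Grow a MAG step by step; the category rank is monotone in evidence."""
    genes = _genes({"porin": 0, "peri": 1, "extra": 2, "gsu": 3})
    cyts_steps = [
        [],
        [_cyt("peri", 10, "periplasmic")],
        [_cyt("peri", 10, "periplasmic"), _cyt("extra", 12, "extracellular")],
    ]
    hit_steps = [
        [],
        [_hit("porin", "gpcc_porin_ombB"), _hit("peri", "gpcc_periplasmic_omaB"),
         _hit("extra", "gpcc_extracellular_omcB")],
        [_hit("porin", "gpcc_porin_ombB"), _hit("peri", "gpcc_periplasmic_omaB"),
         _hit("extra", "gpcc_extracellular_omcB"), _hit("gsu", "gpcc_periplasmic_gsu1999")],
    ]
    last_rank = 0
    for cyts in cyts_steps:
        clusters = find_porin_cytochrome_clusters(genes, cyts, ["porin"], 5)
        call = classify_eet_system("m1", genes, clusters, [], SYSTEMS, 5)
        assert CATEGORY_RANK[call.category] >= last_rank
        last_rank = CATEGORY_RANK[call.category]
    for hits in hit_steps[1:]:
        call = classify_eet_system("m1", genes, [], hits, SYSTEMS, 5)
        assert CATEGORY_RANK[call.category] >= last_rank


def test_tightening_thresholds_never_creates_homologous_calls():
    rng = random.Random(31)
    genes = _genes({f"g{i}": i for i in range(12)})
    loose = HitThresholds(max_evalue=1e-3, min_identity=20.0, min_query_coverage=30.0)
    tight = HitThresholds(max_evalue=1e-10, min_identity=50.0, min_query_coverage=70.0)
    for _ in range(50):
        hits = [
            _hit(
                q=f"g{rng.randint(0, 11)}",
                s=rng.choice(
                    ["gpcc_porin_ombB", "gpcc_periplasmic_omaB", "gpcc_extracellular_omcB",
                     "cyc2_fused", "mtrB_porin", "mtrA_periplasmic", "mtrC_extracellular"]
                ),
                evalue=10 ** rng.uniform(-20, -1),
                pident=rng.uniform(10, 90),
                qcov=rng.uniform(20, 100),
            )
            for _ in range(rng.randint(1, 10))
        ]
        call_tight = classify_eet_system(
            "m1", genes, [], filter_homology_hits(hits, tight), SYSTEMS, 5
        )
        call_loose = classify_eet_system(
            "m1", genes, [], filter_homology_hits(hits, loose), SYSTEMS, 5
        )
        if call_tight.category != "none":
            assert call_loose.category != "none"


def test_porin_identification_by_label_or_homology():
    annotations = {"gA": frozenset({"product:outer membrane porin"}), "gB": frozenset()}
    hits = [_hit("gC", "mtrB_porin"), _hit("gD", "mtrA_periplasmic")]
    porins = find_porin_genes(annotations, hits, SYSTEMS)
    assert porins == {"gA", "gC"}


def test_cluster_unknown_gene_reference_is_an_error():
    genes = _genes({"porin": 0})
    with pytest.raises(ValueError, match="ghost"):
        find_porin_cytochrome_clusters(genes, [_cyt("ghost")], ["porin"], 5)
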