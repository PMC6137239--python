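"""Coverage normalization, abundant flags, category breakdowns, OTU summaries."""

from __future__ import annotations

import random

import pandas as pd
import pytest

from magscreen import abundance
from magscreen.abundance import (
    AbundanceProfile,
    aggregate_category_fractions,
    flag_abundant,
    normalize_coverage,
    rank_abundance,
    summarize_otu_table,
)
from magscreen.carbon_fixation import (
    load_pathway_definitions,
    screen_pathways,
    screen_phototrophy,
)
from magscreen.eet import EETCall, Evidence
from magscreen.io_formats import CoverageRecord, OTUTable

DEFINITIONS, PHOTO = load_pathway_definitions()


def test_single_sample_normalization_is_identity():
    cov = [
        CoverageRecord("c1", "s1", 10.0, 1000, 10000),
        CoverageRecord("c2", "s1", 20.0, 500, 2500),
    ]
    profiles = normalize_coverage(cov, {"c1": "m1", "c2": "m1"})
    assert len(profiles) == 1
    p = profiles[0]
    expected_raw = (10.0 * 10000 + 20.0 * 2500) / 12500
    assert p.raw_mean_depth == pytest.approx(expected_raw)
    assert p.normalized_coverage == pytest.approx(expected_raw)  # scale factor 1
    assert p.mapped_read_fraction == pytest.approx(1.0)


def test_double_read_sample_gets_half_scale():
    cov = [
        CoverageRecord("c1", "sA", 10.0, 1000, 10000),
        CoverageRecord("c1", "sB", 10.0, 2000, 10000),
    ]
    profiles = {p.sample_id: p for p in normalize_coverage(cov, {"c1": "m1"})}
    assert profiles["sA"].normalized_coverage == pytest.approx(10.0)
    assert profiles["sB"].normalized_coverage == pytest.approx(5.0)


def test_unassigned_contigs_go_to_unbinned_pseudo_mag():
    cov = [
        CoverageRecord("c1", "s1", 10.0, 600, 1000),
        CoverageRecord("cX", "s1", 5.0, 400, 1000),
    ]
    profiles = {p.mag_id: p for p in normalize_coverage(cov, {"c1": "m1"})}
    assert set(profiles) == {"m1", abundance.UNBINNED}
    assert profiles["m1"].mapped_read_fraction == pytest.approx(0.6)


def test_random_multi_sample_profiles_match_recompute_oracle():
    rng = random.Random(29)
    mags = [f"m{i}" for i in range(8)]
    contig2mag = {}
    cov = []
    for m in mags:
        for k in range(rng.randint(1, 4)):
            contig2mag[f"{m}_c{k}"] = m
    samples = ["s1", "s2", "s3"]
    for contig in contig2mag:
        for s in samples:
            cov.append(
                CoverageRecord(contig, s, rng.uniform(0, 40), rng.randint(1, 5000), rng.randint(500, 9000))
            )
    profiles = normalize_coverage(cov, contig2mag)

    totals = {s: sum(r.mapped_reads for r in cov if r.sample_id == s) for s in samples}
    min_total = min(totals.values())
    for p in profiles:
        recs = [r for r in cov if r.sample_id == p.sample_id and contig2mag[r.contig_id] == p.mag_id]
        raw = sum(r.mean_depth * r.contig_length for r in recs) / sum(r.contig_length for r in recs)
        assert p.raw_mean_depth == pytest.approx(raw)
        assert p.normalized_coverage == pytest.approx(raw * min_total / totals[p.sample_id])
        assert p.mapped_read_fraction == pytest.approx(
            sum(r.mapped_reads for r in recs) / totals[p.sample_id]
        )
    # Read-fraction conservation per sample.
    for s in samples:
        assert sum(p.mapped_read_fraction for p in profiles if p.sample_id == s) == pytest.approx(1.0)


def _profiles(coverages, sample="s1"):
    return [
        AbundanceProfile(f"m{i}", sample, c, c, 1.0 / len(coverages))
        for i, c in enumerate(coverages)
    ]


def test_flag_abundant_strictly_above_mean():
    flags = [p.abundant for p in flag_abundant(_profiles([10.0, 20.0, 30.0]))]
    assert flags == [False, False, True]  # mean is 20; strict inequality


def test_flag_abundant_all_equal_none_abundant():
    assert not any(p.abundant for p in flag_abundant(_profiles([7.0] * 5)))


def test_flag_abundant_just_above_mean():
    """A MAG barely above the sample mean coverage (15.10 vs 15.09) is abundant."""
    coverages = [15.10] + [15.09 - 0.01 / 61] * 61  # mean = 15.09 (+ 0.01/62 spread)
    profiles = flag_abundant(_profiles(coverages))
    mean = sum(coverages) / len(coverages)
    assert profiles[0].normalized_coverage > mean
    assert profiles[0].abundant
    assert sum(p.abundant for p in profiles) == 1


def test_flag_abundant_is_scale_invariant():
    rng = random.Random(37)
    coverages = [rng.uniform(1, 50) for _ in range(20)]
    base = [p.abundant for p in flag_abundant(_profiles(coverages))]
    scaled = [p.abundant for p in flag_abundant(_profiles([c * 13.7 for c in coverages]))]
    assert base == scaled


def _call_set(mag, category, cfix, photo_roles=()):
    eet_call = (
        EETCall(mag, category, "complete", (Evidence("g", "porin", "cluster"),))
        if category != "none"
        else EETCall(mag, "none", None, ())
    )
    labels = set()
    if cfix:
        labels = {sorted(r.labels)[0] for r in DEFINITIONS["WL"].roles}
    labels |= {sorted(PHOTO.role_labels[r])[0] for r in photo_roles}
    pathway = list(screen_pathways(mag, labels, DEFINITIONS).values())
    photo = screen_phototrophy(mag, labels, PHOTO)
    return eet_call, pathway, photo


def test_category_breakdown_example_partition():
    spec = {
        "m0": ("pcc_like", False, 0.40, True),
        "m1": ("none", True, 0.10, True),
        "m2": ("mto_like", True, 0.05, True),
        "m3": ("none", False, 0.25, True),
        "m4": ("none", False, 0.20, False),
    }
    profiles, eet_calls, pathway_calls, photo_calls = [], {}, {}, {}
    for mag, (cat, cfix, frac, abundant) in spec.items():
        profiles.append(AbundanceProfile(mag, "s1", 1.0, 1.0, frac, abundant))
        eet_calls[mag], pathway_calls[mag], photo_calls[mag] = _call_set(mag, cat, cfix)
    (bd,) = aggregate_category_fractions(profiles, eet_calls, pathway_calls, photo_calls)
    assert bd.read_percent == {
        "eet_only": 40.0,
        "cfix_only": 10.0,
        "eet_and_cfix": 5.0,
        "abundant_no_pathway": 25.0,
        "below_average": 20.0,
    }
    assert sum(bd.read_percent.values()) == pytest.approx(100.0)
    assert sum(bd.mag_counts.values()) == 5


def test_breakdown_no_abundant_mags_pools_everything_below_average():
    profiles = [AbundanceProfile(f"m{i}", "s1", 1.0, 1.0, 0.2, False) for i in range(5)]
    calls = {f"m{i}": _call_set(f"m{i}", "pcc_like", True) for i in range(5)}
    (bd,) = aggregate_category_fractions(
        profiles,
        {m: c[0] for m, c in calls.items()},
        {m: c[1] for m, c in calls.items()},
        {m: c[2] for m, c in calls.items()},
    )
    assert bd.mag_counts["below_average"] == 5
    assert bd.read_percent["below_average"] == pytest.approx(100.0)


def test_breakdown_random_partition_matches_group_sum_oracle():
    rng = random.Random(53)
    profiles, eet_calls, pathway_calls, photo_calls = [], {}, {}, {}
    fractions = [rng.uniform(0, 1) for _ in range(50)]
    total = sum(fractions)
    expected = {c: 0.0 for c in abundance.BREAKDOWN_CATEGORIES}
    counts = {c: 0 for c in abundance.BREAKDOWN_CATEGORIES}
    for i, frac in enumerate(fractions):
        mag = f"m{i:02d}"
        category = rng.choice(["none", "pcc_like", "mto_like"])
        cfix = rng.random() < 0.5
        abundant = rng.random() < 0.5
        photo_roles = ("psII", "psI") if rng.random() < 0.3 else ()
        profiles.append(AbundanceProfile(mag, "s1", 1.0, 1.0, frac / total, abundant))
        eet_calls[mag], pathway_calls[mag], photo_calls[mag] = _call_set(
            mag, category, cfix, photo_roles
        )
        if not abundant:
            bucket = "below_average"
        elif category != "none" and cfix:
            bucket = "eet_and_cfix"
        elif category != "none":
            bucket = "eet_only"
        elif cfix:
            bucket = "cfix_only"  # phototroph_cfix folds in here
        else:
            bucket = "abundant_no_pathway"
        expected[bucket] += frac / total
        counts[bucket] += 1
    (bd,) = aggregate_category_fractions(profiles, eet_calls, pathway_calls, photo_calls)
    assert bd.mag_counts == counts
    for cat in abundance.BREAKDOWN_CATEGORIES:
        assert bd.read_percent[cat] == pytest.approx(100 * expected[cat], abs=0.051)
    assert sum(bd.read_percent.values()) == pytest.approx(100.0, abs=0.3)


def test_breakdown_requires_calls_for_every_mag():
    profiles = [AbundanceProfile("m1", "s1", 1.0, 1.0, 1.0, True)]
    with pytest.raises(ValueError, match="m1"):
        aggregate_category_fractions(profiles, {}, {}, {})


def test_rank_abundance_sorting_ties_and_top_n():
    coverages = [5.0, 30.0, 30.0, 1.0, 12.0]
    profiles = flag_abundant(_profiles(coverages))
    table = rank_abundance(profiles, top_n=3)
    assert list(table["mag_id"]) == ["m1", "m2", "m4"]  # tie 30/30 by mag_id
    assert table.attrs["mean_coverage"] == pytest.approx(sum(coverages) / 5)
    full = rank_abundance(profiles, top_n=20)
    assert len(full) == 5
    assert list(full["normalized_coverage"]) == sorted(coverages, reverse=True)


def _otu_table(counts: dict[str, list[int]], lineages, samples):
    df = pd.DataFrame(counts, index=samples).astype(int)
    df.index.name = "sample_id"
    return OTUTable(counts=df, lineages=lineages)


def test_summarize_single_dominant_otu():
    table = _otu_table({"o1": [500]}, {"o1": "k__B;p__P;c__C;o__O;f__F;g__"}, ["s1"])
    summary = summarize_otu_table(table, "family", 1.0)
    assert summary.retained_count == 1
    assert summary.cumulative_percent == 100.0


def test_summarize_collapse_conserves_reads_and_threshold_is_strict():
    lineages = {
        "o1": "k__B;p__P1;c__C1;o__O1;f__F1;g__G1",
        "o2": "k__B;p__P1;c__C1;o__O1;f__F1;g__G2",  # same family as o1
        "o3": "k__B;p__P2;c__C2;o__O2;f__F2;g__",
        "o4": "k__B;p__P3;c__C3;o__O3;f__F3;g__",
    }
    table = _otu_table(
        {"o1": [30, 10], "o2": [30, 10], "o3": [39, 79], "o4": [1, 1]},
        lineages,
        ["s1", "s2"],
    )
    summary = summarize_otu_table(table, "family", 1.0)
    assert summary.n_collapsed == 3  # o1+o2 merge at family
    # Per-sample percents: F1 = 60% / 20%, F2 = 39% / 79%, F4 = 1% / 1%.
    merged = summary.table.set_index("lineage")["mean_percent"]
    assert merged["k__B;p__P1;c__C1;o__O1;f__F1;g__"] == pytest.approx(40.0)
    assert merged["k__B;p__P2;c__C2;o__O2;f__F2;g__"] == pytest.approx(59.0)
    # o4 sits exactly at 1%: the strict > filter drops it.
    assert summary.retained_count == 2
    assert summary.cumulative_percent == pytest.approx(99.0)


def test_summarize_unknown_rank_is_an_error():
    table = _otu_table({"o1": [10]}, {"o1": "k__B"}, ["s1"])
    with pytest.raises(ValueError, match="rank"):
        summarize_otu_table(table, "species", 1.0)
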