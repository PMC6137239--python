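"""Coverage-based MAG abundance profiles and OTU-table summaries.

Per-MAG coverage is the length-weighted mean of contig depths. Coverage is
normalized across samples by smallest-library scaling: each sample's
depths are multiplied by (smallest per-sample total of mapped reads) /
(that sample's total), so a single-sample run is the identity. A MAG is
"abundant" in a sample when its normalized coverage strictly exceeds the
arithmetic mean over that sample's MAGs; a MAG exactly at the mean is not
abundant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from magscreen._util import round_half_away
from magscreen.carbon_fixation import PathwayCall, PhototrophyCall, infer_trophic_category
from magscreen.eet import EETCall
from magscreen.io_formats import CoverageRecord, OTUTable
from magscreen.taxonomy import RANKS, truncate_lineage_string

#: Pseudo-MAG collecting contigs with coverage but no bin assignment.
UNBINNED = "unbinned"

BREAKDOWN_CATEGORIES = (
    "eet_only",
    "cfix_only",
    "eet_and_cfix",
    "abundant_no_pathway",
    "below_average",
)


@dataclass(frozen=True)
class AbundanceProfile:
    mag_id: str
    sample_id: str
    raw_mean_depth: float
    normalized_coverage: float
    mapped_read_fraction: float
    abundant: bool | None = None  # None until flag_abundant has run


@dataclass(frozen=True)
class CategoryBreakdown:
    sample_id: str
    mag_counts: dict[str, int]
    read_percent: dict[str, float]  # summed mapped-read percentage, 1 decimal


def normalize_coverage(
    coverage: Sequence[CoverageRecord],
    mag_membership: Mapping[str, str],
) -> list[AbundanceProfile]:
    """Aggregate contig coverage into per-MAG, per-sample profiles.

    Contigs with coverage but no MAG assignment are pooled into an
    ``unbinned`` pseudo-MAG (its reads count toward sample totals but it is
    not a MAG for flagging purposes).
    """
    if not coverage:
        return []
    samples = sorted({r.sample_id for r in coverage})
    totals = {s: 0 for s in samples}
    per_mag: dict[tuple[str, str], list[CoverageRecord]] = {}
    for rec in coverage:
        mag = mag_membership.get(rec.contig_id, UNBINNED)
        per_mag.setdefault((mag, rec.sample_id), []).append(rec)
        totals[rec.sample_id] += rec.mapped_reads
    for s, total in totals.items():
        if total <= 0:
            raise ValueError(f"sample {s!r} has no mapped reads")
    min_total = min(totals.values())

    profiles = []
    for (mag, sample) in sorted(per_mag):
        recs = per_mag[(mag, sample)]
        total_len = sum(r.contig_length for r in recs)
        if total_len == 0:
            raise ValueError(f"MAG {mag!r} has zero total contig length in sample {sample!r}")
        raw = sum(r.mean_depth * r.contig_length for r in recs) / total_len
        scale = min_total / totals[sample]
        reads = sum(r.mapped_reads for r in recs)
        profiles.append(
            AbundanceProfile(
                mag_id=mag,
                sample_id=sample,
                raw_mean_depth=raw,
                normalized_coverage=raw * scale,
                mapped_read_fraction=reads / totals[sample],
            )
        )
    return profiles


def flag_abundant(profiles: Sequence[AbundanceProfile]) -> list[AbundanceProfile]:
    """Set the abundant flag: strictly above the per-sample mean over MAGs.

    The ``unbinned`` pseudo-MAG neither enters the mean nor gets a flag.
    """
    by_sample: dict[str, list[AbundanceProfile]] = {}
    for p in profiles:
        by_sample.setdefault(p.sample_id, []).append(p)
    out = []
    for sample in sorted(by_sample):
        mags = [p for p in by_sample[sample] if p.mag_id != UNBINNED]
        if not mags:
            raise ValueError(f"sample {sample!r} has no MAG profiles")
        mean = sum(p.normalized_coverage for p in mags) / len(mags)
        for p in by_sample[sample]:
            if p.mag_id == UNBINNED:
                out.append(replace(p, abundant=None))
            else:
                out.append(replace(p, abundant=p.normalized_coverage > mean))
    return out


def sample_mean_coverage(profiles: Sequence[AbundanceProfile], sample_id: str) -> float:
    mags = [p for p in profiles if p.sample_id == sample_id and p.mag_id != UNBINNED]
    if not mags:
        raise ValueError(f"no MAG profiles for sample {sample_id!r}")
    return sum(p.normalized_coverage for p in mags) / len(mags)


def aggregate_category_fractions(
    profiles: Sequence[AbundanceProfile],
    eet_calls: Mapping[str, EETCall],
    pathway_calls: Mapping[str, Sequence[PathwayCall]],
    photo_calls: Mapping[str, PhototrophyCall],
) -> list[CategoryBreakdown]:
    """Per-sample breakdown of MAG counts and mapped-read percentages.

    Abundant MAGs are split by trophic category (phototroph_cfix folds into
    cfix_only: a CO2-fixing MAG without an EET system); non-abundant MAGs
    pool into ``below_average`` regardless of content. Percentages are
    100 x summed mapped-read fraction, half-away-from-zero at one decimal.
    """
    by_sample: dict[str, list[AbundanceProfile]] = {}
    for p in profiles:
        if p.mag_id == UNBINNED:
            continue
        if p.abundant is None:
            raise ValueError("run flag_abundant before aggregating categories")
        by_sample.setdefault(p.sample_id, []).append(p)

    breakdowns = []
    for sample in sorted(by_sample):
        counts = {c: 0 for c in BREAKDOWN_CATEGORIES}
        fractions = {c: 0.0 for c in BREAKDOWN_CATEGORIES}
        for p in by_sample[sample]:
            if p.mag_id not in eet_calls or p.mag_id not in pathway_calls:
                raise ValueError(f"MAG {p.mag_id!r} has a profile but no calls")
            if not p.abundant:
                cat = "below_average"
            else:
                trophic = infer_trophic_category(
                    eet_calls[p.mag_id], pathway_calls[p.mag_id], photo_calls[p.mag_id]
                )
                cat = {
                    "eet_only": "eet_only",
                    "cfix_only": "cfix_only",
                    "phototroph_cfix": "cfix_only",
                    "eet_and_cfix": "eet_and_cfix",
                    "none": "abundant_no_pathway",
                }[trophic]
            counts[cat] += 1
            fractions[cat] += p.mapped_read_fraction
        breakdowns.append(
            CategoryBreakdown(
                sample_id=sample,
                mag_counts=counts,
                read_percent={c: round_half_away(100.0 * f, 1) for c, f in fractions.items()},
            )
        )
    return breakdowns


def rank_abundance(
    profiles: Sequence[AbundanceProfile],
    top_n: int = 20,
    eet_calls: Mapping[str, EETCall] | None = None,
    pathway_calls: Mapping[str, Sequence[PathwayCall]] | None = None,
) -> pd.DataFrame:
    """Rank-abundance table for one sample's MAGs.

    Sorted by normalized coverage descending, ties by mag_id; EET ("E") and
    complete CO2-fixation ("C") flags are attached when calls are given.
    The per-sample mean coverage is stored in ``df.attrs["mean_coverage"]``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    mags = [p for p in profiles if p.mag_id != UNBINNED]
    samples = {p.sample_id for p in mags}
    if len(samples) != 1:
        raise ValueError(f"rank_abundance expects one sample, got {sorted(samples)}")
    mean = sum(p.normalized_coverage for p in mags) / len(mags)
    ranked = sorted(mags, key=lambda p: (-p.normalized_coverage, p.mag_id))[:top_n]
    rows = []
    for rank, p in enumerate(ranked, start=1):
        flags = ""
        if eet_calls and eet_calls.get(p.mag_id) and eet_calls[p.mag_id].category != "none":
            flags += "E"
        if pathway_calls and any(c.status == "complete" for c in pathway_calls.get(p.mag_id, [])):
            flags += "C"
        rows.append(
            {
                "rank": rank,
                "mag_id": p.mag_id,
                "normalized_coverage": p.normalized_coverage,
                "abundant": p.abundant,
                "flags": flags,
            }
        )
    df = pd.DataFrame(rows, columns=["rank", "mag_id", "normalized_coverage", "abundant", "flags"])
    df.attrs["mean_coverage"] = mean
    return df


@dataclass(frozen=True)
class OTUSummary:
    """Rank-collapsed OTU table summary after a relative-abundance filter."""

    rank: str
    threshold_percent: float
    table: pd.DataFrame  # retained rows: lineage, mean_percent (descending)
    n_collapsed: int  # collapsed taxa before filtering
    retained_count: int
    cumulative_percent: float  # sum of retained unrounded percentages, 1 decimal


def summarize_otu_table(
    table: OTUTable,
    rank: str = "family",
    threshold_percent: float = 1.0,
) -> OTUSummary:
    """Collapse an OTU table at a rank and keep taxa above a mean-percent cutoff.

    Counts are collapsed by lineage truncated at ``rank``; per-taxon percent
    is computed per sample and averaged unweighted across samples; rows with
    mean percent strictly above the threshold are retained, sorted
    descending. The cumulative percent is the sum of the retained rows'
    unrounded percentages, reported at one decimal.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose one of {RANKS}")
    if threshold_percent < 0:
        raise ValueError("threshold_percent must be >= 0")
    counts = table.counts
    collapsed_cols: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        key = truncate_lineage_string(table.lineages[otu], rank)
        collapsed_cols.setdefault(key, []).append(otu)
    collapsed = pd.DataFrame(
        {key: counts[otus].sum(axis=1) for key, otus in collapsed_cols.items()},
        index=counts.index,
    )
    sample_totals = counts.sum(axis=1)
    if (sample_totals <= 0).any():
        raise ValueError("every sample must have at least one read")
    percents = collapsed.div(sample_totals, axis=0) * 100.0
    mean_percent = percents.mean(axis=0)

    retained = mean_percent[mean_percent > threshold_percent].sort_values(
        ascending=False, kind="mergesort"
    )
    df = pd.DataFrame(
        {"lineage": retained.index, "mean_percent": retained.to_numpy()}
    ).reset_index(drop=True)
    return OTUSummary(
        rank=rank,
        threshold_percent=threshold_percent,
        table=df,
        n_collapsed=collapsed.shape[1],
        retained_count=len(df),
        cumulative_percent=round_half_away(float(retained.sum()), 1),
    )


def write_profiles(profiles: Iterable[AbundanceProfile], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("mag_id\tsample_id\traw_mean_depth\tnormalized_coverage\tmapped_read_fraction\tabundant\n")
        for p in sorted(profiles, key=lambda p: (p.sample_id, p.mag_id)):
            flag = "" if p.abundant is None else str(p.abundant).lower()
            fh.write(
                f"{p.mag_id}\t{p.sample_id}\t{p.raw_mean_depth:.6f}\t"
                f"{p.normalized_coverage:.6f}\t{p.mapped_read_fraction:.6f}\t{flag}\n"
            )


def write_breakdowns(breakdowns: Iterable[CategoryBreakdown], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\tcategory\tn_mags\tread_percent\n")
        for b in sorted(breakdowns, key=lambda b: b.sample_id):
            for cat in BREAKDOWN_CATEGORIES:
                fh.write(f"{b.sample_id}\t{cat}\t{b.mag_counts[cat]}\t{b.read_percent[cat]}\n")
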