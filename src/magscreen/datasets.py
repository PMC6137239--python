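"""Published 16S community profiles of an Fe-rich hot-spring system.

Two family-level amplicon community compositions from a Yellowstone
iron-depositing hot spring are shipped as inputs: the combined sediment-core
libraries (22 family-level taxa above 1% mean read abundance out of 320)
and the vent-pool water column (8 out of 267). The publication prints the
per-taxon mean percent read abundances; this module reconstructs synthetic
integer count tables consistent with those printed percentages so the
summarization pipeline can recompute the filter and cumulative numbers from
counts at run time.

The reconstruction is exact for the retained rows: with a 10,000-read
total, each printed percent maps to an integer count (percent x 100), and
the remaining reads are spread over the sub-1% background families so that
every background family stays strictly below the 1% cutoff.
"""

from __future__ import annotations

import pandas as pd

from magscreen.io_formats import OTUTable

#: Combined sediment-core libraries: (taxon name, rank letter, printed mean %).
CORE_COMBINED_FAMILIES: tuple[tuple[str, str, float], ...] = (
    ("Crenarchaeota", "p", 9.0),
    ("Chlorobi", "p", 5.0),
    ("Chlorobi_2", "p", 4.7),
    ("Acetothermales", "o", 4.7),
    ("Nitrospirales", "o", 3.8),
    ("GAL15", "p", 3.6),
    ("Acidobacteria", "p", 3.5),
    ("Crenarchaeota_2", "p", 3.1),
    ("Anaerolineae", "c", 2.5),
    ("Cenarchaeaceae", "f", 2.2),
    ("Thaumarchaeota", "c", 2.1),
    ("Syntrophobacteraceae", "f", 2.1),
    ("NC10", "p", 2.1),
    ("Methylomirabiliaceae", "f", 1.9),
    ("Chloroflexi", "p", 1.7),
    ("Aigarchaeota", "c", 1.7),
    ("Betaproteobacteria", "c", 1.4),
    ("SBR1093", "p", 1.4),
    ("NC10_2", "p", 1.3),
    ("Methanomassiliicoccaceae", "f", 1.2),
    ("Acetothermaceae", "f", 1.0),
    ("Acidobacteria_2", "p", 1.0),
)
#: Family-level taxa in the combined core libraries after collapse.
CORE_COMBINED_N_FAMILIES = 320

#: Vent-pool water column: (taxon name, rank letter, printed mean %).
VENT_POOL_FAMILIES: tuple[tuple[str, str, float], ...] = (
    ("Pseudanabaenaceae", "f", 20.1),
    ("Thermodesulfovibrionaceae", "f", 10.3),
    ("Roseiflexaceae", "f", 2.6),
    ("Betaproteobacteria", "c", 2.6),
    ("Chlorobi", "p", 2.2),
    ("Rhodocyclaceae", "f", 2.2),
    ("Chloroherpetales", "o", 2.1),
    ("Anaerolineae", "c", 1.3),
)
VENT_POOL_N_FAMILIES = 267

_NOMINAL_TOTAL = 10_000


def _build_table(
    rows: tuple[tuple[str, str, float], ...],
    n_families: int,
    sample_id: str,
    total_reads: int = _NOMINAL_TOTAL,
) -> OTUTable:
    """Reconstruct a single-sample family-level count table (synthetic counts).

    Each table row becomes one collapsed family with count = printed percent
    x 100 (relative to the nominal 10,000-read total); the remaining reads
    are distributed over the background families as evenly as possible,
    which keeps each strictly below 1%. Publications print percentages
    rounded to one decimal, so a row printed at exactly the filter cutoff
    was in truth strictly above it; passing a ``total_reads`` slightly under
    the nominal total reproduces that by lifting every percentage
    proportionally.
    """
    counts: dict[str, int] = {}
    lineages: dict[str, str] = {}
    for i, (name, rank_letter, percent) in enumerate(rows):
        otu = f"fam{i:03d}_{name}"
        count = round(percent * _NOMINAL_TOTAL / 100)
        counts[otu] = count
        # Place the printed name at its stated rank; pad other ranks with
        # unique tokens down to family so rows stay distinct after collapse.
        tokens = {"k": "", "p": "", "c": "", "o": "", "f": "", "g": ""}
        order = "kpcofg"
        depth = order.index(rank_letter)
        for j in range(depth + 1):
            tokens[order[j]] = name if j == depth else f"{name}_{order[j]}"
        for j in range(depth + 1, 5):  # fill through family
            tokens[order[j]] = f"{name}_{order[j]}"
        lineages[otu] = (
            f"k__{tokens['k']};p__{tokens['p']};c__{tokens['c']};"
            f"o__{tokens['o']};f__{tokens['f']};g__"
        )
    remaining = total_reads - sum(counts.values())
    n_background = n_families - len(rows)
    base, extra = divmod(remaining, n_background)
    if base + 1 >= total_reads // 100:
        raise ValueError("background families would cross the 1% cutoff")
    for i in range(n_background):
        otu = f"bg{i:03d}"
        counts[otu] = base + (1 if i < extra else 0)
        lineages[otu] = f"k__bg{i:03d}_k;p__bg{i:03d}_p;c__bg{i:03d}_c;o__bg{i:03d}_o;f__bg{i:03d}_f;g__"
    df = pd.DataFrame({otu: [n] for otu, n in counts.items()}, index=[sample_id]).astype(int)
    df.index.name = "sample_id"
    return OTUTable(counts=df, lineages=lineages)


def core_combined_table() -> OTUTable:
    """Synthetic count reconstruction of the combined sediment-core libraries.

    Two rows print at exactly 1.0%; the slightly sub-nominal total keeps
    them strictly above the 1% filter, as in the published summary.
    """
    return _build_table(
        CORE_COMBINED_FAMILIES, CORE_COMBINED_N_FAMILIES, "cores_combined", total_reads=9990
    )


def vent_pool_table() -> OTUTable:
    """Synthetic count reconstruction of the vent-pool water column library."""
    return _build_table(VENT_POOL_FAMILIES, VENT_POOL_N_FAMILIES, "vent_pool")
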