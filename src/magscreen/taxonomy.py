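"""Rank-prefixed lineages, LCA, and consensus taxonomy for MAGs.

A MAG's taxonomy is assigned by majority vote over per-gene lineage labels
(one label per detected housekeeping gene, produced upstream), reconciled
with a placement-based lineage (e.g. from a marker-gene tree) by taking the
lowest common ancestor of the two. Lineages are fixed six-slot rank vectors
(kingdom/domain, phylum, class, order, family, genus); an empty token means
"unassigned below this point" and may never be followed by a non-empty one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")
N_RANKS = len(RANKS)


@dataclass(frozen=True)
class Lineage:
    """A six-slot taxonomic lineage with prefix structure."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != N_RANKS:
            raise ValueError(f"lineage needs {N_RANKS} rank tokens, got {len(self.tokens)}")
        seen_empty = False
        for tok in self.tokens:
            if tok == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(f"non-empty rank below an empty one in {self.tokens}")

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        """Parse a semicolon-delimited, optionally rank-prefixed lineage string."""
        return cls(tuple(parse_lineage_tokens(text)))

    def to_string(self) -> str:
        return ";".join(p + t for p, t in zip(RANK_PREFIXES, self.tokens))

    @property
    def depth(self) -> int:
        """Number of assigned (non-empty) ranks."""
        return sum(1 for t in self.tokens if t != "")

    def truncate(self, depth: int) -> "Lineage":
        kept = tuple(t if i < depth else "" for i, t in enumerate(self.tokens))
        return Lineage(kept)


ROOT = Lineage(("",) * N_RANKS)


def parse_lineage_tokens(text: str) -> list[str]:
    """Normalize a lineage string to six bare rank tokens.

    Accepts rank-prefixed (``k__Bacteria;p__Chlorobi``) or bare
    (``Bacteria;Chlorobi``) forms; short lineages are padded with empty
    tokens, the literal ``Unassigned`` maps to the root.
    """
    text = text.strip()
    if text == "" or text.lower() == "unassigned":
        return [""] * N_RANKS
    parts = [p.strip() for p in text.split(";")]
    if len(parts) > N_RANKS:
        raise ValueError(f"lineage has more than {N_RANKS} ranks: {text!r}")
    tokens: list[str] = []
    for i, part in enumerate(parts):
        for j, prefix in enumerate(RANK_PREFIXES):
            if part.startswith(prefix):
                if j != i:
                    raise ValueError(f"rank prefix {prefix!r} out of order in {text!r}")
                part = part[len(prefix):]
                break
        tokens.append(part.strip())
    tokens.extend([""] * (N_RANKS - len(tokens)))
    return tokens


def normalize_lineage_string(text: str) -> str:
    """Canonical rank-prefixed form with all six ranks present."""
    return ";".join(p + t for p, t in zip(RANK_PREFIXES, parse_lineage_tokens(text)))


def truncate_lineage_string(text: str, rank: str) -> str:
    """Truncate a lineage string at ``rank`` (inclusive), normalized form."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose one of {RANKS}")
    depth = RANKS.index(rank) + 1
    tokens = parse_lineage_tokens(text)
    kept = [t if i < depth else "" for i, t in enumerate(tokens)]
    return ";".join(p + t for p, t in zip(RANK_PREFIXES, kept))


def lca(lineages: list[Lineage]) -> Lineage:
    """Lowest common ancestor: the longest common rank prefix."""
    if not lineages:
        raise ValueError("lca of an empty lineage list is undefined")
    tokens: list[str] = []
    for i in range(N_RANKS):
        col = {lin.tokens[i] for lin in lineages}
        if len(col) == 1 and "" not in col:
            tokens.append(col.pop())
        else:
            break
    tokens.extend([""] * (N_RANKS - len(tokens)))
    return Lineage(tuple(tokens))


@dataclass(frozen=True)
class ConsensusReport:
    """Consensus lineage with per-rank vote support."""

    lineage: Lineage
    majority: Lineage
    placement: Lineage
    support: tuple[float, ...]  # agreement fraction at each rank (nan-free: 0 where no votes)
    truncated_by_placement: bool


def consensus_taxonomy(
    gene_lineages: list[Lineage],
    placement: Lineage,
    min_support: float = 0.5,
) -> ConsensusReport:
    """Majority-vote lineage over gene assignments, reconciled with a placement.

    At each rank (top-down, restricted to lineages consistent with the
    accepted prefix) the most common non-empty token wins if its share of
    all non-empty votes at that rank is at least ``min_support``; the vote
    lineage is truncated at the first failing rank. The final call is the
    LCA of the vote lineage and the placement lineage, unless the placement
    is empty, in which case the vote lineage stands alone.
    """
    if not (0.0 < min_support <= 1.0):
        raise ValueError(f"min_support must be in (0, 1], got {min_support}")
    if not gene_lineages:
        raise ValueError("need at least one gene lineage")

    tokens: list[str] = []
    support: list[float] = []
    consistent = list(gene_lineages)
    accepted = True
    for i in range(N_RANKS):
        n_votes = sum(1 for lin in gene_lineages if lin.tokens[i] != "")
        counts = Counter(lin.tokens[i] for lin in consistent if lin.tokens[i] != "")
        if not accepted or n_votes == 0 or not counts:
            support.append(0.0)
            continue
        # Deterministic winner: highest count, ties by token text.
        winner, winner_count = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        frac = winner_count / n_votes
        support.append(frac)
        if frac >= min_support:
            tokens.append(winner)
            consistent = [lin for lin in consistent if lin.tokens[i] == winner]
        else:
            accepted = False
    tokens.extend([""] * (N_RANKS - len(tokens)))
    majority = Lineage(tuple(tokens))

    if placement == ROOT:
        final = majority
    else:
        final = lca([majority, placement])
    truncated = final.depth < max(majority.depth, placement.depth)
    return ConsensusReport(
        lineage=final,
        majority=majority,
        placement=placement,
        support=tuple(support),
        truncated_by_placement=truncated,
    )
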