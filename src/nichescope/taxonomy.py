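"""Marker-gene consensus taxonomy and merging with genome-level assignments.

Per rank, the assignment probabilities of all marker genes are summed per
candidate taxon; the taxon with the highest total wins, with confidence equal
to its share of the total probability mass.  A winner holding less than one
third of the mass is discarded as a low-confidence assignment.  Genome-level
(whole-genome comparison) calls take precedence; consensus calls fill only
the unassigned ranks, and genomes without a kingdom-level call in the merged
lineage are flagged for removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger("nichescope")

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]
LOW_CONFIDENCE = "low confidence assignment"


@dataclass(frozen=True)
class ConsensusCall:
    rmag_id: str
    rank: str
    taxon: str  # winning taxon or LOW_CONFIDENCE
    confidence: float
    source: str = "consensus"


def consensus_assign(
    assignments: pd.DataFrame, min_frac: float = 1.0 / 3.0
) -> ConsensusCall:
    """Combine marker-gene assignments for one rMAG at one rank.

    ``assignments`` needs columns rmag_id, rank, taxon, probability (raw
    non-negative weights; the result is invariant to their overall scale).
    Ties are broken lexicographically with a logged warning.
    """
    if assignments.empty:
        raise ValueError("no assignments given")
    rmags = assignments["rmag_id"].unique()
    ranks = assignments["rank"].unique()
    if len(rmags) != 1 or len(ranks) != 1:
        raise ValueError("consensus_assign expects a single (rMAG, rank) slice")
    scores = assignments.groupby("taxon")["probability"].sum().sort_index()
    total = scores.sum()
    if total <= 0:
        return ConsensusCall(rmags[0], ranks[0], LOW_CONFIDENCE, 0.0)
    best = scores.max()
    winners = scores[scores == best]
    if len(winners) > 1:
        log.warning(
            "tie at rank %s of %s between %s: broken lexicographically",
            ranks[0], rmags[0], list(winners.index),
        )
    winner = winners.index[0]
    confidence = float(best / total)
    if confidence < min_frac:
        return ConsensusCall(rmags[0], ranks[0], LOW_CONFIDENCE, confidence)
    return ConsensusCall(rmags[0], ranks[0], winner, confidence)


def consensus_table(
    markers: pd.DataFrame, min_frac: float = 1.0 / 3.0
) -> pd.DataFrame:
    """consensus_assign over every (rMAG, rank) slice of a marker table."""
    rows = []
    for (r, rank), grp in markers.groupby(["rmag_id", "rank"]):
        call = consensus_assign(grp, min_frac=min_frac)
        rows.append(
            {
                "rmag_id": r,
                "rank": rank,
                "taxon": call.taxon,
                "confidence": call.confidence,
                "source": "consensus",
            }
        )
    return pd.DataFrame(rows)


def merge_assignments(
    genome_calls: pd.DataFrame, consensus_calls: pd.DataFrame
) -> pd.DataFrame:
    """Merge genome-level and consensus lineages per rMAG and rank.

    Genome-level calls win where present (conflicts logged); consensus fills
    only unassigned ranks, and low-confidence consensus entries do not fill.
    Output columns: rmag_id, rank, taxon, source, remove_flag — the flag is
    set for rMAGs without a kingdom-level taxon in the merged lineage.
    """
    rmags = sorted(
        set(genome_calls.get("rmag_id", pd.Series(dtype=str)))
        | set(consensus_calls.get("rmag_id", pd.Series(dtype=str)))
    )
    g = genome_calls.set_index(["rmag_id", "rank"])["taxon"] if len(genome_calls) else pd.Series(dtype=str)
    c = (
        consensus_calls.set_index(["rmag_id", "rank"])["taxon"]
        if len(consensus_calls)
        else pd.Series(dtype=str)
    )
    rows = []
    for r in rmags:
        lineage = {}
        for rank in RANKS:
            taxon, source = None, None
            if (r, rank) in g.index:
                taxon, source = g[(r, rank)], "genome"
                if (r, rank) in c.index and c[(r, rank)] not in (taxon, LOW_CONFIDENCE):
                    log.info(
                        "conflict for %s %s: genome=%s consensus=%s (genome wins)",
                        r, rank, taxon, c[(r, rank)],
                    )
            elif (r, rank) in c.index and c[(r, rank)] != LOW_CONFIDENCE:
                taxon, source = c[(r, rank)], "consensus"
            lineage[rank] = (taxon, source)
        remove = lineage["kingdom"][0] is None
        for rank in RANKS:
            taxon, source = lineage[rank]
            if taxon is not None:
                rows.append(
                    {
                        "rmag_id": r,
                        "rank": rank,
                        "taxon": taxon,
                        "source": source,
                        "remove_flag": remove,
                    }
                )
        if remove:
            rows.append(
                {
                    "rmag_id": r,
                    "rank": "kingdom",
                    "taxon": None,
                    "source": None,
                    "remove_flag": True,
                }
            )
    return pd.DataFrame(rows)
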