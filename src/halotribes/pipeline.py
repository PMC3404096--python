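"""End-to-end convenience driver: hits -> tribes -> join -> matrix.

Ties the stage modules together the way the full analysis runs them:
within-genus tribe construction from similarity hits for each genus,
cross-genus joining on averaged bit scores, profile-hit filtering and
best-profile assignment, and presence/absence matrix tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrix import (
    PresenceMatrix,
    assign_best_profile,
    build_presence_matrix,
    filter_profile_hits,
)
from .tribes import Tribe, TribeJoin, assign_functions, build_within_genus_tribes, join_tribes

__all__ = ["PipelineResult", "build_joined_tribes", "profile_presence_matrix"]


@dataclass
class PipelineResult:
    tribes: list
    joins: list
    matrix: PresenceMatrix


def build_joined_tribes(
    hits: pd.DataFrame, genes: pd.DataFrame, genera: list
) -> tuple[list, list]:
    """Build per-genus tribes and join them across the two genera.

    ``hits`` is the full all-vs-all table; within-genus subsets and the
    cross-genus subset are selected by the genomes' genus labels.
    """
    if len(genera) != 2:
        raise ValueError("exactly two genera required")
    genus_of = genes.set_index("gene_id")["genus_id"]
    q_genus = hits["query_id"].map(genus_of)
    s_genus = hits["subject_id"].map(genus_of)

    per_genus = {}
    for genus in genera:
        within = hits.loc[(q_genus == genus) & (s_genus == genus)]
        per_genus[genus] = build_within_genus_tribes(within, genes, genus)
    cross = hits.loc[q_genus != s_genus]
    return join_tribes(per_genus[genera[0]], per_genus[genera[1]], cross)


def profile_presence_matrix(
    profile_hits: pd.DataFrame,
    tribe_ids: list,
    genes: pd.DataFrame,
    genome_ids: list,
    e_max: float = 1e-4,
    cov_min: float = 0.80,
) -> PresenceMatrix:
    """Filter profile hits, assign best profiles, tabulate the matrix."""
    filtered = filter_profile_hits(profile_hits, e_max=e_max, cov_min=cov_min)
    assignments = assign_best_profile(filtered)
    gene_to_genome = dict(zip(genes["gene_id"], genes["genome_id"]))
    return build_presence_matrix(assignments, tribe_ids, genome_ids, gene_to_genome)


def run(
    hits: pd.DataFrame,
    profile_hits: pd.DataFrame,
    genes: pd.DataFrame,
    genera: list,
    genome_ids: list,
    profile_tribe_ids: list,
) -> PipelineResult:
    """Run the full tribe-and-matrix pipeline on in-memory tables."""
    tribes, joins = build_joined_tribes(hits, genes, genera)
    if "product" in genes.columns:
        tribes = assign_functions(tribes, genes)
    matrix = profile_presence_matrix(
        profile_hits, profile_tribe_ids, genes, genome_ids
    )
    return PipelineResult(tribes=tribes, joins=joins, matrix=matrix)
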