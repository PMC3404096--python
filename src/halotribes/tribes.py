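"""Ortholog tribe construction and cross-genus joining.

A *tribe* is a set of orthologous genes drawn from the genomes of one
genus (or, after joining, of two genera).  Within a genus, tribes are the
connected components of the reciprocal-best-hit (RBH) graph built from
all-vs-all protein similarity hits: for every gene and every other genome
of the genus, the best hit is the one with the highest bit score (ties
broken by lower E-value, then lexicographic subject id), and an edge is
drawn when two genes are each other's best hit in the respective genome.
Genes with no RBH partner become singleton tribes, so the tribes always
partition the genus's gene set.

Across genera, tribes are joined one-to-one by an RBH rule on *averaged*
bit scores: the score of a tribe pair is the arithmetic mean of the bit
scores of every cross hit between their members (both search directions
pooled), and a join is accepted only when each tribe is the other's
highest-scoring partner.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Tribe",
    "TribeJoin",
    "build_within_genus_tribes",
    "join_tribes",
    "assign_tribe_function",
    "assign_functions",
]

JOINED_SCOPE = "joined"


@dataclass(frozen=True)
class Tribe:
    """An ortholog set: id, member gene ids, genus scope, consensus label."""

    tribe_id: str
    members: frozenset = field(default_factory=frozenset)
    scope: str = ""
    function_label: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"tribe {self.tribe_id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass(frozen=True)
class TribeJoin:
    """An accepted one-to-one mapping between two genus-level tribes."""

    tribe_a: str
    tribe_b: str
    pair_score: float

    def __post_init__(self):
        if self.pair_score < 0:
            raise ValueError("pair_score must be non-negative")


def _gene_to_genome(genes: pd.DataFrame) -> pd.Series:
    return genes.set_index("gene_id")["genome_id"]


def _drop_self_hits(hits: pd.DataFrame) -> pd.DataFrame:
    # Self hits inflate averaged scores; they carry no orthology signal.
    return hits.loc[hits["query_id"] != hits["subject_id"]]


def build_within_genus_tribes(hits: pd.DataFrame, genes: pd.DataFrame, genus: str) -> list[Tribe]:
    """Partition the genes of one genus into RBH connected-component tribes.

    Parameters
    ----------
    hits
        Similarity hits restricted to genomes of *genus*; columns
        ``query_id, subject_id, bitscore, evalue`` (coverage columns
        optional).
    genes
        Gene records with ``gene_id, genome_id, genus_id``.
    genus
        The genus whose genes are partitioned.

    Returns
    -------
    list of Tribe sorted by tribe id, covering every gene of the genus
    exactly once.
    """
    genus_genes = genes.loc[genes["genus_id"] == genus]
    if genus_genes.empty:
        raise ValueError(f"no genes for genus {genus!r}")
    genome_of = _gene_to_genome(genus_genes)

    hits = _drop_self_hits(hits)
    for col in ("query_id", "subject_id"):
        unknown = set(hits[col]) - set(genome_of.index)
        if unknown:
            raise ValueError(
                f"hit references gene(s) outside genus {genus!r} or unknown "
                f"genome: {sorted(unknown)[:5]}"
            )

    edges = []
    if not hits.empty:
        work = hits[["query_id", "subject_id", "bitscore", "evalue"]].copy()
        work["query_genome"] = genome_of.loc[work["query_id"]].to_numpy()
        work["subject_genome"] = genome_of.loc[work["subject_id"]].to_numpy()
        # RBH is defined between genomes, never within one.
        work = work.loc[work["query_genome"] != work["subject_genome"]]
        if not work.empty:
            work = work.sort_values(
                ["query_id", "subject_genome", "bitscore", "evalue", "subject_id"],
                ascending=[True, True, False, True, True],
                kind="mergesort",
            )
            best = work.groupby(["query_id", "subject_genome"], sort=False).head(1)
            best_map = {
                (q, sg): s
                for q, sg, s in zip(
                    best["query_id"], best["subject_genome"], best["subject_id"]
                )
            }
            for (q, _sg), s in best_map.items():
                if q < s and best_map.get((s, genome_of.loc[q])) == q:
                    edges.append((q, s))

    graph = nx.Graph()
    graph.add_nodes_from(genus_genes["gene_id"])
    graph.add_edges_from(edges)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    width = max(4, len(str(len(components))))
    return [
        Tribe(tribe_id=f"{genus}:T{i:0{width}d}", members=frozenset(c), scope=genus)
        for i, c in enumerate(components, start=1)
    ]


def join_tribes(
    tribes_a: list[Tribe], tribes_b: list[Tribe], cross_hits: pd.DataFrame
) -> tuple[list[Tribe], list[TribeJoin]]:
    """Join tribes across two genera by averaged-bit-score RBH.

    The pair score of tribes (A, B) is the arithmetic mean of the bit
    scores of all cross hits between members of A and members of B, both
    directions pooled.  A join is accepted iff B is A's highest-scoring
    partner and A is B's; accepted joins merge into a single tribe with
    scope ``"joined"``.  Tribe pairs with no hits have no pair score and
    are never candidates.

    Returns the merged tribe list (unjoined tribes pass through) and the
    accepted joins.
    """
    tribe_of_a = {g: t.tribe_id for t in tribes_a for g in t.members}
    tribe_of_b = {g: t.tribe_id for t in tribes_b for g in t.members}
    by_id = {t.tribe_id: t for t in [*tribes_a, *tribes_b]}

    hits = _drop_self_hits(cross_hits)
    pair_rows = []
    for q, s, bit, qc, sc in zip(
        hits["query_id"],
        hits["subject_id"],
        hits["bitscore"],
        hits.get("q_cov", pd.Series(np.nan, index=hits.index)),
        hits.get("s_cov", pd.Series(np.nan, index=hits.index)),
    ):
        if q in tribe_of_a and s in tribe_of_b:
            ta, tb = tribe_of_a[q], tribe_of_b[s]
        elif q in tribe_of_b and s in tribe_of_a:
            ta, tb = tribe_of_a[s], tribe_of_b[q]
        else:
            raise ValueError(
                f"cross hit {q!r}->{s!r} does not connect the two genera"
            )
        cov = np.nanmean([qc, sc]) if not (pd.isna(qc) and pd.isna(sc)) else 0.0
        pair_rows.append((ta, tb, float(bit), float(cov)))

    joins: list[TribeJoin] = []
    if pair_rows:
        pairs = pd.DataFrame(pair_rows, columns=["tribe_a", "tribe_b", "bitscore", "cov"])
        agg = (
            pairs.groupby(["tribe_a", "tribe_b"], sort=True)
            .agg(pair_score=("bitscore", "mean"), mean_cov=("cov", "mean"))
            .reset_index()
        )
        best_for_a = _best_partner(agg, "tribe_a", "tribe_b")
        best_for_b = _best_partner(agg, "tribe_b", "tribe_a")
        for ta, tb in sorted(best_for_a.items()):
            if best_for_b.get(tb) == ta:
                score = float(
                    agg.loc[(agg["tribe_a"] == ta) & (agg["tribe_b"] == tb), "pair_score"].iloc[0]
                )
                joins.append(TribeJoin(tribe_a=ta, tribe_b=tb, pair_score=score))

    joined_ids = {j.tribe_a for j in joins} | {j.tribe_b for j in joins}
    out = [t for t in [*tribes_a, *tribes_b] if t.tribe_id not in joined_ids]
    for j in joins:
        a, b = by_id[j.tribe_a], by_id[j.tribe_b]
        out.append(
            Tribe(
                tribe_id=f"{j.tribe_a}|{j.tribe_b}",
                members=a.members | b.members,
                scope=JOINED_SCOPE,
            )
        )
    out.sort(key=lambda t: t.tribe_id)
    return out, joins


def _best_partner(agg: pd.DataFrame, own: str, other: str) -> dict:
    # Highest pair score wins; ties by higher mean coverage, then
    # lexicographically smallest partner id (deterministic).
    ordered = agg.sort_values(
        [own, "pair_score", "mean_cov", other],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    top = ordered.groupby(own, sort=False).head(1)
    return dict(zip(top[own], top[other]))


def assign_tribe_function(tribe: Tribe, genes: pd.DataFrame) -> str:
    """Most common product string among the tribe's members.

    Ties are broken by the lexicographically smallest product.  Raises if
    any member is missing from the annotation table.
    """
    products = genes.set_index("gene_id")["product"]
    missing = tribe.members - set(products.index)
    if missing:
        raise ValueError(
            f"tribe {tribe.tribe_id!r}: members missing from annotations: "
            f"{sorted(missing)[:5]}"
        )
    counts = Counter(products.loc[g] for g in tribe.members)
    top = max(counts.values())
    return min(p for p, c in counts.items() if c == top)


def assign_functions(tribes: list[Tribe], genes: pd.DataFrame) -> list[Tribe]:
    """Return tribes with consensus function labels filled in."""
    return [replace(t, function_label=assign_tribe_function(t, genes)) for t in tribes]
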