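"""Per-genome COG-category fractions and genus-vs-genus enrichment.

For each genome the fraction of protein-coding genes carrying a given
COG category letter is computed (a multi-category gene counts toward
every letter it carries; the denominator is always the genome's full
CDS complement, COG-annotated or not).  Genus differences are then
tested category by category with a two-sided Wilcoxon rank-sum test.

For the tiny group sizes typical of a two-genus comparison (four or
five genomes per genus) the test is computed *exactly*, by complete
enumeration of all C(m+n, m) assignments of the pooled mid-ranks to the
first group, conditioned on the observed tie pattern.  Above 12 pooled
observations a normal approximation with continuity and tie correction
is used.  No multiple-testing correction is applied: per-category raw
p-values are reported, and callers that screen many categories should
bear the implied family-wise error in mind.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = ["EnrichmentResult", "cog_fractions", "rank_sum_exact", "enrichment_table"]

#: Largest pooled sample size for which the exact enumeration is used.
EXACT_LIMIT = 12


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    mean_a: float
    mean_b: float
    u_statistic: float
    p_value: float
    significant: bool

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must lie in (0, 1]")


def cog_fractions(genes: pd.DataFrame, genomes: list | None = None) -> pd.DataFrame:
    """Per-genome fraction of CDSs carrying each COG category letter.

    Returns a genomes x categories DataFrame; a category absent from a
    genome yields 0.0.  Raises when a requested genome has no genes.
    """
    if genomes is None:
        genomes = sorted(genes["genome_id"].unique())
    counts = genes.groupby("genome_id").size()
    for g in genomes:
        if counts.get(g, 0) == 0:
            raise ValueError(f"genome {g!r} has zero genes")
    letters = sorted({c for s in genes["cog"] for c in s})
    out = pd.DataFrame(0.0, index=list(genomes), columns=letters)
    for letter in letters:
        has = genes.loc[genes["cog"].str.contains(letter, regex=False)]
        per_genome = has.groupby("genome_id").size()
        out[letter] = per_genome.reindex(genomes).fillna(0) / counts.reindex(genomes)
    return out


def rank_sum_exact(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, exact for small samples.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of the first
    group.  Ties are handled with mid-ranks; for pooled sizes up to
    :data:`EXACT_LIMIT` the p-value is the exact probability, under
    random assignment of the observed (possibly tied) ranks, of a rank
    sum at least as far from its mean as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:m].sum())
    u = w - m * (m + 1) / 2.0
    mu = m * (m + n + 1) / 2.0
    observed_dev = abs(w - mu)

    total = m + n
    if total <= EXACT_LIMIT:
        n_splits = comb(total, m)
        extreme = 0
        for idx in combinations(range(total), m):
            w_perm = ranks[list(idx)].sum()
            if abs(w_perm - mu) >= observed_dev - 1e-9:
                extreme += 1
        p = extreme / n_splits
    else:
        _t, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (total * (total - 1))
        var = m * n / 12.0 * ((total + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = max(observed_dev - 0.5, 0.0) / np.sqrt(var)
            p = min(1.0, 2.0 * norm.sf(z))
    return u, float(min(max(p, np.finfo(float).tiny), 1.0))


def enrichment_table(
    fractions: pd.DataFrame,
    groups: dict,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test each category for a genus difference in per-genome fractions.

    ``fractions`` is the genomes x categories table from
    :func:`cog_fractions`; ``groups`` maps genome id to genus.  One
    result per category (ordered as in ``fractions``); a category is
    flagged significant when its raw two-sided p-value is below
    ``alpha``.
    """
    unknown = set(groups) - set(fractions.index)
    if unknown:
        raise ValueError(f"unknown genome(s) in groups: {sorted(unknown)}")
    genera = sorted(set(groups.values()))
    if len(genera) != 2:
        raise ValueError(f"need exactly two genera, got {genera}")
    members = {
        genus: [g for g in fractions.index if groups.get(g) == genus]
        for genus in genera
    }
    for genus, ids in members.items():
        if len(ids) < 2:
            raise ValueError(f"genus {genus!r} has fewer than 2 genomes")

    results = []
    for category in fractions.columns:
        a = fractions.loc[members[genera[0]], category].to_numpy()
        b = fractions.loc[members[genera[1]], category].to_numpy()
        if not (a.any() or b.any()):
            continue  # category present in no genome
        u, p = rank_sum_exact(a, b)
        results.append(
            EnrichmentResult(
                category=category,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                u_statistic=u,
                p_value=p,
                significant=p < alpha,
            )
        )
    return results


def enrichment_frame(results: list[EnrichmentResult], genera: tuple = ("A", "B")) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per category)."""
    return pd.DataFrame(
        {
            "category": [r.category for r in results],
            f"mean_{genera[0]}": [r.mean_a for r in results],
            f"mean_{genera[1]}": [r.mean_b for r in results],
            "U": [r.u_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
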