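"""Targeted gene screens over annotations, matrices, domains and repeats.

These are the small, sharp tools of the analysis: substring screens over
product annotations (counts per genome, optionally painted onto a species
tree), detection of tribes differentially present between two clades of
the presence/absence matrix, a two-domain combined-probability filter for
multi-domain homolog vetting, and per-column conservation profiling of
aligned CRISPR direct repeats.
"""

from __future__ import annotations

from collections import Counter

import dendropy
import numpy as np
import pandas as pd

from .matrix import PresenceMatrix

__all__ = [
    "screen_by_annotation",
    "clade_differential_genes",
    "multi_domain_filter",
    "dr_conservation",
    "annotate_tree",
]

DR_ALPHABET = set("ACGTU-")


def screen_by_annotation(genes: pd.DataFrame, patterns: list) -> pd.DataFrame:
    """Count genes per genome whose product contains each pattern
    (case-insensitive substring match).

    Returns a dense genomes x patterns table; cells with no match are 0.
    """
    if not patterns:
        raise ValueError("at least one pattern required")
    if any(p == "" for p in patterns):
        raise ValueError("empty pattern string")
    genomes = sorted(genes["genome_id"].unique())
    out = pd.DataFrame(0, index=genomes, columns=list(patterns))
    lowered = genes["product"].str.lower()
    for pat in patterns:
        hit = genes.loc[lowered.str.contains(pat.lower(), regex=False)]
        counts = hit.groupby("genome_id").size()
        out[pat] = counts.reindex(genomes).fillna(0).astype(int)
    return out


def clade_differential_genes(
    matrix: PresenceMatrix, clade_in: set, clade_out: set
) -> list:
    """Tribes present in *every* clade_in genome and absent from *every*
    clade_out genome (strict all-in / none-out rule).

    Both clades must be non-empty, disjoint subsets of the matrix's
    genomes.  Returns tribe ids in matrix row order.
    """
    clade_in, clade_out = set(clade_in), set(clade_out)
    if not clade_in or not clade_out:
        raise ValueError("both clades must be non-empty")
    if clade_in & clade_out:
        raise ValueError(f"clades overlap: {sorted(clade_in & clade_out)}")
    known = set(matrix.genome_ids)
    missing = (clade_in | clade_out) - known
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")

    frame = matrix.to_frame()
    mask = frame[sorted(clade_in)].all(axis=1) & ~frame[sorted(clade_out)].any(axis=1)
    return [t for t in matrix.tribe_ids if mask[t]]


def multi_domain_filter(
    evidence: pd.DataFrame, required_domains: list, per_domain_alpha: float = 0.001
) -> list:
    """Retain genes supported by every required domain.

    A gene passes when each required domain was found AND either (a)
    every per-domain E-value is below ``per_domain_alpha``, or (b) the
    *product* of the per-domain E-values is below ``per_domain_alpha``.
    Rule (b) treats E-values as approximate per-domain chance
    probabilities: even individually insignificant matches are unlikely
    to co-occur, so their combined probability can rescue the gene.

    ``evidence`` has one row per (gene_id, domain, evalue), keeping the
    best E-value per domain per gene.  Returns retained gene ids sorted.
    """
    if not required_domains:
        raise ValueError("required_domains must be non-empty")
    required = list(dict.fromkeys(required_domains))
    best = (
        evidence.groupby(["gene_id", "domain"])["evalue"].min().unstack("domain")
    )
    retained = []
    for gene, row in best.iterrows():
        evals = [row.get(d, np.nan) for d in required]
        if any(pd.isna(e) for e in evals):
            continue  # a required domain was not found at all
        if all(e < per_domain_alpha for e in evals):
            retained.append(gene)
        elif float(np.prod(evals)) < per_domain_alpha:
            retained.append(gene)
    return sorted(retained)


def dr_conservation(aligned_repeats: list) -> np.ndarray:
    """Per-column majority-symbol frequency of an aligned repeat set.

    Input sequences must be equal length over the alphabet ACGTU- (case
    insensitive).  Returns one fraction in (0, 1] per column; at a
    four-way tie among four sequences the fraction is 0.25 (which symbol
    "won" is a display matter only and is resolved lexicographically).
    """
    seqs = [str(s).upper() for s in aligned_repeats]
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned repeats")
    width = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != width:
            raise ValueError(
                f"ragged alignment: sequence {i} has length {len(s)}, expected {width}"
            )
        bad = set(s) - DR_ALPHABET
        if bad:
            raise ValueError(f"sequence {i}: invalid symbol(s) {sorted(bad)}")
    profile = np.empty(width)
    for col in range(width):
        counts = Counter(s[col] for s in seqs)
        top = max(counts.values())
        profile[col] = top / len(seqs)
    return profile


def annotate_tree(
    tree: dendropy.Tree, counts: pd.DataFrame, default_missing: bool = False
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Decorate tree leaves with per-genome count vectors.

    ``counts`` is a genomes x quantities table (as produced by
    :func:`screen_by_annotation`).  Every leaf must appear in it unless
    ``default_missing`` is set, in which case absent leaves get zero
    counts.  Returns a decorated copy of the tree (leaf labels become
    ``name|col-value|...``, characters that survive unquoted Newick) and
    a companion table ordered by tree leaf order.
    """
    decorated = tree.clone(depth=1)
    leaves = [lf.taxon.label for lf in decorated.leaf_node_iter()]
    missing = [lf for lf in leaves if lf not in counts.index]
    if missing and not default_missing:
        raise ValueError(f"leaves missing from counts: {missing}")
    table = counts.reindex(leaves).fillna(0)
    if (counts.dtypes == int).all():
        table = table.astype(int)
    for leaf in decorated.leaf_node_iter():
        row = table.loc[leaf.taxon.label]
        suffix = "|".join(f"{col}-{row[col]}" for col in table.columns)
        leaf.taxon.label = f"{leaf.taxon.label}|{suffix}"
    return decorated, table.rename_axis("genome_id")
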