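"""Seed-reproducible synthetic two-genus pangenomes with known truth.

The generator stands in for a pair of sequenced prokaryotic genera (by
default five genomes in one genus and four in the other, as in a
two-genus haloarchaeal comparison).  It draws a fixed species tree,
places *core* ortholog tribes at the root and *genus-specific* tribes on
each genus stem, and then replays independent Bernoulli gain/loss
toggles per tribe down every branch, with an optional loss-rate boost on
one designated clade (emulating a lineage with a burst of gene loss).
One gene is emitted per (tribe, genome) wherever the tribe is present at
a leaf.

From the resulting truth it derives every input table the downstream
pipeline consumes: all-vs-all similarity hits (within-tribe pairs from a
high-score distribution, cross-tribe decoys from a low-score one),
profile hits (true member hits comfortably inside the E-value/coverage
filters, decoys straddling them), and gene annotations with controlled
product vocabulary and per-genus COG-category fractions.

Everything is a pure function of (truth, params): the same SimParams,
including the seed, reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COG_ALPHABET, HIT_COLUMNS
from .tribes import Tribe

__all__ = ["SimParams", "PangenomeTruth", "generate_pangenome",
           "emit_similarity_hits", "emit_profile_hits", "emit_annotations",
           "write_outputs", "PRODUCT_VOCABULARY"]

#: Controlled product vocabulary, so annotation screens have known truth counts.
PRODUCT_VOCABULARY = (
    "TATA-binding protein",
    "transcription factor B",
    "DNA sliding clamp (PCNA)",
    "cellulase family protein",
    "histidine kinase",
    "CheY-like response regulator",
    "ABC transporter permease",
    "polyhydroxyalkanoate synthase",
    "methylaspartate ammonia-lyase",
    "bacteriorhodopsin",
    "halorhodopsin",
    "sensory rhodopsin",
    "CRISPR-associated protein Cas1",
    "gluconolactonase",
    "2-keto-3-deoxygluconate kinase",
    "ribosomal protein L2",
    "DNA gyrase subunit A",
    "preprotein translocase SecY",
    "thermosome subunit",
    "V-type ATP synthase subunit A",
    "heavy metal transporting P-type ATPase",
    "universal stress protein UspA",
    "transducer protein Htr",
    "phosphate ABC transporter substrate-binding protein",
)

_HYPOTHETICAL = "hypothetical protein"


@dataclass(frozen=True)
class SimParams:
    """Generator settings; the defaults are the study conditions.

    ``n_genomes_per_genus`` and ``n_genus_tribes`` map genus name to a
    count; ``cog_effect`` maps a COG category letter to per-genus mean
    fractions, e.g. ``{"T": {"Haloferax": 0.030, "Haloarcula": 0.042}}``.
    ``clade_loss_boost`` multiplies the loss rate on every branch inside
    the designated clade (by default the last three genomes of the first
    genus).
    """

    n_genomes_per_genus: dict = field(
        default_factory=lambda: {"Haloferax": 5, "Haloarcula": 4}
    )
    n_core_tribes: int = 2600
    n_genus_tribes: dict = field(
        default_factory=lambda: {"Haloferax": 900, "Haloarcula": 900}
    )
    loss_rate: float = 0.02
    gain_rate: float = 0.005
    clade_loss_boost: float = 5.0
    boost_clade: tuple = ()  # genome ids; empty = default clade
    cog_effect: dict = field(
        default_factory=lambda: {"T": {"Haloferax": 0.030, "Haloarcula": 0.042}}
    )
    cog_background: float = 0.62
    product_fidelity: float = 0.85
    decoy_fraction: float = 0.05
    profile_decoy_fraction: float = 0.10
    score_noise_sd: float = 2.0
    tree_newick: str = ""  # empty = default ladderized two-genus topology
    seed: int = 0

    def __post_init__(self):
        if len(self.n_genomes_per_genus) != 2:
            raise ValueError("n_genomes_per_genus: exactly two genera required")
        for genus, n in self.n_genomes_per_genus.items():
            if n < 1:
                raise ValueError(f"n_genomes_per_genus[{genus!r}] must be positive")
        if self.n_core_tribes < 0:
            raise ValueError("n_core_tribes must be non-negative")
        for genus in self.n_genus_tribes:
            if genus not in self.n_genomes_per_genus:
                raise ValueError(f"n_genus_tribes: unknown genus {genus!r}")
            if self.n_genus_tribes[genus] < 0:
                raise ValueError(f"n_genus_tribes[{genus!r}] must be non-negative")
        for name in ("loss_rate", "gain_rate", "cog_background", "product_fidelity",
                     "decoy_fraction", "profile_decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.clade_loss_boost < 1.0:
            raise ValueError("clade_loss_boost must be >= 1")
        if self.loss_rate * self.clade_loss_boost > 1.0:
            raise ValueError("loss_rate * clade_loss_boost exceeds 1")
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be non-negative")
        for letter, per_genus in self.cog_effect.items():
            if letter not in COG_ALPHABET or len(letter) != 1:
                raise ValueError(f"cog_effect: invalid COG letter {letter!r}")
            for genus, frac in per_genus.items():
                if genus not in self.n_genomes_per_genus:
                    raise ValueError(f"cog_effect[{letter!r}]: unknown genus {genus!r}")
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"cog_effect[{letter!r}][{genus!r}] not in [0, 1]")

    @property
    def genera(self) -> list:
        return list(self.n_genomes_per_genus)

    def genome_ids(self, genus: str) -> list:
        return [f"{genus}_g{i}" for i in range(1, self.n_genomes_per_genus[genus] + 1)]


@dataclass
class PangenomeTruth:
    """Ground truth: tribes, tree, per-branch event log, leaf presence."""

    params: SimParams
    tree_newick: str
    tribes: list  # list[Tribe], true membership at the leaves
    tribe_table: pd.DataFrame  # tribe_id, scope, product, length_aa
    presence: pd.DataFrame  # tribes x genomes, 0/1
    events: pd.DataFrame  # node, tribe_id, event ("gain" | "loss")
    genes: pd.DataFrame  # gene_id, genome_id, genus_id, tribe_id

    @property
    def genome_ids(self) -> list:
        return list(self.presence.columns)

    @property
    def tribe_ids(self) -> list:
        return list(self.presence.index)


# ---------------------------------------------------------------------------
# tree plumbing (simple node records; Newick is the exchange format)
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "children", "parent")

    def __init__(self, name, children=()):
        self.name = name
        self.children = list(children)
        self.parent = None
        for c in self.children:
            c.parent = self

    def leaves(self):
        if not self.children:
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves()]

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def newick(self):
        if not self.children:
            return self.name
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}){self.name}"


def _genus_subtree(genus: str, leaves: list, counter: list) -> _Node:
    """Two-cherry-versus-ladder topology: ((g1,g2),(g3,(g4,(g5,...)))).

    For >= 3 leaves the clade of leaves g3..gn is a proper subtree, which
    is the default target of the clade loss boost.
    """
    def internal():
        counter[0] += 1
        return f"N{counter[0]}"

    tips = [_Node(name) for name in leaves]
    if len(tips) == 1:
        return tips[0]
    if len(tips) == 2:
        return _Node(internal(), tips)
    ladder = tips[-1]
    for tip in reversed(tips[2:-1]):
        ladder = _Node(internal(), [tip, ladder])
    cherry = _Node(internal(), tips[:2])
    return _Node(internal(), [cherry, ladder])


def _parse_simple_newick(text: str) -> _Node:
    """Parse a branch-length-free Newick string into _Node records."""
    text = text.strip().rstrip(";")
    pos = [0]
    counter = [0]

    def read_name():
        start = pos[0]
        while pos[0] < len(text) and text[pos[0]] not in "(),:;":
            pos[0] += 1
        name = text[start:pos[0]]
        if pos[0] < len(text) and text[pos[0]] == ":":
            pos[0] += 1
            while pos[0] < len(text) and text[pos[0]] not in "(),;":
                pos[0] += 1
        return name

    def node():
        if text[pos[0]] == "(":
            pos[0] += 1
            children = [node()]
            while text[pos[0]] == ",":
                pos[0] += 1
                children.append(node())
            if text[pos[0]] != ")":
                raise ValueError(f"Newick syntax error at position {pos[0]}")
            pos[0] += 1
            name = read_name()
            if not name:
                counter[0] += 1
                name = f"N{counter[0]}"
            return _Node(name, children)
        name = read_name()
        if not name:
            raise ValueError(f"Newick syntax error at position {pos[0]}")
        return _Node(name)

    root = node()
    return root


def _species_tree(params: SimParams) -> tuple:
    """Return (root, genus stem node per genus, default boost clade)."""
    if params.tree_newick:
        root = _parse_simple_newick(params.tree_newick)
        expected = {g for genus in params.genera for g in params.genome_ids(genus)}
        if set(root.leaves()) != expected:
            raise ValueError("tree_newick leaves do not match genome ids")
        stems = {}
        for genus in params.genera:
            want = set(params.genome_ids(genus))
            stems[genus] = next(
                n for n in root.preorder() if set(n.leaves()) == want
            )
    else:
        counter = [0]
        stems = {
            genus: _genus_subtree(genus, params.genome_ids(genus), counter)
            for genus in params.genera
        }
        counter[0] += 1
        root = _Node("root", list(stems.values()))
    if params.boost_clade:
        boost = set(params.boost_clade)
    else:
        first = params.genera[0]
        ids = params.genome_ids(first)
        boost = set(ids[2:])  # empty when the genus has < 3 genomes
    return root, stems, boost


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _rng(params: SimParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def generate_pangenome(params: SimParams) -> PangenomeTruth:
    """Simulate tribe gain/loss down the species tree and emit the truth."""
    rng = _rng(params, 0)
    root, stems, boost = _species_tree(params)
    genera = params.genera

    tribe_ids, scope = [], []
    width = max(4, len(str(params.n_core_tribes + sum(params.n_genus_tribes.values()))))
    for i in range(1, params.n_core_tribes + 1):
        tribe_ids.append(f"CORE{i:0{width}d}")
        scope.append("core")
    for genus in genera:
        for i in range(1, params.n_genus_tribes.get(genus, 0) + 1):
            tribe_ids.append(f"{genus.upper()}{i:0{width}d}")
            scope.append(genus)
    n_tribes = len(tribe_ids)
    scope = np.array(scope)

    lengths = rng.integers(150, 601, size=n_tribes)
    products = rng.choice(np.array(PRODUCT_VOCABULARY, dtype=object), size=n_tribes)

    # Root presence: core tribes only; genus tribes arrive as forced gains
    # on their genus stem edge.
    root_presence = scope == "core"
    presence_at = {root: root_presence}
    event_rows = []
    leaf_presence = {}

    for node in root.preorder():
        if node is root:
            if not node.children:
                leaf_presence[node.name] = presence_at[node]
            continue
        parent_state = presence_at[node.parent]
        state = parent_state.copy()

        node_leaves = set(node.leaves())
        boosted = bool(boost) and node_leaves <= boost
        loss_p = params.loss_rate * (params.clade_loss_boost if boosted else 1.0)
        u = rng.random(n_tribes)
        # A tribe present at the parent may be lost; an absent one gained.
        toggles = np.where(state, u < loss_p, u < params.gain_rate)

        stem_genus = next((g for g, s in stems.items() if s is node), None)
        if stem_genus is not None:
            # Genus-specific tribes arrive deterministically on their stem.
            toggles[(scope == stem_genus) & ~state] = True

        state = state ^ toggles
        presence_at[node] = state
        for idx in np.flatnonzero(toggles):
            event_rows.append(
                (node.name, tribe_ids[idx], "gain" if state[idx] else "loss")
            )
        if not node.children:
            leaf_presence[node.name] = state

    genome_ids = [g for genus in genera for g in params.genome_ids(genus)]
    presence = pd.DataFrame(
        {g: leaf_presence[g].astype(np.int8) for g in genome_ids}, index=tribe_ids
    )

    genus_of = {g: genus for genus in genera for g in params.genome_ids(genus)}
    gene_rows = []
    for g in genome_ids:
        for idx in np.flatnonzero(presence[g].to_numpy()):
            tid = tribe_ids[idx]
            gene_rows.append((f"{g}|{tid}", g, genus_of[g], tid))
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "genome_id", "genus_id", "tribe_id"]
    )

    tribe_table = pd.DataFrame(
        {
            "tribe_id": tribe_ids,
            "scope": scope,
            "product": products,
            "length_aa": lengths,
        }
    )
    member_lists = genes.groupby("tribe_id")["gene_id"].agg(list)
    truth_tribes = [
        Tribe(tribe_id=t, members=frozenset(member_lists[t]), scope=s)
        for t, s in zip(tribe_ids, scope)
        if t in member_lists.index
    ]
    events = pd.DataFrame(event_rows, columns=["node", "tribe_id", "event"])
    return PangenomeTruth(
        params=params,
        tree_newick=root.newick() + ";",
        tribes=truth_tribes,
        tribe_table=tribe_table,
        presence=presence,
        events=events,
        genes=genes,
    )


# ---------------------------------------------------------------------------
# derived tables
# ---------------------------------------------------------------------------

def _gene_lengths(truth: PangenomeTruth) -> pd.Series:
    base = truth.tribe_table.set_index("tribe_id")["length_aa"]
    return pd.Series(
        base.loc[truth.genes["tribe_id"]].to_numpy(),
        index=truth.genes["gene_id"].to_numpy(),
    )


def emit_similarity_hits(truth: PangenomeTruth, params: SimParams) -> pd.DataFrame:
    """All-vs-all style hit table: every directed within-tribe pair gets a
    high bit score (about 2 bits per aligned residue), plus a fraction of
    random cross-tribe decoy pairs from a clearly lower score range.

    With ``score_noise_sd = 0`` the two score distributions are fully
    separated.  E-values are a fixed monotone transform of the bit score.
    """
    if truth.genes.empty:
        return pd.DataFrame(columns=HIT_COLUMNS + ["q_cov", "s_cov"])
    rng = _rng(params, 1)
    lengths = _gene_lengths(truth)

    q_list, s_list = [], []
    for members in truth.genes.groupby("tribe_id", sort=True)["gene_id"].agg(list):
        members = sorted(members)
        for a in members:
            for b in members:
                if a != b:
                    q_list.append(a)
                    s_list.append(b)
    n_within = len(q_list)

    all_genes = truth.genes["gene_id"].to_numpy()
    tribe_of = dict(zip(truth.genes["gene_id"], truth.genes["tribe_id"]))
    n_decoys = int(round(params.decoy_fraction * n_within))
    d_q, d_s = [], []
    while len(d_q) < n_decoys:
        need = n_decoys - len(d_q)
        qs = rng.choice(all_genes, size=need * 2)
        ss = rng.choice(all_genes, size=need * 2)
        for q, s in zip(qs, ss):
            if q != s and tribe_of[q] != tribe_of[s] and len(d_q) < n_decoys:
                d_q.append(q)
                d_s.append(s)

    query = np.array(q_list + d_q, dtype=object)
    subject = np.array(s_list + d_s, dtype=object)
    is_within = np.zeros(len(query), dtype=bool)
    is_within[:n_within] = True

    qlen = lengths.loc[query].to_numpy(dtype=float)
    slen = lengths.loc[subject].to_numpy(dtype=float)
    span_frac = np.where(
        is_within, rng.uniform(0.90, 1.0, len(query)), rng.uniform(0.30, 0.75, len(query))
    )
    aln_len = np.maximum(1, np.round(span_frac * np.minimum(qlen, slen))).astype(int)

    noise = rng.normal(0.0, params.score_noise_sd, len(query))
    bitscore = np.where(
        is_within, 2.0 * np.minimum(qlen, slen), rng.uniform(30.0, 70.0, len(query))
    ) + noise
    bitscore = np.round(np.maximum(bitscore, 25.0), 1)
    evalue = np.minimum(10.0, 1e6 * np.exp2(-bitscore))
    evalue = np.maximum(evalue, 1e-180)
    pident = np.where(
        is_within, rng.uniform(55.0, 95.0, len(query)), rng.uniform(22.0, 38.0, len(query))
    )
    mismatches = np.round(aln_len * (1 - pident / 100.0)).astype(int)

    hits = pd.DataFrame(
        {
            "query_id": query,
            "subject_id": subject,
            "pident": np.round(pident, 1),
            "aln_len": aln_len,
            "mismatches": mismatches,
            "gap_opens": np.zeros(len(query), dtype=int),
            "qstart": np.ones(len(query), dtype=int),
            "qend": aln_len,
            "sstart": np.ones(len(query), dtype=int),
            "send": aln_len,
            "evalue": evalue,
            "bitscore": bitscore,
        }
    )
    hits["q_cov"] = aln_len / qlen
    hits["s_cov"] = aln_len / slen
    return hits


def emit_profile_hits(truth: PangenomeTruth, params: SimParams) -> pd.DataFrame:
    """Profile search results, one profile per tribe.

    True member hits are well inside the downstream filters (E < 1e-6,
    coverage > 0.9); decoy gene-profile pairs straddle both thresholds
    (E-values in [1e-6, 1], coverages in [0.5, 1.0]) but can never win a
    best-E-value contest against a true hit.
    """
    if truth.genes.empty:
        return pd.DataFrame(
            columns=["gene_id", "profile_id", "evalue", "cov_gene", "cov_profile"]
        )
    rng = _rng(params, 2)
    genes = truth.genes["gene_id"].to_numpy()
    profiles = truth.genes["tribe_id"].to_numpy()
    n_true = len(genes)

    true_e = 10.0 ** (-rng.uniform(8.0, 30.0, n_true))
    true_cg = rng.uniform(0.905, 1.0, n_true)
    true_cp = rng.uniform(0.905, 1.0, n_true)

    all_profiles = truth.tribe_table["tribe_id"].to_numpy()
    tribe_of = dict(zip(genes, profiles))
    n_decoys = int(round(params.profile_decoy_fraction * n_true))
    d_g, d_p = [], []
    while len(d_g) < n_decoys:
        need = n_decoys - len(d_g)
        gs = rng.choice(genes, size=need * 2)
        ps = rng.choice(all_profiles, size=need * 2)
        for g, p in zip(gs, ps):
            if tribe_of[g] != p and len(d_g) < n_decoys:
                d_g.append(g)
                d_p.append(p)
    decoy_e = 10.0 ** (-rng.uniform(0.0, 6.0, n_decoys))
    decoy_cg = rng.uniform(0.5, 1.0, n_decoys)
    decoy_cp = rng.uniform(0.5, 1.0, n_decoys)

    return pd.DataFrame(
        {
            "gene_id": np.concatenate([genes, np.array(d_g, dtype=object)]),
            "profile_id": np.concatenate([profiles, np.array(d_p, dtype=object)]),
            "evalue": np.concatenate([true_e, decoy_e]),
            "cov_gene": np.concatenate([true_cg, decoy_cg]),
            "cov_profile": np.concatenate([true_cp, decoy_cp]),
        }
    )


def emit_annotations(truth: PangenomeTruth, params: SimParams) -> pd.DataFrame:
    """Gene records with product strings and COG category letters.

    Each gene carries its tribe's product with probability
    ``product_fidelity`` (otherwise "hypothetical protein").  For every
    category in ``cog_effect`` a gene receives that letter independently
    with the genus-mean probability, so the expected per-genome fraction
    equals the target; remaining genes get a background letter with
    probability ``cog_background``.
    """
    rng = _rng(params, 3)
    genes = truth.genes
    n = len(genes)
    tribe_info = truth.tribe_table.set_index("tribe_id")
    product = tribe_info.loc[genes["tribe_id"], "product"].to_numpy(dtype=object)
    keep = rng.random(n) < params.product_fidelity
    product = np.where(keep, product, _HYPOTHETICAL)
    length = tribe_info.loc[genes["tribe_id"], "length_aa"].to_numpy()

    target_letters = sorted(params.cog_effect)
    cogs = [[] for _ in range(n)]
    genus = genes["genus_id"].to_numpy()
    for letter in target_letters:
        p = np.array([params.cog_effect[letter].get(g, 0.0) for g in genus])
        hit = rng.random(n) < p
        for i in np.flatnonzero(hit):
            cogs[i].append(letter)
    background_pool = [c for c in COG_ALPHABET if c not in target_letters]
    bg_hit = rng.random(n) < params.cog_background
    bg_letter = rng.choice(np.array(background_pool), size=n)
    for i in np.flatnonzero(bg_hit):
        if not cogs[i]:
            cogs[i].append(bg_letter[i])

    return pd.DataFrame(
        {
            "gene_id": genes["gene_id"],
            "genome_id": genes["genome_id"],
            "genus_id": genes["genus_id"],
            "product": product,
            "cog": ["".join(c) for c in cogs],
            "length_aa": length,
        }
    )


def write_outputs(truth: PangenomeTruth, params: SimParams, outdir) -> dict:
    """Write every derived table plus tree and truth matrix to a directory."""
    from pathlib import Path

    from . import io as htio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotations": outdir / "annotations.tsv",
        "hits": outdir / "similarity_hits.tsv",
        "profile_hits": outdir / "profile_hits.tsv",
        "tree": outdir / "species_tree.nwk",
        "truth_matrix": outdir / "truth_matrix.tsv",
        "events": outdir / "events.tsv",
    }
    htio.write_annotations(emit_annotations(truth, params), paths["annotations"])
    htio.write_hits(emit_similarity_hits(truth, params), paths["hits"])
    htio.write_profile_hits(emit_profile_hits(truth, params), paths["profile_hits"])
    paths["tree"].write_text(truth.tree_newick + "\n")
    truth.presence.rename_axis("tribe_id").to_csv(
        paths["truth_matrix"], sep="\t", lineterminator="\n"
    )
    truth.events.to_csv(paths["events"], sep="\t", index=False, lineterminator="\n")
    return paths
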