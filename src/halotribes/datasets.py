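"""Published summary numbers for the two-genus haloarchaeal comparison.

These are the printed per-assembly characteristics of the five
*Haloferax* and four *Haloarcula* genomes (plus the resequencing control
run of *Hfx. volcanii*), the CRISPR/Cas and general-transcription-factor
counts, the control-vs-reference discrepancy figures, and the worked
two-domain E-value example.  They are inputs to the comparison
operations in :mod:`halotribes.genome_stats` and the screens — small
published tables, not computed results.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "genome_characteristics",
    "crispr_counts",
    "gtf_counts",
    "SPECIES_TREE_NEWICK",
    "SIZE_COMPARISON_GROUP_HFX",
    "SIZE_COMPARISON_GROUP_HAR",
    "FRAGMENT_CONTIG_GROUP_HFX",
    "FRAGMENT_CONTIG_GROUP_HAR",
    "NEW_GENOME_FINAL_CONTIGS",
    "CONTROL_DISCREPANCIES",
    "PCNA_EXAMPLE_EVALUES",
]

_NA = np.nan

# genome, genus, fragment-assembly contigs (>200 bp), final assembly count
# (scaffolds where mate-pair libraries were added), assembled bp, fold
# coverage, CDS count, RNA count, % coding, % GC.  GenBank reference
# genomes have no fragment assembly; the volcanii control was not
# annotated.
_TABLE_ROWS = [
    # genome_id,            genus,       frag, final, assembled_bp, cov,  cds,  rna, pct_coding, pct_gc
    ("Har_californiae",     "Haloarcula", 168, 168, 4_420_514, 21.0, 4627, 69, 87.00, 60.82),
    ("Har_sinaiiensis",     "Haloarcula", 140,  10, 4_524_388, 19.0, 4538, 55, 84.62, 60.77),
    ("Har_vallismortis",    "Haloarcula",  88,  88, 3_930_055, 24.0, 4084, 84, 88.22, 61.79),
    ("Har_marismortui_ref", "Haloarcula", _NA,   9, 4_274_642, _NA, 4325, 62, 85.83, 61.12),
    ("Hfx_denitrificans",   "Haloferax",   21,  21, 3_848_468, 25.0, 3809, 58, 85.80, 66.27),
    ("Hfx_mediterranei",    "Haloferax",  141,   5, 3_905_749, 26.0, 3942, 62, 85.83, 60.27),
    ("Hfx_mucosum",         "Haloferax",   26,  26, 3_371_699, 29.0, 3455, 61, 86.38, 61.84),
    ("Hfx_sulfurifontis",   "Haloferax",   29,  29, 3_816_558, 27.0, 3856, 59, 86.56, 66.30),
    ("Hfx_volcanii_control","Haloferax",  145, 145, 3_920_004, 25.0, _NA, _NA, _NA, _NA),
    ("Hfx_volcanii_ref",    "Haloferax",  _NA,   5, 4_012_900, _NA, 4015, 49, 85.56, 65.48),
]


def genome_characteristics() -> pd.DataFrame:
    """Per-assembly characteristics table, indexed by genome id."""
    df = pd.DataFrame(
        _TABLE_ROWS,
        columns=[
            "genome_id", "genus", "fragment_contigs", "final_contigs",
            "assembled_bp", "coverage", "cds_count", "rna_count",
            "pct_coding", "pct_gc",
        ],
    ).set_index("genome_id")
    return df


#: Groupings for the genus mean size / CDS comparison: the five Haloferax
#: (new assemblies plus the reference volcanii genome, excluding the
#: resequencing control) against the four Haloarcula (three new plus the
#: reference marismortui genome).
SIZE_COMPARISON_GROUP_HFX = [
    "Hfx_denitrificans", "Hfx_mediterranei", "Hfx_mucosum",
    "Hfx_sulfurifontis", "Hfx_volcanii_ref",
]
SIZE_COMPARISON_GROUP_HAR = [
    "Har_californiae", "Har_sinaiiensis", "Har_vallismortis",
    "Har_marismortui_ref",
]

#: Groupings for the fragment-assembly contig-count ratio: the three
#: Haloarcula fragment assemblies against the five Haloferax fragment
#: assemblies (including the resequenced control).  This is the only
#: grouping consistent with comparing like-for-like single-plate
#: fragment runs.
FRAGMENT_CONTIG_GROUP_HFX = [
    "Hfx_denitrificans", "Hfx_mediterranei", "Hfx_mucosum",
    "Hfx_sulfurifontis", "Hfx_volcanii_control",
]
FRAGMENT_CONTIG_GROUP_HAR = [
    "Har_californiae", "Har_sinaiiensis", "Har_vallismortis",
]

#: The seven newly sequenced genomes (excluding the control and the two
#: reference genomes), with their final assembly counts — scaffolds for
#: the two mate-pair-improved assemblies, contigs over 200 bp otherwise.
NEW_GENOME_FINAL_CONTIGS = {
    "Har_californiae": 168,
    "Har_sinaiiensis": 10,
    "Har_vallismortis": 88,
    "Hfx_denitrificans": 21,
    "Hfx_mediterranei": 5,
    "Hfx_mucosum": 26,
    "Hfx_sulfurifontis": 29,
}

#: Resequencing control vs reference: thirteen single-base discrepancies
#: between the two volcanii assemblies; the control lacked 123 regions
#: (total 119,245 bp) present in the reference and carried 140 short
#: extra sequences (total 1,319 bp).
CONTROL_DISCREPANCIES = {
    "n_base_discrepancies": 13,
    "assembly_lengths": (3_920_004, 4_012_900),
    "missing_regions": {"count": 123, "median_bp": 1126, "total_bp": 119_245},
    "extra_regions": {"count": 140, "median_bp": 3, "total_bp": 1_319},
}

#: Worked two-domain example: a sliding-clamp homolog with individually
#: insignificant matches to the clamp's N- and C-terminal domains.
PCNA_EXAMPLE_EVALUES = {"PCNA_N": 0.0011, "PCNA_C": 0.17}

#: Species tree for the nine focal genomes (topology only).
SPECIES_TREE_NEWICK = (
    "(((Hfx_mucosum,Hfx_mediterranei),"
    "(Hfx_denitrificans,(Hfx_sulfurifontis,Hfx_volcanii))),"
    "(((Har_californiae,Har_sinaiiensis),Har_marismortui),Har_vallismortis));"
)

_CRISPR_ROWS = [
    ("Hfx_mucosum", 16, 7),
    ("Hfx_denitrificans", 12, 7),
    ("Hfx_sulfurifontis", 10, 6),
    ("Hfx_mediterranei", 5, 7),
    ("Hfx_volcanii", 4, 6),
    ("Har_californiae", 6, 4),
    ("Har_marismortui", 5, 7),
    ("Har_sinaiiensis", 3, 6),
    ("Har_vallismortis", 1, 0),
]


def crispr_counts() -> pd.DataFrame:
    """CRISPR locus and Cas gene counts for the nine focal genomes."""
    return pd.DataFrame(
        _CRISPR_ROWS, columns=["genome_id", "crisprs", "cas_genes"]
    ).set_index("genome_id")


_GTF_ROWS = [
    ("Hfx_mucosum", 4, 7),
    ("Hfx_denitrificans", 4, 8),
    ("Hfx_sulfurifontis", 3, 9),
    ("Hfx_mediterranei", 4, 8),
    ("Hfx_volcanii", 4, 9),
    ("Har_californiae", 2, 8),
    ("Har_marismortui", 1, 8),
    ("Har_sinaiiensis", 1, 8),
    ("Har_vallismortis", 1, 7),
]


def gtf_counts() -> pd.DataFrame:
    """TATA-binding protein and TFB counts for the nine focal genomes."""
    return pd.DataFrame(
        _GTF_ROWS, columns=["genome_id", "tbps", "tfbs"]
    ).set_index("genome_id")
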