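"""Curated reference tables for the M. rubrum / G. cryophila system.

Two small tables ship with the package:

* subcategory protein counts — per-KEGG-subcategory annotated protein
  counts for the free-living cryptophyte library (GC) and the
  kleptokaryon gene set (KN), with the originally reported FDR-adjusted
  p-values (one significant figure) and significance flags;
* pigment-pathway log2 fold changes — per-transcript log2FC (KN over GC)
  for the porphyrin & chlorophyll metabolism and carotenoid biosynthesis
  pathways, as reported for the no-replicate differential-expression
  analysis of reciprocal best hits.

Both are used as worked examples and as regression anchors: the pipeline
is expected to reproduce the significance pattern of the first table and
the classification arithmetic of the second.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .categories import CategoryCounts

PORPHYRIN = "Porphyrin & chlorophyll metabolism"
CAROTENOID = "Carotenoid biosynthesis"


def _read(name: str) -> pd.DataFrame:
    with resources.files("kleptotx.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_subcategory_protein_counts() -> pd.DataFrame:
    """17 analyzed KEGG subcategories with GC/KN protein counts."""
    df = _read("subcategory_protein_counts.tsv")
    df["reported_significant"] = df["reported_significant"].astype(bool)
    return df


def subcategory_counts_as_rows() -> list[CategoryCounts]:
    """The protein-count table as CategoryCounts rows for the enrichment engine."""
    df = load_subcategory_protein_counts()
    rows: list[CategoryCounts] = []
    for rec in df.itertuples():
        rows.append(CategoryCounts(rec.subcategory, "subcategory", "GC", int(rec.n_gc)))
        rows.append(CategoryCounts(rec.subcategory, "subcategory", "KN", int(rec.n_kn)))
    return rows


def load_pigment_pathway_log2fc() -> pd.DataFrame:
    """Per-transcript log2FC for the two pigment/oxidative-stress pathways.

    Note: the accompanying text refers to nine carotenoid-biosynthesis
    transcripts, but only eight rows are individually listed; the table
    records the rows as printed.
    """
    return _read("pigment_pathway_log2fc.tsv")
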