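"""End-to-end orchestration: partition -> rollup -> enrichment ->
expression -> RBBH -> DEG, with every threshold echoed into run metadata.

The pipeline is a pure function of (input files, config): identical
inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as kio
from .categories import ko_level_expression, rollup_protein_counts
from .deg import reciprocal_best_hits, run_deg
from .partition import KN, assign_origin, best_hit_per_query, threshold_sweep
from .stats import (
    category_expression,
    category_protein_enrichment,
    gene_rpbp_vectors,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRpbpRow:
    """One gene's length-normalized expression in one unit (long format,
    the boxplot-ready export)."""

    unit_id: str
    level: str
    library: str
    gene_id: str
    reads_per_bp: float


@dataclass
class RunConfig:
    fasta_gc: Path
    fasta_mr: Path
    hits: Path
    taxa: Path
    gene_ko: Path
    hierarchy: Path
    counts: Path
    fwd_hits: Path
    rev_hits: Path
    out_dir: Path
    evalue: float = 1e-4
    sweep: tuple[float, ...] = (1e-4, 1e-30)
    alpha: float = 0.05
    dispersion: float = 0.3
    log2fc_boundary: float = 1.0
    denominators: str = "category_sum"
    norm_method: str = "tmm"
    seed: int = 0

    def validate(self) -> None:
        for name in ("fasta_gc", "fasta_mr", "hits", "taxa", "gene_ko", "hierarchy",
                     "counts", "fwd_hits", "rev_hits"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.evalue <= 0 or any(t <= 0 for t in self.sweep):
            raise ValueError("e-value thresholds must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.log2fc_boundary <= 0:
            raise ValueError("log2fc class boundary must be positive")
        if self.denominators not in ("category_sum", "annotated_total"):
            raise ValueError(f"unknown denominators mode {self.denominators!r}")
        if self.norm_method not in ("tmm", "median_ratio"):
            raise ValueError(f"unknown normalization method {self.norm_method!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write all result TSVs plus run metadata.

    Any stage failure propagates wrapped with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read-inputs"
    try:
        genes_gc = kio.read_fasta(config.fasta_gc, library="GC")
        genes_mr = kio.read_fasta(config.fasta_mr, library="MR")
        hits = kio.read_hit_table(config.hits)
        taxa = kio.read_taxon_map(config.taxa)
        hier = kio.read_ko_hierarchy(config.gene_ko, config.hierarchy)
        counts = kio.read_count_table(config.counts, genes_gc + genes_mr)
        fwd = kio.read_hit_table(config.fwd_hits)
        rev = kio.read_hit_table(config.rev_hits)

        stage = "partition"
        mr_ids = [g.gene_id for g in genes_mr]
        best = best_hit_per_query(hits)
        calls, summary = assign_origin(best, taxa, config.evalue, genes=mr_ids)
        summaries = threshold_sweep(hits, taxa, list(config.sweep), genes=mr_ids)
        kio.write_results_tsv(calls, out / "origin_calls.tsv")
        kio.write_results_tsv(summaries, out / "partition_summary.tsv")

        stage = "rollup"
        kn_genes = {c.gene_id for c in calls if c.origin == KN}
        analysis_counts = counts.relabel({"MR": "KN"}, genes={"MR": kn_genes})
        annotated = {
            lib: [g for g in analysis_counts.genes(lib) if hier.kos_of(g)]
            for lib in ("GC", "KN")
        }
        subcat_counts = rollup_protein_counts(annotated, hier, "subcategory")

        stage = "enrichment"
        totals = {lib: len(annotated[lib]) for lib in annotated}
        enrich_rows = category_protein_enrichment(
            subcat_counts, denominators=config.denominators, alpha=config.alpha, totals=totals
        )
        kio.write_results_tsv(enrich_rows, out / "enrichment_subcategory.tsv")

        stage = "expression"
        for level in ("subcategory", "pathway"):
            rows = category_expression(analysis_counts, hier, level, alpha=config.alpha)
            kio.write_results_tsv(rows, out / f"expression_{level}.tsv")
        rpbp_rows = [
            GeneRpbpRow(unit, "pathway", lib, gene, rpb)
            for lib in ("GC", "KN")
            for unit, vec in sorted(
                _rpbp_long(analysis_counts, hier, lib).items()
            )
            for gene, rpb in vec
        ]
        kio.write_results_tsv(rpbp_rows, out / "gene_rpbp_pathway.tsv", row_type=GeneRpbpRow)

        stage = "ko-expression"
        ko_rows = []
        for lib in ("GC", "KN"):
            ko_rows.extend(ko_level_expression(analysis_counts, hier, lib))
        kio.write_results_tsv(ko_rows, out / "ko_expression.tsv")

        stage = "rbbh-deg"
        pairs = reciprocal_best_hits(fwd, rev, e_threshold=config.evalue)
        if pairs:
            deg_rows, factors = run_deg(
                analysis_counts, pairs, method=config.norm_method,
                dispersion=config.dispersion, alpha=config.alpha,
            )
            kio.write_results_tsv(deg_rows, out / "deg.tsv")
            factor_meta = dataclasses.asdict(factors)
        else:
            from .deg import DegRow

            kio.write_results_tsv([], out / "deg.tsv", row_type=DegRow)
            factor_meta = None
            logger.warning("no reciprocal best hits found; DEG table is empty")

        stage = "metadata"
        meta = {
            "kleptotx_version": __version__,
            "seed": config.seed,
            "thresholds": {
                "evalue": config.evalue,
                "sweep": list(config.sweep),
                "alpha": config.alpha,
                "dispersion": config.dispersion,
                "log2fc_boundary": config.log2fc_boundary,
            },
            "denominators": config.denominators,
            "norm_method": config.norm_method,
            "norm_factors": factor_meta,
            "n_rbbh_pairs": len(pairs),
            "partition": dataclasses.asdict(summary),
            "tie_break": "evalue, then bitscore, then subject id (lexicographic)",
            "input_sha256": {
                name: _sha256(Path(getattr(config, name)))
                for name in ("fasta_gc", "fasta_mr", "hits", "taxa", "gene_ko",
                             "hierarchy", "counts", "fwd_hits", "rev_hits")
            },
        }
        with open(out / "run_metadata.yaml", "w") as handle:
            yaml.safe_dump(meta, handle, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _rpbp_long(counts, hier, library):
    """unit -> [(gene_id, reads_per_bp)] helper for the long export."""
    out: dict[str, list[tuple[str, float]]] = {u: [] for u in hier.units("pathway")}
    for gene_id in counts.genes(library):
        rpb = counts.count(library, gene_id) / counts.length(library, gene_id)
        for unit in hier.units_of_gene(gene_id, "pathway"):
            out[unit].append((gene_id, rpb))
    return out


REPORT_INPUTS = (
    "enrichment_subcategory.tsv",
    "gene_rpbp_pathway.tsv",
    "deg.tsv",
)


def make_report(results_dir: str | Path, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Assemble the three report tables from pipeline outputs.

    * subcategory summary (counts, percentages, adjusted p, flags),
    * gene-level reads-per-bp long table by pathway and library
      (boxplot-ready), and
    * the DEG listing joined with each pair's pathways.
    """
    import pandas as pd

    results = Path(results_dir)
    out = Path(out_dir) if out_dir is not None else results
    out.mkdir(parents=True, exist_ok=True)
    missing = [n for n in REPORT_INPUTS if not (results / n).exists()]
    if missing:
        raise FileNotFoundError(f"missing pipeline outputs: {missing}")

    produced: dict[str, Path] = {}

    enrich = pd.read_csv(results / "enrichment_subcategory.tsv", sep="\t")
    summary = enrich[
        ["unit_id", "a", "c", "pct_gc", "pct_kn", "p_adj", "direction", "significant"]
    ].rename(columns={"a": "n_proteins_gc", "c": "n_proteins_kn"})
    produced["subcategory_summary"] = out / "report_subcategory_summary.tsv"
    summary.to_csv(produced["subcategory_summary"], sep="\t", index=False)

    rpbp = pd.read_csv(results / "gene_rpbp_pathway.tsv", sep="\t")
    produced["expression_long"] = out / "report_expression_by_pathway.tsv"
    rpbp.to_csv(produced["expression_long"], sep="\t", index=False)

    deg = pd.read_csv(results / "deg.tsv", sep="\t")
    produced["deg_listing"] = out / "report_deg.tsv"
    deg.sort_values(["klass", "log2fc"], ascending=[True, False]).to_csv(
        produced["deg_listing"], sep="\t", index=False
    ) if len(deg) else deg.to_csv(produced["deg_listing"], sep="\t", index=False)
    return produced
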