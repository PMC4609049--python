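"""Category-level comparison statistics.

Two engines compare the free-living (GC) and kleptokaryon (KN) gene sets
at the level of functional units:

* protein-count enrichment — a 2x2 chi-square per unit (in-unit vs
  out-of-unit counts for each library) asking whether a unit holds a
  larger share of one library's annotated proteins than the other's;
* expression comparison — a Mann-Whitney rank test per unit on the
  gene-level reads-per-base-pair vectors of the two libraries.

Both are corrected per analysis family with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import CountTable, KoHierarchy

OVER = "over_in_KN"
UNDER = "under_in_KN"
NONE = "none"


@dataclass(frozen=True)
class EnrichmentRow:
    unit_id: str
    level: str
    a: int  # GC in-unit
    b: int  # GC out-of-unit
    c: int  # KN in-unit
    d: int  # KN out-of-unit
    pct_gc: float
    pct_kn: float
    chi2: float
    p_raw: float
    p_adj: float
    direction: str
    significant: bool


@dataclass(frozen=True)
class ExpressionRow:
    unit_id: str
    level: str
    n_gc: int
    n_kn: int
    sum_rpbp_gc: float  # summed reads-per-bp: the total-expression proxy
    sum_rpbp_kn: float
    U: float | None
    p_raw: float | None
    p_adj: float | None
    direction: str
    significant: bool


def chi_square_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a,b],[c,d]], 1 df.

    Yates continuity correction on by default.  A zero row or column
    margin leaves the expected counts undefined and is an error.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("chi-square undefined: zero margin in 2x2 table")
    chi2, p, _, _ = sps.chi2_contingency([[a, b], [c, d]], correction=yates)
    return float(chi2), float(p)


def bh_adjust(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def reads_per_bp(count: int, length_bp: int) -> float:
    """Length-normalized read count — the expression proxy."""
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / length_bp


def mann_whitney_u(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (midranks for ties).

    method='auto' uses exact enumeration when the smaller sample has at
    most 8 observations and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.  Returns the U
    statistic of `x`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if method == "auto":
        has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
        method = "normal" if (min(x.size, y.size) > 8 or has_ties) else "exact"
    scipy_method = {"exact": "exact", "normal": "asymptotic"}[method]
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=scipy_method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def category_protein_enrichment(
    counts: list,
    denominators: str = "category_sum",
    alpha: float = 0.05,
    totals: dict[str, int] | None = None,
    lib_gc: str = "GC",
    lib_kn: str = "KN",
) -> list[EnrichmentRow]:
    """Per-unit 2x2 protein-count enrichment between two libraries.

    `counts` is a list of CategoryCounts covering both libraries at one
    level.  The out-of-unit denominator is either the sum of unit counts
    over all analyzed units ('category_sum' — a gene in several units is
    counted once per unit) or an externally supplied per-library total of
    annotated proteins ('annotated_total', via `totals`).  BH correction
    runs across all tested units; direction compares the two percentages.
    """
    levels = {r.level for r in counts}
    if len(levels) > 1:
        raise ValueError(f"counts mix levels {sorted(levels)}")
    per_lib: dict[str, dict[str, int]] = {lib_gc: {}, lib_kn: {}}
    for r in counts:
        if r.library not in per_lib:
            raise ValueError(f"unexpected library {r.library!r}")
        per_lib[r.library][r.unit_id] = r.n_proteins
    units = sorted(set(per_lib[lib_gc]) | set(per_lib[lib_kn]))
    gc_counts = {u: per_lib[lib_gc].get(u, 0) for u in units}
    kn_counts = {u: per_lib[lib_kn].get(u, 0) for u in units}

    if denominators == "category_sum":
        denom_gc = sum(gc_counts.values())
        denom_kn = sum(kn_counts.values())
    elif denominators == "annotated_total":
        if totals is None:
            raise ValueError("denominators='annotated_total' requires totals")
        denom_gc, denom_kn = totals[lib_gc], totals[lib_kn]
    else:
        raise ValueError(f"unknown denominators mode {denominators!r}")

    level = levels.pop() if levels else "subcategory"
    stats_rows: list[tuple[str, int, int, int, int, float, float]] = []
    for u in units:
        a, c = gc_counts[u], kn_counts[u]
        b, d = denom_gc - a, denom_kn - c
        chi2, p = chi_square_2x2(a, b, c, d)
        stats_rows.append((u, a, b, c, d, chi2, p))

    p_adj = bh_adjust([r[6] for r in stats_rows])
    rows: list[EnrichmentRow] = []
    for (u, a, b, c, d, chi2, p), padj in zip(stats_rows, p_adj):
        pct_gc = 100.0 * a / denom_gc
        pct_kn = 100.0 * c / denom_kn
        sig = bool(padj < alpha)
        if pct_kn > pct_gc:
            direction = OVER
        elif pct_kn < pct_gc:
            direction = UNDER
        else:
            direction = NONE
        rows.append(
            EnrichmentRow(
                unit_id=u, level=level, a=a, b=b, c=c, d=d,
                pct_gc=pct_gc, pct_kn=pct_kn, chi2=chi2,
                p_raw=p, p_adj=float(padj), direction=direction, significant=sig,
            )
        )
    return rows


def gene_rpbp_vectors(
    counts: CountTable,
    hier: KoHierarchy,
    level: str,
    library: str,
    genes: list[str] | None = None,
    drop_zero: bool = False,
) -> dict[str, np.ndarray]:
    """Per-unit vector of gene-level reads-per-bp values for one library."""
    pool = counts.genes(library) if genes is None else sorted(genes)
    vectors: dict[str, list[float]] = {u: [] for u in hier.units(level)}
    for gene_id in pool:
        rpb = reads_per_bp(counts.count(library, gene_id), counts.length(library, gene_id))
        if drop_zero and rpb == 0:
            continue
        for unit in hier.units_of_gene(gene_id, level):
            vectors[unit].append(rpb)
    return {u: np.asarray(v, dtype=float) for u, v in vectors.items()}


def category_expression(
    counts: CountTable,
    hier: KoHierarchy,
    level: str,
    alpha: float = 0.05,
    lib_gc: str = "GC",
    lib_kn: str = "KN",
    genes_gc: list[str] | None = None,
    genes_kn: list[str] | None = None,
    drop_zero: bool = False,
    cpm_scale: bool = False,
) -> list[ExpressionRow]:
    """Mann-Whitney comparison of per-gene reads-per-bp between libraries,
    one test per unit at `level`, BH-corrected across that level only.

    Units empty in either library get p = NA and are excluded from BH.
    Genes with zero reads are included unless `drop_zero`.  `cpm_scale`
    divides each library's values by its total read count (per million)
    before ranking, for libraries with grossly different per-gene depth.
    """
    vec_gc = gene_rpbp_vectors(counts, hier, level, lib_gc, genes_gc, drop_zero)
    vec_kn = gene_rpbp_vectors(counts, hier, level, lib_kn, genes_kn, drop_zero)
    if cpm_scale:
        for lib, vec in ((lib_gc, vec_gc), (lib_kn, vec_kn)):
            total = counts.library_total(lib)
            if total == 0:
                raise ValueError(f"cpm_scale: library {lib!r} has zero total reads")
            for u in vec:
                vec[u] = vec[u] * 1e6 / total
    units = hier.units(level)

    tested: list[str] = []
    results: dict[str, tuple[float, float]] = {}
    for u in units:
        x, y = vec_gc[u], vec_kn[u]
        if x.size and y.size:
            results[u] = mann_whitney_u(x, y)
            tested.append(u)

    p_adj = dict(zip(tested, bh_adjust([results[u][1] for u in tested])))
    rows: list[ExpressionRow] = []
    for u in units:
        x, y = vec_gc[u], vec_kn[u]
        if u in results:
            U, p = results[u]
            padj = float(p_adj[u])
            sig = bool(padj < alpha)
        else:
            U = p = padj = None
            sig = False
        sum_gc, sum_kn = float(x.sum()), float(y.sum())
        mean_gc = x.mean() if x.size else 0.0
        mean_kn = y.mean() if y.size else 0.0
        if mean_kn > mean_gc:
            direction = OVER
        elif mean_kn < mean_gc:
            direction = UNDER
        else:
            direction = NONE
        rows.append(
            ExpressionRow(
                unit_id=u, level=level, n_gc=int(x.size), n_kn=int(y.size),
                sum_rpbp_gc=sum_gc, sum_rpbp_kn=sum_kn,
                U=U, p_raw=p, p_adj=padj, direction=direction, significant=sig,
            )
        )
    return rows
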