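"""Origin assignment for genes of a chimeric (host + kleptokaryon) library.

Each gene in the host library is assigned an origin from its best homology
hit: a best hit to a cryptophyte subject at or below the e-value threshold
marks the gene as kleptokaryon-derived (KN); everything else — a best hit
to a non-cryptophyte, a hit above threshold, or no hit at all — is
conservatively attributed to the host (HOST).  A strict variant counts a
gene as *confirmed* host only when its best hit is to a ciliate subject at
or below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import HitRecord, TaxonMap

KN = "KN"
HOST = "HOST"


@dataclass(frozen=True)
class OriginCall:
    gene_id: str
    origin: str  # KN or HOST
    best_subject: str | None
    best_taxon: str | None
    best_evalue: float | None
    best_bitscore: float | None
    threshold: float


@dataclass(frozen=True)
class PartitionSummary:
    threshold: float
    mode: str  # "default" or "strict_ciliate"
    n_total: int
    n_kn: int
    n_host: int
    fraction_kn: float
    n_confirmed_host: int | None = None  # strict_ciliate mode only

    def __post_init__(self) -> None:
        if self.n_kn + self.n_host != self.n_total:
            raise ValueError("n_kn + n_host must equal n_total")


def best_hit_per_query(
    hits: list[HitRecord], *, exclude_self: bool = True
) -> dict[str, HitRecord]:
    """Select each query's top hit: minimal e-value, ties broken by maximal
    bitscore, then lexicographically smallest subject id.

    Self-hits (query id == subject id) are dropped first by default — the
    reference database may contain the query library's own proteins.
    The result is invariant under permutation of the input rows.
    """
    best: dict[str, HitRecord] = {}
    for hit in hits:
        if exclude_self and hit.query_id == hit.subject_id:
            continue
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.query_id] = hit
    return best


def _hit_rank(hit: HitRecord) -> tuple[float, float, str]:
    return (hit.evalue, -hit.bitscore, hit.subject_id)


def assign_origin(
    best_hits: dict[str, HitRecord],
    taxa: TaxonMap,
    e_threshold: float = 1e-4,
    mode: str = "default",
    genes: list[str] | None = None,
) -> tuple[list[OriginCall], PartitionSummary]:
    """Assign KN/HOST origin to every gene in the universe.

    `genes` is the gene universe (so hit-less genes are called HOST); when
    omitted, the universe is the set of queries with a best hit.
    """
    if mode not in ("default", "strict_ciliate"):
        raise ValueError(f"unknown mode {mode!r}")
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    universe = sorted(best_hits) if genes is None else sorted(set(genes) | set(best_hits))

    calls: list[OriginCall] = []
    n_kn = 0
    n_confirmed_host = 0
    for gene_id in universe:
        hit = best_hits.get(gene_id)
        if hit is None:
            calls.append(OriginCall(gene_id, HOST, None, None, None, None, e_threshold))
            continue
        taxon = taxa.taxon_of(hit.subject_id)
        is_kn = taxon in taxa.cryptophyte_labels and hit.evalue <= e_threshold
        origin = KN if is_kn else HOST
        if is_kn:
            n_kn += 1
        elif taxon in taxa.ciliate_labels and hit.evalue <= e_threshold:
            n_confirmed_host += 1
        calls.append(
            OriginCall(gene_id, origin, hit.subject_id, taxon, hit.evalue, hit.bitscore, e_threshold)
        )

    n_total = len(universe)
    summary = PartitionSummary(
        threshold=e_threshold,
        mode=mode,
        n_total=n_total,
        n_kn=n_kn,
        n_host=n_total - n_kn,
        fraction_kn=n_kn / n_total if n_total else 0.0,
        n_confirmed_host=n_confirmed_host if mode == "strict_ciliate" else None,
    )
    return calls, summary


def threshold_sweep(
    hits: list[HitRecord],
    taxa: TaxonMap,
    thresholds: list[float],
    genes: list[str] | None = None,
    mode: str = "default",
) -> list[PartitionSummary]:
    """Partition at each threshold (most lenient first).

    Because a KN call requires evalue <= threshold, fraction_kn is
    non-increasing as the threshold tightens.
    """
    if any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be positive")
    best = best_hit_per_query(hits)
    return [assign_origin(best, taxa, t, mode=mode, genes=genes)[1] for t in thresholds]
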