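"""Per-gene differential expression without replicates.

Orthologous gene pairs between the free-living (GC) and kleptokaryon (KN)
gene sets are identified as reciprocal best hits (RBBH).  Library scale is
estimated either by the trimmed mean of M-values (TMM) or by the
median-of-ratios size factors; each pair is then tested with an exact
conditional negative-binomial test at a fixed dispersion (default 0.3 —
a deliberate biological-variability allowance in the absence of
replicates), and classified by its normalized log2 fold change (KN over
GC), with |log2FC| >= 1 as the over/under-expression boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .io import HitRecord
from .partition import best_hit_per_query
from .stats import bh_adjust

LOG2FC_CLASS_BOUNDARY = 1.0


@dataclass(frozen=True)
class RbbhPair:
    gc_gene: str
    kn_gene: str
    fwd_evalue: float
    rev_evalue: float


@dataclass(frozen=True)
class NormFactors:
    method: str  # "tmm" or "median_ratio"
    factor_gc: float
    factor_kn: float
    effective_size_gc: float
    effective_size_kn: float


@dataclass(frozen=True)
class DegRow:
    gc_gene: str
    kn_gene: str
    y_gc: int
    y_kn: int
    log2fc: float  # KN over GC
    p_raw: float
    p_adj: float
    klass: str  # over / under / ns, by |log2fc| >= 1 alone
    significant: bool  # p_adj < alpha


def classify_log2fc(log2fc: float, boundary: float = LOG2FC_CLASS_BOUNDARY) -> str:
    if log2fc >= boundary:
        return "over"
    if log2fc <= -boundary:
        return "under"
    return "ns"


def reciprocal_best_hits(
    fwd: list[HitRecord],
    rev: list[HitRecord],
    e_threshold: float = 1e-4,
) -> list[RbbhPair]:
    """Mutual best-hit pairing between two gene sets.

    (g, k) is a pair iff k is g's best hit in the forward search and g is
    k's best hit in the reverse search, both at e-value <= threshold.
    Best-hit ties resolve as in partitioning (e-value, bitscore, subject
    id), so the pairing is a deterministic partial matching.  Query and
    subject namespaces belong to different gene sets here, so equal ids do
    not mark self-hits and are kept.
    """
    best_fwd = best_hit_per_query(fwd, exclude_self=False)
    best_rev = best_hit_per_query(rev, exclude_self=False)
    pairs: list[RbbhPair] = []
    for g in sorted(best_fwd):
        f = best_fwd[g]
        if f.evalue > e_threshold:
            continue
        r = best_rev.get(f.subject_id)
        if r is None or r.subject_id != g or r.evalue > e_threshold:
            continue
        pairs.append(RbbhPair(gc_gene=g, kn_gene=f.subject_id, fwd_evalue=f.evalue, rev_evalue=r.evalue))
    return pairs


# ---------------------------------------------------------------------------
# normalization


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    logratio_trim: float = 0.3, sum_trim: float = 0.05,
) -> float:
    """TMM factor of `obs` against `ref` (weighted, doubly trimmed).

    M = log2 relative abundance ratio, A = average log2 abundance; genes
    zero in either library drop out, the extreme 30 % of M and 5 % of A
    are trimmed, and the remaining M are averaged with inverse asymptotic
    binomial-variance weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0:
        raise ValueError("TMM: no usable genes (every gene zero in one library)")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = math.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = math.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep2 = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep2.any():
        return 1.0
    f = np.sum(log_r[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(2.0**f) if np.isfinite(f) else 1.0


def tmm_factors(counts_gc: np.ndarray | list[int], counts_kn: np.ndarray | list[int]) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors for a GC/KN library pair.

    The reference library is the one whose upper-quartile/library-size
    ratio is nearer the mean of the two; factors are rescaled to geometric
    mean 1 and effective sizes are library size x factor.
    """
    gc = np.asarray(counts_gc, dtype=float)
    kn = np.asarray(counts_kn, dtype=float)
    if gc.shape != kn.shape or gc.ndim != 1:
        raise ValueError("count vectors must be 1-D and aligned")
    if not np.any((gc > 0) & (kn > 0)):
        raise ValueError("TMM needs at least one gene positive in both libraries")
    n_gc, n_kn = gc.sum(), kn.sum()
    f75 = np.array([np.quantile(gc, 0.75) / n_gc, np.quantile(kn, 0.75) / n_kn])
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    cols = [(gc, n_gc), (kn, n_kn)]
    ref, n_ref = cols[ref_idx]
    raw = [
        1.0 if i == ref_idx else _tmm_pair_factor(col, ref, n_col, n_ref)
        for i, (col, n_col) in enumerate(cols)
    ]
    geo = math.exp(np.mean(np.log(raw)))
    f_gc, f_kn = raw[0] / geo, raw[1] / geo
    return NormFactors(
        method="tmm",
        factor_gc=f_gc,
        factor_kn=f_kn,
        effective_size_gc=float(n_gc * f_gc),
        effective_size_kn=float(n_kn * f_kn),
    )


def median_ratio_factors(
    counts_gc: np.ndarray | list[int], counts_kn: np.ndarray | list[int]
) -> NormFactors:
    """Median-of-ratios size factors.

    Per library, the factor is the median over genes of
    count / geometric-mean-across-libraries; genes with a zero geometric
    mean are excluded.  The effective size here is the size factor itself
    scaled to geometric mean 1 times the library size ratio structure of
    the data — effective counts y/factor are directly comparable.
    """
    gc = np.asarray(counts_gc, dtype=float)
    kn = np.asarray(counts_kn, dtype=float)
    if gc.shape != kn.shape or gc.ndim != 1:
        raise ValueError("count vectors must be 1-D and aligned")
    ok = (gc > 0) & (kn > 0)
    if not ok.any():
        raise ValueError("median-ratio needs at least one gene positive in both libraries")
    geomean = np.sqrt(gc[ok] * kn[ok])
    s_gc = float(np.median(gc[ok] / geomean))
    s_kn = float(np.median(kn[ok] / geomean))
    # size factors already have geometric mean ~1 by construction of the
    # per-gene geometric means; normalize exactly for the invariant.
    geo = math.sqrt(s_gc * s_kn)
    s_gc, s_kn = s_gc / geo, s_kn / geo
    return NormFactors(
        method="median_ratio",
        factor_gc=s_gc,
        factor_kn=s_kn,
        effective_size_gc=s_gc,
        effective_size_kn=s_kn,
    )


# ---------------------------------------------------------------------------
# the exact test


def nb_exact_test(
    y_gc: int,
    y_kn: int,
    eff_size_gc: float,
    eff_size_kn: float,
    dispersion: float = 0.3,
) -> float:
    """Exact conditional negative-binomial test for one gene, two libraries.

    Counts are rescaled to the geometric mean of the effective library
    sizes and rounded; conditional on the rescaled sum s, the null
    distribution over splits k + (s-k) is P(k|s) proportional to
    f(k) f(s-k) with f the NB pmf of mean s/2 and the given dispersion
    (variance mu + dispersion * mu^2).  The two-sided p-value sums P(k|s)
    over all k at most as probable as the observation, capped at 1.
    """
    if y_gc < 0 or y_kn < 0:
        raise ValueError("counts must be non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if eff_size_gc <= 0 or eff_size_kn <= 0:
        raise ValueError("effective sizes must be positive")
    s_geo = math.sqrt(eff_size_gc * eff_size_kn)
    y1 = int(round(y_gc * s_geo / eff_size_gc))
    y2 = int(round(y_kn * s_geo / eff_size_kn))
    s = y1 + y2
    if s == 0:
        return 1.0
    r = 1.0 / dispersion
    mu = s / 2.0
    p_nb = r / (r + mu)
    k = np.arange(s + 1)
    logf = sps.nbinom.logpmf(k, r, p_nb)
    logp = logf + logf[::-1]
    w = np.exp(logp - logp.max())
    w /= w.sum()
    # tolerance guards against float noise in "equally probable" splits
    pval = float(w[w <= w[y1] * (1 + 1e-10)].sum())
    return min(pval, 1.0)


def log2_fold_change(
    y_gc: int, y_kn: int, factors: NormFactors, prior: float = 0.5
) -> float:
    """Shrunken log2 fold change of KN over GC at the given scale factors.

    A prior count (default 0.5) keeps zeros finite.
    """
    if prior <= 0:
        raise ValueError("prior must be positive")
    rate_kn = (y_kn + prior) / factors.effective_size_kn
    rate_gc = (y_gc + prior) / factors.effective_size_gc
    return math.log2(rate_kn / rate_gc)


def run_deg(
    counts,
    pairs: list[RbbhPair],
    method: str = "tmm",
    dispersion: float = 0.3,
    alpha: float = 0.05,
    prior: float = 0.5,
    lib_gc: str = "GC",
    lib_kn: str = "KN",
) -> tuple[list[DegRow], NormFactors]:
    """Full no-replicate DEG pass over RBBH pairs.

    Scale factors are estimated once on the aligned pair count vectors;
    each pair gets an exact-test p-value and a normalized log2FC; BH runs
    across all pairs.  `klass` reflects the log2FC boundary alone (the
    fold-change-focused reading); `significant` records p_adj < alpha so
    a stricter call can intersect the two.
    """
    if not pairs:
        raise ValueError("run_deg requires at least one RBBH pair")
    y_gc = np.array([counts.count(lib_gc, p.gc_gene) for p in pairs])
    y_kn = np.array([counts.count(lib_kn, p.kn_gene) for p in pairs])
    if method == "tmm":
        factors = tmm_factors(y_gc, y_kn)
    elif method == "median_ratio":
        factors = median_ratio_factors(y_gc, y_kn)
    else:
        raise ValueError(f"unknown normalization method {method!r}")

    p_raw = [
        nb_exact_test(int(a), int(b), factors.effective_size_gc, factors.effective_size_kn, dispersion)
        for a, b in zip(y_gc, y_kn)
    ]
    p_adj = bh_adjust(p_raw)
    rows = [
        DegRow(
            gc_gene=pair.gc_gene,
            kn_gene=pair.kn_gene,
            y_gc=int(a),
            y_kn=int(b),
            log2fc=log2_fold_change(int(a), int(b), factors, prior),
            p_raw=float(pr),
            p_adj=float(pa),
            klass=classify_log2fc(log2_fold_change(int(a), int(b), factors, prior)),
            significant=bool(pa < alpha),
        )
        for pair, a, b, pr, pa in zip(pairs, y_gc, y_kn, p_raw, p_adj)
    ]
    return rows, factors
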