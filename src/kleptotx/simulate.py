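"""Synthetic chimeric-transcriptome datasets with known ground truth.

The generator emulates the statistical shape of a two-library experiment
on a kleptokaryon-bearing ciliate: a free-living algal library (GC) and a
chimeric host library (MR) whose genes are a mixture of host-derived and
kleptokaryon-derived (KN) transcripts.  Defaults mirror the study system:
~61.5 % of the chimeric library of KN origin, coding-sequence lengths
lognormal with mean ~850 and sd ~648 bp, a 4-category / 21-subcategory /
89-pathway functional hierarchy, negative-binomial read counts at
dispersion 0.3, and homology-hit tables consistent with the true origin
up to a configurable misassignment rate epsilon.

Every KN gene has a same-id ortholog in the GC library, so reciprocal
best hits are recoverable by construction; decoy GC-only and host-only
genes exercise matching failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as kio
from .io import CountTable, GeneRecord, HitRecord, KoHierarchy, TaxonMap

CATEGORY_NAMES = (
    "Metabolism",
    "Genetic Information Processing",
    "Environmental Information Processing",
    "Cellular Processes",
)


def _length_params(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) matching a target arithmetic mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for one synthetic dataset."""

    seed: int = 0
    n_genes: int = 12650            # chimeric (MR) library size
    pi_kn: float = 0.615            # true kleptokaryon fraction of MR
    decoy_factor: float = 3.0       # GC-only decoys per MR gene (GC >> MR)
    n_categories: int = 4
    n_subcategories: int = 21
    n_pathways: int = 89
    kos_per_pathway: int = 4
    annotation_rate: float = 0.3    # fraction of genes carrying a KO
    length_mean: float = 850.0      # bp
    length_sd: float = 648.0        # bp
    baseline_log_sd: float = 1.0    # gene-to-gene spread of log expression
    effects: dict = field(default_factory=dict)  # pathway_id -> Δlog2 in KN
    dispersion_sim: float = 0.3
    reads_per_gene_gc: float = 400.0  # mean coverage; library total ~ n x this
    reads_per_gene_mr: float = 400.0
    epsilon: float = 0.0            # best-hit taxon misassignment rate
    evalue_log10_range: tuple = (-50.0, -5.0)  # true-hit e-values, log10

    def __post_init__(self) -> None:
        for name in ("pi_kn", "annotation_rate", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.n_categories, self.n_subcategories, self.n_pathways) < 1:
            raise ValueError("hierarchy sizes must be positive")
        if self.n_genes < self.n_pathways:
            raise ValueError("infeasible hierarchy: fewer genes than pathways")
        if self.dispersion_sim <= 0:
            raise ValueError("dispersion_sim must be positive")


@dataclass
class SimTruth:
    """Ground truth paired with an emitted dataset."""

    pi_kn: float                       # configured mixture weight
    realized_kn_fraction: float        # empirical fraction in this draw
    origin: dict[str, str]             # MR gene -> "KN" | "HOST"
    pathway_of_gene: dict[str, str]    # gene -> pathway (annotated genes)
    effect_of_pathway: dict[str, float]
    mean_gc: dict[str, float]          # GC gene -> true NB mean
    mean_mr: dict[str, float]          # MR gene -> true NB mean
    pairs: list[tuple[str, str]]       # (gc_gene, kn_gene) true orthologs


@dataclass
class SimDataset:
    """In-memory view of one simulated dataset."""

    genes: list[GeneRecord]
    hits: list[HitRecord]            # MR queries vs reference database
    taxa: TaxonMap
    hierarchy: KoHierarchy
    counts: CountTable
    fwd_hits: list[HitRecord]        # GC -> KN homology (for RBBH)
    rev_hits: list[HitRecord]        # KN -> GC homology
    truth: SimTruth


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance mean + dispersion * mean^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def build_hierarchy(config: SimConfig) -> KoHierarchy:
    """Deterministic KO hierarchy: pathways round-robin over subcategories,
    subcategories round-robin over categories, a fixed KO block per
    pathway.  Gene assignments are added separately."""
    cats = list(CATEGORY_NAMES[: config.n_categories])
    while len(cats) < config.n_categories:
        cats.append(f"Category {len(cats) + 1}")
    sub_to_cat = {
        f"sc{j:02d}": cats[j % config.n_categories] for j in range(config.n_subcategories)
    }
    subs = sorted(sub_to_cat)
    pw_to_sub = {f"pw{k:03d}": subs[k % config.n_subcategories] for k in range(config.n_pathways)}
    ko_to_pw: dict[str, frozenset[str]] = {}
    ko_index = 1
    for pw in sorted(pw_to_sub):
        for _ in range(config.kos_per_pathway):
            ko_to_pw[f"K{ko_index:05d}"] = frozenset([pw])
            ko_index += 1
    return KoHierarchy(
        gene_to_kos={},
        ko_to_pathways=ko_to_pw,
        pathway_to_subcategory=pw_to_sub,
        subcategory_to_category=sub_to_cat,
    )


def simulate(config: SimConfig) -> SimDataset:
    """Draw one complete dataset (fully determined by config.seed)."""
    rng = np.random.default_rng(config.seed)
    skeleton = build_hierarchy(config)
    kos = sorted(skeleton.ko_to_pathways)

    # --- gene universe -----------------------------------------------------
    n_mr = config.n_genes
    origin_flags = rng.random(n_mr) < config.pi_kn
    mr_ids = [f"mr{i:06d}" for i in range(n_mr)]
    kn_ids = [g for g, kn in zip(mr_ids, origin_flags) if kn]
    n_decoy = int(round(config.decoy_factor * n_mr))
    gc_only_ids = [f"gcd{i:06d}" for i in range(n_decoy)]
    # every KN gene has a same-id GC ortholog; decoys are GC-only
    gc_ids = kn_ids + gc_only_ids

    mu_len, sigma_len = _length_params(config.length_mean, config.length_sd)
    all_ids = mr_ids + gc_only_ids
    lengths = np.maximum(1, np.rint(rng.lognormal(mu_len, sigma_len, size=len(all_ids)))).astype(int)
    length_of = dict(zip(all_ids, lengths.tolist()))

    genes = [GeneRecord(g, "MR", length_of[g]) for g in mr_ids] + [
        GeneRecord(g, "GC", length_of[g]) for g in gc_ids
    ]

    # --- annotation --------------------------------------------------------
    annotated_mask = rng.random(len(all_ids)) < config.annotation_rate
    gene_to_kos: dict[str, frozenset[str]] = {}
    pathway_of_gene: dict[str, str] = {}
    ko_choices = rng.integers(0, len(kos), size=len(all_ids))
    for gid, annotated, ko_i in zip(all_ids, annotated_mask, ko_choices):
        if annotated:
            ko = kos[ko_i]
            gene_to_kos[gid] = frozenset([ko])
            pathway_of_gene[gid] = next(iter(skeleton.ko_to_pathways[ko]))
    hierarchy = KoHierarchy(
        gene_to_kos=gene_to_kos,
        ko_to_pathways=skeleton.ko_to_pathways,
        pathway_to_subcategory=skeleton.pathway_to_subcategory,
        subcategory_to_category=skeleton.subcategory_to_category,
    )

    # --- true expression means --------------------------------------------
    baseline = dict(zip(all_ids, rng.normal(0.0, config.baseline_log_sd, size=len(all_ids))))

    def weight(gid: str, kn_shift: bool) -> float:
        w = math.exp(baseline[gid]) * length_of[gid]
        if kn_shift:
            pw = pathway_of_gene.get(gid)
            if pw is not None and pw in config.effects:
                w *= 2.0 ** config.effects[pw]
        return w

    w_gc = np.array([weight(g, False) for g in gc_ids])
    # KN genes carry the pathway shift inside the chimeric library
    w_mr = np.array([weight(g, kn) for g, kn in zip(mr_ids, origin_flags)])
    # deterministic normalizer = E[exp(baseline)] * E[length]: a gene's
    # expected coverage is then independent of how many genes share the
    # library, so an effect-free dataset is a genuine null between libraries
    norm = math.exp(config.baseline_log_sd**2 / 2.0) * config.length_mean
    mean_gc = w_gc / norm * config.reads_per_gene_gc
    mean_mr = w_mr / norm * config.reads_per_gene_mr
    counts_gc = _draw_nb(rng, mean_gc, config.dispersion_sim)
    counts_mr = _draw_nb(rng, mean_mr, config.dispersion_sim)

    counts = CountTable(
        counts={
            **{("MR", g): int(c) for g, c in zip(mr_ids, counts_mr)},
            **{("GC", g): int(c) for g, c in zip(gc_ids, counts_gc)},
        },
        lengths={(g.library, g.gene_id): g.length_bp for g in genes},
    )

    # --- taxonomic reference & hit table -----------------------------------
    taxa_subjects = {
        "crypt_ref": "Geminigera cryophila",
        "crypt_ref2": "Guillardia theta",
        "ciliate_ref": "Tetrahymena thermophila",
        "other_ref": "Arabidopsis thaliana",
        "other_ref2": "Saccharomyces cerevisiae",
    }
    taxa = TaxonMap(
        subject_to_taxon=taxa_subjects,
        cryptophyte_labels=frozenset({"Geminigera cryophila", "Guillardia theta"}),
        ciliate_labels=frozenset({"Tetrahymena thermophila"}),
    )
    lo, hi = config.evalue_log10_range
    evalues = 10.0 ** rng.uniform(lo, hi, size=n_mr)
    flip = rng.random(n_mr) < config.epsilon
    host_is_ciliate = rng.random(n_mr) < 0.1  # host best hits mostly non-ciliate
    hits: list[HitRecord] = []
    for gid, is_kn, ev, fl, cil in zip(mr_ids, origin_flags, evalues, flip, host_is_ciliate):
        looks_kn = bool(is_kn) != bool(fl)
        subject = "crypt_ref" if looks_kn else ("ciliate_ref" if cil else "other_ref")
        hits.append(_make_hit(gid, subject, ev, length_of[gid]))

    # --- RBBH homology tables ----------------------------------------------
    pairs = [(g, g) for g in kn_ids]
    rbbh_ev = 10.0 ** rng.uniform(lo, hi, size=len(kn_ids))
    fwd_hits = [_make_hit(g, g, ev, length_of[g]) for g, ev in zip(kn_ids, rbbh_ev)]
    rev_hits = [_make_hit(g, g, ev, length_of[g]) for g, ev in zip(kn_ids, rbbh_ev)]
    # decoy forward hits: their subject's reverse best points elsewhere, so
    # mutuality fails and no pair may contain these queries
    if kn_ids:
        n_conflict = min(50, len(gc_only_ids))
        targets = rng.integers(0, len(kn_ids), size=n_conflict)
        fwd_hits.extend(
            _make_hit(gc_only_ids[i], kn_ids[t], 1e-20, length_of[gc_only_ids[i]])
            for i, t in enumerate(targets)
        )

    truth = SimTruth(
        pi_kn=config.pi_kn,
        realized_kn_fraction=float(origin_flags.mean()) if n_mr else 0.0,
        origin={g: ("KN" if kn else "HOST") for g, kn in zip(mr_ids, origin_flags)},
        pathway_of_gene=pathway_of_gene,
        effect_of_pathway=dict(config.effects),
        mean_gc=dict(zip(gc_ids, mean_gc.tolist())),
        mean_mr=dict(zip(mr_ids, mean_mr.tolist())),
        pairs=pairs,
    )
    return SimDataset(
        genes=genes,
        hits=hits,
        taxa=taxa,
        hierarchy=hierarchy,
        counts=counts,
        fwd_hits=fwd_hits,
        rev_hits=rev_hits,
        truth=truth,
    )


def _make_hit(query: str, subject: str, evalue: float, qlen: int) -> HitRecord:
    """A plausible 12-column hit row; alignment geometry is cosmetic."""
    aln = max(30, qlen // 3)
    return HitRecord(
        query_id=query,
        subject_id=subject,
        pct_identity=80.0,
        aln_len=aln,
        mismatches=aln // 10,
        gap_opens=1,
        qstart=1,
        qend=aln,
        sstart=1,
        send=aln,
        evalue=float(evalue),
        bitscore=200.0,
    )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_dataset(config: SimConfig, out_dir: str | Path) -> tuple[SimDataset, dict[str, Path]]:
    """Simulate and write every input file the pipeline reads.

    Emits FASTA coding sequences for both libraries (random bases of the
    true lengths), the origin hit table, taxon map, gene->KO and hierarchy
    TSVs, the count TSV, the RBBH homology tables and a pairs TSV.
    Byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate(config)
    seq_rng = np.random.default_rng(config.seed + 1)

    paths = {
        "fasta_mr": out / "mr_cds.fasta",
        "fasta_gc": out / "gc_cds.fasta",
        "hits": out / "mr_vs_refdb.tsv",
        "taxa": out / "taxon_map.tsv",
        "gene_ko": out / "gene_ko.tsv",
        "hierarchy": out / "ko_hierarchy.tsv",
        "counts": out / "counts.tsv",
        "fwd_hits": out / "gc_vs_kn.tsv",
        "rev_hits": out / "kn_vs_gc.tsv",
        "pairs": out / "rbbh_pairs.tsv",
        "truth": out / "truth.tsv",
    }
    for library, path in (("MR", paths["fasta_mr"]), ("GC", paths["fasta_gc"])):
        with open(path, "w") as fa:
            for g in data.genes:
                if g.library != library:
                    continue
                seq = seq_rng.integers(0, 4, size=g.length_bp)
                fa.write(f">{g.gene_id}\n{_BASES[seq].tobytes().decode()}\n")
    kio.write_hit_table(data.hits, paths["hits"])
    kio.write_taxon_map(data.taxa, paths["taxa"])
    kio.write_ko_hierarchy(data.hierarchy, paths["gene_ko"], paths["hierarchy"])
    kio.write_count_table(data.counts, paths["counts"])
    kio.write_hit_table(data.fwd_hits, paths["fwd_hits"])
    kio.write_hit_table(data.rev_hits, paths["rev_hits"])
    with open(paths["pairs"], "w") as out_pairs:
        for gc_gene, kn_gene in data.truth.pairs:
            out_pairs.write(f"{gc_gene}\t{kn_gene}\n")
    with open(paths["truth"], "w") as out_truth:
        out_truth.write("gene_id\torigin\tpathway\n")
        for g in sorted(data.truth.origin):
            out_truth.write(
                f"{g}\t{data.truth.origin[g]}\t{data.truth.pathway_of_gene.get(g, 'NA')}\n"
            )
    return data, paths


def dominance_hit_table(
    n_total: int = 12650,
    n_crypt: int = 7782,
    n_crypt_strict: int = 7337,
    seed: int = 0,
) -> tuple[list[HitRecord], TaxonMap, list[str]]:
    """Best-hit table reproducing a stated kleptokaryon dominance split.

    `n_crypt` of `n_total` queries get a cryptophyte best hit at
    e <= 1e-4; of those, `n_crypt_strict` survive a 1e-30 cutoff (the
    rest sit in (1e-30, 1e-4]).  Remaining queries hit non-cryptophyte
    subjects.  Row order is shuffled by `seed`; the partition result is
    order-independent.
    """
    if not 0 <= n_crypt_strict <= n_crypt <= n_total:
        raise ValueError("need n_crypt_strict <= n_crypt <= n_total")
    taxa = TaxonMap(
        subject_to_taxon={
            "crypt_ref": "Geminigera cryophila",
            "ciliate_ref": "Tetrahymena thermophila",
            "other_ref": "Arabidopsis thaliana",
        },
        cryptophyte_labels=frozenset({"Geminigera cryophila"}),
        ciliate_labels=frozenset({"Tetrahymena thermophila"}),
    )
    rng = np.random.default_rng(seed)
    gene_ids = [f"q{i:06d}" for i in range(n_total)]
    hits = []
    for i, gid in enumerate(gene_ids):
        if i < n_crypt_strict:
            subject, ev = "crypt_ref", 1e-35
        elif i < n_crypt:
            subject, ev = "crypt_ref", 1e-10
        else:
            subject, ev = ("ciliate_ref" if i % 20 == 0 else "other_ref"), 1e-10
        hits.append(_make_hit(gid, subject, ev, 850))
    rng.shuffle(hits)
    return hits, taxa, gene_ids


# ---------------------------------------------------------------------------
# recovery metrics


@dataclass(frozen=True)
class RecoveryReport:
    pi_kn_abs_error: float
    partition_accuracy: float       # genes with hits, assigned vs true origin
    pathway_tpr: float | None       # at FDR alpha, vs true nonzero effects
    pathway_fpr: float | None
    log2fc_rmse: float | None       # per-pair estimate vs true pathway shift


def recovery_report(
    truth: SimTruth,
    summary,
    calls=None,
    expression_rows=None,
    deg_rows=None,
    alpha: float = 0.05,
) -> RecoveryReport:
    """Score pipeline outputs against the generator's ground truth."""
    pi_err = abs(summary.fraction_kn - truth.pi_kn)

    accuracy = float("nan")
    if calls is not None:
        with_hit = [c for c in calls if c.best_subject is not None]
        if any(c.gene_id not in truth.origin for c in with_hit):
            raise ValueError("origin calls refer to genes outside the simulated universe")
        if with_hit:
            accuracy = sum(c.origin == truth.origin[c.gene_id] for c in with_hit) / len(with_hit)

    tpr = fpr = None
    if expression_rows is not None:
        true_pos = {p for p, d in truth.effect_of_pathway.items() if d != 0}
        tested = [r for r in expression_rows if r.p_raw is not None]
        pos = [r for r in tested if r.unit_id in true_pos]
        neg = [r for r in tested if r.unit_id not in true_pos]
        tpr = sum(r.significant for r in pos) / len(pos) if pos else None
        fpr = sum(r.significant for r in neg) / len(neg) if neg else None

    rmse = None
    if deg_rows is not None and deg_rows:
        errs = []
        for row in deg_rows:
            pw = truth.pathway_of_gene.get(row.kn_gene)
            true_fc = truth.effect_of_pathway.get(pw, 0.0) if pw else 0.0
            errs.append((row.log2fc - true_fc) ** 2)
        rmse = math.sqrt(sum(errs) / len(errs))

    return RecoveryReport(
        pi_kn_abs_error=pi_err,
        partition_accuracy=accuracy,
        pathway_tpr=tpr,
        pathway_fpr=fpr,
        log2fc_rmse=rmse,
    )
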