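import math
import shutil
import subprocess

import numpy as np
import pytest
from scipy.stats import binomtest, nbinom

from kleptotx.deg import (
    NormFactors,
    classify_log2fc,
    log2_fold_change,
    median_ratio_factors,
    nb_exact_test,
    reciprocal_best_hits,
    run_deg,
    tmm_factors,
)
from kleptotx.io import CountTable

from conftest import make_hit


class TestReciprocalBestHits:
    def test_mutual_bests_pair_up(self):
        fwd = [make_hit("a", "x", 1e-50), make_hit("b", "y", 1e-40)]
        rev = [make_hit("x", "a", 1e-50), make_hit("y", "b", 1e-40)]
        pairs = reciprocal_best_hits(fwd, rev)
        assert {(p.gc_gene, p.kn_gene) for p in pairs} == {("a", "x"), ("b", "y")}

    def test_broken_mutuality_yields_no_pair(self):
        fwd = [make_hit("a", "x", 1e-50)]
        rev = [make_hit("x", "b", 1e-60)]  # x's best is b, not a
        assert reciprocal_best_hits(fwd, rev) == []

    def test_threshold_excludes_weak_pairs(self):
        fwd = [make_hit("a", "x", 1e-3)]
        rev = [make_hit("x", "a", 1e-50)]
        assert reciprocal_best_hits(fwd, rev, e_threshold=1e-4) == []

    def test_matches_exhaustive_double_loop_on_random_matrices(self):
        """RBBH equals brute-force mutual-best search over full score matrices."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            n, m = 6, 6
            ev = 10.0 ** rng.uniform(-60, -5, size=(n, m))
            qs = [f"q{i}" for i in range(n)]
            ss = [f"s{j}" for j in range(m)]
            fwd = [make_hit(qs[i], ss[j], ev[i, j]) for i in range(n) for j in range(m)]
            rev = [make_hit(ss[j], qs[i], ev[i, j]) for i in range(n) for j in range(m)]
            got = {(p.gc_gene, p.kn_gene) for p in reciprocal_best_hits(fwd, rev)}
            want = set()
            for i in range(n):
                j = int(np.argmin(ev[i]))
                if int(np.argmin(ev[:, j])) == i and ev[i, j] <= 1e-4:
                    want.add((qs[i], ss[j]))
            assert got == want


def tmm_oracle(gc, kn):
    """Straightforward re-implementation of the doubly trimmed, weighted
    mean of M-values, written from the published formula with explicit
    midrank arithmetic (independent of the library implementation)."""
    gc = np.asarray(gc, float)
    kn = np.asarray(kn, float)
    n_gc, n_kn = gc.sum(), kn.sum()
    q = [np.quantile(gc, 0.75) / n_gc, np.quantile(kn, 0.75) / n_kn]
    ref_is_gc = abs(q[0] - np.mean(q)) <= abs(q[1] - np.mean(q))
    obs, n_obs = (kn, n_kn) if ref_is_gc else (gc, n_gc)
    ref, n_ref = (gc, n_gc) if ref_is_gc else (kn, n_kn)
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    # quotient form, so exact count ties stay exactly tied in M (their
    # midranks, and hence the trim window, are tie-sensitive)
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(m)) < 1e-6:
        f = 1.0
    else:
        k = len(m)

        def midranks(v):
            return np.array([np.sum(v < vi) + 0.5 * (np.sum(v == vi) + 1) for vi in v])

        rm, ra = midranks(m), midranks(a)
        lo_m = math.floor(k * 0.3) + 1
        lo_a = math.floor(k * 0.05) + 1
        keep = (
            (rm >= lo_m) & (rm <= k + 1 - lo_m) & (ra >= lo_a) & (ra <= k + 1 - lo_a)
        )
        f = 2.0 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    raw = [1.0, f] if ref_is_gc else [f, 1.0]
    geo = math.sqrt(raw[0] * raw[1])
    return raw[0] / geo, raw[1] / geo


def random_count_pair(rng, n=150):
    mu = rng.lognormal(4.0, 1.5, n)
    gc = rng.poisson(mu)
    kn = rng.poisson(mu * rng.lognormal(0.0, 0.6, n))
    if not np.any((gc > 0) & (kn > 0)):
        gc[0] = kn[0] = 5
    return gc, kn


class TestTmmFactors:
    def test_identical_vectors_give_unit_factors(self):
        v = np.array([10, 50, 200, 3, 0, 77])
        f = tmm_factors(v, v)
        assert f.factor_gc == pytest.approx(1.0) and f.factor_kn == pytest.approx(1.0)

    def test_pure_depth_scaling_is_absorbed(self):
        gc = np.array([10, 50, 200, 3, 8, 77])
        f = tmm_factors(gc, 2 * gc)
        assert f.factor_gc == pytest.approx(1.0, abs=1e-9)
        assert f.factor_kn == pytest.approx(1.0, abs=1e-9)
        assert f.effective_size_kn == pytest.approx(2 * f.effective_size_gc)

    def test_matches_independent_reimplementation_on_100_fixtures(self):
        rng = np.random.default_rng(2024)
        for i in range(100):
            gc, kn = random_count_pair(rng)
            if i % 7 == 0:  # inject composition bias
                kn = kn.copy()
                kn[:15] *= 8
            f = tmm_factors(gc, kn)
            og, ok_ = tmm_oracle(gc, kn)
            assert f.factor_gc == pytest.approx(og, abs=1e-6)
            assert f.factor_kn == pytest.approx(ok_, abs=1e-6)

    def test_all_zero_overlap_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors([0, 5, 0], [3, 0, 2])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_edger_reference(self, tmp_path):
        """Cross-check against the canonical TMM implementation (edgeR)."""
        rng = np.random.default_rng(99)
        pairs = [random_count_pair(rng, 120) for _ in range(4)]
        pairs[1] = (pairs[1][0], pairs[1][1] * 3)  # depth difference
        np.savetxt(tmp_path / "gc.txt", np.array([p[0] for p in pairs]).T, fmt="%d")
        np.savetxt(tmp_path / "kn.txt", np.array([p[1] for p in pairs]).T, fmt="%d")
        script = tmp_path / "tmm.R"
        script.write_text(
            'suppressMessages(library(edgeR))\n'
            f'gc <- as.matrix(read.table("{tmp_path}/gc.txt"))\n'
            f'kn <- as.matrix(read.table("{tmp_path}/kn.txt"))\n'
            'for (i in 1:ncol(gc)) {\n'
            '  f <- calcNormFactors(DGEList(counts=cbind(gc[,i], kn[,i])), method="TMM")$samples$norm.factors\n'
            '  cat(sprintf("%.12f %.12f\\n", f[1], f[2]))\n'
            '}\n'
        )
        try:
            out = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=300, check=True
            ).stdout
        except (subprocess.CalledProcessError, subprocess.TimeoutExpired) as exc:
            pytest.skip(f"edgeR reference unavailable: {exc}")
        for (gc, kn), line in zip(pairs, out.strip().splitlines()):
            fr, fk = map(float, line.split())
            f = tmm_factors(gc, kn)
            assert f.factor_gc == pytest.approx(fr, abs=1e-6)
            assert f.factor_kn == pytest.approx(fk, abs=1e-6)


class TestMedianRatioFactors:
    def test_identical_vectors(self):
        v = [4, 9, 100, 3]
        f = median_ratio_factors(v, v)
        assert f.factor_gc == pytest.approx(1.0) and f.factor_kn == pytest.approx(1.0)

    def test_pure_scaling_gives_factor_ratio(self):
        gc = np.array([10, 40, 90, 7, 22])
        f = median_ratio_factors(gc, 3 * gc)
        assert f.factor_kn / f.factor_gc == pytest.approx(3.0)

    def test_hand_computed_five_gene_case(self):
        gc = np.array([10, 20, 30, 40, 0])
        kn = np.array([20, 10, 60, 40, 5])
        # usable genes: first four; ratios r_gc = c/sqrt(gc*kn)
        geo = np.sqrt(gc[:4] * kn[:4])
        s_gc = np.median(gc[:4] / geo)
        s_kn = np.median(kn[:4] / geo)
        norm = math.sqrt(s_gc * s_kn)
        f = median_ratio_factors(gc, kn)
        assert f.factor_gc == pytest.approx(s_gc / norm)
        assert f.factor_kn == pytest.approx(s_kn / norm)

    def test_no_common_positive_gene_rejected(self):
        with pytest.raises(ValueError):
            median_ratio_factors([0, 1], [1, 0])


def nb_p_oracle(y1, y2, e1, e2, phi):
    """Brute-force conditional enumeration with direct pmf products."""
    g = math.sqrt(e1 * e2)
    a = int(round(y1 * g / e1))
    b = int(round(y2 * g / e2))
    s = a + b
    if s == 0:
        return 1.0
    r = 1.0 / phi
    pp = r / (r + s / 2.0)
    probs = [nbinom.pmf(k, r, pp) * nbinom.pmf(s - k, r, pp) for k in range(s + 1)]
    tot = sum(probs)
    return min(1.0, sum(p for p in probs if p <= probs[a] * (1 + 1e-10)) / tot)


class TestNbExactTest:
    def test_symmetric_counts_give_p_one(self):
        assert nb_exact_test(20, 20, 1.0, 1.0) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        assert nb_exact_test(10, 40, 1.0, 1.0, 0.3) == pytest.approx(
            nb_p_oracle(10, 40, 1.0, 1.0, 0.3), abs=1e-12
        )

    def test_poisson_limit_recovers_conditional_binomial(self):
        p_nb = nb_exact_test(10, 40, 1.0, 1.0, dispersion=1e-8)
        p_binom = binomtest(10, 50, 0.5).pvalue
        assert p_nb == pytest.approx(p_binom, abs=1e-4)

    def test_random_cases_against_oracle(self):
        rng = np.random.default_rng(321)
        for _ in range(50):
            y1, y2 = int(rng.integers(0, 250)), int(rng.integers(0, 250))
            e1, e2 = rng.uniform(0.5, 2.0, 2)
            phi = float(rng.uniform(0.05, 1.0))
            p = nb_exact_test(y1, y2, e1, e2, phi)
            assert 0.0 <= p <= 1.0
            assert p == pytest.approx(nb_p_oracle(y1, y2, e1, e2, phi), abs=1e-12)

    def test_swap_symmetry(self):
        assert nb_exact_test(7, 31, 1.3, 0.8, 0.3) == pytest.approx(
            nb_exact_test(31, 7, 0.8, 1.3, 0.3)
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test(-1, 5, 1.0, 1.0)


class TestLog2FoldChange:
    def unit(self):
        return NormFactors("tmm", 1.0, 1.0, 1.0, 1.0)

    def test_equal_counts_zero(self):
        assert log2_fold_change(12, 12, self.unit()) == pytest.approx(0.0)

    def test_double_zero_is_zero(self):
        assert log2_fold_change(0, 0, self.unit()) == pytest.approx(0.0)

    def test_prior_arithmetic(self):
        assert log2_fold_change(10, 40, self.unit(), prior=0.5) == pytest.approx(
            math.log2(40.5 / 10.5)
        )

    def test_classification_boundaries(self):
        assert classify_log2fc(1.0) == "over"
        assert classify_log2fc(-1.0) == "under"
        assert classify_log2fc(0.99) == "ns"


def pair_table(y_gc, y_kn):
    from kleptotx.deg import RbbhPair

    counts, lengths = {}, {}
    pairs = []
    for i, (a, b) in enumerate(zip(y_gc, y_kn)):
        g = f"g{i:04d}"
        counts[("GC", g)] = int(a)
        counts[("KN", g)] = int(b)
        lengths[("GC", g)] = lengths[("KN", g)] = 500
        pairs.append(RbbhPair(g, g, 1e-30, 1e-30))
    return CountTable(counts=counts, lengths=lengths), pairs


class TestRunDeg:
    def test_empty_pairs_rejected(self):
        table, _ = pair_table([1], [1])
        with pytest.raises(ValueError):
            run_deg(table, [])

    def test_library_swap_antisymmetry_median_ratio(self):
        rng = np.random.default_rng(12)
        mu = rng.lognormal(4, 1, 80)
        y1, y2 = rng.poisson(mu), rng.poisson(mu * rng.lognormal(0, 0.4, 80))
        table, pairs = pair_table(y1, y2)
        swapped, _ = pair_table(y2, y1)
        a, _ = run_deg(table, pairs, method="median_ratio")
        b, _ = run_deg(swapped, pairs, method="median_ratio")
        for ra, rb in zip(a, b):
            assert ra.log2fc == pytest.approx(-rb.log2fc, abs=1e-9)
            assert ra.p_raw == pytest.approx(rb.p_raw, abs=1e-9)

    def test_null_deg_call_rate_controlled(self):
        """Effect-free NB pairs at dispersion 0.3: across 20 seeds, at most
        8 % of pairs are *called* (|log2fc| >= 1 and FDR-significant)."""
        called = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mu = rng.lognormal(5, 1, 150)
            shape = 1 / 0.3
            y1 = rng.poisson(rng.gamma(shape, mu * 0.3))
            y2 = rng.poisson(rng.gamma(shape, mu * 0.3))
            table, pairs = pair_table(y1, y2)
            rows, _ = run_deg(table, pairs, method="tmm", dispersion=0.3)
            called += sum(r.klass != "ns" and r.significant for r in rows)
            total += len(rows)
        assert called / total <= 0.08

    def test_recovers_injected_fold_change(self):
        """True +2 log2 shift on 50 genes: median estimated log2fc within 0.3."""
        rng = np.random.default_rng(77)
        mu = rng.lognormal(5, 1, 50)
        shape = 1 / 0.3
        y1 = rng.poisson(rng.gamma(shape, mu * 0.3))
        y2 = rng.poisson(rng.gamma(shape, 4 * mu * 0.3))
        # embed among a majority of effect-free pairs so the trimmed-mean
        # normalization is anchored by the unchanged genes
        mu0 = rng.lognormal(5, 1, 1000)
        z1 = rng.poisson(rng.gamma(shape, mu0 * 0.3))
        z2 = rng.poisson(rng.gamma(shape, mu0 * 0.3))
        table, pairs = pair_table(np.r_[y1, z1], np.r_[y2, z2])
        rows, _ = run_deg(table, pairs, method="tmm", dispersion=0.3)
        est = np.median([r.log2fc for r in rows[:50]])
        assert abs(est - 2.0) <= 0.3
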