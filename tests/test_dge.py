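"""Normalization, voom weights, moderated statistics and DEG calling."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import digamma, polygamma

from holoseq import dge
from holoseq.simulate import SimulationConfig, default_design, gen_counts


class TestFilterMinCount:
    def test_boundary(self):
        counts = pd.DataFrame(
            [[1, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 0]],
            index=["keep", "drop", "zero"], columns=list("abcd"))
        assert dge.filter_min_count(counts) == ["keep"]


class TestTmm:
    def test_proportional_columns_give_unit_factors(self, rng):
        base = rng.integers(1, 500, size=200).astype(float)
        counts = pd.DataFrame({"a": base, "b": 3 * base, "c": 0.5 * base})
        f = dge.tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_two_sample_hand_oracle(self):
        # direct evaluation of the trimmed weighted-mean formula on the
        # genes surviving the double trim
        counts = pd.DataFrame({"A": [100, 100, 100, 700],
                               "B": [100, 100, 100, 100]})
        f = dge.tmm_factors(counts, logratio_trim=0.0, abs_trim=0.0)
        na, nb = 1000.0, 400.0
        obs = np.array([100, 100, 100, 700]) / na
        ref = np.array([100, 100, 100, 100]) / nb
        m = np.log2(obs / ref)
        v = (na - np.array([100, 100, 100, 700])) / (na * np.array([100, 100, 100, 700])) \
            + (nb - 100) / (nb * 100)
        fa = 2 ** (np.sum(m / v) / np.sum(1 / v))
        expected = np.array([fa, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        # reference sample is chosen by the f75 rule; compare as a set
        assert np.allclose(sorted(f), sorted(expected), rtol=1e-12)

    def test_permutation_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(0, 800, size=(300, 4)),
                              columns=list("abcd"))
        f1 = dge.tmm_factors(counts)
        f2 = dge.tmm_factors(counts[["c", "a", "d", "b"]])
        assert np.allclose(f1.sort_index(), f2.sort_index())

    def test_geometric_mean_is_one(self, counts_fixture):
        *_, counts, _, _ = counts_fixture[0], counts_fixture[1], \
            counts_fixture[2], counts_fixture[3], counts_fixture[4]
        f = dge.tmm_factors(counts_fixture[2])
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_edger(self, tmp_path, rng):
        """Independent oracle: edgeR's calcNormFactors on the same matrix."""
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(300, 5)),
            index=[f"g{i}" for i in range(300)],
            columns=[f"s{j}" for j in range(5)])
        counts.iloc[:30, 0] *= 8  # plant composition bias
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim("{path}", row.names=1))
            f <- calcNormFactors(x)
            cat(sprintf("%.10f", f), sep="\\n")
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True, timeout=120)
        assert r.returncode == 0, r.stderr
        expected = np.array([float(v) for v in r.stdout.split()])
        mine = dge.tmm_factors(counts).to_numpy()
        assert np.allclose(mine, expected, rtol=1e-6)


class TestLogCpm:
    def test_formula_instance(self):
        counts = pd.DataFrame({"s": [1, 1]})
        # library size 2, default factor 1, prior 0.5
        got = dge.logcpm(counts).iloc[0, 0]
        assert got == pytest.approx(np.log2(1.5 / 3 * 1e6))

    def test_all_zero_column_constant(self):
        counts = pd.DataFrame({"s1": [0, 0, 0], "s2": [5, 5, 5]})
        col = dge.logcpm(counts)["s1"]
        assert col.nunique() == 1

    def test_scale_invariance_without_prior(self):
        c1 = pd.DataFrame({"s": [10, 20, 30]})
        c2 = 2 * c1
        a = dge.logcpm(c1, prior_count=1e-9)
        b = dge.logcpm(c2, prior_count=1e-9)
        assert np.allclose(a, b, atol=1e-6)


class TestMds:
    def test_identical_samples_zero_distance(self, rng):
        y = rng.normal(size=(600, 1))
        expr = pd.DataFrame(np.hstack([y, y, rng.normal(size=(600, 1))]),
                            columns=["a", "b", "c"])
        res = dge.mds_coordinates(expr)
        assert res.distances.loc["a", "b"] == pytest.approx(0.0)

    def test_shifted_sample_distance_equals_delta(self, rng):
        base = rng.normal(size=(500, 1))
        delta = 1.7
        expr = pd.DataFrame(np.hstack([base, base, base + delta]),
                            columns=["a", "b", "c"])
        res = dge.mds_coordinates(expr, top=500)
        assert res.distances.loc["a", "c"] == pytest.approx(delta)
        assert res.distances.loc["b", "c"] == pytest.approx(delta)

    def test_embedding_reproduces_exact_euclidean_distances(self):
        # three points in the plane: principal coordinates must recover
        # the distance geometry exactly
        expr = pd.DataFrame({"a": [0.0, 0], "b": [3.0, 0], "c": [0, 4.0]},
                            index=["g1", "g2"])
        res = dge.mds_coordinates(expr, top=2)
        coords = res.coordinates.to_numpy()
        for i, si in enumerate(res.coordinates.index):
            for j, sj in enumerate(res.coordinates.index):
                d_embed = np.linalg.norm(coords[i] - coords[j])
                assert d_embed == pytest.approx(res.distances.iloc[i, j], abs=1e-8)


class TestVoom:
    def test_weights_positive_and_flat_under_constant_cv(self, rng):
        # gamma-Poisson with constant dispersion at high counts has a
        # nearly flat mean-variance trend on the log scale
        mu = rng.uniform(500, 2000, size=(400, 1)) * np.ones((1, 12))
        counts = pd.DataFrame(rng.poisson(rng.gamma(10.0, mu / 10.0)))
        X = np.ones((12, 1))
        _, w = dge.voom_weights(counts, X)
        assert (w > 0).all()
        assert w.max() / w.min() < 2.0

    def test_library_doubling_preserves_weight_order(self, counts_fixture):
        _, design, counts, _, _ = counts_fixture
        X = np.column_stack([np.ones(len(design)),
                             (design["site"] == "waiopae").astype(float)])
        _, w1 = dge.voom_weights(counts, X)
        _, w2 = dge.voom_weights(2 * counts, X)
        rho = stats.spearmanr(w1.ravel(), w2.ravel()).statistic
        assert rho > 0.99

    def test_rank_deficient_design_rejected(self, counts_fixture):
        counts = counts_fixture[2]
        X = np.ones((counts.shape[1], 2))  # duplicated column
        with pytest.raises(ValueError):
            dge.voom_weights(counts, X)


class TestModeration:
    def test_squeeze_var_matches_bisection_oracle(self):
        s2 = np.array([1.0, 4.0, 9.0])
        d = 4.0
        d0, s0 = dge.squeeze_var(s2, d)
        # independent oracle: solve the trigamma moment equation by bisection
        z = np.log(s2)
        e = z - digamma(d / 2) + np.log(d / 2)
        evar = e.var(ddof=1) - polygamma(1, d / 2)
        assert evar > 0
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = (lo + hi) / 2
            if polygamma(1, mid) > evar:
                lo = mid
            else:
                hi = mid
        d0_oracle = 2 * (lo + hi) / 2
        s0_oracle = np.exp(e.mean() + digamma(d0_oracle / 2) - np.log(d0_oracle / 2))
        assert d0 == pytest.approx(d0_oracle, rel=1e-6)
        assert s0 == pytest.approx(s0_oracle, rel=1e-6)

    def test_infinite_prior_df_limit(self, rng):
        y = pd.DataFrame(rng.normal(size=(50, 8)))
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = dge.fit_and_moderate(y, None, X, [0, 1], d0=np.inf)
        t_expected = fit.coefficients / (fit.stdev_unscaled * np.sqrt(fit.s0sq))
        assert np.allclose(fit.t, t_expected)
        assert np.allclose(fit.p, 2 * stats.norm.sf(np.abs(fit.t)))

    def test_single_gene_falls_back_to_ordinary_t(self, rng):
        y = pd.DataFrame(rng.normal(size=(1, 8)))
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = dge.fit_and_moderate(y, None, X, [0, 1])
        assert fit.d0 == 0.0
        t_ord = fit.coefficients / (fit.stdev_unscaled * np.sqrt(fit.sigma2))
        assert np.allclose(fit.t, t_ord)

    def test_matches_limma_voom_ebayes(self, tmp_path):
        """Independent oracle: limma's voom + lmFit + eBayes pipeline."""
        cfg = SimulationConfig(seed=31, n_genes=300, n_deg_site=20,
                               n_deg_clade=0, module_spec=(), n_samples=10)
        design = default_design(cfg)
        counts, _, _ = gen_counts(cfg, design)
        path = tmp_path / "counts.tsv"
        counts.to_csv(path, sep="\t")
        grp = "".join("1" if s == "waiopae" else "0" for s in design["site"])
        script = textwrap.dedent(f"""
            suppressMessages({{library(edgeR); library(limma)}})
            x <- as.matrix(read.delim("{path}", row.names=1))
            grp <- as.numeric(strsplit("{grp}", "")[[1]])
            design <- cbind(1, grp)
            y <- DGEList(x); y <- calcNormFactors(y)
            v <- voom(y, design)
            fit <- eBayes(lmFit(v, design))
            out <- cbind(fit$coefficients[,2], fit$t[,2], fit$df.prior, fit$s2.prior)
            write.table(format(out, digits=12), "{tmp_path}/limma.tsv",
                        col.names=FALSE, row.names=FALSE, quote=FALSE)
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True, timeout=180)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(tmp_path / "limma.tsv", sep=r"\s+", header=None)
        factors = dge.tmm_factors(counts)
        X = np.column_stack([np.ones(len(design)),
                             (design["site"] == "waiopae").astype(float)])
        y, w = dge.voom_weights(counts, X, factors)
        fit = dge.fit_and_moderate(y, w, X, [0, 1])
        # log-fold changes agree closely; t and the prior within a few
        # percent (lowess implementations differ slightly)
        assert np.allclose(fit.coefficients, ref[0], atol=0.02)
        r_t = np.corrcoef(fit.t, ref[1])[0, 1]
        assert r_t > 0.999
        assert fit.d0 == pytest.approx(ref[2].iloc[0], rel=0.1)
        assert fit.s0sq == pytest.approx(ref[3].iloc[0], rel=0.1)


class TestDegCalling:
    def test_fdr_equals_bh_oracle(self, rng):
        y = pd.DataFrame(rng.normal(size=(40, 8)))
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = dge.fit_and_moderate(y, None, X, [0, 1])
        p = fit.p.to_numpy()
        m = len(p)
        order = np.argsort(p)
        bh = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            bh[i] = running
        assert np.allclose(fit.fdr, bh)

    def test_split_by_sign(self, rng):
        y = pd.DataFrame(np.vstack([
            np.repeat([[0.0, 0, 0, 0, 5, 5, 5, 5]], 5, axis=0)
            + rng.normal(0, 0.1, size=(5, 8)),
            np.repeat([[5.0, 5, 5, 5, 0, 0, 0, 0]], 5, axis=0)
            + rng.normal(0, 0.1, size=(5, 8)),
        ]), index=[f"up{i}" for i in range(5)] + [f"dn{i}" for i in range(5)])
        X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
        fit = dge.fit_and_moderate(y, None, X, [0, 1])
        up, down = dge.call_degs(fit, alpha=0.05)
        assert up == {f"up{i}" for i in range(5)}
        assert down == {f"dn{i}" for i in range(5)}

    def test_all_p_one_no_calls(self):
        fit = dge.DgeFit(
            coefficients=pd.Series([1.0, -1.0]),
            stdev_unscaled=pd.Series([1.0, 1.0]), sigma2=pd.Series([1.0, 1.0]),
            df_residual=4, d0=0, s0sq=1.0, t=pd.Series([0.0, 0.0]),
            p=pd.Series([1.0, 1.0]), fdr=pd.Series([1.0, 1.0]))
        up, down = dge.call_degs(fit)
        assert up == down == set()


class TestSetOverlap:
    def test_pairwise(self):
        regions = dge.set_overlap({"A": {1, 2}, "B": {2, 3}})
        assert regions[("A",)] == 1
        assert regions[("B",)] == 1
        assert regions[("A", "B")] == 1

    def test_disjoint(self):
        regions = dge.set_overlap({"A": {1}, "B": {2}})
        assert regions[("A", "B")] == 0

    def test_subset(self):
        regions = dge.set_overlap({"A": {1, 2}, "B": {1, 2, 3}})
        assert regions[("A", "B")] == 2
        assert regions[("A",)] == 0


def test_outlier_flagging_is_flag_only(rng):
    y = rng.normal(size=(200, 6))
    y[:, 5] += 4.0  # one sample far from the rest
    expr = pd.DataFrame(y, columns=list("abcdef"))
    flagged = dge.flag_expression_outliers(expr)
    assert flagged == ["f"]
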