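"""Statistical battery: partial Spearman, group comparison, the
longitudinal mixed model, and mediation — each against an independent
oracle where one exists."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import dtialps as da
from dtialps import stats as st
from dtialps.errors import ModelError, ValidationError


def brute_spearman(x, y):
    """Textbook Spearman: Pearson correlation of average ranks."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


class TestPartialSpearman:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        r = st.partial_spearman(x, x)
        assert r.rho == pytest.approx(1.0)

    def test_no_covariates_equals_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        r = st.partial_spearman(x, y)
        assert r.rho == pytest.approx(brute_spearman(x, y), abs=1e-12)
        ref = sps.spearmanr(x, y)
        assert r.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert r.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_common_cause_partialled_out(self):
        """x and y driven only by a shared covariate: the adjusted rho
        averages to ~0 across seeds while the raw rho stays strong."""
        raws, adjs = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 2000
            z = rng.normal(size=n)
            x = 2.0 * z + rng.normal(size=n)
            y = -1.5 * z + rng.normal(size=n)
            raws.append(st.partial_spearman(x, y).rho)
            adjs.append(st.partial_spearman(x, y, z).rho)
        assert np.mean(np.abs(raws)) > 0.7
        assert abs(np.mean(adjs)) < 0.02

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n = 98
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "age": rng.normal(65, 8, n),
                "sex": rng.integers(0, 2, n).astype(float),
            }
        )
        df["y"] = 0.3 * df.x - 0.02 * df.age + rng.normal(size=n)
        ref = pg.partial_corr(df, x="x", y="y", covar=["age", "sex"], method="spearman")
        r = st.partial_spearman(df.x, df.y, df[["age", "sex"]])
        assert r.rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert r.n_used == int(ref["n"].iloc[0])

    def test_nan_rows_dropped(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan, 7, 8])
        y = np.array([1.0, 2, 3, 4, 5, 6, 7, np.nan])
        r = st.partial_spearman(x, y)
        assert r.n_used == 6 and r.rho == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            st.partial_spearman(np.ones(10), np.arange(10.0))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            st.partial_spearman(np.arange(4.0), np.arange(4.0), np.arange(4.0))


class TestCompareGroups:
    def test_clear_separation_significant(self):
        a = np.array([1.0, 1.01, 0.99, 1.0, 1.02])
        b = a + 10.0
        c = a - 10.0
        res = st.compare_groups(np.r_[a, b, c], ["a"] * 5 + ["b"] * 5 + ["c"] * 5)
        assert res.pvalue < 1e-4
        assert len(res.posthoc) == 3
        assert (res.posthoc["p_adjusted"] < 0.01).all()

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=60)
        lab = np.repeat(["a", "b", "c"], 20)
        r1 = st.compare_groups(v, lab)
        r2 = st.compare_groups(v, lab)
        assert r1.statistic == r2.statistic and r1.pvalue == r2.pvalue
        assert r1.posthoc.equals(r2.posthoc)

    def test_branches_agree_on_separated_data(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        c = rng.normal(10, 1, 30)
        v = np.r_[a, b, c]
        lab = np.repeat(["a", "b", "c"], 30)
        assert st.compare_groups(v, lab, force="anova").pvalue < 1e-6
        assert st.compare_groups(v, lab, force="kruskal").pvalue < 1e-6

    def test_gate_selects_kruskal_for_skewed_data(self):
        rng = np.random.default_rng(6)
        v = np.r_[rng.lognormal(0, 1.5, 40), rng.lognormal(0.2, 1.5, 40)]
        res = st.compare_groups(v, ["a"] * 40 + ["b"] * 40)
        assert res.test_name == "kruskal" and res.posthoc_name == "dunn"

    def test_dunn_two_group_z_squares_to_kruskal_h(self):
        """With two groups and no ties, the Dunn z statistic squares to the
        Kruskal-Wallis H — an independent identity check."""
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 25), rng.normal(0.8, 1, 30)
        res = st.compare_groups(np.r_[a, b], ["a"] * 25 + ["b"] * 30, force="kruskal")
        h = sps.kruskal(a, b).statistic
        z = res.posthoc["statistic"].iloc[0]
        assert z**2 == pytest.approx(h, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            st.compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestGroupTimeModel:
    def test_linearity_of_coefficients(self, default_cohort):
        lm1 = st.fit_group_time_model(default_cohort)
        doubled = default_cohort.copy()
        doubled["alps_mean"] = 2.0 * doubled["alps_mean"]
        lm2 = st.fit_group_time_model(doubled)
        assert lm2.interaction_beta == pytest.approx(2 * lm1.interaction_beta, rel=1e-6)
        for term in lm1.coefficients.index:
            if term in ("age", "sex") or "group" in term.lower() or term in ("Intercept", "time"):
                assert lm2.term(term) == pytest.approx(2 * lm1.term(term), rel=1e-5, abs=1e-10)

    def test_recovers_embedded_interaction_roughly(self, default_cohort):
        lm = st.fit_group_time_model(default_cohort)
        # single cohort: within ~3 SE of the embedded -0.057
        se = float(lm.coefficients.loc[lm.coefficients.index[-2], "se"])
        assert lm.interaction_beta == pytest.approx(-0.057, abs=0.05)
        assert lm.n_subjects == 126 and lm.n_observations == 252

    def test_singular_design_named(self, default_cohort):
        broken = default_cohort[
            ~((default_cohort.group == "PD_poor") & (default_cohort.session == 2))
        ]
        with pytest.raises(ModelError, match="PD_poor"):
            st.fit_group_time_model(broken)

    def test_rm_anova_crosscheck_flags_strong_interaction(self):
        strong = da.simulate_cohort(
            da.CohortSimParams(group_time_beta=-0.3, session_noise_sd=0.02), seed=1
        )
        table = st.rm_anova_crosscheck(strong)
        assert table.loc["group:session", "pvalue"] < 1e-6
        null = da.simulate_cohort(
            da.CohortSimParams(
                alps_mean_per_group={"HC": 1.15, "PD_good": 1.15, "PD_poor": 1.15},
                group_time_beta=0.0,
            ),
            seed=1,
        )
        assert st.rm_anova_crosscheck(null).loc["group:session", "pvalue"] > 0.01


class TestMediation:
    def _data(self, n=500, seed=0, direct=0.0, through=0.8):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        m = through * x + rng.normal(size=n)
        y = 0.6 * m * (through != 0) + direct * x + rng.normal(size=n)
        return x, m, y

    def test_decomposition_identity_exact(self):
        x, m, y = self._data(n=80, seed=1, direct=0.3)
        res = st.mediation(x, m, y, n_boot=50, seed=0)
        assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-12)

    def test_identity_with_covariates(self):
        rng = np.random.default_rng(2)
        x, m, y = self._data(n=120, seed=2, direct=0.2)
        cov = rng.normal(size=(120, 2))
        res = st.mediation(x, m, y, cov, n_boot=50, seed=0)
        assert res.total == pytest.approx(res.direct + res.indirect, abs=1e-12)

    def test_fully_mediated_construction(self):
        """x -> m -> y with no direct path: across 20 replicates the 95%
        direct-effect CI covers 0 (binomial band >= 16/20) and the indirect
        CI excludes 0 essentially always."""
        hits_direct, hits_indirect = 0, 0
        for s in range(20):
            x, m, y = self._data(n=500, seed=100 + s, direct=0.0, through=0.8)
            res = st.mediation(x, m, y, n_boot=400, seed=s)
            hits_direct += res.ci_direct[0] <= 0.0 <= res.ci_direct[1]
            hits_indirect += not (res.ci_indirect[0] <= 0.0 <= res.ci_indirect[1])
        assert hits_direct >= 16 and hits_indirect >= 18

    def test_null_indirect_covered(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            x = rng.normal(size=200)
            m = rng.normal(size=200)  # independent mediator
            y = 0.5 * x + rng.normal(size=200)
            res = st.mediation(x, m, y, n_boot=400, seed=s)
            hits += res.ci_indirect[0] <= 0.0 <= res.ci_indirect[1]
        assert hits >= 16

    def test_matches_pingouin_point_estimates(self):
        pg = pytest.importorskip("pingouin")
        x, m, y = self._data(n=98, seed=5, direct=0.25)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        ref = pg.mediation_analysis(df, x="x", m="m", y="y", n_boot=100, seed=0)
        res = st.mediation(x, m, y, n_boot=100, seed=0)
        ref_by = dict(zip(ref["path"], ref["coef"]))
        assert res.total == pytest.approx(ref_by["Total"], abs=1e-10)
        assert res.direct == pytest.approx(ref_by["Direct"], abs=1e-10)
        assert res.indirect == pytest.approx(ref_by["Indirect"], abs=1e-10)

    def test_reproducible_given_seed(self):
        x, m, y = self._data(n=60, seed=9, direct=0.2)
        r1 = st.mediation(x, m, y, n_boot=200, seed=7)
        r2 = st.mediation(x, m, y, n_boot=200, seed=7)
        assert r1.ci_indirect == r2.ci_indirect

    def test_zero_variance_mediator_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValidationError):
            st.mediation(x, np.ones(20), x, n_boot=10, seed=0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            st.mediation(np.arange(5.0), np.arange(5.0), np.arange(5.0), n_boot=10, seed=0)
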