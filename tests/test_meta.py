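import subprocess
import textwrap

import numpy as np
import pytest

from epiaging import MetaResult, dl_pool, forest_plot, reml_pool
from epiaging.assoc import AssocEstimate, Z975
from epiaging.meta import reml_loglik
from oracles import grid_search_reml


def _est(beta, se, i=0, **kw):
    defaults = dict(cohort_id=f"c{i}", outcome="eaa", factor="education",
                    category="Low", model="M1")
    defaults.update(kw)
    return AssocEstimate.from_fit(defaults["cohort_id"], defaults["outcome"],
                                  defaults["factor"], defaults["category"],
                                  defaults["model"], beta, se, 100)


def make_estimates(betas, ses):
    return [_est(b, s, i) for i, (b, s) in enumerate(zip(betas, ses))]


class TestREML:
    def test_zero_heterogeneity(self):
        res = reml_pool(make_estimates([0.3] * 5, [0.1] * 5))
        assert res.beta_pooled == pytest.approx(0.3, abs=1e-10)
        assert res.tau2 == pytest.approx(0.0, abs=1e-10)
        assert res.i2 == 0.0
        assert res.k == 5

    def test_three_study_grid_oracle(self):
        betas, ses = [0.1, 0.3, 0.8], [0.1, 0.1, 0.1]
        res = reml_pool(make_estimates(betas, ses))
        tau2_o, beta_o = grid_search_reml(betas, ses)
        assert res.tau2 == pytest.approx(tau2_o, abs=1e-6)
        assert res.beta_pooled == pytest.approx(beta_o, abs=1e-6)

    def test_random_problems_match_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            k = int(rng.integers(3, 26))
            betas = rng.normal(0.3, 0.4, k)
            ses = rng.uniform(0.05, 0.3, k)
            res = reml_pool(make_estimates(betas, ses))
            tau2_o, beta_o = grid_search_reml(betas, ses)
            assert res.tau2 == pytest.approx(tau2_o, abs=1e-6)
            assert res.beta_pooled == pytest.approx(beta_o, abs=1e-6)

    def test_fixed_effect_limit(self):
        """Homogeneous inputs drive tau2 to 0 and the pooled mean to the
        inverse-variance fixed-effect mean."""
        betas, ses = [0.28, 0.31, 0.30, 0.29], [0.05, 0.08, 0.06, 0.07]
        res = reml_pool(make_estimates(betas, ses))
        assert res.tau2 == pytest.approx(0.0, abs=1e-8)
        w = 1.0 / np.array(ses) ** 2
        fe = np.sum(w * betas) / np.sum(w)
        assert res.beta_pooled == pytest.approx(fe, abs=1e-8)

    def test_ci_is_wald_normal(self):
        res = reml_pool(make_estimates([0.1, 0.5, 0.9], [0.1, 0.2, 0.15]))
        lo, hi = res.ci95
        assert lo == pytest.approx(res.beta_pooled - Z975 * res.se_pooled, abs=1e-9)
        assert hi == pytest.approx(res.beta_pooled + Z975 * res.se_pooled, abs=1e-9)

    def test_ci_width_shrinks_with_k(self):
        widths = []
        for k in (2, 4, 8, 16):
            res = reml_pool(make_estimates([0.3] * k, [0.1] * k))
            lo, hi = res.ci95
            widths.append(hi - lo)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_i2_zero_when_q_small(self):
        res = reml_pool(make_estimates([0.30, 0.301, 0.299], [0.2, 0.2, 0.2]))
        assert res.q_stat <= 2
        assert res.i2 == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 2"):
            reml_pool(make_estimates([0.3], [0.1]))
        with pytest.raises(ValueError, match="positive"):
            reml_pool(make_estimates([0.3, 0.4], [0.1, 0.0]))

    def test_loglik_shape(self):
        """The profile log-likelihood at the optimum is no worse than at
        neighbouring tau2 values."""
        beta = np.array([0.1, 0.3, 0.8])
        v = np.full(3, 0.01)
        res = reml_pool(make_estimates(beta, np.sqrt(v)))
        ll_star = reml_loglik(res.tau2, beta, v)
        for t2 in (res.tau2 * 0.9, res.tau2 * 1.1, 0.0, 1.0):
            assert ll_star >= reml_loglik(t2, beta, v) - 1e-9

    def test_knapp_hartung_widens_ci(self):
        ests = make_estimates([0.1, 0.5, 0.9, 0.2], [0.1, 0.1, 0.1, 0.1])
        plain = reml_pool(ests)
        kh = reml_pool(ests, knapp_hartung=True)
        assert (kh.ci95[1] - kh.ci95[0]) > (plain.ci95[1] - plain.ci95[0])
        assert kh.beta_pooled == pytest.approx(plain.beta_pooled, abs=1e-12)


class TestDL:
    def test_homogeneous_matches_reml(self):
        ests = make_estimates([0.3] * 4, [0.1] * 4)
        assert dl_pool(ests).tau2 == pytest.approx(reml_pool(ests).tau2, abs=1e-10)

    def test_hand_arithmetic_fixture(self):
        """k=3, beta={0.1,0.3,0.8}, v=0.01: w=100 each, beta_FE=0.4,
        Q=100*(0.09+0.01+0.16)=26, denom=300-100=... =200,
        tau2_DL=(26-2)/200=0.12."""
        res = dl_pool(make_estimates([0.1, 0.3, 0.8], [0.1, 0.1, 0.1]))
        assert res.q_stat == pytest.approx(26.0, abs=1e-10)
        assert res.tau2 == pytest.approx(0.12, abs=1e-10)
        assert res.i2 == pytest.approx((26 - 2) / 26 * 100, abs=1e-9)

    def test_reml_dl_simulation_agreement(self):
        """With k=30 studies and true tau2=0.04 the two estimators agree on
        average within 25%."""
        rng = np.random.default_rng(77)
        rel = []
        for _ in range(300):
            k = 30
            v = rng.uniform(0.005, 0.02, k)
            beta = rng.normal(0.3, np.sqrt(v + 0.04))
            ests = make_estimates(beta, np.sqrt(v))
            t_r = reml_pool(ests).tau2
            t_d = dl_pool(ests).tau2
            denom = (t_r + t_d) / 2
            if denom > 1e-6:
                rel.append(abs(t_r - t_d) / denom)
        assert np.mean(rel) < 0.25


class TestMetaforCrossCheck:
    def test_matches_r_metafor(self, tmp_path):
        """Independent oracle: R metafor rma(method='REML') on a 6-study
        fixture gives the same tau2, pooled beta and SE."""
        betas = [0.12, 0.45, 0.30, -0.05, 0.62, 0.28]
        ses = [0.10, 0.15, 0.08, 0.12, 0.20, 0.09]
        res = reml_pool(make_estimates(betas, ses))
        script = tmp_path / "meta.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(metafor))
            yi <- c({', '.join(map(str, betas))})
            sei <- c({', '.join(map(str, ses))})
            fit <- rma(yi=yi, sei=sei, method="REML", control=list(tol=1e-12))
            cat(sprintf("%.10f %.10f %.10f\\n", fit$b[1], fit$tau2, fit$se))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        b_r, tau2_r, se_r = map(float, out.stdout.split())
        # metafor's Fisher scoring and our bounded profile search stop at
        # slightly different points; 1e-5 is beyond either's stated tolerance
        assert res.beta_pooled == pytest.approx(b_r, abs=1e-5)
        assert res.tau2 == pytest.approx(tau2_r, abs=1e-5)
        assert res.se_pooled == pytest.approx(se_r, abs=1e-5)


class TestForestPlot:
    def _results(self):
        out = []
        for outcome in ("sem", "pantissue", "blood", "phenoage"):
            out.append(reml_pool(make_estimates([0.2, 0.4, 0.3], [0.1, 0.1, 0.1])
                                 ).__class__(**{**reml_pool(
                                     make_estimates([0.2, 0.4, 0.3],
                                                    [0.1, 0.1, 0.1])).__dict__,
                                     "outcome": outcome}))
        return out

    def test_renders_rows(self, tmp_path):
        path = tmp_path / "forest.svg"
        forest_plot(self._results(), str(path))
        text = path.read_text()
        assert text.startswith("<?xml")
        assert text.count("<g id=\"line2d") >= 4  # one CI line per outcome

    def test_deterministic_output(self, tmp_path):
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        forest_plot(self._results(), str(p1))
        forest_plot(self._results(), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_input_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no results"):
            forest_plot([], str(tmp_path / "x.svg"))
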