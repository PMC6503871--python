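"""Random-effects meta-analysis of per-cohort estimates.

The pooled model is beta_i ~ N(beta, v_i + tau2) with known within-cohort
sampling variances v_i = se_i^2 and between-cohort variance tau2 estimated
by restricted maximum likelihood (REML). The REML profile log-likelihood

    l(tau2) = -1/2 sum ln(v_i + tau2) - 1/2 ln(sum w_i)
              - 1/2 sum w_i (beta_i - beta_hat)^2,   w_i = 1/(v_i + tau2)

is maximized over tau2 in [0, tau2_max] on a variance-standardized scale:
the stationary point of the profile likelihood is found by bracketing the
root of its closed-form derivative (near machine precision), falling back
to bounded scalar minimization when no interior root exists; beta_hat is
the weighted mean at the optimum and se_pooled = (sum w_i)^(-1/2). Heterogeneity is summarized
by Cochran's Q (fixed-effect weights) and I2 = max(0, (Q - (k-1))/Q) * 100.
The DerSimonian-Laird closed-form estimator is provided as a comparator.
Confidence intervals are plain Wald normal intervals; a Knapp-Hartung
t-based adjustment is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm, t as t_dist

from .assoc import AssocEstimate, Z975

__all__ = ["MetaResult", "reml_loglik", "reml_pool", "dl_pool", "forest_plot"]


@dataclass
class MetaResult:
    outcome: str
    factor: str
    category: str
    model: str
    k: int
    beta_pooled: float
    se_pooled: float
    ci95: tuple[float, float]
    tau2: float
    i2: float
    q_stat: float
    p_value: float
    method: str = "REML"
    estimates_in: list[AssocEstimate] = field(default_factory=list)


def _validate(estimates: list[AssocEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) < 2:
        raise ValueError("meta-analysis needs at least 2 estimates")
    beta = np.array([e.beta for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if (se <= 0).any():
        raise ValueError("all standard errors must be positive")
    return beta, se


def _q_and_i2(beta: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    w_fe = 1.0 / v
    beta_fe = float(np.sum(w_fe * beta) / np.sum(w_fe))
    q = float(np.sum((beta - beta_fe) ** 2 / v))
    k = len(beta)
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    return q, i2


def reml_loglik(tau2: float, beta: np.ndarray, v: np.ndarray) -> float:
    """REML profile log-likelihood of the between-study variance."""
    w = 1.0 / (v + tau2)
    bh = np.sum(w * beta) / np.sum(w)
    return float(-0.5 * np.sum(np.log(v + tau2)) - 0.5 * np.log(np.sum(w))
                 - 0.5 * np.sum(w * (beta - bh) ** 2))


def _reml_score(tau2: float, beta: np.ndarray, v: np.ndarray) -> float:
    """d/d(tau2) of the REML profile log-likelihood."""
    w = 1.0 / (v + tau2)
    bh = np.sum(w * beta) / np.sum(w)
    return float(0.5 * (np.sum(w ** 2 * (beta - bh) ** 2) - np.sum(w)
                        + np.sum(w ** 2) / np.sum(w)))


def _finish(estimates, beta, v, tau2, method, knapp_hartung) -> MetaResult:
    w = 1.0 / (v + tau2)
    beta_hat = float(np.sum(w * beta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    k = len(beta)
    if knapp_hartung:
        q_kh = float(np.sum(w * (beta - beta_hat) ** 2) / (k - 1))
        se_kh = se * max(q_kh, 1.0) ** 0.5
        crit = float(t_dist.ppf(0.975, k - 1))
        ci = (beta_hat - crit * se_kh, beta_hat + crit * se_kh)
        p = float(2 * t_dist.sf(abs(beta_hat / se_kh), k - 1))
        se = se_kh
    else:
        ci = (beta_hat - Z975 * se, beta_hat + Z975 * se)
        p = float(2 * norm.sf(abs(beta_hat / se)))
    q, i2 = _q_and_i2(beta, v)
    e0 = estimates[0]
    same = lambda attr: (getattr(e0, attr)
                         if len({getattr(e, attr) for e in estimates}) == 1 else "mixed")
    return MetaResult(outcome=same("outcome"), factor=same("factor"),
                      category=same("category"), model=same("model"), k=k,
                      beta_pooled=beta_hat, se_pooled=se, ci95=ci,
                      tau2=float(tau2), i2=i2, q_stat=q, p_value=p,
                      method=method, estimates_in=list(estimates))


def reml_pool(estimates: list[AssocEstimate],
              knapp_hartung: bool = False) -> MetaResult:
    """Pool per-cohort estimates with tau2 by REML (bounded 1-D search)."""
    beta, se = _validate(estimates)
    v = se ** 2
    # optimize on a standardized scale (variances ~ 1) so the search is
    # well conditioned and pooling is equivariant under linear rescaling
    s2 = float(np.mean(v))
    bs, vs = beta / np.sqrt(s2), v / s2
    tau2_max = 10.0 * float(vs.max()) * len(beta)
    if _reml_score(0.0, bs, vs) <= 0.0:
        # likelihood decreasing at the boundary: truncate at zero
        tau2_s = 0.0
    elif _reml_score(tau2_max, bs, vs) > 0.0:
        # no interior stationary point below the cap (pathological spread)
        res = minimize_scalar(lambda t2: -reml_loglik(t2, bs, vs),
                              bounds=(0.0, tau2_max), method="bounded",
                              options={"xatol": 1e-12})
        tau2_s = float(res.x)
    else:
        # the score is the exact derivative of the profile log-likelihood;
        # root bracketing localizes the optimum to near machine precision
        tau2_s = float(brentq(_reml_score, 0.0, tau2_max, args=(bs, vs),
                              xtol=1e-14, rtol=8.9e-16))
    return _finish(estimates, beta, v, tau2_s * s2, "REML", knapp_hartung)


def dl_pool(estimates: list[AssocEstimate],
            knapp_hartung: bool = False) -> MetaResult:
    """DerSimonian-Laird moment estimator of tau2 (closed form)."""
    beta, se = _validate(estimates)
    v = se ** 2
    w = 1.0 / v
    q, _ = _q_and_i2(beta, v)
    k = len(beta)
    denom = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return _finish(estimates, beta, v, tau2, "DL", knapp_hartung)


def forest_plot(results: list[MetaResult], path: str,
                title: str | None = None) -> None:
    """Forest plot of pooled effects: one panel row per factor x category,
    one marker + 95% CI per outcome, a vertical null line at zero."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not results:
        raise ValueError("no results to plot")
    # fixed hash salt + stripped date metadata make SVG output byte-stable
    plt.rcParams["svg.hashsalt"] = "epiaging"
    groups: dict[tuple[str, str], list[MetaResult]] = {}
    for r in results:
        groups.setdefault((r.factor, r.category), []).append(r)
    outcomes = sorted({r.outcome for r in results})
    cmap = plt.get_cmap("tab10")
    colors = {o: cmap(i % 10) for i, o in enumerate(outcomes)}
    n_rows = sum(len(v) for v in groups.values())
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.32 * n_rows + 1.2)))
    ytick, ylab = [], []
    y = 0
    for (factor, category), rs in sorted(groups.items()):
        ytick.append(y - (len(rs) - 1) / 2)
        ylab.append(f"{factor}: {category}")
        for r in sorted(rs, key=lambda r: r.outcome):
            lo, hi = r.ci95
            ax.errorbar(r.beta_pooled, y, xerr=[[r.beta_pooled - lo], [hi - r.beta_pooled]],
                        fmt="o", ms=4, color=colors[r.outcome], capsize=2,
                        label=r.outcome)
            y -= 1
        y -= 0.5
    ax.axvline(0.0, color="0.4", lw=0.8, ls="--")
    ax.set_yticks(ytick, ylab, fontsize=8)
    ax.set_xlabel("pooled effect (years)")
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), fontsize=7, loc="best")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
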