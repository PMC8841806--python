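"""Survival machinery for prognostic validation.

Cox proportional-hazards fitting is done by Newton-Raphson on the partial
likelihood (Efron tie correction by default, Breslow by option), with Wald
standard errors from the observed information. On top of it sit the
univariable screen, candidate intersection, greedy collinearity exclusion,
the prognostic index (linear predictor), median-split risk groups, the
product-limit (Kaplan-Meier) estimator, the two-group log-rank test, group
t-tests, and the 2x2 chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConvergenceError, ValidationError

__all__ = [
    "SurvivalData",
    "CoxFit",
    "RiskGroups",
    "KMCurve",
    "cox_fit",
    "univariable_screen",
    "intersect_candidates",
    "collinearity_filter",
    "prognostic_index",
    "median_split",
    "km_estimate",
    "logrank_test",
    "ttest_by_group",
    "chisq_2x2",
]

_Z95 = 1.959963984540054  # norm.ppf(0.975)


@dataclass
class SurvivalData:
    time: pd.Series
    event: pd.Series
    endpoint: str = "os"

    def __post_init__(self) -> None:
        self.time = pd.to_numeric(self.time)
        self.event = pd.to_numeric(self.event)
        if not self.time.index.equals(self.event.index):
            self.event = self.event.reindex(self.time.index)
        if self.event.isna().any() or self.time.isna().any():
            bad = self.time.index[self.time.isna() | self.event.isna()][0]
            raise ValidationError(f"missing survival data for sample {bad!r}")
        if (self.time <= 0).any():
            bad = self.time.index[(self.time <= 0).to_numpy()][0]
            raise ValidationError(f"non-positive time for sample {bad!r}")
        if not self.event.isin([0, 1]).all():
            bad = self.time.index[~self.event.isin([0, 1]).to_numpy()][0]
            raise ValidationError(f"event for sample {bad!r} is not 0/1")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.time.loc[idx], self.event.loc[idx], self.endpoint)


@dataclass
class CoxFit:
    covariates: list[str]
    coef: pd.Series
    se: pd.Series
    loglik: float
    n: int
    n_events: int
    ties: str

    @property
    def hr(self) -> pd.Series:
        return np.exp(self.coef)

    @property
    def ci_lower(self) -> pd.Series:
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_upper(self) -> pd.Series:
        return np.exp(self.coef + _Z95 * self.se)

    @property
    def p(self) -> pd.Series:
        z = self.coef / self.se
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.coef.index)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hr": self.hr,
            "ci_lower": self.ci_lower, "ci_upper": self.ci_upper, "p": self.p,
        })


@dataclass
class RiskGroups:
    labels: pd.Series       # "high" / "low"
    rule: str               # e.g. "pi_median" or "mbs_cutoff"
    threshold: float

    def sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


@dataclass
class KMCurve:
    times: np.ndarray       # observed event times (ascending)
    at_risk: np.ndarray     # risk-set sizes just before each event time
    survival: np.ndarray    # S(t) just after each event time
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


# ---------------------------------------------------------------------------
# Cox partial likelihood (Newton-Raphson)
# ---------------------------------------------------------------------------


def _cox_loglik(beta: np.ndarray, x: np.ndarray, time: np.ndarray,
                event: np.ndarray, ties: str):
    """Log partial likelihood, gradient and (negative) Hessian.

    Subjects are processed from the latest time backwards so the risk-set
    sums accumulate incrementally.
    """
    n, p = x.shape
    order = np.argsort(-time, kind="stable")
    xs, ts, ds = x[order], time[order], event[order]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))  # negative Hessian
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    eta = xs @ beta
    w = np.exp(eta)
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:
            s0 += w[j]
            s1 += w[j] * xs[j]
            s2 += w[j] * np.outer(xs[j], xs[j])
            j += 1
        dead = [k for k in range(i, j) if ds[k] == 1]
        d = len(dead)
        if d:
            xd = xs[dead]
            wd = w[dead]
            ll += float(eta[dead].sum())
            grad += xd.sum(axis=0)
            d0 = wd.sum()
            d1 = (wd[:, None] * xd).sum(axis=0)
            d2 = np.einsum("k,ki,kj->ij", wd, xd, xd)
            for ell in range(d):
                frac = ell / d if ties == "efron" else 0.0
                a0 = s0 - frac * d0
                a1 = s1 - frac * d1
                a2 = s2 - frac * d2
                ll -= np.log(a0)
                mu = a1 / a0
                grad -= mu
                info += a2 / a0 - np.outer(mu, mu)
        i = j
    return ll, grad, info


def cox_fit(covariates: pd.DataFrame, survival: SurvivalData, ties: str = "efron",
            max_iter: int = 100, tol: float = 1e-9) -> CoxFit:
    """Maximize the Cox partial likelihood over ``covariates``.

    Parameters
    ----------
    covariates
        Sample x covariate numeric matrix aligned (by index) to ``survival``.
    ties
        "efron" (default) or "breslow" tie handling.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties method {ties!r}")
    X = covariates.reindex(survival.time.index)
    if X.isna().any().any():
        bad = X.index[X.isna().any(axis=1)][0]
        raise ValidationError(f"missing covariate value for sample {bad!r}")
    if survival.n_events < 2:
        raise ValidationError(
            f"need >= 2 observed events, got {survival.n_events}"
        )
    for c in X.columns:
        if np.ptp(X[c].to_numpy(dtype=float)) == 0:
            raise ValidationError(f"constant covariate {c!r}")
    names = list(X.columns)
    # center for numerical stability; leaves the partial likelihood's argmax unchanged
    center = X.mean(axis=0)
    x = (X - center).to_numpy(dtype=float)
    time = survival.time.to_numpy(dtype=float)
    event = survival.event.to_numpy(dtype=int)
    beta = np.zeros(x.shape[1])
    ll, grad, info = _cox_loglik(beta, x, time, event, ties)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_loglik(new_beta, x, time, event, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_loglik(new_beta, x, time, event, ties)
            halvings += 1
        delta = np.max(np.abs(new_beta - beta))
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(last step {delta:.3e}, loglik {ll:.6f})"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(f"singular information at optimum: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        covariates=names,
        coef=pd.Series(beta, index=names, name="coef"),
        se=pd.Series(se, index=names, name="se"),
        loglik=float(ll),
        n=len(survival),
        n_events=survival.n_events,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# Screening / model building
# ---------------------------------------------------------------------------


@dataclass
class UnivariableScreen:
    table: pd.DataFrame                 # gene, coef, se, hr, ci, p; ascending p
    fits: dict[str, CoxFit]
    retained: list[str]                 # p < alpha, ascending p
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (gene, reason)
    alpha: float = 0.1


def univariable_screen(expr: pd.DataFrame, survival: SurvivalData,
                       alpha: float = 0.1, ties: str = "efron") -> UnivariableScreen:
    """Per-gene univariable Cox fits; keep Wald p < alpha, ordered by p."""
    rows, fits, skipped = [], {}, []
    samples = survival.time.index
    for g in expr.index:
        xg = expr.loc[g].reindex(samples)
        try:
            fit = cox_fit(xg.to_frame(name=g), survival, ties=ties)
        except (ValidationError, ConvergenceError) as exc:
            skipped.append((g, str(exc)))
            continue
        fits[g] = fit
        rows.append((g, float(fit.coef[g]), float(fit.se[g]), float(fit.hr[g]),
                     float(fit.ci_lower[g]), float(fit.ci_upper[g]), float(fit.p[g])))
    if not rows:
        first = skipped[0] if skipped else ("", "no genes")
        raise ValidationError(
            f"no gene could be fitted; first failure ({first[0]!r}): {first[1]}"
        )
    table = pd.DataFrame(rows, columns=["gene", "coef", "se", "hr",
                                        "ci_lower", "ci_upper", "p"])
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    retained = table.loc[table["p"] < alpha, "gene"].tolist()
    return UnivariableScreen(table=table, fits=fits, retained=retained,
                             skipped=skipped, alpha=alpha)


def intersect_candidates(dfs_candidates: Sequence[str],
                         os_candidates: Sequence[str]) -> list[str]:
    """Genes significant for both endpoints, ordered as in the first list."""
    os_set = set(os_candidates)
    return [g for g in dfs_candidates if g in os_set]


def collinearity_filter(expr: pd.DataFrame, candidates: Sequence[str],
                        r_cutoff: float = 0.8):
    """Greedy pass in the given (ascending-p) order; drop a gene when its
    |Pearson r| with any already-kept gene reaches the cutoff.

    Returns (kept, exclusions) where exclusions are dicts with the excluded
    gene, the kept partner it collided with, and their correlation.
    """
    missing = [g for g in candidates if g not in expr.index]
    if missing:
        raise ValidationError(f"candidate genes absent from matrix: {missing}")
    kept: list[str] = []
    exclusions: list[dict] = []
    for g in candidates:
        xg = expr.loc[g].to_numpy(dtype=float)
        hit = None
        for k in kept:
            r = np.corrcoef(xg, expr.loc[k].to_numpy(dtype=float))[0, 1]
            if abs(r) >= r_cutoff:
                hit = (k, float(r))
                break
        if hit is None:
            kept.append(g)
        else:
            exclusions.append({"gene": g, "partner": hit[0], "r": hit[1]})
    return kept, exclusions


def prognostic_index(fit: CoxFit, expr: pd.DataFrame) -> pd.Series:
    """Linear predictor sum_g beta_g * x_g per sample (no baseline term)."""
    missing = [g for g in fit.covariates if g not in expr.index]
    if missing:
        raise ValidationError(f"genes of the fitted model absent from matrix: {missing}")
    X = expr.loc[fit.covariates].to_numpy(dtype=float)
    pi = fit.coef.to_numpy() @ X
    return pd.Series(pi, index=expr.columns, name="prognostic_index")


def median_split(pi: pd.Series) -> RiskGroups:
    """High-risk iff PI >= cohort median (ties go high)."""
    if len(pi) < 2:
        raise ValidationError("median split needs at least 2 samples")
    med = float(np.median(pi.to_numpy(dtype=float)))
    labels = pd.Series(np.where(pi.to_numpy(dtype=float) >= med, "high", "low"),
                       index=pi.index, name="risk_group")
    return RiskGroups(labels=labels, rule="pi_median", threshold=med)


# ---------------------------------------------------------------------------
# Nonparametric comparisons
# ---------------------------------------------------------------------------


def km_estimate(survival: SurvivalData, groups: pd.Series | None = None
                ) -> dict[str, KMCurve]:
    """Product-limit survival curve per group (single group if none given)."""
    if groups is None:
        groups = pd.Series("all", index=survival.time.index)
    groups = groups.reindex(survival.time.index)
    out: dict[str, KMCurve] = {}
    for label in pd.unique(groups):
        idx = groups.index[groups == label]
        if len(idx) == 0:
            raise ValidationError(f"empty group {label!r}")
        t = survival.time.loc[idx].to_numpy(dtype=float)
        d = survival.event.loc[idx].to_numpy(dtype=int)
        ev_times = np.unique(t[d == 1])
        at_risk = np.array([(t >= et).sum() for et in ev_times], dtype=int)
        deaths = np.array([((t == et) & (d == 1)).sum() for et in ev_times], dtype=int)
        with np.errstate(divide="ignore"):
            surv = np.cumprod(1.0 - deaths / at_risk) if len(ev_times) else np.array([])
        out[str(label)] = KMCurve(times=ev_times, at_risk=at_risk,
                                  survival=surv, label=str(label))
    return out


def logrank_test(survival: SurvivalData, groups: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test (1 df) returning (chi-square, p)."""
    groups = groups.reindex(survival.time.index)
    labels = pd.unique(groups.dropna())
    if len(labels) != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    t = survival.time.to_numpy(dtype=float)
    d = survival.event.to_numpy(dtype=int)
    g1 = (groups == labels[0]).to_numpy()
    if d.sum() == 0:
        raise ValidationError("log-rank needs at least 1 event")
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[d == 1]):
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        deaths = ((t == et) & (d == 1))
        dd = deaths.sum()
        d1 = (deaths & g1).sum()
        o_minus_e += d1 - dd * n1 / n
        if n > 1:
            var += dd * (n1 / n) * (1 - n1 / n) * (n - dd) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def plot_km(curves: Mapping[str, KMCurve], path, title: str = "") -> None:
    """Export step-function KM curves to an image file (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        t = np.concatenate([[0.0], c.times])
        s = np.concatenate([[1.0], c.survival])
        ax.step(t, s, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def ttest_by_group(values: pd.Series, groups: pd.Series,
                   welch: bool = True) -> tuple[float, float]:
    """Two-sided independent two-sample t-test (Welch by default)."""
    groups = groups.reindex(values.index)
    labels = pd.unique(groups.dropna())
    if len(labels) != 2:
        raise ValidationError(f"t-test needs exactly 2 groups, got {len(labels)}")
    a = values[groups == labels[0]].to_numpy(dtype=float)
    b = values[groups == labels[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def chisq_2x2(table, yates: bool = True) -> tuple[float, float]:
    """Chi-square test on a 2x2 count table (Yates correction by default)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("2x2 table has a zero margin")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(stat), float(p)
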