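"""Window-level design assembly, the mixed-effects engagement model and the
post-hoc Wilcoxon procedure.

The model predicts windowed ISC from movement category (reference
``neither``), age group (reference ``adults``), their interaction and the
ALD covariate, with a subject-level random intercept, fit by REML.
Fixed-effect degrees of freedom use a Satterthwaite approximation by
default (configurable to residual df).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MOVEMENT_LEVELS = ("neither", "arm", "leg", "both")


# ---------------------------------------------------------------------------
# Design table


def build_design(isc_series, moves, ald, groups: dict[str, str],
                 group_reference: str = "adults") -> pd.DataFrame:
    """Long-format table with one row per subject x retained window.

    All three series must share the identical window grid; windows with a
    missing ALD value are dropped (logged).
    """
    g = isc_series.grid
    for other, name in ((moves.grid, "movement"), (ald.grid, "ald")):
        if not (np.array_equal(g.starts, other.starts)
                and g.window_len == other.window_len and g.hop == other.hop):
            raise ValueError(f"{name} series is not on the ISC window grid")
    rows = []
    for i, subj in enumerate(isc_series.subjects):
        grp = groups.get(subj)
        if grp is None:
            raise ValueError(f"no group assignment for subject {subj!r}")
        for j, t0 in enumerate(g.starts):
            rows.append({
                "subject": subj, "window_start": t0, "block": g.blocks[j],
                "isc": isc_series.windows[i, j],
                "group": grp, "movement": moves.categories[j],
                "ald": ald.per_window[j],
            })
    df = pd.DataFrame(rows)
    n_nan = int(df["ald"].isna().sum())
    if n_nan:
        logger.warning("dropping %d rows with missing ALD", n_nan)
        df = df.dropna(subset=["ald"]).reset_index(drop=True)
    if df["isc"].isna().any():
        raise ValueError("design table has missing ISC values")
    df.attrs["group_reference"] = group_reference
    return df


# ---------------------------------------------------------------------------
# Mixed model


@dataclass
class EngagementModelFit:
    """Fixed effects, random-intercept variance and fit metadata."""

    effects: pd.DataFrame       # effect, estimate, se, t, df, p
    random_intercept_var: float
    residual_var: float
    converged: bool
    df_method: str
    aliased: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"{'Effect':<20}{'Est.':>10}{'S.E.':>10}{'t':>10}"
                 f"{'d.f.':>14}{'p':>12}"]
        for _, r in self.effects.iterrows():
            p = "<0.0001" if r["p"] < 1e-4 else f"{r['p']:.4f}"
            lines.append(f"{r['effect']:<20}{r['estimate']:>10.4f}{r['se']:>10.4f}"
                         f"{r['t']:>10.3f}{r['df']:>14.3f}{p:>12}")
        lines.append(f"Random intercept variance: {self.random_intercept_var:.6g}")
        lines.append(f"Residual variance: {self.residual_var:.6g}")
        lines.append(f"Converged: {self.converged}  (df method: {self.df_method})")
        return "\n".join(lines)


class _RandomInterceptREML:
    """Closed-form REML machinery for a random-intercept-only LMM.

    Used for the Satterthwaite degrees-of-freedom approximation: with
    theta = (sigma2, tau2), f_j(theta) = [(X' V^-1 X)^-1]_jj and

        df_j = 2 f_j^2 / (grad f_j' A grad f_j)

    where A is the asymptotic covariance of theta from the REML Hessian.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, group_idx: np.ndarray):
        self.X, self.y = X, y
        self.groups = [np.flatnonzero(group_idx == g)
                       for g in np.unique(group_idx)]
        self.parts = []
        for idx in self.groups:
            Xi, yi = X[idx], y[idx]
            self.parts.append({
                "n": len(idx), "XtX": Xi.T @ Xi, "s": Xi.sum(axis=0),
                "Xty": Xi.T @ yi, "sy": yi.sum(), "yty": yi @ yi,
            })

    def _xtvix(self, s2: float, t2: float) -> np.ndarray:
        p = self.X.shape[1]
        out = np.zeros((p, p))
        for pt in self.parts:
            a = s2 + pt["n"] * t2
            c = t2 / (s2 * a)
            out += pt["XtX"] / s2 - c * np.outer(pt["s"], pt["s"])
        return out

    def _xtviy(self, s2: float, t2: float) -> np.ndarray:
        out = np.zeros(self.X.shape[1])
        for pt in self.parts:
            a = s2 + pt["n"] * t2
            c = t2 / (s2 * a)
            out += pt["Xty"] / s2 - c * pt["s"] * pt["sy"]
        return out

    def reml_loglike(self, s2: float, t2: float) -> float:
        XtViX = self._xtvix(s2, t2)
        XtViy = self._xtviy(s2, t2)
        beta = np.linalg.solve(XtViX, XtViy)
        ytViy = sum(pt["yty"] / s2 - (t2 / (s2 * (s2 + pt["n"] * t2)))
                    * pt["sy"] ** 2 for pt in self.parts)
        quad = ytViy - beta @ XtViy
        logdetV = sum((pt["n"] - 1) * np.log(s2) + np.log(s2 + pt["n"] * t2)
                      for pt in self.parts)
        sign, logdetX = np.linalg.slogdet(XtViX)
        return -0.5 * (logdetV + logdetX + quad)

    def fe_cov(self, s2: float, t2: float) -> np.ndarray:
        return np.linalg.inv(self._xtvix(s2, t2))

    def gls_beta(self, s2: float, t2: float) -> np.ndarray:
        return np.linalg.solve(self._xtvix(s2, t2), self._xtviy(s2, t2))

    def refine(self, s2: float, t2: float) -> tuple[float, float, bool]:
        """Maximize the REML log-likelihood from a starting point.

        Guards against upstream optimizers stopping short of the optimum;
        the problem is 2-dimensional so a derivative-free polish is cheap.
        """
        from scipy.optimize import minimize

        def nll(logtheta):
            return -self.reml_loglike(float(np.exp(logtheta[0])),
                                      float(np.exp(logtheta[1])))

        x0 = np.log([max(s2, 1e-12), max(t2, 1e-12)])
        opt = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 2000})
        s2r, t2r = np.exp(opt.x)
        return float(s2r), float(t2r), bool(opt.success)

    def satterthwaite_df(self, s2: float, t2: float,
                         contrasts: np.ndarray | None = None) -> np.ndarray:
        """Satterthwaite df at the REML estimate, one per contrast row
        (default: the unit contrasts, i.e. per coefficient).

        Finite differences run in log-variance space, which keeps the
        parameters positive near the tau^2 = 0 boundary; the df quantity
        2 f^2 / (g' A g) is invariant under this reparametrization.
        """
        C = (np.eye(self.X.shape[1]) if contrasts is None
             else np.atleast_2d(contrasts))
        lth = np.log([max(s2, 1e-12), max(t2, 1e-12)])
        h = 1e-4

        def f(l):
            return np.einsum("jc,cd,jd->j", C,
                             self.fe_cov(np.exp(l[0]), np.exp(l[1])), C)

        def ll(l):
            return self.reml_loglike(float(np.exp(l[0])), float(np.exp(l[1])))

        # gradient of each f_j w.r.t. log-theta (central differences)
        grads = np.zeros((C.shape[0], 2))
        for d in range(2):
            up, dn = lth.copy(), lth.copy()
            up[d] += h
            dn[d] -= h
            grads[:, d] = (f(up) - f(dn)) / (2 * h)
        # Hessian of the REML log-likelihood w.r.t. log-theta
        H = np.zeros((2, 2))
        ll0 = ll(lth)
        for a in range(2):
            up, dn = lth.copy(), lth.copy()
            up[a] += h
            dn[a] -= h
            H[a, a] = (ll(up) - 2 * ll0 + ll(dn)) / h**2
        pp = lth + np.array([h, h])
        pm = lth + np.array([h, -h])
        mp = lth + np.array([-h, h])
        mm = lth + np.array([-h, -h])
        H[0, 1] = H[1, 0] = (ll(pp) - ll(pm) - ll(mp) + ll(mm)) / (4 * h**2)
        try:
            A = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            A = np.linalg.pinv(-H)
        fvals = f(lth)
        dfs = np.empty(C.shape[0])
        n, p = self.X.shape
        resid_df = n - p
        for j in range(C.shape[0]):
            denom = grads[j] @ A @ grads[j]
            dfs[j] = 2 * fvals[j] ** 2 / denom if denom > 0 else resid_df
            if not np.isfinite(dfs[j]) or dfs[j] <= 0:
                dfs[j] = resid_df
        return dfs


_EFFECT_RENAMES = [
    ("Intercept", "(Intercept)"),
]


def _canonical_effect(name: str, group_levels: list[str],
                      group_reference: str) -> str:
    """Map patsy term names onto readable effect labels."""
    nonref = [g for g in group_levels if g != group_reference]
    out = name
    out = out.replace("Intercept", "(Intercept)")
    for g in nonref:
        out = out.replace(f"C(group, Treatment('{group_reference}'))[T.{g}]",
                          g.capitalize())
    for m in MOVEMENT_LEVELS:
        out = out.replace(f"C(movement, Treatment('neither'))[T.{m}]",
                          m.capitalize())
    out = out.replace(":", " x ").replace("ald", "ALD")
    return out


def fit_engagement_model(design: pd.DataFrame, df_method: str = "satterthwaite",
                         reml: bool = True) -> EngagementModelFit:
    """REML fit of ``isc ~ group * movement + ald`` with subject random
    intercepts; per-effect t, approximate df and p.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    import warnings

    if df_method not in ("satterthwaite", "residual"):
        raise ValueError("df_method must be 'satterthwaite' or 'residual'")
    for grp, sub in design.groupby("group"):
        if sub["subject"].nunique() < 2:
            raise ValueError(f"group {grp!r} has < 2 subjects")
    group_reference = design.attrs.get("group_reference", "adults")
    # Standardize the covariate internally: a linear reparametrization that
    # leaves the REML fit invariant but keeps the optimizer and the df
    # machinery well conditioned.  Coefficients are reported on the raw scale.
    work = design.copy()
    ald_mu = float(work["ald"].mean())
    ald_sd = float(work["ald"].std(ddof=0))
    if ald_sd == 0:
        raise ValueError("ALD covariate is constant; model is rank deficient")
    work["ald_std"] = (work["ald"] - ald_mu) / ald_sd
    formula = (f"isc ~ C(group, Treatment('{group_reference}'))"
               " * C(movement, Treatment('neither')) + ald_std")
    md = smf.mixedlm(formula, work, groups=work["subject"])
    X = md.exog
    aliased: list[str] = []
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report which columns are linearly dependent on the preceding ones
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, :j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                aliased.append(md.exog_names[j])
        raise ValueError(f"design matrix is rank deficient; aliased: {aliased}")
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = md.fit(reml=reml)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning("mixed model optimizer reported convergence issues")
    converged = converged and bool(res.converged)

    s2 = float(res.scale)
    t2 = float(np.asarray(res.cov_re)[0, 0])
    codes = pd.Categorical(work["subject"]).codes
    machinery = _RandomInterceptREML(X, md.endog, codes)
    # polish the variance components on the closed-form REML surface; the
    # generic optimizer stops short of the optimum on some designs
    s2, t2, refined_ok = machinery.refine(s2, t2)
    converged = converged or refined_ok
    # contrast matrix mapping standardized-covariate coefficients back to
    # the raw ALD scale: beta_raw = T beta_std
    p = X.shape[1]
    names = list(md.exog_names)
    T = np.eye(p)
    j_ald = names.index("ald_std")
    j_int = names.index("Intercept")
    T[j_ald, j_ald] = 1.0 / ald_sd
    T[j_int, j_ald] = -ald_mu / ald_sd
    beta = T @ machinery.gls_beta(s2, t2)
    cov = T @ machinery.fe_cov(s2, t2) @ T.T
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    if df_method == "satterthwaite":
        dfs = machinery.satterthwaite_df(s2, t2, contrasts=T)
    else:
        dfs = np.full(len(beta), float(len(work) - p))
    pvals = 2 * stats.t.sf(np.abs(tvals), dfs)

    group_levels = sorted(design["group"].unique())
    effects = pd.DataFrame({
        "effect": [_canonical_effect(n.replace("ald_std", "ald"), group_levels,
                                     group_reference) for n in names],
        "estimate": beta, "se": se, "t": tvals, "df": dfs, "p": pvals,
    })
    return EngagementModelFit(
        effects=effects, random_intercept_var=t2, residual_var=s2,
        converged=converged, df_method=df_method, aliased=aliased,
    )


# ---------------------------------------------------------------------------
# Post-hoc Wilcoxon procedure


def signed_rank_exact_p(diffs: np.ndarray) -> tuple[float, float]:
    """Independent exact signed-rank oracle by full sign enumeration.

    Only for small n; returns (W+, two-sided p).  Zero differences are
    dropped (Wilcoxon zero handling); average ranks for ties.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = ranks.sum()
    stat_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if min(w, total - w) <= stat_obs + 1e-12:
            count += 1
    return w_plus, min(1.0, count / 2 ** n)


def wilcoxon_signed_rank(diffs: np.ndarray, exact_max_n: int = 25
                         ) -> tuple[float, float, str]:
    """Paired signed-rank test: exact null for n <= ``exact_max_n`` (when
    scipy supports it for the data), normal approximation with continuity
    correction above.  Returns (statistic, p, method used).
    """
    d = np.asarray(diffs, dtype=float)
    nz = d[d != 0]
    if len(nz) == 0:
        return 0.0, 1.0, "degenerate"
    if len(nz) <= exact_max_n:
        try:
            r = stats.wilcoxon(d, zero_method="wilcox", method="exact")
            return float(r.statistic), float(r.pvalue), "exact"
        except (ValueError, AttributeError):
            pass
    r = stats.wilcoxon(d, zero_method="wilcox", method="approx", correction=True)
    return float(r.statistic), float(r.pvalue), "approx"


def posthoc_wilcoxon(design: pd.DataFrame, family: str = "per_panel",
                     ald_cutoff: float | None = None) -> pd.DataFrame:
    """Fig.-2-style post-hoc table.

    Per subject, windows are averaged within each (movement, ALD-level)
    cell, ALD binarized at the sample median (over unique windows) unless
    ``ald_cutoff`` is given.  Within each (group, ald_level) panel, all
    pairwise movement comparisons are tested with the paired signed-rank
    test and Bonferroni-corrected; each cell also gets a Shapiro-Wilk
    normality check.
    """
    if family not in ("per_panel", "all"):
        raise ValueError("family must be 'per_panel' or 'all'")
    df = design.copy()
    if ald_cutoff is None:
        per_window = df.drop_duplicates(subset=["block", "window_start"])
        ald_cutoff = float(per_window["ald"].median())
    df["ald_level"] = np.where(df["ald"] <= ald_cutoff, "low", "high")
    cell_means = (df.groupby(["group", "ald_level", "movement", "subject"],
                             observed=True)["isc"].mean().reset_index())

    rows = []
    for (grp, lev), panel in cell_means.groupby(["group", "ald_level"],
                                                observed=True):
        wide = panel.pivot(index="subject", columns="movement", values="isc")
        levels = [m for m in MOVEMENT_LEVELS if m in wide.columns]
        for m1, m2 in itertools.combinations(levels, 2):
            paired = wide[[m1, m2]].dropna()
            n = len(paired)
            if n == 0:
                continue
            diffs = (paired[m1] - paired[m2]).to_numpy()
            stat, p, method = wilcoxon_signed_rank(diffs)
            sw_p = {}
            for m in (m1, m2):
                vals = wide[m].dropna()
                sw_p[m] = (float(stats.shapiro(vals).pvalue)
                           if len(vals) >= 3 and np.ptp(vals) > 0 else np.nan)
            rows.append({
                "group": grp, "ald_level": lev, "cond_a": m1, "cond_b": m2,
                "mean_a": float(paired[m1].mean()),
                "mean_b": float(paired[m2].mean()),
                "n_subjects": n, "statistic": stat, "p_raw": p,
                "method": method, "underpowered": n < 6,
                "shapiro_p_a": sw_p[m1], "shapiro_p_b": sw_p[m2],
                "ald_cutoff": ald_cutoff,
            })
            if n < 6:
                logger.warning("comparison %s vs %s in (%s, %s ALD) has only "
                               "%d paired subjects", m1, m2, grp, lev, n)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    if family == "per_panel":
        m_sizes = out.groupby(["group", "ald_level"], observed=True)["p_raw"] \
                     .transform("size")
    else:
        m_sizes = pd.Series(len(out), index=out.index)
    out["m_comparisons"] = m_sizes.astype(int)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * out["m_comparisons"])
    return out


def condition_means_table(design: pd.DataFrame,
                          ald_cutoff: float | None = None) -> pd.DataFrame:
    """Fig.-2-style per-condition means (across per-subject means)."""
    df = design.copy()
    if ald_cutoff is None:
        per_window = df.drop_duplicates(subset=["block", "window_start"])
        ald_cutoff = float(per_window["ald"].median())
    df["ald_level"] = np.where(df["ald"] <= ald_cutoff, "low", "high")
    per_subj = (df.groupby(["group", "ald_level", "movement", "subject"],
                           observed=True)["isc"].mean().reset_index())
    return (per_subj.groupby(["group", "ald_level", "movement"], observed=True)
            ["isc"].agg(["mean", "std", "count"]).reset_index())
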