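"""Statistical decision protocol for the grasp-and-lift analysis.

The centrepiece is a balanced split-plot ANOVA -- one between-subject
factor (stimulation location group) crossed with three within-subject
factors (stimulation condition x previous weight x current weight) -- with
Mauchly's sphericity test and Greenhouse-Geisser correction, Bonferroni
post hocs, and the location-split rule: whenever the between factor is
involved in a significant effect, the analysis is re-run per group as a
repeated-measures ANOVA.

Relation analyses regress perceptual (difference) scores on force-rate
covariates with fixed factors and their interactions, a first-order
autoregressive within-participant residual structure, and maximum
likelihood estimation.  Between-subject Pearson correlations get 95%
confidence intervals through the Fisher z-transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

ALPHA = 0.05

WITHIN_FACTORS = ("condition", "previous", "current")
WITHIN_LEVELS = {
    "condition": ("dynamic", "static", "none"),
    "previous": ("light", "heavy"),
    "current": ("light", "heavy"),
}
_PAIR_PREV = {"LL": "light", "HL": "heavy", "LH": "light", "HH": "heavy"}
_PAIR_CURR = {"LL": "light", "HL": "light", "LH": "heavy", "HH": "heavy"}


@dataclass
class AnovaResult:
    """Split-plot / repeated-measures ANOVA table."""

    dv: str
    effects: list[dict] = field(default_factory=list)
    n_subjects: int = 0
    groups: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects)

    def effect(self, name: str) -> dict:
        for e in self.effects:
            if e["effect"] == name:
                return e
        raise KeyError(name)


@dataclass
class LmmResult:
    """Fixed-effect tests from the AR(1) maximum-likelihood regression."""

    label: str
    terms: pd.DataFrame
    coefficients: pd.Series
    covariate: str
    covariate_coef: float | None
    rho: float
    loglik: float
    converged: bool
    covariate_omitted: bool = False


@dataclass
class CorrResult:
    """Pearson correlation with a Fisher-z 95% confidence interval."""

    r: float
    ci95: tuple[float, float]
    p: float
    n: int


# ---------------------------------------------------------------------------
# mixed / repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _center(arr: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    for ax in axes:
        arr = arr - arr.mean(axis=ax, keepdims=True)
    return arr


def _cells_to_array(cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list]:
    """Pivot tidy cell means to Y[subject, condition, previous, current]."""
    df = cells.copy()
    if "previous" not in df or "current" not in df:
        df["previous"] = df["order_pair"].map(_PAIR_PREV)
        df["current"] = df["order_pair"].map(_PAIR_CURR)
    if df[["previous", "current"]].isna().any().any():
        raise ValueError("cells contain undefined order pairs")

    subjects = sorted(df["participant"].unique())
    group_of = df.drop_duplicates("participant").set_index("participant")["group"]
    shape = tuple(len(WITHIN_LEVELS[f]) for f in WITHIN_FACTORS)
    y = np.full((len(subjects),) + shape, np.nan)
    s_index = {s: i for i, s in enumerate(subjects)}
    si = df["participant"].map(s_index).to_numpy()
    ci = df["tms_condition"].map(
        {lev: i for i, lev in enumerate(WITHIN_LEVELS["condition"])}
    ).to_numpy()
    pi = df["previous"].map(
        {lev: i for i, lev in enumerate(WITHIN_LEVELS["previous"])}
    ).to_numpy()
    cu = df["current"].map(
        {lev: i for i, lev in enumerate(WITHIN_LEVELS["current"])}
    ).to_numpy()
    y[si, ci, pi, cu] = df["value"].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("incomplete design: every participant needs all "
                         "12 condition x previous x current cells")
    groups = np.asarray([group_of[s] for s in subjects])
    return y, groups, subjects


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast rows (orthogonal to the unit vector)."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):  # Helmert
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1)
    q, _ = np.linalg.qr(h.T)
    return q.T


def _sphericity(
    scores: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float]:
    """Mauchly p-value and Greenhouse-Geisser epsilon for contrast scores.

    ``scores`` is (subjects x m); the covariance pools within-group
    deviations.  Returns (mauchly_w, mauchly_p, epsilon).
    """
    n, m = scores.shape
    labels = np.unique(groups)
    centered = scores.astype(float).copy()
    for g in labels:
        sel = groups == g
        centered[sel] -= centered[sel].mean(axis=0)
    n_e = n - len(labels)
    if n_e < 1:
        return np.nan, np.nan, 1.0
    cov = centered.T @ centered / n_e
    tr = np.trace(cov)
    if tr <= 0 or not np.isfinite(tr):
        return np.nan, np.nan, 1.0
    eigs = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
    eps = float(tr**2 / (m * np.sum(eigs**2)))
    eps = min(1.0, max(eps, 1.0 / m))

    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return 0.0, 0.0, eps  # singular covariance: certainly non-spherical
    log_w = logdet - m * np.log(tr / m)
    d = 1.0 - (2.0 * m**2 + m + 2.0) / (6.0 * m * n_e)
    chi2 = -n_e * d * log_w
    dof = m * (m + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, dof))
    return float(np.exp(log_w)), p, eps


def _within_subsets() -> list[tuple[str, ...]]:
    names = WITHIN_FACTORS
    subsets: list[tuple[str, ...]] = []
    for mask in range(1, 2 ** len(names)):
        subsets.append(tuple(n for i, n in enumerate(names) if mask >> i & 1))
    subsets.sort(key=len)
    return subsets


def mixed_anova(
    cells: pd.DataFrame, dv: str | None = None, alpha: float = ALPHA
) -> AnovaResult:
    """Split-plot ANOVA on participant cell means.

    With two groups this is the mixed 2 (location, between) x 3 (condition)
    x 2 (previous weight) x 2 (current weight) analysis; with a single
    group it reduces to the 3 x 2 x 2 repeated-measures ANOVA used after a
    location split.  Within effects whose numerator df exceeds 1 are tested
    for sphericity (Mauchly); on violation (p < alpha) Greenhouse-Geisser
    adjusted degrees of freedom are used.
    """
    df = cells
    if dv is not None and "dv" in df.columns:
        df = df[df["dv"] == dv]
    elif "dv" in df.columns:
        uniq = df["dv"].unique()
        if len(uniq) > 1:
            raise ValueError("multiple dvs present; pass dv=...")
        dv = uniq[0]
    y, groups, _ = _cells_to_array(df)
    n_subj = y.shape[0]
    labels = [str(g) for g in dict.fromkeys(groups)]
    n_groups = len(labels)
    group_sizes = np.asarray([(groups == g).sum() for g in labels], float)
    m_cells = int(np.prod(y.shape[1:]))
    axis_of = {f: i + 1 for i, f in enumerate(WITHIN_FACTORS)}
    levels = {f: y.shape[axis_of[f]] for f in WITHIN_FACTORS}

    effects: list[dict] = []

    def add_effect(name, ss, df1, ss_err, df2, gg=None):
        if df1 <= 0 or df2 <= 0:
            raise ValueError(f"non-positive degrees of freedom for {name}")
        ms, ms_err = ss / df1, ss_err / df2
        f_val = ms / ms_err if ms_err > 0 else np.inf
        eps_applied = gg is not None and gg["applied"]
        d1 = df1 * gg["epsilon"] if eps_applied else df1
        d2 = df2 * gg["epsilon"] if eps_applied else df2
        p = float(stats.f.sf(f_val, d1, d2)) if np.isfinite(f_val) else 0.0
        effects.append(
            {
                "effect": name,
                "F": float(f_val),
                "df_num": float(d1),
                "df_den": float(d2),
                "p": p,
                "partial_eta_sq": float(ss / (ss + ss_err)) if ss + ss_err > 0 else 0.0,
                "gg_applied": bool(eps_applied),
                "epsilon": float(gg["epsilon"]) if gg is not None else 1.0,
                "mauchly_p": float(gg["mauchly_p"]) if gg is not None else np.nan,
            }
        )

    # between-subject stratum
    subj_means = y.mean(axis=(1, 2, 3))
    grand = subj_means.mean()
    gmeans = np.asarray([subj_means[groups == g].mean() for g in labels])
    ss_sub_g = 0.0
    for g, gm in zip(labels, gmeans):
        ss_sub_g += m_cells * np.sum((subj_means[groups == g] - gm) ** 2)
    df_sub_g = n_subj - n_groups
    if n_groups > 1:
        ss_g = m_cells * np.sum(group_sizes * (gmeans - grand) ** 2)
        add_effect("location", ss_g, n_groups - 1, ss_sub_g, df_sub_g)

    # within strata: each subset of within factors shares an error term
    for subset in _within_subsets():
        w_axes = tuple(axis_of[f] for f in subset)
        rest_axes = tuple(a for a in (1, 2, 3) if a not in w_axes)
        mult_rest = int(np.prod([y.shape[a] for a in rest_axes])) if rest_axes else 1
        m_sw = y.mean(axis=rest_axes) if rest_axes else y  # (S, *levels_W)
        local = tuple(range(1, len(subset) + 1))

        c_sw = _center(m_sw, local)
        grand_w = c_sw.mean(axis=0)
        ss_w = n_subj * mult_rest * np.sum(grand_w**2)
        df_w = int(np.prod([levels[f] - 1 for f in subset]))

        c_gw = np.stack([c_sw[groups == g].mean(axis=0) for g in labels])
        err = c_sw - c_gw[[labels.index(str(g)) for g in groups]]
        ss_err = mult_rest * np.sum(err**2)
        df_err = df_sub_g * df_w

        gg = {"epsilon": 1.0, "mauchly_p": np.nan, "applied": False}
        if df_w >= 2:
            k_mat = _orthonormal_contrasts(levels[subset[0]])
            for f in subset[1:]:
                k_mat = np.kron(k_mat, _orthonormal_contrasts(levels[f]))
            scores = m_sw.reshape(n_subj, -1) @ k_mat.T * np.sqrt(mult_rest)
            _, m_p, eps = _sphericity(scores, groups)
            gg = {
                "epsilon": eps,
                "mauchly_p": m_p,
                "applied": bool(np.isfinite(m_p) and m_p < alpha),
            }

        add_effect(":".join(subset), ss_w, df_w, ss_err, df_err, gg)
        if n_groups > 1:
            diff_g = c_gw - grand_w
            ss_gw = mult_rest * np.sum(
                group_sizes[:, None] * diff_g.reshape(n_groups, -1) ** 2
            )
            add_effect(
                "location:" + ":".join(subset), ss_gw,
                (n_groups - 1) * df_w, ss_err, df_err, gg,
            )

    return AnovaResult(
        dv=dv or "value", effects=effects, n_subjects=n_subj,
        groups=tuple(labels),
    )


def split_anova_protocol(
    full: AnovaResult, cells: pd.DataFrame, dv: str | None = None,
    alpha: float = ALPHA,
) -> list[AnovaResult]:
    """Per-group repeated-measures ANOVAs when location is implicated.

    Returns one 3 x 2 x 2 repeated-measures result per group iff any main
    effect or interaction involving the location factor reached p < alpha
    in the full mixed analysis; otherwise an empty list.
    """
    triggered = any(
        "location" in e["effect"] and e["p"] < alpha for e in full.effects
    )
    if not triggered:
        return []
    df = cells if dv is None else cells[cells["dv"] == dv]
    out = []
    for g in dict.fromkeys(df["group"]):
        sub = df[df["group"] == g]
        res = mixed_anova(sub, dv=None if "dv" not in sub else sub["dv"].iloc[0])
        res.dv = f"{res.dv}[{g}]"
        out.append(res)
    return out


def posthoc_bonferroni(
    cells: pd.DataFrame, factor: str, dv: str | None = None
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise contrasts for one factor.

    Within factors use paired t-tests on participant means; the location
    factor uses an independent t-test between groups.  Raw p-values are
    multiplied by the family size (all pairwise contrasts) and capped at 1.
    """
    df = cells if dv is None else cells[cells["dv"] == dv]
    df = df.copy()
    if "previous" not in df or "current" not in df:
        df["previous"] = df["order_pair"].map(_PAIR_PREV)
        df["current"] = df["order_pair"].map(_PAIR_CURR)
    col = {"condition": "tms_condition", "previous": "previous",
           "current": "current", "location": "group"}[factor]

    if factor == "location":
        lvls = list(dict.fromkeys(df[col]))
        means = df.groupby(["participant", col], observed=True)["value"].mean()
        a = means.xs(lvls[0], level=col)
        b = means.xs(lvls[1], level=col)
        t, p = stats.ttest_ind(a, b)
        rows = [{
            "contrast": f"{lvls[0]} vs {lvls[1]}",
            "mean_diff": float(a.mean() - b.mean()),
            "t": float(t), "p_raw": float(p), "p_bonferroni": min(1.0, float(p)),
        }]
        return pd.DataFrame(rows)

    means = (
        df.groupby(["participant", col], observed=True)["value"].mean().unstack(col)
    )
    lvls = [l for l in WITHIN_LEVELS.get(factor, means.columns) if l in means]
    contrasts = [(a, b) for i, a in enumerate(lvls) for b in lvls[i + 1:]]
    rows = []
    for a, b in contrasts:
        t, p = stats.ttest_rel(means[a], means[b])
        if not np.isfinite(p):  # identical vectors: no evidence against H0
            t, p = np.nan, 1.0
        rows.append(
            {
                "contrast": f"{a} vs {b}",
                "mean_diff": float(means[a].mean() - means[b].mean()),
                "t": float(t),
                "p_raw": float(p),
                "p_bonferroni": min(1.0, float(p) * len(contrasts)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# AR(1) maximum-likelihood regression
# ---------------------------------------------------------------------------


def _ar1_transform(
    y: np.ndarray, x: np.ndarray, starts: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Prais-Winsten whitening for participant blocks starting at `starts`."""
    yt = y.copy()
    xt = x.copy()
    yt[1:] = y[1:] - rho * y[:-1]
    xt[1:] = x[1:] - rho * x[:-1]
    scale = np.sqrt(1.0 - rho**2)
    yt[starts] = y[starts] * scale
    xt[starts] = x[starts] * scale
    return yt, xt


def lmm_relation(
    records: pd.DataFrame,
    covariate: str,
    dv: str = "percept",
    label: str = "relation",
    order_col: str | None = None,
    factors: tuple[str, ...] = ("current", "tms_condition", "location"),
) -> LmmResult:
    """Fixed-effects regression with AR(1) within-participant residuals.

    The model contains the categorical fixed factors, the force covariate,
    all their interactions and an intercept.  The AR(1) correlation and the
    residual variance are estimated by profile maximum likelihood;
    fixed-effect terms are tested with Wald F statistics.  A covariate with
    (near-)zero variance is dropped from the model and flagged.
    """
    df = records.copy()
    sort_cols = ["participant"] + ([order_col] if order_col else [])
    df = df.sort_values(sort_cols, kind="stable").reset_index(drop=True)

    omitted = False
    use_factors = [f for f in factors if df[f].nunique() > 1]
    rhs_parts = [f"C({f})" for f in use_factors]
    if np.std(df[covariate].to_numpy(float)) < 1e-12:
        omitted = True
    else:
        rhs_parts.append(covariate)
    rhs = " * ".join(rhs_parts) if rhs_parts else "1"
    y_mat, x_mat = patsy.dmatrices(f"{dv} ~ {rhs}", df, return_type="dataframe")
    y = y_mat.to_numpy(float).ravel()
    x = x_mat.to_numpy(float)
    n, p = x.shape
    if n <= p:
        raise ValueError(
            f"too few records ({n}) for the {p}-column fixed-effects design"
        )

    part = df["participant"].to_numpy()
    starts = np.flatnonzero(np.r_[True, part[1:] != part[:-1]])
    n_blocks = len(starts)

    def negloglik(rho: float) -> float:
        yt, xt = _ar1_transform(y, x, starts, rho)
        beta, rss, rank, _ = np.linalg.lstsq(xt, yt, rcond=None)
        resid = yt - xt @ beta
        rss = float(resid @ resid)
        if rss <= 0:
            rss = 1e-300
        ll = (
            -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
            + 0.5 * n_blocks * np.log(1.0 - rho**2)
        )
        return -ll

    opt = optimize.minimize_scalar(
        negloglik, bounds=(-0.95, 0.95), method="bounded",
        options={"xatol": 1e-5},
    )
    rho = float(opt.x)
    yt, xt = _ar1_transform(y, x, starts, rho)
    beta, _, rank, _ = np.linalg.lstsq(xt, yt, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"singular fixed-effects design ({rank} < {p} columns)"
        )
    resid = yt - xt @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.inv(xt.T @ xt)
    vcov = sigma2 * xtx_inv

    rows = []
    info = x_mat.design_info
    for term, sl in info.term_name_slices.items():
        if term == "Intercept":
            continue
        b = beta[sl]
        v = vcov[sl, sl]
        q = len(b)
        try:
            f_val = float(b @ np.linalg.solve(v, b)) / q
        except np.linalg.LinAlgError:
            f_val = np.nan
        p_val = float(stats.f.sf(f_val, q, df_resid)) if np.isfinite(f_val) else np.nan
        rows.append({"term": term, "F": f_val, "df_num": q,
                     "df_den": df_resid, "p": p_val})

    coefs = pd.Series(beta, index=list(info.column_names))
    cov_coef = float(coefs[covariate]) if (not omitted and covariate in coefs) else None
    return LmmResult(
        label=label,
        terms=pd.DataFrame(rows),
        coefficients=coefs,
        covariate=covariate,
        covariate_coef=cov_coef,
        rho=rho,
        loglik=-float(opt.fun),
        converged=bool(opt.success),
        covariate_omitted=omitted,
    )


def pearson_ci(x, y, alpha: float = ALPHA) -> CorrResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    n = len(x)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrResult(r=float(r), ci95=(float(lo), float(hi)), p=float(p), n=n)
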