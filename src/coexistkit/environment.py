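"""Environmental interpretation: PCA, RDA with forward selection, curve fits.

* ``pca_rank`` — principal component analysis of standardized environment
  variables (correlation matrix), used to rank soil indicators.
* ``rda_forward_select`` — redundancy analysis (multivariate regression of
  a community matrix on predictors) with greedy forward selection; each
  candidate's conditional contribution is judged by a pseudo-F statistic
  with an unrestricted row-permutation null (Monte-Carlo test).
* ``fit_curve_families`` — least-squares fits of the eleven standard
  bivariate regression families (linear through logistic), with exact
  log-linearization where available.
* ``screen_outliers`` — 1.5 IQR residual rule with the replace-or-eliminate
  cleanup used before curve fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "OrdinationResult",
    "RDASelection",
    "CurveFit",
    "pca_rank",
    "rda_forward_select",
    "fit_curve_families",
    "screen_outliers",
    "CURVE_FAMILIES",
]


@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    cumulative_proportion: np.ndarray
    site_scores: pd.DataFrame       # plots x components (weighted sums)
    variable_scores: pd.DataFrame   # variables x components (loadings * sqrt(ev))


def pca_rank(env: pd.DataFrame, variables: list[str] | None = None) -> OrdinationResult:
    """Correlation-matrix PCA of the chosen environment columns.

    Variables are standardized to zero mean and unit variance (sample sd),
    so the eigenvalues sum to the number of variables.  Variable scores are
    eigenvectors scaled by the square root of their eigenvalue; site scores
    are the weighted sums of the standardized data.
    """
    if variables is not None:
        env = env[list(variables)]
    if env.shape[1] < 2 or env.shape[0] < 3:
        raise ValueError("PCA needs at least 2 variables and 3 plots")
    if env.isna().any().any():
        raise ValueError("missing values in environment table")
    sd = env.std(ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(f"constant variable(s): {list(constant.index)}")
    z = (env - env.mean()) / sd
    corr = np.corrcoef(env.values, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    evecs = evecs[:, order]
    # Deterministic sign: make the largest-|loading| entry positive.
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] *= -1
    prop = evals / evals.sum()
    comps = [f"PC{i + 1}" for i in range(len(evals))]
    site = pd.DataFrame(z.values @ evecs, index=env.index, columns=comps)
    var = pd.DataFrame(evecs * np.sqrt(evals), index=env.columns, columns=comps)
    return OrdinationResult(evals, prop, np.cumsum(prop), site, var)


# ---------------------------------------------------------------------------
# Redundancy analysis with forward selection


@dataclass
class RDASelection:
    selected: list[str]
    steps: pd.DataFrame          # factor, added_explained, pseudo_f, p_value
    total_explained: float
    all_candidates: pd.DataFrame = field(default=None)
    species_scores: pd.DataFrame = field(default=None)


def _rda_ss(y: np.ndarray, x: np.ndarray) -> float:
    """Explained sum of squares of Y regressed on X (with intercept)."""
    x1 = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(x1, y, rcond=None)
    fitted = x1 @ coef
    return float((fitted ** 2).sum() - len(y) * (y.mean(axis=0) ** 2).sum())


def _partial_f(y: np.ndarray, x_sel: np.ndarray | None, x_new: np.ndarray) -> float:
    """Pseudo-F of adding one predictor to the current RDA model."""
    n = len(y)
    ss_tot = float(((y - y.mean(axis=0)) ** 2).sum())
    ss_red = 0.0 if x_sel is None else _rda_ss(y, x_sel)
    x_full = x_new.reshape(-1, 1) if x_sel is None else np.column_stack([x_sel, x_new])
    ss_full = _rda_ss(y, x_full)
    p_full = x_full.shape[1]
    rss = ss_tot - ss_full
    gain = ss_full - ss_red
    tol = 1e-10 * max(ss_tot, 1.0)
    if rss <= tol:
        return np.inf if gain > tol else 0.0
    return (gain / 1.0) / (rss / (n - p_full - 1))


def rda_forward_select(species_iv: pd.DataFrame, env: pd.DataFrame,
                       n_perm: int = 499, alpha: float = 0.05,
                       seed: int = 0) -> RDASelection:
    """Greedy forward selection of environmental factors for RDA.

    ``species_iv`` is species x plot (relative importance values);
    ``env`` is plot x factor, already numerically coded.  The response is
    centered by species and the predictors standardized.  At each step the
    conditional pseudo-F of every unselected factor is tested with an
    unrestricted row permutation of the response (p = (1 + #{F_perm >=
    F_obs}) / (1 + n_perm)); the factor with the smallest p (ties: larger
    F) is added while p <= alpha.
    """
    plots = list(species_iv.columns)
    if list(env.index) != plots:
        env = env.loc[plots]
    y = species_iv.values.T.astype(float)
    y = y - y.mean(axis=0)
    sd = env.std(ddof=1)
    zero_var = sd[sd == 0]
    if len(zero_var):
        raise ValueError(f"constant factor(s): {list(zero_var.index)}")
    x_all = ((env - env.mean()) / sd).values
    factors = list(env.columns)
    rng = np.random.default_rng(seed)
    n = len(plots)
    ss_tot = float(((y - y.mean(axis=0)) ** 2).sum())

    selected: list[int] = []
    steps = []
    while len(selected) < min(len(factors), n - 2):
        x_sel = x_all[:, selected] if selected else None
        best = None
        for j in range(len(factors)):
            if j in selected:
                continue
            f_obs = _partial_f(y, x_sel, x_all[:, j])
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                if _partial_f(y[perm], x_sel, x_all[:, j]) >= f_obs:
                    exceed += 1
            p = (1 + exceed) / (1 + n_perm)
            cand = (p, -f_obs, j)
            if best is None or cand < best:
                best = cand
        p, neg_f, j = best
        if p > alpha:
            break
        x_new = x_all[:, selected + [j]]
        gain = (_rda_ss(y, x_new) - (_rda_ss(y, x_all[:, selected]) if selected else 0.0)) / ss_tot
        selected.append(j)
        steps.append({"factor": factors[j], "added_explained": gain,
                      "pseudo_f": -neg_f, "p_value": p})
    total = (_rda_ss(y, x_all[:, selected]) / ss_tot) if selected else 0.0
    # Species scores: correlations of each species' IV with the fitted axes
    # (here simply with each selected, standardized factor).
    sp_scores = None
    if selected:
        sel_names = [factors[j] for j in selected]
        sp = np.zeros((species_iv.shape[0], len(selected)))
        for a, j in enumerate(selected):
            xj = x_all[:, j]
            for s in range(species_iv.shape[0]):
                ys = y[:, s]
                sp[s, a] = 0.0 if ys.std() == 0 else np.corrcoef(ys, xj)[0, 1]
        sp_scores = pd.DataFrame(sp, index=species_iv.index, columns=sel_names)
    return RDASelection(
        selected=[factors[j] for j in selected],
        steps=pd.DataFrame(steps),
        total_explained=float(total),
        species_scores=sp_scores,
    )


# ---------------------------------------------------------------------------
# Curve-family regression


@dataclass
class CurveFit:
    family: str
    params: dict
    r2: float
    p_value: float
    n: int
    skipped: str | None = None  # reason, when the family was not applicable

    def predict(self, x: np.ndarray) -> np.ndarray:
        return _FAMILY_PREDICT[self.family](np.asarray(x, float), self.params)


def _poly_fit(x, y, deg):
    coef = np.polyfit(x, y, deg)
    fitted = np.polyval(coef, x)
    names = "abcd"
    params = {names[i]: float(c) for i, c in enumerate(coef[::-1])}
    return params, fitted, y, deg


def _linearized_fit(tx, ty, back_params):
    """Least squares on transformed data; R^2/p on the transformed scale."""
    coef = np.polyfit(tx, ty, 1)
    fitted = np.polyval(coef, tx)
    return back_params(coef[1], coef[0]), fitted, ty, 1


def _fit_family(name, x, y):
    n = len(x)
    pos_x, pos_y = (x > 0).all(), (y > 0).all()
    nonzero_x = (x != 0).all()
    if name == "linear":
        return _poly_fit(x, y, 1)
    if name == "quadratic":
        return _poly_fit(x, y, 2)
    if name == "cubic":
        return _poly_fit(x, y, 3)
    if name == "compound":  # y = a b^x
        if not pos_y:
            raise _Skip("requires y > 0")
        return _linearized_fit(x, np.log(y),
                               lambda i, s: {"a": float(np.exp(i)), "b": float(np.exp(s))})
    if name == "power":  # y = a x^b
        if not (pos_x and pos_y):
            raise _Skip("requires x > 0 and y > 0")
        return _linearized_fit(np.log(x), np.log(y),
                               lambda i, s: {"a": float(np.exp(i)), "b": float(s)})
    if name == "s_curve":  # y = e^(a + b/x)
        if not (nonzero_x and pos_y):
            raise _Skip("requires x != 0 and y > 0")
        return _linearized_fit(1.0 / x, np.log(y),
                               lambda i, s: {"a": float(i), "b": float(s)})
    if name == "growth":  # y = e^(a + b x)
        if not pos_y:
            raise _Skip("requires y > 0")
        return _linearized_fit(x, np.log(y),
                               lambda i, s: {"a": float(i), "b": float(s)})
    if name == "exponential":  # y = a e^(b x)
        if not pos_y:
            raise _Skip("requires y > 0")
        return _linearized_fit(x, np.log(y),
                               lambda i, s: {"a": float(np.exp(i)), "b": float(s)})
    if name == "logarithmic":  # y = a + b ln x
        if not pos_x:
            raise _Skip("requires x > 0")
        coef = np.polyfit(np.log(x), y, 1)
        fitted = np.polyval(coef, np.log(x))
        return {"a": float(coef[1]), "b": float(coef[0])}, fitted, y, 1
    if name == "inverse":  # y = a + b / x
        if not nonzero_x:
            raise _Skip("requires x != 0")
        coef = np.polyfit(1.0 / x, y, 1)
        fitted = np.polyval(coef, 1.0 / x)
        return {"a": float(coef[1]), "b": float(coef[0])}, fitted, y, 1
    if name == "logistic":  # y = 1 / (1/c + a b^x), c > 0
        if not pos_y:
            raise _Skip("requires y > 0")

        def model(x_, a, b, c):
            return 1.0 / (1.0 / c + a * np.power(b, x_))

        c0 = float(y.max()) * 1.05
        # start from the compound fit of 1/y - 1/c
        u = 1.0 / y - 1.0 / c0
        if (u > 0).all():
            coef = np.polyfit(x, np.log(u), 1)
            p0 = [float(np.exp(coef[1])), float(np.exp(coef[0])), c0]
        else:
            p0 = [1.0, 0.5, c0]
        try:
            popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000,
                                         bounds=([-np.inf, 1e-12, 1e-12],
                                                 [np.inf, np.inf, np.inf]))
        except RuntimeError as exc:
            raise _Skip(f"logistic fit did not converge: {exc}")
        fitted = model(x, *popt)
        return ({"a": float(popt[0]), "b": float(popt[1]), "c": float(popt[2])},
                fitted, y, 2)
    raise KeyError(name)


class _Skip(Exception):
    pass


_FAMILY_PREDICT = {
    "linear": lambda x, p: p["a"] + p["b"] * x,
    "quadratic": lambda x, p: p["a"] + p["b"] * x + p["c"] * x ** 2,
    "cubic": lambda x, p: p["a"] + p["b"] * x + p["c"] * x ** 2 + p["d"] * x ** 3,
    "compound": lambda x, p: p["a"] * p["b"] ** x,
    "power": lambda x, p: p["a"] * x ** p["b"],
    "s_curve": lambda x, p: np.exp(p["a"] + p["b"] / x),
    "growth": lambda x, p: np.exp(p["a"] + p["b"] * x),
    "exponential": lambda x, p: p["a"] * np.exp(p["b"] * x),
    "logarithmic": lambda x, p: p["a"] + p["b"] * np.log(x),
    "inverse": lambda x, p: p["a"] + p["b"] / x,
    "logistic": lambda x, p: 1.0 / (1.0 / p["c"] + p["a"] * p["b"] ** x),
}

CURVE_FAMILIES = tuple(_FAMILY_PREDICT)


def fit_curve_families(x, y, families=CURVE_FAMILIES):
    """Fit the requested regression families; return (best fit, all fits).

    Log-linearizable families are fitted exactly on the transformed scale
    (their R^2 and F-test refer to that scale, as is conventional);
    polynomials and the logistic are fitted directly.  ``best`` is the
    highest-R^2 fit among families with p < 0.05, or None if no family
    qualifies.  Families whose domain constraints fail are returned with a
    ``skipped`` reason.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y lengths differ")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    fits: list[CurveFit] = []
    for name in families:
        try:
            params, fitted, target, df_model = _fit_family(name, x, y)
        except _Skip as exc:
            fits.append(CurveFit(name, {}, np.nan, np.nan, len(x), str(exc)))
            continue
        ss_res = float(((target - fitted) ** 2).sum())
        ss_tot = float(((target - target.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        r2 = float(np.clip(r2, 0.0, 1.0))
        df_resid = len(x) - df_model - 1
        if df_resid <= 0:
            p = np.nan
        elif r2 >= 1.0:
            p = 0.0
        else:
            f = (r2 / df_model) / ((1 - r2) / df_resid)
            p = float(stats.f.sf(f, df_model, df_resid))
        fits.append(CurveFit(name, params, r2, p, len(x)))
    usable = [f for f in fits if f.skipped is None and np.isfinite(f.r2)
              and np.isfinite(f.p_value) and f.p_value < 0.05]
    if not any(f.skipped is None for f in fits):
        raise ValueError("no applicable curve family for these data")
    best = max(usable, key=lambda f: f.r2) if usable else None
    return best, fits


def screen_outliers(x, y, mode: str = "replace", decimals: int | None = None):
    """Flag residual outliers by the 1.5 IQR rule and clean them up.

    Residuals come from an ordinary linear fit.  In ``replace`` mode an
    outlier's y is replaced by the mean y of the other observations sharing
    its x level (exact x equality, optionally after rounding to
    ``decimals``) when at least two such neighbours exist; otherwise —
    and always in ``eliminate`` mode — the point is dropped.  Returns
    (x_clean, y_clean, report) where the report lists every action taken.
    """
    if mode not in ("replace", "eliminate"):
        raise ValueError("mode must be 'replace' or 'eliminate'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    coef = np.polyfit(x, y, 1)
    resid = y - np.polyval(coef, x)
    q1, q3 = np.percentile(resid, [25, 75])
    iqr = q3 - q1
    # absolute guard so numerically exact fits do not flag rounding noise
    tol = 1e-8 * max(1.0, float(np.abs(y).max()))
    lo, hi = q1 - 1.5 * iqr - tol, q3 + 1.5 * iqr + tol
    flagged = np.flatnonzero((resid < lo) | (resid > hi))
    levels = np.round(x, decimals) if decimals is not None else x
    keep = np.ones(len(x), dtype=bool)
    y_new = y.copy()
    report = []
    flagged_set = set(flagged.tolist())
    for i in flagged:
        neighbours = [j for j in range(len(x))
                      if j != i and j not in flagged_set and levels[j] == levels[i]]
        if mode == "replace" and len(neighbours) >= 2:
            y_new[i] = float(np.mean(y[neighbours]))
            report.append({"index": int(i), "x": float(x[i]), "y": float(y[i]),
                           "action": "replaced", "new_y": float(y_new[i])})
        else:
            keep[i] = False
            reason = ("eliminate mode" if mode == "eliminate"
                      else "fewer than 2 same-x neighbours")
            report.append({"index": int(i), "x": float(x[i]), "y": float(y[i]),
                           "action": "eliminated", "reason": reason})
    return x[keep], y_new[keep], report
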