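"""Breakage-rate statistics: screening, stepwise OLS, path analysis.

The analysis chain this package supports runs: (1) a Spearman rank
correlation screen of every structural parameter against breakage rate,
(2) stepwise ordinary least squares at a 5% entry/removal significance
criterion to find the parameters that jointly predict breakage, and
(3) a path analysis that decomposes each retained predictor's correlation
with breakage into a direct effect (its standardized regression
coefficient) and indirect effects routed through the other predictors
(inter-predictor correlation x the other predictor's direct coefficient).
The decomposition satisfies, exactly, the identity

    r(Xi, y) = direct(i) + sum_{j != i} r(Xi, Xj) * direct(j)

whenever all quantities are computed from the same data.

Also here: the sieve-mass breakage-rate formula, gravimetric moisture
content, and a one-way ANOVA convenience with a compact letter display.

``StepwiseRegressor`` and ``PathAnalysis`` are sklearn-style estimators
(fit/predict, ``get_params``, trailing-underscore fitted attributes); the
module-level functions are thin wrappers over them.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "breakage_rate",
    "moisture_content",
    "spearman_screen",
    "fit_ols",
    "stepwise_select",
    "path_analysis",
    "anova_letters",
    "OLSFit",
    "StepwiseResult",
    "PathAnalysisResult",
    "StepwiseRegressor",
    "PathAnalysis",
]


def breakage_rate(w_pan: float, w_5mm: float, w_2mm: float) -> float:
    """Breakage rate from the grind-and-sieve masses (grams).

    BR = W_p / (W_5mm + W_2mm + W_p): the mass fraction of fines reaching
    the receiving pan below a 2-mm sieve. Returns a fraction in [0, 1].
    """
    if min(w_pan, w_5mm, w_2mm) < 0:
        raise ValueError("sieve masses must be >= 0")
    total = w_pan + w_5mm + w_2mm
    if total <= 0:
        raise ValueError("total sieved mass is zero")
    return w_pan / total


def moisture_content(w_before_g: float, w_after_g: float) -> float:
    """Gravimetric moisture fraction: (Wa - Wb) / Wa after oven drying."""
    if w_after_g <= 0:
        raise ValueError("dry weight must be positive")
    if w_after_g > w_before_g:
        raise ValueError("dry weight exceeds wet weight")
    return (w_before_g - w_after_g) / w_before_g


def spearman_screen(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman rank correlation of each parameter with the response.

    Ties get average ranks; significance is two-sided ("*" p<0.05,
    "**" p<0.01). A constant column cannot be ranked against anything:
    its row is flagged ``undefined`` rather than silently NaN.
    Returns a DataFrame indexed by parameter with columns
    ``rho``, ``p_value``, ``stars``, ``undefined``.
    """
    if response not in table.columns:
        raise ValueError(f"response column {response!r} not in table")
    y = table[response].to_numpy(dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 rows for a rank screen")
    if predictors is None:
        predictors = [
            c for c in table.columns
            if c != response and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for name in predictors:
        x = table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"parameter": name, "rho": np.nan, "p_value": np.nan,
                         "stars": "", "undefined": True})
            continue
        rho, p = sps.spearmanr(x, y)
        stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
        rows.append({"parameter": name, "rho": float(rho), "p_value": float(p),
                     "stars": stars, "undefined": False})
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class OLSFit:
    """Least-squares fit with both raw and standardized coefficients."""

    predictors: list[str]
    intercept: float
    coef: dict[str, float]
    std_coef: dict[str, float]
    pvalues: dict[str, float]
    r_squared: float
    model: object = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept)
        for name, b in self.coef.items():
            out = out + b * X[name].to_numpy(dtype=float)
        return out


def _as_frame(X, names: list[str] | None = None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = names or [f"x{i + 1}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=names)


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        bad = []
        for name in X.columns:
            others = X.drop(columns=[name])
            sub = np.column_stack([np.ones(len(X)), others.to_numpy(dtype=float)])
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad or list(X.columns)}"
        )


def fit_ols(y, X, names: list[str] | None = None) -> OLSFit:
    """OLS of y on X with intercept; also reports standardized coefficients.

    Standardized coefficient of x_j is ``b_j * sd(x_j) / sd(y)`` — the
    coefficient the regression would have after z-scoring, i.e. the direct
    path coefficient in a path analysis.
    """
    X = _as_frame(X, names)
    y = np.asarray(y, dtype=float)
    if len(X) <= X.shape[1]:
        raise ValueError("need more rows than predictors")
    _check_rank(X)
    design = sm.add_constant(X.to_numpy(dtype=float))
    fit = sm.OLS(y, design).fit()
    sy = y.std(ddof=1)
    coef, std_coef, pvals = {}, {}, {}
    for j, name in enumerate(X.columns, start=1):
        coef[name] = float(fit.params[j])
        std_coef[name] = float(fit.params[j] * X[name].std(ddof=1) / sy)
        pvals[name] = float(fit.pvalues[j])
    return OLSFit(
        predictors=list(X.columns),
        intercept=float(fit.params[0]),
        coef=coef,
        std_coef=std_coef,
        pvalues=pvals,
        r_squared=float(fit.rsquared),
        model=fit,
    )


@dataclass
class StepwiseResult:
    """Outcome of the stepwise entry/removal loop."""

    selected: list[str]
    fit: OLSFit | None
    trace: list[tuple[str, str, float]]  # (action, predictor, p-value)

    @property
    def empty(self) -> bool:
        return not self.selected


def stepwise_select(
    y,
    X,
    alpha_in: float = 0.05,
    alpha_out: float = 0.05,
    names: list[str] | None = None,
) -> StepwiseResult:
    """Forward-entry / backward-removal OLS variable selection.

    Each round adds the candidate whose coefficient would be most
    significant, if its p-value is <= ``alpha_in``, then removes any
    retained predictor whose p-value exceeds ``alpha_out``, until no move
    is possible. Termination is guaranteed by refusing to revisit a
    predictor set already seen. If nothing enters, the result is the
    empty (intercept-only) model, flagged via ``StepwiseResult.empty``.
    """
    X = _as_frame(X, names)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate predictors")
    y = np.asarray(y, dtype=float)
    selected: list[str] = []
    trace: list[tuple[str, str, float]] = []
    seen: set[frozenset] = {frozenset()}
    while True:
        moved = False
        candidates = [c for c in X.columns if c not in selected]
        best_name, best_p = None, np.inf
        for name in candidates:
            trial = selected + [name]
            try:
                f = fit_ols(y, X[trial])
            except np.linalg.LinAlgError:
                continue
            p = f.pvalues[name]
            if p < best_p:
                best_name, best_p = name, p
        if best_name is not None and best_p <= alpha_in:
            state = frozenset(selected + [best_name])
            if state not in seen:
                selected.append(best_name)
                seen.add(state)
                trace.append(("add", best_name, best_p))
                moved = True
        if selected:
            f = fit_ols(y, X[selected])
            worst = max(selected, key=lambda n: f.pvalues[n])
            if f.pvalues[worst] > alpha_out:
                state = frozenset(s for s in selected if s != worst)
                if state not in seen or not moved:
                    selected.remove(worst)
                    seen.add(state)
                    trace.append(("remove", worst, f.pvalues[worst]))
                    moved = True
        if not moved:
            break
    if not selected:
        warnings.warn("no predictor met the entry criterion; empty model",
                      stacklevel=2)
        return StepwiseResult([], None, trace)
    return StepwiseResult(selected, fit_ols(y, X[selected]), trace)


@dataclass
class PathAnalysisResult:
    """Direct/indirect decomposition of predictor-response correlations.

    ``indirect`` is a DataFrame whose (i, j) entry, j != i, is
    r(Xi, Xj) * direct(Xj); the diagonal is NaN (undefined). ``total`` per
    predictor is direct + row-sum of indirect and reproduces
    ``correlations_with_response`` up to numerical precision.
    """

    predictors: list[str]
    direct: pd.Series
    indirect: pd.DataFrame
    total: pd.Series
    correlations_with_response: pd.Series
    predictor_correlations: pd.DataFrame

    def to_table(self) -> pd.DataFrame:
        """Direct-plus-indirect table, one row per predictor."""
        table = self.indirect.copy()
        table.insert(0, "DPC", self.direct)
        table["total"] = self.total
        table["r_with_response"] = self.correlations_with_response
        return table


def path_analysis(y, X, names: list[str] | None = None) -> PathAnalysisResult:
    """Decompose each predictor's correlation with y into path coefficients.

    Direct path coefficients are the standardized OLS coefficients; the
    indirect coefficient of Xi via Xj is r(Xi, Xj) * direct(Xj).
    """
    X = _as_frame(X, names)
    y = np.asarray(y, dtype=float)
    ols = fit_ols(y, X)
    cols = list(X.columns)
    direct = pd.Series({c: ols.std_coef[c] for c in cols}, name="DPC")
    r_xx = pd.DataFrame(
        np.corrcoef(X.to_numpy(dtype=float), rowvar=False),
        index=cols, columns=cols,
    )
    r_xy = pd.Series(
        {c: float(np.corrcoef(X[c].to_numpy(dtype=float), y)[0, 1]) for c in cols},
        name="r",
    )
    indirect = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, j in itertools.permutations(cols, 2):
        indirect.loc[i, j] = r_xx.loc[i, j] * direct[j]
    total = direct + indirect.sum(axis=1, skipna=True)
    return PathAnalysisResult(
        predictors=cols,
        direct=direct,
        indirect=indirect,
        total=total.rename("total"),
        correlations_with_response=r_xy,
        predictor_correlations=r_xx,
    )


def anova_letters(
    groups: dict[str, np.ndarray], alpha: float = 0.05, method: str = "lsd"
) -> pd.DataFrame:
    """One-way ANOVA plus a compact letter display of pairwise differences.

    Pairwise comparisons use Fisher's LSD on the pooled within-group mean
    square (``method="tukey"`` switches to Tukey HSD via statsmodels).
    Groups sharing a letter do not differ at ``alpha``. Returns a frame
    indexed by group with columns ``mean``, ``n``, ``letters`` plus the
    F statistic and p-value as attrs.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("every group needs at least 2 replicates")
    f_stat, f_p = sps.f_oneway(*arrays.values())

    names = list(arrays)
    if method == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        flat = np.concatenate([arrays[k] for k in names])
        labs = np.concatenate([[k] * len(arrays[k]) for k in names])
        tk = pairwise_tukeyhsd(flat, labs, alpha=alpha)
        pairs = list(itertools.combinations(np.unique(labs), 2))
        differ = {frozenset(p): bool(r) for p, r in zip(pairs, tk.reject)}
    elif method == "lsd":
        n_total = sum(len(v) for v in arrays.values())
        df_err = n_total - len(names)
        mse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values()) / df_err
        differ = {}
        for a, b in itertools.combinations(names, 2):
            na, nb = len(arrays[a]), len(arrays[b])
            se = np.sqrt(mse * (1 / na + 1 / nb))
            if se == 0:
                differ[frozenset((a, b))] = arrays[a].mean() != arrays[b].mean()
                continue
            t = abs(arrays[a].mean() - arrays[b].mean()) / se
            p = 2 * sps.t.sf(t, df_err)
            differ[frozenset((a, b))] = p < alpha
    else:
        raise ValueError(f"unknown method {method!r}")

    letters = _compact_letter_display(names,
                                      {k: arrays[k].mean() for k in names},
                                      differ)
    out = pd.DataFrame({
        "mean": [arrays[k].mean() for k in names],
        "n": [len(arrays[k]) for k in names],
        "letters": [letters[k] for k in names],
    }, index=pd.Index(names, name="group"))
    out.attrs["F"] = float(f_stat)
    out.attrs["p_value"] = float(f_p)
    return out


def _compact_letter_display(
    names: list[str], means: dict[str, float], differ: dict[frozenset, bool]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment, highest mean lettered first."""
    order = sorted(names, key=lambda k: -means[k])
    letter_groups: list[set[str]] = []
    for name in order:
        placed = False
        for grp in letter_groups:
            if all(not differ[frozenset((name, other))] for other in grp):
                grp.add(name)
                placed = True
        if not placed:
            letter_groups.append({name})
    # absorb redundant groups (subsets of another)
    letter_groups = [
        g for g in letter_groups
        if not any(g < h for h in letter_groups if h is not g)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {k: "" for k in names}
    for letter, grp in zip(alphabet, letter_groups):
        for name in grp:
            out[name] += letter
    return {k: "".join(sorted(v)) for k, v in out.items()}


# ---------------------------------------------------------------------------
# sklearn-style estimators


class StepwiseRegressor(BaseEstimator, RegressorMixin):
    """Stepwise OLS as a sklearn regressor.

    Parameters
    ----------
    alpha_in, alpha_out : float
        Significance thresholds for predictor entry and removal (both 0.05
        by default, the "5% criterion").

    Fitted attributes: ``selected_`` (predictor names retained),
    ``intercept_``, ``coef_`` (aligned with the input feature order, zeros
    for dropped features), ``pvalues_``, ``r_squared_``, ``trace_``.
    """

    def __init__(self, alpha_in: float = 0.05, alpha_out: float = 0.05):
        self.alpha_in = alpha_in
        self.alpha_out = alpha_out

    def fit(self, X, y):
        Xf = _as_frame(X)
        self.feature_names_in_ = np.asarray(Xf.columns, dtype=object)
        res = stepwise_select(y, Xf, self.alpha_in, self.alpha_out)
        self.selected_ = list(res.selected)
        self.trace_ = res.trace
        if res.fit is None:
            self.intercept_ = float(np.mean(y))
            self.coef_ = np.zeros(Xf.shape[1])
            self.pvalues_ = {}
            self.r_squared_ = 0.0
        else:
            self.intercept_ = res.fit.intercept
            self.coef_ = np.array(
                [res.fit.coef.get(c, 0.0) for c in Xf.columns]
            )
            self.pvalues_ = dict(res.fit.pvalues)
            self.r_squared_ = res.fit.r_squared
        return self

    def predict(self, X):
        Xf = _as_frame(X)
        return self.intercept_ + Xf.to_numpy(dtype=float) @ self.coef_


class PathAnalysis(BaseEstimator):
    """Path analysis as a sklearn-style estimator.

    ``fit(X, y)`` computes direct path coefficients (``direct_``), the
    indirect coefficient matrix (``indirect_``), totals (``total_``) and
    the correlations they must reproduce (``correlations_``).
    """

    def fit(self, X, y):
        res = path_analysis(y, _as_frame(X))
        self.result_ = res
        self.direct_ = res.direct
        self.indirect_ = res.indirect
        self.total_ = res.total
        self.correlations_ = res.correlations_with_response
        return self
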