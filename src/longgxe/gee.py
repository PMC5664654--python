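"""Marginal mean models for clustered longitudinal data.

Thin, contract-enforcing wrapper around statsmodels' generalized estimating
equations (Gaussian family, identity link) returning subject-clustered
sandwich covariances.  Used for the stage-1 marginal exposure tests and the
single-variant follow-up scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["GEEFit", "fit_gee", "robust_test", "build_design"]

WORKING_STRUCTURES = {
    "independence": sm.cov_struct.Independence,
    "exchangeable": sm.cov_struct.Exchangeable,
}


@dataclass
class GEEFit:
    """Converged GEE fit with model-based and sandwich covariances."""

    params: pd.Series
    cov_robust: pd.DataFrame
    cov_naive: pd.DataFrame
    working: str
    n_subjects: int
    n_obs: int
    converged: bool
    residuals: pd.Series
    fitted: pd.Series
    groups: pd.Series

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov_robust.loc[term, term]))


def build_design(
    data: pd.DataFrame, terms: list[str], add_intercept: bool = True
) -> pd.DataFrame:
    """Assemble a design matrix from named columns.

    Interaction terms may be written ``"a:b"`` (elementwise product) and an
    ``"age2"`` term is derived from ``age`` when absent, so configs can list
    the quadratic term without materializing it.
    """
    cols = {}
    if add_intercept:
        cols["Intercept"] = np.ones(len(data))
    for term in terms:
        if term in data.columns:
            cols[term] = data[term].to_numpy(dtype=float)
        elif term == "age2" and "age" in data.columns:
            cols[term] = data["age"].to_numpy(dtype=float) ** 2
        elif ":" in term:
            left, right = term.split(":", 1)
            for part in (left, right):
                if part not in data.columns:
                    raise KeyError(f"interaction term {term!r}: column {part!r} absent")
            cols[term] = (
                data[left].to_numpy(dtype=float) * data[right].to_numpy(dtype=float)
            )
        else:
            raise KeyError(f"model term {term!r} not found in data")
    return pd.DataFrame(cols, index=data.index)


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offenders: columns whose removal restores full column rank
        offenders = []
        for j, name in enumerate(design.columns):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                offenders.append(name)
        raise np.linalg.LinAlgError(
            f"singular design; collinear terms: {offenders or list(design.columns)}"
        )


def fit_gee(
    data: pd.DataFrame,
    outcome: str,
    terms: list[str],
    groups: str = "subject",
    working: str = "exchangeable",
    add_intercept: bool = True,
    maxiter: int = 100,
    ctol: float = 1e-8,
) -> GEEFit:
    """Fit a Gaussian identity-link GEE of ``outcome`` on ``terms``.

    Rows with missing values in the outcome or any named term are dropped
    (listwise deletion per model).  The returned sandwich covariance is
    aggregated at the cluster (subject) level; with one observation per
    cluster and independence working correlation the coefficient estimates
    coincide with ordinary least squares.
    """
    if working not in WORKING_STRUCTURES:
        raise ValueError(f"unknown working correlation {working!r}")
    design = build_design(data, terms, add_intercept=add_intercept)
    used = pd.concat([data[[outcome, groups]], design], axis=1)
    used = used.dropna()
    if used[groups].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    design = used[design.columns]
    _check_full_rank(design)

    model = sm.GEE(
        used[outcome].to_numpy(dtype=float),
        design.to_numpy(dtype=float),
        groups=used[groups].to_numpy(),
        family=sm.families.Gaussian(),
        cov_struct=WORKING_STRUCTURES[working](),
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(maxiter=maxiter, ctol=ctol)
        for w in caught:
            if "onverge" in str(w.message):
                converged = False
    names = list(design.columns)
    params = pd.Series(result.params, index=names)
    cov_robust = pd.DataFrame(result.cov_robust, index=names, columns=names)
    cov_naive = pd.DataFrame(result.cov_naive, index=names, columns=names)
    if not converged:
        cov_robust.loc[:, :] = np.nan
        cov_naive.loc[:, :] = np.nan
    fitted = pd.Series(result.fittedvalues, index=used.index)
    return GEEFit(
        params=params,
        cov_robust=cov_robust,
        cov_naive=cov_naive,
        working=working,
        n_subjects=int(used[groups].nunique()),
        n_obs=len(used),
        converged=converged,
        residuals=used[outcome] - fitted,
        fitted=fitted,
        groups=used[groups],
    )


def robust_test(fit: GEEFit, term: str) -> tuple[float, float, float]:
    """Two-sided Wald test of one coefficient using the sandwich SE.

    Returns ``(estimate, SE, p)`` with ``p`` the standard-normal two-tail
    probability of ``estimate / SE``.
    """
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in fit")
    if not fit.converged:
        raise RuntimeError("fit did not converge; covariances withheld")
    est = float(fit.params[term])
    se = fit.se(term)
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"term {term!r}: zero or undefined sandwich SE")
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return est, se, max(p, np.finfo(float).tiny)
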