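"""Age and sex effects on recombination frequency.

Replicate-level RFs are modelled with a Gaussian identity-link GLM
(equivalently OLS on group indicators), the predictor being parental age
group or detector sex.  All pairwise group comparisons form one family of
contrasts per line x role, and the family-wise error rate is held at 5%
with a single-step adjustment: each adjusted p-value is the probability,
under the joint central multivariate t distribution of all the test
statistics (design-implied correlation, pooled-error degrees of freedom),
that the maximum absolute statistic exceeds the observed one.  The
multivariate-t tail probability is evaluated by Monte Carlo with an
explicit seed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupModelFit",
    "fit_group_model",
    "pairwise_contrasts",
    "contrast_correlation",
    "single_step_adjust",
    "run_age_analysis",
]


@dataclass(frozen=True)
class GroupModelFit:
    """OLS fit of a one-way group model on replicate RFs.

    With one-hot group coding and identity link the fitted group means are
    the arithmetic group means; ``resid_var`` is the pooled residual
    variance (RSS / dof).
    """

    labels: tuple
    means: np.ndarray
    n_per_group: np.ndarray
    resid_var: float
    dof: int

    def index_of(self, label) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown group {label!r}; groups are {self.labels}") from None


def fit_group_model(values: Sequence[float], groups: Sequence) -> GroupModelFit:
    """Fit RF ~ group by OLS (Gaussian identity-link GLM)."""
    y = np.asarray(values, dtype=float)
    g = pd.Series(list(groups))
    if len(y) != len(g):
        raise ValueError("values and groups must have equal length")
    labels = tuple(sorted(g.unique().tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    counts = g.value_counts()
    empty = [lab for lab in labels if counts.get(lab, 0) == 0]
    if empty:
        raise ValueError(f"groups with zero observations: {empty}")
    dof = len(y) - len(labels)
    if dof < 2:
        raise ValueError(f"need >= 2 residual degrees of freedom, have {dof}")
    design = (g.values[:, None] == np.array(labels, dtype=object)[None, :]).astype(float)
    res = sm.OLS(y, design).fit()
    ssr = float(res.ssr)
    if ssr < 1e-12 * max(1.0, float(y @ y)):  # numerically exact fit
        ssr = 0.0
    return GroupModelFit(
        labels=labels,
        means=np.asarray(res.params, dtype=float),
        n_per_group=design.sum(axis=0).astype(int),
        resid_var=ssr / dof,
        dof=dof,
    )


def _all_pairs(labels: tuple) -> list[tuple]:
    return list(itertools.combinations(labels, 2))


def pairwise_contrasts(fit: GroupModelFit, pairs: Sequence[tuple] | None = None) -> pd.DataFrame:
    """Per-contrast estimate, SE, t and raw two-sided p (no adjustment).

    Each contrast is group_b - group_a.  Requires positive pooled residual
    variance; a degenerate fit (all observations equal) leaves the t
    statistics undefined.
    """
    if fit.resid_var <= 0:
        raise ValueError(
            "pooled residual variance is zero: contrasts are undefined "
            "(all observations equal?)"
        )
    if pairs is None:
        pairs = _all_pairs(fit.labels)
    rows = []
    for a, b in pairs:
        ia, ib = fit.index_of(a), fit.index_of(b)
        est = fit.means[ib] - fit.means[ia]
        se = float(np.sqrt(fit.resid_var * (1.0 / fit.n_per_group[ia] + 1.0 / fit.n_per_group[ib])))
        t = est / se
        p = 2.0 * stats.t.sf(abs(t), fit.dof)
        rows.append(
            {"contrast": f"{b} - {a}", "estimate": est, "se": se, "t": t, "p_raw": p}
        )
    return pd.DataFrame(rows)


def contrast_correlation(fit: GroupModelFit, pairs: Sequence[tuple] | None = None) -> np.ndarray:
    """Design-implied correlation matrix of the pairwise contrast estimates."""
    if pairs is None:
        pairs = _all_pairs(fit.labels)
    k = len(fit.labels)
    L = np.zeros((len(pairs), k))
    for j, (a, b) in enumerate(pairs):
        L[j, fit.index_of(a)] = -1.0
        L[j, fit.index_of(b)] = 1.0
    cov = L @ np.diag(1.0 / fit.n_per_group) @ L.T
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _sample_max_abs_t(corr: np.ndarray, dof: int, mc_draws: int, rng: np.random.Generator) -> np.ndarray:
    """Draws of max_k |T_k| under the joint central multivariate t."""
    corr = np.asarray(corr, dtype=float)
    eigvals, eigvecs = np.linalg.eigh((corr + corr.T) / 2.0)
    if eigvals.min() < -1e-8:
        warnings.warn(
            "contrast correlation matrix is not positive semi-definite; "
            "falling back to an equicorrelation approximation",
            RuntimeWarning,
        )
        k = corr.shape[0]
        rho = float(np.clip((corr.sum() - k) / (k * (k - 1)), 0.0, 1.0 - 1e-9)) if k > 1 else 0.0
        corr = np.full((k, k), rho)
        np.fill_diagonal(corr, 1.0)
        eigvals, eigvecs = np.linalg.eigh(corr)
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))
    z = rng.standard_normal((mc_draws, corr.shape[0])) @ root.T
    w = rng.chisquare(dof, size=mc_draws) / dof
    t = z / np.sqrt(w)[:, None]
    return np.abs(t).max(axis=1)


def single_step_adjust(
    contrasts: pd.DataFrame,
    corr: np.ndarray,
    dof: int,
    mc_draws: int = 100_000,
    rng_seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Append single-step family-wise adjusted p-values to a contrast table.

    p_adj_j = P(max_k |T_k| >= |t_j|) under the central multivariate t with
    the given correlation and degrees of freedom, by Monte Carlo.  Adjusted
    p-values are monotone in |t| by construction (one shared sample) and
    never smaller than the raw p.
    """
    if len(contrasts) == 0:
        raise ValueError("empty contrast family")
    corr = np.atleast_2d(np.asarray(corr, dtype=float))
    if corr.shape != (len(contrasts), len(contrasts)):
        raise ValueError("correlation matrix shape does not match the contrast family")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    max_abs = _sample_max_abs_t(corr, dof, mc_draws, rng)
    out = contrasts.copy()
    tvals = np.abs(out["t"].to_numpy())
    p_adj = np.array([(max_abs >= t).mean() for t in tvals])
    out["p_adjusted"] = np.maximum(p_adj, out["p_raw"].to_numpy())
    return out


def run_age_analysis(
    records,
    role: str,
    alpha: float = 0.05,
    mc_draws: int = 100_000,
    rng_seed: int | np.random.Generator = 0,
    aggregation_column: str = "rf",
) -> pd.DataFrame:
    """Full per-line age analysis for one detector role.

    Fits replicate RFs against age group, forms all pairwise age contrasts
    and adjusts them jointly; ``significant`` marks p_adjusted < alpha.
    Under the replicated finding (no age effect) no contrast is expected to
    be significant.
    """
    from .rf import add_rf_column

    df = records if isinstance(records, pd.DataFrame) and aggregation_column in records else add_rf_column(records)
    df = df[df["role"] == role]
    if df.empty:
        raise ValueError(f"no records with role {role!r}")
    fit = fit_group_model(df[aggregation_column].to_numpy(), df["age_das"].tolist())
    contrasts = pairwise_contrasts(fit)
    corr = contrast_correlation(fit)
    out = single_step_adjust(contrasts, corr, fit.dof, mc_draws=mc_draws, rng_seed=rng_seed)
    out.insert(0, "role", role)
    if "line" in df.columns:
        lines = df["line"].unique()
        out.insert(0, "line", lines[0] if len(lines) == 1 else "multiple")
    out["significant"] = out["p_adjusted"] < alpha
    return out
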