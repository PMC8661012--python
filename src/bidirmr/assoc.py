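"""Per-SNP association testing and instrument selection.

Covariate-adjusted GWAS with an additive genotype coding: ordinary least
squares for a continuous trait, maximum-likelihood logistic regression
(IRLS) for a binary trait, per-SNP complete-case handling, instrument
selection at a p-value threshold (strict inequality) and weak-instrument
screening by the partial F-statistic (inclusive at the threshold).

The regression engines are deliberately lightweight numpy implementations:
a GWAS loop calls them once per SNP, and their outputs are cross-checked
against statsmodels in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidInputError,
    NoInstrumentsError,
    SeparationError,
    SingularDesignError,
)
from .simulate import GenotypeMatrix

__all__ = [
    "LinearFit",
    "LogisticFit",
    "fit_linear",
    "fit_logistic",
    "gwas",
    "select_instruments",
    "f_statistic",
    "screen_instruments",
    "InstrumentSet",
]

#: Summary-statistics table columns shared with the I/O layer.
SUMMARY_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "p",
    "n_used",
    "model",
    "testable",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS fit: coefficients (intercept first), SEs, two-sided t p-values."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    residual_variance: float
    rss: float
    n: int
    df_resid: int


@dataclass(frozen=True)
class LogisticFit:
    """Logistic ML fit: coefficients (intercept first), Wald SEs, normal p-values."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    loglik: float
    n: int


def _design_with_intercept(design) -> np.ndarray:
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(X.shape[0]), X])


def fit_linear(y, design) -> LinearFit:
    """Ordinary least squares of y on the predictor columns plus an intercept.

    SEs come from sigma^2 (X'X)^-1; p-values are two-sided from the t
    reference with n - p residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = _design_with_intercept(design)
    n, p = X.shape
    if n < p + 1:
        raise InvalidInputError(f"need at least {p + 1} rows for {p} parameters")
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(xtx)
    if rank < p:
        raise SingularDesignError(f"design matrix rank {rank} < {p}")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / df
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    pvals = 2.0 * stats.t.sf(np.abs(t), df=df)
    return LinearFit(beta, se, pvals, sigma2, rss, n, df)


def fit_logistic(
    y, design, max_iter: int = 25, tol: float = 1e-8
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    Newton-Raphson on the log-likelihood, convergence on a log-likelihood
    change below ``tol``; Wald SEs from the observed information; two-sided
    normal p-values.  Diverging coefficients raise ``SeparationError``;
    hitting ``max_iter`` flags ``converged=False`` rather than failing.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidInputError("binary outcome must be coded {0, 1}")
    if y.min() == y.max():
        raise InvalidInputError("both outcome classes must be present")
    X = _design_with_intercept(design)
    n, p = X.shape
    if np.linalg.matrix_rank(X.T @ X) < p:
        raise SingularDesignError("rank-deficient logistic design")
    beta = np.zeros(p)
    loglik = -n * np.log(2.0)  # at beta = 0
    converged = False
    info = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix singular (separation or degenerate fit)"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 1e2:
            raise SeparationError(
                "coefficients diverging: complete or quasi-complete separation"
            )
        eta = np.clip(X @ beta, -30.0, 30.0)
        new_loglik = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if abs(new_loglik - loglik) < tol:
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik
    if not converged:
        warnings.warn("logistic IRLS did not converge", RuntimeWarning, stacklevel=2)
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    # a "converged" fit that classifies perfectly with runaway coefficients
    # is complete/quasi-complete separation, not a maximum
    if np.max(np.abs(beta)) > 15.0 and np.all((mu > 0.5) == (y > 0.5)):
        raise SeparationError(
            "perfect classification with diverging coefficients: separation"
        )
    info = (X * (mu * (1 - mu))[:, None]).T @ X
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(beta, se, pvals, converged, loglik, n)


def _covariate_matrix(covariates) -> np.ndarray | None:
    if covariates is None:
        return None
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[1] == 0:
        return None
    return C


def gwas(
    G: GenotypeMatrix,
    trait,
    covariates=None,
    model: str = "linear",
) -> pd.DataFrame:
    """One covariate-adjusted regression per SNP: trait ~ genotype + covariates.

    Complete cases are determined per SNP (PLINK convention).  Monomorphic
    SNPs (zero dosage variance among complete cases) and non-converging or
    separated logistic fits are flagged ``testable=False`` and excluded from
    instrument selection.  Association p-values are two-sided normal on
    beta/se (PLINK-style asymptotic), regardless of model.
    """
    if model not in ("linear", "logistic"):
        raise InvalidInputError("model must be linear|logistic")
    trait = np.asarray(trait, dtype=float)
    if trait.shape[0] != G.n_individuals:
        raise InvalidInputError("trait length does not match genotype rows")
    C = _covariate_matrix(covariates)
    if C is not None and C.shape[0] != G.n_individuals:
        raise InvalidInputError("covariate rows do not match genotype rows")
    base_complete = ~np.isnan(trait)
    if C is not None:
        base_complete &= ~np.isnan(C).any(axis=1)

    rows = []
    meta = G.snp_meta
    for j in range(G.n_snps):
        g = G.calls[:, j]
        complete = base_complete & ~np.isnan(g)
        n_used = int(complete.sum())
        record = {
            "snp_id": meta["id"].iloc[j],
            "chrom": meta["chrom"].iloc[j],
            "pos": meta["pos"].iloc[j],
            "effect_allele": meta["effect_allele"].iloc[j],
            "other_allele": meta["other_allele"].iloc[j],
            "beta": np.nan,
            "se": np.nan,
            "p": np.nan,
            "n_used": n_used,
            "model": model,
            "testable": False,
        }
        g_cc = g[complete]
        if n_used >= 3 and g_cc.size and g_cc.var() > 0:
            design = (
                g_cc[:, None]
                if C is None
                else np.column_stack([g_cc, C[complete]])
            )
            try:
                if model == "linear":
                    fit = fit_linear(trait[complete], design)
                    ok = True
                else:
                    fit = fit_logistic(trait[complete], design)
                    ok = fit.converged
                if ok and fit.se[1] > 0:
                    record.update(
                        beta=float(fit.beta[1]),
                        se=float(fit.se[1]),
                        p=float(2.0 * stats.norm.sf(abs(fit.beta[1] / fit.se[1]))),
                        testable=True,
                    )
            except (SeparationError, SingularDesignError, InvalidInputError):
                pass
        rows.append(record)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def select_instruments(
    results: pd.DataFrame, p_threshold: float = 5e-6
) -> pd.DataFrame:
    """Candidate instruments: testable SNPs with p strictly below the threshold.

    Returns the matching rows sorted by p ascending.  An empty selection is
    legal and returned with a warning.
    """
    if len(results) == 0:
        warnings.warn("empty association results: no instruments", stacklevel=2)
        return results.copy()
    mask = results["testable"].astype(bool) & (results["p"] < p_threshold)
    selected = results.loc[mask].sort_values("p", kind="mergesort")
    if len(selected) == 0:
        warnings.warn(
            f"no SNP reached p < {p_threshold:g}; instrument set is empty",
            stacklevel=2,
        )
    return selected.reset_index(drop=True)


def f_statistic(g, exposure, covariates=None) -> float:
    """Partial F for adding one SNP to the covariate-only exposure model.

    F = (RSS0 - RSS1) / (RSS1 / (n - p1)), the usual one-extra-parameter
    partial F; algebraically equal to the squared t-statistic of the SNP
    coefficient in the full model.  Always computed by Gaussian (least
    squares) regression, also when the exposure is binary.
    """
    g = np.asarray(g, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    C = _covariate_matrix(covariates)
    complete = ~np.isnan(g) & ~np.isnan(exposure)
    if C is not None:
        complete &= ~np.isnan(C).any(axis=1)
    g, exposure = g[complete], exposure[complete]
    Cc = C[complete] if C is not None else None
    full_design = g[:, None] if Cc is None else np.column_stack([g, Cc])
    fit_full = fit_linear(exposure, full_design)
    if Cc is None:
        mean = exposure.mean()
        rss0 = float(((exposure - mean) ** 2).sum())
    else:
        rss0 = fit_linear(exposure, Cc).rss
    rss1 = fit_full.rss
    if rss1 == 0.0:
        return np.inf
    return float((rss0 - rss1) / (rss1 / fit_full.df_resid))


@dataclass(frozen=True)
class InstrumentSet:
    """Selected and screened instruments with their exposure effects.

    ``table`` columns: snp_id, chrom, pos, effect_allele, other_allele,
    beta_exposure, se_exposure, p_selection, f_statistic.
    """

    table: pd.DataFrame
    p_threshold: float
    f_threshold: float

    def __post_init__(self) -> None:
        t = self.table
        if len(t) and not (
            (t["p_selection"] < self.p_threshold).all()
            and (t["f_statistic"] >= self.f_threshold).all()
        ):
            raise InvalidInputError(
                "instrument set violates its own selection thresholds"
            )

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def screen_instruments(
    candidates: pd.DataFrame,
    G: GenotypeMatrix,
    exposure,
    covariates=None,
    f_threshold: float = 10.0,
    p_threshold: float = 5e-6,
) -> InstrumentSet:
    """Weak-instrument screen: retain candidates with partial F >= threshold.

    Raises ``NoInstrumentsError`` when nothing survives, because MR cannot
    proceed without instruments.
    """
    if len(candidates) == 0:
        raise NoInstrumentsError("no candidate instruments to screen")
    col = {s: j for j, s in enumerate(G.snp_ids)}
    rows = []
    for _, cand in candidates.iterrows():
        sid = cand["snp_id"]
        if sid not in col:
            raise InvalidInputError(f"candidate SNP {sid!r} absent from genotypes")
        F = f_statistic(G.calls[:, col[sid]], exposure, covariates)
        if F >= f_threshold:
            rows.append(
                {
                    "snp_id": sid,
                    "chrom": cand.get("chrom"),
                    "pos": cand.get("pos"),
                    "effect_allele": cand.get("effect_allele"),
                    "other_allele": cand.get("other_allele"),
                    "beta_exposure": cand["beta"],
                    "se_exposure": cand["se"],
                    "p_selection": cand["p"],
                    "f_statistic": F,
                }
            )
    if not rows:
        raise NoInstrumentsError(
            f"all {len(candidates)} candidates fell below F = {f_threshold:g}; "
            "MR cannot proceed"
        )
    return InstrumentSet(
        table=pd.DataFrame(rows),
        p_threshold=float(p_threshold),
        f_threshold=float(f_threshold),
    )
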