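"""Summary-statistic Mendelian randomization estimators.

Given per-instrument exposure and outcome associations (beta_Xj, beta_Yj
and their SEs), this module computes the per-SNP ratio (Wald) estimates
and four aggregate causal estimators:

* **IVW** — inverse-variance-weighted mean of the ratio estimates,
  theta = sum_j bY_j bX_j / se(bY_j)^2  /  sum_j bX_j^2 / se(bY_j)^2,
  identical to a weighted regression of bY on bX through the origin with
  weights se(bY_j)^-2.  Fixed-effect SE by default; a multiplicative
  random-effects option inflates the SE by max(1, sigma_hat) from the
  weighted residual mean square.
* **MR-Egger** — the same weighted regression with a free intercept; the
  intercept estimates average directional pleiotropy under InSIDE and its
  test is the pleiotropy diagnostic.  Residual variance factor floored at 1.
* **Simple / weighted median** — the ratio estimate at cumulative
  (standardized) weight 0.5, interpolated; consistent when valid
  instruments carry a majority of the weight.  SEs by seeded parametric
  bootstrap.

All confidence intervals are estimate +/- 1.959964 * SE and all p-values
are two-sided normal, matching the reporting convention of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    HarmonizationError,
    InsufficientInstrumentsError,
    InvalidInputError,
    UnitError,
)

__all__ = [
    "Z95",
    "HarmonizedInstruments",
    "MRResult",
    "harmonize",
    "ratio_estimates",
    "ivw",
    "mr_egger",
    "simple_median",
    "weighted_median",
    "to_odds_ratio",
    "run_all_methods",
    "two_stage_least_squares",
]

Z95 = 1.959964  # normal 97.5% quantile used for all 95% CIs

HARMONIZED_COLUMNS = [
    "snp_id",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
]


@dataclass(frozen=True)
class HarmonizedInstruments:
    """Aligned per-instrument summary statistics, orientation-normalized.

    After construction every beta_exposure is >= 0 (pairs with a negative
    exposure effect have both betas sign-flipped, which leaves every ratio
    beta_Y/beta_X unchanged).
    """

    table: pd.DataFrame
    outcome_binary: bool = False

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        missing = [c for c in HARMONIZED_COLUMNS if c not in t.columns]
        if missing:
            raise InvalidInputError(f"harmonized table missing columns {missing}")
        if len(t) == 0:
            raise InvalidInputError("harmonized table is empty")
        if (t["se_exposure"] <= 0).any() or (t["se_outcome"] <= 0).any():
            raise InvalidInputError("all standard errors must be positive")
        if (t["beta_exposure"] == 0).any():
            raise InvalidInputError("zero exposure effect cannot be oriented")
        flip = t["beta_exposure"] < 0
        t = t.copy()
        t.loc[flip, "beta_exposure"] *= -1
        t.loc[flip, "beta_outcome"] *= -1
        object.__setattr__(self, "table", t)

    @property
    def n_instruments(self) -> int:
        return len(self.table)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        t = self.table
        return (
            t["beta_exposure"].to_numpy(float),
            t["se_exposure"].to_numpy(float),
            t["beta_outcome"].to_numpy(float),
            t["se_outcome"].to_numpy(float),
        )


@dataclass(frozen=True)
class MRResult:
    """One estimator's output on the causal-effect scale.

    ``estimate`` is the causal effect per exposure unit (log-odds when the
    outcome is binary).  For MR-Egger the intercept fields hold the average
    directional-pleiotropy estimate and its test.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int
    outcome_binary: bool = False
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_ci_low: float | None = None
    intercept_ci_high: float | None = None
    intercept_p: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _result(
    method: str, estimate: float, se: float, n: int, outcome_binary: bool, **extra
) -> MRResult:
    z = abs(estimate / se) if se > 0 else (0.0 if estimate == 0 else np.inf)
    return MRResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - Z95 * se),
        ci_high=float(estimate + Z95 * se),
        p=float(2.0 * stats.norm.sf(z)),
        n_instruments=int(n),
        outcome_binary=outcome_binary,
        **extra,
    )


def harmonize(instruments, outcome_stats: pd.DataFrame, outcome_binary: bool = False) -> HarmonizedInstruments:
    """Join exposure-instrument and outcome summary statistics on SNP id.

    ``instruments`` is an ``InstrumentSet`` or a DataFrame with columns
    snp_id, beta_exposure, se_exposure (optionally effect_allele).  Every
    instrument must appear in ``outcome_stats`` with the same effect-allele
    annotation (when both sides carry one); otherwise a
    ``HarmonizationError`` names the offending SNP.
    """
    table = getattr(instruments, "table", instruments)
    out = outcome_stats.set_index("snp_id")
    rows = []
    for _, instr in table.iterrows():
        sid = instr["snp_id"]
        if sid not in out.index:
            raise HarmonizationError(f"instrument {sid!r} missing from outcome statistics")
        o = out.loc[sid]
        if not bool(o.get("testable", True)):
            raise HarmonizationError(f"instrument {sid!r} not testable in outcome GWAS")
        ea_x = instr.get("effect_allele")
        ea_y = o.get("effect_allele")
        if ea_x is not None and ea_y is not None and not pd.isna(ea_x) and ea_x != ea_y:
            raise HarmonizationError(
                f"effect-allele mismatch for {sid!r}: {ea_x!r} vs {ea_y!r}"
            )
        rows.append(
            {
                "snp_id": sid,
                "beta_exposure": float(instr["beta_exposure"]),
                "se_exposure": float(instr["se_exposure"]),
                "beta_outcome": float(o["beta"]),
                "se_outcome": float(o["se"]),
            }
        )
    return HarmonizedInstruments(pd.DataFrame(rows), outcome_binary=outcome_binary)


def ratio_estimates(h: HarmonizedInstruments) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios theta_j = bY_j / bX_j with first-order delta SEs.

    se(theta_j) = se(bY_j) / |bX_j| (exposure-side sampling error enters
    only at second order and is ignored, the convention the weighting
    scheme of the median estimators also uses).
    """
    bx, _, by, sy = h.arrays()
    if np.any(bx == 0):
        raise InvalidInputError("zero exposure effect: ratio undefined")
    return by / bx, sy / np.abs(bx)


def ivw(h: HarmonizedInstruments, model: str = "fixed") -> MRResult:
    """Inverse-variance-weighted causal estimate.

    theta = sum_j w_j bX_j bY_j / sum_j w_j bX_j^2 with w_j = se(bY_j)^-2;
    fixed-effect SE = (sum_j w_j bX_j^2)^(-1/2).  ``model="multiplicative_random"``
    inflates the SE by max(1, sigma_hat), where sigma_hat^2 is the weighted
    residual mean square of the through-origin regression; with a single
    instrument it falls back to fixed with a warning.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise InvalidInputError("model must be fixed|multiplicative_random")
    bx, _, by, sy = h.arrays()
    w = sy**-2
    denom = float(np.sum(w * bx**2))
    estimate = float(np.sum(w * bx * by)) / denom
    se = denom**-0.5
    if model == "multiplicative_random":
        if h.n_instruments < 2:
            import warnings

            warnings.warn(
                "random-effects IVW needs >= 2 instruments; using fixed",
                stacklevel=2,
            )
        else:
            sigma2 = float(np.sum(w * (by - estimate * bx) ** 2)) / (
                h.n_instruments - 1
            )
            se *= max(1.0, np.sqrt(sigma2))
    return _result("IVW", estimate, se, h.n_instruments, h.outcome_binary)


def mr_egger(h: HarmonizedInstruments) -> MRResult:
    """MR-Egger: weighted regression of bY on bX with a free intercept.

    Weights se(bY_j)^-2 on orientation-harmonized inputs.  The slope is the
    causal estimate; the intercept estimates average directional pleiotropy
    and its p-value is the pleiotropy test.  The residual variance factor
    is floored at 1 (SEs never shrink below the fixed-effect level).
    """
    if h.n_instruments < 3:
        raise InsufficientInstrumentsError(
            f"MR-Egger needs >= 3 instruments, got {h.n_instruments}"
        )
    bx, _, by, sy = h.arrays()
    w = sy**-2
    X = np.column_stack([np.ones_like(bx), bx])
    A = (X * w[:, None]).T @ X
    try:
        coef = np.linalg.solve(A, (X * w[:, None]).T @ by)
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError("degenerate exposure effects in Egger fit") from exc
    resid = by - X @ coef
    phi = max(1.0, float(np.sum(w * resid**2)) / (h.n_instruments - 2))
    cov = phi * np.linalg.inv(A)
    se_int, se_slope = np.sqrt(np.diag(cov))
    z_int = abs(coef[0] / se_int) if se_int > 0 else np.inf
    return _result(
        "MR_Egger",
        coef[1],
        se_slope,
        h.n_instruments,
        h.outcome_binary,
        intercept=float(coef[0]),
        intercept_se=float(se_int),
        intercept_ci_low=float(coef[0] - Z95 * se_int),
        intercept_ci_high=float(coef[0] + Z95 * se_int),
        intercept_p=float(2.0 * stats.norm.sf(z_int)),
    )


def _weighted_median_core(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Interpolated weighted median along the last axis.

    Orders the values, forms cumulative standardized weights
    p_j = (S_j - w_j/2) / S_total, and linearly interpolates the value at
    cumulative weight 0.5.  Vectorized over leading axes for the bootstrap.
    """
    values = np.atleast_2d(values)
    weights = np.atleast_2d(weights)
    order = np.argsort(values, axis=-1)
    v = np.take_along_axis(values, order, axis=-1)
    w = np.take_along_axis(weights, order, axis=-1)
    w = w / w.sum(axis=-1, keepdims=True)
    cum = np.cumsum(w, axis=-1) - 0.5 * w
    below = cum < 0.5
    k = below.sum(axis=-1)  # index of first cum >= 0.5
    n_rows, J = v.shape
    rows = np.arange(n_rows)
    out = np.empty(n_rows)
    at_low = k == 0
    at_high = k == J
    out[at_low] = v[at_low, 0]
    out[at_high] = v[at_high, -1]
    mid = ~(at_low | at_high)
    if mid.any():
        km = k[mid]
        rm = rows[mid]
        c0 = cum[rm, km - 1]
        c1 = cum[rm, km]
        v0 = v[rm, km - 1]
        v1 = v[rm, km]
        out[mid] = v0 + (0.5 - c0) * (v1 - v0) / (c1 - c0)
    return out


def _median_estimator(
    h: HarmonizedInstruments,
    weighted: bool,
    n_boot: int,
    seed,
) -> MRResult:
    if h.n_instruments < 3:
        raise InsufficientInstrumentsError(
            f"median estimators need >= 3 instruments, got {h.n_instruments}"
        )
    bx, sx, by, sy = h.arrays()
    ratios = by / bx

    def weights_for(bx_, sy_):
        if weighted:
            return bx_**2 / sy_**2  # inverse delta-method ratio variance
        return np.ones_like(bx_)

    estimate = float(
        _weighted_median_core(ratios[None, :], weights_for(bx, sy)[None, :])[0]
    )
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, sx, size=(n_boot, bx.size))
    by_b = rng.normal(by, sy, size=(n_boot, by.size))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios_b = by_b / bx_b
        w_b = weights_for(bx_b, sy[None, :])
    # a resampled beta_X exactly at zero would give an undefined ratio; map
    # it to an extreme value so the median remains well defined
    bad = ~np.isfinite(ratios_b)
    if bad.any():
        ratios_b[bad] = np.sign(by_b[bad]) * 1e12
        if weighted:
            w_b[bad] = 1e-24
    boot = _weighted_median_core(ratios_b, w_b)
    se = float(np.std(boot, ddof=1))
    return _result(
        "weighted_median" if weighted else "simple_median",
        estimate,
        se,
        h.n_instruments,
        h.outcome_binary,
    )


def simple_median(h: HarmonizedInstruments, n_boot: int = 2000, seed=0) -> MRResult:
    """Equal-weight (simple) median of the per-SNP ratio estimates.

    Consistent when at least half the instruments are valid.  SE by seeded
    parametric bootstrap (``n_boot`` draws from N(beta_hat, se) on each
    side); the p-value is the normal approximation on the bootstrap SE.
    """
    return _median_estimator(h, weighted=False, n_boot=n_boot, seed=seed)


def weighted_median(h: HarmonizedInstruments, n_boot: int = 2000, seed=0) -> MRResult:
    """Inverse-variance weighted median of the per-SNP ratio estimates.

    Weights are the inverse delta-method variances bX_j^2 / se(bY_j)^2;
    consistent when valid instruments carry more than half the total
    weight.  SE by the same seeded parametric bootstrap as simple_median.
    """
    return _median_estimator(h, weighted=True, n_boot=n_boot, seed=seed)


def to_odds_ratio(r: MRResult) -> tuple[float, tuple[float, float]]:
    """Exponentiate a log-odds causal estimate to an odds ratio with CI."""
    if not r.outcome_binary:
        raise UnitError(
            "odds-ratio transform requires a binary-outcome (log-odds) estimate"
        )
    return float(np.exp(r.estimate)), (
        float(np.exp(r.ci_low)),
        float(np.exp(r.ci_high)),
    )


METHODS = ("ivw", "simple_median", "weighted_median", "mr_egger")


def run_all_methods(
    h: HarmonizedInstruments,
    seed=0,
    n_boot: int = 2000,
    methods=METHODS,
    ivw_model: str = "fixed",
) -> dict[str, MRResult | None]:
    """Run the four estimators; partial results carry per-method errors.

    Returns a dict method-name -> MRResult (or None when a method failed,
    with the failure recorded under ``"<method>_error"``).  Deterministic
    given the seed: the two median bootstraps draw from independent child
    streams of one root seed.
    """
    ss = np.random.SeedSequence(seed)
    seeds = dict(zip(("simple_median", "weighted_median"), ss.spawn(2)))
    out: dict = {}
    runners = {
        "ivw": lambda: ivw(h, model=ivw_model),
        "simple_median": lambda: simple_median(h, n_boot, seeds["simple_median"]),
        "weighted_median": lambda: weighted_median(h, n_boot, seeds["weighted_median"]),
        "mr_egger": lambda: mr_egger(h),
    }
    for name in methods:
        if name not in runners:
            raise InvalidInputError(f"unknown method {name!r}; choose from {METHODS}")
        try:
            out[name] = runners[name]()
        except (InsufficientInstrumentsError, InvalidInputError) as exc:
            out[name] = None
            out[f"{name}_error"] = str(exc)
    return out


def two_stage_least_squares(
    genotypes, exposure, outcome, covariates=None
) -> tuple[float, float]:
    """Individual-level 2SLS causal estimate (the IVW cross-check).

    First stage: exposure on instruments (+ covariates); second stage:
    outcome on the fitted exposure (+ covariates).  SE uses the standard
    2SLS residuals (observed exposure in the residual, fitted in the
    bread).  Returns (estimate, se).
    """
    Gm = np.asarray(genotypes, dtype=float)
    if Gm.ndim == 1:
        Gm = Gm[:, None]
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = Gm.shape[0]
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    ones = np.ones((n, 1))
    Z = np.column_stack([ones, Gm] + ([C] if C is not None else []))
    first, *_ = np.linalg.lstsq(Z, x, rcond=None)
    xhat = Z @ first
    X2 = np.column_stack([ones, xhat[:, None]] + ([C] if C is not None else []))
    beta, *_ = np.linalg.lstsq(X2, y, rcond=None)
    # residuals with the *observed* exposure (proper 2SLS variance)
    Xobs = np.column_stack([ones, x[:, None]] + ([C] if C is not None else []))
    resid = y - Xobs @ beta
    dof = n - X2.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X2.T @ X2)
    return float(beta[1]), float(np.sqrt(cov[1, 1]))
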