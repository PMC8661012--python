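"""Registered simulation scenarios and the simulation-study harness.

Each scenario fixes a generative causal structure (valid instruments,
balanced or directional pleiotropy, weak instruments, reverse causation,
winner's-curse comparison) and the harness runs the full one-sample
pipeline — simulate, GWAS, instrument selection, F screening, harmonize,
estimate — on many replicates, reporting per-method bias, empirical SE,
mean model SE, 95% CI coverage and rejection rate at 0.05.

Scenario settings are design-time choices: instrument effects are sized so
discovery at p < 5e-6 is essentially certain where the scenario is about
estimator behaviour (keeping winner's curse negligible), and deliberately
marginal where selection itself is under study.  Cohort sizes are chosen
for desk-scale replicate counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .mr import harmonize, ivw, two_stage_least_squares
from .pipeline import DirectionSpec, run_direction
from .simulate import (
    ConfounderSpec,
    GenotypeMatrix,
    SimulationConfig,
    simulate_cohort,
)

__all__ = [
    "SCENARIOS",
    "scenario_config",
    "simulation_study",
    "headline_config",
    "bidirectional_discrimination",
    "ivw_2sls_gap",
]

_DEFAULT_METHODS = ("ivw", "simple_median", "weighted_median", "mr_egger")


@dataclass(frozen=True)
class _Scenario:
    """A registered scenario: config factory plus its analysis settings."""

    name: str
    make_config: object  # callable(rng, **overrides) -> SimulationConfig
    truth: float | None  # generative causal effect on the estimand scale
    truth_intercept: float | None = None  # generative mean pleiotropy
    analysis_direction: str = "forward"
    p_threshold: float = 5e-6


def _valid_ivs(rng: np.random.Generator, *, theta: float = 0.2, n: int = 10_000):
    """Five strong valid instruments, continuous outcome, no pleiotropy.

    Per-instrument partial F is in the hundreds at the default n, so
    discovery at p < 5e-6 is essentially certain and selection does not
    distort the estimand.
    """
    return SimulationConfig(
        n_individuals=n,
        n_snps=8,
        n_instruments=5,
        maf_range=(0.1, 0.5),
        instrument_effects=np.full(5, 0.5),
        causal_effect=theta,
        outcome_kind="continuous",
        seed=int(rng.integers(2**31)),
    )


def _balanced_pleiotropy(rng: np.random.Generator, *, theta: float = 0.2, n: int = 10_000):
    """Twenty instruments, every alpha_j ~ N(0, 0.15): mean pleiotropy zero."""
    return SimulationConfig(
        n_individuals=n,
        n_snps=20,
        n_instruments=20,
        maf_range=(0.3, 0.3),
        instrument_effects=rng.uniform(0.3, 1.0, size=20),
        pleiotropy_effects=rng.normal(0.0, 0.15, size=20),
        causal_effect=theta,
        outcome_kind="continuous",
        seed=int(rng.integers(2**31)),
    )


#: directional-pleiotropy scenario shape: 50 instruments, 22 invalid (44% of
#: instruments, expected < 50% of inverse-variance weight), constant positive
#: direct effect on the invalid ones, invalid set drawn independently of the
#: instrument strengths (InSIDE holds by construction).
_DIR_J = 50
_DIR_N_INVALID = 22
_DIR_ALPHA = 0.3


def _directional_pleiotropy_inside(
    rng: np.random.Generator, *, theta: float = 0.2, n: int = 20_000
):
    alpha = np.zeros(_DIR_J)
    alpha[rng.choice(_DIR_J, _DIR_N_INVALID, replace=False)] = _DIR_ALPHA
    return SimulationConfig(
        n_individuals=n,
        n_snps=_DIR_J,
        n_instruments=_DIR_J,
        maf_range=(0.3, 0.3),
        instrument_effects=rng.uniform(0.2, 1.0, size=_DIR_J),
        pleiotropy_effects=alpha,
        causal_effect=theta,
        outcome_kind="continuous",
        seed=int(rng.integers(2**31)),
    )


def _weak_instruments(rng: np.random.Generator, *, theta: float = 0.2, n: int = 2_000):
    """Mixture of weak and strong instruments so the F >= 10 screen bites."""
    return SimulationConfig(
        n_individuals=n,
        n_snps=6,
        n_instruments=6,
        maf_range=(0.3, 0.3),
        instrument_effects=np.array([0.06, 0.08, 0.10, 0.45, 0.50, 0.55]),
        causal_effect=theta,
        outcome_kind="continuous",
        seed=int(rng.integers(2**31)),
    )


def _reverse_causation(rng: np.random.Generator, *, theta_rev: float = 0.7, n: int = 6_000):
    """Binary trait from its own instruments; continuous trait responds to it."""
    return SimulationConfig(
        n_individuals=n,
        n_snps=16,
        n_instruments=5,
        maf_range=(0.2, 0.4),
        instrument_effects=np.full(5, 0.5),
        outcome_instrument_effects=np.full(6, 0.35),
        reverse_effect=theta_rev,
        outcome_intercept=-2.4,
        mode="reverse",
        seed=int(rng.integers(2**31)),
    )


def _winner_curse(rng: np.random.Generator, *, theta: float = 0.2, n: int = 8_000):
    """Marginal instruments plus an unmeasured confounder: the one-sample
    winner's-curse setting.

    With a shared confounder the sampling errors of the exposure and
    outcome GWAS coefficients are positively correlated; selecting SNPs on
    the exposure scan in the *same* sample then preferentially picks
    replicates whose outcome coefficient errs in the confounded direction,
    biasing IVW toward the crude association.  Selecting in one half and
    estimating in the other removes the correlation, hence the bias.
    Per-SNP discovery power is ~0.4 at p < 5e-6 so selection genuinely
    distorts; 30 instruments keep enough selections per replicate.
    """
    conf = (ConfounderSpec("u", effect_on_exposure=1.0, effect_on_outcome=1.0),)
    return SimulationConfig(
        n_individuals=n,
        n_snps=30,
        n_instruments=30,
        maf_range=(0.3, 0.3),
        instrument_effects=np.full(30, 0.11),
        causal_effect=theta,
        confounder_spec=conf,
        outcome_kind="continuous",
        seed=int(rng.integers(2**31)),
    )


SCENARIOS = {
    "valid_ivs": _Scenario("valid_ivs", _valid_ivs, truth=0.2),
    "balanced_pleiotropy": _Scenario("balanced_pleiotropy", _balanced_pleiotropy, truth=0.2, truth_intercept=0.0),
    "directional_pleiotropy_inside": _Scenario(
        "directional_pleiotropy_inside",
        _directional_pleiotropy_inside,
        truth=0.2,
        truth_intercept=_DIR_N_INVALID * _DIR_ALPHA / _DIR_J,
    ),
    "weak_instruments": _Scenario(
        "weak_instruments", _weak_instruments, truth=0.2, p_threshold=1e-3
    ),
    "reverse_causation": _Scenario(
        "reverse_causation", _reverse_causation, truth=None, analysis_direction="reverse"
    ),
    "winner_curse_split_compare": _Scenario(
        "winner_curse_split_compare", _winner_curse, truth=0.2, p_threshold=5e-6
    ),
}


def scenario_config(name: str, seed, **overrides) -> SimulationConfig:
    """One replicate's generative config for a registered scenario."""
    if name not in SCENARIOS:
        raise InvalidParameterError(
            f"unknown scenario {name!r}; registered: {sorted(SCENARIOS)}"
        )
    rng = np.random.default_rng(seed)
    sc = SCENARIOS[name]
    if "theta" in overrides and sc.truth is None:
        overrides.pop("theta")
    return sc.make_config(rng, **overrides)


def _direction_spec_for(
    sc: _Scenario, cfg: SimulationConfig, methods, n_boot: int, seed: int
) -> DirectionSpec:
    if sc.analysis_direction == "forward":
        return DirectionSpec(
            exposure=cfg.exposure_name,
            outcome=cfg.outcome_name,
            exposure_kind="continuous",
            outcome_kind=cfg.outcome_kind,
            p_threshold=sc.p_threshold,
            methods=tuple(methods),
            n_boot=n_boot,
            seed=seed,
        )
    return DirectionSpec(
        exposure=cfg.outcome_name,
        outcome=cfg.exposure_name,
        exposure_kind="binary",
        outcome_kind="continuous",
        p_threshold=sc.p_threshold,
        methods=tuple(methods),
        n_boot=n_boot,
        seed=seed,
    )


def _split_sample_ivw(
    G: GenotypeMatrix, pheno: pd.DataFrame, spec: DirectionSpec, rng: np.random.Generator
):
    """Split-sample IVW: select instruments in one half, estimate in the other."""
    n = G.n_individuals
    perm = rng.permutation(n)
    half_a = np.zeros(n, dtype=bool)
    half_a[perm[: n // 2]] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        res_a = run_direction(
            G.take_individuals(half_a), pheno.loc[half_a].reset_index(drop=True), spec
        )
    if res_a.status != "ok":
        return None
    G_b = G.take_individuals(~half_a)
    pheno_b = pheno.loc[~half_a].reset_index(drop=True)
    from .assoc import gwas

    keep = np.isin(G_b.snp_ids, res_a.instruments.snp_ids)
    exposure = pheno_b[spec.exposure].to_numpy(float)
    outcome = pheno_b[spec.outcome].to_numpy(float)
    exp_model = "linear" if spec.exposure_kind == "continuous" else "logistic"
    out_model = "linear" if spec.outcome_kind == "continuous" else "logistic"
    exp_stats = gwas(G_b.take_snps(keep), exposure, model=exp_model)
    out_stats = gwas(G_b.take_snps(keep), outcome, model=out_model)
    exp_stats = exp_stats[exp_stats["testable"]]
    if len(exp_stats) == 0:
        return None
    instr = exp_stats.rename(
        columns={"beta": "beta_exposure", "se": "se_exposure"}
    )[["snp_id", "beta_exposure", "se_exposure", "effect_allele"]]
    h = harmonize(instr, out_stats, outcome_binary=spec.outcome_kind == "binary")
    return ivw(h)


def simulation_study(
    scenarios,
    n_replicates: int,
    seed,
    methods=_DEFAULT_METHODS,
    n_boot: int = 500,
    overrides: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run registered scenarios and summarize estimator behaviour.

    Returns ``(metrics, replicates)``: one metrics row per scenario x
    method (mean bias, empirical SE, mean model SE, 95% CI coverage,
    rejection rate at 0.05, plus intercept summaries for MR-Egger), and the
    replicate-level estimates for audit.  ``n_boot`` is reduced from the
    single-study default because the median SE enters only through
    replicate-level CI/p decisions here.
    """
    if isinstance(scenarios, str):
        scenarios = [scenarios]
    for name in scenarios:
        if name not in SCENARIOS:
            raise InvalidParameterError(
                f"unknown scenario {name!r}; registered: {sorted(SCENARIOS)}"
            )
    overrides = dict(overrides or {})
    root = np.random.SeedSequence(seed)
    rep_rows = []
    for name, sc_seed in zip(scenarios, root.spawn(len(scenarios))):
        sc = SCENARIOS[name]
        for rep, child in enumerate(sc_seed.spawn(n_replicates)):
            rng = np.random.default_rng(child)
            cfg = sc.make_config(rng, **overrides)
            spec = _direction_spec_for(sc, cfg, methods, n_boot, int(rng.integers(2**31)))
            G, pheno = simulate_cohort(cfg)
            with warnings.catch_warnings():
                # empty-selection warnings are expected in weak/split scenarios
                warnings.simplefilter("ignore", UserWarning)
                res = run_direction(G, pheno, spec)
            base = {"scenario": name, "replicate": rep, "status": res.status}
            if res.status != "ok":
                rep_rows.append({**base, "method": None})
                continue
            if name == "winner_curse_split_compare":
                split = _split_sample_ivw(G, pheno, spec, rng)
                same = res.result("ivw")
                if same is not None:
                    rep_rows.append(
                        {**base, "method": "ivw_same_sample",
                         "estimate": same.estimate, "se": same.se,
                         "ci_low": same.ci_low, "ci_high": same.ci_high, "p": same.p}
                    )
                if split is not None:
                    rep_rows.append(
                        {**base, "method": "ivw_split_sample",
                         "estimate": split.estimate, "se": split.se,
                         "ci_low": split.ci_low, "ci_high": split.ci_high, "p": split.p}
                    )
                continue
            for m in methods:
                r = res.result(m)
                if r is None:
                    continue
                row = {
                    **base,
                    "method": m,
                    "estimate": r.estimate,
                    "se": r.se,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p,
                }
                if r.intercept is not None:
                    row["intercept"] = r.intercept
                    row["intercept_p"] = r.intercept_p
                rep_rows.append(row)
    replicates = pd.DataFrame(rep_rows)

    metric_rows = []
    for name in scenarios:
        sc = SCENARIOS[name]
        sub = replicates[(replicates["scenario"] == name) & replicates["method"].notna()]
        for m in sorted(sub["method"].dropna().unique()):
            ms = sub[sub["method"] == m]
            truth = sc.truth if sc.truth is None else overrides.get("theta", sc.truth)
            row = {
                "scenario": name,
                "method": m,
                "n_replicates": len(ms),
                "mean_estimate": ms["estimate"].mean(),
                "empirical_se": ms["estimate"].std(ddof=1),
                "mean_model_se": ms["se"].mean(),
                "rejection_rate_05": (ms["p"] < 0.05).mean(),
            }
            if truth is not None:
                row["truth"] = truth
                row["mean_bias"] = ms["estimate"].mean() - truth
                row["coverage_95"] = (
                    (ms["ci_low"] <= truth) & (truth <= ms["ci_high"])
                ).mean()
            if "intercept" in ms.columns and ms["intercept"].notna().any():
                row["mean_intercept"] = ms["intercept"].mean()
                row["intercept_rejection_05"] = (ms["intercept_p"] < 0.05).mean()
                row["truth_intercept"] = sc.truth_intercept
            metric_rows.append(row)
    return pd.DataFrame(metric_rows), replicates


# ---------------------------------------------------------------------------
# Headline bi-directional cohort and discrimination experiment
# ---------------------------------------------------------------------------

def headline_config(direction: str = "forward", n: int = 6_000, seed: int = 0) -> SimulationConfig:
    """Cohort emulating the study's shape: a continuous platelet-like
    exposure with 8 instruments, a binary hypertension-like outcome with 6
    instruments of its own, plus 5 null SNPs.

    ``direction="forward"`` puts a positive platelet->hypertension effect
    (theta = 0.15 log-odds per exposure unit) and no reverse effect;
    ``"reverse"`` the mirror (theta_rev = 0.7 exposure units per case);
    ``"null"`` neither.  Intercepts put prevalence near 0.25.

    The causal effect sizes are chosen so that the aggregate IVW test in
    the causal direction is well powered (z ~ sqrt(J) per-SNP z) while each
    SNP's *mediated* association with the downstream trait stays below the
    p < 5e-6 discovery threshold: otherwise the acausal direction's
    exposure scan would co-opt the other trait's instruments (whose
    mediated z sits near the selection boundary), which is the known
    instrument-overlap failure mode of bi-directional MR.  The emulated
    study's two instrument sets were disjoint genes, so the generator keeps
    them separable too.
    """
    base = dict(
        n_individuals=n,
        n_snps=19,
        n_instruments=8,
        maf_range=(0.2, 0.4),
        instrument_effects=np.full(8, 0.5),
        outcome_instrument_effects=np.full(6, 0.35),
        seed=seed,
    )
    if direction == "forward":
        return SimulationConfig(
            causal_effect=0.15, outcome_intercept=-2.7, mode="forward", **base
        )
    if direction == "reverse":
        return SimulationConfig(
            reverse_effect=0.7, outcome_intercept=-2.4, mode="reverse", **base
        )
    if direction == "null":
        return SimulationConfig(
            causal_effect=0.0, outcome_intercept=-2.4, mode="forward", **base
        )
    raise InvalidParameterError("direction must be forward|reverse|null")


def headline_direction_specs(seed: int = 0, methods=_DEFAULT_METHODS, n_boot: int = 2000):
    """The two DirectionSpecs for the headline bi-directional analysis."""
    forward = DirectionSpec(
        exposure="platelet",
        outcome="hypertension",
        exposure_kind="continuous",
        outcome_kind="binary",
        methods=tuple(methods),
        n_boot=n_boot,
        seed=seed,
    )
    reverse = DirectionSpec(
        exposure="hypertension",
        outcome="platelet",
        exposure_kind="binary",
        outcome_kind="continuous",
        methods=tuple(methods),
        n_boot=n_boot,
        seed=seed + 1,
    )
    return forward, reverse


def bidirectional_discrimination(
    direction: str, n_seeds: int = 100, seed: int = 0, n: int = 6_000
) -> pd.DataFrame:
    """Fraction of seeds where each direction's IVW is significant at 0.05.

    Under a one-direction generative truth, the causal direction should be
    detected at high rate and the acausal direction at roughly the nominal
    false-positive rate.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(root.spawn(n_seeds)):
        rng = np.random.default_rng(child)
        cfg = headline_config(direction, n=n, seed=int(rng.integers(2**31)))
        G, pheno = simulate_cohort(cfg)
        fwd_spec, rev_spec = headline_direction_specs(
            seed=int(rng.integers(2**31)), methods=("ivw",), n_boot=0
        )
        fwd = run_direction(G, pheno, fwd_spec)
        rev = run_direction(G, pheno, rev_spec)
        rows.append(
            {
                "replicate": rep,
                "forward_status": fwd.status,
                "reverse_status": rev.status,
                "forward_p": fwd.result("ivw").p if fwd.status == "ok" else np.nan,
                "reverse_p": rev.result("ivw").p if rev.status == "ok" else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ivw_2sls_gap(n: int = 20_000, seed: int = 0, theta: float = 0.2) -> float:
    """|IVW - 2SLS| on one valid-instrument continuous-outcome cohort.

    IVW comes from the pipeline's summary statistics, 2SLS from the
    individual-level data with the same selected instruments; with
    independent valid instruments the two converge, so the gap measures
    finite-sample agreement.
    """
    rng = np.random.default_rng(seed)
    cfg = _valid_ivs(rng, theta=theta, n=n)
    G, pheno = simulate_cohort(cfg)
    spec = DirectionSpec(
        exposure=cfg.exposure_name,
        outcome=cfg.outcome_name,
        exposure_kind="continuous",
        outcome_kind="continuous",
        methods=("ivw",),
        n_boot=0,
        seed=int(rng.integers(2**31)),
    )
    res = run_direction(G, pheno, spec)
    if res.status != "ok":
        raise RuntimeError("valid-IV cohort unexpectedly yielded no instruments")
    keep = np.isin(G.snp_ids, res.instruments.snp_ids)
    est_2sls, _ = two_stage_least_squares(
        G.dosages()[:, keep],
        pheno[cfg.exposure_name].to_numpy(float),
        pheno[cfg.outcome_name].to_numpy(float),
    )
    return abs(res.result("ivw").estimate - est_2sls)
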