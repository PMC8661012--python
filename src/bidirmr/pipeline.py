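"""End-to-end orchestration of the bi-directional MR analysis.

One direction = exposure GWAS -> p-value instrument selection -> partial-F
weak-instrument screen -> outcome GWAS on the selected SNPs -> harmonize ->
the four summary-statistic estimators.  ``run_bidirectional`` runs both
directions on one cohort (the one-sample design: instruments are selected
in the same sample used for estimation) and adds the crude multivariable
regressions of each trait on the other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .assoc import (
    InstrumentSet,
    fit_linear,
    fit_logistic,
    gwas,
    screen_instruments,
    select_instruments,
)
from .errors import InvalidInputError, NoInstrumentsError
from .mr import METHODS, MRResult, harmonize, run_all_methods
from .qc import QCReport
from .simulate import COVARIATE_NAMES, GenotypeMatrix

__all__ = [
    "DirectionSpec",
    "DirectionResult",
    "StudyReport",
    "crude_regressions",
    "run_direction",
    "run_bidirectional",
    "render_report",
]


@dataclass(frozen=True)
class DirectionSpec:
    """Configuration for one causal direction of the analysis."""

    exposure: str
    outcome: str
    exposure_kind: str  # "continuous" | "binary"
    outcome_kind: str
    covariates: tuple = ()
    p_threshold: float = 5e-6
    f_threshold: float = 10.0
    methods: tuple = METHODS
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure == self.outcome:
            raise InvalidInputError("exposure and outcome must differ")
        if self.exposure in self.covariates or self.outcome in self.covariates:
            raise InvalidInputError("covariates must exclude both traits")
        for kind in (self.exposure_kind, self.outcome_kind):
            if kind not in ("continuous", "binary"):
                raise InvalidInputError("trait kinds must be continuous|binary")


@dataclass
class DirectionResult:
    """Everything one direction produced, or its failure diagnostics."""

    spec: DirectionSpec
    status: str  # "ok" | "infeasible"
    exposure_gwas: pd.DataFrame | None = None
    instruments: InstrumentSet | None = None
    outcome_gwas: pd.DataFrame | None = None
    harmonized: pd.DataFrame | None = None
    results: dict = field(default_factory=dict)
    message: str = ""

    def result(self, method: str) -> MRResult | None:
        return self.results.get(method)


@dataclass
class StudyReport:
    """Aggregate of QC, both direction blocks and the crude regressions."""

    forward: DirectionResult
    reverse: DirectionResult
    crude: dict
    qc: QCReport | None = None
    provenance: dict = field(default_factory=dict)


def _trait_columns(pheno: pd.DataFrame, names) -> np.ndarray:
    missing = [n for n in names if n not in pheno.columns]
    if missing:
        raise InvalidInputError(f"phenotype table missing columns: {missing}")
    return pheno.loc[:, list(names)].to_numpy(dtype=float)


def crude_regressions(
    pheno: pd.DataFrame,
    exposure: str = "platelet",
    outcome: str = "hypertension",
    covariates=COVARIATE_NAMES,
) -> dict[str, pd.DataFrame]:
    """Crude adjusted association in both directions (no genetics).

    Fits a logistic regression of the binary trait on the continuous trait
    plus covariates, and a linear regression of the continuous trait on the
    binary trait plus covariates.  Returns coefficient tables (term, beta,
    se, p) keyed ``"logistic"`` and ``"linear"``.
    """
    covariates = tuple(covariates)
    cols = _trait_columns(pheno, (exposure, outcome) + covariates)
    x, y, C = cols[:, 0], cols[:, 1], cols[:, 2:]
    complete = ~np.isnan(cols).any(axis=1)
    x, y, C = x[complete], y[complete], C[complete]

    logit = fit_logistic(y, np.column_stack([x, C]))
    linear = fit_linear(x, np.column_stack([y, C]))
    terms_fwd = ("intercept", exposure) + covariates
    terms_rev = ("intercept", outcome) + covariates
    return {
        "logistic": pd.DataFrame(
            {"term": terms_fwd, "beta": logit.beta, "se": logit.se, "p": logit.p}
        ),
        "linear": pd.DataFrame(
            {"term": terms_rev, "beta": linear.beta, "se": linear.se, "p": linear.p}
        ),
    }


def run_direction(
    G: GenotypeMatrix, pheno: pd.DataFrame, spec: DirectionSpec
) -> DirectionResult:
    """Run one causal direction on a QC'd cohort.

    The weak-instrument F screen always uses Gaussian regression of the
    exposure on the SNP after covariate adjustment, also when the exposure
    is binary.  A direction with no surviving instruments is returned as
    ``status="infeasible"`` with diagnostics instead of raising, so the
    other direction is unaffected.
    """
    if not np.array_equal(
        np.asarray(pheno["individual_id"]), G.individual_ids
    ):
        raise InvalidInputError("phenotype rows must align with genotype individuals")
    exposure = _trait_columns(pheno, [spec.exposure])[:, 0]
    outcome = _trait_columns(pheno, [spec.outcome])[:, 0]
    covars = (
        _trait_columns(pheno, spec.covariates) if spec.covariates else None
    )
    exp_model = "linear" if spec.exposure_kind == "continuous" else "logistic"
    out_model = "linear" if spec.outcome_kind == "continuous" else "logistic"

    exposure_stats = gwas(G, exposure, covars, model=exp_model)
    candidates = select_instruments(exposure_stats, spec.p_threshold)
    try:
        instruments = screen_instruments(
            candidates,
            G,
            exposure,
            covars,
            f_threshold=spec.f_threshold,
            p_threshold=spec.p_threshold,
        )
    except NoInstrumentsError as exc:
        return DirectionResult(
            spec=spec,
            status="infeasible",
            exposure_gwas=exposure_stats,
            message=str(exc),
        )
    keep = np.isin(G.snp_ids, instruments.snp_ids)
    outcome_stats = gwas(G.take_snps(keep), outcome, covars, model=out_model)
    try:
        harmonized = harmonize(
            instruments, outcome_stats, outcome_binary=spec.outcome_kind == "binary"
        )
    except InvalidInputError as exc:
        return DirectionResult(
            spec=spec,
            status="infeasible",
            exposure_gwas=exposure_stats,
            instruments=instruments,
            outcome_gwas=outcome_stats,
            message=str(exc),
        )
    results = run_all_methods(
        harmonized, seed=spec.seed, n_boot=spec.n_boot, methods=spec.methods
    )
    return DirectionResult(
        spec=spec,
        status="ok",
        exposure_gwas=exposure_stats,
        instruments=instruments,
        outcome_gwas=outcome_stats,
        harmonized=harmonized.table,
        results=results,
    )


def run_bidirectional(
    G: GenotypeMatrix,
    pheno: pd.DataFrame,
    forward: DirectionSpec,
    reverse: DirectionSpec,
    qc_report: QCReport | None = None,
    crude_covariates=None,
) -> StudyReport:
    """Run both causal directions plus the crude adjusted regressions."""
    fwd = run_direction(G, pheno, forward)
    rev = run_direction(G, pheno, reverse)
    crude: dict = {}
    crude_cov = (
        tuple(crude_covariates)
        if crude_covariates is not None
        else tuple(c for c in COVARIATE_NAMES if c in pheno.columns)
    )
    try:
        cont, binry = (
            (forward.exposure, forward.outcome)
            if forward.exposure_kind == "continuous"
            else (forward.outcome, forward.exposure)
        )
        crude = crude_regressions(pheno, cont, binry, crude_cov)
    except (InvalidInputError, Exception) as exc:  # crude block is best-effort
        crude = {"error": str(exc)}
    return StudyReport(
        forward=fwd,
        reverse=rev,
        crude=crude,
        qc=qc_report,
        provenance={
            "software": f"bidirmr {_version}",
            "forward_seed": forward.seed,
            "reverse_seed": reverse.seed,
            "p_threshold": forward.p_threshold,
            "f_threshold": forward.f_threshold,
        },
    )


def _direction_dict(d: DirectionResult) -> dict:
    out = {
        "exposure": d.spec.exposure,
        "outcome": d.spec.outcome,
        "status": d.status,
        "message": d.message,
        "n_instruments": len(d.instruments) if d.instruments is not None else 0,
        "instruments": d.instruments.table.to_dict("records")
        if d.instruments is not None
        else [],
        "harmonized": d.harmonized.to_dict("records")
        if d.harmonized is not None
        else [],
        "results": {},
    }
    for name, res in d.results.items():
        out["results"][name] = res.to_dict() if isinstance(res, MRResult) else res
    return out


def render_report(report: StudyReport, format: str = "json", precision: int = 3):
    """Render a study report as a dict ("json"), TSV or markdown table.

    The json form is lossless for the per-method numbers; markdown mirrors
    the conventional four-method-per-direction causal-estimate table with
    one intercept row under MR-Egger.
    """
    if format == "json":
        out = {
            "provenance": report.provenance,
            "forward": _direction_dict(report.forward),
            "reverse": _direction_dict(report.reverse),
            "crude": {
                k: (v.to_dict("records") if isinstance(v, pd.DataFrame) else v)
                for k, v in report.crude.items()
            },
        }
        if report.qc is not None:
            out["qc"] = report.qc.to_dict()
        return out

    rows = []
    for label, block in (("forward", report.forward), ("reverse", report.reverse)):
        header = f"{block.spec.outcome} as outcome and {block.spec.exposure} as exposure"
        for name in block.spec.methods:
            res = block.result(name)
            if res is None:
                rows.append((label, header, name, None))
                continue
            rows.append((label, header, name, res))
            if res.intercept is not None:
                rows.append((label, header, "(Intercept)", res))

    if format == "tsv":
        records = []
        for label, _, name, res in rows:
            if res is None:
                records.append({"direction": label, "method": name, "status": "failed"})
            elif name == "(Intercept)":
                records.append(
                    {
                        "direction": label,
                        "method": name,
                        "estimate": res.intercept,
                        "se": res.intercept_se,
                        "ci_low": res.intercept_ci_low,
                        "ci_high": res.intercept_ci_high,
                        "p": res.intercept_p,
                        "status": "ok",
                    }
                )
            else:
                records.append(
                    {
                        "direction": label,
                        "method": name,
                        "estimate": res.estimate,
                        "se": res.se,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p": res.p,
                        "status": "ok",
                    }
                )
        return pd.DataFrame(records).to_csv(sep="\t", index=False)

    if format == "markdown":
        fmt = f"{{:.{precision}f}}"
        lines = []
        current = None
        for label, header, name, res in rows:
            if header != current:
                lines.append(f"\n**{header}**\n")
                lines.append("| Method | Estimate | Standard error | 95% CI | P-value |")
                lines.append("|---|---|---|---|---|")
                current = header
            if res is None:
                lines.append(f"| {name} | failed | | | |")
            elif name == "(Intercept)":
                lines.append(
                    f"| (Intercept) | {fmt.format(res.intercept)} | "
                    f"{fmt.format(res.intercept_se)} | "
                    f"[{fmt.format(res.intercept_ci_low)}, {fmt.format(res.intercept_ci_high)}] | "
                    f"{fmt.format(res.intercept_p)} |"
                )
            else:
                lines.append(
                    f"| {name} | {fmt.format(res.estimate)} | {fmt.format(res.se)} | "
                    f"[{fmt.format(res.ci_low)}, {fmt.format(res.ci_high)}] | "
                    f"{fmt.format(res.p)} |"
                )
        return "\n".join(lines)

    raise InvalidInputError("format must be json|tsv|markdown")


def report_to_json(report: StudyReport) -> str:
    return json.dumps(render_report(report, "json"), indent=2, default=float)
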