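"""Synthetic cohort generator for one-sample Mendelian randomization studies.

Generates individual-level genotype/phenotype cohorts with the causal
structure MR assumes: biallelic SNPs in Hardy-Weinberg equilibrium, a
continuous platelet-like exposure driven by a handful of instrument SNPs
plus confounders, and a binary hypertension-like outcome generated through
a logistic link with a causal exposure effect ``theta`` and optional direct
(pleiotropic) SNP effects ``alpha_j``.  A reverse generative mode produces a
binary trait from its own instruments and a continuous trait that responds
to it, so both causal directions are testable with known ground truth.

Column layout of the simulated SNP panel (by construction, documented so
scenario code can address SNP roles by index):

* columns ``0 .. n_instruments-1`` — exposure instruments (effects
  ``instrument_effects``, optional pleiotropy ``alpha_j``);
* the next ``len(outcome_instrument_effects)`` columns — SNPs acting
  directly on the binary trait (the reverse-direction instruments);
* remaining columns — null SNPs.

Randomness: one root seed, split per stage by a fixed derivation order
(``numpy.random.SeedSequence.spawn``), so each stage is independently
reproducible and the full cohort is bit-identical for a given config+seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "GenotypeMatrix",
    "ConfounderSpec",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_ld_block_genotypes",
    "inject_missingness",
    "simulate_traits",
    "simulate_cohort",
    "default_covariate_specs",
]

#: Names of the nine measured covariates carried by the cohort phenotype
#: table (sex, age and seven routine blood-panel measurements).
COVARIATE_NAMES = (
    "sex",
    "age",
    "fasting_glucose",
    "hematocrit",
    "triglyceride",
    "hdl_cholesterol",
    "hemoglobin",
    "rbc_count",
    "wbc_count",
)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x SNPs additive genotype calls with per-SNP metadata.

    ``calls`` is a float array with values in {0, 1, 2} counting copies of
    the effect allele; missing calls are ``NaN``.  ``snp_meta`` carries one
    row per SNP with columns ``id, chrom, pos, effect_allele, other_allele``.
    """

    calls: np.ndarray
    snp_meta: pd.DataFrame
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=float)
        object.__setattr__(self, "calls", calls)
        ids = np.asarray(self.individual_ids)
        object.__setattr__(self, "individual_ids", ids)
        if calls.ndim != 2:
            raise InvalidInputError("calls must be a 2-D individuals x SNPs array")
        if calls.shape[0] != ids.shape[0]:
            raise InvalidInputError(
                f"{ids.shape[0]} individual ids for {calls.shape[0]} rows"
            )
        if calls.shape[1] != len(self.snp_meta):
            raise InvalidInputError(
                f"{len(self.snp_meta)} SNP meta rows for {calls.shape[1]} columns"
            )
        observed = calls[~np.isnan(calls)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise InvalidInputError("genotype calls must be 0, 1, 2 or missing")
        if len(set(self.snp_meta["id"])) != len(self.snp_meta):
            raise InvalidInputError("SNP ids must be unique")
        if len(set(ids.tolist())) != ids.shape[0]:
            raise InvalidInputError("individual ids must be unique")

    # -- shape helpers -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["id"].to_numpy()

    def individual_missing_fraction(self) -> np.ndarray:
        """Fraction of missing calls per individual."""
        return np.isnan(self.calls).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def take_individuals(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[mask], self.snp_meta, self.individual_ids[mask]
        )

    def take_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[:, mask],
            self.snp_meta.loc[np.asarray(mask)].reset_index(drop=True),
            self.individual_ids,
        )

    def dosages(self, impute_mean: bool = True) -> np.ndarray:
        """Genotype dosages with missing entries mean-imputed per SNP."""
        out = self.calls.copy()
        if impute_mean and np.isnan(out).any():
            col_mean = np.nanmean(out, axis=0)
            idx = np.where(np.isnan(out))
            out[idx] = np.take(col_mean, idx[1])
        return out


@dataclass(frozen=True)
class ConfounderSpec:
    """One confounder: its distribution and effects on both traits.

    The confounder affects the exposure linearly (``effect_on_exposure``,
    exposure units per confounder unit) and the outcome on its linear
    predictor scale (``effect_on_outcome``; log-odds per unit for a binary
    outcome).  ``binary=True`` draws a Bernoulli(``p``) indicator instead of
    a Normal(``mean``, ``sd``) variable.
    """

    name: str
    effect_on_exposure: float = 0.0
    effect_on_outcome: float = 0.0
    mean: float = 0.0
    sd: float = 1.0
    binary: bool = False
    p: float = 0.5

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.binary:
            return rng.binomial(1, self.p, size=n).astype(float)
        return rng.normal(self.mean, self.sd, size=n)


def default_covariate_specs() -> list[ConfounderSpec]:
    """Cosmetic covariate marginals resembling a Han-Chinese biobank cohort.

    Marginals (age ~ N(48.7, 11^2), sex ~ Bernoulli(0.498), routine blood
    panel measurements) make fixtures look like the real cohort; the values
    are cosmetic, not load-bearing.  Effects on both traits default to zero;
    callers set them to create confounding.
    """
    return [
        ConfounderSpec("sex", binary=True, p=0.498),
        ConfounderSpec("age", mean=48.7, sd=11.0),
        ConfounderSpec("fasting_glucose", mean=96.5, sd=21.0),
        ConfounderSpec("hematocrit", mean=43.6, sd=4.5),
        ConfounderSpec("triglyceride", mean=117.0, sd=91.0),
        ConfounderSpec("hdl_cholesterol", mean=53.1, sd=13.0),
        ConfounderSpec("hemoglobin", mean=13.95, sd=1.56),
        ConfounderSpec("rbc_count", mean=4.80, sd=0.52),
        ConfounderSpec("wbc_count", mean=6.10, sd=1.58),
    ]


def _resolve_pleiotropy(
    spec, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Resolve a pleiotropy spec to a length-k vector of alpha_j.

    Accepted forms: ``None`` (no pleiotropy), an explicit vector, or a
    distribution spec ``("balanced", sd)`` / ``("directional", mean, sd)``.
    """
    if spec is None:
        return np.zeros(k)
    if isinstance(spec, tuple) and spec and isinstance(spec[0], str):
        kind = spec[0]
        if kind == "none":
            return np.zeros(k)
        if kind == "balanced":
            (_, sd) = spec
            return rng.normal(0.0, float(sd), size=k)
        if kind == "directional":
            (_, mean, sd) = spec
            return rng.normal(float(mean), float(sd), size=k)
        raise InvalidParameterError(f"unknown pleiotropy kind {kind!r}")
    vec = np.asarray(spec, dtype=float)
    if vec.shape != (k,):
        raise InvalidParameterError(
            f"pleiotropy_effects has length {vec.size}, expected {k}"
        )
    return vec


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model parameters for one synthetic cohort.

    ``causal_effect`` (theta) is the exposure->outcome effect: log-odds per
    exposure unit when the outcome is binary, outcome units per exposure
    unit when continuous.  ``reverse_effect`` (theta_rev) is the
    outcome->exposure effect used only in ``mode="reverse"``; the two modes
    are mutually exclusive because the generator is acyclic.
    """

    n_individuals: int = 2000
    n_snps: int = 20
    n_instruments: int = 5
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_effects: Sequence[float] | None = None
    pleiotropy_effects: object = None
    outcome_instrument_effects: Sequence[float] = ()
    causal_effect: float = 0.0
    reverse_effect: float = 0.0
    confounder_spec: Sequence[ConfounderSpec] = field(default_factory=tuple)
    exposure_noise_sd: float = 1.0
    outcome_noise_sd: float = 1.0
    outcome_intercept: float = 0.0
    outcome_kind: str = "binary"
    mode: str = "forward"
    missing_rate_snp: float = 0.0
    missing_rate_individual: float = 0.0
    exposure_name: str = "platelet"
    outcome_name: str = "hypertension"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise InvalidParameterError("n_individuals and n_snps must be >= 1")
        if not 0 <= self.n_instruments <= self.n_snps:
            raise InvalidParameterError("need 0 <= n_instruments <= n_snps")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidParameterError("maf_range must lie within (0, 0.5]")
        if self.instrument_effects is not None:
            eff = np.asarray(self.instrument_effects, dtype=float)
            if eff.shape != (self.n_instruments,):
                raise InvalidParameterError(
                    "instrument_effects length must equal n_instruments"
                )
        n_out = len(np.atleast_1d(np.asarray(self.outcome_instrument_effects)))
        if self.n_instruments + n_out > self.n_snps:
            raise InvalidParameterError(
                "instrument + outcome-instrument SNPs exceed n_snps"
            )
        for rate in (self.missing_rate_snp, self.missing_rate_individual):
            if not 0.0 <= rate < 1.0:
                raise InvalidParameterError("missing rates must be in [0, 1)")
        if self.exposure_noise_sd < 0 or self.outcome_noise_sd < 0:
            raise InvalidParameterError("noise sds must be non-negative")
        if self.outcome_kind not in ("binary", "continuous"):
            raise InvalidParameterError("outcome_kind must be binary|continuous")
        if self.mode not in ("forward", "reverse"):
            raise InvalidParameterError("mode must be forward|reverse")
        if self.mode == "forward" and self.reverse_effect != 0.0:
            raise InvalidParameterError(
                "reverse_effect requires mode='reverse' (feedback loops are not modelled)"
            )
        if self.mode == "reverse" and self.causal_effect != 0.0:
            raise InvalidParameterError(
                "causal_effect requires mode='forward' (feedback loops are not modelled)"
            )
        if self.mode == "reverse" and self.outcome_kind != "binary":
            raise InvalidParameterError(
                "reverse mode generates a binary trait from its own instruments"
            )

    def resolved_instrument_effects(self) -> np.ndarray:
        if self.instrument_effects is None:
            return np.full(self.n_instruments, 0.5)
        return np.asarray(self.instrument_effects, dtype=float)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _default_snp_meta(m: int, prefix: str = "rs") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f"{prefix}{j + 1:05d}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": [(j + 1) * 5000 for j in range(m)],
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
        }
    )


def simulate_genotypes(
    n: int,
    snp_mafs: Sequence[float],
    seed,
    snp_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Draw n individuals' genotypes independently per SNP under HWE.

    Genotype probabilities per SNP with minor-allele frequency p are
    ((1-p)^2, 2p(1-p), p^2), i.e. Binomial(2, p) counts of the effect
    allele.  No missing values are produced at this stage.
    """
    mafs = np.asarray(snp_mafs, dtype=float)
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if mafs.ndim != 1 or mafs.size == 0:
        raise InvalidParameterError("snp_mafs must be a non-empty vector")
    if np.any(mafs <= 0.0) or np.any(mafs > 0.5):
        raise InvalidParameterError("all mafs must lie in (0, 0.5]")
    rng = _rng(seed)
    calls = rng.binomial(2, mafs, size=(n, mafs.size)).astype(float)
    if snp_meta is None:
        snp_meta = _default_snp_meta(mafs.size)
    ids = np.array([f"ind{i + 1:06d}" for i in range(n)])
    return GenotypeMatrix(calls, snp_meta, ids)


def simulate_ld_block_genotypes(
    n: int,
    snp_mafs: Sequence[float],
    seed,
    block_size: int = 4,
    rho: float = 0.9,
    snp_meta: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Genotypes with block-correlated dosages via a Gaussian copula.

    SNPs are grouped into consecutive blocks of ``block_size``; within a
    block, each of the two allele draws per individual uses latent
    equicorrelated Gaussians (pairwise correlation ``rho``) thresholded at
    the allele frequency, so dosage correlation is high within blocks and
    zero between blocks.  Marginal per-SNP frequencies are preserved, hence
    HWE holds marginally.  This mode exists to exercise the LD pruner.
    """
    mafs = np.asarray(snp_mafs, dtype=float)
    if np.any(mafs <= 0.0) or np.any(mafs > 0.5):
        raise InvalidParameterError("all mafs must lie in (0, 0.5]")
    if not 0.0 <= rho < 1.0:
        raise InvalidParameterError("rho must be in [0, 1)")
    if block_size < 1:
        raise InvalidParameterError("block_size must be >= 1")
    from scipy.stats import norm

    rng = _rng(seed)
    m = mafs.size
    calls = np.zeros((n, m))
    thresholds = norm.ppf(mafs)
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        width = stop - start
        # two independent gametes, each equicorrelated within the block
        for _gamete in range(2):
            shared = rng.normal(size=(n, 1))
            noise = rng.normal(size=(n, width))
            latent = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
            calls[:, start:stop] += latent < thresholds[start:stop]
    if snp_meta is None:
        snp_meta = _default_snp_meta(m)
    ids = np.array([f"ind{i + 1:06d}" for i in range(n)])
    return GenotypeMatrix(calls, snp_meta, ids)


def inject_missingness(
    G: GenotypeMatrix,
    snp_targets: dict | None = None,
    individual_targets: dict | None = None,
    seed=0,
) -> GenotypeMatrix:
    """Mask calls at the requested per-SNP / per-individual rates.

    Entries are masked independently; a call in a targeted row *and*
    column is missing if either draw fires.  The input is not modified.
    """
    snp_targets = snp_targets or {}
    individual_targets = individual_targets or {}
    for rate in list(snp_targets.values()) + list(individual_targets.values()):
        if not 0.0 <= rate < 1.0:
            raise InvalidParameterError("missingness rates must be in [0, 1)")
    snp_index = {s: j for j, s in enumerate(G.snp_ids)}
    ind_index = {s: i for i, s in enumerate(G.individual_ids)}
    for key in snp_targets:
        if key not in snp_index:
            raise KeyError(f"unknown SNP id {key!r}")
    for key in individual_targets:
        if key not in ind_index:
            raise KeyError(f"unknown individual id {key!r}")
    rng = _rng(seed)
    calls = G.calls.copy()
    for key, rate in snp_targets.items():
        j = snp_index[key]
        mask = rng.random(G.n_individuals) < rate
        calls[mask, j] = np.nan
    for key, rate in individual_targets.items():
        i = ind_index[key]
        mask = rng.random(G.n_snps) < rate
        calls[i, mask] = np.nan
    return GenotypeMatrix(calls, G.snp_meta, G.individual_ids)


def _draw_confounders(
    specs: Sequence[ConfounderSpec], n: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Draw confounder columns; returns (table, gamma_exposure, delta_outcome)."""
    cols = {}
    gamma = np.zeros(len(specs))
    delta = np.zeros(len(specs))
    for k, spec in enumerate(specs):
        cols[spec.name] = spec.draw(n, rng)
        gamma[k] = spec.effect_on_exposure
        delta[k] = spec.effect_on_outcome
    table = pd.DataFrame(cols, index=range(n))
    return table, gamma, delta


def simulate_traits(G: GenotypeMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Generate the phenotype table for a simulated genotype matrix.

    Forward mode: exposure ``X_i = sum_j beta_Xj g_ij + gamma'C_i + eps_i``
    with Gaussian noise; binary outcome ``Y_i ~ Bernoulli(logit^-1(
    intercept + theta X_i + sum_j alpha_j g_ij + direct SNP effects +
    delta'C_i))`` (continuous outcome swaps the Bernoulli for additive
    Gaussian noise).  Reverse mode: the binary trait comes first from its
    own instruments, and the continuous trait is ``theta_rev * Y`` plus its
    genetic component, confounders and noise.

    Returns a DataFrame with ``individual_id``, the two trait columns
    (named per config) and one column per confounder.
    """
    k = config.n_instruments
    m_out = len(np.atleast_1d(np.asarray(config.outcome_instrument_effects)))
    if G.n_snps < k + m_out:
        raise InvalidParameterError(
            f"G has {G.n_snps} SNPs; config requires at least {k + m_out}"
        )
    n = G.n_individuals
    ss = np.random.SeedSequence(config.seed)
    rng_conf, rng_noise, rng_pleio, rng_outcome = (
        _rng(child) for child in ss.spawn(4)
    )

    D = G.dosages(impute_mean=True)
    beta_x = config.resolved_instrument_effects()
    beta_out = np.asarray(config.outcome_instrument_effects, dtype=float).ravel()
    alpha = _resolve_pleiotropy(config.pleiotropy_effects, k, rng_pleio)

    conf, gamma, delta = _draw_confounders(config.confounder_spec, n, rng_conf)
    conf_x = conf.to_numpy() @ gamma if len(config.confounder_spec) else 0.0
    conf_y = conf.to_numpy() @ delta if len(config.confounder_spec) else 0.0

    g_instr = D[:, :k]
    g_out = D[:, k : k + m_out]
    genetic_x = g_instr @ beta_x if k else np.zeros(n)
    direct_y = (g_out @ beta_out if m_out else 0.0) + (
        g_instr @ alpha if k else 0.0
    )

    if config.mode == "forward":
        x = genetic_x + conf_x + rng_noise.normal(0.0, config.exposure_noise_sd, n)
        eta = config.outcome_intercept + config.causal_effect * x + direct_y + conf_y
        if config.outcome_kind == "binary":
            y = rng_outcome.binomial(1, expit(eta)).astype(float)
        else:
            y = eta + rng_outcome.normal(0.0, config.outcome_noise_sd, n)
    else:  # reverse: binary trait first, continuous trait responds to it
        eta = config.outcome_intercept + direct_y + conf_y
        y = rng_outcome.binomial(1, expit(eta)).astype(float)
        x = (
            genetic_x
            + config.reverse_effect * y
            + conf_x
            + rng_noise.normal(0.0, config.exposure_noise_sd, n)
        )

    out = pd.DataFrame({"individual_id": G.individual_ids})
    out[config.exposure_name] = x
    out[config.outcome_name] = y
    for name in conf.columns:
        out[name] = conf[name].to_numpy()
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate a full cohort: genotypes, optional missingness, traits.

    Seed derivation order (fixed): mafs, genotypes, missingness, traits.
    """
    ss = np.random.SeedSequence(config.seed)
    s_maf, s_geno, s_miss, s_traits = ss.spawn(4)
    lo, hi = config.maf_range
    mafs = _rng(s_maf).uniform(lo, hi, size=config.n_snps)
    G = simulate_genotypes(config.n_individuals, mafs, s_geno)
    traits = simulate_traits(G, replace(config, seed=s_traits.generate_state(1)[0] % (2**31)))
    if config.missing_rate_snp > 0 or config.missing_rate_individual > 0:
        snp_targets = (
            {s: config.missing_rate_snp for s in G.snp_ids}
            if config.missing_rate_snp > 0
            else {}
        )
        ind_targets = (
            {i: config.missing_rate_individual for i in G.individual_ids}
            if config.missing_rate_individual > 0
            else {}
        )
        G = inject_missingness(G, snp_targets, ind_targets, s_miss)
    return G, traits
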