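"""Genotype quality control: missingness, call rate, HWE, LD pruning.

Implements the standard GWAS QC cascade in its conventional order —
individual missingness, SNP call rate, Hardy-Weinberg equilibrium,
pairwise-r^2 LD pruning — with an auditable exclusion report.  Threshold
semantics follow the usual conventions: individuals with missingness
strictly above the cut-off and SNPs with call rate strictly below the
cut-off are removed; SNP pairs with r^2 strictly above the threshold are
pruned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidInputError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .simulate import GenotypeMatrix

__all__ = [
    "QCStage",
    "QCReport",
    "filter_individual_missingness",
    "filter_snp_call_rate",
    "hwe_exact_test",
    "hwe_chi2_test",
    "filter_hwe",
    "pairwise_r2",
    "ld_prune",
    "ld_audit",
    "run_qc",
]

#: Relative tolerance when comparing conditional probabilities in the
#: two-sided exact test; configurations whose probability exceeds the
#: observed one by less than this relative margin count as "no more
#: probable" so floating-point noise cannot flip exact mathematical ties.
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class QCStage:
    """One QC filter's outcome: what was removed, why, at which threshold."""

    axis: str  # "individual" | "snp"
    reason: str  # e.g. "missingness", "call_rate", "hwe", "ld_pruned"
    removed_ids: tuple
    thresholds: dict


@dataclass
class QCReport:
    """Aggregated exclusion tally across the QC cascade.

    Each removed item carries exactly one reason (the first triggering
    stage wins, because later stages only see survivors).
    """

    n_individuals_in: int
    n_snps_in: int
    n_individuals_out: int = 0
    n_snps_out: int = 0
    stages: list[QCStage] = field(default_factory=list)

    def add(self, stage: QCStage) -> None:
        self.stages.append(stage)

    @property
    def removed_individuals(self) -> pd.DataFrame:
        rows = [
            {"id": rid, "reason": s.reason}
            for s in self.stages
            if s.axis == "individual"
            for rid in s.removed_ids
        ]
        return pd.DataFrame(rows, columns=["id", "reason"])

    @property
    def removed_snps(self) -> pd.DataFrame:
        rows = [
            {"id": rid, "reason": s.reason}
            for s in self.stages
            if s.axis == "snp"
            for rid in s.removed_ids
        ]
        return pd.DataFrame(rows, columns=["id", "reason"])

    @property
    def thresholds_used(self) -> dict:
        out: dict = {}
        for s in self.stages:
            out.update(s.thresholds)
        return out

    @property
    def stage_order(self) -> list[str]:
        return [s.reason for s in self.stages]

    def validate_conservation(self) -> None:
        """Check n_in = n_out + removals on both axes."""
        if self.n_individuals_in != self.n_individuals_out + len(
            self.removed_individuals
        ):
            raise InvalidInputError("individual conservation violated in QC report")
        if self.n_snps_in != self.n_snps_out + len(self.removed_snps):
            raise InvalidInputError("SNP conservation violated in QC report")

    def to_dict(self) -> dict:
        return {
            "n_individuals_in": self.n_individuals_in,
            "n_individuals_out": self.n_individuals_out,
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "stage_order": self.stage_order,
            "thresholds_used": self.thresholds_used,
            "removed_individuals": self.removed_individuals.to_dict("records"),
            "removed_snps": self.removed_snps.to_dict("records"),
        }

    def summary(self) -> str:
        lines = [
            f"QC: {self.n_individuals_in} individuals, {self.n_snps_in} SNPs in"
        ]
        for s in self.stages:
            lines.append(
                f"  - {s.reason} ({s.axis}): removed {len(s.removed_ids)}"
                f"  [{', '.join(f'{k}={v}' for k, v in s.thresholds.items())}]"
            )
        lines.append(
            f"  retained {self.n_individuals_out} individuals, "
            f"{self.n_snps_out} SNPs"
        )
        return "\n".join(lines)


def _require_nonempty(G: GenotypeMatrix) -> None:
    if G.n_individuals == 0 or G.n_snps == 0:
        raise InvalidInputError("empty genotype matrix")


def filter_individual_missingness(
    G: GenotypeMatrix, max_missing: float = 0.05
) -> tuple[GenotypeMatrix, QCStage]:
    """Remove individuals whose missing-call fraction strictly exceeds the cut-off."""
    _require_nonempty(G)
    if not 0.0 <= max_missing < 1.0:
        raise InvalidParameterError("max_missing must be in [0, 1)")
    frac = G.individual_missing_fraction()
    keep = frac <= max_missing
    stage = QCStage(
        "individual",
        "missingness",
        tuple(G.individual_ids[~keep].tolist()),
        {"max_individual_missing": max_missing},
    )
    return G.take_individuals(keep), stage


def filter_snp_call_rate(
    G: GenotypeMatrix, min_call_rate: float = 0.97
) -> tuple[GenotypeMatrix, QCStage]:
    """Remove SNPs whose call rate (over current individuals) is strictly below the cut-off."""
    _require_nonempty(G)
    if not 0.0 < min_call_rate <= 1.0:
        raise InvalidParameterError("min_call_rate must be in (0, 1]")
    rate = G.snp_call_rate()
    keep = rate >= min_call_rate
    stage = QCStage(
        "snp",
        "call_rate",
        tuple(G.snp_ids[~keep].tolist()),
        {"min_call_rate": min_call_rate},
    )
    return G.take_snps(keep), stage


def hwe_exact_test(
    n_hom_ref: int, n_het: int, n_hom_alt: int, midp: bool = False
) -> float:
    """Two-sided conditional exact test of Hardy-Weinberg equilibrium.

    Given the observed genotype counts, conditions on the allele counts and
    sums the probabilities of all heterozygote counts no more probable than
    the observed one under the HWE conditional (hypergeometric-type)
    distribution.  Probabilities are built by the stable ratio recurrence
    over adjacent heterozygote counts.  ``midp`` halves the observed
    configuration's own contribution.

    Returns a p-value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(int(c) != c or c < 0 for c in counts):
        raise InvalidParameterError("genotype counts must be non-negative integers")
    n_hom_ref, n_het, n_hom_alt = (int(c) for c in counts)
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise InvalidParameterError("total genotype count must be >= 1")

    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0  # monomorphic: single attainable configuration

    # admissible het counts share the parity of the rare-allele count;
    # build the conditional distribution by the adjacent-count ratio
    # recurrence, in log space so long tails cannot overflow
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.empty(het_values.size)
    logp[0] = 0.0
    for idx in range(1, het_values.size):
        het = het_values[idx]
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        # log P(het) - log P(het - 2): one rare-hom and one common-hom
        # converted into two heterozygotes
        logp[idx] = logp[idx - 1] + np.log(
            4.0 * (hom_r + 1) * (hom_c + 1) / (het * (het - 1.0))
        )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()

    obs_idx = np.searchsorted(het_values, n_het)
    if obs_idx >= het_values.size or het_values[obs_idx] != n_het:
        raise InvalidParameterError(
            f"heterozygote count {n_het} impossible for rare allele count {n_rare}"
        )
    p_obs = probs[obs_idx]
    include = probs <= p_obs * (1.0 + _TIE_RTOL)
    p = probs[include].sum()
    if midp:
        p -= 0.5 * p_obs
    return float(min(p, 1.0))


def hwe_chi2_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-df chi-square HWE test (fast approximation, no continuity correction)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise InvalidParameterError("total genotype count must be >= 1")
    p = (2 * n_hom_alt + n_het) / (2.0 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    if np.any(exp == 0):
        return 1.0
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(column: np.ndarray) -> tuple[int, int, int]:
    observed = column[~np.isnan(column)]
    return (
        int((observed == 0).sum()),
        int((observed == 1).sum()),
        int((observed == 2).sum()),
    )


def filter_hwe(
    G: GenotypeMatrix, alpha: float = 1e-6, method: str = "exact"
) -> tuple[GenotypeMatrix, QCStage]:
    """Remove SNPs whose HWE test p-value is strictly below alpha."""
    _require_nonempty(G)
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError("alpha must be in (0, 1)")
    if method not in ("exact", "chi2"):
        raise InvalidParameterError("method must be exact|chi2")
    test = hwe_exact_test if method == "exact" else hwe_chi2_test
    keep = np.ones(G.n_snps, dtype=bool)
    for j in range(G.n_snps):
        counts = _genotype_counts(G.calls[:, j])
        if sum(counts) == 0:
            continue  # all-missing SNP: HWE undefined, leave for call-rate stage
        keep[j] = test(*counts) >= alpha
    stage = QCStage(
        "snp",
        "hwe",
        tuple(G.snp_ids[~keep].tolist()),
        {"hwe_alpha": alpha, "hwe_method": method},
    )
    return G.take_snps(keep), stage


def pairwise_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of genotype dosages (composite LD).

    Computed over pairwise-complete observations.  This is the unphased
    dosage r^2, not the EM-phased haplotype r^2.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise InvalidInputError("genotype vectors must have equal length")
    complete = ~np.isnan(g1) & ~np.isnan(g2)
    if complete.sum() < 2:
        raise UndefinedCorrelationError("fewer than 2 pairwise-complete observations")
    a, b = g1[complete], g2[complete]
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise UndefinedCorrelationError("constant genotype vector")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def _chromosome_blocks(G: GenotypeMatrix) -> list[np.ndarray]:
    """Column indices grouped by chromosome in input order; checks position sorting."""
    chrom = G.snp_meta["chrom"].to_numpy()
    pos = G.snp_meta["pos"].to_numpy()
    blocks: list[np.ndarray] = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if np.any(np.diff(pos[idx]) < 0):
            raise InvalidInputError(
                f"SNP positions on chromosome {c} are not sorted; sort before pruning"
            )
        blocks.append(idx)
    return blocks


def _window_starts(m: int, window_snps: int | None, step_snps: int) -> range:
    if window_snps is None:
        return range(0, 1)
    return range(0, max(m - 1, 1), step_snps)


def ld_prune(
    G: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window_snps: int | None = 50,
    step_snps: int = 5,
) -> tuple[GenotypeMatrix, QCStage]:
    """Greedy windowed LD pruning: drop the later-positioned SNP of any
    within-window pair with r^2 strictly above the threshold.

    ``window_snps=None`` compares all pairs within each chromosome.
    Deterministic given input order; SNPs must be position-sorted within
    chromosome.  Pairs with undefined correlation (a constant SNP) are
    never pruned.
    """
    _require_nonempty(G)
    if not 0.0 < r2_threshold <= 1.0:
        raise InvalidParameterError("r2_threshold must be in (0, 1]")
    if window_snps is not None and window_snps < 2:
        raise InvalidParameterError("window_snps must be >= 2 (or None)")
    if step_snps < 1:
        raise InvalidParameterError("step_snps must be >= 1")
    removed = np.zeros(G.n_snps, dtype=bool)
    for idx in _chromosome_blocks(G):
        m = idx.size
        wsize = m if window_snps is None else window_snps
        for start in _window_starts(m, window_snps, step_snps):
            window = idx[start : start + wsize]
            for a_pos in range(window.size):
                i = window[a_pos]
                if removed[i]:
                    continue
                for j in window[a_pos + 1 :]:
                    if removed[j]:
                        continue
                    try:
                        r2 = pairwise_r2(G.calls[:, i], G.calls[:, j])
                    except UndefinedCorrelationError:
                        continue
                    if r2 > r2_threshold:
                        removed[j] = True
    stage = QCStage(
        "snp",
        "ld_pruned",
        tuple(G.snp_ids[removed].tolist()),
        {
            "r2_threshold": r2_threshold,
            "window_snps": window_snps,
            "step_snps": step_snps,
        },
    )
    return G.take_snps(~removed), stage


def ld_audit(
    G: GenotypeMatrix,
    r2_threshold: float = 0.8,
    window_snps: int | None = 50,
    step_snps: int = 5,
) -> list[tuple[str, str, float]]:
    """Exhaustive all-pairs post-condition scan over every pruning window.

    Returns the list of surviving within-window pairs with r^2 above the
    threshold (empty iff the pruning post-condition holds).
    """
    violations = []
    for idx in _chromosome_blocks(G):
        m = idx.size
        wsize = m if window_snps is None else window_snps
        for start in _window_starts(m, window_snps, step_snps):
            window = idx[start : start + wsize]
            for a_pos in range(window.size):
                i = window[a_pos]
                for j in window[a_pos + 1 :]:
                    try:
                        r2 = pairwise_r2(G.calls[:, i], G.calls[:, j])
                    except UndefinedCorrelationError:
                        continue
                    if r2 > r2_threshold:
                        violations.append(
                            (str(G.snp_ids[i]), str(G.snp_ids[j]), r2)
                        )
    return violations


def run_qc(
    G: GenotypeMatrix,
    max_individual_missing: float = 0.05,
    min_call_rate: float = 0.97,
    hwe_alpha: float = 1e-6,
    hwe_method: str = "exact",
    r2_threshold: float = 0.8,
    window_snps: int | None = 50,
    step_snps: int = 5,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the full QC cascade in the standard order.

    Order: individual missingness -> SNP call rate -> HWE -> LD pruning.
    Call rates are computed over the individuals surviving stage one, and
    the HWE test sees only SNPs surviving the call-rate stage, so each
    removal carries a single reason.
    """
    report = QCReport(n_individuals_in=G.n_individuals, n_snps_in=G.n_snps)
    G, stage = filter_individual_missingness(G, max_individual_missing)
    report.add(stage)
    G, stage = filter_snp_call_rate(G, min_call_rate)
    report.add(stage)
    G, stage = filter_hwe(G, hwe_alpha, hwe_method)
    report.add(stage)
    G, stage = ld_prune(G, r2_threshold, window_snps, step_snps)
    report.add(stage)
    report.n_individuals_out = G.n_individuals
    report.n_snps_out = G.n_snps
    report.validate_conservation()
    return G, report
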