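#!/usr/bin/env python
"""Generate the study cohort: a platelet-like continuous exposure, a
hypertension-like binary outcome, and a SNP panel containing instruments
for each trait plus null markers.

The cohort has a forward-only causal structure (platelet count raises
hypertension risk; no reverse effect), so downstream scripts should detect
exactly one causal direction.  Full genotype/phenotype TSVs go to
scratch/cohort/ (they are bulky); a small JSON summary goes to results/.
"""

import json
from pathlib import Path

import numpy as np

from bidirmr.io import write_genotypes, write_phenotypes
from bidirmr.scenarios import headline_config
from bidirmr.simulate import simulate_cohort

SEED = 20240917
OUT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    cfg = headline_config("forward", n=6_000, seed=SEED)
    G, pheno = simulate_cohort(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    write_genotypes(G, OUT / "genotypes.tsv", OUT / "snps.tsv")
    write_phenotypes(pheno, OUT / "phenotypes.tsv")

    y = pheno["hypertension"]
    summary = {
        "seed": SEED,
        "n_individuals": G.n_individuals,
        "n_snps": G.n_snps,
        "n_exposure_instruments": cfg.n_instruments,
        "n_outcome_instruments": len(np.atleast_1d(cfg.outcome_instrument_effects)),
        "causal_effect_log_odds_per_unit": cfg.causal_effect,
        "hypertension_prevalence": float(y.mean()),
        "platelet_mean": float(pheno["platelet"].mean()),
        "platelet_sd": float(pheno["platelet"].std()),
    }
    (RESULTS / "cohort_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"cohort: {G.n_individuals} individuals x {G.n_snps} SNPs -> {OUT}")
    print(f"hypertension prevalence {y.mean():.3f}; "
          f"true forward effect {cfg.causal_effect} log-odds per exposure unit, "
          f"no reverse effect")


if __name__ == "__main__":
    main()
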