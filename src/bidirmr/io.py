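"""Plain-text I/O: genotype/phenotype TSV, summary statistics, YAML configs.

Formats
-------
* genotype TSV — rows = individuals (first column ``individual_id``),
  columns = SNP ids, values 0/1/2/NA; SNP metadata travels in a companion
  TSV with columns ``id, chrom, pos, effect_allele, other_allele``.
* phenotype TSV — ``individual_id``, trait columns, covariate columns.
* summary-statistics TSV — the association-module columns, readable back
  so the MR stage can run from external summary files.
* harmonized-instruments TSV — snp_id, beta_exposure, se_exposure,
  beta_outcome, se_outcome.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import SUMMARY_COLUMNS
from .errors import InvalidInputError
from .mr import HARMONIZED_COLUMNS, HarmonizedInstruments
from .simulate import ConfounderSpec, GenotypeMatrix, SimulationConfig

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_summary_stats",
    "read_summary_stats",
    "write_harmonized",
    "read_harmonized",
    "config_from_yaml",
    "write_json",
]


def write_genotypes(G: GenotypeMatrix, geno_path, meta_path) -> None:
    frame = pd.DataFrame(G.calls, columns=G.snp_ids)
    frame.insert(0, "individual_id", G.individual_ids)
    frame.to_csv(geno_path, sep="\t", index=False, na_rep="NA", float_format="%.0f")
    G.snp_meta.to_csv(meta_path, sep="\t", index=False)


def read_genotypes(geno_path, meta_path) -> GenotypeMatrix:
    frame = pd.read_csv(geno_path, sep="\t", na_values=["NA"], float_precision="round_trip")
    if "individual_id" not in frame.columns:
        raise InvalidInputError("genotype TSV must have an individual_id column")
    meta = pd.read_csv(meta_path, sep="\t", dtype={"chrom": str})
    ids = frame.pop("individual_id").to_numpy()
    if list(frame.columns) != list(meta["id"]):
        raise InvalidInputError("genotype columns do not match SNP metadata ids")
    return GenotypeMatrix(frame.to_numpy(dtype=float), meta, ids)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", na_values=["NA"], float_precision="round_trip")
    if "individual_id" not in pheno.columns:
        raise InvalidInputError("phenotype TSV must have an individual_id column")
    return pheno


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    stats.loc[:, [c for c in SUMMARY_COLUMNS if c in stats.columns]].to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


def read_summary_stats(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str}, float_precision="round_trip")
    required = {"snp_id", "beta", "se", "p"}
    missing = required - set(stats.columns)
    if missing:
        raise InvalidInputError(f"summary statistics missing columns {sorted(missing)}")
    if "testable" not in stats.columns:
        stats["testable"] = stats["beta"].notna() & stats["se"].notna()
    return stats


def write_harmonized(h: HarmonizedInstruments, path) -> None:
    h.table.loc[:, HARMONIZED_COLUMNS].to_csv(path, sep="\t", index=False)


def read_harmonized(path, outcome_binary: bool = False) -> HarmonizedInstruments:
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return HarmonizedInstruments(table, outcome_binary=outcome_binary)


def config_from_yaml(path) -> SimulationConfig:
    """Load a SimulationConfig from YAML.

    Scalar fields map directly; ``confounders`` is a list of mappings with
    the ConfounderSpec field names; ``pleiotropy`` is either a list of
    per-instrument effects or a mapping ``{kind: balanced|directional,
    sd: ..., mean: ...}``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidInputError("config YAML must be a mapping")
    confounders = tuple(
        ConfounderSpec(**c) for c in raw.pop("confounders", [])
    )
    pleio = raw.pop("pleiotropy", None)
    if isinstance(pleio, dict):
        kind = pleio.get("kind")
        if kind == "balanced":
            pleio = ("balanced", float(pleio["sd"]))
        elif kind == "directional":
            pleio = ("directional", float(pleio["mean"]), float(pleio["sd"]))
        elif kind in (None, "none"):
            pleio = None
        else:
            raise InvalidInputError(f"unknown pleiotropy kind {kind!r}")
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    for key in ("instrument_effects", "outcome_instrument_effects"):
        if key in raw and raw[key] is not None:
            raw[key] = np.asarray(raw[key], dtype=float)
    return SimulationConfig(
        confounder_spec=confounders, pleiotropy_effects=pleio, **raw
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
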