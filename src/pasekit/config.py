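"""Typed, range-checked pipeline configuration (YAML key/value file).

Every threshold the analysis uses is surfaced here with its study default:
PSM intensity filters (1000 / 5000), DE cut-offs (BH FDR 0.05, |log2FC| >
1.5), the reciprocal-hybrid screen (p < 0.01, |log2FC| > 0.3), the
regulatory-classification threshold tau = 1 log2 unit, the binomial ASE
test (BH 0.05, minimum depth 10), and the digestion parameters (2 missed
cleavages).  Unknown keys are rejected so typos cannot silently change an
analysis.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationConfig(_Strict):
    n_proteins: int = Field(500, gt=0)
    sigma_additive: float = Field(1.0, ge=0)
    sigma_dominance: float = Field(0.5, ge=0)
    sigma_sex: float = Field(0.2, ge=0)
    sigma_residual: float = Field(0.5, ge=0)
    fraction_null: float = Field(0.3, ge=0, le=1)
    psm_mean: float = Field(4.0, ge=1)
    psm_cv: float = Field(0.1, ge=0)
    n_variant_pairs: int = Field(100, ge=0)
    n_reference_proteins: int = Field(60, gt=0)
    variant_effect: float = Field(2.0, ge=0)
    variant_noise: float = Field(0.25, ge=0)
    n_genes: int = Field(500, ge=0)
    read_depth: float = Field(100.0, ge=1)
    category_mix: list[float] = Field(default=[0.2, 0.2, 0.2, 0.2, 0.2],
                                      min_length=5, max_length=5)
    replicates: int = Field(1, ge=1)


class QuantConfig(_Strict):
    min_intensity: float = Field(1000.0, ge=0)
    min_median: float = Field(5000.0, ge=0)
    trim_fraction: float = Field(0.1, ge=0, lt=0.5)


class DiffExprConfig(_Strict):
    fdr: float = Field(0.05, gt=0, lt=1)
    fc_cut: float = Field(1.5, ge=0)
    spe_high_pct: float = Field(25.0, ge=0, le=100)
    spe_low_pct: float = Field(5.0, ge=0, le=100)
    hybrid_p_cut: float = Field(0.01, gt=0, lt=1)
    hybrid_fc_cut: float = Field(0.3, ge=0)


class PaseConfig(_Strict):
    tau: float = Field(1.0, gt=0)
    alpha: float = Field(0.05, gt=0, lt=1)
    mode: str = Field("quadrant", pattern="^(quadrant|band)$")
    gate_significance: bool = False


class DigestConfig(_Strict):
    missed_cleavages: int = Field(2, ge=0)
    min_len: int = Field(6, ge=1)
    max_len: int = Field(50, ge=1)
    proline_rule: bool = True


class TranscriptConfig(_Strict):
    min_total: int = Field(10, ge=1)
    alpha: float = Field(0.05, gt=0, lt=1)
    pseudocount: float = Field(0.5, gt=0)


class StageFlags(_Strict):
    quant: bool = True
    diffexpr: bool = True
    inheritance: bool = True
    proteogenomics: bool = True
    pase: bool = True
    transcript_ase: bool = True


class PipelineConfig(_Strict):
    seed: int = 0
    psm_table: Optional[str] = None       # external inputs; None => simulate
    sample_metadata: Optional[str] = None
    reference_fasta: Optional[str] = None
    variant_table: Optional[str] = None
    simulation: SimulationConfig = SimulationConfig()
    quant: QuantConfig = QuantConfig()
    diffexpr: DiffExprConfig = DiffExprConfig()
    pase: PaseConfig = PaseConfig()
    digest: DigestConfig = DigestConfig()
    transcript: TranscriptConfig = TranscriptConfig()
    stages: StageFlags = StageFlags()

    def input_paths(self) -> dict[str, str]:
        return {k: v for k, v in
                {"psm_table": self.psm_table,
                 "sample_metadata": self.sample_metadata,
                 "reference_fasta": self.reference_fasta,
                 "variant_table": self.variant_table}.items() if v}


def validate_config(source) -> PipelineConfig:
    """Load and validate a YAML config file (or dict); inject defaults.

    Unknown keys, out-of-range thresholds and type mismatches raise with the
    offending key path; referenced input files must exist.
    """
    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a YAML mapping")
    cfg = PipelineConfig.model_validate(raw)
    for key, path in cfg.input_paths().items():
        if not Path(path).exists():
            raise FileNotFoundError(f"config key {key!r}: no such file {path!r}")
    return cfg


def dump_config(cfg: PipelineConfig, destination) -> None:
    """Write the config as YAML to a path or an open file-like object."""
    if hasattr(destination, "write"):
        yaml.safe_dump(cfg.model_dump(), destination, sort_keys=False)
    else:
        with open(destination, "w") as fh:
            yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)
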