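"""Run configuration with the pipeline's default thresholds."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class RunConfig:
    """All paths, thresholds, and the seed driving one pipeline run.

    Threshold defaults are the analysis protocol's published operating
    points: MAF 0.01, HWE 1e-6, genome-wide 5e-8 / suggestive 1e-5,
    GWAS screen 0.01, D' 0.9 with block cap 1000, module and replication
    and gene significance 0.01, gene window 50 kb.
    """

    genotypes: str | None = None          # PLINK prefix, discovery cohort
    phenotype: str | None = None          # TSV: iid, pheno, age, sex
    kinship: str | None = None            # optional precomputed square matrix
    repl_genotypes: str | None = None     # replication cohort PLINK prefix
    repl_phenotype: str | None = None
    annotation: str | None = None         # gene BED
    gene_sets: str | None = None          # GMT-like TSV
    outdir: str = "epinet_out"
    seed: int = 0

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    gw_threshold: float = 5e-8
    suggestive_threshold: float = 1e-5
    epi_p_cut: float = 0.01
    dprime_min: float = 0.9
    max_block: int = 1000
    soft_power: int | None = None         # None = scale-free selection
    min_module_size: int = 30
    module_p: float = 0.01
    replication_p: float = 0.01
    replication_alternative: str = "mixed"
    gene_window: int = 50_000
    gene_p: float = 0.01
    scan_residualize: bool = True
    similarity: str = "neglogp"
    int_offset: float = 0.375

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
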