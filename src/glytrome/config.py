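"""Scenario configuration for the synthetic study generator.

A :class:`ScenarioConfig` fully determines every synthetic input the
pipeline consumes: the tRNA reference set, bisulfite amplicon reads,
isodecoder/fragment count tables, ribosome footprints, protein/RNA
abundance tables and amino-acid metabolite areas.  Defaults encode the
effect structure of the neuronal Nsun2-knockout study the toolkit was
built around: strong loss of glycine tRNA isodecoders, >50% relative
m5C deficits at Nsun2-regulated cytosines with Dnmt2 sites untouched,
a GGA-specific ribosome stall in the knockout, lower translational
efficiency for glycine-codon-rich genes, and a 2.46-fold glycine
increase in the metabolome.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = ["ScenarioConfig", "ConfigurationError", "derive_seed"]


class ConfigurationError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


def derive_seed(root_seed: int, label: str) -> int:
    """Derive a stage-specific RNG seed from a root seed and a stage label.

    Uses CRC32 of the label so the derivation is stable across sessions and
    independent of stage execution order.  Result is always < 2**31.
    """
    return (int(root_seed) ^ zlib.crc32(label.encode())) % (2**31 - 1)


def _default_methylation_wt() -> dict:
    # Variable-loop Nsun2 sites are highly methylated at baseline; C39 is a
    # moderately methylated (10-20%) but strongly Nsun2-sensitive site.
    return {"C46": 0.90, "C47": 0.90, "C48": 0.90, "C39": 0.15,
            "C37": 0.90, "C38": 0.90}


def _default_methylation_ko() -> dict:
    # Nsun2 sites collapse to near-background; Dnmt2 sites (C37/C38) are
    # genotype-invariant.
    return {"C46": 0.08, "C47": 0.08, "C48": 0.08, "C39": 0.05,
            "C37": 0.90, "C38": 0.90}


@dataclass
class ScenarioConfig:
    """One seeded configuration that determines every synthetic input.

    Replicate numbers follow the study design: 3/group for count-based
    assays, 4/group for metabolites, 5/group for bisulfite amplicons.
    """

    seed: int = 42
    n_replicates_counts: int = 3
    n_replicates_metabolites: int = 4
    n_replicates_bisulfite: int = 5

    # tRNA reference / count structure
    n_isodecoders: int = 162
    gly_isodecoder_count: int = 10
    gly_depletion_strong: float = 0.4   # KO/WT fold change, 7 Gly isodecoders
    gly_depletion_weak: float = 0.85    # remaining 3 Gly isodecoders
    nongly_down_count: int = 2
    nongly_up_count: int = 2
    nongly_down_fc: float = 0.5
    nongly_up_fc: float = 1.8
    nb_dispersion: float = 0.1

    # bisulfite amplicons
    methylation_wt: Mapping[str, float] = field(default_factory=_default_methylation_wt)
    methylation_ko: Mapping[str, float] = field(default_factory=_default_methylation_ko)
    reads_per_amplicon: int = 2000
    conversion_efficiency: float = 0.99

    # ribosome profiling
    ribo_stall_gga_ko: float = 3.0
    n_ribo_transcripts: int = 50
    footprints_per_transcript: int = 2000
    n_replicates_ribo: int = 2
    init_peak: float = 8.0  # initiation enrichment at the first coding A-site

    # omics / logTER
    n_genes: int = 300
    ter_gly_slope: float = -4.0   # KO logTER per unit glycine codon fraction
    rna_lfc_sd: float = 0.3
    protein_lfc_sd: float = 0.25

    # metabolomics
    glycine_metab_fc: float = 2.46
    metab_cv: float = 0.15
    heavy_cv: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_isodecoders < self.gly_isodecoder_count:
            raise ConfigurationError(
                f"n_isodecoders ({self.n_isodecoders}) < gly_isodecoder_count "
                f"({self.gly_isodecoder_count})")
        for name in ("gly_depletion_strong", "gly_depletion_weak",
                     "nongly_down_fc", "nongly_up_fc", "glycine_metab_fc",
                     "ribo_stall_gga_ko"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for label, frac in {**dict(self.methylation_wt),
                            **dict(self.methylation_ko)}.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"methylation fraction for {label} outside [0,1]: {frac}")
        if not 0.0 < self.conversion_efficiency <= 1.0:
            raise ConfigurationError("conversion_efficiency must be in (0,1]")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")

    def stage_seed(self, stage: str) -> int:
        """Seed for one pipeline stage, derived from the root seed."""
        return derive_seed(self.seed, stage)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methylation_wt"] = dict(self.methylation_wt)
        d["methylation_ko"] = dict(self.methylation_ko)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
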