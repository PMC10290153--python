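"""Simulation and pipeline configuration.

``SimConfig`` holds every knob of the synthetic-data generator.  Its defaults
encode the study conditions the pipeline is meant to reproduce: six sequenced
lambs (three coarse-wool, three fine-wool), a read-length window of 18-41 nt,
a canonical 22 nt miRNA peak, a 32 nt tRNA-fragment component that is
5.77-fold more abundant in the coarse group, an intact-tRNA qPCR fold of 6.28
in the opposite direction, a dominant sequence making up 90% of the 32 nt
component in the coarse group, and 71 nt glycine tRNA genes present as 15
dispersed genomic copies.

``PipelineConfig`` is the YAML-backed orchestration config consumed by the
command-line interface and the analysis drivers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigError

# retained read-length window (closed, nt)
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 41

GROUP_COARSE = "coarse"
GROUP_FINE = "fine"
QC_ROLE = "QC"


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generator.

    All downstream stages are exercised against data drawn from this model;
    the defaults are the study conditions, not tuning knobs.
    """

    seed: int = 0
    n_per_group: int = 3

    # genome / tRNA gene layout
    trna_copies: int = 15           # dispersed genomic copies of the tRNA gene
    trna_gene_length: int = 71      # nt, mature glycine tRNA gene length
    fragment_length: int = 32       # nt, 5'-anchored fragment length
    n_chromosomes: int = 5

    # small-RNA read mixture
    read_depth: int = 100_000       # retained reads per sample
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    mirna_peak_length: int = 22
    mirna_weight: float = 0.35      # canonical miRNA component weight
    trf_weight_coarse: float = 0.30  # 32nt component weight, coarse group
    trf_fold: float = 5.77          # true coarse/fine 32nt-component fold
    trna_fold: float = 6.28         # true fine/coarse intact-tRNA fold (qPCR)
    dominant_fraction_coarse: float = 0.90
    dominant_fraction_fine: float = 0.45
    n_decoys: int = 3               # non-tRNA 32nt sequences sharing the peak

    # proteome
    protein_count: int = 400
    n_up_proteins: int = 20         # planted up in coarse vs fine
    n_down_proteins: int = 40       # planted down in coarse vs fine
    protein_effect_log2: float = 1.0
    protein_noise_sd: float = 0.25  # sd of log2 abundance noise
    target_fraction_of_down: float = 0.5  # down proteins that are true targets
    n_extra_targets: int = 40       # targets outside the down set
    utr_length: int = 300

    # metabolome
    metabolite_count: int = 120
    n_discriminators: int = 12
    metabolite_effect_log2: float = 1.5
    metabolite_noise_sd: float = 0.30
    n_sparse_metabolites: int = 10  # mostly-zero features, dropped by filter
    n_qc: int = 3
    qc_noise_sd: float = 0.02       # sd of log2 technical noise on QC columns

    # qPCR
    qpcr_noise_sd: float = 0.1      # sd of Ct noise

    def validate(self) -> "SimConfig":
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.trna_copies < 1:
            raise ConfigError("trna_copies must be >= 1")
        if self.fragment_length > self.trna_gene_length:
            raise ConfigError(
                "fragment_length must not exceed trna_gene_length "
                f"({self.fragment_length} > {self.trna_gene_length})"
            )
        if not self.min_len <= self.max_len:
            raise ConfigError("min_len must be <= max_len")
        if self.read_depth < 0:
            raise ConfigError("read_depth must be >= 0")
        for name in ("trf_fold", "trna_fold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("dominant_fraction_coarse", "dominant_fraction_fine",
                     "mirna_weight", "trf_weight_coarse",
                     "target_fraction_of_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.mirna_weight + self.trf_weight_coarse >= 1.0:
            raise ConfigError("mirna_weight + trf_weight_coarse must be < 1")
        if self.protein_count < 10:
            raise ConfigError("protein_count must be >= 10")
        if self.metabolite_count < 5:
            raise ConfigError("metabolite_count must be >= 5")
        if self.n_qc < 2:
            raise ConfigError("n_qc must be >= 2")
        for name in ("protein_noise_sd", "metabolite_noise_sd",
                     "qc_noise_sd", "qpcr_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        return self

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs).validate()


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}

# top-level pipeline config schema: section -> allowed keys (None = free-form)
_PIPELINE_SCHEMA: dict[str, set[str] | None] = {
    "seed": None,
    "outdir": None,
    "groups": None,
    "sim": _SIM_FIELDS,
    "spectrum": {"min_len", "max_len", "canonical_window", "min_ratio",
                 "alpha", "min_fold", "bh"},
    "annotation": {"trailer", "max_mismatches", "bed_zero_based"},
    "targets": {"match", "gu_wobble", "mismatch", "gap_open", "gap_extend",
                "seed_scale", "seed_start", "seed_end", "score_threshold",
                "stability_threshold", "window_extension", "window_step"},
    "proteome": {"up_fold", "down_fold", "alpha"},
    "metabolome": {"vip_cutoff", "alpha", "n_components", "n_per_group"},
}


@dataclass
class PipelineConfig:
    """Validated orchestration config for the staged pipeline."""

    seed: int = 0
    outdir: Path = Path("trfscan_run")
    groups: tuple[str, str] = (GROUP_COARSE, GROUP_FINE)
    sim: SimConfig = field(default_factory=SimConfig)
    spectrum: dict[str, Any] = field(default_factory=dict)
    annotation: dict[str, Any] = field(default_factory=dict)
    targets: dict[str, Any] = field(default_factory=dict)
    proteome: dict[str, Any] = field(default_factory=dict)
    metabolome: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - set(_PIPELINE_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _PIPELINE_SCHEMA.items():
            if allowed is None or section not in raw:
                continue
            sub = raw[section]
            if not isinstance(sub, dict):
                raise ConfigError(f"config section '{section}' must be a mapping")
            bad = set(sub) - allowed
            if bad:
                raise ConfigError(
                    f"unknown keys in config section '{section}': {sorted(bad)}"
                )
        seed = int(raw.get("seed", 0))
        sim_kwargs = dict(raw.get("sim", {}))
        sim_kwargs.setdefault("seed", seed)
        sim = SimConfig(**sim_kwargs).validate()
        groups = tuple(raw.get("groups", (GROUP_COARSE, GROUP_FINE)))
        if len(groups) != 2:
            raise ConfigError("exactly two group labels are required")
        return cls(
            seed=seed,
            outdir=Path(raw.get("outdir", "trfscan_run")),
            groups=groups,  # type: ignore[arg-type]
            sim=sim,
            spectrum=dict(raw.get("spectrum", {})),
            annotation=dict(raw.get("annotation", {})),
            targets=dict(raw.get("targets", {})),
            proteome=dict(raw.get("proteome", {})),
            metabolome=dict(raw.get("metabolome", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["groups"] = list(self.groups)
        return d
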