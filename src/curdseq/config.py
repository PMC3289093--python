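"""Run configuration: one YAML-serializable object covering every stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import DEFAULT_ADAPTOR


@dataclass
class SimulateParams:
    n_genes: int = 60
    len_min: int = 300
    len_max: int = 1500
    gc: float = 0.4
    n_ests: int = 300
    est_len_mean: int = 500
    est_error_rate: float = 0.005
    n_rrna: int = 2
    n_vector: int = 1
    n_bacterial: int = 2
    contaminant_len: int = 1500
    depth: int = 20000
    read_len: int = 86
    read_error_rate: float = 0.005
    rrna_fraction: float = 0.05
    adaptor: str = DEFAULT_ADAPTOR
    adaptor_rate: float = 0.05
    fraction_up: float = 0.05
    fraction_down: float = 0.05
    fold_values: list = field(default_factory=lambda: [3.0, 5.0, 10.0])


@dataclass
class QCParams:
    quality_min: int = 20
    min_len: int = 30
    max_mismatch: int = 2


@dataclass
class AssemblyParams:
    min_clean_len: int = 100
    min_overlap: int = 40
    min_identity: float = 0.97
    kmer: int = 31
    min_contig_len: int = 100
    max_mismatch: int = 2


@dataclass
class DEParams:
    fdr_max: float = 0.01
    min_fold: float = 3.0
    pvalue_method: str = "chi2"
    n_boot: int = 10000
    counting_policy: str = "discard-ties"


@dataclass
class OverlapParams:
    min_score: float = 50.0
    max_eval: float = 1e-6
    targets_path: str | None = None
    reference_path: str | None = None
    annotation_path: str | None = None


@dataclass
class RunConfig:
    """Full pipeline configuration with a single master seed."""

    seed: int = 0
    outdir: str = "curdseq_run"
    simulate: SimulateParams = field(default_factory=SimulateParams)
    qc: QCParams = field(default_factory=QCParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    de: DEParams = field(default_factory=DEParams)
    overlap: OverlapParams = field(default_factory=OverlapParams)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs = dict(data)
        for name, sub in (
            ("simulate", SimulateParams),
            ("qc", QCParams),
            ("assembly", AssemblyParams),
            ("de", DEParams),
            ("overlap", OverlapParams),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)


def validate_config(config: RunConfig) -> list[str]:
    """Return one finding per violated constraint; empty iff runnable."""
    findings: list[str] = []
    s, q, a, d = config.simulate, config.qc, config.assembly, config.de

    def check(ok: bool, path: str, reason: str) -> None:
        if not ok:
            findings.append(f"{path}: {reason}")

    check(s.n_genes >= 0, "simulate.n_genes", "must be >= 0")
    check(0 < s.len_min <= s.len_max, "simulate.len_min/len_max",
          "need 0 < len_min <= len_max")
    check(0 <= s.gc <= 1, "simulate.gc", "must be in [0, 1]")
    check(s.depth >= 0, "simulate.depth", "must be >= 0")
    check(0 <= s.rrna_fraction <= 1, "simulate.rrna_fraction", "must be in [0, 1]")
    check(0 <= s.adaptor_rate <= 1, "simulate.adaptor_rate", "must be in [0, 1]")
    check(0 <= s.fraction_up + s.fraction_down <= 1,
          "simulate.fraction_up/fraction_down", "must sum to at most 1")
    check(all(f > 0 for f in s.fold_values), "simulate.fold_values", "must be positive")
    check(q.quality_min >= 0, "qc.quality_min", "must be >= 0")
    check(q.min_len >= 1, "qc.min_len", "must be >= 1")
    check(q.max_mismatch >= 0, "qc.max_mismatch", "must be >= 0")
    check(a.min_overlap >= 10, "assembly.min_overlap", "must be >= 10")
    check(0.9 <= a.min_identity <= 1, "assembly.min_identity", "must be in [0.9, 1]")
    check(a.kmer >= 15, "assembly.kmer", "k-mer size must be >= 15")
    check(a.kmer < s.read_len, "assembly.kmer",
          f"k-mer size must be smaller than the read length ({s.read_len})")
    check(d.fdr_max >= 0, "de.fdr_max", "FDR threshold must be >= 0")
    check(d.min_fold > 0, "de.min_fold", "must be > 0")
    check(d.pvalue_method in ("chi2", "bootstrap"), "de.pvalue_method",
          "must be chi2 or bootstrap")
    check(d.counting_policy in ("discard-ties", "best-unique"), "de.counting_policy",
          "must be discard-ties or best-unique")
    for name in ("targets_path", "reference_path", "annotation_path"):
        path = getattr(config.overlap, name)
        if path is not None and not Path(path).exists():
            findings.append(f"overlap.{name}: file not found: {path}")
    return findings
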