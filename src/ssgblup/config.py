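"""Run configuration (INI-style key=value files) and the run report."""

from __future__ import annotations

import configparser
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    """Pipeline-wide settings with the study's default thresholds.

    QC thresholds are strict lower bounds (MAF > 0.01, call rates >
    0.95, HWE p > 0.001); blending is the convex combination
    G* = tau G + omega A22 with tau + omega = 1.
    """

    pedigree: str = "pedigree.csv"
    genotypes: str = "genotypes.csv"
    phenotypes: str = "phenotypes.csv"
    maf_min: float = 0.01
    marker_call_min: float = 0.95
    sample_call_min: float = 0.95
    hwe_p_min: float = 0.001
    tau: float = 0.95
    omega: float = 0.05
    relationship_mode: str = "H"
    varcomp_mode: str = "H"
    n_selected: int = 25
    n_null_iterations: int = 1_000_000
    rng_seed: int = 0
    count_traits: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "marker_call_min", "sample_call_min", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.tau + self.omega - 1.0) > 1e-12:
            raise ValueError("blend weights must satisfy tau + omega = 1")
        if self.relationship_mode not in ("A", "H"):
            raise ValueError("relationship_mode must be A or H")
        if self.varcomp_mode not in ("A", "H", "file"):
            raise ValueError("varcomp_mode must be A, H or file")
        if self.n_selected < 1 or self.n_null_iterations < 1:
            raise ValueError("selection counts must be positive")

    @classmethod
    def from_ini(cls, path) -> "RunConfig":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            text = fh.read()
        if not text.lstrip().startswith("["):
            text = "[run]\n" + text
        cp.read_string(text)
        kv: dict = {}
        for sec in cp.sections():
            kv.update(cp[sec])
        fields = cls.__dataclass_fields__
        kwargs = {}
        for k, v in kv.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            typ = fields[k].type
            if typ == "int":
                kwargs[k] = int(v)
            elif typ == "float":
                kwargs[k] = float(v)
            elif typ == "bool":
                kwargs[k] = v.strip().lower() in ("1", "true", "yes", "on")
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class RunReport:
    """Audit trail: QC counts, convergence diagnostics, output manifest.

    Counts are appended in pipeline order and must be non-increasing
    through the QC stages of the same entity.
    """

    counts: list = field(default_factory=list)  # (stage, entity, count)
    convergence: dict = field(default_factory=dict)
    id_map: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def add_count(self, stage: str, entity: str, count: int) -> None:
        if count < 0:
            raise ValueError("counts must be non-negative")
        prev = [c for s, e, c in self.counts if e == entity]
        if prev and count > prev[-1]:
            raise ValueError(
                f"{entity} count increased through QC ({prev[-1]} -> {count})"
            )
        self.counts.append((stage, entity, int(count)))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))
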