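"""Run configuration: one YAML file with per-stage sections.

Unknown keys are rejected so typos fail loudly; the resolved
configuration is serialised verbatim into every output manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .simulate import SimulationConfig


@dataclass
class QcParams:
    call_rate: float = 0.95
    min_maf: float = 0.05
    hwe_alpha: float = 0.05
    hwe_n_perm: int = 1000
    ld_r2_max: float = 0.80
    dup_mismatch: float = 0.10


@dataclass
class KinParams:
    error_rate: float = 0.005
    target_expected_fp: float = 0.1
    n_sim: int = 50_000


@dataclass
class CkmrParams:
    iterations: int = 1_000_000
    thin: int = 100
    burnin: int = 100_000
    age_cap: int = 15
    n0_prior: tuple[float, float] = (1e2, 1e7)


@dataclass
class NeParams:
    crit_maf: float = 0.05
    group_by_year: bool = True


@dataclass
class CpueParams:
    prime_stations: tuple[str, ...] = ()
    ks_n_perm: int = 9999


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "results"
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcParams = field(default_factory=QcParams)
    kin: KinParams = field(default_factory=KinParams)
    ckmr: CkmrParams = field(default_factory=CkmrParams)
    ne: NeParams = field(default_factory=NeParams)
    cpue: CpueParams = field(default_factory=CpueParams)

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")
    return cls(**data)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sections = {"simulate": SimulationConfig, "qc": QcParams,
                "kin": KinParams, "ckmr": CkmrParams, "ne": NeParams,
                "cpue": CpueParams}
    top_allowed = set(sections) | {"seed", "outdir"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)} "
                         f"in {path}")
    kwargs = {k: raw[k] for k in ("seed", "outdir") if k in raw}
    for name, cls in sections.items():
        if name in raw:
            data = dict(raw[name] or {})
            for key in ("cohort_years", "maf_range", "survey_years",
                        "samples_per_year", "sample_age_range", "n0_prior",
                        "prime_stations"):
                if key in data and isinstance(data[key], list):
                    data[key] = tuple(data[key])
            kwargs[name] = _build(cls, data, f"section {name!r} of {path}")
    return RunConfig(**kwargs)
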