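"""Run configuration: defaults, YAML loading, strict validation.

Every tunable of the pipeline lives here with its default, so a run summary
(which echoes the fully merged config) is enough to reproduce a run.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .tables_io import ViractiveError


class ConfigError(ViractiveError):
    pass


@dataclass
class TmmConfig:
    trim_m: float = 0.30
    trim_a: float = 0.05
    weighted: bool = True
    reference: str = "auto"
    #: normalize DNA and RNA libraries jointly instead of per assay
    joint_assays: bool = False


@dataclass
class ClassConfig:
    window: int = 10
    #: 0.0 = strict plateau detection; decrements must vanish entirely.
    #: Any tolerance expressed as a fraction of the curve peak collapses the
    #: cutoff to the top of the curve once communities hold more than a few
    #: hundred genomes (typical consecutive decrements are ~max/n).
    rel_tol: float = 0.0
    k: int = 3
    linkage: str = "average"
    #: "rpkm" clusters on log2 of the RPKM activity:abundance ratio, which
    #: carries the activity contrast directly; "rank" clusters on
    #: log2((rank_abundance+0.5)/(rank_activity+0.5)).
    ratio_basis: str = "rpkm"
    epsilon: float = 1e-6
    #: one deterministic nearest-centroid pass after the tree cut stabilizes
    #: the cut boundary on noisy data
    refine: bool = True


@dataclass
class ZoneSpecConfig:
    fold: float = 10.0
    min_tmm: float = 1.0


@dataclass
class TopGenesConfig:
    n_activity_groups: int = 20   # highly-active vs other report, sum RPKM
    n_zone_groups: int = 18       # zone-specific report, sum TMM
    basis: str = "sum_tmm"


@dataclass
class DiversityConfig:
    bootstraps: int = 1000


@dataclass
class RunConfig:
    counts_dna: str = ""
    counts_rna: str = ""
    genes: str = ""
    sample_map: str = ""
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"
    tmm: TmmConfig = field(default_factory=TmmConfig)
    classes: ClassConfig = field(default_factory=ClassConfig)
    zonespec: ZoneSpecConfig = field(default_factory=ZoneSpecConfig)
    topgenes: TopGenesConfig = field(default_factory=TopGenesConfig)
    diversity: DiversityConfig = field(default_factory=DiversityConfig)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {"tmm": TmmConfig, "classes": ClassConfig, "zonespec": ZoneSpecConfig,
             "topgenes": TopGenesConfig, "diversity": DiversityConfig}

_COERCIONS = {int: (int,), float: (int, float), str: (str,), bool: (bool,)}


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown config key {path}{key!r}")
    obj = cls()
    for key, value in data.items():
        ftype = type(getattr(obj, key))
        if ftype is bool and not isinstance(value, bool):
            raise ConfigError(f"config key {path}{key} must be a boolean, got {value!r}")
        if ftype in (int, float) and (isinstance(value, bool)
                                      or not isinstance(value, (int, float))):
            raise ConfigError(
                f"config key {path}{key} must be a number, got {value!r}")
        if ftype is int and not isinstance(value, int):
            raise ConfigError(f"config key {path}{key} must be an integer, got {value!r}")
        if ftype is str and not isinstance(value, str):
            raise ConfigError(f"config key {path}{key} must be a string, got {value!r}")
        setattr(obj, key, ftype(value))
    return obj


def config_from_dict(data: dict) -> RunConfig:
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    top_known = {f.name for f in fields(RunConfig)}
    for key in data:
        if key not in top_known:
            raise ConfigError(f"unknown config key {key!r}")
    cfg = RunConfig()
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"config section {key!r} must be a mapping")
            setattr(cfg, key, _build(_SECTIONS[key], value, f"{key}."))
        else:
            ftype = type(getattr(cfg, key))
            if ftype is int and (isinstance(value, bool) or not isinstance(value, int)):
                raise ConfigError(f"config key {key} must be an integer, got {value!r}")
            if ftype is str and not isinstance(value, str):
                raise ConfigError(f"config key {key} must be a string, got {value!r}")
            setattr(cfg, key, ftype(value))
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    if not 0 <= cfg.classes.rel_tol < 1:
        raise ConfigError("classes.rel_tol must be in [0, 1)")
    if cfg.classes.window < 1:
        raise ConfigError("classes.window must be >= 1")
    if cfg.classes.k < 1:
        raise ConfigError("classes.k must be >= 1")
    if cfg.classes.linkage not in ("average", "complete", "ward"):
        raise ConfigError("classes.linkage must be average|complete|ward")
    if cfg.classes.ratio_basis not in ("rank", "rpkm"):
        raise ConfigError("classes.ratio_basis must be rank|rpkm")
    if cfg.zonespec.fold <= 0 or cfg.zonespec.min_tmm < 0:
        raise ConfigError("zonespec thresholds must be positive")
    if not 0 <= cfg.tmm.trim_m < 0.5 or not 0 <= cfg.tmm.trim_a < 0.5:
        raise ConfigError("tmm trim fractions must be in [0, 0.5)")
    if cfg.diversity.bootstraps < 2:
        raise ConfigError("diversity.bootstraps must be >= 2")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)
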