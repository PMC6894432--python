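"""Structured run configuration with strict validation.

One YAML file collects every stage threshold so the whole funnel (DE ->
ceRNA pairs -> modules -> candidates -> survival) is auditable in one place.
Unknown keys are rejected (no silent typos) and every violation is reported
at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .simulate import CohortConfig
from .types import ValidationError


@dataclass
class DEConfig:
    fdr_max: float = 0.01
    min_abs_log2fc: float = 1.0
    mirna_top_k: int = 10
    prior: float = 0.5
    paired: bool = True


@dataclass
class CernaConfig:
    hyper_p_max: float = 0.05
    pcc_p_max: float = 0.05
    require_positive_pcc: bool = True
    adjust_hyper_p: bool = False
    include_mirna_nodes: bool = True
    tumor_only: bool = True
    top_mirna_k: int = 20


@dataclass
class WgcnaConfig:
    powers: list = field(default_factory=lambda: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20])
    r2_min: float = 0.85
    cut_height: float = 0.9
    min_module_size: int = 30
    merge_diss_max: float = 0.25
    module_p_max: float = 0.05
    ordinal_trait: bool = False
    tumor_only: bool = True
    fallback_power: int = 12


@dataclass
class SelectConfig:
    coexp_pcc_min: float = 0.7
    degree_fraction: float = 0.20


@dataclass
class SurvivalConfig:
    p_max: float = 0.05


@dataclass
class EnrichConfig:
    gmt: str | None = None  # defaults to the simulated gene_sets.gmt
    fdr_max: float = 0.05


@dataclass
class InputPaths:
    mrna: str = ""
    lncrna: str = ""
    mirna: str = ""
    clinical: str = ""
    targets: str = ""
    unit: str = "counts"


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "lncsponge_run"
    simulate: CohortConfig | None = None
    inputs: InputPaths | None = None
    de: DEConfig = field(default_factory=DEConfig)
    cerna: CernaConfig = field(default_factory=CernaConfig)
    wgcna: WgcnaConfig = field(default_factory=WgcnaConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}


_SECTIONS = {
    "simulate": CohortConfig,
    "inputs": InputPaths,
    "de": DEConfig,
    "cerna": CernaConfig,
    "wgcna": WgcnaConfig,
    "select": SelectConfig,
    "survival": SurvivalConfig,
    "enrich": EnrichConfig,
}

_RANGES = {
    ("de", "fdr_max"): (0.0, 1.0),
    ("de", "min_abs_log2fc"): (0.0, float("inf")),
    ("de", "prior"): (0.0, float("inf")),
    ("cerna", "hyper_p_max"): (0.0, 1.0),
    ("cerna", "pcc_p_max"): (0.0, 1.0),
    ("wgcna", "r2_min"): (0.0, 1.0),
    ("wgcna", "cut_height"): (0.0, 1.0),
    ("wgcna", "merge_diss_max"): (0.0, 2.0),
    ("wgcna", "module_p_max"): (0.0, 1.0),
    ("select", "coexp_pcc_min"): (0.0, 1.0),
    ("select", "degree_fraction"): (0.0, 1.0),
    ("survival", "p_max"): (0.0, 1.0),
    ("enrich", "fdr_max"): (0.0, 1.0),
}


def _check_section(name: str, cls, payload: dict, errors: list):
    valid = set(cls.__dataclass_fields__)
    for key in payload:
        if key not in valid:
            errors.append(f"{name}.{key}: unknown key")
    clean = {k: v for k, v in payload.items() if k in valid}
    for (sec, key), (lo, hi) in _RANGES.items():
        if sec == name and key in clean:
            v = clean[key]
            if not isinstance(v, (int, float)) or isinstance(v, bool) or not lo < v <= hi:
                errors.append(f"{name}.{key}: must lie in ({lo}, {hi}], got {v!r}")
                clean.pop(key)
    try:
        return cls(**clean)
    except (ValidationError, TypeError) as exc:
        errors.append(f"{name}: {exc}")
        return None


def parse_config(payload: dict) -> RunConfig:
    """Build a RunConfig from a nested dict, raising with *all* violations."""
    errors: list[str] = []
    known_top = {"seed", "outdir"} | set(_SECTIONS)
    for key in payload:
        if key not in known_top:
            errors.append(f"{key}: unknown key")
    kwargs: dict = {}
    if "seed" in payload:
        if not isinstance(payload["seed"], int):
            errors.append(f"seed: must be an integer, got {payload['seed']!r}")
        else:
            kwargs["seed"] = payload["seed"]
    if "outdir" in payload:
        kwargs["outdir"] = str(payload["outdir"])
    for name, cls in _SECTIONS.items():
        if name in payload:
            if not isinstance(payload[name], dict):
                errors.append(f"{name}: must be a mapping")
                continue
            section = _check_section(name, cls, payload[name], errors)
            if section is not None:
                kwargs[name] = section
    if "simulate" not in payload and "inputs" not in payload:
        errors.append("config needs either a 'simulate' block or an 'inputs' block")
    if errors:
        raise ValidationError("invalid config:\n  " + "\n  ".join(errors))
    return RunConfig(**kwargs)


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return parse_config(payload)


def default_config_template(path=None) -> str:
    """Emit the default simulate-mode config as YAML."""
    cfg = RunConfig(simulate=CohortConfig())
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
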