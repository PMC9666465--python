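"""Run configuration: YAML/JSON parsing with exhaustive validation.

A :class:`RunConfig` collects everything a pipeline run needs — stage
selection, output directory, global seed and per-stage parameter blocks.
Validation enumerates every problem (unknown keys, out-of-range values)
instead of stopping at the first, and fills documented defaults so that a
parse -> serialize -> parse round trip is an identity.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .crm import CRMConfig
from .growth import DeviationThresholds

__all__ = ["ConfigError", "RunConfig", "parse_config", "validate_config"]

STAGES = ("generate", "growth", "genomics", "crm", "richness")

_CURVE_KEYS = {
    "mu_max", "od0", "noise_sd", "sample_interval_h", "od_dilution_trigger",
    "linear_range", "n_replicates", "duration_h", "arrest_rate",
    "arrest_ramp_h", "noise_model",
}
_GENOME_KEYS = {
    "n_auxotrophs", "n_prototrophs", "marker_absence_rate_aux",
    "marker_presence_rate_proto", "background_cogs",
    "background_presence_rate", "n_background_pathways",
}
_COMMUNITY_KEYS = {
    "n_strains", "aux_fraction", "mu_range_aux", "mu_range_proto",
    "yield_range_aux", "yield_range_proto", "cfu_per_od_range",
    "stationary_cfu_range",
}
_GENERATOR_KEYS = {"vitamins", "n_curve_strains", "curve", "genome", "community"}
_THRESHOLD_KEYS = {"doubling_gap", "rate_drop_major", "rate_drop_minor"}
_GROWTH_KEYS = {"thresholds", "post_window_h", "post_window_points"}
_CLASSIFIER_KEYS = {"max_depth", "test_fraction", "n_randomizations"}
_GENOMICS_KEYS = {"alpha", "cutoff", "continuity_correction", "classifier"}
_CRM_KEYS = {f.name for f in dataclasses.fields(CRMConfig)}
_TOP_KEYS = {"seed", "outdir", "stages", "log_level", "generator", "growth", "genomics", "crm"}


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled in."""

    seed: int = 0
    outdir: str = "auxokit_out"
    stages: tuple[str, ...] = STAGES
    log_level: str = "INFO"
    generator: dict[str, Any] = field(default_factory=dict)
    growth: dict[str, Any] = field(default_factory=dict)
    genomics: dict[str, Any] = field(default_factory=dict)
    crm: dict[str, Any] = field(default_factory=dict)

    def thresholds(self) -> DeviationThresholds:
        return DeviationThresholds(**self.growth.get("thresholds", {}))

    def crm_config(self) -> CRMConfig:
        kw = dict(self.crm)
        if "dilution_times" in kw:
            kw["dilution_times"] = tuple(kw["dilution_times"])
        return CRMConfig(**kw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "stages": list(self.stages),
            "log_level": self.log_level,
            "generator": self.generator,
            "growth": self.growth,
            "genomics": self.genomics,
            "crm": self.crm,
        }

    def serialize(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=True)
        )
        path.write_text(text)


def _check_unknown(block: dict, allowed: set[str], where: str, problems: list[str]) -> None:
    for key in sorted(set(block) - allowed):
        problems.append(f"{where}: unknown key {key!r}")


def validate_config(raw: dict[str, Any]) -> RunConfig:
    """Validate a raw mapping, fill defaults, and return a RunConfig.

    Raises :class:`ConfigError` listing every problem found.
    """
    problems: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    _check_unknown(raw, _TOP_KEYS, "top level", problems)

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        problems.append("seed: must be an integer")
    stages = tuple(raw.get("stages", list(STAGES)))
    for s in stages:
        if s not in STAGES:
            problems.append(f"stages: unknown stage {s!r} (choose from {STAGES})")

    generator = dict(raw.get("generator", {}))
    _check_unknown(generator, _GENERATOR_KEYS, "generator", problems)
    for sub, allowed in (("curve", _CURVE_KEYS), ("genome", _GENOME_KEYS), ("community", _COMMUNITY_KEYS)):
        _check_unknown(dict(generator.get(sub, {})), allowed, f"generator.{sub}", problems)
    generator.setdefault("vitamins", ["biotin", "niacin", "thiamine", "pantothenate"])
    generator.setdefault("n_curve_strains", 4)
    generator.setdefault("curve", {})
    generator.setdefault("genome", {})
    generator.setdefault("community", {})

    growth = dict(raw.get("growth", {}))
    _check_unknown(growth, _GROWTH_KEYS, "growth", problems)
    thr = dict(growth.get("thresholds", {}))
    _check_unknown(thr, _THRESHOLD_KEYS, "growth.thresholds", problems)
    thr.setdefault("doubling_gap", 0.25)
    thr.setdefault("rate_drop_major", 0.25)
    thr.setdefault("rate_drop_minor", 0.10)
    if not (0 < thr["rate_drop_minor"] <= thr["rate_drop_major"] < 1):
        problems.append("growth.thresholds: need 0 < rate_drop_minor <= rate_drop_major < 1")
    if thr["doubling_gap"] <= 0:
        problems.append("growth.thresholds.doubling_gap: must be positive")
    growth["thresholds"] = thr
    growth.setdefault("post_window_h", 2.0)
    growth.setdefault("post_window_points", 6)

    genomics = dict(raw.get("genomics", {}))
    _check_unknown(genomics, _GENOMICS_KEYS, "genomics", problems)
    genomics.setdefault("alpha", 0.05)
    genomics.setdefault("cutoff", 0.20)
    genomics.setdefault("continuity_correction", False)
    clf = dict(genomics.get("classifier", {}))
    _check_unknown(clf, _CLASSIFIER_KEYS, "genomics.classifier", problems)
    clf.setdefault("max_depth", 3)
    clf.setdefault("test_fraction", 0.4)
    clf.setdefault("n_randomizations", 500)
    genomics["classifier"] = clf
    if not (0 < genomics["alpha"] < 1):
        problems.append("genomics.alpha: must lie in (0, 1)")
    if not (0 < genomics["cutoff"] < 1):
        problems.append("genomics.cutoff: must lie in (0, 1)")

    crm = dict(raw.get("crm", {}))
    _check_unknown(crm, _CRM_KEYS, "crm", problems)
    defaults = CRMConfig()
    for f in dataclasses.fields(CRMConfig):
        value = getattr(defaults, f.name)
        crm.setdefault(f.name, list(value) if isinstance(value, tuple) else value)
    for key, value in list(crm.items()):
        # YAML 1.1 reads bare scientific notation ("1e-12") as a string
        if key != "dilution_times":
            try:
                crm[key] = float(value)
            except (TypeError, ValueError):
                problems.append(f"crm.{key}: expected a number, got {value!r}")
                crm[key] = float(getattr(defaults, key))
        else:
            try:
                crm[key] = [float(t) for t in value]
            except (TypeError, ValueError):
                problems.append(f"crm.{key}: expected a list of times, got {value!r}")
    if crm["dilution_factor"] <= 1:
        problems.append("crm.dilution_factor: must exceed 1")
    if crm["s0"] <= 0:
        problems.append("crm.s0: must be positive")
    if not (0 < crm["presence_threshold"] < 1):
        problems.append("crm.presence_threshold: must lie in (0, 1)")
    if crm["secretion_threshold"] <= 0:
        problems.append("crm.secretion_threshold: must be positive")

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        seed=seed,
        outdir=str(raw.get("outdir", "auxokit_out")),
        stages=stages,
        log_level=str(raw.get("log_level", "INFO")),
        generator=generator,
        growth=growth,
        genomics=genomics,
        crm=crm,
    )


def parse_config(path: str | Path) -> RunConfig:
    """Read a YAML or JSON config file and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    return validate_config(raw or {})
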