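"""Pipeline configuration: one structured object, YAML round-trip, defaults
equal to the published search parameters (4.5/20 ppm localization search,
10/10 ppm localization-free search, 5 and 3 missed cleavages, minimum
length 6, top 20 peaks per 100 Da, isotope offsets up to 3, localization
probability 0.9, 3 ppm precursor deviation)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .digestion import DigestParams
from .localize import ValidationThresholds
from .search import SearchParams
from .simulate import NoiseModel

__all__ = ["PipelineConfig", "load_config", "save_config"]

_SPECIES_CHOICES = ("ADPr", "phosphoribose_gas", "phosphoribose_nudix")


@dataclass
class PipelineConfig:
    digestion: DigestParams = field(default_factory=DigestParams)
    search: SearchParams = field(default_factory=SearchParams)
    validation: ValidationThresholds = field(default_factory=ValidationThresholds)
    noise: NoiseModel = field(default_factory=NoiseModel)
    species: str = "ADPr"
    output_dir: str = "adprscan_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species not in _SPECIES_CHOICES:
            raise ValueError(
                f"species: {self.species!r} is not one of {_SPECIES_CHOICES}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{section}: unknown field(s) {sorted(unknown)}")
    if "noise_mz_range" in data and data["noise_mz_range"] is not None:
        data = {**data, "noise_mz_range": tuple(data["noise_mz_range"])}
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{section}: {exc}") from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration.

    Unknown fields and out-of-range values raise ``ValueError`` messages
    prefixed with the section and field they concern.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {"digestion", "search", "validation", "noise", "species", "output_dir", "seed"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level section(s): {sorted(unknown)}")
    return PipelineConfig(
        digestion=_build_section(DigestParams, raw.get("digestion", {}) or {}, "digestion"),
        search=_build_section(SearchParams, raw.get("search", {}) or {}, "search"),
        validation=_build_section(
            ValidationThresholds, raw.get("validation", {}) or {}, "validation"
        ),
        noise=_build_section(NoiseModel, raw.get("noise", {}) or {}, "noise"),
        species=raw.get("species", "ADPr"),
        output_dir=raw.get("output_dir", "adprscan_out"),
        seed=int(raw.get("seed", 0)),
    )


def save_config(config: PipelineConfig, path: str | Path) -> None:
    data = config.to_dict()
    data["noise"]["noise_mz_range"] = list(data["noise"]["noise_mz_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
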