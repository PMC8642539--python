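"""Pipeline configuration: YAML loading with strict key validation.

Defaults follow the published analysis wherever it states a value: surface
detail 25 µm, spot diameter 10 µm, 50 blank slices, QC thresholds 200 /
6000 genes and 10% mito, volcano thresholds log2FC 0.23 and p 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


_GROUP_KEYS = {"name", "n_organoids", "radius_um", "n_nuclei", "n_tumor",
               "depth_law", "shrinkage"}
_IMAGING_KEYS = {"n_slices", "z_step", "xy_pixel", "n_xy", "psf_sigma",
                 "background", "poisson_scale", "amp_nuclear", "amp_tumor"}
_ORGANOID_PARAM_KEYS = {"detail_um", "spot_diameter_um", "n_blank",
                        "reference_group", "fill_value", "extend_um",
                        "inside_positive", "spot_threshold_rel"}
_SC_PARAM_KEYS = {"species_threshold_pct", "min_genes", "max_genes",
                  "max_mito_pct", "fc_thresh", "p_thresh", "n_bins",
                  "n_ctrl", "run_de"}
_SC_DESIGN_KEYS = {"n_cells", "species_mix", "ambient_rate",
                   "phase_proportions", "cluster_proportions", "n_genes",
                   "n_mouse_genes", "fold_effect", "marker_fold",
                   "frac_high_mito", "frac_low_depth", "dispersion"}
_TOP_KEYS = {"arm", "seed", "output_dir", "mode", "groups", "imaging",
             "params", "design", "inputs"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {unknown}")


@dataclass
class PipelineConfig:
    """Validated configuration for either pipeline arm."""

    arm: str                              # "organoid" | "singlecell"
    seed: int = 0
    output_dir: str = "glioquant_out"
    mode: str = "image"                   # organoid: "image" | "table"
    groups: list[dict] = field(default_factory=list)
    imaging: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        _check_keys(raw, _TOP_KEYS, "config")
        arm = raw.get("arm")
        if arm not in ("organoid", "singlecell"):
            raise ConfigError(f"arm must be 'organoid' or 'singlecell', "
                              f"got {arm!r}")
        cfg = cls(
            arm=arm,
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "glioquant_out")),
            mode=str(raw.get("mode", "image")),
            groups=list(raw.get("groups", [])),
            imaging=dict(raw.get("imaging", {})),
            params=dict(raw.get("params", {})),
            design=dict(raw.get("design", {})),
            inputs=dict(raw.get("inputs", {})),
        )
        for i, g in enumerate(cfg.groups):
            _check_keys(g, _GROUP_KEYS, f"groups[{i}]")
        _check_keys(cfg.imaging, _IMAGING_KEYS, "imaging")
        if arm == "organoid":
            _check_keys(cfg.params, _ORGANOID_PARAM_KEYS, "params")
            if cfg.mode not in ("image", "table"):
                raise ConfigError(f"mode must be 'image' or 'table', "
                                  f"got {cfg.mode!r}")
        else:
            _check_keys(cfg.params, _SC_PARAM_KEYS, "params")
            _check_keys(cfg.design, _SC_DESIGN_KEYS, "design")
        return cfg

    def to_dict(self) -> dict:
        return {
            "arm": self.arm, "seed": self.seed, "output_dir": self.output_dir,
            "mode": self.mode, "groups": self.groups, "imaging": self.imaging,
            "params": self.params, "design": self.design, "inputs": self.inputs,
        }


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping: {path}")
    return PipelineConfig.from_dict(raw)
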