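"""Simulation parameters: defaults, provenance, config loading and validation.

Every numeric constant used by the simulator lives in :class:`ParamSet`.
Constants quoted directly from the source experimental literature (division
times, starvation lifespans, the TGFβ saturation window) are marked
``source: measured`` in ``PARAM_INFO``; everything else (field transport
constants, stromal recruitment kinetics, lattice resolution) is marked
``source: calibrated`` — chosen once so that the tumor-free bone multicellular
unit (BMU) is homeostatic and documented in ``docs/methods.md``.

Config files are flat YAML mappings of ``key: value`` pairs; unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import yaml

__all__ = ["ParamSet", "default_params", "load_config", "ConfigError", "PARAM_INFO"]


class ConfigError(ValueError):
    """Raised for unknown keys, unparsable files, or invariant violations."""


@dataclass
class ParamSet:
    # --- geometry / time -------------------------------------------------
    grid_width_um: float = 1000.0      # BMU width
    grid_height_um: float = 1500.0     # BMU height (bone slab at the bottom)
    site_size_um: float = 10.0         # one lattice site ~ one cell diameter
    dt_hours: float = 1.0              # explicit step; resolves 36 h division
    bone_fraction: float = 0.3         # fraction of grid height that is bone
    horizon_days: int = 250            # clinical horizon (75 for BMU-only runs)
    record_interval_days: float = 1.0
    rng_seed: int = 0

    # --- TGFβ field (ng/ml) ---------------------------------------------
    tgfb_saturation_ng_ml: float = 10.0
    tgfb_floor_ng_ml: float = 0.1
    tgfb_diffusion_um2_h: float = 20.0
    tgfb_decay_per_h: float = 0.05
    tgfb_release_ng_ml: float = 10.0        # quantum per resorbed bone site
    tgfb_resorption_source_ng_ml_h: float = 10.0  # at actively resorbing aOC
    tgfb_secretion_cancer_ng_ml_h: float = 0.06  # TRP/TP, at own site
    tgfb_secretion_ob_ng_ml_h: float = 0.01      # pOB/aOB, at own site
    tgfb_ambient_source_ng_ml_h: float = 0.10    # uniform background turnover

    # --- RANKL field (arbitrary units) ----------------------------------
    rankl_diffusion_um2_h: float = 20.0
    rankl_decay_per_h: float = 0.10
    rankl_secretion_stromal_h: float = 0.02      # MSC/pOB, at own site
    rankl_cancer_amplification: float = 1.5     # upregulation by local cancer
    rankl_secretion_cancer_h: float = 0.04       # direct expression by cancer
    rankl_cancer_window: int = 7                 # box (sites) for local density

    # --- BDN field (normalized 0..1 against release quantum) -------------
    bdn_diffusion_um2_h: float = 5.0
    bdn_decay_per_h: float = 0.025
    bdn_release: float = 55.0                    # per resorbed bone site
    bdn_uptake_per_cell_h: float = 0.001         # cancer consumption
    bdn_contact_threshold: float = 0.02          # "contact with BDN"
    bdn_division_floor: float = 0.01             # clamp floor for division law

    # --- osteoblast lineage ----------------------------------------------
    div_pOB_max_per_h: float = 1.0 / 36.0        # once per 36 h at zero TGFβ
    pob_lifespan_days: float = 6.0
    pob_max: int = 120                           # marrow niche ceiling
    pob_diff_threshold: float = 0.30             # bioavailable T below -> aOB
    pob_diff_rate_per_h: float = 1.0 / 48.0
    pob_move_prob: float = 0.5
    pob_chemotaxis_prob: float = 0.7             # homing to the bone surface
    aob_formation_interval_h: float = 96.0       # hours per deposited site
    aob_lifespan_days: float = 6.0
    msc_count: int = 60
    msc_asym_division_days: float = 8.0          # MSC -> MSC + pOB
    init_pob: int = 30
    init_poc: int = 20

    # --- osteoclast lineage ----------------------------------------------
    div_pOC_max_per_h: float = 1.0 / 6.0        # fusion attempt at zero TGFβ
    fusion_threshold: int = 5                    # pOC nuclei per aOC
    surv_aOC_max: float = 1.0
    aoc_lifespan_days: float = 10.0
    aoc_idle_lifespan_h: float = 48.0
    resorption_interval_h: float = 24.0          # hours per resorbed site
    aoc_initial_resorptions: int = 1             # guaranteed first lacuna
    poc_recruit_coeff: float = 0.010             # spawn rate per total RANKL
    poc_max: int = 400                           # precursor pool ceiling
    poc_lifespan_days: float = 8.0
    poc_move_prob: float = 1.0
    poc_chemotaxis_prob: float = 0.9             # homing to the bone surface

    # --- cancer clones (measured) ----------------------------------------
    div_TRP_days: float = 1.5
    div_TR_days: float = 1.75
    div_TP_days: float = 1.75
    div_TN_days: float = 2.0
    div_TRP_inhibited_days: float = 2.0
    div_TR_inhibited_days: float = 2.0
    lifespan_TRP_days: float = 14.0
    lifespan_TR_days: float = 10.0
    lifespan_TP_days: float = 10.0
    lifespan_TN_days: float = 12.0

    # ----------------------------------------------------------------------
    @property
    def nx(self) -> int:
        return int(round(self.grid_width_um / self.site_size_um))

    @property
    def ny(self) -> int:
        return int(round(self.grid_height_um / self.site_size_um))

    @property
    def site_area_um2(self) -> float:
        return self.site_size_um**2

    def validate(self) -> None:
        """Check all invariants; raise :class:`ConfigError` naming the key."""
        positive = [f.name for f in dc_fields(self)
                    if f.name not in ("rng_seed",)]
        for name in positive:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v <= 0:
                raise ConfigError(f"parameter {name!r} must be strictly "
                                  f"positive, got {v!r}")
        if self.bone_fraction >= 1.0:
            raise ConfigError("bone_fraction must be < 1")
        if self.tgfb_floor_ng_ml >= self.tgfb_saturation_ng_ml:
            raise ConfigError("tgfb_floor_ng_ml must be below "
                              "tgfb_saturation_ng_ml")
        if self.div_TRP_inhibited_days < self.div_TRP_days:
            raise ConfigError("div_TRP_inhibited_days must be >= div_TRP_days")
        if self.div_TR_inhibited_days < self.div_TR_days:
            raise ConfigError("div_TR_inhibited_days must be >= div_TR_days")
        if self.surv_aOC_max > 1.0:
            raise ConfigError("surv_aOC_max is a probability (<= 1)")
        # explicit finite-difference stability for every field
        dx2 = self.site_size_um**2
        for key in ("tgfb_diffusion_um2_h", "rankl_diffusion_um2_h",
                    "bdn_diffusion_um2_h"):
            ratio = getattr(self, key) * self.dt_hours / dx2
            if ratio > 0.25:
                raise ConfigError(
                    f"stability violation for {key}: D*dt/dx^2 = "
                    f"{ratio:.3f} > 0.25")
        if self.nx < 4 or self.ny < 4:
            raise ConfigError("grid must be at least 4x4 sites")

    # inhibitor must not change TP/TN rates, by construction
    @property
    def div_TP_inhibited_days(self) -> float:
        return self.div_TP_days

    @property
    def div_TN_inhibited_days(self) -> float:
        return self.div_TN_days

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **kw: Any) -> "ParamSet":
        p = dataclasses.replace(self, **kw)
        p.validate()
        return p

    def save_json(self, path: str | Path) -> None:
        """Write the fully resolved parameter set (run provenance)."""
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True) + "\n")


#: provenance of every default: "measured" values trace to the experimental
#: characterization of the cell lines / the stated TGFβ concentration window;
#: "calibrated" values are this package's own defaults (see docs/methods.md).
PARAM_INFO: dict[str, str] = {
    name: "measured" if name in {
        "grid_width_um", "grid_height_um",
        "tgfb_saturation_ng_ml", "tgfb_floor_ng_ml",
        "div_pOB_max_per_h", "surv_aOC_max",
        "div_TRP_days", "div_TR_days", "div_TP_days", "div_TN_days",
        "div_TRP_inhibited_days", "div_TR_inhibited_days",
        "lifespan_TRP_days", "lifespan_TR_days", "lifespan_TP_days",
        "lifespan_TN_days", "horizon_days",
    } else "calibrated"
    for name in (f.name for f in dc_fields(ParamSet))
}


def default_params(**overrides: Any) -> ParamSet:
    """Return the default :class:`ParamSet`, optionally with overrides."""
    p = ParamSet(**overrides)
    p.validate()
    return p


def load_config(path: str | Path) -> ParamSet:
    """Load a flat YAML config file over the defaults.

    An empty file yields the defaults. Unknown keys and invariant violations
    raise :class:`ConfigError` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough message
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a flat key: value mapping")
    known = {f.name for f in dc_fields(ParamSet)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return default_params(**raw)
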