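"""Reaction–diffusion fields (TGFβ, RANKL, BDN) and the TGFβ response laws.

Each field obeys ``∂C/∂t = D ∇²C − λC + S`` and is advanced with one explicit
forward-Euler step per simulation step (5-point Laplacian, no-flux boundaries
via edge replication). The explicit scheme requires ``D·dt/dx² ≤ 0.25``,
checked at parameter load.

TGFβ is stored as a raw concentration in ng/ml and normalized against the
10 ng/ml saturation level before any cell rule reads it; the measured
biological response window is 0.1–10 ng/ml, exactly two decades, so the
logarithmic response laws

    response_direct(T)  = clamp(1 + log10 T, 0, 1)
    response_inverse(T) = clamp(  − log10 T, 0, 1)

map that window onto [0, 1] and satisfy the stated boundary behavior (direct
response is 100 % at saturation; inverse response is maximal with no TGFβ).
The BDN division law reuses ``response_direct`` on the normalized nutrient.

The inhibitor acts instantaneously and uniformly on bioavailability: every
cell rule reads ``bioavailable_tgfb(T, efficacy) = T · (1 − efficacy)``, never
the raw field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ParamSet

__all__ = [
    "FieldSet", "make_fields", "laplacian", "step_fields",
    "normalize_tgfb", "bioavailable_tgfb",
    "response_direct", "response_inverse", "release_from_bone",
]


@dataclass
class FieldSet:
    """The three scalar fields plus their transport constants."""

    tgfb: np.ndarray    # ng/ml
    rankl: np.ndarray   # arbitrary units
    bdn: np.ndarray     # normalized, release quantum ~ O(1)
    diffusion: dict[str, float]
    decay: dict[str, float]

    def copy(self) -> "FieldSet":
        return FieldSet(self.tgfb.copy(), self.rankl.copy(), self.bdn.copy(),
                        dict(self.diffusion), dict(self.decay))

    def names(self) -> tuple[str, ...]:
        return ("tgfb", "rankl", "bdn")


def make_fields(shape: tuple[int, int], params: ParamSet) -> FieldSet:
    """Baseline fields: ambient TGFβ at its source/decay steady state,
    no RANKL, no bone-derived nutrients."""
    ambient = params.tgfb_ambient_source_ng_ml_h / params.tgfb_decay_per_h
    return FieldSet(
        tgfb=np.full(shape, ambient, dtype=float),
        rankl=np.zeros(shape, dtype=float),
        bdn=np.zeros(shape, dtype=float),
        diffusion={
            "tgfb": params.tgfb_diffusion_um2_h,
            "rankl": params.rankl_diffusion_um2_h,
            "bdn": params.bdn_diffusion_um2_h,
        },
        decay={
            "tgfb": params.tgfb_decay_per_h,
            "rankl": params.rankl_decay_per_h,
            "bdn": params.bdn_decay_per_h,
        },
    )


def laplacian(c: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with no-flux (reflecting) boundaries."""
    lap = c * -4.0
    lap[1:, :] += c[:-1, :]
    lap[0, :] += c[0, :]       # reflected ghost = edge value
    lap[:-1, :] += c[1:, :]
    lap[-1, :] += c[-1, :]
    lap[:, 1:] += c[:, :-1]
    lap[:, 0] += c[:, 0]
    lap[:, :-1] += c[:, 1:]
    lap[:, -1] += c[:, -1]
    lap /= dx * dx
    return lap


def step_fields(fields: FieldSet, sources: dict[str, np.ndarray | float],
                dt: float, dx: float) -> FieldSet:
    """One explicit forward-Euler step of every species, in place.

    ``sources`` maps species name to a per-site rate grid (units of the field
    per hour) or a uniform scalar. Negative concentrations (possible only
    through explicit sink terms) are clipped at zero.
    """
    for name in fields.names():
        c = getattr(fields, name)
        d = fields.diffusion[name]
        if d * dt / (dx * dx) > 0.25:
            raise ValueError(f"stability violation for field {name!r}")
        lam = fields.decay[name]
        s = sources.get(name, 0.0)
        c += dt * (d * laplacian(c, dx) - lam * c + s)
        np.maximum(c, 0.0, out=c)
    return fields


def normalize_tgfb(raw: np.ndarray | float, params: ParamSet):
    """Raw ng/ml -> normalized T = clamp(raw/sat, floor/sat, 1) in (0, 1]."""
    sat = params.tgfb_saturation_ng_ml
    return np.clip(np.asarray(raw, dtype=float) / sat,
                   params.tgfb_floor_ng_ml / sat, 1.0)


def bioavailable_tgfb(raw, efficacy: float):
    """Inhibitor action: bioavailable T = raw · (1 − efficacy).

    ``raw`` is the normalized TGFβ in [0, 1]; ``efficacy`` the constant
    inhibition fraction in [0, 0.99]. This value, not the raw field, is what
    every cell rule reads.
    """
    if not 0.0 <= efficacy <= 0.99:
        raise ValueError(f"efficacy must be in [0, 0.99], got {efficacy}")
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0) or np.any(raw > 1):
        raise ValueError("normalized TGFβ must lie in [0, 1]")
    out = raw * (1.0 - efficacy)
    return float(out) if out.ndim == 0 else out


def response_direct(t):
    """Directly proportional response, clamp(1 + log10 T, 0, 1)."""
    if isinstance(t, float):          # fast scalar path for agent loops
        if t <= 0:
            raise ValueError("response functions require T > 0")
        v = 1.0 + math.log10(t)
        return 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("response functions require T > 0")
    out = np.clip(1.0 + np.log10(t), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def response_inverse(t):
    """Inversely proportional response, clamp(−log10 T, 0, 1)."""
    if isinstance(t, float):
        if t <= 0:
            raise ValueError("response functions require T > 0")
        v = -math.log10(t)
        return 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("response functions require T > 0")
    out = np.clip(-np.log10(t), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def release_from_bone(fields: FieldSet, site: tuple[int, int],
                      params: ParamSet, *, was_bone: bool = True) -> FieldSet:
    """Release matrix-sequestered TGFβ and nutrients at a resorbed site."""
    if not was_bone:
        raise ValueError(f"site {site} is not bone being resorbed")
    x, y = site
    fields.tgfb[x, y] += params.tgfb_release_ng_ml
    fields.bdn[x, y] += params.bdn_release
    return fields
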