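"""Calibration and density-modulus law chains.

A *law chain* converts a Hounsfield value into a Young's modulus in three
stages:

1. **Calibration** — the scanner's linear HU -> density line,
   ``rho = slope * HU + intercept`` (g/cm^3), producing either a calibrated
   QCT density (rho_CT) or an ash density directly.
2. **Density conversions** — zero or more affine relations between density
   kinds, ``out = scale * (pre_scale * in) + offset``, e.g. the rho_CT ->
   rho_ash and rho_ash -> rho_app relations reported in the QCT literature.
3. **Modulus law** — a piecewise power law over half-open density intervals
   ``(lo, hi]``: ``E = a * rho**b`` MPa, or a constant modulus on an
   interval (the plateau some trabecular-bone studies report).

Densities are floored at ``rho_floor`` and moduli at ``e_floor`` so that a
low-HU voxel (air, marrow) can never produce a non-positive stiffness;
every flooring event is counted when an accumulator is supplied.

Four chains from the QCT bone-mapping literature ship built in; arbitrary
user chains load from a YAML/JSON config with the interval-coverage
invariant enforced at load time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import LawChainError

__all__ = [
    "CalibrationLaw",
    "DensityConversion",
    "ModulusSegment",
    "LawChain",
    "FloorCounts",
    "builtin_chain",
    "builtin_chain_names",
    "load_chain",
    "chain_to_dict",
    "hu_to_density",
    "density_to_modulus",
    "hu_to_modulus",
]

DEFAULT_RHO_FLOOR = 1e-3  # g/cm^3
DEFAULT_E_FLOOR = 0.01  # MPa


@dataclass(frozen=True)
class CalibrationLaw:
    """Scanner calibration line: rho = slope * HU + intercept (g/cm^3)."""

    slope: float  # g/cm^3 per HU
    intercept: float  # g/cm^3
    output: str = "rho_ash"  # or "rho_ct"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise LawChainError(f"calibration slope must be > 0, got {self.slope}")
        if self.output not in ("rho_ash", "rho_ct"):
            raise LawChainError(f"calibration output must be rho_ash or rho_ct, got {self.output!r}")

    def __call__(self, hu):
        return self.slope * np.asarray(hu, dtype=np.float64) + self.intercept


@dataclass(frozen=True)
class DensityConversion:
    """Affine relation between density kinds: out = scale*(pre_scale*in) + offset."""

    scale: float
    offset: float  # g/cm^3
    pre_scale: float = 1.0
    output: str = "rho_ash"  # or "rho_app"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise LawChainError(f"conversion scale must be > 0, got {self.scale}")
        if self.output not in ("rho_ash", "rho_app"):
            raise LawChainError(f"conversion output must be rho_ash or rho_app, got {self.output!r}")

    def __call__(self, rho):
        return self.scale * (self.pre_scale * np.asarray(rho, dtype=np.float64)) + self.offset


@dataclass(frozen=True)
class ModulusSegment:
    """E = a * rho**b (MPa) on the half-open density interval (lo, hi]."""

    a: float = 0.0  # MPa
    b: float = 1.0
    density_lo: float = 0.0  # g/cm^3, exclusive
    density_hi: float = math.inf  # g/cm^3, inclusive
    constant_override: float | None = None  # MPa

    def __post_init__(self) -> None:
        if self.constant_override is None and self.a <= 0:
            raise LawChainError("segment needs a > 0 or a constant_override")
        if not self.density_lo < self.density_hi:
            raise LawChainError(
                f"segment interval empty: ({self.density_lo}, {self.density_hi}]"
            )

    def evaluate(self, rho):
        rho = np.asarray(rho, dtype=np.float64)
        if self.constant_override is not None:
            return np.full_like(rho, self.constant_override)
        return self.a * rho**self.b


@dataclass(frozen=True)
class LawChain:
    """Named HU -> density -> Young's-modulus conversion chain."""

    name: str
    calibration: CalibrationLaw
    conversions: tuple[DensityConversion, ...] = ()
    modulus: tuple[ModulusSegment, ...] = ()
    rho_floor: float = DEFAULT_RHO_FLOOR  # g/cm^3
    e_floor: float = DEFAULT_E_FLOOR  # MPa

    def __post_init__(self) -> None:
        object.__setattr__(self, "conversions", tuple(self.conversions))
        object.__setattr__(self, "modulus", tuple(self.modulus))
        if self.rho_floor <= 0 or self.e_floor <= 0:
            raise LawChainError("rho_floor and e_floor must be > 0")
        if not self.modulus:
            raise LawChainError("chain has no modulus segments")
        _check_segment_coverage(self.modulus, self.rho_floor)

    @property
    def density_kind(self) -> str:
        """The density kind the modulus law consumes."""
        return self.conversions[-1].output if self.conversions else self.calibration.output


def _check_segment_coverage(segments: Sequence[ModulusSegment], rho_floor: float) -> None:
    """Segments must cover (rho_floor, inf) exactly once (no gaps, no overlap)."""
    segs = sorted(segments, key=lambda s: s.density_lo)
    if segs[0].density_lo > rho_floor:
        raise LawChainError(
            f"modulus segments leave a gap ({rho_floor:g}, {segs[0].density_lo:g}] "
            f"above the density floor"
        )
    for prev, nxt in zip(segs, segs[1:]):
        if nxt.density_lo < prev.density_hi:
            raise LawChainError(
                f"modulus segments overlap on ({nxt.density_lo:g}, "
                f"{min(prev.density_hi, nxt.density_hi):g}]"
            )
        if nxt.density_lo > prev.density_hi:
            raise LawChainError(
                f"modulus segments leave a gap ({prev.density_hi:g}, {nxt.density_lo:g}]"
            )
    if not math.isinf(segs[-1].density_hi):
        raise LawChainError(
            f"modulus segments leave a gap ({segs[-1].density_hi:g}, inf)"
        )


@dataclass
class FloorCounts:
    """Accumulator for flooring events during HU -> E conversion."""

    rho_floored: int = 0
    e_floored: int = 0

    def merge(self, other: "FloorCounts") -> None:
        self.rho_floored += other.rho_floored
        self.e_floored += other.e_floored


# ---------------------------------------------------------------------------
# builtin registry
# ---------------------------------------------------------------------------

def _pelvis_uniform() -> LawChain:
    # single power law used for both cortical and trabecular pelvic bone
    return LawChain(
        name="pelvis_uniform_eq1_2",
        calibration=CalibrationLaw(slope=0.00063, intercept=-0.0067, output="rho_ash"),
        modulus=(ModulusSegment(a=10500.0, b=2.29),),
    )


def _cortical_apparent() -> LawChain:
    # cortical-layer law in apparent density; constant trabecular modulus is
    # NOT part of this chain (its source treated the spongy bone separately).
    # The scanner calibration is not published with the law; the QCT test
    # calibration (same slope/intercept as the bonemat_test chain) is used as
    # a replaceable default.
    return LawChain(
        name="cortical_apparent_eq3_5",
        calibration=CalibrationLaw(slope=0.00079, intercept=-0.0039, output="rho_ct"),
        conversions=(
            DensityConversion(scale=0.877, offset=0.079, output="rho_ash"),
            DensityConversion(scale=1.0 / 0.6, offset=0.0, output="rho_app"),
        ),
        modulus=(ModulusSegment(a=6850.0, b=1.49),),
    )


def _piecewise() -> LawChain:
    # three-regime trabecular/cortical law in ash density
    return LawChain(
        name="piecewise_eq6_10",
        calibration=CalibrationLaw(slope=0.0008, intercept=0.0, output="rho_ct"),
        conversions=(
            DensityConversion(scale=0.877, pre_scale=1.15, offset=0.08, output="rho_ash"),
        ),
        modulus=(
            ModulusSegment(a=33900.0, b=2.2, density_lo=0.0, density_hi=0.3),
            ModulusSegment(
                constant_override=2398.0, a=0.0, b=0.0, density_lo=0.3, density_hi=0.486
            ),
            ModulusSegment(a=10200.0, b=2.01, density_lo=0.486, density_hi=math.inf),
        ),
    )


def _bonemat_test() -> LawChain:
    return LawChain(
        name="bonemat_test_eq11_13",
        calibration=CalibrationLaw(slope=0.00079, intercept=-0.0039, output="rho_ct"),
        conversions=(DensityConversion(scale=0.877, offset=0.079, output="rho_ash"),),
        modulus=(ModulusSegment(a=14664.0, b=1.49),),
    )


_BUILTIN = {
    "pelvis_uniform_eq1_2": _pelvis_uniform,
    "cortical_apparent_eq3_5": _cortical_apparent,
    "piecewise_eq6_10": _piecewise,
    "bonemat_test_eq11_13": _bonemat_test,
}


def builtin_chain_names() -> list[str]:
    return sorted(_BUILTIN)


def builtin_chain(name: str) -> LawChain:
    """Return a built-in law chain by name with its published coefficients."""
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise LawChainError(
            f"unknown law chain {name!r}; available: {', '.join(builtin_chain_names())}"
        ) from None


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def hu_to_density(
    chain: LawChain, hu, counts: FloorCounts | None = None
):
    """HU -> density of the kind the chain's modulus law consumes (g/cm^3).

    Scalar in, scalar out; arrays are mapped elementwise.  Results below
    ``chain.rho_floor`` are floored (and counted on ``counts``).
    """
    scalar = np.isscalar(hu) or np.ndim(hu) == 0
    rho = chain.calibration(hu)
    for conv in chain.conversions:
        rho = conv(rho)
    floored = rho < chain.rho_floor
    if counts is not None:
        counts.rho_floored += int(np.count_nonzero(floored))
    rho = np.maximum(rho, chain.rho_floor)
    return float(rho) if scalar else rho


def density_to_modulus(
    chain: LawChain, rho, counts: FloorCounts | None = None
):
    """Density (g/cm^3) -> Young's modulus (MPa) through the piecewise law.

    The unique segment with ``density_lo < rho <= density_hi`` applies;
    results below ``chain.e_floor`` are floored (and counted).
    """
    scalar = np.isscalar(rho) or np.ndim(rho) == 0
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=np.float64))
    if np.any(rho_arr <= 0):
        raise LawChainError("density must be > 0 for the modulus law")
    E = np.full(rho_arr.shape, np.nan)
    for seg in chain.modulus:
        mask = (rho_arr > seg.density_lo) & (rho_arr <= seg.density_hi)
        if mask.any():
            E[mask] = seg.evaluate(rho_arr[mask])
    if np.isnan(E).any():
        bad = float(rho_arr[np.isnan(E)][0])
        raise LawChainError(f"density {bad:g} g/cm^3 outside all modulus segments")
    floored = E < chain.e_floor
    if counts is not None:
        counts.e_floored += int(np.count_nonzero(floored))
    E = np.maximum(E, chain.e_floor)
    return float(E[0]) if scalar else E


def hu_to_modulus(chain: LawChain, hu, counts: FloorCounts | None = None):
    """Composition: HU -> density -> Young's modulus (MPa)."""
    return density_to_modulus(chain, hu_to_density(chain, hu, counts), counts)


# ---------------------------------------------------------------------------
# config round-trip
# ---------------------------------------------------------------------------

def chain_to_dict(chain: LawChain) -> dict:
    """Serialisable form of a chain (inverse of :func:`load_chain`)."""
    return {
        "name": chain.name,
        "calibration": {
            "slope": chain.calibration.slope,
            "intercept": chain.calibration.intercept,
            "output": chain.calibration.output,
        },
        "conversions": [
            {
                "scale": c.scale,
                "offset": c.offset,
                "pre_scale": c.pre_scale,
                "output": c.output,
            }
            for c in chain.conversions
        ],
        "modulus": [
            {
                "a": s.a,
                "b": s.b,
                "density_lo": s.density_lo,
                "density_hi": None if math.isinf(s.density_hi) else s.density_hi,
                "constant_override": s.constant_override,
            }
            for s in chain.modulus
        ],
        "rho_floor": chain.rho_floor,
        "e_floor": chain.e_floor,
    }


def _chain_from_dict(cfg: dict) -> LawChain:
    try:
        cal = CalibrationLaw(**cfg["calibration"])
        convs = tuple(DensityConversion(**c) for c in cfg.get("conversions", []))
        segs = []
        for s in cfg["modulus"]:
            s = dict(s)
            if s.get("density_hi") is None:
                s["density_hi"] = math.inf
            if s.get("constant_override") is not None and not s.get("a"):
                s["a"] = 0.0
            segs.append(ModulusSegment(**{k: v for k, v in s.items() if v is not None or k == "constant_override"}))
        return LawChain(
            name=cfg.get("name", "user_chain"),
            calibration=cal,
            conversions=convs,
            modulus=tuple(segs),
            rho_floor=cfg.get("rho_floor", DEFAULT_RHO_FLOOR),
            e_floor=cfg.get("e_floor", DEFAULT_E_FLOOR),
        )
    except (KeyError, TypeError) as exc:
        raise LawChainError(f"invalid law-chain config: {exc}") from exc


def load_chain(source: str | Path | dict) -> LawChain:
    """Load a user law chain from a YAML/JSON file, text, or dict.

    The segment-coverage invariant (no gaps or overlaps above the density
    floor) is enforced at load time, naming the offending interval.
    """
    if isinstance(source, dict):
        return _chain_from_dict(source)
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        cfg = json.loads(text)
    except json.JSONDecodeError:
        import yaml

        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise LawChainError("law-chain config must be a mapping")
    return _chain_from_dict(cfg)


def resolve_chain(spec: str | Path | dict | LawChain) -> LawChain:
    """Builtin name, config file/dict, or chain instance -> LawChain."""
    if isinstance(spec, LawChain):
        return spec
    if isinstance(spec, str) and spec in _BUILTIN:
        return builtin_chain(spec)
    return load_chain(spec)
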