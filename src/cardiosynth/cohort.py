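"""Systematic families and seeded pseudo-random cohorts of cardiac models.

The default left-ventricle cohort is 22 models: the original, seven with
varied heights (73-89 mm), seven with varied wall thickness, and seven with
varied shape (x-shifted and rescaled control circles).  Valve cohorts are
drawn uniformly at random within the physiological parameter ranges of each
population, reproducibly from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lv import LVModel, LVProfile, build_lv, default_profile, measure_lv
from .valve import (
    ROOT_COMMON_RANGES,
    ROOT_RANGES,
    LeafletParams,
    RootParams,
)

DEFAULT_HEIGHTS = (73.0, 75.0, 77.0, 79.0, 82.0, 85.0, 89.0)
DEFAULT_WALL_OFFSETS = (8.5, 9.0, 9.5, 9.75, 10.5, 11.0, 11.5)

# Seven asymmetric variants: {section index: (cx shift mm, radius scale)}.
# Calibrated stand-ins: mid-section shifts and mild rescales that keep the
# height at 80 mm, the base/apex rings untouched (radius_min stays 21 mm)
# and the average outer radius inside the 30.5-32.0 mm span of the
# systematic families.
DEFAULT_SHAPE_EDITS = (
    {2: (2.0, 1.0), 5: (2.0, 0.99), 6: (2.5, 1.0)},
    {2: (-2.5, 1.0), 3: (-1.0, 1.0), 6: (-3.0, 1.0)},
    {3: (0.5, 1.0), 4: (0.5, 0.995), 5: (1.5, 1.0)},
    {2: (1.5, 0.98), 3: (1.0, 0.98), 4: (0.5, 0.98), 5: (1.0, 0.99)},
    {3: (-1.0, 1.0), 4: (-0.5, 1.005), 5: (-1.0, 1.0)},
    {1: (2.0, 1.0), 2: (3.0, 1.0), 3: (1.0, 0.99), 6: (2.0, 1.0)},
    {4: (0.0, 0.99), 5: (-2.0, 0.995), 6: (-3.0, 1.0)},
)

#: patient-data envelope used for soft physiological validation
PATIENT_ENVELOPE = {
    "lv_height_mm": (75.0, 85.0),
    "lv_wall_mm": (8.0, 11.0),
    "lv_radius_mm": (26.0, 31.0),
    "lv_volume_ml": (108.0, 140.0),
    "valve_radius_mm": (0.0, 14.0),
    "valve_height_mm": (0.0, 14.0),
}

#: generation design ranges (hard limits for the synthetic families)
DESIGN_RANGES = {
    "lv_height_mm": (73.0, 89.0),
    "lv_wall_offset_mm": (8.0, 12.0),
}


@dataclass
class CohortSpec:
    """Declarative cohort description (parsed from YAML by the CLI).

    ``kind`` is one of ``default``, ``height``, ``thickness``, ``shape`` or
    ``valve_random``; systematic kinds take explicit ``levels`` while
    ``valve_random`` takes ``n`` draws and a ``seed``.
    """

    kind: str = "default"
    levels: list = field(default_factory=list)
    n: int = 0
    seed: int = 0
    population: str = "adult"


def height_family(base: LVProfile, heights=DEFAULT_HEIGHTS, n_theta: int = 96) -> list:
    """LV models with the base profile z-rescaled to each target height."""
    models = []
    for i, h in enumerate(heights):
        if h <= 0:
            raise ValueError("heights must be positive")
        models.append(build_lv(base.with_height(h), n_theta=n_theta, model_id=f"height_{i + 1}"))
    return models


def thickness_family(base: LVProfile, offsets=DEFAULT_WALL_OFFSETS, n_theta: int = 96) -> list:
    """LV models with the wall offset replaced per level; inner profile unchanged."""
    models = []
    for i, off in enumerate(offsets):
        if off <= 0:
            raise ValueError("offsets must be positive")
        models.append(build_lv(base.with_wall_offset(off), n_theta=n_theta, model_id=f"thickness_{i + 1}"))
    return models


def shape_family(base: LVProfile, edits=DEFAULT_SHAPE_EDITS, n_theta: int = 96) -> list:
    """LV models with per-section centre shifts / radius rescales applied."""
    return [
        build_lv(base.edited(edit), n_theta=n_theta, model_id=f"shape_{i + 1}")
        for i, edit in enumerate(edits)
    ]


def build_default_cohort(n_theta: int = 96) -> tuple:
    """The 22-model default cohort (1 original + 7 height + 7 thickness +
    7 shape) and its measurement manifest.

    Fully deterministic: reruns are bit-identical.
    """
    base = default_profile()
    models = [build_lv(base, n_theta=n_theta, model_id="original")]
    models += height_family(base, n_theta=n_theta)
    models += thickness_family(base, n_theta=n_theta)
    models += shape_family(base, n_theta=n_theta)
    records = []
    for model in models:
        meas = measure_lv(model)
        flags = validate_physiology({"kind": "lv", **meas.as_dict()}, population="adult")
        records.append(MeasurementRecord(model_id=model.model_id, dimensions=meas.as_dict(), flags=flags))
    return models, cohort_manifest(records)


@dataclass
class MeasurementRecord:
    """One manifest row: model id, measured dimensions, validation flags."""

    model_id: str
    dimensions: dict
    flags: dict


def cohort_manifest(records) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {"id": rec.model_id}
        row.update(rec.dimensions)
        row["hard_failures"] = ";".join(k for k, v in rec.flags.items() if v == "hard_fail")
        row["warnings"] = ";".join(k for k, v in rec.flags.items() if v == "warn")
        rows.append(row)
    return pd.DataFrame(rows)


def sample_valve_cohort(
    n: int,
    seed: int,
    population: str = "adult",
    prefer_common: bool = False,
) -> list:
    """Draw ``n`` (LeafletParams, RootParams) pairs uniformly within the
    physiological ranges of ``population``.

    With ``prefer_common=True`` the aortic diameter is drawn from the
    commonly observed sub-range with probability 0.7 and from the full range
    otherwise.  Identical seeds give identical draws (PCG64 generator).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    ranges = ROOT_RANGES[population]
    out = []
    for _ in range(n):
        lo, hi = ranges["aortic_diameter"]
        if prefer_common and rng.random() < 0.7:
            lo, hi = ROOT_COMMON_RANGES[population]["aortic_diameter"]
        diameter = rng.uniform(lo, hi)
        root = RootParams(
            annulus_radius=diameter / 2.0,
            bulb_height=rng.uniform(*ranges["bulb_height"]),
            sinus_height=rng.uniform(*ranges["sinus_height"]),
            sinus_depth=rng.uniform(*ranges["sinus_depth"]),
            population=population,
        )
        leaflet = LeafletParams(
            R=root.annulus_radius,
            H=rng.uniform(8.0, 14.0),
            a=rng.uniform(0.1, 5.0),
            k=rng.uniform(0.5, 4.0),
        )
        out.append((leaflet, root))
    return out


def validate_physiology(measurements: dict, population: str = "adult") -> dict:
    """Per-dimension validation flags: ``ok``, ``warn`` or ``hard_fail``.

    Hard limits are the generation design ranges (a synthetic model outside
    them is malformed); warnings mark dimensions outside the measured
    patient envelope, which the systematic families intentionally bracket.
    Valve parameters are checked against the population ranges (hard).
    """
    flags = {}
    kind = measurements.get("kind", "lv")
    if kind == "lv":
        h = measurements.get("height_mm")
        if h is not None:
            lo, hi = DESIGN_RANGES["lv_height_mm"]
            flags["height"] = "ok" if lo - 1e-9 <= h <= hi + 1e-9 else "hard_fail"
            plo, phi = PATIENT_ENVELOPE["lv_height_mm"]
            if flags["height"] == "ok" and not (plo <= h <= phi):
                flags["height"] = "warn"
        vol = measurements.get("cavity_volume_ml")
        if vol is not None:
            lo, hi = PATIENT_ENVELOPE["lv_volume_ml"]
            # soft check with 15% slack around the patient span
            if lo * 0.85 <= vol <= hi * 1.15:
                flags["volume"] = "ok" if lo <= vol <= hi else "warn"
            else:
                flags["volume"] = "warn"
        ravg = measurements.get("radius_avg_mm")
        if ravg is not None:
            plo, phi = PATIENT_ENVELOPE["lv_radius_mm"]
            flags["radius"] = "ok" if plo <= ravg <= phi else "warn"
        tavg = measurements.get("thickness_avg_mm")
        if tavg is not None:
            plo, phi = PATIENT_ENVELOPE["lv_wall_mm"]
            flags["thickness"] = "ok" if plo <= tavg <= phi else "warn"
    elif kind == "valve":
        rng = ROOT_RANGES[population]
        diam = measurements.get("aortic_diameter_mm")
        if diam is not None:
            lo, hi = rng["aortic_diameter"]
            flags["aortic_diameter"] = "ok" if lo - 1e-9 <= diam <= hi + 1e-9 else "hard_fail"
        depth = measurements.get("sinus_depth_mm")
        if depth is not None:
            lo, hi = rng["sinus_depth"]
            flags["sinus_depth"] = "ok" if lo - 1e-9 <= depth <= hi + 1e-9 else "hard_fail"
        for key, envelope in (("leaflet_radius_mm", "valve_radius_mm"), ("leaflet_height_mm", "valve_height_mm")):
            val = measurements.get(key)
            if val is not None:
                lo, hi = PATIENT_ENVELOPE[envelope]
                flags[key.replace("_mm", "")] = "ok" if lo <= val <= hi else "warn"
    else:
        raise ValueError(f"unknown measurement kind {kind!r}")
    return flags
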