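"""Synthetic soma contours and full hierarchical studies.

The contour model is a radial Fourier ellipse: an ellipse of given
axis ratio whose radius is modulated by random cosine harmonics in two
bands — a low-frequency band (default harmonics 2–6) producing
large-scale convolutions that raise the shape factor, and a
high-frequency band (default 12–40) producing fine roughness that
lowers the form factor.  The four generative axes map one-to-one onto
the descriptor families: axis ratio ↔ flatness (aspect ratio,
compactness, roundness), low band ↔ shape factor, high band ↔ form
factor, target area ↔ size (area, Feret diameters).

A full synthetic study reproduces the experiment's hierarchical
structure: two groups of birds (6 statin-treated, 7 control), bird-level
random effects on the generative parameters, 13–100 traced birthdated
cells per bird (mean ≈ 40), a larger grid-sampled non-birthdated
population, two brain regions of 10–12 sections each (6 µm thick,
every 8th collected), and experiment-range covariates.  Group effects
are declared through an :class:`EffectSpec` and the realized bird-level
parameters are emitted as a ground-truth table for recovery testing.

All randomness flows from one study-level seed through named
substreams, so any component can be regenerated independently.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .geometry import Contour, _signed_area
from .grid import CellMarker
from .stereology import SectionTracing

__all__ = [
    "MorphGenParams",
    "EffectSpec",
    "CellCountDistribution",
    "StudyDataset",
    "GenerationError",
    "BASE_PARAMS",
    "gen_contour",
    "gen_bird",
    "gen_study",
    "gen_bird_mean_samples",
    "null_effects",
    "reported_direction_effects",
    "substream",
]


class GenerationError(RuntimeError):
    """Raised when contour generation cannot produce a simple polygon."""


@dataclass(frozen=True)
class MorphGenParams:
    """Generative parameters for one soma contour.

    ``convolution_amp`` and ``roughness_amp`` are radial modulation
    amplitudes (relative to the local ellipse radius) spread over their
    harmonic bands; amplitudes must stay small enough that the radius
    remains positive.
    """

    target_area: float = 70.0  # µm²
    axis_ratio: float = 0.75  # minor/major, (0, 1]
    convolution_amp: float = 0.02
    roughness_amp: float = 0.01
    n_vertices: int = 256
    convolution_band: tuple[int, int] = (2, 6)
    roughness_band: tuple[int, int] = (12, 40)
    rng_seed: Optional[int] = None


def substream(seed: int, *names) -> np.random.Generator:
    """A named, order-independent child RNG of the study seed."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def gen_contour(params: MorphGenParams, rng: Optional[np.random.Generator] = None) -> Contour:
    """Draw one simple closed contour from the radial Fourier ellipse model.

    The radial function r(θ) = ellipse(θ; axis_ratio) · (1 + Σ aₖcos(kθ+φₖ))
    is sampled at ``n_vertices`` equally spaced angles, randomly rotated,
    and rescaled so the polygon area equals ``target_area`` exactly.
    Because the radius is positive and angles are strictly increasing,
    the polygon is star-shaped, hence simple and counter-clockwise by
    construction; draws whose radius dips non-positive are rejected and
    resampled.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    n = params.n_vertices
    if n < 8:
        raise GenerationError("need at least 8 vertices")
    if not (0.0 < params.axis_ratio <= 1.0):
        raise GenerationError("axis_ratio must lie in (0, 1]")
    if params.target_area <= 0:
        raise GenerationError("target_area must be positive")
    theta = 2.0 * np.pi * np.arange(n) / n
    b = params.axis_ratio
    r0 = b / np.hypot(b * np.cos(theta), np.sin(theta))  # unit-major-axis ellipse

    for _ in range(100):
        pert = np.zeros(n)
        for (k_lo, k_hi), amp in (
            (params.convolution_band, params.convolution_amp),
            (params.roughness_band, params.roughness_amp),
        ):
            if amp <= 0:
                continue
            ks = np.arange(k_lo, k_hi + 1)
            a_k = rng.normal(0.0, amp / math.sqrt(len(ks)), size=len(ks))
            phi = rng.uniform(0.0, 2.0 * np.pi, size=len(ks))
            pert += (a_k[:, None] * np.cos(ks[:, None] * theta[None, :] + phi[:, None])).sum(0)
        r = r0 * (1.0 + pert)
        if r.min() > 1e-3:
            break
    else:
        raise GenerationError("could not draw a positive-radius contour in 100 attempts")

    rot = rng.uniform(0.0, 2.0 * np.pi)
    v = np.column_stack([r * np.cos(theta + rot), r * np.sin(theta + rot)])
    scale = math.sqrt(params.target_area / _signed_area(v))
    return Contour(v * scale)


@dataclass(frozen=True)
class CellCountDistribution:
    """Discretized log-normal cell count, clipped to [low, high].

    Defaults match the traced birthdated population: 13–100 cells per
    bird, mean ≈ 40, right-skewed.
    """

    mean: float = 40.0
    low: int = 13
    high: int = 100
    sigma: float = 0.6

    def sample(self, rng: np.random.Generator, size=None):
        mu = math.log(self.mean) - 0.5 * self.sigma**2
        x = np.rint(rng.lognormal(mu, self.sigma, size=size))
        return np.clip(x, self.low, self.high).astype(int)


#: baseline generative parameters per neuron population: the birthdated
#: 30–32 day-old cells (BRDU_HU) are smaller than the heterogeneous,
#: mostly older HU_ONLY population
BASE_PARAMS: dict[str, MorphGenParams] = {
    "BRDU_HU": MorphGenParams(target_area=70.0, axis_ratio=0.75,
                              convolution_amp=0.02, roughness_amp=0.010),
    "HU_ONLY": MorphGenParams(target_area=100.0, axis_ratio=0.78,
                              convolution_amp=0.02, roughness_amp=0.008),
}

#: fields of MorphGenParams that carry bird- and cell-level variation;
#: target_area varies multiplicatively (log scale, key "log_area")
_VARYING_FIELDS = ("axis_ratio", "convolution_amp", "roughness_amp", "log_area")


@dataclass
class EffectSpec:
    """Group-level generative deltas and the study's noise structure.

    ``deltas`` maps ``(population, field)`` to ``(mode, value)`` where
    mode is ``"add"`` or ``"mul"``; deltas apply to the statin group
    only.  ``density_scale`` multiplies the statin group's expected
    labeled-cell counts per phenotype.  ``bird_sd`` and ``cell_sd`` are
    the between-bird random-effect and within-bird cell-jitter SDs per
    varying field (``log_area`` on the natural-log scale).
    """

    deltas: Mapping[tuple[str, str], tuple[str, float]] = field(default_factory=dict)
    density_scale: Mapping[str, float] = field(default_factory=dict)
    bird_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "axis_ratio": 0.030,
            "convolution_amp": 0.008,
            "roughness_amp": 0.012,
            "log_area": 0.055,
        }
    )
    cell_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "axis_ratio": 0.080,
            "convolution_amp": 0.015,
            "roughness_amp": 0.020,
            "log_area": 0.250,
        }
    )
    cell_counts: Mapping[str, CellCountDistribution] = field(
        default_factory=lambda: {
            "BRDU_HU": CellCountDistribution(mean=40.0, low=13, high=100, sigma=0.6),
            "HU_ONLY": CellCountDistribution(mean=38.0, low=14, high=66, sigma=0.36),
        }
    )


def null_effects() -> EffectSpec:
    """No group differences anywhere: the type-I-error condition."""
    return EffectSpec()


def reported_direction_effects() -> EffectSpec:
    """The study's reported effect directions as generative deltas.

    Birthdated new neurons in the statin group are flatter (axis ratio
    −0.06) and rougher (high-band amplitude +0.03); the older
    non-birthdated population is 10% smaller in area; labeled-cell
    densities are unaffected.
    """
    return EffectSpec(
        deltas={
            ("BRDU_HU", "axis_ratio"): ("add", -0.06),
            ("BRDU_HU", "roughness_amp"): ("add", +0.03),
            ("HU_ONLY", "target_area"): ("mul", 0.90),
        }
    )


def _apply_deltas(base: MorphGenParams, population: str, group: str,
                  effects: EffectSpec) -> MorphGenParams:
    if group != "statin":
        return base
    p = base
    for (pop, fld), (mode, value) in effects.deltas.items():
        if pop != population:
            continue
        cur = getattr(p, fld)
        new = cur + value if mode == "add" else cur * value
        p = replace(p, **{fld: new})
    return p


def _draw_bird_params(base: MorphGenParams, effects: EffectSpec,
                      rng: np.random.Generator) -> MorphGenParams:
    """Bird-level parameter means: group mean plus bird random effect."""
    sd = effects.bird_sd
    p = replace(
        base,
        axis_ratio=float(np.clip(base.axis_ratio + rng.normal(0, sd["axis_ratio"]), 0.05, 1.0)),
        convolution_amp=max(0.0, base.convolution_amp + rng.normal(0, sd["convolution_amp"])),
        roughness_amp=max(0.0, base.roughness_amp + rng.normal(0, sd["roughness_amp"])),
        target_area=base.target_area * math.exp(rng.normal(0, sd["log_area"])),
    )
    return p


def _jitter_cell_params(bird: MorphGenParams, effects: EffectSpec,
                        rng: np.random.Generator) -> MorphGenParams:
    sd = effects.cell_sd
    return replace(
        bird,
        axis_ratio=float(np.clip(bird.axis_ratio + rng.normal(0, sd["axis_ratio"]), 0.05, 1.0)),
        convolution_amp=max(0.0, bird.convolution_amp + rng.normal(0, sd["convolution_amp"])),
        roughness_amp=max(0.0, bird.roughness_amp + rng.normal(0, sd["roughness_amp"])),
        target_area=bird.target_area * math.exp(rng.normal(0, sd["log_area"])),
    )


def _uniform_points_in(outline: Contour, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by vectorized rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    poly = outline.to_shapely()
    xmin, ymin, xmax, ymax = outline.bounds
    out = []
    got = 0
    while got < n:
        m = max(64, int((n - got) * 2.5))
        xs = rng.uniform(xmin, xmax, m)
        ys = rng.uniform(ymin, ymax, m)
        inside = shapely.contains_xy(poly, xs, ys)
        pts = np.column_stack([xs[inside], ys[inside]])
        out.append(pts)
        got += len(pts)
    return np.concatenate(out)[:n]


#: section-outline generator defaults: smooth ~0.35 mm² cross sections
_SECTION_PARAMS = MorphGenParams(
    target_area=3.5e5, axis_ratio=0.65, convolution_amp=0.05,
    roughness_amp=0.004, n_vertices=128,
)

#: expected DCX+ areal density, cells/mm² (immature-neuron cohort)
DCX_DENSITY_MM2 = 300.0


def gen_bird(
    group: str,
    population: str,
    effects: EffectSpec,
    rng: np.random.Generator,
    outlines: Optional[Sequence[Contour]] = None,
    n_cells: Optional[int] = None,
    with_contours: bool = True,
    id_prefix: str = "cell",
) -> tuple[MorphGenParams, list[CellMarker], list[int]]:
    """Generate one bird's cells for one population.

    Draws the bird-level parameter means (group mean + random effect)
    and the cell count, then per-cell contours with cell-level jitter;
    cells are positioned uniformly inside the provided section outlines
    (allocated in proportion to section area) or inside a single
    generated outline when none are given.

    Returns (bird-level params, markers, per-marker section indices).
    """
    base = _apply_deltas(BASE_PARAMS[population], population, group, effects)
    bird_params = _draw_bird_params(base, effects, rng)
    if n_cells is None:
        n_cells = int(effects.cell_counts[population].sample(rng))
    if outlines is None:
        outlines = [gen_contour(_SECTION_PARAMS, rng)]
    areas = np.array([abs(_signed_area(o.vertices)) for o in outlines], dtype=float)
    alloc = rng.multinomial(n_cells, areas / areas.sum())

    markers: list[CellMarker] = []
    section_of: list[int] = []
    k = 0
    for si, (outline, m) in enumerate(zip(outlines, alloc)):
        pts = _uniform_points_in(outline, int(m), rng)
        for p in pts:
            contour = None
            if with_contours:
                cell_params = _jitter_cell_params(bird_params, effects, rng)
                c = gen_contour(cell_params, rng)
                contour = c.translated(p[0] - c.vertices[:, 0].mean(),
                                       p[1] - c.vertices[:, 1].mean())
            markers.append(
                CellMarker(cell_id=f"{id_prefix}-{k:04d}", position=(float(p[0]), float(p[1])),
                           phenotype=population if population in ("BRDU_HU", "HU_ONLY") else "DCX",
                           contour=contour)
            )
            section_of.append(si)
            k += 1
    return bird_params, markers, section_of


@dataclass
class StudyDataset:
    """A full synthetic study: bird table, traced sections with markers,
    and the generative ground truth."""

    birds: pd.DataFrame
    sections: list[SectionTracing]
    seed: Optional[int] = None
    truth: Optional[pd.DataFrame] = None

    def sections_of(self, bird_id: str, region: Optional[str] = None) -> list[SectionTracing]:
        return [
            s for s in self.sections
            if s.bird_id == bird_id and (region is None or s.region == region)
        ]


def _draw_covariates(rng: np.random.Generator) -> dict[str, int]:
    first_brdu = int(rng.integers(75, 80))
    perfusion = first_brdu + 32  # 2 more injection days + 30 d survival
    lo = max(18, perfusion - 92)
    hi = min(49, perfusion - 62)
    start = int(rng.integers(lo, hi + 1))
    return {
        "age_at_treatment_start": start,
        "treatment_duration": perfusion - start,
        "age_at_first_brdu": first_brdu,
        "age_at_perfusion": perfusion,
    }


def gen_study(
    n_statin: int = 6,
    n_control: int = 7,
    effects: Optional[EffectSpec] = None,
    seed: int = 0,
    regions: Sequence[str] = ("HVC", "NCM"),
    hu_marker_multiplier: int = 4,
) -> StudyDataset:
    """Generate a complete hierarchical study.

    Per bird: covariates from the experimental ranges (treatment start
    18–49 d, first BrdU 75–79 d, perfusion 32 d later, duration the
    difference), 10–12 sections per region (6 µm thick, every 8th
    collected), birthdated BrdU+/Hu+ cells traced in HVC, a
    non-birthdated Hu+ marker population about ``hu_marker_multiplier``
    times the intended traced count (the grid rule later samples ~1/4),
    and DCX+ point markers in both regions.  Deterministic given
    ``seed``; the realized bird-level parameters are returned in
    ``truth``.
    """
    if n_statin < 2 or n_control < 2:
        raise GenerationError("need at least 2 birds per group")
    effects = effects if effects is not None else null_effects()

    bird_rows = []
    truth_rows = []
    sections: list[SectionTracing] = []
    bird_ids = [f"S{i+1:02d}" for i in range(n_statin)] + [
        f"C{i+1:02d}" for i in range(n_control)
    ]
    groups = ["statin"] * n_statin + ["control"] * n_control

    for bird_id, group in zip(bird_ids, groups):
        rng_cov = substream(seed, "covariates", bird_id)
        cov = _draw_covariates(rng_cov)
        bird_rows.append({"bird_id": bird_id, "group": group, **cov})

        for region in regions:
            rng_sec = substream(seed, "sections", bird_id, region)
            n_sec = int(rng_sec.integers(10, 13))
            outlines = []
            for si in range(n_sec):
                area_factor = math.exp(rng_sec.normal(0.0, 0.15))
                sec_params = replace(
                    _SECTION_PARAMS,
                    target_area=_SECTION_PARAMS.target_area * area_factor,
                    axis_ratio=float(rng_sec.uniform(0.55, 0.75)),
                )
                outlines.append(gen_contour(sec_params, rng_sec))
            lateral0 = 300.0 if region == "NCM" else 0.0
            secs = [
                SectionTracing(
                    bird_id=bird_id, region=region, section_index=si,
                    outline=outlines[si], thickness_um=6.0, sampling_interval=8,
                    lateral_position_um=lateral0 + si * 48.0,
                )
                for si in range(n_sec)
            ]

            # birthdated new neurons: traced (with contours) in HVC only
            rng_new = substream(seed, "cells", bird_id, region, "BRDU_HU")
            n_new = int(effects.cell_counts["BRDU_HU"].sample(rng_new))
            if group == "statin":
                n_new = max(0, int(round(n_new * effects.density_scale.get("BRDU_HU", 1.0))))
            params_new, markers_new, sec_of = gen_bird(
                group, "BRDU_HU", effects, rng_new, outlines=outlines,
                n_cells=n_new, with_contours=(region == "HVC"),
                id_prefix=f"{bird_id}-{region}-BRDU",
            )
            for m, si in zip(markers_new, sec_of):
                secs[si].markers.append(m)
            if region == "HVC":
                truth_rows.append(
                    {"bird_id": bird_id, "group": group, "population": "BRDU_HU",
                     "axis_ratio": params_new.axis_ratio,
                     "convolution_amp": params_new.convolution_amp,
                     "roughness_amp": params_new.roughness_amp,
                     "target_area": params_new.target_area,
                     "n_cells": len(markers_new)}
                )

            # non-birthdated Hu+ population: HVC only, traced after grid sampling
            if region == "HVC":
                rng_old = substream(seed, "cells", bird_id, region, "HU_ONLY")
                n_old = hu_marker_multiplier * int(
                    effects.cell_counts["HU_ONLY"].sample(rng_old)
                )
                params_old, markers_old, sec_of = gen_bird(
                    group, "HU_ONLY", effects, rng_old, outlines=outlines,
                    n_cells=n_old, with_contours=True,
                    id_prefix=f"{bird_id}-{region}-HU",
                )
                for m, si in zip(markers_old, sec_of):
                    secs[si].markers.append(m)
                truth_rows.append(
                    {"bird_id": bird_id, "group": group, "population": "HU_ONLY",
                     "axis_ratio": params_old.axis_ratio,
                     "convolution_amp": params_old.convolution_amp,
                     "roughness_amp": params_old.roughness_amp,
                     "target_area": params_old.target_area,
                     "n_cells": len(markers_old)}
                )

            # immature (DCX+) cohort: point markers only
            rng_dcx = substream(seed, "cells", bird_id, region, "DCX")
            dcx_density = DCX_DENSITY_MM2
            if group == "statin":
                dcx_density *= effects.density_scale.get("DCX", 1.0)
            for si, sec in enumerate(secs):
                lam = dcx_density * sec.area_mm2
                n_dcx = int(rng_dcx.poisson(lam))
                pts = _uniform_points_in(outlines[si], n_dcx, rng_dcx)
                for k, p in enumerate(pts):
                    sec.markers.append(
                        CellMarker(
                            cell_id=f"{bird_id}-{region}-DCX-s{si}-{k:04d}",
                            position=(float(p[0]), float(p[1])),
                            phenotype="DCX",
                        )
                    )
            sections.extend(secs)

    birds = pd.DataFrame(bird_rows)
    truth = pd.DataFrame(truth_rows)
    return StudyDataset(birds=birds, sections=sections, seed=seed, truth=truth)


def gen_bird_mean_samples(
    field_name: str,
    effects: EffectSpec,
    population: str = "BRDU_HU",
    n_studies: int = 2000,
    n_statin: int = 6,
    n_control: int = 7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bird-level mean samples of one generative field, vectorized over studies.

    Draws each bird's mean as group mean + bird random effect + the
    cell-jitter average over that bird's drawn cell count — the same
    hierarchy :func:`gen_study` renders into contours, without the
    geometric rendering.  Used for type-I-error calibration and power
    checks of the bird-level t-tests.

    Returns ``(statin, control)`` arrays of shape (n_studies, n_birds).
    """
    if field_name not in _VARYING_FIELDS:
        raise GenerationError(f"unknown varying field {field_name!r}")
    rng = substream(seed, "bird-means", field_name, population)
    base_p = _apply_deltas(BASE_PARAMS[population], population, "statin", effects)
    base_c = BASE_PARAMS[population]

    def base_value(p: MorphGenParams) -> float:
        if field_name == "log_area":
            return math.log(p.target_area)
        return getattr(p, field_name)

    counts = effects.cell_counts[population]
    b_sd = effects.bird_sd[field_name]
    c_sd = effects.cell_sd[field_name]
    out = []
    for mu, n_birds in ((base_value(base_p), n_statin), (base_value(base_c), n_control)):
        n_cells = counts.sample(rng, size=(n_studies, n_birds))
        vals = (
            mu
            + rng.normal(0.0, b_sd, size=(n_studies, n_birds))
            + rng.normal(0.0, 1.0, size=(n_studies, n_birds)) * c_sd / np.sqrt(n_cells)
        )
        out.append(vals)
    return out[0], out[1]
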