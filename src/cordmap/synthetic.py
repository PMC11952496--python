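"""Synthetic-data generator for the whole pipeline.

Emulates the structure of the study's data with known ground truth:

* sections whose anchor landmarks are randomly similarity-transformed copies
  of the idealized template (rotation, translation, per-axis scaling);
* cells whose dorsoventral settling depth in template space is Gaussian per
  neuron family (temporal cohorts settle in adjacent laminae);
* EdU pulse-chase co-labeling counts generated from Gaussian birth waves over
  roughly E10.5-E13.5, sampled through a finite labeling window with binomial
  count noise and litter structure;
* thresholdable two-channel band images for depth-profile fixtures;
* genotype-dependent multiplicative shifts in cell-type frequencies.

All randomness flows through ``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .template import EXTENT, TemplateSpec


# ---------------------------------------------------------------------------
# sections


@dataclass(frozen=True)
class GroundTruthSection:
    """A synthetic section with its generating perturbation stored.

    ``raw = translation + R(angle) @ (diag(scale_x, scale_y) @ template)``;
    re-applying the stored transform to the template anchors reproduces the
    raw anchors to machine precision.
    """

    section_id: str
    genotype: str
    segment_zone: str
    angle_deg: float
    translation: Tuple[float, float]
    scale_x: float
    scale_y: float
    anchors_raw: pd.DataFrame = field(repr=False)
    template: TemplateSpec = field(repr=False)
    seed: int

    def __post_init__(self) -> None:
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValueError("per-axis scale factors must be positive")

    def apply_transform(self, xy: np.ndarray) -> np.ndarray:
        """Map template-space points (n, 2) into raw section space."""
        xy = np.asarray(xy, dtype=float)
        t = np.deg2rad(self.angle_deg)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        scaled = xy * np.array([self.scale_x, self.scale_y])
        return scaled @ rot.T + np.asarray(self.translation)


def perturb_section(
    template: TemplateSpec,
    seed: int,
    *,
    section_id: str = "S0",
    genotype: str = "wt",
    max_rotation_deg: float = 30.0,
    scale_range: Tuple[float, float] = (0.8, 1.25),
    anisotropy_range: Tuple[float, float] = (1.0, 1.0),
    translation_range: float = 500.0,
) -> GroundTruthSection:
    """Sample a random similarity-type perturbation of the template anchors.

    The transform is translation o rotation o per-axis scaling.  With the
    default ``anisotropy_range`` the scaling is isotropic, which the
    registration model inverts exactly.
    """
    if scale_range[0] <= 0 or anisotropy_range[0] <= 0:
        raise ValueError("scale and anisotropy ranges must be positive")
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    s = rng.uniform(*scale_range)
    a = rng.uniform(*anisotropy_range)
    scale_x = s * np.sqrt(a)
    scale_y = s / np.sqrt(a)
    translation = tuple(rng.uniform(-translation_range, translation_range, size=2))
    section = GroundTruthSection(
        section_id=section_id,
        genotype=genotype,
        segment_zone=template.segment_zone,
        angle_deg=float(angle),
        translation=translation,
        scale_x=float(scale_x),
        scale_y=float(scale_y),
        anchors_raw=pd.DataFrame(),
        template=template,
        seed=seed,
    )
    names = list(template.anchors)
    pts = np.array([template.anchors[n] for n in names])
    raw = section.apply_transform(pts)
    anchors = pd.DataFrame(
        {"section_id": section_id, "anchor_name": names, "x": raw[:, 0], "y": raw[:, 1]}
    )
    object.__setattr__(section, "anchors_raw", anchors)
    return section


def sample_family_cells(
    section: GroundTruthSection,
    family_depth_params: Mapping[str, Mapping[str, float]],
    n_per_family: Mapping[str, int] | int,
    seed: int,
) -> pd.DataFrame:
    """Draw per-family cells in template space and map them into raw space.

    ``family_depth_params[family]`` supplies ``y_mean``/``y_sd`` (template
    dorsoventral settling depth) and ``x_center``/``x_sd`` (mediolateral
    position within one hemisection, in positive template units; each cell is
    assigned a random side).  Coordinates are truncated to the template
    extent.  True template coordinates are retained as ``true_x``/``true_y``.
    """
    rng = np.random.default_rng(seed)
    frames: List[pd.DataFrame] = []
    for family, params in family_depth_params.items():
        n = n_per_family if isinstance(n_per_family, int) else n_per_family.get(family, 0)
        if n < 0:
            raise ValueError("n_per_family must be non-negative")
        if n == 0:
            continue
        ym, ys = params["y_mean"], params["y_sd"]
        xc, xs = params["x_center"], params["x_sd"]
        ty = truncnorm.rvs(
            (-EXTENT - ym) / ys, (EXTENT - ym) / ys, loc=ym, scale=ys, size=n,
            random_state=rng,
        )
        side = rng.choice([-1.0, 1.0], size=n)
        tx = truncnorm.rvs(
            (0.0 - xc) / xs, (EXTENT - xc) / xs, loc=xc, scale=xs, size=n,
            random_state=rng,
        ) * side
        raw = section.apply_transform(np.column_stack([tx, ty]))
        frames.append(
            pd.DataFrame(
                {
                    "section_id": section.section_id,
                    "cell_id": [f"{section.section_id}_{family}_{i}" for i in range(n)],
                    "x": raw[:, 0],
                    "y": raw[:, 1],
                    "true_x": tx,
                    "true_y": ty,
                    "family": family,
                    "genotype": section.genotype,
                    "segment_zone": section.segment_zone,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "section_id", "cell_id", "x", "y", "true_x", "true_y",
                "family", "genotype", "segment_zone",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# EdU pulse-chase birthdating


@dataclass(frozen=True)
class WaveParams:
    """Gaussian birth wave of one neuron family."""

    mean: float  # embryonic day of peak neurogenesis
    sd: float    # spread in days

    def __post_init__(self) -> None:
        if not (10.0 <= self.mean <= 14.0):
            raise ValueError("birth wave mean must lie within [E10.0, E14.0]")
        if self.sd <= 0:
            raise ValueError("birth wave sd must be positive")


@dataclass(frozen=True)
class BirthWaveModel:
    """Study design for a cumulative EdU birthdating experiment.

    A pulse delivered at embryonic day ``t`` labels every cell born in the
    window ``[t, t + window]``; half-day window by default because EdU
    remains available for a few hours and pulses are half-day spaced.
    """

    families: Mapping[str, WaveParams]
    window: float = 0.5
    embryos_per_litter: int = 3
    neurons_per_embryo: int = 200

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("labeling window must be positive")
        if self.embryos_per_litter < 1 or self.neurons_per_embryo < 1:
            raise ValueError("embryo and neuron counts must be positive integers")


def labeling_probability(wave: WaveParams, pulse_day: float, window: float) -> float:
    """P(birthdate in [pulse, pulse+window]) under the family's Gaussian wave."""
    return float(
        norm.cdf(pulse_day + window, loc=wave.mean, scale=wave.sd)
        - norm.cdf(pulse_day, loc=wave.mean, scale=wave.sd)
    )


DEFAULT_PULSE_DAYS = (10.5, 11.0, 11.5, 12.0, 12.5, 13.0, 13.5)


def simulate_pulse_panel(
    model: BirthWaveModel,
    pulse_times: Sequence[float] = DEFAULT_PULSE_DAYS,
    n_litters_per_time: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-embryo EdU co-labeling counts per family and pulse time.

    Each litter is pulsed at a single timepoint.  For every embryo and family
    the co-labeled count is Binomial(neurons_per_embryo, p) with p the
    closed-form Gaussian interval probability of :func:`labeling_probability`.
    """
    pulse_times = list(pulse_times)
    if not pulse_times:
        raise ValueError("pulse_times must be non-empty")
    if sorted(pulse_times) != pulse_times:
        raise ValueError("pulse_times must be sorted ascending")
    rng = np.random.default_rng(seed)
    records = []
    litter_counter = 0
    for t in pulse_times:
        for _ in range(n_litters_per_time):
            litter_counter += 1
            litter = f"L{litter_counter:03d}"
            for e in range(model.embryos_per_litter):
                embryo = f"{litter}_E{e + 1}"
                for family, wave in model.families.items():
                    p = labeling_probability(wave, t, model.window)
                    n_total = model.neurons_per_embryo
                    n_co = int(rng.binomial(n_total, p))
                    records.append(
                        (litter, embryo, t, family, n_co, n_total)
                    )
    return pd.DataFrame(
        records,
        columns=["litter", "embryo", "pulse_day", "family", "n_colabeled", "n_total"],
    )


# ---------------------------------------------------------------------------
# depth-profile image fixtures

Interval = Tuple[int, int]


def simulate_depth_images(
    band_spec: Sequence[Sequence[Interval]],
    height: int,
    width: int,
    noise_rate: float = 0.0,
    seed: int = 0,
    *,
    band_value: int = 200,
    background_value: int = 20,
) -> Tuple[np.ndarray, ...]:
    """Render 8-bit grayscale band images, one per channel.

    ``band_spec`` lists, per channel, half-open row intervals ``[start, stop)``
    that carry high intensity.  Salt noise sets random pixels to 255 with
    probability ``noise_rate``.  With a mid-range threshold the supra-threshold
    rows of each channel equal its band rows exactly when ``noise_rate`` is 0.
    """
    rng = np.random.default_rng(seed)
    images = []
    for bands in band_spec:
        img = np.full((height, width), background_value, dtype=np.uint8)
        for start, stop in bands:
            if not (0 <= start < stop <= height):
                raise ValueError(f"invalid band interval ({start}, {stop})")
            img[start:stop, :] = band_value
        if noise_rate > 0:
            salt = rng.random((height, width)) < noise_rate
            img[salt] = 255
        images.append(img)
    return tuple(images)


# ---------------------------------------------------------------------------
# genotype composition effects


@dataclass(frozen=True)
class CompositionEffect:
    """Multiplicative per-cell-type frequency factors for a mutant genotype."""

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        for k, v in self.factors.items():
            if v < 0:
                raise ValueError(f"negative factor for {k!r}")


def apply_composition_effect(
    base_means: Mapping[str, float],
    effect: CompositionEffect,
    n_replicates: int,
    seed: int,
) -> pd.DataFrame:
    """Draw mutant per-replicate counts ~ Poisson(factor x base mean).

    Cell types absent from ``effect.factors`` keep factor 1 (unchanged mean).
    """
    for v in base_means.values():
        if v < 0:
            raise ValueError("base means must be non-negative")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_replicates):
        for cell_type, mean in base_means.items():
            f = effect.factors.get(cell_type, 1.0)
            records.append((f"mut_rep{rep + 1}", cell_type, int(rng.poisson(f * mean))))
    return pd.DataFrame(records, columns=["replicate", "cell_type", "count"])


# ---------------------------------------------------------------------------
# dataset assembly (used by the CLI `simulate` stage)

DEFAULT_FAMILY_DEPTHS: Dict[str, Dict[str, float]] = {
    # temporal cohorts settle at progressively more dorsal template depths
    "dILB1": {"y_mean": 600.0, "y_sd": 220.0, "x_center": 1000.0, "x_sd": 350.0},
    "dILB2": {"y_mean": 1000.0, "y_sd": 200.0, "x_center": 1000.0, "x_sd": 350.0},
    "dILB3": {"y_mean": 1400.0, "y_sd": 180.0, "x_center": 950.0, "x_sd": 330.0},
    "dILB4": {"y_mean": 1750.0, "y_sd": 150.0, "x_center": 900.0, "x_sd": 300.0},
}

DEFAULT_WAVES: Dict[str, WaveParams] = {
    "dILB1": WaveParams(mean=11.0, sd=0.35),
    "dILB2": WaveParams(mean=11.5, sd=0.35),
    "dILB3": WaveParams(mean=12.0, sd=0.35),
    "dILB4": WaveParams(mean=12.5, sd=0.35),
}


def simulate_dataset(
    template: TemplateSpec,
    seed: int,
    *,
    n_sections_per_genotype: int = 3,
    n_cells_per_family: int = 150,
    genotypes: Sequence[str] = ("wt", "mut"),
    effect: CompositionEffect | None = None,
    family_depth_params: Mapping[str, Mapping[str, float]] | None = None,
    waves: Mapping[str, WaveParams] | None = None,
) -> Dict[str, object]:
    """Generate a coherent demo dataset: sections, cells, pulse panel, truth.

    Returns a dict with keys ``sections`` (list of GroundTruthSection),
    ``anchors`` / ``cells`` / ``pulse_counts`` (DataFrames) and ``truth``
    (JSON-serializable ground-truth record).
    """
    depths = dict(family_depth_params or DEFAULT_FAMILY_DEPTHS)
    waves = dict(waves or DEFAULT_WAVES)
    effect = effect or CompositionEffect(factors={})
    rng = np.random.default_rng(seed)
    sections: List[GroundTruthSection] = []
    cell_frames: List[pd.DataFrame] = []
    anchor_frames: List[pd.DataFrame] = []
    for genotype in genotypes:
        for i in range(n_sections_per_genotype):
            sec_seed = int(rng.integers(0, 2**31 - 1))
            section = perturb_section(
                template,
                sec_seed,
                section_id=f"{genotype}_S{i + 1}",
                genotype=genotype,
            )
            n_per_family = {}
            for family in depths:
                f = effect.factors.get(family, 1.0) if genotype != genotypes[0] else 1.0
                n_per_family[family] = int(rng.poisson(f * n_cells_per_family))
            cells = sample_family_cells(
                section, depths, n_per_family, seed=int(rng.integers(0, 2**31 - 1))
            )
            sections.append(section)
            anchor_frames.append(section.anchors_raw)
            cell_frames.append(cells)
    panel = simulate_pulse_panel(
        BirthWaveModel(families=waves),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    truth = {
        "seed": seed,
        "sections": [
            {
                "section_id": s.section_id,
                "genotype": s.genotype,
                "segment_zone": s.segment_zone,
                "angle_deg": s.angle_deg,
                "translation": list(s.translation),
                "scale_x": s.scale_x,
                "scale_y": s.scale_y,
            }
            for s in sections
        ],
        "waves": {k: {"mean": w.mean, "sd": w.sd} for k, w in waves.items()},
        "depths": {k: dict(v) for k, v in depths.items()},
        "effect": dict(effect.factors),
    }
    return {
        "sections": sections,
        "anchors": pd.concat(anchor_frames, ignore_index=True),
        "cells": pd.concat(cell_frames, ignore_index=True),
        "pulse_counts": panel,
        "truth": truth,
    }
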