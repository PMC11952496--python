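"""File formats, run configuration and the pipeline driver.

Conventions fixed package-wide: template y increases dorsally; CSV
coordinates are continuous; images must declare their row orientation
(pass ``y_down=True`` for image coordinates with row 0 at the top to flip
them on read).  Percentages are stored on the 0-100 scale in outputs,
fractions on 0-1 internally.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import birthdating, composition, density, depth, registration, synthetic
from .template import ANCHOR_NAMES, make_template

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A CSV file failed schema validation."""


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def _require_numeric(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[vals.isna() & df[c].notna()].tolist()
        if bad:
            raise SchemaError(f"{path}: non-numeric values in {c!r} at rows {bad[:10]}")
        df[c] = vals


def read_anchors(path) -> pd.DataFrame:
    """Read and validate an anchors.csv (section_id, anchor_name, x, y)."""
    df = pd.read_csv(path)
    _require_columns(df, ["section_id", "anchor_name", "x", "y"], path)
    _require_numeric(df, ["x", "y"], path)
    unknown = set(df["anchor_name"]) - set(ANCHOR_NAMES)
    if unknown:
        raise SchemaError(f"{path}: unknown anchor names {sorted(unknown)}")
    for sec, sub in df.groupby("section_id"):
        dupes = sub["anchor_name"][sub["anchor_name"].duplicated()].tolist()
        if dupes:
            raise SchemaError(
                f"{path}: duplicate anchor {dupes[0]!r} in section {sec!r}"
            )
    return df


def read_cells(path, y_down: bool = False) -> pd.DataFrame:
    """Read and validate a cells.csv (section_id, cell_id, x, y, labels...)."""
    df = pd.read_csv(path)
    _require_columns(df, ["section_id", "cell_id", "x", "y"], path)
    _require_numeric(df, ["x", "y"], path)
    if y_down:
        df["y"] = -df["y"]
    return df


def read_counts(path) -> pd.DataFrame:
    """Read and validate a pulse_counts.csv."""
    df = pd.read_csv(path)
    cols = ["litter", "embryo", "pulse_day", "family", "n_colabeled", "n_total"]
    _require_columns(df, cols, path)
    _require_numeric(df, ["pulse_day", "n_colabeled", "n_total"], path)
    bad = df.index[(df["n_colabeled"] < 0) | (df["n_colabeled"] > df["n_total"])].tolist()
    if bad:
        raise SchemaError(
            f"{path}: rows with n_colabeled outside [0, n_total]: {bad[:10]}"
        )
    return df


def read_image(path, y_down: bool = True) -> np.ndarray:
    """Read a grayscale image (PNG via imageio or NPY); flip if row 0 is dorsal."""
    path = Path(path)
    if path.suffix == ".npy":
        img = np.load(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img if y_down else img[::-1]


@dataclass
class RunConfig:
    """Parameters for a pipeline run; defaults follow the study's constants."""

    segment_zone: str = "brachial"
    seed: int = 0
    out_dir: str = "cordmap_out"
    resolution: int = 100
    fractions: Tuple[float, ...] = (0.5, 0.25, 0.15, 0.05, 0.025)
    depth_bins: int = 80
    display_bins: int = 56
    dv_bins: int = 200
    smooth_window: int = 9
    threshold: int = 128
    sigmoid_model: str = "auto"
    n_sections_per_genotype: int = 3
    n_cells_per_family: int = 150
    mutant_factors: Dict[str, float] = field(default_factory=dict)
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(config: RunConfig) -> Dict:
    """Run simulate -> register -> birthdate -> density -> depth -> compose.

    Returns (and writes) a manifest listing parameters, seeds and the SHA-256
    of every artifact.  Stage failures propagate with the stage name logged.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = make_template(config.segment_zone)
    manifest: Dict = {"config": asdict(config), "stages": {}, "outputs": {}}

    stage = "simulate"
    try:
        effect = synthetic.CompositionEffect(factors=dict(config.mutant_factors))
        data = synthetic.simulate_dataset(
            template,
            config.seed,
            n_sections_per_genotype=config.n_sections_per_genotype,
            n_cells_per_family=config.n_cells_per_family,
            effect=effect,
        )
        _write_csv(data["anchors"], out / "anchors.csv")
        _write_csv(data["cells"], out / "cells.csv")
        _write_csv(data["pulse_counts"], out / "pulse_counts.csv")
        (out / "truth.json").write_text(json.dumps(data["truth"], indent=1))
        manifest["stages"][stage] = "ok"

        stage = "register"
        registered = []
        for sec_id, anchors in data["anchors"].groupby("section_id"):
            cells_sec = data["cells"][data["cells"]["section_id"] == sec_id]
            registered.append(
                registration.register_section(cells_sec, anchors, template)
            )
        reg = registration.overlay_sections(registered)
        _write_csv(reg, out / "registered_cells.csv")
        manifest["stages"][stage] = "ok"

        stage = "birthdate"
        half = birthdating.half_birthdates(
            data["pulse_counts"], model=config.sigmoid_model, seed=config.seed
        )
        curves = []
        lt = birthdating.litter_points(data["pulse_counts"])
        for family in sorted(data["pulse_counts"]["family"].unique()):
            c = birthdating.cumulative_curve(lt, family)
            cv = c.litter_values.copy()
            cv.insert(0, "family", family)
            curves.append(cv)
        _write_csv(pd.concat(curves, ignore_index=True), out / "cumulative_curves.csv")
        (out / "half_birthdates.json").write_text(
            half.to_json(orient="records", indent=1)
        )
        manifest["stages"][stage] = "ok"

        stage = "density"
        maps = density.cohort_density_maps(
            reg,
            group_keys=("genotype", "family"),
            fractions=config.fractions,
            resolution=config.resolution,
        )
        for key, (dmap, levels) in maps.items():
            tag = "_".join(str(k) for k in key)
            np.save(out / f"density_{tag}.npy", dmap.grid)
            (out / f"levels_{tag}.json").write_text(
                json.dumps({str(q): t for q, t in levels.thresholds.items()}, indent=1)
            )
        manifest["stages"][stage] = "ok"

        stage = "depth"
        dv = depth.dv_frequency(
            reg, n_bins=config.dv_bins, smooth_window=config.smooth_window
        )
        _write_csv(dv, out / "dv_frequency.csv")
        images = synthetic.simulate_depth_images(
            [[(20, 60)], [(40, 90)]], height=320, width=60, seed=config.seed
        )
        roi = depth.ProfileROI(0, 60, 0, 320)
        profiles = {
            "markerA": {"rep1": depth.vertical_profile(
                depth.binarize(images[0], config.threshold), roi)},
            "markerA+markerB": {"rep1": depth.vertical_profile(
                depth.colocalize(
                    depth.binarize(images[0], config.threshold),
                    depth.binarize(images[1], config.threshold),
                ), roi)},
        }
        _write_csv(depth.depth_profile_table(profiles), out / "depth_profiles.csv")
        manifest["stages"][stage] = "ok"

        stage = "compose"
        # in the demo dataset each section is one complete replicate
        inv = data["cells"][["section_id"]].drop_duplicates()
        inv["replicate"] = inv["section_id"]
        inv["weight"] = 1.0
        cells_rep = data["cells"].copy()
        cells_rep["replicate"] = cells_rep["section_id"]
        comp = composition.build_composition(cells_rep, inv, type_col="family")
        _write_csv(comp, out / "composition.csv")
        try:
            result = composition.compare_genotypes(comp)
            (out / "anova.json").write_text(result.anova.to_json(indent=1))
            _write_csv(result.tukey, out / "tukey.csv")
        except ValueError as exc:
            logger.warning("compose comparison skipped: %s", exc)
        manifest["stages"][stage] = "ok"
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
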