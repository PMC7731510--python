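"""Disk layout for studies: TIFF channels and stacks, PNG stains, JSON ROIs,
CSV tables.

A study directory holds one subdirectory per animal plus study-level tables:

    study/
      animals.csv                 animal, diet, week
      echo.csv                    animal, diet, week, lvidd_mm, lvids_mm, hr_bpm
      scores.csv                  animal, diet, week, marker, region, rater1..3
      truth.csv                   (optional) long-format ground-truth metrics
      <animal>/
        channel_a755_460.tif      one 32-bit TIFF per TPEF channel
        channel_a860_525.tif ...
        polarization_stack.tif    K-page TIFF
        angles.yaml               polarizer angles (degrees)
        psr.png  ars.png          RGB stain images
        regions.json              ROI polygons
        truth_summary.json        (optional) per-region ground truth
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .histology import StainImage
from .phantom import PhantomDataset, StudyData
from .qpli import PolarizationStack
from .roi import RegionAnnotation
from .tpef import CHANNEL_KEYS, ChannelSet


def write_dataset(ds: PhantomDataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in CHANNEL_KEYS:
        tifffile.imwrite(out / f"channel_{key}.tif", getattr(ds.channel_set, key).astype(np.float32))
    tifffile.imwrite(out / "polarization_stack.tif", ds.polarization_stack.frames.astype(np.float32))
    with open(out / "angles.yaml", "w") as fh:
        yaml.safe_dump({"angles_deg": ds.polarization_stack.angles_deg.tolist()}, fh)
    iio.imwrite(out / "psr.png", ds.psr.rgb)
    iio.imwrite(out / "ars.png", ds.ars.rgb)
    ds.annotation.save(out / "regions.json")
    summary = {
        "meta": ds.meta,
        "pixel_pitch": ds.config.pixel_pitch,
        "ars_fraction": ds.truth["ars_fraction"],
        "calcium_burden": ds.truth["calcium_burden"],
        "psr_bin_fractions": {k: np.asarray(v).tolist() for k, v in ds.truth["psr_bin_fractions"].items()},
        "effect_size": ds.truth["effect_size"],
    }
    with open(out / "truth_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return out


def read_dataset(in_dir: str | Path) -> dict:
    """Read one animal directory back into pipeline inputs.

    Missing required files are enumerated in a single error rather than
    silently skipped.
    """
    src = Path(in_dir)
    required = (
        [f"channel_{k}.tif" for k in CHANNEL_KEYS]
        + ["polarization_stack.tif", "angles.yaml", "psr.png", "ars.png", "regions.json"]
    )
    missing = [name for name in required if not (src / name).exists()]
    if missing:
        raise FileNotFoundError(f"{src}: missing input files {missing}")

    channels = ChannelSet(
        **{k: tifffile.imread(src / f"channel_{k}.tif").astype(float) for k in CHANNEL_KEYS}
    )
    with open(src / "angles.yaml") as fh:
        angles = np.asarray(yaml.safe_load(fh)["angles_deg"], dtype=float)
    stack = PolarizationStack(
        frames=tifffile.imread(src / "polarization_stack.tif").astype(float), angles_deg=angles
    )
    truth = None
    pitch = 1.0
    if (src / "truth_summary.json").exists():
        with open(src / "truth_summary.json") as fh:
            truth = json.load(fh)
        pitch = float(truth.get("pixel_pitch", 1.0))
    return {
        "channels": channels,
        "stack": stack,
        "psr": StainImage(rgb=iio.imread(src / "psr.png"), stain="PSR", pixel_pitch=pitch),
        "ars": StainImage(rgb=iio.imread(src / "ars.png"), stain="ARS", pixel_pitch=pitch),
        "annotation": RegionAnnotation.load(src / "regions.json"),
        "truth": truth,
    }


def write_study(study: StudyData, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    animals = []
    for ds in study.datasets:
        animal = ds.meta["animal"]
        write_dataset(ds, out / animal)
        animals.append({"animal": animal, "diet": ds.meta["diet"], "week": ds.meta["week"]})
    pd.DataFrame(animals).to_csv(out / "animals.csv", index=False)
    study.echo_table.to_csv(out / "echo.csv", index=False)
    study.score_table.to_csv(out / "scores.csv", index=False)
    study.truth_table.to_csv(out / "truth.csv", index=False)
    return out


def read_study(in_dir: str | Path) -> dict:
    src = Path(in_dir)
    if not (src / "animals.csv").exists():
        raise FileNotFoundError(f"{src}: animals.csv not found; not a study directory")
    animals = pd.read_csv(src / "animals.csv")
    sections = {}
    for row in animals.itertuples():
        sections[row.animal] = read_dataset(src / row.animal)
    out = {"animals": animals, "sections": sections}
    for name in ("echo", "scores", "truth"):
        path = src / f"{name}.csv"
        out[name] = pd.read_csv(path) if path.exists() else None
    return out
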