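"""Shared fixtures: one default-scale synthetic plate, built once.

The expensive session fixtures (full plate, fitted forests) are shared
across module and acceptance tests so the whole suite performs the
plate simulation and feature extraction exactly once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cyclescope import synthetic_data as sd
from cyclescope.features import catalog_names
from cyclescope.modeling import ModelSpec, train
from cyclescope.pipeline import RunConfig, run
from cyclescope.segmentation import segment_field

#: master seed of the default plate experiment used throughout the suite
PLATE_SEED = 1


@pytest.fixture(scope="session")
def plate(tmp_path_factory) -> RunConfig:
    """Default HeLa-like plate, processed through the split stage.

    Control + five drug presets, 20 fields each, ~12 000 nuclei;
    segmentation, 240-feature extraction, Fucci gating and the
    7500/2500 normalized split.
    """
    out = tmp_path_factory.mktemp("plate")
    config = RunConfig(seed=PLATE_SEED, out_dir=str(out),
                       fields_per_condition=20, nuclei_per_field=100,
                       families=["random_forest"], tasks=["G1", "SG2M"],
                       rf_trees=100)
    for stage in ("simulate", "segment", "extract", "gate", "split"):
        run(stage, config)
    return config


@pytest.fixture(scope="session")
def gated_df(plate) -> pd.DataFrame:
    return pd.read_csv(Path(plate.out_dir) / "dataset" / "gated.csv")


@pytest.fixture(scope="session")
def train_df(plate) -> pd.DataFrame:
    return pd.read_csv(Path(plate.out_dir) / "dataset" / "train.csv")


@pytest.fixture(scope="session")
def validation_df(plate) -> pd.DataFrame:
    return pd.read_csv(Path(plate.out_dir) / "dataset" / "validation.csv")


def _fit_forest(train_df: pd.DataFrame, task: str):
    X = train_df[catalog_names()].to_numpy(float)
    y = train_df[f"label_{task}"].to_numpy(int)
    spec = ModelSpec("random_forest",
                     {"n_estimators": 100}, seed=PLATE_SEED)
    return train(spec, X, y)


@pytest.fixture(scope="session")
def sg2m_forest(train_df):
    """Random forest (100 trees) fitted on the S/G2/M-vs-else task."""
    return _fit_forest(train_df, "SG2M")


@pytest.fixture(scope="session")
def g1_forest(train_df):
    """Random forest (100 trees) fitted on the G1-vs-else task."""
    return _fit_forest(train_df, "G1")


@pytest.fixture(scope="session")
def default_field():
    """One rendered control field with default noise, segmented."""
    states = sd.sample_population(sd.get_preset("HeLa", "control"), 100,
                                  seed=11)
    fld = sd.render_field(states, seed=11)
    rois, corrected = segment_field(fld)
    return fld, rois, corrected


@pytest.fixture(scope="session")
def noiseless_field():
    """One fully deterministic (noise-free) field, segmented."""
    states = sd.sample_population(sd.get_preset("HeLa", "control"), 80,
                                  seed=12)
    fld = sd.render_field(states, noise=sd.NoiseParams.none(), seed=12)
    rois, corrected = segment_field(fld)
    return fld, rois, corrected


def truth_mask_global(fld, t) -> np.ndarray:
    """Full-field boolean mask of one truth nucleus."""
    full = np.zeros(fld.pixels.shape[1:], dtype=bool)
    r0, c0, r1, c1 = t.bbox
    full[r0:r1, c0:c1] = t.mask
    return full


def roi_mask_global(shape, roi) -> np.ndarray:
    full = np.zeros(shape, dtype=bool)
    r0, c0, r1, c1 = roi.bbox
    full[r0:r1, c0:c1] = roi.mask
    return full


def match_iou(fld, rois) -> list[float]:
    """Best detection IoU per truth nucleus (greedy, centroid-pruned)."""
    shape = fld.pixels.shape[1:]
    roi_masks = [roi_mask_global(shape, r) for r in rois]
    centroids = np.array([r.centroid for r in rois]) if rois else \
        np.empty((0, 2))
    best = []
    for t in fld.truth:
        tm = truth_mask_global(fld, t)
        iou = 0.0
        if len(rois):
            d = np.hypot(centroids[:, 0] - t.centroid[0],
                         centroids[:, 1] - t.centroid[1])
            for idx in np.nonzero(d < 30)[0]:
                inter = (tm & roi_masks[idx]).sum()
                union = (tm | roi_masks[idx]).sum()
                iou = max(iou, inter / union)
        best.append(iou)
    return best
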