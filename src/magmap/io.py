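"""Time-series and configuration I/O.

BOLD matrices travel as plain vertex-by-volume CSV/TSV or as GIFTI
functional files (one data array per volume); fitting configuration
(HRF shape, search grid) loads from a small YAML file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fit import FitGrid
from .model import HRFSpec


def write_timeseries_csv(data: np.ndarray, path, sep: str = ",") -> None:
    """Write a (vertices x volumes) matrix with volume-named columns."""
    data = np.atleast_2d(np.asarray(data, float))
    df = pd.DataFrame(data, columns=[f"vol{i}" for i in range(data.shape[1])])
    df.insert(0, "vertex", np.arange(len(df)))
    df.to_csv(path, sep=sep, index=False)


def read_timeseries_csv(path, sep: str = ",") -> np.ndarray:
    df = pd.read_csv(path, sep=sep)
    cols = [c for c in df.columns if c.startswith("vol")]
    if not cols:
        raise ValueError("no volume columns (vol0, vol1, ...) found")
    return df[cols].to_numpy(float)


def write_timeseries_gifti(data: np.ndarray, path) -> None:
    """Write a (vertices x volumes) matrix as a functional GIFTI."""
    import nibabel as nib

    data = np.atleast_2d(np.asarray(data, np.float32))
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(data[:, t], intent="NIFTI_INTENT_TIME_SERIES")
        for t in range(data.shape[1])
    ])
    nib.save(img, str(path))


def read_timeseries_gifti(path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    return np.column_stack([np.asarray(d.data, float) for d in img.darrays])


def load_config(path) -> dict:
    """Load an analysis configuration.

    Recognised sections: ``hrf`` (HRFSpec fields) and ``grid`` (mu /
    sigma / theta arrays or {start, stop, num[, log]} range specs).
    Returns {"hrf": HRFSpec, "grid": FitGrid}; missing sections get
    defaults.
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    hrf = HRFSpec(**cfg.get("hrf", {}))

    def axis(spec, default):
        if spec is None:
            return default
        if isinstance(spec, dict):
            if spec.get("log"):
                return np.geomspace(spec["start"], spec["stop"], spec["num"])
            return np.linspace(spec["start"], spec["stop"], spec["num"])
        return np.asarray(spec, float)

    g = cfg.get("grid", {})
    default = FitGrid()
    grid = FitGrid(mu=axis(g.get("mu"), default.mu),
                   sigma=axis(g.get("sigma"), default.sigma),
                   theta=axis(g.get("theta"), default.theta))
    return {"hrf": hrf, "grid": grid}
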