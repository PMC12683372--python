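"""Survey tables and seascape raster stacks on disk.

Surveys travel as plain CSV with a documented header (site_id, coordinates,
depth, method, sampled area, per-species counts/densities, substrate covers,
covariates).  Seascapes are stored as a compressed .npz of named 2-D bands
with a JSON sidecar recording the band list and cell size, so a stack
round-trips bit-exactly without any geospatial dependency.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .seascape import Seascape

logger = logging.getLogger(__name__)

REQUIRED_SURVEY_COLUMNS = ["site_id", "depth", "method", "area"]


class SurveyValidationError(ValueError):
    pass


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read and validate a survey CSV.

    Requires the documented header; rejects rows with non-positive sampled
    area or negative/non-integer counts (dropped with a logged count).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"missing required column(s): {missing}")
    n0 = len(df)
    bad = ~(pd.to_numeric(df["area"], errors="coerce") > 0)
    for col in df.columns:
        if col.startswith("count_"):
            counts = pd.to_numeric(df[col], errors="coerce")
            bad |= counts.isna() | (counts < 0) | (counts % 1 != 0)
        if col.startswith("density_"):
            bad |= pd.to_numeric(df[col], errors="coerce").isna()
    df = df[~bad].reset_index(drop=True)
    if n0 - len(df):
        logger.warning("read_survey: rejected %d/%d rows", n0 - len(df), n0)
    df.attrs["n_rejected"] = int(n0 - len(df))
    return df


def write_survey(survey: pd.DataFrame, path: str | Path) -> None:
    survey.to_csv(path, index=False)


def save_seascape(seascape: Seascape, path: str | Path) -> None:
    """Write the band stack as .npz plus a JSON sidecar naming the bands."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), **seascape.covariates)
    sidecar = {
        "bands": seascape.names,
        "cell_size": seascape.cell_size,
        "shape": list(seascape.shape),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_seascape(path: str | Path) -> Seascape:
    """Read a seascape written by :func:`save_seascape`; band shapes are
    verified against the sidecar."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as npz:
        cov = {}
        for band in sidecar["bands"]:
            arr = npz[band]
            if list(arr.shape) != sidecar["shape"]:
                raise ValueError(f"band {band!r} has shape {arr.shape}, "
                                 f"sidecar says {sidecar['shape']}")
            cov[band] = arr
    return Seascape(covariates=cov, cell_size=float(sidecar["cell_size"]))


def read_rasters(paths: dict[str, str | Path], cell_size: float = 10.0
                 ) -> Seascape:
    """Assemble a seascape from per-band .npy files (name -> path); all bands
    must align."""
    cov = {}
    shape = None
    for name, p in paths.items():
        arr = np.load(p)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"band {name!r} shape {arr.shape} != {shape}")
        cov[name] = arr
    return Seascape(covariates=cov, cell_size=cell_size)
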