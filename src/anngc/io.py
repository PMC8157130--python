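"""Delimited-text panels and JSON model files.

Panels are tab-delimited text with an optional header row of channel
names; models are JSON documents holding the coefficient stack (row-major
by lag), the innovation covariance, the optional link list, and method
metadata, serialized at full double precision so a write/read round trip
is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .models import TimeSeriesPanel, VARModel

__all__ = ["read_panel", "write_panel", "read_model", "write_model"]


def read_panel(path: str | Path) -> TimeSeriesPanel:
    """Load an N x M panel from delimited text (header row optional)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    try:
        # cells kept as text so the float conversion is correctly rounded
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed rows ({exc})") from exc

    def _is_number(v) -> bool:
        try:
            float(v)
            return True
        except (TypeError, ValueError):
            return False

    labels = None
    if not df.iloc[0].map(_is_number).all():
        labels = [str(v) for v in df.iloc[0]]
        df = df.iloc[1:].reset_index(drop=True)
    raw = df.to_numpy(dtype=object)
    try:
        # numpy's string->float conversion is correctly rounded
        values = raw.astype(np.float64)
    except (TypeError, ValueError):
        values = np.full(raw.shape, np.nan)
        for (r, c), cell in np.ndenumerate(raw):
            if _is_number(cell):
                values[r, c] = np.float64(cell)
    bad = np.argwhere(~np.isfinite(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at row {r + 1}, "
            f"column {c + 1}")
    return TimeSeriesPanel(values, sample_labels=labels)


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    path = Path(path)
    labels = panel.sample_labels or [f"ch{j + 1}" for j in range(panel.M)]
    df = pd.DataFrame(panel.values, columns=labels)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_model(model: VARModel, path: str | Path) -> None:
    doc = {
        "M": model.M,
        "p": model.p,
        "coeffs": model.coeffs.tolist(),
        "innov_cov": model.innov_cov.tolist(),
        "links": model.links.tolist() if model.links is not None else None,
        "meta": {k: v for k, v in model.meta.items()
                 if isinstance(v, (str, int, float, bool, type(None)))},
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path: str | Path) -> VARModel:
    doc = json.loads(Path(path).read_text())
    for key in ("M", "p", "coeffs", "innov_cov"):
        if key not in doc:
            raise ValueError(f"model file missing required field {key!r}")
    coeffs = np.asarray(doc["coeffs"], dtype=float)
    if coeffs.shape != (doc["p"], doc["M"], doc["M"]):
        raise ValueError("coefficient stack shape disagrees with M, p")
    links = np.asarray(doc["links"], bool) if doc.get("links") is not None \
        else None
    return VARModel(coeffs, np.asarray(doc["innov_cov"], float),
                    links=links, meta=doc.get("meta", {}))
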