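"""Reading and writing AlphaFold-style PAE JSON files.

Two common dialects are accepted, auto-detected:

* the modern full-matrix layout — an object (or one-element list of
  objects) with the square matrix under ``predicted_aligned_error``
  (or ``pae``), optionally ``max_predicted_aligned_error``, ``iptm``;
* the legacy paired-arrays layout — ``residue1`` / ``residue2`` /
  ``distance`` arrays of equal length with 1-based indices, from which
  the square matrix is rebuilt.

Chain lengths are taken from a ``chain_lengths`` key embedded in the
JSON, or from a ``<name>.chains.json`` sidecar next to the file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .errors import FormatError
from .scoring import PAE_MAX_DEFAULT, PaePrediction

logger = logging.getLogger(__name__)

__all__ = ["read_pae_file", "write_pae_file"]

_MATRIX_KEYS = ("predicted_aligned_error", "pae", "predicted_alignment_error")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".chains.json")


def _matrix_from_obj(obj: dict) -> np.ndarray | None:
    for key in _MATRIX_KEYS:
        if key in obj and obj[key] and isinstance(obj[key][0], (list, tuple)):
            return np.asarray(obj[key], dtype=float)
    if {"residue1", "residue2", "distance"} <= obj.keys():
        r1 = np.asarray(obj["residue1"], dtype=int)
        r2 = np.asarray(obj["residue2"], dtype=int)
        d = np.asarray(obj["distance"], dtype=float)
        if not (r1.size == r2.size == d.size) or r1.size == 0:
            raise FormatError("residue1/residue2/distance arrays inconsistent")
        side = int(max(r1.max(), r2.max()))
        mat = np.full((side, side), np.nan)
        mat[r1 - 1, r2 - 1] = d
        if np.isnan(mat).any():
            raise FormatError("paired-array PAE does not cover the full matrix")
        logger.debug("parsed paired-arrays PAE dialect (side %d)", side)
        return mat
    return None


def read_pae_file(
    path: str | Path,
    len_a: int | None = None,
    len_b: int | None = None,
) -> PaePrediction:
    """Parse one PAE JSON file into a :class:`PaePrediction`.

    Chain lengths may be passed explicitly; otherwise they must come
    from the file's ``chain_lengths`` key or its ``.chains.json``
    sidecar.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot parse PAE JSON: {exc}") from exc

    if isinstance(data, list):
        if len(data) != 1 or not isinstance(data[0], dict):
            raise FormatError("list-wrapped PAE JSON must hold exactly one object")
        obj = data[0]
    elif isinstance(data, dict):
        obj = data
    else:
        raise FormatError("PAE JSON must be an object or a one-element list")

    mat = _matrix_from_obj(obj)
    if mat is None:
        raise FormatError("no PAE matrix found under any known key")

    if len_a is None or len_b is None:
        lengths = obj.get("chain_lengths")
        if lengths is None:
            sidecar = _sidecar_path(path)
            if sidecar.exists():
                lengths = json.loads(sidecar.read_text()).get("chain_lengths")
        if lengths is None or len(lengths) != 2:
            raise FormatError(
                "chain lengths not given and not found in file or sidecar"
            )
        len_a, len_b = int(lengths[0]), int(lengths[1])

    iptm = obj.get("iptm")
    model_id = str(obj.get("model_id", path.stem))
    return PaePrediction(
        pae=mat, len_a=len_a, len_b=len_b, model_id=model_id,
        iptm=float(iptm) if iptm is not None else None,
    )


def write_pae_file(
    pred: PaePrediction,
    path: str | Path,
    pae_max: float = PAE_MAX_DEFAULT,
    sidecar: bool = False,
) -> Path:
    """Write a prediction in the full-matrix JSON dialect.

    With ``sidecar=True`` the chain lengths go to ``<name>.chains.json``
    instead of being embedded.
    """
    path = Path(path)
    obj = {
        "predicted_aligned_error": np.round(pred.pae, 4).tolist(),
        "max_predicted_aligned_error": pae_max,
        "model_id": pred.model_id,
    }
    if pred.iptm is not None:
        obj["iptm"] = pred.iptm
    if sidecar:
        _sidecar_path(path).write_text(
            json.dumps({"chain_lengths": [pred.len_a, pred.len_b]})
        )
    else:
        obj["chain_lengths"] = [pred.len_a, pred.len_b]
    path.write_text(json.dumps(obj))
    return path
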