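"""Quantitative eye-pigmentation (PEV) measurement.

Position-effect variegation silences a reporter gene relocated near
heterochromatin, giving mottled eye pigmentation.  It is quantified
from RGB photographs: the mean red-channel intensity under an eye mask
is subtracted from the mean under a background mask (the darker the
pigment, the lower the eye value, so background − eye grows with
pigmentation), and each genotype's corrected intensity is expressed as
a fold change of a control genotype.

The subtraction direction is configurable: the default convention is
``background - eye``; ``eye-minus-background`` covers the opposite
reading.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError, UnusableImageError

__all__ = [
    "EyeImage",
    "EyeMeasurement",
    "FoldChangeResult",
    "measure_eye",
    "fold_changes",
    "load_sample_sheet",
]

Convention = Literal["background-minus-eye", "eye-minus-background"]


@dataclass(frozen=True)
class EyeImage:
    """An RGB eye photograph with its eye and background masks."""

    rgb: np.ndarray  # (H, W, 3), uint8 or uint16
    eye_mask: np.ndarray  # (H, W) bool
    background_mask: np.ndarray  # (H, W) bool
    genotype: str
    fly_id: str = "fly_0"

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        eye = np.asarray(self.eye_mask, dtype=bool)
        bg = np.asarray(self.background_mask, dtype=bool)
        object.__setattr__(self, "rgb", rgb)
        object.__setattr__(self, "eye_mask", eye)
        object.__setattr__(self, "background_mask", bg)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise UnusableImageError(f"expected (H, W, 3) raster, got {rgb.shape}")
        if eye.shape != rgb.shape[:2] or bg.shape != rgb.shape[:2]:
            raise UnusableImageError("mask shapes must match the raster")
        if not eye.any() or not bg.any():
            raise UnusableImageError("masks must be non-empty")
        if (eye & bg).any():
            raise UnusableImageError("eye and background masks overlap")


@dataclass(frozen=True)
class EyeMeasurement:
    """Red-channel means and the background-corrected intensity of one eye."""

    eye_mean_red: float
    background_mean_red: float
    corrected: float
    genotype: str
    fly_id: str = "fly_0"


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-genotype pigmentation relative to the control genotype."""

    mean_fold: float  # fold change of group means (default summary)
    per_fly_folds: tuple[float, ...]  # each fly's corrected / control group mean
    n: int


def measure_eye(
    image: EyeImage, convention: Convention = "background-minus-eye"
) -> EyeMeasurement:
    """Mean red intensity under each mask and the corrected value.

    Means are arithmetic means of red-channel pixels under the
    respective mask only; green and blue never contribute.
    """
    red = image.rgb[..., 0].astype(float)
    eye = float(red[image.eye_mask].mean())
    bg = float(red[image.background_mask].mean())
    if convention == "background-minus-eye":
        corrected = bg - eye
    elif convention == "eye-minus-background":
        corrected = eye - bg
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return EyeMeasurement(
        eye_mean_red=eye,
        background_mean_red=bg,
        corrected=corrected,
        genotype=image.genotype,
        fly_id=image.fly_id,
    )


def fold_changes(
    measurements: Iterable[EyeMeasurement], control_genotype: str
) -> dict[str, FoldChangeResult]:
    """Fold change of each genotype's mean corrected intensity vs control.

    The primary summary divides group means (control maps to exactly
    1.0); per-fly folds (each fly's corrected value over the control
    group mean) are reported alongside.
    """
    by_geno: dict[str, list[float]] = {}
    for m in measurements:
        by_geno.setdefault(m.genotype, []).append(m.corrected)
    if control_genotype not in by_geno:
        raise UndefinedRatioError(
            f"no measurements for control genotype {control_genotype!r}"
        )
    ctrl_mean = float(np.mean(by_geno[control_genotype]))
    if ctrl_mean == 0:
        raise UndefinedRatioError("control mean corrected intensity is 0")
    return {
        geno: FoldChangeResult(
            mean_fold=float(np.mean(vals)) / ctrl_mean,
            per_fly_folds=tuple(v / ctrl_mean for v in vals),
            n=len(vals),
        )
        for geno, vals in by_geno.items()
    }


def load_sample_sheet(path: str | Path) -> list[EyeImage]:
    """Read a TSV sample sheet (image, eye_mask, background_mask,
    genotype[, fly_id]) of PNG/TIFF paths into EyeImage objects."""
    import imageio.v3 as iio

    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"image", "eye_mask", "background_mask", "genotype"}
    if not required <= set(df.columns):
        raise UnusableImageError(f"sample sheet needs columns {sorted(required)}")
    images = []
    for i, row in df.iterrows():
        base = path.parent
        rgb = np.asarray(iio.imread(base / row["image"]))
        if rgb.ndim == 3 and rgb.shape[2] == 4:  # drop alpha
            rgb = rgb[..., :3]
        eye = np.asarray(iio.imread(base / row["eye_mask"])) > 0
        bg = np.asarray(iio.imread(base / row["background_mask"])) > 0
        if eye.ndim == 3:
            eye = eye[..., 0]
        if bg.ndim == 3:
            bg = bg[..., 0]
        images.append(
            EyeImage(
                rgb=rgb,
                eye_mask=eye,
                background_mask=bg,
                genotype=str(row["genotype"]),
                fly_id=str(row.get("fly_id", f"fly_{i}")),
            )
        )
    return images


def measurements_frame(
    measurements: Iterable[EyeMeasurement],
    folds: Mapping[str, FoldChangeResult] | None = None,
) -> pd.DataFrame:
    """Tidy per-fly table; adds the genotype mean fold when given."""
    rows = [
        {
            "fly_id": m.fly_id,
            "genotype": m.genotype,
            "eye_mean_red": m.eye_mean_red,
            "background_mean_red": m.background_mean_red,
            "corrected": m.corrected,
        }
        for m in measurements
    ]
    df = pd.DataFrame(rows)
    if folds is not None and not df.empty:
        df["genotype_mean_fold"] = df["genotype"].map(
            {g: r.mean_fold for g, r in folds.items()}
        )
    return df
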