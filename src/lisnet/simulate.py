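"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's inputs so the downstream stages
are testable without any external download:

* replicate spectral-count tables with a planted set of bait-enriched
  preys (Poisson counts, optional negative-binomial overdispersion);
* two-chain PAE matrices with a planted low-error inter-chain patch
  for true interactors and uniformly high inter-chain error for
  decoys;
* RGB eye images with a planted per-genotype red-channel mean over a
  disk-shaped eye mask and a constant-mean background strip.

All generators are pure functions of their configuration and an
explicit integer seed; no global random state is touched.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .enrichment import SpectralCountTable
from .pigmentation import EyeImage
from .scoring import PAE_MAX_DEFAULT, PaePrediction

__all__ = [
    "SimCountConfig",
    "InterfaceSpec",
    "SyntheticTruth",
    "ScreenScenario",
    "SyntheticPredictionProvider",
    "simulate_spectral_counts",
    "simulate_pae_prediction",
    "simulate_eye_images",
    "simulate_screen_scenario",
    "write_eye_dataset",
]

#: Default planted interface: a mirrored 60x60 low-error patch whose
#: per-model LIA (2*60*60 = 7200) clears the 3432 default threshold and
#: whose LIS is at least (12-8)/12 = 1/3 >= 0.203, so planted pairs
#: pass the default classification without rescaling any cutoff.
DEFAULT_INTERFACE_KW = dict(
    patch_len_a=60,
    patch_len_b=60,
    pae_low_range=(2.0, 8.0),
    pae_high_range=(20.0, PAE_MAX_DEFAULT),
    mirrored=True,
)


@dataclass(frozen=True)
class SimCountConfig:
    """Configuration of the spectral-count generator.

    ``background_rate`` is the expected control count; enriched preys
    draw bait counts at ``background_rate * fold``.  ``dispersion``
    switches to negative-binomial counts with that shape parameter
    (Poisson when None).
    """

    n_prey: int
    n_replicates: int
    background_rate: float
    enriched_prey_ids: frozenset[str]
    fold: float
    seed: int
    dispersion: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "enriched_prey_ids", frozenset(self.enriched_prey_ids))
        if self.n_prey < 1 or self.n_replicates < 1:
            raise ConfigurationError("n_prey and n_replicates must be positive")
        if self.background_rate <= 0:
            raise ConfigurationError("background_rate must be > 0")
        if self.fold <= 1 and self.enriched_prey_ids:
            raise ConfigurationError("fold must be > 1 when preys are enriched")
        ids = set(prey_id(i) for i in range(self.n_prey))
        extra = set(self.enriched_prey_ids) - ids
        if extra:
            raise ConfigurationError(f"enriched ids not among generated preys: {sorted(extra)}")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")


@dataclass(frozen=True)
class InterfaceSpec:
    """A planted low-PAE contact patch between two chains."""

    patch_len_a: int
    patch_len_b: int
    pae_low_range: tuple[float, float] = (2.0, 8.0)
    pae_high_range: tuple[float, float] = (20.0, PAE_MAX_DEFAULT)
    mirrored: bool = True
    pae_max: float = PAE_MAX_DEFAULT

    def __post_init__(self) -> None:
        if self.patch_len_a < 1 or self.patch_len_b < 1:
            raise ConfigurationError("patch extents must be positive")
        lo, hi = self.pae_low_range, self.pae_high_range
        for rng, name in ((lo, "pae_low_range"), (hi, "pae_high_range")):
            if not (0 <= rng[0] <= rng[1] <= self.pae_max):
                raise ConfigurationError(f"{name} must lie within [0, pae_max]")
        if lo[1] >= hi[0]:
            raise ConfigurationError("low range must end below the high range")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth of one synthetic interactome.

    ``planted_direct`` preys truly bind the bait; ``planted_bridge``
    maps each bridging prey to the direct interactor it binds instead;
    ``planted_tertiary`` maps each tertiary prey to the bridge node it
    contacts; ``decoys`` bind nothing.  The sets are pairwise disjoint.
    """

    planted_direct: frozenset[str] = frozenset()
    planted_bridge: dict[str, str] = field(default_factory=dict)
    decoys: frozenset[str] = frozenset()
    planted_tertiary: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [
            set(self.planted_direct),
            set(self.planted_bridge),
            set(self.decoys),
            set(self.planted_tertiary),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ConfigurationError("truth sets must be pairwise disjoint")


def prey_id(i: int) -> str:
    return f"prey{i + 1:03d}"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean)
    # NB with mean m and shape k: p = k / (k + m)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_spectral_counts(
    config: SimCountConfig,
) -> tuple[SpectralCountTable, SyntheticTruth]:
    """Draw a bait-vs-control count table with planted enrichment.

    Control counts are i.i.d. with mean ``background_rate``; bait
    counts have mean ``background_rate * fold`` for enriched preys and
    ``background_rate`` otherwise.  Byte-identical for identical
    (config, seed).
    """
    rng = _rng(config.seed)
    ids = tuple(prey_id(i) for i in range(config.n_prey))
    enriched = np.array([p in config.enriched_prey_ids for p in ids])
    bait_mean = np.where(enriched, config.background_rate * config.fold, config.background_rate)
    shape = (config.n_prey, config.n_replicates)
    ctrl = _counts(rng, np.full(shape, config.background_rate), config.dispersion)
    bait = _counts(rng, np.broadcast_to(bait_mean[:, None], shape).copy(), config.dispersion)
    table = SpectralCountTable(prey_ids=ids, bait_counts=bait, control_counts=ctrl)
    truth = SyntheticTruth(
        planted_direct=frozenset(config.enriched_prey_ids),
        decoys=frozenset(ids) - config.enriched_prey_ids,
    )
    return table, truth


def simulate_pae_prediction(
    len_a: int,
    len_b: int,
    interface: InterfaceSpec | None,
    n_models: int = 1,
    seed: int = 0,
    intra_range: tuple[float, float] = (1.0, 5.0),
    pae_max: float = PAE_MAX_DEFAULT,
) -> list[PaePrediction]:
    """Draw ``n_models`` square PAE matrices for a two-chain pair.

    Intra-chain blocks are uniformly low-error; inter-chain cells come
    from the interface's high range, except a planted top-left patch
    (mirrored into the transposed block when requested) drawn from the
    low range.  ``interface=None`` plants nothing: every inter-chain
    cell is high-error, so the pair scores LIS = LIA = 0 under the
    default 12 Å cutoff.
    """
    if len_a < 1 or len_b < 1 or n_models < 1:
        raise ConfigurationError("chain lengths and n_models must be positive")
    high = interface.pae_high_range if interface is not None else (20.0, pae_max)
    if interface is not None:
        if interface.patch_len_a > len_a or interface.patch_len_b > len_b:
            raise ConfigurationError("planted patch larger than a chain")
        pae_max = interface.pae_max
    rng = _rng(seed)
    side = len_a + len_b
    preds = []
    for m in range(n_models):
        mat = np.empty((side, side))
        mat[:len_a, :len_a] = rng.uniform(*intra_range, (len_a, len_a))
        mat[len_a:, len_a:] = rng.uniform(*intra_range, (len_b, len_b))
        mat[:len_a, len_a:] = rng.uniform(*high, (len_a, len_b))
        mat[len_a:, :len_a] = rng.uniform(*high, (len_b, len_a))
        if interface is not None:
            pa, pb = interface.patch_len_a, interface.patch_len_b
            mat[:pa, len_a : len_a + pb] = rng.uniform(*interface.pae_low_range, (pa, pb))
            if interface.mirrored:
                mat[len_a : len_a + pb, :pa] = rng.uniform(
                    *interface.pae_low_range, (pb, pa)
                )
        preds.append(
            PaePrediction(pae=mat, len_a=len_a, len_b=len_b, model_id=f"model_{m}")
        )
    return preds


# ---------------------------------------------------------------------------
# synthetic interactome scenarios for the iterative screen


def pair_seed(base_seed: int, a: str, b: str) -> int:
    """Stable per-pair seed, symmetric in pair order, < 2**31."""
    u, v = sorted((a, b))
    return (zlib.crc32(f"{u}|{v}".encode()) ^ (base_seed * 2654435761)) % (2**31)


class SyntheticPredictionProvider:
    """Prediction provider backed by a planted-truth scenario.

    Returns mirrored low-error-patch predictions for planted pairs and
    no-interface predictions for everything else; ``absent_pairs``
    return None (no prediction available).  Deterministic per
    (scenario, seed) and symmetric in pair order.
    """

    def __init__(
        self,
        planted_pairs: set[frozenset[str]],
        interface: InterfaceSpec,
        len_a: int = 100,
        len_b: int = 100,
        n_models: int = 1,
        seed: int = 0,
        absent_pairs: set[frozenset[str]] | None = None,
    ) -> None:
        self.planted_pairs = {frozenset(p) for p in planted_pairs}
        self.interface = interface
        self.len_a = len_a
        self.len_b = len_b
        self.n_models = n_models
        self.seed = seed
        self.absent_pairs = {frozenset(p) for p in (absent_pairs or set())}
        self.calls: list[tuple[str, str]] = []  # instrumentation for tests

    def __call__(self, a: str, b: str) -> list[PaePrediction] | None:
        self.calls.append(tuple(sorted((a, b))))
        key = frozenset((a, b))
        if key in self.absent_pairs:
            return None
        iface = self.interface if key in self.planted_pairs else None
        return simulate_pae_prediction(
            self.len_a,
            self.len_b,
            iface,
            n_models=self.n_models,
            seed=pair_seed(self.seed, a, b),
        )


@dataclass(frozen=True)
class ScreenScenario:
    """One synthetic interactome: bait, candidate list, provider, truth."""

    bait: str
    candidates: tuple[str, ...]
    provider: SyntheticPredictionProvider
    truth: SyntheticTruth


def simulate_screen_scenario(
    n_direct: int = 5,
    n_bridge: int = 3,
    n_decoy: int = 12,
    n_tertiary: int = 0,
    bait: str = "bait",
    chain_len: int = 100,
    interface: InterfaceSpec | None = None,
    n_models: int = 1,
    seed: int = 0,
) -> ScreenScenario:
    """Build a planted interactome for exercising the three-round screen.

    Direct preys carry an interface with the bait; each bridge carries
    one with a direct prey (assigned round-robin); each tertiary prey
    with a bridge; decoys with nobody.
    """
    if n_bridge > 0 and n_direct == 0:
        raise ConfigurationError("bridges require at least one direct prey")
    if n_tertiary > 0 and n_bridge == 0:
        raise ConfigurationError("tertiary preys require at least one bridge")
    interface = interface or InterfaceSpec(**DEFAULT_INTERFACE_KW)
    direct = tuple(f"direct{i + 1:02d}" for i in range(n_direct))
    bridge = tuple(f"bridge{i + 1:02d}" for i in range(n_bridge))
    tert = tuple(f"tert{i + 1:02d}" for i in range(n_tertiary))
    decoy = tuple(f"decoy{i + 1:02d}" for i in range(n_decoy))

    planted: set[frozenset[str]] = {frozenset((bait, d)) for d in direct}
    bridge_map = {b: direct[i % n_direct] for i, b in enumerate(bridge)}
    planted |= {frozenset((b, g)) for b, g in bridge_map.items()}
    tert_map = {t: bridge[i % n_bridge] for i, t in enumerate(tert)}
    planted |= {frozenset((t, g)) for t, g in tert_map.items()}

    provider = SyntheticPredictionProvider(
        planted_pairs=planted,
        interface=interface,
        len_a=chain_len,
        len_b=chain_len,
        n_models=n_models,
        seed=seed,
    )
    truth = SyntheticTruth(
        planted_direct=frozenset(direct),
        planted_bridge=bridge_map,
        decoys=frozenset(decoy),
        planted_tertiary=tert_map,
    )
    return ScreenScenario(
        bait=bait,
        candidates=tuple(sorted(direct + bridge + tert + decoy)),
        provider=provider,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# synthetic eye images


def _disk_mask(size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[:size, :size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def simulate_eye_images(
    genotype_intensities: Mapping[str, float],
    background_value: float = 200.0,
    noise_sd: float = 2.0,
    size: int = 64,
    n_per_genotype: int = 10,
    seed: int = 0,
) -> tuple[list[EyeImage], dict[str, float]]:
    """Draw eye photographs with planted red-channel means.

    The eye is a disk in the left half of the frame; the background
    mask is a strip along the right edge.  Eye-mask red pixels are
    Normal(planted mean, noise_sd) clipped to [0, 255]; background
    pixels Normal(background_value, noise_sd).  Green and blue are
    constants.  Returns the images and the planted corrected intensity
    (``background_value - planted mean``) per genotype.
    """
    for g, v in genotype_intensities.items():
        if not 0 <= v <= 255:
            raise ConfigurationError(f"planted mean for {g!r} outside 8-bit range")
    if not 0 <= background_value <= 255:
        raise ConfigurationError("background_value outside 8-bit range")
    if noise_sd < 0 or size < 8 or n_per_genotype < 1:
        raise ConfigurationError("invalid noise_sd, size or n_per_genotype")

    eye_mask = _disk_mask(size, (size / 2, size * 0.3), size * 0.22)
    bg_mask = np.zeros((size, size), dtype=bool)
    bg_mask[:, int(size * 0.8) :] = True
    if (eye_mask & bg_mask).any():
        raise ConfigurationError("eye and background masks overlap")

    rng = _rng(seed)
    images: list[EyeImage] = []
    for geno in sorted(genotype_intensities):
        mean = genotype_intensities[geno]
        for k in range(n_per_genotype):
            red = np.full((size, size), 128.0)
            red[eye_mask] = rng.normal(mean, noise_sd, int(eye_mask.sum()))
            red[bg_mask] = rng.normal(background_value, noise_sd, int(bg_mask.sum()))
            rgb = np.stack(
                [np.clip(red, 0, 255), np.full_like(red, 64), np.full_like(red, 32)],
                axis=-1,
            ).astype(np.uint8)
            images.append(
                EyeImage(
                    rgb=rgb,
                    eye_mask=eye_mask,
                    background_mask=bg_mask,
                    genotype=geno,
                    fly_id=f"{geno}_fly{k + 1:02d}",
                )
            )
    truth = {g: background_value - v for g, v in genotype_intensities.items()}
    return images, truth


def write_eye_dataset(
    images: Sequence[EyeImage], out_dir: str | Path
) -> Path:
    """Write images and masks as PNG plus a sample-sheet TSV; returns the
    sheet path (readable by :func:`lisnet.pigmentation.load_sample_sheet`)."""
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        stem = img.fly_id
        iio.imwrite(out / f"{stem}.png", img.rgb)
        iio.imwrite(out / f"{stem}.eye.png", (img.eye_mask * 255).astype(np.uint8))
        iio.imwrite(out / f"{stem}.bg.png", (img.background_mask * 255).astype(np.uint8))
        rows.append(
            {
                "image": f"{stem}.png",
                "eye_mask": f"{stem}.eye.png",
                "background_mask": f"{stem}.bg.png",
                "genotype": img.genotype,
                "fly_id": img.fly_id,
            }
        )
    sheet = out / "samples.tsv"
    pd.DataFrame(rows).to_csv(sheet, sep="\t", index=False)
    return sheet


def default_interface(**overrides) -> InterfaceSpec:
    """The default planted interface (mirrored 60x60 patch, PAE 2-8)."""
    kw = dict(DEFAULT_INTERFACE_KW)
    kw.update(overrides)
    return InterfaceSpec(**kw)
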