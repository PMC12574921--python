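"""Interface confidence scoring from AlphaFold-Multimer PAE maps.

A two-chain prediction carries a square predicted-aligned-error (PAE)
matrix over the concatenated residues of both chains.  Confident
interfaces show up as low-error cells in the two off-diagonal
(inter-chain) blocks.  Two summary statistics are computed per model:

``LIA`` (Local Interaction Area)
    the number of inter-chain residue pairs whose PAE falls strictly
    below a cutoff (default 12 Å) — a proxy for interface size.

``LIS`` (Local Interaction Score)
    the mean of ``(cutoff - PAE) / cutoff`` over those same cells, a
    confidence score in [0, 1]; 0 when no cell clears the cutoff.

Per-model scores are aggregated across the models of one pair and the
pair is classified as a positive PPI when ``LIS >= tau_lis`` and
``LIA >= tau_lia`` (defaults 0.203 and 3432, both inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import ConfigurationError, FormatError, MissingPredictionError

PAE_MAX_DEFAULT = 31.75

__all__ = [
    "PAE_MAX_DEFAULT",
    "PaePrediction",
    "ScoreConfig",
    "ModelScore",
    "InteractionScore",
    "interchain_cells",
    "score_model",
    "aggregate_scores",
    "classify",
    "score_pair",
]


@dataclass(frozen=True)
class PaePrediction:
    """One model's square PAE matrix plus the two chain lengths.

    The matrix side must equal ``len_a + len_b``; chain A occupies the
    leading ``len_a`` indices.  PAE is generally asymmetric (the error
    of residue j when aligned on residue i's frame).
    """

    pae: np.ndarray
    len_a: int
    len_b: int
    model_id: str = "model_0"
    iptm: float | None = None

    def __post_init__(self) -> None:
        pae = np.asarray(self.pae, dtype=float)
        object.__setattr__(self, "pae", pae)
        if pae.ndim != 2 or pae.shape[0] != pae.shape[1]:
            raise FormatError(f"PAE matrix must be square, got shape {pae.shape}")
        if self.len_a < 1 or self.len_b < 1:
            raise FormatError("chain lengths must be positive")
        if pae.shape[0] != self.len_a + self.len_b:
            raise FormatError(
                f"matrix side {pae.shape[0]} != len_a + len_b = "
                f"{self.len_a + self.len_b}"
            )
        if np.any(pae < 0) or not np.all(np.isfinite(pae)):
            raise FormatError("PAE entries must be finite and non-negative")
        if self.iptm is not None and not 0.0 <= self.iptm <= 1.0:
            raise FormatError("ipTM must lie in [0, 1]")


@dataclass(frozen=True)
class ScoreConfig:
    """Cutoffs and aggregation policy for LIS/LIA scoring.

    Parameters
    ----------
    pae_cutoff:
        PAE threshold in Å below which (strictly) an inter-chain cell
        counts toward the interface.  Default 12.
    tau_lis, tau_lia:
        Inclusive classification thresholds on the aggregated scores.
    aggregation:
        How per-model scores combine: ``mean`` (default), ``max``
        (field-wise maxima) or ``best_model`` (the model with highest
        LIS; ties broken by lowest model id).
    block_mode:
        ``both`` (default) counts cells from both off-diagonal blocks;
        ``max`` scores each block separately and keeps the better one.
    pae_max:
        Ceiling of the PAE scale, used for validation only.
    """

    pae_cutoff: float = 12.0
    tau_lis: float = 0.203
    tau_lia: float = 3432.0
    aggregation: Literal["mean", "max", "best_model"] = "mean"
    block_mode: Literal["both", "max"] = "both"
    pae_max: float = PAE_MAX_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.pae_cutoff <= self.pae_max:
            raise ConfigurationError("require 0 < pae_cutoff <= pae_max")
        if self.tau_lis < 0 or self.tau_lia < 0:
            raise ConfigurationError("thresholds must be non-negative")
        if self.aggregation not in ("mean", "max", "best_model"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")
        if self.block_mode not in ("both", "max"):
            raise ConfigurationError(f"unknown block_mode {self.block_mode!r}")


@dataclass(frozen=True)
class ModelScore:
    """Per-model (LIS, LIA) pair, tagged with the model id."""

    lis: float
    lia: float
    model_id: str = "model_0"
    iptm: float | None = None


@dataclass(frozen=True)
class InteractionScore:
    """Aggregated interface score for one protein pair."""

    pair: tuple[str, str]
    lis: float
    lia: float
    n_models: int
    passed: bool
    iptm: float | None = None
    per_model: tuple[ModelScore, ...] = field(default=())


def interchain_cells(pred: PaePrediction) -> np.ndarray:
    """Return the PAE values of the two off-diagonal blocks.

    Exactly ``2 * len_a * len_b`` values: the A→B block (rows in A,
    columns in B) followed by the B→A block.  Intra-chain cells never
    contribute.
    """
    a, b = pred.len_a, pred.len_b
    ab = pred.pae[:a, a:]
    ba = pred.pae[a:, :a]
    return np.concatenate([ab.ravel(), ba.ravel()])


def _score_values(values: np.ndarray, cutoff: float) -> tuple[float, int]:
    sel = values[values < cutoff]
    lia = int(sel.size)
    if lia == 0:
        return 0.0, 0
    lis = float(np.mean((cutoff - sel) / cutoff))
    return lis, lia


def score_model(pred: PaePrediction, config: ScoreConfig | None = None) -> tuple[float, int]:
    """Compute (LIS, LIA) for a single model.

    Cells with PAE strictly below ``config.pae_cutoff`` are selected
    from the inter-chain blocks; LIA is their count and LIS the mean of
    ``(cutoff - PAE) / cutoff`` over them (0 if none qualify).
    """
    config = config or ScoreConfig()
    if np.any(pred.pae > config.pae_max):
        raise FormatError(
            f"PAE entries exceed pae_max={config.pae_max}; "
            "pass a ScoreConfig with a larger pae_max"
        )
    if config.block_mode == "both":
        return _score_values(interchain_cells(pred), config.pae_cutoff)
    a = pred.len_a
    scores = [
        _score_values(pred.pae[:a, a:].ravel(), config.pae_cutoff),
        _score_values(pred.pae[a:, :a].ravel(), config.pae_cutoff),
    ]
    # keep the block with larger LIA, ties by larger LIS
    return max(scores, key=lambda s: (s[1], s[0]))


def classify(lis: float, lia: float, config: ScoreConfig | None = None) -> bool:
    """True iff both thresholds are met (inclusive ``>=`` on both)."""
    config = config or ScoreConfig()
    if not (np.isfinite(lis) and np.isfinite(lia)):
        raise ConfigurationError("classify requires finite inputs")
    return lis >= config.tau_lis and lia >= config.tau_lia


def aggregate_scores(
    per_model: Sequence[ModelScore | tuple[float, float]],
    config: ScoreConfig | None = None,
    pair: tuple[str, str] = ("A", "B"),
) -> InteractionScore:
    """Combine per-model (LIS, LIA) scores into one InteractionScore.

    ``mean`` averages both fields, ``max`` takes field-wise maxima and
    ``best_model`` copies the fields of the model with the highest LIS
    (ties broken by lexicographically lowest model id).
    """
    config = config or ScoreConfig()
    if len(per_model) == 0:
        raise MissingPredictionError("aggregate_scores requires at least one model")
    models = tuple(
        m if isinstance(m, ModelScore) else ModelScore(lis=m[0], lia=m[1], model_id=f"model_{i}")
        for i, m in enumerate(per_model)
    )
    if config.aggregation == "mean":
        lis = float(np.mean([m.lis for m in models]))
        lia = float(np.mean([m.lia for m in models]))
        iptm_vals = [m.iptm for m in models if m.iptm is not None]
        iptm = float(np.mean(iptm_vals)) if iptm_vals else None
    elif config.aggregation == "max":
        lis = max(m.lis for m in models)
        lia = max(m.lia for m in models)
        iptm_vals = [m.iptm for m in models if m.iptm is not None]
        iptm = max(iptm_vals) if iptm_vals else None
    else:  # best_model
        best = min(models, key=lambda m: (-m.lis, m.model_id))
        lis, lia, iptm = best.lis, best.lia, best.iptm
    return InteractionScore(
        pair=pair,
        lis=lis,
        lia=lia,
        n_models=len(models),
        passed=classify(lis, lia, config),
        iptm=iptm,
        per_model=models,
    )


def score_predictions(
    predictions: Iterable[PaePrediction],
    config: ScoreConfig | None = None,
    pair: tuple[str, str] = ("A", "B"),
) -> InteractionScore:
    """Score each in-memory prediction and aggregate."""
    config = config or ScoreConfig()
    per_model = [
        ModelScore(*score_model(p, config), model_id=p.model_id, iptm=p.iptm)
        for p in predictions
    ]
    return aggregate_scores(per_model, config, pair=pair)


def score_pair(
    prediction_files: Sequence[str | Path],
    config: ScoreConfig | None = None,
    pair: tuple[str, str] = ("A", "B"),
) -> InteractionScore:
    """Parse PAE files for one pair, score each model, aggregate, classify."""
    from .paeio import read_pae_file

    config = config or ScoreConfig()
    if len(prediction_files) == 0:
        raise MissingPredictionError(f"no prediction files for pair {pair}")
    preds = []
    for f in prediction_files:
        try:
            preds.append(read_pae_file(f))
        except FormatError as exc:
            raise FormatError(f"{f}: {exc}") from exc
    return score_predictions(preds, config, pair=pair)


def config_with(config: ScoreConfig | None = None, **kwargs) -> ScoreConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config or ScoreConfig(), **kwargs)
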