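"""IP-MS spectral-count enrichment filtering.

Converts a bait-vs-control spectral-count table into the candidate
interactome for the structure-based screen.  A prey is a candidate when
its bait/control fold change — mean of replicate counts per arm, with a
pseudocount added to both arms — strictly exceeds a threshold
(default 2, i.e. the ">2-fold" rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, UndefinedRatioError

__all__ = ["SpectralCountTable", "CandidateSet", "fold_change", "select_candidates"]


@dataclass(frozen=True)
class SpectralCountTable:
    """Replicate spectral counts per prey, bait arm vs control arm."""

    prey_ids: tuple[str, ...]
    bait_counts: np.ndarray  # shape (n_prey, n_bait_reps)
    control_counts: np.ndarray  # shape (n_prey, n_ctrl_reps)
    bait_id: str = "bait"

    def __post_init__(self) -> None:
        bait = np.atleast_2d(np.asarray(self.bait_counts))
        ctrl = np.atleast_2d(np.asarray(self.control_counts))
        object.__setattr__(self, "bait_counts", bait)
        object.__setattr__(self, "control_counts", ctrl)
        n = len(self.prey_ids)
        if len(set(self.prey_ids)) != n:
            raise FormatError("prey ids must be unique")
        if bait.shape[0] != n or ctrl.shape[0] != n:
            raise FormatError("count arrays must have one row per prey")
        if bait.shape[1] < 1 or ctrl.shape[1] < 1:
            raise FormatError("need at least one replicate per arm")
        for arr, name in ((bait, "bait"), (ctrl, "control")):
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise FormatError(f"{name} counts must be non-negative integers")

    def to_frame(self) -> pd.DataFrame:
        k, m = self.bait_counts.shape[1], self.control_counts.shape[1]
        df = pd.DataFrame({"prey_id": self.prey_ids})
        for j in range(k):
            df[f"bait_rep{j + 1}"] = self.bait_counts[:, j].astype(int)
        for j in range(m):
            df[f"ctrl_rep{j + 1}"] = self.control_counts[:, j].astype(int)
        return df

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, bait_id: str = "bait") -> "SpectralCountTable":
        df = pd.read_csv(path, sep="\t")
        bait_cols = sorted(c for c in df.columns if c.startswith("bait_rep"))
        ctrl_cols = sorted(c for c in df.columns if c.startswith("ctrl_rep"))
        if "prey_id" not in df.columns or not bait_cols or not ctrl_cols:
            raise FormatError(
                "count TSV needs prey_id, bait_rep* and ctrl_rep* columns"
            )
        return cls(
            prey_ids=tuple(df["prey_id"].astype(str)),
            bait_counts=df[bait_cols].to_numpy(),
            control_counts=df[ctrl_cols].to_numpy(),
            bait_id=bait_id,
        )


@dataclass(frozen=True)
class CandidateSet:
    """Preys passing the enrichment filter, ordered by descending fold
    change (ties broken lexicographically by prey id)."""

    bait_id: str
    candidates: tuple[tuple[str, float], ...] = field(default=())

    @property
    def prey_ids(self) -> tuple[str, ...]:
        return tuple(p for p, _ in self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame(self.candidates, columns=["prey_id", "fold_change"]).to_csv(
            path, sep="\t", index=False
        )
        return path

    @classmethod
    def from_tsv(cls, path: str | Path, bait_id: str = "bait") -> "CandidateSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            bait_id=bait_id,
            candidates=tuple(
                (str(r.prey_id), float(r.fold_change)) for r in df.itertuples()
            ),
        )


def fold_change(
    bait_counts: Sequence[float],
    control_counts: Sequence[float],
    pseudocount: float = 1.0,
) -> float:
    """Bait/control ratio of mean replicate counts, pseudocounted.

    Returns ``(mean(bait) + pseudocount) / (mean(control) + pseudocount)``.
    Raises :class:`UndefinedRatioError` when the control mean and the
    pseudocount are both zero.
    """
    if len(bait_counts) == 0 or len(control_counts) == 0:
        raise FormatError("need at least one replicate per arm")
    if pseudocount < 0:
        raise FormatError("pseudocount must be >= 0")
    num = float(np.mean(bait_counts)) + pseudocount
    den = float(np.mean(control_counts)) + pseudocount
    if den == 0:
        raise UndefinedRatioError(
            "control mean is 0 with pseudocount 0; fold change undefined"
        )
    return num / den


def select_candidates(
    table: SpectralCountTable,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> CandidateSet:
    """Retain exactly the preys with fold change strictly above ``min_fold``.

    An empty table yields an empty candidate set.
    """
    hits = []
    for i, prey in enumerate(table.prey_ids):
        fc = fold_change(table.bait_counts[i], table.control_counts[i], pseudocount)
        if fc > min_fold:
            hits.append((prey, fc))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return CandidateSet(bait_id=table.bait_id, candidates=tuple(hits))
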