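"""Kinase-panel selectivity scoring.

Raw docking scores (kcal/mol; lower = more favorable) for one compound across
a kinase panel are min-max rescaled to [0, 1] and the selectivity score is
the fraction of panel kinases whose rescaled score falls strictly below a
threshold (default 0.5):

    S = |{k : rescaled_k < 0.5}| / panel size.

A lower S means the compound docks favorably into fewer kinases, i.e. a more
selective profile. Min-max is the default rescaling strategy; any callable
mapping raw scores to [0, 1] can be substituted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DegeneratePanelError


def rescale(raw: Sequence[float] | np.ndarray) -> np.ndarray:
    """Min-max rescale raw docking scores to [0, 1], order-preserving.

    The most favorable (lowest) raw score maps to 0. Raises
    :class:`DegeneratePanelError` for panels without at least two distinct
    values.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2 or np.ptp(raw) == 0.0:
        raise DegeneratePanelError(
            "min-max rescaling needs at least two distinct panel scores"
        )
    return (raw - raw.min()) / np.ptp(raw)


@dataclass
class DockScoreTable:
    """One compound's docking scores across a kinase panel."""

    kinase_ids: list[str]
    raw: np.ndarray
    rescaled: np.ndarray

    @classmethod
    def from_raw(
        cls,
        kinase_ids: Sequence[str],
        raw: Sequence[float],
        rescaler: Callable[[Sequence[float]], np.ndarray] = rescale,
    ) -> "DockScoreTable":
        if len(kinase_ids) != len(raw):
            raise ValueError("kinase_ids and raw scores differ in length")
        return cls(list(kinase_ids), np.asarray(raw, float), np.asarray(rescaler(raw), float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DockScoreTable":
        """Read a ``kinase_id,raw_score`` CSV for one compound."""
        df = pd.read_csv(path)
        if not {"kinase_id", "raw_score"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns kinase_id,raw_score")
        return cls.from_raw(df["kinase_id"].astype(str).tolist(), df["raw_score"].to_numpy())

    @property
    def panel_size(self) -> int:
        return len(self.kinase_ids)


def selectivity_score(
    table: DockScoreTable | Sequence[float] | np.ndarray, threshold: float = 0.5
) -> float:
    """Fraction of panel kinases with rescaled score strictly below threshold.

    Accepts a :class:`DockScoreTable` or a bare rescaled-score vector. A
    score exactly at the threshold is *not* counted.
    """
    rescaled = table.rescaled if isinstance(table, DockScoreTable) else np.asarray(table, float)
    if rescaled.size == 0:
        raise DegeneratePanelError("empty kinase panel")
    return float(np.count_nonzero(rescaled < threshold)) / rescaled.size


def selectivity_report(
    table: DockScoreTable, compound_id: str, threshold: float = 0.5
) -> dict:
    s = selectivity_score(table, threshold)
    return {
        "compound": compound_id,
        "S": s,
        "n_below": int(round(s * table.panel_size)),
        "panel_size": table.panel_size,
        "threshold": threshold,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
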