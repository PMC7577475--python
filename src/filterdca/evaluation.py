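"""Evaluation of ranked contact predictions.

Positive predictive value (PPV = TP / (TP + FP)) as a function of the number
of top-ranked predictions, averaged over families, plus a probability
calibration table (binned predicted probability vs empirical contact
fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PPVCurve", "CalibrationTable", "rank_pairs", "ppv_curve", "average_ppv", "calibration"]


@dataclass
class PPVCurve:
    """Cumulative precision at each rank cutoff n = 1..N.

    ``n_families`` tracks, for averaged curves, how many families reached
    each cutoff.
    """

    ppv: np.ndarray
    averaged: bool = False
    n_families: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ppv = np.asarray(self.ppv, dtype=float)
        if np.any((self.ppv < 0) | (self.ppv > 1)):
            raise ValueError("PPV values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ppv)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"n": np.arange(1, len(self.ppv) + 1), "ppv": self.ppv})
        if self.n_families is not None:
            df["n_families"] = self.n_families
        df.to_csv(path, sep="\t", index=False)


@dataclass
class CalibrationTable:
    bin_edges: np.ndarray
    counts: np.ndarray
    fractions: np.ndarray
    slope: float

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "count": self.counts,
                "contact_fraction": self.fractions,
            }
        ).to_csv(path, sep="\t", index=False)


def rank_pairs(table: pd.DataFrame, score_column: str = "p") -> pd.DataFrame:
    """Deterministic ranking: stable sort by (-score, i, j)."""
    if table[score_column].isna().any():
        raise ValueError("ranking scores contain NaN")
    out = table.sort_values(
        [score_column, "i", "j"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return out


def ppv_curve(ranked: pd.DataFrame, n_max: int | None = None) -> PPVCurve:
    """PPV at every cutoff 1..n_max of an already-ranked prediction table."""
    labels = ranked["label"].to_numpy()
    if np.isin(labels, (0, 1)).sum() != len(labels):
        raise ValueError("ppv_curve requires binary labels")
    if n_max is None:
        n_max = len(labels)
    if n_max > len(labels):
        raise ValueError(f"requested N={n_max} exceeds {len(labels)} available pairs")
    if n_max < 1:
        raise ValueError("N must be at least 1")
    tp = np.cumsum(labels[:n_max])
    n = np.arange(1, n_max + 1)
    return PPVCurve(ppv=tp / n)


def average_ppv(curves: list[PPVCurve]) -> PPVCurve:
    """Per-cutoff arithmetic mean over family curves.

    Shorter curves contribute up to their own maximum n only; at each cutoff
    the mean runs over the families that reach it.
    """
    if not curves:
        raise ValueError("cannot average an empty curve list")
    n_max = max(len(c) for c in curves)
    total = np.zeros(n_max)
    count = np.zeros(n_max, dtype=int)
    for c in curves:
        total[: len(c)] += c.ppv
        count[: len(c)] += 1
    return PPVCurve(ppv=total / count, averaged=True, n_families=count)


def calibration(predictions: pd.DataFrame, bins: int = 10) -> CalibrationTable:
    """Bin predicted probabilities on [0, 1]; report empirical contact fraction.

    The slope is an (unweighted) least-squares fit of fraction vs bin
    midpoint over the occupied bins — each bin counts once, as in a
    calibration scatter plot.
    """
    if predictions.empty:
        raise ValueError("calibration requires at least one prediction")
    p = predictions["p"].to_numpy(float)
    y = predictions["label"].to_numpy(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, bins - 1)
    counts = np.bincount(idx, minlength=bins)
    sums = np.bincount(idx, weights=y, minlength=bins)
    with np.errstate(invalid="ignore"):
        fractions = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = 0.5 * (edges[:-1] + edges[1:])
    occ = counts > 0
    if occ.sum() >= 2:
        slope = float(np.polyfit(mids[occ], fractions[occ], 1)[0])
    else:
        slope = float("nan")
    return CalibrationTable(bin_edges=edges, counts=counts, fractions=fractions, slope=slope)
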