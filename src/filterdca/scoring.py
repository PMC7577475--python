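"""Per-pair feature extraction: DCA score x1 and filter score x2.

For every inter-domain residue pair (i, j), x1 is the DCA score itself and
x2 is the maximum, over the six filters, of the Pearson correlation between
the filter and the window of DCA scores centered on (i, j).  The central
element is removed from both the window and the filter.  For pairs near the
matrix border the correlation runs over the positions contained in both the
(truncated) window and the filter.  Degenerate (zero-variance) cases fall
back to a correlation of 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dca_io import ScoreMatrix
from .patterns import FilterBank, Window, extract_window
from .structure import ContactMap

__all__ = ["pearson_masked", "filter_score", "feature_table", "write_feature_table", "read_feature_table"]

FEATURE_COLUMNS = ["i", "j", "x1", "x2", "best_filter", "label", "family"]


def pearson_masked(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Sample Pearson correlation of ``a`` and ``b`` over masked positions.

    Returns 0.0 when either masked vector has zero variance; raises if the
    mask selects fewer than 2 positions.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.sum() < 2:
        raise ValueError(f"mask selects {int(mask.sum())} positions; need at least 2")
    x = a[mask]
    y = b[mask]
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        return 0.0
    return float((xc @ yc) / denom)


def filter_score(window: Window, bank: FilterBank) -> tuple[float, int]:
    """Max Pearson correlation of a DCA-score window against the filter bank.

    The window's center element (and the filters' center) is excluded; only
    positions valid in the window enter the correlation.  Returns the maximum
    correlation and the index of the winning filter.
    """
    if window.k != bank.k:
        raise ValueError(f"window size {window.k} does not match filter bank k={bank.k}")
    c = (bank.k - 1) // 2
    mask = window.valid.copy()
    mask[c, c] = False
    if mask.sum() < 2:
        raise ValueError("fewer than 2 usable non-center positions in window")
    best_score, best_id = -np.inf, -1
    for fid, f in enumerate(bank.filters):
        r = pearson_masked(window.values, f, mask)
        if r > best_score:
            best_score, best_id = r, fid
    return float(best_score), int(best_id)


def _interior_filter_scores(values: np.ndarray, bank: FilterBank):
    """Vectorized filter scores for all pairs with untruncated windows.

    Returns (scores, best_ids) arrays of shape (L_A - k + 1, L_B - k + 1)
    aligned so that entry (0, 0) corresponds to pair (h, h) with h=(k-1)/2.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    k = bank.k
    c = (k - 1) // 2
    center_col = c * k + c
    wins = sliding_window_view(values, (k, k)).reshape(
        values.shape[0] - k + 1, values.shape[1] - k + 1, k * k
    )
    wins = np.delete(wins, center_col, axis=2).astype(float)
    wc = wins - wins.mean(axis=2, keepdims=True)
    wnorm2 = np.einsum("ijk,ijk->ij", wc, wc)
    corrs = np.empty((len(bank.filters),) + wnorm2.shape)
    for fid, f in enumerate(bank.filters):
        fv = np.delete(f.ravel(), center_col)
        fc = fv - fv.mean()
        fnorm2 = fc @ fc
        denom = np.sqrt(wnorm2 * fnorm2)
        num = wc @ fc
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        corrs[fid] = r
    best_ids = corrs.argmax(axis=0)
    scores = corrs.max(axis=0)
    return scores, best_ids


def feature_table(
    scores: ScoreMatrix,
    bank: FilterBank,
    truth: ContactMap | None = None,
) -> pd.DataFrame:
    """Feature table with one row per represented pair.

    Columns: i, j (0-based), x1, x2, best_filter, label (1 contact,
    0 non-contact, -1 unknown), family.
    """
    la, lb = scores.shape
    if la * lb < 2:
        raise ValueError("score matrix too small: no usable window")
    if truth is not None and truth.shape != scores.shape:
        raise ValueError(f"truth shape {truth.shape} does not match scores {scores.shape}")
    k = bank.k
    h = (k - 1) // 2
    values = scores.values
    all_present = bool(scores.present.all())

    x2 = np.zeros((la, lb), dtype=float)
    best = np.zeros((la, lb), dtype=int)
    done = np.zeros((la, lb), dtype=bool)

    if all_present and la >= k and lb >= k:
        s, b = _interior_filter_scores(values, bank)
        x2[h:la - h, h:lb - h] = s
        best[h:la - h, h:lb - h] = b
        done[h:la - h, h:lb - h] = True

    for i in range(la):
        for j in range(lb):
            if done[i, j] or not scores.present[i, j]:
                continue
            w = extract_window(values, i, j, k)
            if not all_present:
                pw = extract_window(scores.present.astype(float), i, j, k)
                w.valid &= pw.values > 0.5
            x2[i, j], best[i, j] = filter_score(w, bank)

    ii, jj = np.nonzero(scores.present)
    if truth is not None:
        labels = truth.values[ii, jj].astype(int)
    else:
        labels = np.full(len(ii), -1, dtype=int)
    return pd.DataFrame(
        {
            "i": ii,
            "j": jj,
            "x1": values[ii, jj],
            "x2": x2[ii, jj],
            "best_filter": best[ii, jj],
            "label": labels,
            "family": scores.family,
        }
    )


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as TSV with 1-based residue indices."""
    out = table.copy()
    out["i"] = out["i"] + 1
    out["j"] = out["j"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["i"] = table["i"] - 1
    table["j"] = table["j"] - 1
    return table
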