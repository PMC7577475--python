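"""Parsing of plmDCA-style score files and effective-sequence-number binning.

Score files are whitespace-separated ``i j score`` triplets, 1-based, with
``#`` comment lines; the effective sequence number may be declared in a
``# Meff=<value>`` header.  Indices are either *joint* (both domains
concatenated, inter-domain pairs being those with i <= L_A < j) or *split*
(i over domain A, j over domain B independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScoreMatrix", "ParseReport", "parse_scores", "write_scores", "meff_bin", "MEFF_BINS"]

#: bin name -> (exclusive lower bound, inclusive upper bound) on M_eff
MEFF_BINS = {
    "small": (0.0, 50.0),
    "medium": (50.0, 200.0),
    "large": (200.0, float("inf")),
}


@dataclass
class ScoreMatrix:
    """Dense L_A x L_B matrix of inter-domain DCA scores.

    ``present`` flags which pairs were actually observed in the source file;
    absent pairs hold 0 in ``values`` but are excluded from ranking and
    feature extraction.
    """

    values: np.ndarray
    meff: float | None = None
    family: str = ""
    present: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score matrix must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix entries must be finite")
        if self.present is None:
            self.present = np.ones(self.values.shape, dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
            if self.present.shape != self.values.shape:
                raise ValueError("present mask shape mismatch")
        if self.meff is not None and self.meff <= 0:
            raise ValueError("M_eff must be positive")

    @property
    def shape(self):
        return self.values.shape

    @property
    def bin(self) -> str:
        if self.meff is None:
            raise ValueError("no M_eff attached to score matrix")
        return meff_bin(self.meff)


@dataclass
class ParseReport:
    n_inter: int = 0
    n_intra_skipped: int = 0
    n_comment: int = 0


def meff_bin(meff: float) -> str:
    """Assign an M_eff value to the {large, medium, small} bin.

    Boundaries are inclusive at the top of each of the lower bins:
    small is M_eff <= 50, medium is 50 < M_eff <= 200, large is M_eff > 200.
    """
    meff = float(meff)
    if meff <= 0:
        raise ValueError(f"M_eff must be positive, got {meff}")
    if meff > 200:
        return "large"
    if meff > 50:
        return "medium"
    return "small"


def parse_scores(path, l_a: int, l_b: int, indexing: str = "joint",
                 meff: float | None = None, family: str = "") -> tuple[ScoreMatrix, ParseReport]:
    """Parse a plmDCA-style triplet file into a dense inter-domain ScoreMatrix.

    Parameters
    ----------
    indexing
        ``"joint"``: indices run 1..L_A+L_B over the concatenated domains and
        only pairs with i <= L_A < j are inter-domain (others are skipped and
        counted).  ``"split"``: i is 1..L_A, j is 1..L_B.
    meff
        Overrides any ``# Meff=`` header when given.
    """
    if indexing not in ("joint", "split"):
        raise ValueError(f"unknown indexing convention {indexing!r}")
    values = np.zeros((l_a, l_b), dtype=float)
    present = np.zeros((l_a, l_b), dtype=bool)
    report = ParseReport()
    header_meff = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                report.n_comment += 1
                stripped = line[1:].replace(" ", "")
                if stripped.lower().startswith("meff="):
                    header_meff = float(stripped.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'i j score', got {line!r}")
            i, j, score = int(parts[0]), int(parts[1]), float(parts[2])
            if indexing == "joint":
                if i > j:
                    i, j = j, i
                if not (1 <= i <= l_a + l_b and 1 <= j <= l_a + l_b):
                    raise ValueError(f"{path}:{lineno}: index out of range 1..{l_a + l_b}")
                if not (i <= l_a < j):
                    report.n_intra_skipped += 1
                    continue
                r, c = i - 1, j - l_a - 1
            else:
                if not (1 <= i <= l_a):
                    raise ValueError(f"{path}:{lineno}: i={i} out of range 1..{l_a}")
                if not (1 <= j <= l_b):
                    raise ValueError(f"{path}:{lineno}: j={j} out of range 1..{l_b}")
                r, c = i - 1, j - 1
            if present[r, c] and values[r, c] != score:
                raise ValueError(
                    f"{path}:{lineno}: conflicting duplicate for pair ({i}, {j}): "
                    f"{values[r, c]} vs {score}"
                )
            values[r, c] = score
            present[r, c] = True
            report.n_inter += 1
    if meff is None:
        meff = header_meff
    return ScoreMatrix(values, meff=meff, family=family, present=present), report


def write_scores(sm: ScoreMatrix, path, indexing: str = "joint") -> None:
    """Write a ScoreMatrix in the triplet format accepted by ``parse_scores``."""
    l_a, l_b = sm.shape
    with open(path, "w") as fh:
        if sm.meff is not None:
            fh.write(f"# Meff={sm.meff}\n")
        for i in range(l_a):
            for j in range(l_b):
                if not sm.present[i, j]:
                    continue
                jj = j + l_a + 1 if indexing == "joint" else j + 1
                fh.write(f"{i + 1} {jj} {float(sm.values[i, j])!r}\n")
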