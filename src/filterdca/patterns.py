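"""Construction of structural filters from contact-map windows.

Windows of size k x k (k odd) are cut out of contact maps around every
contact whose two residues are both helical (HH) or both extended (EE).
Per class, the fully valid (untruncated) windows are flattened and clustered
with k-means (3 clusters by default); the cluster centroids are the filters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .structure import ContactMap, SSAnnotation, classify_contact

__all__ = [
    "Window",
    "FilterBank",
    "extract_window",
    "mean_contact_pattern",
    "collect_class_windows",
    "build_filters_from_windows",
    "build_filters",
]


def _check_k(k: int) -> int:
    k = int(k)
    if k % 2 == 0:
        raise ValueError(f"window size k must be odd, got {k}")
    if k < 3:
        raise ValueError(f"window size k must be >= 3, got {k}")
    return k


@dataclass
class Window:
    """k x k window of a matrix centered on (i, j).

    ``values`` holds matrix entries where defined and 0 elsewhere; ``valid``
    marks positions that fall inside the source matrix (False where the
    window is truncated at a border).
    """

    values: np.ndarray
    valid: np.ndarray
    center: tuple

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def is_full(self) -> bool:
        return bool(self.valid.all())


def extract_window(matrix: np.ndarray, i: int, j: int, k: int) -> Window:
    """Extract the k x k window of ``matrix`` centered on (i, j).

    Positions outside the matrix are flagged invalid in the window mask.
    """
    k = _check_k(k)
    matrix = np.asarray(matrix)
    la, lb = matrix.shape
    if not (0 <= i < la and 0 <= j < lb):
        raise IndexError(f"center ({i}, {j}) outside matrix of shape {matrix.shape}")
    h = (k - 1) // 2
    values = np.zeros((k, k), dtype=float)
    valid = np.zeros((k, k), dtype=bool)
    r0, r1 = max(0, i - h), min(la, i + h + 1)
    c0, c1 = max(0, j - h), min(lb, j + h + 1)
    values[r0 - i + h:r1 - i + h, c0 - j + h:c1 - j + h] = matrix[r0:r1, c0:c1]
    valid[r0 - i + h:r1 - i + h, c0 - j + h:c1 - j + h] = True
    return Window(values=values, valid=valid, center=(i, j))


def mean_contact_pattern(windows: list[Window]) -> np.ndarray:
    """Element-wise mean over fully valid windows of identical size."""
    if not windows:
        raise ValueError("cannot average an empty window list")
    k = windows[0].k
    full = [w for w in windows if w.k == k and w.is_full]
    if len(full) != len(windows):
        bad = next(w for w in windows if w.k != k or not w.is_full)
        if bad.k != k:
            raise ValueError(f"window size mismatch: {bad.k} vs {k}")
        raise ValueError("truncated (border) windows cannot enter pattern averaging")
    return np.mean([w.values for w in full], axis=0)


@dataclass
class FilterBank:
    """Six k x k centroid filters: 3 from HH contacts, 3 from EE contacts."""

    filters: np.ndarray          # (6, k, k)
    classes: list                # class label per filter, e.g. "HH"/"EE"
    cluster_sizes: list
    k: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters, dtype=float)
        if self.filters.ndim != 3 or self.filters.shape[1] != self.filters.shape[2]:
            raise ValueError("filters must be a stack of square matrices")
        if self.filters.shape[1] != self.k:
            raise ValueError("filter size disagrees with declared k")
        if len(self.classes) != len(self.filters):
            raise ValueError("one class label per filter required")

    def __len__(self) -> int:
        return len(self.filters)

    def to_json(self, path) -> None:
        payload = {
            "k": int(self.k),
            "seed": self.seed,
            "classes": list(self.classes),
            "cluster_sizes": [int(s) for s in self.cluster_sizes],
            "filters": [f.ravel().tolist() for f in self.filters],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "FilterBank":
        with open(path) as fh:
            payload = json.load(fh)
        k = int(payload["k"])
        filters = np.array([np.asarray(f, dtype=float).reshape(k, k) for f in payload["filters"]])
        return cls(
            filters=filters,
            classes=payload["classes"],
            cluster_sizes=payload["cluster_sizes"],
            k=k,
            seed=payload["seed"],
        )


def collect_class_windows(
    contact_maps: list[ContactMap],
    ss_pairs: list[tuple[SSAnnotation, SSAnnotation]],
    k: int,
) -> dict:
    """Windows around every HH and EE contact, keeping only untruncated ones.

    Returns ``{"HH": (n, k, k) array, "EE": (n, k, k) array}``.
    """
    k = _check_k(k)
    out = {"HH": [], "EE": []}
    for cmap, (ss_a, ss_b) in zip(contact_maps, ss_pairs):
        la, lb = cmap.shape
        if len(ss_a) != la or len(ss_b) != lb:
            raise ValueError("secondary-structure length disagrees with contact map shape")
        for i, j in zip(*np.nonzero(cmap.values)):
            cls = classify_contact(int(i), int(j), ss_a, ss_b)
            if cls == "other":
                continue
            w = extract_window(cmap.values, int(i), int(j), k)
            if w.is_full:
                out[cls].append(w.values)
    return {c: np.array(ws) if ws else np.empty((0, k, k)) for c, ws in out.items()}


def build_filters_from_windows(
    windows_by_class: dict,
    k: int,
    n_clusters: int = 3,
    seed: int = 0,
) -> FilterBank:
    """Cluster flattened class windows with k-means; centroids become filters."""
    k = _check_k(k)
    filters, classes, sizes = [], [], []
    for cls in ("HH", "EE"):
        ws = np.asarray(windows_by_class.get(cls, np.empty((0, k, k))), dtype=float)
        if len(ws) < n_clusters:
            raise ValueError(
                f"class {cls}: {len(ws)} usable windows but {n_clusters} clusters requested"
            )
        flat = ws.reshape(len(ws), -1)
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(flat)
        # order clusters by descending size for stable labeling
        order = np.argsort([-(labels == c).sum() for c in range(n_clusters)], kind="stable")
        for c in order:
            filters.append(km.cluster_centers_[c].reshape(k, k))
            classes.append(cls)
            sizes.append(int((labels == c).sum()))
    return FilterBank(
        filters=np.array(filters),
        classes=classes,
        cluster_sizes=sizes,
        k=k,
        seed=seed,
    )


def build_filters(
    contact_maps: list[ContactMap],
    ss_pairs: list[tuple[SSAnnotation, SSAnnotation]],
    k: int,
    n_clusters: int = 3,
    seed: int = 0,
) -> FilterBank:
    """Build the filter bank from a training collection of contact maps.

    Windows truncated at matrix borders are excluded from construction.
    """
    windows = collect_class_windows(contact_maps, ss_pairs, k)
    return build_filters_from_windows(windows, k, n_clusters=n_clusters, seed=seed)
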