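"""Contact-map derivation from coordinates and secondary-structure handling.

Distances between residues of two domains are minimum heavy-atom (non-hydrogen)
distances; a contact is a pair strictly below the distance threshold (default
8 A).  Secondary structure is handled as 3-state strings over {H, E, O}.
All in-memory matrices are 0-based with rows indexing domain A residues and
columns indexing domain B residues; 1-based conversion happens only in file
readers/writers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ResidueCoords",
    "DistanceMatrix",
    "ContactMap",
    "SSAnnotation",
    "min_heavy_atom_distances",
    "merge_distance_matrices",
    "contact_map",
    "ss_three_state",
    "classify_contact",
    "dataset_filters",
    "read_pdb_coords",
    "read_distance_matrix_tsv",
    "write_contact_map",
    "read_contact_map",
    "read_ss_file",
    "write_ss_file",
]

DEFAULT_CONTACT_THRESHOLD = 8.0

# DSSP 8-state alphabet plus common padding characters.
EIGHT_STATE_ALPHABET = set("HGIEBTSC- .~")
_EIGHT_TO_THREE = {c: "O" for c in EIGHT_STATE_ALPHABET}
_EIGHT_TO_THREE.update({"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"})

THREE_STATE_ALPHABET = frozenset("HEO")


@dataclass
class ResidueCoords:
    """Per-residue heavy-atom coordinates for one domain.

    ``atoms[r]`` is an (n_r, 3) float array of the heavy-atom positions of
    residue ``r``; residue order must match the score-matrix axis.
    """

    atoms: list

    def __post_init__(self) -> None:
        cleaned = []
        for r, a in enumerate(self.atoms):
            arr = np.asarray(a, dtype=float)
            if arr.ndim == 1:
                arr = arr.reshape(1, 3)
            if arr.size == 0 or arr.shape[0] == 0:
                raise ValueError(f"residue {r} has zero atoms")
            if arr.shape[1] != 3:
                raise ValueError(f"residue {r}: atom coordinates must be 3D")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"residue {r}: non-finite coordinates")
            cleaned.append(arr)
        self.atoms = cleaned

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class DistanceMatrix:
    """L_A x L_B matrix of minimal inter-residue heavy-atom distances (A)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("distance matrix must be 2D")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ContactMap:
    """Binary L_A x L_B inter-domain contact map."""

    values: np.ndarray
    threshold: float = DEFAULT_CONTACT_THRESHOLD
    distances: DistanceMatrix | None = None
    n_copies: int = 1

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError("contact map must be 2D")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("contact map entries must be 0 or 1")
        self.values = arr.astype(np.int8)

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_contacts(self) -> int:
        return int(self.values.sum())

    @property
    def density(self) -> float:
        return float(self.values.mean())


@dataclass
class SSAnnotation:
    """3-state secondary-structure string over {H, E, O} for one domain."""

    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - THREE_STATE_ALPHABET
        if bad:
            raise ValueError(f"invalid 3-state characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, i: int) -> str:
        return self.states[i]


def min_heavy_atom_distances(coords_a: ResidueCoords, coords_b: ResidueCoords) -> DistanceMatrix:
    """Minimum Euclidean distance over all heavy-atom pairs, per residue pair."""
    if len(coords_a) == 0 or len(coords_b) == 0:
        raise ValueError("both domains must contain at least one residue")
    la, lb = len(coords_a), len(coords_b)
    out = np.empty((la, lb), dtype=float)
    # flatten domain B atoms once; cdist row-blocks per residue of A
    b_stack = np.vstack(coords_b.atoms)
    b_offsets = np.cumsum([0] + [a.shape[0] for a in coords_b.atoms])
    for i, a_atoms in enumerate(coords_a.atoms):
        d = cdist(a_atoms, b_stack)
        dmin = d.min(axis=0)
        out[i, :] = np.minimum.reduceat(dmin, b_offsets[:-1])
    return DistanceMatrix(out)


def merge_distance_matrices(matrices: list[DistanceMatrix]) -> DistanceMatrix:
    """Element-wise minimum over PDB copies of the same domain pair."""
    if not matrices:
        raise ValueError("need at least one distance matrix")
    shape = matrices[0].shape
    for m in matrices[1:]:
        if m.shape != shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {shape}")
    merged = np.minimum.reduce([m.values for m in matrices])
    return DistanceMatrix(merged)


def contact_map(distances: DistanceMatrix, threshold: float = DEFAULT_CONTACT_THRESHOLD) -> ContactMap:
    """Binary contact map: contact iff distance strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return ContactMap(
        (distances.values < threshold).astype(np.int8),
        threshold=threshold,
        distances=distances,
    )


def ss_three_state(eight_state: str) -> str:
    """Collapse an 8-state (DSSP-style) string to 3 states.

    H, G, I -> H;  E, B -> E;  everything else in the declared alphabet -> O.
    """
    out = []
    for pos, c in enumerate(eight_state):
        cu = c.upper() if c.isalpha() else c
        if cu not in _EIGHT_TO_THREE:
            raise ValueError(f"unknown 8-state character {c!r} at position {pos}")
        out.append(_EIGHT_TO_THREE[cu])
    return "".join(out)


def classify_contact(i: int, j: int, ss_a: SSAnnotation, ss_b: SSAnnotation) -> str:
    """Class of a residue pair: 'HH', 'EE', or 'other'."""
    if not (0 <= i < len(ss_a)):
        raise IndexError(f"index i={i} out of range for domain A (length {len(ss_a)})")
    if not (0 <= j < len(ss_b)):
        raise IndexError(f"index j={j} out of range for domain B (length {len(ss_b)})")
    a, b = ss_a[i], ss_b[j]
    if a == "H" and b == "H":
        return "HH"
    if a == "E" and b == "E":
        return "EE"
    return "other"


def dataset_filters(
    cmap: ContactMap,
    coverage_fraction: float,
    min_contacts: int = 10,
    max_contacts: int = 2000,
    min_coverage: float = 0.40,
):
    """Dataset inclusion check: 10 <= contacts <= 2000 and coverage >= 40%.

    Returns ``(passed, reasons)`` where ``reasons`` lists every violated rule.
    """
    reasons = []
    n = cmap.n_contacts
    if n < min_contacts:
        reasons.append(f"too few contacts: {n} < {min_contacts}")
    if n > max_contacts:
        reasons.append(f"too many contacts: {n} > {max_contacts}")
    if coverage_fraction < min_coverage:
        reasons.append(f"coverage {coverage_fraction:.3f} < {min_coverage:.2f}")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_pdb_coords(path, chain_id: str, residue_range=None) -> ResidueCoords:
    """Read heavy-atom coordinates for one chain of a PDB file.

    Hydrogens (and deuteriums) are excluded; for alternate locations only the
    first conformer encountered is kept.  ``residue_range`` is an optional
    inclusive (first, last) pair of author residue numbers.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure("s", str(path))[0]
    if chain_id not in model:
        raise ValueError(f"chain {chain_id!r} not found in {path}")
    atoms_per_residue = []
    for residue in model[chain_id]:
        hetflag, resseq, _ = residue.id
        if hetflag.strip():
            continue
        if residue_range is not None and not (residue_range[0] <= resseq <= residue_range[1]):
            continue
        coords, seen = [], set()
        for atom in residue:
            if (atom.element or "").upper() in ("H", "D"):
                continue
            if atom.get_name() in seen:  # altloc duplicates: keep first
                continue
            seen.add(atom.get_name())
            coords.append(atom.get_coord())
        if coords:
            atoms_per_residue.append(np.asarray(coords, dtype=float))
    if not atoms_per_residue:
        raise ValueError(f"no heavy-atom residues found for chain {chain_id!r} in {path}")
    return ResidueCoords(atoms_per_residue)


def read_distance_matrix_tsv(path) -> DistanceMatrix:
    """Read a TSV distance matrix with a 1-based header row and column."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float))


def write_contact_map(cmap: ContactMap, path) -> None:
    """Write a contact map as 1-based "i j" pairs with a shape header."""
    la, lb = cmap.shape
    with open(path, "w") as fh:
        fh.write(f"# shape {la} {lb} threshold {cmap.threshold}\n")
        for i, j in zip(*np.nonzero(cmap.values)):
            fh.write(f"{i + 1} {j + 1}\n")


def read_contact_map(path) -> ContactMap:
    threshold = DEFAULT_CONTACT_THRESHOLD
    shape = None
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                tok = line[1:].split()
                if tok[:1] == ["shape"]:
                    shape = (int(tok[1]), int(tok[2]))
                    if "threshold" in tok:
                        threshold = float(tok[tok.index("threshold") + 1])
                continue
            i, j = line.split()[:2]
            pairs.append((int(i) - 1, int(j) - 1))
    if shape is None:
        raise ValueError(f"{path}: missing '# shape L_A L_B' header")
    values = np.zeros(shape, dtype=np.int8)
    for i, j in pairs:
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            raise ValueError(f"{path}: pair ({i + 1}, {j + 1}) outside shape {shape}")
        values[i, j] = 1
    return ContactMap(values, threshold=threshold)


def read_ss_file(path) -> tuple[SSAnnotation, SSAnnotation]:
    """Read a two-line secondary-structure file (one line per domain)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if len(lines) != 2:
        raise ValueError(f"{path}: expected 2 secondary-structure lines, got {len(lines)}")
    return SSAnnotation(lines[0]), SSAnnotation(lines[1])


def write_ss_file(ss_a: SSAnnotation, ss_b: SSAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write(ss_a.states + "\n" + ss_b.states + "\n")
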