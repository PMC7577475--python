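"""Synthetic domain-pair generator.

Produces matched triples (contact map, secondary-structure strings, DCA-like
score matrix) with the local structure the method exploits: helix-helix
interface blocks carry a near-periodic contact pattern (period 3-4, low
probability at offsets +-2), strand-strand blocks carry a parallel or
anti-parallel diagonal stripe, and scores separate contacts from
non-contacts only partially.  The detection probability ``p_det`` plays the
role of alignment depth: each true contact carries signal with probability
p_det, so at p_det -> 0 the contact and non-contact score distributions
coincide.

All randomness flows from a single master seed: ``generate_benchmark``
spawns one child ``SeedSequence`` per family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dca_io import ScoreMatrix
from .structure import ContactMap, SSAnnotation

__all__ = [
    "SyntheticFamily",
    "helix_offset_profile",
    "helix_template",
    "strand_template",
    "generate_ss_layout",
    "generate_contact_map",
    "generate_scores",
    "add_spurious_stripes",
    "generate_family",
    "generate_benchmark",
    "sample_class_windows",
]

# secondary-structure segment length ranges and composition targets
SS_RUN_LENGTHS = {"H": (8, 20), "E": (4, 8), "O": (2, 6)}
SS_TARGETS = {"H": 0.35, "E": 0.25, "O": 0.40}

HELIX_PERIOD = 3.6        # residues per helical turn
HELIX_PEAK = 0.85         # contact probability scale inside an HH block
STRAND_BACKGROUND = 0.02  # off-stripe probability in EE windows


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class SyntheticFamily:
    """One generated domain-domain interaction."""

    family: str
    ss_a: SSAnnotation
    ss_b: SSAnnotation
    contacts: ContactMap
    scores: ScoreMatrix
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def shape(self):
        return self.contacts.shape


def helix_offset_profile(d) -> np.ndarray:
    """In-phase weight of a sequence offset on a helical face.

    1 at offset 0, high again near +-3/+-4 (one turn), zero on the opposite
    face (+-1, +-2).
    """
    d = np.asarray(d, dtype=float)
    return np.maximum(np.cos(2.0 * np.pi * d / HELIX_PERIOD), 0.0)


HELIX_VARIANTS = ("crossed", "parallel", "antiparallel")
_PACKING_WIDTH = 3.0  # diagonal decay width of packed helix pairs


def helix_template(k: int, peak: float = HELIX_PEAK, variant: str = "crossed") -> np.ndarray:
    """k x k contact-probability template around a central HH contact.

    Variants model the packing geometry of the two helices: ``crossed``
    keeps the full periodic product pattern; ``parallel`` and
    ``antiparallel`` additionally concentrate contacts near the diagonal
    di = dj resp. the anti-diagonal di = -dj.
    """
    h = (k - 1) // 2
    off = np.arange(-h, h + 1)
    prof = helix_offset_profile(off)
    t = peak * np.outer(prof, prof)
    if variant == "parallel":
        t *= np.exp(-((off[:, None] - off[None, :]) ** 2) / (2 * _PACKING_WIDTH**2))
    elif variant == "antiparallel":
        t *= np.exp(-((off[:, None] + off[None, :]) ** 2) / (2 * _PACKING_WIDTH**2))
    elif variant != "crossed":
        raise ValueError(f"unknown helix variant {variant!r}")
    t[h, h] = 1.0
    return t


def strand_template(k: int, orientation: int, p_diag: float = 0.95,
                    background: float = STRAND_BACKGROUND) -> np.ndarray:
    """k x k template with a (anti-)diagonal stripe through the center.

    ``orientation`` +1 gives a parallel-strand main diagonal, -1 the
    anti-parallel anti-diagonal, 0 the crossing-strand case (both
    diagonals at reduced probability).
    """
    if orientation not in (1, -1, 0):
        raise ValueError("orientation must be +1, -1 or 0")
    h = (k - 1) // 2
    di = np.arange(-h, h + 1)[:, None]
    dj = np.arange(-h, h + 1)[None, :]
    t = np.full((k, k), background)
    if orientation == 0:
        t[di == dj] = 0.5 * p_diag
        t[di == -dj] = 0.5 * p_diag
    else:
        t[di == orientation * dj] = p_diag
    t[h, h] = 1.0
    return t


def generate_ss_layout(length: int, seed) -> SSAnnotation:
    """Random 3-state layout of alternating H/E/O runs.

    Segment types are drawn with a bias toward whichever class is furthest
    below its composition target (~35% H, ~25% E, ~40% O), never repeating
    the previous type, so compositions stay close to target even at modest
    lengths.
    """
    if length < 10:
        raise ValueError(f"domain length must be >= 10, got {length}")
    rng = _rng(seed)
    counts = {c: 0 for c in "HEO"}
    out: list = []
    prev = None
    while len(out) < length:
        total = max(len(out), 1)
        deficits = {
            c: max(SS_TARGETS[c] * length - counts[c], 0.0) + 1e-3 for c in "HEO"
        }
        if prev is not None:
            deficits[prev] = 0.0
        cands = [c for c in "HEO" if deficits[c] > 0]
        if not cands:
            cands = [c for c in "HEO" if c != prev]
        weights = np.array([deficits[c] if deficits[c] > 0 else 1e-3 for c in cands])
        c = cands[int(rng.choice(len(cands), p=weights / weights.sum()))]
        lo, hi = SS_RUN_LENGTHS[c]
        run = int(rng.integers(lo, hi + 1))
        run = min(run, length - len(out))
        out.extend(c * run)
        counts[c] += run
        prev = c
    return SSAnnotation("".join(out[:length]))


def _runs(ss: SSAnnotation, state: str, min_len: int):
    """(start, end) half-open intervals of maximal runs of ``state``."""
    runs = []
    start = None
    for idx, c in enumerate(ss.states + "$"):
        if c == state and start is None:
            start = idx
        elif c != state and start is not None:
            if idx - start >= min_len:
                runs.append((start, idx))
            start = None
    return runs


def generate_contact_map(
    ss_a: SSAnnotation,
    ss_b: SSAnnotation,
    n_interface_blocks: int,
    seed,
    background: float = 0.0,
    hh_fraction: float = 0.5,
) -> ContactMap:
    """Plant interface blocks between secondary-structure runs.

    Helix-helix block pairs draw contacts from the periodic template
    centered on a random anchor pair; strand-strand pairs get a
    deterministic diagonal (parallel) or anti-diagonal stripe; optional
    sparse Bernoulli background everywhere else.
    """
    rng = _rng(seed)
    la, lb = len(ss_a), len(ss_b)
    cmap = np.zeros((la, lb), dtype=np.int8)
    h_runs = (_runs(ss_a, "H", 6), _runs(ss_b, "H", 6))
    e_runs = (_runs(ss_a, "E", 3), _runs(ss_b, "E", 3))
    have_hh = bool(h_runs[0] and h_runs[1])
    have_ee = bool(e_runs[0] and e_runs[1])
    if n_interface_blocks > 0 and not (have_hh or have_ee):
        raise ValueError("no H or E runs available to place interface blocks")
    for _ in range(n_interface_blocks):
        if have_hh and (not have_ee or rng.random() < hh_fraction):
            ra = h_runs[0][int(rng.integers(len(h_runs[0])))]
            rb = h_runs[1][int(rng.integers(len(h_runs[1])))]
            ci = int(rng.integers(ra[0] + 2, ra[1] - 2))
            cj = int(rng.integers(rb[0] + 2, rb[1] - 2))
            di = np.arange(ra[0], ra[1]) - ci
            dj = np.arange(rb[0], rb[1]) - cj
            probs = HELIX_PEAK * np.outer(helix_offset_profile(di), helix_offset_profile(dj))
            variant = HELIX_VARIANTS[int(rng.integers(len(HELIX_VARIANTS)))]
            if variant == "parallel":
                probs *= np.exp(-((di[:, None] - dj[None, :]) ** 2) / (2 * _PACKING_WIDTH**2))
            elif variant == "antiparallel":
                probs *= np.exp(-((di[:, None] + dj[None, :]) ** 2) / (2 * _PACKING_WIDTH**2))
            block = (rng.random(probs.shape) < probs).astype(np.int8)
            block[ci - ra[0], cj - rb[0]] = 1  # anchor contact always present
            cmap[ra[0]:ra[1], rb[0]:rb[1]] |= block
        else:
            ra = e_runs[0][int(rng.integers(len(e_runs[0])))]
            rb = e_runs[1][int(rng.integers(len(e_runs[1])))]
            orientation = 1 if rng.random() < 0.5 else -1
            length = min(ra[1] - ra[0], rb[1] - rb[0])
            ii = np.arange(ra[0], ra[0] + length)
            if orientation == 1:
                jj = np.arange(rb[0], rb[0] + length)
            else:
                jj = np.arange(rb[0] + length - 1, rb[0] - 1, -1)
            cmap[ii, jj] = 1
    if background > 0:
        cmap |= (rng.random((la, lb)) < background).astype(np.int8)
    return ContactMap(cmap)


def generate_scores(
    contacts: ContactMap,
    s: float,
    p_det: float,
    sigma: float,
    seed,
    meff: float | None = None,
    family: str = "",
) -> ScoreMatrix:
    """DCA-like scores F = s * c * B + noise.

    ``c`` is the contact indicator, ``B ~ Bernoulli(p_det)`` i.i.d. (the
    alignment-depth proxy), and the noise is Normal(0, sigma^2).
    """
    if s < 0:
        raise ValueError("signal strength s must be >= 0")
    if not (0.0 <= p_det <= 1.0):
        raise ValueError("p_det must lie in [0, 1]")
    if sigma <= 0:
        raise ValueError("noise sigma must be positive")
    rng = _rng(seed)
    c = contacts.values.astype(float)
    detected = rng.random(c.shape) < p_det
    noise = rng.normal(0.0, sigma, size=c.shape)
    return ScoreMatrix(s * c * detected + noise, meff=meff, family=family)


def add_spurious_stripes(
    scores: ScoreMatrix,
    contacts: ContactMap,
    n_stripes: int,
    s: float,
    p_det: float,
    seed,
    length: int = 6,
) -> ScoreMatrix:
    """Plant coherent false signal: short diagonal score stripes on
    non-contact pairs.

    Emulates spurious coevolutionary signal (e.g. from repeated motifs),
    so that even score-coherent regions are not guaranteed contacts.
    """
    rng = _rng(seed)
    values = scores.values.copy()
    la, lb = values.shape
    for _ in range(n_stripes):
        for _attempt in range(50):
            i0 = int(rng.integers(0, max(la - length, 1)))
            j0 = int(rng.integers(0, max(lb - length, 1)))
            ori = 1 if rng.random() < 0.5 else -1
            ii = np.arange(i0, i0 + length)
            jj = np.arange(j0, j0 + length) if ori == 1 else np.arange(j0 + length - 1, j0 - 1, -1)
            if contacts.values[ii, jj].sum() == 0:
                detected = rng.random(length) < p_det
                values[ii, jj] += s * detected
                break
    return ScoreMatrix(values, meff=scores.meff, family=scores.family, present=scores.present)


def generate_family(
    name: str,
    seed,
    l_range=(90, 120),
    n_interface_blocks: int = 5,
    s: float = 0.4,
    p_det: float = 0.5,
    sigma: float = 0.1,
    background: float = 0.002,
    meff: float = 300.0,
    n_spurious_stripes: int = 2,
) -> SyntheticFamily:
    """One complete synthetic family (SS strings, contacts, scores)."""
    rng = _rng(seed)
    la = int(rng.integers(l_range[0], l_range[1] + 1))
    lb = int(rng.integers(l_range[0], l_range[1] + 1))
    ss_a = generate_ss_layout(la, rng)
    ss_b = generate_ss_layout(lb, rng)
    contacts = generate_contact_map(ss_a, ss_b, n_interface_blocks, rng, background=background)
    # top up sparse draws so densities stay in the configured 0.5-5% band
    blocks = n_interface_blocks
    while contacts.density < 0.005 and blocks < n_interface_blocks + 8:
        blocks += 1
        contacts = generate_contact_map(ss_a, ss_b, blocks, rng, background=background)
    scores = generate_scores(contacts, s, p_det, sigma, rng, meff=meff, family=name)
    if n_spurious_stripes > 0:
        scores = add_spurious_stripes(scores, contacts, n_spurious_stripes, s, p_det, rng)
    return SyntheticFamily(
        family=name,
        ss_a=ss_a,
        ss_b=ss_b,
        contacts=contacts,
        scores=scores,
        params={
            "s": s, "p_det": p_det, "sigma": sigma,
            "background": background, "n_interface_blocks": n_interface_blocks,
            "meff": meff, "n_spurious_stripes": n_spurious_stripes,
        },
    )


def generate_benchmark(n_families: int, seed, prefix: str = "fam", **params) -> list:
    """Independent synthetic families with per-family seeds spawned from
    the master seed."""
    if n_families < 2:
        raise ValueError("need at least 2 families for a benchmark")
    children = np.random.SeedSequence(seed).spawn(n_families)
    return [
        generate_family(f"{prefix}{idx:04d}", np.random.default_rng(child), **params)
        for idx, child in enumerate(children)
    ]


def sample_class_windows(cls: str, n: int, k: int, seed, orientation=None) -> np.ndarray:
    """Draw n binary k x k windows around a central contact of a class.

    HH windows are Bernoulli draws from the periodic helix templates
    (cycling through the packing variants); EE windows from the parallel
    (+1) or anti-parallel (-1) stripe template, alternating when
    ``orientation`` is None.  Centers are always 1.
    """
    rng = _rng(seed)
    if cls == "HH":
        templates = [helix_template(k, variant=v) for v in HELIX_VARIANTS]
    elif cls == "EE":
        if orientation is None:
            templates = [strand_template(k, 1), strand_template(k, -1), strand_template(k, 0)]
        else:
            templates = [strand_template(k, orientation)]
    else:
        raise ValueError(f"unknown window class {cls!r}")
    out = np.empty((n, k, k), dtype=np.int8)
    for idx in range(n):
        t = templates[idx % len(templates)]
        out[idx] = (rng.random((k, k)) < t).astype(np.int8)
        out[idx, (k - 1) // 2, (k - 1) // 2] = 1
    return out
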