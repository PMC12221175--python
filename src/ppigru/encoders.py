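"""Six sequence-to-vector feature coding techniques and pair concatenation.

Three encoders read a 13-component physicochemical property profile
(PseAAC, autocorrelation descriptors, autocovariance); three read the
seven-class dipole/side-chain-volume alphabet (conjoint triad, local
descriptor, multivariate mutual information).  Per-protein dimensions:

======== ==============================
PseAAC   20 + lag
AD       3 * 13 * lag  (Moreau-Broto, Moran, Geary)
AC       13 * lag
CT       343 = 7^3
LD       630 = 10 regions x (7 C + 21 T + 35 D)
MMI      119 = 84 + 28 + 7
======== ==============================

A protein pair is represented by concatenating the two per-protein vectors
(first protein of the pair first), doubling the dimension.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .aaprops import (
    CANONICAL_RESIDUES,
    N_CLASSES,
    ClassMap,
    PropertyTable,
    ResidueError,
)

TECHNIQUES = ("pseaac", "ad", "ac", "ct", "ld", "mmi")

#: Techniques whose encoders take a lag parameter.
LAGGED_TECHNIQUES = ("pseaac", "ad", "ac")


class LagTooLargeError(ValueError):
    """The requested lag is not smaller than the sequence length."""


class SequenceTooShortError(ValueError):
    """The sequence is shorter than the encoder's minimum length."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence over the canonical 20-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein '{self.id}': empty sequence")
        bad = set(self.sequence) - set(CANONICAL_RESIDUES)
        if bad:
            pos = next(i for i, r in enumerate(self.sequence) if r in bad)
            raise ResidueError(
                f"protein '{self.id}': non-canonical residue "
                f"'{self.sequence[pos]}' at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureBlock:
    """One protein's descriptor vector for one coding technique."""

    technique: str
    lag: int | None
    vector: np.ndarray

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


@dataclass(frozen=True)
class PairFeature:
    """Concatenated descriptors enc(A) || enc(B) for a protein pair."""

    technique: str
    lag: int | None
    vector: np.ndarray

    @property
    def dim(self) -> int:
        return self.vector.shape[0]


def feature_dim(technique: str, lag: int | None = None) -> int:
    """Per-protein dimension of a technique (pair dimension is twice this)."""
    if technique in LAGGED_TECHNIQUES and (lag is None or lag < 1):
        raise ValueError(f"technique '{technique}' requires a positive lag")
    return {
        "pseaac": lambda: 20 + lag,
        "ad": lambda: 3 * 13 * lag,
        "ac": lambda: 13 * lag,
        "ct": lambda: 343,
        "ld": lambda: 630,
        "mmi": lambda: 119,
    }[technique]()


def _check_lag(seq: ProteinRecord, lag: int) -> None:
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if len(seq) <= lag:
        raise LagTooLargeError(
            f"protein '{seq.id}': length {len(seq)} <= lag {lag}"
        )


def _check_props(props: PropertyTable) -> None:
    if not props.standardized:
        raise ValueError("property table must be standardized before encoding")


# ---------------------------------------------------------------------------
# SVHEHS-profile encoders


def encode_pseaac(
    seq: ProteinRecord, lag: int, props: PropertyTable, weight: float = 0.05
) -> FeatureBlock:
    """Pseudo amino-acid composition (type 1) with 13-component correlation.

    The first 20 entries are the weighted residue composition; the last
    ``lag`` entries are sequence-order factors theta_1..theta_lag, where
    theta_j averages, over all residue pairs (i, i+j), the mean squared
    difference of the 13 standardized property components.  All 20 + lag
    entries share the denominator sum(composition) + weight * sum(theta),
    so the vector sums to one.
    """
    _check_lag(seq, lag)
    _check_props(props)
    if weight <= 0:
        raise ValueError("PseAAC weight must be positive")
    L = len(seq)
    profile = props.profile(seq.sequence)  # L x 13
    comp = np.zeros(20)
    for r in seq.sequence:
        comp[CANONICAL_RESIDUES.index(r)] += 1
    comp /= L
    theta = np.empty(lag)
    for j in range(1, lag + 1):
        diff = profile[j:] - profile[:-j]
        theta[j - 1] = np.mean(diff * diff) if diff.size else 0.0
    denom = comp.sum() + weight * theta.sum()
    vec = np.concatenate([comp, weight * theta]) / denom
    return FeatureBlock("pseaac", lag, vec)


def encode_ad(seq: ProteinRecord, lag: int, props: PropertyTable) -> FeatureBlock:
    """Normalized Moreau-Broto, Moran and Geary autocorrelation descriptors.

    Computed per property column of the standardized profile at distances
    d = 1..lag; ordering is descriptor-major, then property, then distance.
    When a property is constant along the sequence, Moran and Geary are
    defined as 0 (the continuous limit of a vanishing denominator).
    """
    _check_lag(seq, lag)
    _check_props(props)
    L = len(seq)
    P = props.profile(seq.sequence)  # L x 13
    mean = P.mean(axis=0)
    dev = P - mean
    # a constant property column has zero variance by definition; test it
    # exactly so rounding in the mean cannot fake a tiny nonzero variance
    constant = P.max(axis=0) == P.min(axis=0)
    denom_moran = np.where(constant, 0.0, (dev * dev).sum(axis=0) / L)
    denom_geary = (
        np.where(constant, 0.0, (dev * dev).sum(axis=0) / (L - 1))
        if L > 1 else np.zeros(13)
    )
    mb = np.empty((13, lag))
    moran = np.zeros((13, lag))
    geary = np.zeros((13, lag))
    for d in range(1, lag + 1):
        a, b = P[:-d], P[d:]
        mb[:, d - 1] = (a * b).sum(axis=0) / (L - d)
        num_moran = (dev[:-d] * dev[d:]).sum(axis=0) / (L - d)
        num_geary = ((a - b) ** 2).sum(axis=0) / (2 * (L - d))
        ok = denom_moran > 0
        moran[ok, d - 1] = num_moran[ok] / denom_moran[ok]
        okg = denom_geary > 0
        geary[okg, d - 1] = num_geary[okg] / denom_geary[okg]
    vec = np.concatenate([mb.ravel(), moran.ravel(), geary.ravel()])
    return FeatureBlock("ad", lag, vec)


def encode_ac(seq: ProteinRecord, lag: int, props: PropertyTable) -> FeatureBlock:
    """Autocovariance of each property at distances 1..lag (property-major)."""
    _check_lag(seq, lag)
    _check_props(props)
    L = len(seq)
    P = props.profile(seq.sequence)
    dev = P - P.mean(axis=0)
    out = np.empty((13, lag))
    for d in range(1, lag + 1):
        out[:, d - 1] = (dev[:-d] * dev[d:]).sum(axis=0) / (L - d)
    return FeatureBlock("ac", lag, out.ravel())


# ---------------------------------------------------------------------------
# Seven-class encoders


def encode_ct(seq: ProteinRecord, cmap: ClassMap) -> FeatureBlock:
    """Conjoint triad: min-max-normalized counts of ordered class 3-mers."""
    if len(seq) < 3:
        raise SequenceTooShortError(f"protein '{seq.id}': CT needs length >= 3")
    c = cmap.classes_of(seq.sequence) - 1
    codes = c[:-2] * 49 + c[1:-1] * 7 + c[2:]
    counts = np.bincount(codes, minlength=343).astype(float)
    return FeatureBlock("ct", None, (counts - counts.min()) / counts.max())


# Region fraction intervals: four quarters, two halves, middle half,
# first/last three quarters, central 75%.
_LD_REGIONS = (
    (0.0, 0.25), (0.25, 0.5), (0.5, 0.75), (0.75, 1.0),
    (0.0, 0.5), (0.5, 1.0),
    (0.25, 0.75),
    (0.0, 0.75), (0.25, 1.0),
    (0.125, 0.875),
)

_LD_PAIRS = tuple(itertools.combinations(range(N_CLASSES), 2))


def _ld_bounds(L: int) -> list[tuple[int, int]]:
    """0-based half-open [start, end) index ranges of the 10 regions."""
    bounds = []
    for f0, f1 in _LD_REGIONS:
        start = int(round(f0 * L))
        end = max(int(round(f1 * L)), start + 1)
        bounds.append((min(start, L - 1), min(end, L)))
    return bounds


def encode_ld(seq: ProteinRecord, cmap: ClassMap) -> FeatureBlock:
    """Local descriptor: composition/transition/distribution in 10 regions.

    Per region: 7 class frequencies (C); 21 adjacent-pair transition
    frequencies for unordered class pairs (T); and, for each class, the
    relative positions of its 1st, 25th-, 50th-, 75th-percentile and last
    occurrence (D), zeros when the class is absent.
    """
    L = len(seq)
    if L < 10:
        raise SequenceTooShortError(f"protein '{seq.id}': LD needs length >= 10")
    classes = cmap.classes_of(seq.sequence) - 1
    out = np.zeros(630)
    off = 0
    for start, end in _ld_bounds(L):
        region = classes[start:end]
        n = region.shape[0]
        comp = np.bincount(region, minlength=N_CLASSES) / n
        out[off : off + 7] = comp
        off += 7
        if n > 1:
            a, b = region[:-1], region[1:]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            mask = lo != hi
            pair_idx = {p: i for i, p in enumerate(_LD_PAIRS)}
            trans = np.zeros(21)
            for x, y in zip(lo[mask], hi[mask]):
                trans[pair_idx[(x, y)]] += 1
            out[off : off + 21] = trans / (n - 1)
        off += 21
        for cls in range(N_CLASSES):
            pos = np.flatnonzero(region == cls) + 1  # 1-based within region
            m = pos.shape[0]
            if m:
                picks = [
                    pos[0],
                    pos[int(np.ceil(0.25 * m)) - 1],
                    pos[int(np.ceil(0.5 * m)) - 1],
                    pos[int(np.ceil(0.75 * m)) - 1],
                    pos[-1],
                ]
                out[off : off + 5] = np.array(picks) / n
            off += 5
    return FeatureBlock("ld", None, out)


_MMI_PAIRS = tuple(itertools.combinations_with_replacement(range(N_CLASSES), 2))
_MMI_TRIPLES = tuple(itertools.combinations_with_replacement(range(N_CLASSES), 3))


def _safe_h(p: float, q: float) -> float:
    """-p * ln(p / q) with the 0*ln0 convention (0 when p or q vanish)."""
    if p <= 0.0 or q <= 0.0:
        return 0.0
    return -p * np.log(p / q)


def encode_mmi(seq: ProteinRecord, cmap: ClassMap) -> FeatureBlock:
    """Multivariate mutual information over unordered class 2/3-grams.

    Output is 84 three-way informations I(a,b,c) over class multisets,
    28 pairwise informations I(a,b), and the 7 class frequencies, in
    lexicographic multiset order.  All entropies use natural logarithms
    with 0*ln(0) := 0.
    """
    L = len(seq)
    if L < 3:
        raise SequenceTooShortError(f"protein '{seq.id}': MMI needs length >= 3")
    c = cmap.classes_of(seq.sequence) - 1
    f1 = np.bincount(c, minlength=7) / L
    pair_counts = np.zeros((7, 7))
    for x, y in zip(c[:-1], c[1:]):
        lo, hi = (x, y) if x <= y else (y, x)
        pair_counts[lo, hi] += 1
    f2 = pair_counts / (L - 1)
    triple_counts: dict[tuple[int, int, int], float] = {}
    for i in range(L - 2):
        key = tuple(sorted((c[i], c[i + 1], c[i + 2])))
        triple_counts[key] = triple_counts.get(key, 0.0) + 1.0
    f3 = {t: triple_counts.get(t, 0.0) / (L - 2) for t in _MMI_TRIPLES}

    def H1(a):  # H(a)
        return _safe_h(f1[a], 1.0)

    def Hcond(a, b):  # H(a|b) = -f(a,b) ln(f(a,b)/f(b))
        return _safe_h(f2[min(a, b), max(a, b)], f1[b])

    def I2(a, b):
        return H1(a) - Hcond(a, b)

    vec = np.empty(119)
    k = 0
    for a, b, cc in _MMI_TRIPLES:
        h_abc = _safe_h(f3[(a, b, cc)], f2[min(b, cc), max(b, cc)])
        i_ab_c = Hcond(a, cc) - h_abc
        vec[k] = I2(a, b) - i_ab_c
        k += 1
    for a, b in _MMI_PAIRS:
        vec[k] = I2(a, b)
        k += 1
    vec[k : k + 7] = f1
    return FeatureBlock("mmi", None, vec)


# ---------------------------------------------------------------------------


def encode_pair(a: FeatureBlock, b: FeatureBlock) -> PairFeature:
    """Concatenate two same-technique blocks (first protein first)."""
    if a.technique != b.technique:
        raise ValueError(f"technique mismatch: {a.technique} vs {b.technique}")
    if a.lag != b.lag:
        raise ValueError(f"lag mismatch: {a.lag} vs {b.lag}")
    return PairFeature(a.technique, a.lag, np.concatenate([a.vector, b.vector]))


def encode_protein(
    seq: ProteinRecord,
    technique: str,
    props: PropertyTable,
    cmap: ClassMap,
    lag: int | None = None,
    weight: float = 0.05,
) -> FeatureBlock:
    """Dispatch to the named technique."""
    if technique == "pseaac":
        return encode_pseaac(seq, lag, props, weight)
    if technique == "ad":
        return encode_ad(seq, lag, props)
    if technique == "ac":
        return encode_ac(seq, lag, props)
    if technique == "ct":
        return encode_ct(seq, cmap)
    if technique == "ld":
        return encode_ld(seq, cmap)
    if technique == "mmi":
        return encode_mmi(seq, cmap)
    raise ValueError(f"unknown technique '{technique}'")


def encode_pair_matrix(
    proteins: dict[str, ProteinRecord],
    pairs: list[tuple[str, str, int]],
    technique: str,
    props: PropertyTable,
    cmap: ClassMap,
    lag: int | None = None,
    weight: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every pair in order; returns (n_pairs x 2*dim matrix, labels).

    Per-protein encodings are cached so each protein is encoded once per
    technique regardless of how many pairs it participates in.
    """
    cache: dict[str, np.ndarray] = {}

    def enc(pid: str) -> np.ndarray:
        if pid not in cache:
            cache[pid] = encode_protein(
                proteins[pid], technique, props, cmap, lag, weight
            ).vector
        return cache[pid]

    rows = [np.concatenate([enc(a), enc(b)]) for a, b, _ in pairs]
    labels = np.array([lab for _, _, lab in pairs], dtype=np.int64)
    return np.stack(rows), labels
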