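"""Amino-acid property tables and the seven-class alphabet.

Two small data objects underpin every sequence encoder in this package:

* :class:`PropertyTable` — a 20 x 13 matrix of physicochemical components,
  one row per canonical residue.  The packaged default
  (``data/svhehs_synthetic.tsv``) is a synthetic stand-in with the same
  shape and scale heterogeneity as a PCA-derived amino-acid descriptor;
  any user-supplied 20 x 13 table in the same format is accepted.
* :class:`ClassMap` — the partition of the 20 residues into seven classes
  by dipole and side-chain volume (Shen et al. grouping), used by the
  conjoint-triad, local-descriptor and mutual-information encoders.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

CANONICAL_RESIDUES: tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))
N_PROPERTIES = 13
N_CLASSES = 7

#: Residues outside the canonical 20-letter alphabet that appear in real data.
NONCANONICAL = frozenset("BJOUXZ")


class FormatError(ValueError):
    """A delimited input file violates the documented layout."""


class ResidueError(ValueError):
    """A sequence contains a residue the current policy rejects."""


@dataclass
class PropertyTable:
    """20 residues x 13 physicochemical components.

    ``values[i, k]`` is component ``k`` of residue ``residues[i]``; rows are
    ordered alphabetically by one-letter code.  After :func:`standardize_table`
    each column has zero mean and unit standard deviation over the 20 residues.
    """

    residues: tuple[str, ...]
    values: np.ndarray
    standardized: bool = False
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (20, N_PROPERTIES):
            raise FormatError(
                f"property table must be 20x{N_PROPERTIES}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("property table contains non-finite values")
        self._index = {r: i for i, r in enumerate(self.residues)}

    def row(self, residue: str) -> np.ndarray:
        return self.values[self._index[residue]]

    def profile(self, sequence: str) -> np.ndarray:
        """Return the L x 13 property profile of a sequence."""
        idx = [self._index[r] for r in sequence]
        return self.values[idx]


@dataclass(frozen=True)
class ClassMap:
    """Partition of the 20 canonical residues into classes 1..7."""

    mapping: dict[str, int]

    def __post_init__(self) -> None:
        if sorted(self.mapping) != list(CANONICAL_RESIDUES):
            missing = set(CANONICAL_RESIDUES) - set(self.mapping)
            extra = set(self.mapping) - set(CANONICAL_RESIDUES)
            raise FormatError(
                f"class map must cover the 20 canonical residues exactly "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        bad = {r: c for r, c in self.mapping.items() if c not in range(1, N_CLASSES + 1)}
        if bad:
            raise FormatError(f"class ids must lie in 1..{N_CLASSES}: {bad}")

    def classes_of(self, sequence: str) -> np.ndarray:
        """Vector of class ids (1..7) for a canonical sequence."""
        return np.array([self.mapping[r] for r in sequence], dtype=np.int64)


def load_property_table(path) -> PropertyTable:
    """Read a tab-delimited ``residue<TAB>c1..c13`` file (unstandardized).

    Rows are canonicalized to alphabetical residue order regardless of file
    order.  Lines starting with ``#`` are ignored.
    """
    rows: dict[str, np.ndarray] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty property table")
    header = lines[0].split("\t")
    if len(header) != N_PROPERTIES + 1:
        raise FormatError(
            f"{path}: header must have 1 + {N_PROPERTIES} columns, got {len(header)}"
        )
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != N_PROPERTIES + 1:
            raise FormatError(f"{path}: row '{parts[0]}' has {len(parts) - 1} value columns")
        res = parts[0].strip().upper()
        if res in rows:
            raise FormatError(f"{path}: duplicate residue row '{res}'")
        try:
            rows[res] = np.array([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric cell in row '{res}': {exc}") from exc
    missing = [r for r in CANONICAL_RESIDUES if r not in rows]
    if missing:
        raise FormatError(f"{path}: missing residue rows {missing}")
    extra = [r for r in rows if r not in CANONICAL_RESIDUES]
    if extra:
        raise FormatError(f"{path}: unknown residue rows {extra}")
    values = np.stack([rows[r] for r in CANONICAL_RESIDUES])
    return PropertyTable(CANONICAL_RESIDUES, values, standardized=False)


def standardize_table(table: PropertyTable) -> PropertyTable:
    """Z-score each property column over the 20 residues (ddof=1).

    Standardization makes the encoders invariant to the units in which raw
    properties are reported.  Re-standardizing an already standardized table
    is rejected rather than silently performed.
    """
    if table.standardized:
        raise ValueError("table is already standardized")
    sd = table.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"property column(s) {zero.tolist()} have zero variance")
    z = (table.values - table.values.mean(axis=0)) / sd
    return PropertyTable(table.residues, z, standardized=True)


def class_of(residue: str, cmap: ClassMap, *, position: int | None = None) -> int:
    """Class id (1..7) of a residue; raises :class:`ResidueError` otherwise."""
    try:
        return cmap.mapping[residue]
    except KeyError:
        where = f" at position {position}" if position is not None else ""
        raise ResidueError(f"unknown residue '{residue}'{where}") from None


def load_class_map(path) -> ClassMap:
    """Read a tab-delimited ``residue<TAB>class`` file."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    body = lines[1:] if lines and lines[0].lower().startswith("residue") else lines
    for ln in body:
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}: malformed class-map line '{ln}'")
        res = parts[0].strip().upper()
        if res in mapping:
            raise FormatError(f"{path}: duplicate residue '{res}'")
        try:
            mapping[res] = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}: bad class id in line '{ln}'") from exc
    return ClassMap(mapping)


def _data_path(name: str):
    return importlib.resources.files("ppigru.data").joinpath(name)


def default_property_table(standardized: bool = True) -> PropertyTable:
    """The packaged 20x13 property table (synthetic stand-in values)."""
    with importlib.resources.as_file(_data_path("svhehs_synthetic.tsv")) as p:
        table = load_property_table(p)
    return standardize_table(table) if standardized else table


def default_class_map() -> ClassMap:
    """The packaged dipole/side-chain-volume seven-class partition."""
    with importlib.resources.as_file(_data_path("class_map.tsv")) as p:
        return load_class_map(p)
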