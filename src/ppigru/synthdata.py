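"""Synthetic protein-pair generator with tunable compositional signal.

Sequences are drawn residue-by-residue from one of two class-frequency
profiles over the seven dipole/side-chain-volume classes: a background
profile and an "interactor" profile shifted from it by a chosen total
variation distance (``effect``).  A positive pair takes both proteins from
the interactor profile; a negative pair mismatches one interactor-profile
protein with one background protein.  The interaction label is therefore
recoverable from sequence composition alone, every encoder carries some
signal, and the class-alphabet encoders (CT, LD, MMI) carry the most.
With ``effect=0`` the profiles coincide and labels are independent of the
sequences — the null regime for calibration checks.

Residue identity within a class is uniform.  Everything is driven by one
seed, so a configuration regenerates byte-identical FASTA and pair lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aaprops import CANONICAL_RESIDUES, N_CLASSES, ClassMap, default_class_map
from .encoders import ProteinRecord

#: Background class profile: the natural frequency of each class when all
#: 20 residues are equiprobable (class sizes 3,4,4,4,2,2,1 over 20).
BACKGROUND_PROFILE = np.array([3, 4, 4, 4, 2, 2, 1], dtype=float) / 20.0

#: Classes losing probability mass under the effect shift (large classes)...
_DONORS = np.array([0, 1])
#: ...and classes gaining it (small classes, including the Cys singleton).
_RECEIVERS = np.array([4, 5, 6])


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_pairs: int = 1000
    length_range: tuple[int, int] = (50, 300)
    effect: float = 0.3
    positive_fraction: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 12:
            raise ValueError("minimum length must be >= 12 (supports lag <= 11)")
        if hi < lo:
            raise ValueError("length range is inverted")
        if self.n_pairs < 10:
            raise ValueError("need at least 10 pairs")
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive fraction must lie in (0, 1)")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        max_effect = BACKGROUND_PROFILE[_DONORS].sum()
        if self.effect > max_effect:
            raise ValueError(f"effect must be <= {max_effect}")


def shifted_profile(effect: float) -> np.ndarray:
    """The interactor profile: TV distance ``effect`` from the background."""
    p = BACKGROUND_PROFILE.copy()
    don_w = p[_DONORS] / p[_DONORS].sum()
    rec_w = p[_RECEIVERS] / p[_RECEIVERS].sum()
    p[_DONORS] -= effect * don_w
    p[_RECEIVERS] += effect * rec_w
    return p


def _class_members(cmap: ClassMap) -> list[list[str]]:
    members: list[list[str]] = [[] for _ in range(N_CLASSES)]
    for r in CANONICAL_RESIDUES:
        members[cmap.mapping[r] - 1].append(r)
    return members


def _draw_sequence(rng, profile, members, length) -> str:
    classes = rng.choice(N_CLASSES, size=length, p=profile)
    return "".join(
        members[c][rng.integers(len(members[c]))] for c in classes
    )


def generate(
    config: GeneratorConfig, cmap: ClassMap | None = None
) -> tuple[dict[str, ProteinRecord], list[tuple[str, str, int]]]:
    """Generate (proteins, pair list) under the configured conditions.

    The pair list holds ``round(positive_fraction * n_pairs)`` positives;
    each pair uses two freshly drawn proteins (never the same protein with
    itself), and proteins are not shared across pairs.
    """
    cmap = cmap or default_class_map()
    rng = np.random.default_rng(config.seed)
    members = _class_members(cmap)
    p_bg = BACKGROUND_PROFILE
    p_int = shifted_profile(config.effect)
    lo, hi = config.length_range
    n_pos = int(round(config.positive_fraction * config.n_pairs))

    proteins: dict[str, ProteinRecord] = {}
    pairs: list[tuple[str, str, int]] = []
    counter = 0

    def new_protein(profile) -> str:
        nonlocal counter
        counter += 1
        pid = f"SYN{counter:06d}"
        length = int(rng.integers(lo, hi + 1))
        proteins[pid] = ProteinRecord(pid, _draw_sequence(rng, profile, members, length))
        return pid

    for i in range(config.n_pairs):
        label = 1 if i < n_pos else 0
        if label == 1:
            a, b = new_protein(p_int), new_protein(p_int)
        else:
            a, b = new_protein(p_int), new_protein(p_bg)
            if rng.random() < 0.5:
                a, b = b, a
        pairs.append((a, b, label))
    order = rng.permutation(config.n_pairs)
    pairs = [pairs[i] for i in order]
    return proteins, pairs


def worked_fixtures() -> dict:
    """Hand-checkable micro-inputs used across the encoder examples.

    Returns named sequences together with the facts that hold for them by
    construction (dimensions, zero-correlation structure, the width-56
    PseAAC pair).  Larger expected values are computed in the test-suite
    oracles rather than stored here.
    """
    rng = np.random.default_rng(123)
    residues = CANONICAL_RESIDUES
    random60 = "".join(rng.choice(list(residues), size=60))
    random30 = "".join(rng.choice(list(residues), size=30))
    return {
        "homopolymer": ProteinRecord("homo_A10", "A" * 10),
        # G and A share the small/aliphatic class: one triad type only.
        "single_class": ProteinRecord("gaga", "GAGAGA"),
        "random60": ProteinRecord("rand60", random60),
        "random30": ProteinRecord("rand30", random30),
        "pseaac_pair": (
            ProteinRecord("pA", random60),
            ProteinRecord("pB", random30),
        ),
        "expected": {
            "pseaac_lag8_dim": 28,
            "pseaac_pair_dim": 56,
            "homopolymer_ct_nonzeros": 1,
        },
    }
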