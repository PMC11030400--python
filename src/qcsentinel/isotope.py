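"""Peptide elemental composition, theoretical isotope envelopes, and the isotope dot product.

The isotope dot product (idotp) scores how well a precursor's observed M0, M+1,
M+2 ... peak areas match the envelope predicted from natural isotope abundances.
A clean signal scores near 1; selective loss of the heavy (M+1/M+2) peaks — a
hardware failure mode of ion optics — drags the score down even when total
intensity looks normal, which is why the score is tracked as a first-class QC
metric alongside areas, retention time and mass error.

Envelopes are aggregated by nucleon number (no fine structure, no m/z spacing):
each element contributes a distribution of "extra nucleons" per atom, and the
peptide envelope is the convolution of those per-element multinomials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np

from .errors import UndefinedScoreError, ValidationError

__all__ = [
    "FixedMod",
    "HeavyLabel",
    "ElementalComposition",
    "IsotopeEnvelope",
    "peptide_composition",
    "isotope_distribution",
    "idotp",
]


class FixedMod(Enum):
    """Fixed modifications applied during composition bookkeeping."""

    CARBAMIDOMETHYL_C = "carbamidomethyl_c"


class HeavyLabel(Enum):
    """Stable-isotope labeling schemes.

    K8R10 is the scheme used by commercial heavy retention-time peptide mixes:
    C-terminal lysine carries 13C6 + 15N2 (+8.0142 Da), C-terminal arginine
    carries 13C6 + 15N4 (+10.0083 Da).
    """

    NONE = "none"
    K8R10 = "13C6-15N2-K/13C6-15N4-R"


_ELEMENTS = ("C", "H", "N", "O", "S")

# Natural isotope abundances, aggregated by extra-nucleon offset.
# Representative IUPAC values, frozen here for reproducibility.
ISOTOPE_ABUNDANCE: dict[str, tuple[tuple[int, float], ...]] = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
}

MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# Mass added per labeled atom (heavy minus light monoisotopic mass).
_LABEL_MASS_SHIFT = {"C": 1.0033548378, "N": 0.9970348934}

# Residue (peptide-bond) elemental compositions for the 20 canonical residues.
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

_WATER = {"H": 2, "O": 1}
_CARBAMIDOMETHYL = {"C": 2, "H": 3, "N": 1, "O": 1}


@dataclass(frozen=True)
class ElementalComposition:
    """Elemental composition with an annotation of fixed-heavy (labeled) atoms.

    ``counts`` holds total atom counts per element (labeled atoms included);
    ``labeled`` holds, per element, how many of those atoms are isotopically
    pure heavy substitutions. Labeled atoms shift the monoisotopic mass but
    carry no abundance spread, so they are excluded from the natural pool when
    the envelope is convolved.
    """

    counts: tuple[tuple[str, int], ...]
    labeled: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        cd, ld = dict(self.counts), dict(self.labeled)
        if any(v < 0 for v in cd.values()) or not any(v > 0 for v in cd.values()):
            raise ValidationError("composition must have nonnegative counts, at least one > 0")
        for el, n in ld.items():
            if n < 0 or n > cd.get(el, 0):
                raise ValidationError(f"labeled {el} count exceeds total")

    @classmethod
    def from_dict(cls, counts: dict[str, int], labeled: dict[str, int] | None = None):
        mk = lambda d: tuple(sorted((k, v) for k, v in d.items() if v))
        return cls(mk(counts), mk(labeled or {}))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def labeled_dict(self) -> dict[str, int]:
        return dict(self.labeled)

    def natural_pool(self) -> dict[str, int]:
        """Atom counts subject to natural-abundance variation."""
        lab = self.labeled_dict()
        return {el: n - lab.get(el, 0) for el, n in self.counts}

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        c, l = self.as_dict(), self.labeled_dict()
        for el, n in other.counts:
            c[el] = c.get(el, 0) + n
        for el, n in other.labeled:
            l[el] = l.get(el, 0) + n
        return ElementalComposition.from_dict(c, l)

    @property
    def monoisotopic_mass(self) -> float:
        m = sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts)
        m += sum(_LABEL_MASS_SHIFT[el] * n for el, n in self.labeled)
        return m


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Truncated, renormalized aggregated-nucleon envelope.

    ``probs`` sums to exactly 1 after truncation to ``n_peaks``; ``raw_probs``
    holds the untruncated-mass probabilities of the retained peaks (their sum is
    the mass fraction captured). ``renormalized`` records that truncation
    dropped probability mass.
    """

    probs: tuple[float, ...]
    raw_probs: tuple[float, ...]
    renormalized: bool

    @property
    def n_peaks(self) -> int:
        return len(self.probs)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probs, dtype=float)


def peptide_composition(
    sequence: str,
    fixed_mods: frozenset[FixedMod] | set[FixedMod] = frozenset({FixedMod.CARBAMIDOMETHYL_C}),
    heavy_label: HeavyLabel = HeavyLabel.NONE,
) -> ElementalComposition:
    """Elemental composition of a linear peptide: residue sum + one water.

    CARBAMIDOMETHYL_C adds C2H3NO per cysteine. The K8R10 heavy label marks the
    6 carbons and 2 (K) or 4 (R) nitrogens of a C-terminal lysine/arginine as
    isotopically pure heavy atoms, tracked in the ``labeled`` annotation.
    """
    if not sequence:
        raise ValidationError("sequence must be non-empty")
    counts: dict[str, int] = dict(_WATER)
    for ch in sequence:
        try:
            res = RESIDUE_FORMULAS[ch]
        except KeyError:
            raise ValidationError(f"unknown residue character {ch!r}") from None
        for el, n in res.items():
            counts[el] = counts.get(el, 0) + n
    if FixedMod.CARBAMIDOMETHYL_C in fixed_mods:
        n_cys = sequence.count("C")
        for el, n in _CARBAMIDOMETHYL.items():
            counts[el] = counts.get(el, 0) + n * n_cys
    labeled: dict[str, int] = {}
    if heavy_label is HeavyLabel.K8R10 and sequence[-1] in ("K", "R"):
        labeled = {"C": 6, "N": 2 if sequence[-1] == "K" else 4}
    return ElementalComposition.from_dict(counts, labeled)


def _poly_pow(base: np.ndarray, n: int, trunc: int) -> np.ndarray:
    """(Σ a_k x^k)^n truncated to the first `trunc` coefficients.

    Truncation commutes with convolution for the retained low-order terms, so
    the kept coefficients are exact.
    """
    out = np.zeros(trunc)
    out[0] = 1.0
    b = np.zeros(trunc)
    b[: len(base)] = base[:trunc]
    while n:
        if n & 1:
            out = np.convolve(out, b)[:trunc]
        n >>= 1
        if n:
            b = np.convolve(b, b)[:trunc]
    return out


@lru_cache(maxsize=4096)
def _envelope_cached(pool: tuple[tuple[str, int], ...], n_peaks: int) -> tuple[float, ...]:
    env = np.zeros(n_peaks)
    env[0] = 1.0
    for el, n_atoms in pool:
        if n_atoms <= 0:
            continue
        offsets = ISOTOPE_ABUNDANCE[el]
        base = np.zeros(max(o for o, _ in offsets) + 1)
        for off, p in offsets:
            base[off] = p
        env = np.convolve(env, _poly_pow(base, n_atoms, n_peaks))[:n_peaks]
    return tuple(env.tolist())


def isotope_distribution(comp: ElementalComposition, n_peaks: int = 3) -> IsotopeEnvelope:
    """Aggregated-nucleon isotope envelope by iterated elementwise convolution.

    Labeled (isotopically pure) atoms are excluded from the natural pool: they
    shift every peak by a constant nucleon count, which leaves the relative
    M0..M+k pattern unchanged.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    pool = tuple(sorted((el, n) for el, n in comp.natural_pool().items() if n > 0))
    raw = np.array(_envelope_cached(pool, n_peaks))
    total = raw.sum()
    if total > 1 + 1e-12:
        raise AssertionError("envelope mass exceeds 1")
    renorm = total < 1 - 1e-12
    probs = raw / total
    return IsotopeEnvelope(tuple(probs.tolist()), tuple(raw.tolist()), renorm)


def idotp(expected, observed, transform: str = "none") -> float:
    """Normalized dot product (cosine similarity) of expected vs observed peaks.

    Equals 1 iff the vectors are proportional; invariant to positive scaling of
    either argument; symmetric. ``transform="sqrt"`` scores square-rooted
    abundances instead (some integration software weights peaks this way).
    An all-zero observed vector is an undefined score, not a low one.
    """
    e = expected.as_array() if isinstance(expected, IsotopeEnvelope) else np.asarray(expected, dtype=float)
    o = np.asarray(observed, dtype=float)
    if e.shape != o.shape or e.ndim != 1 or e.size < 2:
        raise ValueError("expected and observed must be equal-length vectors of length >= 2")
    if np.any(e < 0) or np.any(o < 0):
        raise ValueError("peak abundances must be nonnegative")
    if not np.any(o > 0):
        raise UndefinedScoreError("observed envelope is all zero; idotp undefined")
    if not np.any(e > 0):
        raise UndefinedScoreError("expected envelope is all zero; idotp undefined")
    if transform == "sqrt":
        e, o = np.sqrt(e), np.sqrt(o)
    elif transform != "none":
        raise ValueError("transform must be 'none' or 'sqrt'")
    score = float(np.dot(e, o) / (np.linalg.norm(e) * np.linalg.norm(o)))
    return min(max(score, 0.0), 1.0)
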