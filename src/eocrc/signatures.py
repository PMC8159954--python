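"""96-channel mutational profiles and signature refitting.

Single-base substitutions are classified into the standard 96 channels:
six pyrimidine-centric substitution types (C>A, C>G, C>T, T>A, T>C, T>G)
by 16 flanking trinucleotide contexts, contexts alphabetical within each
type. Substitutions reported on the purine strand are reverse-complemented
into the pyrimidine-centric channel.

Refitting decomposes a tumour's profile onto a fixed catalog (COSMIC v2
style: one column per signature, each a probability vector over the 96
channels) by nonnegative least squares, with the exposures renormalized
to sum to one. De-novo signature extraction (NMF discovery) is out of
scope; the catalog is an input, and catalogs whose channel labels do not
match the standard order are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import optimize

from eocrc.errors import DataError

__all__ = [
    "CHANNELS",
    "SUBSTITUTION_TYPES",
    "MutationalProfile",
    "SignatureCatalog",
    "SignatureExposure",
    "build_96_profile",
    "fit_signatures",
    "rank_exposures",
]

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the standard channel order, e.g. "A[C>A]A", "A[C>A]C", ... "T[T>G]T"
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


@dataclass(frozen=True)
class MutationalProfile:
    """Counts over the 96 substitution channels, in standard order."""

    counts: tuple[float, ...]

    def __post_init__(self):
        if len(self.counts) != 96:
            raise ValueError(f"a profile has exactly 96 channels, got {len(self.counts)}")
        if any(c < 0 for c in self.counts):
            raise ValueError("channel counts must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.counts))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    def normalized(self) -> np.ndarray:
        total = self.total
        if total <= 0:
            raise DataError("cannot normalize an all-zero profile")
        return self.as_array() / total


@dataclass(frozen=True)
class SignatureCatalog:
    """A named collection of signature probability vectors (96 x k)."""

    names: tuple[str, ...]
    matrix: tuple[tuple[float, ...], ...]  # one inner tuple per signature (column)

    def __post_init__(self):
        if len(self.names) != len(self.matrix):
            raise ValueError("one name per signature column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("signature names must be unique")
        for name, col in zip(self.names, self.matrix):
            if len(col) != 96:
                raise ValueError(f"signature {name} does not have 96 channels")
            if any(v < 0 for v in col):
                raise ValueError(f"signature {name} has negative entries")
            if abs(sum(col) - 1.0) > 1e-8:
                raise ValueError(f"signature {name} does not sum to 1 (got {sum(col)!r})")

    def __len__(self) -> int:
        return len(self.names)

    def as_array(self) -> np.ndarray:
        """96 x k matrix with one column per signature."""
        return np.asarray(self.matrix, dtype=float).T

    def to_tsv(self, path) -> None:
        """Write the catalog as a TSV: a channel-label column followed by
        one column per signature, rows in standard channel order."""
        arr = self.as_array()
        with open(Path(path), "w") as fh:
            fh.write("\t".join(["channel", *self.names]) + "\n")
            for i, channel in enumerate(CHANNELS):
                fh.write("\t".join([channel, *(repr(float(v)) for v in arr[i])]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        """Read a catalog TSV, rejecting any file whose channel labels do
        not exactly match the standard 96-channel order."""
        with open(Path(path)) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            names = tuple(header[1:])
            labels: list[str] = []
            rows: list[list[float]] = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                labels.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        if tuple(labels) != CHANNELS:
            raise DataError(
                "catalog channel labels do not match the standard 96-channel order"
            )
        arr = np.asarray(rows, dtype=float)
        return cls(names=names, matrix=tuple(tuple(col) for col in arr.T))


@dataclass(frozen=True)
class SignatureExposure:
    """Nonnegative signature weights (summing to 1) for one profile."""

    names: tuple[str, ...]
    weights: tuple[float, ...]
    reconstruction_cosine: float

    def __post_init__(self):
        if len(self.names) != len(self.weights):
            raise ValueError("one weight per signature required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        if not -1e-12 <= self.reconstruction_cosine <= 1.0 + 1e-12:
            raise ValueError("cosine similarity must lie in [0, 1]")

    @property
    def most_prevalent(self) -> str:
        best = max(self.weights)
        return min(n for n, w in zip(self.names, self.weights) if w == best)

    def weight_of(self, name: str) -> float:
        return self.weights[self.names.index(name)]


def build_96_profile(
    substitutions: Iterable[tuple[str, str, str, str]]
) -> MutationalProfile:
    """Tally substitutions into the 96-channel profile.

    Each substitution is (ref_base, alt_base, 5' flanking base,
    3' flanking base). Purine-reference substitutions are mapped to the
    pyrimidine strand by reverse complement (which also swaps and
    complements the flanks); applying the mapping to an
    already-pyrimidine substitution is the identity. Anything but a
    single-base substitution is an error.
    """
    counts = [0.0] * 96
    for ref, alt, five, three in substitutions:
        for name, base in (("ref", ref), ("alt", alt), ("5'", five), ("3'", three)):
            if base not in _BASES:
                raise DataError(f"non-SNV or invalid {name} base {base!r}")
        if ref == alt:
            raise DataError(f"ref and alt are both {ref!r}")
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
            five, three = _COMPLEMENT[three], _COMPLEMENT[five]
        counts[_CHANNEL_INDEX[f"{five}[{ref}>{alt}]{three}"]] += 1
    return MutationalProfile(counts=tuple(counts))


def fit_signatures(profile: MutationalProfile, catalog: SignatureCatalog) -> SignatureExposure:
    """Refit a profile against a fixed catalog.

    Solves min ||M w - p||_2 subject to w >= 0, where p is the profile
    normalized to sum 1 and M the catalog matrix, then renormalizes w to
    sum 1. Deterministic for a fixed input.
    """
    if profile.total <= 0:
        raise DataError("cannot fit signatures to an all-zero profile")
    p = profile.normalized()
    m = catalog.as_array()
    w, _ = optimize.nnls(m, p)
    total = w.sum()
    if total <= 0:
        raise DataError("nonnegative refit degenerated to the zero solution")
    recon = m @ w
    cosine = float(
        np.clip(recon @ p / (np.linalg.norm(recon) * np.linalg.norm(p)), 0.0, 1.0)
    )
    weights = w / total
    return SignatureExposure(
        names=catalog.names, weights=tuple(float(x) for x in weights),
        reconstruction_cosine=cosine,
    )


def rank_exposures(
    exposure: SignatureExposure, marginal_floor: float = 0.01
) -> list[tuple[str, float, bool]]:
    """Order exposures by weight descending (ties alphabetically).

    Returns (signature, weight, marginal) triples, where ``marginal``
    flags weights below ``marginal_floor`` as contributing only
    marginally.
    """
    ranked = sorted(
        zip(exposure.names, exposure.weights), key=lambda t: (-t[1], t[0])
    )
    return [(name, w, w < marginal_floor) for name, w in ranked]
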