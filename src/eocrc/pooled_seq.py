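"""Rare-variant detection in pooled-amplicon sequencing.

Candidate genes are re-sequenced in pools of 48-96 patient DNAs at very
high coverage (thousands of reads per base, only bases with quality >= 30
counted). A heterozygous carrier contributes one mutated allele among
``2 * n_samples`` pooled alleles, so the alternate-allele read fraction
``f`` estimates the number of mutated alleles in the pool as

    ENMA = f * 2 * n_samples

("estimated number of mutated alleles"). Detection must separate a single
allele in up to 192 from the sequencing-error floor, so a pool call is
reported only when ENMA clears a minimum, alternate reads appear on both
strands, a one-sided binomial test rejects the background error rate,
and the position is not a common polymorphism (population MAF below 1%).
All gates are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from eocrc.errors import DataError
from eocrc.prioritization import (
    ImpactThresholds,
    RarityThresholds,
    functional_class_filter,
    impact_filter,
    rarity_filter,
)
from eocrc.variant_io import AnnotatedVariant, Annotation, VariantCall, VariantKey, chrom_sort_key

__all__ = [
    "PoolPileup",
    "PoolCall",
    "DetectionGates",
    "compute_enma",
    "detect_pool_variants",
    "prioritize_pool_variants",
    "read_pileup_table",
    "write_pileup_table",
]


@dataclass(frozen=True)
class PoolPileup:
    """Base-level counts at one candidate position in one DNA pool.

    ``depth_hq``/``alt_hq`` count only reads passing the base-quality
    cutoff (default Q30). ``annotation`` carries the position's
    functional/frequency annotation when available; population MAF is
    read from it during detection.
    """

    pool_id: str
    n_samples: int
    key: VariantKey
    depth_hq: int
    alt_hq: int
    alt_fwd: int
    alt_rev: int
    base_qual_min: int = 30
    annotation: Annotation | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0 <= self.alt_hq <= self.depth_hq:
            raise ValueError("require 0 <= alt_hq <= depth_hq")
        if self.alt_fwd + self.alt_rev != self.alt_hq:
            raise ValueError("alt_fwd + alt_rev must equal alt_hq")


@dataclass(frozen=True)
class PoolCall:
    """A pool pileup with its ENMA estimate and detection verdict."""

    pileup: PoolPileup
    alt_fraction: float
    enma: float
    detected: bool = False
    error_p: float | None = None

    @property
    def key(self) -> VariantKey:
        return self.pileup.key


@dataclass(frozen=True)
class DetectionGates:
    """Thresholds a pool call must clear to be reported."""

    error_rate: float = 0.001
    enma_min: float = 0.65
    maf_max: float = 0.01
    alpha: float = 1e-6
    require_both_strands: bool = True

    def __post_init__(self):
        if not 0.0 < self.error_rate <= 0.01:
            raise ValueError("error_rate must lie in (0, 0.01]")
        if self.enma_min <= 0:
            raise ValueError("enma_min must be > 0")


def compute_enma(pileup: PoolPileup) -> PoolCall:
    """Estimate the number of mutated alleles in the pool.

    ``ENMA = alt_fraction * 2 * n_samples``; deterministic, and linear in
    both the alternate-read fraction and the pool size.
    """
    if pileup.depth_hq <= 0:
        raise DataError(
            f"pool {pileup.pool_id} has no high-quality coverage at {pileup.key}; "
            "ENMA is undefined"
        )
    frac = pileup.alt_hq / pileup.depth_hq
    return PoolCall(pileup=pileup, alt_fraction=frac, enma=frac * 2 * pileup.n_samples)


def detect_pool_variants(
    pileups: Iterable[PoolPileup],
    error_rate: float = 0.001,
    enma_min: float = 0.65,
    maf_max: float = 0.01,
    alpha: float = 1e-6,
    require_both_strands: bool = True,
) -> list[PoolCall]:
    """Call variants across pool pileups; returns only detected calls.

    A call is detected when ENMA >= ``enma_min``, alternate reads are
    seen on both strands, the one-sided binomial test of ``alt_hq`` out
    of ``depth_hq`` against ``error_rate`` gives p < ``alpha``, and the
    annotated population MAF (if any) is below ``maf_max``.
    """
    gates = DetectionGates(
        error_rate=error_rate,
        enma_min=enma_min,
        maf_max=maf_max,
        alpha=alpha,
        require_both_strands=require_both_strands,
    )
    detected: list[PoolCall] = []
    for pileup in pileups:
        call = compute_enma(pileup)
        # survival function at alt_hq - 1 = P(X >= alt_hq) under the error model
        p_err = float(stats.binom.sf(pileup.alt_hq - 1, pileup.depth_hq, gates.error_rate))
        call = replace(call, error_p=p_err)
        maf = pileup.annotation.maf_ref if pileup.annotation is not None else None
        ok = (
            call.enma >= gates.enma_min
            and (not gates.require_both_strands or (pileup.alt_fwd > 0 and pileup.alt_rev > 0))
            and p_err < gates.alpha
            and (maf is None or maf < gates.maf_max)
        )
        if ok:
            detected.append(replace(call, detected=True))
    return detected


def prioritize_pool_variants(
    detected: Sequence[PoolCall],
    rarity: RarityThresholds = RarityThresholds(),
    impact: ImpactThresholds = ImpactThresholds(),
) -> list[PoolCall]:
    """Apply the discovery-phase prioritization rules to detected pool
    calls (functional class, rarity, impact; no caller-concordance stage
    — pools are sequenced once).

    Pool genotypes are heterozygous by construction (carrier identity
    within a pool is not recoverable), so the heterozygous rarity bound
    applies.
    """
    qualifying: list[PoolCall] = []
    for call in detected:
        if call.pileup.annotation is None:
            raise DataError(f"pool call at {call.key} carries no annotation")
        record = AnnotatedVariant(
            call=VariantCall(
                key=call.key,
                sample_id=call.pileup.pool_id,
                genotype="het",
                caller="pooled",
            ),
            annotation=call.pileup.annotation,
        )
        _, functional = functional_class_filter([record])
        if not functional:
            continue
        if not rarity_filter(record, rarity):
            continue
        if not impact_filter(record, impact):
            continue
        qualifying.append(call)
    return qualifying


# ---------------------------------------------------------------------------
# tab-separated pileup tables

_PILEUP_COLUMNS = (
    "pool_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_fwd",
    "alt_rev",
    "n_samples",
)


def read_pileup_table(path) -> list[PoolPileup]:
    """Read pool pileups from a tab-separated count table with columns
    pool_id, chrom, pos, ref, alt, depth, alt_fwd, alt_rev, n_samples."""
    import csv

    pileups: list[PoolPileup] = []
    with open(Path(path), newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            fwd, rev = int(row["alt_fwd"]), int(row["alt_rev"])
            pileups.append(
                PoolPileup(
                    pool_id=row["pool_id"],
                    n_samples=int(row["n_samples"]),
                    key=VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                    depth_hq=int(row["depth"]),
                    alt_hq=fwd + rev,
                    alt_fwd=fwd,
                    alt_rev=rev,
                )
            )
    return pileups


def write_pileup_table(pileups: Iterable[PoolPileup], path) -> None:
    import csv

    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PILEUP_COLUMNS)
        for p in sorted(
            pileups, key=lambda p: (p.pool_id, chrom_sort_key(p.key.chrom), p.key.pos, p.key.alt)
        ):
            writer.writerow(
                [
                    p.pool_id,
                    p.key.chrom,
                    p.key.pos,
                    p.key.ref,
                    p.key.alt,
                    p.depth_hq,
                    p.alt_fwd,
                    p.alt_rev,
                    p.n_samples,
                ]
            )
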