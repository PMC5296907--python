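"""Gene-group assembly: activity classification from ChIP evidence and
length-based subsets.

Pol III promoter metaplots are aggregated over gene groups — active tRNAs,
active non-tRNAs, inactive tRNAs, and short (<100 bp) pol II genes with a
size-matched random control.  Activity is decided from ChIP evidence at the
promoter: either a called peak overlapping the promoter window or a mean
coverage z-score above threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval (0-based half-open) with class and activity call."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str = "tRNA"  # tRNA | non_tRNA | polII
    activity: str = "unknown"  # active | inactive | unknown

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be + or -")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class ChipTrack:
    """Binned ChIP coverage with log-stabilised z-scores.

    z = (log2(x + 1) − mean) / sd over all bins of all chromosomes; the
    transform tames the heavy right tail of coverage before standardising.
    """

    bin_size: int
    coverage: dict[str, np.ndarray]
    z: dict[str, np.ndarray]
    mean: float
    sd: float

    def z_in_window(self, chrom: str, start: int, end: int) -> float | None:
        """Mean z over bins overlapping [start, end); None if off-track."""
        if chrom not in self.z:
            return None
        zs = self.z[chrom]
        lo = max(start // self.bin_size, 0)
        hi = min(int(np.ceil(end / self.bin_size)), zs.size)
        if hi <= lo:
            return None
        return float(np.mean(zs[lo:hi]))


def zscore_track(
    coverage: Mapping[str, np.ndarray] | np.ndarray,
    bin_size: int = 50,
    log_transform: bool = True,
) -> ChipTrack:
    """Standardise binned ChIP coverage into z-scores.

    Accepts a single array (treated as chromosome ``"chr"``) or a mapping
    of per-chromosome bin arrays.  Raises on fewer than two finite bins or
    zero variance.
    """
    if isinstance(coverage, np.ndarray):
        coverage = {"chr": coverage}
    cov = {c: np.asarray(v, dtype=float) for c, v in coverage.items()}
    pooled = np.concatenate([v for v in cov.values()]) if cov else np.empty(0)
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size < 2:
        raise ValueError("need at least two finite coverage bins")
    x = np.log2(pooled + 1.0) if log_transform else pooled
    mean, sd = float(np.mean(x)), float(np.std(x))
    if sd == 0:
        raise ValueError("coverage has zero variance; z-scores undefined")
    z = {
        c: ((np.log2(v + 1.0) if log_transform else v) - mean) / sd
        for c, v in cov.items()
    }
    return ChipTrack(bin_size, cov, z, mean, sd)


def classify_activity(
    genes: Sequence[GeneRecord],
    chip: ChipTrack | None = None,
    peaks: Sequence[tuple[str, int, int]] | None = None,
    promoter_window: int = 100,
    z_min: float = 1.64,
) -> list[GeneRecord]:
    """Set each gene's activity from ChIP evidence at its promoter.

    A gene is active iff a peak overlaps [TSS − window, TSS + window] or
    the mean ChIP z-score in that window reaches ``z_min`` (one-sided 5%
    by default); otherwise inactive.  Genes outside the track (and not hit
    by any peak) stay ``unknown`` and are logged.
    """
    if chip is None and peaks is None:
        raise ValueError("need ChIP track or peak set")
    out: list[GeneRecord] = []
    n_unknown = 0
    for g in genes:
        lo, hi = g.tss - promoter_window, g.tss + promoter_window + 1
        peak_hit = any(
            c == g.chrom and s < hi and e > lo for c, s, e in (peaks or ())
        )
        zw = chip.z_in_window(g.chrom, max(lo, 0), hi) if chip else None
        if peak_hit or (zw is not None and zw >= z_min):
            activity = "active"
        elif chip is not None and zw is None:
            activity = "unknown"  # outside the track, no peak either
            n_unknown += 1
        else:
            activity = "inactive"
        out.append(replace(g, activity=activity))
    if n_unknown:
        logger.info("classify_activity: %d genes outside ChIP track left "
                    "unknown", n_unknown)
    return out


def select_short_genes(
    genes: Sequence[GeneRecord],
    max_len: int = 100,
    seed: int = 0,
) -> tuple[list[GeneRecord], list[GeneRecord]]:
    """Split off genes shorter than ``max_len`` bp plus a matched control.

    Returns ``(short, control)`` where the control is a seeded uniform
    sample, of equal size, from the remaining genes.  Strict inequality:
    a 100 bp gene is not "<100 bp".
    """
    short = [g for g in genes if g.length_bp < max_len]
    rest = [g for g in genes if g.length_bp >= max_len]
    if len(rest) < len(short):
        raise ValueError(
            f"cannot draw a size-matched control: only {len(rest)} regular "
            f"genes for {len(short)} short ones"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rest), size=len(short), replace=False)
    control = [rest[i] for i in sorted(idx)]
    return short, control
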