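"""Anchored percent-accessibility metaplots and profile feature extraction.

Site observations from many molecules and loci are mapped to signed offsets
from an anchor (TSS or TTS; offsets are negated for − strand loci so that
"downstream" is always positive), pooled at the read level — percent
accessibility at an offset bin is 100 × accessible / (accessible +
protected) over *all* site observations in the bin, not an average of
per-locus means — and summarised into a nucleosome-depleted region (NDR),
accessibility troughs (nucleosome centres), and flanking phasing.  A
native-vs-salt-washed comparison flags intervals that gain accessibility
after the wash: candidate non-histone protein footprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .states import MoleculeStates, STATE_ACCESSIBLE, STATE_MISSING, STATE_PROTECTED


@dataclass
class Metaplot:
    """Anchored percent-accessibility profile with per-offset coverage.

    ``offsets`` holds the left edge of each bin; ``percent`` is NaN where
    coverage (accessible + protected observations) falls below
    ``min_coverage``.  ``smoothing_window`` is 0 for a raw profile and the
    effective kernel width in bp after :func:`smooth_profile`.
    """

    anchor: str
    bin_width: int
    offsets: np.ndarray
    accessible: np.ndarray
    protected: np.ndarray
    missing: np.ndarray
    min_coverage: int
    percent: np.ndarray = field(default=None)  # type: ignore[assignment]
    smoothing_window: int = 0

    def __post_init__(self) -> None:
        if self.percent is None:
            cov = self.coverage
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = 100.0 * self.accessible / cov
            pct[cov < self.min_coverage] = np.nan
            self.percent = pct

    @property
    def coverage(self) -> np.ndarray:
        return self.accessible + self.protected

    def bin_index(self, offset: int) -> int:
        i = int((offset - self.offsets[0]) // self.bin_width)
        if not 0 <= i < self.offsets.size:
            raise ValueError(f"offset {offset} outside profile range")
        return i


def build_metaplot(
    states_by_locus: Mapping[str, Sequence[MoleculeStates]],
    loci: Mapping[str, object],
    anchor: str = "TSS",
    flank: int = 1000,
    bin_width: int = 10,
    min_coverage: int = 10,
) -> Metaplot:
    """Pool per-molecule site states into an anchored profile.

    ``loci`` maps locus ids to objects exposing ``strand``, ``tss_offset``
    and ``tts_offset`` (e.g. :class:`~nomefoot.simulate.ReferenceLocus`).
    Offsets run over ``[-flank, flank)``; observations outside are dropped.
    """
    if anchor.upper() not in ("TSS", "TTS"):
        raise ValueError(f"anchor must be TSS or TTS, got {anchor!r}")
    nbins = int(np.ceil(2 * flank / bin_width))
    acc = np.zeros(nbins, dtype=np.int64)
    prot = np.zeros(nbins, dtype=np.int64)
    miss = np.zeros(nbins, dtype=np.int64)

    for locus_id, molecules in states_by_locus.items():
        if locus_id not in loci:
            raise ValueError(f"no annotation for locus {locus_id!r}")
        ref = loci[locus_id]
        strand = getattr(ref, "strand", None)
        if strand not in ("+", "-"):
            raise ValueError(f"locus {locus_id!r} lacks a usable strand")
        a = ref.tss_offset if anchor.upper() == "TSS" else ref.tts_offset
        length = len(getattr(ref, "sequence", "")) or getattr(ref, "length", 0)
        if length and not 0 <= a < length:
            raise ValueError(f"anchor outside locus {locus_id!r}")
        sign = 1 if strand == "+" else -1
        for m in molecules:
            off = (m.acc_positions - a) * sign
            bins = (off + flank) // bin_width
            ok = (bins >= 0) & (bins < nbins)
            b = bins[ok].astype(np.int64)
            s = m.acc_states[ok]
            acc += np.bincount(b[s == STATE_ACCESSIBLE], minlength=nbins)
            prot += np.bincount(b[s == STATE_PROTECTED], minlength=nbins)
            miss += np.bincount(b[s == STATE_MISSING], minlength=nbins)

    offsets = np.arange(-flank, -flank + nbins * bin_width, bin_width)
    return Metaplot(anchor.upper(), bin_width, offsets, acc, prot, miss,
                    min_coverage)


def smooth_profile(mp: Metaplot, window: int = 20) -> Metaplot:
    """Coverage-weighted centred running mean.

    The kernel spans an odd number of bins covering approximately
    ``window`` bp (the effective width, ``m * bin_width``, is recorded in
    ``smoothing_window``).  Edges use the available support; bins without
    coverage stay NaN.
    """
    if window < mp.bin_width:
        raise ValueError(
            f"smoothing window {window} bp is narrower than bin width "
            f"{mp.bin_width} bp"
        )
    m = int(round(window / mp.bin_width))
    if m % 2 == 0:
        m += 1
    kernel = np.ones(m)
    w = mp.coverage.astype(float)
    p = np.where(np.isnan(mp.percent), 0.0, mp.percent)
    w_valid = np.where(np.isnan(mp.percent), 0.0, w)
    num = np.convolve(p * w_valid, kernel, mode="same")
    den = np.convolve(w_valid, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[den == 0] = np.nan
    return replace(mp, percent=sm, smoothing_window=m * mp.bin_width)


def detect_ndr(
    mp: Metaplot,
    theta: float = 0.6,
    search: int = 1000,
) -> tuple[int, int] | None:
    """Locate the nucleosome-depleted region around the anchor.

    The NDR is the maximal contiguous offset interval containing the anchor
    where percent accessibility stays at or above ``theta`` times the
    profile maximum within ±``search`` bp.  Returns ``(start, end)`` bp
    offsets (half-open), or ``None`` when the anchor itself is below
    threshold (no NDR).
    """
    y = mp.percent
    near = np.abs(mp.offsets + mp.bin_width / 2) <= search
    if not np.any(near & np.isfinite(y)):
        return None
    thresh = theta * np.nanmax(y[near])
    i0 = mp.bin_index(0)
    if not np.isfinite(y[i0]) or y[i0] < thresh:
        return None
    lo = i0
    while lo > 0 and np.isfinite(y[lo - 1]) and y[lo - 1] >= thresh:
        lo -= 1
    hi = i0
    while hi + 1 < y.size and np.isfinite(y[hi + 1]) and y[hi + 1] >= thresh:
        hi += 1
    return int(mp.offsets[lo]), int(mp.offsets[hi] + mp.bin_width)


@dataclass(frozen=True)
class ProfileFeatures:
    """NDR bounds, accessibility troughs/peaks and nucleosome phasing."""

    ndr: tuple[int, int] | None
    troughs: tuple[tuple[int, float], ...]  # (centre offset, prominence)
    peaks: tuple[int, ...]
    phasing_period: float | None
    minus_one: int | None  # trough centre upstream of the NDR (−1 nucleosome)
    plus_one: int | None


def locate_nucleosome_centers(
    mp: Metaplot,
    prominence: float = 5.0,
    theta: float = 0.6,
    search: int = 1000,
) -> ProfileFeatures:
    """Find accessibility troughs (nucleosome centres) on a smoothed profile.

    Troughs are local minima with prominence at or above ``prominence``
    percentage points; ties on flat minima break leftmost.  The −1/+1
    nucleosomes are the troughs nearest the NDR on each side, and the
    phasing period is the median spacing of successive troughs per side
    when at least two exist there.
    """
    y = mp.percent.copy()
    finite = np.isfinite(y)
    if finite.sum() < 3:
        return ProfileFeatures(None, (), (), None, None, None)
    # interpolate across low-coverage gaps for detection only
    idx = np.arange(y.size)
    y[~finite] = np.interp(idx[~finite], idx[finite], y[finite])

    half = mp.bin_width // 2
    t_idx, t_props = find_peaks(-y, prominence=prominence,
                                plateau_size=(0, None))
    t_pos = np.where(t_props["plateau_sizes"] > 1,
                     t_props["left_edges"], t_idx)  # leftmost on plateaus
    troughs = tuple(
        (int(mp.offsets[i] + half), float(p))
        for i, p in zip(t_pos, t_props["prominences"])
    )
    p_idx, _ = find_peaks(y, prominence=prominence)
    peaks = tuple(int(mp.offsets[i] + half) for i in p_idx)

    ndr = detect_ndr(mp, theta=theta, search=search)
    left_of, right_of = (ndr[0], ndr[1]) if ndr else (0, 0)
    up = sorted(c for c, _ in troughs if c < left_of)
    down = sorted(c for c, _ in troughs if c >= right_of)
    minus_one = up[-1] if up else None
    plus_one = down[0] if down else None

    spacings: list[float] = []
    for side in (up, down):
        if len(side) >= 2:
            spacings.extend(np.diff(side).tolist())
    period = float(np.median(spacings)) if spacings else None
    return ProfileFeatures(ndr, troughs, peaks, period, minus_one, plus_one)


@dataclass(frozen=True)
class FlaggedInterval:
    """An offset interval gaining accessibility after the salt wash."""

    start: int
    end: int
    mean_delta: float


def compare_conditions(
    mp_native: Metaplot,
    mp_salt: Metaplot,
    min_delta: float = 10.0,
    min_bins: int = 2,
) -> list[FlaggedInterval]:
    """Flag candidate protein footprints from a native-vs-NaCl comparison.

    The 400 mM NaCl wash removes chromatin-associated proteins but not
    histones, so intervals where salt accessibility exceeds native by at
    least ``min_delta`` percentage points over ``min_bins`` consecutive
    bins mark footprints of salt-labile proteins; nucleosomal troughs are
    unchanged and stay unflagged.
    """
    if (mp_native.anchor != mp_salt.anchor
            or mp_native.bin_width != mp_salt.bin_width
            or not np.array_equal(mp_native.offsets, mp_salt.offsets)):
        raise ValueError("profiles have mismatched anchors or binning")
    delta = mp_salt.percent - mp_native.percent
    hot = np.isfinite(delta) & (delta >= min_delta)

    out: list[FlaggedInterval] = []
    i = 0
    n = hot.size
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1]:
            j += 1
        if j - i + 1 >= min_bins:
            out.append(FlaggedInterval(
                int(mp_native.offsets[i]),
                int(mp_native.offsets[j] + mp_native.bin_width),
                float(np.mean(delta[i:j + 1])),
            ))
        i = j + 1
    return out


def plot_metaplot(mp: Metaplot, ax=None, label: str | None = None,
                  path: str | None = None):
    """Simple figure export of a profile (matplotlib, imported lazily)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.plot(mp.offsets + mp.bin_width / 2, mp.percent, label=label)
    ax.set_xlabel(f"offset from {mp.anchor} (bp)")
    ax.set_ylabel("% accessibility")
    ax.set_ylim(0, 100)
    if label:
        ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
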