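"""Single-molecule nucleosome and footprint calling.

A molecule's accessibility states (teal/white circles in lollipop plots)
are scanned for maximal runs of protected informative sites.  The protected
*span* of a run is the open interval between the nearest flanking
accessible sites (exclusive), truncated at the outermost informative site
when no flank exists — "continuous inaccessibility" is measured in bp, not
in sites, which is the only definition consistent at dense site spacing and
conservative at sparse spacing.  Classification:

* span >= 146 bp                      -> nucleosome ("pink bar")
* 25 < span < 146 bp near TSS or TTS  -> footprint  ("orange bar")
* anything else protected             -> unclassified_protected

Missing states neither break runs nor count as accessible: runs are
computed over informative sites only.  A single isolated protected site
never forms a region (minimum two sites), guarding against the ~0.9%
bisulfite inconversion noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .simulate import NUCLEOSOME_BP, ReferenceLocus
from .states import MoleculeStates, STATE_MISSING, STATE_PROTECTED

FOOTPRINT_MIN_BP = 26  # smallest span that counts as a footprint (span > 25)
ANCHOR_WINDOW_BP = 150  # "around the TSS or TTS"


@dataclass(frozen=True)
class CalledRegion:
    """A maximal protected interval on one molecule (0-based half-open)."""

    molecule_id: str
    start: int
    end: int
    n_sites: int
    label: str  # nucleosome | footprint | unclassified_protected

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


def _intersects_anchor(start: int, end: int, anchor: int, window: int) -> bool:
    # region [start, end) vs closed window [anchor - w, anchor + w]
    return start <= anchor + window and end > anchor - window


def call_regions(
    molecule: MoleculeStates,
    ref: ReferenceLocus,
    anchor_window: int = ANCHOR_WINDOW_BP,
    nucleosome_bp: int = NUCLEOSOME_BP,
    footprint_min_bp: int = FOOTPRINT_MIN_BP,
    min_sites: int = 2,
) -> list[CalledRegion]:
    """Call nucleosomes and footprints on one molecule.

    Requires at least one informative accessibility site.  Footprints must
    intersect ±``anchor_window`` bp of the TSS or the TTS.
    """
    informative = molecule.acc_states != STATE_MISSING
    pos = molecule.acc_positions[informative]
    states = molecule.acc_states[informative]
    order = np.argsort(pos, kind="stable")
    pos, states = pos[order], states[order]
    if pos.size == 0:
        raise ValueError(
            f"molecule {molecule.molecule_id} has no informative sites"
        )

    out: list[CalledRegion] = []
    protected = states == STATE_PROTECTED
    i = 0
    n = pos.size
    while i < n:
        if not protected[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and protected[j + 1]:
            j += 1
        if j - i + 1 >= min_sites:
            start = int(pos[i - 1]) + 1 if i > 0 else int(pos[i])
            end = int(pos[j + 1]) if j + 1 < n else int(pos[j]) + 1
            span = end - start
            if span >= nucleosome_bp:
                label = "nucleosome"
            elif span >= footprint_min_bp and (
                _intersects_anchor(start, end, ref.tss_offset, anchor_window)
                or _intersects_anchor(start, end, ref.tts_offset, anchor_window)
            ):
                label = "footprint"
            else:
                label = "unclassified_protected"
            out.append(CalledRegion(molecule.molecule_id, start, end,
                                    j - i + 1, label))
        i = j + 1
    return out


@dataclass(frozen=True)
class OccupancySummary:
    """k-of-n nucleosome occupancy of an anchor-relative window."""

    locus_id: str
    window: tuple[int, int]
    k_occupied: int
    n_molecules: int

    @property
    def fraction(self) -> float:
        return self.k_occupied / self.n_molecules


def occupancy_summary(
    molecules: Sequence[MoleculeStates],
    ref: ReferenceLocus,
    window: tuple[int, int],
    min_overlap: float = 0.5,
    anchor_window: int = ANCHOR_WINDOW_BP,
    regions: Iterable[CalledRegion] | None = None,
) -> OccupancySummary:
    """Count molecules whose called nucleosome covers the window.

    ``window`` is a TSS-relative, strand-aware offset interval; a molecule
    is occupied when a called nucleosome overlaps it by at least
    ``min_overlap`` of the window length.  Pass precomputed ``regions`` to
    avoid re-calling.
    """
    if len(molecules) == 0:
        raise ValueError("occupancy undefined for zero molecules")
    a, b = window
    d = ref.direction
    x, y = ref.tss_offset + a * d, ref.tss_offset + b * d
    lo, hi = (x, y) if x <= y else (y, x)
    if not (0 <= lo < hi <= len(ref)):
        raise ValueError(f"window {window} falls outside the locus")
    need = min_overlap * (hi - lo)

    if regions is None:
        regions = [r for m in molecules for r in call_regions(m, ref, anchor_window)]
    occupied_ids = {
        r.molecule_id
        for r in regions
        if r.label == "nucleosome" and r.overlap(lo, hi) >= need
    }
    k = sum(1 for m in molecules if m.molecule_id in occupied_ids)
    return OccupancySummary(ref.locus_id, (int(a), int(b)), k, len(molecules))


def sort_for_display(
    molecules: Sequence[MoleculeStates],
    ref: ReferenceLocus | None = None,
    windows: Sequence[tuple[int, int]] | None = None,
    anchor_window: int = ANCHOR_WINDOW_BP,
) -> list[str]:
    """Deterministic molecule ordering for lollipop-style panels.

    Molecules are keyed by their occupied-window pattern (nucleosome calls
    over a tiling of the locus, most-occupied first), then by id; the
    result is invariant under permutation of the input.  Without a
    reference, the raw state vector is the key.
    """
    keyed = []
    for m in molecules:
        if ref is not None:
            if windows is None:
                tiles = [
                    (s, min(s + NUCLEOSOME_BP, len(ref)))
                    for s in range(0, len(ref), NUCLEOSOME_BP)
                ]
            else:
                d = ref.direction
                tiles = []
                for a, b in windows:
                    x, y = ref.tss_offset + a * d, ref.tss_offset + b * d
                    tiles.append((min(x, y), max(x, y)))
            calls = [r for r in call_regions(m, ref, anchor_window)
                     if r.label == "nucleosome"]
            bits = tuple(
                int(any(r.overlap(lo, hi) >= 0.5 * (hi - lo) for r in calls))
                for lo, hi in tiles
            )
            key = (tuple(-b for b in bits), m.molecule_id)
        else:
            key = (tuple(-int(s) for s in m.acc_states), m.molecule_id)
        keyed.append((key, m.molecule_id))
    keyed.sort(key=lambda t: t[0])
    return [mid for _, mid in keyed]
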