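"""Cytosine context classification and per-molecule methylation-state calling.

NOMe-seq reads accessibility out of bisulfite sequence: M.CviPI methylates
cytosines in GpC dinucleotides that are not protected by a nucleosome or a
bound protein, bisulfite conversion then turns every *unmethylated* C into T,
so a retained C at a GpC site marks an accessible position on that single
molecule.  Three trinucleotide contexts matter:

* ``GCH`` (GpC not followed by G) — the accessibility channel.
* ``HCG`` (CpG not preceded by G) — the endogenous-methylation channel in
  single-enzyme mode; a second accessibility channel in dual (M.CviPI +
  M.SssI) mode.
* ``GCG`` — ambiguous (enzyme and endogenous signal confounded), excluded
  from all state calling.

Coordinates are 0-based.  A site's position is the C on the + strand; for
− strand contexts the + strand position of the base-paired G is recorded and
the site is flagged with strand ``-``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# context codes used internally (per reference position, per strand)
CODE_NONE = 0
CODE_GCH = 1
CODE_HCG = 2
CODE_GCG = 3
CODE_OTHER_C = 4  # a cytosine in neither GpC nor CpG context (conversion QC)

_CODE_TO_CONTEXT = {CODE_GCH: "GCH", CODE_HCG: "HCG", CODE_GCG: "GCG"}

STATE_MISSING = -1
STATE_PROTECTED = 0   # accessibility channel: unmethylated ("white circle")
STATE_ACCESSIBLE = 1  # accessibility channel: methylated  ("teal circle")
# endogenous channel reuses the ints: 0 = unmethylated, 1 = methylated

_ACC_STATE_NAMES = {1: "accessible", 0: "protected", -1: "missing"}
_ENDO_STATE_NAMES = {1: "methylated", 0: "unmethylated", -1: "missing"}


def context_code_arrays(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-position context codes for both strands.

    Returns ``(codes_plus, codes_minus)``, each of length ``len(sequence)``.
    ``codes_plus[i]`` is nonzero iff ``sequence[i] == 'C'``; ``codes_minus[i]``
    is nonzero iff ``sequence[i] == 'G'`` (the − strand cytosine base-pairs
    with that G, and its context is read 5'→3' on the − strand).
    """
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    n = seq.size
    is_c = seq == ord("C")
    is_g = seq == ord("G")

    prev_g = np.zeros(n, dtype=bool)  # + strand: base 5' of position i is G
    next_g = np.zeros(n, dtype=bool)
    prev_g[1:] = is_g[:-1]
    next_g[:-1] = is_g[1:]

    codes_plus = np.zeros(n, dtype=np.int8)
    codes_plus[is_c] = CODE_OTHER_C
    codes_plus[is_c & prev_g & next_g] = CODE_GCG
    codes_plus[is_c & prev_g & ~next_g] = CODE_GCH
    codes_plus[is_c & ~prev_g & next_g] = CODE_HCG

    # − strand: at plus position i (plus base G, minus base C) the 5'
    # neighbour on the − strand sits at plus i+1 and is G iff plus i+1 is C;
    # the 3' neighbour sits at plus i-1 and is G iff plus i-1 is C.
    prev_g_m = np.zeros(n, dtype=bool)
    next_g_m = np.zeros(n, dtype=bool)
    prev_g_m[:-1] = is_c[1:]
    next_g_m[1:] = is_c[:-1]

    codes_minus = np.zeros(n, dtype=np.int8)
    codes_minus[is_g] = CODE_OTHER_C
    codes_minus[is_g & prev_g_m & next_g_m] = CODE_GCG
    codes_minus[is_g & prev_g_m & ~next_g_m] = CODE_GCH
    codes_minus[is_g & ~prev_g_m & next_g_m] = CODE_HCG
    return codes_plus, codes_minus


@dataclass(frozen=True)
class SiteContext:
    """An informative cytosine on the reference.

    ``channel`` is mode-dependent: in dual mode HCG sites report
    accessibility (both enzymes probe openness), in single mode they report
    endogenous CpG methylation.  GCG sites are always ``excluded``.
    """

    position: int
    context: str           # GCH | HCG | GCG
    strand: str            # + | -
    channel: str           # accessibility | endogenous | excluded


def _channel_for(context: str, mode: str) -> str:
    if context == "GCG":
        return "excluded"
    if context == "GCH":
        return "accessibility"
    # HCG
    return "accessibility" if mode == "dual" else "endogenous"


def classify_contexts(ref, mode: str = "single", strands: str = "+") -> list[SiteContext]:
    """Scan the reference for informative cytosines.

    Parameters
    ----------
    ref : ReferenceLocus
    mode : "single" or "dual"
        Dual (M.CviPI + M.SssI) mode routes HCG sites into the accessibility
        channel.
    strands : "+" or "both"
        Default "+" matches top-strand-only reads (the simulator's default
        output); "both" additionally reports − strand contexts at the plus
        coordinate of the paired G.
    """
    if mode not in ("single", "dual"):
        raise ValueError(f"mode must be 'single' or 'dual', got {mode!r}")
    if strands not in ("+", "both", "-"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    codes_plus, codes_minus = context_code_arrays(ref.sequence)
    in_primer = np.zeros(len(ref.sequence), dtype=bool)
    for start, end in ref.primer_masks:
        in_primer[start:end] = True

    out: list[SiteContext] = []
    wanted = []
    if strands in ("+", "both"):
        wanted.append(("+", codes_plus))
    if strands in ("-", "both"):
        wanted.append(("-", codes_minus))
    for strand, codes in wanted:
        for code in (CODE_GCH, CODE_HCG, CODE_GCG):
            positions = np.flatnonzero((codes == code) & ~in_primer)
            ctx = _CODE_TO_CONTEXT[code]
            chan = _channel_for(ctx, mode)
            out.extend(SiteContext(int(p), ctx, strand, chan) for p in positions)
    out.sort(key=lambda s: (s.position, s.strand))
    return out


@dataclass
class MoleculeStates:
    """Per-site ternary states of one sequenced molecule.

    Accessibility states are stored as an int8 array aligned with
    ``acc_positions`` (1 accessible, 0 protected, -1 missing); likewise the
    endogenous channel (1 methylated, 0 unmethylated, -1 missing).
    ``conversion_qc`` is the converted fraction of non-context, non-ambiguous
    cytosines on the read (NaN when the read has none).
    """

    molecule_id: str
    locus_id: str
    acc_positions: np.ndarray
    acc_states: np.ndarray
    endo_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    endo_states: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    conversion_qc: float = np.nan
    read_strand: str = "+"

    def __post_init__(self) -> None:
        self.acc_positions = np.asarray(self.acc_positions, dtype=np.int64)
        self.acc_states = np.asarray(self.acc_states, dtype=np.int8)
        self.endo_positions = np.asarray(self.endo_positions, dtype=np.int64)
        self.endo_states = np.asarray(self.endo_states, dtype=np.int8)
        if self.acc_positions.shape != self.acc_states.shape:
            raise ValueError("accessibility positions/states length mismatch")
        if self.endo_positions.shape != self.endo_states.shape:
            raise ValueError("endogenous positions/states length mismatch")

    @property
    def n_informative(self) -> int:
        return int(np.sum(self.acc_states != STATE_MISSING))

    def accessibility_map(self) -> dict[int, str]:
        return {int(p): _ACC_STATE_NAMES[int(s)]
                for p, s in zip(self.acc_positions, self.acc_states)}

    def endogenous_map(self) -> dict[int, str]:
        return {int(p): _ENDO_STATE_NAMES[int(s)]
                for p, s in zip(self.endo_positions, self.endo_states)}


def _read_matrix(reads: Sequence[str], length: int) -> np.ndarray:
    for i, r in enumerate(reads):
        if len(r) != length:
            raise ValueError(
                f"read {i} has length {len(r)}, reference has length {length}"
            )
    buf = "".join(reads).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(reads), length)


def call_states_batch(
    reads: Sequence[str],
    ref,
    mode: str = "single",
    read_strands: Sequence[str] | str = "+",
    molecule_ids: Sequence[str] | None = None,
) -> list[MoleculeStates]:
    """Vectorised :func:`call_states` over many same-locus reads."""
    n = len(reads)
    if isinstance(read_strands, str):
        read_strands = [read_strands] * n
    if molecule_ids is None:
        molecule_ids = [f"mol{i:05d}" for i in range(n)]
    if not (len(read_strands) == len(molecule_ids) == n):
        raise ValueError("reads, read_strands and molecule_ids lengths differ")

    mat = _read_matrix(reads, len(ref.sequence)) if n else np.empty((0, 0), np.uint8)
    out: list[tuple[int, MoleculeStates]] = []
    for strand in ("+", "-"):
        rows = [i for i, s in enumerate(read_strands) if s == strand]
        if not rows:
            continue
        contexts = classify_contexts(ref, mode=mode, strands=strand)
        acc_pos = np.array([c.position for c in contexts if c.channel == "accessibility"],
                           dtype=np.int64)
        endo_pos = np.array([c.position for c in contexts if c.channel == "endogenous"],
                            dtype=np.int64)
        codes_plus, codes_minus = context_code_arrays(ref.sequence)
        other_pos = np.flatnonzero(
            (codes_plus if strand == "+" else codes_minus) == CODE_OTHER_C)

        retained = ord("C") if strand == "+" else ord("G")
        converted = ord("T") if strand == "+" else ord("A")
        sub = mat[rows]

        def states_at(positions: np.ndarray) -> np.ndarray:
            if positions.size == 0:
                return np.empty((len(rows), 0), dtype=np.int8)
            bases = sub[:, positions]
            st = np.full(bases.shape, STATE_MISSING, dtype=np.int8)
            st[bases == retained] = 1
            st[bases == converted] = 0
            return st

        acc = states_at(acc_pos)
        endo = states_at(endo_pos)
        if other_pos.size:
            ob = sub[:, other_pos]
            n_conv = np.sum(ob == converted, axis=1)
            n_ret = np.sum(ob == retained, axis=1)
            denom = n_conv + n_ret
            with np.errstate(invalid="ignore"):
                qc = np.where(denom > 0, n_conv / np.maximum(denom, 1), np.nan)
        else:
            qc = np.full(len(rows), np.nan)

        for k, i in enumerate(rows):
            m = MoleculeStates(
                molecule_id=molecule_ids[i],
                locus_id=ref.locus_id,
                acc_positions=acc_pos,
                acc_states=acc[k],
                endo_positions=endo_pos,
                endo_states=endo[k],
                conversion_qc=float(qc[k]),
                read_strand=strand,
            )
            if m.n_informative == 0:
                logger.warning(
                    "molecule %s has zero informative accessibility sites",
                    m.molecule_id,
                )
            out.append((i, m))
    out.sort(key=lambda t: t[0])
    return [m for _, m in out]


def call_states(
    read: str,
    ref,
    mode: str = "single",
    read_strand: str = "+",
    molecule_id: str = "mol00000",
) -> MoleculeStates:
    """Convert one aligned bisulfite read into per-site states.

    The read must be the full-length amplicon in + strand orientation (for a
    bottom-strand read, its reverse complement), so positions map one-to-one
    onto the reference.  At each context site a retained C (G for − strand
    reads) is called methylated, a converted T (A) unmethylated, anything
    else missing.
    """
    return call_states_batch([read], ref, mode=mode, read_strands=[read_strand],
                             molecule_ids=[molecule_id])[0]


def filter_molecules(
    molecules: Iterable[MoleculeStates],
    min_conversion: float = 0.95,
    min_informative: int = 5,
) -> list[MoleculeStates]:
    """Standard clone-level bisulfite QC.

    Drops molecules whose conversion QC (converted fraction of
    non-informative cytosines) falls below ``min_conversion`` or that carry
    fewer than ``min_informative`` informative accessibility sites.
    Molecules with no QC-able cytosines (NaN) are retained.  Removal counts
    are logged.
    """
    kept: list[MoleculeStates] = []
    n_conv = n_sites = 0
    for m in molecules:
        if not np.isnan(m.conversion_qc) and m.conversion_qc < min_conversion:
            n_conv += 1
            continue
        if m.n_informative < min_informative:
            n_sites += 1
            continue
        kept.append(m)
    if n_conv or n_sites:
        logger.info(
            "filter_molecules removed %d (conversion < %.3f) and %d "
            "(< %d informative sites)", n_conv, min_conversion, n_sites,
            min_informative,
        )
    return kept


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    mean_endogenous_methylation: float
    n_observations: int


def check_dual_eligibility(
    molecules: Iterable[MoleculeStates],
    threshold: float = 0.10,
) -> EligibilityResult:
    """Decide whether a locus qualifies for dual-enzyme (M.CviPI + M.SssI) mode.

    Dual mode reads accessibility out of CpG sites too, which only works
    where endogenous CpG methylation is absent.  Pools the endogenous
    channel of single-enzyme (or untreated) molecules; eligible iff the mean
    methylated fraction is at or below ``threshold``.

    Raises
    ------
    ValueError
        If no informative HCG observations exist (eligibility undecidable).
    """
    n_meth = 0
    n_obs = 0
    for m in molecules:
        informative = m.endo_states != STATE_MISSING
        n_obs += int(informative.sum())
        n_meth += int(np.sum(m.endo_states == 1))
    if n_obs == 0:
        raise ValueError("no informative HCG sites: dual-mode eligibility undecidable")
    mean = n_meth / n_obs
    return EligibilityResult(mean <= threshold, mean, n_obs)
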