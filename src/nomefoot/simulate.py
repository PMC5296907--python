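"""Synthetic single-molecule NOMe-seq data with known ground truth.

The generator emulates the physical steps of the assay on a per-molecule
basis: phased nucleosomes with jittered dyads and per-molecule occupancy
probabilities around a nucleosome-depleted region (NDR), sub-nucleosomal
protein footprints near TSS/TTS, M.CviPI labelling of unprotected GpC sites
(plus M.SssI labelling of unprotected CpG sites in dual mode), endogenous
CpG methylation (optionally allele-structured, e.g. 50/50 monoallelic),
bisulfite conversion with a small inconversion (failure) rate, and a
"salt-washed" condition that strips salt-labile protein footprints but
leaves nucleosomes in place.

Model choices
-------------
* A nucleosome protects ``dyad - 73 .. dyad + 73`` (146 bp).
* Dyads are drawn from a normal centred on the configured offset, truncated
  to keep the particle inside the reference.
* Protection from *nucleosomes* is carved out inside the configured NDR
  (remodeler eviction keeps the NDR open); protein footprints are not
  carved out — they live inside the NDR.
* Reads are full-length amplicons; the bisulfite top strand is emitted by
  default, with an option to also emit bottom-strand reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .states import (
    CODE_GCG,
    CODE_GCH,
    CODE_HCG,
    context_code_arrays,
)

NUCLEOSOME_BP = 146          # bp of DNA wrapped around the histone core
_HALF = NUCLEOSOME_BP // 2   # protection extent on either side of the dyad

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# reference construction
# --------------------------------------------------------------------------

@dataclass
class ReferenceLocus:
    """An amplicon-scale reference with annotated anchors.

    ``tss_offset``/``tts_offset`` are 0-based indices of the first
    transcribed base and the termination site.  ``primer_masks`` are
    0-based half-open intervals that must not contain GpC or CpG
    dinucleotides (primers are designed to avoid informative sites).
    """

    locus_id: str
    sequence: str
    tss_offset: int
    tts_offset: int
    strand: str = "+"
    primer_masks: tuple[tuple[int, int], ...] = ()
    gene_class: str = "tRNA"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference sequence must be uppercase ACGT")
        n = len(self.sequence)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        lo, hi = ((self.tss_offset, self.tts_offset) if self.strand == "+"
                  else (self.tts_offset, self.tss_offset))
        # transcription must run in the strand direction: TSS upstream of TTS
        if not (0 <= lo < hi < n):
            raise ValueError(
                f"anchors tss={self.tss_offset}, tts={self.tts_offset} are "
                f"not ordered along strand {self.strand} within [0, {n})"
            )
        self.primer_masks = tuple((int(a), int(b)) for a, b in self.primer_masks)
        for a, b in self.primer_masks:
            region = self.sequence[max(a - 1, 0): b + 1]
            if "GC" in region or "CG" in region:
                raise ValueError(
                    f"primer region [{a},{b}) contains a GpC or CpG site"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1

    def anchor(self, which: str) -> int:
        if which.upper() == "TSS":
            return self.tss_offset
        if which.upper() == "TTS":
            return self.tts_offset
        raise ValueError(f"anchor must be TSS or TTS, got {which!r}")


def make_reference(
    length: int,
    gpc_spacing: int = 20,
    cpg_spacing: int = 0,
    seed: int = 0,
    *,
    tss_offset: int | None = None,
    tts_offset: int | None = None,
    primer_len: int = 20,
    strand: str = "+",
    gene_class: str = "tRNA",
    locus_id: str | None = None,
) -> ReferenceLocus:
    """Construct a reference with controlled informative-site density.

    The backbone is random A/T; ``GC`` dinucleotides (GCH accessibility
    sites) are placed every ``gpc_spacing`` bp and, when ``cpg_spacing`` is
    positive, ``CG`` dinucleotides (HCG endogenous sites) on an interleaved
    grid.  No GCG trinucleotide is ever produced, which caps the achievable
    density: requested GpC spacings below 3 bp are rounded up to 3 (the
    densest GCG-free layout).  ``primer_len`` bases at both ends stay A/T
    only and are recorded as primer masks.

    Deterministic for a fixed seed.  Raises ``ValueError`` when the
    requested spacing does not fit between the primers.
    """
    if length < 200:
        raise ValueError("length must be >= 200")
    if gpc_spacing < 1:
        raise ValueError("gpc_spacing must be >= 1")
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=length)

    s = max(int(gpc_spacing), 3)
    lo, hi = primer_len, length - primer_len
    if hi - lo < s + 2:
        raise ValueError(
            f"gpc_spacing {gpc_spacing} does not fit in usable window "
            f"[{lo},{hi}) of a {length} bp reference"
        )
    occupied = np.zeros(length, dtype=bool)

    def place(dinuc: bytes, start: int) -> bool:
        # keep one A/T margin on each side so no GCG can arise
        if start < lo or start + 2 > hi:
            return False
        if occupied[max(start - 1, 0): start + 3].any():
            return False
        seq[start] = dinuc[0]
        seq[start + 1] = dinuc[1]
        occupied[start: start + 2] = True
        return True

    # seeded grid phase and per-placement jitter: real loci have irregular
    # GpC spacing, and pooled metaplots rely on site phases differing
    # between loci
    jitter = 0 if s == 3 else max(s // 3, 1)
    phase = int(rng.integers(0, s))
    for p in range(lo + phase, hi - 1, s):
        shift = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        for cand in (p + shift, p, p + shift - 1, p + shift + 1):
            if place(b"GC", cand):
                break

    if cpg_spacing and cpg_spacing > 0:
        shift = max(s // 2, 2)
        for q in range(lo + shift, hi - 1, int(cpg_spacing)):
            for cand in (q, q - 2, q + 2, q - 3, q + 3, q - 4, q + 4,
                         q - 5, q + 5):
                if place(b"CG", cand):
                    break

    # lone C and G bases in neither GpC nor CpG context: these carry no
    # accessibility signal but report bisulfite conversion efficiency
    at = (ord("A"), ord("T"))
    for k, base in enumerate((ord("C"), ord("G"))):
        for q in range(lo + 3 + 7 * k, hi - 1, max(2 * s, 14)):
            for cand in (q, q + 1, q - 1, q + 2, q - 2, q + 3, q - 3):
                if (lo <= cand < hi and not occupied[cand]
                        and seq[cand - 1] in at and seq[cand] in at
                        and seq[cand + 1] in at):
                    seq[cand] = base
                    occupied[cand] = True
                    break

    if tss_offset is None:
        tss_offset = length // 2
    if tts_offset is None:
        if strand == "+":
            tts_offset = min(tss_offset + 100, length - primer_len - 1)
        else:
            tts_offset = max(tss_offset - 100, primer_len)
    return ReferenceLocus(
        locus_id=locus_id or f"locus_seed{seed}",
        sequence=seq.tobytes().decode("ascii"),
        tss_offset=tss_offset,
        tts_offset=tts_offset,
        strand=strand,
        primer_masks=((0, primer_len), (length - primer_len, length)),
        gene_class=gene_class,
    )


# --------------------------------------------------------------------------
# architecture configuration
# --------------------------------------------------------------------------

@dataclass
class NucleosomeSpec:
    """One phased nucleosome: dyad offset (bp, TSS-relative, strand-aware),
    dyad jitter SD (bp) and per-molecule occupancy probability."""

    offset: int
    jitter_sd: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass
class FootprintSpec:
    """A sub-nucleosomal protein footprint: centre offset (TSS-relative),
    width (bp), per-molecule presence probability, and whether a 400 mM
    NaCl wash removes it (TFIIIB-like footprints are salt-resistant)."""

    center: int
    width: int
    presence: float = 1.0
    salt_labile: bool = True

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("footprint width must be >= 1")
        if not 0.0 <= self.presence <= 1.0:
            raise ValueError("presence must be in [0, 1]")


@dataclass
class ArchitectureConfig:
    """Generative parameters for one locus.

    ``endogenous_cpg_meth`` is either a per-site methylation probability
    applied to every molecule, or a list of ``(fraction, probability)``
    alleles (e.g. ``[(0.5, 1.0), (0.5, 0.0)]`` for a 50/50 monoallelically
    methylated locus).  ``inconversion_rate`` is the probability that an
    unmethylated C survives bisulfite conversion (assay noise floor,
    default 0.9%).
    """

    nucleosomes: list[NucleosomeSpec] = field(default_factory=list)
    footprints: list[FootprintSpec] = field(default_factory=list)
    ndr: tuple[int, int] | None = None
    nucleosome_len: int = NUCLEOSOME_BP
    enzyme_efficiency: float = 0.95
    endogenous_cpg_meth: float | list[tuple[float, float]] = 0.0
    inconversion_rate: float = 0.009
    n_molecules: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.nucleosomes = [
            n if isinstance(n, NucleosomeSpec) else NucleosomeSpec(*n)
            for n in self.nucleosomes
        ]
        self.footprints = [
            f if isinstance(f, FootprintSpec) else FootprintSpec(*f)
            for f in self.footprints
        ]
        if self.nucleosome_len < 1:
            raise ValueError("nucleosome_len must be >= 1")
        for p, name in ((self.enzyme_efficiency, "enzyme_efficiency"),
                        (self.inconversion_rate, "inconversion_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.ndr is not None:
            a, b = self.ndr
            if a >= b:
                raise ValueError("ndr start must be < ndr end")

    def allele_table(self) -> list[tuple[float, float]]:
        if isinstance(self.endogenous_cpg_meth, (int, float)):
            return [(1.0, float(self.endogenous_cpg_meth))]
        fracs = [f for f, _ in self.endogenous_cpg_meth]
        if not np.isclose(sum(fracs), 1.0):
            raise ValueError("allele fractions must sum to 1")
        return [(float(f), float(p)) for f, p in self.endogenous_cpg_meth]


@dataclass
class SimTruth:
    """Per-molecule ground truth plus the generative configuration."""

    config: ArchitectureConfig
    locus_id: str
    length: int
    dyads: np.ndarray              # (n_molecules, n_nucleosomes) float
    occupied: np.ndarray           # (n_molecules, n_nucleosomes) bool
    footprint_present: np.ndarray  # (n_molecules, n_footprints) bool
    footprint_intervals: list[tuple[int, int]]
    nucleosome_mask: np.ndarray    # (n_molecules, length) uint8, NDR carved out
    masks: np.ndarray              # nucleosome_mask | present footprints
    alleles: np.ndarray | None = None  # (n_molecules,) int allele index

    @property
    def n_molecules(self) -> int:
        return self.masks.shape[0]


def _oriented_interval(ref: ReferenceLocus, a: int, b: int) -> tuple[int, int]:
    """Map a TSS-relative, strand-aware offset interval to plus coordinates."""
    d = ref.direction
    x, y = ref.tss_offset + a * d, ref.tss_offset + b * d
    lo, hi = (x, y) if x <= y else (y + 1, x + 1)
    return max(int(lo), 0), min(int(hi), len(ref))


def simulate_molecules(
    ref: ReferenceLocus,
    cfg: ArchitectureConfig,
) -> tuple[np.ndarray, SimTruth]:
    """Draw per-molecule protection masks from the architecture.

    Each nucleosome is occupied with its occupancy probability; its dyad is
    drawn from a normal (mean = configured offset, sd = jitter_sd) truncated
    to keep the particle inside the reference.  Nucleosomal protection is
    removed inside the configured NDR.  Footprints are present with their
    presence probability.  Returns ``(masks, truth)``; reproducible for a
    fixed ``cfg.seed``.
    """
    n, L = cfg.n_molecules, len(ref)
    if not cfg.nucleosomes and not cfg.footprints and cfg.ndr is None:
        raise ValueError("nothing to simulate: no nucleosomes, footprints or NDR")
    rng = np.random.default_rng(cfg.seed)
    d = ref.direction
    half = cfg.nucleosome_len // 2

    n_nuc = len(cfg.nucleosomes)
    dyads = np.zeros((n, n_nuc))
    occupied = np.zeros((n, n_nuc), dtype=bool)
    nuc_mask = np.zeros((n, L), dtype=np.uint8)
    for j, spec in enumerate(cfg.nucleosomes):
        mean = ref.tss_offset + spec.offset * d
        if not 0 <= mean < L:
            raise ValueError(
                f"nucleosome dyad offset {spec.offset} falls outside the reference"
            )
        occupied[:, j] = rng.random(n) < spec.occupancy
        if spec.jitter_sd == 0:
            dy = np.full(n, float(mean))
        else:
            lo = (half - mean) / spec.jitter_sd
            hi = (L - half - 1 - mean) / spec.jitter_sd
            dy = stats.truncnorm.rvs(lo, hi, loc=mean, scale=spec.jitter_sd,
                                     size=n, random_state=rng)
        dy = np.clip(np.rint(dy), half, L - half - 1).astype(np.int64)
        dyads[:, j] = dy
        for i in np.flatnonzero(occupied[:, j]):
            start = dy[i] - half
            nuc_mask[i, start: start + cfg.nucleosome_len] = 1
    if cfg.ndr is not None:
        a, b = _oriented_interval(ref, cfg.ndr[0], cfg.ndr[1])
        nuc_mask[:, a:b] = 0

    n_fp = len(cfg.footprints)
    fp_present = np.zeros((n, n_fp), dtype=bool)
    fp_intervals: list[tuple[int, int]] = []
    masks = nuc_mask.copy()
    for j, spec in enumerate(cfg.footprints):
        a = spec.center - spec.width // 2
        lo, hi = _oriented_interval(ref, a, a + spec.width)
        if hi - lo == 0:
            raise ValueError(f"footprint {j} falls outside the reference")
        fp_intervals.append((lo, hi))
        fp_present[:, j] = rng.random(n) < spec.presence
        masks[np.flatnonzero(fp_present[:, j]), lo:hi] = 1

    truth = SimTruth(
        config=cfg,
        locus_id=ref.locus_id,
        length=L,
        dyads=dyads,
        occupied=occupied,
        footprint_present=fp_present,
        footprint_intervals=fp_intervals,
        nucleosome_mask=nuc_mask,
        masks=masks,
    )
    return masks, truth


def simulate_salt_condition(truth: SimTruth) -> np.ndarray:
    """Protection masks after a 400 mM NaCl wash.

    The wash removes chromatin-associated proteins but not histones: all
    salt-labile footprints disappear, nucleosomes and salt-resistant
    footprints (e.g. a TFIIIB-like upstream footprint) are retained.
    """
    masks = truth.nucleosome_mask.copy()
    for j, spec in enumerate(truth.config.footprints):
        if spec.salt_labile:
            continue
        lo, hi = truth.footprint_intervals[j]
        masks[np.flatnonzero(truth.footprint_present[:, j]), lo:hi] = 1
    return masks


# --------------------------------------------------------------------------
# chemistry: enzymes + bisulfite
# --------------------------------------------------------------------------

@dataclass
class ChemistryResult:
    """Bisulfite read sequences plus emission metadata."""

    reads: list[str]
    molecule_ids: list[str]
    read_strands: list[str]
    mode: str
    warnings: list[str] = field(default_factory=list)
    alleles: np.ndarray | None = None


def apply_chemistry(
    ref: ReferenceLocus,
    masks: np.ndarray,
    cfg: ArchitectureConfig,
    mode: str = "single",
    *,
    rng: np.random.Generator | None = None,
    both_strands: bool = False,
    id_prefix: str = "mol",
) -> ChemistryResult:
    """Run M.CviPI (and M.SssI in dual mode) plus bisulfite conversion.

    Unprotected GCH (and GCG) cytosines are methylated with
    ``enzyme_efficiency``; in dual mode unprotected, endogenously
    unmethylated HCG cytosines are additionally methylated by M.SssI.
    Endogenous CpG methylation is applied per molecule according to
    ``cfg.endogenous_cpg_meth`` (scalar or allele-structured).  Bisulfite
    then converts every unmethylated C to T except with probability
    ``inconversion_rate``; methylated cytosines are unchanged.  Reads are
    emitted on the bisulfite top strand (plus bottom-strand reads,
    represented in + orientation with G→A conversion, when
    ``both_strands``).
    """
    if mode not in ("single", "dual"):
        raise ValueError(f"mode must be 'single' or 'dual', got {mode!r}")
    masks = np.asarray(masks, dtype=np.uint8)
    n, L = masks.shape
    if L != len(ref):
        raise ValueError("masks do not match reference length")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))

    codes_plus, codes_minus = context_code_arrays(ref.sequence)
    seq = np.frombuffer(ref.sequence.encode("ascii"), dtype=np.uint8)
    unprotected = masks == 0

    alleles_tab = cfg.allele_table()
    allele_idx = rng.choice(len(alleles_tab), size=n,
                            p=[f for f, _ in alleles_tab])
    p_endo = np.array([alleles_tab[i][1] for i in allele_idx])[:, None]

    warnings: list[str] = []
    mean_endo = float(np.mean([p * f for f, p in alleles_tab]) * len(alleles_tab))
    if mode == "dual" and mean_endo > 0.10:
        warnings.append(
            f"dual mode requested but mean endogenous CpG methylation "
            f"{mean_endo:.2f} exceeds the eligibility bound 0.10; the assay "
            f"requires endogenously unmethylated regions"
        )

    def methylation(codes: np.ndarray) -> np.ndarray:
        gpc = (codes == CODE_GCH) | (codes == CODE_GCG)
        cpg = (codes == CODE_HCG) | (codes == CODE_GCG)
        meth = np.zeros((n, L), dtype=bool)
        # endogenous CpG methylation pre-exists, protection-independent
        meth |= cpg[None, :] & (rng.random((n, L)) < p_endo)
        # M.CviPI on accessible GpC
        meth |= gpc[None, :] & unprotected & (rng.random((n, L)) < cfg.enzyme_efficiency)
        if mode == "dual":
            # M.SssI on accessible, endogenously unmethylated CpG
            meth |= (codes == CODE_HCG)[None, :] & unprotected & \
                (rng.random((n, L)) < cfg.enzyme_efficiency)
        return meth

    reads: list[str] = []
    ids: list[str] = []
    strands: list[str] = []

    # top strand: C -> T unless methylated or inconversion failure
    meth_plus = methylation(codes_plus)
    is_c = seq == ord("C")
    retain = meth_plus | (rng.random((n, L)) < cfg.inconversion_rate)
    top = np.broadcast_to(seq, (n, L)).copy()
    conv = is_c[None, :] & ~retain
    top[conv] = ord("T")
    for i in range(n):
        reads.append(top[i].tobytes().decode("ascii"))
        ids.append(f"{id_prefix}{i:05d}")
        strands.append("+")

    if both_strands:
        # bottom strand in + orientation: G -> A unless the paired minus-C
        # is methylated or inconversion fails
        meth_minus = methylation(codes_minus)
        is_g = seq == ord("G")
        retain_m = meth_minus | (rng.random((n, L)) < cfg.inconversion_rate)
        bot = np.broadcast_to(seq, (n, L)).copy()
        conv_m = is_g[None, :] & ~retain_m
        bot[conv_m] = ord("A")
        for i in range(n):
            reads.append(bot[i].tobytes().decode("ascii"))
            ids.append(f"{id_prefix}{i:05d}")
            strands.append("-")

    return ChemistryResult(
        reads=reads,
        molecule_ids=ids,
        read_strands=strands,
        mode=mode,
        warnings=warnings,
        alleles=allele_idx,
    )
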