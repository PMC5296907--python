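# Methods

## The assay, in brief

M.CviPI methylates cytosines of GpC dinucleotides wherever the DNA is not
occluded by a nucleosome or a bound protein. After bisulfite conversion and
sequencing of cloned amplicons, a retained C at a GpC site reports an
accessible position on one molecule; a converted T reports protection. In
dual mode, M.SssI additionally methylates accessible CpG sites, roughly
doubling the informative-site density — usable only where endogenous CpG
methylation is absent, since pre-existing methylation is indistinguishable
from enzyme labelling. `nomefoot` analyses such data and simulates it with
ground truth.

## Cytosine contexts and coordinates

Each cytosine is classified by its immediate neighbours on its own strand:
G on the 5′ side only → GCH (accessibility channel); G on the 3′ side only →
HCG (endogenous channel in single mode, accessibility in dual); G on both
sides → GCG, excluded as ambiguous (enzyme and endogenous signal are
confounded there); neither → non-informative, used for conversion QC.
Coordinates are 0-based; a − strand site is recorded at the + strand
position of its base-paired G and flagged. Because the simulator emits
bisulfite **top-strand** reads by default, `classify_contexts` defaults to
the + strand; `strands="both"` serves bottom-strand reads (emitted with
`both_strands=True`), where retention is read as G vs A.

## State and region calling

At each context site: retained base → methylated, converted base →
unmethylated, anything else (e.g. N) → **missing**, never protected.
Conversion QC is the converted fraction of non-context, non-ambiguous
cytosines; molecules below 0.95, or with fewer than 5 informative
accessibility sites, are dropped (conventional clone-level QC; both
thresholds configurable).

Region calling scans the informative sites of one molecule for maximal runs
of protected states. The protected span is measured in bp as the open
interval between the nearest flanking accessible sites (exclusive); with no
flank, the span is truncated at the outermost informative site — no
extrapolation beyond evidence. Missing sites neither break runs nor count
as accessible. Classification: span ≥ 146 bp (the DNA content of a
nucleosome core) → nucleosome; span > 25 bp and < 146 bp intersecting
± 150 bp of the TSS or TTS → footprint; otherwise unclassified. A run needs
at least two protected sites, so a single retained C — the signature of a
bisulfite inconversion failure (0.9 % of unmethylated cytosines) — never
creates a region on its own. The span-between-flanks definition is exact at
dense site spacing and conservative at sparse spacing. An important
consequence of per-site literalism: one inconversion artifact *inside* a
nucleosomal run splits it into two sub-146 bp pieces, which makes called
occupancy a slight underestimate of true occupancy (≈ 0.77 recovered for a
true 0.8 at ~7 sites per nucleosome); bridging single discordant sites was
deliberately not implemented, matching how the lollipop figures are read.

Window occupancy counts a molecule when a called nucleosome overlaps the
window by ≥ 50 % of the window length; display order sorts molecules by
their occupied-window bit pattern then id, so panels are permutation
invariant.

## Metaplots and features

Site observations are pooled at the read level across molecules and loci —
percent accessibility per offset bin is 100 × accessible/(accessible +
protected), not an average of per-locus means. Offsets are signed bp from
the anchor (TSS or TTS), negated for − strand loci; bins default to 10 bp
and percent is undefined below 10 observations. TTS anchoring is a separate
pass, not a rescaling of the TSS profile. Smoothing is a coverage-weighted
running mean over an odd number of bins approximating the requested window
(default 30 bp ≈ 3 bins); edges use available support.

The NDR is the maximal contiguous interval containing the anchor whose
(smoothed) accessibility stays at or above θ = 0.6 of the profile maximum
within ± 1 kb; an anchor below threshold yields an explicit no-NDR result.
Troughs are local minima with prominence ≥ 5 percentage points (flat minima
break leftmost); the −1/+1 nucleosomes are the troughs nearest the NDR on
either side, and the phasing period is the median spacing of successive
troughs per side when at least two exist. The native-vs-salt comparison
flags maximal runs of ≥ 2 consecutive bins where salt accessibility exceeds
native by ≥ 10 points. θ, prominence, bin width, smoothing window and the
delta threshold are all unpublished analysis constants exposed in
configuration and echoed into output headers.

## The simulator

The generator emulates the assay's physical steps per molecule:

1. **Nucleosomes.** Each configured nucleosome is occupied with its
   occupancy probability; its dyad is drawn from a normal (configured
   offset, jitter SD) truncated to keep the 146 bp particle inside the
   reference; protection covers dyad ± 73 bp. Offsets are TSS-relative and
   strand-aware.
2. **NDR.** Nucleosomal protection is carved out inside the configured NDR
   interval, modelling remodeler-enforced eviction: the configured NDR *is*
   the ground truth an NDR detector should recover. Protein footprints are
   not carved out — they live inside the NDR (polymerase and TF
   footprints).
3. **Footprints.** Sub-nucleosomal intervals present per molecule with a
   presence probability and a salt-lability flag; `simulate_salt_condition`
   rebuilds masks with salt-labile footprints removed and everything else —
   nucleosomes and salt-resistant (TFIIIB-like) footprints — retained.
4. **Chemistry.** Unprotected GpC cytosines are methylated with the enzyme
   efficiency; endogenous CpG methylation is applied per molecule (a scalar
   probability or allele table such as 50/50 fully-methylated/unmethylated,
   drawn independently per site and strand); in dual mode M.SssI methylates
   accessible unmethylated CpGs. Bisulfite converts unmethylated C → T
   except with the inconversion probability. Reads are full-length,
   clone-style amplicons on the bisulfite top strand (bottom-strand reads
   optional); no fragmentation, sequencer error or PCR-duplicate model.

Defaults, chosen once as the study conditions: enzyme efficiency 0.95
(labelling efficiency is not quantified in the literature for this design;
0.95 leaves a visible ceiling below 100 %), inconversion 0.009 (the assay's
measured noise floor), nucleosome length 146 bp, GpC placement spacing
20 bp (human GCH density after GCG exclusion is roughly one site per
20 bp per strand — low GpC density is exactly why the dual-enzyme mode
exists), CpG spacing 25 bp, dyad jitter 40 bp for genome-wide-style
architectures ("weak positioning") and 20 bp for well-positioned
single-locus nucleosomes. Synthetic references use an A/T backbone with GC,
CG and lone C/G placements on seeded, jittered grids: sequence composition
is not realistic, but site density, phase variability between loci and the
absence of GCG are, and those are the properties the analysis depends on.
Requested GpC spacings below 3 bp are rounded up: a denser layout would
create GCG contexts.

All randomness flows from per-call `numpy` generators seeded from the
configuration, so every artifact is byte-reproducible.

## What the simulations do and do not show

Passing recovery tests shows the pipeline is internally consistent — the
caller inverts the generative model it was pointed at, at realistic site
densities and noise levels. It does not validate against real sequencing
artifacts this model omits: alignment and mapping error, PCR duplicates and
cloning bias, strand-specific conversion failure, CpG/GpC density
heterogeneity of real promoters, or partially methylated endogenous states.
Genome-scale claims (active/inactive counts, mapping rates) depend on
external data and are out of scope.

## Numerical and design notes

* Reference anchors must be ordered along the transcription direction
  (tss < tts on "+", reversed on "−"); amplicon-local coordinates.
* The dense molecules used for span-threshold tests are constructed
  directly as state vectors with a site at every base — the region caller
  accepts states at arbitrary positions, and no GCG-free sequence can carry
  a site at every position.
* Trough detection interpolates across low-coverage (NaN) bins for peak
  finding only; reported percent values are never interpolated.
* `occupancy_summary` errors on zero molecules; `detect_ndr` returns an
  explicit `None` rather than raising when the anchor is closed.
* z-scores use log2(x+1) stabilisation by default (raw scale available);
  zero-variance tracks are an error, not a silent zero.
* The activity rule (peak overlap OR mean promoter z ≥ 1.64) is a
  documented choice: the exact published criterion is not printed anywhere,
  and 1.64 corresponds to a one-sided 5 % cut.
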