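"""Readers and writers for the pipeline's text formats.

FASTA via Biopython; tabular artifacts (states, occupancy, profiles) as TSV
through pandas; intervals as BED / bedGraph.  All coordinates are written
0-based half-open; anchored offsets are signed integers with 0 at the
anchor base.  Analysis parameters are echoed as ``# key=value`` header
lines so every artifact records its provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metaplot import Metaplot
from .regions import CalledRegion, OccupancySummary
from .simulate import ReferenceLocus, SimTruth
from .states import MoleculeStates, SiteContext


# ---------------------------------------------------------------- FASTA ---

def write_fasta(path, records: Iterable[tuple[str, str]],
                descriptions: Mapping[str, str] | None = None) -> None:
    seqs = [
        SeqRecord(Seq(seq), id=name, description=(descriptions or {}).get(name, ""))
        for name, seq in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Returns (id, sequence, description) triples."""
    return [(r.id, str(r.seq).upper(), r.description)
            for r in SeqIO.parse(str(path), "fasta")]


def write_reference(path, ref: ReferenceLocus) -> None:
    """Reference FASTA with anchor/primer metadata in the description."""
    meta = json.dumps({
        "tss": ref.tss_offset, "tts": ref.tts_offset, "strand": ref.strand,
        "primers": list(ref.primer_masks), "gene_class": ref.gene_class,
    })
    write_fasta(path, [(ref.locus_id, ref.sequence)],
                descriptions={ref.locus_id: meta})


def read_reference(path) -> ReferenceLocus:
    recs = read_fasta(path)
    if len(recs) != 1:
        raise ValueError(f"expected one reference record in {path}")
    name, seq, desc = recs[0]
    meta = json.loads(desc.split(None, 1)[1]) if " " in desc else {}
    return ReferenceLocus(
        locus_id=name,
        sequence=seq,
        tss_offset=int(meta.get("tss", 0)),
        tts_offset=int(meta.get("tts", len(seq) - 1)),
        strand=meta.get("strand", "+"),
        primer_masks=tuple(tuple(p) for p in meta.get("primers", [])),
        gene_class=meta.get("gene_class", "tRNA"),
    )


# ------------------------------------------------------------- headers ---

def _header_lines(params: Mapping[str, object] | None) -> str:
    if not params:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in sorted(params.items()))


def _read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


# -------------------------------------------------------------- states ---

_ACC_NAME = {1: "accessible", 0: "protected", -1: "missing"}
_ENDO_NAME = {1: "methylated", 0: "unmethylated", -1: "missing"}
_ACC_CODE = {v: k for k, v in _ACC_NAME.items()}
_ENDO_CODE = {v: k for k, v in _ENDO_NAME.items()}


def write_states_tsv(path, molecules: Sequence[MoleculeStates],
                     params: Mapping[str, object] | None = None) -> None:
    rows = []
    for m in molecules:
        for p, s in zip(m.acc_positions, m.acc_states):
            rows.append((m.molecule_id, m.locus_id, int(p), "accessibility",
                         _ACC_NAME[int(s)], m.read_strand, m.conversion_qc))
        for p, s in zip(m.endo_positions, m.endo_states):
            rows.append((m.molecule_id, m.locus_id, int(p), "endogenous",
                         _ENDO_NAME[int(s)], m.read_strand, m.conversion_qc))
    df = pd.DataFrame(rows, columns=[
        "molecule_id", "locus_id", "position", "channel", "state",
        "read_strand", "conversion_qc"])
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t", index=False)


def read_states_tsv(path) -> list[MoleculeStates]:
    df = _read_table(path)
    out: list[MoleculeStates] = []
    for (mid, locus, strand), grp in df.groupby(
            ["molecule_id", "locus_id", "read_strand"], sort=True):
        acc = grp[grp.channel == "accessibility"]
        endo = grp[grp.channel == "endogenous"]
        out.append(MoleculeStates(
            molecule_id=str(mid),
            locus_id=str(locus),
            acc_positions=acc.position.to_numpy(np.int64),
            acc_states=np.array([_ACC_CODE[s] for s in acc.state], np.int8),
            endo_positions=endo.position.to_numpy(np.int64),
            endo_states=np.array([_ENDO_CODE[s] for s in endo.state], np.int8),
            conversion_qc=float(grp.conversion_qc.iloc[0]),
            read_strand=str(strand),
        ))
    return out


# ----------------------------------------------------------- BED-style ---

def write_contexts_bed(path, locus_id: str, contexts: Sequence[SiteContext],
                       params: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        for c in contexts:
            fh.write(f"{locus_id}\t{c.position}\t{c.position + 1}\t"
                     f"{c.context}:{c.channel}\t0\t{c.strand}\n")


def write_calls_bed(path, locus_id: str, calls: Sequence[CalledRegion],
                    params: Mapping[str, object] | None = None) -> None:
    """Calls as BED6+1: name = molecule id, extra column = label."""
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        for r in calls:
            fh.write(f"{locus_id}\t{r.start}\t{r.end}\t{r.molecule_id}\t"
                     f"{r.span_bp}\t+\t{r.label}\n")


def read_calls_bed(path) -> list[CalledRegion]:
    df = _read_table(path, header=None,
                     names=["chrom", "start", "end", "name", "score",
                            "strand", "label"])
    return [CalledRegion(str(r.name_), int(r.start), int(r.end), 0, str(r.label))
            for r in df.rename(columns={"name": "name_"}).itertuples()]


def write_masks_bed(path, locus_id: str, masks: np.ndarray,
                    molecule_ids: Sequence[str] | None = None) -> None:
    """Per-molecule protection masks as run-length BED intervals."""
    masks = np.asarray(masks)
    with open(path, "w") as fh:
        for i, row in enumerate(masks):
            mid = molecule_ids[i] if molecule_ids else f"mol{i:05d}"
            padded = np.concatenate(([0], row, [0]))
            d = np.diff(padded)
            for s, e in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
                fh.write(f"{locus_id}\t{s}\t{e}\t{mid}\n")


def read_bed6(path) -> pd.DataFrame:
    df = _read_table(path, header=None)
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "name", "score", "strand"]
    return df


def write_bedgraph(path, chrom: str, starts: np.ndarray, step: int,
                   values: np.ndarray,
                   params: Mapping[str, object] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        for s, v in zip(starts, values):
            if np.isfinite(v):
                fh.write(f"{chrom}\t{int(s)}\t{int(s) + step}\t{v:.4f}\n")


# ------------------------------------------------------------ profiles ---

def write_profile_tsv(path, mp: Metaplot,
                      params: Mapping[str, object] | None = None) -> None:
    hdr = dict(params or {})
    hdr.update(anchor=mp.anchor, bin_width=mp.bin_width,
               min_coverage=mp.min_coverage,
               smoothing_window=mp.smoothing_window)
    df = pd.DataFrame({
        "offset": mp.offsets,
        "percent_accessible": np.round(mp.percent, 4),
        "coverage": mp.coverage,
        "accessible": mp.accessible,
        "protected": mp.protected,
        "missing": mp.missing,
    })
    with open(path, "w") as fh:
        fh.write(_header_lines(hdr))
        df.to_csv(fh, sep="\t", index=False)


def read_profile_tsv(path) -> Metaplot:
    hdr: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            hdr[k.strip()] = v
    df = _read_table(path)
    return Metaplot(
        anchor=hdr.get("anchor", "TSS"),
        bin_width=int(hdr.get("bin_width", 10)),
        offsets=df.offset.to_numpy(np.int64),
        accessible=df.accessible.to_numpy(np.int64),
        protected=df.protected.to_numpy(np.int64),
        missing=df.missing.to_numpy(np.int64),
        min_coverage=int(hdr.get("min_coverage", 10)),
        percent=df.percent_accessible.to_numpy(float),
        smoothing_window=int(hdr.get("smoothing_window", 0)),
    )


def write_occupancy_tsv(path, summaries: Sequence[OccupancySummary],
                        params: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame([
        {"locus_id": s.locus_id, "window_start": s.window[0],
         "window_end": s.window[1], "k_occupied": s.k_occupied,
         "n_molecules": s.n_molecules, "fraction": round(s.fraction, 4)}
        for s in summaries
    ])
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t", index=False)


def write_truth(dirpath, truth: SimTruth) -> None:
    """SimTruth as a TSV (per-molecule realisations) + JSON (config)."""
    d = Path(dirpath)
    cfg = truth.config
    with open(d / "truth_config.json", "w") as fh:
        json.dump({
            "locus_id": truth.locus_id,
            "length": truth.length,
            "seed": cfg.seed,
            "n_molecules": cfg.n_molecules,
            "nucleosome_len": cfg.nucleosome_len,
            "enzyme_efficiency": cfg.enzyme_efficiency,
            "inconversion_rate": cfg.inconversion_rate,
            "ndr": cfg.ndr,
            "nucleosomes": [
                {"offset": s.offset, "jitter_sd": s.jitter_sd,
                 "occupancy": s.occupancy} for s in cfg.nucleosomes],
            "footprints": [
                {"center": s.center, "width": s.width, "presence": s.presence,
                 "salt_labile": s.salt_labile} for s in cfg.footprints],
        }, fh, indent=1, sort_keys=True)
    rows = []
    for i in range(truth.n_molecules):
        rows.append({
            "molecule_id": f"mol{i:05d}",
            "dyads": ",".join(f"{x:.0f}" for x in truth.dyads[i]),
            "occupied": ",".join(str(int(x)) for x in truth.occupied[i]),
            "footprints": ",".join(str(int(x)) for x in truth.footprint_present[i]),
            "allele": -1 if truth.alleles is None else int(truth.alleles[i]),
        })
    pd.DataFrame(rows).to_csv(d / "truth_molecules.tsv", sep="\t", index=False)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
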