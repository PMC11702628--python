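"""Readers and writers for the plain-text formats the pipeline touches.

VCF handling goes through pysam. Structural variants are emitted with a
symbolic ALT (``<INS>``/``<DEL>``/``<INV>``), the standard ``SVTYPE`` /
``SVLEN`` / ``END`` INFO keys and, when the allele sequence is resolved,
an ``SVSEQ`` INFO tag carrying it, so read(write(records)) round-trips
exactly. The reader additionally accepts padded REF/ALT sequence
representations (``REF=N, ALT=N<ins>`` and ``REF=N<del>, ALT=N``), the
form produced when symbolic alleles have been replaced with reference
sequence.

Coordinate bookkeeping: under the anchor-before convention the printed
``(POS, END)`` pair is numerically the internal 0-based half-open span
(see :mod:`svqtl.records`), so conversion at the VCF boundary is the
identity on the numbers while remaining a genuine 1-based <-> 0-based
conversion of the anchor base.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .records import SV_TYPES, GenotypeMatrix, SVRecord

log = logging.getLogger(__name__)

_GT_TO_DOSAGE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def _info_get(info, key):
    """info.get tolerant of keys absent from the header entirely."""
    try:
        return info.get(key)
    except (KeyError, ValueError):
        return None
_DOSAGE_TO_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


class VCFParseError(ValueError):
    pass


def read_sv_vcf(path: str | Path, caller: str | None = None) -> list[SVRecord]:
    """Read SV records from a VCF file.

    ``caller`` labels the records; if omitted, a ``##caller=`` header line
    must be present. Records with an unknown SVTYPE (e.g. BND) are skipped
    with a warning. Raises :class:`VCFParseError` naming the offending line
    on malformed input and on a missing GT FORMAT field.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"{path}: cannot parse VCF: {exc}") from exc
    with vf:
        if caller is None:
            for hrec in vf.header.records:
                if hrec.key == "caller":
                    caller = hrec.value
                    break
            if caller is None:
                raise ValueError(
                    f"{path}: no caller given and no ##caller= header line"
                )
        if "GT" not in vf.header.formats:
            raise VCFParseError(f"{path}: VCF has no GT FORMAT field")
        samples = list(vf.header.samples)
        out: list[SVRecord] = []
        for rec in vf:
            parsed = _parse_record(rec, caller, samples, path)
            if parsed is not None:
                out.append(parsed)
    return out


def _parse_record(rec, caller, samples, path) -> SVRecord | None:
    alt = rec.alts[0] if rec.alts else None
    if alt is None:
        return None
    info = rec.info
    symbolic = alt.startswith("<")
    svtype = _info_get(info, "SVTYPE")
    if symbolic and svtype is None:
        svtype = alt.strip("<>")
    seq: str | None = None
    if symbolic:
        if svtype not in SV_TYPES:
            log.warning("%s: skipping record %s with SV type %s", path, rec.id, svtype)
            return None
        start = rec.pos  # POS == internal 0-based start (anchor-before)
        svlen = _info_get(info, "SVLEN")
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        end = rec.stop if svtype != "INS" else start
        if svlen is None:
            svlen = (end - start) if svtype != "INS" else None
            if svlen is None:
                raise VCFParseError(f"{path}: symbolic INS without SVLEN at {rec.pos}")
            if svtype == "DEL":
                svlen = -svlen
        svseq = _info_get(info, "SVSEQ")
        if svseq:
            seq = str(svseq)
    else:
        ref, a = rec.ref, alt
        if len(a) > len(ref) and a.startswith(ref):
            svtype, seq = "INS", a[len(ref):]
            start, end, svlen = rec.pos, rec.pos, len(seq)
        elif len(ref) > len(a) and ref.startswith(a):
            deleted = ref[len(a):]
            svtype, seq = "DEL", deleted
            start = rec.pos
            end, svlen = start + len(deleted), -len(deleted)
        else:
            log.warning("%s: skipping non-SV allele at %s:%s", path, rec.chrom, rec.pos)
            return None
        if svtype not in SV_TYPES:
            log.warning("%s: skipping record with SV type %s", path, svtype)
            return None
    genotypes: dict[str, int] = {}
    for s in samples:
        call = rec.samples[s]
        if "GT" not in call:
            raise VCFParseError(f"{path}: missing GT for sample {s} at {rec.pos}")
        gt = call["GT"]
        if gt is None or any(a is None for a in gt):
            continue
        genotypes[s] = _GT_TO_DOSAGE[tuple(gt)]
    quality = rec.qual if rec.qual is not None else 0.0
    prov = _info_get(info, "PROV")
    if isinstance(prov, str):
        prov = (prov,)
    try:
        sv = SVRecord(
            chrom=rec.chrom,
            start=start,
            end=end,
            svtype=svtype,
            svlen=int(svlen),
            seq=seq,
            quality=float(quality),
            caller=caller,
            genotypes=genotypes,
            provenance=tuple(prov) if prov else (),
        )
    except ValueError as exc:
        raise VCFParseError(f"{path}: bad SV record at {rec.chrom}:{rec.pos}: {exc}")
    return sv


def write_sv_vcf(
    records: list[SVRecord],
    path: str | Path,
    samples: list[str],
    contigs: dict[str, int],
    caller: str | None = None,
) -> None:
    """Write SV records as an uncompressed VCF with symbolic ALT + SVSEQ."""
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=SVSEQ,Number=1,Type=String,Description="Resolved allele sequence">')
    header.add_line('##INFO=<ID=PROV,Number=.,Type=String,Description="Constituent pre-merge record ids">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if caller is not None:
        header.add_line(f"##caller={caller}")
    for s in samples:
        header.add_sample(s)
    # htslib warns spuriously about END==POS insertion records
    verbosity = pysam.set_verbosity(0)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in sorted(records, key=lambda r: (r.chrom, r.start, r.name)):
            if r.start < 1:
                raise ValueError(f"cannot emit VCF for start < 1: {r.name}")
            rec = vf.new_record(
                contig=r.chrom,
                start=r.start - 1,  # pysam start is POS-1; POS == r.start
                alleles=("N", f"<{r.svtype}>"),
                id=r.name,
                qual=r.quality,
            )
            rec.info["SVTYPE"] = r.svtype
            rec.info["SVLEN"] = r.svlen
            if r.svtype != "INS":
                rec.stop = r.end
            # for INS the default 1-base rlen already prints END == POS
            if r.seq is not None:
                rec.info["SVSEQ"] = r.seq
            if r.provenance:
                rec.info["PROV"] = r.provenance
            for s in samples:
                if s in r.genotypes:
                    rec.samples[s]["GT"] = _DOSAGE_TO_GT[r.genotypes[s]]
                else:
                    rec.samples[s]["GT"] = (None, None)
            vf.write(rec)
    pysam.set_verbosity(verbosity)


# ---------------------------------------------------------------------------
# bedMethyl-like tracks


def read_bedmethyl(path: str | Path, counts: bool = False) -> pd.DataFrame:
    """Read a per-CpG methylation track.

    Expects tab-separated ``chrom  pos  coverage  value`` rows where value
    is a methylated fraction in [0,1], or a methylated read count when
    ``counts=True`` (converted to a fraction). Returns a DataFrame sorted
    by (chrom, pos); duplicate positions on a chromosome are an error,
    unsorted input is sorted with a warning.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "pos", "coverage", "value"],
        dtype={"chrom": str},
    )
    if (df["coverage"] < 0).any():
        raise ValueError(f"{path}: negative coverage")
    if counts:
        if (df["value"] > df["coverage"]).any():
            raise ValueError(f"{path}: methylated count exceeds coverage")
        with np.errstate(invalid="ignore"):
            frac = df["value"] / df["coverage"]
        df["fraction"] = frac.fillna(0.0)
    else:
        df["fraction"] = df["value"].astype(float)
    if ((df["fraction"] < 0) | (df["fraction"] > 1)).any():
        raise ValueError(f"{path}: methylation fraction outside [0, 1]")
    df = df[["chrom", "pos", "coverage", "fraction"]]
    if df.duplicated(["chrom", "pos"]).any():
        raise ValueError(f"{path}: duplicate CpG position")
    if not df.equals(df.sort_values(["chrom", "pos"], kind="mergesort")):
        warnings.warn(f"{path}: unsorted bedMethyl input; sorting")
        df = df.sort_values(["chrom", "pos"], kind="mergesort")
    return df.reset_index(drop=True)


def write_bedmethyl(track: pd.DataFrame, path: str | Path) -> None:
    track[["chrom", "pos", "coverage", "fraction"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# BED coverage tracks and simple matrices


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end"], usecols=[0, 1, 2], dtype={0: str},
    )
    if (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: BED interval with start >= end")
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_phenotype_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a phenotype matrix TSV.

    Layout: one row per phenotype with columns ``phenotype_id, chrom,
    anchor`` followed by one column per sample. Returns ``(values, meta)``
    where values is phenotypes x samples and meta carries chrom/anchor.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df = df.set_index("phenotype_id")
    meta = df[["chrom", "anchor"]]
    values = df.drop(columns=["chrom", "anchor"])
    return values, meta


def write_phenotype_tsv(values: pd.DataFrame, meta: pd.DataFrame, path: str | Path) -> None:
    out = pd.concat([meta[["chrom", "anchor"]], values], axis=1)
    out.index.name = "phenotype_id"
    out.to_csv(path, sep="\t")


def read_covariates_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_covariates_tsv(cov: pd.DataFrame, path: str | Path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a small plain FASTA into a dict (synthetic references only)."""
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# dosage matrix TSV (variants x samples)


def write_genotype_tsv(gmat: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gmat.dosages, index=gmat.variants.index, columns=gmat.samples)
    out = pd.concat([gmat.variants, df], axis=1)
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id", dtype={"chrom": str})
    meta_cols = ["chrom", "start", "end", "svtype", "svlen", "is_sv"]
    variants = df[meta_cols]
    dosages = df.drop(columns=meta_cols).astype(np.int16)
    return GenotypeMatrix(dosages.to_numpy(), variants, list(dosages.columns))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Thresholds and knobs for a full pipeline run."""

    seed: int = 0
    seq_similarity_min: float = 0.75
    size_similarity_min: float = 0.75
    refdist: int = 500
    loose_refdist: int = 1000
    loose_size_similarity_min: float = 0.5
    max_sv_size: int = 60_000
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    hwe_alpha: float = 0.001
    hwe_remove_low: bool = True
    cis_window: int = 1_000_000
    permutations: int = 1000
    n_candidates: int = 100
    missingness_max: float = 0.25
    cohort_labels: tuple[str, str] = ("cohortA", "cohortB")
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for name in ("seq_similarity_min", "size_similarity_min",
                     "loose_size_similarity_min"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("maf_min", "call_rate_min", "hwe_alpha", "missingness_max"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.refdist <= 0 or self.loose_refdist <= 0:
            raise ValueError("refdist must be positive")
        if self.permutations < 100:
            raise ValueError("permutations must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        extra = {k: v for k, v in data.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra.update(extra)
        return cfg
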