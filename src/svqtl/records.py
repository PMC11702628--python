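"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package. For
structural variants we use the anchor-before convention of symbolic VCF
records, under which the internal ``[start, end)`` span is numerically
identical to the ``(POS, END)`` pair printed in a VCF: a deletion of
``L`` bases starting at 0-based ``s`` has ``POS == s`` (the 1-based anchor
base preceding the event) and ``END == s + L``. Insertions have
``end == start``.

Genotypes are diploid dosages. In per-record dicts a sample that is absent
from the dict is *missing* (``./.``); an explicit ``0`` is a called
homozygous-reference genotype. In dosage matrices missing is ``-1``. The
two encodings keep "no call" distinct from "reference call", which the
coverage-based reference-genotyping step and the carrier-frequency
definition both rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

MISSING = -1

SV_TYPES = ("INS", "DEL", "INV")

#: callers recognised by the harmonization engine
ASSEMBLY_CALLER = "assembly"
READ_CALLER = "read"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= start and end <= self.end


@dataclass
class SVRecord:
    """One structural variant with provenance and per-sample genotypes.

    ``svlen`` is signed: negative for deletions (matching the sign printed
    in IDs such as ``napu_chr19_54964613_54965703_DEL_-1090``), positive
    for insertions and inversions. ``seq`` holds the resolved allele
    sequence (inserted bases for INS, deleted reference bases for DEL) or
    ``None`` when the call was symbolic / sequence-unresolved.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    svlen: int
    seq: str | None = None
    quality: float = 0.0
    caller: str = READ_CALLER
    genotypes: dict[str, int] = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if abs(self.svlen) < 50:
            raise ValueError(f"|svlen| must be >= 50, got {self.svlen}")
        if self.svtype == "INS":
            if self.end != self.start:
                raise ValueError("INS must have end == start")
            if self.svlen <= 0:
                raise ValueError("INS svlen must be positive")
        else:
            if self.end - self.start != abs(self.svlen):
                raise ValueError(
                    f"{self.svtype} span {self.end - self.start} != |svlen| "
                    f"{abs(self.svlen)}"
                )
            if self.svtype == "DEL" and self.svlen >= 0:
                raise ValueError("DEL svlen must be negative")
        if self.seq is not None and self.svtype in ("INS", "DEL"):
            if len(self.seq) != abs(self.svlen):
                raise ValueError("resolved allele sequence length must equal |svlen|")
        if self.quality < 0:
            raise ValueError("quality must be non-negative")
        if not self.provenance:
            self.provenance = (f"{self.caller}:{self.name}",)

    @property
    def sequence_resolved(self) -> bool:
        return self.seq is not None

    @property
    def name(self) -> str:
        """ID in the ``napu_<chrom>_<pos>_<end>_<TYPE>_<signedlen>`` style."""
        return f"napu_{self.chrom}_{self.start}_{self.end}_{self.svtype}_{self.svlen}"

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint used for coverage / annotation queries."""
        if self.svtype == "INS":
            return self.start, self.start + 1
        return self.start, self.end

    def copy(self, **changes) -> "SVRecord":
        out = replace(self, **changes)
        if "genotypes" not in changes:
            out.genotypes = dict(self.genotypes)
        return out


@dataclass
class GenotypeMatrix:
    """Variants x samples diploid dosage matrix with ``-1`` for missing."""

    dosages: np.ndarray
    variants: pd.DataFrame  # indexed by variant id
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError("dosage shape does not match variants x samples")
        bad = ~np.isin(self.dosages, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {-1, 0, 1, 2}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_variants(self, mask_or_ids) -> "GenotypeMatrix":
        if isinstance(mask_or_ids, (list, pd.Index)):
            idx = self.variants.index.get_indexer(mask_or_ids)
        else:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        return GenotypeMatrix(
            self.dosages[idx], self.variants.iloc[idx], list(self.samples)
        )

    @classmethod
    def from_records(
        cls, records: Iterable[SVRecord], samples: list[str]
    ) -> "GenotypeMatrix":
        records = list(records)
        col = {s: j for j, s in enumerate(samples)}
        dos = np.full((len(records), len(samples)), MISSING, dtype=np.int16)
        rows = []
        for i, r in enumerate(records):
            for s, g in r.genotypes.items():
                dos[i, col[s]] = g
            rows.append(
                dict(
                    id=r.name,
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    svtype=r.svtype,
                    svlen=r.svlen,
                    is_sv=True,
                )
            )
        variants = pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
            columns=["chrom", "start", "end", "svtype", "svlen", "is_sv"]
        )
        return cls(dos, variants, list(samples))


@dataclass
class MethylRegion:
    """A methylation phenotype unit (adaptive window, CGI, promoter, gene body)."""

    interval: GenomicInterval
    kind: str  # window | CGI | promoter | gene_body
    n_cpgs: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("window", "CGI", "promoter", "gene_body"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.kind == "window":
            if self.n_cpgs is None or self.n_cpgs < 1:
                raise ValueError("window region needs n_cpgs >= 1")
        if self.name is None:
            iv = self.interval
            self.name = f"{iv.chrom}_{iv.start}_{iv.end}_{self.kind}"

    @property
    def anchor(self) -> int:
        """Coordinate used to centre the cis window (region start)."""
        return self.interval.start
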