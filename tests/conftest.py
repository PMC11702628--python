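import numpy as np
import pandas as pd
import pytest

from svqtl.records import GenotypeMatrix, SVRecord
from svqtl.simulate import CohortSpec, generate_cohort


def make_sv(
    start=10_000,
    svtype="INS",
    svlen=300,
    chrom="chr1",
    seq=None,
    quality=0.0,
    caller="read",
    genotypes=None,
    end=None,
):
    """Convenience SVRecord factory with consistent span bookkeeping."""
    if svtype == "DEL" and svlen > 0:
        svlen = -svlen
    if end is None:
        end = start if svtype == "INS" else start + abs(svlen)
    if svtype == "INS" and seq == "random":
        rng = np.random.default_rng(start + svlen)
        seq = "".join(rng.choice(list("ACGT"), size=svlen))
    return SVRecord(
        chrom=chrom,
        start=start,
        end=end,
        svtype=svtype,
        svlen=svlen,
        seq=seq,
        quality=quality,
        caller=caller,
        genotypes=genotypes or {},
    )


def make_gmat(dosages, positions=None, is_sv=None, chrom="chr1", samples=None):
    dosages = np.asarray(dosages, dtype=np.int16)
    nv, ns = dosages.shape
    samples = samples or [f"s{i}" for i in range(ns)]
    positions = positions if positions is not None else np.arange(nv) * 1000 + 1000
    is_sv = is_sv if is_sv is not None else np.zeros(nv, dtype=bool)
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "start": positions,
            "end": np.asarray(positions) + 1,
            "svtype": "SNV",
            "svlen": 0,
            "is_sv": is_sv,
        },
        index=[f"v{i}" for i in range(nv)],
    )
    return GenotypeMatrix(dosages, variants, samples)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small but complete cohort bundle reused across tests."""
    spec = CohortSpec(
        name="tiny",
        n_samples=30,
        n_sv=60,
        n_snv=180,
        chrom_length=3_000_000,
        common_fraction=0.5,
    )
    return generate_cohort(
        spec, seed=7, n_genes=25, n_eqtl=6, n_mqtl=4, n_age_regions=6
    )
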