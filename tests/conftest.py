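import numpy as np
import pandas as pd
import pytest

from hlagdiv.cohort import PhasedCohort, SampleManifest, VariantRecord
from hlagdiv.genemodel import GeneModel, GenomicInterval
from hlagdiv.simulate import simulate_structured_locus


def make_manifest(samples, population="POP1", country="C1", region="R1"):
    if isinstance(population, str):
        population = [population] * len(samples)
    return SampleManifest(
        pd.DataFrame(
            {
                "sample": samples,
                "population": population,
                "country": [country] * len(samples),
                "region": [region] * len(samples),
            }
        )
    )


def make_cohort(variants, H, samples=None, **manifest_kw):
    H = np.asarray(H)
    n = H.shape[0] // 2
    samples = samples or [f"S{i}" for i in range(n)]
    return PhasedCohort(variants, samples, H, make_manifest(samples, **manifest_kw))


def snp(pos, ref="C", alt="T", contig="chr6S"):
    return VariantRecord(contig, pos, ".", ref, (alt,))


@pytest.fixture(scope="session")
def toy_model():
    """Two-exon plus-strand model with the ATG at the start of exon 1."""
    c = "chrT"
    return GeneModel(
        c,
        "+",
        1000,
        [GenomicInterval(c, 1000, 1030), GenomicInterval(c, 1050, 1080)],
        promoter_upstream_bp=100,
        downstream_bp=20,
        n_coding_exons=2,
    )


@pytest.fixture(scope="session")
def bundle():
    """Structured synthetic locus shared across test modules (fixed seed)."""
    return simulate_structured_locus(seed=1)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    from hlagdiv.simulate import write_fixture_bundle

    out = tmp_path_factory.mktemp("fixture") / "bundle"
    write_fixture_bundle(bundle, out)
    return out
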