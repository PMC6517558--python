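from pathlib import Path

import numpy as np
import pytest

from rarecohort import load_cohort, read_panel
from rarecohort.filtering import AnnotatedVariant

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_paths():
    return {
        "vcf": DATA / "toy.vcf",
        "annotations": DATA / "toy_annotations.tsv",
        "panel": DATA / "toy_panel.tsv",
    }


@pytest.fixture(scope="session")
def toy_cohort(toy_paths):
    return load_cohort(toy_paths["vcf"], toy_paths["annotations"])


@pytest.fixture(scope="session")
def toy_panel(toy_paths):
    return read_panel(toy_paths["panel"])


def make_variant(**overrides) -> AnnotatedVariant:
    """An AnnotatedVariant with innocuous defaults, overridable per test."""
    defaults = dict(
        chrom="chr1",
        pos=1000,
        ref="A",
        alt="G",
        gene="G1",
        transcript="G1-T1",
        consequence="missense",
        maf_1000g_eur=0.0,
        maf_exac=0.0,
        maf_inhouse=0.0,
        cadd_phred=25.0,
        svm_label="tolerated",
        clinvar_flag=False,
        rd=100.0,
        mq=55.0,
        qd=12.0,
        genotypes=np.array([1, 0, 0, 0], dtype=np.int8),
    )
    defaults.update(overrides)
    return AnnotatedVariant(**defaults)
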