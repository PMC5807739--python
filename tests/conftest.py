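import pytest

from domlink import segmentation, synth


@pytest.fixture(scope="session")
def worked_example():
    """The curated two-species dataset: (proteomes, annotations, dictionary)."""
    return synth.worked_example_fixture()


@pytest.fixture(scope="session")
def worked_segments(worked_example):
    proteomes, annotations, _ = worked_example
    return {
        species: segmentation.segment_proteome(proteomes[species], annotations)
        for species in proteomes
    }


@pytest.fixture(scope="session")
def planted_study():
    """The reference synthetic study with arginine planted at +50%."""
    spec = synth.default_study_spec(seed=1, arg_enrichment=0.5)
    return synth.generate(spec)


@pytest.fixture(scope="session")
def planted_segments(planted_study):
    proteomes, annotations, _ = planted_study
    return {
        species: segmentation.segment_proteome(proteomes[species], annotations)
        for species in proteomes
    }
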