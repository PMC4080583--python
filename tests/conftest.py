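import pytest

from edarch import PublicationConfig, TestProvider, login, mount
from edarch.publication import RecordingRegistrar, Reviewer, ReviewerRole


@pytest.fixture
def alice():
    return login(TestProvider(), username="alice")


@pytest.fixture
def bob():
    return login(TestProvider(), username="bob")


def make_pubconfig(**overrides):
    defaults = dict(
        reviewers=(
            Reviewer("legal@example.org", ReviewerRole.LEGAL),
            Reviewer("scientific@example.org", ReviewerRole.SCIENTIFIC),
            Reviewer("master@example.org", ReviewerRole.MASTER),
        ),
        doi_prefix="10.5072",
        namespace="IPK/Test",
        registrar=RecordingRegistrar(),
    )
    defaults.update(overrides)
    return PublicationConfig(**defaults)


@pytest.fixture
def pubconfig():
    return make_pubconfig()


@pytest.fixture
def repo(tmp_path, alice, pubconfig):
    r = mount(tmp_path / "repo", alice, publication_config=pubconfig)
    yield r
    r.close()


#: Canonical record mirroring the published NGS example data set.
NGS_METADATA = {
    "contributor": "Scholz, Uwe, IPK Gatersleben, Corrensstr.3 OT Gatersleben, 06466 Seeland, Germany",
    "coverage": "Sequences of pooled flow sorted rye A chromosomes (1R-7R)",
    "creator": "Schmutzer, Thomas, IPK Gatersleben, Corrensstr.3 OT Gatersleben, 06466 Seeland, Germany",
    "description": "Individual rye chromosomes were isolated by flow sorting and shotgun sequenced by 454 Titanium pyrosequencing",
    "identifier": "ERS077775",
    "publisher": "Leibniz Institute of Plant Genetics and Crop Plant Research Gatersleben",
    "rights": "http://www.ebi.ac.uk/about/terms-of-use",
    "source": "Secale cereale L.; CoL tax ID 9793059",
    "subject": "NGS, Rye",
    "title": "F32CY7K01.sff",
}

NGS_SIZE_BYTES = 101_069  # renders as "98.7 KB"
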