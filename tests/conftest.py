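import pytest
from hypothesis import HealthCheck, settings

from tspeg import EditSpec, ReferenceSequence

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# 60-mer worked toy locus used throughout: 8 PAM occurrences, with the
# forward PAM starting at 25 (cut 22) serving as the design example site.
TOYREF_SEQ = "AACCGGTCACCTTGAAGATGCTGAATGGCATTGCAGGATCTCCAAGTTACGGAACCTAGC"


@pytest.fixture
def toyref() -> ReferenceSequence:
    return ReferenceSequence("TOYREF", TOYREF_SEQ)


@pytest.fixture
def toy_site(toyref):
    from tspeg import scan_pams

    (site,) = [
        s for s in scan_pams(toyref) if s.strand == "forward" and s.pam_start == 25
    ]
    return site


@pytest.fixture
def cut_insertion() -> EditSpec:
    """Single-base insertion exactly at the toy cut (inter-base 22)."""
    return EditSpec("insertion", 22, 22, alt_allele="A")


@pytest.fixture
def single_pam_ref() -> ReferenceSequence:
    """30-mer with exactly one PAM (TGG at 22), unique cut at 19."""
    return ReferenceSequence("ONEPAM", "A" * 22 + "TGG" + "A" * 5)
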