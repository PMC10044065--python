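import hypothesis
import pytest

from hv1pop.haplotyping import HaplotypeCatalog, HaplotypeRecord, profile_from_window
from hv1pop.sequence_io import ReferenceWindow

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")

#: 30-bp toy reference used across unit tests; window starts at coordinate 101
TOY_REF_SEQ = "ACGTACGGTTCAGCTAAGGCTTACGATCGA"


@pytest.fixture
def toy_ref() -> ReferenceWindow:
    return ReferenceWindow(TOY_REF_SEQ, start_pos=101, name="toy")


def make_record(name: str, seq: str, ref: ReferenceWindow, sub=None) -> HaplotypeRecord:
    return HaplotypeRecord(
        name=name,
        haplogroup=name[0].upper(),
        profile=profile_from_window(seq, ref),
        window_seq=seq,
        subhaplogroup=sub,
    )


def mutate(seq: str, offset: int, base: str) -> str:
    assert seq[offset] != base
    return seq[:offset] + base + seq[offset + 1 :]


@pytest.fixture
def toy_catalog(toy_ref) -> HaplotypeCatalog:
    """Two haplogroups on the toy reference: A at the reference itself plus a
    1-step neighbour, B ten substitutions away plus a 1-step neighbour."""
    ref = toy_ref.ref_seq
    a1 = ref
    a2 = mutate(ref, 5, "T")
    b_base = ref
    for off, base in [(0, "T"), (2, "A"), (7, "C"), (9, "A"), (12, "T"),
                      (15, "C"), (18, "T"), (21, "A"), (24, "T"), (27, "A")]:
        b_base = mutate(b_base, off, base)
    b2 = mutate(b_base, 29, "T")
    return HaplotypeCatalog(
        toy_ref,
        [
            make_record("A1", a1, toy_ref, sub="a1"),
            make_record("A2", a2, toy_ref, sub="a2"),
            make_record("B1", b_base, toy_ref, sub="b1"),
            make_record("B2", b2, toy_ref, sub="b1"),
        ],
    )
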