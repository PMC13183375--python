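import numpy as np
import pytest

from channelome.annotation import (
    ChannelAnnotation,
    MembraneSegment,
    PoreDomain,
    SegmentKind,
    Unit,
)

# Printed exemplar row of the curated annotation table (Aquaporin-1)
AQP1_TMS_LIST = (
    "T:8–36,T:49–66,I:71–76,I:77–84,T:95–115,T:137–155,"
    "T:167–183,I:187–192,I:193–200,T:208–228"
)


@pytest.fixture
def aqp1_segments_text() -> str:
    return AQP1_TMS_LIST


@pytest.fixture
def small_table() -> list[ChannelAnnotation]:
    segs = [
        MembraneSegment(SegmentKind.TM, 10, 30),
        MembraneSegment(SegmentKind.IM, 35, 40),
        MembraneSegment(SegmentKind.TM, 50, 70),
    ]
    return [
        ChannelAnnotation(
            accession="P00001",
            name="Channel one",
            symbol="CH1",
            tdl="Tbio",
            length=120,
            family="FamA",
            group="VGIC",
            unit=Unit.pore_containing,
            segments=segs,
            pore_domain=PoreDomain(10, 70),
            ion="K+",
            gating="Voltage-gated",
        ),
        ChannelAnnotation(
            accession="P00002",
            name="Channel two",
            symbol="CH2",
            tdl="Tdark",
            length=300,
            family="FamA",
            group="VGIC",
            unit=Unit.two_pore,
            segments=segs,
            pore_domain=PoreDomain(10, 70),
            extra={"Lit Resource": "PMID:1"},
        ),
        ChannelAnnotation(
            accession="P00003",
            name="Helper",
            symbol="AUX1",
            tdl="Tclin",
            length=90,
            family="FamB",
            group="Other",
            unit=Unit.auxiliary,
            segments=[],
            pore_domain=None,
            complex_evidence=True,
        ),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
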