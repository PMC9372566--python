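import numpy as np
import pandas as pd
import pytest

from ibdshare import GeneticMap, IbdSegment, PopulationPanel

CM_PER_MB = 1.0


@pytest.fixture
def toy_map() -> GeneticMap:
    """Three chromosomes with a uniform 1 cM/Mb rate."""
    return GeneticMap.linear({"1": 100.0, "2": 80.0, "3": 120.0}, CM_PER_MB)


def make_segment(
    sample_a: str,
    sample_b: str,
    chrom: str = "1",
    start_cm: float = 10.0,
    length_cm: float = 5.0,
    hap_a: int = 1,
    hap_b: int = 1,
    lod: float = 5.0,
) -> IbdSegment:
    """Segment with bp coordinates consistent with the toy 1 cM/Mb map."""
    end_cm = start_cm + length_cm
    seg = IbdSegment(
        sample_a=sample_a, hap_a=hap_a, sample_b=sample_b, hap_b=hap_b,
        chrom=chrom,
        start_bp=int(round(1 + start_cm / CM_PER_MB * 1e6)),
        end_bp=int(round(1 + end_cm / CM_PER_MB * 1e6)),
        start_cm=start_cm, end_cm=end_cm, length_cm=length_cm, lod=lod,
    )
    return seg.canonical()


def make_panel(groups: dict[str, list[str]], **attrs) -> PopulationPanel:
    """Panel from {group: [individuals]}; attrs maps group -> (region,
    subregion, kula, lat, lon), defaulting to a Massim non-Kula group."""
    rows = []
    for group, members in groups.items():
        region, sub, kula, lat, lon = attrs.get(
            group, ("Massim", "southern", "non_kula", -10.0, 152.0)
        )
        for ind in members:
            rows.append((ind, group, region, sub, kula, lat, lon))
    df = pd.DataFrame(
        rows,
        columns=["individual", "group", "region", "massim_subregion", "kula", "lat", "lon"],
    )
    return PopulationPanel.from_frame(df)


@pytest.fixture
def two_group_panel() -> PopulationPanel:
    return make_panel(
        {"X": ["a1", "a2"], "Y": ["b1", "b2"]},
        X=("Massim", "northern", "kula", -8.5, 151.0),
        Y=("Massim", "southern", "non_kula", -11.0, 153.0),
    )
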