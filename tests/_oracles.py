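"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately share no code with the implementation: plain loops over
individual pairs and a fine bp grid for the ancestry labelling.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from ibdshare import AncestryTractSet, GeneticMap, IbdSegment, PopulationPanel


def random_panel_and_segments(rng: np.random.Generator):
    """A random small panel (<= 6 individuals, <= 3 groups) with random
    segments on <= 3 chromosomes, for oracle cross-checks."""
    from conftest import make_panel, make_segment

    n_ind = int(rng.integers(2, 7))
    inds = [f"i{k}" for k in range(n_ind)]
    n_groups = int(rng.integers(1, min(3, n_ind) + 1))
    groups: dict[str, list] = {f"G{g}": [] for g in range(n_groups)}
    for ind in inds:
        groups[f"G{int(rng.integers(0, n_groups))}"].append(ind)
    groups = {g: m for g, m in groups.items() if m}
    panel = make_panel(groups)
    segs = []
    for _ in range(int(rng.integers(0, 15))):
        a, b = rng.choice(inds, size=2, replace=False)
        segs.append(
            make_segment(str(a), str(b), chrom=str(rng.integers(1, 4)),
                         start_cm=float(np.round(rng.uniform(0, 50), 2)),
                         length_cm=float(np.round(rng.uniform(1, 20), 2)),
                         hap_a=int(rng.integers(1, 3)), hap_b=int(rng.integers(1, 3)))
        )
    return panel, segs


def brute_L_within(segments, panel: PopulationPanel, group: str):
    """L(X), N(X) by explicit enumeration of all unordered member pairs."""
    members = panel.members(group)
    n = len(members)
    if n < 2:
        return math.nan, math.nan
    total_cm = 0.0
    total_n = 0
    for a, b in combinations(members, 2):
        for s in segments:
            if s.sample_a == s.sample_b:
                continue
            if {s.sample_a, s.sample_b} == {a, b}:
                total_cm += s.length_cm
                total_n += 1
    pairs = n * (n - 1) / 2
    return total_cm / pairs, total_n / pairs


def brute_L_between(segments, panel: PopulationPanel, gx: str, gy: str):
    mx, my = panel.members(gx), panel.members(gy)
    total_cm = 0.0
    total_n = 0
    for a in mx:
        for b in my:
            for s in segments:
                if {s.sample_a, s.sample_b} == {a, b}:
                    total_cm += s.length_cm
                    total_n += 1
    pairs = len(mx) * len(my)
    return total_cm / pairs, total_n / pairs


def brute_S(segments, panel: PopulationPanel, gx: str, gy: str) -> float:
    lx, _ = brute_L_within(segments, panel, gx)
    ly, _ = brute_L_within(segments, panel, gy)
    lxy, _ = brute_L_between(segments, panel, gx, gy)
    if math.isnan(lx) or math.isnan(ly) or lx + ly == 0:
        return math.nan
    return 2 * lxy / (lx + ly)


def grid_ancestry_lengths(
    segment: IbdSegment,
    tracts: AncestryTractSet,
    gmap: GeneticMap,
    step_bp: int = 10_000,
) -> dict[str, float]:
    """Total cM per shared confident ancestry label, by sampling a fine bp
    grid across the segment (step of 10 kb = 0.01 cM on a 1 cM/Mb map).

    Each grid cell is labelled by the tract containing its midpoint on each
    haplotype; cells where both haplotypes agree on a confident label
    accumulate their cM width under that label.
    """

    def label(ind, hap, bp):
        for t in tracts.tracts_for(ind, hap, segment.chrom):
            if t.start_bp <= bp <= t.end_bp:
                return t.ancestry
        return "UNKNOWN"

    scale = segment.length_cm / (
        float(gmap.interpolate(segment.chrom, segment.end_bp))
        - float(gmap.interpolate(segment.chrom, segment.start_bp))
    )
    out: dict[str, float] = {}
    bp = segment.start_bp
    while bp <= segment.end_bp:
        hi = min(bp + step_bp - 1, segment.end_bp)
        mid = (bp + hi) // 2
        la = label(segment.sample_a, segment.hap_a, mid)
        lb = label(segment.sample_b, segment.hap_b, mid)
        if la == lb and la != "UNKNOWN":
            width_cm = (
                float(gmap.interpolate(segment.chrom, hi))
                - float(gmap.interpolate(segment.chrom, bp))
            ) * scale
            out[la] = out.get(la, 0.0) + width_cm
        bp = hi + 1
    return out
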