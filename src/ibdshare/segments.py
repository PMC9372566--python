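"""Interval algebra on IBD segments.

Gap merging (with an optional genotype-consistency check), length binning,
within-group demography summaries and partitioning of segments into
ancestry-specific subsegments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    UNKNOWN,
    AncestryTractSet,
    GeneticMap,
    IbdSegment,
    PhasedGenotypes,
    PopulationPanel,
)

logger = logging.getLogger(__name__)

DEFAULT_MERGE_GAP_CM = 0.6
DEFAULT_MAX_DISCORDANT = 1
DEFAULT_MIN_SUB_CM = 1.0
DEFAULT_WITHIN_MIN_CM = 2.0


# ---------------------------------------------------------------------------
# Length bins
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthBins:
    """Half-open cM length bins [e_i, e_{i+1}), last bin open-ended.

    ``time_labels`` are optional per-bin annotations (e.g. approximate kya of
    the shared ancestor); they are metadata only and never computed from.
    """

    edges: tuple[float, ...]
    time_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError(f"bin edges must be strictly increasing, got {edges}")
        object.__setattr__(self, "edges", edges)
        if self.time_labels is not None and len(self.time_labels) != len(edges):
            raise ValueError("need one time label per bin")

    @property
    def intervals(self) -> list[tuple[float, float]]:
        uppers = list(self.edges[1:]) + [math.inf]
        return list(zip(self.edges, uppers))

    @property
    def labels(self) -> list[str]:
        out = []
        for low, high in self.intervals:
            out.append(f"{low:g}-{high:g}cM" if math.isfinite(high) else f">{low:g}cM")
        return out

    def assign(self, length_cm: float) -> str | None:
        """Bin label for a length, or None if below the first edge."""
        if length_cm < self.edges[0]:
            return None
        idx = int(np.searchsorted(self.edges, length_cm, side="right")) - 1
        return self.labels[idx]


#: the network / time-slice bins: 1-5, 5-10, >10 cM
NETWORK_BINS = LengthBins((1.0, 5.0, 10.0), ("~2.7 kya", "~0.675 kya", "~0.225 kya"))

#: finer series for the relative-similarity-vs-length analysis; the kya
#: strings are cited annotations and the edges are configuration, not a
#: published table.
R_SERIES_BINS = LengthBins(
    (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 10.0),
    ("~2.7 kya", "~1.5 kya", "~1.1 kya", "~0.8 kya", "~0.7 kya", "~0.6 kya", "~0.2 kya"),
)


def bin_segments(
    segments: Iterable[IbdSegment], bins: LengthBins
) -> dict[str, list[IbdSegment]]:
    """Assign each segment to its length bin; segments below the first edge
    are dropped (a count is logged)."""
    out: dict[str, list[IbdSegment]] = {label: [] for label in bins.labels}
    dropped = 0
    for seg in segments:
        label = bins.assign(seg.length_cm)
        if label is None:
            dropped += 1
        else:
            out[label].append(seg)
    if dropped:
        logger.info("bin_segments: dropped %d segments below %.3g cM", dropped, bins.edges[0])
    return out


# ---------------------------------------------------------------------------
# Gap merging
# ---------------------------------------------------------------------------


def merge_segments(
    segments: Iterable[IbdSegment],
    gap_cm: float = DEFAULT_MERGE_GAP_CM,
    genotypes: PhasedGenotypes | None = None,
    max_discordant: int = DEFAULT_MAX_DISCORDANT,
) -> list[IbdSegment]:
    """Merge consecutive segments of one haplotype pair separated by small gaps.

    Two consecutive segments of the same (haplotype pair, chromosome) stream
    merge when their genetic gap is strictly less than ``gap_cm`` (the
    refinedIBD post-processing convention: a 0.6 cM threshold merges a
    0.599 cM gap but not a 0.600 cM one). When ``genotypes`` is supplied the
    merge additionally requires that the two haplotypes disagree at no more
    than ``max_discordant`` sites across the union of both blocks and the
    gap. Merging is applied transitively left-to-right; the merged LOD is the
    maximum of the parts. Input order and grouping are arbitrary.
    """
    if gap_cm < 0:
        raise ValueError("gap_cm must be >= 0")
    groups: dict[tuple, list[IbdSegment]] = {}
    for seg in segments:
        groups.setdefault(seg.canonical().pair_key(), []).append(seg.canonical())

    merged: list[IbdSegment] = []
    for key in sorted(groups):
        stream = sorted(groups[key], key=lambda s: (s.start_cm, s.end_cm))
        current = stream[0]
        for nxt in stream[1:]:
            gap = nxt.start_cm - current.end_cm
            if gap < gap_cm and _merge_allowed(current, nxt, genotypes, max_discordant):
                current = _join(current, nxt)
            else:
                merged.append(current)
                current = nxt
        merged.append(current)
    merged.sort(key=lambda s: (s.chrom, s.sample_a, s.hap_a, s.sample_b, s.hap_b, s.start_cm))
    return merged


def _merge_allowed(
    a: IbdSegment, b: IbdSegment, genotypes: PhasedGenotypes | None, max_discordant: int
) -> bool:
    if genotypes is None:
        return True
    n_bad = genotypes.count_discordant(
        a.chrom,
        min(a.start_bp, b.start_bp),
        max(a.end_bp, b.end_bp),
        a.sample_a, a.hap_a, a.sample_b, a.hap_b,
    )
    return n_bad <= max_discordant


def _join(a: IbdSegment, b: IbdSegment) -> IbdSegment:
    start_cm = min(a.start_cm, b.start_cm)
    end_cm = max(a.end_cm, b.end_cm)
    return replace(
        a,
        start_bp=min(a.start_bp, b.start_bp),
        end_bp=max(a.end_bp, b.end_bp),
        start_cm=start_cm,
        end_cm=end_cm,
        length_cm=end_cm - start_cm,
        lod=max(a.lod, b.lod),
    )


# ---------------------------------------------------------------------------
# Within-group demography summary
# ---------------------------------------------------------------------------


def within_group_ibd_summary(
    segments: Iterable[IbdSegment],
    panel: PopulationPanel,
    min_cm: float = DEFAULT_WITHIN_MIN_CM,
) -> tuple[pd.DataFrame, pd.Series]:
    """Within-group sharing of blocks >= ``min_cm`` plus per-individual ROH.

    Returns ``(per_group, roh)``: ``per_group`` has columns ``mean_sum_cm``
    (the mean per-pair summed length L), ``mean_count`` (the count analogue N)
    and ``n``; groups of size < 2 get NaN statistics. ``roh`` is the summed
    HBD length per individual (runs of homozygosity), also filtered at
    ``min_cm``.
    """
    from .sharing import mean_within  # local import to avoid a cycle

    segs = [s for s in segments if s.length_cm >= min_cm]
    ibd = [s for s in segs if not s.is_hbd]
    hbd = [s for s in segs if s.is_hbd]

    rows = []
    for group in panel.group_names:
        n = panel.n(group)
        if n < 2:
            rows.append((group, np.nan, np.nan, n))
            continue
        L, N = mean_within(ibd, panel, group)
        rows.append((group, L, N, n))
    per_group = pd.DataFrame(rows, columns=["group", "mean_sum_cm", "mean_count", "n"])
    per_group = per_group.set_index("group")

    roh = pd.Series(0.0, index=panel.individuals.index, name="roh_cm")
    for s in hbd:
        roh[s.sample_a] += s.length_cm
    return per_group, roh


# ---------------------------------------------------------------------------
# Ancestry-specific partition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncestrySubsegment:
    """A maximal sub-interval of an IBD segment on which both haplotypes carry
    the same confident ancestry label."""

    parent: IbdSegment
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    ancestry: str

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    def to_segment(self) -> IbdSegment:
        """The subsegment as a standalone IBD segment (for re-binning and
        ancestry-specific sharing networks)."""
        return replace(
            self.parent,
            start_bp=self.start_bp,
            end_bp=self.end_bp,
            start_cm=self.start_cm,
            end_cm=self.end_cm,
            length_cm=self.end_cm - self.start_cm,
        )


def ancestry_partition(
    segment: IbdSegment,
    tracts: AncestryTractSet,
    gmap: GeneticMap,
    min_sub_cm: float = DEFAULT_MIN_SUB_CM,
) -> list[AncestrySubsegment]:
    """Split an IBD segment into ancestry-specific subsegments.

    The segment interval is intersected with the confident (non-UNKNOWN)
    local-ancestry tracts of BOTH involved haplotypes; maximal sub-intervals
    where the two haplotypes carry the SAME label are emitted with that
    label. Stretches where the labels differ, either haplotype is UNKNOWN, or
    tract coverage is missing are discarded, as are subsegments shorter than
    ``min_sub_cm``. Genetic lengths of subsegments are scaled so that a fully
    and identically labelled parent yields exactly its own length back.
    """
    hap_a_tracts = tracts.confident_tracts(
        segment.sample_a, segment.hap_a, segment.chrom, segment.start_bp, segment.end_bp
    )
    hap_b_tracts = tracts.confident_tracts(
        segment.sample_b, segment.hap_b, segment.chrom, segment.start_bp, segment.end_bp
    )
    if not hap_a_tracts or not hap_b_tracts:
        return []

    # elementary intervals between all tract/segment breakpoints
    points = {segment.start_bp, segment.end_bp + 1}
    for s, e, _ in hap_a_tracts + hap_b_tracts:
        points.add(s)
        points.add(e + 1)
    cuts = sorted(p for p in points if segment.start_bp <= p <= segment.end_bp + 1)

    def label_at(tr: list[tuple[int, int, str]], lo: int, hi: int) -> str:
        for s, e, lab in tr:
            if s <= lo and hi <= e:
                return lab
        return UNKNOWN

    pieces: list[tuple[int, int, str]] = []  # inclusive bp intervals
    for lo, nxt in zip(cuts, cuts[1:]):
        hi = nxt - 1
        la = label_at(hap_a_tracts, lo, hi)
        lb = label_at(hap_b_tracts, lo, hi)
        if la == lb and la != UNKNOWN:
            if pieces and pieces[-1][2] == la and pieces[-1][1] == lo - 1:
                pieces[-1] = (pieces[-1][0], hi, la)  # coalesce adjacent
            else:
                pieces.append((lo, hi, la))

    scale = _cm_rescale_factor(segment, gmap)
    out: list[AncestrySubsegment] = []
    for lo, hi, lab in pieces:
        cm_lo = float(gmap.interpolate(segment.chrom, lo))
        cm_hi = float(gmap.interpolate(segment.chrom, hi))
        start_cm = segment.start_cm + (cm_lo - float(gmap.interpolate(segment.chrom, segment.start_bp))) * scale
        end_cm = segment.start_cm + (cm_hi - float(gmap.interpolate(segment.chrom, segment.start_bp))) * scale
        sub = AncestrySubsegment(segment, lo, hi, start_cm, end_cm, lab)
        if sub.length_cm >= min_sub_cm:
            out.append(sub)
    return out


def _cm_rescale_factor(segment: IbdSegment, gmap: GeneticMap) -> float:
    """Ratio between the segment's authoritative printed length and its
    map-derived length, so subsegment lengths stay conserved within the
    parent."""
    map_len = float(gmap.interpolate(segment.chrom, segment.end_bp)) - float(
        gmap.interpolate(segment.chrom, segment.start_bp)
    )
    if map_len <= 0:
        return 0.0
    return segment.length_cm / map_len


def partition_all(
    segments: Iterable[IbdSegment],
    tracts: AncestryTractSet,
    gmap: GeneticMap,
    min_sub_cm: float = DEFAULT_MIN_SUB_CM,
) -> dict[str, list[IbdSegment]]:
    """Ancestry-specific segment sets, keyed by ancestry label.

    Subsegments are converted to standalone segments and are later binned by
    their OWN cM length.
    """
    out: dict[str, list[IbdSegment]] = {}
    for seg in segments:
        for sub in ancestry_partition(seg, tracts, gmap, min_sub_cm):
            out.setdefault(sub.ancestry, []).append(sub.to_segment())
    return out


def write_subsegments(subsegments: Iterable[AncestrySubsegment], path) -> None:
    """9-column dialect plus a trailing ancestry column."""
    with open(path, "w") as fh:
        for sub in subsegments:
            p = sub.parent
            fh.write(
                f"{p.sample_a}\t{p.hap_a}\t{p.sample_b}\t{p.hap_b}\t{p.chrom}\t"
                f"{sub.start_bp}\t{sub.end_bp}\t{p.lod:g}\t{sub.length_cm:g}\t{sub.ancestry}\n"
            )
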