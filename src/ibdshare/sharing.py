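"""Group-level IBD sharing statistics.

The central quantities are the per-pair averages

    L(X)   = 2 / (n (n - 1)) * sum_{i < j} ibd(X_i, X_j)
    L(X,Y) = 1 / (n m)       * sum_{i, j}  ibd(X_i, Y_j)

(the mean summed IBD length over within- and between-group individual pairs;
the count analogue N replaces summed length with block count) and the
FST-motivated similarity statistic

    S(X,Y) = 2 L(X,Y) / (L(X) + L(Y))

which is 0 with no between-group sharing and 1 when sharing is independent
of population structure (L(X) = L(Y) = L(X,Y)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import IbdSegment, PopulationPanel, segments_to_frame

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
DEFAULT_MIN_MEAN_COUNT = 0.5


# ---------------------------------------------------------------------------
# Pair aggregation
# ---------------------------------------------------------------------------


def aggregate_pair_sharing(
    segments: Iterable[IbdSegment] | pd.DataFrame,
    panel: PopulationPanel,
    by_chrom: bool = False,
) -> pd.DataFrame:
    """Summed length and count of segments per unordered group pair.

    HBD segments are aggregated onto a separate ``is_hbd`` stratum so callers
    can include or exclude them. With ``by_chrom`` the aggregation is also
    split by chromosome (the basis of the exact chromosome jackknife, since L
    and N are additive over chromosomes).
    """
    df = segments if isinstance(segments, pd.DataFrame) else segments_to_frame(segments)
    if df.empty:
        cols = ["group_a", "group_b", "is_hbd"] + (["chrom"] if by_chrom else [])
        return pd.DataFrame(columns=cols + ["sum_cm", "count"])
    unknown = set(df["sample_a"]) | set(df["sample_b"])
    unknown -= set(panel.individuals.index)
    if unknown:
        raise KeyError(
            f"segment individuals absent from panel: {sorted(unknown)}"
        )
    group_of = panel.group_of()
    ga = df["sample_a"].map(group_of)
    gb = df["sample_b"].map(group_of)
    lo = np.minimum(ga, gb)
    hi = np.maximum(ga, gb)
    work = pd.DataFrame(
        {"group_a": lo, "group_b": hi, "is_hbd": df["is_hbd"], "length_cm": df["length_cm"]}
    )
    keys = ["group_a", "group_b", "is_hbd"]
    if by_chrom:
        work["chrom"] = df["chrom"]
        keys.append("chrom")
    agg = (
        work.groupby(keys, as_index=False)["length_cm"]
        .agg(sum_cm="sum", count="size")
    )
    return agg


# ---------------------------------------------------------------------------
# SharingMatrix
# ---------------------------------------------------------------------------


@dataclass
class SharingMatrix:
    """Symmetric group x group matrices of mean summed length L (cM) and mean
    block count N (blocks per pair); the diagonal holds within-group values.

    Within-group entries are NaN for groups of size < 2 (undefined). By
    default HBD blocks are excluded; ``include_hbd=True`` adds each
    individual's within-individual haplotype pair as one extra pair on the
    diagonal (a pairwise-shared-coalescence-style sensitivity analysis).
    """

    L: pd.DataFrame
    N: pd.DataFrame
    include_hbd: bool = False
    bin_label: str | None = None

    @classmethod
    def from_segments(
        cls,
        segments: Iterable[IbdSegment] | pd.DataFrame,
        panel: PopulationPanel,
        include_hbd: bool = False,
        bin_label: str | None = None,
    ) -> "SharingMatrix":
        agg = aggregate_pair_sharing(segments, panel)
        return cls.from_aggregate(agg, panel, include_hbd=include_hbd, bin_label=bin_label)

    @classmethod
    def from_aggregate(
        cls,
        agg: pd.DataFrame,
        panel: PopulationPanel,
        include_hbd: bool = False,
        bin_label: str | None = None,
        exclude_chrom: str | None = None,
    ) -> "SharingMatrix":
        """Build matrices from an :func:`aggregate_pair_sharing` table,
        optionally leaving one chromosome out (requires ``by_chrom``
        aggregation)."""
        groups = panel.group_names
        idx = {g: i for i, g in enumerate(groups)}
        sizes = panel.sizes().to_numpy(dtype=float)
        work = agg
        if exclude_chrom is not None:
            if "chrom" not in work.columns:
                raise ValueError("exclude_chrom requires a by-chromosome aggregate")
            work = work[work["chrom"] != str(exclude_chrom)]
        if not include_hbd and not work.empty:
            work = work[~work["is_hbd"]]
        G = len(groups)
        sum_cm = np.zeros((G, G))
        count = np.zeros((G, G))
        if not work.empty:
            summed = work.groupby(["group_a", "group_b"], as_index=False)[["sum_cm", "count"]].sum()
            ia = summed["group_a"].map(idx).to_numpy()
            ib = summed["group_b"].map(idx).to_numpy()
            np.add.at(sum_cm, (ia, ib), summed["sum_cm"].to_numpy())
            np.add.at(count, (ia, ib), summed["count"].to_numpy())
            # each unordered pair appears once; mirror off-diagonal entries
            d_sum, d_cnt = np.diag(sum_cm).copy(), np.diag(count).copy()
            sum_cm = sum_cm + sum_cm.T
            count = count + count.T
            np.fill_diagonal(sum_cm, d_sum)
            np.fill_diagonal(count, d_cnt)
        # pair counts: n*m off-diagonal, n(n-1)/2 (+ n self-pairs with HBD) on it
        pairs = np.outer(sizes, sizes)
        diag_pairs = sizes * (sizes - 1) / 2 + (sizes if include_hbd else 0)
        np.fill_diagonal(pairs, diag_pairs)
        with np.errstate(invalid="ignore", divide="ignore"):
            L_arr = np.where(pairs > 0, sum_cm / np.where(pairs > 0, pairs, 1), np.nan)
            N_arr = np.where(pairs > 0, count / np.where(pairs > 0, pairs, 1), np.nan)
        L = pd.DataFrame(L_arr, index=groups, columns=groups)
        N = pd.DataFrame(N_arr, index=groups, columns=groups)
        return cls(L=L, N=N, include_hbd=include_hbd, bin_label=bin_label)

    @property
    def groups(self) -> list[str]:
        return list(self.L.index)


def mean_within(
    segments: Iterable[IbdSegment], panel: PopulationPanel, group: str
) -> tuple[float, float]:
    """L(X) and N(X): mean per-pair summed length and count within a group.

    Undefined (NaN) for groups of fewer than two individuals. HBD segments
    are ignored (the sums run over distinct-individual pairs).
    """
    n = panel.n(group)
    if n < 2:
        return (math.nan, math.nan)
    members = set(panel.members(group))
    total_cm = 0.0
    count = 0
    for s in segments:
        if s.is_hbd:
            continue
        if s.sample_a in members and s.sample_b in members:
            total_cm += s.length_cm
            count += 1
    pairs = n * (n - 1) / 2
    return total_cm / pairs, count / pairs


def mean_between(
    segments: Iterable[IbdSegment], panel: PopulationPanel, group_x: str, group_y: str
) -> tuple[float, float]:
    """L(X,Y) and N(X,Y): mean per-pair summed length and count between two
    groups (symmetric in X and Y)."""
    if group_x == group_y:
        raise ValueError("mean_between requires two distinct groups")
    mx, my = set(panel.members(group_x)), set(panel.members(group_y))
    total_cm = 0.0
    count = 0
    for s in segments:
        if (s.sample_a in mx and s.sample_b in my) or (s.sample_a in my and s.sample_b in mx):
            total_cm += s.length_cm
            count += 1
    pairs = len(mx) * len(my)
    return total_cm / pairs, count / pairs


# ---------------------------------------------------------------------------
# Similarity S
# ---------------------------------------------------------------------------


@dataclass
class SimilarityResult:
    """Pairwise similarity matrix S for one segment set / length bin.

    The diagonal is 1 by convention and is excluded from all averages.
    S is NaN (undefined, not zero) wherever L(X) + L(Y) is zero or either
    within-group L is itself undefined.
    """

    S: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_sharing(cls, sharing: SharingMatrix, **provenance) -> "SimilarityResult":
        groups = sharing.groups
        L = sharing.L.to_numpy(dtype=float)
        diag = np.diag(L)
        denom = diag[:, None] + diag[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            S_arr = np.where(denom > 0, 2.0 * L / np.where(denom > 0, denom, 1.0), np.nan)
        np.fill_diagonal(S_arr, 1.0)  # S(X, X) = 1 by convention
        S = pd.DataFrame(S_arr, index=groups, columns=groups)
        prov = dict(provenance)
        prov.setdefault("bin", sharing.bin_label)
        prov.setdefault("include_hbd", sharing.include_hbd)
        return cls(S=S, provenance=prov)

    def mean_over_pairs(self, groups: Sequence[str]) -> float:
        """Mean S over unordered distinct pairs of ``groups``; NaN entries are
        excluded from the mean (missing propagates as missing, not zero)."""
        ids = [self.S.index.get_loc(g) for g in sorted(set(groups))]
        sub = self.S.to_numpy()[np.ix_(ids, ids)]
        vals = sub[np.triu_indices(len(ids), 1)]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            return math.nan
        return float(np.mean(vals))


def similarity_S(sharing: SharingMatrix, X: str, Y: str) -> float:
    """S(X,Y) = 2 L(X,Y) / (L(X) + L(Y)); NaN when the denominator is zero or
    either within-group mean is undefined."""
    lx = sharing.L.loc[X, X]
    ly = sharing.L.loc[Y, Y]
    lxy = sharing.L.loc[X, Y]
    if pd.isna(lx) or pd.isna(ly):
        return math.nan
    denom = lx + ly
    if denom == 0:
        return math.nan
    return float(2.0 * lxy / denom)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def network_edges(
    sharing: SharingMatrix,
    min_mean_count: float = DEFAULT_MIN_MEAN_COUNT,
    include_loops: bool = False,
) -> pd.DataFrame:
    """Edge list of group pairs whose mean block count passes the noise filter.

    Pairs with N(X,Y) >= ``min_mean_count`` (default 0.5: on average at least
    half of the individual pairs share a block) are retained; the edge weight
    is the mean summed length L(X,Y).
    """
    rows = []
    groups = sharing.groups
    for i, X in enumerate(groups):
        for Y in groups[i:]:
            if X == Y and not include_loops:
                continue
            n_val = sharing.N.loc[X, Y]
            if pd.isna(n_val) or n_val < min_mean_count:
                continue
            rows.append((X, Y, sharing.bin_label, float(n_val), float(sharing.L.loc[X, Y])))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "bin", "mean_count", "mean_sum_cm"])


def edges_to_graph(edges: pd.DataFrame):
    """The edge list as a weighted :class:`networkx.Graph` (weight = mean
    summed length)."""
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["group_a"], row["group_b"],
                   weight=row["mean_sum_cm"], mean_count=row["mean_count"])
    return g


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a 6371 km sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def pair_class(panel: PopulationPanel, X: str, Y: str) -> str:
    kx = panel.groups.loc[X, "kula"]
    ky = panel.groups.loc[Y, "kula"]
    if "outside_massim" in (kx, ky):
        return "outside"
    if kx == ky == "kula":
        return "kula-kula"
    if kx == ky == "non_kula":
        return "non_kula-non_kula"
    return "mixed"


def distance_table(sim: SimilarityResult, panel: PopulationPanel) -> pd.DataFrame:
    """Great-circle distance vs. similarity for every group pair with known
    coordinates; pairs missing coordinates are omitted (and logged)."""
    rows = []
    skipped = 0
    for X, Y in combinations(sim.S.index, 2):
        cx, cy = panel.coordinates(X), panel.coordinates(Y)
        if cx is None or cy is None:
            skipped += 1
            continue
        rows.append(
            (X, Y, haversine_km(*cx, *cy), float(sim.S.loc[X, Y]), pair_class(panel, X, Y))
        )
    if skipped:
        logger.info("distance_table: omitted %d pairs lacking coordinates", skipped)
    return pd.DataFrame(rows, columns=["group_a", "group_b", "distance_km", "S", "pair_class"])


def sharing_by_bin(
    segments: Iterable[IbdSegment],
    panel: PopulationPanel,
    bins,
    include_hbd: bool = False,
) -> dict[str, SharingMatrix]:
    """One SharingMatrix per length bin."""
    from .segments import bin_segments

    binned = bin_segments(segments, bins)
    return {
        label: SharingMatrix.from_segments(segs, panel, include_hbd=include_hbd, bin_label=label)
        for label, segs in binned.items()
    }
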