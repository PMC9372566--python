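"""Relative IBD similarity for culturally defined group sets.

The relative similarity statistic

    R = (S_within - S_all) / (1 - S_all)

measures the excess of the mean pairwise similarity among a focal set of
groups (e.g. the Kula-practicing groups of the Massim) over the mean across
all groups in the analysis universe (here, all Oceanian groups). R is zero
when focal sharing matches the background and grows with shared migration
among the focal groups.

Uncertainty comes from a delete-one-chromosome jackknife: L and N are
additive over chromosomes, so each replicate recomputes the full
L -> S -> R pipeline exactly on the segments of the remaining chromosomes.
Significance of the Kula-vs-non-Kula difference comes from permuting the
kula / non_kula labels across Massim groups while keeping class sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import IbdSegment, PopulationPanel, segments_to_frame
from .segments import LengthBins
from .sharing import SharingMatrix, SimilarityResult, aggregate_pair_sharing


def relative_R(
    sim: SimilarityResult,
    focal: Sequence[str],
    universe: Sequence[str] | None = None,
) -> float:
    """R = (S_within - S_all) / (1 - S_all).

    ``S_within`` is the mean S over unordered pairs of ``focal`` groups and
    ``S_all`` the mean over all unordered pairs of ``universe`` (defaulting
    to every group in the matrix, focal pairs included). Missing S values are
    excluded from both means. Raises when S_all >= 1 (non-positive
    denominator); returns NaN when no focal pair has a defined S.
    """
    universe = list(sim.S.index) if universe is None else list(universe)
    focal = list(focal)
    if not set(focal) <= set(universe):
        raise ValueError("focal groups must be a subset of the universe")
    if len(focal) < 2:
        raise ValueError("need at least two focal groups")
    s_within = sim.mean_over_pairs(focal)
    s_all = sim.mean_over_pairs(universe)
    if math.isnan(s_within) or math.isnan(s_all):
        return math.nan
    if s_all >= 1.0:
        raise ValueError(f"S_all = {s_all:.4f} >= 1: relative similarity undefined")
    return (s_within - s_all) / (1.0 - s_all)


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------


@dataclass
class JackknifeR:
    """Full-data R with its delete-one-chromosome jackknife standard error."""

    r: float
    se: float
    replicates: pd.Series  # index: left-out chromosome

    @property
    def band_3se(self) -> tuple[float, float]:
        return (self.r - 3 * self.se, self.r + 3 * self.se)


def jackknife_se(replicates: np.ndarray) -> float:
    """Delete-one jackknife SE: sqrt((C-1)/C * sum (r_c - mean)^2)."""
    reps = np.asarray(replicates, dtype=float)
    reps = reps[~np.isnan(reps)]
    c = len(reps)
    if c < 2:
        return math.nan
    mean = reps.mean()
    return math.sqrt((c - 1) / c * np.sum((reps - mean) ** 2))


def jackknife_R(
    segments: Iterable[IbdSegment] | pd.DataFrame,
    panel: PopulationPanel,
    bins: LengthBins,
    focal: Sequence[str],
    universe: Sequence[str] | None = None,
    include_hbd: bool = False,
) -> dict[str, JackknifeR]:
    """Per-bin R with chromosome-jackknife SE.

    Replicates are exact: per-pair sums are aggregated per chromosome once,
    and each leave-one-out replicate rebuilds L, S and R from the remaining
    chromosomes' sums (additivity of L over chromosomes).
    """
    df = segments if isinstance(segments, pd.DataFrame) else segments_to_frame(segments)
    out: dict[str, JackknifeR] = {}
    for label, agg, chroms in _binned_aggregates(df, panel, bins):
        full = _r_from_aggregate(agg, panel, focal, universe, include_hbd)
        reps = pd.Series(
            {c: _r_from_aggregate(agg, panel, focal, universe, include_hbd, exclude_chrom=c)
             for c in chroms},
            dtype=float,
        )
        se = jackknife_se(reps.to_numpy()) if len(chroms) >= 2 else math.nan
        out[label] = JackknifeR(r=full, se=se, replicates=reps)
    return out


def _binned_aggregates(df: pd.DataFrame, panel: PopulationPanel, bins: LengthBins):
    chroms = sorted(df["chrom"].unique()) if not df.empty else []
    for label, (low, high) in zip(bins.labels, bins.intervals):
        mask = (df["length_cm"] >= low) & (df["length_cm"] < high) if not df.empty else None
        sub = df[mask] if mask is not None else df
        agg = aggregate_pair_sharing(sub, panel, by_chrom=True)
        yield label, agg, chroms


def _r_from_aggregate(
    agg: pd.DataFrame,
    panel: PopulationPanel,
    focal: Sequence[str],
    universe: Sequence[str] | None,
    include_hbd: bool,
    exclude_chrom: str | None = None,
) -> float:
    sharing = SharingMatrix.from_aggregate(
        agg, panel, include_hbd=include_hbd, exclude_chrom=exclude_chrom
    )
    sim = SimilarityResult.from_sharing(sharing)
    try:
        return relative_R(sim, focal, universe)
    except ValueError:
        return math.nan


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def _triu_mean(s: np.ndarray, ids: Sequence[int]) -> float:
    """NaN-aware mean of S over unordered distinct pairs of the given rows."""
    sub = s[np.ix_(ids, ids)]
    iu = np.triu_indices(len(ids), 1)
    vals = sub[iu]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if len(vals) else math.nan


@dataclass
class PermutationOutcome:
    """Observed Kula-minus-non-Kula difference in R with its permutation null.

    ``p_values`` use the add-one estimator
    p = (1 + #{dR_perm >= dR_obs}) / (1 + n_perm), one-sided for the
    directional hypothesis that Kula groups share more.
    """

    observed: pd.Series  # per bin: dR = R_kula - R_non_kula
    replicates: pd.DataFrame  # n_perm x bins
    p_values: pd.Series
    n_perm: int
    seed: int | None


def permutation_test(
    segments: Iterable[IbdSegment] | pd.DataFrame,
    panel: PopulationPanel,
    bins: LengthBins,
    n_perm: int = 999,
    seed: int | None = None,
    universe: Sequence[str] | None = None,
    include_hbd: bool = False,
) -> PermutationOutcome:
    """Permutation test for excess sharing among Kula-practicing groups.

    Each replicate randomly reassigns the kula / non_kula labels across the
    Massim groups (class sizes preserved) and recomputes
    dR = R_kula - R_non_kula per length bin from the unchanged S matrix.
    """
    massim = panel.massim_groups
    kula = panel.kula_groups
    non_kula = panel.non_kula_groups
    if not kula or not non_kula:
        raise ValueError("permutation test needs both kula and non_kula Massim groups")
    if len(kula) < 2 or len(non_kula) < 2:
        raise ValueError("need at least two groups per Kula class to average pairwise S")

    df = segments if isinstance(segments, pd.DataFrame) else segments_to_frame(segments)
    sims = {}
    for label, agg, _ in _binned_aggregates(df, panel, bins):
        sharing = SharingMatrix.from_aggregate(agg, panel, include_hbd=include_hbd)
        sims[label] = SimilarityResult.from_sharing(sharing)

    # numpy fast path: dR = (S_kula_mean - S_nonkula_mean) / (1 - S_all),
    # with S_all fixed across label permutations.
    group_index = {g: i for label in sims for i, g in enumerate(sims[label].S.index)}
    s_arrays = {label: sim.S.to_numpy() for label, sim in sims.items()}
    universe_groups = list(next(iter(sims.values())).S.index) if universe is None else list(universe)
    s_all = {
        label: _triu_mean(s_arrays[label], [group_index[g] for g in universe_groups])
        for label in sims
    }

    def delta(k: Sequence[str], nk: Sequence[str]) -> pd.Series:
        vals = {}
        ik = [group_index[g] for g in k]
        ink = [group_index[g] for g in nk]
        for label in sims:
            denom = 1.0 - s_all[label]
            if math.isnan(s_all[label]) or denom <= 0:
                vals[label] = math.nan
                continue
            sk = _triu_mean(s_arrays[label], ik)
            snk = _triu_mean(s_arrays[label], ink)
            vals[label] = (sk - snk) / denom
        return pd.Series(vals)

    observed = delta(kula, non_kula)
    rng = np.random.default_rng(seed)
    massim_arr = np.array(massim)
    k = len(kula)
    reps = []
    for _ in range(n_perm):
        perm = rng.permutation(massim_arr)
        reps.append(delta(list(perm[:k]), list(perm[k:])))
    replicates = pd.DataFrame(reps).reset_index(drop=True)

    p_values = {}
    for label in observed.index:
        obs = observed[label]
        if math.isnan(obs):
            p_values[label] = math.nan
            continue
        rep = replicates[label].to_numpy()
        rep = rep[~np.isnan(rep)]
        p_values[label] = (1 + int(np.sum(rep >= obs))) / (1 + len(rep))
    return PermutationOutcome(
        observed=observed,
        replicates=replicates,
        p_values=pd.Series(p_values),
        n_perm=n_perm,
        seed=seed,
    )
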