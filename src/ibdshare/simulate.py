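"""Synthetic IBD datasets with known planted structure.

Sharing is simulated directly at the segment level: for every individual
pair and length era, the number of shared blocks is Poisson with a rate
determined by the pair's group relationship (same group, same region,
background) and an optional multiplicative Kula excess on pairs of
Kula-practicing groups; block lengths are exponential above a 1 cM floor
(matching the smallest analysis bin edge). Local-ancestry tracts are
two-state (Austronesian / Papuan) Markov mosaics per haplotype with a given
stationary AN fraction and switch rate. This exercises every downstream
formula without coalescent genotype simulation and keeps tests fast; a hook
for ingesting externally simulated segments is simply
:func:`ibdshare.io.read_ibd_segments`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    AncestryTract,
    AncestryTractSet,
    GeneticMap,
    IbdSegment,
    PopulationPanel,
    write_ibd_segments,
)

#: approximate sex-averaged human autosome lengths (cM)
HUMAN_AUTOSOME_CM = {
    "1": 286.0, "2": 269.0, "3": 223.0, "4": 214.0, "5": 204.0, "6": 192.0,
    "7": 187.0, "8": 168.0, "9": 166.0, "10": 181.0, "11": 158.0, "12": 174.0,
    "13": 125.0, "14": 120.0, "15": 141.0, "16": 134.0, "17": 128.0, "18": 117.0,
    "19": 107.0, "20": 108.0, "21": 62.0, "22": 74.0,
}

LENGTH_FLOOR_CM = 1.0


@dataclass
class GroupSpec:
    name: str
    size: int
    region: str
    massim_subregion: str | None = None
    kula: str = "outside_massim"
    lat: float | None = None
    lon: float | None = None
    an_proportion: float = 0.5
    hbd_rate: float = 0.3  # expected HBD blocks per individual per era

    def __post_init__(self):
        if not 0.0 <= self.an_proportion <= 1.0:
            raise ValueError(f"{self.name}: an_proportion must be in [0, 1]")
        if self.hbd_rate < 0 or self.size < 1:
            raise ValueError(f"{self.name}: negative rate or empty group")


@dataclass
class EraSpec:
    """One length era: mean (above-floor) exponential block length and the
    Poisson sharing rates per pair."""

    name: str
    mean_cm: float  # mean of the exponential part; block length = 1 cM + Exp(mean_cm)
    rate_within: float  # blocks per within-group pair
    rate_between: float  # blocks per cross-group pair (before multipliers)

    def __post_init__(self):
        if min(self.mean_cm, self.rate_within, self.rate_between) < 0:
            raise ValueError(f"era {self.name}: rates and means must be >= 0")


@dataclass
class SimScenario:
    """Full specification of a synthetic study; the seed fully determines
    the dataset.

    ``region_multiplier`` scales cross-group rates for pairs of groups in
    the same region (e.g. Massim-Massim contact); ``kula_boost`` additionally
    scales pairs where both groups practice Kula. With ``ancestry_split``
    set, every haplotype is deterministically AN on the first ``split``
    fraction of each chromosome and PAP on the rest, and with
    ``between_region_on_an`` blocks shared across regions are placed in the
    AN zone while within-region blocks go to the PAP zone (for planting
    ancestry-restricted gene-flow patterns).
    """

    groups: list[GroupSpec]
    eras: list[EraSpec]
    chrom_lengths_cm: dict[str, float] = field(default_factory=lambda: dict(HUMAN_AUTOSOME_CM))
    cm_per_mb: float = 1.0
    region_multiplier: float = 1.0
    kula_boost: float = 1.0
    switch_rate_per_cm: float = 0.05
    low_posterior_frac: float = 0.05
    ancestry_split: float | None = None
    between_region_on_an: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.region_multiplier < 0 or self.kula_boost < 0:
            raise ValueError("multipliers must be >= 0")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")

    # -- derived objects ---------------------------------------------------

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.linear(self.chrom_lengths_cm, self.cm_per_mb)

    def panel(self) -> PopulationPanel:
        rows = []
        for g in self.groups:
            for i in range(g.size):
                rows.append(
                    (f"{g.name}_{i:02d}", g.name, g.region, g.massim_subregion,
                     g.kula if g.kula != "outside_massim" else None, g.lat, g.lon)
                )
        df = pd.DataFrame(
            rows,
            columns=["individual", "group", "region", "massim_subregion", "kula", "lat", "lon"],
        )
        return PopulationPanel.from_frame(df)

    def individuals(self) -> list[tuple[str, GroupSpec]]:
        out = []
        for g in self.groups:
            for i in range(g.size):
                out.append((f"{g.name}_{i:02d}", g))
        return out

    # -- (de)serialisation -------------------------------------------------

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["groups"] = [GroupSpec(**g) for g in data["groups"]]
        data["eras"] = [EraSpec(**e) for e in data["eras"]]
        return cls(**data)


def default_scenario(
    kula_boost: float = 1.0,
    seed: int = 0,
    n_per_group: int = 5,
) -> SimScenario:
    """A Massim-like study design: eight Massim groups (five Kula, three
    non-Kula, one of them a drifted isolate) plus four outside Oceanian
    groups, three length eras matching the 1-5 / 5-10 / >10 cM analysis
    bins, and elevated within-region contact."""
    massim = [
        ("TrobriandLike", "northern", "kula", -8.5, 151.1, 0.5),
        ("WoodlarkLike", "northern", "kula", -9.1, 152.8, 0.5),
        ("GawaLike", "northern", "kula", -8.9, 151.9, 0.5),
        ("FergussonLike", "western", "kula", -9.5, 150.7, 0.45),
        ("MisimaLike", "southern", "kula", -10.7, 152.8, 0.45),
        ("NormanbyLike", "western", "non_kula", -10.0, 151.0, 0.45),
        ("SudestLike", "southern", "non_kula", -11.4, 153.5, 0.35),
        ("RosselLike", "southern", "non_kula", -11.3, 154.2, 0.2),
    ]
    outside = [
        ("BismarckA", "Bismarck", -4.3, 152.2, 0.35),
        ("BismarckB", "Bismarck", -5.5, 150.5, 0.3),
        ("SolomonA", "Solomon", -9.4, 159.9, 0.45),
        ("HighlandA", "Highlands", -6.0, 145.0, 0.02),
    ]
    groups = [
        GroupSpec(
            name=name, size=n_per_group, region="Massim", massim_subregion=sub,
            kula=kula, lat=lat, lon=lon, an_proportion=an,
            hbd_rate=2.0 if name == "RosselLike" else 0.3,
        )
        for name, sub, kula, lat, lon, an in massim
    ] + [
        GroupSpec(
            name=name, size=n_per_group, region=region, kula="outside_massim",
            lat=lat, lon=lon, an_proportion=an,
        )
        for name, region, lat, lon, an in outside
    ]
    eras = [
        EraSpec("old", mean_cm=1.8, rate_within=12.0, rate_between=1.2),
        EraSpec("middle", mean_cm=6.0, rate_within=3.0, rate_between=0.25),
        EraSpec("recent", mean_cm=12.0, rate_within=1.0, rate_between=0.06),
    ]
    return SimScenario(
        groups=groups,
        eras=eras,
        region_multiplier=3.0,
        kula_boost=kula_boost,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Segment simulation
# ---------------------------------------------------------------------------


def _pair_rate(ga: GroupSpec, gb: GroupSpec, era: EraSpec, scenario: SimScenario) -> float:
    if ga.name == gb.name:
        return era.rate_within
    rate = era.rate_between
    if ga.region == gb.region:
        rate *= scenario.region_multiplier
    if ga.kula == gb.kula == "kula":
        rate *= scenario.kula_boost
    return rate


def _draw_batch(
    scenario: SimScenario,
    rng: np.random.Generator,
    chrom_names: list[str],
    chrom_probs: np.ndarray,
    pair_names: list[tuple[str, str]],
    same_region: np.ndarray,
    era: EraSpec,
    hbd: bool,
) -> list[IbdSegment]:
    """Vectorised draw of one era's segments for a list of haplotype-pair owners."""
    k = len(pair_names)
    if k == 0:
        return []
    chrom_lens = np.array([scenario.chrom_lengths_cm[c] for c in chrom_names])
    lengths = LENGTH_FLOOR_CM + rng.exponential(era.mean_cm, size=k)
    ci = rng.choice(len(chrom_names), size=k, p=chrom_probs)
    clen = chrom_lens[ci]
    zone_lo = np.zeros(k)
    zone_hi = clen.copy()
    if scenario.ancestry_split is not None and scenario.between_region_on_an:
        split = scenario.ancestry_split * clen
        zone_lo = np.where(same_region, split, 0.0)
        zone_hi = np.where(same_region, clen, split)
    zone_len = zone_hi - zone_lo
    lengths = np.where(
        lengths >= zone_len, np.maximum(LENGTH_FLOOR_CM, 0.95 * zone_len), lengths
    )
    start_cm = zone_lo + rng.uniform(size=k) * (zone_len - lengths)
    end_cm = start_cm + lengths
    # the scenario's map is linear: bp = 1 + cM / (cM/Mb) * 1e6
    start_bp = np.rint(1.0 + start_cm / scenario.cm_per_mb * 1e6).astype(np.int64)
    end_bp = np.rint(1.0 + end_cm / scenario.cm_per_mb * 1e6).astype(np.int64)
    if hbd:
        haps = np.tile([1, 2], (k, 1))
    else:
        haps = rng.integers(1, 3, size=(k, 2))
    out = []
    for j in range(k):
        na, nb = pair_names[j]
        ha, hb = int(haps[j, 0]), int(haps[j, 1])
        if (na, ha) > (nb, hb):
            na, nb, ha, hb = nb, na, hb, ha
        out.append(
            IbdSegment(
                sample_a=na, hap_a=ha, sample_b=nb, hap_b=hb,
                chrom=chrom_names[ci[j]],
                start_bp=int(start_bp[j]), end_bp=int(max(end_bp[j], start_bp[j])),
                start_cm=float(start_cm[j]), end_cm=float(end_cm[j]),
                length_cm=float(lengths[j]),
                lod=round(3.0 + 2.0 * float(lengths[j]), 2),
            )
        )
    return out


def simulate_ibd(scenario: SimScenario) -> tuple[list[IbdSegment], list[IbdSegment]]:
    """Draw (ibd_segments, hbd_segments) for a scenario.

    Per individual pair and era the block count is Poisson; per individual
    and era the HBD count is Poisson at the group's HBD rate (high for
    drifted isolates). Chromosomes are chosen with probability proportional
    to genetic length; positions are uniform within the chromosome (or
    within the ancestry zone in planted-ancestry mode).
    """
    rng = np.random.default_rng([scenario.seed, 1])
    chrom_names = list(scenario.chrom_lengths_cm)
    lens = np.array([scenario.chrom_lengths_cm[c] for c in chrom_names])
    chrom_probs = lens / lens.sum()
    inds = scenario.individuals()

    pair_a, pair_b, pair_same_region = [], [], []
    pair_rates = {era.name: [] for era in scenario.eras}
    for i, (name_a, grp_a) in enumerate(inds):
        for name_b, grp_b in inds[i + 1:]:
            pair_a.append(name_a)
            pair_b.append(name_b)
            pair_same_region.append(grp_a.region == grp_b.region)
            for era in scenario.eras:
                pair_rates[era.name].append(_pair_rate(grp_a, grp_b, era, scenario))
    same_region = np.array(pair_same_region)

    ibd: list[IbdSegment] = []
    for era in scenario.eras:
        counts = rng.poisson(np.array(pair_rates[era.name]))
        owner = np.repeat(np.arange(len(pair_a)), counts)
        names = [(pair_a[o], pair_b[o]) for o in owner]
        ibd.extend(
            _draw_batch(scenario, rng, chrom_names, chrom_probs, names,
                        same_region[owner], era, hbd=False)
        )

    hbd: list[IbdSegment] = []
    ind_names = [n for n, _ in inds]
    hbd_rates = np.array([g.hbd_rate for _, g in inds])
    for era in scenario.eras:
        counts = rng.poisson(hbd_rates)
        owner = np.repeat(np.arange(len(ind_names)), counts)
        names = [(ind_names[o], ind_names[o]) for o in owner]
        hbd.extend(
            _draw_batch(scenario, rng, chrom_names, chrom_probs, names,
                        np.ones(len(names), dtype=bool), era, hbd=True)
        )
    return ibd, hbd


# ---------------------------------------------------------------------------
# Tract simulation
# ---------------------------------------------------------------------------


def _mosaic_cm(
    rng: np.random.Generator, chrom_len: float, p_an: float, switch_rate: float
) -> list[tuple[float, float, str]]:
    """Alternating (start_cm, end_cm, ancestry) sojourns of a stationary
    two-state Markov mosaic with AN fraction ``p_an``."""
    if p_an >= 1.0:
        return [(0.0, chrom_len, "AN")]
    if p_an <= 0.0:
        return [(0.0, chrom_len, "PAP")]
    if switch_rate <= 0.0:
        state = "AN" if rng.random() < p_an else "PAP"
        return [(0.0, chrom_len, state)]
    exit_rate = {"AN": switch_rate * (1.0 - p_an), "PAP": switch_rate * p_an}
    state = "AN" if rng.random() < p_an else "PAP"
    pos = 0.0
    out = []
    while pos < chrom_len:
        sojourn = rng.exponential(1.0 / exit_rate[state])
        end = min(chrom_len, pos + sojourn)
        out.append((pos, end, state))
        pos = end
        state = "PAP" if state == "AN" else "AN"
    return out


def simulate_tracts(scenario: SimScenario) -> AncestryTractSet:
    """Per-haplotype AN/PAP mosaics with posteriors concentrated near 1.

    A configurable fraction of tracts gets a posterior below the 0.95
    confidence cutoff (those become UNKNOWN downstream). With
    ``ancestry_split`` set, tracts are deterministic: AN on the first
    fraction of each chromosome, PAP on the rest, posterior 1.
    """
    rng = np.random.default_rng([scenario.seed, 2])
    gmap = scenario.genetic_map()
    tracts: dict[tuple[str, int, str], list[AncestryTract]] = {}
    for name, grp in scenario.individuals():
        for hap in (1, 2):
            for chrom, chrom_len in scenario.chrom_lengths_cm.items():
                if scenario.ancestry_split is not None:
                    split = scenario.ancestry_split * chrom_len
                    pieces = [(0.0, split, "AN"), (split, chrom_len, "PAP")]
                    pieces = [p for p in pieces if p[1] > p[0]]
                    posts = [1.0] * len(pieces)
                else:
                    pieces = _mosaic_cm(rng, chrom_len, grp.an_proportion,
                                        scenario.switch_rate_per_cm)
                    posts = [
                        round(rng.uniform(0.5, 0.949), 3)
                        if rng.random() < scenario.low_posterior_frac
                        else round(rng.uniform(0.96, 1.0), 3)
                        for _ in pieces
                    ]
                items = []
                prev_end_bp = 0
                for (s_cm, e_cm, anc), post in zip(pieces, posts):
                    s_bp = max(prev_end_bp + 1, int(round(float(gmap.bp_at(chrom, s_cm)))))
                    e_bp = max(s_bp, int(round(float(gmap.bp_at(chrom, e_cm))) - 1))
                    label = anc if post >= 0.95 else "UNKNOWN"
                    items.append(AncestryTract(s_bp, e_bp, label, post))
                    prev_end_bp = e_bp
                tracts[(name, hap, chrom)] = items
    return AncestryTractSet(tracts, posterior_cutoff=0.95)


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    scenario: SimScenario
    panel: PopulationPanel
    genetic_map: GeneticMap
    ibd: list[IbdSegment]
    hbd: list[IbdSegment]
    tracts: AncestryTractSet


def simulate(scenario: SimScenario, with_tracts: bool = True) -> SimulatedDataset:
    ibd, hbd = simulate_ibd(scenario)
    tracts = simulate_tracts(scenario) if with_tracts else AncestryTractSet({})
    return SimulatedDataset(
        scenario=scenario,
        panel=scenario.panel(),
        genetic_map=scenario.genetic_map(),
        ibd=ibd,
        hbd=hbd,
        tracts=tracts,
    )


def emit(scenario: SimScenario, outdir) -> dict[str, Path]:
    """Write the full file set (IBD, HBD, tracts, panel, map, truth manifest).

    Regeneration with the same scenario (same seed) is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate(scenario)
    paths = {
        "ibd": outdir / "ibd.tsv",
        "hbd": outdir / "hbd.tsv",
        "tracts": outdir / "tracts.tsv",
        "panel": outdir / "panel.tsv",
        "map": outdir / "genetic.map",
        "truth": outdir / "truth.json",
    }
    write_ibd_segments(ds.ibd, paths["ibd"])
    write_ibd_segments(ds.hbd, paths["hbd"])
    ds.tracts.write(paths["tracts"])
    ds.panel.write(paths["panel"])
    ds.genetic_map.write(paths["map"])
    truth = dataclasses.asdict(scenario)
    truth["n_ibd_segments"] = len(ds.ibd)
    truth["n_hbd_segments"] = len(ds.hbd)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
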