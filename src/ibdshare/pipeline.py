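"""Config-driven orchestration of the full analysis.

merge -> bin -> L/N/S -> networks -> R / jackknife / permutation, with
ancestry-specific reruns when local-ancestry tracts are supplied. All
outputs are plain-text TSV plus a JSON run manifest, so runs are diffable
and deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (
    AncestryTractSet,
    GeneticMap,
    PhasedGenotypes,
    PopulationPanel,
    read_hbd_segments,
    read_ibd_segments,
)
from .model import KulaSharingModel
from .segments import (
    DEFAULT_MERGE_GAP_CM,
    DEFAULT_MIN_SUB_CM,
    DEFAULT_WITHIN_MIN_CM,
    LengthBins,
    NETWORK_BINS,
    R_SERIES_BINS,
    merge_segments,
    partition_all,
    within_group_ibd_summary,
)
from .sharing import (
    DEFAULT_MIN_MEAN_COUNT,
    SimilarityResult,
    distance_table,
    network_edges,
    sharing_by_bin,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and tunables of a run; defaults follow the published
    analysis settings wherever one exists (0.6 cM merge gap, 1/5/10 cM
    network bins, >= 2 cM within-group blocks, 0.95 posterior cutoff,
    >= 0.5 mean-count network filter)."""

    ibd_path: str
    panel_path: str
    map_path: str
    hbd_path: str | None = None
    tracts_path: str | None = None
    vcf_path: str | None = None
    merge_gap_cm: float = DEFAULT_MERGE_GAP_CM
    max_discordant: int = 1
    network_bin_edges: list[float] = field(default_factory=lambda: [1.0, 5.0, 10.0])
    r_bin_edges: list[float] = field(default_factory=lambda: list(R_SERIES_BINS.edges))
    demography_min_cm: float = DEFAULT_WITHIN_MIN_CM
    posterior_cutoff: float = 0.95
    min_mean_count: float = DEFAULT_MIN_MEAN_COUNT
    min_sub_cm: float = DEFAULT_MIN_SUB_CM
    n_perm: int = 999
    seed: int = 0
    ancestry_mode: str = "all"  # all | AN | PAP
    dialect: str = "refinedibd"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @property
    def network_bins(self) -> LengthBins:
        return LengthBins(tuple(self.network_bin_edges))

    @property
    def r_bins(self) -> LengthBins:
        edges = tuple(self.r_bin_edges)
        labels = R_SERIES_BINS.time_labels if edges == R_SERIES_BINS.edges else None
        return LengthBins(edges, labels)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute every stage and write the result bundle.

    Returns the manifest dict. Raises if segment files mention individuals
    absent from the panel (listing them) or chromosomes absent from the map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("ibdshare")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        manifest = _run_all_inner(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return manifest


def _run_all_inner(config: RunConfig, outdir: Path) -> dict:
    gmap = GeneticMap.read(config.map_path)
    panel = PopulationPanel.read(config.panel_path)
    segments = read_ibd_segments(config.ibd_path, gmap, config.dialect)
    n_raw_ibd = len(segments)
    if config.hbd_path:
        hbd = read_hbd_segments(config.hbd_path, gmap, config.dialect)
        segments += hbd
        logger.info("read %d IBD + %d HBD segments", n_raw_ibd, len(hbd))
    else:
        logger.info("read %d IBD segments", n_raw_ibd)

    seg_inds = {s.sample_a for s in segments} | {s.sample_b for s in segments}
    missing = sorted(seg_inds - set(panel.individuals.index))
    if missing:
        raise ValueError(f"individuals in segment files but not in panel: {missing}")

    genotypes = PhasedGenotypes.read(config.vcf_path) if config.vcf_path else None
    merged = merge_segments(
        segments, gap_cm=config.merge_gap_cm,
        genotypes=genotypes, max_discordant=config.max_discordant,
    )
    logger.info("merge: %d -> %d segments (gap < %g cM)",
                len(segments), len(merged), config.merge_gap_cm)

    # within-group demography (>= 2 cM) and per-individual ROH
    demography, roh = within_group_ibd_summary(merged, panel, config.demography_min_cm)
    demography.to_csv(outdir / "within_group_demography.tsv", sep="\t", float_format="%.6g")
    roh.to_frame().to_csv(outdir / "roh.tsv", sep="\t", float_format="%.6g")

    # per-bin sharing matrices and the filtered network
    _write_networks(merged, panel, config, outdir, suffix="")

    # ancestry-specific reruns
    tracts = None
    if config.tracts_path:
        tracts = AncestryTractSet.read(config.tracts_path, config.posterior_cutoff)
        by_ancestry = partition_all(merged, tracts, gmap, config.min_sub_cm)
        for ancestry in ("AN", "PAP"):
            if config.ancestry_mode not in ("all", ancestry):
                continue
            subs = by_ancestry.get(ancestry, [])
            logger.info("ancestry %s: %d subsegments", ancestry, len(subs))
            _write_networks(subs, panel, config, outdir, suffix=f"_{ancestry}")

    # Kula inference
    model = KulaSharingModel(merged, panel, bins=config.r_bins)
    results = model.fit(n_perm=config.n_perm, seed=config.seed)
    results.to_tsv(outdir / "relative_similarity.tsv")
    (outdir / "summary.txt").write_text(results.summary() + "\n")

    # similarity vs. geographic distance (for the 1-5 cM bin if present)
    net_sharing = sharing_by_bin(merged, panel, config.network_bins)
    first_bin = config.network_bins.labels[0]
    sim = SimilarityResult.from_sharing(net_sharing[first_bin])
    distance_table(sim, panel).to_csv(
        outdir / "similarity_vs_distance.tsv", sep="\t", index=False, float_format="%.6g"
    )

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (
                ("ibd", config.ibd_path), ("hbd", config.hbd_path),
                ("tracts", config.tracts_path), ("panel", config.panel_path),
                ("map", config.map_path), ("vcf", config.vcf_path),
            )
            if p
        },
        "counts": {
            "segments_read": len(segments),
            "segments_merged": len(merged),
            "groups": len(panel.group_names),
            "individuals": len(panel.individuals),
        },
        "seed": config.seed,
        "n_perm": config.n_perm,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _write_networks(segments, panel, config: RunConfig, outdir: Path, suffix: str) -> None:
    sharing = sharing_by_bin(segments, panel, config.network_bins)
    edges_all = []
    for label, sh in sharing.items():
        safe = label.replace(">", "gt")
        sh.L.to_csv(outdir / f"L_{safe}{suffix}.tsv", sep="\t", float_format="%.6g")
        sh.N.to_csv(outdir / f"N_{safe}{suffix}.tsv", sep="\t", float_format="%.6g")
        edges = network_edges(sh, config.min_mean_count)
        edges_all.append(edges)
        logger.info("network%s %s: %d edges pass mean-count >= %g",
                    suffix, label, len(edges), config.min_mean_count)
    nonempty = [e for e in edges_all if not e.empty]
    combined = (
        pd.concat(nonempty, ignore_index=True) if nonempty else edges_all[0]
    )
    combined.to_csv(
        outdir / f"network_edges{suffix}.tsv", sep="\t", index=False, float_format="%.6g"
    )
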