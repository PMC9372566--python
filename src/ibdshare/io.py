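"""Readers, writers and the core data model.

Everything downstream of this module consumes only the types defined here:
:class:`IbdSegment`, :class:`PopulationPanel`, :class:`GeneticMap`,
:class:`AncestryTractSet` and :class:`PhasedGenotypes`.

Physical coordinates are 1-based inclusive (VCF convention); genetic
coordinates are real-valued centimorgans interpolated from a genetic map.
The printed cM length in a segment file is authoritative for all sharing
statistics; interpolated endpoints are rescaled to match it so that
``length_cm == end_cm - start_cm`` always holds (a warning is logged when
the map-derived length deviates from the printed one by more than 0.1 cM).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANCESTRIES = ("AN", "PAP")
UNKNOWN = "UNKNOWN"
KULA_STATES = ("kula", "non_kula", "outside_massim")

#: tolerance (cM) beyond which a printed-vs-interpolated length mismatch is logged
LENGTH_RECONCILE_WARN_CM = 0.1


class FormatError(ValueError):
    """A malformed input file; the message names the offending line."""


class PanelError(ValueError):
    """An inconsistent sample panel (duplicates, bad Kula flags, ...)."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


class GeneticMap:
    """Piecewise-linear bp <-> cM interpolation per chromosome.

    Anchors are (bp, cM) pairs with cM non-decreasing in bp. Queries outside
    the anchor range clamp to the boundary cM value.
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(bp)
            bp, cm = bp[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise FormatError(
                    f"genetic map for chromosome {chrom}: cM not non-decreasing in bp"
                )
            self._anchors[str(chrom)] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def __contains__(self, chrom: str) -> bool:
        return str(chrom) in self._anchors

    def interpolate(self, chrom: str, bp) -> np.ndarray | float:
        """cM position(s) at physical position(s) ``bp``, clamped at the ends."""
        try:
            xs, ys = self._anchors[str(chrom)]
        except KeyError:
            raise FormatError(f"chromosome {chrom!r} absent from genetic map") from None
        return np.interp(bp, xs, ys)

    def bp_at(self, chrom: str, cm) -> np.ndarray | float:
        """Inverse query: physical position(s) at genetic position(s) ``cm``."""
        xs, ys = self._anchors[str(chrom)]
        return np.interp(cm, ys, xs)

    def chrom_length_cm(self, chrom: str) -> float:
        xs, ys = self._anchors[str(chrom)]
        return float(ys[-1] - ys[0])

    def chrom_span_bp(self, chrom: str) -> tuple[int, int]:
        xs, _ = self._anchors[str(chrom)]
        return int(xs[0]), int(xs[-1])

    @classmethod
    def linear(cls, chrom_lengths_cm: dict[str, float], cm_per_mb: float = 1.0) -> "GeneticMap":
        """A uniform-rate map: ``cm_per_mb`` centimorgans per megabase, starting at bp 1."""
        anchors = {}
        for chrom, length_cm in chrom_lengths_cm.items():
            end_bp = 1 + length_cm / cm_per_mb * 1e6
            anchors[str(chrom)] = (np.array([1.0, end_bp]), np.array([0.0, float(length_cm)]))
        return cls(anchors)

    @classmethod
    def read(cls, path) -> "GeneticMap":
        """Read a PLINK ``.map``-style or HapMap-style table, auto-detected by header.

        PLINK: four headerless columns (chrom, id, cM, bp). HapMap: four
        columns with a header naming position/rate/map (chrom, bp, rate, cM).
        """
        lines = _read_text_lines(path)
        if not lines:
            raise FormatError(f"{path}: empty genetic map")
        first = lines[0].split()
        header_tokens = " ".join(first[1:]).lower()
        is_hapmap = any(k in header_tokens for k in ("pos", "rate", "map", "cm"))
        rows = lines[1:] if is_hapmap else lines
        per_chrom: dict[str, list[tuple[float, float]]] = {}
        for lineno, line in enumerate(rows, start=2 if is_hapmap else 1):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                if is_hapmap:
                    chrom, bp, _rate, cm = parts[0], float(parts[1]), parts[2], float(parts[3])
                else:
                    chrom, _snp, cm, bp = parts[0], parts[1], float(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            per_chrom.setdefault(chrom, []).append((bp, cm))
        anchors = {
            chrom: (np.array([r[0] for r in rows_]), np.array([r[1] for r in rows_]))
            for chrom, rows_ in per_chrom.items()
        }
        return cls(anchors)

    def write(self, path) -> None:
        """Write in PLINK .map layout (chrom, id, cM, bp)."""
        with _open_text(path, "wt") as fh:
            for chrom in self.chromosomes:
                bp, cm = self._anchors[chrom]
                for i, (b, c) in enumerate(zip(bp, cm)):
                    fh.write(f"{chrom}\tanchor_{chrom}_{i}\t{c:.6f}\t{int(b)}\n")


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IbdSegment:
    """One shared haplotype block between two (individual, haplotype) pairs.

    HBD (homozygosity-by-descent) blocks are represented with
    ``sample_a == sample_b`` and the two haplotype indices differing.
    """

    sample_a: str
    hap_a: int
    sample_b: str
    hap_b: int
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    length_cm: float
    lod: float

    @property
    def is_hbd(self) -> bool:
        return self.sample_a == self.sample_b

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError(f"segment end_bp {self.end_bp} < start_bp {self.start_bp}")
        if self.length_cm < 0:
            raise ValueError(f"negative genetic length {self.length_cm}")
        if self.is_hbd and self.hap_a == self.hap_b:
            raise ValueError(
                f"HBD segment for {self.sample_a} must pair the two distinct haplotypes"
            )

    def canonical(self) -> "IbdSegment":
        """Order the two (sample, hap) keys lexicographically."""
        if (self.sample_a, self.hap_a) <= (self.sample_b, self.hap_b):
            return self
        return replace(
            self,
            sample_a=self.sample_b,
            hap_a=self.hap_b,
            sample_b=self.sample_a,
            hap_b=self.hap_a,
        )

    def pair_key(self) -> tuple:
        return (self.sample_a, self.hap_a, self.sample_b, self.hap_b, self.chrom)


_IBD_COLUMNS = [
    "sample_a", "hap_a", "sample_b", "hap_b", "chrom",
    "start_bp", "end_bp", "start_cm", "end_cm", "length_cm", "lod", "is_hbd",
]


def segments_to_frame(segments: Iterable[IbdSegment]) -> pd.DataFrame:
    """Tabular view of a segment collection (one row per segment)."""
    rows = [
        (s.sample_a, s.hap_a, s.sample_b, s.hap_b, s.chrom,
         s.start_bp, s.end_bp, s.start_cm, s.end_cm, s.length_cm, s.lod, s.is_hbd)
        for s in segments
    ]
    return pd.DataFrame(rows, columns=_IBD_COLUMNS)


def _parse_segment_row(
    parts: Sequence[str], gmap: GeneticMap, hap_base: int, where: str
) -> IbdSegment:
    if len(parts) != 9:
        raise FormatError(f"{where}: expected 9 columns, got {len(parts)}")
    try:
        sample_a, hap_a, sample_b, hap_b = parts[0], int(parts[1]), parts[2], int(parts[3])
        chrom = parts[4]
        start_bp, end_bp = int(parts[5]), int(parts[6])
        lod, length_cm = float(parts[7]), float(parts[8])
    except ValueError as exc:
        raise FormatError(f"{where}: {exc}") from None
    if hap_base == 0:
        hap_a, hap_b = hap_a + 1, hap_b + 1
    if length_cm < 0:
        raise FormatError(f"{where}: negative length {length_cm}")
    if end_bp < start_bp:
        raise FormatError(f"{where}: end_bp {end_bp} < start_bp {start_bp}")
    start_cm = float(gmap.interpolate(chrom, start_bp))
    end_cm_map = float(gmap.interpolate(chrom, end_bp))
    if abs((end_cm_map - start_cm) - length_cm) > LENGTH_RECONCILE_WARN_CM:
        logger.warning(
            "%s: map-derived length %.3f cM deviates from printed %.3f cM; "
            "printed length kept", where, end_cm_map - start_cm, length_cm,
        )
    # printed length is authoritative: anchor the interval at start_cm
    seg = IbdSegment(
        sample_a=sample_a, hap_a=hap_a, sample_b=sample_b, hap_b=hap_b,
        chrom=chrom, start_bp=start_bp, end_bp=end_bp,
        start_cm=start_cm, end_cm=start_cm + length_cm, length_cm=length_cm, lod=lod,
    )
    return seg.canonical()


def read_ibd_segments(path, gmap: GeneticMap, dialect: str = "refinedibd") -> list[IbdSegment]:
    """Read a 9-column whitespace-delimited IBD segment table.

    Columns: sample_a, hap_a, sample_b, hap_b, chrom, start_bp, end_bp, LOD,
    length_cM (the refinedIBD output layout). ``dialect`` may be
    ``"refinedibd"`` (1-based haplotypes) or ``"refinedibd-hap0"`` (0-based).
    Gzip-transparent. Pairs are canonicalised on read.
    """
    hap_base = _dialect_hap_base(dialect)
    out: list[IbdSegment] = []
    for lineno, line in enumerate(_iter_text_lines(path), start=1):
        out.append(_parse_segment_row(line.split(), gmap, hap_base, f"{path}:{lineno}"))
    return out


def read_hbd_segments(path, gmap: GeneticMap, dialect: str = "refinedibd") -> list[IbdSegment]:
    """Like :func:`read_ibd_segments` but every row must be within-individual.

    A row pairing two different individuals raises :class:`FormatError`
    (it signals an IBD/HBD file mix-up).
    """
    segments = read_ibd_segments(path, gmap, dialect)
    for i, seg in enumerate(segments, start=1):
        if not seg.is_hbd:
            raise FormatError(
                f"{path}: row {i} pairs two individuals ({seg.sample_a}, {seg.sample_b}); "
                "not an HBD file"
            )
    return segments


def write_ibd_segments(segments: Iterable[IbdSegment], path) -> None:
    """Write segments in the 9-column dialect (tab-delimited, gzip-transparent)."""
    with _open_text(path, "wt") as fh:
        for s in segments:
            fh.write(
                f"{s.sample_a}\t{s.hap_a}\t{s.sample_b}\t{s.hap_b}\t{s.chrom}\t"
                f"{s.start_bp}\t{s.end_bp}\t{s.lod:g}\t{s.length_cm:g}\n"
            )


def _dialect_hap_base(dialect: str) -> int:
    if dialect == "refinedibd":
        return 1
    if dialect == "refinedibd-hap0":
        return 0
    raise ValueError(f"unknown IBD dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Population panel
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["individual", "group", "region", "massim_subregion", "kula", "lat", "lon"]


class PopulationPanel:
    """Individual -> group assignment plus per-group attributes.

    Group attributes: region, Massim subregion (or missing), Kula membership
    (``kula`` / ``non_kula`` for Massim groups, ``outside_massim`` otherwise)
    and decimal-degree coordinates (or missing). Kula labels may only be
    carried by Massim groups.
    """

    def __init__(self, individuals: pd.DataFrame, groups: pd.DataFrame):
        self.individuals = individuals  # index: individual; column: group
        self.groups = groups  # index: group; columns: region, massim_subregion, kula, lat, lon
        self._validate()

    def _validate(self) -> None:
        if self.individuals.index.duplicated().any():
            dups = self.individuals.index[self.individuals.index.duplicated()].tolist()
            raise PanelError(f"duplicate individual IDs: {sorted(set(dups))}")
        unknown = set(self.individuals["group"]) - set(self.groups.index)
        if unknown:
            raise PanelError(f"individuals assigned to unlisted groups: {sorted(unknown)}")
        bad_kula = ~self.groups["kula"].isin(KULA_STATES)
        if bad_kula.any():
            raise PanelError(
                f"invalid kula values: {self.groups.loc[bad_kula, 'kula'].to_dict()}"
            )
        massim = self.groups["massim_subregion"].notna()
        flagged = self.groups["kula"].isin(["kula", "non_kula"])
        offenders = self.groups.index[flagged & ~massim].tolist()
        if offenders:
            raise PanelError(
                f"kula/non_kula flags on non-Massim groups: {offenders} "
                "(only Massim groups participate in, or abstain from, Kula)"
            )

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationPanel":
        missing = set(_PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise PanelError(f"panel missing columns: {sorted(missing)}")
        individuals = df.set_index("individual")[["group"]]
        attrs = df[["group", "region", "massim_subregion", "kula", "lat", "lon"]]
        grouped = attrs.drop_duplicates()
        if grouped["group"].duplicated().any():
            bad = grouped.loc[grouped["group"].duplicated(), "group"].tolist()
            raise PanelError(f"conflicting attributes within groups: {sorted(set(bad))}")
        groups = grouped.set_index("group")
        groups["kula"] = groups["kula"].fillna("outside_massim")
        return cls(individuals, groups)

    @classmethod
    def read(cls, path) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", dtype={"individual": str, "group": str},
                         na_values=["NA"], keep_default_na=False)
        return cls.from_frame(df)

    def write(self, path) -> None:
        df = self.individuals.reset_index().merge(
            self.groups.reset_index(), on="group", how="left"
        )[_PANEL_COLUMNS]
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%g")

    # -- queries -----------------------------------------------------------

    @property
    def group_names(self) -> list[str]:
        return list(self.groups.index)

    def group_of(self) -> pd.Series:
        """individual -> group mapping as a Series."""
        return self.individuals["group"]

    def n(self, group: str) -> int:
        return int((self.individuals["group"] == group).sum())

    def sizes(self) -> pd.Series:
        return self.individuals["group"].value_counts().reindex(self.groups.index, fill_value=0)

    def members(self, group: str) -> list[str]:
        return self.individuals.index[self.individuals["group"] == group].tolist()

    @property
    def massim_groups(self) -> list[str]:
        return self.groups.index[self.groups["massim_subregion"].notna()].tolist()

    @property
    def kula_groups(self) -> list[str]:
        return self.groups.index[self.groups["kula"] == "kula"].tolist()

    @property
    def non_kula_groups(self) -> list[str]:
        return self.groups.index[self.groups["kula"] == "non_kula"].tolist()

    def coordinates(self, group: str) -> tuple[float, float] | None:
        lat, lon = self.groups.loc[group, ["lat", "lon"]]
        if pd.isna(lat) or pd.isna(lon):
            return None
        return float(lat), float(lon)


# ---------------------------------------------------------------------------
# Ancestry tracts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AncestryTract:
    start_bp: int
    end_bp: int
    ancestry: str  # AN / PAP / UNKNOWN (after posterior masking)
    posterior: float


class AncestryTractSet:
    """Per-(individual, haplotype, chromosome) mosaic of local-ancestry tracts.

    Tracts whose posterior falls below the cutoff (default 0.95, the usual
    confidence threshold on RFMix forward-backward probabilities) are
    relabelled UNKNOWN at load time; downstream ancestry-specific analyses
    ignore UNKNOWN intervals.
    """

    def __init__(self, tracts: dict[tuple[str, int, str], list[AncestryTract]],
                 posterior_cutoff: float = 0.95):
        self.posterior_cutoff = posterior_cutoff
        self._tracts: dict[tuple[str, int, str], list[AncestryTract]] = {}
        for key, items in tracts.items():
            items = sorted(items, key=lambda t: t.start_bp)
            for prev, nxt in zip(items, items[1:]):
                if nxt.start_bp <= prev.end_bp:
                    raise FormatError(
                        f"overlapping ancestry tracts on {key}: "
                        f"[{prev.start_bp},{prev.end_bp}] and [{nxt.start_bp},{nxt.end_bp}]"
                    )
            self._tracts[key] = items

    def __len__(self) -> int:
        return sum(len(v) for v in self._tracts.values())

    @property
    def keys(self):
        return self._tracts.keys()

    def tracts_for(self, individual: str, hap: int, chrom: str) -> list[AncestryTract]:
        return self._tracts.get((individual, hap, str(chrom)), [])

    def confident_tracts(self, individual: str, hap: int, chrom: str,
                         start_bp: int, end_bp: int) -> list[tuple[int, int, str]]:
        """Non-UNKNOWN tract pieces overlapping [start_bp, end_bp], clipped."""
        out = []
        for t in self.tracts_for(individual, hap, chrom):
            if t.ancestry == UNKNOWN or t.end_bp < start_bp or t.start_bp > end_bp:
                continue
            out.append((max(t.start_bp, start_bp), min(t.end_bp, end_bp), t.ancestry))
        return out

    @classmethod
    def read(cls, path, posterior_cutoff: float = 0.95) -> "AncestryTractSet":
        """Read a 7-column TSV: individual, hap, chrom, start_bp, end_bp, ancestry, posterior."""
        tracts: dict[tuple[str, int, str], list[AncestryTract]] = {}
        lines = _read_text_lines(path)
        start = 1 if lines and lines[0].split("\t")[0] == "individual" else 0
        for lineno, line in enumerate(lines[start:], start=start + 1):
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                ind, hap, chrom = parts[0], int(parts[1]), parts[2]
                s, e = int(parts[3]), int(parts[4])
                ancestry, post = parts[5], float(parts[6])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if not 0.0 <= post <= 1.0:
                raise FormatError(f"{path}:{lineno}: posterior {post} outside [0, 1]")
            if e < s:
                raise FormatError(f"{path}:{lineno}: end_bp < start_bp")
            label = ancestry if post >= posterior_cutoff else UNKNOWN
            tracts.setdefault((ind, hap, chrom), []).append(
                AncestryTract(s, e, label, post)
            )
        return cls(tracts, posterior_cutoff)

    def write(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write("individual\thap\tchrom\tstart_bp\tend_bp\tancestry\tposterior\n")
            for (ind, hap, chrom) in sorted(self._tracts):
                for t in self._tracts[(ind, hap, chrom)]:
                    fh.write(
                        f"{ind}\t{hap}\t{chrom}\t{t.start_bp}\t{t.end_bp}\t"
                        f"{t.ancestry}\t{t.posterior:g}\n"
                    )


# ---------------------------------------------------------------------------
# Phased genotypes (for the genotype-consistency merge check)
# ---------------------------------------------------------------------------


class PhasedGenotypes:
    """In-memory phased genotype table read from a VCF.

    Used only by the optional genotype-consistency check of the gap-merge
    rule, which counts sites where two haplotypes carry different alleles.
    The whole (small) VCF is loaded so that no index is required.
    """

    def __init__(self, samples: list[str],
                 positions: dict[str, np.ndarray],
                 alleles: dict[str, np.ndarray]):
        self.samples = list(samples)
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}
        self._positions = positions  # chrom -> sorted int array
        self._alleles = alleles  # chrom -> (n_sites, n_samples, 2) int array, -1 = missing

    @classmethod
    def read(cls, path) -> "PhasedGenotypes":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        positions: dict[str, list[int]] = {}
        alleles: dict[str, list[np.ndarray]] = {}
        for variant in vcf:
            gt = np.asarray([g[:2] for g in variant.genotypes], dtype=np.int16)
            positions.setdefault(variant.CHROM, []).append(variant.POS)
            alleles.setdefault(variant.CHROM, []).append(gt)
        vcf.close()
        pos_arr = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
        al_arr = {c: np.stack(a) for c, a in alleles.items()}
        return cls(samples, pos_arr, al_arr)

    def count_discordant(self, chrom: str, start_bp: int, end_bp: int,
                         sample_a: str, hap_a: int, sample_b: str, hap_b: int) -> int:
        """Number of sites in [start_bp, end_bp] where the two haplotypes differ.

        Missing alleles at a site exclude it from the count.
        """
        chrom = str(chrom)
        if chrom not in self._positions:
            return 0
        pos = self._positions[chrom]
        lo, hi = np.searchsorted(pos, [start_bp, end_bp + 1])
        block = self._alleles[chrom][lo:hi]
        ia, ib = self._sample_idx[sample_a], self._sample_idx[sample_b]
        a = block[:, ia, hap_a - 1]
        b = block[:, ib, hap_b - 1]
        valid = (a >= 0) & (b >= 0)
        return int(np.sum((a != b) & valid))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _iter_text_lines(path) -> Iterator[str]:
    with _open_text(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                yield line


def _read_text_lines(path) -> list[str]:
    return list(_iter_text_lines(path))
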