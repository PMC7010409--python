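"""Genome reference tables: chromosome lengths, arm boundaries and cytobands.

A :class:`GenomeReference` carries everything downstream modules need to turn
base-pair coordinates into arm/chromosome fractions and genomic windows: per
chromosome length, the p/q arm intervals flanking the centromere gap, and a
cytoband table in UCSC ``cytoBand.txt`` column order
(chrom, chromStart, chromEnd, name, gieStain; 0-based half-open coordinates).

The bundled band tables for hg19/hg38 are *synthetic*: chromosome lengths are
the exact public GRCh37/GRCh38 assembly constants, centromere positions are
approximate, and the banding pattern itself is generated deterministically
(see :func:`synthesize_cytobands`). They provide a structurally faithful
windowing scaffold, not real Giemsa band coordinates.

Internally all intervals exposed to callers are 1-based inclusive, matching
segmentation-output conventions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .errors import UnknownBuildError, ValidationError

CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]

# Exact assembly chromosome lengths (bp).
CHROM_LENGTHS = {
    "hg19": {
        "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
        "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
        "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
        "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
        "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
        "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
        "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
        "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
    },
    "hg38": {
        "chr1": 248956422, "chr2": 242193529, "chr3": 198295559,
        "chr4": 190214555, "chr5": 181538259, "chr6": 170805979,
        "chr7": 159345973, "chr8": 145138636, "chr9": 138394717,
        "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
        "chr13": 114364328, "chr14": 107043718, "chr15": 101991189,
        "chr16": 90338345, "chr17": 83257441, "chr18": 80373285,
        "chr19": 58617616, "chr20": 64444167, "chr21": 46709983,
        "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
    },
}

# Approximate centromere gaps (bp, 0-based half-open), used to synthesize the
# bundled band tables. Acrocentric short arms are retained as small p arms.
CENTROMERES = {
    "hg19": {
        "chr1": (121_500_000, 124_500_000), "chr2": (92_300_000, 95_300_000),
        "chr3": (90_500_000, 93_500_000), "chr4": (49_700_000, 52_700_000),
        "chr5": (46_400_000, 49_400_000), "chr6": (58_800_000, 61_800_000),
        "chr7": (58_100_000, 61_100_000), "chr8": (43_800_000, 46_800_000),
        "chr9": (47_400_000, 50_400_000), "chr10": (39_300_000, 42_300_000),
        "chr11": (51_600_000, 54_600_000), "chr12": (34_900_000, 37_900_000),
        "chr13": (16_000_000, 19_000_000), "chr14": (16_100_000, 19_100_000),
        "chr15": (15_800_000, 18_800_000), "chr16": (35_300_000, 38_300_000),
        "chr17": (22_300_000, 25_300_000), "chr18": (15_400_000, 18_400_000),
        "chr19": (24_400_000, 27_400_000), "chr20": (26_400_000, 29_400_000),
        "chr21": (11_300_000, 14_300_000), "chr22": (13_700_000, 16_700_000),
        "chrX": (58_600_000, 61_600_000), "chrY": (11_600_000, 14_600_000),
    },
    "hg38": {
        "chr1": (122_000_000, 125_100_000), "chr2": (92_200_000, 94_100_000),
        "chr3": (90_800_000, 93_700_000), "chr4": (49_700_000, 51_800_000),
        "chr5": (46_500_000, 50_100_000), "chr6": (58_600_000, 60_600_000),
        "chr7": (58_200_000, 61_300_000), "chr8": (44_200_000, 46_300_000),
        "chr9": (43_000_000, 45_500_000), "chr10": (39_700_000, 41_600_000),
        "chr11": (51_100_000, 54_400_000), "chr12": (34_800_000, 37_200_000),
        "chr13": (16_500_000, 18_900_000), "chr14": (16_100_000, 18_200_000),
        "chr15": (17_500_000, 20_000_000), "chr16": (36_300_000, 38_300_000),
        "chr17": (22_800_000, 27_400_000), "chr18": (15_400_000, 20_900_000),
        "chr19": (24_500_000, 27_200_000), "chr20": (26_400_000, 30_000_000),
        "chr21": (10_900_000, 13_000_000), "chr22": (13_700_000, 17_400_000),
        "chrX": (58_100_000, 63_800_000), "chrY": (10_300_000, 13_300_000),
    },
}

SUPPORTED_BUILDS = tuple(sorted(CHROM_LENGTHS))

_STAINS = ("gneg", "gpos25", "gneg", "gpos50", "gneg", "gpos75", "gneg", "gpos100")
_MAJOR_BAND_BP = 10_000_000  # target major-band width when synthesizing
_SPLIT_BP = 4_000_000        # major bands longer than this get two sub-bands


def _arm_bands(chrom: str, start: int, end: int, arm: str) -> list[tuple]:
    """Synthesize sub-cytoband rows for one arm (0-based half-open span)."""
    length = end - start
    if length <= 0:
        return []
    n_major = max(1, round(length / _MAJOR_BAND_BP))
    edges = [start + round(length * k / n_major) for k in range(n_major + 1)]
    rows = []
    stain_i = 0
    for k in range(n_major):
        lo, hi = edges[k], edges[k + 1]
        # major indices count outward from the centromere starting at 12
        if arm == "p":
            major = 11 + (n_major - k)
        else:
            major = 12 + k
        if hi - lo > _SPLIT_BP:
            mid = (lo + hi) // 2
            subs = [(lo, mid), (mid, hi)]
            # sub-band numbers increase away from the centromere
            names = [f"{arm}{major}.2", f"{arm}{major}.1"] if arm == "p" \
                else [f"{arm}{major}.1", f"{arm}{major}.2"]
        else:
            subs = [(lo, hi)]
            names = [f"{arm}{major}"]
        for (lo_s, hi_s), name in zip(subs, names):
            rows.append((chrom, lo_s, hi_s, name, _STAINS[stain_i % len(_STAINS)]))
            stain_i += 1
    return rows


def synthesize_cytobands(build: str) -> pd.DataFrame:
    """Deterministically generate a synthetic cytoband table for *build*.

    Output follows the UCSC cytoBand.txt column layout. Centromeres become a
    pair of ``acen`` rows (``p11``/``q11``) splitting the gap at its midpoint.
    """
    if build not in CHROM_LENGTHS:
        raise UnknownBuildError(
            f"unknown build {build!r}; supported: {', '.join(SUPPORTED_BUILDS)}"
        )
    rows: list[tuple] = []
    for chrom in CHROMOSOMES:
        length = CHROM_LENGTHS[build][chrom]
        cen_start, cen_end = CENTROMERES[build][chrom]
        rows.extend(_arm_bands(chrom, 0, cen_start, "p"))
        mid = (cen_start + cen_end) // 2
        rows.append((chrom, cen_start, mid, "p11", "acen"))
        rows.append((chrom, mid, cen_end, "q11", "acen"))
        rows.extend(_arm_bands(chrom, cen_end, length, "q"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])


@dataclass(frozen=True, eq=False)
class GenomeReference:
    """Chromosome lengths, arm boundaries and cytobands for one build.

    ``arm_bounds[chrom]`` maps ``"p"``/``"q"`` to 1-based inclusive intervals;
    the centromere gap between them is excluded from both arms.
    """

    build: str
    chrom_lengths: dict[str, int]
    arm_bounds: dict[str, dict[str, tuple[int, int]]]
    cytobands: pd.DataFrame = field(repr=False)

    @property
    def hg_length(self) -> int:
        """Total genome length: sum of all chromosome lengths."""
        return sum(self.chrom_lengths.values())

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    def arm_length(self, chrom: str, arm: str) -> int:
        lo, hi = self.arm_bounds[chrom][arm]
        return hi - lo + 1

    def centromere_span(self, chrom: str) -> tuple[int, int]:
        """1-based inclusive span of the centromere gap."""
        p_hi = self.arm_bounds[chrom]["p"][1]
        q_lo = self.arm_bounds[chrom]["q"][0]
        return p_hi + 1, q_lo - 1


def from_cytobands(build: str, bands: pd.DataFrame) -> GenomeReference:
    """Build a :class:`GenomeReference` from a cytoBand-format table.

    Chromosome lengths are the maximal band ends; arm boundaries are derived
    from the ``acen`` rows (p arm ends where the first acen row starts).
    """
    lengths: dict[str, int] = {}
    arm_bounds: dict[str, dict[str, tuple[int, int]]] = {}
    for chrom, sub in bands.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
            raise ValidationError(f"overlapping cytoband rows on {chrom}")
        length = int(sub["end"].max())
        acen = sub[sub["stain"] == "acen"]
        if acen.empty:
            raise ValidationError(f"no acen (centromere) rows for {chrom}")
        cen_start = int(acen["start"].min())
        cen_end = int(acen["end"].max())
        lengths[chrom] = length
        arm_bounds[chrom] = {"p": (1, cen_start), "q": (cen_end + 1, length)}
    order = [c for c in CHROMOSOMES if c in lengths] + [
        c for c in lengths if c not in CHROMOSOMES
    ]
    return GenomeReference(
        build=build,
        chrom_lengths={c: lengths[c] for c in order},
        arm_bounds={c: arm_bounds[c] for c in order},
        cytobands=bands.reset_index(drop=True),
    )


def load_genome(build: str) -> GenomeReference:
    """Load the bundled reference for ``hg19`` or ``hg38``.

    The bundled band tables are synthetic (see module docstring); chromosome
    lengths and hence arm/genome fractions are exact assembly constants.
    """
    if build not in SUPPORTED_BUILDS:
        raise UnknownBuildError(
            f"unknown build {build!r}; supported: {', '.join(SUPPORTED_BUILDS)}"
        )
    fname = f"cytoBand_{build}.synthetic.txt"
    ref = importlib.resources.files("cnaburden.data").joinpath(fname)
    with importlib.resources.as_file(ref) as path:
        bands = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "stain"],
        )
    return from_cytobands(build, bands)


def toy_genome() -> GenomeReference:
    """A small 3-chromosome genome (100/80/60 Mb) for fast tests and examples.

    Centromeres sit at 40%, 50% and 50% of each chromosome with a 3 Mb gap.
    """
    specs = [("chr1", 100_000_000, 40), ("chr2", 80_000_000, 40),
             ("chr3", 60_000_000, 30)]
    rows = []
    for chrom, length, cen_mid_mb in specs:
        mid = cen_mid_mb * 1_000_000
        cen_start, cen_end = mid - 1_500_000, mid + 1_500_000
        rows.extend(_arm_bands(chrom, 0, cen_start, "p"))
        rows.append((chrom, cen_start, mid, "p11", "acen"))
        rows.append((chrom, mid, cen_end, "q11", "acen"))
        rows.extend(_arm_bands(chrom, cen_end, length, "q"))
    bands = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])
    return from_cytobands("toy", bands)
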