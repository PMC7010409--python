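"""Synthetic tumor-cohort generator with known ground truth.

Each simulated sample receives broad events (whole arms, occasionally whole
chromosomes) and focal events (log-normally sized sub-arm intervals) with
true copy-number levels drawn from a configurable distribution. True log2
ratios sit at the midpoints of the CNA-level bands; optionally some unaltered
arms become copy-neutral LOH (log2 ~ 0, BAF deviation ~ 0.35). Observed
segment means dilute the true values through the tumor-purity admixture
model ``observed = log2(r * 2**true + (1 - r))`` — deliberately the exact
inverse of the purity correction applied downstream, so round-trip identities
hold — and add Gaussian amplitude noise. Each chromosome arm is tiled
completely: events plus neutral background segments.

Ground truth records every event's scope, level, weight and arm fraction, so
expected BCS/FCS can be computed without touching the segment-processing
pipeline (:func:`ground_truth_scores`).

Event loads are graded across samples: each sample draws its expected broad
and focal event counts uniformly from [0, 2 x rate], producing cohorts that
span quiet to highly rearranged genomes as real pan-cancer cohorts do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome import GenomeReference, toy_genome
from .io import SEGMENT_COLUMNS, SampleTable
from .scores import WEIGHTS, coverage_weight

#: true log2 ratios at the midpoints of the CNA-level bands (safe margins
#: from every calling threshold)
LEVEL_LOG2 = {
    "low_gain": 0.39, "medium_gain": 0.79, "high_gain": 1.32,
    "low_loss": -0.60, "medium_loss": -1.37, "high_loss": -2.0,
}

DEFAULT_AMPLITUDES = {
    "low_gain": 0.30, "medium_gain": 0.15, "high_gain": 0.05,
    "low_loss": 0.30, "medium_loss": 0.15, "high_loss": 0.05,
}


@dataclass(frozen=True, eq=False)
class SimParams:
    """Cohort-level simulation settings.

    Rates are expected events per sample (each sample's own expectation is
    drawn uniformly from [0, 2 x rate]); amplitudes are probabilities over
    the CNA levels; purity is uniform over ``purity_range`` and dilutes the
    observed log2 ratios; ``noise_sd`` is additive Gaussian noise on the
    observed (diluted) segment means.
    """

    n_samples: int = 100
    genome: GenomeReference = field(default_factory=toy_genome)
    broad_rate: float = 2.0
    focal_rate: float = 3.0
    chrom_event_prob: float = 0.15      # broad event covers the whole chromosome
    focal_length_log_mean: float = np.log(4e6)
    focal_length_log_sd: float = 0.7
    amplitude_levels: dict = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    purity_range: tuple[float, float] = (0.6, 1.0)
    noise_sd: float = 0.05
    baf_loh_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.broad_rate < 0 or self.focal_rate < 0:
            raise ValidationError("rates must be non-negative")
        probs = np.array(list(self.amplitude_levels.values()), float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("amplitude probabilities must sum to 1")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValidationError("purity_range must lie within (0, 1]")


def dilute(true_log2, purity):
    """Observed log2 ratio of a clonal event in a sample of given purity."""
    return np.log2(np.asarray(purity) * np.exp2(true_log2)
                   + (1.0 - np.asarray(purity)))


def _pick_level(rng, levels: dict) -> str:
    names = list(levels)
    return names[rng.choice(len(names), p=np.array(list(levels.values())))]


#: spacing between simulated events; just above the default merge gap so
#: adjacent events never coalesce during re-segmentation
MIN_CLEARANCE = 1_200_000


def _draw_focal(rng, lo: int, hi: int, arm_len: int, occupied: list,
                params: SimParams, min_clearance: int = MIN_CLEARANCE):
    """Draw a focal interval on [lo, hi] clear of occupied intervals.

    The event length is log-normal (clipped to stay focal); the position is
    drawn uniformly inside a free gap large enough to hold the event plus the
    clearance that keeps neighboring events from merging downstream.
    """
    length = int(np.exp(rng.normal(params.focal_length_log_mean,
                                   params.focal_length_log_sd)))
    length = int(np.clip(length, 200_000, int(0.45 * arm_len)))
    # free gaps between occupied intervals, shrunk by the clearance
    edges = [lo - min_clearance - 1]
    for s, e in sorted(occupied):
        edges.extend([s, e])
    edges.append(hi + min_clearance + 1)
    gaps = []
    for i in range(0, len(edges), 2):
        g_lo = max(lo, edges[i] + min_clearance + 1)
        g_hi = min(hi, edges[i + 1] - min_clearance - 1)
        if g_hi - g_lo + 1 >= length:
            gaps.append((g_lo, g_hi))
    if not gaps:
        return None
    g_lo, g_hi = gaps[int(rng.integers(len(gaps)))]
    start = int(rng.integers(g_lo, g_hi - length + 2))
    return start, start + length - 1


def simulate_sample(sample_id: str, params: SimParams, rng) -> tuple[list, list]:
    """Simulate one sample; returns (segment rows, ground-truth event rows)."""
    genome = params.genome
    purity = float(rng.uniform(*params.purity_range))
    lam_broad = rng.uniform(0, 2 * params.broad_rate) if params.broad_rate else 0.0
    lam_focal = rng.uniform(0, 2 * params.focal_rate) if params.focal_rate else 0.0
    n_broad = rng.poisson(lam_broad)
    n_focal = rng.poisson(lam_focal)

    arms = [(c, a) for c in genome.chromosomes for a in ("p", "q")]
    events = []          # (chrom, start, end, level, scope, arm, arm_fraction)
    taken_arms: set[tuple[str, str]] = set()
    taken_chroms: set[str] = set()

    for _ in range(int(n_broad)):
        free = [(c, a) for c, a in arms
                if (c, a) not in taken_arms and c not in taken_chroms]
        if not free:
            break
        level = _pick_level(rng, params.amplitude_levels)
        if rng.random() < params.chrom_event_prob:
            free_chroms = sorted({c for c, _ in free
                                  if (c, "p") not in taken_arms
                                  and (c, "q") not in taken_arms})
            if free_chroms:
                chrom = free_chroms[int(rng.integers(len(free_chroms)))]
                taken_chroms.add(chrom)
                events.append((chrom, 1, genome.chrom_lengths[chrom],
                               level, "chromosomal", "q", 1.0))
                continue
        chrom, arm = free[int(rng.integers(len(free)))]
        taken_arms.add((chrom, arm))
        lo, hi = genome.arm_bounds[chrom][arm]
        events.append((chrom, lo, hi, level, "arm_level", arm, 1.0))

    focal_occupied: dict[tuple[str, str], list] = {}
    for _ in range(int(n_focal)):
        free = [(c, a) for c, a in arms
                if (c, a) not in taken_arms and c not in taken_chroms]
        if not free:
            break
        placed = False
        order = rng.permutation(len(free))
        for k in order:
            chrom, arm = free[int(k)]
            lo, hi = genome.arm_bounds[chrom][arm]
            arm_len = hi - lo + 1
            occ = focal_occupied.setdefault((chrom, arm), [])
            drawn = _draw_focal(rng, lo, hi, arm_len, occ, params)
            if drawn is not None:
                start, end = drawn
                occ.append((start, end))
                level = _pick_level(rng, params.amplitude_levels)
                frac = (end - start + 1) / arm_len
                events.append((chrom, start, end, level, "focal", arm, frac))
                placed = True
                break
        if not placed:
            # every free arm is saturated: the genome holds no further focal
            # events, so the sample keeps the events placed so far
            break

    loh_arms: set[tuple[str, str]] = set()
    if params.baf_loh_rate > 0:
        for chrom, arm in arms:
            if (chrom, arm) in taken_arms or chrom in taken_chroms:
                continue
            if focal_occupied.get((chrom, arm)):
                continue  # focal events already occupy this arm
            if rng.random() < params.baf_loh_rate:
                loh_arms.add((chrom, arm))
                lo, hi = genome.arm_bounds[chrom][arm]
                events.append((chrom, lo, hi, "cn_loh", "arm_level", arm, 1.0))

    # tile every chromosome: events + neutral background
    seg_rows = []
    truth_rows = []
    for chrom in genome.chromosomes:
        length = genome.chrom_lengths[chrom]
        ch_events = sorted([e for e in events if e[0] == chrom],
                           key=lambda e: e[1])
        pos = 1
        pieces = []
        for (_, start, end, level, scope, arm, frac) in ch_events:
            if start > pos:
                pieces.append((pos, start - 1, "neutral", None))
            pieces.append((start, end, level, (scope, arm, frac)))
            pos = end + 1
        if pos <= length:
            pieces.append((pos, length, "neutral", None))
        for start, end, level, meta in pieces:
            if level == "neutral":
                true_log2, baf = 0.0, abs(rng.normal(0, 0.02))
            elif level == "cn_loh":
                true_log2, baf = 0.0, 0.35
            else:
                true_log2 = LEVEL_LOG2[level]
                baf = abs(rng.normal(0.2, 0.05))
            observed = float(dilute(true_log2, purity))
            observed += float(rng.normal(0, params.noise_sd))
            seg_rows.append({
                "sample_id": sample_id, "chrom": chrom, "start": int(start),
                "end": int(end), "seg_mean": observed, "purity": purity,
                "baf": baf,
            })
        for (_, start, end, level, scope, arm, frac) in ch_events:
            truth_rows.append({
                "sample_id": sample_id, "chrom": chrom, "start": int(start),
                "end": int(end), "level": level, "scope": scope, "arm": arm,
                "arm_fraction": frac, "weight": WEIGHTS[level],
                "purity": purity,
            })
    return seg_rows, truth_rows


def simulate_cohort(params: SimParams) -> tuple[SampleTable, pd.DataFrame]:
    """Simulate a cohort; returns (SampleTable, ground-truth event frame)."""
    rng = np.random.default_rng(params.seed)
    seg_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i in range(params.n_samples):
        sid = f"S{i + 1:04d}"
        segs, truth = simulate_sample(sid, params, rng)
        seg_rows.extend(segs)
        truth_rows.extend(truth)
    segments = pd.DataFrame(seg_rows, columns=SEGMENT_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "start", "end", "level", "scope",
                 "arm", "arm_fraction", "weight", "purity"],
    )
    table = SampleTable(segments)
    ann = pd.DataFrame(index=pd.Index(table.samples, name="sample_id"))
    return SampleTable(segments, ann), truth


def ground_truth_scores(truth: pd.DataFrame,
                        sample_ids=None) -> pd.DataFrame:
    """Expected (BCS, FCS) per sample straight from the ground-truth events,
    bypassing all segment processing."""
    rows = {}
    ids = list(sample_ids) if sample_ids is not None else \
        list(dict.fromkeys(truth["sample_id"]))
    for sid in ids:
        rows[sid] = {"bcs": 0, "fcs": 0}
    for ev in truth.itertuples():
        entry = rows.setdefault(ev.sample_id, {"bcs": 0, "fcs": 0})
        if ev.scope == "focal":
            entry["fcs"] += ev.weight * coverage_weight(ev.arm_fraction)
        else:
            entry["bcs"] += ev.weight
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out
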