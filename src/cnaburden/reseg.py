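"""Purity correction, re-segmentation and scope classification.

Re-segmentation homogenizes segmented copy-number profiles before scoring:

1. log2 ratios are baseline-corrected for tumor purity by inverting the
   two-component tumor/normal admixture, ``N = log2((2**n + r - 1) / r)``,
   where *n* is the observed log2 ratio and *r* the tumor-cell fraction.
   With r = 1 the correction is the identity; corrected values are floored at
   the cap ``log2(0.2)`` (~ -2.32), the deepest loss representable once a
   heterozygous deletion is diluted at the minimal accepted purity of 40%.
2. near-neutral segments (|log2| below a deviation-from-zero threshold) are
   set to exactly 0; adjacent segments closer than a maximum gap whose
   amplitudes (and BAF deviations, when both known) agree within tolerances
   are merged with length-weighted means; residual segments shorter than a
   minimum length are absorbed into a compatible neighbor or dropped. The
   three steps iterate to a fixpoint, so re-segmentation is idempotent.
3. each segment is tagged *chromosomal* / *arm-level* / *focal* from the
   fraction of the chromosome (>= 90%) or of its dominant arm (>= 50%) that
   it covers; centromere-gap base pairs are excluded from both denominators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome import GenomeReference
from .io import SampleTable

#: deepest corrected log2 ratio: a heterozygous deletion at 40% purity
CAP_FLOOR = math.log2(0.2)


@dataclass(frozen=True)
class ReSegParams:
    """Tunable re-segmentation thresholds (defaults match common practice
    for SNP-array segment profiles)."""

    min_seg_length: int = 100_000          # bp; shorter segments are absorbed/dropped
    min_amp_dev_zero: float = 0.16         # log2; |m| below this is copy-neutral
    max_gap: int = 1_000_000               # bp between mergeable neighbors
    max_amp_dev_between: float = 0.16      # log2 difference allowing a merge
    max_baf_dev_between: float = 0.1       # BAF-deviation difference allowing a merge
    chromosomal_frac: float = 0.90         # chromosome fraction tagging "chromosomal"
    armlevel_frac: float = 0.50            # arm fraction tagging "arm_level"
    purity_floor: float = 0.40             # purities below are raised to this
    cap_floor: float = CAP_FLOOR           # floor for corrected log2 ratios

    def __post_init__(self):
        if self.min_seg_length <= 0 or self.max_gap <= 0:
            raise ValidationError("lengths must be positive")
        for frac in (self.chromosomal_frac, self.armlevel_frac, self.purity_floor):
            if not 0 < frac <= 1:
                raise ValidationError("fractions must lie in (0, 1]")
        if self.chromosomal_frac <= self.armlevel_frac:
            raise ValidationError("chromosomal_frac must exceed armlevel_frac")


def adjust_for_purity(seg_mean, purity, params: ReSegParams = ReSegParams()):
    """Baseline-correct observed log2 ratio(s) for tumor purity.

    Accepts scalars or numpy arrays. Purity below ``params.purity_floor`` is
    raised to the floor first; corrected values are floored at
    ``params.cap_floor``, and a non-positive admixture argument (a deep loss
    observed at low purity) maps to the cap rather than raising.
    """
    n = np.asarray(seg_mean, dtype=float)
    r = np.asarray(purity, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise ValidationError("purity must lie in (0, 1]")
    r = np.maximum(r, params.purity_floor)
    arg = (np.exp2(n) + r - 1.0) / r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(arg > 0, np.log2(np.maximum(arg, 1e-300)), params.cap_floor)
    out = np.maximum(out, params.cap_floor)
    if np.isscalar(seg_mean) and np.isscalar(purity):
        return float(out)
    return out


def correct_sample_table(table: SampleTable,
                         params: ReSegParams = ReSegParams()) -> SampleTable:
    """Apply the purity correction to every segment (missing purity -> 1)."""
    df = table.segments.copy()
    purity = df["purity"].fillna(1.0).to_numpy()
    df["seg_mean"] = adjust_for_purity(df["seg_mean"].to_numpy(), purity, params)
    return table.with_segments(df)


def _weighted(values, lengths):
    return float(np.dot(values, lengths) / np.sum(lengths))


def _merge_pass(segs: list[dict], params: ReSegParams) -> tuple[list[dict], bool]:
    """One left-to-right pass merging compatible adjacent segments."""
    if not segs:
        return segs, False
    out = [segs[0]]
    changed = False
    for nxt in segs[1:]:
        cur = out[-1]
        if cur["chrom"] != nxt["chrom"]:
            out.append(nxt)
            continue
        gap = nxt["start"] - cur["end"] - 1
        if gap < 0:
            raise ValidationError("overlapping segments passed to merge_segments")
        ok = gap <= params.max_gap and abs(
            nxt["seg_mean"] - cur["seg_mean"]) <= params.max_amp_dev_between
        if ok and not (math.isnan(cur["baf"]) or math.isnan(nxt["baf"])):
            ok = abs(nxt["baf"] - cur["baf"]) <= params.max_baf_dev_between
        if ok:
            l1 = cur["end"] - cur["start"] + 1
            l2 = nxt["end"] - nxt["start"] + 1
            cur["seg_mean"] = _weighted([cur["seg_mean"], nxt["seg_mean"]], [l1, l2])
            if not (math.isnan(cur["baf"]) or math.isnan(nxt["baf"])):
                cur["baf"] = _weighted([cur["baf"], nxt["baf"]], [l1, l2])
            else:
                cur["baf"] = float("nan")
            cur["end"] = nxt["end"]
            changed = True
        else:
            out.append(nxt)
    return out, changed


def _short_pass(segs: list[dict], params: ReSegParams) -> tuple[list[dict], bool]:
    """Absorb or drop segments shorter than the minimum length.

    A short segment is absorbed into the neighbor (same chromosome, within
    the merge gap) with the smaller amplitude difference (ties: left
    neighbor); with no eligible neighbor it is dropped.
    """
    changed = False
    i = 0
    while i < len(segs):
        seg = segs[i]
        if seg["end"] - seg["start"] + 1 >= params.min_seg_length:
            i += 1
            continue
        candidates = []
        if i > 0:
            left = segs[i - 1]
            if (left["chrom"] == seg["chrom"]
                    and seg["start"] - left["end"] - 1 <= params.max_gap):
                candidates.append(("left", i - 1, abs(left["seg_mean"] - seg["seg_mean"])))
        if i + 1 < len(segs):
            right = segs[i + 1]
            if (right["chrom"] == seg["chrom"]
                    and right["start"] - seg["end"] - 1 <= params.max_gap):
                candidates.append(("right", i + 1, abs(right["seg_mean"] - seg["seg_mean"])))
        if candidates:
            candidates.sort(key=lambda c: (c[2], c[0] != "left"))
            _, j, _ = candidates[0]
            nb = segs[j]
            l_nb = nb["end"] - nb["start"] + 1
            l_seg = seg["end"] - seg["start"] + 1
            nb["seg_mean"] = _weighted([nb["seg_mean"], seg["seg_mean"]], [l_nb, l_seg])
            if not (math.isnan(nb["baf"]) or math.isnan(seg["baf"])):
                nb["baf"] = _weighted([nb["baf"], seg["baf"]], [l_nb, l_seg])
            nb["start"] = min(nb["start"], seg["start"])
            nb["end"] = max(nb["end"], seg["end"])
        del segs[i]
        changed = True
    return segs, changed


def merge_segments(segments: pd.DataFrame,
                   params: ReSegParams = ReSegParams()) -> pd.DataFrame:
    """Re-segment one sample's (purity-corrected) segments to a fixpoint.

    Input must be sorted by chromosome and start and non-overlapping; the
    output satisfies the same contract and re-running is a no-op.
    """
    if segments.empty:
        return segments.copy()
    if segments["sample_id"].nunique() > 1:
        raise ValidationError("merge_segments expects segments of one sample")
    by_chrom = segments.groupby("chrom", sort=False)
    for _, sub in by_chrom:
        if not sub["start"].is_monotonic_increasing:
            raise ValidationError("segments must be sorted by chromosome and start")
    segs = segments.to_dict("records")
    for _ in range(1000):
        changed = False
        for seg in segs:
            if abs(seg["seg_mean"]) < params.min_amp_dev_zero and seg["seg_mean"] != 0.0:
                seg["seg_mean"] = 0.0
                changed = True
        segs, ch = _merge_pass(segs, params)
        changed |= ch
        segs, ch = _short_pass(segs, params)
        changed |= ch
        if not changed:
            break
    else:  # pragma: no cover - defensive
        warnings.warn("re-segmentation did not reach a fixpoint in 1000 rounds")
    out = pd.DataFrame(segs, columns=segments.columns)
    return out.reset_index(drop=True)


def resegment(table: SampleTable, params: ReSegParams = ReSegParams(),
              correct_purity: bool = True, skip: bool = False) -> SampleTable:
    """Purity-correct and re-segment a whole cohort.

    ``skip=True`` bypasses merging (original boundaries kept) but still
    applies the purity correction when requested.
    """
    out = correct_sample_table(table, params) if correct_purity else table
    if skip:
        return out
    pieces = [merge_segments(sub, params) for _, sub in out.per_sample()]
    merged = pd.concat(pieces, ignore_index=True) if pieces else out.segments
    return out.with_segments(merged)


def _overlap(lo1: int, hi1: int, lo2: int, hi2: int) -> int:
    return max(0, min(hi1, hi2) - max(lo1, lo2) + 1)


def classify_scope(chrom: str, start: int, end: int, genome: GenomeReference,
                   params: ReSegParams = ReSegParams()) -> dict:
    """Tag one segment as chromosomal / arm_level / focal.

    Returns a dict with scope, arm (p/q), arm_fraction and chrom_fraction.
    The centromere gap contributes to neither the numerator nor the
    denominators; a segment entirely inside the gap is focal with
    arm_fraction 0 (warned).
    """
    if chrom not in genome.chrom_lengths:
        raise ValidationError(f"{chrom} not in genome reference")
    if start < 1 or end > genome.chrom_lengths[chrom]:
        raise ValidationError(
            f"segment {chrom}:{start}-{end} outside chromosome bounds")
    bounds = genome.arm_bounds[chrom]
    cov = {arm: _overlap(start, end, *bounds[arm]) for arm in ("p", "q")}
    arm_lens = {arm: genome.arm_length(chrom, arm) for arm in ("p", "q")}
    if cov["p"] == cov["q"] == 0:
        warnings.warn(
            f"segment {chrom}:{start}-{end} lies entirely in the centromere gap",
            stacklevel=2,
        )
        return {"scope": "focal", "arm": "q", "arm_fraction": 0.0,
                "chrom_fraction": 0.0}
    arm = "p" if cov["p"] >= cov["q"] else "q"
    arm_fraction = cov[arm] / arm_lens[arm]
    chrom_fraction = (cov["p"] + cov["q"]) / (arm_lens["p"] + arm_lens["q"])
    if chrom_fraction >= params.chromosomal_frac:
        scope = "chromosomal"
    elif arm_fraction >= params.armlevel_frac:
        scope = "arm_level"
    else:
        scope = "focal"
    return {"scope": scope, "arm": arm, "arm_fraction": arm_fraction,
            "chrom_fraction": chrom_fraction}


def classify_table(table: SampleTable, genome: GenomeReference,
                   params: ReSegParams = ReSegParams()) -> pd.DataFrame:
    """Classify every segment; returns the segment frame with scope columns."""
    df = table.segments.copy()
    tags = [
        classify_scope(row.chrom, row.start, row.end, genome, params)
        for row in df.itertuples()
    ]
    tag_df = pd.DataFrame(tags, index=df.index)
    return pd.concat([df, tag_df], axis=1)


def sweep_armlevel_counts(table: SampleTable, genome: GenomeReference,
                          fractions=(0.40, 0.50, 0.70),
                          params: ReSegParams = ReSegParams()) -> pd.Series:
    """Count arm_level-tagged segments for a sweep of arm-fraction thresholds
    (diagnostic mirroring how broad-event calls respond to the threshold)."""
    counts = {}
    for frac in fractions:
        p = replace(params, armlevel_frac=frac)
        classified = classify_table(table, genome, p)
        counts[frac] = int((classified["scope"] == "arm_level").sum())
    return pd.Series(counts, name="arm_level_segments")
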