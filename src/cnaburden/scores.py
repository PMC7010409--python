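"""Per-sample CNA burden scores: BCS, FCS, GCS and altered-genome fractions.

Every non-neutral segment receives a CNA level from its log2 ratio and an
integer weight A:

=============  ==================  ======  ======
log2 threshold CNA level           copies  A
=============  ==================  ======  ======
>= 1           high-level gain     >= 4    3
>= 0.58        medium-level gain   [3,4)   2
>= 0.2         low-level gain      ~2.3-3  1
<= -0.2        low-level loss      ~1.7-1  1
<= -1          medium-level loss   (0.6,1] 2
<= -1.74       high-level loss     <= 0.6  3
|log2| < 0.2,
BAF dev >= .25 CN-LOH              ~2      2
=============  ==================  ======  ======

The broad score BCS of a sample is the sum of weights A over its chromosomal
and arm-level events. The focal score FCS additionally multiplies each focal
event's weight by a coverage score L in 1..4 growing with the fraction of the
arm covered (<=5%, <=15%, <=30%, >30%). The global score GCS is the sum of
the cohort z-normalized BCS and FCS, so it is defined relative to a cohort.
Altered-genome fractions divide the summed lengths of non-neutral segments
(all / broad-only / focal-only) by the total genome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome import GenomeReference
from .io import SampleTable
from .reseg import ReSegParams, classify_table, resegment

GAIN_LEVELS = ("low_gain", "medium_gain", "high_gain")
LOSS_LEVELS = ("low_loss", "medium_loss", "high_loss")
WEIGHTS = {
    "high_gain": 3, "medium_gain": 2, "low_gain": 1,
    "neutral": 0,
    "low_loss": 1, "medium_loss": 2, "high_loss": 3,
    "cn_loh": 2,
}


@dataclass(frozen=True)
class AmplitudeThresholds:
    """log2-ratio cutoffs defining the CNA levels (inclusive at the bound).

    The defaults correspond to integer copy-number landmarks on a diploid
    background: log2(4/2)=1, log2(3/2)~0.58, log2(1/2)=-1, log2(0.6/2)~-1.74;
    |0.2| (~2.3 / ~1.7 copies) bounds the low-level calls.
    """

    high_gain: float = 1.0
    medium_gain: float = 0.58
    low_gain: float = 0.2
    low_loss: float = -0.2
    medium_loss: float = -1.0
    high_loss: float = -1.74
    cnloh_baf: float = 0.25

    def __post_init__(self):
        if not (self.high_gain > self.medium_gain > self.low_gain > 0
                > self.low_loss > self.medium_loss > self.high_loss):
            raise ValidationError("amplitude thresholds must be ordered")


DEFAULT_THRESHOLDS = AmplitudeThresholds()


class CnaCall(NamedTuple):
    level: str
    weight: int


def call_level(seg_mean: float, baf: float | None = None,
               thresholds: AmplitudeThresholds = DEFAULT_THRESHOLDS) -> CnaCall:
    """Assign a CNA level and weight to one segment.

    ``baf`` is the B-allele-frequency *deviation* from the heterozygous 0.5
    band; raw frequencies in (0.5, 1] are folded. A near-neutral segment with
    deviation >= 0.25 is called copy-neutral LOH (weight 2).
    """
    if not np.isfinite(seg_mean):
        raise ValidationError("seg_mean must be finite")
    t = thresholds
    if seg_mean >= t.high_gain:
        return CnaCall("high_gain", 3)
    if seg_mean >= t.medium_gain:
        return CnaCall("medium_gain", 2)
    if seg_mean >= t.low_gain:
        return CnaCall("low_gain", 1)
    if seg_mean <= t.high_loss:
        return CnaCall("high_loss", 3)
    if seg_mean <= t.medium_loss:
        return CnaCall("medium_loss", 2)
    if seg_mean <= t.low_loss:
        return CnaCall("low_loss", 1)
    if baf is not None and not np.isnan(baf):
        dev = abs(baf - 0.5) if baf > 0.5 else baf
        if dev >= t.cnloh_baf:
            return CnaCall("cn_loh", 2)
    return CnaCall("neutral", 0)


def coverage_weight(arm_fraction: float) -> int:
    """Coverage score L for a focal event from its arm-coverage fraction."""
    if arm_fraction < 0:
        raise ValidationError("arm_fraction must be non-negative")
    if arm_fraction <= 0.05:
        return 1
    if arm_fraction <= 0.15:
        return 2
    if arm_fraction <= 0.30:
        return 3
    return 4


def call_table(classified: pd.DataFrame,
               thresholds: AmplitudeThresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Add level/weight/L columns to a classified segment frame."""
    df = classified.copy()
    calls = [
        call_level(row.seg_mean, row.baf, thresholds)
        for row in df.itertuples()
    ]
    df["level"] = [c.level for c in calls]
    df["weight"] = [c.weight for c in calls]
    df["coverage_l"] = [
        coverage_weight(af) if scope == "focal" else 0
        for scope, af in zip(df["scope"], df["arm_fraction"])
    ]
    return df


def score_sample(called: pd.DataFrame) -> tuple[int, int]:
    """(BCS, FCS) for one sample's called + classified segments.

    BCS sums weights A over chromosomal and arm-level events; FCS sums A*L
    over focal events. Neutral segments contribute nothing.
    """
    if called.empty:
        return 0, 0
    if called["sample_id"].nunique() > 1:
        raise ValidationError("score_sample expects segments of one sample")
    broad = called["scope"].isin(("chromosomal", "arm_level"))
    bcs = int(called.loc[broad, "weight"].sum())
    focal = called["scope"] == "focal"
    fcs = int((called.loc[focal, "weight"] * called.loc[focal, "coverage_l"]).sum())
    return bcs, fcs


def altered_fraction(called: pd.DataFrame, genome: GenomeReference,
                     which: str = "all") -> float:
    """Fraction of the genome covered by non-neutral segments of one sample.

    ``which`` selects all events, broad-only (chromosomal + arm-level) or
    focal-only; lengths are end - start + 1.
    """
    if which not in ("all", "broad", "focal"):
        raise ValidationError(f"unknown selector {which!r}")
    sel = called["weight"] > 0
    if which == "broad":
        sel &= called["scope"].isin(("chromosomal", "arm_level"))
    elif which == "focal":
        sel &= called["scope"] == "focal"
    lengths = called.loc[sel, "end"] - called.loc[sel, "start"] + 1
    return float(lengths.sum() / genome.hg_length)


def normalize_scores(rows: pd.DataFrame) -> pd.DataFrame:
    """Fill normBCS / normFCS (cohort z-scores, n-1 sd) and GCS = sum of both.

    A degenerate cohort (all-equal scores, sd 0) gets zeros with a warning.
    """
    if len(rows) < 2:
        warnings.warn("normalization needs >= 2 samples; scores set to 0")
    out = rows.copy()
    for col, norm in (("bcs", "norm_bcs"), ("fcs", "norm_fcs")):
        sd = out[col].std(ddof=1) if len(out) > 1 else 0.0
        if not sd > 0:
            warnings.warn(f"all {col.upper()} values equal; norm_{col} set to 0")
            out[norm] = 0.0
        else:
            out[norm] = (out[col] - out[col].mean()) / sd
    out["gcs"] = out["norm_bcs"] + out["norm_fcs"]
    return out


def score_cohort(table: SampleTable, genome: GenomeReference,
                 params: ReSegParams = ReSegParams(),
                 thresholds: AmplitudeThresholds = DEFAULT_THRESHOLDS,
                 reseg: bool = True, correct_purity: bool = True) -> pd.DataFrame:
    """Full scoring pipeline: purity correction, re-segmentation, scope
    classification, CNA calling, scores and altered fractions per sample.

    Returns one row per sample with columns sample_id, bcs, fcs, norm_bcs,
    norm_fcs, gcs, alt_fract, broad_alt_fract, focal_alt_fract.
    """
    processed = resegment(table, params, correct_purity=correct_purity,
                          skip=not reseg)
    classified = classify_table(processed, genome, params)
    called = call_table(classified, thresholds)
    rows = []
    for sid, sub in called.groupby("sample_id", sort=False):
        bcs, fcs = score_sample(sub)
        rows.append({
            "sample_id": sid, "bcs": bcs, "fcs": fcs,
            "alt_fract": altered_fraction(sub, genome, "all"),
            "broad_alt_fract": altered_fraction(sub, genome, "broad"),
            "focal_alt_fract": altered_fraction(sub, genome, "focal"),
        })
    scores = pd.DataFrame(rows)
    if scores.empty:
        return scores
    return normalize_scores(scores)[
        ["sample_id", "bcs", "fcs", "norm_bcs", "norm_fcs", "gcs",
         "alt_fract", "broad_alt_fract", "focal_alt_fract"]
    ]
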