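"""Independent brute-force oracles, kept deliberately naive.

The score oracle recomputes scope, level and coverage score per segment from
scratch with its own constants and plain Python, so it shares no code path
with the package implementation it checks.
"""


def oracle_call(seg_mean, baf):
    if seg_mean >= 1:
        return "high_gain", 3
    if seg_mean >= 0.58:
        return "medium_gain", 2
    if seg_mean >= 0.2:
        return "low_gain", 1
    if seg_mean <= -1.74:
        return "high_loss", 3
    if seg_mean <= -1:
        return "medium_loss", 2
    if seg_mean <= -0.2:
        return "low_loss", 1
    if baf is not None and baf == baf and baf >= 0.25:
        return "cn_loh", 2
    return "neutral", 0


def oracle_coverage(frac):
    if frac <= 0.05:
        return 1
    if frac <= 0.15:
        return 2
    if frac <= 0.30:
        return 3
    return 4


def oracle_scores(segments, genome, chromosomal_frac=0.90, armlevel_frac=0.50):
    """(BCS, FCS) for one sample's segments: list of dicts with chrom, start,
    end, seg_mean, baf. Scope is recomputed per segment from arm bounds."""
    bcs = fcs = 0
    for seg in segments:
        level, weight = oracle_call(seg["seg_mean"], seg.get("baf"))
        if weight == 0:
            continue
        bounds = genome.arm_bounds[seg["chrom"]]
        cov = {}
        for arm in ("p", "q"):
            lo, hi = bounds[arm]
            cov[arm] = max(0, min(seg["end"], hi) - max(seg["start"], lo) + 1)
        arm = "p" if cov["p"] >= cov["q"] else "q"
        arm_len = {a: bounds[a][1] - bounds[a][0] + 1 for a in ("p", "q")}
        if cov["p"] + cov["q"] == 0:
            frac_arm, frac_chrom = 0.0, 0.0
        else:
            frac_arm = cov[arm] / arm_len[arm]
            frac_chrom = (cov["p"] + cov["q"]) / (arm_len["p"] + arm_len["q"])
        if frac_chrom >= chromosomal_frac or frac_arm >= armlevel_frac:
            bcs += weight
        else:
            fcs += weight * oracle_coverage(frac_arm)
    return bcs, fcs
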