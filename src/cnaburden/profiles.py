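"""Genome-window profiles: length-weighted window means, CNA states,
frequencies, correlation matrices and hierarchical clustering.

A window set tiles the non-centromeric genome at a chosen resolution
(chromosome arms, half-arms, major cytobands, sub-cytobands, or fixed-width
windows of 40/30/20/10/5/1 Mb). For each sample and window *i* the window
mean is ``W(i) = sum_t S_t * l_t / L(i)`` where ``S_t`` is a segment's log2
ratio, ``l_t`` its overlap with the window and ``L(i)`` the window length;
uncovered base pairs therefore contribute 0, diluting sparse coverage toward
neutral. States (gain / loss / neutral) come from inclusive cutoffs at
+0.2 / -0.2 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ConfigError, ValidationError
from .genome import GenomeReference
from .io import SampleTable
from .reseg import ReSegParams, classify_table

WINDOW_KINDS = ("arm", "half_arm", "cytoband", "sub_cytoband", "fixed")
FIXED_WIDTHS = tuple(int(w * 1e6) for w in (40, 30, 20, 10, 5, 1))


@dataclass(frozen=True, eq=False)
class WindowSet:
    """Ordered, non-overlapping windows covering the non-centromeric genome.

    ``windows`` columns: window_id, chrom, start, end (1-based inclusive).
    """

    kind: str
    windows: pd.DataFrame = field(repr=False)
    fixed_width: int | None = None

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def ids(self) -> list[str]:
        return list(self.windows["window_id"])


def _short(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def make_windows(genome: GenomeReference, kind: str,
                 fixed_width: int | None = None) -> WindowSet:
    """Construct a window set of the requested kind.

    ``fixed_width`` (bp) is required iff kind == "fixed" and must be one of
    40/30/20/10/5/1 Mb. Arm windows span whole arms; half-arm windows split
    each arm at its midpoint; cytoband windows merge sub-bands into their
    major band (e.g. 8q24.1/8q24.2 -> 8q24); sub-cytoband windows are the
    full-resolution band rows; fixed windows tile each arm from its start,
    truncating the last tile.
    """
    if kind not in WINDOW_KINDS:
        raise ValidationError(f"unknown window kind {kind!r}")
    if (fixed_width is None) != (kind != "fixed"):
        raise ConfigError("fixed_width must be given exactly when kind='fixed'")
    rows = []
    if kind in ("arm", "half_arm", "fixed"):
        if kind == "fixed" and fixed_width not in FIXED_WIDTHS:
            raise ConfigError(
                f"fixed_width must be one of {sorted(FIXED_WIDTHS)} bp")
        for chrom in genome.chromosomes:
            for arm in ("p", "q"):
                lo, hi = genome.arm_bounds[chrom][arm]
                if hi < lo:
                    continue
                name = f"{_short(chrom)}{arm}"
                if kind == "arm":
                    rows.append((name, chrom, lo, hi))
                elif kind == "half_arm":
                    mid = (lo + hi) // 2
                    rows.append((f"{name}.1", chrom, lo, mid))
                    rows.append((f"{name}.2", chrom, mid + 1, hi))
                else:
                    k = 1
                    pos = lo
                    while pos <= hi:
                        end = min(pos + fixed_width - 1, hi)
                        rows.append((f"{name}:w{k}", chrom, pos, end))
                        pos = end + 1
                        k += 1
    else:
        bands = genome.cytobands
        non_acen = bands[bands["stain"] != "acen"]
        if kind == "sub_cytoband":
            for r in non_acen.itertuples():
                rows.append((f"{_short(r.chrom)}{r.name}", r.chrom,
                             int(r.start) + 1, int(r.end)))
        else:
            major = non_acen.assign(
                major=non_acen["name"].str.split(".").str[0])
            # contiguous runs of one major band merge into one window
            grp = (major["major"] != major["major"].shift()).cumsum()
            for (_, sub) in major.groupby([major["chrom"], grp], sort=False):
                rows.append((
                    f"{_short(sub['chrom'].iloc[0])}{sub['major'].iloc[0]}",
                    sub["chrom"].iloc[0],
                    int(sub["start"].min()) + 1,
                    int(sub["end"].max()),
                ))
    df = pd.DataFrame(rows, columns=["window_id", "chrom", "start", "end"])
    order = {c: i for i, c in enumerate(genome.chromosomes)}
    df = df.sort_values(["chrom", "start"],
                        key=lambda s: s.map(order) if s.name == "chrom" else s,
                        kind="stable").reset_index(drop=True)
    return WindowSet(kind=kind, windows=df, fixed_width=fixed_width)


@dataclass(eq=False)
class ProfileMatrix:
    """samples x windows matrix of length-weighted mean log2 ratios."""

    means: pd.DataFrame                 # index: sample_id, columns: window_id
    windows: WindowSet
    gain_cut: float = 0.2
    loss_cut: float = -0.2

    @property
    def samples(self) -> list[str]:
        return list(self.means.index)


def profile_sample(segments: pd.DataFrame, windows: WindowSet) -> np.ndarray:
    """Window means W for one sample's segments (vector over windows)."""
    win = windows.windows
    out = np.zeros(len(win))
    for chrom, wsub in win.groupby("chrom", sort=False):
        ssub = segments[segments["chrom"] == chrom]
        if ssub.empty:
            continue
        ws = wsub["start"].to_numpy()[:, None]
        we = wsub["end"].to_numpy()[:, None]
        ss = ssub["start"].to_numpy()[None, :]
        se = ssub["end"].to_numpy()[None, :]
        ov = np.clip(np.minimum(we, se) - np.maximum(ws, ss) + 1, 0, None)
        means = ssub["seg_mean"].to_numpy()
        out[wsub.index] = (ov @ means) / (we[:, 0] - ws[:, 0] + 1)
    return out


def profile_cohort(table: SampleTable, windows: WindowSet,
                   scope_filter: str = "all",
                   genome: GenomeReference | None = None,
                   params: ReSegParams = ReSegParams(),
                   gain_cut: float = 0.2, loss_cut: float = -0.2) -> ProfileMatrix:
    """Profile every sample of a cohort.

    ``scope_filter`` of "broad"/"focal" restricts the contributing segments
    to non-neutral events of that scope (requires ``genome`` to classify).
    """
    if scope_filter not in ("all", "broad", "focal"):
        raise ValidationError(f"unknown scope filter {scope_filter!r}")
    segs = table.segments
    if scope_filter != "all":
        if genome is None:
            raise ConfigError("scope filtering requires a genome reference")
        classified = classify_table(table, genome, params)
        altered = classified["seg_mean"].abs() >= min(gain_cut, -loss_cut)
        if scope_filter == "broad":
            keep = altered & classified["scope"].isin(("chromosomal", "arm_level"))
        else:
            keep = altered & (classified["scope"] == "focal")
        segs = classified[keep]
    mat = {}
    for sid in table.samples:
        mat[sid] = profile_sample(segs[segs["sample_id"] == sid], windows)
    means = pd.DataFrame.from_dict(mat, orient="index", columns=windows.ids)
    means.index.name = "sample_id"
    return ProfileMatrix(means=means, windows=windows,
                         gain_cut=gain_cut, loss_cut=loss_cut)


def call_states(profile: ProfileMatrix) -> pd.DataFrame:
    """Per-cell gain / loss / neutral states from the inclusive cutoffs."""
    if profile.gain_cut <= profile.loss_cut:
        raise ConfigError("gain_cut must exceed loss_cut")
    w = profile.means
    states = pd.DataFrame("neutral", index=w.index, columns=w.columns)
    states = states.mask(w >= profile.gain_cut, "gain")
    states = states.mask(w <= profile.loss_cut, "loss")
    return states


def frequencies(states: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window gain/loss percentages and per-sample gained/lost counts."""
    n = len(states)
    per_window = pd.DataFrame({
        "gain_pct": (states == "gain").sum(axis=0) / n * 100.0,
        "loss_pct": (states == "loss").sum(axis=0) / n * 100.0,
    })
    per_window.index.name = "window_id"
    per_sample = pd.DataFrame({
        "gained_windows": (states == "gain").sum(axis=1),
        "lost_windows": (states == "loss").sum(axis=1),
    })
    return per_window, per_sample


def correlate_profiles(profile: ProfileMatrix, method: str = "pearson",
                       axis: str = "samples",
                       groups: pd.Series | None = None) -> pd.DataFrame:
    """Correlation matrix between sample (or group-average) profiles.

    Zero-variance profiles yield NaN rows/columns (undefined, not an error);
    the diagonal is forced to 1.
    """
    if method not in ("pearson", "spearman", "kendall"):
        raise ValidationError(f"unknown correlation method {method!r}")
    if axis == "samples":
        data = profile.means
    elif axis == "groups":
        if groups is None:
            raise ConfigError("axis='groups' requires group labels")
        data = profile.means.groupby(groups.reindex(profile.means.index)).mean()
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    if len(data) < 2:
        raise ValidationError("need >= 2 items to correlate")
    corr = data.T.corr(method=method)
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(eq=False)
class ClusterResult:
    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    newick: str


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster(corr: pd.DataFrame) -> ClusterResult:
    """Complete-linkage hierarchical clustering on distance 1 - correlation.

    Undefined (NaN) correlations are imputed to 0 with a warning. The leaf
    order supports heatmap reordering; the dendrogram serializes to Newick.
    """
    labels = list(corr.index)
    c = corr.to_numpy(dtype=float).copy()
    if np.isnan(c).any():
        warnings.warn("undefined correlations imputed to 0 before clustering")
        c = np.nan_to_num(c, nan=0.0)
    if len(labels) == 1:
        return ClusterResult(np.empty((0, 4)), labels, labels, f"{labels[0]};")
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    tree = hierarchy.to_tree(link)
    order = [labels[i] for i in hierarchy.leaves_list(link)]
    return ClusterResult(link, labels, order, _to_newick(tree, labels) + ";")
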