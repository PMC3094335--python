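"""Differential-regulation callers for paired (uninfected, infected) data.

Four families of caller are provided:

* the percentile fold-change rule — log2 ratios above the 81.25th
  percentile of the positive ratios are "up", below the 18.75th
  percentile of the negative ratios "down" (both tails hold 18.75 % of
  their sign class);
* two geometric callers working on the log10–log10 scatter of infected
  against uninfected expression, designed to be less permissive at low
  expression, where the ratio noise is largest: a binned percentile
  envelope with a fitted hyperbola after 45° rotation, and a band
  method thresholding on a line through local 99th-percentile offsets;
* the legacy platform rules used for older oligo- and cDNA-array data.

Transcripts expressed in only one condition have an infinite or
undefined ratio; they are excluded from ratio-based calling and flagged
separately (``infection_specific`` / ``lost_on_infection``), since a
transcript induced from zero is arguably the most infection-specific
signal there is.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ("transcript_id", "control", "infected")


class FitError(RuntimeError):
    pass


@dataclass
class PercentileConfig:
    up_percentile: float = 81.25
    down_percentile: float = 18.75
    epsilon: float = 0.00001

    def __post_init__(self):
        if not 0 < self.down_percentile < self.up_percentile < 100:
            raise ValueError("need 0 < down < up < 100")


@dataclass
class EnvelopeConfig:
    """Binned-envelope caller settings: number of equal-width bins along
    the rotated abscissa and the percentile cut-off (typically 0.5–10 %)
    defining each bin's upper and lower limits."""

    n_bins: int = 20
    cutoff_percent: float = 2.0
    min_bin_count: int = 3
    d_grid_size: int = 200

    def __post_init__(self):
        if self.n_bins < 3:
            raise ValueError("need at least 3 bins")
        if not 0 < self.cutoff_percent < 50:
            raise ValueError("cutoff percent must be in (0, 50)")


@dataclass
class BandConfig:
    anchor_low: tuple[float, float] = (20.0, 30.0)
    anchor_high: tuple[float, float] = (70.0, 80.0)
    tail_percentile: float = 99.0  # down calls use the axis-swapped mirror
    ortho_bin_halfwidth: float = 0.05  # fraction of the along-line range

    def __post_init__(self):
        lo, hi = self.anchor_low, self.anchor_high
        if not (0 < lo[0] < lo[1] <= hi[0] < hi[1] < 100):
            raise ValueError("anchor percentile intervals must be disjoint in (0,100)")


@dataclass
class RegulationCall:
    transcript_id: str
    verdict: str  # up | down | none
    method: str
    score: float = float("nan")
    flags: tuple[str, ...] = ()


def up_set(calls: Iterable[RegulationCall]) -> set[str]:
    return {c.transcript_id for c in calls if c.verdict == "up"}


def down_set(calls: Iterable[RegulationCall]) -> set[str]:
    return {c.transcript_id for c in calls if c.verdict == "down"}


def calls_to_frame(calls: Iterable[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": c.transcript_id,
                "verdict": c.verdict,
                "method": c.method,
                "score": c.score,
                "flags": ",".join(c.flags),
            }
            for c in calls
        ]
    )


def _as_pairs(pairs) -> pd.DataFrame:
    df = pd.DataFrame(pairs)
    if not set(PAIR_COLUMNS) <= set(df.columns):
        raise ValueError(f"paired table needs columns {PAIR_COLUMNS}")
    if ((df["control"] < 0) | (df["infected"] < 0)).any():
        raise ValueError("expression values must be non-negative")
    return df


# ---------------------------------------------------------------------------
# fold changes

def log2_fold_changes(pairs) -> pd.DataFrame:
    """log2(infected/control) with explicit status for degenerate ratios.

    status is ``finite`` iff both values are positive; a zero control
    with positive infected value gives ``plus_infinite``, the mirror case
    ``minus_infinite`` and a 0/0 pair ``undefined``.
    """
    df = _as_pairs(pairs)
    c = df["control"].to_numpy(dtype=float)
    i = df["infected"].to_numpy(dtype=float)
    fc = np.full(len(df), np.nan)
    status = np.empty(len(df), dtype=object)
    both = (c > 0) & (i > 0)
    fc[both] = np.log2(i[both] / c[both])
    status[both] = "finite"
    status[(c == 0) & (i > 0)] = "plus_infinite"
    status[(c > 0) & (i == 0)] = "minus_infinite"
    status[(c == 0) & (i == 0)] = "undefined"
    return pd.DataFrame(
        {"transcript_id": df["transcript_id"], "log2_fc": fc, "status": status}
    )


def percentile_fc_call(
    fc_records: pd.DataFrame, config: PercentileConfig | None = None
) -> list[RegulationCall]:
    """Percentile fold-change rule with strict thresholds.

    Within the strictly positive ratios (log2 FC > ε) the up threshold is
    their 81.25th percentile (linear interpolation between closest
    ranks); symmetrically for down.  The two tails each hold 18.75 % of
    the corresponding sign class, up to tie/boundary effects.  Infinite
    and undefined ratios are flagged, never silently dropped.
    """
    config = config or PercentileConfig()
    fc = fc_records["log2_fc"].to_numpy(dtype=float)
    status = fc_records["status"].to_numpy()
    ids = fc_records["transcript_id"].to_numpy()
    finite = status == "finite"
    if not finite.any():
        logger.warning("no finite fold changes; no percentile calls made")
        return [
            RegulationCall(t, "none", "percentile", flags=(str(s),))
            for t, s in zip(ids, status)
        ]
    calls: list[RegulationCall] = []
    pos = finite & (fc > config.epsilon)
    neg = finite & (fc < -config.epsilon)
    up_thr = np.percentile(fc[pos], config.up_percentile) if pos.any() else np.inf
    down_thr = np.percentile(fc[neg], config.down_percentile) if neg.any() else -np.inf
    for k in range(len(ids)):
        if not finite[k]:
            calls.append(
                RegulationCall(ids[k], "none", "percentile", flags=(str(status[k]),))
            )
            continue
        verdict = "none"
        if pos[k] and fc[k] > up_thr:
            verdict = "up"
        elif neg[k] and fc[k] < down_thr:
            verdict = "down"
        calls.append(RegulationCall(ids[k], verdict, "percentile", score=float(fc[k])))
    return calls


def infection_specific(pairs) -> pd.DataFrame:
    """Flag transcripts expressed in exactly one condition.

    Zero control with positive infected expression marks the transcript
    infection-specific; the mirror case is flagged lost-on-infection.
    Transcripts silent in both conditions get no flag.
    """
    df = _as_pairs(pairs)
    flag = np.where(
        (df["control"] == 0) & (df["infected"] > 0),
        "infection_specific",
        np.where((df["control"] > 0) & (df["infected"] == 0), "lost_on_infection", ""),
    )
    return pd.DataFrame({"transcript_id": df["transcript_id"], "flag": flag})


# ---------------------------------------------------------------------------
# geometric caller 1: binned percentile envelope after 45-degree rotation

def _rotated(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log10 both conditions and rotate the scatter 45 degrees clockwise:
    u = (x+y)/sqrt(2) tracks overall expression, v = (y-x)/sqrt(2) tracks
    regulation.  Only strictly positive pairs are representable."""
    mask = (df["control"] > 0) & (df["infected"] > 0)
    x = np.log10(df.loc[mask, "control"].to_numpy(dtype=float))
    y = np.log10(df.loc[mask, "infected"].to_numpy(dtype=float))
    u = (x + y) / math.sqrt(2.0)
    v = (y - x) / math.sqrt(2.0)
    return u, v, mask.to_numpy()


def _fit_hyperbola(
    centers: np.ndarray, anchors: np.ndarray, grid_size: int
) -> tuple[float, float, float]:
    """Least-squares fit of v = a + b/(u - d), d constrained below the
    smallest bin center.  d is found by a deterministic grid search (a and
    b are linear given d), which keeps the fit reproducible and
    shift-equivariant."""
    if centers.size < 3:
        raise FitError(f"only {centers.size} usable anchors; need >= 3")
    span = centers.max() - centers.min()
    if span <= 0:
        raise FitError("degenerate anchor spread")
    offsets = np.geomspace(1e-3 * span, 10 * span, grid_size)
    best = None
    for off in offsets:
        d = centers.min() - off
        basis = np.column_stack([np.ones_like(centers), 1.0 / (centers - d)])
        coef, res, rank, _ = np.linalg.lstsq(basis, anchors, rcond=None)
        if rank < 2:
            continue
        sse = float(((basis @ coef - anchors) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, coef[0], coef[1], d)
    if best is None:
        # degenerate geometry: fall back to the two-parameter form
        logger.warning("hyperbola fit ill-conditioned; falling back to v = a + b/u")
        d = centers.min() - span
        basis = np.column_stack([np.ones_like(centers), 1.0 / (centers - d)])
        coef, *_ = np.linalg.lstsq(basis, anchors, rcond=None)
        return float(coef[0]), float(coef[1]), float(d)
    return float(best[1]), float(best[2]), float(best[3])


def envelope_call(
    pairs, config: EnvelopeConfig | None = None
) -> list[RegulationCall]:
    """Binned percentile envelope on the rotated log–log scatter.

    The rotated abscissa is split into equal-width bins; each bin
    contributes an upper anchor at its (100 − cutoff)-th percentile of
    the rotated ordinate and a lower anchor at the cutoff percentile,
    placed at the bin center.  A hyperbola is fitted to the upper and,
    separately, the lower anchors; transcripts strictly outside the two
    curves are called up/down, scored by their vertical distance to the
    curve.  Working in bin-relative coordinates makes the caller exactly
    invariant under rescaling both conditions by a common factor.
    """
    config = config or EnvelopeConfig()
    df = _as_pairs(pairs)
    u, v, mask = _rotated(df)
    ids = df.loc[mask, "transcript_id"].to_numpy()
    if u.size < config.n_bins:
        raise FitError("fewer points than bins")
    u0 = u.min()
    us = u - u0  # shift-invariant coordinate
    span = us.max()
    if span == 0:
        raise FitError("all points share one expression level")
    width = span / config.n_bins
    bin_idx = np.minimum((us / width).astype(int), config.n_bins - 1)

    centers, uppers, lowers = [], [], []
    for b in range(config.n_bins):
        sel = bin_idx == b
        n = int(sel.sum())
        if n < config.min_bin_count:
            if n:
                logger.info("envelope bin %d skipped (%d points)", b, n)
            continue
        centers.append((b + 0.5) * width)
        uppers.append(np.percentile(v[sel], 100.0 - config.cutoff_percent))
        lowers.append(np.percentile(v[sel], config.cutoff_percent))
    centers = np.asarray(centers)
    a_u, b_u, d_u = _fit_hyperbola(centers, np.asarray(uppers), config.d_grid_size)
    a_l, b_l, d_l = _fit_hyperbola(centers, np.asarray(lowers), config.d_grid_size)

    upper_curve = a_u + b_u / (us - d_u)
    lower_curve = a_l + b_l / (us - d_l)
    calls = []
    for k in range(ids.size):
        if v[k] > upper_curve[k]:
            calls.append(
                RegulationCall(ids[k], "up", "envelope", score=float(v[k] - upper_curve[k]))
            )
        elif v[k] < lower_curve[k]:
            calls.append(
                RegulationCall(ids[k], "down", "envelope", score=float(v[k] - lower_curve[k]))
            )
        else:
            calls.append(RegulationCall(ids[k], "none", "envelope"))
    return calls


# ---------------------------------------------------------------------------
# geometric caller 2: threshold line through local tail percentiles

def outlier_distance(
    point: tuple[float, float],
    line: tuple[tuple[float, float], tuple[float, float]],
) -> float:
    """Signed perpendicular distance from a point to a line given by two
    points, positive on the up (greater-y) side."""
    (x1, y1), (x2, y2) = line
    dx, dy = x2 - x1, y2 - y1
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("degenerate line: the two points coincide")
    nx, ny = -dy / norm, dx / norm
    if ny < 0 or (ny == 0 and nx < 0):
        nx, ny = -nx, -ny
    return (point[0] - x1) * nx + (point[1] - y1) * ny


def _band_anchor(
    x: np.ndarray, y: np.ndarray, lo_pct: float, hi_pct: float
) -> tuple[float, float]:
    lo, hi = np.percentile(x, [lo_pct, hi_pct])
    sel = (x >= lo) & (x < hi)
    if not sel.any():
        raise ValueError(f"empty anchor band [{lo_pct}, {hi_pct})")
    return float(np.percentile(x, (lo_pct + hi_pct) / 2.0)), float(y[sel].mean())


def _band_up_distances(x: np.ndarray, y: np.ndarray, config: BandConfig) -> np.ndarray:
    """Signed distance of every point to the up-threshold line T.

    A trend line L joins (25th percentile of x, mean y of the 20–30th
    percentile band) and the analogous 70–80th anchor.  Around each
    anchor, points falling in a bin orthogonal to L are projected onto
    L's normal; the ``tail_percentile``-th percentile of their signed
    offsets fixes one point of T.  Positive distance = above T.
    """
    p_low = _band_anchor(x, y, *config.anchor_low)
    p_high = _band_anchor(x, y, *config.anchor_high)
    dx, dy = p_high[0] - p_low[0], p_high[1] - p_low[1]
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise ValueError("anchor points coincide; trend line undefined")
    tx, ty = dx / norm, dy / norm
    nx, ny = -ty, tx
    if ny < 0:
        nx, ny = -nx, -ny

    s = (x - p_low[0]) * tx + (y - p_low[1]) * ty  # along-line position
    e = (x - p_low[0]) * nx + (y - p_low[1]) * ny  # signed offset from L
    halfwidth = config.ortho_bin_halfwidth * (s.max() - s.min())
    s_anchor = {"low": 0.0, "high": (p_high[0] - p_low[0]) * tx + (p_high[1] - p_low[1]) * ty}

    pts = []
    for name, anchor in (("low", p_low), ("high", p_high)):
        sel = np.abs(s - s_anchor[name]) <= halfwidth
        if not sel.any():
            raise ValueError(f"empty orthogonal bin at the {name} anchor")
        q = float(np.percentile(e[sel], config.tail_percentile))
        pts.append((anchor[0] + q * nx, anchor[1] + q * ny))
    t_up = (pts[0], pts[1])
    return np.array([outlier_distance((x[k], y[k]), t_up) for k in range(x.size)])


def band_call(pairs, config: BandConfig | None = None) -> list[RegulationCall]:
    """Threshold-line caller on the log10–log10 scatter.

    Up calls lie strictly above a threshold line built from local 99th
    percentile offsets around two trend-line anchors (see
    :func:`_band_up_distances`), scored by their perpendicular distance
    to it.  Down-regulation is the same calculation with the axes
    swapped, so swapping the two conditions exactly swaps the up and
    down call sets.
    """
    config = config or BandConfig()
    df = _as_pairs(pairs)
    mask = (df["control"] > 0) & (df["infected"] > 0)
    ids = df.loc[mask, "transcript_id"].to_numpy()
    x = np.log10(df.loc[mask, "control"].to_numpy(dtype=float))
    y = np.log10(df.loc[mask, "infected"].to_numpy(dtype=float))

    d_up = _band_up_distances(x, y, config)
    d_down = _band_up_distances(y, x, config)  # mirror procedure

    calls = []
    for k in range(ids.size):
        if d_up[k] > 0:
            calls.append(RegulationCall(ids[k], "up", "band", score=float(d_up[k])))
        elif d_down[k] > 0:
            calls.append(RegulationCall(ids[k], "down", "band", score=float(-d_down[k])))
        else:
            calls.append(RegulationCall(ids[k], "none", "band", score=float(d_up[k])))
    return calls


# ---------------------------------------------------------------------------
# legacy platform rules

def legacy_oligo_call(
    ratio_matrix: pd.DataFrame,
    up_ratio: float = 1.01,
    down_ratio: float = 0.99,
    min_arrays: int = 10,
    expected_arrays: int = 14,
    percentile: float = 18.75,
    allow_any_array_count: bool = False,
) -> list[RegulationCall]:
    """Oligo-array rule: genes whose infected/control ratio departs from
    unity (>1.01 or <0.99) in at least ten of fourteen arrays form the
    eligible set; the uppermost and lowermost 18.75 % of their median
    ratios are called up and down."""
    mat = ratio_matrix.to_numpy(dtype=float)
    if mat.shape[1] != expected_arrays and not allow_any_array_count:
        raise ValueError(
            f"expected {expected_arrays} arrays, got {mat.shape[1]} "
            "(pass allow_any_array_count=True to override)"
        )
    ids = ratio_matrix.index.to_numpy()
    beyond = (mat > up_ratio) | (mat < down_ratio)
    eligible = beyond.sum(axis=1) >= min_arrays
    med = np.median(mat, axis=1)
    calls: list[RegulationCall] = []
    if eligible.any():
        hi = np.percentile(med[eligible], 100.0 - percentile)
        lo = np.percentile(med[eligible], percentile)
    for k in range(len(ids)):
        if not eligible[k]:
            calls.append(
                RegulationCall(str(ids[k]), "none", "oligo", flags=("ineligible",))
            )
            continue
        verdict = "up" if med[k] > hi else ("down" if med[k] < lo else "none")
        calls.append(RegulationCall(str(ids[k]), verdict, "oligo", score=float(med[k])))
    return calls


def legacy_cdna_call(
    expr_set_i: pd.DataFrame,
    expr_set_ii: pd.DataFrame,
    psl_threshold: float = 40.0,
    config: PercentileConfig | None = None,
) -> list[RegulationCall]:
    """cDNA-array rule over two paired experiments in PSL units.

    A gene detected (>40 PSL in either channel) in both experiments
    contributes the mean of the two fold changes, one detected in exactly
    one contributes that fold change, and undetected genes leave the base
    set.  The combined fold changes are log2-transformed and passed to
    the percentile rule.
    """
    config = config or PercentileConfig()
    a = _as_pairs(expr_set_i).set_index("transcript_id")
    b = _as_pairs(expr_set_ii).set_index("transcript_id")
    genes = a.index.union(b.index)
    rows = []
    for g in genes:
        fcs = []
        for df in (a, b):
            if g not in df.index:
                continue
            c, i = float(df.loc[g, "control"]), float(df.loc[g, "infected"])
            if max(c, i) > psl_threshold:
                fcs.append(np.inf if c == 0 else i / c)
        if not fcs:
            continue  # below detection in both experiments: outside base set
        fc = float(np.mean(fcs))
        if not np.isfinite(fc):
            rows.append((g, np.nan, "plus_infinite"))
        elif fc == 0:
            rows.append((g, np.nan, "minus_infinite"))
        else:
            rows.append((g, math.log2(fc), "finite"))
    records = pd.DataFrame(rows, columns=["transcript_id", "log2_fc", "status"])
    calls = percentile_fc_call(records, config)
    return [
        RegulationCall(c.transcript_id, c.verdict, "cdna", c.score, c.flags)
        for c in calls
    ]
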