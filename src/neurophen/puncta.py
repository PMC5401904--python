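"""Two-channel puncta quantification and cell-count arithmetic.

Covers spot detection in rendered channels, pairing of near-parallel neurite
polylines (< 0.5 um apart by default), one-to-one colocalization counting by
centroid distance, puncta density per microscope field, one-way ANOVA with
post-hoc Tukey HSD for multi-condition comparisons, and survival-ratio
percentages for double-labelled cell-count tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "SpotSet",
    "NeuritePair",
    "GroupTestResult",
    "detect_spots",
    "pair_neurites",
    "count_colocalized",
    "match_colocalized",
    "count_colocalized_per_pair",
    "density_per_field",
    "group_test",
    "survival_ratio",
    "survival_table",
    "verify_reported_percent",
]


@dataclass(frozen=True)
class SpotSet:
    """Detected or simulated spot centroids of one channel, in micrometres."""

    coordinates: np.ndarray  # (n, 2) of (x_um, y_um)
    channel: str = ""
    intensities: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "coordinates", coords)

    def __len__(self) -> int:
        return len(self.coordinates)


def detect_spots(
    image: np.ndarray,
    pixel_size_um: float,
    psf_sigma_um: float,
    threshold_rel: float = 0.2,
) -> SpotSet:
    """Scale-matched blob detection in one channel.

    A Laplacian-of-Gaussian operator at the PSF scale enhances blobs, local
    maxima above ``threshold_rel`` of the strongest response are extracted
    (peaks closer than one PSF sigma merge into one detection), and each peak
    is refined to a sub-pixel centroid by the centre of mass of its local
    response. Pixel (r, c) has its centre at (c, r) * pixel_size_um.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel size must be known and positive")
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    sigma_px = psf_sigma_um / pixel_size_um
    response = -ndimage.gaussian_laplace(image, sigma=sigma_px)
    peak = response.max()
    if peak <= 0:
        return SpotSet(np.empty((0, 2)))
    peaks = peak_local_max(
        response,
        min_distance=max(1, int(round(sigma_px))),
        threshold_abs=threshold_rel * peak,
    )
    half = max(1, int(round(sigma_px)))
    coords, intensities = [], []
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(image.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(image.shape[1], c + half + 1)
        patch = np.clip(response[r0:r1, c0:c1], 0, None)
        total = patch.sum()
        rr, cc = np.mgrid[r0:r1, c0:c1]
        r_sub = (patch * rr).sum() / total
        c_sub = (patch * cc).sum() / total
        coords.append((c_sub * pixel_size_um, r_sub * pixel_size_um))
        intensities.append(image[r, c])
    return SpotSet(np.array(coords), intensities=np.array(intensities))


@dataclass(frozen=True)
class NeuritePair:
    """Accepted close-running stretch between one polyline per channel."""

    polyline_a: np.ndarray
    polyline_b: np.ndarray
    mean_separation_um: float
    parallel_length_um: float
    index_a: int = 0
    index_b: int = 0


def _resample_polyline(poly: np.ndarray, step_um: float) -> np.ndarray:
    """Points along a polyline at (approximately) fixed arc-length spacing."""
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or len(poly) < 2:
        raise ValueError("polylines need at least 2 points")
    seg = np.diff(poly, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arclen[-1]
    if total == 0:
        raise ValueError("degenerate polyline with zero length")
    n = max(2, int(np.ceil(total / step_um)) + 1)
    s = np.linspace(0, total, n)
    x = np.interp(s, arclen, poly[:, 0])
    y = np.interp(s, arclen, poly[:, 1])
    return np.column_stack([x, y])


def _point_polyline_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Minimum distance of each point to any segment of a polyline."""
    a = poly[:-1][None, :, :]  # (1, m, 2)
    b = poly[1:][None, :, :]
    p = points[:, None, :]  # (k, 1, 2)
    ab = b - a
    denom = np.maximum((ab**2).sum(-1), 1e-300)
    t = np.clip(((p - a) * ab).sum(-1) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    d = np.hypot(*(p - proj).transpose(2, 0, 1))
    return d.min(axis=1)


def pair_neurites(
    polylines_a: list[np.ndarray],
    polylines_b: list[np.ndarray],
    max_sep_um: float = 0.5,
    min_parallel_um: float = 5.0,
    step_um: float = 0.05,
) -> list[NeuritePair]:
    """Accept (A, B) polyline pairs that run side-by-side.

    A pair qualifies when a contiguous stretch of at least ``min_parallel_um``
    exists along A whose distance to B stays below ``max_sep_um``; the
    reported separation is the mean over the longest such stretch.
    """
    pairs = []
    for i, pa in enumerate(polylines_a):
        samples = _resample_polyline(pa, step_um)
        ds = np.hypot(*np.diff(samples, axis=0).T)
        for j, pb in enumerate(polylines_b):
            dist = _point_polyline_distances(samples, np.asarray(pb, dtype=float))
            close = dist < max_sep_um
            # longest contiguous close-running stretch, by arc length
            best_len, best_slice = 0.0, None
            start = None
            for k in range(len(close) + 1):
                if k < len(close) and close[k]:
                    if start is None:
                        start = k
                elif start is not None:
                    run_len = ds[start : k - 1].sum() if k - 1 > start else 0.0
                    if run_len > best_len:
                        best_len, best_slice = run_len, slice(start, k)
                    start = None
            if best_slice is not None and best_len >= min_parallel_um:
                pairs.append(
                    NeuritePair(
                        polyline_a=np.asarray(pa, dtype=float),
                        polyline_b=np.asarray(pb, dtype=float),
                        mean_separation_um=float(dist[best_slice].mean()),
                        parallel_length_um=float(best_len),
                        index_a=i,
                        index_b=j,
                    )
                )
    return pairs


def match_colocalized(
    spots_a: SpotSet | np.ndarray,
    spots_b: SpotSet | np.ndarray,
    radius_um: float = 0.5,
) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching of A-B spots within a radius.

    Candidate pairs are sorted by distance with ties broken by coordinate
    (index) order, then accepted greedily so that every spot participates in
    at most one match. One-to-one matching avoids double-counting in dense
    fields.
    """
    if radius_um < 0:
        raise ValueError("radius must be non-negative")
    a = spots_a.coordinates if isinstance(spots_a, SpotSet) else np.asarray(spots_a, float).reshape(-1, 2)
    b = spots_b.coordinates if isinstance(spots_b, SpotSet) else np.asarray(spots_b, float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        return []
    tree = cKDTree(b)
    candidates = []
    for i, neighbours in enumerate(tree.query_ball_point(a, r=radius_um)):
        for j in neighbours:
            d = float(np.hypot(*(a[i] - b[j])))
            candidates.append((d, i, j))
    candidates.sort()
    used_a, used_b, matches = set(), set(), []
    for _, i, j in candidates:
        if i not in used_a and j not in used_b:
            matches.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return matches


def count_colocalized(
    spots_a: SpotSet | np.ndarray,
    spots_b: SpotSet | np.ndarray,
    radius_um: float = 0.5,
) -> int:
    """Number of one-to-one A-B matches within ``radius_um``."""
    return len(match_colocalized(spots_a, spots_b, radius_um))


def count_colocalized_per_pair(
    spots_a: SpotSet | np.ndarray,
    spots_b: SpotSet | np.ndarray,
    pairs: list[NeuritePair],
    radius_um: float = 0.5,
    corridor_um: float = 0.5,
) -> list[int]:
    """Colocalization counts restricted to each neurite-pair corridor.

    A spots within ``corridor_um`` of the pair's A polyline and B spots within
    ``corridor_um`` of the B polyline are matched per pair.
    """
    a = spots_a.coordinates if isinstance(spots_a, SpotSet) else np.asarray(spots_a, float).reshape(-1, 2)
    b = spots_b.coordinates if isinstance(spots_b, SpotSet) else np.asarray(spots_b, float).reshape(-1, 2)
    counts = []
    for pair in pairs:
        sel_a = a[_point_polyline_distances(a, pair.polyline_a) < corridor_um] if len(a) else a
        sel_b = b[_point_polyline_distances(b, pair.polyline_b) < corridor_um] if len(b) else b
        counts.append(count_colocalized(sel_a, sel_b, radius_um))
    return counts


def density_per_field(
    spots: SpotSet | np.ndarray,
    field_bounds: tuple[float, float, float, float],
) -> int:
    """Spot count inside a rectangular field (xmin, ymin, xmax, ymax), in um."""
    coords = spots.coordinates if isinstance(spots, SpotSet) else np.asarray(spots, float).reshape(-1, 2)
    xmin, ymin, xmax, ymax = field_bounds
    if len(coords) == 0:
        return 0
    inside = (
        (coords[:, 0] >= xmin)
        & (coords[:, 0] <= xmax)
        & (coords[:, 1] >= ymin)
        & (coords[:, 1] <= ymax)
    )
    return int(inside.sum())


@dataclass(frozen=True)
class GroupTestResult:
    """One-way ANOVA with post-hoc Tukey HSD over all condition pairs."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    group_labels: list[str]

    def summary(self) -> str:
        lines = [
            f"one-way ANOVA: F={self.f_statistic:.4g}, p={self.p_value:.4g}",
            self.tukey.to_string(index=False),
        ]
        return "\n".join(lines)


def group_test(
    groups: list[np.ndarray],
    labels: list[str] | None = None,
) -> GroupTestResult:
    """One-way ANOVA F test plus Tukey HSD over >= 2 value groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    f_stat, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            lo, hi = hsd.confidence_interval().low[i, j], hsd.confidence_interval().high[i, j]
            rows.append(
                (
                    labels[i],
                    labels[j],
                    float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    float(hsd.pvalue[i, j]),
                    float(lo),
                    float(hi),
                )
            )
    tukey = pd.DataFrame(
        rows, columns=["group1", "group2", "mean_diff", "p_adj", "ci_low", "ci_high"]
    )
    return GroupTestResult(float(f_stat), float(p), tukey, list(labels))


def survival_ratio(double_positive: int, total: int) -> float:
    """Percentage of double-positive cells, rounded to one decimal.

    E.g. 29 double-labelled neurons out of 78 marked cells -> 37.2.
    """
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= double_positive <= total:
        raise ValueError("double_positive must be in [0, total]")
    return round(100.0 * double_positive / total, 1)


def survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``percent`` column of survival ratios to a count table.

    Expects columns ``region``, ``double_positive`` and ``total``.
    """
    out = table.copy()
    out["percent"] = [
        survival_ratio(int(dp), int(tot))
        for dp, tot in zip(out["double_positive"], out["total"])
    ]
    return out


def verify_reported_percent(
    table: pd.DataFrame, tolerance: float = 0.05
) -> pd.DataFrame:
    """Flag rows whose reported percentage disagrees with the pooled ratio.

    Adds ``computed_percent`` and a boolean ``mismatch`` column; a row is
    flagged when |reported - computed| exceeds ``tolerance`` (published
    tables sometimes average per-section ratios instead of pooling counts,
    which this check surfaces rather than reproduces).
    """
    out = survival_table(table).rename(columns={"percent": "computed_percent"})
    out["mismatch"] = (
        (out["reported_percent"] - out["computed_percent"]).abs() > tolerance
    )
    return out
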