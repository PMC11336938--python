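"""Ground-truth pipeline: synthetic liver sections, droplet counting, group stats.

In the real protocol, stained liver sections (Oil Red O highlights lipid)
are thresholded and subjected to particle analysis; fatty livers show a
marked excess of small lipid droplets, and per-size-bin counts are
compared between groups by analysis of variance.  Subject labels for the
impedance classifier derive from this droplet analysis.

This module emulates that pipeline end-to-end on synthetic sections:
bright disks (droplets) on a dark background with additive Gaussian
noise, Otsu thresholding, connected-component particle analysis,
half-open size binning over equivalent diameters (default bin edges
2, 7, 13 pixels), per-bin one-way ANOVA, and a monotone labelling rule
on the small-droplet count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import disk as _disk
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label
from skimage.measure import regionprops_table

__all__ = [
    "DEFAULT_BINS",
    "write_image",
    "read_image",
    "SectionSpec",
    "healthy_section_spec",
    "nafld_section_spec",
    "render_section",
    "segment_droplets",
    "size_distribution",
    "SizeHistogram",
    "compare_groups",
    "two_way_anova",
    "label_from_droplets",
]

# equivalent-diameter bin edges in pixels: "small" droplets 2-7, "large" 7-13
DEFAULT_BINS = (2.0, 7.0, 13.0)

# default labelling threshold on the small-droplet count, calibrated on the
# shipped synthetic section generators (healthy ~ a dozen droplets, fatty
# ~ seventy, mostly small): midway between the two regimes.
DEFAULT_LABEL_THRESHOLD = 30


@dataclass(frozen=True)
class SectionSpec:
    """Synthetic stained-section description: canvas, droplets, intensities."""

    size: tuple[int, int] = (256, 256)
    droplets: tuple[tuple[tuple[float, float], float], ...] = ()
    background: float = 0.15
    foreground: float = 0.85
    noise_scale: float = 0.03

    def __post_init__(self) -> None:
        h, w = self.size
        for (r, c), radius in self.droplets:
            if radius <= 0:
                raise ValueError("droplet radii must be positive")
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"droplet centre ({r}, {c}) outside the {h}x{w} canvas")


def _sample_droplets(
    rng: np.random.Generator,
    n: int,
    size: tuple[int, int],
    radius_median: float,
    radius_sigma: float,
    margin: float = 12.0,
    max_tries: int = 20_000,
) -> tuple[tuple[tuple[float, float], float], ...]:
    """Rejection-sample non-overlapping disks with log-normal radii."""
    placed: list[tuple[tuple[float, float], float]] = []
    tries = 0
    while len(placed) < n and tries < max_tries:
        tries += 1
        radius = float(radius_median * np.exp(radius_sigma * rng.standard_normal()))
        radius = float(np.clip(radius, 1.0, margin - 2.0))
        r = rng.uniform(margin, size[0] - margin)
        c = rng.uniform(margin, size[1] - margin)
        if all(np.hypot(r - pr, c - pc) > radius + prad + 2.0 for (pr, pc), prad in placed):
            placed.append(((float(r), float(c)), radius))
    return tuple(placed)


def healthy_section_spec(seed: int = 0, n_droplets: int = 12) -> SectionSpec:
    """Sparse large-ish droplets: a healthy liver section in miniature."""
    rng = np.random.default_rng(seed)
    droplets = _sample_droplets(rng, n_droplets, (256, 256), radius_median=3.2, radius_sigma=0.25)
    return SectionSpec(droplets=droplets)


def nafld_section_spec(seed: int = 0, n_droplets: int = 70) -> SectionSpec:
    """Dense small droplets: the early fatty-liver phenotype."""
    rng = np.random.default_rng(seed)
    droplets = _sample_droplets(rng, n_droplets, (256, 256), radius_median=2.2, radius_sigma=0.25)
    return SectionSpec(droplets=droplets)


def render_section(spec: SectionSpec, seed: int = 0) -> np.ndarray:
    """Rasterise a section: foreground disks on background plus noise.

    Returns a float image in roughly [0, 1]; identical for identical
    (spec, seed).
    """
    img = np.full(spec.size, spec.background, dtype=np.float64)
    for (r, c), radius in spec.droplets:
        rr, cc = _disk((r, c), radius, shape=spec.size)
        img[rr, cc] = spec.foreground
    if spec.noise_scale > 0:
        rng = np.random.default_rng(seed)
        img = img + spec.noise_scale * rng.standard_normal(spec.size)
    return img


def segment_droplets(
    image: np.ndarray, threshold: float | None = None, min_size: int = 4
) -> pd.DataFrame:
    """Threshold + connected components + size filter -> droplet table.

    ``threshold=None`` selects Otsu's automatic intensity-histogram
    threshold.  Returns one row per retained object with columns
    ``area`` (pixels), ``equivalent_diameter`` (pixels) and centroid
    coordinates.  Touching droplets merge into one object (no watershed
    splitting).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a single-channel image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    empty = pd.DataFrame(columns=["area", "equivalent_diameter", "centroid_r", "centroid_c"])
    if image.max() == image.min():
        return empty
    thr = float(threshold_otsu(image)) if threshold is None else float(threshold)
    mask = image > thr
    if not mask.any() or mask.all():
        return empty
    if threshold is None:
        # Otsu always splits, even pure noise; require the class gap to
        # dominate the within-class spread before accepting foreground.
        fg, bg = image[mask], image[~mask]
        pooled = 0.5 * (fg.std() + bg.std())
        if pooled > 0 and (fg.mean() - bg.mean()) < 4.0 * pooled:
            return empty
    labelled = _cc_label(mask)
    props = regionprops_table(
        labelled, properties=("area", "equivalent_diameter", "centroid")
    )
    table = pd.DataFrame(props).rename(
        columns={"centroid-0": "centroid_r", "centroid-1": "centroid_c"}
    )
    table = table[table["area"] >= min_size].reset_index(drop=True)
    return table


@dataclass(frozen=True)
class SizeHistogram:
    """Droplet counts per equivalent-diameter bin for one section."""

    counts: np.ndarray
    bins: tuple[float, ...] = DEFAULT_BINS
    group: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.size != len(self.bins) - 1:
            raise ValueError(f"expected {len(self.bins) - 1} counts for {len(self.bins)} bin edges")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def size_distribution(
    table: pd.DataFrame, bins: tuple[float, ...] = DEFAULT_BINS, group: str = ""
) -> SizeHistogram:
    """Bin droplet equivalent diameters into half-open bins [b_i, b_{i+1})."""
    bins = tuple(float(b) for b in bins)
    if len(bins) < 2:
        raise ValueError("need at least two bin edges")
    if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
        raise ValueError("bin edges must be strictly increasing")
    diameters = np.asarray(table["equivalent_diameter"], dtype=float) if len(table) else np.empty(0)
    counts = [
        int(np.sum((diameters >= lo) & (diameters < hi))) for lo, hi in zip(bins, bins[1:])
    ]
    return SizeHistogram(counts=np.array(counts), bins=bins, group=group)


def compare_groups(
    group_a: list[SizeHistogram], group_b: list[SizeHistogram]
) -> pd.DataFrame:
    """Per-bin one-way ANOVA of droplet counts across two groups.

    Returns a frame with one row per size bin: group means, the F
    statistic and the p value.  Degenerate bins (zero variance, equal
    means) report F = 0, p = 1 by convention.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 sections per group")
    bins = group_a[0].bins
    if any(h.bins != bins for h in group_a + group_b):
        raise ValueError("all histograms must share the same bins")
    a = np.stack([h.counts for h in group_a]).astype(float)
    b = np.stack([h.counts for h in group_b]).astype(float)
    rows = []
    for k in range(len(bins) - 1):
        xa, xb = a[:, k], b[:, k]
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = stats.f_oneway(xa, xb)
        rows.append(
            {
                "bin_low": bins[k],
                "bin_high": bins[k + 1],
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "F": float(f_stat),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def two_way_anova(group_a: list[SizeHistogram], group_b: list[SizeHistogram]) -> pd.DataFrame:
    """Two-factor (group x size-bin) ANOVA decomposition of droplet counts.

    Balanced fixed-effects decomposition computed from cell means;
    returns sum of squares, degrees of freedom, F and p per effect.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 sections per group")
    a = np.stack([h.counts for h in group_a]).astype(float)
    b = np.stack([h.counts for h in group_b]).astype(float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same bins")
    data = [a, b]
    n_bins = a.shape[1]
    grand = np.concatenate([a.ravel(), b.ravel()]).mean()
    n_total = a.size + b.size
    ss_group = sum(g.size * (g.mean() - grand) ** 2 for g in data)
    bin_means = [np.concatenate([a[:, k], b[:, k]]).mean() for k in range(n_bins)]
    ss_bin = sum((a.shape[0] + b.shape[0]) * (m - grand) ** 2 for m in bin_means)
    cell_means = np.array([[g[:, k].mean() for k in range(n_bins)] for g in data])
    ss_cells = sum(
        g.shape[0] * (cell_means[i, k] - grand) ** 2 for i, g in enumerate(data) for k in range(n_bins)
    )
    ss_inter = ss_cells - ss_group - ss_bin
    ss_within = sum(
        ((g[:, k] - cell_means[i, k]) ** 2).sum() for i, g in enumerate(data) for k in range(n_bins)
    )
    df_group, df_bin = 1, n_bins - 1
    df_inter = df_group * df_bin
    df_within = n_total - 2 * n_bins
    rows = []
    for name, ss, df in (
        ("group", ss_group, df_group),
        ("bin", ss_bin, df_bin),
        ("group:bin", ss_inter, df_inter),
        ("residual", ss_within, df_within),
    ):
        ms = ss / df if df else np.nan
        if name == "residual":
            f_stat, p = np.nan, np.nan
        else:
            ms_within = ss_within / df_within
            f_stat = ms / ms_within if ms_within > 0 else 0.0
            p = float(stats.f.sf(f_stat, df, df_within)) if ms_within > 0 else 1.0
        rows.append({"effect": name, "ss": ss, "df": df, "F": f_stat, "p": p})
    return pd.DataFrame(rows)


def write_image(path, image: np.ndarray) -> None:
    """Write a section image: float32 TIFF (lossless) or 8-bit PNG by suffix."""
    import imageio.v3 as iio

    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        iio.imwrite(path, np.asarray(image, dtype=np.float32))
    else:
        clipped = np.clip(image, 0.0, 1.0)
        iio.imwrite(path, (clipped * 255).round().astype(np.uint8))


def read_image(path) -> np.ndarray:
    """Read a section image back to float64 in [0, 1] (PNG) or raw (TIFF)."""
    import imageio.v3 as iio

    arr = iio.imread(str(path))
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    return arr.astype(np.float64)


def label_from_droplets(
    histogram: SizeHistogram,
    threshold: int = DEFAULT_LABEL_THRESHOLD,
    small_bin_high: float = 7.0,
) -> str:
    """Label a section fatty-liver iff its small-droplet count exceeds ``threshold``.

    "Small" means equivalent diameter below ``small_bin_high`` (default:
    the 2-7 bin).  The rule is monotone in the threshold: scanning the
    threshold flips the label exactly once.
    """
    bins = histogram.bins
    small = [k for k in range(len(bins) - 1) if bins[k + 1] <= small_bin_high]
    if not small:
        raise ValueError(f"no bins below {small_bin_high} in {bins}")
    n_small = int(histogram.counts[small].sum())
    return "nafld" if n_small > threshold else "healthy"
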