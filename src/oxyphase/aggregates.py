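"""Aggregate identification and size statistics.

Lattice pathway: sites with occupancy η ≥ 3 are thresholded and labelled by
8-connected components with periodic wrap; a representative set keeps the
largest aggregates whose cumulative area first exceeds 90% of all aggregate
area, and the typical radius is a = √(⟨A⟩/π) over that set.

Image pathway: dark quasi-circular domains on a lighter background are
segmented by intensity threshold (Otsu by default), holes filled, small
specks discarded; per-domain equivalent radii a′ = √(A/π) and
nearest-neighbour distances d′ are summarised by the mode and full width at
half maximum of their histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

__all__ = [
    "AggregateSet",
    "DomainStats",
    "UndefinedStatisticError",
    "label_lattice_aggregates",
    "representative_radius",
    "detect_domains_image",
    "domain_statistics",
    "background_density_lattice",
    "histogram_mode_fwhm",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class UndefinedStatisticError(ValueError):
    """A statistic was requested on too few components."""


@dataclass
class AggregateSet:
    """Labelled connected components, sorted by decreasing area.

    ``labels`` maps each pixel/site to a component id (0 = background);
    ``areas`` are in sites (lattice) or pixels (image), sorted descending;
    ``centroids`` are in the same order.  ``representative`` flags the
    components of the 90% set (lattice pathway).
    """

    labels: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray
    source: str = "lattice"
    periodic: bool = True
    representative: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def components(self) -> list[int]:
        return list(range(len(self.areas)))

    def to_frame(self, scale: float = 1.0) -> pd.DataFrame:
        """Per-component table with areas and equivalent radii.

        ``scale`` is the physical size of one site/pixel (μm).
        """
        a_um2 = self.areas * scale**2
        return pd.DataFrame({
            "id": np.arange(len(self.areas)),
            "area_sites": self.areas,
            "area_um2": a_um2,
            "a_prime_um": np.sqrt(a_um2 / np.pi),
            "centroid_x": self.centroids[:, 0] * scale,
            "centroid_y": self.centroids[:, 1] * scale,
            "representative": (self.representative
                               if self.representative is not None
                               else np.ones(len(self.areas), dtype=bool)),
        })


def _periodic_relabel(labels: np.ndarray, n: int) -> np.ndarray:
    """Merge component labels across the periodic boundaries (union-find)."""
    if n == 0:
        return labels
    parent = np.arange(n + 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    L0, L1 = labels.shape
    # 8-connectivity across each wrapped edge, including corners
    for shift in (-1, 0, 1):
        top = labels[0, :]
        bottom = np.roll(labels[L0 - 1, :], shift)
        for a, b in zip(top, bottom):
            if a and b:
                union(int(a), int(b))
        left = labels[:, 0]
        right = np.roll(labels[:, L1 - 1], shift)
        for a, b in zip(left, right):
            if a and b:
                union(int(a), int(b))
    roots = np.array([find(x) for x in range(n + 1)])
    # compress to consecutive ids
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]]


def _periodic_centroid(mask_idx: np.ndarray, L: int) -> float:
    """Circular-mean coordinate of a set of indices on a ring of length L."""
    ang = mask_idx * (2.0 * np.pi / L)
    c = np.mean(np.cos(ang))
    s = np.mean(np.sin(ang))
    return (np.arctan2(s, c) % (2.0 * np.pi)) * L / (2.0 * np.pi)


def _build_set(labels: np.ndarray, periodic: bool, source: str) -> AggregateSet:
    n = int(labels.max())
    if n == 0:
        return AggregateSet(labels=labels, areas=np.empty(0, dtype=int),
                            centroids=np.empty((0, 2)), source=source,
                            periodic=periodic,
                            representative=np.empty(0, dtype=bool))
    areas = np.bincount(labels.ravel())[1:]
    order = np.argsort(-areas, kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    labels = remap[labels]
    areas = areas[order]
    centroids = np.empty((n, 2))
    for lab in range(1, n + 1):
        ii, jj = np.nonzero(labels == lab)
        if periodic:
            centroids[lab - 1] = (_periodic_centroid(ii, labels.shape[0]),
                                  _periodic_centroid(jj, labels.shape[1]))
        else:
            centroids[lab - 1] = (ii.mean(), jj.mean())
    return AggregateSet(labels=labels, areas=areas, centroids=centroids,
                        source=source, periodic=periodic,
                        representative=_representative_mask(areas))


def _representative_mask(areas: np.ndarray) -> np.ndarray:
    """Largest-first inclusion until cumulative area first exceeds 90%."""
    mask = np.zeros(len(areas), dtype=bool)
    if len(areas) == 0:
        return mask
    total = areas.sum()
    cum = np.cumsum(areas)
    stop = int(np.argmax(cum > 0.9 * total))  # first index strictly exceeding
    mask[: stop + 1] = True
    return mask


def label_lattice_aggregates(eta: np.ndarray, eta_threshold: int = 3) -> AggregateSet:
    """Aggregates of a lattice occupancy: η ≥ threshold, 8-connected, periodic."""
    mask = np.asarray(eta) >= eta_threshold
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    labels = _periodic_relabel(labels, n)
    return _build_set(labels, periodic=True, source="lattice")


def representative_radius(aset: AggregateSet, b_um: float = 10.0) -> float:
    """Typical radius a = √(⟨A⟩/π)·b̄ over the representative set, in μm."""
    if len(aset.areas) == 0:
        raise UndefinedStatisticError("no aggregates: typical radius undefined")
    mean_area = aset.areas[aset.representative].mean()
    return float(np.sqrt(mean_area / np.pi) * b_um)


def detect_domains_image(image: np.ndarray, pixel_size_um: float = 1.0,
                         threshold: float | None = None,
                         min_area_px: int = 20) -> AggregateSet:
    """Detect dark domains in a grayscale micrograph-like image.

    The image is thresholded (automatic inter-class-variance/Otsu threshold
    unless ``threshold`` is given; pixels *below* it are foreground), holes
    are filled and components smaller than ``min_area_px`` dropped.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel grayscale image")
    img = image.astype(float)
    if img.max() == img.min():
        labels = np.zeros(img.shape, dtype=np.int32)
        return _build_set(labels, periodic=False, source="image")
    thr = threshold_otsu(img) if threshold is None else threshold
    mask = img < thr
    mask = ndimage.binary_fill_holes(mask)
    labels, _ = ndimage.label(mask, structure=_STRUCT8)
    if min_area_px > 0:
        areas = np.bincount(labels.ravel())
        small = np.nonzero(areas < min_area_px)[0]
        labels[np.isin(labels, small[small > 0])] = 0
    # use skimage regionprops for sub-pixel centroids on the bounded image
    props = regionprops(labels)
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    labs = [p.label for p in props]
    keep[labs] = np.arange(1, len(labs) + 1)
    labels = keep[labels]
    aset = _build_set(labels, periodic=False, source="image")
    return aset


def histogram_mode_fwhm(values: np.ndarray, min_bins: int = 8) -> tuple[float, float]:
    """Mode (centre of the maximal histogram bin) and FWHM of a sample.

    Binning is Freedman–Diaconis with a floor of ``min_bins`` bins; the
    half-maximum crossings are located by linear interpolation between bin
    centres, clamped to the histogram support.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise UndefinedStatisticError("empty sample")
    if np.ptp(values) == 0:
        return float(values[0]), 0.0
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    width = 2 * iqr / len(values) ** (1 / 3) if iqr > 0 else 0.0
    nbins = int(np.ceil(np.ptp(values) / width)) if width > 0 else min_bins
    nbins = max(nbins, min_bins)
    counts, edges = np.histogram(values, bins=nbins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    imax = int(np.argmax(counts))
    mode = float(centres[imax])
    half = counts[imax] / 2.0

    def cross(idx_range, reverse: bool) -> float:
        prev_i = imax
        for i in idx_range:
            if counts[i] < half:
                x0, x1 = centres[i], centres[prev_i]
                y0, y1 = counts[i], counts[prev_i]
                return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))
            prev_i = i
        return float(edges[0] if reverse else edges[-1])

    left = cross(range(imax - 1, -1, -1), reverse=True)
    right = cross(range(imax + 1, len(counts)), reverse=False)
    return mode, right - left


@dataclass
class DomainStats:
    """Mode/FWHM summaries of equivalent radii and nearest-neighbour spacing."""

    radii: np.ndarray
    nn_distances: np.ndarray
    mode_a: float
    fwhm_a: float
    mode_d: float
    fwhm_d: float

    def to_json_dict(self) -> dict:
        return {
            "a": self.mode_a, "fwhm_a": self.fwhm_a,
            "d": self.mode_d, "fwhm_d": self.fwhm_d,
            "n_domains": int(len(self.radii)),
        }


def domain_statistics(aset: AggregateSet, scale_um: float = 1.0,
                      min_bins: int = 8) -> DomainStats:
    """Equivalent-radius and nearest-neighbour statistics of a domain set.

    Radii a′ = √(A/π) per component; d′ is the centroid distance to the
    nearest neighbour under the metric of the source (periodic for lattice
    states, bounded for images).  Needs ≥1 component for radii and ≥2 for
    distances.
    """
    if len(aset.areas) < 1:
        raise UndefinedStatisticError("no components: radius statistics undefined")
    radii = np.sqrt(aset.areas * scale_um**2 / np.pi)
    mode_a, fwhm_a = histogram_mode_fwhm(radii, min_bins)
    if len(aset.areas) >= 2:
        pts = aset.centroids * scale_um
        if aset.periodic:
            box = np.array(aset.labels.shape, dtype=float) * scale_um
            tree = cKDTree(np.mod(pts, box), boxsize=box)
        else:
            tree = cKDTree(pts)
        dd, _ = tree.query(pts, k=2)
        nn = dd[:, 1]
        mode_d, fwhm_d = histogram_mode_fwhm(nn, min_bins)
    else:
        nn = np.empty(0)
        mode_d, fwhm_d = np.nan, np.nan
    return DomainStats(radii=radii, nn_distances=nn, mode_a=mode_a,
                       fwhm_a=fwhm_a, mode_d=mode_d, fwhm_d=fwhm_d)


def background_density_lattice(eta: np.ndarray, aset: AggregateSet,
                               b_um: float = 10.0) -> float:
    """Mean cell density (cm⁻²) outside identified aggregates."""
    background = aset.labels == 0
    if not background.any():
        raise UndefinedStatisticError("no background sites")
    mean_eta = float(np.asarray(eta)[background].mean())
    return mean_eta / (b_um * 1e-4) ** 2
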