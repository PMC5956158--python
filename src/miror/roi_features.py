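"""First-order histogram features and morphology of a parametric-map ROI.

Feature conventions (each recorded in the repository alongside the values):

* quantiles: linear interpolation at rank h = (n - 1) * p on the raw values,
  never on binned data;
* skewness: population g1 = m3 / m2^1.5;
* kurtosis: Pearson (non-excess) m4 / m2^2, so a Gaussian scores 3;
* entropy: H = -sum p_i log2 p_i over a 256-bin equal-width histogram
  spanning [min, max] of the ROI values (bits).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable

import numpy as np
from scipy import ndimage, stats

from miror.imaging_io import ParametricMap, ROIMask

#: Centiles reported for every ROI (percent).
CENTILES = (2, 5, 10, 15, 25, 75, 85, 90, 95, 98)

DEFAULT_NBINS = 256


@dataclass
class Histogram:
    """Equal-width histogram of ROI values.

    ``degenerate`` marks a constant-valued ROI, binned into a single
    epsilon-width bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need nbins+1 edges for nbins counts")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def nbins(self) -> int:
        return len(self.counts)

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class FeatureVector:
    """First-order histogram features of one ROI on one map."""

    mean: float
    median: float
    c2: float
    c5: float
    c10: float
    c15: float
    c25: float
    c75: float
    c85: float
    c90: float
    c95: float
    c98: float
    skewness: float
    kurtosis: float
    entropy: float
    n_voxels: int
    volume_ml: float = float("nan")
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureVector":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class Morphology:
    """Geometric descriptors of a binary ROI."""

    n_voxels: int
    volume_mm3: float
    volume_ml: float
    bounding_lengths_mm: tuple[float, float, float]
    center_of_mass: tuple[float, float, float]
    surface_voxel_count: int


def extract_roi_values(pmap: ParametricMap, roi: ROIMask) -> tuple[np.ndarray, int]:
    """All finite map values inside the ROI, plus the dropped-NaN count.

    Raises if the mask shape differs from the map shape or no finite value
    lies inside the mask.
    """
    if roi.mask.shape != pmap.shape:
        raise ValueError(f"mask shape {roi.mask.shape} != map shape {pmap.shape}")
    if not roi.mask.any():
        raise ValueError("ROI contains no voxels")
    vals = pmap.values[roi.mask]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("ROI contains no finite map values")
    return finite, int(vals.size - finite.size)


def compute_histogram(values, nbins: int = DEFAULT_NBINS) -> Histogram:
    """Equal-width histogram over [min, max]; the max value falls in the last bin.

    A constant input collapses to a single epsilon-width bin flagged
    degenerate.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to bin")
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        eps = np.spacing(abs(lo)) if lo != 0 else np.finfo(float).tiny
        return Histogram(bin_edges=np.array([lo, lo + eps]),
                         counts=np.array([values.size]), degenerate=True)
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    return Histogram(bin_edges=edges, counts=counts)


def histogram_entropy(hist: Histogram) -> float:
    """Shannon entropy of the normalised bin counts, in bits (0*log0 = 0)."""
    p = hist.probabilities
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def compute_features(values, nbins: int = DEFAULT_NBINS,
                     voxel_volume_mm3: float | None = None,
                     sample_moments: bool = False) -> FeatureVector:
    """Compute the full first-order feature set of an ROI value list.

    ``sample_moments`` switches skewness/kurtosis from population (biased)
    to sample-corrected moments.  Constant or single-value input yields
    zero shape features and entropy, flagged degenerate.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    degenerate = bool(values.size < 2 or np.ptp(values) == 0)
    q = {c: float(np.quantile(values, c / 100.0)) for c in CENTILES}
    if degenerate:
        skew = kurt = entropy = 0.0
    else:
        skew = float(stats.skew(values, bias=not sample_moments))
        kurt = float(stats.kurtosis(values, fisher=False, bias=not sample_moments))
        entropy = histogram_entropy(compute_histogram(values, nbins))
    volume_ml = (values.size * voxel_volume_mm3 / 1000.0
                 if voxel_volume_mm3 is not None else float("nan"))
    return FeatureVector(
        mean=float(values.mean()),
        median=float(np.median(values)),
        **{f"c{c}": q[c] for c in CENTILES},
        skewness=skew,
        kurtosis=kurt,
        entropy=entropy,
        n_voxels=int(values.size),
        volume_ml=volume_ml,
        degenerate=degenerate,
    )


def roi_morphology(roi: ROIMask) -> Morphology:
    """Volume, bounding lengths, centre of mass and surface voxel count."""
    if not roi.mask.any():
        raise ValueError("empty ROI mask")
    n = roi.n_voxels
    voxel_vol = float(np.prod(roi.spacing))
    idx = np.argwhere(roi.mask)
    extents = idx.max(axis=0) - idx.min(axis=0) + 1
    lengths = tuple(float(e * s) for e, s in zip(extents, roi.spacing))
    com = tuple(float(c) for c in idx.mean(axis=0))
    eroded = ndimage.binary_erosion(roi.mask)  # 6-connected structuring element
    surface = int((roi.mask & ~eroded).sum())
    return Morphology(
        n_voxels=n,
        volume_mm3=n * voxel_vol,
        volume_ml=n * voxel_vol / 1000.0,
        bounding_lengths_mm=lengths,
        center_of_mass=com,
        surface_voxel_count=surface,
    )
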