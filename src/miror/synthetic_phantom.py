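"""Synthetic DWI phantoms and feature cohorts with known ground truth.

Every pipeline stage is testable without patient data:

* :func:`generate_phantom` builds a 4-D DWI series from ellipsoidal lesions
  embedded in a background tissue, each voxel following the IVIM
  biexponential decay, corrupted by Rician noise (the magnitude-MRI noise
  law) whose sigma is anchored to the b=0 signal-to-noise ratio of the
  emulated protocol (SNR ≈ 60 at b0, ≈ 30 at b1000).  The acquisition
  defaults mirror the emulated study: b = 0, 50, 100, 150, 600, 1000 s/mm²
  in 3 orthogonal directions, 1.56 × 1.56 × 5 mm voxels.
* :func:`generate_feature_cohort` draws two-group Gaussian feature records
  whose default means/SDs are the published ADC histogram statistics of a
  48-case paediatric body-tumour cohort (37 malignant, 11 benign).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from miror.diffusion_maps import ivim_signal
from miror.imaging_io import DWISeries, ParametricMap, ROIMask
from miror.repository import FeatureRecord

#: Acquisition b-values of the emulated protocol (s/mm²).
DEFAULT_BVALUES = (0.0, 50.0, 100.0, 150.0, 600.0, 1000.0)

#: Voxel size of the emulated protocol (mm).
DEFAULT_SPACING = (1.56, 1.56, 5.0)

#: Published ADC histogram statistics (mean, SD) per tumour group; ADC-scale
#: features are in 10⁻⁶ mm²/s, shape features dimensionless, entropy in bits.
MALIGNANT_FEATURE_STATS: dict[str, tuple[float, float]] = {
    "mean": (1098.0, 295.0),
    "median": (996.0, 262.0),
    "kurtosis": (2.1, 0.09),
    "skewness": (0.02, 0.004),
    "entropy": (7.1, 0.42),
    "c15": (710.0, 201.0),
    "c75": (1319.0, 329.0),
}
BENIGN_FEATURE_STATS: dict[str, tuple[float, float]] = {
    "mean": (1443.0, 462.0),
    "median": (1442.0, 511.0),
    "kurtosis": (2.031, 0.11),
    "skewness": (0.0007, 0.01),
    "entropy": (6.85, 0.4),
    "c15": (1072.0, 406.0),
    "c75": (1683.0, 538.0),
}

#: Cohort sizes of the emulated study.
DEFAULT_N_PER_GROUP = {"malignant": 37, "benign": 11}

# Ascending order of the quantile-family features; enforced per record.
_CENTILE_ORDER = ("c2", "c5", "c10", "c15", "c25", "median",
                  "c75", "c85", "c90", "c95", "c98")


@dataclass
class TissueParams:
    """IVIM ground-truth parameters of one tissue type."""

    S0: float
    D: float
    Dstar: float
    f: float

    def __post_init__(self) -> None:
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")
        if not (0 <= self.f <= 1):
            raise ValueError("f must lie in [0, 1]")
        if not (0 <= self.D <= self.Dstar):
            raise ValueError("requires 0 <= D <= Dstar")


@dataclass
class Lesion:
    """Ellipsoidal lesion: centre and radii in voxel units, tissue label."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    label: str


@dataclass
class PhantomSpec:
    """Geometry, tissues and acquisition of a synthetic DWI phantom.

    ``snr_b0`` sets the Rician noise level: sigma = background S0 / snr_b0;
    ``float('inf')`` disables noise.
    """

    shape: tuple[int, int, int] = (32, 32, 8)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    directions: int = 3
    snr_b0: float = 60.0
    seed: int = 0
    background: TissueParams = field(
        default_factory=lambda: TissueParams(S0=1000.0, D=1.8e-3, Dstar=10e-3, f=0.08))
    lesions: list[Lesion] = field(default_factory=list)
    tissues: dict[str, TissueParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.snr_b0 <= 0:
            raise ValueError("snr_b0 must be positive")
        for les in self.lesions:
            if les.label not in self.tissues:
                raise ValueError(f"lesion label {les.label!r} has no tissue parameters")
            for c, r, n in zip(les.center, les.radii, self.shape):
                if c - r < -0.5 or c + r > n - 0.5:
                    raise ValueError(f"lesion {les.label!r} extends outside the grid")


@dataclass
class PhantomResult:
    dwi: DWISeries
    truth_maps: dict[str, ParametricMap]  # keys: IVIM-D, IVIM-Dstar, IVIM-f, S0
    masks: dict[str, ROIMask]  # one per lesion label
    sigma: float  # Rician noise sigma actually applied


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Corrupt a noise-free magnitude signal with Rician noise:
    S' = sqrt((S + n1)^2 + n2^2), n1, n2 ~ Normal(0, sigma)."""
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Build a DWI series with known IVIM ground truth and per-lesion masks.

    The noise-free signal follows the IVIM biexponential per voxel and
    direction (directions are copies of the trace decay — the phantom is
    isotropic); Rician corruption uses one sigma for the whole series,
    anchored to the background S0 and the b0 SNR.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    label_map = np.full(shape, "", dtype=object)
    truth = {
        "S0": np.full(shape, spec.background.S0),
        "IVIM-D": np.full(shape, spec.background.D),
        "IVIM-Dstar": np.full(shape, spec.background.Dstar),
        "IVIM-f": np.full(shape, spec.background.f),
    }
    masks = {}
    for les in spec.lesions:
        m = _ellipsoid_mask(shape, les.center, les.radii)
        tp = spec.tissues[les.label]
        truth["S0"][m] = tp.S0
        truth["IVIM-D"][m] = tp.D
        truth["IVIM-Dstar"][m] = tp.Dstar
        truth["IVIM-f"][m] = tp.f
        label_map[m] = les.label
        masks[les.label] = ROIMask(mask=m, spacing=spec.spacing, label=les.label)

    n_acq = len(spec.bvalues) * spec.directions
    signal = np.empty(shape + (n_acq,))
    bvalues, direction_index = [], []
    acq = 0
    for b in spec.bvalues:
        clean = ivim_signal(b, truth["S0"], truth["IVIM-D"],
                            truth["IVIM-Dstar"], truth["IVIM-f"])
        for d in range(spec.directions):
            signal[..., acq] = clean
            bvalues.append(float(b))
            direction_index.append(d if spec.directions > 1 else -1)
            acq += 1
    sigma = 0.0
    if np.isfinite(spec.snr_b0):
        sigma = spec.background.S0 / spec.snr_b0
        signal = rician(signal, sigma, rng)

    dwi = DWISeries(signal=signal, bvalues=bvalues,
                    direction_index=direction_index, spacing=spec.spacing,
                    series_id=f"phantom-seed{spec.seed}")
    truth_maps = {k: ParametricMap(v.astype(float), kind=k, spacing=spec.spacing)
                  for k, v in truth.items()}
    return PhantomResult(dwi=dwi, truth_maps=truth_maps, masks=masks, sigma=sigma)


@dataclass
class CohortSpec:
    """Two-group Gaussian feature cohort specification.

    Defaults reproduce the emulated study's published group statistics and
    cohort sizes (37 malignant, 11 benign).  ``equicorrelation`` draws the
    per-record features from an equicorrelated Gaussian (shared latent
    factor) instead of independently — used to exercise correlation
    pruning; 0 means independent features.
    """

    group_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {"malignant": dict(MALIGNANT_FEATURE_STATS),
                                 "benign": dict(BENIGN_FEATURE_STATS)})
    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    map_kind: str = "ADC"
    nbins: int = 256
    seed: int = 0
    equicorrelation: float = 0.0

    def __post_init__(self) -> None:
        for group, stats in self.group_stats.items():
            if self.n_per_group.get(group, 0) < 2:
                raise ValueError(f"need n >= 2 for group {group!r}")
            for feat, (_, sd) in stats.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {group}/{feat}")
        if not (0.0 <= self.equicorrelation < 1.0):
            raise ValueError("equicorrelation must lie in [0, 1)")


def generate_feature_cohort(spec: CohortSpec) -> list[FeatureRecord]:
    """Draw Gaussian feature records for each tumour group.

    Each feature is Normal(mean, SD); centile-family features (c2..c98 and
    the median) are sorted into ascending order per record so the centile
    monotonicity invariant holds.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.equicorrelation
    records = []
    for group, stats in spec.group_stats.items():
        feats = list(stats)
        means = np.array([stats[f][0] for f in feats])
        sds = np.array([stats[f][1] for f in feats])
        n = spec.n_per_group[group]
        if rho > 0:
            shared = rng.normal(size=(n, 1))
            own = rng.normal(size=(n, len(feats)))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        else:
            z = rng.normal(size=(n, len(feats)))
        draws = means + sds * z
        chain = [f for f in _CENTILE_ORDER if f in feats]
        chain_idx = [feats.index(f) for f in chain]
        for i in range(n):
            row = dict(zip(feats, draws[i]))
            ordered = np.sort(draws[i, chain_idx])
            for f, v in zip(chain, ordered):
                row[f] = v
            records.append(FeatureRecord(
                case_id=f"{group[:3]}-{i:03d}",
                group=group,
                map_kind=spec.map_kind,
                features={k: float(v) for k, v in row.items()},
                diagnosis="synthetic",
                nbins=spec.nbins,
            ))
    return records
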