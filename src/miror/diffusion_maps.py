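"""ADC and IVIM parametric-map computation from multi-b-value DWI.

The signal model is the intravoxel-incoherent-motion (IVIM) biexponential

    S(b) = S0 * [(1 - f) * exp(-b * D) + f * exp(-b * (D + D*))]

where D is the tissue diffusion coefficient (mm²/s), D* the pseudo-diffusion
coefficient of capillary perfusion (mm²/s), and f the perfusion fraction.
The apparent diffusion coefficient (ADC) is the monoexponential decay rate
between a low/high b-value pair, ADC = ln(S(b_low)/S(b_high)) / (b_high - b_low).

Fitting is segmented around a b-value threshold b* (default 200 s/mm²): a
log-linear fit over b >= b* yields D and an intercept A, f = 1 - A/S(0), and
a bounded 1-D least squares over all b yields D*.  Because the perfusion
term is not perfectly extinct at b = 600 s/mm² when D* is small, the
segmented estimates seed a bounded joint least-squares refinement of
(S0, D, D*, f) by default; noise-free signals are then recovered exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from miror.imaging_io import DWISeries, ParametricMap

log = logging.getLogger(__name__)


def ivim_signal(b, S0: float, D: float, Dstar: float, f: float):
    """Evaluate the IVIM biexponential signal model at b (s/mm²)."""
    b = np.asarray(b, dtype=float)
    return S0 * ((1.0 - f) * np.exp(-b * D) + f * np.exp(-b * (D + Dstar)))


@dataclass
class FitConfig:
    """Configuration of the ADC/IVIM fitting strategy.

    Parameters
    ----------
    segmented_threshold
        b* in s/mm² separating the perfusion-sensitive (b < b*) from the
        pure-diffusion (b >= b*) segment.
    d_bounds, dstar_max, f_bounds
        Physiological parameter bounds; D* is additionally bounded below by
        the fitted D.
    adc_b_pair
        (b_low, b_high) for the ADC log-ratio; ``None`` means (0, max b).
    refine
        Run the joint bounded least-squares refinement after the segmented
        initialisation.
    """

    segmented_threshold: float = 200.0
    d_bounds: tuple[float, float] = (1e-5, 4e-3)
    dstar_max: float = 0.5
    f_bounds: tuple[float, float] = (0.0, 1.0)
    adc_b_pair: tuple[float, float] | None = None
    refine: bool = True

    def __post_init__(self) -> None:
        if self.adc_b_pair is not None and self.adc_b_pair[0] >= self.adc_b_pair[1]:
            raise ValueError("adc_b_pair must satisfy b_low < b_high")


@dataclass
class IVIMParams:
    """Result of a single-voxel IVIM fit.

    ``status`` is 'ok' when the parameter invariants hold (f in [0,1],
    0 <= D <= D*, S0 > 0), 'degenerate' for unusable input signals,
    'nonconverged' when the optimiser left the physiological box, and
    'infeasible' when the b-value protocol cannot support an IVIM fit.
    """

    S0: float
    D: float
    Dstar: float
    f: float
    status: str = "ok"

    def __post_init__(self) -> None:
        if self.status == "ok":
            if not (0.0 <= self.f <= 1.0):
                raise ValueError("f out of [0,1] for status=ok")
            if not (0.0 <= self.D <= self.Dstar):
                raise ValueError("requires 0 <= D <= Dstar for status=ok")
            if not self.S0 > 0:
                raise ValueError("requires S0 > 0 for status=ok")


@dataclass
class Feasibility:
    feasible: bool
    reason: str

    def __bool__(self) -> bool:
        return self.feasible


def check_ivim_feasibility(bvalues, threshold: float = 200.0) -> Feasibility:
    """Decide whether the b-value protocol supports an IVIM fit.

    Feasible iff there are >= 4 distinct b-values with >= 2 distinct values
    on each side of the segmentation threshold (4 unknowns, and each decay
    segment needs two points to fix a slope).
    """
    if len(bvalues) == 0:
        raise ValueError("empty b-value list")
    distinct = sorted(set(float(b) for b in bvalues))
    if len(distinct) < 4:
        return Feasibility(False, "needs >=4 distinct b-values")
    low = [b for b in distinct if b < threshold]
    high = [b for b in distinct if b >= threshold]
    if len(low) < 2:
        return Feasibility(False, f"needs >=2 b-values < {threshold:g}")
    if len(high) < 2:
        return Feasibility(False, f"needs >=2 b-values >= {threshold:g}")
    return Feasibility(True, f"feasible: {len(distinct)} distinct b-values")


def combine_directions(dwi: DWISeries) -> DWISeries:
    """Combine orthogonal diffusion directions into trace-weighted frames.

    Returns one frame per b-value, each voxel the geometric mean of the
    per-direction signals (the trace-weighted signal); direction indices
    become -1.  Already-combined series pass through unchanged.
    """
    if all(d == -1 for d in dwi.direction_index):
        return dwi
    groups: dict[float, list[int]] = {}
    order: list[float] = []
    for i, b in enumerate(dwi.bvalues):
        key = float(b)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)
    counts = {len(v) for v in groups.values()}
    if len(counts) != 1:
        raise ValueError(
            "unequal direction coverage per b-value: "
            + ", ".join(f"b={b:g}: {len(groups[b])}" for b in order)
        )
    frames = []
    n_zero = 0
    for b in order:
        stack = dwi.signal[..., groups[b]]
        n = stack.shape[-1]
        zero = (stack <= 0).any(axis=-1)
        n_zero += int(zero.sum())
        with np.errstate(divide="ignore"):
            gm = np.exp(np.mean(np.log(np.where(stack > 0, stack, 1.0)), axis=-1))
        frames.append(np.where(zero, 0.0, gm))
    if n_zero:
        log.warning("geometric mean annihilated %d voxel-frames with a zero direction", n_zero)
    return DWISeries(
        signal=np.stack(frames, axis=3),
        bvalues=order,
        direction_index=[-1] * len(order),
        spacing=dwi.spacing,
        series_id=dwi.series_id,
    )


def compute_adc_map(dwi: DWISeries, config: FitConfig | None = None) -> ParametricMap:
    """Compute the ADC map from a low/high b-value pair.

    ADC = ln(S(b_low)/S(b_high)) / (b_high - b_low); NaN where either signal
    is nonpositive, and negative decay rates (signal increase with b) are
    invalid and set to NaN.
    """
    config = config or FitConfig()
    dwi = combine_directions(dwi)
    pair = config.adc_b_pair or (min(dwi.bvalues), max(dwi.bvalues))
    b_low, b_high = float(pair[0]), float(pair[1])
    try:
        i_low = dwi.bvalues.index(b_low)
        i_high = dwi.bvalues.index(b_high)
    except ValueError:
        raise ValueError(
            f"requested ADC b-pair ({b_low:g}, {b_high:g}) absent from series "
            f"b-values {dwi.bvalues}"
        ) from None
    s_low = dwi.signal[..., i_low]
    s_high = dwi.signal[..., i_high]
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.log(s_low / s_high) / (b_high - b_low)
    adc = np.where((s_low > 0) & (s_high > 0), adc, np.nan)
    adc = np.where(adc < 0, np.nan, adc)
    return ParametricMap(values=adc, kind="ADC", spacing=dwi.spacing)


def _nan_params(status: str) -> IVIMParams:
    return IVIMParams(S0=np.nan, D=np.nan, Dstar=np.nan, f=np.nan, status=status)


def fit_ivim_voxel(signals, bvalues, config: FitConfig | None = None) -> IVIMParams:
    """Fit the IVIM model to a single voxel's per-b signals.

    Segmented initialisation: (i) log-linear fit over b >= b* gives D and
    intercept A; (ii) f = 1 - A/S(0); (iii) with D and f fixed, a bounded
    1-D least squares over all b gives D*.  With ``config.refine`` (default)
    a joint bounded least squares of (S0, D, D*, f) polishes the estimate.
    """
    config = config or FitConfig()
    b = np.asarray(bvalues, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.shape != s.shape:
        raise ValueError("signals and bvalues must have equal length")
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        return _nan_params("degenerate")
    verdict = check_ivim_feasibility(b, config.segmented_threshold)
    if not verdict:
        return _nan_params("infeasible")

    order = np.argsort(b)
    b, s = b[order], s[order]
    thr = config.segmented_threshold
    d_lo, d_hi = config.d_bounds

    # (i) monoexponential tail: ln S = ln A - b D for b >= b*
    high = b >= thr
    slope, ln_a = np.polyfit(b[high], np.log(s[high]), 1)
    d_init = float(np.clip(-slope, d_lo, d_hi))
    a = float(np.exp(ln_a))
    # (ii) perfusion fraction from the extrapolated intercept deficit
    s0_meas = float(s[0])
    f_init = float(np.clip(1.0 - a / s0_meas, 0.0, 0.95))

    # (iii) bounded 1-D search for D* with S0, D, f fixed
    dstar_lo = max(d_init, d_lo)
    dstar_hi = config.dstar_max

    def sse_dstar(dstar: float) -> float:
        resid = ivim_signal(b, s0_meas, d_init, dstar, f_init) - s
        return float(resid @ resid)

    try:
        res1d = minimize_scalar(sse_dstar, bounds=(dstar_lo, dstar_hi), method="bounded")
        dstar_init = float(res1d.x)
    except Exception:
        return _nan_params("nonconverged")

    s0, d, dstar, f = s0_meas, d_init, dstar_init, f_init
    if config.refine:
        x0 = np.array([s0, d, max(dstar, dstar_lo), np.clip(f, 1e-6, 0.95)])
        lower = np.array([1e-6, d_lo, d_lo, config.f_bounds[0]])
        upper = np.array([np.inf, d_hi, dstar_hi, config.f_bounds[1]])
        x0 = np.clip(x0, lower, np.minimum(upper, np.finfo(float).max))

        def resid(x):
            return ivim_signal(b, x[0], x[1], x[2], x[3]) - s

        try:
            sol = least_squares(resid, x0, bounds=(lower, upper),
                                x_scale=[s0_meas, 1e-3, 1e-2, 0.1])
        except Exception:
            return _nan_params("nonconverged")
        if not sol.success:
            return _nan_params("nonconverged")
        s0, d, dstar, f = (float(v) for v in sol.x)

    status = "ok"
    if not (0.0 <= f <= 1.0 and 0.0 <= d <= dstar and s0 > 0):
        # clip into the physiological box but flag the voxel
        f = float(np.clip(f, 0.0, 1.0))
        dstar = max(dstar, d)
        status = "nonconverged"
    return IVIMParams(S0=s0, D=d, Dstar=dstar, f=f, status=status)


def fit_ivim_maps(dwi: DWISeries, config: FitConfig | None = None
                  ) -> tuple[ParametricMap, ParametricMap, ParametricMap, ParametricMap]:
    """Voxel-wise IVIM fit of a DWI series.

    Directions are combined first; voxels whose fit status is not 'ok' are
    NaN in all four maps.  Returns (D, D*, f, S0) maps.
    """
    config = config or FitConfig()
    verdict = check_ivim_feasibility(dwi.bvalues, config.segmented_threshold)
    if not verdict:
        raise ValueError(f"IVIM analysis infeasible: {verdict.reason}")
    dwi = combine_directions(dwi)
    shape = dwi.shape
    out = {k: np.full(shape, np.nan) for k in ("D", "Dstar", "f", "S0")}
    flat = dwi.signal.reshape(-1, dwi.n_acquisitions)
    n_bad = 0
    for idx in range(flat.shape[0]):
        p = fit_ivim_voxel(flat[idx], dwi.bvalues, config)
        if p.status != "ok":
            n_bad += 1
            continue
        vox = np.unravel_index(idx, shape)
        out["D"][vox] = p.D
        out["Dstar"][vox] = p.Dstar
        out["f"][vox] = p.f
        out["S0"][vox] = p.S0
    if n_bad:
        log.info("IVIM fit: %d/%d voxels not ok -> NaN", n_bad, flat.shape[0])
    sp = dwi.spacing
    return (
        ParametricMap(out["D"], kind="IVIM-D", spacing=sp),
        ParametricMap(out["Dstar"], kind="IVIM-Dstar", spacing=sp),
        ParametricMap(out["f"], kind="IVIM-f", spacing=sp),
        ParametricMap(out["S0"], kind="S0", spacing=sp),
    )
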