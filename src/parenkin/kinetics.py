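"""Voxel-wise contrast-enhancement kinetics and breast-wise summary measures.

A breast DCE-MRI study here consists of one pre-contrast volume ``S0`` and
three post-contrast volumes ``S1..S3`` acquired on the same grid.  For every
voxel of fibroglandular tissue (FGT) the relative enhancement

    E_k = (S_k - S0) / S0,   k = 1..3

defines a three-point kinetic curve, from which the standard kinetic
variables are derived:

* peak enhancement        ``max_k E_k``
* time to peak            acquisition time of the (earliest) maximum
* wash-in slope           peak enhancement / time to peak   [1/min]
* wash-out slope          (E_3 - peak)/(t_3 - time to peak), 0 when the
                          curve peaks at the last timepoint [1/min]
* SER                     SUB1/SUB3 = (S1 - S0)/(S3 - S0)

SER bands map voxels onto the canonical kinetic classes: persistent
(SER < 0.9), plateau (0.9 <= SER <= 1.3) and washout (SER > 1.3).

Breast-wise measures aggregate the maps over the FGT mask: the mean and
variance of each of the four kinetic variables (eight measures; the variance
of the wash-in slope, WISV, is the headline heterogeneity measure), the SER
volume (cm^3 of enhancing voxels with SER >= 0.9, i.e. plateau or washout
kinetics) and BPE% (percent of breast volume occupied by FGT voxels whose
first-post enhancement is at least 20%).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

__all__ = [
    "KineticThresholds",
    "DCESeries",
    "SegmentationMasks",
    "KineticMaps",
    "BreastMeasures",
    "compute_subtractions",
    "voxel_kinetics",
    "ser_class",
    "ser_class_codes",
    "aggregate_measures",
    "pair_change_class",
    "CLASS_PERSISTENT",
    "CLASS_PLATEAU",
    "CLASS_WASHOUT",
    "CLASS_UNCLASSIFIED",
]

# integer codes for SER-based kinetic classes (vectorised maps)
CLASS_UNCLASSIFIED = -1
CLASS_PERSISTENT = 0
CLASS_PLATEAU = 1
CLASS_WASHOUT = 2

_CLASS_NAMES = {
    CLASS_PERSISTENT: "persistent",
    CLASS_PLATEAU: "plateau",
    CLASS_WASHOUT: "washout",
    CLASS_UNCLASSIFIED: "unclassified",
}


@dataclass(frozen=True)
class KineticThresholds:
    """Decision thresholds of the quantification pipeline.

    Attributes
    ----------
    ser_enhancing_min:
        Lower SER bound of the plateau band; voxels at or above it count
        toward the SER volume (plateau or washout kinetics).
    ser_washout:
        SER strictly above this value is washout kinetics.
    enhancement_min:
        Minimum first-post relative enhancement for a voxel to count as
        enhancing (the BPE rule, "at least 20%").
    pair_band:
        Relative band for classifying matched-pair differences
        (case vs control) as greater/less/within.
    ser_eps_rel:
        SER denominators SUB3 <= ser_eps_rel * (median pre-contrast signal)
        are treated as degenerate and flagged invalid.
    """

    ser_enhancing_min: float = 0.9
    ser_washout: float = 1.3
    enhancement_min: float = 0.20
    pair_band: float = 0.15
    ser_eps_rel: float = 1e-6


DEFAULT_THRESHOLDS = KineticThresholds()


@dataclass
class DCESeries:
    """One pre-contrast and three post-contrast co-registered volumes.

    ``signal`` has shape ``(4,) + grid_shape`` with index 0 the pre-contrast
    volume; ``times_min`` are the four acquisition times in minutes (first
    must be 0) and ``voxel_spacing_mm`` the per-axis spacing.
    """

    signal: np.ndarray
    times_min: np.ndarray
    voxel_spacing_mm: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.voxel_spacing_mm = np.asarray(self.voxel_spacing_mm, dtype=float)
        if self.signal.ndim != 4 or self.signal.shape[0] != 4:
            raise ValueError(
                f"signal must have shape (4, nx, ny, nz), got {self.signal.shape}"
            )
        if self.times_min.shape != (4,):
            raise ValueError("times_min must hold exactly four acquisition times")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        if self.voxel_spacing_mm.shape != (3,) or np.any(self.voxel_spacing_mm <= 0):
            raise ValueError("voxel_spacing_mm must be three positive values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[1:]

    @property
    def s0(self) -> np.ndarray:
        return self.signal[0]

    @property
    def s1(self) -> np.ndarray:
        return self.signal[1]

    @property
    def s2(self) -> np.ndarray:
        return self.signal[2]

    @property
    def s3(self) -> np.ndarray:
        return self.signal[3]

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_spacing_mm)) / 1000.0


@dataclass
class SegmentationMasks:
    """Binary breast and fibroglandular-tissue masks on the series grid."""

    breast: np.ndarray
    fgt: np.ndarray

    def __post_init__(self) -> None:
        self.breast = np.asarray(self.breast, dtype=bool)
        self.fgt = np.asarray(self.fgt, dtype=bool)
        if self.breast.shape != self.fgt.shape:
            raise ValueError("breast and fgt masks must share a grid")
        if np.any(self.fgt & ~self.breast):
            raise ValueError("fgt mask must be a subset of the breast mask")


@dataclass
class KineticMaps:
    """Per-voxel kinetic maps on the FGT mask (NaN elsewhere).

    ``valid`` marks FGT voxels with a positive pre-contrast signal; all
    aggregates are restricted to it.  ``valid_ser`` additionally requires a
    non-degenerate SER denominator.  ``enhancing`` applies the first-post
    >= 20% rule.
    """

    peak_enhancement: np.ndarray
    time_to_peak: np.ndarray
    wash_in_slope: np.ndarray
    wash_out_slope: np.ndarray
    ser: np.ndarray
    valid: np.ndarray
    valid_ser: np.ndarray
    enhancing: np.ndarray
    n_invalid_s0: int
    times_min: np.ndarray


@dataclass
class BreastMeasures:
    """Breast-wise summary of the kinetic maps.

    ``var_wash_in_slope`` (alias :attr:`wisv`) is the wash-in slope variance;
    tables conventionally report it multiplied by 100 (:attr:`wisv_x100`).
    """

    mean_peak_enhancement: float
    var_peak_enhancement: float
    mean_time_to_peak: float
    var_time_to_peak: float
    mean_wash_in_slope: float
    var_wash_in_slope: float
    mean_wash_out_slope: float
    var_wash_out_slope: float
    serv_cm3: float
    bpe_pct: float
    breast_volume_cm3: float
    fgt_volume_cm3: float
    n_valid_ser_voxels: int
    n_enhancing_voxels: int

    @property
    def wisv(self) -> float:
        return self.var_wash_in_slope

    @property
    def wisv_x100(self) -> float:
        return 100.0 * self.var_wash_in_slope

    def as_dict(self) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["wisv"] = self.wisv
        return d


def compute_subtractions(series: DCESeries) -> np.ndarray:
    """Return the three subtraction volumes SUB_k = S_k - S0, shape (3,)+grid.

    Negative values are retained; no clamping is applied.
    """
    return series.signal[1:] - series.signal[0]


def voxel_kinetics(
    series: DCESeries,
    masks: SegmentationMasks,
    thresholds: KineticThresholds = DEFAULT_THRESHOLDS,
) -> KineticMaps:
    """Compute per-voxel kinetic maps over the FGT mask.

    Voxels with non-positive pre-contrast signal are flagged invalid and
    excluded from every aggregate; their count is reported.

    Raises
    ------
    ValueError
        If the masks do not match the series grid or the FGT mask is empty.
    """
    if masks.breast.shape != series.grid_shape:
        raise ValueError("mask grid does not match series grid")
    fgt = masks.fgt
    if not fgt.any():
        raise ValueError("FGT mask is empty")

    s = series.signal[:, fgt]  # (4, n)
    s0 = s[0]
    valid_flat = s0 > 0
    n_invalid = int(np.count_nonzero(~valid_flat))

    n = s.shape[1]
    enh = np.full((3, n), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        enh[:, valid_flat] = (s[1:, valid_flat] - s0[valid_flat]) / s0[valid_flat]

    post_times = series.times_min[1:]
    # earliest timepoint achieving the maximum (np.argmax returns the first)
    peak = np.nanmax(np.where(np.isnan(enh), -np.inf, enh), axis=0)
    peak[~valid_flat] = np.nan
    ttp_idx = np.argmax(np.where(np.isnan(enh), -np.inf, enh), axis=0)
    ttp = post_times[ttp_idx]
    ttp[~valid_flat] = np.nan

    wash_in = peak / ttp
    t3 = post_times[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        wash_out = np.where(ttp < t3, (enh[2] - peak) / (t3 - ttp), 0.0)
    wash_out[~valid_flat] = np.nan

    sub1 = s[1] - s0
    sub3 = s[3] - s0
    eps = thresholds.ser_eps_rel * float(np.median(s0[valid_flat]))
    valid_ser_flat = valid_flat & (sub3 > eps)
    ser = np.full(n, np.nan)
    ser[valid_ser_flat] = sub1[valid_ser_flat] / sub3[valid_ser_flat]

    enhancing_flat = valid_flat & (enh[0] >= thresholds.enhancement_min)

    def _scatter(values: np.ndarray, fill=np.nan, dtype=float) -> np.ndarray:
        out = np.full(fgt.shape, fill, dtype=dtype)
        out[fgt] = values
        return out

    return KineticMaps(
        peak_enhancement=_scatter(peak),
        time_to_peak=_scatter(ttp),
        wash_in_slope=_scatter(wash_in),
        wash_out_slope=_scatter(wash_out),
        ser=_scatter(ser),
        valid=_scatter(valid_flat, fill=False, dtype=bool),
        valid_ser=_scatter(valid_ser_flat, fill=False, dtype=bool),
        enhancing=_scatter(enhancing_flat, fill=False, dtype=bool),
        n_invalid_s0=n_invalid,
        times_min=series.times_min.copy(),
    )


def ser_class(
    ser: float, valid: bool = True, thresholds: KineticThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Classify a single SER value as persistent / plateau / washout.

    Washout: SER > 1.3; plateau: 0.9 <= SER <= 1.3; persistent: SER < 0.9.
    Invalid or non-finite SER values return ``"unclassified"``.
    """
    if not valid or not np.isfinite(ser):
        return _CLASS_NAMES[CLASS_UNCLASSIFIED]
    if ser > thresholds.ser_washout:
        return _CLASS_NAMES[CLASS_WASHOUT]
    if ser >= thresholds.ser_enhancing_min:
        return _CLASS_NAMES[CLASS_PLATEAU]
    return _CLASS_NAMES[CLASS_PERSISTENT]


def ser_class_codes(
    ser: np.ndarray,
    valid_ser: np.ndarray | None = None,
    thresholds: KineticThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Vectorised SER classification to integer codes (CLASS_* constants)."""
    ser = np.asarray(ser, dtype=float)
    ok = np.isfinite(ser)
    if valid_ser is not None:
        ok = ok & np.asarray(valid_ser, dtype=bool)
    codes = np.full(ser.shape, CLASS_UNCLASSIFIED, dtype=np.int8)
    codes[ok & (ser < thresholds.ser_enhancing_min)] = CLASS_PERSISTENT
    codes[ok & (ser >= thresholds.ser_enhancing_min) & (ser <= thresholds.ser_washout)] = (
        CLASS_PLATEAU
    )
    codes[ok & (ser > thresholds.ser_washout)] = CLASS_WASHOUT
    return codes


def aggregate_measures(
    maps: KineticMaps,
    masks: SegmentationMasks,
    voxel_spacing_mm: Sequence[float],
    thresholds: KineticThresholds = DEFAULT_THRESHOLDS,
    ser_volume_requires_enhancing: bool = True,
) -> BreastMeasures:
    """Aggregate kinetic maps into breast-wise measures.

    Means and variances (population form, divide by n) are taken over valid
    FGT voxels.  The SER volume counts voxels with a valid SER >= 0.9 that
    also pass the enhancing gate (switchable via
    ``ser_volume_requires_enhancing``); BPE% is the volume of enhancing FGT
    voxels as a percentage of breast volume.

    Raises
    ------
    ValueError
        If fewer than two valid voxels are available (variance undefined).
    """
    spacing = np.asarray(voxel_spacing_mm, dtype=float)
    voxel_vol = float(np.prod(spacing)) / 1000.0  # cm^3

    valid = maps.valid
    n_valid = int(np.count_nonzero(valid))
    if n_valid < 2:
        raise ValueError(f"need >= 2 valid FGT voxels, got {n_valid}")

    def _stats(arr: np.ndarray) -> tuple[float, float]:
        vals = arr[valid]
        return float(np.mean(vals)), float(np.var(vals))

    mean_pe, var_pe = _stats(maps.peak_enhancement)
    mean_ttp, var_ttp = _stats(maps.time_to_peak)
    mean_wis, var_wis = _stats(maps.wash_in_slope)
    mean_wos, var_wos = _stats(maps.wash_out_slope)

    ser_ok = maps.valid_ser & (maps.ser >= thresholds.ser_enhancing_min)
    if ser_volume_requires_enhancing:
        ser_ok = ser_ok & maps.enhancing
    n_serv = int(np.count_nonzero(ser_ok))
    n_enh = int(np.count_nonzero(maps.enhancing))

    breast_vol = float(np.count_nonzero(masks.breast)) * voxel_vol
    fgt_vol = float(np.count_nonzero(masks.fgt)) * voxel_vol

    return BreastMeasures(
        mean_peak_enhancement=mean_pe,
        var_peak_enhancement=var_pe,
        mean_time_to_peak=mean_ttp,
        var_time_to_peak=var_ttp,
        mean_wash_in_slope=mean_wis,
        var_wash_in_slope=var_wis,
        mean_wash_out_slope=mean_wos,
        var_wash_out_slope=var_wos,
        serv_cm3=n_serv * voxel_vol,
        bpe_pct=100.0 * (n_enh * voxel_vol) / breast_vol,
        breast_volume_cm3=breast_vol,
        fgt_volume_cm3=fgt_vol,
        n_valid_ser_voxels=n_serv,
        n_enhancing_voxels=n_enh,
    )


def pair_change_class(
    case_value: float, control_value: float, band: float = 0.15
) -> str:
    """Classify a matched-pair difference relative to the control value.

    Returns ``"greater15"`` when the case exceeds the control by more than
    ``band`` (default 15%), ``"less15"`` when it falls short by more than
    ``band``, else ``"within15"``.
    """
    if control_value <= 0:
        raise ValueError("control value must be positive")
    if case_value > (1.0 + band) * control_value:
        return "greater15"
    if case_value < (1.0 - band) * control_value:
        return "less15"
    return "within15"
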