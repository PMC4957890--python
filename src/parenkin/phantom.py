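"""Digital DCE-MRI phantom and synthetic matched case-control cohorts.

The phantom emulates the imaging substrate of a normal-parenchyma kinetics
study: a pre-contrast volume plus three post-contrast volumes in which every
fibroglandular-tissue (FGT) voxel follows one of the canonical kinetic
classes — persistent, plateau, washout — or does not enhance.  Curves are
built so each class maps one-to-one onto its SER band (persistent < 0.9,
plateau in [0.9, 1.3], washout > 1.3), which makes every breast-wise
measure analytically known and lets the quantification pipeline be checked
against exact ground truth.

Curve construction, with relative enhancement E(t) = S(t)/S(0) - 1 and a
per-voxel peak-enhancement draw PE and SER target r:

* washout / plateau: E1 = PE, E3 = PE / r, E2 linear in time between them,
  so SER = SUB1/SUB3 = r exactly on noiseless data.
* persistent: rises through the last timepoint, E3 = 1.1 PE and E1 = r E3
  (r < 0.9), E2 linear in between.
* non-enhancing: flat, E = 0 (fails the 20% first-post rule).

Cohort generation produces 1:1 matched case-control cohorts in two modes:
``measures-only`` draws the breast-wise measures directly from log-normal
marginals (cases shifted multiplicatively, dependence via a Gaussian
copula); ``full-image`` builds one phantom per subject — cases receive
larger washout/plateau fractions and a wider peak-enhancement range — and
computes the measures through the kinetics module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import MatchedCohort, SubjectRecord, greedy_match
from .kinetics import (
    BreastMeasures,
    DCESeries,
    KineticThresholds,
    DEFAULT_THRESHOLDS,
    SegmentationMasks,
    aggregate_measures,
    voxel_kinetics,
)

__all__ = [
    "InvalidSpecError",
    "CurveClassParams",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "MeasureModel",
    "CovariateModel",
    "FullImageModel",
    "CohortSpec",
    "make_cohort",
    "KINETIC_CLASSES",
    "CLASS_CODES",
]

KINETIC_CLASSES = ("persistent", "plateau", "washout", "nonenhancing")
CLASS_CODES = {name: i for i, name in enumerate(KINETIC_CLASSES)}
CLASS_CODE_OUTSIDE = -1


class InvalidSpecError(ValueError):
    """A phantom or cohort specification violates its invariants."""


@dataclass(frozen=True)
class CurveClassParams:
    """Per-class generative ranges: peak enhancement and SER target."""

    pe_range: tuple[float, float]
    ser_range: tuple[float, float]


def default_curve_params() -> dict[str, CurveClassParams]:
    return {
        "persistent": CurveClassParams(pe_range=(0.3, 0.9), ser_range=(0.15, 0.60)),
        "plateau": CurveClassParams(pe_range=(0.3, 0.9), ser_range=(0.95, 1.25)),
        "washout": CurveClassParams(pe_range=(0.3, 0.9), ser_range=(1.40, 2.40)),
        "nonenhancing": CurveClassParams(pe_range=(0.0, 0.0), ser_range=(1.0, 1.0)),
    }


def default_class_fractions() -> dict[str, float]:
    return {"persistent": 0.35, "plateau": 0.15, "washout": 0.10, "nonenhancing": 0.40}


@dataclass
class PhantomSpec:
    """Specification of one synthetic DCE-MRI examination.

    The breast is an ellipsoid centred in the grid and the FGT a smaller
    concentric ellipsoid; semi-axes are given as fractions of the grid
    extent per axis.  ``class_fractions`` partition the FGT voxels (must sum
    to 1); ``curve_params`` give per-class peak-enhancement and SER-target
    ranges (each SER range must sit inside its class band).  Acquisition
    times default to 0, 1.5, 4.5 and 7.5 min: a first post-contrast sequence
    centred around 90 s after injection and subsequent sequences spaced by
    the ~3-minute sequence duration.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 8)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    acquisition_times_min: tuple[float, float, float, float] = (0.0, 1.5, 4.5, 7.5)
    class_fractions: dict[str, float] = field(default_factory=default_class_fractions)
    curve_params: dict[str, CurveClassParams] = field(default_factory=default_curve_params)
    baseline_signal: float = 500.0
    noise_sd: float = 0.0
    breast_semiaxes_frac: tuple[float, float, float] = (0.45, 0.45, 0.45)
    fgt_semiaxes_frac: tuple[float, float, float] = (0.30, 0.30, 0.30)
    seed: int = 0

    def validate(self, thresholds: KineticThresholds = DEFAULT_THRESHOLDS) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise InvalidSpecError("grid_shape must be three positive integers")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise InvalidSpecError("voxel spacing must be positive")
        t = np.asarray(self.acquisition_times_min, dtype=float)
        if t.shape != (4,) or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise InvalidSpecError(
                "acquisition times must be four values, start at 0 and increase strictly"
            )
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.baseline_signal <= 0:
            raise InvalidSpecError("baseline_signal must be positive")
        fracs = self.class_fractions
        if set(fracs) != set(KINETIC_CLASSES):
            raise InvalidSpecError(f"class_fractions must have keys {KINETIC_CLASSES}")
        if any(v < 0 for v in fracs.values()):
            raise InvalidSpecError("class fractions must be non-negative")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise InvalidSpecError("class fractions must sum to 1 within 1e-9")
        if any(
            f > b for f, b in zip(self.fgt_semiaxes_frac, self.breast_semiaxes_frac)
        ):
            raise InvalidSpecError("FGT ellipsoid must fit inside the breast ellipsoid")
        bands = {
            "persistent": (0.0, thresholds.ser_enhancing_min, False),
            "plateau": (thresholds.ser_enhancing_min, thresholds.ser_washout, True),
            "washout": (thresholds.ser_washout, math.inf, False),
        }
        for name, (lo, hi, closed) in bands.items():
            cp = self.curve_params[name]
            slo, shi = cp.ser_range
            if slo > shi:
                raise InvalidSpecError(f"{name}: empty SER range")
            in_band = (slo >= lo and shi <= hi) if closed else (slo > lo and shi < hi)
            if name == "persistent":
                in_band = slo >= 0.0 and shi < hi
            if name == "washout":
                in_band = slo > lo
            if not in_band:
                raise InvalidSpecError(
                    f"{name}: SER range {cp.ser_range} falls outside the class band"
                )
            if cp.pe_range[0] < 0 or cp.pe_range[0] > cp.pe_range[1]:
                raise InvalidSpecError(f"{name}: invalid peak-enhancement range")


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom.

    ``class_map`` holds CLASS_CODES on FGT voxels and -1 elsewhere;
    ``enhancement`` the noiseless relative enhancement (3 post-contrast
    timepoints, NaN outside FGT); ``true_measures`` the analytic
    breast-wise measures implied by the noiseless curves.
    """

    class_map: np.ndarray
    enhancement: np.ndarray
    masks: SegmentationMasks
    true_measures: BreastMeasures


def _ellipsoid_mask(shape, semiaxes_frac) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    semi = [max(f * n, 0.5) for f, n in zip(semiaxes_frac, shape)]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _largest_remainder_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Integer class counts summing to n, by largest-remainder apportionment."""
    raw = {k: fractions[k] * n for k in KINETIC_CLASSES}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    shortfall = n - sum(counts.values())
    order = sorted(
        KINETIC_CLASSES, key=lambda k: (raw[k] - counts[k], k), reverse=True
    )
    for k in order[:shortfall]:
        counts[k] += 1
    return counts


def _noiseless_enhancement(
    codes: np.ndarray, pe: np.ndarray, ser_target: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Relative enhancement at the three post-contrast times, shape (n, 3)."""
    t1, t2, t3 = times[1], times[2], times[3]
    frac = (t2 - t1) / (t3 - t1)
    e = np.zeros((codes.size, 3))

    pers = codes == CLASS_CODES["persistent"]
    e3 = 1.1 * pe[pers]
    e1 = ser_target[pers] * e3
    e[pers, 0] = e1
    e[pers, 2] = e3
    e[pers, 1] = e1 + (e3 - e1) * frac

    for name in ("plateau", "washout"):
        sel = codes == CLASS_CODES[name]
        e1 = pe[sel]
        e3 = e1 / ser_target[sel]
        e[sel, 0] = e1
        e[sel, 2] = e3
        e[sel, 1] = e1 + (e3 - e1) * frac

    return e


def _analytic_measures(
    enh: np.ndarray,
    masks: SegmentationMasks,
    spec: PhantomSpec,
    thresholds: KineticThresholds,
) -> BreastMeasures:
    """Breast-wise measures implied by noiseless enhancement curves.

    Computed directly from the generative curves (plain sums and counts),
    independent of the image round-trip through the kinetics module.
    """
    times = np.asarray(spec.acquisition_times_min, dtype=float)
    post = times[1:]
    n = enh.shape[0]

    peak = enh.max(axis=1)
    ttp = post[np.argmax(enh, axis=1)]  # earliest maximum
    wis = peak / ttp
    with np.errstate(invalid="ignore", divide="ignore"):
        wos = np.where(ttp < post[-1], (enh[:, 2] - peak) / (post[-1] - ttp), 0.0)

    # SER in signal units: SUBk = baseline * Ek, so SER = E1/E3; the
    # denominator is degenerate when E3 <= eps_rel (baseline scale cancels).
    valid_ser = enh[:, 2] > thresholds.ser_eps_rel
    ser = np.where(valid_ser, enh[:, 0] / np.where(valid_ser, enh[:, 2], 1.0), np.nan)
    enhancing = enh[:, 0] >= thresholds.enhancement_min

    def mv(x: np.ndarray) -> tuple[float, float]:
        m = float(x.sum() / n)
        return m, float((x * x).sum() / n - m * m)

    mean_pe, var_pe = mv(peak)
    mean_ttp, var_ttp = mv(ttp)
    mean_wis, var_wis = mv(wis)
    mean_wos, var_wos = mv(wos)

    voxel_vol = float(np.prod(spec.voxel_spacing_mm)) / 1000.0
    n_serv = int(
        np.count_nonzero(enhancing & valid_ser & (ser >= thresholds.ser_enhancing_min))
    )
    n_enh = int(np.count_nonzero(enhancing))
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


def make_phantom(
    spec: PhantomSpec,
    masks: SegmentationMasks | None = None,
    thresholds: KineticThresholds = DEFAULT_THRESHOLDS,
) -> tuple[DCESeries, PhantomTruth]:
    """Generate one synthetic DCE series with analytically known truth.

    Parameters
    ----------
    spec:
        Validated phantom specification.
    masks:
        Optional explicit breast/FGT masks overriding the ellipsoidal
        geometry (FGT must be a subset of breast; grid must match).

    Returns
    -------
    (DCESeries, PhantomTruth)
        The (optionally noisy) image series, and the ground truth computed
        from the noiseless curves.
    """
    spec.validate(thresholds)
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)

    if masks is None:
        breast = _ellipsoid_mask(shape, spec.breast_semiaxes_frac)
        fgt = _ellipsoid_mask(shape, spec.fgt_semiaxes_frac)
        masks = SegmentationMasks(breast=breast, fgt=fgt)
    else:
        if masks.breast.shape != shape:
            raise InvalidSpecError("provided masks do not match the grid shape")
    fgt_idx = np.flatnonzero(masks.fgt.ravel())
    n_fgt = fgt_idx.size
    if n_fgt == 0:
        raise InvalidSpecError("FGT mask is empty")

    counts = _largest_remainder_counts(spec.class_fractions, n_fgt)
    codes = np.concatenate(
        [np.full(counts[name], CLASS_CODES[name], dtype=np.int8) for name in KINETIC_CLASSES]
    )
    codes = codes[rng.permutation(n_fgt)]

    pe = np.zeros(n_fgt)
    ser_target = np.ones(n_fgt)
    for name in KINETIC_CLASSES:
        sel = codes == CLASS_CODES[name]
        cp = spec.curve_params[name]
        pe[sel] = rng.uniform(cp.pe_range[0], cp.pe_range[1], sel.sum())
        ser_target[sel] = rng.uniform(cp.ser_range[0], cp.ser_range[1], sel.sum())

    times = np.asarray(spec.acquisition_times_min, dtype=float)
    enh = _noiseless_enhancement(codes, pe, ser_target, times)

    base = spec.baseline_signal
    signal = np.empty((4,) + shape)
    background = 0.05 * base  # air / non-breast tissue
    for k in range(4):
        vol = np.full(shape, background)
        vol[masks.breast] = base
        flat = vol.ravel()
        if k > 0:
            flat[fgt_idx] = base * (1.0 + enh[:, k - 1])
        else:
            flat[fgt_idx] = base
        signal[k] = flat.reshape(shape)

    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
        np.maximum(signal, 0.0, out=signal)  # signal magnitudes cannot go negative

    series = DCESeries(
        signal=signal,
        times_min=times,
        voxel_spacing_mm=np.asarray(spec.voxel_spacing_mm, dtype=float),
    )

    class_map = np.full(shape, CLASS_CODE_OUTSIDE, dtype=np.int8)
    class_map.ravel()[fgt_idx] = codes
    enh_maps = np.full((3,) + shape, np.nan)
    for k in range(3):
        flat = enh_maps[k].ravel()
        flat[fgt_idx] = enh[:, k]
        enh_maps[k] = flat.reshape(shape)

    truth = PhantomTruth(
        class_map=class_map,
        enhancement=enh_maps,
        masks=masks,
        true_measures=_analytic_measures(enh, masks, spec, thresholds),
    )
    return series, truth


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

HEADLINE_MEASURES = ("wisv", "serv_cm3", "bpe_pct")


@dataclass(frozen=True)
class MeasureModel:
    """Log-normal marginal for one breast-wise measure (natural scale)."""

    control_mean: float
    control_sd: float


def default_measure_models() -> dict[str, MeasureModel]:
    # control-group moments of the cohort table: WISVx100 1.75 +/- 1.26
    # (0.0175 +/- 0.0126 unscaled), SERV 80.4 +/- 42.9 cm^3, BPE% 39.8 +/- 11.4
    return {
        "wisv": MeasureModel(control_mean=0.0175, control_sd=0.0126),
        "serv_cm3": MeasureModel(control_mean=80.4, control_sd=42.9),
        "bpe_pct": MeasureModel(control_mean=39.8, control_sd=11.4),
    }


def default_effect_sizes() -> dict[str, float]:
    # ratios of case to control means in the cohort table
    return {"wisv": 2.90 / 1.75, "serv_cm3": 118.9 / 80.4, "bpe_pct": 44.6 / 39.8}


def default_case_sigma_scale() -> dict[str, float]:
    # case/control ratio of log-scale SDs implied by the reported CVs
    return {"wisv": 1.229, "serv_cm3": 1.291, "bpe_pct": 0.704}


def default_copula_corr() -> np.ndarray:
    # latent Gaussian correlation mirroring the reported rank-correlation
    # pattern: WISV-SERV weak, both moderately correlated with BPE%
    return np.array(
        [
            [1.00, 0.17, 0.56],
            [0.17, 1.00, 0.48],
            [0.56, 0.48, 1.00],
        ]
    )


@dataclass
class CovariateModel:
    """Generative model for subject covariates.

    Ages are truncated-normal; each control is drawn close to its generative
    case (offset well inside the matching tolerances) so that 1:1 matching
    is feasible by construction.  Postmenopausal probability rises with age
    through a logistic link centred near the typical age at menopause.
    """

    age_mean: float = 47.3
    age_sd: float = 7.3
    age_min: float = 31.0
    age_max: float = 60.0
    control_age_offset_max: int = 2
    mri_years: tuple[int, int] = (2009, 2011)
    menopause_center_age: float = 50.0
    menopause_scale: float = 2.5
    family_history_p: float = 0.56
    density_probs: tuple[float, float, float, float] = (0.03, 0.26, 0.64, 0.07)


@dataclass
class FullImageModel:
    """Per-subject phantom parameters for full-image cohort generation.

    Cases receive larger washout and plateau fractions and a wider
    peak-enhancement range than controls; per-subject heterogeneity comes
    from a Dirichlet draw of the class fractions, a jitter on the upper
    peak-enhancement bound and a jitter on the FGT size.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 8)
    voxel_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 2.0)
    baseline_signal: float = 500.0
    noise_sd: float = 10.0
    control_class_means: dict[str, float] = field(
        default_factory=lambda: {
            "persistent": 0.40,
            "plateau": 0.15,
            "washout": 0.10,
            "nonenhancing": 0.35,
        }
    )
    case_class_means: dict[str, float] = field(
        default_factory=lambda: {
            "persistent": 0.32,
            "plateau": 0.20,
            "washout": 0.17,
            "nonenhancing": 0.31,
        }
    )
    dirichlet_concentration: float = 25.0
    pe_low: float = 0.3
    control_pe_high: float = 0.9
    case_pe_high: float = 1.05
    pe_high_jitter: float = 0.25
    breast_semiaxes_frac: tuple[float, float, float] = (0.45, 0.45, 0.45)
    fgt_semiaxes_frac: tuple[float, float, float] = (0.32, 0.32, 0.32)
    fgt_scale_jitter: float = 0.10


@dataclass
class CohortSpec:
    """Specification of a synthetic matched case-control cohort.

    ``effect_sizes`` are multiplicative shifts of the case-group mean for
    each measure (measures-only mode); ``case_sigma_scale`` scales the
    case-group log-SD.  A *null* cohort — case and control measures
    identical in law — is obtained with all effect sizes and sigma scales
    equal to 1 (see :meth:`null`).
    """

    n_pairs: int = 51
    effect_sizes: dict[str, float] = field(default_factory=default_effect_sizes)
    measure_models: dict[str, MeasureModel] = field(default_factory=default_measure_models)
    case_sigma_scale: dict[str, float] = field(default_factory=default_case_sigma_scale)
    copula_corr: np.ndarray = field(default_factory=default_copula_corr)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    age_tolerance: float = 3.0
    year_tolerance: int = 1
    full_image: FullImageModel = field(default_factory=FullImageModel)
    seed: int = 0

    @classmethod
    def null(cls, **kwargs) -> "CohortSpec":
        """Cohort spec with case and control measures identical in law."""
        spec = cls(**kwargs)
        spec.effect_sizes = {k: 1.0 for k in spec.effect_sizes}
        spec.case_sigma_scale = {k: 1.0 for k in spec.case_sigma_scale}
        fi = spec.full_image
        fi.case_class_means = dict(fi.control_class_means)
        fi.case_pe_high = fi.control_pe_high
        return spec

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise InvalidSpecError("n_pairs must be >= 1")
        if set(self.effect_sizes) != set(self.measure_models):
            raise InvalidSpecError("effect_sizes keys must match measure_models keys")
        if any(v <= 0 for v in self.effect_sizes.values()):
            raise InvalidSpecError("effect sizes must be positive")
        corr = np.asarray(self.copula_corr, dtype=float)
        k = len(self.measure_models)
        if corr.shape != (k, k):
            raise InvalidSpecError("copula_corr shape must match the number of measures")
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise InvalidSpecError("copula_corr must be positive definite") from exc


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given natural-scale moments."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def _draw_covariates(
    rng: np.random.Generator, cm: CovariateModel
) -> tuple[float, int, int, int, int]:
    """Draw (age, mri_year, menopausal, family_history, density) for a case."""
    age = float(np.clip(rng.normal(cm.age_mean, cm.age_sd), cm.age_min, cm.age_max))
    age = round(age)
    year = int(rng.integers(cm.mri_years[0], cm.mri_years[1] + 1))
    p_post = 1.0 / (1.0 + math.exp(-(age - cm.menopause_center_age) / cm.menopause_scale))
    menopausal = int(rng.random() < p_post)
    famhx = int(rng.random() < cm.family_history_p)
    density = int(rng.choice(4, p=cm.density_probs)) + 1
    return age, year, menopausal, famhx, density


def _subject_records_measures_only(
    cspec: CohortSpec, rng: np.random.Generator
) -> tuple[list[SubjectRecord], list[SubjectRecord], dict]:
    names = list(cspec.measure_models)
    chol = np.linalg.cholesky(np.asarray(cspec.copula_corr, dtype=float))
    params = {"case": {}, "control": {}}
    for m in names:
        mm = cspec.measure_models[m]
        mu_c, sig_c = _lognormal_params(mm.control_mean, mm.control_sd)
        params["control"][m] = (mu_c, sig_c)
        sig_case = sig_c * cspec.case_sigma_scale[m]
        mu_case = math.log(cspec.effect_sizes[m] * mm.control_mean) - 0.5 * sig_case**2
        params["case"][m] = (mu_case, sig_case)

    cm = cspec.covariate_model
    cases, controls = [], []
    for i in range(cspec.n_pairs):
        age, year, meno, famhx, dens = _draw_covariates(rng, cm)
        for group, store in (("case", cases), ("control", controls)):
            if group == "control":
                off = int(
                    rng.integers(-cm.control_age_offset_max, cm.control_age_offset_max + 1)
                )
                a = float(np.clip(age + off, cm.age_min, cm.age_max))
                y = int(
                    np.clip(year + rng.integers(-1, 2), cm.mri_years[0], cm.mri_years[1])
                )
                p_post = 1.0 / (
                    1.0 + math.exp(-(a - cm.menopause_center_age) / cm.menopause_scale)
                )
                meno_g = int(rng.random() < p_post)
                famhx_g = int(rng.random() < cm.family_history_p)
                dens_g = int(rng.choice(4, p=cm.density_probs)) + 1
            else:
                a, y, meno_g, famhx_g, dens_g = age, year, meno, famhx, dens
            z = chol @ rng.standard_normal(len(names))
            measures = {
                m: math.exp(params[group][m][0] + params[group][m][1] * z[j])
                for j, m in enumerate(names)
            }
            store.append(
                SubjectRecord(
                    subject_id=f"{'case' if group == 'case' else 'ctrl'}-{i:03d}",
                    group=group,
                    age=a,
                    mri_year=y,
                    menopausal=meno_g,
                    family_history=famhx_g,
                    density=dens_g,
                    measures=measures,
                )
            )
    return cases, controls, {"marginals": params}


def _subject_phantom_spec(
    fim: FullImageModel, group: str, rng: np.random.Generator
) -> PhantomSpec:
    means = fim.case_class_means if group == "case" else fim.control_class_means
    alpha = fim.dirichlet_concentration * np.array(
        [means[k] for k in KINETIC_CLASSES]
    )
    fracs = rng.dirichlet(alpha)
    fracs = fracs / fracs.sum()
    class_fractions = dict(zip(KINETIC_CLASSES, fracs.tolist()))

    pe_high_base = fim.case_pe_high if group == "case" else fim.control_pe_high
    jit = fim.pe_high_jitter
    pe_high = pe_high_base * rng.uniform(1.0 - jit, 1.0 + jit)
    pe_high = max(pe_high, fim.pe_low + 0.05)
    cp = default_curve_params()
    for name in ("persistent", "plateau", "washout"):
        cp[name] = replace(cp[name], pe_range=(fim.pe_low, pe_high))

    fscale = rng.uniform(1.0 - fim.fgt_scale_jitter, 1.0 + fim.fgt_scale_jitter)
    fgt_frac = tuple(
        min(f * fscale, b)
        for f, b in zip(fim.fgt_semiaxes_frac, fim.breast_semiaxes_frac)
    )
    return PhantomSpec(
        grid_shape=fim.grid_shape,
        voxel_spacing_mm=fim.voxel_spacing_mm,
        class_fractions=class_fractions,
        curve_params=cp,
        baseline_signal=fim.baseline_signal,
        noise_sd=fim.noise_sd,
        breast_semiaxes_frac=fim.breast_semiaxes_frac,
        fgt_semiaxes_frac=fgt_frac,
        seed=int(rng.integers(2**31)),
    )


def make_cohort(
    cspec: CohortSpec,
    mode: str = "measures-only",
    return_images: bool = False,
    thresholds: KineticThresholds = DEFAULT_THRESHOLDS,
) -> MatchedCohort:
    """Generate a matched case-control cohort.

    Parameters
    ----------
    cspec:
        Cohort specification (validated here).
    mode:
        ``"measures-only"`` draws breast-wise measures from the log-normal
        marginals; ``"full-image"`` builds one phantom per subject and
        computes measures through the kinetics module.
    return_images:
        In full-image mode, keep each subject's ``(DCESeries, PhantomTruth)``
        in ``cohort.metadata["images"]``.

    Returns
    -------
    MatchedCohort
        Pairs satisfy the age and MRI-year tolerances (greedy nearest-age
        matching; a :class:`~parenkin.cohort.MatchingError` lists any case
        that cannot be matched).  ``metadata`` records the generative
        parameters and the cohort spec.
    """
    cspec.validate()
    if mode not in ("measures-only", "full-image"):
        raise ValueError(f"unknown cohort mode {mode!r}")
    rng = np.random.default_rng(cspec.seed)

    if mode == "measures-only":
        cases, controls, generative = _subject_records_measures_only(cspec, rng)
        images = None
    else:
        cm = cspec.covariate_model
        fim = cspec.full_image
        cases, controls = [], []
        images = {}
        generative = {"phantom_specs": {}}
        for i in range(cspec.n_pairs):
            age, year, meno, famhx, dens = _draw_covariates(rng, cm)
            for group, store in (("case", cases), ("control", controls)):
                if group == "control":
                    off = int(
                        rng.integers(
                            -cm.control_age_offset_max, cm.control_age_offset_max + 1
                        )
                    )
                    a = float(np.clip(age + off, cm.age_min, cm.age_max))
                    y = int(
                        np.clip(
                            year + rng.integers(-1, 2), cm.mri_years[0], cm.mri_years[1]
                        )
                    )
                else:
                    a, y = age, year
                pspec = _subject_phantom_spec(fim, group, rng)
                series, truth = make_phantom(pspec, thresholds=thresholds)
                maps = voxel_kinetics(series, truth.masks, thresholds)
                measures = aggregate_measures(
                    maps, truth.masks, series.voxel_spacing_mm, thresholds
                ).as_dict()
                sid = f"{'case' if group == 'case' else 'ctrl'}-{i:03d}"
                generative["phantom_specs"][sid] = pspec
                if return_images:
                    images[sid] = (series, truth)
                store.append(
                    SubjectRecord(
                        subject_id=sid,
                        group=group,
                        age=a,
                        mri_year=y,
                        menopausal=meno if group == "case" else int(
                            rng.random()
                            < 1.0
                            / (1.0 + math.exp(-(a - cm.menopause_center_age) / cm.menopause_scale))
                        ),
                        family_history=famhx if group == "case" else int(
                            rng.random() < cm.family_history_p
                        ),
                        density=dens if group == "case" else int(rng.choice(4, p=cm.density_probs)) + 1,
                        measures=measures,
                    )
                )

    cohort = greedy_match(
        cases,
        controls,
        age_tolerance=cspec.age_tolerance,
        year_tolerance=cspec.year_tolerance,
    )
    cohort.metadata["spec"] = cspec
    cohort.metadata["mode"] = mode
    cohort.metadata["generative"] = generative
    if return_images and images is not None:
        cohort.metadata["images"] = images
    return cohort
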