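"""Synthetic 3D tumor phantoms with controllable fractal texture.

The generator emulates the structure of a skull-stripped multimodal MRI
glioma case: a brain ellipsoid containing nested tumor sub-regions (necrotic
core, enhancing-tumor shell, edema shell), each modality rendered as
region-dependent mean intensity plus fractional-Brownian-motion texture plus
white Gaussian noise.  The tumor texture roughness is governed by a Hurst
exponent H in (0, 1) that can differ between molecular classes, so the
ground truth of every downstream roughness estimator is known.  Molecular
labels, and survival times with a log-linear hazard in a designated driver
covariate, are drawn per cohort.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import CaseRecord, Cohort, SegmentationMask, VolumeImage, write_case


class DomainError(ValueError):
    """A phantom specification violates its geometric or stochastic domain."""


# ---------------------------------------------------------------------------
# fractional Brownian fields


def generate_fbm_field(shape: tuple[int, ...], H: float, seed: int) -> np.ndarray:
    """Spectrally synthesized fractional Brownian field, zero mean, unit variance.

    White Gaussian noise is filtered in Fourier space with amplitude
    (|f|^2 + f0^2)^(-(2H + d)/4) for a d-dimensional grid, which gives the
    power-law spectrum of fBm with Hurst exponent ``H``; the low-frequency
    regularizer f0 = 1/max(shape) removes the DC singularity.  Deterministic
    given (shape, H, seed).  The increments obey the variogram scaling
    E|I(x+h) - I(x)|^2 ∝ |h|^(2H) over lags small relative to the grid.
    """
    if not 0.0 < H < 1.0:
        raise DomainError(f"Hurst exponent must lie in (0, 1), got {H}")
    shape = tuple(int(s) for s in shape)
    if any(s < 8 for s in shape):
        raise DomainError(f"all grid dimensions must be >= 8, got {shape}")
    d = len(shape)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    freqs = np.meshgrid(*[np.fft.fftfreq(s) for s in shape], indexing="ij", sparse=True)
    f2 = sum(f**2 for f in freqs)
    f0 = 1.0 / max(shape)
    amp = (f2 + f0**2) ** (-(2 * H + d) / 4.0)
    field = np.fft.ifftn(np.fft.fftn(white) * amp).real
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def _increment_var(shape: tuple[int, ...], H: float, lag: int) -> float:
    """Expected lag-k increment variance E|I(x+k) - I(x)|² of the
    unit-variance synthesized field, from its spectrum (axis-averaged)."""
    shape = tuple(int(s) for s in shape)
    freqs = np.meshgrid(*[np.fft.fftfreq(s) for s in shape], indexing="ij", sparse=True)
    f2 = sum(f**2 for f in freqs)
    f0 = 1.0 / max(shape)
    power = (f2 + f0**2) ** (-(2 * H + len(shape)) / 2.0)
    power = power / power.sum()
    out = 0.0
    for f in freqs:
        out += (2.0 * power * (1.0 - np.cos(2 * np.pi * lag * f))).sum()
    return float(out / len(shape))


def matched_texture_mix(
    shape: tuple[int, ...],
    H: float,
    match_h: float,
    filler_h: float = 0.02,
    strength: float = 1.0,
) -> tuple[float, float, float]:
    """Weights (a, b, 0) for the fine-scale-matched mixture
    a·fBm(H) + b·fBm(filler_h).

    The squared weights solve for unit total variance and the lag-1
    increment variance of a pure fBm field with Hurst ``match_h``,
    independently of H (lag-2 follows to within a few percent).  Classes
    that differ only in H then share their fine-scale second-order
    statistics — single-scale texture measures become nearly uninformative
    by construction — while the multi-scale spectral decay still carries H
    for scaling-exponent estimators (wavelet variance slopes, prism-area
    slopes, oscillation slopes at larger radii).  The rough filler
    (``filler_h`` well below ``match_h``) supplies the fine-scale energy a
    smooth class field lacks.  Returns the pure field (1, 0, 0) when the
    moment system has no admissible solution.
    """
    x1 = _increment_var(shape, H, 1)
    y1 = _increment_var(shape, filler_h, 1)
    t1 = _increment_var(shape, match_h, 1)
    t1 = x1 + strength * (t1 - x1)  # partial matching closes this share of the gap
    if abs(y1 - x1) < 1e-12:
        return 1.0, 0.0, 0.0
    u = (y1 - t1) / (y1 - x1)
    if u <= 1e-9 or u > 1.0:
        return 1.0, 0.0, 0.0
    return float(np.sqrt(u)), float(np.sqrt(1.0 - u)), 0.0


def variogram_slope(field: np.ndarray, lags: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)) -> float:
    """Independent Hurst oracle: slope of log E|ΔI|^2 vs log lag equals 2H.

    Structure function averaged isotropically over the grid axes.
    """
    gammas = []
    for lag in lags:
        diffs = []
        for ax in range(field.ndim):
            a = np.moveaxis(field, ax, 0)
            diffs.append(np.mean((a[lag:] - a[:-lag]) ** 2))
        gammas.append(np.mean(diffs))
    x = np.log(np.asarray(lags, dtype=float))
    y = np.log(np.asarray(gammas))
    return float(np.polyfit(x, y, 1)[0])


# ---------------------------------------------------------------------------
# phantom specification


def _default_modality_means() -> dict[tuple[str, str], float]:
    # Loosely mimics relative tissue contrasts of post-contrast T1, T2, FLAIR.
    return {
        ("T1", "brain"): 6.0, ("T1", "NCR"): 3.0, ("T1", "ET"): 5.0, ("T1", "ED"): 5.0,
        ("T1Gd", "brain"): 6.0, ("T1Gd", "NCR"): 2.5, ("T1Gd", "ET"): 9.0, ("T1Gd", "ED"): 5.0,
        ("T2", "brain"): 5.0, ("T2", "NCR"): 9.0, ("T2", "ET"): 7.0, ("T2", "ED"): 8.0,
        ("FLAIR", "brain"): 5.0, ("FLAIR", "NCR"): 4.0, ("FLAIR", "ET"): 7.5, ("FLAIR", "ED"): 9.0,
    }


@dataclass
class PhantomSpec:
    """Geometry, contrast and texture parameters of one tumor phantom.

    The tumor must be large relative to the texture-analysis window so that
    in-slice windows see texture rather than region boundaries; defaults give
    a 26 mm whole-tumor diameter on a 64 mm grid.  ``bias_strength`` scales a
    smooth multiplicative gain field (uncorrected MRI shading); ``noise_sd``
    is white thermal noise, both in units of the unit-variance texture.
    """

    grid_size: int = 72
    brain_semi_axes: tuple[float, float, float] = (33.0, 31.0, 29.0)
    region_radii: tuple[float, float, float] = (5.0, 9.0, 16.0)  # (r_ncr, r_et, r_ed)
    modality_means: dict = field(default_factory=_default_modality_means)
    hurst_by_class: dict = field(default_factory=lambda: {"negative": 0.5, "positive": 0.5})
    background_hurst: float = 0.5
    texture_amplitude: float = 1.0
    noise_sd: float = 0.1
    bias_strength: float = 0.0
    pv_blur: float = 1.0  # partial-volume PSF, voxels
    bias_scale_frac: float = 0.3  # bias-field correlation length / grid size
    gamma_log_range: float = 0.0  # per-case monotone intensity distortion exp(U(-g, g))
    increment_match_h: float | None = None  # fine-scale matching reference (None: off)
    filler_hurst: float = 0.02
    match_strength: float = 0.8  # fraction of the fine-scale gap removed
    seed: int = 0

    def validate(self) -> None:
        r_ncr, r_et, r_ed = self.region_radii
        if not (0 < r_ncr < r_et < r_ed < min(self.brain_semi_axes)):
            raise DomainError(
                f"region radii must satisfy 0 < r_ncr < r_et < r_ed < min(brain semi-axes), "
                f"got {self.region_radii} inside {self.brain_semi_axes}"
            )
        for key, h in self.hurst_by_class.items():
            if not 0.0 < h < 1.0:
                raise DomainError(f"Hurst exponent for class {key!r} must be in (0, 1), got {h}")
        if self.grid_size < 8:
            raise DomainError("grid_size must be >= 8")


@dataclass
class SyntheticCohortSpec:
    """Cohort-level design: class balance, effect sizes, survival model."""

    n_cases: int = 40
    prevalence: dict = field(default_factory=lambda: {"IDH": 0.5})
    effect_target: str = "IDH"
    effect_hurst: float = 0.0
    effect_volume: float = 1.0
    hurst_jitter_sd: float = 0.03
    bias_field_max: float = 1.0
    survival_beta: float = 0.0
    baseline_rate: float = 1.0 / 40.0  # events per month
    censor_rate: float = 1.0 / 80.0
    exact_counts: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 4:
            raise DomainError("n_cases must be >= 4")
        for tgt, p in self.prevalence.items():
            if not 0.0 < p < 1.0:
                raise DomainError(f"prevalence for {tgt!r} must be in (0, 1), got {p}")


# ---------------------------------------------------------------------------
# geometry and rendering


def _ellipsoid(shape: tuple[int, int, int], center: np.ndarray, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, np.broadcast_to(semi_axes, (3,))))
    return r2 <= 1.0


def generate_phantom_case(
    spec: PhantomSpec,
    class_assignments: dict[str, str] | None = None,
    seed: int | None = None,
    case_id: str = "phantom",
    effect_target: str = "IDH",
) -> CaseRecord:
    """Render one phantom case as a :class:`CaseRecord`.

    The tumor (nested spheres NCR ⊂ ET ⊂ ED) sits at the brain center; each
    modality is region mean + texture_amplitude * fBm + N(0, noise_sd).  The
    tumor-region texture uses the Hurst exponent of the case's class on
    ``effect_target``; background brain texture uses ``background_hurst``.
    """
    spec.validate()
    if seed is None:
        seed = spec.seed
    class_assignments = class_assignments or {}
    n = spec.grid_size
    shape = (n, n, n)
    center = np.array([n / 2.0] * 3) - 0.5
    brain = _ellipsoid(shape, center, spec.brain_semi_axes)
    r_ncr, r_et, r_ed = spec.region_radii
    ncr = _ellipsoid(shape, center, r_ncr)
    et = _ellipsoid(shape, center, r_et) & ~ncr
    ed = _ellipsoid(shape, center, r_ed) & ~_ellipsoid(shape, center, r_et)
    labels = np.zeros(shape, dtype=np.int64)
    labels[ncr & brain] = 1
    labels[ed & brain] = 2
    labels[et & brain] = 4
    tumor = labels > 0

    cls = class_assignments.get(effect_target, "negative")
    h_tumor = spec.hurst_by_class.get(cls, 0.5)

    ss = np.random.SeedSequence([seed, 2**20])
    child = ss.generate_state(2 * len(("T1", "T1Gd", "T2", "FLAIR")) + 2, dtype=np.uint32)

    # One smooth multiplicative gain field per case, shared across modalities
    # (scanner shading is a property of the acquisition, not the sequence).
    bias_rng = np.random.default_rng(int(child[-2]))
    if spec.bias_strength > 0:
        rough = gaussian_filter(bias_rng.standard_normal(shape), sigma=n * spec.bias_scale_frac)
        rough /= rough.std()
        gain = np.clip(1.0 + spec.bias_strength * rough, 0.2, None)
    else:
        gain = 1.0

    images = {}
    if spec.increment_match_h is not None:
        a_mix, b_mix, c_mix = matched_texture_mix(
            shape, h_tumor, spec.increment_match_h, spec.filler_hurst, spec.match_strength
        )
    else:
        a_mix, b_mix, c_mix = 1.0, 0.0, 0.0
    white_rng = np.random.default_rng(int(child[-2]) + 7)
    for i, modality in enumerate(("T1", "T1Gd", "T2", "FLAIR")):
        bg_tex = generate_fbm_field(shape, spec.background_hurst, int(child[2 * i]))
        tumor_tex = generate_fbm_field(shape, h_tumor, int(child[2 * i + 1]))
        if b_mix > 0 or c_mix > 0:
            filler = generate_fbm_field(shape, spec.filler_hurst, int(child[2 * i + 1]) + 2**16)
            tumor_tex = (
                a_mix * tumor_tex + b_mix * filler + c_mix * white_rng.standard_normal(shape)
            )
        vol = np.zeros(shape)
        vol[brain] = spec.modality_means[(modality, "brain")]
        for reg, msk in (("NCR", labels == 1), ("ED", labels == 2), ("ET", labels == 4)):
            vol[msk] = spec.modality_means[(modality, reg)]
        if spec.pv_blur > 0:
            # Partial-volume effect: tissue boundaries are blurred by the
            # scanner point-spread function, not step edges.
            vol = gaussian_filter(vol, spec.pv_blur)
        tex = np.where(tumor, tumor_tex, bg_tex)
        noise_rng = np.random.default_rng(int(child[-1]) + i)
        vol = (vol + spec.texture_amplitude * tex) * gain + noise_rng.normal(0.0, spec.noise_sd, shape)
        if spec.gamma_log_range > 0:
            # Scanner-nonlinearity surrogate: a smooth monotone remap of the
            # brain intensity range.  Locally this is a gain, which log-log
            # slope estimators cancel; value-distribution statistics do not.
            gamma = float(np.exp(bias_rng.uniform(-spec.gamma_log_range, spec.gamma_log_range)))
            lo, hi = vol[brain].min(), vol[brain].max()
            if hi > lo:
                vol[brain] = lo + (hi - lo) * ((vol[brain] - lo) / (hi - lo)) ** gamma
        vol[~brain] = 0.0
        images[modality] = VolumeImage(vol, (1.0, 1.0, 1.0), modality)
    return CaseRecord(case_id, images, SegmentationMask(labels), brain, dict(class_assignments))


# ---------------------------------------------------------------------------
# survival and cohorts


def generate_survival(
    z: np.ndarray, beta: float, baseline_rate: float, censor_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with log-linear hazard rate * exp(beta * z),
    independently exponentially censored; returns (time_months, event)."""
    z = np.asarray(z, dtype=float)
    rates = baseline_rate * np.exp(beta * z)
    death = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor = rng.exponential(1.0 / censor_rate, size=z.shape)
    else:
        censor = np.full_like(death, np.inf)
    event = (death <= censor).astype(int)
    return np.minimum(death, censor), event


def _draw_labels(n: int, p: float, exact: bool, rng: np.random.Generator) -> np.ndarray:
    if exact:
        k = int(round(p * n))
        lab = np.array(["positive"] * k + ["negative"] * (n - k))
        rng.shuffle(lab)
        return lab
    return np.where(rng.random(n) < p, "positive", "negative")


def generate_cohort(spec: SyntheticCohortSpec, phantom: PhantomSpec) -> Cohort:
    """Generate a full synthetic cohort of phantom cases with labels and survival.

    The class on ``spec.effect_target`` shifts the tumor Hurst exponent by
    ±effect_hurst/2 around the phantom's base H and multiplies the tumor
    radii by effect_volume for positives.  Survival is exponential with
    log-hazard beta per SD of the driver covariate z (the case's tumor Hurst
    plus small jitter, standardized); z is recorded in the label table.
    """
    spec.validate()
    phantom.validate()
    ss = np.random.SeedSequence([spec.seed, 2**19])
    label_rng = np.random.default_rng(ss.generate_state(1, dtype=np.uint32)[0])
    surv_rng = np.random.default_rng(ss.generate_state(2, dtype=np.uint32)[1])
    case_seeds = np.random.default_rng(ss.generate_state(3, dtype=np.uint32)[2]).integers(
        0, 2**31 - 1, size=spec.n_cases
    )

    labels = {t: _draw_labels(spec.n_cases, p, spec.exact_counts, label_rng) for t, p in spec.prevalence.items()}
    base_h = phantom.hurst_by_class.get("negative", 0.5)
    h_by_class = {
        "negative": np.clip(base_h - spec.effect_hurst / 2.0, 0.05, 0.95),
        "positive": np.clip(base_h + spec.effect_hurst / 2.0, 0.05, 0.95),
    }

    nuisance_rng = np.random.default_rng(ss.generate_state(4, dtype=np.uint32)[3])
    cases = []
    zs = []
    for i in range(spec.n_cases):
        assign = {t: str(labels[t][i]) for t in labels}
        cls = assign.get(spec.effect_target, "negative")
        radii = tuple(
            r * (spec.effect_volume if cls == "positive" else 1.0) for r in phantom.region_radii
        )
        h_case = float(
            np.clip(h_by_class[cls] + nuisance_rng.normal(0.0, spec.hurst_jitter_sd), 0.05, 0.95)
        )
        bias_case = float(nuisance_rng.uniform(0.0, spec.bias_field_max))
        case_spec = replace(
            phantom,
            region_radii=radii,
            hurst_by_class={cls: h_case},
            bias_strength=bias_case,
            seed=int(case_seeds[i]),
        )
        case = generate_phantom_case(
            case_spec, assign, case_id=f"SYN-{i + 1:03d}", effect_target=spec.effect_target
        )
        zs.append(h_case)
        cases.append(case)

    z = np.asarray(zs) + surv_rng.normal(0.0, 0.02, size=spec.n_cases)
    z = (z - z.mean()) / z.std() if z.std() > 0 else z - z.mean()
    times, events = generate_survival(z, spec.survival_beta, spec.baseline_rate, spec.censor_rate, surv_rng)

    table = pd.DataFrame({"case_id": [c.case_id for c in cases]})
    for t in labels:
        table[t] = labels[t]
    table["survival_months"] = times
    table["event"] = events
    table["driver_z"] = z
    for case, t, e in zip(cases, times, events):
        case.survival_months = float(t)
        case.event = int(e)
    return Cohort(cases, table)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> str:
    """Write a cohort in the NIfTI + CSV layout that :mod:`gliomics.io` reads."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for case in cohort.cases:
        write_case(case, os.path.join(out_dir, case.case_id))
    csv_path = os.path.join(out_dir, "cohort.csv")
    cohort.label_table.to_csv(csv_path, index=False)
    return csv_path
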