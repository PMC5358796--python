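"""Synthetic osteochondral sections and study tables.

Generates 2D phantoms of decalcified knee sections — uncalcified cartilage,
calcified cartilage, subchondral bone plate and trabecular bone with marrow —
whose layer thicknesses, interface roughness and plate fenestration follow a
four-stage ordinal grade of subchondral bone change (0 = thin porous plate
with open fenestrae, 3 = massive sclerosis under worn cartilage). The same
module simulates the tabular side of such a study: patients contributing
adjacent samples from three harvest-site categories, OARSI cartilage grades,
layer thicknesses, interface descriptors, and replicate ordinal ratings.

The per-grade thickness and OARSI parameters in :func:`default_grade_profiles`
are the published group means and standard deviations for human tibial
plateau samples; everything else (roughness amplitudes, fenestra rates,
intensity levels) is a documented modelling choice, see ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import (
    BACKGROUND,
    CALCIFIED_CARTILAGE,
    MARROW,
    SUBCHONDRAL_PLATE,
    TRABECULAR_BONE,
    UNCALCIFIED_CARTILAGE,
    HistoImage,
    LayerMap,
)

__all__ = [
    "GradeProfile",
    "SectionFitError",
    "default_grade_profiles",
    "generate_section",
    "generate_study_table",
    "sinusoid_displacement",
]


class SectionFitError(ValueError):
    """Raised when a requested layer does not fit in the raster."""

    def __init__(self, layer: str, detail: str):
        self.layer = layer
        super().__init__(f"layer '{layer}' does not fit in the raster: {detail}")


@dataclass(frozen=True)
class GradeProfile:
    """Simulation parameters for one subchondral bone grade.

    Thickness parameters are in micrometres. ``roughness_amplitude`` is the
    root-sum-square amplitude of the sinusoidal displacement applied to layer
    boundaries (micrometres); ``roughness_wavelengths`` are the component
    wavelengths (micrometres). ``fenestra_rate`` is the expected number of
    open plate gaps per millimetre of section width; open fenestrae occur in
    grades 0-1 only. OARSI parameters are on the 0-6 cartilage grade scale.
    """

    grade: int
    uncalc_cart_mean: float
    uncalc_cart_sd: float
    calc_cart_mean: float
    calc_cart_sd: float
    plate_mean: float
    plate_sd: float
    roughness_amplitude: float
    roughness_wavelengths: tuple[float, ...]
    fenestra_rate: float
    oarsi_mean: float
    oarsi_sd: float

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3):
            raise ValueError("grade must be one of 0, 1, 2, 3")
        for name in (
            "uncalc_cart_mean",
            "calc_cart_mean",
            "plate_mean",
            "uncalc_cart_sd",
            "calc_cart_sd",
            "plate_sd",
            "roughness_amplitude",
            "oarsi_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.grade >= 2 and self.fenestra_rate != 0:
            raise ValueError(
                "open fenestrae connect marrow to cartilage only in grades 0-1; "
                "fenestra_rate must be 0 for grades 2 and 3"
            )
        if self.fenestra_rate < 0:
            raise ValueError("fenestra_rate must be non-negative")
        if any(w <= 0 for w in self.roughness_wavelengths):
            raise ValueError("roughness wavelengths must be positive")


# Geometrically spaced roughness wavelengths (um). The long component gives
# the boundary a slow undulation; the shortest (a few pixels at the working
# resolution) makes high-amplitude interfaces jagged from pixel to pixel,
# the way fibrillated plates look at x5.
_DEFAULT_WAVELENGTHS = (400.0, 100.0, 25.0)

# Interface roughness amplitude per grade (um, root-sum-square). Strictly
# increasing over grades 0-2 (plate fibrillation builds up with sclerosis);
# grade 3 plates are smooth and worn again, so the amplitude drops.
_ROUGHNESS_AMPLITUDE = (6.0, 25.0, 60.0, 5.0)

# Expected open fenestrae per mm of width; present only in grades 0-1.
_FENESTRA_RATE = (2.0, 0.8, 0.0, 0.0)

# Per-grade OARSI spread (SD); group means are published, spreads are not.
_OARSI_SD = (0.9, 0.8, 0.8, 0.7)

# Bone area fraction of the trabecular compartment, increasing with sclerosis.
_TRABECULAR_BONE_FRACTION = (0.25, 0.35, 0.45, 0.60)


def default_grade_profiles() -> list[GradeProfile]:
    """The four subchondral bone grades with published thickness statistics.

    Group means +/- SD (micrometres): uncalcified cartilage 2374+/-506,
    1753+/-615, 1826+/-1268, 82+/-142; calcified cartilage 84+/-69,
    104+/-62, 128+/-50, 36+/-46; subchondral plate 58+/-28, 176+/-87,
    473+/-229, 1245+/-448 for grades 0-3. Mean OARSI per grade: 1.46, 3.45,
    3.99, 5.19.
    """
    uncalc = ((2374.0, 506.0), (1753.0, 615.0), (1826.0, 1268.0), (82.0, 142.0))
    calc = ((84.0, 69.0), (104.0, 62.0), (128.0, 50.0), (36.0, 46.0))
    plate = ((58.0, 28.0), (176.0, 87.0), (473.0, 229.0), (1245.0, 448.0))
    oarsi = (1.46, 3.45, 3.99, 5.19)
    return [
        GradeProfile(
            grade=g,
            uncalc_cart_mean=uncalc[g][0],
            uncalc_cart_sd=uncalc[g][1],
            calc_cart_mean=calc[g][0],
            calc_cart_sd=calc[g][1],
            plate_mean=plate[g][0],
            plate_sd=plate[g][1],
            roughness_amplitude=_ROUGHNESS_AMPLITUDE[g],
            roughness_wavelengths=_DEFAULT_WAVELENGTHS,
            fenestra_rate=_FENESTRA_RATE[g],
            oarsi_mean=oarsi[g],
            oarsi_sd=_OARSI_SD[g],
        )
        for g in range(4)
    ]


def sinusoid_displacement(
    width_px: int,
    pixel_size: float,
    amplitude: float,
    wavelengths: tuple[float, ...],
    phases: np.ndarray,
) -> np.ndarray:
    """Boundary displacement profile in micrometres, one value per column.

    A random-phase sum of sinusoids with component amplitudes proportional
    to the square root of their wavelength — a red spectrum in which long
    waves dominate the displacement while short waves contribute the
    pixel-scale jaggedness whose slope grows with the overall amplitude.
    Amplitudes are normalized so their root-sum-square equals
    ``amplitude``, which makes the column-wise standard deviation of the
    profile ``amplitude / sqrt(2)``.
    """
    x = np.arange(width_px) * pixel_size
    if len(wavelengths) == 0 or amplitude == 0:
        return np.zeros(width_px)
    w = np.sqrt(np.asarray(wavelengths, dtype=float))
    amps = amplitude * w / np.sqrt((w**2).sum())
    d = np.zeros(width_px)
    for lam, a, phi in zip(wavelengths, amps, phases):
        d += a * np.sin(2.0 * np.pi * x / lam + phi)
    return d


# Nominal stain-channel intensity per tissue label (8-bit scale); bone is
# brighter than cartilage in the analyzed channel by default.
_INTENSITY = {
    BACKGROUND: 15.0,
    UNCALCIFIED_CARTILAGE: 90.0,
    CALCIFIED_CARTILAGE: 130.0,
    SUBCHONDRAL_PLATE: 210.0,
    TRABECULAR_BONE: 210.0,
    MARROW: 55.0,
}

# Width range of a single open fenestra (um).
_FENESTRA_WIDTH_UM = (20.0, 60.0)


def generate_section(
    profile: GradeProfile,
    width_px: int = 512,
    height_px: int = 512,
    pixel_size: float = 8.0,
    seed: int = 0,
    noise_sd: float = 6.0,
    blur_sigma_px: float = 1.0,
    invert: bool = False,
    bci_row_frac: float = 0.5,
) -> tuple[HistoImage, LayerMap]:
    """Render one synthetic osteochondral section for a grade profile.

    The bone-cartilage interface (BCI, calcified cartilage / plate boundary)
    is anchored at ``bci_row_frac`` of the raster height. Layer boundaries
    are horizontal baselines displaced by independent random-phase sinusoid
    sums (see :func:`sinusoid_displacement`); one thickness per layer is
    drawn for the whole section, so column-to-column variation comes from
    the roughness term alone. Cartilage thicker than the space above the
    interface is clipped by the top of the raster, mimicking a microscope
    field of view; the calcified cartilage and plate themselves must fit or
    a :class:`SectionFitError` names the offending layer.

    Open fenestrae (grades 0-1) are inserted as vertical gaps at a Poisson
    rate of ``profile.fenestra_rate`` per millimetre of width, replacing
    calcified cartilage and plate with marrow so the articular cartilage
    contacts the marrow space directly.

    Intensities are per-label constants blurred by a Gaussian point-spread
    function of ``blur_sigma_px`` pixels (the microscope optics; without it
    the flat tissue plateaus would be exact intensity ties) plus additive
    Gaussian noise of standard deviation ``noise_sd`` (8-bit scale);
    ``invert`` flips the polarity for stains where bone is the darker
    phase. Fully deterministic for a fixed ``seed``.
    """
    if width_px < 64 or height_px < 64:
        raise ValueError("raster must be at least 64x64 pixels")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng(seed)

    t_uncalc = max(rng.normal(profile.uncalc_cart_mean, profile.uncalc_cart_sd), 0.0)
    t_calc = max(rng.normal(profile.calc_cart_mean, profile.calc_cart_sd), 0.0)
    t_plate = max(rng.normal(profile.plate_mean, profile.plate_sd), 0.0)

    n_waves = len(profile.roughness_wavelengths)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(4, max(n_waves, 1)))

    def disp(i: int) -> np.ndarray:
        return (
            sinusoid_displacement(
                width_px,
                pixel_size,
                profile.roughness_amplitude,
                profile.roughness_wavelengths,
                phases[i],
            )
            / pixel_size
        )

    bci_base = bci_row_frac * height_px
    bci = bci_base + disp(0)
    calc_top = np.minimum(bci - t_calc / pixel_size + disp(1), bci)
    surface = np.clip(np.minimum(calc_top - t_uncalc / pixel_size + disp(2), calc_top), 0.0, None)
    plate_bot = np.maximum(bci + t_plate / pixel_size + disp(3), bci)

    if calc_top.min() < 0:
        raise SectionFitError(
            "calcified_cartilage",
            f"needs {t_calc / pixel_size:.0f} px above row {bci_base:.0f}",
        )
    if plate_bot.max() > height_px:
        raise SectionFitError(
            "subchondral_plate",
            f"extends to row {plate_bot.max():.0f} of {height_px}",
        )

    rows = np.arange(height_px, dtype=float)[:, None]
    labels = np.full((height_px, width_px), BACKGROUND, dtype=np.uint8)
    labels[(rows >= surface) & (rows < calc_top)] = UNCALCIFIED_CARTILAGE
    labels[(rows >= calc_top) & (rows < bci)] = CALCIFIED_CARTILAGE
    labels[(rows >= bci) & (rows < plate_bot)] = SUBCHONDRAL_PLATE

    # Trabecular compartment: thresholded smooth noise, bone fraction by grade.
    below = rows >= plate_bot
    smooth = gaussian_filter(
        rng.standard_normal((height_px, width_px)), sigma=50.0 / pixel_size
    )
    frac = _TRABECULAR_BONE_FRACTION[profile.grade]
    cut = np.quantile(smooth, 1.0 - frac)
    labels[below & (smooth > cut)] = TRABECULAR_BONE
    labels[below & (smooth <= cut)] = MARROW

    # Open fenestrae: plate gaps at a Poisson rate per mm of section width.
    width_mm = width_px * pixel_size / 1000.0
    n_fen = rng.poisson(profile.fenestra_rate * width_mm)
    for _ in range(n_fen):
        center = rng.uniform(0, width_px)
        half_px = rng.uniform(*_FENESTRA_WIDTH_UM) / (2.0 * pixel_size)
        lo = max(int(np.floor(center - half_px)), 0)
        hi = min(int(np.ceil(center + half_px)), width_px)
        if hi <= lo:
            continue
        gap = labels[:, lo:hi]
        gap[(gap == CALCIFIED_CARTILAGE) | (gap == SUBCHONDRAL_PLATE)] = MARROW

    lut = np.zeros(max(_INTENSITY) + 1)
    for lab, val in _INTENSITY.items():
        lut[lab] = val
    img = lut[labels]
    if blur_sigma_px > 0:
        img = gaussian_filter(img, sigma=blur_sigma_px)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    if invert:
        img = 255.0 - img

    return (
        HistoImage(img, pixel_size=pixel_size, channel="red"),
        LayerMap(labels, pixel_size=pixel_size),
    )


# Probability of each bone grade (0-3) by harvest-site category. Site 1
# (visually most intact cartilage) skews low, site 3 (exposed bone) high;
# the weights reproduce site-level mean OARSI of roughly 2.1 / 4.4 / 5.3.
SITE_GRADE_WEIGHTS: dict[int, tuple[float, float, float, float]] = {
    1: (0.70, 0.20, 0.05, 0.05),
    2: (0.00, 0.15, 0.45, 0.40),
    3: (0.00, 0.00, 0.05, 0.95),
}

# Linear coupling of interface descriptors to OARSI grade, plus residual
# noise. Slopes and noise SDs are chosen so that, over the analyzed range
# (OARSI < 5), entropy regresses on OARSI with R^2 near 0.6 and homogeneity
# with R^2 near 0.6 with the opposite sign -- the correlation structure the
# statistics layer is meant to detect. See docs/methods.md.
_ENTROPY_INTERCEPT = 1.4
_ENTROPY_SLOPE = 0.16  # bits per OARSI grade
_ENTROPY_NOISE_SD = 0.18
_HOMOGENEITY_INTERCEPT = 0.86
_HOMOGENEITY_SLOPE = -0.032  # per OARSI grade
_HOMOGENEITY_NOISE_SD = 0.0385

#: OARSI grade at or above which the interface analysis is not attempted
#: (too little remaining cartilage to segment a BCI).
OARSI_LBP_CUTOFF = 5.0


def generate_study_table(
    n_patients: int = 20,
    samples_per_patient: int = 3,
    n_raters: int = 3,
    rater_sd: float = 0.28,
    seed: int = 0,
    profiles: list[GradeProfile] | None = None,
    site_grade_weights: dict[int, tuple[float, ...]] | None = None,
) -> pd.DataFrame:
    """Simulate the per-sample study table.

    Each patient contributes ``samples_per_patient`` samples cycling through
    the three harvest-site categories. A bone grade is drawn from the site's
    grade mix, then OARSI, layer thicknesses and interface descriptors are
    drawn from that grade's profile (thicknesses truncated at zero). Entropy
    and homogeneity are present only for samples with OARSI below
    :data:`OARSI_LBP_CUTOFF`. Replicate rater scores are the true grade plus
    rounded Gaussian noise of SD ``rater_sd`` clipped to 0-3; ``rater_sd=0``
    makes all raters agree exactly. Deterministic for a fixed ``seed``.
    """
    if n_patients < 1 or samples_per_patient < 1:
        raise ValueError("n_patients and samples_per_patient must be >= 1")
    if rater_sd < 0:
        raise ValueError("rater_sd must be non-negative")
    profiles = profiles if profiles is not None else default_grade_profiles()
    weights = site_grade_weights if site_grade_weights is not None else SITE_GRADE_WEIGHTS
    rng = np.random.default_rng(seed)

    rows = []
    for p in range(1, n_patients + 1):
        for j in range(samples_per_patient):
            site = (j % 3) + 1
            w = np.asarray(weights[site], dtype=float)
            grade = int(rng.choice(4, p=w / w.sum()))
            prof = profiles[grade]
            oarsi = float(
                np.round(np.clip(rng.normal(prof.oarsi_mean, prof.oarsi_sd), 0.0, 6.0), 1)
            )
            t_u = max(rng.normal(prof.uncalc_cart_mean, prof.uncalc_cart_sd), 0.0)
            t_c = max(rng.normal(prof.calc_cart_mean, prof.calc_cart_sd), 0.0)
            t_p = max(rng.normal(prof.plate_mean, prof.plate_sd), 0.0)
            if oarsi < OARSI_LBP_CUTOFF:
                entropy = float(
                    np.clip(
                        _ENTROPY_INTERCEPT
                        + _ENTROPY_SLOPE * oarsi
                        + rng.normal(0.0, _ENTROPY_NOISE_SD),
                        0.0,
                        3.0,
                    )
                )
                homogeneity = float(
                    np.clip(
                        _HOMOGENEITY_INTERCEPT
                        + _HOMOGENEITY_SLOPE * oarsi
                        + rng.normal(0.0, _HOMOGENEITY_NOISE_SD),
                        1e-3,
                        1.0,
                    )
                )
            else:
                entropy = np.nan
                homogeneity = np.nan
            raters = np.clip(
                grade + np.rint(rng.normal(0.0, rater_sd, size=n_raters)), 0, 3
            ).astype(int)
            row = {
                "sample_id": f"P{p:02d}S{j + 1}",
                "patient_id": p,
                "site_category": site,
                "oarsi": oarsi,
                "bone_grade": grade,
                "thickness_uncalc_um": t_u,
                "thickness_calc_um": t_c,
                "thickness_plate_um": t_p,
                "entropy_bits": entropy,
                "homogeneity": homogeneity,
            }
            for k in range(n_raters):
                row[f"rater_{k + 1}"] = int(raters[k])
            rows.append(row)
    return pd.DataFrame(rows)
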