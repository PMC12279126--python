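"""Synthetic periapical phantoms and survival cohorts.

Periapical radiograph phantoms: a round/elliptical radiolucent lesion on a
trabecular-textured bone background.  The radial intensity profile rises from
the dark lesion interior to the brighter surrounding bone as a logistic
sigmoid; the transition width is defined as the 10%->90% rise distance, which
makes the paper-style "grayscale gradient transition zone" a measurable
quantity.  An optional corticated rim adds a radiopaque overshoot just
outside the edge.  Because plain radiographs are 2-D projections, the
trabecular texture of the buccal/lingual plates is superimposed over the
lesion as well as the background, so the texture field is added everywhere.

Survival cohorts follow a Weibull proportional-hazards model whose linear
predictor combines six clinical covariates (gender, age, diabetes, lesion
diameter, tooth position, tooth location) with the latent boundary sharpness
1/transition_width.  Healing is only observed at 3-month radiograph visits:
latent times are rounded up to the next visit, with administrative censoring
at the end of follow-up and optional uniform dropout.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .image import Radiograph, write_radiograph

_LN81 = np.log(81.0)  # logistic 10->90 rise distance in units of its scale


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and texture parameters of one phantom.

    Distances are mm, intensities are gray levels on the 0-255 scale.
    ``transition_width`` is the 10%->90% radial rise distance; it must fit
    centered inside a 1 mm fragment-analysis square.  ``lesion_diameter``
    mirrors the 5-15 mm inclusion criterion for apical lesions.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_spacing: float = 0.1
    lesion_center: tuple[float, float] | None = None  # (row, col) px
    lesion_diameter: float = 10.0
    eccentricity: float = 0.0
    orientation: float = 0.0  # radians, major-axis direction
    transition_width: float = 0.4
    cortication_amplitude: float = 0.0
    interior_level: float = 60.0
    exterior_level: float = 160.0
    trabecular_sigma: float = 0.3  # mm, blob scale of the texture field
    trabecular_amplitude: float = 6.0  # gray-level SD of the texture field
    trabecular_anisotropy: float = 1.0  # row-axis elongation factor
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (5.0 <= self.lesion_diameter <= 15.0):
            raise ValueError("lesion_diameter must be within 5-15 mm")
        if not (0 < self.transition_width < 1.0):
            raise ValueError("transition_width must be in (0, 1) mm")
        if not (0 <= self.eccentricity < 1):
            raise ValueError("eccentricity must be in [0, 1)")
        if self.interior_level >= self.exterior_level:
            raise ValueError("interior_level must be < exterior_level")
        if self.cortication_amplitude < 0:
            raise ValueError("cortication_amplitude must be >= 0")


def generate_phantom(params: PhantomParams) -> tuple[Radiograph, np.ndarray]:
    """Render a phantom radiograph and its ground-truth lesion contour.

    Returns ``(radiograph, contour)`` where ``contour`` is the closed 50%%
    intensity-crossing polygon as an (N, 2) array of (row, col) pixel
    coordinates (counter-clockwise in (x=col, y=row) axes).

    Raises ``ValueError`` if the lesion (including its transition zone) does
    not fit inside the image.
    """
    p = params
    h, w = p.image_size
    sp = p.pixel_spacing
    center = p.lesion_center if p.lesion_center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    a = p.lesion_diameter / 2.0  # semi-major axis, mm
    b = a * np.sqrt(1.0 - p.eccentricity**2)

    margin_mm = a + p.transition_width + 0.5
    if (
        center[0] * sp < margin_mm
        or center[1] * sp < margin_mm
        or (h - 1 - center[0]) * sp < margin_mm
        or (w - 1 - center[1]) * sp < margin_mm
    ):
        raise ValueError(
            f"lesion of diameter {p.lesion_diameter} mm (+ transition) does not "
            f"fit inside a {h}x{w} image at {sp} mm/px"
        )

    rows = (np.arange(h) - center[0])[:, None] * sp
    cols = (np.arange(w) - center[1])[None, :] * sp
    ct, st = np.cos(p.orientation), np.sin(p.orientation)
    # coordinates in the ellipse frame (x along the major axis)
    x = cols * ct + rows * st
    y = -cols * st + rows * ct
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2)
    # signed distance to the ellipse boundary; exact on the axes, first-order
    # elsewhere: d = (rho - 1) / |grad rho|
    grad = np.sqrt((x / a**2) ** 2 + (y / b**2) ** 2)
    grad = np.where(grad > 1e-12, grad, 1e-12)
    dist = (rho - 1.0) * rho / grad

    tau = p.transition_width / _LN81
    img = p.interior_level + (p.exterior_level - p.interior_level) * expit(
        dist / tau
    )
    if p.cortication_amplitude > 0:
        rim_center = p.transition_width
        rim_sigma = max(p.transition_width / 2.0, 0.05)
        img += p.cortication_amplitude * np.exp(
            -((dist - rim_center) ** 2) / (2.0 * rim_sigma**2)
        )

    rng = np.random.default_rng(p.seed)
    if p.trabecular_amplitude > 0:
        field_ = rng.standard_normal((h, w))
        sig_px = p.trabecular_sigma / sp
        field_ = gaussian_filter(
            field_, sigma=(sig_px * p.trabecular_anisotropy, sig_px)
        )
        field_ /= max(field_.std(), 1e-12)
        img = img + p.trabecular_amplitude * field_
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 255.0)

    phi = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    ex = a * np.cos(phi)
    ey = b * np.sin(phi)
    crow = center[0] + (ex * st + ey * ct) / sp
    ccol = center[1] + (ex * ct - ey * st) / sp
    contour = np.column_stack([crow, ccol])

    return Radiograph(img, sp, id=f"phantom-{p.seed}"), contour


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

CLINICAL_TERMS = (
    "gender",        # 1 = female
    "age",           # years, centered at 52 in the linear predictor
    "diabetes",      # 1 = diabetic
    "lesion_mm",     # greatest lesion diameter, centered at 10 mm
    "position",      # 1 = mandible
    "loc_premolar",  # tooth-location dummies vs anterior teeth
    "loc_molar",
)


@dataclass(frozen=True)
class CohortParams:
    """Design of a synthetic cohort.

    ``beta_clinical`` holds log-hazard coefficients for the seven encoded
    clinical terms (``CLINICAL_TERMS``: gender, age, diabetes, lesion
    diameter, tooth position, and two tooth-location dummies); the hazard is
    for the *healing* event, so positive coefficients mean faster healing.
    ``beta_boundary`` is the coefficient of the standardized latent boundary
    sharpness 1/transition_width; the default is negative (blurred,
    ill-defined borders heal faster, consistent with the radiological
    reading of vague borders as acute lesions).
    """

    n_patients: int = 254
    beta_clinical: tuple[float, ...] = (0.10, -0.008, -0.40, -0.06, 0.15, -0.10, -0.25)
    beta_boundary: float = -1.2
    weibull_shape: float = 1.4
    weibull_scale: float = 23.0  # months
    followup_grid: float = 3.0  # months between radiographs
    max_followup: float = 36.0  # months, administrative censoring
    dropout_prob: float = 0.25
    split_ratio: float = 0.6  # development fraction (6:4)
    # covariate frequencies (female, diabetes, mandible; anterior/premolar/molar)
    p_female: float = 97 / 254
    p_diabetes: float = 82 / 254
    p_mandible: float = 167 / 254
    p_location: tuple[float, float, float] = (76 / 254, 69 / 254, 109 / 254)
    age_mean: float = 52.0
    age_sd: float = 19.0
    lesion_mean: float = 10.0
    lesion_sd: float = 3.5
    transition_width_range: tuple[float, float] = (0.2, 0.8)
    eccentricity_range: tuple[float, float] = (0.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta_clinical) != len(CLINICAL_TERMS):
            raise ValueError(
                f"beta_clinical must have {len(CLINICAL_TERMS)} entries "
                f"(order: {CLINICAL_TERMS})"
            )
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.followup_grid <= 0:
            raise ValueError("followup_grid must be positive")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio fraction must be in (0, 1)")


@dataclass
class SyntheticCohort:
    """Images, ground truth and the clinical/outcome table of one cohort."""

    images: list[Radiograph]
    contours: list[np.ndarray]
    truth: pd.DataFrame  # per-patient transition_width, sharpness, lp, latent T
    table: pd.DataFrame  # covariates + (time_months, event, cohort)


def _design_matrix(table: pd.DataFrame, cp: CohortParams) -> np.ndarray:
    z = np.column_stack(
        [
            table["gender"].to_numpy(float),
            table["age"].to_numpy(float) - cp.age_mean,
            table["diabetes"].to_numpy(float),
            table["lesion_mm"].to_numpy(float) - cp.lesion_mean,
            table["position"].to_numpy(float),
            table["loc_premolar"].to_numpy(float),
            table["loc_molar"].to_numpy(float),
        ]
    )
    return z


def generate_cohort(
    cp: CohortParams,
    phantom_defaults: PhantomParams | None = None,
    with_images: bool = True,
) -> SyntheticCohort:
    """Simulate a full cohort: phantom images, truth, and the outcome table.

    Each patient's phantom is rendered with their own lesion diameter and
    transition width, so the prognostic boundary signal lives in the images.
    Set ``with_images=False`` to generate the table/truth only (fast path for
    purely statistical tests).
    """
    rng = np.random.default_rng(cp.seed)
    n = cp.n_patients
    base = phantom_defaults if phantom_defaults is not None else PhantomParams()

    gender = (rng.random(n) < cp.p_female).astype(int)
    diabetes = (rng.random(n) < cp.p_diabetes).astype(int)
    position = (rng.random(n) < cp.p_mandible).astype(int)
    location = rng.choice(3, size=n, p=np.asarray(cp.p_location) / sum(cp.p_location))
    age = np.clip(rng.normal(cp.age_mean, cp.age_sd, n), 18.0, 90.0)
    lesion = np.clip(rng.normal(cp.lesion_mean, cp.lesion_sd, n), 5.0, 15.0)
    width = rng.uniform(*cp.transition_width_range, size=n)
    ecc = rng.uniform(*cp.eccentricity_range, size=n)
    orient = rng.uniform(0.0, np.pi, size=n)

    sharpness = 1.0 / width
    sharp_std = (sharpness - sharpness.mean()) / sharpness.std()

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "gender": gender,
            "age": np.round(age, 1),
            "diabetes": diabetes,
            "lesion_mm": np.round(lesion, 2),
            "position": position,
            "loc_premolar": (location == 1).astype(int),
            "loc_molar": (location == 2).astype(int),
        }
    )

    z = _design_matrix(table, cp)
    lp = z @ np.asarray(cp.beta_clinical) + cp.beta_boundary * sharp_std

    # Weibull PH: S(t|z) = exp(-(t/scale)^shape * e^lp)
    u = rng.random(n)
    latent_t = cp.weibull_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / cp.weibull_shape)

    grid = cp.followup_grid
    t_seen = np.ceil(latent_t / grid) * grid  # healing first SEEN at a visit
    n_visits = int(np.floor(cp.max_followup / grid))
    dropout = rng.random(n) < cp.dropout_prob
    dropout_visit = grid * rng.integers(1, n_visits + 1, size=n)
    censor_time = np.where(dropout, dropout_visit, cp.max_followup)

    event = (t_seen <= censor_time).astype(int)
    time = np.where(event == 1, t_seen, censor_time)

    table["time_months"] = time
    table["event"] = event
    dev_size = int(round(cp.split_ratio * n))
    cohort = np.array(["val"] * n, dtype=object)
    cohort[rng.permutation(n)[:dev_size]] = "dev"
    table["cohort"] = cohort

    truth = pd.DataFrame(
        {
            "patient_id": table["patient_id"],
            "transition_width": width,
            "sharpness_std": sharp_std,
            "eccentricity": ecc,
            "linear_predictor": lp,
            "latent_time": latent_t,
        }
    )

    images: list[Radiograph] = []
    contours: list[np.ndarray] = []
    if with_images:
        for i in range(n):
            pp = replace(
                base,
                lesion_diameter=float(lesion[i]),
                transition_width=float(width[i]),
                eccentricity=float(ecc[i]),
                orientation=float(orient[i]),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            img, contour = generate_phantom(pp)
            img.id = table["patient_id"].iloc[i]
            images.append(img)
            contours.append(contour)

    return SyntheticCohort(images, contours, truth, table)


def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write images (PNG + spacing sidecars) and CSV tables to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    for img in cohort.images:
        write_radiograph(img_dir / f"{img.id}.png", img)
    cohort.table.to_csv(out / "cohort.csv", index=False)
    cohort.truth.to_csv(out / "truth.csv", index=False)
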