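"""Synthetic OCT volumes and synthetic two-eyes-per-person cohorts.

The volume generator renders 6x6 mm macular raster volumes (128 B-scans
of 512 A-scans, emulating a Topcon 3D OCT-1000 export) with a known
continuous geometry: a curved retinal pigment epithelium (RPE), an
internal limiting membrane (ILM) carrying a foveal pit whose profile is
*exactly* quadratic within +/-20 columns of the pit centre, multiplicative
gamma speckle, and exported ground-truth boundary rows.  Ground truth is
exported exactly as rendered, so every downstream stage (segmentation,
curvature fitting, thickness) can be scored against it.

The cohort generator emulates the statistical structure of a large
population eye study: two eyes per person, a person-level random
intercept, and configurable standardized covariate effects on the foveal
curvature outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# volume geometry
# --------------------------------------------------------------------------

N_SLICES = 128
N_COLUMNS = 512


@dataclass
class VolumeParams:
    """Scene parameters of one synthetic volume.

    a_fovea is the realized leading coefficient (rows/column^2, pit-positive
    sign) of the ILM within the quadratic core, i.e. exactly what an ideal
    foveal-curvature fit should recover.  a_macula plays the same role for
    the RPE.  cprt_px is the ILM-to-RPE thickness (pixel rows) at the pit
    centre.  noise_sigma is the SD of the unit-mean multiplicative speckle.
    """

    n_slices: int = N_SLICES
    width: int = N_COLUMNS
    height: int = 650
    a_fovea: float = 0.0725
    a_macula: float = 0.0021
    cprt_px: float = 87.0
    pit_center: tuple[int, int] = (64, 256)
    pit_quadratic_halfwidth: int = 20
    pit_rim_halfwidth: int = 60
    pit_slice_sd: float = 6.0
    pit_depth_factor: float = 1.2  # pit depth relative to the quadratic core span
    rpe_center_row: float = 420.0
    noise_sigma: float = 0.35
    intensity_vitreous: float = 20.0
    intensity_retina: float = 160.0
    intensity_choroid: float = 45.0
    lateral_scale_mm: float = 6.0 / 512
    axial_scale_um: float = 2.6

    def validate(self) -> None:
        if self.n_slices < 1 or self.width < 32 or self.height < 64:
            raise ValueError("volume dimensions out of range")
        if not (0 <= self.pit_center[0] < self.n_slices and 0 <= self.pit_center[1] < self.width):
            raise ValueError(f"pit_center {self.pit_center} outside volume bounds")
        if self.cprt_px <= 0:
            raise ValueError("cprt_px must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not (0 <= self.a_fovea < 0.25):
            raise ValueError("a_fovea outside documented range [0, 0.25)")
        if not (0 <= self.a_macula < 0.01):
            raise ValueError("a_macula outside documented range [0, 0.01)")
        if self.pit_quadratic_halfwidth >= self.pit_rim_halfwidth:
            raise ValueError("quadratic core must be narrower than the rim halfwidth")
        if not (self.intensity_vitreous < self.intensity_retina):
            raise ValueError("retina must be brighter than vitreous")
        ilm, rpe = _surfaces(self)
        if np.any(rpe < ilm + 1):
            raise ValueError("parameters violate rpe >= ilm + 1 somewhere")
        if np.any(ilm < 1) or np.any(rpe > self.height - 2):
            raise ValueError("surfaces leave the frame; adjust rows/curvatures")


@dataclass
class SceneTruth:
    """Ground truth exported with each rendered volume."""

    ilm_truth: np.ndarray  # (S, W) continuous row of the ILM
    rpe_truth: np.ndarray  # (S, W) continuous row of the RPE
    a_fovea_true: float
    a_macula_true: float
    pit_center: tuple[int, int]
    cprt_true_px: float
    noise_sigma: float
    seed: int


@dataclass
class OCTVolume:
    """Ordered stack of B-scans with pixel scales and identifiers."""

    frames: np.ndarray  # (128, H, 512) float32 intensities
    lateral_scale_mm: float
    axial_scale_um: float
    eye_id: str = "eye-0"
    person_id: str = "person-0"
    laterality: str = "right"

    def validate(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] != N_SLICES:
            raise ValueError(f"a volume is exactly {N_SLICES} frames, got {self.frames.shape}")
        if self.frames.shape[2] != N_COLUMNS:
            raise ValueError(f"frames must be {N_COLUMNS} columns wide, got {self.frames.shape}")
        if self.lateral_scale_mm <= 0 or self.axial_scale_um <= 0:
            raise ValueError("pixel scales must be strictly positive")


def _pit_bump(u: np.ndarray, b: float, q: int, r: int, depth_factor: float) -> np.ndarray:
    """Lateral pit profile (rows of downward ILM displacement).

    Exactly B0 - b*u^2 on |u| <= q, then a C1 cubic Hermite segment that
    lands on the flat rim (value 0, slope 0) at |u| = r.
    """
    b0 = depth_factor * b * q * q
    au = np.abs(u).astype(np.float64)
    out = np.zeros_like(au)
    core = au <= q
    out[core] = b0 - b * au[core] ** 2
    taper = (au > q) & (au < r)
    t = (au[taper] - q) / (r - q)
    v_q = b0 - b * q * q
    m_q = -2.0 * b * q  # d(bump)/d|u| at the junction
    out[taper] = v_q * (2 * t**3 - 3 * t**2 + 1) + m_q * (r - q) * (t**3 - 2 * t**2 + t)
    return out


def _surfaces(params: VolumeParams) -> tuple[np.ndarray, np.ndarray]:
    """Continuous (ilm, rpe) row coordinates, shape (n_slices, width)."""
    s0, x0 = params.pit_center
    x = np.arange(params.width, dtype=np.float64)
    u = x - x0
    rpe_row = params.rpe_center_row - params.a_macula * u**2
    rpe = np.broadcast_to(rpe_row, (params.n_slices, params.width)).copy()

    b = params.a_fovea - params.a_macula  # bump coefficient on top of the RPE bowl
    bump = _pit_bump(u, b, params.pit_quadratic_halfwidth,
                     params.pit_rim_halfwidth, params.pit_depth_factor)
    b0 = params.pit_depth_factor * b * params.pit_quadratic_halfwidth**2
    t_rim = params.cprt_px + b0
    s = np.arange(params.n_slices, dtype=np.float64)
    phi = np.exp(-0.5 * ((s - s0) / params.pit_slice_sd) ** 2)
    ilm = rpe - t_rim + phi[:, None] * bump[None, :]
    return ilm, rpe


def render_frame(ilm_rows: np.ndarray, rpe_rows: np.ndarray, params: VolumeParams) -> np.ndarray:
    """Render one clean B-scan by area-sampling the three-zone scene.

    The retina band occupies continuous rows [ilm, rpe + 1): the pixel row
    equal to the reported RPE row is the last retina row, matching the
    convention that thickness in pixels is rpe_row - ilm_row.
    """
    H = params.height
    r = np.arange(H, dtype=np.float64)[:, None]
    top = ilm_rows[None, :]
    bot = rpe_rows[None, :] + 1.0
    ret_cov = np.clip(np.minimum(r + 1, bot) - np.maximum(r, top), 0.0, 1.0)
    sub_cov = np.clip(r + 1 - np.maximum(r, bot), 0.0, 1.0)
    vit_cov = 1.0 - ret_cov - sub_cov
    frame = (params.intensity_vitreous * vit_cov
             + params.intensity_retina * ret_cov
             + params.intensity_choroid * sub_cov)
    return frame


def _speckle(frame: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return frame
    k = 1.0 / sigma**2  # unit-mean gamma multiplier with SD sigma
    mult = rng.standard_gamma(k, size=frame.shape, dtype=np.float32)
    return frame * (mult / np.float32(k))


def generate_volume(params: VolumeParams | None = None, seed: int = 0,
                    eye_id: str = "eye-0", person_id: str = "person-0",
                    laterality: str = "right") -> tuple[OCTVolume, SceneTruth]:
    """Render a full volume plus its exported ground truth.

    Deterministic for a fixed (params, seed).
    """
    params = params or VolumeParams()
    params.validate()
    ilm, rpe = _surfaces(params)
    rng = np.random.default_rng(seed)
    frames = np.empty((params.n_slices, params.height, params.width), dtype=np.float32)
    for s in range(params.n_slices):
        frames[s] = _speckle(render_frame(ilm[s], rpe[s], params), params.noise_sigma, rng)
    truth = SceneTruth(
        ilm_truth=ilm, rpe_truth=rpe,
        a_fovea_true=params.a_fovea, a_macula_true=params.a_macula,
        pit_center=params.pit_center,
        cprt_true_px=float(params.cprt_px),
        noise_sigma=params.noise_sigma, seed=seed,
    )
    vol = OCTVolume(frames=frames, lateral_scale_mm=params.lateral_scale_mm,
                    axial_scale_um=params.axial_scale_um,
                    eye_id=eye_id, person_id=person_id, laterality=laterality)
    if params.n_slices == N_SLICES and params.width == N_COLUMNS:
        vol.validate()
    return vol, truth


def generate_bscan(params: VolumeParams | None = None, seed: int = 0,
                   slice_index: int | None = None):
    """Render a single B-scan (defaults to the pit slice) with truth rows.

    Returns (frame, ilm_rows, rpe_rows).  Cheaper than a full volume for
    scan-level experiments such as segmentation validation.
    """
    params = params or VolumeParams()
    params.validate()
    s = params.pit_center[0] if slice_index is None else slice_index
    if not 0 <= s < params.n_slices:
        raise ValueError(f"slice_index {s} outside [0, {params.n_slices})")
    ilm, rpe = _surfaces(params)
    rng = np.random.default_rng(seed)
    frame = _speckle(render_frame(ilm[s], rpe[s], params), params.noise_sigma, rng)
    return frame.astype(np.float32), ilm[s], rpe[s]


def truth_mask(ilm_rows: np.ndarray, rpe_rows: np.ndarray, height: int) -> np.ndarray:
    """Binary retina mask implied by continuous truth rows (one B-scan).

    A pixel row belongs to the retina when its index lies in
    [round(ilm), round(rpe)], mirroring the rendered band [ilm, rpe+1).
    """
    r = np.arange(height)[:, None]
    top = np.rint(ilm_rows)[None, :]
    bot = np.rint(rpe_rows)[None, :]
    return (r >= top) & (r <= bot)


def sample_fovea_params(rng: np.random.Generator, base: VolumeParams | None = None,
                        fc_mean: float = 0.0725, fc_sd: float = 0.02) -> VolumeParams:
    """Draw a volume's foveal curvature from the population spread.

    The population FC distribution is normal with mean 0.072-0.073 and SD
    0.02; draws are clipped to [0.02, 0.15] to keep a recognisable pit.
    The pit centre jitters by a couple of slices/columns.  If a draw
    violates the scene invariants of a non-default base (e.g. a short
    frame), the offending fields fall back to the base values so the
    returned parameters are always renderable.
    """
    base = base or VolumeParams()
    a = float(np.clip(rng.normal(fc_mean, fc_sd), 0.02, 0.15))
    s0 = int(np.clip(base.pit_center[0] + rng.integers(-3, 4), 4, base.n_slices - 5))
    x0 = int(np.clip(base.pit_center[1] + rng.integers(-8, 9), 40, base.width - 41))
    cprt = float(np.clip(rng.normal(base.cprt_px, 5.0),
                         base.cprt_px - 10.0, base.cprt_px + 10.0))
    for cand in (replace(base, a_fovea=a, pit_center=(s0, x0), cprt_px=cprt),
                 replace(base, a_fovea=a, pit_center=(s0, x0)),
                 replace(base, pit_center=(s0, x0))):
        try:
            cand.validate()
            return cand
        except ValueError:
            continue
    return base


# --------------------------------------------------------------------------
# synthetic cohort
# --------------------------------------------------------------------------

ETHNICITY_LEVELS = ["white", "black", "asian", "mixed", "chinese", "other",
                    "prefer_not", "missing"]
ETHNICITY_PROBS = [0.921, 0.025, 0.023, 0.008, 0.004, 0.013, 0.004, 0.002]
TOWNSEND_LEVELS = ["q1", "q2", "q3", "q4", "q5", "missing"]
TOWNSEND_PROBS = [0.319, 0.208, 0.185, 0.175, 0.112, 0.001]
INCOME_LEVELS = ["lt_18k", "18_31k", "31_52k", "52_100k", "gt_100k",
                 "prefer_not", "missing"]
INCOME_PROBS = [0.153, 0.212, 0.239, 0.212, 0.069, 0.111, 0.004]
INCOME_INFORMATIVE = INCOME_LEVELS[:5]  # ordered bands scored 1..5 for trends
EDUCATION_LEVELS = ["degree", "a_levels", "o_levels", "none", "missing"]
EDUCATION_PROBS = [0.373, 0.215, 0.248, 0.129, 0.035]
BIRTH_ORDER_LEVELS = ["1", "2", "3", "4", "missing"]
BIRTH_ORDER_PROBS = [0.558, 0.316, 0.063, 0.062, 0.001]
CENTER_LEVELS = [f"c{i}" for i in range(1, 7)]
DISEASE_FLAGS = ["amd", "diabetic_retinopathy", "macular_disease",
                 "cataract_surgery", "refractive_surgery", "corneal_graft_surgery"]


@dataclass
class CohortParams:
    """Marginals and noise structure of the synthetic cohort.

    Defaults approximate the population study the generator emulates:
    ~55% female, age 56 (SD 8), 92.1% white, sex-specific height, and a
    strong fellow-eye correlation (between-person SD 0.85 vs residual SD
    0.5 on the FC outcome scale).
    """

    p_female: float = 0.549
    age_mean: float = 56.0
    age_sd: float = 8.0
    height_mean: dict = field(default_factory=lambda: {"female": 163.0, "male": 176.0})
    height_sd: dict = field(default_factory=lambda: {"female": 6.3, "male": 6.7})
    va_mean: float = 85.1
    va_sd: float = 5.0
    se_mean: float = -0.69
    se_sd: float = 2.6
    astig_mean: float = 0.85
    astig_sd: float = 0.5
    iop_mean: float = 16.0
    iop_sd: float = 3.0
    mc_mean: float = 0.0021
    mc_sd: float = 0.0008
    cprt_mean: float = 226.0
    cprt_sd: float = 18.0
    fi_mean: float = 6.0
    fi_sd: float = 2.1
    disease_probs: dict = field(default_factory=lambda: {
        "amd": 0.010, "diabetic_retinopathy": 0.010, "macular_disease": 0.005,
        "cataract_surgery": 0.020, "refractive_surgery": 0.015,
        "corneal_graft_surgery": 0.001})
    missing_eye_rate: float = 0.30  # fraction of persons contributing one eye
    fc_intercept: float = 0.0


#: effect-map keys the generator and the model design share.  Continuous
#: keys apply per the stated reporting increment (age per decade, height
#: per 5 cm, VA per 5 letters, CPRT per 10 um, MC per 0.01, SE/astig per
#: diopter, IOP per mm Hg); "income_trend" applies per ordered income band.
EFFECT_KEYS = (
    ["sex_male", "age_per_decade", "height_per_5cm", "va_per_5letters",
     "se_per_diopter", "astigmatism_per_diopter", "iop_per_mmhg",
     "mc_per_001", "cprt_per_10um", "fluid_intelligence", "income_trend"]
    + [f"ethnicity_{l}" for l in ETHNICITY_LEVELS[1:]]
    + [f"townsend_{l}" for l in TOWNSEND_LEVELS[1:]]
    + [f"income_{l}" for l in INCOME_LEVELS[1:]]
    + [f"education_{l}" for l in EDUCATION_LEVELS[1:]]
    + [f"birth_order_{l}" for l in BIRTH_ORDER_LEVELS[1:]]
    + [f"center_{l}" for l in CENTER_LEVELS[1:]]
)


def _effect_value(value, sex: np.ndarray) -> np.ndarray:
    """Resolve a scalar or per-sex {'female': .., 'male': ..} effect."""
    if isinstance(value, dict):
        out = np.zeros(len(sex))
        out[sex == "female"] = float(value.get("female", 0.0))
        out[sex == "male"] = float(value.get("male", 0.0))
        return out
    return np.full(len(sex), float(value))


def effect_increments(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-record covariate values on the reporting-increment scale.

    Shared by the generator (to build the linear predictor) and reusable
    for checking moments; keys match EFFECT_KEYS.
    """
    n = len(df)
    inc: dict[str, np.ndarray] = {
        "sex_male": (df["sex"] == "male").to_numpy(float),
        "age_per_decade": df["age"].to_numpy() / 10.0,
        "height_per_5cm": df["height_cm"].to_numpy() / 5.0,
        "va_per_5letters": df["va_letters"].to_numpy() / 5.0,
        "se_per_diopter": df["se_diopters"].to_numpy(),
        "astigmatism_per_diopter": df["astigmatism_diopters"].to_numpy(),
        "iop_per_mmhg": df["iop_mmhg"].to_numpy(),
        "mc_per_001": df["mc"].to_numpy() / 0.01,
        "cprt_per_10um": df["cprt_um"].to_numpy() / 10.0,
        "fluid_intelligence": df["fluid_intelligence"].to_numpy(float),
    }
    score = np.zeros(n)
    for i, lev in enumerate(INCOME_INFORMATIVE):
        score[(df["income"] == lev).to_numpy()] = i + 1
    inc["income_trend"] = score
    for col, levels in [("ethnicity", ETHNICITY_LEVELS), ("townsend", TOWNSEND_LEVELS),
                        ("income", INCOME_LEVELS), ("education", EDUCATION_LEVELS),
                        ("birth_order", BIRTH_ORDER_LEVELS), ("center", CENTER_LEVELS)]:
        for lev in levels[1:]:
            inc[f"{col}_{lev}"] = (df[col] == lev).to_numpy(float)
    return inc


def generate_cohort(n_persons: int, effects: dict | None = None,
                    variance_components: tuple[float, float] = (0.85, 0.5),
                    seed: int = 0, params: CohortParams | None = None) -> pd.DataFrame:
    """Simulate a two-eyes-per-person cohort with known effect structure.

    fc_raw = intercept + sum(effect * increment) + person intercept + eye
    noise, with the person intercept SD and eye-level residual SD given by
    `variance_components`.  Effects may be scalars or {'female','male'}
    dicts; unknown keys raise.
    """
    if n_persons < 2:
        raise ValueError("n_persons must be >= 2")
    sd_between, sd_resid = variance_components
    if sd_between < 0 or sd_resid <= 0:
        raise ValueError("variance component SDs must be positive (between may be 0)")
    effects = dict(effects or {})
    unknown = set(effects) - set(EFFECT_KEYS)
    if unknown:
        raise KeyError(f"unknown effect keys: {sorted(unknown)}")
    p = params or CohortParams()
    rng = np.random.default_rng(seed)

    # person-level covariates
    sex_p = np.where(rng.random(n_persons) < p.p_female, "female", "male")
    age_p = np.clip(rng.normal(p.age_mean, p.age_sd, n_persons), 40, 70)
    hmu = np.where(sex_p == "female", p.height_mean["female"], p.height_mean["male"])
    hsd = np.where(sex_p == "female", p.height_sd["female"], p.height_sd["male"])
    height_p = rng.normal(hmu, hsd)
    eth_p = rng.choice(ETHNICITY_LEVELS, n_persons, p=_renorm(ETHNICITY_PROBS))
    town_p = rng.choice(TOWNSEND_LEVELS, n_persons, p=_renorm(TOWNSEND_PROBS))
    inc_p = rng.choice(INCOME_LEVELS, n_persons, p=_renorm(INCOME_PROBS))
    edu_p = rng.choice(EDUCATION_LEVELS, n_persons, p=_renorm(EDUCATION_PROBS))
    bo_p = rng.choice(BIRTH_ORDER_LEVELS, n_persons, p=_renorm(BIRTH_ORDER_PROBS))
    ctr_p = rng.choice(CENTER_LEVELS, n_persons)
    fi_p = np.clip(np.rint(rng.normal(p.fi_mean, p.fi_sd, n_persons)), 0, 13)

    n_eyes_p = np.where(rng.random(n_persons) < p.missing_eye_rate, 1, 2)
    rows = []
    for i in range(n_persons):
        eyes = ["right"] if n_eyes_p[i] == 1 else ["right", "left"]
        for eye in eyes:
            rows.append((f"p{i:06d}", eye, i))
    df = pd.DataFrame(rows, columns=["person_id", "eye", "_pidx"])
    pi = df["_pidx"].to_numpy()
    n = len(df)

    df["sex"] = sex_p[pi]
    df["age"] = age_p[pi]
    df["height_cm"] = height_p[pi]
    df["ethnicity"] = eth_p[pi]
    df["townsend"] = town_p[pi]
    df["income"] = inc_p[pi]
    df["education"] = edu_p[pi]
    df["birth_order"] = bo_p[pi]
    df["center"] = ctr_p[pi]
    df["fluid_intelligence"] = fi_p[pi]

    # eye-level ocular covariates: person mean plus small fellow-eye deviation
    def _eye_level(mean, sd):
        person = rng.normal(mean, sd * 0.8, n_persons)
        return person[pi] + rng.normal(0.0, sd * 0.6, n)

    df["va_letters"] = np.clip(_eye_level(p.va_mean, p.va_sd), 40, 100)
    df["se_diopters"] = _eye_level(p.se_mean, p.se_sd)
    df["astigmatism_diopters"] = np.clip(_eye_level(p.astig_mean, p.astig_sd), 0, None)
    df["iop_mmhg"] = np.clip(_eye_level(p.iop_mean, p.iop_sd), 5, 40)
    df["mc"] = _eye_level(p.mc_mean, p.mc_sd)
    df["cprt_um"] = np.clip(_eye_level(p.cprt_mean, p.cprt_sd), 120, 350)

    for flag in DISEASE_FLAGS:
        prob = p.disease_probs[flag]
        person_flag = rng.random(n_persons) < prob
        df[flag] = person_flag[pi]

    inc = effect_increments(df)
    eta = np.full(n, p.fc_intercept)
    sex_e = df["sex"].to_numpy()
    for key, val in effects.items():
        eta = eta + _effect_value(val, sex_e) * inc[key]

    b_person = rng.normal(0.0, sd_between, n_persons)
    eps = rng.normal(0.0, sd_resid, n)
    df["fc_raw"] = eta + b_person[pi] + eps
    mu, sd = df["fc_raw"].mean(), df["fc_raw"].std(ddof=1)
    df["fc_z"] = (df["fc_raw"] - mu) / sd if sd > 0 else np.nan
    return df.drop(columns="_pidx")


def _renorm(probs) -> np.ndarray:
    a = np.asarray(probs, dtype=float)
    return a / a.sum()
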