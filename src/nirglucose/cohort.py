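"""Synthetic cohorts under a personalized Beer-Lambert transmittance model.

Each subject carries six personalized medical features (PMF) and latent optical
parameters: aggregate attenuation terms ``N_i`` for a few interfering species
(tissue, bone, water/fat) and an effective glucose beam path ``l_g``.  Detector
readout at band *b* is Beer-Lambert transmittance

    T_b = exp(-[ sigma_g[b] * phi(g) / g_scale * l_g  +  sum_i sigma_ig[b,i] * N_i ])

where ``phi`` is a smooth (C-infinity) saturating transform of glucose ``g``:
its slope is 1 below the turning point and drops to ``turnover_slope_ratio``
above it, capturing the regime where scattering starts to dominate absorption
and the marginal attenuation per mg/dL of glucose shrinks.  The latent
attenuation terms are a linear function of the standardized PMF vector plus a
small per-person perturbation, so two subjects with different PMF trace
different NIR-vs-glucose curves while the PMF remain informative about the
optical confounders.

All randomness flows through explicit ``numpy.random.Generator`` objects (or
integer seeds), so datasets regenerate bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PMF_FIELDS",
    "NIR_FIELDS",
    "MODEL_INPUT_FIELDS",
    "DATASET_COLUMNS",
    "DM_THRESHOLD",
    "PersonProfile",
    "OpticalModelConfig",
    "CohortDistributions",
    "GlucoseMixture",
    "generate_population",
    "transmittance",
    "make_dataset",
    "meal_timeseries",
    "write_dataset",
    "read_dataset",
]

PMF_FIELDS = ["gender", "age", "weight", "height", "bmi", "blood_pressure"]
NIR_FIELDS = ["nir_1", "nir_2", "nir_3"]
MODEL_INPUT_FIELDS = NIR_FIELDS + PMF_FIELDS
DATASET_COLUMNS = ["person_id"] + MODEL_INPUT_FIELDS + ["glucose_ref", "dm_label"]

#: Fasting plasma glucose diagnosis threshold for diabetes mellitus (mg/dL).
DM_THRESHOLD = 126.0

# Reference location/scale used to standardize PMF before the linear map onto
# latent attenuation.  Fixed constants (not cohort estimates) so that a
# subject's optical parameters do not depend on who else was sampled.
_PMF_REF_MEAN = np.array([0.5, 50.0, 65.0, 162.0, 24.5, 125.0])
_PMF_REF_SD = np.array([0.5, 15.0, 12.0, 9.0, 4.0, 15.0])


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class PersonProfile:
    """One subject: medical features plus latent optical parameters.

    ``latent_attenuation`` holds the aggregate per-species terms
    ``N_i = l_i/l_g * n_i`` (dimensionless, >= 0), one entry per interfering
    species; ``path_length_g`` is the effective glucose beam path scale
    (dimensionless, > 0).
    """

    person_id: str
    gender: int
    age: float
    weight: float
    height: float
    bmi: float
    blood_pressure: float
    latent_attenuation: np.ndarray
    path_length_g: float

    def __post_init__(self):
        object.__setattr__(
            self, "latent_attenuation", np.asarray(self.latent_attenuation, dtype=float)
        )
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 or 1, got {self.gender}")
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        expected_bmi = self.weight / (self.height / 100.0) ** 2
        if abs(self.bmi - expected_bmi) > 0.01:
            raise ValueError(
                f"bmi={self.bmi:.3f} inconsistent with weight/height "
                f"(expected {expected_bmi:.3f})"
            )
        if self.path_length_g <= 0:
            raise ValueError("path_length_g must be > 0")
        if np.any(self.latent_attenuation < 0):
            raise ValueError("latent_attenuation entries must be >= 0")

    @property
    def pmf_vector(self) -> np.ndarray:
        """PMF in canonical order: gender, age, weight, height, bmi, blood_pressure."""
        return np.array(
            [self.gender, self.age, self.weight, self.height, self.bmi, self.blood_pressure],
            dtype=float,
        )


@dataclass(frozen=True)
class OpticalModelConfig:
    """Parameters of the personalized Beer-Lambert readout model.

    Defaults describe three detection bands centered at 850/950/1150 nm, three
    aggregate interfering species, a glucose attenuation turning point at
    220 mg/dL beyond which the marginal attenuation drops to 30% of its
    low-glucose value, and a low multiplicative readout noise.
    """

    band_centers_nm: tuple = (850.0, 950.0, 1150.0)
    band_ranges_nm: tuple = ((800.0, 900.0), (900.0, 1000.0), (1100.0, 1200.0))
    #: per-band glucose attenuation cross-section (dimensionless, > 0)
    sigma_g: tuple = (2.0, 1.5, 1.0)
    #: relative cross-sections sigma_i/sigma_g: rows = bands, cols = species
    sigma_ig: tuple = (
        (0.5, 0.8, 0.3),
        (0.7, 0.4, 0.5),
        (0.4, 0.3, 0.9),
    )
    #: glucose concentration (mg/dL) where scattering starts to dominate
    turning_point: float = 220.0
    #: logistic width (mg/dL) of the slope transition; smaller = sharper
    turnover_sharpness: float = 25.0
    #: marginal attenuation per mg/dL above the turning point, relative to below
    turnover_slope_ratio: float = 0.3
    #: linear map standardized-PMF -> latent attenuation mean: rows = species
    pmf_coefficients: tuple = (
        (0.05, 0.02, 0.10, -0.04, 0.16, 0.05),
        (0.12, 0.06, 0.04, 0.10, -0.02, 0.00),
        (-0.04, 0.03, 0.08, 0.02, 0.10, 0.08),
    )
    #: baseline latent attenuation per species (at reference PMF)
    latent_base: tuple = (0.40, 0.30, 0.30)
    #: sd of the per-person perturbation added to each latent attenuation term
    person_sd: float = 0.015
    #: sd of log path_length_g across persons
    path_length_sd: float = 0.03
    #: multiplicative log-normal readout noise scale
    noise_sd: float = 0.005
    #: glucose normalization used inside the attenuation term (mg/dL)
    glucose_scale: float = 400.0
    seed: int = 0

    def __post_init__(self):
        if len(self.band_centers_nm) != 3 or tuple(self.band_centers_nm) != (850.0, 950.0, 1150.0):
            raise ValueError("exactly 3 bands centered at 850, 950, 1150 nm are supported")
        sg = np.asarray(self.sigma_g, dtype=float)
        if sg.shape != (3,) or np.any(sg <= 0) or not np.all(np.isfinite(sg)):
            raise ValueError("sigma_g must be 3 positive finite values")
        sig = np.asarray(self.sigma_ig, dtype=float)
        if sig.ndim != 2 or sig.shape[0] != 3 or not np.all(np.isfinite(sig)):
            raise ValueError("sigma_ig must be a finite (3 bands x n_species) matrix")
        if not 60.0 < self.turning_point < 400.0:
            raise ValueError("turning_point must lie inside (60, 400) mg/dL")
        if self.turnover_sharpness <= 0:
            raise ValueError("turnover_sharpness must be > 0")
        pc = np.asarray(self.pmf_coefficients, dtype=float)
        if pc.shape != (self.n_species, len(PMF_FIELDS)):
            raise ValueError(
                f"pmf_coefficients must be (n_species={self.n_species} x {len(PMF_FIELDS)})"
            )
        if self.noise_sd < 0 or self.person_sd < 0 or self.path_length_sd < 0:
            raise ValueError("noise scales must be >= 0")

    @property
    def n_species(self) -> int:
        return np.asarray(self.sigma_ig).shape[1]

    def replace(self, **kwargs) -> "OpticalModelConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class CohortDistributions:
    """Marginal distributions of the PMF across the cohort.

    Ages are drawn from a truncated normal whose median sits at ``age_median``
    (50 years by default); weight is derived from sampled height and BMI so the
    BMI identity holds exactly.
    """

    age_median: float = 50.0
    age_sd: float = 13.0
    age_min: float = 18.0
    age_max: float = 90.0
    p_female: float = 0.5
    height_mean: float = 162.0
    height_sd: float = 9.0
    height_min: float = 130.0
    height_max: float = 200.0
    bmi_mean: float = 24.5
    bmi_sd: float = 4.0
    bmi_min: float = 16.0
    bmi_max: float = 45.0
    bp_mean: float = 125.0
    bp_sd: float = 15.0
    bp_min: float = 85.0
    bp_max: float = 200.0

    def __post_init__(self):
        if self.height_min <= 0 or self.height_max <= self.height_min:
            raise ValueError("invalid height bounds")
        if not (0.0 <= self.p_female <= 1.0):
            raise ValueError("p_female must lie in [0, 1]")
        if self.age_min < 0 or self.age_max <= self.age_min:
            raise ValueError("invalid age bounds")
        if self.bmi_min <= 0 or self.bmi_max <= self.bmi_min:
            raise ValueError("invalid bmi bounds")
        if self.bp_min <= 0 or self.bp_max <= self.bp_min:
            raise ValueError("invalid blood pressure bounds")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw from N(mean, sd) truncated to [lo, hi] by resampling."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_population(
    n_persons: int,
    config: OpticalModelConfig | None = None,
    pmf_distributions: CohortDistributions | None = None,
    rng=None,
    id_prefix: str = "P",
) -> list[PersonProfile]:
    """Sample ``n_persons`` subjects with PMF-linked latent optical parameters.

    The latent attenuation of each subject is
    ``clip(latent_base + pmf_coefficients @ standardized(PMF) + eps, 0)`` with
    ``eps ~ N(0, person_sd)`` i.i.d. per species, and ``log path_length_g ~
    N(0, path_length_sd)``.  Deterministic given the generator state.
    """
    if n_persons < 1:
        raise ValueError("n_persons must be >= 1")
    config = config or OpticalModelConfig()
    dist = pmf_distributions or CohortDistributions()
    rng = _rng(config.seed if rng is None else rng)

    age = _truncated_normal(rng, dist.age_median, dist.age_sd, dist.age_min, dist.age_max, n_persons)
    gender = (rng.random(n_persons) < dist.p_female).astype(int)
    height = _truncated_normal(
        rng, dist.height_mean, dist.height_sd, dist.height_min, dist.height_max, n_persons
    )
    bmi = _truncated_normal(rng, dist.bmi_mean, dist.bmi_sd, dist.bmi_min, dist.bmi_max, n_persons)
    weight = bmi * (height / 100.0) ** 2
    bp = _truncated_normal(rng, dist.bp_mean, dist.bp_sd, dist.bp_min, dist.bp_max, n_persons)

    coeff = np.asarray(config.pmf_coefficients, dtype=float)
    base = np.asarray(config.latent_base, dtype=float)
    persons = []
    for j in range(n_persons):
        pmf = np.array([gender[j], age[j], weight[j], height[j], bmi[j], bp[j]])
        z = (pmf - _PMF_REF_MEAN) / _PMF_REF_SD
        eps = rng.normal(0.0, config.person_sd, size=config.n_species)
        latent = np.clip(base + coeff @ z + eps, 0.0, None)
        l_g = float(np.exp(rng.normal(0.0, config.path_length_sd)))
        persons.append(
            PersonProfile(
                person_id=f"{id_prefix}{j:04d}",
                gender=int(gender[j]),
                age=float(age[j]),
                weight=float(weight[j]),
                height=float(height[j]),
                bmi=float(bmi[j]),
                blood_pressure=float(bp[j]),
                latent_attenuation=latent,
                path_length_g=l_g,
            )
        )
    return persons


def _glucose_transform(glucose, config: OpticalModelConfig):
    """C-infinity saturating transform phi(g) with phi(0)=0.

    phi'(g) = r + (1 - r) * logistic((g* - g) / w): slope 1 well below the
    turning point g*, slope r well above, blended over width w.  Closed form by
    integration, written with logaddexp for numerical stability.
    """
    g = np.asarray(glucose, dtype=float)
    gstar = config.turning_point
    w = config.turnover_sharpness
    r = config.turnover_slope_ratio
    # integral of logistic((g*-u)/w) du from 0 to g
    soft = g - w * (np.logaddexp(0.0, (g - gstar) / w) - np.logaddexp(0.0, -gstar / w))
    return r * g + (1.0 - r) * soft


def transmittance(
    person: PersonProfile,
    glucose,
    band_index: int,
    config: OpticalModelConfig | None = None,
):
    """Noise-free detector readout in (0, 1] at one band (``band_index`` in 1..3).

    Accepts a scalar or array of glucose values (mg/dL, >= 0).
    """
    config = config or OpticalModelConfig()
    if band_index not in (1, 2, 3):
        raise ValueError("band_index must be 1, 2 or 3")
    g = np.asarray(glucose, dtype=float)
    if np.any(g < 0) or not np.all(np.isfinite(g)):
        raise ValueError("glucose must be finite and >= 0")
    b = band_index - 1
    sigma_g = np.asarray(config.sigma_g)[b]
    sigma_ig = np.asarray(config.sigma_ig)[b]
    depth = (
        sigma_g * _glucose_transform(g, config) / config.glucose_scale * person.path_length_g
        + sigma_ig @ person.latent_attenuation
    )
    return np.exp(-depth)


@dataclass(frozen=True)
class GlucoseMixture:
    """Reference-glucose sampler: healthy normal component plus a diabetic
    right tail (126 + gamma), truncated to the 60-400 mg/dL detection range.

    ``dm_fraction`` is calibrated so that roughly 26% of draws exceed the
    126 mg/dL threshold, matching a general-population screening cohort with
    about 104 of 401 subjects in the high class.
    """

    dm_fraction: float = 0.26
    healthy_mean: float = 95.0
    healthy_sd: float = 12.0
    dm_gamma_shape: float = 1.5
    dm_gamma_scale: float = 60.0
    lo: float = 60.0
    hi: float = 400.0

    def __post_init__(self):
        if not 0.0 <= self.dm_fraction <= 1.0:
            raise ValueError("dm_fraction must lie in [0, 1]")
        if self.lo >= self.hi:
            raise ValueError("invalid glucose range")

    def sample(self, n: int, rng) -> np.ndarray:
        rng = _rng(rng)
        is_dm = rng.random(n) < self.dm_fraction
        healthy = rng.normal(self.healthy_mean, self.healthy_sd, size=n)
        dm = DM_THRESHOLD + rng.gamma(self.dm_gamma_shape, self.dm_gamma_scale, size=n)
        g = np.where(is_dm, dm, healthy)
        return np.clip(g, self.lo, self.hi)

    def p_high(self, n_mc: int = 200_000, seed: int = 12345) -> float:
        """Monte-Carlo estimate of P(glucose >= 126 mg/dL)."""
        g = self.sample(n_mc, np.random.default_rng(seed))
        return float(np.mean(g >= DM_THRESHOLD))


def make_dataset(
    persons: Sequence[PersonProfile],
    samples_per_person: int = 1,
    glucose_sampler: GlucoseMixture | None = None,
    config: OpticalModelConfig | None = None,
    rng=None,
) -> pd.DataFrame:
    """Simulate observation records for a cohort.

    Each record holds the three noisy band readouts (transmittance times
    multiplicative log-normal noise of scale ``noise_sd``, clipped to (0, 1]),
    the six PMF, the reference glucose and the DM label
    (``glucose_ref >= 126``).  Returns a DataFrame with the canonical column
    schema; byte-identical under a fixed seed.
    """
    persons = list(persons)
    if not persons:
        raise ValueError("persons list must be nonempty")
    if samples_per_person < 1:
        raise ValueError("samples_per_person must be >= 1")
    config = config or OpticalModelConfig()
    sampler = glucose_sampler or GlucoseMixture()
    rng = _rng(config.seed if rng is None else rng)

    rows = []
    for person in persons:
        glucose = sampler.sample(samples_per_person, rng)
        for g in glucose:
            nir = np.empty(3)
            for b in (1, 2, 3):
                t = float(transmittance(person, g, b, config))
                if config.noise_sd > 0:
                    t *= float(np.exp(rng.normal(0.0, config.noise_sd)))
                nir[b - 1] = min(max(t, np.finfo(float).tiny), 1.0)
            rows.append(
                {
                    "person_id": person.person_id,
                    "nir_1": nir[0],
                    "nir_2": nir[1],
                    "nir_3": nir[2],
                    "gender": person.gender,
                    "age": person.age,
                    "weight": person.weight,
                    "height": person.height,
                    "bmi": person.bmi,
                    "blood_pressure": person.blood_pressure,
                    "glucose_ref": float(g),
                    "dm_label": int(g >= DM_THRESHOLD),
                }
            )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


#: meal event types and their glucose excursion (mg/dL); noodle draws uniformly
#: from its range, cake is a fixed rise.
MEAL_EVENTS = {"cake": (20.0, 20.0), "noodle": (25.0, 30.0)}


def meal_timeseries(
    person: PersonProfile,
    events: Sequence[tuple],
    duration: float,
    config: OpticalModelConfig | None = None,
    baseline: float = 95.0,
    decay_rate: float = 0.0173,
    step: float = 1.0,
    rng=None,
    noisy: bool = False,
) -> pd.DataFrame:
    """Glucose and NIR time series around meal events.

    Each event ``(time_min, event_type)`` raises glucose by the event's
    excursion at the event time, after which the excursion decays exponentially
    back to baseline at ``decay_rate`` per minute (the insulin response;
    ``decay_rate=0`` leaves a permanent step).  Events must be sorted by time.
    Returns columns ``time_min, glucose, nir_1, nir_2, nir_3``.
    """
    config = config or OpticalModelConfig()
    rng = _rng(config.seed if rng is None else rng)
    times = [t for t, _ in events]
    if times != sorted(times):
        raise ValueError("events must be sorted by time")
    for t, kind in events:
        if kind not in MEAL_EVENTS:
            raise ValueError(f"unknown event_type {kind!r}; expected one of {sorted(MEAL_EVENTS)}")

    grid = np.arange(0.0, duration + step / 2, step)
    glucose = np.full_like(grid, baseline)
    for t_event, kind in events:
        lo, hi = MEAL_EVENTS[kind]
        amp = lo if lo == hi else float(rng.uniform(lo, hi))
        dt = grid - t_event
        glucose = glucose + np.where(dt >= 0, amp * np.exp(-decay_rate * np.maximum(dt, 0.0)), 0.0)

    out = {"time_min": grid, "glucose": glucose}
    for b in (1, 2, 3):
        t = transmittance(person, glucose, b, config)
        if noisy and config.noise_sd > 0:
            t = t * np.exp(rng.normal(0.0, config.noise_sd, size=t.shape))
        out[f"nir_{b}"] = np.clip(t, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(out)


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a cohort dataset as CSV with the canonical column schema."""
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    df.to_csv(path, index=False, columns=DATASET_COLUMNS)


def read_dataset(path) -> pd.DataFrame:
    """Read a cohort dataset CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset file {path} missing columns: {missing}")
    return df
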