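"""Synthetic PPMI-like cohorts with known planted parameters.

Every downstream stage of the package (GMD extraction, norming, subtyping,
milestone survival, group statistics) is exercised on data from this module,
so that the whole chain is testable without any imaging download.  The
generator emits three things:

* a healthy-control norming cohort whose Ch4 GMD follows a known linear
  model in age, sex, scanner type and TIV;
* a PD-MCI cohort in which a latent "low Ch4" subgroup has its GMD shifted
  down and its clinical scores shifted toward greater burden, plus 6-monthly
  longitudinal visits whose first qualifying visit encodes an exponential
  proportional-hazards time-to-milestone with a planted hazard ratio;
* tiny 3D grey-matter volumes paired with a probabilistic mask whose
  weighted-mean GMD equals a requested value exactly, for round-trip tests
  of the extraction formula.

The planted truth (latent labels, coefficients, latent event times) is
returned alongside the data in a :class:`SyntheticTruth` object that no
analysis module ever reads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .gmd import GreyMatterMap, ProbabilisticMask

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_hc_cohort",
    "generate_pdmci_cohort",
    "generate_gm_image",
]


@dataclass
class SimulationConfig:
    """All planted parameters of the synthetic study.

    Cohort sizes, the healthy-control age/sex mix and the latent low-Ch4
    fraction default to the study design being emulated (171 controls of
    mean age 60.6 +/- 11.6 with 61.4% males; 148 PD-MCI of whom 32 are low
    Ch4); the survival truth defaults to a hazard ratio of 1.95 for the low
    group.  GMD-model coefficients are in GMD units (grey-matter fraction);
    hazard rates are per month.
    """

    # cohort sizes
    n_hc: int = 171
    n_pd: int = 148
    frac_low_ch4: float = 32 / 148
    seed: int = 0

    # covariate marginals
    age_mean: float = 60.6
    age_sd: float = 11.6
    age_min: float = 30.0          # study entry criterion: 30 years or older
    male_frac: float = 0.614
    tiv_mean: float = 1450.0       # mL
    tiv_sd: float = 130.0
    scanner_probs: tuple = (0.6, 0.2, 0.2)   # Siemens, GE, Philips

    # norming truth: GMD = const + b_age*age + b_sex*sex + b_ge + b_philips
    #                      + b_tiv*tiv + Normal(0, residual_sd)
    gmd_constant: float = 0.55
    b_age: float = -0.0015
    b_sex: float = -0.005
    b_ge: float = -0.010
    b_philips: float = -0.008
    b_tiv: float = 2.0e-5
    residual_sd: float = 0.03
    low_gmd_shift: float = -0.075  # -2.5 residual SDs for the latent low group

    # clinical score shifts applied to the latent low-Ch4 subgroup
    clinical_shifts: dict = field(default_factory=lambda: {
        "updrs1": 1.0, "updrs2": 2.0, "updrs3": 5.0,
        "scopa_aut": 6.0, "rbdsq": 1.0, "upsit": -5.0, "moca": -1.0,
    })
    # baseline symptom-presence probability (item >= 1) per part-1 item,
    # (normal group, low group); loosely matched to the emulated frequencies
    item_presence: dict = field(default_factory=lambda: {
        "updrs_1_1": (0.32, 0.44),
        "updrs_1_2": (0.02, 0.19),
        "updrs_1_3": (0.26, 0.38),
        "updrs_1_4": (0.41, 0.47),
        "updrs_1_5": (0.13, 0.28),
        "updrs_1_6": (0.005, 0.03),
    })

    # survival truth
    baseline_hazard: float = 0.0144       # per month (median ~48 mo)
    log_hr_low: float = math.log(1.95)
    log_hr_age: float = 0.02              # per year, centered at 65
    log_hr_sex: float = 0.10
    log_hr_moca: float = -0.10            # per MoCA point, centered at 24
    visit_interval: float = 6.0           # months
    max_follow_up: float = 60.0           # months
    censoring_rate: float = 0.005         # per month, random loss to follow-up

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_hc < 2:
            raise ValueError(f"n_hc must be >= 2, got {self.n_hc}")
        if self.n_pd < 2:
            raise ValueError(f"n_pd must be >= 2, got {self.n_pd}")
        if not 0.0 < self.frac_low_ch4 < 1.0:
            raise ValueError(
                f"frac_low_ch4 must lie in (0, 1), got {self.frac_low_ch4}"
            )
        if self.residual_sd < 0:
            # zero is the legitimate noise-free limit used by exactness tests
            raise ValueError(f"residual_sd must be >= 0, got {self.residual_sd}")
        if not self.visit_interval > 0:
            raise ValueError(f"visit_interval must be > 0, got {self.visit_interval}")
        for name in ("male_frac",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        probs = np.asarray(self.scanner_probs, dtype=float)
        if probs.size != 3 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError(
                f"scanner_probs must be 3 nonnegative values summing to 1, "
                f"got {self.scanner_probs}"
            )
        for item, (p0, p1) in self.item_presence.items():
            if not (0 <= p0 <= 1 and 0 <= p1 <= 1):
                raise ValueError(f"item_presence[{item}] must be probabilities")
        if self.age_sd <= 0 or self.tiv_sd <= 0:
            raise ValueError("age_sd and tiv_sd must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be >= 0")
        if self.max_follow_up <= 0:
            raise ValueError("max_follow_up must be > 0")

    # -- serialization --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["scanner_probs"] = list(d["scanner_probs"])
        d["item_presence"] = {k: list(v) for k, v in d["item_presence"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "scanner_probs" in d:
            d["scanner_probs"] = tuple(d["scanner_probs"])
        if "item_presence" in d:
            d["item_presence"] = {k: tuple(v) for k, v in d["item_presence"].items()}
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted parameters and latent per-subject state.

    Emitted alongside generated data for calibration experiments and tests;
    analysis modules never consume it.
    """

    latent_low: np.ndarray                  # bool per PD subject
    gmd_coefficients: dict                  # name -> true value
    log_hazard_ratios: dict                 # name -> true log-HR
    latent_event_time: np.ndarray           # months, continuous
    censor_time: np.ndarray                 # months (inf if none)
    baseline_hazard: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "latent_low": [bool(v) for v in self.latent_low],
            "gmd_coefficients": self.gmd_coefficients,
            "log_hazard_ratios": self.log_hazard_ratios,
            "latent_event_time": [float(v) for v in self.latent_event_time],
            "censor_time": [
                None if np.isinf(v) else float(v) for v in self.censor_time
            ],
            "baseline_hazard": self.baseline_hazard,
        }, indent=2))


_SCANNERS = np.array(["Siemens", "GE", "Philips"], dtype=object)


def _draw_covariates(rng: np.random.Generator, n: int, cfg: SimulationConfig):
    a = (cfg.age_min - cfg.age_mean) / cfg.age_sd
    age = sps.truncnorm.rvs(a, np.inf, loc=cfg.age_mean, scale=cfg.age_sd,
                            size=n, random_state=rng)
    sex = (rng.random(n) < cfg.male_frac).astype(int)   # male = 1
    scanner = rng.choice(_SCANNERS, size=n, p=np.asarray(cfg.scanner_probs))
    tiv = np.clip(rng.normal(cfg.tiv_mean, cfg.tiv_sd, size=n), 800.0, None)
    return age, sex, scanner, tiv


def _gmd_linear_predictor(cfg: SimulationConfig, age, sex, scanner, tiv):
    return (
        cfg.gmd_constant
        + cfg.b_age * age
        + cfg.b_sex * sex
        + cfg.b_ge * (scanner == "GE").astype(float)
        + cfg.b_philips * (scanner == "Philips").astype(float)
        + cfg.b_tiv * tiv
    )


def generate_hc_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Healthy-control norming cohort: covariates plus model-drawn Ch4 GMD.

    GMD follows the configured linear model with Normal(0, residual_sd)
    noise; with ``residual_sd`` effectively 0 each GMD equals the linear
    predictor exactly.  MoCA and the MCI flag are drawn already-eligible
    (MoCA >= 27, flag False) so the cohort passes control selection intact.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_hc
    age, sex, scanner, tiv = _draw_covariates(rng, n, config)
    noise = rng.normal(0.0, config.residual_sd, size=n) if config.residual_sd > 0 \
        else np.zeros(n)
    gmd = _gmd_linear_predictor(config, age, sex, scanner, tiv) + noise
    return pd.DataFrame({
        "subject_id": [f"HC{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "scanner": scanner,
        "tiv": tiv,
        "ch4_gmd": gmd,
        "moca": rng.integers(27, 31, size=n),
        "mci_flag": np.zeros(n, dtype=bool),
    })


def _clip_round(x, lo, hi, integer=True):
    x = np.clip(x, lo, hi)
    return np.round(x) if integer else x


def _draw_item(rng, n, p_present, elevated=None):
    """0-4 ordinal item: present (>=1) with prob p, then mostly 1s and 2s."""
    present = rng.random(n) < p_present
    severity = rng.choice([1, 2], size=n, p=[0.7, 0.3])
    return np.where(present, severity, 0)


def generate_pdmci_cohort(
    config: SimulationConfig,
    include_visits: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """PD-MCI cohort + 6-monthly visits + planted truth.

    A fixed-count latent subset (``round(frac_low_ch4 * n_pd)`` subjects,
    randomly placed) receives the configured downward GMD shift and the
    clinical-score burden shifts.  Time to first cognitive milestone is
    exponential with hazard ``baseline_hazard * exp(lp)`` where the linear
    predictor holds the low-group log-HR plus centered age/sex/MoCA effects;
    events are detected at the first 6-month visit after the latent time,
    under random and administrative censoring.  The visit table encodes the
    observed milestone (a qualifying score at the event visit, unremarkable
    scores before), so milestone detection on the visits reproduces the
    cohort's observed times exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_pd
    age, sex, scanner, tiv = _draw_covariates(rng, n, config)

    n_low = int(round(config.frac_low_ch4 * n))
    n_low = min(max(n_low, 1), n - 1)
    latent_low = np.zeros(n, dtype=bool)
    latent_low[rng.choice(n, size=n_low, replace=False)] = True

    gmd = (
        _gmd_linear_predictor(config, age, sex, scanner, tiv)
        + rng.normal(0.0, config.residual_sd, size=n)
        + np.where(latent_low, config.low_gmd_shift, 0.0)
    )

    sh = config.clinical_shifts
    low_f = latent_low.astype(float)
    duration = rng.exponential(0.75, size=n)           # years; median ~0.5
    updrs1 = _clip_round(rng.normal(1.8, 1.8, n) + sh["updrs1"] * low_f, 0, 52)
    updrs2 = _clip_round(rng.normal(5.5, 3.5, n) + sh["updrs2"] * low_f, 0, 52)
    updrs3 = _clip_round(rng.normal(23.0, 8.0, n) + sh["updrs3"] * low_f, 0, 132)
    scopa = _clip_round(rng.normal(14.0, 9.0, n) + sh["scopa_aut"] * low_f, 0, 69)
    rbdsq = _clip_round(rng.normal(3.5, 2.5, n) + sh["rbdsq"] * low_f, 0, 13)
    upsit = _clip_round(rng.normal(21.0, 8.0, n) + sh["upsit"] * low_f, 0, 40)
    # MoCA clipped to the 21-26 inclusion window for PD-MCI
    moca = _clip_round(rng.normal(24.5, 1.5, n) + sh["moca"] * low_f, 21, 26)

    items = {}
    for item, (p_norm, p_low) in config.item_presence.items():
        p = np.where(latent_low, p_low, p_norm)
        items[item] = _draw_item(rng, n, p)

    # --- survival truth -------------------------------------------------
    lp = (
        config.log_hr_low * low_f
        + config.log_hr_age * (age - 65.0)
        + config.log_hr_sex * sex
        + config.log_hr_moca * (moca - 24.0)
    )
    rate = config.baseline_hazard * np.exp(lp)
    latent_t = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        censor_t = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        censor_t = np.full(n, np.inf)

    dt = config.visit_interval
    event_visit = dt * np.ceil(latent_t / dt)
    follow_limit = np.minimum(censor_t, config.max_follow_up)
    last_visit = dt * np.floor(follow_limit / dt)
    observed_event = event_visit <= last_visit
    obs_time = np.where(observed_event, event_visit, last_visit)

    cohort = pd.DataFrame({
        "subject_id": [f"PD{i:05d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "scanner": scanner,
        "tiv": tiv,
        "ch4_gmd": gmd,
        "disease_duration": duration,
        "updrs1": updrs1,
        "updrs2": updrs2,
        "updrs3": updrs3,
        "scopa_aut": scopa,
        "rbdsq": rbdsq,
        "upsit": upsit,
        "moca": moca,
        **{k: v for k, v in items.items()},
        "event_time": obs_time,
        "event": observed_event,
    })

    # the visit table is drawn after the cohort, so skipping it (for large
    # replicate studies that only need the cohort) leaves the cohort identical
    if include_visits:
        visits = _build_visits(rng, cohort, config)
    else:
        visits = pd.DataFrame(columns=[
            "subject_id", "visit_month", "moca", "updrs_1_1", "updrs_1_2",
            "updrs_1_5", "dementia_clinical", "dementia_composite",
        ])

    truth = SyntheticTruth(
        latent_low=latent_low,
        gmd_coefficients={
            "constant": config.gmd_constant, "b_age": config.b_age,
            "b_sex": config.b_sex, "b_ge": config.b_ge,
            "b_philips": config.b_philips, "b_tiv": config.b_tiv,
            "residual_sd": config.residual_sd,
            "low_gmd_shift": config.low_gmd_shift,
        },
        log_hazard_ratios={
            "low_ch4": config.log_hr_low, "age": config.log_hr_age,
            "sex": config.log_hr_sex, "moca": config.log_hr_moca,
        },
        latent_event_time=latent_t,
        censor_time=censor_t,
        baseline_hazard=config.baseline_hazard,
    )
    return cohort, visits, truth


# relative frequency of which milestone fires first at the event visit
_MILESTONE_MIX = (
    ("moca", 0.50), ("updrs_1_1", 0.20), ("updrs_1_2", 0.10),
    ("updrs_1_5", 0.10), ("dementia_clinical", 0.05), ("dementia_composite", 0.05),
)


def _build_visits(rng, cohort: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    """Long-format visit table consistent with the cohort's observed events."""
    dt = cfg.visit_interval
    rows = {k: [] for k in (
        "subject_id", "visit_month", "moca", "updrs_1_1", "updrs_1_2",
        "updrs_1_5", "dementia_clinical", "dementia_composite",
    )}
    labels = [m for m, _ in _MILESTONE_MIX]
    probs = np.array([p for _, p in _MILESTONE_MIX])
    for sid, t_obs, ev in zip(
        cohort["subject_id"], cohort["event_time"], cohort["event"]
    ):
        months = np.arange(0.0, t_obs + 0.5 * dt, dt)
        if months.size == 0:
            months = np.array([0.0])
        k = months.size
        moca = rng.integers(21, 27, size=k).astype(float)
        i11 = _draw_item(rng, k, 0.3)
        i12 = _draw_item(rng, k, 0.05)
        i15 = _draw_item(rng, k, 0.1)
        # pre-event visits must not qualify: items capped at 2, MoCA >= 21
        dem_c = np.zeros(k, dtype=bool)
        dem_x = np.zeros(k, dtype=bool)
        if ev:
            kind = labels[rng.choice(len(labels), p=probs)]
            if kind == "moca":
                moca[-1] = float(rng.integers(16, 21))
            elif kind == "updrs_1_1":
                i11[-1] = int(rng.integers(3, 5))
            elif kind == "updrs_1_2":
                i12[-1] = int(rng.integers(3, 5))
            elif kind == "updrs_1_5":
                i15[-1] = int(rng.integers(3, 5))
            elif kind == "dementia_clinical":
                dem_c[-1] = True
            else:
                dem_x[-1] = True
        rows["subject_id"].extend([sid] * k)
        rows["visit_month"].extend(months.tolist())
        rows["moca"].extend(moca.tolist())
        rows["updrs_1_1"].extend(np.asarray(i11).tolist())
        rows["updrs_1_2"].extend(np.asarray(i12).tolist())
        rows["updrs_1_5"].extend(np.asarray(i15).tolist())
        rows["dementia_clinical"].extend(dem_c.tolist())
        rows["dementia_composite"].extend(dem_x.tolist())
    return pd.DataFrame(rows)


def generate_gm_image(
    planted_gmd: float,
    grid_shape: tuple = (8, 8, 8),
    seed: int = 0,
) -> tuple[GreyMatterMap, ProbabilisticMask]:
    """A small GM volume + probabilistic mask with a known weighted GMD.

    The mask holds random nonnegative weights on a central block; voxel
    values over the mask support are ``planted_gmd`` plus a perturbation with
    zero *weighted* mean, so the weighted-mean extraction recovers
    ``planted_gmd`` to float precision while the voxel pattern varies with
    the seed.  The affine is 1.5 mm isotropic with a fixed translation and
    is shared between map and mask.
    """
    if not 0.0 <= planted_gmd <= 1.0:
        raise ValueError(f"planted_gmd must be in [0, 1], got {planted_gmd}")
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError(f"grid_shape must be 3 dims each >= 4, got {grid_shape}")
    rng = np.random.default_rng(seed)

    weights = np.zeros(shape)
    lo = [s // 4 for s in shape]
    hi = [max(s // 4 + 2, 3 * s // 4) for s in shape]
    block = tuple(slice(l, h) for l, h in zip(lo, hi))
    weights[block] = rng.random([h - l for l, h in zip(lo, hi)]) + 0.05

    gm = rng.random(shape) * 0.5            # background outside the region
    w = weights[block]
    u = rng.uniform(-1.0, 1.0, size=w.shape)
    u = u - (w * u).sum() / w.sum()          # zero weighted mean
    headroom = min(planted_gmd, 1.0 - planted_gmd)
    peak = np.max(np.abs(u))
    scale = 0.0 if peak == 0 else 0.9 * headroom / peak
    gm[block] = planted_gmd + scale * u

    affine = np.diag([1.5, 1.5, 1.5, 1.0])
    affine[:3, 3] = (-90.0, -126.0, -72.0)
    gm_map = GreyMatterMap(voxels=gm, affine=affine, source=f"<synthetic seed={seed}>")
    mask = ProbabilisticMask(weights=weights, affine=affine, region_name="Ch4",
                             source=f"<synthetic seed={seed}>")
    return gm_map, mask
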