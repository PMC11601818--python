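"""Regression-based norming of Ch4 grey-matter density.

The reference (healthy-control) sample anchors two transforms:

1. **Scaled scores** — raw GMD is mapped to an instrument-style scale with
   mean 10 and SD 3 in the reference sample:
   ``scaled = 10 + 3 * (raw - mean_HC) / sd_HC``.
2. **Covariate adjustment** — reference scaled scores are regressed (OLS) on
   age, sex, scanner type (GE and Philips indicators, Siemens as baseline)
   and total intracranial volume.  A subject's adjusted z-score is the gap
   between their actual and predicted scaled score in residual-SD units:
   ``z = (scaled_actual - scaled_predicted) / RMSE``.

Subjects with z <= -1 are classified as *low Ch4*, the rest as *normal Ch4*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "SCANNER_LEVELS",
    "NormingModel",
    "Ch4Classification",
    "CollinearityError",
    "to_scaled_score",
    "fit_norming_model",
    "adjusted_z",
    "score_table",
]

#: Scanner categories the model knows; Siemens is the regression baseline.
SCANNER_LEVELS = ("Siemens", "GE", "Philips")

#: Column names expected in reference / subject tables.
REQUIRED_COLUMNS = ("ch4_gmd", "age", "sex", "scanner", "tiv")


class CollinearityError(ValueError):
    """Design matrix is rank deficient (e.g. a single scanner type)."""


@dataclass(frozen=True)
class NormingModel:
    """Fitted reference model: scaling anchors, OLS coefficients, RMSE.

    Coefficients are on the scaled-score scale: ``constant``,
    ``b_age`` (per year), ``b_sex`` (per unit of the male=1 code),
    ``b_ge`` / ``b_philips`` (scanner offsets vs Siemens), ``b_tiv`` (per mL).
    ``rmse`` is the residual SD with denominator n - p - 1 (p = 5 predictors);
    ``scaling`` records whether the GMD→scaled-score map was linear or
    rank-based (normal scores).
    """

    hc_gmd_mean: float
    hc_gmd_sd: float
    constant: float
    b_age: float
    b_sex: float
    b_ge: float
    b_philips: float
    b_tiv: float
    rmse: float
    n_reference: int
    scaling: str = "linear"
    threshold: float = -1.0

    def __post_init__(self) -> None:
        if not self.hc_gmd_sd > 0:
            raise ValueError("degenerate reference: hc_gmd_sd must be > 0")
        if not self.rmse > 0:
            raise ValueError("rmse must be > 0")
        if self.n_reference <= 6:
            raise ValueError("reference sample must exceed predictors + 1")

    # -- prediction -----------------------------------------------------
    def predict_scaled(self, age, sex, scanner, tiv):
        """Predicted scaled score from the covariates (vectorized)."""
        scanner = np.asarray(scanner, dtype=object)
        unknown = set(np.unique(scanner)) - set(SCANNER_LEVELS)
        if unknown:
            raise ValueError(
                f"unknown scanner categor{'ies' if len(unknown) > 1 else 'y'} "
                f"{sorted(unknown)}; model knows {list(SCANNER_LEVELS)}"
            )
        ge = (scanner == "GE").astype(float)
        ph = (scanner == "Philips").astype(float)
        return (
            self.constant
            + self.b_age * np.asarray(age, dtype=float)
            + self.b_sex * np.asarray(sex, dtype=float)
            + self.b_ge * ge
            + self.b_philips * ph
            + self.b_tiv * np.asarray(tiv, dtype=float)
        )

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormingModel":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


@dataclass(frozen=True)
class Ch4Classification:
    """Adjusted z-score and the low/normal label (low iff z <= threshold)."""

    z: float
    label: str
    threshold: float = -1.0

    def __post_init__(self) -> None:
        expected = "low" if self.z <= self.threshold else "normal"
        if self.label != expected:
            raise ValueError(
                f"label '{self.label}' inconsistent with z={self.z} and "
                f"threshold {self.threshold}"
            )


def to_scaled_score(raw_gmd, model: NormingModel):
    """Map raw GMD to the reference-anchored scale (mean 10, SD 3)."""
    raw = np.asarray(raw_gmd, dtype=float)
    out = 10.0 + 3.0 * (raw - model.hc_gmd_mean) / model.hc_gmd_sd
    return float(out) if np.isscalar(raw_gmd) else out


def _rank_scaled(gmd: np.ndarray) -> np.ndarray:
    # blom-style normal scores mapped onto mean 10 / SD 3
    n = gmd.size
    ranks = sps.rankdata(gmd, method="average")
    return 10.0 + 3.0 * sps.norm.ppf((ranks - 0.375) / (n + 0.25))


def fit_norming_model(
    hc: pd.DataFrame,
    *,
    scaling: str = "linear",
    threshold: float = -1.0,
) -> NormingModel:
    """Fit the norming model on a healthy-control reference table.

    ``hc`` must contain complete columns ``ch4_gmd, age, sex, scanner, tiv``.
    Scaled scores are regressed on age, sex, GE/Philips indicators and TIV;
    the residual SD (denominator n - p - 1) becomes the model RMSE.

    Raises :class:`CollinearityError` when the design is rank deficient, for
    instance when only one scanner type is present in the reference.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in hc.columns]
    if missing_cols:
        raise ValueError(f"reference table is missing columns {missing_cols}")
    sub = hc[list(REQUIRED_COLUMNS)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(
            f"reference table has missing values in {bad}; norming requires "
            "complete covariates (no imputation)"
        )
    n = len(sub)
    if n <= 6:
        raise ValueError(f"need more than 6 reference subjects, got {n}")
    if scaling not in ("linear", "rank"):
        raise ValueError(f"scaling must be 'linear' or 'rank', got {scaling!r}")

    gmd = sub["ch4_gmd"].to_numpy(dtype=float)
    gmd_mean = float(np.mean(gmd))
    gmd_sd = float(np.std(gmd, ddof=1))
    if gmd_sd <= 0:
        raise ValueError("degenerate reference: all GMD values identical")

    if scaling == "linear":
        scaled = 10.0 + 3.0 * (gmd - gmd_mean) / gmd_sd
    else:
        scaled = _rank_scaled(gmd)

    scanner = sub["scanner"].to_numpy(dtype=object)
    unknown = set(np.unique(scanner)) - set(SCANNER_LEVELS)
    if unknown:
        raise ValueError(
            f"unknown scanner categories {sorted(unknown)} in reference; "
            f"expected {list(SCANNER_LEVELS)}"
        )
    X = np.column_stack([
        sub["age"].to_numpy(dtype=float),
        sub["sex"].to_numpy(dtype=float),
        (scanner == "GE").astype(float),
        (scanner == "Philips").astype(float),
        sub["tiv"].to_numpy(dtype=float),
    ])
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        names = ["const", "age", "sex", "GE", "Philips", "tiv"]
        degenerate = [
            names[j] for j in range(1, Xc.shape[1])
            if np.all(Xc[:, j] == Xc[0, j])
        ]
        raise CollinearityError(
            f"design matrix is rank deficient (rank {rank} of {Xc.shape[1]}); "
            f"constant/degenerate columns: {degenerate or 'linear dependence'}"
        )
    fit = sm.OLS(scaled, Xc).fit()
    # statsmodels mse_resid already uses df n - p - 1
    rmse = float(np.sqrt(fit.mse_resid))
    if rmse == 0.0:
        # noise-free reference: keep the model usable, z becomes exact 0/inf
        rmse = np.finfo(float).tiny ** 0.5
    const, b_age, b_sex, b_ge, b_philips, b_tiv = (float(c) for c in fit.params)
    return NormingModel(
        hc_gmd_mean=gmd_mean, hc_gmd_sd=gmd_sd, constant=const,
        b_age=b_age, b_sex=b_sex, b_ge=b_ge, b_philips=b_philips,
        b_tiv=b_tiv, rmse=rmse, n_reference=n, scaling=scaling,
        threshold=threshold,
    )


def adjusted_z(subject, model: NormingModel) -> Ch4Classification:
    """Adjusted Ch4 z-score and low/normal label for one subject.

    ``subject`` is a mapping (dict / pandas row) with ``ch4_gmd, age, sex,
    scanner, tiv``.  z = (scaled_actual - scaled_predicted) / RMSE; the low
    label applies at z <= threshold (boundary inclusive).
    """
    actual = to_scaled_score(float(subject["ch4_gmd"]), model)
    predicted = float(model.predict_scaled(
        subject["age"], subject["sex"], np.array([subject["scanner"]], dtype=object),
        subject["tiv"],
    )[0])
    z = (actual - predicted) / model.rmse
    label = "low" if z <= model.threshold else "normal"
    return Ch4Classification(z=float(z), label=label, threshold=model.threshold)


def score_table(table: pd.DataFrame, model: NormingModel) -> pd.DataFrame:
    """Vectorized scoring: returns a copy with ``ch4_scaled``, ``ch4_z``,
    ``ch4_group`` columns appended."""
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table is missing columns {missing_cols}")
    out = table.copy()
    scaled = to_scaled_score(out["ch4_gmd"].to_numpy(dtype=float), model)
    predicted = model.predict_scaled(
        out["age"].to_numpy(dtype=float),
        out["sex"].to_numpy(dtype=float),
        out["scanner"].to_numpy(dtype=object),
        out["tiv"].to_numpy(dtype=float),
    )
    z = (scaled - predicted) / model.rmse
    out["ch4_scaled"] = scaled
    out["ch4_z"] = z
    out["ch4_group"] = np.where(z <= model.threshold, "low", "normal")
    return out
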