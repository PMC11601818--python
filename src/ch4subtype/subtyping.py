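"""Data-driven PD subtypes from duration-specific 75th-percentile rules.

Each subject is placed on four burden axes: a composite motor score
(MDS-UPDRS-II + MDS-UPDRS-III) and three non-motor axes — autonomic
(SCOPA-AUT), REM-sleep behaviour (RBDSQ), and cognition.  Because a *low*
MoCA means *worse* cognition, the cognitive axis is the burden ``30 - MoCA``,
so exceeding its 75th percentile means cognition in the worst quartile.

Thresholds (75th percentiles, linear-interpolation quantiles) are computed
within disease-duration bins so that early- and later-disease subjects are
compared against peers.  The label rules, with strict inequalities and ties
falling to intermediate:

* diffuse malignant — motor > threshold AND >= 1 non-motor axis above, OR
  all 3 non-motor axes above;
* mild motor predominant — motor < threshold AND all 3 non-motor axes below;
* intermediate — everything else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AXES",
    "SubtypeInputs",
    "SubtypeThresholds",
    "SubtypeLabel",
    "composite_motor_score",
    "cognitive_burden",
    "compute_thresholds",
    "assign_subtype",
    "assign_subtypes_table",
]

AXES = ("motor", "scopa_aut", "rbdsq", "cognitive")

_SCORE_RANGES = {
    "updrs2": (0, 52),
    "updrs3": (0, 132),
    "scopa_aut": (0, 69),
    "rbdsq": (0, 13),
    "moca": (0, 30),
}


@dataclass(frozen=True)
class SubtypeInputs:
    updrs2: float
    updrs3: float
    scopa_aut: float
    rbdsq: float
    moca: float
    disease_duration: float

    def __post_init__(self) -> None:
        for name, (lo, hi) in _SCORE_RANGES.items():
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite {name}")
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside instrument range [{lo},{hi}]")
        if self.disease_duration < 0:
            raise ValueError("disease duration must be >= 0")


@dataclass(frozen=True)
class SubtypeLabel:
    label: str
    exceedances: dict  # axis -> bool (strictly above the bin's 75th pct)
    duration_bin: int


def composite_motor_score(updrs2: float, updrs3: float) -> float:
    """Sum of MDS-UPDRS part II and part III."""
    if updrs2 is None or updrs3 is None or not (
        np.isfinite(updrs2) and np.isfinite(updrs3)
    ):
        raise ValueError("composite motor score needs both UPDRS-II and UPDRS-III")
    return float(updrs2) + float(updrs3)


def cognitive_burden(moca: float) -> float:
    """Cognitive burden axis: 30 - MoCA (higher = worse cognition)."""
    return 30.0 - float(moca)


class SubtypeThresholds:
    """Duration-binned 75th percentiles for the four burden axes.

    ``bin_edges`` are interior edges in years; bin i covers
    [edge[i-1], edge[i]) with the first bin starting at 0 and the last
    unbounded above.
    """

    QUANTILE_METHOD = "linear"
    PERCENTILE = 75.0

    def __init__(self, bin_edges, percentiles, n_per_bin, min_bin_n: int = 20):
        self.bin_edges = [float(e) for e in bin_edges]
        if sorted(self.bin_edges) != self.bin_edges or any(e < 0 for e in self.bin_edges):
            raise ValueError("bin edges must be nonnegative and increasing")
        self.percentiles = [
            {axis: float(p[axis]) for axis in AXES} for p in percentiles
        ]
        self.n_per_bin = [int(n) for n in n_per_bin]
        self.min_bin_n = int(min_bin_n)
        if len(self.percentiles) != len(self.bin_edges) + 1:
            raise ValueError("need one percentile row per duration bin")
        if len(self.n_per_bin) != len(self.percentiles):
            raise ValueError("n_per_bin length mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.percentiles)

    def bin_index(self, duration: float) -> int:
        if duration < 0 or not np.isfinite(duration):
            raise ValueError(f"duration {duration} outside all bins")
        return int(np.searchsorted(self.bin_edges, duration, side="right"))

    def thresholds_for(self, duration: float) -> dict:
        return self.percentiles[self.bin_index(duration)]

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "bin_edges_years": self.bin_edges,
            "percentile": self.PERCENTILE,
            "quantile_method": self.QUANTILE_METHOD,
            "percentiles": self.percentiles,
            "n_per_bin": self.n_per_bin,
            "min_bin_n": self.min_bin_n,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubtypeThresholds":
        d = json.loads(Path(path).read_text())
        return cls(d["bin_edges_years"], d["percentiles"], d["n_per_bin"],
                   d.get("min_bin_n", 20))


def _axis_values(cohort: pd.DataFrame) -> pd.DataFrame:
    need = ["updrs2", "updrs3", "scopa_aut", "rbdsq", "moca", "disease_duration"]
    missing = [c for c in need if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")
    ax = pd.DataFrame(index=cohort.index)
    ax["motor"] = cohort["updrs2"].astype(float) + cohort["updrs3"].astype(float)
    ax["scopa_aut"] = cohort["scopa_aut"].astype(float)
    ax["rbdsq"] = cohort["rbdsq"].astype(float)
    ax["cognitive"] = 30.0 - cohort["moca"].astype(float)
    ax["disease_duration"] = cohort["disease_duration"].astype(float)
    return ax


def compute_thresholds(
    cohort: pd.DataFrame,
    duration_bins=None,
    min_bin_n: int = 20,
) -> SubtypeThresholds:
    """75th percentiles per duration bin from a reference PD cohort.

    ``duration_bins``: interior bin edges in years; by default the cohort's
    duration tertiles.  Each bin must hold at least ``min_bin_n`` subjects.
    """
    ax = _axis_values(cohort)
    dur = ax["disease_duration"].to_numpy()
    if duration_bins is None:
        edges = list(np.percentile(dur, [100 / 3, 200 / 3], method="linear"))
        # degenerate durations collapse to a single bin
        edges = sorted(set(float(e) for e in edges if e > dur.min()))
    else:
        edges = sorted(float(e) for e in duration_bins)
    idx = np.searchsorted(edges, dur, side="right")
    percentiles, n_per_bin = [], []
    for b in range(len(edges) + 1):
        in_bin = idx == b
        n = int(in_bin.sum())
        if n < min_bin_n:
            lo = 0.0 if b == 0 else edges[b - 1]
            hi = "inf" if b == len(edges) else edges[b]
            raise ValueError(
                f"duration bin {b} [{lo}, {hi}) holds only {n} subjects "
                f"(minimum {min_bin_n}); widen the bins"
            )
        row = {
            axis: float(np.percentile(ax.loc[in_bin, axis], 75.0, method="linear"))
            for axis in AXES
        }
        percentiles.append(row)
        n_per_bin.append(n)
    return SubtypeThresholds(edges, percentiles, n_per_bin, min_bin_n)


def assign_subtype(inputs: SubtypeInputs, thresholds: SubtypeThresholds) -> SubtypeLabel:
    """Apply the percentile rules to one subject.

    Strict inequalities throughout: a score exactly at its threshold counts
    neither as above (for malignant) nor below (for mild), so all-ties lands
    in intermediate.
    """
    b = thresholds.bin_index(inputs.disease_duration)
    t = thresholds.percentiles[b]
    values = {
        "motor": composite_motor_score(inputs.updrs2, inputs.updrs3),
        "scopa_aut": float(inputs.scopa_aut),
        "rbdsq": float(inputs.rbdsq),
        "cognitive": cognitive_burden(inputs.moca),
    }
    above = {axis: values[axis] > t[axis] for axis in AXES}
    below = {axis: values[axis] < t[axis] for axis in AXES}
    nonmotor = ("scopa_aut", "rbdsq", "cognitive")
    n_nm_above = sum(above[a] for a in nonmotor)
    if (above["motor"] and n_nm_above >= 1) or n_nm_above == 3:
        label = "diffuse_malignant"
    elif below["motor"] and all(below[a] for a in nonmotor):
        label = "mild_motor_predominant"
    else:
        label = "intermediate"
    return SubtypeLabel(label=label, exceedances=above, duration_bin=b)


def assign_subtypes_table(
    cohort: pd.DataFrame, thresholds: SubtypeThresholds
) -> pd.DataFrame:
    """Label every row; returns a copy with ``subtype`` and per-axis
    ``exceeds_<axis>`` flag columns appended.

    Vectorized application of the same strict-inequality rules as
    :func:`assign_subtype` (a property test holds the two paths together).
    """
    ax = _axis_values(cohort)
    dur = ax["disease_duration"].to_numpy()
    if np.any(dur < 0) or np.any(~np.isfinite(dur)):
        raise ValueError("disease durations outside all bins")
    bins = np.searchsorted(thresholds.bin_edges, dur, side="right")
    t = {
        axis: np.array([thresholds.percentiles[b][axis] for b in bins])
        for axis in AXES
    }
    above = {axis: ax[axis].to_numpy() > t[axis] for axis in AXES}
    below = {axis: ax[axis].to_numpy() < t[axis] for axis in AXES}
    nonmotor = ("scopa_aut", "rbdsq", "cognitive")
    n_nm_above = sum(above[a].astype(int) for a in nonmotor)
    malignant = (above["motor"] & (n_nm_above >= 1)) | (n_nm_above == 3)
    mild = below["motor"]
    for a in nonmotor:
        mild = mild & below[a]
    out = cohort.copy()
    out["subtype"] = np.select(
        [malignant, mild], ["diffuse_malignant", "mild_motor_predominant"],
        default="intermediate",
    )
    for axis in AXES:
        out[f"exceeds_{axis}"] = above[axis]
    return out
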