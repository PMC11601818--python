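"""End-to-end orchestration: selection → GMD → norming → subtyping →
milestones → survival → group statistics.

The pipeline is deliberately linear and file-anchored: a config names the
input tables (or asks for a simulated cohort), every stage writes its output
into a fresh run directory, and a manifest records the config hash, row
counts in/out per stage and any warnings, so a rerun with the same config and
seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .norming import fit_norming_model, score_table
from .simulate import SimulationConfig, generate_hc_cohort, generate_pdmci_cohort
from .stats import (
    ContingencyTable2x2,
    kruskal_wallis,
    median_iqr,
    pearson_chi2,
    two_sample_power,
)
from .subtyping import assign_subtypes_table, compute_thresholds
from .survival import (
    MilestoneCriteria,
    cox_fit,
    detect_milestones_table,
    km_estimate,
    logrank_test,
)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "SelectionResult",
    "select_pd_mci",
    "select_healthy_controls",
    "run_full_pipeline",
]


class SelectionResult(NamedTuple):
    selected: pd.DataFrame
    excluded: pd.DataFrame     # subject_id, reason


def select_pd_mci(cohort: pd.DataFrame, cognitive_z_cols=()) -> SelectionResult:
    """Apply the PD-MCI eligibility rules.

    Kept: MoCA in [21, 26], or MoCA >= 21 with two or more neurocognitive
    test scores more than 1.5 SD below the normative mean (standardized
    scores < -1.5 in the named columns).  MoCA below 21 is always excluded
    (dementia risk).  Exclusion reasons are returned per subject.
    """
    if "moca" not in cohort.columns:
        raise ValueError("cohort table needs a 'moca' column")
    moca = cohort["moca"].astype(float)
    if moca.isna().any():
        raise ValueError("missing MoCA values; selection requires complete MoCA")
    z_cols = [c for c in cognitive_z_cols if c in cohort.columns]
    if z_cols:
        n_impaired = (cohort[z_cols].astype(float) < -1.5).sum(axis=1)
    else:
        n_impaired = pd.Series(0, index=cohort.index)
    crit1 = (moca >= 21) & (moca <= 26)
    crit2 = (moca >= 21) & (n_impaired >= 2)
    keep = crit1 | crit2
    reasons = np.where(
        moca < 21, "moca_below_21",
        np.where(~keep, "no_mci_criterion_met", ""),
    )
    excluded = cohort.loc[~keep, ["subject_id"]].copy() if "subject_id" in cohort \
        else pd.DataFrame(index=cohort.index[~keep])
    excluded["reason"] = reasons[~keep.to_numpy()]
    return SelectionResult(cohort.loc[keep].copy(), excluded.reset_index(drop=True))


def select_healthy_controls(cohort: pd.DataFrame) -> SelectionResult:
    """Keep controls with MoCA >= 27 whose cognitive status is not MCI."""
    for col in ("moca", "mci_flag"):
        if col not in cohort.columns:
            raise ValueError(f"control table needs a '{col}' column")
    moca = cohort["moca"].astype(float)
    flag = cohort["mci_flag"].astype(bool)
    keep = (moca >= 27) & ~flag
    reasons = np.where(flag, "mci_flag", np.where(moca < 27, "moca_below_27", ""))
    excluded = cohort.loc[~keep, ["subject_id"]].copy() if "subject_id" in cohort \
        else pd.DataFrame(index=cohort.index[~keep])
    excluded["reason"] = reasons[~keep.to_numpy()]
    return SelectionResult(cohort.loc[keep].copy(), excluded.reset_index(drop=True))


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML."""

    out_dir: str
    seed: int = 0
    # either simulate (default) or point at existing tables
    simulate: bool = True
    hc_table: str | None = None
    pd_table: str | None = None
    visits_table: str | None = None
    # simulation overrides forwarded to SimulationConfig
    simulation_overrides: dict = field(default_factory=dict)
    # analysis knobs
    z_threshold: float = -1.0
    duration_bins: list | None = None
    min_bin_n: int = 20
    moca_milestone_cutoff: float = 21.0
    cox_covariates: list = field(default_factory=lambda: ["low_ch4", "age", "sex", "moca"])
    cognitive_z_cols: list = field(default_factory=list)
    scaling: str = "linear"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        if not self.simulate:
            for name in ("hc_table", "pd_table", "visits_table"):
                p = getattr(self, name)
                if p is None:
                    raise FileNotFoundError(f"config.{name} is required when simulate=False")
                if not Path(p).exists():
                    raise FileNotFoundError(f"config.{name} does not exist: {p}")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict              # stage -> {"rows_in": .., "rows_out": ..}
    warnings: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


_CONTINUOUS_VARS = (
    "age", "disease_duration", "updrs1", "updrs2", "updrs3",
    "scopa_aut", "rbdsq", "upsit", "moca",
)
_PART1_ITEMS = (
    "updrs_1_1", "updrs_1_2", "updrs_1_3", "updrs_1_4", "updrs_1_5", "updrs_1_6",
)


def _group_comparisons(scored: pd.DataFrame, warnings: list) -> dict:
    low = scored[scored["ch4_group"] == "low"]
    normal = scored[scored["ch4_group"] == "normal"]
    out = {"n_low": int(len(low)), "n_normal": int(len(normal)),
           "continuous": {}, "items": {}, "subtype": {}}
    for col in _CONTINUOUS_VARS:
        if col not in scored.columns:
            continue
        med_n, q1_n, q3_n = median_iqr(normal[col])
        med_l, q1_l, q3_l = median_iqr(low[col])
        try:
            res = kruskal_wallis(normal[col], low[col])
            p = res.p_value
        except ValueError as exc:
            warnings.append(f"kruskal-wallis skipped for {col}: {exc}")
            p = None
        out["continuous"][col] = {
            "normal_median_iqr": [med_n, q1_n, q3_n],
            "low_median_iqr": [med_l, q1_l, q3_l],
            "p": p,
        }
    for item in _PART1_ITEMS:
        if item not in scored.columns:
            continue
        pres_n = int((normal[item] >= 1).sum())
        pres_l = int((low[item] >= 1).sum())
        tab = ContingencyTable2x2(
            a=pres_n, b=int(len(normal)) - pres_n,
            c=pres_l, d=int(len(low)) - pres_l,
            row_labels=("normal", "low"),
        )
        try:
            p = pearson_chi2(tab).p_value
        except ValueError as exc:
            warnings.append(f"chi-square skipped for {item}: {exc}")
            p = None
        out["items"][item] = {
            "normal": [pres_n, int(len(normal))],
            "low": [pres_l, int(len(low))],
            "p": p,
        }
    if "subtype" in scored.columns:
        counts = scored.groupby(["ch4_group", "subtype"]).size()
        out["subtype"] = {
            f"{g}/{s}": int(v) for (g, s), v in counts.items()
        }
        dm_n = int(counts.get(("normal", "diffuse_malignant"), 0))
        dm_l = int(counts.get(("low", "diffuse_malignant"), 0))
        if len(normal) and len(low):
            tab = ContingencyTable2x2(
                a=dm_n, b=len(normal) - dm_n, c=dm_l, d=len(low) - dm_l,
                row_labels=("normal", "low"), col_labels=("diffuse_malignant", "other"),
            )
            try:
                out["subtype"]["diffuse_malignant_p"] = pearson_chi2(tab).p_value
            except ValueError as exc:
                warnings.append(f"subtype chi-square skipped: {exc}")
    out["power_moderate_effect"] = two_sample_power(
        max(len(normal), 2), max(len(low), 2), d=0.56, alpha=0.05
    )
    return out


def run_full_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage in order and write all outputs under ``out_dir``.

    Stages: select cohorts → ingest GMD → fit norms on controls → z-score
    and classify the PD-MCI cohort → subtype → detect milestones → KM /
    log-rank / Cox → group statistics.  Outputs: ``hc_selected.csv``,
    ``pd_scored.csv``, ``norming_model.json``, ``subtype_thresholds.json``,
    ``events.csv``, ``km_<group>.csv``, ``results.json``, ``manifest.json``.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    stages: dict[str, dict] = {}

    # --- ingest ---------------------------------------------------------
    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation_overrides)
        hc_raw = generate_hc_cohort(sim_cfg)
        pd_raw, visits, _truth = generate_pdmci_cohort(sim_cfg)
    else:
        hc_raw = pd.read_csv(config.hc_table)
        pd_raw = pd.read_csv(config.pd_table)
        visits = pd.read_csv(config.visits_table)

    hc_sel, hc_excl = select_healthy_controls(hc_raw)
    stages["select_healthy_controls"] = {
        "rows_in": int(len(hc_raw)), "rows_out": int(len(hc_sel)),
        "rows_excluded": int(len(hc_excl)),
    }
    pd_sel, pd_excl = select_pd_mci(pd_raw, config.cognitive_z_cols)
    stages["select_pd_mci"] = {
        "rows_in": int(len(pd_raw)), "rows_out": int(len(pd_sel)),
        "rows_excluded": int(len(pd_excl)),
    }
    if len(hc_sel) + len(hc_excl) != len(hc_raw) or len(pd_sel) + len(pd_excl) != len(pd_raw):
        raise RuntimeError("row-count conservation violated at selection")

    # --- norming --------------------------------------------------------
    model = fit_norming_model(hc_sel, scaling=config.scaling,
                              threshold=config.z_threshold)
    model.to_json(out_dir / "norming_model.json")
    scored = score_table(pd_sel, model)
    n_low = int((scored["ch4_group"] == "low").sum())
    stages["norming"] = {
        "rows_in": int(len(pd_sel)), "rows_out": int(len(scored)),
        "n_low": n_low, "n_normal": int(len(scored)) - n_low,
    }
    if n_low == 0 or n_low == len(scored):
        warnings.append("classification produced a single Ch4 group")

    # --- subtyping ------------------------------------------------------
    thresholds = compute_thresholds(scored, config.duration_bins, config.min_bin_n)
    thresholds.to_json(out_dir / "subtype_thresholds.json")
    scored = assign_subtypes_table(scored, thresholds)
    stages["subtyping"] = {
        "rows_in": int(len(scored)), "rows_out": int(len(scored)),
        "labels": {k: int(v) for k, v in scored["subtype"].value_counts().items()},
    }

    # --- milestones + survival -----------------------------------------
    criteria = MilestoneCriteria(moca_cutoff=config.moca_milestone_cutoff)
    visits_sel = visits[visits["subject_id"].isin(scored["subject_id"])]
    events = detect_milestones_table(visits_sel, criteria)
    events.to_csv(out_dir / "events.csv", index=False)
    n_baseline = int(events["at_baseline"].sum())
    if n_baseline:
        warnings.append(f"{n_baseline} subjects met a milestone at baseline")
    stages["milestones"] = {
        "rows_in": int(len(visits_sel)), "rows_out": int(len(events)),
        "n_events": int(events["event"].sum()),
    }

    covars = scored[["subject_id", "age", "sex", "moca"]].copy()
    covars["low_ch4"] = (scored["ch4_group"] == "low").astype(int)
    ev = events.merge(scored[["subject_id", "ch4_group"]], on="subject_id")
    results: dict = {"groups": {}}
    for grp in ("low", "normal"):
        sub = ev[ev["ch4_group"] == grp]
        if len(sub):
            km = km_estimate(sub)
            km.to_csv(out_dir / f"km_{grp}.csv", index=False)
            results["groups"][grp] = {
                "n": int(len(sub)), "n_events": int(sub["event"].sum()),
            }
    if all(len(ev[ev["ch4_group"] == g]) for g in ("low", "normal")):
        chi2, p = logrank_test(ev[ev["ch4_group"] == "low"],
                               ev[ev["ch4_group"] == "normal"])
        results["logrank"] = {"chi2": chi2, "p": p}
        cox = cox_fit(events, covars, covariate_cols=config.cox_covariates)
        results["cox"] = {
            cov: {
                "hr": float(cox.table.loc[cov, "hr"]),
                "ci_low": float(cox.table.loc[cov, "ci_low"]),
                "ci_high": float(cox.table.loc[cov, "ci_high"]),
                "p": float(cox.table.loc[cov, "p"]),
            }
            for cov in cox.table.index
        }
        stages["survival"] = {"rows_in": int(len(events)), "rows_out": len(cox.table)}
    else:
        warnings.append("survival contrasts skipped: a Ch4 group is empty")

    # --- group statistics ----------------------------------------------
    results["group_comparisons"] = _group_comparisons(scored, warnings)
    stages["group_stats"] = {"rows_in": int(len(scored)), "rows_out": 1}

    hc_sel.to_csv(out_dir / "hc_selected.csv", index=False)
    scored.to_csv(out_dir / "pd_scored.csv", index=False)
    (out_dir / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))

    manifest = RunManifest(
        config_hash=config.content_hash(), version=__version__,
        seed=config.seed, stages=stages, warnings=warnings,
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
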