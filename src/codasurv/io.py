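"""Readers, writers and the federated pipeline orchestration.

Cohort tables travel as CSV (one row per subject; a missing ``sleep_min``
column marks a waking-day study), study fits travel as JSON carrying the
coefficients and variance-covariance matrix — the only artefacts that
cross study boundaries in a federated design.  Every JSON output embeds a
manifest (input checksums, config snapshot, package version, warnings) so
results are traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

import codasurv
from codasurv.coda import Composition, DetectionLimits, impute_zeros
from codasurv.pooling import PooledModel, pool_random_effects
from codasurv.survival import Cohort, StudyFit, SubjectRecord, fit_compositional_cox
from codasurv.effects import hazard_ratio, solve_reallocation, unit_hazard_ratios

__all__ = [
    "read_cohort",
    "write_cohort",
    "study_fit_to_json",
    "study_fit_from_json",
    "pooled_model_to_json",
    "pooled_model_from_json",
    "RunManifest",
    "run_pipeline",
    "SchemaError",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "sb_min", "lipa_min", "mvpa_min", "followup_years", "event")


class SchemaError(ValueError):
    pass


@dataclass
class RunManifest:
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    config: Dict = field(default_factory=dict)
    version: str = codasurv.__version__
    created: str = ""
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def as_dict(self) -> Dict:
        return asdict(self)


def read_cohort(
    path: str | Path,
    study_name: Optional[str] = None,
    device_placement: str = "hip",
) -> Cohort:
    """Read a cohort CSV into a typed :class:`Cohort`.

    Columns: ``id, [sleep_min,] sb_min, lipa_min, mvpa_min,
    followup_years, event`` then covariates.  Absence of ``sleep_min``
    marks a waking-day study.  Rows with negative minutes or missing
    follow-up are rejected with their line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {missing}; expected "
            f"{list(REQUIRED_COLUMNS)} (+ optional sleep_min and covariates)"
        )
    has_sleep = "sleep_min" in df.columns
    part_cols = (["sleep_min"] if has_sleep else []) + ["sb_min", "lipa_min", "mvpa_min"]
    bad_rows = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if any(pd.notna(row[c]) and row[c] < 0 for c in part_cols):
            bad_rows.append(f"line {line}: negative minutes")
        elif pd.isna(row["followup_years"]) or row["followup_years"] <= 0:
            bad_rows.append(f"line {line}: missing or non-positive follow-up")
        elif row["event"] not in (0, 1):
            bad_rows.append(f"line {line}: event must be 0 or 1")
    if bad_rows:
        raise SchemaError(f"{path.name}: invalid rows: " + "; ".join(bad_rows))
    covariate_cols = [
        c for c in df.columns if c not in REQUIRED_COLUMNS and c != "sleep_min"
    ]
    total = float((df[part_cols].sum(axis=1)).median())
    records = []
    for _, row in df.iterrows():
        kwargs = dict(
            mvpa=float(row["mvpa_min"]),
            lipa=float(row["lipa_min"]),
            sb=float(row["sb_min"]),
            total=float(row[part_cols].sum()),
        )
        if has_sleep:
            kwargs["sleep"] = float(row["sleep_min"])
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                composition=Composition(**kwargs),
                followup=float(row["followup_years"]),
                event=int(row["event"]),
                covariates={c: float(row[c]) for c in covariate_cols},
            )
        )
    name = study_name or path.stem
    logger.info("read %d subjects from %s (sleep=%s, total~%g)", len(records), path, has_sleep, total)
    return Cohort(records=records, study_name=name, device_placement=device_placement)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    rows = []
    for r in cohort.records:
        row = {"id": r.id}
        if cohort.measures_sleep:
            row["sleep_min"] = r.composition.sleep
        row.update(
            sb_min=r.composition.sb,
            lipa_min=r.composition.lipa,
            mvpa_min=r.composition.mvpa,
            followup_years=r.followup,
            event=r.event,
        )
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# StudyFit / PooledModel JSON exchange


def study_fit_to_json(fit: StudyFit, path: str | Path, manifest: Optional[RunManifest] = None) -> None:
    payload = {
        "study": fit.study_name,
        "n": fit.n,
        "n_events": fit.n_events,
        "measures_sleep": fit.measures_sleep,
        "device_placement": fit.device_placement,
        "gamma": fit.gamma,
        "beta": fit.beta,
        "gamma_names": fit.gamma_names,
        "vcov_gamma": fit.vcov_gamma.ravel().tolist(),
        "software_version": codasurv.__version__,
    }
    if manifest is not None:
        payload["manifest"] = manifest.as_dict()
    Path(path).write_text(json.dumps(payload, indent=1))


def study_fit_from_json(path: str | Path) -> StudyFit:
    d = json.loads(Path(path).read_text())
    k = len(d["gamma"])
    return StudyFit(
        study_name=d["study"],
        gamma={k_: float(v) for k_, v in d["gamma"].items()},
        beta={k_: float(v) for k_, v in d.get("beta", {}).items()},
        vcov_gamma=np.array(d["vcov_gamma"], float).reshape(k, k),
        n=int(d["n"]),
        n_events=int(d["n_events"]),
        measures_sleep=bool(d["measures_sleep"]),
        device_placement=d.get("device_placement", "hip"),
    )


def pooled_model_to_json(
    model: PooledModel, path: str | Path, manifest: Optional[RunManifest] = None
) -> None:
    payload = {
        "stratum": model.stratum,
        "k_studies": model.k_studies,
        "method": model.method,
        "gamma": model.gamma,
        "gamma_names": model.gamma_names,
        "vcov_gamma": model.vcov_gamma.ravel().tolist(),
        "psi": model.psi.ravel().tolist(),
        "heterogeneity": model.heterogeneity,
        "studies": model.study_names,
        "software_version": codasurv.__version__,
    }
    if manifest is not None:
        payload["manifest"] = manifest.as_dict()
    Path(path).write_text(json.dumps(payload, indent=1, allow_nan=True))


def pooled_model_from_json(path: str | Path) -> PooledModel:
    d = json.loads(Path(path).read_text())
    k = len(d["gamma"])
    return PooledModel(
        gamma={k_: float(v) for k_, v in d["gamma"].items()},
        vcov_gamma=np.array(d["vcov_gamma"], float).reshape(k, k),
        psi=np.array(d["psi"], float).reshape(k, k),
        k_studies=int(d["k_studies"]),
        stratum=d.get("stratum", "all"),
        heterogeneity=d.get("heterogeneity", {}),
        study_names=d.get("studies", []),
        method=d.get("method", "reml"),
    )


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: Dict, out_dir: str | Path) -> Dict:
    """Run the federated workflow from a config mapping.

    Stages per cohort: zero imputation -> landmark filter -> compositional
    Cox fit; then masking + random-effects pooling per stratum, unit-HR
    tables and optional substitution solving.  ``config`` keys:

    ``cohorts``: list of {path, device_placement, study_name};
    ``fits``: list of StudyFit JSON paths (alternative to cohorts);
    ``landmark_years`` (default 2); ``pool_method`` (default "reml");
    ``detection_limit_min`` (default 1.0); ``reference``: {mvpa, lipa, sb,
    [sleep], total}; ``substitutions``: list of {target_hr, mode}.

    Deterministic given inputs; artefacts are written under ``out_dir``
    and a summary dict is returned.
    """
    if not config or not (config.get("cohorts") or config.get("fits")):
        raise ValueError("config must list 'cohorts' or 'fits'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config={k: v for k, v in config.items() if k != "cohorts"})
    fits: List[StudyFit] = []

    for spec in config.get("cohorts", []):
        path = spec["path"]
        manifest.add_input(path)
        cohort = read_cohort(
            path,
            study_name=spec.get("study_name"),
            device_placement=spec.get("device_placement", "hip"),
        )
        try:
            cohort = _impute_cohort(cohort, config.get("detection_limit_min", 1.0))
            fit = fit_compositional_cox(
                cohort, landmark_years=config.get("landmark_years", 2.0)
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage 'fit' failed for cohort {cohort.study_name}: {exc}; "
                f"manifest: {manifest.as_dict()}"
            ) from exc
        fits.append(fit)
        study_fit_to_json(fit, out_dir / f"fit_{fit.study_name}.json", manifest)

    for path in config.get("fits", []):
        manifest.add_input(path)
        fits.append(study_fit_from_json(path))

    method = config.get("pool_method", "reml")
    pools: Dict[str, PooledModel] = {}
    if len(fits) >= 2:
        pools["all"] = pool_random_effects(fits, method=method, stratum="all")
        for placement in ("wrist", "hip"):
            sub = [f for f in fits if f.device_placement == placement]
            if len(sub) >= 2:
                pools[placement] = pool_random_effects(sub, method=method, stratum=placement)
    elif len(fits) == 1:
        pools["all"] = pool_random_effects(fits, method=method)
    for label, model in pools.items():
        pooled_model_to_json(model, out_dir / f"pooled_{label}.json", manifest)
        unit_hazard_ratios(model).to_csv(out_dir / f"unit_hr_{label}.csv")

    results: Dict = {
        "fits": [f.study_name for f in fits],
        "pools": sorted(pools),
        "out_dir": str(out_dir),
    }

    ref_spec = config.get("reference")
    if ref_spec and pools:
        model = pools.get(config.get("effects_stratum", "all"), next(iter(pools.values())))
        ref = Composition(**ref_spec)
        subs = []
        for req in config.get("substitutions", []):
            res = solve_reallocation(
                model, ref, target_hr=req.get("target_hr", 0.9), mode=req["mode"]
            )
            subs.append(
                {
                    "mode": res.mode,
                    "target_hr": res.target_hr,
                    "minutes": res.minutes_rounded,
                    "ci_low": None if res.ci_low is None else int(round(res.ci_low)),
                    "ci_high": None if res.ci_high is None else int(round(res.ci_high)),
                }
            )
        if subs:
            (out_dir / "substitutions.json").write_text(
                json.dumps({"reference": ref.as_dict(), "results": subs, "manifest": manifest.as_dict()}, indent=1)
            )
            results["substitutions"] = subs
    return results


def _impute_cohort(cohort: Cohort, limit: float) -> Cohort:
    mat = np.array([r.composition.parts() for r in cohort.records])
    if not (mat == 0).any():
        return cohort
    names = cohort.records[0].composition.part_names
    limits = DetectionLimits(mvpa=limit, lipa=limit, sb=limit, sleep=limit)
    imputed = impute_zeros(mat, limits, part_names=names)
    new_records = []
    for r, row in zip(cohort.records, imputed):
        kwargs = dict(zip(names, row))
        comp = Composition(total=r.composition.total, **kwargs)
        new_records.append(
            SubjectRecord(
                id=r.id, composition=comp, followup=r.followup, event=r.event,
                covariates=r.covariates,
            )
        )
    return Cohort(
        records=new_records,
        study_name=cohort.study_name,
        device_placement=cohort.device_placement,
        waking_total=cohort.waking_total,
    )
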