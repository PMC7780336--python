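"""End-to-end pipeline: simulate -> weights -> CMI -> ITS -> attribution.

Configuration is a single YAML mapping (all defaults embedded); outputs are
delimited-text tables plus a JSON manifest recording the config hash, seed,
per-stage row counts and timings.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import attribution as attr_mod
from . import cmi as cmi_mod
from . import its as its_mod
from . import synthetic, weights as weights_mod
from .records import (
    COLUMNS,
    CPT_PATTERN,
    ICD_PATTERN,
    OWNERSHIPS,
    read_records,
    write_records,
)

__all__ = ["PipelineConfig", "PipelineError", "run_all", "validate_records"]

log = logging.getLogger(__name__)

#: Strata fitted by default: (case_type, stay, ownership, component)
DEFAULT_STRATA = [
    ("medical", "all", "all", "all"),
    ("medical", "short", "all", "all"),
    ("medical", "medium", "all", "all"),
    ("medical", "long", "all", "all"),
    ("surgical", "all", "all", "all"),
    ("mixed", "all", "all", "all"),
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "casemix_out"
    records_path: str | None = None  # None -> simulate
    fees_path: str | None = None  # CSV code,fee; only used with records_path
    monthly_volume: int = 2000
    seed: int = 0
    weight_window: tuple = (2011, 2016)
    intervention_month: str = "2014-08"
    lag_months: int = 2
    seasonal: bool = True
    hac_lag: int | None = None
    sensitivity_lags: tuple = (0, 1, 2, 3, 4)
    pre_years: tuple = (2013, 2014)
    post_years: tuple = (2015, 2016)
    top_k: int = 20
    exclude_chemo: bool = True
    strata: list = field(default_factory=lambda: [list(s) for s in DEFAULT_STRATA])
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        for key in ("weight_window", "sensitivity_lags", "pre_years", "post_years"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def its_config(self) -> its_mod.ItsConfig:
        return its_mod.ItsConfig(
            intervention_month=self.intervention_month,
            lag_months=self.lag_months,
            seasonal=self.seasonal,
            hac_lag=self.hac_lag,
        )


def validate_records(path) -> dict:
    """Check a record file: column presence, date parsing, LOS consistency,
    code syntax.  Returns counts of rejected rows with reasons."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        return {
            "n_rows": len(df),
            "n_rejected": len(df),
            "missing_columns": missing,
            "reasons": {"missing_columns": len(df)},
        }
    reasons: dict[str, int] = {}
    bad = pd.Series(False, index=df.index)

    def flag(mask, reason):
        nonlocal bad
        mask = mask & ~bad  # first failing check wins per row
        if mask.any():
            reasons[reason] = int(mask.sum())
        bad |= mask

    adm = pd.to_datetime(df["admission_date"], errors="coerce")
    dis = pd.to_datetime(df["discharge_date"], errors="coerce")
    flag(adm.isna() | dis.isna(), "unparseable_date")
    flag(dis < adm, "discharge_before_admission")
    los = pd.to_numeric(df["length_of_stay"], errors="coerce")
    flag(los.isna() | (los < 0), "bad_length_of_stay")
    flag(((dis - adm).dt.days != los), "los_mismatch")
    charge = pd.to_numeric(df["total_charge"], errors="coerce")
    flag(charge.isna() | (charge < 0), "bad_charge")
    has_icd = df["icd_code"] != ""
    has_cpt = df["cpt_codes"] != ""
    flag(~has_icd & ~has_cpt, "no_code")
    bad_icd = has_icd & ~df["icd_code"].str.upper().str.match(ICD_PATTERN)
    flag(bad_icd, "bad_icd_syntax")
    bad_cpt = has_cpt & ~df["cpt_codes"].apply(
        lambda s: all(CPT_PATTERN.match(c) for c in s.split("|")) if s else True
    )
    flag(bad_cpt, "bad_cpt_syntax")
    flag(~df["ownership"].isin(OWNERSHIPS), "bad_ownership")
    flag(df["record_id"].duplicated(keep="first"), "duplicate_record_id")

    return {
        "n_rows": len(df),
        "n_rejected": int(bad.sum()),
        "missing_columns": [],
        "reasons": reasons,
    }


def _stage(manifest, name, func):
    t0 = time.perf_counter()
    try:
        result = func()
    except Exception as exc:  # noqa: BLE001 - stage isolation boundary
        raise PipelineError(name, exc) from exc
    manifest["stages"].append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
    log.info("stage %s done in %.2fs", name, manifest["stages"][-1]["seconds"])
    return result


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written to disk).

    On any stage failure, files already written for this run are removed and
    a :class:`PipelineError` naming the stage is raised.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
        "counts": {},
    }
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = out_dir / name
        writer(path)
        written.append(path)
        manifest["outputs"][name] = str(path)

    try:
        # 1. records: simulate or load
        if config.records_path is None:
            scenario = synthetic.preset_paper_like(
                monthly_volume=config.monthly_volume, seed=config.seed
            )
            records = _stage(manifest, "simulate", lambda: synthetic.generate(scenario))
            emit("records.csv", lambda p: write_records(records, p))
            fees = synthetic.fee_schedule(scenario)
        else:
            report = validate_records(config.records_path)
            if report["missing_columns"]:
                raise PipelineError(
                    "validate",
                    weights_mod.WeightingError(
                        f"missing column(s): {', '.join(report['missing_columns'])}"
                    ),
                )
            records = _stage(manifest, "load", lambda: read_records(config.records_path))
            fees = None
            if config.fees_path:
                fee_df = pd.read_csv(config.fees_path, dtype={"code": str})
                fees = dict(zip(fee_df["code"], fee_df["fee"].astype(float)))
        manifest["counts"]["records"] = len(records)

        # 2. weights
        wt = _stage(
            manifest,
            "weights",
            lambda: weights_mod.build_weight_table(records, config.weight_window, fees),
        )
        emit("weights.csv", wt.write)
        manifest["counts"]["weights"] = len(wt.table)
        manifest["counts"]["rejected_charges"] = wt.n_rejected_charges

        # 3. monthly CMI per stratum
        series_by_stratum = {}

        def compute_cmi():
            for case_type, stay, ownership, component in config.strata:
                s = cmi_mod.monthly_cmi(
                    records, wt, case_type, stay, ownership, component,
                    exclude_chemo=config.exclude_chemo,
                )
                series_by_stratum[(case_type, stay, ownership, component)] = s
            return series_by_stratum

        _stage(manifest, "cmi", compute_cmi)
        for key, s in series_by_stratum.items():
            emit("cmi_" + "_".join(key) + ".csv", lambda p, s=s: cmi_mod.write_series(s, p))
        emit("table1.csv", lambda p: cmi_mod.descriptive_table(records).to_csv(p, index=False))

        # 4. ITS + lag sensitivity
        its_cfg = config.its_config()

        def run_its():
            rows = []
            for key, s in series_by_stratum.items():
                f = its_mod.fit(s, its_cfg)
                summary = f.summary()
                summary.insert(0, "term", summary.index)
                summary.insert(0, "stratum", "/".join(key))
                rel = f.relative_summary()
                for name, val in rel.items():
                    rows.append({"stratum": "/".join(key), "term": name, "estimate": val})
                emit(
                    "its_" + "_".join(key) + ".csv",
                    lambda p, summary=summary: summary.to_csv(p, index=False),
                )
            return pd.DataFrame(rows)

        relative = _stage(manifest, "its", run_its)
        emit("its_relative_changes.csv", lambda p: relative.to_csv(p, index=False))

        main_series = next(iter(series_by_stratum.values()))
        sens = _stage(
            manifest,
            "its_sensitivity",
            lambda: its_mod.lag_sensitivity(main_series, its_cfg, config.sensitivity_lags),
        )
        emit("its_lag_sensitivity.csv", lambda p: sens.to_csv(p, index=False))

        # 5. attribution per case-type stratum
        def run_attribution():
            tops = {}
            for case_type, stay in (
                ("medical", "short"), ("medical", "medium"), ("medical", "long"),
                ("surgical", "all"),
            ):
                ctx = attr_mod.AttributionContext(
                    weights=wt,
                    pre_years=config.pre_years,
                    post_years=config.post_years,
                    case_type=case_type,
                    stay=stay,
                    exclude_chemo=config.exclude_chemo,
                )
                table = attr_mod.attribute(records, ctx)
                tops[(case_type, stay)] = attr_mod.top_k(table, config.top_k)
            return tops

        tops = _stage(manifest, "attribution", run_attribution)
        for (case_type, stay), table in tops.items():
            emit(
                f"attribution_{case_type}_{stay}.csv",
                lambda p, table=table: table.to_csv(p, index=False),
            )

        manifest["n_stages"] = len(manifest["stages"])
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except PipelineError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
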