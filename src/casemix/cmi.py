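"""Case classification and casemix-index (CMI) computation.

The CMI of a set of cases is the weighted mean severity

    CMI = sum_g(W_g * N_g) / sum_g(N_g),

with W_g the per-code weight (see :mod:`casemix.weights`) and N_g the number
of included cases carrying code g.  Cases are classified as

* **medical** — discharge diagnosis (ICD-10) and no procedure; stratified by
  length of stay into short (<2 d), medium (2-15 d) and long (>15 d);
* **surgical** — procedure(s) (CPT) and no diagnosis; the case weight sums
  over *all* listed procedures, secondary ones included;
* **mixed** — both present; the medical component uses the single discharge
  diagnosis, the surgical component the summed procedures, and the
  "all-components" series pools both contributions of each case as separate
  entries.

Chemotherapy session cases (Z51.1, Z51.2) are excluded before CMI
computation by default: they are low-cost short stays whose (improving)
coding would otherwise artificially depress the index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import CASE_TYPES, check_columns, discharge_month, split_cpt
from .weights import WeightTable, _stay_class

__all__ = [
    "CHEMOTHERAPY_CODES",
    "CaseClassification",
    "ClassificationError",
    "classify",
    "classify_records",
    "case_weight",
    "monthly_cmi",
    "descriptive_table",
    "procedure_ratio",
    "share_pct",
    "read_series",
    "write_series",
]

log = logging.getLogger(__name__)

CHEMOTHERAPY_CODES = ("Z51.1", "Z51.2")


class ClassificationError(ValueError):
    """A record carries neither a diagnosis nor a procedure code."""


@dataclass(frozen=True)
class CaseClassification:
    case_type: str  # medical | surgical | mixed
    stay_class: str | None  # short | medium | long; None for pure surgical


def classify(record) -> CaseClassification:
    """Classify a single record (mapping or Series with the table columns)."""
    icd = str(record["icd_code"] or "")
    cpt = str(record["cpt_codes"] or "")
    if icd and not cpt:
        case_type = "medical"
    elif cpt and not icd:
        case_type = "surgical"
    elif icd and cpt:
        case_type = "mixed"
    else:
        raise ClassificationError(
            f"record {record.get('record_id', '?')} has neither diagnosis nor procedure"
        )
    stay = None
    if case_type != "surgical":
        los = int(record["length_of_stay"])
        stay = "short" if los < 2 else ("medium" if los <= 15 else "long")
    return CaseClassification(case_type, stay)


def classify_records(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification: columns ``case_type`` and ``stay_class``."""
    check_columns(records)
    has_icd = records["icd_code"].fillna("") != ""
    has_cpt = records["cpt_codes"].fillna("") != ""
    if (~has_icd & ~has_cpt).any():
        bad = records.loc[~has_icd & ~has_cpt, "record_id"].iloc[0]
        raise ClassificationError(f"record {bad} has neither diagnosis nor procedure")
    case_type = np.where(has_icd & has_cpt, "mixed", np.where(has_icd, "medical", "surgical"))
    stay = _stay_class(records["length_of_stay"]).where(case_type != "surgical", other=None)
    return pd.DataFrame({"case_type": case_type, "stay_class": stay}, index=records.index)


def case_weight(record, weights: WeightTable, component: str = "all"):
    """Weight(s) of one record.

    ``component``: ``"medical"`` -> weight of the discharge diagnosis;
    ``"surgical"`` -> sum over all listed procedures; ``"all"`` -> for mixed
    records, the list of both component contributions (each pooled as a
    separate entry in an all-components CMI).
    """
    cls = classify(record)
    icd = str(record["icd_code"] or "").upper()
    cpts = [c for c in str(record["cpt_codes"] or "").split("|") if c]
    med = weights.weight(cls.stay_class, icd) if icd else None
    surg = sum(weights.weight("surgical", c) for c in cpts) if cpts else None
    if component == "medical":
        if med is None:
            raise ClassificationError("record has no medical component")
        return med
    if component == "surgical":
        if surg is None:
            raise ClassificationError("record has no surgical component")
        return surg
    contributions = [w for w in (med, surg) if w is not None]
    return contributions if len(contributions) > 1 else contributions[0]


def _contributions(
    records: pd.DataFrame,
    weights: WeightTable,
    case_type: str,
    stay: str = "all",
    ownership: str = "all",
    component: str = "all",
    exclude_chemo: bool = True,
) -> pd.DataFrame:
    """Per-contribution table: month, weight, record index; after exclusions.

    For medical/surgical series each case is one contribution; for mixed
    all-components each case yields up to two.
    """
    if case_type not in CASE_TYPES:
        raise ValueError(f"case_type must be one of {CASE_TYPES}")
    cls = classify_records(records)
    mask = cls["case_type"] == case_type
    if ownership != "all":
        mask &= records["ownership"] == ownership
    if case_type == "medical" and stay != "all":
        mask &= cls["stay_class"] == stay
    sub = records[mask]
    sub_cls = cls[mask]
    month = discharge_month(sub)

    pieces = []
    if case_type in ("medical", "mixed"):
        icd = sub["icd_code"].str.upper()
        keep = ~icd.isin(CHEMOTHERAPY_CODES) if exclude_chemo else pd.Series(True, index=sub.index)
        if case_type == "medical" or component in ("medical", "all"):
            med = sub[keep]
            w = weights.weights_for(sub_cls.loc[keep, "stay_class"], icd[keep])
            pieces.append(pd.DataFrame({"month": month[keep.to_numpy()], "weight": w.to_numpy(), "rec": med.index}))
    if case_type in ("surgical", "mixed") and (case_type == "surgical" or component in ("surgical", "all")):
        cpt_lists = split_cpt(sub["cpt_codes"])
        exploded = cpt_lists.explode()
        strata = pd.Series("surgical", index=exploded.index)
        w_each = weights.weights_for(strata, exploded)
        w_sum = w_each.groupby(level=0).sum()
        pieces.append(
            pd.DataFrame({"month": month, "weight": w_sum.reindex(sub.index).to_numpy(), "rec": sub.index})
        )
    out = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(columns=["month", "weight", "rec"])
    return out


def monthly_cmi(
    records: pd.DataFrame,
    weights: WeightTable,
    case_type: str = "medical",
    stay: str = "all",
    ownership: str = "all",
    component: str = "all",
    exclude_chemo: bool = True,
    months: pd.PeriodIndex | None = None,
) -> pd.DataFrame:
    """Monthly CMI series for one stratum.

    Records are bucketed by *discharge* month.  Returns a DataFrame with
    columns ``month`` (Period), ``cmi`` and ``n_cases`` covering every month
    of the span (``months`` overrides the span); months with no included
    case carry ``cmi = NaN`` and ``n_cases = 0`` and are logged.

    ``n_cases`` counts cases after exclusions; for mixed all-components
    series the CMI denominator counts the pooled contributions (two per
    case) while ``n_cases`` still counts cases.
    """
    contrib = _contributions(records, weights, case_type, stay, ownership, component, exclude_chemo)
    if months is None:
        all_months = discharge_month(records)
        months = pd.period_range(all_months.min(), all_months.max(), freq="M")
    grouped = contrib.groupby("month")["weight"]
    cmi = grouped.mean().reindex(months)
    n_cases = contrib.groupby("month")["rec"].nunique().reindex(months).fillna(0).astype(int)
    empty = n_cases[n_cases == 0]
    if len(empty):
        log.warning(
            "%d month(s) with zero included cases in %s/%s/%s series: %s",
            len(empty), case_type, stay, ownership, ", ".join(str(m) for m in empty.index[:6]),
        )
    out = pd.DataFrame({"month": months, "cmi": cmi.to_numpy(), "n_cases": n_cases.to_numpy()})
    out.attrs["stratum"] = {
        "case_type": case_type, "stay": stay, "ownership": ownership, "component": component,
    }
    return out


def write_series(series: pd.DataFrame, path) -> None:
    out = series.copy()
    out["month"] = out["month"].astype(str)
    for key, val in series.attrs.get("stratum", {}).items():
        out[key] = val
    out.to_csv(path, index=False)


def read_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    stratum = {k: df[k].iloc[0] for k in ("case_type", "stay", "ownership", "component") if k in df}
    out = df[["month", "cmi", "n_cases"]].copy()
    out.attrs["stratum"] = stratum
    return out


# ---------------------------------------------------------------------------
# descriptive composition tables


def procedure_ratio(n_procedures: float, n_cases: float) -> float:
    """Case:procedure ratio as printed in composition tables (1 decimal)."""
    return round(n_procedures / n_cases, 1)


def share_pct(part: float, total: float, decimals: int = 0) -> float:
    """Percentage share rounded to the printed precision."""
    return round(100.0 * part / total, decimals)


def descriptive_table(records: pd.DataFrame) -> pd.DataFrame:
    """Composition table: per ownership scope and year, counts and column
    percentages by case group, plus procedure counts and case:procedure
    ratios for surgical and mixed cases."""
    cls = classify_records(records)
    year = pd.DatetimeIndex(records["discharge_date"]).year
    n_procs = split_cpt(records["cpt_codes"]).str.len()

    rows = []
    for scope in ("all", "public", "private"):
        in_scope = pd.Series(True, index=records.index) if scope == "all" else records["ownership"] == scope
        for yr in ["all", *sorted(year.unique())]:
            sel = in_scope if yr == "all" else (in_scope & (year == yr))
            total = int(sel.sum())
            if total == 0:
                continue
            groups = {
                "medical_short": sel & (cls["case_type"] == "medical") & (cls["stay_class"] == "short"),
                "medical_medium": sel & (cls["case_type"] == "medical") & (cls["stay_class"] == "medium"),
                "medical_long": sel & (cls["case_type"] == "medical") & (cls["stay_class"] == "long"),
                "medical_all": sel & (cls["case_type"] == "medical"),
                "surgical": sel & (cls["case_type"] == "surgical"),
                "mixed": sel & (cls["case_type"] == "mixed"),
                "total": sel,
            }
            for name, gmask in groups.items():
                n = int(gmask.sum())
                np_ = int(n_procs[gmask].sum())
                rows.append(
                    {
                        "ownership": scope,
                        "year": yr,
                        "group": name,
                        "n_cases": n,
                        "pct": share_pct(n, total, 1),
                        "n_procedures": np_,
                        "case_procedure_ratio": procedure_ratio(np_, n) if np_ and n else np.nan,
                    }
                )
    return pd.DataFrame(rows)
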