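"""Pre/post code-level decomposition of CMI change.

Compares a pre-intervention window (default discharge years 2013+2014) with
a post-intervention window (2015+2016).  For each code g with fixed weight
W_g and case counts N:

    WN0 = W_g * N_g(pre),   WN1 = W_g * N_g(post)
    CCE  = [(WN1 - WN0) * (W_g - CMI_ref)]^2        (code count effect)
    attributable % = 100 * CCE_g / sum_g CCE_g
    share change   = (WN1 - WN0) / WN0

CCE is a squared magnitude: it ranks codes by the size of their impact on
the CMI in either direction; the direction itself is carried by the sign of
the case change.  Because weights are fixed across years, the share change
reduces identically to the relative case change.  CMI_ref is the stratum's
reference CMI, by default its pre-window value.  The table additionally
carries ``share_point_change`` = 100*(WN1/sum(WN1) - WN0/sum(WN0)), the
change in the code's percentage share of total weighted volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmi import CHEMOTHERAPY_CODES, classify_records
from .records import check_columns, discharge_year, split_cpt
from .weights import WeightTable

__all__ = [
    "AttributionContext",
    "AttributionError",
    "attribute",
    "attribute_counts",
    "top_k",
    "aggregate_code_group",
    "window_change",
]


class AttributionError(ValueError):
    """Empty stratum or invalid attribution inputs."""


@dataclass(frozen=True)
class AttributionContext:
    weights: WeightTable
    pre_years: tuple = (2013, 2014)
    post_years: tuple = (2015, 2016)
    case_type: str = "medical"
    stay: str = "all"  # short | medium | long | all (medical only)
    ownership: str = "all"
    cmi_ref: float | None = None  # None -> pre-window CMI of the stratum
    exclude_chemo: bool = True

    def __post_init__(self):
        if set(self.pre_years) & set(self.post_years):
            raise AttributionError("pre and post windows must be disjoint")


def window_change(n_pre: float, n_post: float) -> tuple:
    """(absolute, percentage) case change; percentage is NaN when n_pre = 0."""
    change_n = n_post - n_pre
    change_pct = 100.0 * change_n / n_pre if n_pre else float("nan")
    return change_n, change_pct


def _stratum_counts(records: pd.DataFrame, ctx: AttributionContext) -> pd.DataFrame:
    """Per-code case counts in each window for the context's stratum.

    Surgical strata count procedure occurrences per CPT code (secondary
    procedures included), mirroring how they enter the surgical CMI.
    """
    check_columns(records)
    cls = classify_records(records)
    year = discharge_year(records)
    mask = cls["case_type"] == ctx.case_type
    if ctx.ownership != "all":
        mask &= records["ownership"] == ctx.ownership
    if ctx.case_type == "medical" and ctx.stay != "all":
        mask &= cls["stay_class"] == ctx.stay

    pre = mask & year.isin(ctx.pre_years)
    post = mask & year.isin(ctx.post_years)

    if ctx.case_type == "surgical":
        def count(sel):
            codes = split_cpt(records.loc[sel, "cpt_codes"]).explode().dropna()
            return codes.value_counts()
        strata = "surgical"
    else:
        def count(sel):
            codes = records.loc[sel, "icd_code"].str.upper()
            if ctx.exclude_chemo:
                codes = codes[~codes.isin(CHEMOTHERAPY_CODES)]
            return codes.value_counts()
        strata = ctx.stay

    n_pre = count(pre)
    n_post = count(post)
    if n_pre.empty and n_post.empty:
        raise AttributionError(
            f"no cases in stratum {ctx.case_type}/{ctx.stay}/{ctx.ownership} in either window"
        )
    counts = pd.DataFrame({"n_pre": n_pre, "n_post": n_post}).fillna(0).astype(int)
    counts.index.name = "code"
    counts = counts.reset_index().sort_values("code", ignore_index=True)
    counts["stratum"] = strata
    return counts


def attribute_counts(
    counts: pd.DataFrame, code_weights: pd.Series, cmi_ref: float
) -> pd.DataFrame:
    """Attribution arithmetic on a per-code count table.

    ``counts`` needs columns ``code``, ``n_pre``, ``n_post``;
    ``code_weights`` maps code -> fixed weight W_g.  This is the arithmetic
    core shared by :func:`attribute`; feeding it published count tables
    reproduces their change columns exactly.
    """
    if counts.empty:
        raise AttributionError("empty count table")
    if cmi_ref is None or not np.isfinite(cmi_ref) or cmi_ref <= 0:
        raise AttributionError(f"cmi_ref must be a positive number; got {cmi_ref}")
    out = counts.copy()
    w = out["code"].map(code_weights)
    if w.isna().any():
        missing = out.loc[w.isna(), "code"].tolist()[:10]
        raise AttributionError(f"missing weight for code(s): {', '.join(missing)}")
    out["weight"] = w.astype(float)
    out["change_n"] = out["n_post"] - out["n_pre"]
    out["change_pct"] = np.where(
        out["n_pre"] > 0, 100.0 * out["change_n"] / out["n_pre"].replace(0, np.nan), np.nan
    )
    out["wn0"] = out["weight"] * out["n_pre"]
    out["wn1"] = out["weight"] * out["n_post"]
    out["cce"] = ((out["wn1"] - out["wn0"]) * (out["weight"] - cmi_ref)) ** 2
    total_cce = out["cce"].sum()
    out["attributable_pct"] = 100.0 * out["cce"] / total_cce if total_cce > 0 else 0.0
    out["share_change"] = np.where(
        out["wn0"] > 0, (out["wn1"] - out["wn0"]) / out["wn0"].replace(0, np.nan), np.nan
    )
    wn0_tot, wn1_tot = out["wn0"].sum(), out["wn1"].sum()
    out["share_point_change"] = 100.0 * (out["wn1"] / wn1_tot - out["wn0"] / wn0_tot)
    out["direction"] = np.sign(out["change_n"]).astype(int)
    return out


def attribute(records: pd.DataFrame, ctx: AttributionContext) -> pd.DataFrame:
    """One attribution row per code observed in either window of the stratum."""
    counts = _stratum_counts(records, ctx)
    strata = counts["stratum"]
    code_weights = pd.Series(
        {c: ctx.weights.weight(s, c) for c, s in zip(counts["code"], strata)}
    )
    cmi_ref = ctx.cmi_ref
    if cmi_ref is None:
        # pre-window CMI of the stratum: case-weighted mean code weight
        w = counts["code"].map(code_weights)
        n_pre_total = counts["n_pre"].sum()
        if n_pre_total == 0:
            raise AttributionError("pre window is empty; supply cmi_ref explicitly")
        cmi_ref = float((w * counts["n_pre"]).sum() / n_pre_total)
    out = attribute_counts(counts[["code", "n_pre", "n_post"]], code_weights, cmi_ref)
    out.attrs["cmi_ref"] = cmi_ref
    out.attrs["stratum"] = {
        "case_type": ctx.case_type, "stay": ctx.stay, "ownership": ctx.ownership,
    }
    return out


def top_k(table: pd.DataFrame, k: int = 20, key: str = "attributable_pct") -> pd.DataFrame:
    """Top-k codes by ``key`` (descending); ties by |change_n|, then code.

    Returns the whole table ranked when k exceeds its length; adds a
    ``rank`` column starting at 1.
    """
    if k <= 0:
        raise AttributionError(f"k must be positive; got {k}")
    if key not in table.columns:
        raise AttributionError(f"unknown ranking key {key!r}")
    work = table.copy()
    work["_abs_change"] = work["change_n"].abs()
    work = work.sort_values(
        [key, "_abs_change", "code"], ascending=[False, False, True], ignore_index=True
    ).drop(columns="_abs_change")
    out = work.head(k).copy()
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def aggregate_code_group(
    records: pd.DataFrame,
    code_prefixes,
    pre_years: tuple = (2013, 2014),
    post_years: tuple = (2015, 2016),
    by: str | None = None,
) -> pd.DataFrame:
    """Pre/post counts for a family of codes (matched by prefix).

    Matches both diagnosis and procedure codes whose string starts with any
    given prefix; optionally grouped ``by`` ``"ownership"``, ``"year"`` or
    ``"stay"``.  Returns counts with absolute and relative change (the
    latter in percent, to be rounded to 1 decimal for presentation).
    """
    prefixes = tuple(code_prefixes)
    if not prefixes:
        raise AttributionError("empty code prefix set")
    check_columns(records)
    year = discharge_year(records)

    icd = records["icd_code"].str.upper()
    icd_hit = icd.str.startswith(prefixes)
    cpt_lists = split_cpt(records["cpt_codes"])
    cpt_hits = cpt_lists.apply(lambda lst: sum(c.startswith(prefixes) for c in lst))
    hits = icd_hit.astype(int) + cpt_hits

    frame = pd.DataFrame({"hits": hits, "year": year, "ownership": records["ownership"]})
    if by == "stay":
        frame["stay"] = classify_records(records)["stay_class"]

    def window_total(years, group_val=None):
        sel = frame["year"].isin(years)
        if by and by != "year" and group_val is not None:
            sel &= frame[by] == group_val
        return int(frame.loc[sel, "hits"].sum())

    groups = ["all"] if by in (None, "year") else sorted(frame[by].dropna().unique())
    rows = []
    for g in groups:
        gv = None if g == "all" else g
        n_pre = window_total(pre_years, gv)
        n_post = window_total(post_years, gv)
        change_n, change_pct = window_change(n_pre, n_post)
        rows.append(
            {
                "group": g,
                "n_pre": n_pre,
                "n_post": n_post,
                "change_n": change_n,
                "change_pct": change_pct,
            }
        )
    out = pd.DataFrame(rows)
    if by == "year":
        yr_rows = []
        for yr in sorted(set(pre_years) | set(post_years)):
            yr_rows.append({"group": yr, "n": int(frame.loc[frame["year"] == yr, "hits"].sum())})
        out.attrs["per_year"] = pd.DataFrame(yr_rows)
    return out
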