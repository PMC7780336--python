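"""Per-code casemix weight-setting.

Medical weights come from multi-year average charges: within each stay
stratum (short <2 d, medium 2-15 d, long >15 d), a diagnosis with at least
``low_volume_threshold`` (default 20) cases in the weight-setting window gets

    W_g = mean(total_charge of its cases) / reference_cost_medical,

where the medical reference cost is the grand mean charge over *all* medical
cases in the window (so a code billing exactly at the average carries weight
1.0).  Diagnoses below the volume threshold are assigned the case-weighted
average weight of their stratum.  Weights are fixed for the whole analysis
period.

Surgical procedures have flat fees, so their weights need no averaging:
W_g = fee / 1,000,000 LBP, capped at 10.00 to limit outlier leverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import check_columns, discharge_year

__all__ = [
    "WeightTable",
    "WeightingError",
    "UnknownCodeError",
    "build_medical_weights",
    "build_surgical_weights",
    "build_weight_table",
    "read_weight_table",
]

SURGICAL_REFERENCE_COST = 1_000_000.0
SURGICAL_WEIGHT_CAP = 10.0
LOW_VOLUME_THRESHOLD = 20

_TABLE_COLUMNS = ["stratum", "code", "n_cases", "mean_charge", "weight", "capped"]


class WeightingError(ValueError):
    """Weight-setting preconditions violated (e.g. no usable medical cases)."""


class UnknownCodeError(KeyError):
    """A record carries a code absent from the weight table."""


@dataclass
class WeightTable:
    """Per-(stratum, code) weights plus the reference costs behind them.

    ``table`` has columns stratum, code, n_cases, mean_charge, weight,
    capped; ``fallback`` maps each medical stratum to the average weight
    assigned to its low-volume codes.
    """

    table: pd.DataFrame
    reference_cost_medical: float = float("nan")
    reference_cost_surgical: float = SURGICAL_REFERENCE_COST
    low_volume_threshold: int = LOW_VOLUME_THRESHOLD
    cap: float = SURGICAL_WEIGHT_CAP
    window: tuple = (None, None)
    fallback: dict = field(default_factory=dict)
    n_rejected_charges: int = 0

    def __post_init__(self):
        self._lookup = {
            (s, c): w
            for s, c, w in zip(self.table["stratum"], self.table["code"], self.table["weight"])
        }

    def weight(self, stratum: str, code: str) -> float:
        try:
            return self._lookup[(stratum, code)]
        except KeyError:
            raise UnknownCodeError(f"no weight for code {code!r} in stratum {stratum!r}") from None

    def weights_for(self, strata: pd.Series, codes: pd.Series) -> pd.Series:
        """Vectorized lookup; raises :class:`UnknownCodeError` listing gaps."""
        keys = list(zip(strata, codes))
        missing = sorted({k for k in keys if k not in self._lookup})
        if missing:
            shown = ", ".join(f"{c}[{s}]" for s, c in missing[:10])
            raise UnknownCodeError(f"no weight for {len(missing)} code(s): {shown}")
        return pd.Series([self._lookup[k] for k in keys], index=strata.index, dtype=float)

    def merged_with(self, other: "WeightTable") -> "WeightTable":
        """Combine a medical and a surgical table into one."""
        merged = pd.concat([self.table, other.table], ignore_index=True)
        ref_med = (
            self.reference_cost_medical
            if np.isfinite(self.reference_cost_medical)
            else other.reference_cost_medical
        )
        return WeightTable(
            table=merged,
            reference_cost_medical=ref_med,
            low_volume_threshold=self.low_volume_threshold,
            cap=self.cap,
            window=self.window if self.window != (None, None) else other.window,
            fallback={**self.fallback, **other.fallback},
            n_rejected_charges=self.n_rejected_charges + other.n_rejected_charges,
        )

    def write(self, path) -> None:
        self.table[_TABLE_COLUMNS].to_csv(path, index=False)


def read_weight_table(path) -> WeightTable:
    table = pd.read_csv(path, dtype={"stratum": str, "code": str})
    return WeightTable(table=table)


def _stay_class(los: pd.Series) -> pd.Series:
    """Stay stratum from integer length of stay: <2 short, 2-15 medium, >15 long."""
    return pd.cut(
        los, bins=[-1, 1, 15, np.inf], labels=["short", "medium", "long"]
    ).astype(str)


def build_medical_weights(
    records: pd.DataFrame,
    window: tuple,
    low_volume_threshold: int = LOW_VOLUME_THRESHOLD,
    reference_cost: float | None = None,
    fallback_scope: str = "stratum",
) -> WeightTable:
    """Weight-setting over medical cases discharged within ``window`` (years).

    ``reference_cost`` overrides the grand-mean-charge normalizer;
    ``fallback_scope`` is ``"stratum"`` (default) or ``"medical"`` for the
    low-volume average.  Non-positive charges are rejected (counted in the
    result); having no usable medical case in the window is an error.
    """
    check_columns(records)
    y0, y1 = int(window[0]), int(window[1])
    years = discharge_year(records)
    medical = records[
        (records["icd_code"] != "")
        & (records["cpt_codes"] == "")
        & (years >= y0)
        & (years <= y1)
    ]
    n_rejected = int((medical["total_charge"] <= 0).sum())
    medical = medical[medical["total_charge"] > 0]
    if medical.empty:
        raise WeightingError(f"no medical cases with positive charges in window {y0}-{y1}")

    work = pd.DataFrame(
        {
            "stratum": _stay_class(medical["length_of_stay"]),
            "code": medical["icd_code"].str.upper(),
            "charge": medical["total_charge"].astype(float),
        }
    )
    ref = float(work["charge"].mean()) if reference_cost is None else float(reference_cost)

    grouped = work.groupby(["stratum", "code"], observed=True)["charge"].agg(["size", "mean"])
    grouped = grouped.rename(columns={"size": "n_cases", "mean": "mean_charge"}).reset_index()
    grouped["weight"] = grouped["mean_charge"] / ref

    eligible = grouped["n_cases"] >= low_volume_threshold
    # low-volume fallback: case-weighted average weight among eligible codes
    fallback = {}
    if fallback_scope == "medical":
        pool = grouped[eligible]
        avg = _case_weighted_average(pool)
        for s in grouped["stratum"].unique():
            fallback[s] = avg
    else:
        for s, block in grouped.groupby("stratum", observed=True):
            pool = block[block["n_cases"] >= low_volume_threshold]
            # stratum with no high-volume code: fall back to all-medical average
            fallback[s] = (
                _case_weighted_average(pool)
                if not pool.empty
                else _case_weighted_average(grouped[eligible])
            )
    grouped.loc[~eligible, "weight"] = grouped.loc[~eligible, "stratum"].map(fallback)
    grouped["capped"] = False

    return WeightTable(
        table=grouped[_TABLE_COLUMNS],
        reference_cost_medical=ref,
        low_volume_threshold=low_volume_threshold,
        window=(y0, y1),
        fallback=fallback,
        n_rejected_charges=n_rejected,
    )


def _case_weighted_average(block: pd.DataFrame) -> float:
    if block.empty:
        raise WeightingError("no high-volume codes available for low-volume fallback")
    return float(np.average(block["weight"], weights=block["n_cases"]))


def build_surgical_weights(
    fee_schedule: dict,
    cap: float = SURGICAL_WEIGHT_CAP,
    reference_cost: float = SURGICAL_REFERENCE_COST,
) -> WeightTable:
    """Weights from a flat-fee schedule: W = fee / 1M LBP, capped at 10.00."""
    if not fee_schedule:
        raise WeightingError("empty fee schedule")
    codes, fees = zip(*sorted(fee_schedule.items()))
    fees = np.asarray(fees, dtype=float)
    if (fees <= 0).any():
        bad = [c for c, f in zip(codes, fees) if f <= 0]
        raise WeightingError(f"non-positive fee(s) for: {', '.join(bad)}")
    raw = fees / reference_cost
    table = pd.DataFrame(
        {
            "stratum": "surgical",
            "code": codes,
            "n_cases": 0,
            "mean_charge": fees,
            "weight": np.minimum(raw, cap),
            "capped": raw > cap,
        }
    )
    return WeightTable(
        table=table[_TABLE_COLUMNS],
        reference_cost_surgical=reference_cost,
        cap=cap,
    )


def build_weight_table(
    records: pd.DataFrame,
    window: tuple,
    fee_schedule: dict | None = None,
    **medical_kwargs,
) -> WeightTable:
    """Convenience: medical weights from records, surgical from flat fees."""
    medical = build_medical_weights(records, window, **medical_kwargs)
    if fee_schedule:
        return medical.merged_with(build_surgical_weights(fee_schedule))
    return medical
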