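"""Malmö-ratio imputation of non-hip fracture incidence.

Many fracture registries observe hip fracture well (it almost always
reaches hospital) but other major osteoporotic fractures (distal forearm,
proximal humerus, clinical spine) poorly.  The standard remedy assumes the
local age- and sex-specific ratio of a non-hip site to hip fracture equals
that of a fully enumerated reference population (historically Malmö,
Sweden):

    OMF_local = HF_local x OMF_reference / HF_reference

per (sex, age band).  Where both local hip and local non-hip incidence are
observed, the imputation can be audited by comparing predicted against
observed rates; a predicted rate is flagged as significantly different
when it falls outside the observed rate's exact 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Column contract for reference incidence tables.
REFERENCE_COLUMNS = ("sex", "age_lo", "age_hi", "site", "rate")


def impute_omf_rate(hf_local: float, hf_ref: float, omf_ref: float) -> float:
    """Impute a local non-hip rate from local hip and reference rates.

    Linear in ``hf_local`` and ``omf_ref``, inverse in ``hf_ref``.
    """
    if hf_ref <= 0:
        raise ValueError("reference hip rate must be positive")
    if hf_local < 0 or omf_ref < 0:
        raise ValueError("rates must be non-negative")
    return hf_local * omf_ref / hf_ref


def read_reference_table(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    frame = pd.read_csv(path, sep=delimiter)
    missing = [c for c in REFERENCE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"reference table missing column {missing[0]!r}")
    return frame


def impute_table(
    local_hip: pd.DataFrame,
    reference: pd.DataFrame,
    sites: tuple[str, ...] = ("forearm", "humerus"),
) -> pd.DataFrame:
    """Predict local non-hip incidence per (sex, band) for each site.

    ``local_hip`` is an incidence table restricted to hip; ``reference``
    holds reference rates for hip and the requested sites on the same band
    scheme.  Output columns: sex, age_lo, age_hi, site, rate.
    """
    hip_ref = reference[reference["site"] == "hip"]
    rows = []
    for rec in local_hip.itertuples(index=False):
        key = (
            (hip_ref["sex"] == rec.sex)
            & (hip_ref["age_lo"] == rec.age_lo)
        )
        ref_hip_rows = hip_ref[key]
        if ref_hip_rows.empty:
            raise ValueError(
                f"reference hip rate missing for {rec.sex} {rec.age_lo}+"
            )
        hf_ref = float(ref_hip_rows["rate"].iloc[0])
        for site in sites:
            ref_site = reference[
                (reference["site"] == site)
                & (reference["sex"] == rec.sex)
                & (reference["age_lo"] == rec.age_lo)
            ]
            if ref_site.empty:
                continue
            omf_ref = float(ref_site["rate"].iloc[0])
            rows.append({
                "sex": rec.sex, "age_lo": rec.age_lo, "age_hi": rec.age_hi,
                "site": site,
                "rate": impute_omf_rate(float(rec.rate), hf_ref, omf_ref),
            })
    return pd.DataFrame(rows, columns=list(REFERENCE_COLUMNS))


@dataclass(frozen=True)
class PredictionComparison:
    sex: str
    age_lo: int
    age_hi: float
    site: str
    predicted: float
    observed: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        """Predicted lies outside the observed 95% interval."""
        return not (self.ci_low <= self.predicted <= self.ci_high)


def compare_predicted_observed(
    predicted: pd.DataFrame, observed: pd.DataFrame
) -> pd.DataFrame:
    """Audit imputation: one row per stratum with a significance flag.

    ``predicted`` carries (sex, age_lo, age_hi, site, rate); ``observed``
    is an incidence table with ci_low/ci_high.  Strata present on one side
    only are kept with status "missing_observed"/"missing_predicted"
    rather than silently dropped.
    """
    keys = ["sex", "age_lo", "site"]
    pred = predicted.rename(columns={"rate": "predicted"})
    obs = observed.rename(columns={"rate": "observed"})[
        keys + ["age_hi", "observed", "ci_low", "ci_high"]
    ]
    merged = pred.merge(obs, on=keys, how="outer", suffixes=("", "_obs"))
    if "age_hi_obs" in merged.columns:
        merged["age_hi"] = merged["age_hi"].fillna(merged.pop("age_hi_obs"))

    def status(row) -> str:
        if np.isnan(row["predicted"]):
            return "missing_predicted"
        if np.isnan(row["observed"]):
            return "missing_observed"
        return "ok"

    merged["status"] = merged.apply(status, axis=1)
    merged["significant"] = (
        (merged["status"] == "ok")
        & ~(
            (merged["ci_low"] <= merged["predicted"])
            & (merged["predicted"] <= merged["ci_high"])
        )
    )
    cols = ["sex", "age_lo", "age_hi", "site", "predicted", "observed",
            "ci_low", "ci_high", "significant", "status"]
    return merged[cols].sort_values(keys).reset_index(drop=True)
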