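"""Agreement statistics between quantification variants.

Variants (e.g. full-protocol V_T, PBIF-derived V_T, an SUV epoch) are tidy
per-(participant, region) tables; this module pools them, computes Spearman
rank correlations with Fisher-z confidence intervals, Bland-Altman bias and
limits of agreement, percent differences relative to the reference variant,
and between-subject coefficients of variation (BS-CV).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import ValidationError


def make_roi_table(records, variant: str) -> pd.DataFrame:
    """Tidy table with columns (participant, region, value, variant)."""
    df = pd.DataFrame(records)
    needed = {"participant", "region", "value"}
    if not needed <= set(df.columns):
        raise ValidationError(f"ROI table needs columns {sorted(needed)}")
    if df.duplicated(["participant", "region"]).any():
        raise ValidationError("duplicate (participant, region) rows")
    if not np.all(np.isfinite(df["value"])):
        raise ValidationError("non-finite values in ROI table")
    out = df[["participant", "region", "value"]].copy()
    out["variant"] = variant
    return out


def pool(reference: pd.DataFrame, test: pd.DataFrame) -> pd.DataFrame:
    """Align two variants on (participant, region); errors list missing cells."""
    merged = reference.merge(test, on=["participant", "region"], how="outer",
                             suffixes=("_ref", "_test"), indicator=True)
    missing = merged[merged["_merge"] != "both"]
    if len(missing):
        cells = [f"{r.participant}/{r.region}" for r in missing.itertuples()]
        raise ValidationError(f"unmatched (participant, region) cells: {cells}")
    return merged.drop(columns="_merge")


def spearman_ci(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Spearman rho (average ranks on ties) with a Fisher-z CI,
    SE = 1/sqrt(n-3). A constant vector gives (nan, nan, nan)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("need paired vectors with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (np.nan, np.nan, np.nan)
    rho = float(spearmanr(x, y).statistic)
    if abs(rho) >= 1.0 - 1e-12:  # snap numerically perfect rank agreement
        rho = float(np.sign(rho))
        return (rho, rho, rho)
    z = np.arctanh(rho)
    half = 1.959963984540054 / np.sqrt(x.size - 3)
    return (rho, float(np.tanh(z - half)), float(np.tanh(z + half)))


def bland_altman(x, y) -> dict:
    """Bias = mean(y - x), limits of agreement = bias +/- 1.96 sd, plus
    pairwise percent differences 100 (y - x)/x (pairs with x = 0 flagged and
    excluded from the percent summary)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValidationError("need paired vectors with n >= 2")
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    ok = x != 0
    pct = 100.0 * diff[ok] / x[ok]
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd_diff": sd,
        "mean": (x + y) / 2.0,
        "diff": diff,
        "pct_diff": pct,
        "mean_pct_diff": float(pct.mean()) if pct.size else np.nan,
        "sd_pct_diff": float(pct.std(ddof=1)) if pct.size > 1 else np.nan,
        "n_zero_reference": int(np.sum(~ok)),
    }


def bs_cv(values) -> float:
    """Between-subject coefficient of variation, %: 100 sd/mean across
    participants (sample sd). Undefined (nan) for nonpositive means."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValidationError("BS-CV needs >= 2 participants")
    m = values.mean()
    if m <= 0:
        return np.nan
    return float(100.0 * values.std(ddof=1) / m)


@dataclass
class AgreementReport:
    """Full comparison of a test variant against a reference variant."""

    reference_variant: str
    test_variant: str
    n_pairs: int
    rho: float
    rho_ci: tuple[float, float]
    per_roi_rho: pd.DataFrame          # region, rho, ci_low, ci_high
    bias: float
    loa: tuple[float, float]
    mean_pct_diff: float
    sd_pct_diff: float
    per_roi_pct_diff: pd.DataFrame     # region, mean_pct_diff
    bs_cv_table: pd.DataFrame          # region, bscv_ref, bscv_test, delta
    scatter: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "reference_variant": self.reference_variant,
            "test_variant": self.test_variant,
            "n_pairs": self.n_pairs,
            "rho": self.rho,
            "rho_ci": list(self.rho_ci),
            "bias": self.bias,
            "loa": list(self.loa),
            "mean_pct_diff": self.mean_pct_diff,
            "sd_pct_diff": self.sd_pct_diff,
            "per_roi_rho": self.per_roi_rho.to_dict(orient="records"),
            "per_roi_pct_diff": self.per_roi_pct_diff.to_dict(orient="records"),
            "bs_cv": self.bs_cv_table.to_dict(orient="records"),
        }


def compare_variants(reference: pd.DataFrame, test: pd.DataFrame) -> AgreementReport:
    """Pooled and per-ROI agreement between two tidy ROI tables."""
    merged = pool(reference, test)
    x = merged["value_ref"].to_numpy()
    y = merged["value_test"].to_numpy()
    rho, lo, hi = spearman_ci(x, y)
    ba = bland_altman(x, y)

    roi_rows, pct_rows, cv_rows = [], [], []
    for region, grp in merged.groupby("region", sort=True):
        xr = grp["value_ref"].to_numpy()
        yr = grp["value_test"].to_numpy()
        if xr.size >= 4:
            r, rl, rh = spearman_ci(xr, yr)
        else:
            r = rl = rh = np.nan
        roi_rows.append({"region": region, "rho": r, "ci_low": rl, "ci_high": rh})
        ok = xr != 0
        pct_rows.append({"region": region,
                         "mean_pct_diff": float((100.0 * (yr[ok] - xr[ok]) / xr[ok]).mean())})
        cv_ref = bs_cv(xr)
        cv_test = bs_cv(yr)
        cv_rows.append({"region": region, "bscv_ref": cv_ref, "bscv_test": cv_test,
                        "delta": cv_test - cv_ref})

    scatter = pd.DataFrame({
        "participant": merged["participant"], "region": merged["region"],
        "mean": ba["mean"], "diff": ba["diff"],
    })
    ref_name = reference["variant"].iloc[0] if "variant" in reference else "reference"
    test_name = test["variant"].iloc[0] if "variant" in test else "test"
    return AgreementReport(
        reference_variant=str(ref_name), test_variant=str(test_name),
        n_pairs=int(len(merged)), rho=rho, rho_ci=(lo, hi),
        per_roi_rho=pd.DataFrame(roi_rows),
        bias=ba["bias"], loa=(ba["loa_low"], ba["loa_high"]),
        mean_pct_diff=ba["mean_pct_diff"], sd_pct_diff=ba["sd_pct_diff"],
        per_roi_pct_diff=pd.DataFrame(pct_rows),
        bs_cv_table=pd.DataFrame(cv_rows),
        scatter=scatter,
    )
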