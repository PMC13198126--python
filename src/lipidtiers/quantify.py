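"""Internal-standard quantification and method-validation metrics.

Peak areas from targeted MRM acquisition are converted to absolute amounts
by ratio to a co-injected stable-isotope internal standard:

    amount_pmol = (area_analyte / area_IS) * spiked_IS_pmol

and normalized to nmol/g when a tissue mass is available (pmol / mg is
numerically nmol/g).  Calibration curves are ordinary least squares of peak
area on nominal concentration in mmol/L; detection and quantification
limits follow LOD = 3.3 sigma / S and LOQ = 10 sigma / S with sigma the
residual standard error (n - 2 denominator) and S the slope.  Recovery is
the background-subtracted fold increase of a 3x spike over a 1x spike, and
precision is the coefficient of variation of technical replicates within
and across days.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel import AnalyteDef, InternalStandardDef, assign_internal_standard, IS_SCHEME

__all__ = [
    "PEAK_AREA_COLUMNS",
    "QuantifyError",
    "validate_peak_area_table",
    "quantify_by_internal_standard",
    "CalibrationFit",
    "fit_calibration",
    "recovery",
    "PrecisionAssay",
    "precision_cov",
]

#: Required columns of a long-format peak-area table.  ``analyte`` holds an
#: analyte_id, internal-standard id, or lipid shorthand name (tier A).
PEAK_AREA_COLUMNS = ["sample_id", "tier", "analyte", "transition", "area"]
METADATA_COLUMNS = ["tissue_mass_mg", "group", "day", "replicate"]


class QuantifyError(ValueError):
    pass


def validate_peak_area_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants of a peak-area table.

    One area per (sample, tier, analyte, transition); areas must be numeric.
    Non-positive areas are set to NaN (treated as missing downstream, never
    clamped into amounts).  Returns a validated copy.
    """
    missing = [c for c in PEAK_AREA_COLUMNS if c not in table.columns]
    if missing:
        raise QuantifyError(f"peak-area table lacks required columns: {missing}")
    t = table.copy()
    t["area"] = pd.to_numeric(t["area"], errors="coerce")
    t.loc[t["area"] <= 0, "area"] = np.nan
    bad_tier = set(t["tier"].unique()) - {"A", "B", "C"}
    if bad_tier:
        raise QuantifyError(f"unknown tier labels: {sorted(bad_tier)}")
    key = ["sample_id", "tier", "analyte", "transition"]
    dup = t.duplicated(key)
    if dup.any():
        raise QuantifyError(
            f"{int(dup.sum())} duplicate (sample, tier, analyte, transition) rows"
        )
    if "tissue_mass_mg" in t.columns:
        mass = pd.to_numeric(t["tissue_mass_mg"], errors="coerce")
        if (mass <= 0).any():
            raise QuantifyError("tissue_mass_mg must be positive where given")
    return t


def quantify_by_internal_standard(
    table: pd.DataFrame,
    panel: Sequence[AnalyteDef],
    is_map: Sequence[InternalStandardDef],
    scheme=IS_SCHEME,
    tissue_normalize: bool = True,
) -> pd.DataFrame:
    """Convert a validated peak-area table to absolute amounts.

    Returns a long table (sample_id, tier, analyte, amount_pmol, and
    amount_nmol_per_g when tissue masses are present, plus carried-over
    metadata) with a ``flag`` column: samples lacking an internal-standard
    area have their dependent analytes withheld (NaN amount, flag
    ``missing_is``); a zero IS area raises.
    """
    by_id = {a.analyte_id: a for a in panel}
    is_of = {a.analyte_id: assign_internal_standard(a, is_map, scheme) for a in panel}
    spike = {s.is_id: s.spiked_pmol for s in is_map}

    raw_is = table[table["analyte"].isin(spike)] if "analyte" in table.columns else table.iloc[0:0]
    if len(raw_is) and (pd.to_numeric(raw_is["area"], errors="coerce") == 0).any():
        bad = raw_is.loc[pd.to_numeric(raw_is["area"], errors="coerce") == 0]
        raise QuantifyError(
            "zero internal-standard area for "
            + ", ".join(f"{r.analyte} in sample {r.sample_id}" for r in bad.itertuples())
        )
    t = validate_peak_area_table(table)

    # internal-standard areas per (sample, tier)
    is_rows = t[t["analyte"].isin(spike)]
    is_area = is_rows.set_index(["sample_id", "tier", "analyte"])["area"]

    records = []
    analyte_rows = t[t["analyte"].isin(by_id)]
    for row in analyte_rows.itertuples(index=False):
        is_id = is_of[row.analyte]
        try:
            a_is = is_area.loc[(row.sample_id, row.tier, is_id)]
        except KeyError:
            a_is = np.nan
        if a_is == 0:
            raise QuantifyError(
                f"zero internal-standard area for {is_id} in sample {row.sample_id}"
            )
        flag = ""
        if np.isnan(a_is):
            amount = np.nan
            flag = "missing_is"
        elif np.isnan(row.area):
            amount = np.nan
            flag = "missing_area"
        else:
            amount = row.area / a_is * spike[is_id]
        rec = {
            "sample_id": row.sample_id,
            "tier": row.tier,
            "analyte": row.analyte,
            "internal_standard": is_id,
            "amount_pmol": amount,
            "flag": flag,
        }
        for c in METADATA_COLUMNS:
            if hasattr(row, c):
                rec[c] = getattr(row, c)
        records.append(rec)
    out = pd.DataFrame.from_records(records)
    if tissue_normalize and "tissue_mass_mg" in out.columns:
        out["amount_nmol_per_g"] = out["amount_pmol"] / out["tissue_mass_mg"]
    return out


@dataclass(frozen=True)
class CalibrationFit:
    """OLS calibration of peak area on concentration (mmol/L)."""

    analyte_id: str
    slope: float
    intercept: float
    sigma: float  # residual standard error, n-2 denominator
    r_squared: float
    lod_mmol_l: float
    loq_mmol_l: float
    lod_pmol: Optional[float]
    loq_pmol: Optional[float]
    linear_range: tuple  # contiguous subset of input levels (mg/L)
    n_points: int


def _ols(x: np.ndarray, y: np.ndarray):
    """Least-squares line fit returning slope, intercept, sigma, R^2."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise QuantifyError("degenerate calibration: all concentrations equal")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ssr = float(np.sum(resid**2))
    sst = float(np.sum((y - ym) ** 2))
    sigma = np.sqrt(ssr / (n - 2)) if n > 2 else 0.0
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return slope, intercept, sigma, r2


def fit_calibration(
    levels_mg_l: Sequence[float],
    areas: Sequence[float],
    mw: float,
    analyte_id: str = "",
    injection_volume_ul: Optional[float] = None,
    r2_cutoff: float = 0.98,
    weighting: Optional[str] = None,
) -> CalibrationFit:
    """Fit a calibration series and derive LOD/LOQ.

    ``levels_mg_l`` are nominal concentrations (repeated for replicate
    injections); ``mw`` (g/mol) converts them to mmol/L before the fit so the
    slope is a response per mmol/L.  LOD = 3.3 sigma/S, LOQ = 10 sigma/S;
    both are also expressed in pmol on column when ``injection_volume_ul``
    is given (mmol/L x uL = pmol).  The linear range is the longest
    contiguous run of distinct levels (>= 3) whose own fit reaches
    ``r2_cutoff``.  ``weighting='1/x'`` applies inverse-concentration
    weighted least squares; the default is unweighted.
    """
    x_mg = np.asarray(levels_mg_l, dtype=float)
    y = np.asarray(areas, dtype=float)
    if x_mg.size != y.size:
        raise QuantifyError("levels and areas differ in length")
    if mw <= 0:
        raise QuantifyError("molecular weight must be positive")
    if np.unique(x_mg).size < 3:
        raise QuantifyError("calibration needs >= 3 distinct concentration levels")
    x = x_mg / mw  # mg/L -> mmol/L

    if weighting == "1/x":
        w = np.sqrt(1.0 / np.where(x > 0, x, np.nan))
        keep = np.isfinite(w)
        slope, intercept, sigma, r2 = _ols_weighted(x[keep], y[keep], w[keep])
    elif weighting in (None, "none"):
        slope, intercept, sigma, r2 = _ols(x, y)
    else:
        raise QuantifyError(f"unknown weighting {weighting!r}")

    if slope <= 0:
        raise QuantifyError(f"non-responsive analyte {analyte_id or '?'}: slope <= 0")

    lod = 3.3 * sigma / slope
    loq = 10.0 * sigma / slope
    lod_pmol = lod * injection_volume_ul if injection_volume_ul else None
    loq_pmol = loq * injection_volume_ul if injection_volume_ul else None

    linear_range = _linear_range(x_mg, y, mw, r2_cutoff)
    return CalibrationFit(
        analyte_id=analyte_id,
        slope=float(slope),
        intercept=float(intercept),
        sigma=float(sigma),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        lod_mmol_l=float(lod),
        loq_mmol_l=float(loq),
        lod_pmol=lod_pmol,
        loq_pmol=loq_pmol,
        linear_range=linear_range,
        n_points=int(x.size),
    )


def _ols_weighted(x, y, w):
    xw, yw = x * w, y * w
    A = np.column_stack([xw, w])
    coef, _, _, _ = np.linalg.lstsq(A, yw, rcond=None)
    slope, intercept = coef
    resid = w * (y - (intercept + slope * x))
    n = x.size
    sigma = np.sqrt(float(np.sum(resid**2)) / (n - 2)) if n > 2 else 0.0
    yw_mean = np.average(y, weights=w**2)
    sst = float(np.sum((w * (y - yw_mean)) ** 2))
    ssr = float(np.sum(resid**2))
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    return float(slope), float(intercept), sigma, r2


def _linear_range(x_mg, y, mw, r2_cutoff):
    """Longest contiguous run of distinct levels whose fit has R^2 >= cutoff."""
    levels = np.unique(x_mg)
    k = levels.size
    best = ()
    for i in range(k):
        for j in range(i + 3, k + 1):  # >= 3 levels
            sel = np.isin(x_mg, levels[i:j])
            _, _, _, r2 = _ols(x_mg[sel] / mw, y[sel])
            if r2 >= r2_cutoff and (j - i) > len(best):
                best = tuple(levels[i:j])
    return best


def recovery(s0: float, s1: float, s3: float) -> float:
    """Spike recovery in percent: [(S3 - S0) / (S1 - S0)] / 3 x 100.

    S0/S1/S3 are the quantified levels in unspiked matrix and in matrix
    spiked with one and three portions of the reference mix.  Undefined
    (raises) when the 1x spike does not rise above background.
    """
    if s1 <= s0:
        raise QuantifyError("recovery undefined: 1x spike not above background")
    return (s3 - s0) / (s1 - s0) / 3.0 * 100.0


@dataclass(frozen=True)
class PrecisionAssay:
    """Intra-day and inter-day coefficients of variation (percent)."""

    analyte_id: str
    intra_day_cov_pct: float
    inter_day_cov_pct: float
    n_per_day: dict


def _cov_pct(values: np.ndarray) -> float:
    m = values.mean()
    if m == 0:
        raise QuantifyError("COV undefined: zero mean")
    return float(values.std(ddof=1) / m * 100.0)


def precision_cov(
    amounts: Sequence[float],
    days: Sequence,
    analyte_id: str = "",
) -> PrecisionAssay:
    """Replicate precision: per-day COVs averaged (intra-day) and the COV of
    the pooled multi-day set (inter-day).  Needs >= 2 replicates per day."""
    v = np.asarray(amounts, dtype=float)
    d = np.asarray(days)
    if v.size != d.size:
        raise QuantifyError("amounts and days differ in length")
    per_day = {}
    intra = []
    for day in pd.unique(d):
        sel = v[d == day]
        if sel.size < 2:
            raise QuantifyError(f"day {day!r}: needs >= 2 replicates")
        per_day[day] = int(sel.size)
        intra.append(_cov_pct(sel))
    return PrecisionAssay(
        analyte_id=analyte_id,
        intra_day_cov_pct=float(np.mean(intra)),
        inter_day_cov_pct=_cov_pct(v),
        n_per_day=per_day,
    )
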