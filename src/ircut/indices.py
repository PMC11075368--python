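"""Surrogate insulin-resistance indices computed from raw cohort measurements.

All functions are pure and vectorized.  Unit contracts are strict: glucose
mg/dL, insulin µIU/mL, triglycerides and HDL mg/dL, leptin ng/mL,
adiponectin µg/mL, waist/height cm, weight kg.  Conversions to mmol/L use
TG/88.57 and HDL/38.67.

The Matsuda whole-body insulin-sensitivity index uses the four sampled OGTT
timepoints (0, 30, 60, 120 min) with equal weights:

    Matsuda = 10000 / sqrt(G0 * I0 * mean(G) * mean(I))

Lower Matsuda values indicate insulin resistance.  LAP and VAI use the male
formulas (the emulated cohort is all men).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError

OGTT_MINUTES = (0, 30, 60, 120)

MG_DL_PER_MMOL_TG = 88.57
MG_DL_PER_MMOL_HDL = 38.67

#: panel columns evaluated against the Matsuda reference (report order);
#: the Matsuda index itself is first.
TABLE2_VARIABLES = (
    "matsuda",
    "bmi",
    "wc",
    "whtr",
    "tfm_pct",
    "af_pct",
    "homa_ir",
    "leptin",
    "lar",
    "quicki",
    "tyg",
    "tg_hdl",
    "tyg_wc",
    "tyg_whtr",
    "tyg_bmi",
    "lap",
    "vai",
    "fasting_glucose",
    "glucose_60",
    "glucose_120",
    "fasting_insulin",
)


def _require_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        idx = np.flatnonzero(~(np.isfinite(arr) & (arr > 0)))
        raise DomainError(f"{name} must be strictly positive and finite "
                          f"(first offending position: {int(idx[0])})")
    return arr


def compute_matsuda(glucose_series, insulin_series) -> np.ndarray | float:
    """Matsuda index from OGTT series sampled at 0/30/60/120 min.

    Accepts length-4 sequences (one subject) or (n, 4) arrays.
    """
    g = np.atleast_2d(np.asarray(glucose_series, dtype=float))
    i = np.atleast_2d(np.asarray(insulin_series, dtype=float))
    if g.shape[-1] != 4 or i.shape[-1] != 4:
        raise DomainError("OGTT series must have exactly the 4 timepoints 0/30/60/120 min")
    for t, col in enumerate(OGTT_MINUTES):
        _require_positive(f"glucose at {col} min", g[:, t])
        _require_positive(f"insulin at {col} min", i[:, t])
    out = 10000.0 / np.sqrt(g[:, 0] * i[:, 0] * g.mean(axis=1) * i.mean(axis=1))
    return out if np.ndim(glucose_series) == 2 else float(out[0])


def homa_ir(fasting_glucose, fasting_insulin):
    """HOMA-IR = (G0[mg/dL] * I0[uIU/mL]) / 405; higher = more resistant."""
    g = _require_positive("fasting glucose", fasting_glucose)
    i = _require_positive("fasting insulin", fasting_insulin)
    return g * i / 405.0


def quicki(fasting_glucose, fasting_insulin):
    """QUICKI = 1 / (log10 I0 + log10 G0); lower = more resistant."""
    g = _require_positive("fasting glucose", fasting_glucose)
    i = _require_positive("fasting insulin", fasting_insulin)
    return 1.0 / (np.log10(i) + np.log10(g))


def tyg(tg, fasting_glucose):
    """TyG = ln(TG[mg/dL] * G0[mg/dL]) / 2."""
    t = _require_positive("triglycerides", tg)
    g = _require_positive("fasting glucose", fasting_glucose)
    return np.log(t * g) / 2.0


def lap_male(wc_cm, tg):
    """Lipid accumulation product, male: (WC - 65) * TG[mmol/L]."""
    w = _require_positive("waist circumference", wc_cm)
    t = _require_positive("triglycerides", tg)
    if np.any(w <= 65.0):
        raise DomainError("LAP requires waist circumference > 65 cm (male formula)")
    return (w - 65.0) * (t / MG_DL_PER_MMOL_TG)


def vai_male(wc_cm, bmi, tg, hdl):
    """Visceral adiposity index, male formula (lipids converted to mmol/L)."""
    w = _require_positive("waist circumference", wc_cm)
    b = _require_positive("BMI", bmi)
    t = _require_positive("triglycerides", tg) / MG_DL_PER_MMOL_TG
    h = _require_positive("HDL cholesterol", hdl) / MG_DL_PER_MMOL_HDL
    return (w / (39.68 + 1.88 * b)) * (t / 1.03) * (1.31 / h)


def index_panel(cohort: pd.DataFrame) -> pd.DataFrame:
    """Compute every evaluated index/measurement for each cohort row.

    Input follows the cohort schema of :mod:`ircut.io`.  Output has one row
    per subject with all derived indices plus the raw measurements that are
    themselves evaluated as predictors (WC, fat fractions, leptin, glucose
    and insulin values).  ``subject_id`` and, when present, ``true_group``
    are carried through.
    """
    g_series = cohort[[f"glucose_{t}" for t in OGTT_MINUTES]].to_numpy(dtype=float)
    i_series = cohort[[f"insulin_{t}" for t in OGTT_MINUTES]].to_numpy(dtype=float)

    height_m = _require_positive("height", cohort["height_cm"]) / 100.0
    bmi = _require_positive("weight", cohort["weight_kg"]) / height_m**2
    wc = _require_positive("waist circumference", cohort["wc_cm"])
    whtr = wc / (height_m * 100.0)
    g0 = g_series[:, 0]
    i0 = i_series[:, 0]
    tyg_v = tyg(cohort["tg"], g0)
    leptin = _require_positive("leptin", cohort["leptin"])
    adiponectin = _require_positive("adiponectin", cohort["adiponectin"])

    panel = pd.DataFrame(
        {
            "matsuda": compute_matsuda(g_series, i_series),
            "bmi": bmi,
            "wc": wc,
            "whtr": whtr,
            "tfm_pct": cohort["tfm_pct"].to_numpy(dtype=float),
            "af_pct": cohort["af_pct"].to_numpy(dtype=float),
            "homa_ir": homa_ir(g0, i0),
            "leptin": leptin,
            "lar": leptin / adiponectin,
            "quicki": quicki(g0, i0),
            "tyg": tyg_v,
            "tg_hdl": _require_positive("triglycerides", cohort["tg"])
            / _require_positive("HDL cholesterol", cohort["hdl"]),
            "tyg_wc": tyg_v * wc,
            "tyg_whtr": tyg_v * whtr,
            "tyg_bmi": tyg_v * bmi,
            "lap": lap_male(wc, cohort["tg"]),
            "vai": vai_male(wc, bmi, cohort["tg"], cohort["hdl"]),
            "fasting_glucose": g0,
            "glucose_60": g_series[:, 2],
            "glucose_120": g_series[:, 3],
            "fasting_insulin": i0,
        },
        index=cohort.index,
    )
    for carried in ("true_group", "subject_id"):
        if carried in cohort.columns:
            panel.insert(0, carried, cohort[carried].to_numpy())
    return panel
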