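"""Phenotype derivation: AAM exclusions and categories, NCEP-ATP III MetS status.

Turns a raw cohort table (one row per woman) into analysis-ready variables:

* exclusion filtering on implausible / missing age at menarche (AAM),
* the six ordered AAM categories with 16 years as the reference,
* the binary early-menarche indicator (AAM <= 12),
* the five metabolic-syndrome component flags and overall MetS status
  (three or more adverse components).

Cutoff boundaries follow the printed criteria exactly: ">=" inclusive,
"<" strict. Medication flags force their component regardless of the
measured value. Missing component inputs propagate to a missing MetS
status with a recorded reason; nothing is imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C

__all__ = [
    "ExclusionReport",
    "AamCategory",
    "MetSProfile",
    "apply_exclusions",
    "categorize_aam",
    "categorize_aam_column",
    "classify_mets",
    "phenotype_cohort",
]


@dataclass(frozen=True)
class ExclusionReport:
    """Counts of rows removed per exclusion rule, in application order."""

    n_input: int
    n_aam_le10: int
    n_aam_ge19: int
    n_aam_missing: int
    n_retained: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"input rows: {self.n_input}\n"
            f"excluded AAM <= 10: {self.n_aam_le10}\n"
            f"excluded AAM >= 19: {self.n_aam_ge19}\n"
            f"excluded AAM missing: {self.n_aam_missing}\n"
            f"retained: {self.n_retained}\n"
        )


@dataclass(frozen=True)
class AamCategory:
    category: str  # one of constants.AAM_CATEGORIES
    early: bool    # category == "<=12"

    @property
    def is_reference(self) -> bool:
        return self.category == C.REFERENCE_CATEGORY


@dataclass(frozen=True)
class MetSProfile:
    central_obesity: bool | None
    high_tg: bool | None
    low_hdl: bool | None
    hypertension: bool | None
    high_fg: bool | None
    n_criteria: int | None
    mets: bool | None
    missing_reason: str | None = None


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop women with AAM <= 10, >= 19 or missing; report counts per reason.

    Rules are applied in that fixed order so the per-reason counts are
    reproducible. Returns a copy; the input is not modified.
    """
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    aam = pd.to_numeric(cohort["aam"], errors="coerce")
    le10 = aam.notna() & (aam <= 10)
    ge19 = aam.notna() & (aam >= 19)
    missing = aam.isna()
    keep = ~(le10 | ge19 | missing)
    report = ExclusionReport(
        n_input=len(cohort),
        n_aam_le10=int(le10.sum()),
        n_aam_ge19=int(ge19.sum()),
        n_aam_missing=int(missing.sum()),
        n_retained=int(keep.sum()),
    )
    return cohort.loc[keep].copy(), report


def categorize_aam(aam: float) -> AamCategory:
    """Map a single retained AAM (integer years, 11..18) to its category.

    11-12 pool into the early category "<=12"; 13..16 are their own
    categories; 17-18 pool into ">=17". Values outside [11, 18] are a
    caller error: run :func:`apply_exclusions` first.
    """
    if aam is None or (isinstance(aam, float) and np.isnan(aam)):
        raise ValueError("AAM is missing; apply exclusions first")
    if aam != int(aam):
        raise ValueError(f"AAM must be an integer year, got {aam!r}")
    a = int(aam)
    if not (C.AAM_MIN <= a <= C.AAM_MAX):
        raise ValueError(f"AAM {a} outside retained range [{C.AAM_MIN}, {C.AAM_MAX}]")
    if a <= 12:
        cat = "<=12"
    elif a >= 17:
        cat = ">=17"
    else:
        cat = str(a)
    return AamCategory(category=cat, early=(cat == C.EARLY_CATEGORY))


def categorize_aam_column(aam: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Vectorised categorisation of a retained AAM column.

    Returns (ordered categorical series, boolean early-indicator series).
    """
    vals = pd.to_numeric(aam, errors="raise")
    if vals.isna().any():
        raise ValueError("missing AAM present; apply exclusions first")
    if ((vals < C.AAM_MIN) | (vals > C.AAM_MAX)).any():
        bad = vals[(vals < C.AAM_MIN) | (vals > C.AAM_MAX)].unique()
        raise ValueError(f"AAM values outside [11, 18]: {sorted(bad)}")
    labels = np.select(
        [vals <= 12, vals >= 17],
        ["<=12", ">=17"],
        default="",
    )
    labels = np.where(labels == "", vals.astype(int).astype(str), labels)
    cats = pd.Series(
        pd.Categorical(labels, categories=list(C.AAM_CATEGORIES), ordered=True),
        index=aam.index,
        name="aam_category",
    )
    early = pd.Series(cats == C.EARLY_CATEGORY, index=aam.index, name="early")
    return cats, early


_MET_COMPONENTS = ("wc", "tg", "hdl", "sbp", "dbp", "fg")


def classify_mets(row) -> MetSProfile:
    """NCEP-ATP III MetS profile for one woman (mapping or Series).

    Components: WC >= 85 cm (Korean cutoff), TG >= 150 mg/dl, HDL < 50
    mg/dl, SBP >= 130 or DBP >= 85 mmHg or antihypertensive medication,
    FG >= 100 mg/dl or antidiabetic medication. MetS requires >= 3.

    A missing measured component yields a missing profile with the reason
    recorded, unless the relevant medication flag already forces it.
    """
    def _get(key):
        v = row[key] if key in row else None
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    aht = bool(_get("antihypertensive_med") or False)
    adm = bool(_get("antidiabetic_med") or False)
    vals = {k: _get(k) for k in _MET_COMPONENTS}

    def _flag(value, fn, med=False):
        if med:
            return True
        if value is None:
            return None
        return bool(fn(value))

    central = _flag(vals["wc"], lambda v: v >= C.WC_CUTOFF_CM)
    high_tg = _flag(vals["tg"], lambda v: v >= C.TG_CUTOFF_MGDL)
    low_hdl = _flag(vals["hdl"], lambda v: v < C.HDL_CUTOFF_MGDL)
    if aht:
        hyper = True
    elif vals["sbp"] is None or vals["dbp"] is None:
        hyper = None
    else:
        hyper = vals["sbp"] >= C.SBP_CUTOFF_MMHG or vals["dbp"] >= C.DBP_CUTOFF_MMHG
    high_fg = _flag(vals["fg"], lambda v: v >= C.FG_CUTOFF_MGDL, med=adm)

    flags = (central, high_tg, low_hdl, hyper, high_fg)
    if any(f is None for f in flags):
        missing = [
            name
            for name, f in zip(
                ("central_obesity", "high_tg", "low_hdl", "hypertension", "high_fg"),
                flags,
            )
            if f is None
        ]
        return MetSProfile(
            central_obesity=central, high_tg=high_tg, low_hdl=low_hdl,
            hypertension=hyper, high_fg=high_fg,
            n_criteria=None, mets=None,
            missing_reason="missing component(s): " + ", ".join(missing),
        )
    n = int(sum(flags))
    return MetSProfile(
        central_obesity=central, high_tg=high_tg, low_hdl=low_hdl,
        hypertension=hyper, high_fg=high_fg,
        n_criteria=n, mets=n >= C.METS_MIN_CRITERIA,
    )


def phenotype_cohort(cohort: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full phenotyping pass: exclusions, AAM categories, MetS columns.

    Returns an augmented copy with columns ``aam_category``, ``early``,
    the five component flags, ``n_criteria`` and ``mets`` (nullable
    booleans where inputs were missing), plus the exclusion report.
    """
    kept, report = apply_exclusions(cohort)
    cats, early = categorize_aam_column(kept["aam"])
    out = kept.copy()
    out["aam_category"] = cats
    out["early"] = early.astype(int)
    profiles = [classify_mets(r) for _, r in out.iterrows()]
    for field in ("central_obesity", "high_tg", "low_hdl", "hypertension",
                  "high_fg", "n_criteria", "mets"):
        out[field] = pd.array(
            [getattr(p, field) for p in profiles],
            dtype="Int64" if field == "n_criteria" else "boolean",
        )
    out["mets_missing_reason"] = [p.missing_reason for p in profiles]
    return out, report
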