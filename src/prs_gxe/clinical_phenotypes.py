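"""Derived clinical variables for the glycaemia cohort.

Covers the homeostasis-model insulin indices (HOMA-IR, HOMA-B), HbA1c unit
conversion (NGSP % to IFCC mmol/mol), the 75 g OGTT gestational-diabetes
classification used by the Finnish Current Care guidelines, the postpartum
IFG/IGT/T2D classification, the 0-18-point healthy food intake index (HFII)
and the 0-5-point lifestyle-goal success score.

All glucose values are venous plasma glucose in mmol/l; insulin is in
pmol/l and converted internally to µU/ml.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .errors import ValidationError

__all__ = [
    "OgttRecord",
    "VisitRecord",
    "DietActivityRecord",
    "GlycaemicDiagnosis",
    "homa_ir",
    "homa_b",
    "hba1c_pct_to_mmol_mol",
    "diagnose_gdm",
    "classify_early_and_booking",
    "classify_postpartum",
    "hfii_score",
    "success_score",
    "INSULIN_PMOL_PER_UU",
]

log = logging.getLogger(__name__)

#: Conversion factor: 1 µU/ml of insulin = 6.0 pmol/l (common clinical
#: convention; configurable per call).
INSULIN_PMOL_PER_UU = 6.0

#: OGTT thresholds (mmol/l) for GDM in pregnancy: 0 h, 1 h, 2 h.
GDM_CUTOFFS = (5.3, 10.0, 8.6)

#: Postpartum bands (mmol/l).
IFG_BAND = (6.1, 6.9)
IGT_BAND = (7.8, 11.0)
T2D_FASTING = 7.0
T2D_2H = 11.1

TIMEPOINTS = ("pre_pregnancy", "T1", "T2", "T3", "pp6wk", "pp6mo", "pp12mo")


def _is_missing(x: Optional[float]) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class OgttRecord:
    """2 h 75 g OGTT plasma glucose triple; the 1 h draw may be absent."""

    glucose_0h: Optional[float] = None
    glucose_1h: Optional[float] = None
    glucose_2h: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("glucose_0h", "glucose_1h", "glucose_2h"):
            v = getattr(self, name)
            if not _is_missing(v) and v <= 0:
                raise ValidationError(f"{name}={v} must be positive")


@dataclass
class VisitRecord:
    """One study visit's measurements."""

    timepoint: str
    fasting_glucose: Optional[float] = None
    fasting_insulin: Optional[float] = None
    hba1c_pct: Optional[float] = None
    ogtt: Optional[OgttRecord] = None
    physician_diagnosed_diabetes: bool = False

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )


#: (field, max points) for the 11 HFII diet-quality components.
HFII_COMPONENTS = (
    ("snacks", 2),
    ("sugar_sweetened_beverages", 1),
    ("fast_food", 1),
    ("high_fibre_grains", 2),
    ("fat_spread", 2),
    ("low_fat_cheese", 1),
    ("low_fat_milk", 2),
    ("fish", 2),
    ("red_processed_meat", 2),
    ("vegetables", 2),
    ("fruits_berries", 1),
)


@dataclass
class DietActivityRecord:
    """Diet-quality component points plus the five lifestyle-goal inputs."""

    snacks: int = 0
    sugar_sweetened_beverages: int = 0
    fast_food: int = 0
    high_fibre_grains: int = 0
    fat_spread: int = 0
    low_fat_cheese: int = 0
    low_fat_milk: int = 0
    fish: int = 0
    red_processed_meat: int = 0
    vegetables: int = 0
    fruits_berries: int = 0
    fibre_g_per_day: Optional[float] = None
    fruit_veg_portions_per_day: Optional[float] = None
    saturated_fat_pct_energy: Optional[float] = None
    gwg_category: Optional[Literal["below", "adequate", "above"]] = None
    pa_min_per_week: Optional[float] = None


@dataclass(frozen=True)
class GlycaemicDiagnosis:
    """Postpartum glycaemic state; ``abnormal`` iff the label is not normal."""

    label: Literal["normal", "IFG", "IGT", "IFG+IGT", "T2D"]
    abnormal: bool

    def __post_init__(self) -> None:
        if self.abnormal != (self.label != "normal"):
            raise ValidationError("abnormal flag inconsistent with label")


def homa_ir(
    fasting_glucose: float,
    fasting_insulin: float,
    insulin_pmol_per_uu: float = INSULIN_PMOL_PER_UU,
) -> float:
    """HOMA insulin-resistance index: glucose [mmol/l] x insulin [µU/ml] / 22.5.

    ``fasting_insulin`` is given in pmol/l. Missing inputs propagate as nan.
    """
    if _is_missing(fasting_glucose) or _is_missing(fasting_insulin):
        return math.nan
    if fasting_glucose <= 0:
        raise ValidationError("fasting glucose must be positive")
    if fasting_insulin < 0:
        raise ValidationError("fasting insulin must be non-negative")
    return fasting_glucose * (fasting_insulin / insulin_pmol_per_uu) / 22.5


def homa_b(
    fasting_glucose: float,
    fasting_insulin: float,
    insulin_pmol_per_uu: float = INSULIN_PMOL_PER_UU,
) -> float:
    """HOMA beta-cell secretion index: 20 x insulin [µU/ml] / (glucose - 3.5).

    Undefined at or below 3.5 mmol/l fasting glucose (the model's
    singularity); missing inputs propagate as nan.
    """
    if _is_missing(fasting_glucose) or _is_missing(fasting_insulin):
        return math.nan
    if fasting_glucose <= 3.5:
        raise ValidationError(
            f"HOMA-B undefined for fasting glucose {fasting_glucose} <= 3.5 mmol/l"
        )
    if fasting_insulin < 0:
        raise ValidationError("fasting insulin must be non-negative")
    return 20.0 * (fasting_insulin / insulin_pmol_per_uu) / (fasting_glucose - 3.5)


def hba1c_pct_to_mmol_mol(hba1c_pct: float) -> int:
    """Convert NGSP HbA1c (%) to IFCC mmol/mol via the master equation
    ``10.929 x (pct - 2.15)``, rounded to the nearest integer."""
    if _is_missing(hba1c_pct):
        raise ValidationError("HbA1c value is missing")
    if hba1c_pct <= 2.15:
        raise ValidationError(f"HbA1c {hba1c_pct}% is at or below the 2.15% intercept")
    return int(round(10.929 * (hba1c_pct - 2.15)))


def diagnose_gdm(ogtt: Optional[OgttRecord]) -> Optional[bool]:
    """GDM from one OGTT: any value at or above its cut-off (0 h >= 5.3,
    1 h >= 10.0, 2 h >= 8.6 mmol/l) is diagnostic. Returns ``None`` when no
    value was measured (a missing OGTT is not a negative one)."""
    if ogtt is None:
        return None
    values = (ogtt.glucose_0h, ogtt.glucose_1h, ogtt.glucose_2h)
    present = [(v, cut) for v, cut in zip(values, GDM_CUTOFFS) if not _is_missing(v)]
    if not present:
        return None
    return any(v >= cut for v, cut in present)


def classify_early_and_booking(
    visits: Sequence[VisitRecord],
    recruitment: Literal["pre_pregnancy", "early_pregnancy"],
) -> tuple[Optional[bool], Optional[bool]]:
    """Early-GDM and booking-GDM flags from the first-trimester OGTT.

    Early GDM is a positive first-trimester OGTT for anyone. Booking GDM is
    defined only for women recruited in early pregnancy, whose enrolment
    OGTT is the first-trimester one; pre-pregnancy recruits cannot have
    booking GDM. A missing first-trimester OGTT yields missing flags.
    """
    if recruitment not in ("pre_pregnancy", "early_pregnancy"):
        raise ValidationError(f"unknown recruitment arm {recruitment!r}")
    t1 = next((v for v in visits if v.timepoint == "T1" and v.ogtt is not None), None)
    early = diagnose_gdm(t1.ogtt) if t1 is not None else None
    if early is None:
        return None, None
    booking = bool(early) if recruitment == "early_pregnancy" else False
    return bool(early), booking


def classify_postpartum(visit: VisitRecord) -> Optional[GlycaemicDiagnosis]:
    """Classify a postpartum visit into normal / IFG / IGT / IFG+IGT / T2D.

    Bands: IFG fasting 6.1-6.9, IGT 2 h 7.8-11.0; T2D fasting >= 7.0 or
    2 h >= 11.1 mmol/l (all inclusive). Prior physician-diagnosed diabetes
    forces an abnormal (T2D) classification. Returns ``None`` when nothing
    is measured and no diagnosis flag is set.
    """
    fg = visit.fasting_glucose
    g2 = visit.ogtt.glucose_2h if visit.ogtt is not None else None
    if visit.physician_diagnosed_diabetes:
        return GlycaemicDiagnosis("T2D", True)
    if _is_missing(fg) and _is_missing(g2):
        return None
    if (not _is_missing(fg) and fg >= T2D_FASTING) or (
        not _is_missing(g2) and g2 >= T2D_2H
    ):
        return GlycaemicDiagnosis("T2D", True)
    # Bands are printed for one-decimal measurements (6.1-6.9, 7.8-11.0);
    # read them as contiguous half-open intervals up to the T2D cut-offs so
    # the classification is monotone in glucose.
    ifg = not _is_missing(fg) and IFG_BAND[0] <= fg < T2D_FASTING
    igt = not _is_missing(g2) and IGT_BAND[0] <= g2 < T2D_2H
    if ifg and igt:
        return GlycaemicDiagnosis("IFG+IGT", True)
    if igt:
        return GlycaemicDiagnosis("IGT", True)
    if ifg:
        return GlycaemicDiagnosis("IFG", True)
    return GlycaemicDiagnosis("normal", False)


def hfii_score(record: DietActivityRecord) -> int:
    """Healthy food intake index: sum of the 11 component points (0-18)."""
    total = 0
    for name, mx in HFII_COMPONENTS:
        v = getattr(record, name)
        if v is None or not (0 <= v <= mx) or int(v) != v:
            raise ValidationError(f"HFII component {name}={v!r} outside 0..{mx}")
        total += int(v)
    return total


def success_score(record: DietActivityRecord) -> tuple[int, bool]:
    """Lifestyle-goal score (0-5) and the success flag (>= 3 points).

    One point each for fibre >= 30 g/day, >= 5 fruit/vegetable/berry
    portions/day, saturated fat < 10% of energy, gestational weight gain
    adequate or below per the IOM categories, and >= 150 min/week of
    moderate physical activity. A missing goal input contributes 0 points
    and is logged.
    """
    points = 0
    missing = []
    goals = (
        ("fibre_g_per_day", lambda v: v >= 30),
        ("fruit_veg_portions_per_day", lambda v: v >= 5),
        ("saturated_fat_pct_energy", lambda v: v < 10),
        ("gwg_category", lambda v: v in ("below", "adequate")),
        ("pa_min_per_week", lambda v: v >= 150),
    )
    for name, met in goals:
        v = getattr(record, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            missing.append(name)
            continue
        if met(v):
            points += 1
    if missing:
        log.info("success_score: missing goal inputs scored 0: %s", missing)
    return points, points >= 3


# ---------------------------------------------------------------------------
# Cohort-table derivation

#: Map cohort-CSV HFII column -> DietActivityRecord field.
_HFII_CSV_FIELDS = {
    "hfii_snacks": "snacks",
    "hfii_ssb": "sugar_sweetened_beverages",
    "hfii_fast_food": "fast_food",
    "hfii_grains": "high_fibre_grains",
    "hfii_fat_spread": "fat_spread",
    "hfii_cheese": "low_fat_cheese",
    "hfii_milk": "low_fat_milk",
    "hfii_fish": "fish",
    "hfii_meat": "red_processed_meat",
    "hfii_vegetables": "vegetables",
    "hfii_fruits": "fruits_berries",
}


def _opt(row, col) -> Optional[float]:
    if col not in row.index:
        return None
    v = row[col]
    return None if _is_missing(v) else float(v)


def derive_cohort_phenotypes(cohort: "pandas.DataFrame") -> "pandas.DataFrame":  # noqa: F821
    """Add every derived clinical column to a cohort table.

    Expects the documented cohort CSV layout (``ogtt_t1_0h`` ...,
    ``fg_<visit>``, ``insulin_<visit>``, ``hba1c_<visit>``, ``hfii_*``, goal
    inputs, ``recruitment``, ``physician_diabetes``) and adds, where the
    inputs exist: ``homa_ir_<visit>``, ``homa_b_<visit>``,
    ``hba1c_mmol_<visit>``, ``gdm``, ``early_gdm``, ``booking_gdm``,
    ``pp12_label``, ``pp12_abnormal``, ``hfii``, ``success_score`` and
    ``success``. Missing inputs yield missing outputs, never silent zeros.
    """
    import pandas as pd

    out = cohort.copy()
    visits = ("t1", "t2", "t3", "pp6wk", "pp6mo", "pp12")
    for v in visits:
        fg, ins, hb = f"fg_{v}", f"insulin_{v}", f"hba1c_{v}"
        if fg in out.columns and ins in out.columns:
            out[f"homa_ir_{v}"] = [
                homa_ir(g, i) if not (_is_missing(g) or _is_missing(i)) else math.nan
                for g, i in zip(out[fg], out[ins])
            ]
            out[f"homa_b_{v}"] = [
                homa_b(g, i)
                if not (_is_missing(g) or _is_missing(i)) and g > 3.5
                else math.nan
                for g, i in zip(out[fg], out[ins])
            ]
        if hb in out.columns:
            out[f"hba1c_mmol_{v}"] = [
                float(hba1c_pct_to_mmol_mol(x)) if not _is_missing(x) else math.nan
                for x in out[hb]
            ]

    def _ogtt(row, prefix):
        vals = [_opt(row, f"{prefix}_{h}") for h in ("0h", "1h", "2h")]
        if all(v is None for v in vals):
            return None
        return OgttRecord(*vals)

    gdm, early, booking, pp_label, pp_abn = [], [], [], [], []
    for _, row in out.iterrows():
        t1 = _ogtt(row, "ogtt_t1")
        t2 = _ogtt(row, "ogtt_t2")
        d_t1, d_t2 = diagnose_gdm(t1), diagnose_gdm(t2)
        if d_t1 is None and d_t2 is None:
            gdm.append(math.nan)
        else:
            gdm.append(float(bool(d_t1) or bool(d_t2)))
        recruit = row.get("recruitment", "pre_pregnancy")
        t1_visit = [VisitRecord("T1", ogtt=t1)] if t1 is not None else []
        e, b = classify_early_and_booking(t1_visit, recruit)
        early.append(math.nan if e is None else float(e))
        booking.append(math.nan if b is None else float(b))

        pp_visit = VisitRecord(
            "pp12mo",
            fasting_glucose=_opt(row, "fg_pp12"),
            ogtt=OgttRecord(glucose_2h=_opt(row, "g2h_pp12"))
            if _opt(row, "g2h_pp12") is not None
            else None,
            physician_diagnosed_diabetes=bool(row.get("physician_diabetes", 0)),
        )
        diag = classify_postpartum(pp_visit)
        pp_label.append(diag.label if diag is not None else None)
        pp_abn.append(math.nan if diag is None else float(diag.abnormal))

    out["gdm"], out["early_gdm"], out["booking_gdm"] = gdm, early, booking
    out["pp12_label"], out["pp12_abnormal"] = pp_label, pp_abn

    if all(c in out.columns for c in _HFII_CSV_FIELDS):
        hfii_vals, sscores, succ = [], [], []
        for _, row in out.iterrows():
            rec = DietActivityRecord(
                **{f: int(row[c]) for c, f in _HFII_CSV_FIELDS.items()},
                fibre_g_per_day=_opt(row, "fibre_g"),
                fruit_veg_portions_per_day=_opt(row, "fruit_veg_portions"),
                saturated_fat_pct_energy=_opt(row, "sat_fat_pct"),
                gwg_category=row.get("gwg_category"),
                pa_min_per_week=_opt(row, "pa_min_week"),
            )
            hfii_vals.append(hfii_score(rec))
            s, ok = success_score(rec)
            sscores.append(s)
            succ.append(float(ok))
        out["hfii"], out["success_score"], out["success"] = hfii_vals, sscores, succ
    return out
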