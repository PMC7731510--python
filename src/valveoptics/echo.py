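"""Echocardiographic volume/function formulas and ordinal IHC score grading.

M-mode left-ventricle internal dimensions at diastole (LVIDd) and systole
(LVIDs), in mm, convert to volumes via the Teichholz cube-correction

    V(D) = 7.0 * D^3 / (2.4 + D)        [uL]

giving end-diastolic and end-systolic volumes EDV = V(LVIDd), ESV = V(LVIDs),
ejection fraction EF = (LVIDd^3 - LVIDs^3) * 100 / LVIDd^3 (%), and cardiac
output CO = (EDV - ESV) * HR (uL/min). A literal variant V(D) = (7.0 + D^3) /
(2.4 + D) is kept behind a flag for auditability against sources that print
the formula that way.

Immunohistochemistry panels are scored 0 (no/low), 1 (moderate) or 2 (high
expression) by multiple blinded raters; the rater mean maps to an ordinal
grade: "-" for a mean of exactly 0, "+" for (0, 2/3], "++" for (2/3, 4/3] and
"+++" above 4/3. Boundaries use exact rational arithmetic — the printed cut
points 0.66 and 1.33 are rounded thirds.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

IHC_MARKERS = ("aSMA", "vimentin", "RUNX2", "osteopontin", "BMP4", "Ki67", "TGFb1")
GRADES = ("-", "+", "++", "+++")

_LOW_CUT = Fraction(2, 3)
_HIGH_CUT = Fraction(4, 3)


@dataclass
class EchoRecord:
    """One echo measurement with derived volumes and function indices."""

    lvidd: float  # mm
    lvids: float  # mm
    hr: float  # beats/min
    edv: float  # uL
    esv: float  # uL
    ef: float  # %
    co: float  # uL/min
    literal_volumes: bool = False


def teichholz_volume(d: float) -> float:
    """LV volume (uL) from internal diameter (mm), Teichholz correction."""
    return 7.0 * d**3 / (2.4 + d)


def literal_volume(d: float) -> float:
    """Literal printed rendering (7.0 + D^3)/(2.4 + D); audit variant."""
    return (7.0 + d**3) / (2.4 + d)


def echo_derive(lvidd: float, lvids: float, hr: float, literal_volumes: bool = False) -> EchoRecord:
    """Derive EDV, ESV, EF and CO from M-mode diameters and heart rate."""
    if lvidd <= 0:
        raise ValueError(f"LVIDd must be > 0 mm, got {lvidd}")
    if lvids < 0 or lvids > lvidd:
        raise ValueError(f"need 0 <= LVIDs <= LVIDd, got LVIDs={lvids}, LVIDd={lvidd}")
    if hr <= 0:
        raise ValueError(f"heart rate must be > 0, got {hr}")

    vol = literal_volume if literal_volumes else teichholz_volume
    edv, esv = vol(lvidd), vol(lvids)
    ef = (lvidd**3 - lvids**3) * 100.0 / lvidd**3
    co = (edv - esv) * hr
    return EchoRecord(
        lvidd=lvidd, lvids=lvids, hr=hr, edv=edv, esv=esv, ef=ef, co=co,
        literal_volumes=literal_volumes,
    )


def echo_derive_table(table: pd.DataFrame, literal_volumes: bool = False) -> pd.DataFrame:
    """Append edv_ul, esv_ul, ef_pct, co_ul_min columns to an echo table with
    lvidd_mm, lvids_mm, hr_bpm columns."""
    out = table.copy()
    recs = [
        echo_derive(r.lvidd_mm, r.lvids_mm, r.hr_bpm, literal_volumes)
        for r in table.itertuples()
    ]
    out["edv_ul"] = [r.edv for r in recs]
    out["esv_ul"] = [r.esv for r in recs]
    out["ef_pct"] = [r.ef for r in recs]
    out["co_ul_min"] = [r.co for r in recs]
    return out


@dataclass
class ScorePanel:
    """Aggregated rater scores for one marker/region: exact mean and grade."""

    scores: tuple[int, ...]
    mean: Fraction
    grade: str
    marker: str | None = None


def grade_from_mean(mean: Fraction) -> str:
    """Map an exact mean rater score in [0, 2] to the -/+/++/+++ scale."""
    if mean < 0 or mean > 2:
        raise ValueError(f"mean score outside [0, 2]: {mean}")
    if mean == 0:
        return "-"
    if mean <= _LOW_CUT:
        return "+"
    if mean <= _HIGH_CUT:
        return "++"
    return "+++"


def aggregate_scores(scores, marker: str | None = None, n_raters: int = 3) -> ScorePanel:
    """Aggregate per-rater expression scores (each in {0, 1, 2}) to a grade."""
    scores = tuple(scores)
    if len(scores) != n_raters:
        raise ValueError(f"expected {n_raters} rater scores, got {len(scores)}")
    for s in scores:
        if s not in (0, 1, 2):
            raise ValueError(f"rater score must be 0, 1 or 2, got {s!r}")
    mean = Fraction(sum(scores), len(scores))
    return ScorePanel(scores=scores, mean=mean, grade=grade_from_mean(mean), marker=marker)


def aggregate_score_table(table: pd.DataFrame, n_raters: int = 3) -> pd.DataFrame:
    """Grade a score table with rater1..raterN columns; adds mean_score and
    grade columns."""
    rater_cols = [f"rater{i}" for i in range(1, n_raters + 1)]
    missing = [c for c in rater_cols if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing rater columns: {missing}")
    out = table.copy()
    panels = [
        aggregate_scores([int(row[c]) for c in rater_cols], n_raters=n_raters)
        for _, row in table.iterrows()
    ]
    out["mean_score"] = [float(p.mean) for p in panels]
    out["grade"] = [p.grade for p in panels]
    return out
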