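"""Visual-field covariates: binocular summation, reliability, classification.

Standard automated perimetry (SAP, 24-2 pattern) measures light sensitivity
in decibels at 54 test locations per eye; the two locations covering the
physiologic blind spot are excluded, leaving 52.  The monocular fields of the
two eyes are combined into an integrated binocular field by quadratic
(Nelson-Quigg) summation of linear sensitivities, whose mean is the
"binocular SAP sensitivity" covariate used in the survival analysis.

Reliability filtering and abnormality classification follow the usual
clinical rules: a field is unreliable with more than 33% fixation losses or
false negatives or more than 15% false positives; a field is abnormal when
the pattern standard deviation is depressed at P < 0.05 and/or the glaucoma
hemifield test is outside normal limits; glaucoma requires at least three
consecutive abnormal fields, or documented progressive optic-disc change
regardless of the fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GRID_24_2",
    "N_LOCATIONS",
    "VisualFieldPair",
    "BinocularField",
    "binocular_summation",
    "reliability_filter",
    "classify_abnormal",
    "classify_glaucoma",
]


def _build_grid() -> tuple[tuple[float, float], ...]:
    # 24-2 pattern: rows of test points 6 degrees apart, offset 3 degrees from
    # the meridians, with the nasal row extended to 27 degrees; the two points
    # at (15, +/-3) fall on the blind spot and are excluded.
    half_widths = {21: 9, 15: 15, 9: 21, 3: 21}
    pts = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        hw = half_widths[abs(y)]
        xs = list(range(-hw, hw + 1, 6))
        if abs(y) == 3:
            xs = [-27] + xs  # nasal extension
        for x in xs:
            if abs(y) == 3 and x == 15:
                continue  # blind spot
            pts.append((float(x), float(y)))
    return tuple(pts)


GRID_24_2 = _build_grid()
N_LOCATIONS = len(GRID_24_2)  # 52


@dataclass(frozen=True)
class VisualFieldPair:
    """One visit's monocular SAP results for both eyes plus summary indices.

    Sensitivities are decibels at the 52 non-blind-spot 24-2 locations; a
    value of ``-inf`` encodes an unmeasurable ("<0 dB") location whose linear
    sensitivity is floored at zero.
    """

    left_db: np.ndarray
    right_db: np.ndarray
    fixation_loss_pct: float = 0.0
    false_neg_pct: float = 0.0
    false_pos_pct: float = 0.0
    psd_p: float = 1.0
    ght_outside: bool = False

    def __post_init__(self):
        ld = np.asarray(self.left_db, dtype=float)
        rd = np.asarray(self.right_db, dtype=float)
        if ld.shape != rd.shape:
            raise ValueError("left and right fields must share the location grid")
        for arr in (ld, rd):
            if np.any(arr[np.isfinite(arr)] > 40.0) or np.any(arr[np.isfinite(arr)] < -10):
                raise ValueError("dB sensitivities expected within perimetric range")
        for name in ("fixation_loss_pct", "false_neg_pct", "false_pos_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        object.__setattr__(self, "left_db", ld)
        object.__setattr__(self, "right_db", rd)


@dataclass(frozen=True)
class BinocularField:
    """Integrated binocular visual field (dB per location, plus the mean)."""

    sensitivity_db: np.ndarray
    mean_sensitivity: float


def _db_to_linear(db: np.ndarray) -> np.ndarray:
    # perimetric convention: sensitivity in 1/Lambert, 10 dB per log unit
    db = np.asarray(db, dtype=float)
    with np.errstate(over="ignore"):
        lin = np.power(10.0, db / 10.0)
    return np.where(np.isneginf(db), 0.0, lin)


def binocular_summation(pair: VisualFieldPair) -> BinocularField:
    """Quadratic binocular summation of the two monocular fields.

    Per location, dB sensitivities are converted to linear scale
    ``S = 10**(dB/10)``, combined as ``sqrt(S_L**2 + S_R**2)`` and converted
    back to dB.  Two equal eyes therefore gain exactly ``5*log10(2)`` (about
    1.505 dB) over either eye alone, and a blind eye leaves the fellow eye's
    sensitivity unchanged.
    """
    sl = _db_to_linear(pair.left_db)
    sr = _db_to_linear(pair.right_db)
    combined = np.hypot(sl, sr)
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(combined)
    return BinocularField(sensitivity_db=db, mean_sensitivity=float(np.mean(db)))


def reliability_filter(pair: VisualFieldPair) -> tuple[bool, str | None]:
    """Retain or exclude a field on its reliability indices.

    Excluded when fixation losses or false negatives exceed 33% or false
    positives exceed 15% — strictly "more than", so fields exactly at a
    threshold are retained.

    Returns ``(retained, reason)`` with ``reason`` one of ``"fixation"``,
    ``"false-negative"``, ``"false-positive"`` or ``None``.
    """
    if pair.fixation_loss_pct > 33.0:
        return False, "fixation"
    if pair.false_neg_pct > 33.0:
        return False, "false-negative"
    if pair.false_pos_pct > 15.0:
        return False, "false-positive"
    return True, None


def classify_abnormal(pair: VisualFieldPair) -> bool:
    """A field is abnormal with PSD depressed at P < 0.05 and/or a glaucoma
    hemifield test outside normal limits."""
    return pair.psd_p < 0.05 or pair.ght_outside


def classify_glaucoma(
    series: Sequence[VisualFieldPair], progressive_disc: bool = False
) -> bool:
    """Glaucoma: >= 3 consecutive abnormal fields in a chronological,
    reliability-filtered series, or progressive optic-disc change regardless
    of the fields."""
    if progressive_disc:
        return True
    if len(series) == 0:
        raise ValueError("cannot classify: empty field series without disc evidence")
    run = longest = 0
    for pair in series:
        run = run + 1 if classify_abnormal(pair) else 0
        longest = max(longest, run)
    return longest >= 3
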