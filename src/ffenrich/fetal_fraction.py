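"""Fetal-fraction estimators: chrY read fraction and fragment-size features.

**chrY method** (male fetuses only): the chrY read fraction is linear in the
fetal fraction, interpolating between a female-pregnancy baseline ``b_f``
(mismapped reads) and the chrY fraction ``y_m`` of pure male tissue:
``FF = (observed - b_f) / (y_m - b_f)``.  Both constants are calibrated from
cohorts of known composition.

**Size method** (fetus-sex agnostic): samples with more fetal DNA carry more
short fragments (region A, 130-140 bp) and fewer long ones (region B,
155-175 bp).  Loess curves fit the chrY-labelled fetal fraction against each
region's read share in a male-fetus training cohort; at prediction time the
two curve readouts P_A and P_B are cross-checked through their relative
discrepancy ``P_diff = (P_A - P_B) * 2 / (P_A + P_B)``.  When |P_diff|
exceeds 0.40 the features disagree and the fetal fraction is unpredictable;
otherwise the estimate is ``P = (P_A + P_B) / 2``.  The printed discrepancy
formula is signed; the rule is applied to its magnitude, since a signed rule
could never flag the case P_B >> P_A.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loess import loess_smooth

REGION_A = (130, 140)   # half-open, bp
REGION_B = (155, 175)
PDIFF_CEILING = 0.40


@dataclass(frozen=True)
class FFEstimate:
    p_a: float | None
    p_b: float | None
    p_diff: float | None      # signed, as printed: (P_A - P_B) * 2/(P_A + P_B)
    p: float | None           # (P_A + P_B)/2 when predictable, else None
    predictable: bool
    method: str               # "chrY" | "size"


@dataclass(frozen=True)
class ChrYCalibration:
    """Linear calibration of the chrY read fraction against fetal fraction."""

    b_f: float    # female-pregnancy baseline chrY fraction
    y_m: float    # chrY fraction of pure male tissue

    def __post_init__(self) -> None:
        if not self.y_m > self.b_f:
            raise ValueError("invalid calibration: y_m must exceed b_f")


def chry_fraction(records: pd.DataFrame) -> float:
    if len(records) == 0:
        raise ValueError("empty fragment table")
    return float((records["chrom"] == "chrY").to_numpy().mean())


def ff_from_chry(records_or_fraction, cal: ChrYCalibration) -> float:
    """Fetal fraction from the chrY read fraction, clamped to [0, 1]."""
    y = records_or_fraction
    if not np.isscalar(y):
        y = chry_fraction(y)
    return float(np.clip((y - cal.b_f) / (cal.y_m - cal.b_f), 0.0, 1.0))


def calibrate_chry(
    male_samples: list[tuple[pd.DataFrame, float]],
    female_samples: list[pd.DataFrame] | None = None,
) -> ChrYCalibration:
    """Fit the calibration constants from a synthetic calibration cohort.

    ``male_samples`` are (fragments, known fetal fraction) pairs.  The chrY
    fraction is linear in the fetal fraction, so the regression intercept is
    the zero-fetal baseline ``b_f`` and intercept + slope extrapolates to
    pure male tissue ``y_m``.  A cohort of female-fetus pregnancies, when
    given, serves as a consistency check: its mean chrY fraction is the
    baseline diluted by the maternal share and must not exceed ``b_f`` by
    more than trivial sampling noise.
    """
    if len(male_samples) < 2:
        raise ValueError("need >= 2 male calibration samples")
    ffs = np.array([ff for _, ff in male_samples])
    ys = np.array([chry_fraction(s) for s, _ in male_samples])
    slope, intercept = np.polyfit(ffs, ys, 1)
    cal = ChrYCalibration(b_f=float(intercept), y_m=float(intercept + slope))
    if female_samples:
        female_mean = float(np.mean([chry_fraction(s) for s in female_samples]))
        if female_mean > cal.b_f * 1.5 + 1e-4:
            raise ValueError(
                "female-pregnancy chrY fraction inconsistent with the "
                "male-cohort baseline; check the calibration cohorts"
            )
    return cal


# ----------------------------------------------------------------------
# size-based estimator


def size_ratios(
    records: pd.DataFrame,
    region_a: tuple[int, int] = REGION_A,
    region_b: tuple[int, int] = REGION_B,
) -> tuple[float, float]:
    """Read shares of the short (A) and long (B) length regions (half-open)."""
    n = len(records)
    if n == 0:
        raise ValueError("empty fragment table")
    lengths = records["length"].to_numpy()
    r_a = float(((lengths >= region_a[0]) & (lengths < region_a[1])).sum() / n)
    r_b = float(((lengths >= region_b[0]) & (lengths < region_b[1])).sum() / n)
    return r_a, r_b


@dataclass(frozen=True)
class SizeFFModel:
    """Two fitted loess curves mapping region read ratios to fetal fraction.

    The curves are stored as sorted (knot, fitted value) arrays and evaluated
    by linear interpolation; predictions outside the training range are
    clamped to the range edge.
    """

    xa: np.ndarray
    ya: np.ndarray
    xb: np.ndarray
    yb: np.ndarray
    span: float = 0.75
    region_a: tuple[int, int] = REGION_A
    region_b: tuple[int, int] = REGION_B

    def predict_a(self, r_a: float) -> float:
        return float(np.interp(r_a, self.xa, self.ya))

    def predict_b(self, r_b: float) -> float:
        return float(np.interp(r_b, self.xb, self.yb))

    def in_range(self, r_a: float, r_b: float) -> bool:
        return (self.xa[0] <= r_a <= self.xa[-1]
                and self.xb[0] <= r_b <= self.xb[-1])

    # -- serialization --------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "xa": self.xa.tolist(), "ya": self.ya.tolist(),
            "xb": self.xb.tolist(), "yb": self.yb.tolist(),
            "span": self.span,
            "region_a": list(self.region_a), "region_b": list(self.region_b),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SizeFFModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            xa=np.asarray(payload["xa"]), ya=np.asarray(payload["ya"]),
            xb=np.asarray(payload["xb"]), yb=np.asarray(payload["yb"]),
            span=payload["span"],
            region_a=tuple(payload["region_a"]),
            region_b=tuple(payload["region_b"]),
        )


def _fit_curve(x: np.ndarray, y: np.ndarray, span: float):
    """Loess fit collapsed onto unique sorted knots (ties become weights)."""
    ux, inverse, counts = np.unique(x, return_inverse=True, return_counts=True)
    if len(ux) < 2:
        raise ValueError("degenerate feature range in training data")
    uy = np.bincount(inverse, weights=y) / counts
    fitted = loess_smooth(ux, uy, span=span, degree=2, weights=counts.astype(float))
    return ux, fitted


def train_size_ff_model(
    training: list[tuple[pd.DataFrame, float]] | list[tuple[tuple[float, float], float]],
    span: float = 0.75,
    min_samples: int = 30,
    region_a: tuple[int, int] = REGION_A,
    region_b: tuple[int, int] = REGION_B,
) -> SizeFFModel:
    """Fit the two region-ratio -> fetal-fraction loess curves.

    ``training`` pairs each sample (a fragment table, or a precomputed
    ``(r_A, r_B)`` tuple) with its fetal-fraction label — in practice the
    chrY estimate of a male-fetus sample.
    """
    if len(training) < min_samples:
        raise ValueError(f"need >= {min_samples} training samples")
    ra, rb, ff = [], [], []
    for sample, label in training:
        if isinstance(sample, pd.DataFrame):
            a, b = size_ratios(sample, region_a, region_b)
        else:
            a, b = sample
        ra.append(a)
        rb.append(b)
        ff.append(label)
    ra, rb, ff = map(np.asarray, (ra, rb, ff))
    xa, ya = _fit_curve(ra, ff, span)
    xb, yb = _fit_curve(rb, ff, span)
    return SizeFFModel(xa=xa, ya=ya, xb=xb, yb=yb, span=span,
                       region_a=region_a, region_b=region_b)


def estimate_ff_size(
    model: SizeFFModel,
    r_a: float,
    r_b: float,
    pdiff_ceiling: float = PDIFF_CEILING,
) -> FFEstimate:
    """Predict the fetal fraction from the two size features.

    Predictable iff ``|P_diff| <= pdiff_ceiling`` (the boundary itself is
    predictable: the rule flags only strictly larger discrepancies).
    """
    p_a = max(0.0, model.predict_a(r_a))
    p_b = max(0.0, model.predict_b(r_b))
    total = p_a + p_b
    if total <= 0:
        return FFEstimate(p_a=p_a, p_b=p_b, p_diff=None, p=None,
                          predictable=False, method="size")
    p_diff = (p_a - p_b) * 2.0 / total
    predictable = abs(p_diff) <= pdiff_ceiling
    p = (p_a + p_b) / 2.0 if predictable else None
    return FFEstimate(p_a=p_a, p_b=p_b, p_diff=p_diff, p=p,
                      predictable=predictable, method="size")


def estimate_ff_size_from_records(
    model: SizeFFModel, records: pd.DataFrame,
    pdiff_ceiling: float = PDIFF_CEILING,
) -> FFEstimate:
    r_a, r_b = size_ratios(records, model.region_a, model.region_b)
    return estimate_ff_size(model, r_a, r_b, pdiff_ceiling)
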