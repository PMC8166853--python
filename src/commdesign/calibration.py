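"""Measurement-side calibrations and sample quality control.

Covers the phenol-red pH standard curve (a Henderson-Hasselbalch form fitted
by linear regression on the log-absorbance term), conversion of sequencing
relative abundances to absolute abundances via OD600, per-biomass
normalization of metabolite concentrations, and the read-count/contamination
sample-exclusion rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PhStandardCurve",
    "fit_ph_curve",
    "ph_from_absorbance",
    "absorbance_from_ph",
    "absolute_abundance",
    "qc_filter",
    "per_biomass",
    "CalibrationError",
]

VALID_PH_RANGE = (5.2, 11.0)
QC_CONTAMINATION_FRAC = 0.01   # >1% reads from unexpected species
QC_MIN_READS = 1000            # <1000 reads AND OD600 > 0.1 excludes
QC_OD_THRESHOLD = 0.1


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class PhStandardCurve:
    """pH = pKa + b * log10((A - A_min) / (A_max - A)) with absorbance A at
    560 nm bounded by the pH-3 (A_min) and pH-11 (A_max) standards."""

    pKa: float
    b: float
    A_min: float
    A_max: float
    valid_ph_range: tuple[float, float] = VALID_PH_RANGE

    def __post_init__(self) -> None:
        if not self.A_min < self.A_max:
            raise CalibrationError("A_min must be less than A_max")
        if not np.isfinite(self.b) or self.b == 0:
            raise CalibrationError("slope b must be finite and nonzero")


def fit_ph_curve(standards: list[tuple[float, float]]) -> PhStandardCurve:
    """Fit (pKa, b) by ordinary least squares of pH on the log term.

    ``standards`` are (pH, absorbance) pairs; the pH 3 and pH 11 standards
    define A_min and A_max and do not enter the regression.  Standards
    outside the linear pH range [5.2, 11] or with absorbance outside
    (A_min, A_max) are excluded (with a warning for the latter).
    """
    standards = [(float(p), float(a)) for p, a in standards]
    by_ph = {round(p, 6): a for p, a in standards}
    try:
        A_min = by_ph[3.0]
        A_max = by_ph[11.0]
    except KeyError:
        raise CalibrationError("standards must include pH 3 and pH 11 anchors")

    lo, hi = VALID_PH_RANGE
    ph_vals, log_terms = [], []
    for p, a in standards:
        if not (lo <= p <= hi) or p == 11.0:
            continue
        if not (A_min < a < A_max):
            warnings.warn(f"standard at pH {p} has absorbance outside (A_min, A_max); excluded")
            continue
        ph_vals.append(p)
        log_terms.append(np.log10((a - A_min) / (A_max - a)))
    if len(ph_vals) < 3:
        raise CalibrationError(
            f"need at least 3 usable standards in the linear range, got {len(ph_vals)}"
        )
    b, pKa = np.polyfit(log_terms, ph_vals, 1)
    return PhStandardCurve(pKa=float(pKa), b=float(b), A_min=A_min, A_max=A_max)


def ph_from_absorbance(curve: PhStandardCurve, A: float) -> float:
    """Invert an absorbance reading to pH; raises outside (A_min, A_max)."""
    if not (curve.A_min < A < curve.A_max):
        raise CalibrationError(
            f"absorbance {A} outside the calibrated range ({curve.A_min}, {curve.A_max})"
        )
    return curve.pKa + curve.b * np.log10((A - curve.A_min) / (curve.A_max - A))


def absorbance_from_ph(curve: PhStandardCurve, ph: float) -> float:
    """Forward map pH -> absorbance (the inverse of :func:`ph_from_absorbance`)."""
    z = 10.0 ** ((ph - curve.pKa) / curve.b)
    return (curve.A_min + curve.A_max * z) / (1.0 + z)


def absolute_abundance(relative: np.ndarray, od600: float) -> np.ndarray:
    """Absolute abundance = relative abundance x OD600."""
    relative = np.asarray(relative, dtype=float)
    if np.any(relative < 0):
        raise CalibrationError("relative abundances must be non-negative")
    if abs(relative.sum() - 1.0) > 1e-6:
        raise CalibrationError(
            f"relative abundances must sum to 1 (got {relative.sum():.8f})"
        )
    if od600 < 0:
        raise CalibrationError("od600 must be non-negative")
    return relative * od600


def per_biomass(value_mM: float, od600: float) -> float:
    """Concentration per unit biomass (mM OD600^-1)."""
    if od600 <= 0:
        raise CalibrationError("per-biomass normalization undefined for OD600 <= 0")
    return value_mM / od600


def qc_filter(
    samples: pd.DataFrame,
    read_prefix: str = "reads_",
    contamination_frac: float = QC_CONTAMINATION_FRAC,
    min_reads: int = QC_MIN_READS,
    od_threshold: float = QC_OD_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the sample-exclusion rules to an experiment table.

    A sample is excluded if strictly more than 1% of its reads map to species
    outside its expected membership (contamination), or if it has strictly
    fewer than 1000 total reads while OD600 is strictly above 0.1
    (insufficient reads not explained by lack of growth).  Low-read samples
    with OD600 <= 0.1 are retained as genuinely non-growing communities.

    ``samples`` must carry ``sample_id``, ``community`` ("+"-joined expected
    members), ``od600``, and per-species read-count columns named
    ``reads_<id>``.  Returns (retained table, exclusion log).
    """
    read_cols = [c for c in samples.columns if c.startswith(read_prefix)]
    if not read_cols or "od600" not in samples.columns:
        raise ValueError("table must contain od600 and read-count columns")
    species = [c[len(read_prefix):] for c in read_cols]

    keep = np.ones(len(samples), dtype=bool)
    log_rows = []
    counts = samples[read_cols].to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    for i, (_, row) in enumerate(samples.iterrows()):
        expected = set(str(row["community"]).split("+"))
        unexpected_mask = np.array([s not in expected for s in species])
        total = totals[i]
        unexpected_frac = counts[i, unexpected_mask].sum() / total if total > 0 else 0.0
        od = float(row["od600"])
        if unexpected_frac > contamination_frac:
            keep[i] = False
            log_rows.append(
                dict(sample_id=row.get("sample_id", i), rule="contamination",
                     unexpected_fraction=unexpected_frac, total_reads=total, od600=od)
            )
        elif total < min_reads and od > od_threshold:
            keep[i] = False
            log_rows.append(
                dict(sample_id=row.get("sample_id", i), rule="insufficient reads",
                     unexpected_fraction=unexpected_frac, total_reads=total, od600=od)
            )
    exclusion_log = pd.DataFrame(
        log_rows,
        columns=["sample_id", "rule", "unexpected_fraction", "total_reads", "od600"],
    )
    return samples.loc[keep].reset_index(drop=True), exclusion_log
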