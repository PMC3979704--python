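"""Diagnostic accuracy of NIPT for Down's syndrome: per-study and pooled estimates.

Eight published validity studies are shipped as a CSV fixture of 2×2 counts
(true/false positives and negatives).  Sensitivity and specificity are simple
binomial proportions with Wilson score confidence intervals; pooling sums the
counts element-wise before re-estimating.

Note: the published summary row of the source table (tp 736, fn 5, tn 11601,
fp 6) does not equal the column sums of its own eight study rows (701, 5,
11480, 6).  The published counts are kept as :data:`PUBLISHED_MERGED` so the
printed merged cells can be reproduced verbatim; :func:`merge_studies` always
reports the sums it actually computes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
from scipy.stats import norm


@dataclass(frozen=True)
class Study2x2:
    """One study's 2×2 validity table."""

    study_label: str
    sequencing_approach: str  # "whole-genome" or "targeted"
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            value = getattr(self, name)
            if not isinstance(value, (int,)) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")


@dataclass(frozen=True)
class AccuracyEstimate:
    """Point estimates and 95% CIs, on the percentage scale."""

    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]


def wilson_interval(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, as proportions in [0, 1]."""
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError(f"require 0 <= successes <= n with n > 0, got ({successes}, {n})")
    z = norm.ppf(0.5 + level / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    # boundary counts give exact bounds (avoids float residue at 0 and 1)
    low = 0.0 if successes == 0 else max(0.0, centre - half)
    high = 1.0 if successes == n else min(1.0, centre + half)
    return low, high


def accuracy_from_counts(study: Study2x2, level: float = 0.95) -> AccuracyEstimate:
    """Sensitivity/specificity with Wilson CIs from one 2×2 table."""
    if study.tp + study.fn == 0:
        raise ValueError(f"{study.study_label}: sensitivity undefined (tp + fn == 0)")
    if study.tn + study.fp == 0:
        raise ValueError(f"{study.study_label}: specificity undefined (tn + fp == 0)")
    sens = study.tp / (study.tp + study.fn)
    spec = study.tn / (study.tn + study.fp)
    s_lo, s_hi = wilson_interval(study.tp, study.tp + study.fn, level)
    p_lo, p_hi = wilson_interval(study.tn, study.tn + study.fp, level)
    return AccuracyEstimate(
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        sens_ci=(100.0 * s_lo, 100.0 * s_hi),
        spec_ci=(100.0 * p_lo, 100.0 * p_hi),
    )


def merge_studies(studies: list[Study2x2]) -> tuple[Study2x2, AccuracyEstimate]:
    """Pool studies by element-wise count summation, then re-estimate."""
    if not studies:
        raise ValueError("cannot merge an empty study list")
    pooled = Study2x2(
        study_label="Merged data",
        sequencing_approach="mixed",
        tp=sum(s.tp for s in studies),
        fn=sum(s.fn for s in studies),
        tn=sum(s.tn for s in studies),
        fp=sum(s.fp for s in studies),
    )
    return pooled, accuracy_from_counts(pooled)


#: Published pooled counts of the eight validity studies, kept verbatim because
#: they do not equal the column sums of the printed per-study rows.
PUBLISHED_MERGED = Study2x2(
    study_label="Merged data (as published)",
    sequencing_approach="mixed",
    tp=736,
    fn=5,
    tn=11601,
    fp=6,
)


def load_studies(path: str | Path | None = None) -> list[Study2x2]:
    """Load study 2×2 tables from CSV (columns: study,approach,tp,fn,tn,fp).

    With no path, loads the packaged eight-study fixture.
    """
    if path is None:
        with resources.files("niptscreen.data").joinpath("nipt_validity_studies.csv").open() as fh:
            frame = pd.read_csv(fh)
    else:
        frame = pd.read_csv(path)
    expected = ["study", "approach", "tp", "fn", "tn", "fp"]
    if list(frame.columns) != expected:
        raise ValueError(f"expected header {','.join(expected)}, got {list(frame.columns)}")
    return [
        Study2x2(
            study_label=row.study,
            sequencing_approach=row.approach,
            tp=int(row.tp),
            fn=int(row.fn),
            tn=int(row.tn),
            fp=int(row.fp),
        )
        for row in frame.itertuples()
    ]


def accuracy_table(studies: list[Study2x2] | None = None) -> pd.DataFrame:
    """Per-study and pooled accuracy in the published table layout."""
    studies = studies if studies is not None else load_studies()
    rows = []
    for study in studies + [merge_studies(studies)[0]]:
        est = accuracy_from_counts(study)
        rows.append(
            {
                "study": study.study_label,
                "approach": study.sequencing_approach,
                "tp": study.tp,
                "fn": study.fn,
                "tn": study.tn,
                "fp": study.fp,
                "sensitivity_pct": est.sensitivity,
                "sens_ci_low": est.sens_ci[0],
                "sens_ci_high": est.sens_ci[1],
                "specificity_pct": est.specificity,
                "spec_ci_low": est.spec_ci[0],
                "spec_ci_high": est.spec_ci[1],
            }
        )
    return pd.DataFrame(rows)
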