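"""Cohort-definition computations for semen-quality study designs.

Three pieces: aggregation and approval classification of sperm morphology
defect percentages; derived CASA kinematic ratios (STR/LIN/WOB); and
quartile allocation of samples into Low/Moderate vs High motility groups.

Morphology convention: *major* defects are acrosomal abnormalities, head
defects, vacuoles, proximal cytoplasmic droplet (PCD) and midpiece damage;
*minor* defects are detached head and bent tail.  A sample fails approval
when major defects exceed 20% or total abnormalities (major + minor)
exceed 30% — strict inequalities, so a sample sitting exactly on a
boundary is approved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ValidationError

MAJOR_COMPONENTS = ("acrosome", "head", "vacuoles", "pcd", "midpiece")
MINOR_COMPONENTS = ("detached_head", "bent_tail")

MAJOR_LIMIT = 20.0   # % — approval fails when major defects exceed this
TOTAL_LIMIT = 30.0   # % — or when total abnormalities exceed this


def _check_percent(value: float, name: str) -> None:
    if not (0.0 <= value <= 100.0):
        raise ValidationError(f"{name} = {value} outside [0, 100] %")


@dataclass
class MorphologyRecord:
    """Defect percentages for one sample (% of >= 100 assessed spermatozoa).

    ``major``/``minor``/``total`` may be supplied directly (they are then
    authoritative — upstream per-sample rounding can make a reported major
    differ from the component sum) or left ``None`` to be derived by
    :func:`aggregate_defects`.
    """

    sample: str
    acrosome: float = 0.0
    head: float = 0.0
    vacuoles: float = 0.0
    pcd: float = 0.0
    midpiece: float = 0.0
    detached_head: float = 0.0
    bent_tail: float = 0.0
    major: float | None = None
    minor: float | None = None
    total: float | None = None
    approved: bool | None = None

    def __post_init__(self) -> None:
        for name in MAJOR_COMPONENTS + MINOR_COMPONENTS:
            _check_percent(getattr(self, name), name)
        for name in ("major", "minor", "total"):
            v = getattr(self, name)
            if v is not None:
                _check_percent(v, name)


def aggregate_defects(record: MorphologyRecord) -> MorphologyRecord:
    """Fill major/minor/total from components (given values take precedence)."""
    major = record.major
    if major is None:
        major = sum(getattr(record, n) for n in MAJOR_COMPONENTS)
    minor = record.minor
    if minor is None:
        minor = sum(getattr(record, n) for n in MINOR_COMPONENTS)
    total = record.total
    if total is None:
        total = major + minor
    record.major, record.minor, record.total = major, minor, total
    record.approved = classify_morphology(major, total)
    return record


def classify_morphology(major: float, total: float) -> bool:
    """Approval flag: True (approved) unless major > 20% or total > 30%."""
    _check_percent(major, "major")
    _check_percent(total, "total")
    return not (major > MAJOR_LIMIT or total > TOTAL_LIMIT)


@dataclass
class KinematicsRecord:
    """CASA output for one sample; STR/LIN/WOB are derived, not measured."""

    sample: str
    total_motility: float | None = None   # %
    progressive_motility: float | None = None  # %
    dap: float | None = None   # mean path distance, um
    dcl: float | None = None   # curvilinear distance, um
    dsl: float | None = None   # straight-line distance, um
    vap: float | None = None   # average path velocity, um/s
    vcl: float | None = None   # curvilinear velocity, um/s
    vsl: float | None = None   # straight-line velocity, um/s
    alh: float | None = None   # lateral head displacement, um
    bcf: float | None = None   # beat-cross frequency, Hz
    str_pct: float | None = None
    lin_pct: float | None = None
    wob_pct: float | None = None
    flags: list[str] = field(default_factory=list)


def derive_kinematics(record: KinematicsRecord) -> KinematicsRecord:
    """Fill STR = 100*VSL/VAP, LIN = 100*VSL/VCL, WOB = 100*VAP/VCL.

    Zero denominators leave the ratio undefined (None) with a flag; a
    violation of the expected velocity ordering VSL <= VAP <= VCL is
    flagged but the ratios are still computed.
    """
    vsl, vap, vcl = record.vsl, record.vap, record.vcl
    for m in ("total_motility", "progressive_motility"):
        v = getattr(record, m)
        if v is not None:
            _check_percent(v, m)
    if vsl is None or vap is None or vcl is None:
        record.flags.append("missing velocity; ratios not derived")
        return record
    if not (vsl <= vap <= vcl):
        record.flags.append(f"velocity ordering violated: VSL={vsl}, VAP={vap}, VCL={vcl}")
    if vap > 0:
        record.str_pct = 100.0 * vsl / vap
    else:
        record.flags.append("VAP = 0; STR undefined")
    if vcl > 0:
        record.lin_pct = 100.0 * vsl / vcl
        record.wob_pct = 100.0 * vap / vcl
    else:
        record.flags.append("VCL = 0; LIN/WOB undefined")
    return record


def quartile_groups(
    values: pd.Series | dict[str, float],
    *,
    low_label: str = "Low/Moderate",
    high_label: str = "High",
) -> pd.DataFrame:
    """Allocate samples to motility cohorts by quartiles.

    Values at or below the first quartile form the low/moderate group;
    values strictly above the third quartile form the high group; the
    middle is left unassigned.  Quartiles use linear interpolation between
    order statistics (numpy default) — group membership near Q1/Q3 depends
    on the quantile convention, so it is fixed and documented here.
    """
    series = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    if len(series) < 4:
        raise ContractError(f"quartile grouping needs >= 4 values, got {len(series)}")
    q1, q3 = np.quantile(series.to_numpy(dtype=float), [0.25, 0.75])
    degenerate = q1 == q3
    group = []
    for v in series:
        if v <= q1:
            group.append(low_label)
        elif v > q3:
            group.append(high_label)
        else:
            group.append("")
    return pd.DataFrame(
        {
            "sample": series.index,
            "value": series.to_numpy(),
            "group": group,
            "q1": q1,
            "q3": q3,
            "degenerate": degenerate,
        }
    )


def group_summary(
    values_a: np.ndarray | list[float],
    values_b: np.ndarray | list[float],
    *,
    labels: tuple[str, str] = ("A", "B"),
    test: str = "student",
    alpha: float = 0.05,
) -> dict:
    """Mean +/- SEM per group and a two-tailed unpaired t-test between them."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs n >= 2")
    if test not in {"student", "welch"}:
        raise ContractError(f"unknown test variant {test!r}")
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    out = {"t": float(res.statistic), "p": float(res.pvalue),
           "significant": bool(res.pvalue < alpha)}
    for label, arr in zip(labels, (a, b)):
        out[label] = {
            "n": len(arr),
            "mean": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / np.sqrt(len(arr))),
        }
    return out
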