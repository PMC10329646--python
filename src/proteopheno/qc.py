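"""Aptamer-level quality control and normalization.

The cascade mirrors standard aptamer-proteomics processing: (1) drop
aptamers whose plate scale factor diverges from the plate median by more
than 0.5; (2) drop aptamers whose median cross-plate coefficient of
variation exceeds 0.15; (3) mask values outside 1.5 x IQR fences; (4) a
two-stage call-rate filter (< 65% then, after recomputation, < 85%)
applied to both samples and aptamers; (5) per-aptamer log10 + z-score
normalization.

Conventions that the upstream description leaves open, fixed here and
configurable: IQR outliers are set missing (not winsorized); quartiles use
linear interpolation (numpy's default, "type 7"); z-scores use the sample
standard deviation (ddof=1); the scale-factor rule fires if any single
plate diverges; stage-2 call-rate removal handles aptamers before samples.
All thresholds are strict inequalities, so a value exactly at a boundary
is retained.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ProteinMatrix

logger = logging.getLogger(__name__)


def _check_positive(values: pd.DataFrame) -> None:
    with np.errstate(invalid="ignore"):
        bad = values.le(0)
    if bad.any().any():
        apt = bad.any(axis=0).idxmax()
        smp = bad[apt].idxmax()
        raise ValueError(f"nonpositive value at sample {smp!r}, aptamer {apt!r}")

__all__ = [
    "RawAptamerData",
    "QcReport",
    "filter_scale_factor",
    "filter_cv",
    "iqr_screen",
    "call_rate_cascade",
    "normalize",
    "run_qc",
]


@dataclass
class RawAptamerData:
    """Raw (RFU-like) measurements plus plate-level QC metadata.

    values: samples x aptamers, positive reals or NaN.
    plate_of: plate assignment per sample.
    scale_factors / cvs: plate x aptamer tables; either may be None (the
    5K-panel situation, where scale-factor and CV filtering is skipped).
    """

    values: pd.DataFrame
    plate_of: pd.Series
    scale_factors: pd.DataFrame | None = None
    cvs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.plate_of.index.equals(self.values.index):
            missing = self.values.index.difference(self.plate_of.index)
            if len(missing):
                raise ValueError(f"samples without plate assignment: {list(missing)[:5]}")
            self.plate_of = self.plate_of.loc[self.values.index]
        _check_positive(self.values)

    def drop_aptamers(self, aptamers) -> "RawAptamerData":
        keep = [a for a in self.values.columns if a not in set(aptamers)]
        return RawAptamerData(
            values=self.values[keep],
            plate_of=self.plate_of,
            scale_factors=None if self.scale_factors is None else self.scale_factors[keep],
            cvs=None if self.cvs is None else self.cvs[keep],
        )

    def drop_samples(self, samples) -> "RawAptamerData":
        keep = self.values.index.difference(pd.Index(samples), sort=False)
        return RawAptamerData(
            values=self.values.loc[keep],
            plate_of=self.plate_of.loc[keep],
            scale_factors=self.scale_factors,
            cvs=self.cvs,
        )


@dataclass
class QcReport:
    """Audit trail of the QC cascade: every removal with exactly one reason."""

    removed_aptamers: dict[str, dict[str, str]] = field(default_factory=dict)
    removed_samples: dict[str, list[str]] = field(default_factory=dict)
    n_iqr_masked: int = 0
    call_rate_before: dict[str, float] = field(default_factory=dict)
    call_rate_after: dict[str, float] = field(default_factory=dict)

    def record_aptamers(self, stage: str, reasons: dict[str, str]) -> None:
        if reasons:
            self.removed_aptamers.setdefault(stage, {}).update(reasons)

    def record_samples(self, stage: str, samples: list[str]) -> None:
        if samples:
            self.removed_samples.setdefault(stage, []).extend(samples)

    def all_removed_aptamers(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for stage, reasons in self.removed_aptamers.items():
            for apt, why in reasons.items():
                if apt in out:
                    raise ValueError(f"aptamer {apt} removed twice ({out[apt]} and {stage})")
                out[apt] = f"{stage}: {why}"
        return out

    def merge(self, other: "QcReport") -> "QcReport":
        for stage, reasons in other.removed_aptamers.items():
            self.record_aptamers(stage, reasons)
        for stage, samples in other.removed_samples.items():
            self.record_samples(stage, samples)
        self.n_iqr_masked += other.n_iqr_masked
        self.call_rate_before.update(other.call_rate_before)
        self.call_rate_after.update(other.call_rate_after)
        return self

    def to_dict(self) -> dict:
        return {
            "removed_aptamers": self.removed_aptamers,
            "removed_samples": self.removed_samples,
            "n_iqr_masked": self.n_iqr_masked,
        }


def filter_scale_factor(
    data: RawAptamerData, max_divergence: float = 0.5, per_plate: bool = True
) -> tuple[RawAptamerData, QcReport]:
    """Remove aptamers whose scale factor diverges from the median by more
    than ``max_divergence`` (strict), on any plate when ``per_plate`` else
    on the cross-plate aggregate."""
    report = QcReport()
    if data.scale_factors is None:
        logger.warning("no scale factors available; scale-factor filtering skipped")
        return data, report
    sf = data.scale_factors
    reasons: dict[str, str] = {}
    if per_plate:
        med = sf.median(axis=1)  # per-plate median over aptamers
        div = (sf.sub(med, axis=0)).abs()
        bad = div.max(axis=0) > max_divergence
        for apt in sf.columns[bad]:
            worst = div[apt].idxmax()
            reasons[apt] = (
                f"scale factor {sf.loc[worst, apt]:.3g} diverges from plate "
                f"{worst} median {med.loc[worst]:.3g} by more than {max_divergence}"
            )
    else:
        agg = sf.mean(axis=0)
        med = agg.median()
        bad = (agg - med).abs() > max_divergence
        for apt in sf.columns[bad]:
            reasons[apt] = f"aggregate scale factor {agg[apt]:.3g} diverges from median {med:.3g}"
    report.record_aptamers("scale_factor", reasons)
    return data.drop_aptamers(reasons), report


def filter_cv(data: RawAptamerData, max_cv: float = 0.15) -> tuple[RawAptamerData, QcReport]:
    """Remove aptamers whose median cross-plate CV exceeds ``max_cv`` (strict)."""
    report = QcReport()
    if data.cvs is None:
        logger.warning("no plate CVs available; CV filtering skipped")
        return data, report
    med = data.cvs.median(axis=0)
    reasons = {
        apt: f"median cross-plate CV {med[apt]:.3g} > {max_cv}"
        for apt in data.cvs.columns[med > max_cv]
    }
    report.record_aptamers("cv", reasons)
    return data.drop_aptamers(reasons), report


def iqr_screen(data: RawAptamerData, k: float = 1.5) -> tuple[RawAptamerData, QcReport]:
    """Mask values outside [Q1 - k*IQR, Q3 + k*IQR] per aptamer.

    Quartiles use linear interpolation; values exactly on a fence are kept.
    Aptamers with fewer than 4 non-missing values are skipped with a
    warning.
    """
    report = QcReport()
    values = data.values.copy()
    masked = 0
    for apt in values.columns:
        col = values[apt]
        obs = col.dropna()
        if len(obs) < 4:
            warnings.warn(f"aptamer {apt}: <4 non-missing values, IQR screen skipped")
            continue
        q1, q3 = np.quantile(obs.to_numpy(), [0.25, 0.75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        out = col.notna() & ((col < lo) | (col > hi))
        masked += int(out.sum())
        values.loc[out, apt] = np.nan
    report.n_iqr_masked = masked
    return (
        RawAptamerData(values, data.plate_of, data.scale_factors, data.cvs),
        report,
    )


def call_rate_cascade(
    data: RawAptamerData,
    first: float = 0.65,
    second: float = 0.85,
    aptamers_first: bool = True,
) -> tuple[RawAptamerData, QcReport]:
    """Two-stage call-rate filter on samples and aptamers.

    Stage 1 removes samples and aptamers with call rate < ``first``
    (evaluated on the incoming table); call rates are then recomputed on
    the surviving table and stage 2 removes at < ``second``, aptamers then
    samples by default (order configurable).
    """
    report = QcReport()
    values = data.values
    report.call_rate_before = {
        "aptamer_mean": float(values.notna().mean(axis=0).mean()),
        "sample_mean": float(values.notna().mean(axis=1).mean()),
    }

    apt_cr = values.notna().mean(axis=0)
    smp_cr = values.notna().mean(axis=1)
    bad_apts = {
        a: f"call rate {apt_cr[a]:.3g} < {first}" for a in values.columns[apt_cr < first]
    }
    bad_smps = list(values.index[smp_cr < first])
    report.record_aptamers("call_rate_1", bad_apts)
    report.record_samples("call_rate_1", bad_smps)
    data = data.drop_aptamers(bad_apts).drop_samples(bad_smps)
    if data.values.empty:
        raise ValueError("all samples or aptamers filtered at stage-1 call rate")

    def _stage2_aptamers(d: RawAptamerData) -> RawAptamerData:
        cr = d.values.notna().mean(axis=0)
        bad = {a: f"call rate {cr[a]:.3g} < {second}" for a in d.values.columns[cr < second]}
        report.record_aptamers("call_rate_2", bad)
        return d.drop_aptamers(bad)

    def _stage2_samples(d: RawAptamerData) -> RawAptamerData:
        cr = d.values.notna().mean(axis=1)
        bad = list(d.values.index[cr < second])
        report.record_samples("call_rate_2", bad)
        return d.drop_samples(bad)

    if aptamers_first:
        data = _stage2_samples(_stage2_aptamers(data))
    else:
        data = _stage2_aptamers(_stage2_samples(data))
    if data.values.empty:
        raise ValueError("all samples or aptamers filtered at stage-2 call rate")
    report.call_rate_after = {
        "aptamer_mean": float(data.values.notna().mean(axis=0).mean()),
        "sample_mean": float(data.values.notna().mean(axis=1).mean()),
    }
    return data, report


def normalize(
    data: RawAptamerData, annotations: pd.DataFrame | None = None
) -> tuple[ProteinMatrix, QcReport]:
    """Per-aptamer log10 then z-score over non-missing values (sample sd).

    Constant columns (sd 0 after log) are dropped with a warning.  A
    nonpositive value raises, naming the offending cell.
    """
    report = QcReport()
    values = data.values
    _check_positive(values)
    logged = np.log10(values)
    sd = logged.std(axis=0, ddof=1)
    constant = sd.index[(sd <= 1e-12) | sd.isna()]  # sd of a constant column can round to ~1e-16
    if len(constant):
        warnings.warn(f"dropping {len(constant)} constant aptamer(s): {list(constant)[:5]}")
        report.record_aptamers(
            "normalize", {a: "constant column (sd = 0)" for a in constant}
        )
        logged = logged.drop(columns=constant)
        sd = sd.drop(constant)
    z = (logged - logged.mean(axis=0)) / sd
    if annotations is not None:
        annotations = annotations.loc[annotations.index.intersection(z.columns)]
    else:
        annotations = pd.DataFrame(index=z.columns)
    return ProteinMatrix(values=z, annotations=annotations), report


def run_qc(
    data: RawAptamerData,
    annotations: pd.DataFrame | None = None,
    max_divergence: float = 0.5,
    max_cv: float = 0.15,
    iqr_k: float = 1.5,
    call_rate_first: float = 0.65,
    call_rate_second: float = 0.85,
) -> tuple[ProteinMatrix, QcReport]:
    """Run the full cascade: scale factor -> CV -> IQR -> call rate -> normalize."""
    n_in = data.values.shape[1]
    data, report = filter_scale_factor(data, max_divergence)
    data, r2 = filter_cv(data, max_cv)
    report.merge(r2)
    data, r3 = iqr_screen(data, iqr_k)
    report.merge(r3)
    data, r4 = call_rate_cascade(data, call_rate_first, call_rate_second)
    report.merge(r4)
    proteins, r5 = normalize(data, annotations)
    report.merge(r5)
    n_removed = sum(len(v) for v in report.removed_aptamers.values())
    assert n_in == proteins.values.shape[1] + n_removed, "QC bookkeeping mismatch"
    return proteins, report
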