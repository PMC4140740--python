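"""Precision statistics for repeated segmentations.

Implements the Glüer precision-error formulation for repeated-measures
designs (n subjects, each measured m times, e.g. by m raters):

    SD_j      per-subject standard deviation, (m - 1) denominator
    PE_SD     = sqrt( mean_j SD_j^2 )                    [metric units]
    CV_j      = SD_j / mean_j
    PE_%CV    = 100 * sqrt( mean_j CV_j^2 )              [percent]
    dof       = n * (m - 1); designs with dof >= 27 are flagged adequate

together with ICC(A,1) -- the two-way random-effects, absolute-agreement,
single-measurement intraclass correlation (McGraw & Wong):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

where MSR/MSC/MSE are the rows (subjects), columns (raters) and residual
mean squares of the two-way ANOVA and k = m.  PE quantifies how much
repeated masks of the same subject differ; ICC whether that error is small
enough to resolve differences *between* subjects.  Negative ICC values are
reported as computed, not clamped: they flag the degenerate situation where
between-subject variation is below the measurement error.

Voxel-level agreement between two masks of the same scan is quantified by
the Pearson correlation of the two binary fields over the padded bounding
box of the union of foregrounds (whole-scan background would inflate r
arbitrarily), and by an overlap map labelling common / A-only / B-only
regions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .morphometry import MorphometryResult, morphometry_all
from .volume_io import VoxelGrid

__all__ = [
    "RepeatedMeasuresTable",
    "PrecisionReport",
    "PairwiseMaskComparison",
    "PrecisionStudyResult",
    "precision_error",
    "icc_two_way_absolute_single",
    "pairwise_pearson",
    "overlap_map",
    "precision_study",
]

#: recommended minimum degrees of freedom for a precision study
DOF_RECOMMENDED = 27

#: labels of the overlap volume
OVERLAP_BACKGROUND, OVERLAP_COMMON, OVERLAP_A_ONLY, OVERLAP_B_ONLY = 0, 1, 2, 3


@dataclass
class RepeatedMeasuresTable:
    """n_subjects x m_repeats matrix of one morphometric metric."""

    values: np.ndarray
    metric_name: str = ""
    subject_ids: tuple[str, ...] = ()
    repeat_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("values must be a 2D subjects x repeats matrix")
        n, m = v.shape
        if n < 2:
            raise ValueError(f"need >= 2 subjects, got {n}")
        if m < 2:
            raise ValueError(f"need >= 2 repeats, got {m}")
        if not np.isfinite(v).all():
            raise ValueError("table contains missing or non-finite cells")
        self.values = v
        if not self.subject_ids:
            self.subject_ids = tuple(f"S{i+1}" for i in range(n))
        if not self.repeat_ids:
            self.repeat_ids = tuple(f"R{j+1}" for j in range(m))
        if len(self.subject_ids) != n or len(self.repeat_ids) != m:
            raise ValueError("id lengths do not match table shape")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def m_repeats(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PrecisionReport:
    """Precision summary for one metric."""

    metric_name: str
    mean: float
    pe_sd: float
    pe_pct_cv: float
    dof: int
    dof_ok: bool
    icc: float

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "mean": self.mean,
            "pe_sd": self.pe_sd,
            "pe_pct_cv": self.pe_pct_cv,
            "dof": self.dof,
            "dof_ok": self.dof_ok,
            "icc": self.icc,
        }


@dataclass(frozen=True)
class PairwiseMaskComparison:
    """Voxelwise agreement between two masks of the same scan."""

    pearson_r: float
    common_fraction: float
    a_only_fraction: float
    b_only_fraction: float


def precision_error(table: RepeatedMeasuresTable, icc: float | None = None) -> PrecisionReport:
    """Glüer precision errors (PE_SD, PE_%CV) for a repeated-measures table.

    If ``icc`` is not supplied it is computed with
    :func:`icc_two_way_absolute_single`.

    Raises
    ------
    ValueError
        If any subject mean is non-positive (CV undefined).
    """
    v = table.values
    n, m = v.shape
    means = v.mean(axis=1)
    if (means <= 0).any():
        bad = [table.subject_ids[i] for i in np.flatnonzero(means <= 0)]
        raise ValueError(f"non-positive subject mean(s) for {bad}: %CV undefined")
    sd = v.std(axis=1, ddof=1)
    pe_sd = float(np.sqrt(np.mean(sd**2)))
    cv = sd / means
    pe_pct_cv = 100.0 * float(np.sqrt(np.mean(cv**2)))
    dof = n * (m - 1)
    if icc is None:
        icc = icc_two_way_absolute_single(table)
    return PrecisionReport(
        metric_name=table.metric_name,
        mean=float(means.mean()),
        pe_sd=pe_sd,
        pe_pct_cv=pe_pct_cv,
        dof=dof,
        dof_ok=dof >= DOF_RECOMMENDED,
        icc=float(icc),
    )


def icc_two_way_absolute_single(table: RepeatedMeasuresTable) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measures."""
    v = table.values
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((v - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("ICC undefined: degenerate table (zero denominator)")
    return float((msr - mse) / denom)


def _union_bbox_domain(a: VoxelGrid, b: VoxelGrid, pad: int = 2) -> tuple[slice, ...]:
    union = a.data | b.data
    idx = np.nonzero(union)
    return tuple(
        slice(max(int(i.min()) - pad, 0), min(int(i.max()) + pad + 1, s))
        for i, s in zip(idx, union.shape)
    )


def _check_same_frame(a: VoxelGrid, b: VoxelGrid) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(f"mask shapes differ: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"mask spacings differ: {a.spacing} vs {b.spacing}")


def pairwise_pearson(a: VoxelGrid, b: VoxelGrid) -> float:
    """Pearson correlation of two binary masks of the same scan.

    Computed over the bounding box of the union of foregrounds padded by two
    voxels, so the score reflects boundary agreement rather than the amount
    of empty background included in the scan.
    """
    _check_same_frame(a, b)
    if not a.data.any() or not b.data.any():
        raise ValueError("r undefined: empty mask")
    dom = _union_bbox_domain(a, b)
    x = a.data[dom].ravel().astype(np.float64)
    y = b.data[dom].ravel().astype(np.float64)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("r undefined: constant field over the comparison domain")
    return float(np.corrcoef(x, y)[0, 1])


def overlap_map(a: VoxelGrid, b: VoxelGrid) -> tuple[PairwiseMaskComparison, np.ndarray]:
    """Label volume {0: background, 1: common, 2: a_only, 3: b_only} plus
    union-normalized fractions and the pairwise Pearson r."""
    _check_same_frame(a, b)
    union = a.data | b.data
    n_union = int(union.sum())
    if n_union == 0:
        raise ValueError("both masks empty")
    common = a.data & b.data
    a_only = a.data & ~b.data
    b_only = b.data & ~a.data
    labels = np.zeros(a.data.shape, dtype=np.uint8)
    labels[common] = OVERLAP_COMMON
    labels[a_only] = OVERLAP_A_ONLY
    labels[b_only] = OVERLAP_B_ONLY
    try:
        r = pairwise_pearson(a, b)
    except ValueError:
        r = float("nan")
    cmp = PairwiseMaskComparison(
        pearson_r=r,
        common_fraction=float(common.sum()) / n_union,
        a_only_fraction=float(a_only.sum()) / n_union,
        b_only_fraction=float(b_only.sum()) / n_union,
    )
    return cmp, labels


@dataclass
class PrecisionStudyResult:
    """Full output of a precision study."""

    reports: dict[str, PrecisionReport]
    morphometry: pd.DataFrame
    pairwise: pd.DataFrame
    pearson_mean: float
    pearson_sd: float
    tables: dict[str, RepeatedMeasuresTable] = field(default_factory=dict)


METRICS = ("cg_v", "cg_s", "cg_th")


def precision_study(
    masks: Mapping[str, Mapping[str, VoxelGrid]],
    compute_overlaps: bool = True,
    isotropic_target: float | None = None,
) -> PrecisionStudyResult:
    """Run morphometry on a complete subject x rater mask collection and
    assemble per-metric precision reports plus all rater-pair comparisons.

    Parameters
    ----------
    masks
        ``masks[subject_id][rater_id]`` -> :class:`VoxelGrid`.  The design
        must be complete (every subject segmented by every rater).
    """
    subjects = list(masks.keys())
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    raters = list(masks[subjects[0]].keys())
    if len(raters) < 2:
        raise ValueError("m_repeats < 2: need >= 2 raters/repeats")
    missing = [
        (s, r) for s in subjects for r in raters if r not in masks[s]
    ]
    extra = [
        (s, r) for s in subjects for r in masks[s] if r not in raters
    ]
    if missing or extra:
        raise ValueError(f"incomplete design: missing cells {missing}, unexpected {extra}")

    rows = []
    results: dict[tuple[str, str], MorphometryResult] = {}
    for s in subjects:
        for r in raters:
            res = morphometry_all(
                masks[s][r], specimen_id=f"{s}/{r}", isotropic_target=isotropic_target
            )
            results[(s, r)] = res
            rows.append(
                {"subject": s, "rater": r, "cg_v": res.cg_v, "cg_s": res.cg_s,
                 "cg_th": res.cg_th}
            )
    morpho = pd.DataFrame(rows)

    reports: dict[str, PrecisionReport] = {}
    tables: dict[str, RepeatedMeasuresTable] = {}
    for metric in METRICS:
        values = np.array(
            [[results[(s, r)].__getattribute__(metric) for r in raters] for s in subjects]
        )
        table = RepeatedMeasuresTable(
            values, metric_name=metric,
            subject_ids=tuple(subjects), repeat_ids=tuple(raters),
        )
        tables[metric] = table
        try:
            icc = icc_two_way_absolute_single(table)
        except ValueError:
            icc = float("nan")  # degenerate variance; PE is still defined
        reports[metric] = precision_error(table, icc=icc)

    pair_rows = []
    if compute_overlaps:
        for s in subjects:
            for ra, rb in itertools.combinations(raters, 2):
                cmp, _ = overlap_map(masks[s][ra], masks[s][rb])
                pair_rows.append(
                    {"subject": s, "rater_a": ra, "rater_b": rb,
                     "pearson_r": cmp.pearson_r,
                     "common_fraction": cmp.common_fraction,
                     "a_only_fraction": cmp.a_only_fraction,
                     "b_only_fraction": cmp.b_only_fraction}
                )
    pairwise = pd.DataFrame(pair_rows)
    if len(pair_rows):
        r_vals = pairwise["pearson_r"].to_numpy()
        pearson_mean = float(np.mean(r_vals))
        pearson_sd = float(np.std(r_vals, ddof=1)) if len(r_vals) > 1 else 0.0
    else:
        pearson_mean = pearson_sd = float("nan")
    return PrecisionStudyResult(
        reports=reports, morphometry=morpho, pairwise=pairwise,
        pearson_mean=pearson_mean, pearson_sd=pearson_sd, tables=tables,
    )
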