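"""Accuracy assessment: MRI-chain metrics against a micro-CT reference chain.

For each specimen the same object is measured twice -- once at clinical MRI
resolution after (simulated or manual) rater segmentation, once through the
high-resolution micro-CT segmentation chain -- and the per-metric agreement
is summarized by the Pearson correlation across specimens.  Because r is
blind to a constant bias, the least-squares slope/intercept and identity-line
residuals are reported alongside, and for mean thickness a 1-voxel error band
(|dTh| <= the MRI in-plane voxel, 0.45 mm by default) is tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ct_segmentation import CtSegmentationParams, segment_ct
from .morphometry import morphometry_all
from .volume_io import GrayscaleVolume, VoxelGrid

__all__ = [
    "PairedMeasurements",
    "AccuracySpecimen",
    "AccuracyReport",
    "cross_method_correlation",
    "one_voxel_band",
    "accuracy_study",
]

MIN_SPECIMENS = 3

METRICS = ("cg_v", "cg_s", "cg_th")


@dataclass
class PairedMeasurements:
    """Per-specimen paired metric values from two measurement chains.

    ``values_a``/``values_b`` map metric name -> array over specimens
    (chain A = test method, chain B = reference).  ``voxel_ref`` is the MRI
    in-plane voxel in mm, the width of the thickness error band.
    """

    specimen_ids: tuple[str, ...]
    values_a: dict[str, np.ndarray]
    values_b: dict[str, np.ndarray]
    voxel_ref: float = 0.45

    def __post_init__(self) -> None:
        n = len(self.specimen_ids)
        if n < MIN_SPECIMENS:
            raise ValueError(f">= {MIN_SPECIMENS} specimens required for correlation, got {n}")
        for d in (self.values_a, self.values_b):
            for k, v in d.items():
                v = np.asarray(v, dtype=np.float64)
                if v.shape != (n,):
                    raise ValueError(f"metric {k}: expected {n} values, got {v.shape}")
                if (v <= 0).any():
                    raise ValueError(f"metric {k}: paired values must be positive")
                d[k] = v


def cross_method_correlation(pairs: PairedMeasurements) -> dict[str, dict[str, float]]:
    """Per-metric Pearson r plus least-squares slope/intercept and RMS
    identity-line residual (chain B, the reference, on x)."""
    out: dict[str, dict[str, float]] = {}
    for metric in pairs.values_a:
        a = pairs.values_a[metric]
        b = pairs.values_b[metric]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError(f"r undefined: constant series for metric {metric}")
        r, _ = stats.pearsonr(a, b)
        fit = stats.linregress(b, a)
        out[metric] = {
            "pearson_r": float(r),
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "identity_rms_residual": float(np.sqrt(np.mean((a - b) ** 2))),
            "n": len(a),
        }
    return out


def one_voxel_band(pairs: PairedMeasurements, metric: str = "cg_th") -> pd.DataFrame:
    """Per-specimen |difference| for ``metric`` and whether it lies within
    the 1-voxel band (closed bound: a difference equal to ``voxel_ref``
    counts as inside)."""
    a = pairs.values_a[metric]
    b = pairs.values_b[metric]
    diff = np.abs(a - b)
    return pd.DataFrame(
        {
            "specimen": pairs.specimen_ids,
            "value_a": a,
            "value_b": b,
            "abs_diff": diff,
            "within_band": diff <= pairs.voxel_ref,
        }
    )


@dataclass
class AccuracySpecimen:
    """One specimen's two-chain input: an MRI-chain mask and a CT-chain
    grayscale volume (or an already-segmented CT mask)."""

    specimen_id: str
    mri_mask: VoxelGrid
    ct_volume: GrayscaleVolume | None = None
    ct_mask: VoxelGrid | None = None

    def __post_init__(self) -> None:
        if (self.ct_volume is None) == (self.ct_mask is None):
            raise ValueError(
                f"specimen {self.specimen_id!r}: exactly one of ct_volume/ct_mask required"
            )


@dataclass
class AccuracyReport:
    correlations: dict[str, dict[str, float]]
    band_table: pd.DataFrame
    band_fraction: float
    scatter: pd.DataFrame
    voxel_ref: float

    def to_dict(self) -> dict:
        return {
            "voxel_ref_mm": self.voxel_ref,
            "correlations": self.correlations,
            "thickness_band": {
                "fraction_within": self.band_fraction,
                "per_specimen": self.band_table.to_dict(orient="records"),
            },
        }


def accuracy_study(
    specimens: Mapping[str, AccuracySpecimen] | list[AccuracySpecimen],
    ct_params: CtSegmentationParams | None = None,
    voxel_ref: float = 0.45,
    isotropic_target: float | None = None,
) -> AccuracyReport:
    """Run both measurement chains per specimen and compare the metric sets.

    The MRI chain applies morphometry directly to the rater mask; the CT
    chain first segments the grayscale volume (Gaussian filter + attenuation
    threshold), then applies the identical morphometry.
    """
    if isinstance(specimens, Mapping):
        for sid, spec in specimens.items():
            if spec.specimen_id != sid:
                raise ValueError(
                    f"manifest mismatch: key {sid!r} vs specimen_id {spec.specimen_id!r}"
                )
        spec_list = list(specimens.values())
    else:
        spec_list = list(specimens)
    if len(spec_list) < MIN_SPECIMENS:
        raise ValueError(
            f">= {MIN_SPECIMENS} specimens required for correlation, got {len(spec_list)}"
        )
    ids = tuple(s.specimen_id for s in spec_list)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate specimen ids")

    va: dict[str, list[float]] = {m: [] for m in METRICS}
    vb: dict[str, list[float]] = {m: [] for m in METRICS}
    scatter_rows = []
    for spec in spec_list:
        res_a = morphometry_all(
            spec.mri_mask, specimen_id=f"{spec.specimen_id}/mri",
            isotropic_target=isotropic_target,
        )
        ct_mask = spec.ct_mask
        if ct_mask is None:
            ct_mask = segment_ct(spec.ct_volume, ct_params)
        res_b = morphometry_all(ct_mask, specimen_id=f"{spec.specimen_id}/ct")
        for m in METRICS:
            a = getattr(res_a, m)
            b = getattr(res_b, m)
            va[m].append(a)
            vb[m].append(b)
            scatter_rows.append(
                {"specimen": spec.specimen_id, "metric": m,
                 "method_a": a, "method_b": b}
            )

    pairs = PairedMeasurements(
        specimen_ids=ids,
        values_a={m: np.array(v) for m, v in va.items()},
        values_b={m: np.array(v) for m, v in vb.items()},
        voxel_ref=voxel_ref,
    )
    corr = cross_method_correlation(pairs)
    band = one_voxel_band(pairs)
    return AccuracyReport(
        correlations=corr,
        band_table=band,
        band_fraction=float(band["within_band"].mean()),
        scatter=pd.DataFrame(scatter_rows),
        voxel_ref=voxel_ref,
    )
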