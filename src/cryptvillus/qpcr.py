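"""Raw Cp/Cq handling: detectability QC, global-mean normalization, ΔΔCt.

A qPCR panel reports one quantification cycle (Cp, also written Cq or Ct)
per assay per sample; lower cycles mean more template.  Three operations
turn raw cycles into relative expression:

* :func:`assay_passes_qc` — the panel inclusion rule: an assay is kept when
  its Cp is below 37 cycles and at least 5 cycles below its no-template
  negative control.
* :func:`global_mean_normalize` — per-sample global-mean normalization:
  each assay's normalized value is (mean Cp of the assays detected in
  *every* sample) − (assay Cp), so higher values mean more expressed and
  per-sample constant offsets cancel exactly.
* :func:`delta_delta_ct` — the classical ΔΔCt relative quantification,
  fold = 2^−ΔΔCt.

Cp matrices are pandas DataFrames (assays × samples) with NaN for
undetected reactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, NormalizationError, QuantificationError

DETECTION_CAP = 40.0
QC_MAX_CP = 37.0
QC_NEG_MARGIN = 5.0


@dataclass
class CpMatrix:
    """Raw panel quantification cycles plus per-assay negative controls.

    Parameters
    ----------
    cp : DataFrame
        Assays (rows) × samples (columns); NaN encodes an undetected
        reaction.
    negative_control : Series
        Per-assay no-template control Cp; NaN means the control never
        amplified and is treated as amplifying at ``detection_cap``.
    groups : Series
        Sample id → group label (e.g. WTV/WTC/KOV/KOC).
    detection_cap : float
        Maximum cycle number the instrument reports.
    """

    cp: pd.DataFrame
    negative_control: pd.Series
    groups: pd.Series
    detection_cap: float = DETECTION_CAP

    def __post_init__(self) -> None:
        if self.cp.index.duplicated().any():
            raise InputError("assay ids must be unique")
        missing = set(self.cp.columns) - set(self.groups.index)
        if missing:
            raise InputError(f"samples without a group label: {sorted(missing)}")
        vals = self.cp.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite <= 0).any():
            raise InputError("Cp values must be positive")
        if finite.size and (finite > self.detection_cap).any():
            raise InputError(
                f"Cp values exceed the detection cap ({self.detection_cap})"
            )


@dataclass
class NormalizedMatrix:
    """Global-mean-normalized expression index (cycles scale).

    ``values`` holds, for each assay a and sample s,
    ``mean(common Cp in s) − Cp(a, s)``; entries failing QC are NaN.
    Higher values mean more expressed.  ``common_assays`` records the
    normalizer set for provenance.
    """

    values: pd.DataFrame
    common_assays: list[str]
    method: str = "global_mean"
    groups: pd.Series | None = None


@dataclass
class FoldInduction:
    """ΔΔCt result for one target/reference pair across two conditions."""

    delta_delta_ct: float
    fold: float
    target: str = ""
    reference: str = ""
    test_group: str = ""
    control_group: str = ""


def assay_passes_qc(
    cp: float,
    negative_control_cp: float | None = None,
    cap: float = DETECTION_CAP,
) -> bool:
    """Panel inclusion rule for a single reaction.

    True iff Cp < 37 and the negative control is at least 5 cycles later
    than the assay.  An absent (NaN) negative control is read as a control
    that never amplified, i.e. as amplifying at the detection cap — the
    most permissive consistent interpretation.  A missing Cp is simply
    undetected and returns False.
    """
    if cp is None or (isinstance(cp, float) and math.isnan(cp)):
        return False
    neg = negative_control_cp
    if neg is None or (isinstance(neg, float) and math.isnan(neg)):
        neg = cap
    return cp < QC_MAX_CP and (neg - cp) >= QC_NEG_MARGIN


def qc_mask(m: CpMatrix) -> pd.DataFrame:
    """Vectorized :func:`assay_passes_qc` over a whole Cp matrix."""
    cp = m.cp.to_numpy(dtype=float)
    neg = m.negative_control.reindex(m.cp.index).to_numpy(dtype=float)
    neg = np.where(np.isfinite(neg), neg, m.detection_cap)[:, None]
    ok = np.isfinite(cp) & (cp < QC_MAX_CP) & ((neg - cp) >= QC_NEG_MARGIN)
    return pd.DataFrame(ok, index=m.cp.index, columns=m.cp.columns)


def apply_qc(m: CpMatrix) -> CpMatrix:
    """Return a copy of ``m`` with QC-failing entries set to undetected."""
    mask = qc_mask(m)
    return CpMatrix(
        cp=m.cp.where(mask),
        negative_control=m.negative_control,
        groups=m.groups,
        detection_cap=m.detection_cap,
    )


def global_mean_normalize(
    m: CpMatrix,
    *,
    fallback_min_detected_frac: float | None = None,
) -> NormalizedMatrix:
    """Global-mean normalization against the assays detected in all samples.

    For sample s and assay a the normalized value is
    ``mean over common assays of Cp(·, s) − Cp(a, s)``, where the common
    set contains the assays that pass QC in *every* sample.  Values are
    defined only where the assay itself passes QC.

    If the common set is empty a :class:`NormalizationError` is raised
    unless ``fallback_min_detected_frac`` is given, in which case the
    normalizer set is relaxed to assays detected in at least that fraction
    of samples (no imputation: per-sample means use the normalizer assays
    actually detected in that sample).
    """
    mask = qc_mask(m)
    cp = m.cp.where(mask)
    common = mask.all(axis=1)
    common_ids = list(m.cp.index[common])
    method = "global_mean"
    if not common_ids:
        if fallback_min_detected_frac is None:
            raise NormalizationError(
                "no assay passes QC in every sample; rerun with "
                "fallback_min_detected_frac to relax the normalizer set"
            )
        frac = mask.mean(axis=1)
        common_ids = list(m.cp.index[frac >= fallback_min_detected_frac])
        method = f"global_mean(detected>={fallback_min_detected_frac:g})"
        if not common_ids:
            raise NormalizationError(
                "no assay meets the relaxed detection fraction "
                f"{fallback_min_detected_frac:g}"
            )
    sample_means = cp.loc[common_ids].mean(axis=0, skipna=True)
    if sample_means.isna().any():
        bad = list(sample_means.index[sample_means.isna()])
        raise NormalizationError(f"no normalizer assay detected in samples {bad}")
    values = sample_means - cp  # broadcasts over rows
    return NormalizedMatrix(
        values=values, common_assays=common_ids, method=method, groups=m.groups
    )


def delta_delta_ct(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_control: float,
    ct_ref_control: float,
    **ids: str,
) -> FoldInduction:
    """ΔΔCt relative quantification.

    ΔΔCt = (Ct_target,test − Ct_ref,test) − (Ct_target,control −
    Ct_ref,control); fold = 2^−ΔΔCt.  Fold > 1 means the target is induced
    in the test condition relative to control.
    """
    names = ("ct_target_test", "ct_ref_test", "ct_target_control", "ct_ref_control")
    for name, v in zip(names, (ct_target_test, ct_ref_test, ct_target_control, ct_ref_control)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise QuantificationError(f"missing Ct value: {name}")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_control - ct_ref_control)
    return FoldInduction(delta_delta_ct=ddct, fold=2.0 ** (-ddct), **ids)


def to_linear_signal(norm_values: pd.DataFrame | pd.Series, scale: float) -> pd.DataFrame | pd.Series:
    """Map cycles-scale normalized values onto a linear signal scale.

    ``signal = scale × 2^value``: one cycle earlier doubles the signal.
    ``scale`` anchors the panel-average assay (normalized value 0); it is
    a property of the data source and is supplied by configuration.
    """
    if scale <= 0:
        raise InputError("signal scale must be positive")
    return scale * np.exp2(norm_values)


# ---------------------------------------------------------------------------
# TSV round trip

def read_cp_matrix(cp_path, groups_path, *, neg_control_row: str = "NEG_CTRL",
                   detection_cap: float = DETECTION_CAP) -> CpMatrix:
    """Read a Cp matrix TSV (assays × samples; blank = undetected).

    One reserved row (``neg_control_row``) carries the per-sample negative
    control; its per-assay value is taken as the row mean when controls are
    assay-independent, otherwise supply a two-column per-assay control TSV.
    A sidecar two-column TSV maps sample → group.
    """
    df = pd.read_csv(cp_path, sep="\t", index_col=0, comment="#")
    df = df.apply(pd.to_numeric, errors="coerce")
    groups = pd.read_csv(groups_path, sep="\t", index_col=0, comment="#").iloc[:, 0]
    if neg_control_row in df.index:
        neg = df.loc[neg_control_row]
        df = df.drop(index=neg_control_row)
        neg_per_assay = pd.Series(float(neg.mean()), index=df.index)
    else:
        neg_per_assay = pd.Series(np.nan, index=df.index)
    return CpMatrix(cp=df, negative_control=neg_per_assay,
                    groups=groups, detection_cap=detection_cap)


def write_cp_matrix(m: CpMatrix, cp_path, groups_path, *, neg_control_row: str = "NEG_CTRL") -> None:
    out = m.cp.copy()
    out.loc[neg_control_row] = float(m.negative_control.mean())
    out.to_csv(cp_path, sep="\t", na_rep="")
    m.groups.rename("group").to_frame().to_csv(groups_path, sep="\t")
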