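"""Per-gene median/MAD calibration between expression platforms.

A validation cohort measured on a different platform (RNA-seq log2 FPKM or
qPCR delta-Ct) is mapped onto the training distribution gene by gene: each
gene's values are linearly transformed so its median and median absolute
deviation (raw MAD, no normal-consistency constant) match the training
cohort exactly.  The same code path serves both platform directions; genes
with zero source MAD get a shift-only transform.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ValidationError
from .io import ExpressionMatrix


def _median_mad(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


class MedianMadCalibrator(BaseEstimator, TransformerMixin):
    """sklearn-style transformer matching per-feature median and raw MAD.

    ``fit(X)`` learns the *target* statistics from the training cohort
    (samples × genes); ``transform(X)`` computes the source statistics of
    the batch it is given and maps it onto the targets.  The map is
    batch-dependent by design — the calibration is defined relative to the
    validation cohort's own distribution.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.target_median_ = np.median(X, axis=0)
        self.target_mad_ = np.median(
            np.abs(X - self.target_median_), axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        src_med = np.median(X, axis=0)
        src_mad = np.median(np.abs(X - src_med), axis=0)
        gain = np.ones_like(src_mad)
        ok = src_mad > 0
        gain[ok] = self.target_mad_[ok] / src_mad[ok]
        offset = self.target_median_ - gain * src_med
        return X * gain + offset


def fit_calibration(training: ExpressionMatrix, validation: ExpressionMatrix,
                    genes: list[str]) -> pd.DataFrame:
    """Per-gene affine map aligning validation median/MAD to training.

    Returns a CalibrationMap DataFrame indexed by gene with columns
    target_median, target_mad, source_median, source_mad, gain, offset,
    shift_only.  gain = target_mad / source_mad, offset = target_median −
    gain · source_median; a zero source MAD yields a shift-only map
    (gain 1) with a warning.  Metadata: attrs["target_platform"].
    """
    if validation.n_samples < 3:
        raise ValidationError("need >= 3 validation samples to calibrate")
    rows = []
    for gene in genes:
        for m, side in ((training, "training"), (validation, "validation")):
            if gene not in m.values.index:
                raise ValidationError(f"gene {gene!r} absent from {side} matrix")
        t_med, t_mad = _median_mad(training.values.loc[gene].to_numpy())
        s_med, s_mad = _median_mad(validation.values.loc[gene].to_numpy())
        shift_only = s_mad == 0
        gain = 1.0 if shift_only else t_mad / s_mad
        offset = t_med - gain * s_med
        rows.append((gene, t_med, t_mad, s_med, s_mad, gain, offset,
                     shift_only))
    cmap = pd.DataFrame(rows, columns=[
        "gene", "target_median", "target_mad", "source_median", "source_mad",
        "gain", "offset", "shift_only"]).set_index("gene")
    n_flat = int(cmap["shift_only"].sum())
    if n_flat:
        warnings.warn(f"{n_flat} gene(s) with zero source MAD; shift-only map")
    cmap.attrs["target_platform"] = training.platform
    return cmap


def apply_calibration(cmap: pd.DataFrame,
                      validation: ExpressionMatrix) -> ExpressionMatrix:
    """Apply a fitted calibration map; unmapped genes pass through untouched.

    The returned matrix carries the training platform tag (its values now
    live on the training scale).
    """
    values = validation.values.copy()
    mapped = [g for g in cmap.index if g in values.index]
    gains = cmap.loc[mapped, "gain"].to_numpy()[:, None]
    offsets = cmap.loc[mapped, "offset"].to_numpy()[:, None]
    values.loc[mapped] = values.loc[mapped].to_numpy() * gains + offsets
    platform = cmap.attrs.get("target_platform", validation.platform)
    note = (validation.scale_note + " | median/MAD calibrated").strip(" |")
    return ExpressionMatrix(values, platform=platform, scale_note=note)
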