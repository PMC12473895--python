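"""NIR spectra pretreatment and the phenomic relationship matrix.

The phenomic-prediction pipeline pretreats per-plot reflectance spectra with
a Savitzky-Golay first derivative (window 11, polynomial order 2), scales
each retained band to zero mean and unit SD, and builds the phenomic
relationship matrix ``P = D D' / q`` over records from the scaled
derivative matrix ``D`` with ``q`` retained bands.  Both pretreatment steps
are scikit-learn transformers so they compose into pipelines.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import savgol_coeffs
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .kernels import RelationshipKernel

__all__ = [
    "SpectraMatrix",
    "SavitzkyGolayDerivative",
    "BandScaler",
    "savitzky_golay_first_derivative",
    "scale_bands",
    "phenomic_relationship",
    "band_trait_correlation",
]

logger = logging.getLogger(__name__)


class SpectraMatrix:
    """Records x bands reflectance with wavelength labels.

    ``values`` holds the reflectance matrix, ``wavelengths`` the band
    positions in nm (strictly increasing, uniform step), and ``labels`` an
    optional record-metadata frame (hybrid, environment, replicate).
    """

    def __init__(
        self,
        values: np.ndarray,
        wavelengths: np.ndarray,
        labels: pd.DataFrame | None = None,
        uniform: bool = True,
    ):
        values = np.asarray(values, dtype=float)
        wavelengths = np.asarray(wavelengths, dtype=float)
        if values.ndim != 2:
            raise ValueError("spectra values must be 2-D (records x bands)")
        if wavelengths.shape != (values.shape[1],):
            raise ValueError("wavelengths must match the band dimension")
        if np.isnan(values).any():
            raise ValueError("spectra contain missing values")
        steps = np.diff(wavelengths)
        if len(steps) and steps.min() <= 0:
            raise ValueError("wavelengths must be strictly increasing")
        # uniform spacing is an ingestion contract; pretreatment that drops
        # flat bands may legitimately leave gaps
        if uniform and len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("wavelengths must have a uniform step")
        if labels is not None and len(labels) != values.shape[0]:
            raise ValueError("labels must have one row per spectra record")
        self.values = values
        self.wavelengths = wavelengths
        self.labels = labels.reset_index(drop=True) if labels is not None else None

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, wavelengths: np.ndarray) -> "SpectraMatrix":
        return SpectraMatrix(values, wavelengths, self.labels, uniform=False)

    def to_frame(self) -> pd.DataFrame:
        wide = pd.DataFrame(self.values, columns=[f"{w:g}" for w in self.wavelengths])
        if self.labels is not None:
            wide = pd.concat([self.labels, wide], axis=1)
        return wide


class SavitzkyGolayDerivative(BaseEstimator, TransformerMixin):
    """Savitzky-Golay first-derivative pretreatment with edge trimming.

    Each output value is the least-squares local-polynomial first derivative
    at the center of a sliding window; the ``window - 1`` edge bands are
    dropped rather than padded, so a 4200-band matrix becomes 4190 bands at
    the default window of 11.

    Parameters
    ----------
    window : odd int, default 11
        Sliding-window width in bands.
    polyorder : int, default 2
        Local polynomial order (must be < window).
    delta : float, default 1.0
        Band spacing used for the derivative; 1.0 gives the derivative per
        band step (the conventional chemometrics choice).
    """

    def __init__(self, window: int = 11, polyorder: int = 2, delta: float = 1.0):
        self.window = window
        self.polyorder = polyorder
        self.delta = delta

    def fit(self, X, y=None):
        X = self._matrix(X)
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if not 3 <= self.window <= X.shape[1]:
            raise ValueError(
                f"window {self.window} out of range for {X.shape[1]} bands"
            )
        if self.polyorder >= self.window:
            raise ValueError("polyorder must be < window")
        self.n_features_in_ = X.shape[1]
        # filter taps for the derivative at the window center
        self.coeffs_ = savgol_coeffs(
            self.window, self.polyorder, deriv=1, delta=self.delta, use="dot"
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "coeffs_")
        spectra = X if isinstance(X, SpectraMatrix) else None
        X = self._matrix(X)
        half = (self.window - 1) // 2
        n_out = X.shape[1] - (self.window - 1)
        if n_out < 1:
            raise ValueError("window exceeds band count")
        windows = np.lib.stride_tricks.sliding_window_view(X, self.window, axis=1)
        out = windows @ self.coeffs_
        if spectra is not None:
            wl = spectra.wavelengths[half:-half]
            return spectra.with_values(out, wl)
        return out

    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, SpectraMatrix):
            return X.values
        return np.asarray(X, dtype=float)


class BandScaler(BaseEstimator, TransformerMixin):
    """Scale each band to zero mean and unit sample SD, dropping flat bands.

    Zero-variance bands cannot be scaled; they are removed (with a logged
    warning) instead of producing divide-by-zero artifacts.

    Parameters
    ----------
    with_std : bool, default True
        If False, bands are only centered ("scaled around zero" read as
        centering); the default also divides by the sample SD.
    """

    def __init__(self, with_std: bool = True):
        self.with_std = with_std

    def fit(self, X, y=None):
        M = X.values if isinstance(X, SpectraMatrix) else np.asarray(X, dtype=float)
        if M.shape[0] < 2:
            raise ValueError("scaling needs at least 2 records")
        self.mean_ = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        self.keep_ = sd > 0
        if not self.keep_.all():
            logger.warning(
                "dropping %d zero-variance band(s)", int((~self.keep_).sum())
            )
        self.scale_ = np.where(self.keep_, sd, 1.0)
        # residual mean after scaling, nonzero only at the float
        # cancellation floor (near-constant bands); subtracted in transform
        # so training-batch output is exactly centered
        self.scaled_mean_ = ((M - self.mean_) / self.scale_).mean(axis=0)
        self.n_features_in_ = M.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        spectra = X if isinstance(X, SpectraMatrix) else None
        M = X.values if spectra is not None else np.asarray(X, dtype=float)
        out = M - self.mean_
        if self.with_std:
            out = out / self.scale_ - self.scaled_mean_
        out = out[:, self.keep_]
        if spectra is not None:
            return spectra.with_values(out, spectra.wavelengths[self.keep_])
        return out


def savitzky_golay_first_derivative(
    spectra: SpectraMatrix, window: int = 11, polyorder: int = 2
) -> SpectraMatrix:
    """First-derivative pretreatment; output has ``window - 1`` fewer bands."""
    return SavitzkyGolayDerivative(window=window, polyorder=polyorder).fit_transform(
        spectra
    )


def scale_bands(spectra: SpectraMatrix, with_std: bool = True) -> SpectraMatrix:
    """Center (and by default unit-SD scale) each band; drop flat bands."""
    return BandScaler(with_std=with_std).fit_transform(spectra)


def phenomic_relationship(
    derivative: SpectraMatrix | np.ndarray,
    ids: list | None = None,
) -> RelationshipKernel:
    """Phenomic relationship ``P = D D' / q`` from pretreated spectra.

    ``D`` is the scaled first-derivative matrix (records x q bands).  With
    100 records and 4190 retained bands this yields the 100 x 100 phenomic
    kernel; applied across environments it is record-level directly.
    """
    if isinstance(derivative, SpectraMatrix):
        D = derivative.values
        if ids is None:
            if derivative.labels is not None and "record" in derivative.labels:
                ids = list(derivative.labels["record"])
            else:
                ids = [f"R{i + 1}" for i in range(D.shape[0])]
    else:
        D = np.asarray(derivative, dtype=float)
        if ids is None:
            ids = [f"R{i + 1}" for i in range(D.shape[0])]
    q = D.shape[1]
    if q == 0:
        raise ValueError("no bands: cannot build phenomic relationship")
    P = D @ D.T / q
    return RelationshipKernel(P, ids, "phenomic")


def band_trait_correlation(
    spectra_blues: np.ndarray | SpectraMatrix,
    trait_blues: np.ndarray | pd.Series,
) -> np.ndarray:
    """Per-band Pearson correlation of spectral BLUEs with a trait BLUE.

    Returns one r in [-1, 1] per band (NaN for zero-variance bands).
    """
    M = (
        spectra_blues.values
        if isinstance(spectra_blues, SpectraMatrix)
        else np.asarray(spectra_blues, dtype=float)
    )
    y = np.asarray(trait_blues, dtype=float)
    if M.shape[0] != y.shape[0]:
        raise ValueError("spectra and trait BLUEs must share hybrid ordering/length")
    if M.shape[0] < 3:
        raise ValueError("need at least 3 hybrids for correlations")
    Mc = M - M.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Mc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc.T @ yc) / denom
    return r
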