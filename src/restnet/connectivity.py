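"""Band-limited lagged-coherence connectivity from segmented ROI time series.

Cross-spectra are estimated as the mean tapered periodogram over artifact-free
epochs (Hann taper, zero-padded to a power-of-two transform length). Lagged
coherence between a pair of channels at a frequency bin,

    LagC_xy(f) = Im(S_xy)^2 / (S_xx * S_yy - Re(S_xy)^2),

uses only the non-instantaneous part of the cross-spectrum: any static
(zero-lag) linear mixing of a common source — the volume-conduction artifact
of scalp EEG projected into source space — contributes a purely real
cross-spectral term and is cancelled by construction. The band value is the
mean over the frequency bins whose centers fall in ``[f_lo, f_hi)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from restnet.bands import BandSpec

logger = logging.getLogger(__name__)


@dataclass
class EpochSet:
    """Segmented multichannel ROI time series.

    Attributes
    ----------
    epochs : list of ndarray
        Each ``(n_samples, n_channels)``; all epochs share one shape.
    fs : float
        Sampling rate in Hz (default 250).
    """

    epochs: list[np.ndarray]
    fs: float = 250.0

    def __post_init__(self) -> None:
        if len(self.epochs) == 0:
            raise ValueError("EpochSet requires at least one epoch")
        self.epochs = [np.asarray(e, dtype=float) for e in self.epochs]
        shape = self.epochs[0].shape
        if len(shape) != 2:
            raise ValueError("epochs must be 2-D (samples x channels)")
        for i, e in enumerate(self.epochs):
            if e.shape != shape:
                raise ValueError(
                    f"epoch {i} has shape {e.shape}, expected {shape}"
                )
            if not np.all(np.isfinite(e)):
                raise ValueError(f"epoch {i} contains non-finite values")
        if shape[0] < 2:
            raise ValueError("epochs must contain at least 2 samples")

    @property
    def n_channels(self) -> int:
        return self.epochs[0].shape[1]

    @property
    def epoch_len(self) -> int:
        return self.epochs[0].shape[0]


@dataclass
class CrossSpectrum:
    """Per-frequency-bin Hermitian cross-spectral matrices.

    Attributes
    ----------
    S : ndarray, shape (n_freqs, n_channels, n_channels), complex
        ``S[k]`` is Hermitian with real non-negative diagonal.
    freqs : ndarray
        Bin-center frequencies in Hz.
    """

    S: np.ndarray
    freqs: np.ndarray

    def band_bins(self, band: BandSpec) -> np.ndarray:
        """Indices of bins whose centers fall in ``[f_lo, f_hi)``."""
        return np.nonzero((self.freqs >= band.f_lo) & (self.freqs < band.f_hi))[0]


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def estimate_cross_spectra(epochs: EpochSet, nfft: int | None = None) -> CrossSpectrum:
    """Mean Hann-tapered periodogram cross-spectra across epochs.

    Epochs shorter than the transform length are zero-padded; ``nfft``
    defaults to the next power of two >= the epoch length (so the standard
    1024-sample epoch maps onto a 1024-point transform and a bin spacing of
    fs/1024 ≈ 0.244 Hz at 250 Hz sampling).

    Parameters
    ----------
    epochs : EpochSet
    nfft : int, optional
        Transform length; must be >= the epoch length.

    Returns
    -------
    CrossSpectrum
    """
    n_samples = epochs.epoch_len
    if nfft is None:
        nfft = _next_pow2(n_samples)
    if nfft < n_samples:
        raise ValueError(f"nfft={nfft} shorter than epoch length {n_samples}")

    taper = np.hanning(n_samples)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / epochs.fs)
    n_ch = epochs.n_channels
    S = np.zeros((freqs.size, n_ch, n_ch), dtype=complex)
    for ep in epochs.epochs:
        X = np.fft.rfft(ep * taper[:, None], n=nfft, axis=0)  # (freq, ch)
        S += X[:, :, None] * np.conj(X[:, None, :])
    S /= len(epochs.epochs)
    return CrossSpectrum(S=S, freqs=freqs)


def _band_bin_indices(cs: CrossSpectrum, band: BandSpec) -> np.ndarray:
    bins = cs.band_bins(band)
    if bins.size == 0:
        raise ValueError(
            f"band {band.name!r} [{band.f_lo}, {band.f_hi}) contains no "
            f"frequency bins (resolution {cs.freqs[1] - cs.freqs[0]:.4g} Hz)"
        )
    return bins


def lagged_coherence(cs: CrossSpectrum, band: BandSpec) -> np.ndarray:
    """Band-averaged lagged-coherence adjacency matrix.

    Per bin, ``Im(S_xy)^2 / (S_xx S_yy - Re(S_xy)^2)`` clamped to [0, 1];
    bins with a non-positive denominator (degenerate spectra) contribute 0.
    The band value is the mean over bins in ``[f_lo, f_hi)``.

    Returns
    -------
    ndarray, shape (n_channels, n_channels)
        Symmetric, entries in [0, 1], zero diagonal.
    """
    bins = _band_bin_indices(cs, band)
    Sb = cs.S[bins]
    sxx = np.real(np.diagonal(Sb, axis1=1, axis2=2))  # (bins, ch)
    num = np.imag(Sb) ** 2
    den = sxx[:, :, None] * sxx[:, None, :] - np.real(Sb) ** 2
    bad = den <= 0
    n_bad = int(np.count_nonzero(bad & ~np.eye(Sb.shape[1], dtype=bool)))
    if n_bad:
        logger.warning(
            "lagged_coherence: %d off-diagonal (bin, pair) cells with "
            "non-positive denominator set to 0", n_bad
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        lc = np.where(bad, 0.0, num / np.where(bad, 1.0, den))
    lc = np.clip(lc, 0.0, 1.0)
    W = lc.mean(axis=0)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return W


def magnitude_squared_coherence(cs: CrossSpectrum, band: BandSpec) -> np.ndarray:
    """Band-averaged ordinary magnitude-squared coherence |S_xy|^2/(S_xx S_yy).

    Retains the instantaneous component; used as the volume-conduction-
    sensitive reference against which lagged coherence is compared.
    """
    bins = _band_bin_indices(cs, band)
    Sb = cs.S[bins]
    sxx = np.real(np.diagonal(Sb, axis1=1, axis2=2))
    den = sxx[:, :, None] * sxx[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.where(den <= 0, 0.0, np.abs(Sb) ** 2 / np.where(den <= 0, 1.0, den))
    msc = np.clip(msc, 0.0, 1.0)
    W = msc.mean(axis=0)
    W = 0.5 * (W + W.T)
    np.fill_diagonal(W, 0.0)
    return W
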