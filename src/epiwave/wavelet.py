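"""Orthogonal DWT (matrix form) and row-wise stationary wavelet transform.

Electrograms are transformed along time, row by row.  Two variants:

* ``orthogonal-dwt`` — the critically sampled periodized transform; as a
  matrix ``W`` it is orthogonal (``W^-1 = W^T``) and norm-preserving.
* ``stationary-swt`` — the undecimated (shift-invariant) transform; it is
  redundant by a factor ``levels + 1`` and no longer orthogonal: with an
  orthogonal filter pair the band energy grows by a factor ``2^j`` with
  scale coarseness ``j``.

Band layout everywhere: approximation (coarsest) first, then detail
bands from coarsest to finest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .recording import PotentialRecording

__all__ = [
    "WaveletSpec",
    "WaveletCoefficients",
    "dwt_matrix",
    "swt_forward",
    "swt_inverse",
]


@dataclass(frozen=True)
class WaveletSpec:
    """Wavelet transform configuration.

    Parameters
    ----------
    name : str
        Orthogonal wavelet identifier (PyWavelets name); default ``db2``
        (Daubechies, 2 vanishing moments, filter length 4).
    levels : int
        Decomposition depth N >= 1; default 3.
    variant : str
        ``"stationary-swt"`` (default) or ``"orthogonal-dwt"``.
    """

    name: str = "db2"
    levels: int = 3
    variant: str = "stationary-swt"
    boundary: str = "periodic"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.variant not in ("stationary-swt", "orthogonal-dwt"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.boundary != "periodic":
            raise ValueError("only periodic boundary handling is supported")
        w = pywt.Wavelet(self.name)
        if not w.orthogonal:
            raise ValueError(f"wavelet {self.name!r} is not orthogonal")

    @property
    def block(self) -> int:
        """Signal lengths must be divisible by ``2**levels``."""
        return 2**self.levels

    def band_labels(self) -> list[str]:
        """Coarsest-first band names, e.g. ['a3', 'd3', 'd2', 'd1']."""
        n = self.levels
        return [f"a{n}"] + [f"d{j}" for j in range(n, 0, -1)]


@dataclass
class WaveletCoefficients:
    """Nodes x coefficients matrix with scale-band bookkeeping.

    ``band_index`` maps each band label to its column slice; for the
    stationary variant every band has the (padded) signal length, so the
    total column count is ``(levels + 1) * m_padded``.  ``original_length``
    records the pre-padding sample count for exact truncation on
    inversion.
    """

    matrix: np.ndarray
    spec: WaveletSpec
    band_index: dict[str, slice]
    original_length: int
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        cols = sorted(self.band_index.values(), key=lambda s: s.start)
        covered = 0
        for s in cols:
            if s.start != covered:
                raise ValueError("band_index does not partition the columns")
            covered = s.stop
        if covered != self.matrix.shape[1]:
            raise ValueError("band_index does not cover all columns")
        expected = set(self.spec.band_labels())
        if set(self.band_index) != expected:
            raise ValueError(f"band labels {set(self.band_index)} != {expected}")
        widths = {s.stop - s.start for s in self.band_index.values()}
        if self.spec.variant == "stationary-swt" and len(widths) != 1:
            raise ValueError("stationary bands must all have the same width")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def band(self, label: str) -> np.ndarray:
        """View of one scale band (nodes x band width)."""
        return self.matrix[:, self.band_index[label]]

    def band_energies(self) -> dict[str, float]:
        """Squared Frobenius norm per scale band."""
        return {k: float(np.sum(self.band(k) ** 2)) for k in self.band_index}


def dwt_matrix(m: int, spec: WaveletSpec | None = None) -> np.ndarray:
    """Orthogonal DWT as an m x m matrix acting on row signals.

    For a row vector ``x``, ``x @ W`` is the periodized DWT of ``x`` with
    bands laid out coarsest first.  ``W`` is orthogonal: ``W^-1 = W^T``
    and the transform preserves the 2-norm.

    Raises
    ------
    ValueError
        If ``m`` is not divisible by ``2**levels`` (pad the signal
        periodically to the next multiple first).
    """
    spec = spec or WaveletSpec(variant="orthogonal-dwt")
    if spec.variant != "orthogonal-dwt":
        raise ValueError("dwt_matrix requires the orthogonal-dwt variant")
    if m % spec.block:
        raise ValueError(
            f"signal length {m} not divisible by 2^{spec.levels}; "
            "pad periodically to the next multiple"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # short-signal notice
        coeffs = pywt.wavedec(
            np.eye(m), spec.name, mode="periodization", level=spec.levels, axis=1
        )
    return np.hstack(coeffs)


def _pad_periodic(data: np.ndarray, block: int) -> np.ndarray:
    m = data.shape[1]
    pad = (-m) % block
    if pad == 0:
        return data
    return np.pad(data, ((0, 0), (0, pad)), mode="wrap")


def swt_forward(
    phi: PotentialRecording | np.ndarray, spec: WaveletSpec | None = None
) -> WaveletCoefficients:
    """Row-wise stationary wavelet transform of a potential matrix.

    Rows are padded by periodic extension to a multiple of ``2**levels``
    when needed; the original length is recorded for exact inversion.
    """
    spec = spec or WaveletSpec()
    if spec.variant != "stationary-swt":
        raise ValueError("swt_forward requires the stationary-swt variant")
    if isinstance(phi, PotentialRecording):
        data, fs = phi.data, phi.fs
    else:
        data, fs = np.atleast_2d(np.asarray(phi, dtype=float)), 1000.0
    if not np.isfinite(data).all():
        raise ValueError("input contains non-finite values")
    m = data.shape[1]
    padded = _pad_periodic(data, spec.block)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        bands = pywt.swt(padded, spec.name, level=spec.levels,
                         axis=1, trim_approx=True, norm=False)
    mp = padded.shape[1]
    labels = spec.band_labels()
    band_index = {
        lab: slice(i * mp, (i + 1) * mp) for i, lab in enumerate(labels)
    }
    return WaveletCoefficients(
        matrix=np.hstack(bands), spec=spec, band_index=band_index,
        original_length=m, fs=fs,
    )


def swt_inverse(coeffs: WaveletCoefficients) -> PotentialRecording:
    """Invert the row-wise stationary wavelet transform.

    Exact on the range of :func:`swt_forward`; for modified coefficient
    matrices (e.g. after sparsification) this is the standard
    average-of-shifts inverse-SWT reconstruction.  Padding introduced by
    the forward transform is removed.
    """
    spec = coeffs.spec
    labels = spec.band_labels()
    widths = {lab: coeffs.band_index[lab].stop - coeffs.band_index[lab].start
              for lab in labels}
    if len(set(widths.values())) != 1:
        raise ValueError("inconsistent band widths in band_index")
    bands = [np.ascontiguousarray(coeffs.band(lab)) for lab in labels]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rec = pywt.iswt(bands, spec.name, norm=False, axis=1)
    return PotentialRecording(rec[:, : coeffs.original_length], fs=coeffs.fs)
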