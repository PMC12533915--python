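"""Synthesis of orthogonal X/Y/Z vectorcardiographic signals from 12 leads.

Each transform is a fixed 3 x 8 matrix applied sample-wise to the eight
independent leads (I, II, V1..V6).  Four methods ship as editable plain-text
coefficient files: the inverse Dower matrix, the Kors regression matrix, and
two wave-specific least-squares matrices (QLSV for the QRS loop, PLSV for the
P loop).  A truncated-Fourier smoother produces the low-pass "f" variants of
the loop features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .beats import INDEPENDENT_LEADS, MedianBeat12

#: method name -> (feature-name tag, bundled coefficient file)
METHODS: dict[str, tuple[str, str]] = {
    "inverse_dower": ("D", "inverse_dower.txt"),
    "kors": ("K", "kors.txt"),
    "qlsv": ("Q", "qlsv_synthetic.txt"),
    "plsv": ("P", "plsv_synthetic.txt"),
}

DEFAULT_HARMONICS = 8


@dataclass(frozen=True)
class TransformMatrix:
    """A 3 x 8 lead-to-XYZ coefficient matrix for one synthesis method."""

    method: str
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (3, 8):
            raise ValueError(
                f"coefficient matrix must be 3 x 8 (X/Y/Z by "
                f"{INDEPENDENT_LEADS}), got {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError("coefficient matrix contains non-finite values")
        object.__setattr__(self, "coefficients", c)

    @property
    def tag(self) -> str:
        return METHODS[self.method][0] if self.method in METHODS else self.method


@dataclass
class VcgSignal:
    """An N x 3 orthogonal (X, Y, Z) amplitude sequence in uV."""

    xyz: np.ndarray
    fs: float
    method: str

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must be N x 3, got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite VCG sample")

    @property
    def n_samples(self) -> int:
        return self.xyz.shape[0]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs


def load_matrix(method: str, matrix_dir: str | Path | None = None) -> TransformMatrix:
    """Load a transform's coefficients from a plain-text 3 x 8 grid.

    ``matrix_dir`` overrides the bundled defaults; the file name is the
    method's default file name.  Lines starting with ``#`` are comments.
    """
    if method not in METHODS:
        raise ValueError(f"unknown VCG synthesis method {method!r}; "
                         f"choose from {sorted(METHODS)}")
    fname = METHODS[method][1]
    if matrix_dir is not None:
        text = (Path(matrix_dir) / fname).read_text()
    else:
        text = resources.files("vcglvh.data").joinpath(fname).read_text()
    rows = [[float(v) for v in line.split()]
            for line in text.splitlines()
            if line.strip() and not line.lstrip().startswith("#")]
    return TransformMatrix(method=method, coefficients=np.array(rows))


def synthesize(beat: MedianBeat12,
               method: str | TransformMatrix,
               matrix_dir: str | Path | None = None) -> VcgSignal:
    """Apply a transform matrix sample-wise: xyz(t) = M . (I, II, V1..V6)(t).

    The derived limb leads (III, aVR, aVL, aVF) never enter the transform.
    """
    matrix = method if isinstance(method, TransformMatrix) else \
        load_matrix(method, matrix_dir)
    leads8 = beat.independent_leads()          # (8, N)
    xyz = (matrix.coefficients @ leads8).T     # (N, 3)
    return VcgSignal(xyz=xyz, fs=beat.fs, method=matrix.method)


def truncate_fourier(points: np.ndarray, harmonics: int) -> np.ndarray:
    """Truncated Fourier series of each column: DC + first ``harmonics``
    harmonics of the window-length fundamental."""
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if harmonics < 1:
        raise ValueError("harmonics must be >= 1")
    if harmonics >= n / 2:
        raise ValueError(
            f"harmonics={harmonics} leaves nothing to truncate for a "
            f"window of {n} samples")
    spec = np.fft.rfft(pts, axis=0)
    spec[harmonics + 1:] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def fourier_smooth(sig: VcgSignal, harmonics: int = DEFAULT_HARMONICS) -> VcgSignal:
    """Low-pass each of X, Y, Z by Fourier-series truncation.

    Output length and sampling rate are unchanged.  Idempotent at a fixed
    harmonic count.
    """
    return replace(sig, xyz=truncate_fourier(sig.xyz, harmonics))
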