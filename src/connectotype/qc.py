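"""Frame censoring, nuisance regression, gap interpolation, band-pass.

The cleaning pipeline applies, in fixed order:

1. motion censoring — frames with FD > 0.2 mm or DVARS > 50 are flagged,
   flags are dilated one frame back and two forward, kept runs shorter
   than five contiguous frames are also censored, and a subject whose
   censored fraction exceeds one half is excluded;
2. nuisance regression — OLS on kept frames against an 18-column design
   (intercept, linear trend, six motion parameters, mean white-matter and
   ventricle proxies, and the temporal derivatives of those eight);
3. spectral interpolation of censored frames via a least-squares sinusoid
   (Lomb-Scargle-style) fit on the kept frames;
4. zero-phase band-pass filtering at 0.009-0.08 Hz.

Interpolation exists only to make the band-pass well-posed: censored
frames are re-excluded from all downstream correlation computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CensorMask:
    keep: np.ndarray          # per-frame boolean
    subject_excluded: bool

    @property
    def n_censored(self) -> int:
        return int((~self.keep).sum())

    @property
    def n_frames(self) -> int:
        return len(self.keep)

    @property
    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)


def censor_mask(fd: np.ndarray, dvars: np.ndarray, fd_thresh: float = 0.2,
                dvars_thresh: float = 50.0, pre: int = 1, post: int = 2,
                min_run: int = 5, exclusion_fraction: float = 0.5) -> CensorMask:
    """Flag -> dilate -> short-run censor -> exclusion decision.

    Raw outliers are frames with ``fd > fd_thresh`` or
    ``dvars > dvars_thresh``; each is dilated ``pre`` frames before and
    ``post`` after (clipped at the series ends); any maximal kept run
    shorter than ``min_run`` is also censored.  ``subject_excluded`` is
    true when the censored fraction exceeds ``exclusion_fraction``.
    """
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape or fd.ndim != 1 or fd.size < 1:
        raise ValidationError("fd and dvars must be equal-length 1-D arrays")
    T = fd.size
    bad = (fd > fd_thresh) | (dvars > dvars_thresh)
    dilated = bad.copy()
    for t in np.flatnonzero(bad):
        dilated[max(0, t - pre): min(T, t + post + 1)] = True
    keep = ~dilated
    # censor kept runs shorter than min_run
    t = 0
    while t < T:
        if keep[t]:
            start = t
            while t < T and keep[t]:
                t += 1
            if t - start < min_run:
                keep[start:t] = False
        else:
            t += 1
    censored_fraction = 1.0 - keep.mean()
    return CensorMask(keep=keep, subject_excluded=bool(censored_fraction > exclusion_fraction))


# ---------------------------------------------------------------------------
# nuisance regression
# ---------------------------------------------------------------------------

def _derivative(x: np.ndarray) -> np.ndarray:
    """Backward temporal difference with a leading zero."""
    d = np.zeros_like(x)
    d[1:] = np.diff(x, axis=0)
    return d


@dataclass(frozen=True)
class NuisanceDesign:
    """18-column regression design.

    Columns: intercept, linear trend, six motion parameters, mean
    white-matter proxy, mean ventricle proxy, and the temporal
    derivatives of the motion/white-matter/ventricle columns (8 more).
    """
    matrix: np.ndarray  # (T, 18)

    @classmethod
    def build(cls, motion_params: np.ndarray, wm: np.ndarray,
              ventricle: np.ndarray) -> "NuisanceDesign":
        motion_params = np.asarray(motion_params, dtype=float)
        T = motion_params.shape[0]
        if motion_params.shape != (T, 6):
            raise ValidationError("motion_params must be (T, 6)")
        wm = np.asarray(wm, dtype=float).reshape(T, 1)
        ventricle = np.asarray(ventricle, dtype=float).reshape(T, 1)
        trend = np.linspace(-1.0, 1.0, T).reshape(T, 1)
        base = np.hstack([motion_params, wm, ventricle])
        cols = np.hstack([np.ones((T, 1)), trend, base, _derivative(base)])
        return cls(matrix=cols)

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def nuisance_regress(signals: np.ndarray, design: NuisanceDesign,
                     mask: CensorMask) -> np.ndarray:
    """OLS nuisance removal fitted on kept frames, applied at all frames.

    Residuals on kept frames are orthogonal to every retained design
    column.  Collinear columns are dropped with a warning.
    """
    signals = np.asarray(signals, dtype=float)
    X = design.matrix
    if X.shape[0] != signals.shape[1]:
        raise ValidationError("design rows must equal frame count")
    kept = mask.kept_indices
    Xk = X[kept]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        # greedy column selection preserving order
        keep_cols, basis = [], np.zeros((Xk.shape[0], 0))
        for c in range(Xk.shape[1]):
            cand = np.column_stack([basis, Xk[:, c]])
            if np.linalg.matrix_rank(cand) > basis.shape[1]:
                keep_cols.append(c)
                basis = cand
        warnings.warn(f"nuisance design rank-deficient; using columns {keep_cols}")
        X, Xk = X[:, keep_cols], Xk[:, keep_cols]
    beta, *_ = np.linalg.lstsq(Xk, signals[:, kept].T, rcond=None)
    return signals - (X @ beta).T


# ---------------------------------------------------------------------------
# spectral interpolation of censored frames
# ---------------------------------------------------------------------------

def interpolate_censored(residuals: np.ndarray, mask: CensorMask,
                         frame_interval_s: float = 3.0,
                         min_kept: int = 5) -> np.ndarray:
    """Fill censored frames by least-squares spectral reconstruction.

    A constant plus sinusoids on the linear frequency grid ``j / (T * TR)``
    is fit jointly to the kept frames by ridge-regularized least squares
    and synthesized at the censored times.  The grid is truncated at
    ``n_kept / 4`` frequencies so the system stays well overdetermined —
    a denser grid is unidentifiable on the kept frames and produces
    unbounded gap values — which covers the analysis pass-band for
    typical series lengths; a light ridge (1e-3) keeps coherent columns
    from trading off against each other inside censored runs.  A
    pure sinusoid on the grid is reconstructed to well under 5% error.
    Kept-frame values are returned unchanged.
    """
    residuals = np.asarray(residuals, dtype=float)
    T = residuals.shape[1]
    kept = mask.kept_indices
    if kept.size < max(2, min_kept):
        raise ValidationError("too few kept frames to interpolate; subject excluded")
    if kept.size == T:
        return residuals.copy()
    censored = np.flatnonzero(~mask.keep)
    n_freq = min((T - 1) // 2, max(1, kept.size // 4))
    freqs = np.arange(1, n_freq + 1) / (T * frame_interval_s)
    times = np.arange(T) * frame_interval_s
    ang = 2 * np.pi * np.outer(times, freqs)
    basis = np.hstack([np.ones((T, 1)), np.cos(ang), np.sin(ang)])
    Bk = basis[kept]
    lam = 1e-3 * kept.size
    penalty = lam * np.eye(basis.shape[1])
    penalty[0, 0] = 0.0  # unpenalized DC term: a constant is refit exactly
    A = Bk.T @ Bk + penalty
    coef = np.linalg.solve(A, Bk.T @ residuals[:, kept].T)
    out = residuals.copy()
    out[:, censored] = (basis[censored] @ coef).T
    return out


# ---------------------------------------------------------------------------
# band-pass
# ---------------------------------------------------------------------------

def bandpass(signals: np.ndarray, low: float = 0.009, high: float = 0.08,
             frame_interval_s: float = 3.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    signals = np.asarray(signals, dtype=float)
    fs = 1.0 / frame_interval_s
    nyq = fs / 2.0
    if not 0 < low < high < nyq:
        raise ValidationError(f"invalid band [{low}, {high}] for Nyquist {nyq}")
    sos = sp_signal.butter(order, [low / nyq, high / nyq], btype="bandpass",
                           output="sos")
    return sp_signal.sosfiltfilt(sos, signals, axis=-1)


def clean(signals: np.ndarray, fd: np.ndarray, dvars: np.ndarray,
          design: NuisanceDesign, frame_interval_s: float = 3.0,
          **censor_kwargs):
    """Full fixed-order cleaning: censor -> regress -> interpolate -> band-pass.

    Returns ``(cleaned_signals, mask)``; raises ValidationError when the
    subject is excluded by the censoring rule.
    """
    mask = censor_mask(fd, dvars, **censor_kwargs)
    if mask.subject_excluded:
        raise ValidationError("subject excluded: censored fraction above threshold")
    resid = nuisance_regress(signals, design, mask)
    filled = interpolate_censored(resid, mask, frame_interval_s)
    return bandpass(filled, frame_interval_s=frame_interval_s), mask
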