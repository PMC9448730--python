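"""Resting-state fMRI cleaning: motion QC, scrubbing, nuisance regression,
band-pass filtering.

The order of operations matches common volume-based resting-state pipelines:
the first four volumes are dropped, nuisance regression (24 motion
parameters, spike regressors, linear/quadratic trends, global/white-matter/
CSF signals) runs in a single OLS step, and band-pass filtering (0.01-0.08 Hz
by default) is applied to the residuals, before any network construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotionTrace",
    "NuisanceSet",
    "CleanSeries",
    "framewise_displacement",
    "flag_spikes",
    "spike_regressors",
    "qc_retention",
    "friston24",
    "build_nuisance",
    "regress_nuisance",
    "bandpass",
    "clean_subject",
]

#: Power-convention head radius converting rotations (rad) to arc length (mm).
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Scrubbing threshold on framewise displacement.
FD_THRESHOLD_MM = 0.5

#: QC rule: at most 90 volumes (1/3 of a 270-volume-equivalent run) may be
#: flagged for scrubbing.
MAX_REMOVED_VOLUMES = 90


def framewise_displacement(params: np.ndarray,
                           head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Power framewise displacement from 6 rigid-body parameters.

    ``FD_t = sum |d translations| + r * sum |d rotations|`` with translations
    in mm (columns 0-2), rotations in rad (columns 3-5); ``FD_0 = 0``.
    """
    params = np.asarray(params, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"motion parameters must be (n, 6), got {params.shape}")
    if params.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.diff(params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


@dataclass
class MotionTrace:
    params: np.ndarray  # (n, 6): translations mm, rotations rad
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    fd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, float)
        self.fd = framewise_displacement(self.params, self.head_radius_mm)


def flag_spikes(fd: np.ndarray, threshold_mm: float = FD_THRESHOLD_MM,
                back: int = 1, forward: int = 2) -> np.ndarray:
    """Volumes to scrub: every FD exceedance plus ``back`` preceding and
    ``forward`` following neighbours, clipped to the valid range.

    Idempotent by construction: the flagged set depends only on which frames
    exceed the threshold, not on FD values at neighbours.
    """
    fd = np.asarray(fd, float)
    n = fd.size
    hits = np.flatnonzero(fd > threshold_mm)
    flagged: set[int] = set()
    for t in hits:
        flagged.update(range(max(0, t - back), min(n, t + forward + 1)))
    return np.array(sorted(flagged), dtype=int)


def spike_regressors(flagged: np.ndarray, n_volumes: int) -> np.ndarray:
    """One 0/1 indicator column per flagged volume, shape (n_volumes, n_flagged)."""
    flagged = np.asarray(flagged, int)
    out = np.zeros((n_volumes, flagged.size))
    out[flagged, np.arange(flagged.size)] = 1.0
    return out


def qc_retention(n_total_volumes: int, n_flagged: int,
                 max_removed: int = MAX_REMOVED_VOLUMES) -> bool:
    """Pass iff no more than ``max_removed`` volumes are scrubbed (inclusive)."""
    if n_total_volumes < 0 or n_flagged < 0:
        raise ValueError("volume counts must be nonnegative")
    return n_flagged <= max_removed


def friston24(params: np.ndarray) -> np.ndarray:
    """24-parameter motion model: [p, p_{t-1}, p^2, p_{t-1}^2] for the six
    rigid-body parameters; the first-volume lag is zero-padded."""
    params = np.asarray(params, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError(f"motion parameters must be (n, 6), got {params.shape}")
    lag = np.vstack([np.zeros((1, 6)), params[:-1]])
    return np.hstack([params, lag, params ** 2, lag ** 2])


@dataclass
class NuisanceSet:
    """Full nuisance design: intercept, Friston-24, spikes, trends, tissue means."""

    matrix: np.ndarray
    names: list[str]
    flagged: np.ndarray

    @property
    def n_spikes(self) -> int:
        return int(self.flagged.size)


def build_nuisance(motion: MotionTrace | np.ndarray,
                   global_signal: np.ndarray | None = None,
                   wm_signal: np.ndarray | None = None,
                   csf_signal: np.ndarray | None = None,
                   fd_threshold_mm: float = FD_THRESHOLD_MM) -> NuisanceSet:
    if not isinstance(motion, MotionTrace):
        motion = MotionTrace(motion)
    n = motion.params.shape[0]
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    cols.append(friston24(motion.params))
    names += [f"friston24_{i}" for i in range(24)]
    flagged = flag_spikes(motion.fd, fd_threshold_mm)
    cols.append(spike_regressors(flagged, n))
    names += [f"spike_t{t}" for t in flagged]
    t = np.arange(n, dtype=float)
    t = (t - t.mean()) / max(t.std(), 1.0)
    cols.append(np.column_stack([t, t ** 2]))
    names += ["trend_linear", "trend_quadratic"]
    for sig, name in ((global_signal, "global"), (wm_signal, "white_matter"),
                      (csf_signal, "csf")):
        if sig is not None:
            cols.append(np.asarray(sig, float).reshape(n, 1))
            names.append(name)
    return NuisanceSet(np.hstack(cols), names, flagged)


@dataclass
class CleanSeries:
    data: np.ndarray  # (m voxels, t volumes) residuals (optionally filtered)
    tr_seconds: float
    n_retained: int
    qc_pass: bool
    flagged: np.ndarray = field(default_factory=lambda: np.array([], int))


def regress_nuisance(series: np.ndarray, nuisance: NuisanceSet | np.ndarray,
                     names: list[str] | None = None,
                     drop_collinear: bool = False) -> np.ndarray:
    """Per-voxel OLS residuals of ``series`` (m, t) against the nuisance design.

    Raises if the design is rank deficient after dropping exactly duplicated
    columns, naming the collinear columns; with ``drop_collinear`` the named
    columns are dropped with a warning instead (degenerate motion traces make
    quadratic Friston terms exactly collinear, which should not kill a
    pipeline run).
    """
    if isinstance(nuisance, NuisanceSet):
        X, names = nuisance.matrix, nuisance.names
    else:
        X = np.asarray(nuisance, float)
        names = names or [f"col{i}" for i in range(X.shape[1])]
    series = np.asarray(series, float)
    # drop exact duplicate columns (e.g. a spike regressor duplicated by caller)
    _, keep_idx = np.unique(X.round(12), axis=1, return_index=True)
    keep_idx = np.sort(keep_idx)
    Xu = X[:, keep_idx]
    kept_names = [names[i] for i in keep_idx]
    rank = np.linalg.matrix_rank(Xu)
    if rank < Xu.shape[1]:
        # name the columns involved in the remaining collinearity
        bad = []
        r = 0
        basis = np.zeros((Xu.shape[0], 0))
        for j in range(Xu.shape[1]):
            cand = np.column_stack([basis, Xu[:, j]])
            if np.linalg.matrix_rank(cand) > r:
                basis, r = cand, r + 1
            else:
                bad.append(kept_names[j])
        if not drop_collinear:
            raise ValueError(f"nuisance design is rank deficient; collinear columns: {bad}")
        import warnings
        warnings.warn(f"dropping collinear nuisance columns: {bad}")
        keep = [j for j, n in enumerate(kept_names) if n not in bad]
        Xu = Xu[:, keep]
    beta, *_ = np.linalg.lstsq(Xu, series.T, rcond=None)
    return series - (Xu @ beta).T


def bandpass(series: np.ndarray, tr_seconds: float,
             low_hz: float = 0.01, high_hz: float = 0.08) -> np.ndarray:
    """Ideal FFT-domain band-pass after linear detrend.

    Frequency bins with ``low_hz <= f <= high_hz`` are kept, all others
    (including DC) zeroed — a hard-cutoff filter with an exactly reproducible
    transfer function.
    """
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist:
        raise ValueError(f"high_hz={high_hz} exceeds Nyquist {nyquist:.4f} Hz")
    series = np.asarray(series, float)
    squeeze = series.ndim == 1
    series = np.atleast_2d(series)
    n = series.shape[1]
    t = np.arange(n, dtype=float)
    t -= t.mean()
    slope = (series @ t) / (t @ t)
    detrended = series - series.mean(axis=1, keepdims=True) - np.outer(slope, t)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(detrended, axis=1)
    spec[:, ~keep] = 0.0
    out = np.fft.irfft(spec, n=n, axis=1)
    return out[0] if squeeze else out


def clean_subject(series: np.ndarray, motion_params: np.ndarray,
                  tr_seconds: float,
                  *,
                  drop_initial: int = 4,
                  global_signal: np.ndarray | None = None,
                  wm_signal: np.ndarray | None = None,
                  csf_signal: np.ndarray | None = None,
                  low_hz: float = 0.01, high_hz: float = 0.08,
                  fd_threshold_mm: float = FD_THRESHOLD_MM,
                  max_removed: int = MAX_REMOVED_VOLUMES) -> CleanSeries:
    """Full per-subject cleaning driver.

    Drops the first ``drop_initial`` volumes (T1 equilibration), regresses the
    nuisance set (spikes included) and band-pass filters the residuals.  If no
    tissue signals are supplied the in-mask mean of the trimmed series is used
    as the global signal.
    """
    series = np.asarray(series, float)[:, drop_initial:]
    motion_params = np.asarray(motion_params, float)[drop_initial:]
    if global_signal is None:
        global_signal = series.mean(axis=0)
    nuis = build_nuisance(MotionTrace(motion_params), global_signal,
                          wm_signal, csf_signal, fd_threshold_mm)
    resid = regress_nuisance(series, nuis, drop_collinear=True)
    filtered = bandpass(resid, tr_seconds, low_hz, high_hz)
    n = series.shape[1]
    return CleanSeries(
        data=filtered, tr_seconds=tr_seconds,
        n_retained=n - nuis.n_spikes,
        qc_pass=qc_retention(n, nuis.n_spikes, max_removed),
        flagged=nuis.flagged,
    )
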