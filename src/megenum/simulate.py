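"""Synthetic multichannel MEG recordings with controlled statistics.

Sources are cosines with random frequency (10–30 Hz) and phase, centered and
orthonormalized, then mixed by the Cholesky factor of a target correlation
matrix so the sample Pearson correlations hit the target exactly.  Sensor
noise is white Gaussian or AR(6), scaled so the Frobenius-norm SNR (in the
amplitude convention, 20·log10 of the signal/noise Frobenius ratio) equals
the request exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
from scipy import signal as sps

from .geometry import LeadFieldSet

#: Default dipole amplitude at the user interface, nAm.
DEFAULT_AMPLITUDE_NAM = 200.0

FREQ_RANGE_HZ = (10.0, 30.0)


@dataclass
class SourceActivity:
    """Q source waveforms plus the correlation target they satisfy."""

    waveforms: np.ndarray  # (Q, N), A·m
    target_correlation: np.ndarray  # (Q, Q)
    frequencies: np.ndarray  # Hz
    phases: np.ndarray  # radians

    @property
    def Q(self) -> int:
        return self.waveforms.shape[0]

    @property
    def n_samples(self) -> int:
        return self.waveforms.shape[1]


@dataclass
class DipoleSet:
    """Ground-truth dipoles: indices into a source grid plus geometry."""

    grid_indices: np.ndarray  # (Q,) ints
    positions: np.ndarray  # (Q, 3) meters
    orientations: Optional[np.ndarray] = None  # (Q, 3) unit; None = freely oriented

    def __post_init__(self):
        self.grid_indices = np.asarray(self.grid_indices, dtype=int)
        if len(np.unique(self.grid_indices)) != self.grid_indices.size:
            raise ValueError("dipole grid indices must be unique")

    @property
    def Q(self) -> int:
        return self.grid_indices.size


@dataclass
class Recording:
    """An M×N sensor recording with optional baseline, trials, and truth."""

    data: np.ndarray  # (M, N)
    fs: float
    baseline: Optional[np.ndarray] = None  # (M, N_b)
    trials: Optional[np.ndarray] = None  # (n_trials, M, N)
    snr_db: Optional[float] = None
    noise_model: str = "white"
    ar_coefficients: Optional[np.ndarray] = None
    # ground truth (present for simulated recordings)
    truth_dipoles: Optional[DipoleSet] = None
    truth_activity: Optional[SourceActivity] = None
    signal_part: Optional[np.ndarray] = None
    noise_part: Optional[np.ndarray] = None
    seed: Optional[int] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValueError("data must be M×N with N >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def M(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.attrs["fs"] = self.fs
            f.attrs["noise_model"] = self.noise_model
            if self.snr_db is not None:
                f.attrs["snr_db"] = self.snr_db
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            if self.baseline is not None:
                f.create_dataset("baseline", data=self.baseline)
            if self.trials is not None:
                f.create_dataset("trials", data=self.trials)
            if self.truth_dipoles is not None:
                t = f.create_group("truth")
                t.create_dataset("indices", data=self.truth_dipoles.grid_indices)
                t.create_dataset("positions", data=self.truth_dipoles.positions)
                if self.truth_dipoles.orientations is not None:
                    t.create_dataset("orientations", data=self.truth_dipoles.orientations)
                if self.truth_activity is not None:
                    t.create_dataset("waveforms", data=self.truth_activity.waveforms)

    @classmethod
    def load(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            rec = cls(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                snr_db=float(f.attrs["snr_db"]) if "snr_db" in f.attrs else None,
                noise_model=str(f.attrs.get("noise_model", "white")),
                baseline=f["baseline"][()] if "baseline" in f else None,
                trials=f["trials"][()] if "trials" in f else None,
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )
            if "truth" in f:
                t = f["truth"]
                rec.truth_dipoles = DipoleSet(
                    grid_indices=t["indices"][()],
                    positions=t["positions"][()],
                    orientations=t["orientations"][()] if "orientations" in t else None,
                )
        return rec


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------


def generate_base_waveforms(Q: int, N: int, fs: float, rng_seed) -> np.ndarray:
    """Q centered, orthonormal cosine rows (frequencies 10–30 Hz).

    Row q starts as cos(2π f_q t + φ_q) with f_q ~ U[10, 30] Hz and
    φ_q ~ U[0, 2π); rows are then mean-centered and Gram–Schmidt
    orthonormalized so the Cholesky mixing step reproduces a target
    correlation exactly.
    """
    if Q < 1 or N < 2:
        raise ValueError("need Q >= 1 and N >= 2")
    if N < Q + 1:
        raise ValueError("N too small to orthonormalize Q centered rows")
    if fs <= 60.0:
        raise ValueError("sampling rate must exceed 60 Hz")
    rng = np.random.default_rng(rng_seed)
    freqs = rng.uniform(*FREQ_RANGE_HZ, size=Q)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=Q)
    t = np.arange(N) / fs
    base = np.cos(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    base -= base.mean(axis=1, keepdims=True)
    # Gram–Schmidt via thin QR, sign-fixed to keep rows aligned with the originals
    q, r = np.linalg.qr(base.T)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return (q * signs[None, :]).T


def impose_correlation(base: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Mix orthonormal rows by the Cholesky factor of the correlation target.

    Output rows have sample Pearson correlation matrix exactly ``R`` (to
    numerical precision) because the input rows are centered and orthonormal.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-12):
        raise ValueError("correlation target must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-12):
        raise ValueError("correlation target must have unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w[0] <= 0:
        raise ValueError(
            f"correlation target not positive definite (smallest eigenvalue {w[0]:.3e})"
        )
    L = np.linalg.cholesky(R)
    return L @ np.asarray(base, dtype=float)


def make_activity(
    Q: int,
    N: int,
    fs: float,
    rho: float | np.ndarray = 0.0,
    amplitude_nam: float = DEFAULT_AMPLITUDE_NAM,
    rng_seed=None,
) -> SourceActivity:
    """Correlated cosine activity with RMS amplitude ``amplitude_nam`` nAm.

    ``rho`` is either a common pairwise Pearson correlation or a full Q×Q
    target matrix.
    """
    rng = np.random.default_rng(rng_seed)
    seed_wave = int(rng.integers(2**31))
    if np.isscalar(rho):
        R = np.full((Q, Q), float(rho))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(rho, dtype=float)
    base = generate_base_waveforms(Q, N, fs, seed_wave)
    mixed = impose_correlation(base, R)
    # orthonormal rows have unit Frobenius norm -> scale to requested RMS
    scale = amplitude_nam * 1e-9 * np.sqrt(N)
    rng2 = np.random.default_rng(seed_wave)
    freqs = rng2.uniform(*FREQ_RANGE_HZ, size=Q)
    phases = rng2.uniform(0.0, 2.0 * np.pi, size=Q)
    return SourceActivity(
        waveforms=scale * mixed,
        target_correlation=R,
        frequencies=freqs,
        phases=phases,
    )


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def scale_noise_to_snr(signal_field: np.ndarray, noise: np.ndarray, snr_db: float) -> np.ndarray:
    """Scale ``noise`` so 20·log10(‖signal‖_F / ‖noise‖_F) equals ``snr_db``."""
    ns = np.linalg.norm(noise)
    if ns == 0:
        raise ValueError("noise matrix is zero")
    ss = np.linalg.norm(signal_field)
    if ss == 0 and np.isfinite(snr_db):
        raise ValueError("zero signal with finite SNR request")
    c = ss / (ns * 10.0 ** (snr_db / 20.0))
    return c * noise


def generate_ar_noise(coeffs: Sequence[float], M: int, N: int, rng_seed) -> np.ndarray:
    """M independent AR processes driven by unit-variance white noise.

    ``coeffs`` are the AR coefficients a_1..a_p of
    x[t] = sum_k a_k x[t-k] + w[t]; a burn-in of 500 samples is discarded.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    a_poly = np.concatenate([[1.0], -coeffs])
    roots = np.roots(a_poly)
    if np.any(np.abs(roots) >= 1.0 - 1e-12):
        raise ValueError("unstable AR coefficients (root on/outside unit circle)")
    rng = np.random.default_rng(rng_seed)
    burn = 500
    w = rng.standard_normal((M, N + burn))
    x = sps.lfilter([1.0], a_poly, w, axis=1)
    return x[:, burn:]


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------


def draw_dipoles(
    lf: LeadFieldSet,
    Q: int,
    rng_seed,
    fixed_oriented: bool = True,
    min_separation: float = 0.0,
    min_leadfield_fraction: float = 0.1,
) -> DipoleSet:
    """Draw Q distinct source locations (and tangential orientations).

    Orientations are uniform random with the radial component projected out
    and renormalized (radial dipoles are silent in a spherical conductor).
    ``min_separation`` (meters) optionally enforces a minimum pairwise
    distance; 0 leaves the draw unconstrained.

    Grid points whose lead-field norm falls below ``min_leadfield_fraction``
    of the grid median are excluded from the draw: a dipole at the sphere
    center (or close to it) is magnetically silent, so placing a "source"
    there would make the source count unidentifiable for every estimator.
    """
    rng = np.random.default_rng(rng_seed)
    pts = lf.grid.points
    norms = np.linalg.norm(lf.matrix.reshape(lf.n_points, -1), axis=1)
    eligible = np.flatnonzero(norms >= min_leadfield_fraction * np.median(norms))
    if eligible.size < Q:
        raise ValueError("not enough magnetically visible grid points to draw from")
    for _ in range(1000):
        idx = rng.choice(eligible, size=Q, replace=False)
        if Q < 2 or min_separation <= 0:
            break
        d = np.linalg.norm(pts[idx][:, None] - pts[idx][None, :], axis=-1)
        if np.min(d[np.triu_indices(Q, 1)]) >= min_separation:
            break
    else:
        raise ValueError("could not satisfy min_separation; relax it or enlarge grid")
    positions = pts[idx]
    orientations = None
    if fixed_oriented:
        o = rng.standard_normal((Q, 3))
        radial = positions / np.maximum(np.linalg.norm(positions, axis=1, keepdims=True), 1e-30)
        o -= np.sum(o * radial, axis=1, keepdims=True) * radial
        nrm = np.linalg.norm(o, axis=1, keepdims=True)
        if np.any(nrm < 1e-12):
            o = np.cross(radial, [0.0, 0.0, 1.0])
            nrm = np.linalg.norm(o, axis=1, keepdims=True)
        orientations = o / nrm
    return DipoleSet(grid_indices=idx, positions=positions, orientations=orientations)


def simulate_recording(
    lf: LeadFieldSet,
    dipoles: DipoleSet,
    activity: Optional[SourceActivity],
    snr_db: float,
    noise_model: str = "white",
    rng_seed=None,
    fs: float = 1000.0,
    n_samples: Optional[int] = None,
    ar_coefficients: Optional[Sequence[float]] = None,
    noise_scale: float = 1.0,
    n_baseline: int = 0,
) -> Recording:
    """Superpose dipole fields and add noise at an exact Frobenius SNR.

    ``snr_db = inf`` disables noise.  With ``Q = 0`` (``dipoles`` empty /
    ``activity`` None) the output is pure noise with Frobenius norm set by
    ``noise_scale``.  ``n_baseline`` > 0 additionally generates a pre-stimulus
    noise-only segment from the same noise model.
    """
    if activity is not None and dipoles.Q != activity.Q:
        raise ValueError("dipole count and activity Q mismatch")
    if activity is not None:
        N = activity.n_samples
    elif n_samples is not None:
        N = n_samples
    else:
        raise ValueError("need activity or n_samples")
    M = lf.M
    rng = np.random.default_rng(rng_seed)

    if dipoles.Q > 0:
        blocks = lf.matrix[dipoles.grid_indices]  # (Q, M, 3)
        if dipoles.orientations is not None:
            topos = np.einsum("qmi,qi->qm", blocks, dipoles.orientations)  # (Q, M)
            signal = topos.T @ activity.waveforms
        else:
            raise ValueError(
                "freely-oriented simulation requires explicit orientations; "
                "draw them with draw_dipoles(fixed_oriented=True)"
            )
    else:
        signal = np.zeros((M, N))

    def _noise(n_cols: int, seed) -> np.ndarray:
        if noise_model == "white":
            return np.random.default_rng(seed).standard_normal((M, n_cols))
        if noise_model == "ar6":
            if ar_coefficients is None:
                raise ValueError("ar6 noise model needs ar_coefficients")
            return generate_ar_noise(ar_coefficients, M, n_cols, seed)
        raise ValueError(f"unknown noise model {noise_model!r}")

    noise_seed = int(rng.integers(2**31))
    base_seed = int(rng.integers(2**31))
    if np.isinf(snr_db) and snr_db > 0:
        noise = np.zeros((M, N))
        scale = 0.0
    else:
        raw = _noise(N, noise_seed)
        if dipoles.Q > 0:
            noise = scale_noise_to_snr(signal, raw, snr_db)
            scale = np.linalg.norm(noise) / np.linalg.norm(raw)
        else:
            scale = noise_scale / np.linalg.norm(raw)
            noise = scale * raw
    baseline = None
    if n_baseline > 0:
        baseline = scale * _noise(n_baseline, base_seed) if scale > 0 else np.zeros((M, n_baseline))
    return Recording(
        data=signal + noise,
        fs=fs,
        baseline=baseline,
        snr_db=None if np.isinf(snr_db) else float(snr_db),
        noise_model=noise_model,
        ar_coefficients=None if ar_coefficients is None else np.asarray(ar_coefficients, float),
        truth_dipoles=dipoles,
        truth_activity=activity,
        signal_part=signal,
        noise_part=noise,
        seed=rng_seed if isinstance(rng_seed, (int, np.integer)) else None,
    )


def delayed_mixing(recordings: Sequence[Recording], max_delay_ms: float = 50.0, rng_seed=None) -> Recording:
    """Sum single-source recordings after independent random circular delays.

    Emulates the phantom-style construction of multi-source data from
    individually activated dipoles: each input is circularly shifted by a
    delay drawn uniformly from {0, ..., round(max_delay_ms·fs/1000)} samples,
    then all are summed.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    fs = recordings[0].fs
    M = recordings[0].M
    for r in recordings:
        if r.fs != fs:
            raise ValueError("all recordings must share the sampling rate")
        if r.M != M:
            raise ValueError("all recordings must share the channel count")
    rng = np.random.default_rng(rng_seed)
    max_shift = int(round(max_delay_ms * fs / 1000.0))
    out = np.zeros_like(recordings[0].data)
    delays = []
    for r in recordings:
        d = int(rng.integers(0, max_shift + 1))
        delays.append(d)
        out += np.roll(r.data, d, axis=1)
    rec = Recording(data=out, fs=fs, noise_model=recordings[0].noise_model)
    rec.delays_samples = np.asarray(delays)
    return rec
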