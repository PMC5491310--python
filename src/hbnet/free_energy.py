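"""Umbrella-sampling free energies: bias, exchange, WHAM and errors.

Windows restrain the system in gate-distance space with harmonic biases
U(ζ) = (k/2)(ζ − ζ_s)².  Neighbouring windows may swap centers by a
Metropolis rule on a deterministic odd-even schedule.  The unbiased
potential of mean force is recovered by self-consistent WHAM iteration,
with uncertainties from a block bootstrap whose block length must exceed
twice the measured integrated autocorrelation time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "KB_KCAL",
    "UmbrellaWindow",
    "PMFProfile",
    "Curve2D",
    "bias_energy",
    "exchange_probability",
    "exchange_accept",
    "odd_even_schedule",
    "wham_pmf",
    "autocorr_time",
    "block_bootstrap_error",
    "reconstruct_path_2d",
]

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041
DEFAULT_TEMPERATURE = 310.0  # K


@dataclass
class UmbrellaWindow:
    """Harmonically biased window: center, force constant and samples."""

    center: np.ndarray  # shape (d,) — 1-D or 2-D collective variable
    force_constant: float  # kcal/mol/Å²
    samples: np.ndarray  # shape (n,) or (n, d)
    sample_interval_ps: float = 20.0

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        if self.samples.shape[0] == 0:
            raise ValueError("window has no samples")
        if self.samples.shape[1] != self.center.shape[0]:
            raise ValueError("sample dimension does not match the center")


@dataclass
class PMFProfile:
    """Free-energy profile on a binned support, anchored at min = 0."""

    support: np.ndarray
    free_energy: np.ndarray
    error: Optional[np.ndarray] = None
    temperature: float = DEFAULT_TEMPERATURE


def bias_energy(zeta, window: UmbrellaWindow) -> float:
    """Harmonic restraint energy (k/2)|ζ − ζ_s|² in kcal/mol."""
    diff = np.atleast_1d(np.asarray(zeta, dtype=float)) - window.center
    return float(0.5 * window.force_constant * np.dot(diff, diff))


def exchange_probability(
    window_i: UmbrellaWindow,
    window_j: UmbrellaWindow,
    zeta_i,
    zeta_j,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Metropolis probability min{1, exp(−Δ)} for swapping window centers.

    Δ = [U_i(x_j) + U_j(x_i) − U_i(x_i) − U_j(x_j)] / k_B T; symmetric in
    (i, j).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    delta = (
        bias_energy(zeta_j, window_i)
        + bias_energy(zeta_i, window_j)
        - bias_energy(zeta_i, window_i)
        - bias_energy(zeta_j, window_j)
    ) / (KB_KCAL * temperature)
    return float(min(1.0, np.exp(-delta)))


def exchange_accept(
    window_i: UmbrellaWindow,
    window_j: UmbrellaWindow,
    zeta_i,
    zeta_j,
    temperature: float,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    p = exchange_probability(window_i, window_j, zeta_i, zeta_j, temperature)
    return bool(rng.random() < p), p


def odd_even_schedule(n_windows: int, step: int) -> list[tuple[int, int]]:
    """Neighbour pairs proposed at ``step``: even pairs, then odd pairs."""
    start = 0 if step % 2 == 0 else 1
    return [(i, i + 1) for i in range(start, n_windows - 1, 2)]


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


class WhamConvergenceError(RuntimeError):
    pass


def _window_scalar_samples(windows: Sequence[UmbrellaWindow]) -> list[np.ndarray]:
    out = []
    for w in windows:
        if w.samples.shape[1] != 1:
            raise ValueError(
                "wham_pmf expects scalar samples; project 2-D samples onto "
                "the path arc length first"
            )
        out.append(w.samples[:, 0])
    return out


def wham_pmf(
    windows: Sequence[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    bins: int | np.ndarray = 60,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> PMFProfile:
    """Self-consistent WHAM estimate of the unbiased PMF.

    Iterates the window free-energy offsets f_i until the largest change
    falls below ``tol`` (kcal/mol), then reports −k_B T ln p(ζ) anchored
    at zero.  Neighbouring windows must overlap; a gap leaves some bins
    empty and triggers a disconnected-segment warning.
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    kt = KB_KCAL * temperature
    series = _window_scalar_samples(windows)
    all_samples = np.concatenate(series)
    if isinstance(bins, (int, np.integer)):
        edges = np.linspace(all_samples.min(), all_samples.max(), int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)
    n_win = len(windows)
    hist = np.zeros((n_win, n_bins))
    for i, s in enumerate(series):
        hist[i], _ = np.histogram(s, bins=edges)
    counts = hist.sum(axis=0)
    if (counts == 0).any():
        warnings.warn(
            "empty bins detected: window sampling does not cover the "
            "support contiguously (disconnected segments)",
            stacklevel=2,
        )
    n_i = hist.sum(axis=1)
    # bias energy of every bin center under every window, units of kT
    u = np.array(
        [
            0.5 * w.force_constant * (centers - w.center[0]) ** 2
            for w in windows
        ]
    ) / kt
    f = np.zeros(n_win)  # dimensionless window offsets f_i/kT
    log_counts = np.where(counts > 0, np.log(np.maximum(counts, 1e-300)), -np.inf)
    log_n = np.log(n_i)
    for _ in range(max_iter):
        # log denominator per bin: log sum_i N_i exp(f_i - u_ib)
        a = log_n[:, None] + f[:, None] - u
        amax = a.max(axis=0)
        log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
        log_p = log_counts - log_den
        # update offsets: f_i = -log sum_b p_b exp(-u_ib)
        b = log_p[None, :] - u
        finite = np.isfinite(log_p)
        bmax = b[:, finite].max(axis=1)
        new_f = -(bmax + np.log(np.exp(b[:, finite] - bmax[:, None]).sum(axis=1)))
        new_f = new_f - new_f[0]
        change = float(np.max(np.abs(new_f - f))) * kt
        f = new_f
        if change < tol:
            break
    else:
        raise WhamConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {change:.3g} kcal/mol)"
        )
    with np.errstate(divide="ignore"):
        pmf = -kt * log_p
    finite = np.isfinite(pmf)
    pmf = pmf - pmf[finite].min()
    return PMFProfile(support=centers, free_energy=pmf, temperature=temperature)


def project_onto_windows(
    windows: Sequence[UmbrellaWindow], curve: "Curve2D"
) -> list[UmbrellaWindow]:
    """Project 2-D window samples onto curve arc length (1-D windows).

    Each sample maps to the arc-length coordinate of its nearest curve
    vertex, which allows the PMF to be expressed along the window/image
    index of the reconstructed path.
    """
    arc = curve.arc_lengths()
    out = []
    for w in windows:
        d = np.linalg.norm(
            w.samples[:, None, :] - curve.points[None, :, :], axis=2
        )
        nearest = np.argmin(d, axis=1)
        center_near = int(
            np.argmin(np.linalg.norm(curve.points - w.center[None, :], axis=1))
        )
        out.append(
            UmbrellaWindow(
                center=np.array([arc[center_near]]),
                force_constant=w.force_constant,
                samples=arc[nearest],
                sample_interval_ps=w.sample_interval_ps,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Autocorrelation and block bootstrap
# ---------------------------------------------------------------------------


def autocorr_time(series: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time, 1 + 2 Σ ρ(t), in sample units.

    Uses the standard self-consistent truncation: the sum runs to the
    smallest window W with W >= c·τ(W).  A constant series has no
    fluctuations and is reported as 1 with a warning.
    """
    series = np.asarray(series, dtype=float).ravel()
    n = len(series)
    if n < 50:
        raise ValueError("series too short for autocorrelation analysis")
    x = series - series.mean()
    var = np.dot(x, x) / n
    if var == 0:
        warnings.warn("constant series; IACT defined as 1", stacklevel=2)
        return 1.0
    # FFT autocovariance
    size = 1
    while size < 2 * n:
        size *= 2
    fx = np.fft.rfft(x, size)
    acov = np.fft.irfft(fx * np.conjugate(fx), size)[:n].real / n
    rho = acov / acov[0]
    tau = 1.0
    for w in range(1, n):
        tau = 1.0 + 2.0 * rho[1 : w + 1].sum()
        if w >= c * tau:
            break
    return float(max(tau, 1e-12))


def block_bootstrap_error(
    windows: Sequence[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    block_length: Optional[int] = None,
    n_boot: int = 200,
    bins: int | np.ndarray = 60,
    tol: float = 1e-6,
    seed: int = 0,
) -> PMFProfile:
    """Per-bin PMF standard deviation from a within-window block bootstrap.

    The time series of each window is cut into non-overlapping blocks of
    ``block_length`` samples (validated to be at least twice the largest
    measured integrated autocorrelation time); blocks are resampled with
    replacement within each window and WHAM is re-run per replicate.
    """
    if n_boot < 2:
        raise ValueError("need at least two bootstrap replicates")
    series = _window_scalar_samples(windows)
    taus = [autocorr_time(s) for s in series]
    max_tau = max(taus)
    if block_length is None:
        block_length = int(np.ceil(2 * max_tau))
    for idx, (s, tau) in enumerate(zip(series, taus)):
        if block_length < 2 * tau:
            raise ValueError(
                f"block length {block_length} shorter than twice the "
                f"autocorrelation time ({tau:.1f}) of window {idx}"
            )
        if len(s) // block_length < 2:
            raise ValueError(f"window {idx} has fewer than two blocks")
    base = wham_pmf(windows, temperature, bins=bins, tol=tol)
    edges_support = base.support
    rng = np.random.default_rng(seed)
    replicates = np.empty((n_boot, len(base.free_energy)))
    for b in range(n_boot):
        resampled = []
        for w, s in zip(windows, series):
            n_blocks = len(s) // block_length
            blocks = s[: n_blocks * block_length].reshape(n_blocks, block_length)
            pick = rng.integers(0, n_blocks, size=n_blocks)
            resampled.append(
                UmbrellaWindow(
                    center=w.center,
                    force_constant=w.force_constant,
                    samples=blocks[pick].ravel(),
                    sample_interval_ps=w.sample_interval_ps,
                )
            )
        # reuse the base bin edges so replicate profiles share support
        edges = np.concatenate(
            [
                [edges_support[0] - 0.5 * (edges_support[1] - edges_support[0])],
                0.5 * (edges_support[1:] + edges_support[:-1]),
                [edges_support[-1] + 0.5 * (edges_support[-1] - edges_support[-2])],
            ]
        )
        with warnings.catch_warnings():
            # resampled edge bins may fall empty; expected for replicates
            warnings.simplefilter("ignore")
            prof = wham_pmf(resampled, temperature, bins=edges, tol=tol)
        replicates[b] = prof.free_energy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN bins yield NaN errors
        error = np.nanstd(replicates, axis=0, ddof=1)
    return PMFProfile(
        support=base.support,
        free_energy=base.free_energy,
        error=error,
        temperature=temperature,
    )


# ---------------------------------------------------------------------------
# 2-D path reconstruction
# ---------------------------------------------------------------------------


@dataclass
class Curve2D:
    """Ordered control points of a smooth curve in gate-distance space."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("curve points must have shape (n, 2)")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive curve points must be distinct")

    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


def reconstruct_path_2d(
    points: np.ndarray,
    endpoints: tuple[np.ndarray, np.ndarray],
    n_windows: int = 30,
    smoothing: float = 1.0,
    n_iter: int = 25,
) -> Curve2D:
    """Principal-curve fit through a 2-D scatter of gate distances.

    Starting from the straight segment between the endpoints, vertices are
    iteratively pulled toward the local average of the points assigned to
    them (Gaussian weights along the current polyline, bandwidth =
    ``smoothing`` x the window spacing), lightly smoothed, and finally
    resampled at equal arc length.  The endpoints stay fixed, so the curve
    runs end state to end state through the point-density ridge.
    """
    from .paths import redistribute_images

    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) == 0:
        raise ValueError("scatter must be a non-empty (n, 2) array")
    if len(points) < n_windows:
        raise ValueError("fewer scatter points than requested windows")
    start = np.asarray(endpoints[0], dtype=float)
    end = np.asarray(endpoints[1], dtype=float)
    if n_windows < 2:
        raise ValueError("need at least two windows")
    if n_windows == 2:
        return Curve2D(np.vstack([start, end]))
    t = np.linspace(0, 1, n_windows)[:, None]
    curve = start[None, :] * (1 - t) + end[None, :] * t
    for _ in range(n_iter):
        spacing = np.linalg.norm(curve[1] - curve[0])
        bandwidth = max(smoothing * spacing, 1e-9)
        d2 = (
            np.sum((points[:, None, :] - curve[None, :, :]) ** 2, axis=2)
            / (2 * bandwidth**2)
        )
        w = np.exp(-(d2 - d2.min(axis=1, keepdims=True)))
        w = w / w.sum(axis=1, keepdims=True)
        mass = w.sum(axis=0)
        target = np.where(
            mass[:, None] > 1e-12, (w.T @ points) / np.maximum(mass, 1e-12)[:, None], curve
        )
        new_curve = 0.5 * curve + 0.5 * target
        # light Laplacian smoothing of the interior
        new_curve[1:-1] = 0.5 * new_curve[1:-1] + 0.25 * (
            new_curve[:-2] + new_curve[2:]
        )
        new_curve[0] = start
        new_curve[-1] = end
        new_curve = redistribute_images(new_curve, n_windows)
        if np.max(np.linalg.norm(new_curve - curve, axis=1)) < 1e-10:
            curve = new_curve
            break
        curve = new_curve
    return Curve2D(curve)
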