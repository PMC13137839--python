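"""LFP-derived measures.

Spectra (Welch), aperiodic/periodic spectral parameterization, band powers,
sample entropy, short-window sliding feature series, weighted phase-lag index,
theta->gamma phase-amplitude coupling, bivariate spectral Granger causality,
the 1-100/1-160 Hz LFP SNR ratio, 1-s complexity windows, and peri-event
entropy histograms sorted by wPLI peak time.

Filters are zero-phase 4th-order Butterworth band-passes throughout (phase
neutrality is required by the PAC and wPLI estimators); Hilbert transforms are
taken on whole traces before any windowing to avoid edge bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist

__all__ = [
    "SpectrumFit",
    "PacResult",
    "welch_psd",
    "parameterize_spectrum",
    "band_power",
    "sample_entropy",
    "sliding_features",
    "wpli",
    "pac",
    "pac_permutation_p",
    "spectral_granger",
    "lfp_snr_ratio",
    "complexity_windows",
    "peri_entropy_histogram",
    "bandpass",
    "detect_delta_waves",
    "DELTA_BAND",
    "THETA_BAND",
    "GAMMA_BAND",
]

DELTA_BAND = (1.0, 5.0)
THETA_BAND = (3.0, 12.0)
GAMMA_BAND = (60.0, 100.0)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def bandpass(trace: np.ndarray, fs: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass."""
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, trace)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def welch_psd(
    trace: np.ndarray,
    fs: float,
    seg_s: float = 2.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (Hann taper, density scaling).

    Falls back to a single segment with a warning when the trace is shorter
    than one segment.
    """
    nperseg = int(round(seg_s * fs))
    if trace.size < nperseg:
        warnings.warn("trace shorter than one Welch segment; using a single segment")
        nperseg = trace.size
    noverlap = int(round(overlap * nperseg))
    freqs, psd = signal.welch(
        trace, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, detrend="constant"
    )
    return freqs, psd


@dataclass(frozen=True)
class SpectrumFit:
    freqs: np.ndarray
    psd: np.ndarray
    offset: float  # log10 power at 1 Hz of the aperiodic component
    exponent: float  # negated log-log slope (>= 0 for physiological 1/f)
    peaks: tuple[tuple[float, float, float], ...]  # (center Hz, log10-power height, bandwidth Hz)
    fit_range: tuple[float, float]
    r_squared: float

    def aperiodic_at(self, freqs: np.ndarray) -> np.ndarray:
        return 10.0 ** (self.offset - self.exponent * np.log10(freqs))


def _robust_line(x: np.ndarray, y: np.ndarray, n_iter: int = 3) -> tuple[float, float]:
    """Least-squares line that iteratively down-weights points lying above the
    fit (oscillatory peaks only bias the spectrum upward)."""
    w = np.ones_like(x)
    slope = intercept = 0.0
    for _ in range(n_iter):
        W = np.sqrt(w)
        A = np.vstack([x * W, W]).T
        slope, intercept = np.linalg.lstsq(A, y * W, rcond=None)[0]
        resid = y - (slope * x + intercept)
        sd = resid.std() or 1.0
        w = np.where(resid > sd, 0.0, 1.0)
    return float(slope), float(intercept)


def _gauss(x: np.ndarray, height: float, center: float, width: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((x - center) / width) ** 2)


def parameterize_spectrum(
    freqs: np.ndarray,
    psd: np.ndarray,
    fit_range: tuple[float, float] = (1.0, 100.0),
    max_peaks: int = 4,
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.2,
) -> SpectrumFit:
    """Decompose a PSD into a 1/f aperiodic component and Gaussian peaks.

    Iterative fit: a robust log-log line for the aperiodic background, Gaussian
    peaks on the flattened residual (height >= ``peak_threshold_sd`` residual
    SDs and >= ``min_peak_height`` log10 units, guarding against fitting
    estimator scatter), then an aperiodic refit on the peak-subtracted
    spectrum.  The returned ``exponent`` is the negated log-log slope.
    """
    freqs = np.asarray(freqs, float)
    psd = np.asarray(psd, float)
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1]) & (freqs > 0)
    if not np.any(sel):
        raise ValueError("fit_range does not intersect the spectral support")
    if np.any(psd[sel] <= 0):
        raise ValueError("PSD values must be positive inside the fit range")
    lf = np.log10(freqs[sel])
    lp = np.log10(psd[sel])

    slope, intercept = _robust_line(lf, lp)
    resid = lp - (slope * lf + intercept)

    peaks: list[tuple[float, float, float]] = []
    work = resid.copy()
    for _ in range(max_peaks):
        sd = work.std()
        k = int(np.argmax(work))
        if sd == 0 or work[k] < max(peak_threshold_sd * sd, min_peak_height):
            break
        guess = (work[k], lf[k], 0.05)
        try:
            popt, _ = curve_fit(
                _gauss, lf, work, p0=guess,
                bounds=([0.0, lf.min(), 1e-3], [10 * work[k] + 1, lf.max(), 1.0]),
                maxfev=2000,
            )
        except RuntimeError:
            break
        height, center_lf, width_lf = popt
        span = lf.max() - lf.min()
        if center_lf < lf.min() + 0.05 * span or center_lf > lf.max() - 0.05 * span:
            # edge artifact (leakage at the fit boundary), not an oscillation
            work = work - _gauss(lf, *popt)
            continue
        center_hz = 10.0 ** center_lf
        bw_hz = 10.0 ** (center_lf + width_lf) - 10.0 ** (center_lf - width_lf)
        peaks.append((float(center_hz), float(height), float(bw_hz)))
        work = work - _gauss(lf, *popt)

    # aperiodic refit on the peak-subtracted (flattened) spectrum
    flattened = lp - (resid - work)
    slope, intercept = _robust_line(lf, flattened)
    model = slope * lf + intercept + (resid - work)
    ss_res = float(np.sum((lp - model) ** 2))
    ss_tot = float(np.sum((lp - lp.mean()) ** 2)) or 1.0
    r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return SpectrumFit(
        freqs=freqs[sel],
        psd=psd[sel],
        offset=float(intercept),
        exponent=float(-slope),
        peaks=tuple(peaks),
        fit_range=fit_range,
        r_squared=r2,
    )


def band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float],
    relative: bool = False,
    total_range: tuple[float, float] = (1.0, 100.0),
) -> float:
    """Trapezoidal band-integrated power; ``relative`` divides by the
    ``total_range`` integral."""
    freqs = np.asarray(freqs, float)
    psd = np.asarray(psd, float)

    def integrate(lo: float, hi: float) -> float:
        sel = (freqs >= lo) & (freqs <= hi)
        if sel.sum() < 2:
            raise ValueError(f"band ({lo}, {hi}) has no spectral support")
        return float(np.trapezoid(psd[sel], freqs[sel]))

    p = integrate(*band)
    if not relative:
        return p
    return p / integrate(*total_range)


# ---------------------------------------------------------------------------
# sample entropy
# ---------------------------------------------------------------------------

def sample_entropy(series: np.ndarray, m: int = 2, r_factor: float = 0.2, r: float | None = None) -> float:
    """SampEn = -ln(A/B) with Chebyshev tolerance ``r`` (default 0.2 x SD).

    A counts (m+1)-length template match pairs, B counts m-length pairs, both
    over the first ``N - m`` templates with self-matches excluded.  Returns
    ``inf`` when no (m+1)-matches exist.
    """
    x = np.asarray(series, float)
    n = x.size
    if n < m + 2:
        raise ValueError("series too short for the template length")
    if r is None:
        r = r_factor * x.std()
    if r <= 0:
        raise ValueError("tolerance r must be positive (constant series?)")
    n_templates = n - m
    tm = sliding_window_view(x, m)[:n_templates]
    tm1 = sliding_window_view(x, m + 1)[:n_templates]
    db = cdist(tm, tm, metric="chebyshev")
    da = cdist(tm1, tm1, metric="chebyshev")
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(db[iu] < r))
    a = int(np.count_nonzero(da[iu] < r))
    if a == 0 or b == 0:
        return float("inf")
    return float(-np.log(a / b))


def _sampen_batch(windows: np.ndarray, m: int, r_factor: float) -> np.ndarray:
    """Sample entropy for each row of a (n_windows, width) matrix."""
    out = np.empty(windows.shape[0])
    for i, w in enumerate(windows):
        sd = w.std()
        if sd == 0:
            out[i] = np.inf
            continue
        out[i] = sample_entropy(w, m=m, r=r_factor * sd)
    return out


# ---------------------------------------------------------------------------
# delta-wave detection
# ---------------------------------------------------------------------------

def detect_delta_waves(
    trace: np.ndarray,
    fs: float,
    band: tuple[float, float] = DELTA_BAND,
    threshold_sd: float = 2.0,
) -> list[tuple[float, float]]:
    """Delta waves: negative excursions of the 1-5 Hz band-passed trace below
    ``-threshold_sd`` SD, extended trough-out to the surrounding zero crossings."""
    filt = bandpass(trace, fs, band)
    # robust scale: the waves themselves would inflate a plain SD
    sd = 1.4826 * np.median(np.abs(filt - np.median(filt)))
    if sd == 0:
        sd = filt.std()
    if sd == 0:
        return []
    below = filt < -threshold_sd * sd
    if not below.any():
        return []
    neg = filt < 0
    idx = np.where(below)[0]
    waves: list[tuple[float, float]] = []
    # walk each excursion out to its zero crossings
    starts = idx[np.diff(idx, prepend=-10) > 1]
    for s0 in starts:
        a = s0
        while a > 0 and neg[a - 1]:
            a -= 1
        b = s0
        while b < neg.size - 1 and neg[b + 1]:
            b += 1
        waves.append((a / fs, (b + 1) / fs))
    # merge excursions sharing one negative lobe
    merged: list[tuple[float, float]] = []
    for w in waves:
        if merged and w[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], w[1]))
        else:
            merged.append(w)
    return merged


# ---------------------------------------------------------------------------
# sliding feature series
# ---------------------------------------------------------------------------

def _window_slopes(windows: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    """Log-log periodogram slope proxy per window over [lo, hi] Hz."""
    w = windows.shape[1]
    taper = np.hanning(w)
    spec = np.abs(np.fft.rfft(windows * taper, axis=1)) ** 2
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    sel = (freqs >= lo) & (freqs <= hi)
    lf = np.log10(freqs[sel])
    lp = np.log10(np.maximum(spec[:, sel], 1e-300))
    lf_c = lf - lf.mean()
    denom = float(np.sum(lf_c**2))
    return (lp @ lf_c) / denom


def sliding_features(
    lfp_pair: dict[str, np.ndarray] | np.ndarray,
    fs: float,
    win_s: float = 0.05,
    step_s: float = 0.025,
    context_s: float = 1.0,
    slope_band: tuple[float, float] = (20.0, 100.0),
    m: int = 2,
    r_factor: float = 0.2,
) -> pd.DataFrame:
    """Per-window LFP feature table for the E/I decoder.

    Columns: ``t_center_s``, ``slope`` (20-100 Hz log-log periodogram slope
    proxy; a 50 ms window cannot resolve lower frequencies), ``sampen``,
    ``rel_delta`` and ``rel_gamma`` (from a centered 1 s context window so the
    delta band is resolvable), ``delta_covered`` (window overlaps a detected
    delta wave), ``candidate_e`` (window center > 0.5 s from any delta wave),
    and ``label`` (initialized unlabeled).

    Slope/sampen/delta features come from the BNST trace, relative gamma from
    the NAc trace when a two-region pair is given.
    """
    if fs < 250:
        raise ValueError("fs must be >= 250 Hz")
    if isinstance(lfp_pair, dict):
        primary = lfp_pair.get("BNST", next(iter(lfp_pair.values())))
        gamma_src = lfp_pair.get("NAc", primary)
    else:
        primary = np.asarray(lfp_pair, float)
        gamma_src = primary
    n = primary.size
    w = int(round(win_s * fs))
    step = int(round(step_s * fs))
    starts = np.arange(0, n - w + 1, step)
    centers = (starts + w / 2.0) / fs

    windows = sliding_window_view(primary, w)[starts]
    slope = -_window_slopes(windows, fs, *slope_band)  # store as exponent proxy (>0 = steep)
    sampen = _sampen_batch(windows, m, r_factor)

    # band powers from 1 s context windows (centered, clipped at the edges)
    cw = int(round(context_s * fs))
    c_starts = np.clip(starts + w // 2 - cw // 2, 0, max(n - cw, 0))
    contexts = sliding_window_view(primary, cw)[c_starts]
    contexts_g = sliding_window_view(gamma_src, cw)[c_starts]
    taper = np.hanning(cw)
    freqs = np.fft.rfftfreq(cw, d=1.0 / fs)
    spec_d = np.abs(np.fft.rfft(contexts * taper, axis=1)) ** 2
    spec_g = np.abs(np.fft.rfft(contexts_g * taper, axis=1)) ** 2
    total_sel = (freqs >= 1.0) & (freqs <= 100.0)
    d_sel = (freqs >= DELTA_BAND[0]) & (freqs <= DELTA_BAND[1])
    g_sel = (freqs >= GAMMA_BAND[0]) & (freqs <= GAMMA_BAND[1])
    rel_delta = spec_d[:, d_sel].sum(axis=1) / np.maximum(spec_d[:, total_sel].sum(axis=1), 1e-300)
    rel_gamma = spec_g[:, g_sel].sum(axis=1) / np.maximum(spec_g[:, total_sel].sum(axis=1), 1e-300)

    waves = detect_delta_waves(primary, fs)
    win_lo = starts / fs
    win_hi = (starts + w) / fs
    delta_covered = np.zeros(starts.size, dtype=bool)
    dist = np.full(starts.size, np.inf)
    for ws, we in waves:
        delta_covered |= (win_lo < we) & (win_hi > ws)
        mid = 0.5 * (ws + we)
        dist = np.minimum(dist, np.abs(centers - mid))
    candidate_e = dist > 0.5

    finite = np.isfinite(sampen)
    if not finite.all():  # rare flat windows: carry the max finite value
        fill = sampen[finite].max() if finite.any() else 0.0
        sampen = np.where(finite, sampen, fill)

    return pd.DataFrame(
        {
            "t_center_s": centers,
            "slope": slope,
            "sampen": sampen,
            "rel_delta": rel_delta,
            "rel_gamma": rel_gamma,
            "delta_covered": delta_covered,
            "candidate_e": candidate_e,
            "label": "unlabeled",
        }
    )


# ---------------------------------------------------------------------------
# weighted phase-lag index
# ---------------------------------------------------------------------------

def _windowed_cross_spectra(
    x: np.ndarray, y: np.ndarray, fs: float, win_s: float
) -> tuple[np.ndarray, np.ndarray]:
    w = int(round(win_s * fs))
    step = w // 2
    n_win = (x.size - w) // step + 1
    if n_win < 2:
        raise ValueError("trace too short for windowed cross-spectra")
    idx = np.arange(n_win) * step
    taper = np.hanning(w)
    X = np.fft.rfft(sliding_window_view(x, w)[idx] * taper, axis=1)
    Y = np.fft.rfft(sliding_window_view(y, w)[idx] * taper, axis=1)
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    return freqs, X * np.conj(Y)


def wpli(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float],
    win_s: float = 0.5,
) -> float:
    """Weighted phase-lag index: |E[Im Sxy]| / E[|Im Sxy|], averaged over the
    band.  Symmetric in its arguments; insensitive to zero-lag coupling."""
    freqs, sxy = _windowed_cross_spectra(np.asarray(x, float), np.asarray(y, float), fs, win_s)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("band outside spectral support")
    im = np.imag(sxy[:, sel])
    denom = np.abs(im).mean(axis=0)
    if np.all(denom == 0):
        warnings.warn("imaginary cross-spectrum vanishes; wPLI undefined, returning 0")
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        per_freq = np.abs(im.mean(axis=0)) / denom
    return float(np.nanmean(per_freq))


def wpli_series(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float],
    win_s: float = 0.5,
    step_s: float = 0.25,
    inner_win_s: float = 0.125,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding wPLI time course (window centers, values)."""
    w = int(round(win_s * fs))
    step = int(round(step_s * fs))
    starts = np.arange(0, x.size - w + 1, step)
    vals = np.array(
        [wpli(x[s : s + w], y[s : s + w], fs, band, win_s=inner_win_s) for s in starts]
    )
    centers = (starts + w / 2.0) / fs
    return centers, vals


# ---------------------------------------------------------------------------
# phase-amplitude coupling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PacResult:
    mi: float
    phase_bins_deg: np.ndarray  # 18 bin centers
    amp_dist: np.ndarray  # normalized mean amplitude per bin (sums to 1)
    preferred_phase_deg: float
    n_cycles: float
    low_cycles_warning: bool = False


def _phase_amp(
    phase_sig: np.ndarray,
    amp_sig: np.ndarray,
    fs: float,
    phase_band: tuple[float, float],
    amp_band: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    ph = np.angle(signal.hilbert(bandpass(phase_sig, fs, phase_band)))
    amp = np.abs(signal.hilbert(bandpass(amp_sig, fs, amp_band)))
    return np.rad2deg(ph) % 360.0, amp


def _mi_from_dist(p: np.ndarray) -> float:
    """Kullback-Leibler modulation index: KL(p || uniform) / ln(n_bins)."""
    n = p.size
    nz = p > 0
    kl = float(np.sum(p[nz] * np.log(p[nz] * n)))
    return kl / np.log(n)


def pac(
    phase_sig: np.ndarray,
    amp_sig: np.ndarray,
    fs: float,
    phase_band: tuple[float, float] = THETA_BAND,
    amp_band: tuple[float, float] = GAMMA_BAND,
    n_bins: int = 18,
) -> PacResult:
    """Phase-amplitude coupling via the KL modulation index over 18 phase bins
    of 20 degrees.  ``preferred_phase_deg`` is the argmax bin center."""
    phase_deg, amp = _phase_amp(phase_sig, amp_sig, fs, phase_band, amp_band)
    n_cycles = phase_sig.size / fs * phase_band[0]
    low = n_cycles < 10
    if low:
        warnings.warn("fewer than 10 phase cycles; PAC estimate unreliable")
    bins = np.floor(phase_deg / (360.0 / n_bins)).astype(int) % n_bins
    sums = np.bincount(bins, weights=amp, minlength=n_bins)
    counts = np.maximum(np.bincount(bins, minlength=n_bins), 1)
    mean_amp = sums / counts
    dist = mean_amp / mean_amp.sum()
    centers = (np.arange(n_bins) + 0.5) * (360.0 / n_bins)
    return PacResult(
        mi=_mi_from_dist(dist),
        phase_bins_deg=centers,
        amp_dist=dist,
        preferred_phase_deg=float(centers[int(np.argmax(dist))]),
        n_cycles=float(n_cycles),
        low_cycles_warning=low,
    )


def pac_permutation_p(
    phase_sig: np.ndarray,
    amp_sig: np.ndarray,
    fs: float,
    phase_band: tuple[float, float] = THETA_BAND,
    amp_band: tuple[float, float] = GAMMA_BAND,
    n_bins: int = 18,
    n_perm: int = 200,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """(observed MI, permutation p) using circular shifts of the amplitude
    series as the null (preserves both marginals)."""
    phase_deg, amp = _phase_amp(phase_sig, amp_sig, fs, phase_band, amp_band)
    bins = np.floor(phase_deg / (360.0 / n_bins)).astype(int) % n_bins
    counts = np.maximum(np.bincount(bins, minlength=n_bins), 1)

    def mi_of(a: np.ndarray) -> float:
        mean_amp = np.bincount(bins, weights=a, minlength=n_bins) / counts
        return _mi_from_dist(mean_amp / mean_amp.sum())

    obs = mi_of(amp)
    rng = np.random.default_rng(seed)
    n = amp.size
    null = np.empty(n_perm)
    min_shift = int(0.05 * n)
    for k in range(n_perm):
        shift = int(rng.integers(min_shift, n - min_shift))
        null[k] = mi_of(np.roll(amp, shift))
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return float(obs), float(p)


# ---------------------------------------------------------------------------
# spectral Granger causality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrangerResult:
    freqs: np.ndarray
    gc_xy: np.ndarray  # x -> y
    gc_yx: np.ndarray  # y -> x
    order: int


def spectral_granger(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    max_order: int = 20,
    criterion: str = "aic",
    freq_grid: np.ndarray | None = None,
) -> GrangerResult:
    """Geweke spectral Granger causality from a bivariate VAR.

    The VAR order is selected by the information criterion up to ``max_order``
    (statsmodels fit); the spectral decomposition follows Geweke's frequency-
    domain formulation from the fitted coefficients and residual covariance.
    """
    from statsmodels.tsa.api import VAR

    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    model = VAR(data)
    res = model.fit(maxlags=max_order, ic=criterion, trend="n")
    p = res.k_ar
    if p == 0:
        res = model.fit(1, trend="n")
        p = 1
    coefs = res.coefs  # (p, 2, 2); row i: equation for variable i
    sigma = res.sigma_u

    roots = np.abs(np.linalg.eigvals(_companion(coefs)))
    if np.any(roots >= 1.0):
        raise ValueError(f"unstable VAR fit (max root {roots.max():.3f}); non-stationary input?")

    if freq_grid is None:
        freq_grid = np.linspace(1.0, min(100.0, fs / 2 * 0.99), 100)
    gc_xy = np.empty_like(freq_grid)
    gc_yx = np.empty_like(freq_grid)
    eye = np.eye(2)
    s00, s01, s11 = sigma[0, 0], sigma[0, 1], sigma[1, 1]
    for i, f in enumerate(freq_grid):
        z = np.exp(-2j * np.pi * f / fs)
        a = eye.astype(complex).copy()
        zk = 1.0
        for k in range(p):
            zk *= z
            a -= coefs[k] * zk
        h = np.linalg.inv(a)
        s = h @ sigma @ h.conj().T
        sxx = np.real(s[0, 0])
        syy = np.real(s[1, 1])
        # x -> y: reduction of Syy attributable to x's innovations
        num_xy = syy
        den_xy = syy - (s00 - s01**2 / s11) * np.abs(h[1, 0]) ** 2
        # y -> x
        num_yx = sxx
        den_yx = sxx - (s11 - s01**2 / s00) * np.abs(h[0, 1]) ** 2
        gc_xy[i] = np.log(num_xy / den_xy) if den_xy > 0 else np.inf
        gc_yx[i] = np.log(num_yx / den_yx) if den_yx > 0 else np.inf
    return GrangerResult(freqs=freq_grid, gc_xy=gc_xy, gc_yx=gc_yx, order=p)


def _companion(coefs: np.ndarray) -> np.ndarray:
    p, k, _ = coefs.shape
    comp = np.zeros((k * p, k * p))
    comp[:k, :] = np.concatenate(list(coefs), axis=1)
    if p > 1:
        comp[k:, :-k] = np.eye(k * (p - 1))
    return comp


# ---------------------------------------------------------------------------
# LFP SNR ratio and complexity windows
# ---------------------------------------------------------------------------

def lfp_snr_ratio(trace: np.ndarray, fs: float) -> float:
    """Variance of the 1-100 Hz band over variance of the 1-160 Hz band;
    values near 1 mean no content beyond 100 Hz (e.g. no 160 Hz stimulation
    artifact)."""
    if fs <= 320:
        raise ValueError("fs must exceed 320 Hz to resolve the 1-160 Hz band")
    wide = bandpass(trace, fs, (1.0, 160.0))
    narrow = bandpass(trace, fs, (1.0, 100.0))
    v = float(np.var(wide))
    if v == 0:
        raise ValueError("zero variance trace")
    return float(np.var(narrow)) / v


@dataclass(frozen=True)
class ComplexityWindows:
    t_center_s: np.ndarray
    sampen: np.ndarray
    labels: np.ndarray  # 'low' | 'high' | 'mid'
    low_incidence: float
    high_incidence: float


def complexity_windows(
    trace: np.ndarray, fs: float, win_s: float = 1.0, m: int = 2, r_factor: float = 0.2
) -> ComplexityWindows:
    """Sample entropy in contiguous 1-s windows; windows beyond mean +- 2 SD
    are labeled high/low-complexity extremes and their incidences reported."""
    w = int(round(win_s * fs))
    n_win = trace.size // w
    if n_win < 30:
        raise ValueError("need at least 30 windows")
    windows = trace[: n_win * w].reshape(n_win, w)
    se = _sampen_batch(windows, m, r_factor)
    finite = np.isfinite(se)
    mu, sd = se[finite].mean(), se[finite].std()
    labels = np.full(n_win, "mid", dtype=object)
    labels[se > mu + 2 * sd] = "high"
    labels[se < mu - 2 * sd] = "low"
    return ComplexityWindows(
        t_center_s=(np.arange(n_win) + 0.5) * win_s,
        sampen=se,
        labels=labels,
        low_incidence=float(np.mean(labels == "low")),
        high_incidence=float(np.mean(labels == "high")),
    )


# ---------------------------------------------------------------------------
# peri-event entropy histograms
# ---------------------------------------------------------------------------

def peri_entropy_histogram(
    entropy_t: np.ndarray,
    entropy_series: np.ndarray,
    event_times: Sequence[float],
    wpli_t: np.ndarray,
    wpli_series: np.ndarray,
    window_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-event entropy traces in a +-``window_s`` window, rows sorted
    ascending by the time of the wPLI peak in the same window.

    Returns ``(matrix, rel_time, sort_index, n_dropped)``; events too close to
    the series edges are dropped and counted.
    """
    entropy_t = np.asarray(entropy_t, float)
    wpli_t = np.asarray(wpli_t, float)
    dt = np.median(np.diff(entropy_t))
    rel = np.arange(-window_s, window_s + dt / 2, dt)
    rows: list[np.ndarray] = []
    peak_times: list[float] = []
    dropped = 0
    for ev in event_times:
        if ev - window_s < entropy_t[0] or ev + window_s > entropy_t[-1]:
            dropped += 1
            continue
        rows.append(np.interp(ev + rel, entropy_t, entropy_series))
        wsel = (wpli_t >= ev - window_s) & (wpli_t <= ev + window_s)
        if wsel.any():
            wt = wpli_t[wsel]
            peak_times.append(float(wt[np.argmax(wpli_series[wsel])] - ev))
        else:
            peak_times.append(0.0)
    if not rows:
        return np.empty((0, rel.size)), rel, np.empty(0, int), dropped
    order = np.argsort(np.asarray(peak_times), kind="stable")
    return np.vstack(rows)[order], rel, order, dropped
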