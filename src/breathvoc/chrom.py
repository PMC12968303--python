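"""Raw micro-GC chromatogram preprocessing and peak quantification.

A raw trace (detector intensity on a uniform retention-time grid) is turned
into a per-sample peak table through the chain

    spike removal (Hampel filter)
    -> baseline correction (asymmetric penalized least squares)
    -> detector-overload restoration (Gaussian flank refit)
    -> windowed Gaussian smoothing
    -> second-derivative peak detection
    -> co-elution clustering
    -> sum-of-Gaussians deconvolution with area integration.

The integrated area of every resolved Gaussian component is the quantitative
measure carried downstream.  All numeric knobs live in :class:`ChromConfig`;
none of them is a physical constant, so every default is overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, sparse
from scipy.optimize import curve_fit
from scipy.sparse.linalg import spsolve

__all__ = [
    "Chromatogram",
    "ChromConfig",
    "PEAK_COLUMNS",
    "remove_spikes",
    "correct_baseline",
    "correct_overload",
    "smooth",
    "detect_peaks",
    "cluster_coeluting",
    "fit_cluster",
    "process_chromatogram",
    "read_chromatogram",
    "write_chromatogram",
]

#: Columns of a per-sample peak table.
PEAK_COLUMNS = ["apex_rt_s", "sigma_s", "height", "area", "cluster_id", "n_in_cluster"]


@dataclass
class Chromatogram:
    """One sample's uniformly sampled retention-time/intensity trace."""

    time_s: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    acquisition_date: str | None = None
    saturation_level: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.intensity.shape:
            raise ValueError("time_s and intensity must be equal-length 1-D arrays")
        if self.time_s.size >= 2:
            steps = np.diff(self.time_s)
            if np.any(steps <= 0):
                raise ValueError("time grid must be strictly increasing")
            if np.ptp(steps) > 1e-6 * max(steps.mean(), 1e-30):
                raise ValueError("time grid must have a constant step")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite everywhere")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def with_intensity(self, intensity: np.ndarray) -> "Chromatogram":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass
class ChromConfig:
    """Tuning knobs for the preprocessing chain.

    hampel_window / hampel_nsigma
        Running-median window (grid points, odd) and MAD multiple for
        impulse-spike replacement.
    baseline_smoothness / baseline_asymmetry
        Penalty weight (lambda) and asymmetry (p < 0.5) of the asymmetric
        penalized least-squares baseline.
    smooth_window_s / smooth_sigma_s
        Support and standard deviation (seconds) of the truncated Gaussian
        smoothing kernel.
    detect_nsigma / min_height_frac
        Second-derivative detection threshold (noise multiples, MAD-scaled)
        and minimal apex height as a fraction of the trace maximum.
    cluster_valley_frac / cluster_sep_sigma
        Two apexes join a co-elution cluster when the valley between them
        exceeds this fraction of the smaller apex, or when their separation
        is below this multiple of the larger width estimate.
    """

    hampel_window: int = 11
    hampel_nsigma: float = 6.0
    baseline_smoothness: float = 3e7
    baseline_asymmetry: float = 0.001
    smooth_window_s: float = 5.0
    smooth_sigma_s: float = 0.8
    detect_nsigma: float = 5.0
    min_height_frac: float = 0.01
    cluster_valley_frac: float = 0.3
    cluster_sep_sigma: float = 3.0
    cluster_shared_width: bool = True

    def __post_init__(self) -> None:
        for name in (
            "hampel_window",
            "hampel_nsigma",
            "baseline_smoothness",
            "baseline_asymmetry",
            "smooth_window_s",
            "smooth_sigma_s",
            "detect_nsigma",
            "min_height_frac",
            "cluster_valley_frac",
            "cluster_sep_sigma",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.baseline_asymmetry >= 0.5:
            raise ValueError("baseline_asymmetry must be < 0.5")


# ---------------------------------------------------------------------------
# Stage 1: spike removal
# ---------------------------------------------------------------------------

def remove_spikes(chrom: Chromatogram, cfg: ChromConfig | None = None) -> Chromatogram:
    """Replace impulse outliers by the running median (Hampel filter).

    A short (5-point) running median tracks any chromatographic peak wider
    than about three grid points but not a 1-2-point impulse, so the
    residual against it isolates spikes even on steep peak flanks.  A point
    is flagged when its residual exceeds ``hampel_nsigma`` times the local
    MAD of the residual (window ``hampel_window``), and replaced by the
    running median.  Edge windows are truncated; all other points pass
    unchanged.
    """
    cfg = cfg or ChromConfig()
    if cfg.hampel_window < 3:
        raise ValueError("hampel_window must be >= 3 points")
    y = chrom.intensity
    if y.size < cfg.hampel_window:
        raise ValueError("chromatogram shorter than the Hampel window")
    s = pd.Series(y)
    trend_w = min(5, cfg.hampel_window)
    med = s.rolling(trend_w, center=True, min_periods=1).median().to_numpy()
    dev = pd.Series(y - med)
    mad = (
        dev.abs().rolling(cfg.hampel_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    scale = 1.4826 * mad
    # relative-amplitude floor: on (near-)noiseless traces the MAD collapses
    # to zero and the smooth apex's tiny residual would be flagged; a real
    # impulse is far above 1% of the local intensity.  Peaks narrower than
    # ~3 grid steps are below the filter's resolution by construction.
    floor = 0.01 * np.abs(y) + 1e-12 * (np.max(np.abs(y)) + 1.0)
    flag = np.abs(dev.to_numpy()) > cfg.hampel_nsigma * np.maximum(scale, floor)
    out = np.where(flag, med, y)
    return chrom.with_intensity(out)


# ---------------------------------------------------------------------------
# Stage 2: baseline correction
# ---------------------------------------------------------------------------

def _asls_baseline(y: np.ndarray, lam: float, p: float, n_iter: int = 15) -> np.ndarray:
    """Asymmetric penalized least-squares baseline (second-difference penalty).

    Weights are ``p`` for points above the current fit and ``1 - p`` below,
    so the fit hugs the lower envelope; linear trends lie in the penalty's
    null space and are followed exactly.
    """
    n = y.size
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    dtd = (d.T @ d).tocsc()
    w = np.ones(n)
    z = y
    for _ in range(n_iter):
        a = sparse.diags(w, format="csc") + lam * dtd
        z = spsolve(a, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def correct_baseline(chrom: Chromatogram, cfg: ChromConfig | None = None) -> Chromatogram:
    """Subtract a smooth drifting baseline estimated below the peaks."""
    cfg = cfg or ChromConfig()
    y = chrom.intensity
    if y.size < 10:
        raise ValueError("trace too short for baseline estimation (need >= 10 points)")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensity")
    z = _asls_baseline(y, cfg.baseline_smoothness, cfg.baseline_asymmetry)
    return chrom.with_intensity(y - z)


# ---------------------------------------------------------------------------
# Stage 3: detector overload restoration
# ---------------------------------------------------------------------------

def _gauss(t, h, mu, sig):
    return h * np.exp(-0.5 * ((t - mu) / sig) ** 2)


def correct_overload(chrom: Chromatogram, cfg: ChromConfig | None = None) -> Chromatogram:
    """Restore clipped peak tops by refitting a Gaussian to unsaturated flanks.

    Maximal runs of at least three consecutive points at >= 99% of the
    detector's saturation level are replaced by a Gaussian fitted to the
    enclosing peak's unclipped flanks.  Identity when no saturation level
    is declared.
    """
    cfg = cfg or ChromConfig()
    sat = chrom.saturation_level
    if sat is None:
        return chrom.with_intensity(chrom.intensity.copy())
    y = chrom.intensity.copy()
    t = chrom.time_s
    mask = y >= 0.99 * sat
    if mask.sum() > 0.5 * y.size:
        raise ValueError("saturated plateau occupies more than half the trace")
    # maximal runs of >= 3 consecutive saturated points
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return chrom.with_intensity(y)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if run.size < 3:
            continue
        r = run.size
        lo = max(0, run[0] - 4 * r)
        hi = min(y.size, run[-1] + 4 * r + 1)
        seg = slice(lo, hi)
        flank = ~mask[seg]
        if flank.sum() < 4:
            continue
        tt, yy = t[seg][flank], y[seg][flank]
        mu0 = 0.5 * (t[run[0]] + t[run[-1]])
        sig0 = max(r * chrom.dt, chrom.dt)
        try:
            popt, _ = curve_fit(
                _gauss,
                tt,
                yy,
                p0=[1.5 * sat, mu0, sig0],
                bounds=([sat, t[lo], chrom.dt / 2], [np.inf, t[hi - 1], t[-1] - t[0]]),
                maxfev=5000,
            )
        except RuntimeError:
            warnings.warn("overload flank fit failed; run left clipped")
            continue
        y[run] = _gauss(t[run], *popt)
    return chrom.with_intensity(y)


# ---------------------------------------------------------------------------
# Stage 4: smoothing
# ---------------------------------------------------------------------------

def smooth(chrom: Chromatogram, cfg: ChromConfig | None = None) -> Chromatogram:
    """Convolve with a truncated, renormalized Gaussian kernel.

    Edge effects are handled by renormalizing the kernel mass actually
    overlapping the trace, so a constant trace is returned unchanged.
    """
    cfg = cfg or ChromConfig()
    dt = chrom.dt
    half = int(round(cfg.smooth_window_s / dt / 2))
    if 2 * half + 1 < 3:
        raise ValueError("smooth_window_s must span at least 3 grid steps")
    x = np.arange(-half, half + 1) * dt
    k = np.exp(-0.5 * (x / cfg.smooth_sigma_s) ** 2)
    num = np.convolve(chrom.intensity, k, mode="same")
    den = np.convolve(np.ones_like(chrom.intensity), k, mode="same")
    return chrom.with_intensity(num / den)


# ---------------------------------------------------------------------------
# Stage 5: second-derivative peak detection
# ---------------------------------------------------------------------------

def _second_derivative(y: np.ndarray, dt: float) -> np.ndarray:
    d2 = np.empty_like(y)
    d2[1:-1] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) / dt**2
    d2[0] = d2[1]
    d2[-1] = d2[-2]
    return d2


def detect_peaks(chrom: Chromatogram, cfg: ChromConfig | None = None) -> pd.DataFrame:
    """Apex candidates as local minima of the discrete second derivative.

    A candidate must fall below ``-detect_nsigma`` times the second
    derivative's noise scale (MAD over the lowest-intensity half of the
    trace), be prominent by at least the same amount (so noise ripple
    inside a strong peak's curvature basin is not double-counted), and its
    height must exceed ``min_height_frac`` of the trace maximum.  Returns a
    frame with columns ``rt``, ``height``, ``sigma_est`` and ``index``
    (grid position), sorted by retention time.
    """
    cfg = cfg or ChromConfig()
    y = chrom.intensity
    dt = chrom.dt
    empty = pd.DataFrame(columns=["rt", "height", "sigma_est", "index"])
    if y.size < 5:
        return empty
    d2 = _second_derivative(y, dt)
    low = y <= np.median(y)
    if low.sum() >= 5:
        d2_low = d2[low]
        noise = 1.4826 * np.median(np.abs(d2_low - np.median(d2_low)))
    else:
        noise = 0.0
    floor = 1e-12 * (np.max(np.abs(d2)) + 1.0)
    scale = max(noise, floor)
    cand, _ = signal.find_peaks(
        -d2, height=cfg.detect_nsigma * scale, prominence=cfg.detect_nsigma * scale
    )
    cand = cand[
        (cand > 0)
        & (cand < y.size - 1)
        & (y[cand] >= cfg.min_height_frac * y.max())
    ]
    if cand.size == 0:
        return empty
    sigma_est = np.sqrt(np.maximum(y[cand] / (-d2[cand]), dt**2))
    return pd.DataFrame(
        {
            "rt": chrom.time_s[cand],
            "height": y[cand],
            "sigma_est": sigma_est,
            "index": cand,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stage 6: co-elution clustering
# ---------------------------------------------------------------------------

def cluster_coeluting(
    apexes: pd.DataFrame, chrom: Chromatogram, cfg: ChromConfig | None = None
) -> list[list[int]]:
    """Group adjacent apexes into co-eluting clusters (transitive closure).

    Adjacent apexes merge when their separation is below
    ``cluster_sep_sigma`` times the larger width estimate, or when the
    intensity valley between them stays above ``cluster_valley_frac`` of the
    smaller apex height.  The result partitions the apex list.
    """
    cfg = cfg or ChromConfig()
    n = len(apexes)
    if n == 0:
        return []
    clusters: list[list[int]] = [[0]]
    for i in range(1, n):
        a, b = apexes.iloc[i - 1], apexes.iloc[i]
        sep = b["rt"] - a["rt"]
        close = sep < cfg.cluster_sep_sigma * max(a["sigma_est"], b["sigma_est"])
        lo, hi = int(a["index"]), int(b["index"])
        valley = chrom.intensity[lo : hi + 1].min() if hi > lo else chrom.intensity[lo]
        high_valley = valley > cfg.cluster_valley_frac * min(a["height"], b["height"])
        if close or high_valley:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    return clusters


# ---------------------------------------------------------------------------
# Stage 7: Gaussian-mixture deconvolution
# ---------------------------------------------------------------------------

def _gauss_sum(t, *params):
    """Sum of k Gaussians with free widths, plus a constant offset."""
    c = params[-1]
    out = np.full_like(t, c, dtype=float)
    for j in range(len(params) // 3):
        h, mu, sig = params[3 * j : 3 * j + 3]
        out += h * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return out


def _gauss_sum_shared(t, *params):
    """Sum of k Gaussians sharing one width, plus a constant offset."""
    sig, c = params[-2], params[-1]
    out = np.full_like(t, c, dtype=float)
    for j in range((len(params) - 2) // 2):
        h, mu = params[2 * j : 2 * j + 2]
        out += h * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return out


def fit_cluster(
    chrom: Chromatogram,
    apexes: pd.DataFrame,
    cfg: ChromConfig | None = None,
) -> pd.DataFrame:
    """Resolve one co-eluting cluster by least-squares sum-of-Gaussians fit.

    The fitted curve is a sum of one Gaussian per detected apex plus a
    constant offset, over the cluster segment extended by four width
    estimates each side.  By default components of one cluster share a
    single width (``cluster_shared_width``): co-eluting compounds leave the
    column with near-identical band broadening, and the constraint is what
    makes strongly overlapped doublets statistically identifiable.  Each
    component's area is ``height * sigma * sqrt(2*pi)``; components below
    0.1% of the cluster area are dropped.  On non-convergence after bounded
    restarts the cluster is flagged (``n_in_cluster = -1``) and quantified
    by direct integration.
    """
    cfg = cfg or ChromConfig()
    k = len(apexes)
    if k < 1:
        raise ValueError("cluster must contain at least one apex")
    t, y = chrom.time_s, chrom.intensity
    dt = chrom.dt
    sig_max = float(apexes["sigma_est"].max())
    lo = max(0, int(apexes["index"].min() - round(4 * sig_max / dt)))
    hi = min(y.size, int(apexes["index"].max() + round(4 * sig_max / dt)) + 1)
    tt, yy = t[lo:hi], y[lo:hi]
    span = tt[-1] - tt[0] if tt.size > 1 else dt

    base = float(np.min(yy))
    h_cap = 3.0 * max(yy.max() - base, 1e-12)
    shared = cfg.cluster_shared_width and k >= 2
    p0, lb, ub = [], [], []
    if shared:
        for _, row in apexes.iterrows():
            p0 += [max(row["height"] - base, 1e-12), row["rt"]]
            lb += [0.0, tt[0]]
            ub += [h_cap, tt[-1]]
        sig_idx = [len(p0)]
        p0 += [float(apexes["sigma_est"].median()), base]
        lb += [dt / 2.0, -np.inf]
        ub += [span, np.inf]
        model = _gauss_sum_shared
    else:
        sig_idx = []
        for _, row in apexes.iterrows():
            p0 += [max(row["height"] - base, 1e-12), row["rt"], row["sigma_est"]]
            lb += [0.0, tt[0], dt / 2.0]
            ub += [h_cap, tt[-1], span]
            sig_idx.append(len(p0) - 1)
        p0.append(base)
        lb.append(-np.inf)
        ub.append(np.inf)
        model = _gauss_sum

    popt = None
    for scale in (1.0, 0.5, 2.0):
        trial = list(p0)
        for j in sig_idx:
            trial[j] = min(max(p0[j] * scale, lb[j]), ub[j])
        try:
            popt, _ = curve_fit(model, tt, yy, p0=trial, bounds=(lb, ub), maxfev=8000)
            break
        except RuntimeError:
            continue

    if popt is None:
        warnings.warn("cluster fit did not converge; falling back to direct integration")
        area = float(np.trapezoid(np.maximum(yy, 0.0), tt))
        h = float(yy.max())
        sig = max(area / (h * np.sqrt(2 * np.pi)), dt / 2) if h > 0 else dt
        rec = pd.DataFrame(
            {
                "apex_rt_s": [float(tt[np.argmax(yy)])],
                "sigma_s": [sig],
                "height": [h],
                "area": [area],
                "cluster_id": [0],
                "n_in_cluster": [-1],
            }
        )
        return rec

    rows = []
    for j in range(k):
        if shared:
            h, mu = popt[2 * j : 2 * j + 2]
            sig = popt[-2]
        else:
            h, mu, sig = popt[3 * j : 3 * j + 3]
        rows.append(
            {
                "apex_rt_s": float(mu),
                "sigma_s": float(sig),
                "height": float(h),
                "area": float(h * sig * np.sqrt(2 * np.pi)),
            }
        )
    rec = pd.DataFrame(rows)
    total = rec["area"].sum()
    rec = rec[rec["area"] >= 1e-3 * total].reset_index(drop=True)
    rec["cluster_id"] = 0
    rec["n_in_cluster"] = len(rec)
    return rec.sort_values("apex_rt_s").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def process_chromatogram(
    chrom: Chromatogram, cfg: ChromConfig | None = None
) -> pd.DataFrame:
    """Run the full preprocessing chain and return the sample's peak table.

    Records are sorted by apex retention time; a ``sample_id`` column is
    attached from the input chromatogram.  Stage failures are re-raised
    with the stage name.
    """
    cfg = cfg or ChromConfig()
    stages = [
        ("remove_spikes", remove_spikes),
        ("correct_baseline", correct_baseline),
        ("correct_overload", correct_overload),
        ("smooth", smooth),
    ]
    c = chrom
    for name, fn in stages:
        try:
            c = fn(c, cfg)
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
    apexes = detect_peaks(c, cfg)
    if len(apexes) == 0:
        out = pd.DataFrame(columns=PEAK_COLUMNS)
        out.insert(0, "sample_id", pd.Series(dtype=str))
        return out
    clusters = cluster_coeluting(apexes, c, cfg)
    frames = []
    for cid, members in enumerate(clusters):
        rec = fit_cluster(c, apexes.iloc[members], cfg)
        rec["cluster_id"] = cid
        frames.append(rec)
    out = pd.concat(frames, ignore_index=True)
    out = out[PEAK_COLUMNS].sort_values("apex_rt_s").reset_index(drop=True)
    out.insert(0, "sample_id", chrom.sample_id)
    return out


# ---------------------------------------------------------------------------
# I/O: two-column delimited text
# ---------------------------------------------------------------------------

def write_chromatogram(chrom: Chromatogram, path) -> None:
    """Write a trace as two-column CSV with header ``time_s,intensity``."""
    pd.DataFrame({"time_s": chrom.time_s, "intensity": chrom.intensity}).to_csv(
        path, index=False
    )


def read_chromatogram(
    path,
    sample_id: str = "",
    acquisition_date: str | None = None,
    saturation_level: float | None = None,
) -> Chromatogram:
    """Read a two-column ``time_s,intensity`` CSV back into a Chromatogram."""
    df = pd.read_csv(path)
    return Chromatogram(
        time_s=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        sample_id=sample_id,
        acquisition_date=acquisition_date,
        saturation_level=saturation_level,
    )
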