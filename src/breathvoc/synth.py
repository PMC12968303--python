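"""Synthetic chromatograms and cohorts with known ground truth.

Two generators make the whole pipeline testable without instrument data:

* :func:`make_chromatogram` plants Gaussian peaks of known area on a
  drifting baseline with white noise, impulse spikes, and optional hard
  detector saturation.

* :func:`make_cohort` draws samples x features abundance matrices whose
  per-feature single-marker AUC and fold change are calibrated to
  prescribed values.  Features are lognormal on the raw scale: the
  log-abundance of feature j is Gaussian with a class location shift
  delta_j * log_sd_j, where :func:`calibrate_shift` converts a target AUC
  into the binormal shift delta = sqrt(2) * Phi^-1(AUC).  A multiplicative
  lognormal day effect (shared by every feature of a sample, anchors
  included) emulates day-to-day instrument drift; independent dropout
  exercises the 80% detection filters.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chrom import Chromatogram
from .matrix import AbundanceMatrix

__all__ = [
    "ChromSpec",
    "FeatureSpec",
    "CohortSpec",
    "DEFAULT_ANCHORS",
    "make_chromatogram",
    "calibrate_shift",
    "make_cohort",
    "make_multigroup_cohort",
    "make_cohort_chromatograms",
]

#: The six anchor compounds used for daily drift normalization.
DEFAULT_ANCHORS = (
    "isoprene",
    "n-nonane",
    "alpha-pinene",
    "n-decane",
    "limonene",
    "n-undecane",
)


@dataclass(frozen=True)
class ChromSpec:
    """Recipe for one synthetic raw trace.

    ``peaks`` is a list of (apex_rt_s, area, sigma_s) triples; ``baseline``
    is (offset, slope per second, low-frequency sine amplitude); spikes
    arrive at ``spike_rate`` per minute with fixed ``spike_amplitude``;
    ``saturation_level`` hard-clips the detector when set.
    """

    duration_s: float = 900.0
    sampling_hz: float = 5.0
    peaks: tuple = ()
    baseline: tuple = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    saturation_level: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be non-negative")
        for rt, area, sig in self.peaks:
            if sig <= 0:
                raise ValueError("peaks: all sigma_s must be positive")
            if area <= 0:
                raise ValueError("peaks: all areas must be positive")
            if not (0 <= rt <= self.duration_s):
                raise ValueError("peaks: apex_rt_s must lie within the run")


def make_chromatogram(spec: ChromSpec) -> tuple[Chromatogram, pd.DataFrame]:
    """Generate one trace plus the ground-truth peak table.

    The trace has exactly ``duration_s * sampling_hz`` samples; the truth
    table lists every planted peak with its exact area and height.
    Identical spec and seed give bit-identical output.
    """
    spec.validate()
    n = int(round(spec.duration_s * spec.sampling_hz))
    t = np.arange(n) / spec.sampling_hz
    y = np.zeros(n)
    rows = []
    for rt, area, sig in spec.peaks:
        h = area / (sig * np.sqrt(2 * np.pi))
        y += h * np.exp(-0.5 * ((t - rt) / sig) ** 2)
        rows.append({"apex_rt_s": rt, "sigma_s": sig, "height": h, "area": area})
    off, slope, amp = spec.baseline
    y += off + slope * t + amp * np.sin(2 * np.pi * t / spec.duration_s)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        y += rng.normal(0.0, spec.noise_sd, n)
    if spec.spike_rate > 0:
        n_spikes = rng.poisson(spec.spike_rate * spec.duration_s / 60.0)
        idx = rng.integers(0, n, n_spikes)
        y[idx] += spec.spike_amplitude
    if spec.saturation_level is not None:
        y = np.minimum(y, spec.saturation_level)

    truth = pd.DataFrame(rows, columns=["apex_rt_s", "sigma_s", "height", "area"])
    truth = truth.sort_values("apex_rt_s").reset_index(drop=True)
    chrom = Chromatogram(
        time_s=t, intensity=y, saturation_level=spec.saturation_level
    )
    return chrom, truth


def calibrate_shift(target_auc: float) -> float:
    """Binormal location shift (pooled-SD units) attaining a target AUC.

    For two equal-variance Gaussians separated by delta standard
    deviations, the concordance probability is Phi(delta / sqrt(2)); hence
    delta = sqrt(2) * Phi^-1(AUC).
    """
    if not (0.5 <= target_auc < 1.0):
        raise ValueError("target_auc must lie in [0.5, 1)")
    return float(np.sqrt(2.0) * norm.ppf(target_auc))


@dataclass(frozen=True)
class FeatureSpec:
    """One synthetic VOC feature.

    When both ``target_auc`` and ``target_fold_change`` are given, the
    log-scale class shift is fixed by the fold change (lognormal median
    ratio) and the log SD is then chosen so the binormal AUC also holds.
    Anchors carry no class effect.
    """

    feature_id: str
    target_auc: float | None = None
    target_fold_change: float | None = None
    base_log_mean: float = np.log(100.0)
    log_sd: float = 0.5
    is_anchor: bool = False

    def effect(self) -> tuple[float, float]:
        """Resolve (log shift, log sd) honoring AUC and/or fold change."""
        if self.is_anchor:
            return 0.0, self.log_sd
        if self.target_fold_change is not None and self.target_fold_change <= 0:
            raise ValueError(f"{self.feature_id}: fold change must be positive")
        if self.target_auc is not None and self.target_fold_change is not None:
            shift = float(np.log(self.target_fold_change))
            delta = calibrate_shift(self.target_auc)
            if delta == 0:
                raise ValueError(
                    f"{self.feature_id}: AUC 0.5 is incompatible with a fold change != 1"
                )
            return shift, abs(shift) / delta
        if self.target_auc is not None:
            return calibrate_shift(self.target_auc) * self.log_sd, self.log_sd
        if self.target_fold_change is not None:
            return float(np.log(self.target_fold_change)), self.log_sd
        return 0.0, self.log_sd


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group synthetic cohort.

    ``n_per_group`` sizes the (case, control) groups; the class shift of
    each feature is applied to the case group.  ``correlation`` is the
    pairwise equicorrelation of latent log-abundances; ``detection_prob``
    the per-cell observation probability; samples cycle through ``n_days``
    acquisition days whose multiplicative lognormal drift has log-SD
    ``day_drift_sd``.
    """

    n_per_group: tuple[int, int]
    features: tuple = ()
    correlation: float = 0.0
    detection_prob: float = 1.0
    n_days: int = 1
    day_drift_sd: float = 0.0
    anchor_names: tuple = DEFAULT_ANCHORS
    group_names: tuple[str, str] = ("case", "control")
    start_date: str = "2023-05-15"
    seed: int = 0

    def validate(self) -> None:
        if len(self.anchor_names) != 6:
            raise ValueError("exactly six anchor_names are required")
        if not (0 <= self.correlation < 1):
            raise ValueError("correlation must lie in [0, 1)")
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob must lie in (0, 1]")
        if min(self.n_per_group) < 2:
            raise ValueError("n_per_group must be at least 2 per group")
        if self.n_days < 1:
            raise ValueError("n_days must be positive")
        if self.day_drift_sd < 0:
            raise ValueError("day_drift_sd must be non-negative")


def _anchor_spec(name: str) -> FeatureSpec:
    # anchors: ubiquitous, class-neutral, modest biological variation
    return FeatureSpec(
        feature_id=name, base_log_mean=np.log(100.0), log_sd=0.2, is_anchor=True
    )


def _draw_cohort(
    group_sizes: list[int],
    group_names: list[str],
    bases: np.ndarray,
    sds: np.ndarray,
    shift_by_group: np.ndarray,  # (n_groups, p) log-scale shifts
    feature_ids: list[str],
    correlation: float,
    detection_prob: float,
    n_days: int,
    day_drift_sd: float,
    seed: int,
    start_date: str,
) -> tuple[AbundanceMatrix, pd.Series]:
    """Shared sampler: equicorrelated Gaussian logs + day drift + dropout."""
    n = int(sum(group_sizes))
    p = len(feature_ids)
    labels = pd.Series(
        np.repeat(group_names, group_sizes),
        index=[f"S{i + 1:05d}" for i in range(n)],
        name="group",
    )
    gidx = np.repeat(np.arange(len(group_names)), group_sizes)

    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n)[:, None]
    eps = rng.standard_normal((n, p))
    z = np.sqrt(correlation) * shared + np.sqrt(1.0 - correlation) * eps

    day_idx = np.arange(n) % n_days
    day_effect = rng.normal(0.0, day_drift_sd, n_days)

    logv = bases[None, :] + shift_by_group[gidx] + sds[None, :] * z
    logv += day_effect[day_idx][:, None]
    v = np.exp(logv)

    if detection_prob < 1.0:
        drop = rng.random((n, p)) >= detection_prob
        v = np.where(drop, np.nan, v)

    start = _dt.date.fromisoformat(start_date)
    dates = pd.Series(
        [(start + _dt.timedelta(days=int(d))).isoformat() for d in day_idx],
        index=labels.index,
        name="date",
    )
    values = pd.DataFrame(v, index=labels.index, columns=feature_ids)
    return AbundanceMatrix(values, labels, dates), labels


def make_cohort(spec: CohortSpec) -> tuple[AbundanceMatrix, pd.Series]:
    """Draw a two-group cohort abundance matrix plus its group labels.

    Log-abundances are equicorrelated Gaussians with the per-feature class
    shift from :meth:`FeatureSpec.effect` applied to the case group; a
    per-day lognormal drift factor multiplies every feature of a sample
    (anchors included); cells drop to missing independently with
    probability ``1 - detection_prob``.  Identical spec and seed give an
    identical matrix.
    """
    spec.validate()
    feats = list(spec.features)
    have = {f.feature_id for f in feats}
    feats += [_anchor_spec(a) for a in spec.anchor_names if a not in have]

    p = len(feats)
    shifts = np.empty(p)
    sds = np.empty(p)
    bases = np.empty(p)
    for j, f in enumerate(feats):
        shifts[j], sds[j] = f.effect()
        bases[j] = f.base_log_mean
    shift_by_group = np.vstack([shifts, np.zeros(p)])  # case row, control row

    return _draw_cohort(
        list(spec.n_per_group),
        list(spec.group_names),
        bases,
        sds,
        shift_by_group,
        [f.feature_id for f in feats],
        spec.correlation,
        spec.detection_prob,
        spec.n_days,
        spec.day_drift_sd,
        spec.seed,
        spec.start_date,
    )


def make_multigroup_cohort(
    groups: list[tuple[str, int]],
    features: list[FeatureSpec],
    effects: dict[str, dict[str, dict]] | None = None,
    correlation: float = 0.0,
    detection_prob: float = 1.0,
    n_days: int = 1,
    day_drift_sd: float = 0.0,
    anchor_names: tuple = DEFAULT_ANCHORS,
    seed: int = 0,
    start_date: str = "2023-05-15",
) -> tuple[AbundanceMatrix, pd.Series]:
    """Cohort with any number of groups and per-group effect maps.

    ``effects[feature_id][group]`` may give ``fold_change`` (log shift =
    ln FC) and/or ``auc`` (log shift = delta(AUC) * log_sd); groups without
    an entry are at the feature's baseline.  Used by the CLI to emulate a
    three-arm study; the two-group :func:`make_cohort` honors AUC and fold
    change simultaneously, this generalization keeps one log-SD per
    feature.
    """
    if len(anchor_names) != 6:
        raise ValueError("exactly six anchor_names are required")
    effects = effects or {}
    feats = list(features)
    have = {f.feature_id for f in feats}
    feats += [_anchor_spec(a) for a in anchor_names if a not in have]

    names = [g for g, _ in groups]
    sizes = [int(n) for _, n in groups]
    if min(sizes) < 2:
        raise ValueError("each group needs at least 2 samples")
    p = len(feats)
    bases = np.array([f.base_log_mean for f in feats])
    sds = np.array([f.log_sd for f in feats])
    shift_by_group = np.zeros((len(names), p))
    for j, f in enumerate(feats):
        per_group = effects.get(f.feature_id, {})
        for gi, g in enumerate(names):
            eff = per_group.get(g)
            if not eff:
                continue
            if f.is_anchor:
                raise ValueError(f"anchor {f.feature_id!r} cannot carry a class effect")
            if eff.get("fold_change") is not None:
                shift_by_group[gi, j] = float(np.log(eff["fold_change"]))
            elif eff.get("auc") is not None:
                shift_by_group[gi, j] = calibrate_shift(float(eff["auc"])) * f.log_sd
    return _draw_cohort(
        sizes,
        names,
        bases,
        sds,
        shift_by_group,
        [f.feature_id for f in feats],
        correlation,
        detection_prob,
        n_days,
        day_drift_sd,
        seed,
        start_date,
    )


def make_cohort_chromatograms(
    m: AbundanceMatrix,
    feature_rts: dict[str, float],
    sigma_s: float = 2.0,
    chrom_kwargs: dict | None = None,
    seed: int = 0,
):
    """Yield (sample_id, Chromatogram, truth) realizing a cohort as traces.

    Each sample's chromatogram plants one Gaussian peak per observed
    feature, at that feature's fixed retention time, with area equal to the
    cohort matrix entry.  Per-sample seeds are derived deterministically
    from ``seed``.
    """
    chrom_kwargs = dict(chrom_kwargs or {})
    for i, sid in enumerate(m.sample_ids):
        row = m.values.loc[sid]
        peaks = tuple(
            (feature_rts[f], float(row[f]), sigma_s)
            for f in m.feature_ids
            if f in feature_rts and np.isfinite(row[f])
        )
        spec = ChromSpec(
            peaks=peaks, seed=int((seed * 131071 + i) % 2**31), **chrom_kwargs
        )
        chrom, truth = make_chromatogram(spec)
        chrom.sample_id = sid
        chrom.acquisition_date = str(m.dates.loc[sid])
        yield sid, chrom, truth
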