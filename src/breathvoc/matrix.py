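"""Cross-sample VOC abundance matrix construction and normalization.

Per-sample peak tables are aligned on retention time into a samples x
features matrix of raw areas V, filtered by the 80% detection rules, and
normalized against six anchor compounds: for each acquisition date a
correction factor kappa is the mean anchor peak area on that date, and
every area becomes V' = 100 * V / kappa.  Any whole-sample multiplicative
instrument drift therefore cancels exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "NormalizationFactors",
    "FilterConfig",
    "align_peaks",
    "filter_features",
    "filter_samples",
    "compute_kappa",
    "normalize",
    "impute_missing",
    "find_anchor_features",
]


@dataclass
class FilterConfig:
    """Retention thresholds and alignment tolerance.

    ``feature_detect_frac``: a feature is kept when detected in at least
    this fraction of all samples, or of any single clinical group.
    ``sample_quant_frac``: a sample is kept when at least this fraction of
    the retained features was quantified in it.  Both bounds are inclusive.
    ``rt_tolerance_s``: single-linkage gap (seconds) separating features
    during cross-sample alignment.
    """

    feature_detect_frac: float = 0.80
    sample_quant_frac: float = 0.80
    rt_tolerance_s: float = 2.0

    def __post_init__(self) -> None:
        for name in ("feature_detect_frac", "sample_quant_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.rt_tolerance_s <= 0:
            raise ValueError("rt_tolerance_s must be positive")


@dataclass
class AbundanceMatrix:
    """Samples x features table of VOC abundances.

    ``values`` holds raw areas V (NaN = not detected); ``normalized`` holds
    V' = 100 * V / kappa once :func:`normalize` has run.  ``groups`` and
    ``dates`` are per-sample metadata aligned to the row index.
    """

    values: pd.DataFrame
    groups: pd.Series
    dates: pd.Series
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.groups.index.equals(self.values.index):
            raise ValueError("groups index must match sample index")
        if not self.dates.index.equals(self.values.index):
            raise ValueError("dates index must match sample index")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("raw areas must be non-negative where present")

    @property
    def data(self) -> pd.DataFrame:
        """The active table: normalized areas when available, else raw."""
        return self.normalized if self.normalized is not None else self.values

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, samples=None, features=None) -> "AbundanceMatrix":
        v = self.values
        nrm = self.normalized
        g, d = self.groups, self.dates
        if samples is not None:
            v, g, d = v.loc[samples], g.loc[samples], d.loc[samples]
            nrm = nrm.loc[samples] if nrm is not None else None
        if features is not None:
            v = v[features]
            nrm = nrm[features] if nrm is not None else None
        return AbundanceMatrix(v, g, d, nrm)

    def to_csv(self, path, which: str = "raw") -> None:
        """Round-trip format: sample_id, group, date, then one column per
        feature; empty cell = missing."""
        table = self.values if which == "raw" else self.normalized
        if table is None:
            raise ValueError(f"no {which} table to write")
        out = pd.concat(
            [self.groups.rename("group"), self.dates.rename("date"), table], axis=1
        )
        out.to_csv(path, index=True, index_label="sample_id")

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "AbundanceMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        groups = df.pop("group")
        dates = df.pop("date")
        if normalized:
            return cls(df.copy(), groups, dates, normalized=df.copy())
        return cls(df, groups, dates)


@dataclass
class NormalizationFactors:
    """Per-date kappa: mean anchor peak area on that acquisition date."""

    kappa: pd.Series  # indexed by date
    anchor_ids: list[str]

    def __post_init__(self) -> None:
        if (self.kappa <= 0).any():
            raise ValueError("kappa must be positive for every date")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_peaks(
    tables: list[pd.DataFrame],
    cfg: FilterConfig | None = None,
    groups: dict[str, str] | pd.Series | None = None,
    dates: dict[str, str] | pd.Series | None = None,
) -> AbundanceMatrix:
    """Pool per-sample peak tables into a samples x features matrix.

    Peaks from all samples are pooled, sorted by retention time, and split
    into features wherever the single-linkage gap exceeds
    ``rt_tolerance_s``.  Each feature is named ``VOC@<median rt, 3
    decimals>``; when one sample contributes two peaks to a feature the
    larger area wins (logged).
    """
    cfg = cfg or FilterConfig()
    if len(tables) < 2:
        raise ValueError("alignment needs at least 2 peak tables")
    pooled = pd.concat(tables, ignore_index=True)
    if pooled.empty:
        raise ValueError("no peaks to align")
    pooled = pooled.sort_values("apex_rt_s", kind="mergesort").reset_index(drop=True)
    rts = pooled["apex_rt_s"].to_numpy()
    new_feature = np.zeros(len(pooled), dtype=bool)
    new_feature[0] = True
    new_feature[1:] = np.diff(rts) > cfg.rt_tolerance_s
    pooled["_fidx"] = np.cumsum(new_feature) - 1

    sample_order: list[str] = []
    for tab in tables:
        if len(tab):
            sid = tab["sample_id"].iloc[0]
        else:
            continue
        if sid not in sample_order:
            sample_order.append(sid)

    consensus = pooled.groupby("_fidx")["apex_rt_s"].median()
    fid_by_idx = {i: f"VOC@{rt:.3f}" for i, rt in consensus.items()}
    pooled["feature_id"] = pooled["_fidx"].map(fid_by_idx)

    dup = pooled.duplicated(subset=["sample_id", "feature_id"], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} peaks collided within rt tolerance; keeping the "
            "largest area per sample/feature"
        )
    best = (
        pooled.sort_values("area", kind="mergesort")
        .drop_duplicates(subset=["sample_id", "feature_id"], keep="last")
    )
    mat = best.pivot(index="sample_id", columns="feature_id", values="area")
    mat = mat.reindex(index=sample_order, columns=sorted(mat.columns, key=_rt_of))
    mat.columns.name = None
    mat.index.name = None

    def _meta(source, default=""):
        if source is None:
            return pd.Series(default, index=mat.index)
        if isinstance(source, pd.Series):
            return source.reindex(mat.index)
        return pd.Series({s: source.get(s, default) for s in mat.index})

    return AbundanceMatrix(mat, _meta(groups), _meta(dates))


def _rt_of(feature_id: str) -> float:
    try:
        return float(feature_id.split("@")[1])
    except (IndexError, ValueError):
        return np.inf


# ---------------------------------------------------------------------------
# 80% retention rules
# ---------------------------------------------------------------------------

def filter_features(m: AbundanceMatrix, cfg: FilterConfig | None = None) -> AbundanceMatrix:
    """Keep a feature when detected in >= the threshold fraction of all
    samples, or of any single clinical group (inclusive boundary)."""
    cfg = cfg or FilterConfig()
    present = m.values.notna()
    overall = present.mean(axis=0)
    keep = overall >= cfg.feature_detect_frac
    for g in m.groups.unique():
        rows = m.groups == g
        keep |= present.loc[rows].mean(axis=0) >= cfg.feature_detect_frac
    kept = list(m.values.columns[keep])
    if not kept:
        warnings.warn("no features retained by the detection filter")
    return m.subset(features=kept)


def filter_samples(m: AbundanceMatrix, cfg: FilterConfig | None = None) -> AbundanceMatrix:
    """Keep a sample when >= the threshold fraction of retained features was
    quantified in it (inclusive boundary)."""
    cfg = cfg or FilterConfig()
    frac = m.values.notna().mean(axis=1)
    keep = frac >= cfg.sample_quant_frac
    if not keep.any():
        raise ValueError("all samples excluded by the quantification filter")
    return m.subset(samples=list(m.values.index[keep]))


# ---------------------------------------------------------------------------
# Anchor normalization
# ---------------------------------------------------------------------------

def compute_kappa(m: AbundanceMatrix, anchors: list[str]) -> NormalizationFactors:
    """Per-date kappa = arithmetic mean of all anchor areas observed that
    date, pooled over samples and the six anchors.  Missing anchor
    observations are simply absent from the mean (warned)."""
    missing = [a for a in anchors if a not in m.values.columns]
    if missing:
        raise ValueError(f"anchor features not in matrix: {missing}")
    anchor_vals = m.values[anchors]
    if anchor_vals.isna().any().any():
        warnings.warn("some anchor observations are missing; kappa uses the rest")
    kappas = {}
    for date, rows in m.values.groupby(m.dates):
        vals = rows[anchors].to_numpy().ravel()
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError(f"no anchor observations on date {date!r}")
        kappas[date] = float(vals.mean())
    return NormalizationFactors(pd.Series(kappas), list(anchors))


def normalize(m: AbundanceMatrix, f: NormalizationFactors) -> AbundanceMatrix:
    """Apply V' = 100 * V / kappa(sample date); missing stays missing."""
    missing_dates = set(m.dates.unique()) - set(f.kappa.index)
    if missing_dates:
        raise ValueError(f"kappa undefined for dates: {sorted(missing_dates)!r}")
    k = m.dates.map(f.kappa)
    if (k <= 0).any():
        raise ValueError("kappa must be positive")
    normalized = 100.0 * m.values.div(k, axis=0)
    return AbundanceMatrix(m.values, m.groups, m.dates, normalized=normalized)


# ---------------------------------------------------------------------------
# Missing-value handling
# ---------------------------------------------------------------------------

def impute_missing(m: AbundanceMatrix, strategy: str = "half_min") -> AbundanceMatrix:
    """Complete the active table: ``half_min`` fills each missing cell with
    half the feature's minimum observed value; ``none`` passes through."""
    if strategy not in ("half_min", "none"):
        raise ValueError("strategy must be 'half_min' or 'none'")
    if strategy == "none":
        return m
    table = m.data
    if table.isna().all().any():
        bad = list(table.columns[table.isna().all()])
        raise ValueError(f"features with zero observed values cannot be imputed: {bad}")
    filled = table.fillna(0.5 * table.min(axis=0))
    if m.normalized is not None:
        return AbundanceMatrix(m.values, m.groups, m.dates, normalized=filled)
    return AbundanceMatrix(filled, m.groups, m.dates)


def find_anchor_features(
    m: AbundanceMatrix, anchor_rts: list[float], tol_s: float = 2.0
) -> list[str]:
    """Map known anchor retention times to the nearest feature ids."""
    rts = np.array([_rt_of(f) for f in m.values.columns])
    out = []
    for art in anchor_rts:
        j = int(np.argmin(np.abs(rts - art)))
        if abs(rts[j] - art) > tol_s:
            raise ValueError(f"no feature within {tol_s}s of anchor rt {art}")
        out.append(m.values.columns[j])
    return out
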