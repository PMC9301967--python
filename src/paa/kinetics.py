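"""Kinetic screen analysis: rates, fold changes, SvE scores, clustering.

A fluorogenic substrate screen records fluorescence intensity over time for
every (substrate, protease) pair: cleavage separates fluorophore from
quencher, so intensity rises with proteolysis. This module turns those
progress curves into the standard derived quantities:

* **initial rate** (intensity/min) — ordinary least-squares slope of the
  early, approximately linear phase of the curve (default window: the
  first 30 minutes or the first 5 points, whichever covers more);
* **fold change** — intensity at an evaluation time divided by the
  baseline (first-point) intensity, a proxy for cumulative cleavage;
* **SvE records** — paired standard scores of one activity value: z
  across substrates within a protease column (efficiency) and z across
  proteases within a substrate row (specificity). High both = an
  efficiently *and* specifically cleaved protease-substrate pair;
* bidirectional hierarchical clustering, Spearman correlation between
  conditions, and per-substrate catalytic-class susceptibility counts.

Replicates are averaged pointwise before fitting by default; a
per-replicate-slope-then-mean alternative is available through
:class:`AnalysisConfig`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .errors import DegenerateInputError, InsufficientDataError, PaaError, ValidationError
from .screen_io import KineticRaw, MeasurementKind, ScreenMatrix, write_table

__all__ = [
    "RateWindow",
    "BackgroundPolicy",
    "AnalysisConfig",
    "KineticDataset",
    "SveRecord",
    "initial_rate",
    "fold_change",
    "build_kinetic_dataset",
    "sve_table",
    "cluster_bidirectional",
    "spearman_matrix",
    "class_summary",
    "plot_kinetics",
]

CATALYTIC_CLASSES = ("metallo", "serine", "cysteine", "aspartic", "other")


@dataclass(frozen=True)
class RateWindow:
    """Which early points enter the initial-rate fit.

    Points with ``t <= t0 + max_minutes`` are used; if fewer than
    ``min_points`` qualify, the first ``min_points`` points are used
    instead (all points when the series is shorter).
    """

    max_minutes: float = 30.0
    min_points: int = 5

    def select(self, time: np.ndarray) -> np.ndarray:
        time = np.asarray(time, dtype=float)
        mask = time <= time[0] + self.max_minutes
        if mask.sum() < self.min_points:
            mask = np.zeros_like(mask)
            mask[: self.min_points] = True
        return mask


class BackgroundPolicy(str, enum.Enum):
    none = "none"
    blank_well = "blank_well"
    first_point = "first_point"


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the kinetic pipeline.

    ``fold_time=None`` evaluates fold change at the last common time point.
    ``background`` subtracts either a blank-well intensity or each series'
    first point (floored at ``eps`` so fold changes stay defined).
    """

    rate_window: RateWindow = field(default_factory=RateWindow)
    fold_time: float | None = None
    background: BackgroundPolicy = BackgroundPolicy.none
    blank_value: float = 0.0
    eps: float = 1e-6
    replicate_policy: str = "average"  # or "per_replicate"
    interpolate_fold_time: bool = True


def _apply_background(series: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    if config.background is BackgroundPolicy.none:
        return s
    if config.background is BackgroundPolicy.blank_well:
        out = s - config.blank_value
    else:
        out = s - s[0]
    return np.maximum(out, config.eps)


def initial_rate(
    series: Sequence[float],
    time: Sequence[float],
    window: RateWindow | None = None,
) -> float:
    """OLS slope of intensity vs time (intensity/min) over the rate window.

    NaN points are dropped before fitting; fewer than two usable points in
    the window raises :class:`InsufficientDataError`.
    """
    window = window or RateWindow()
    t = np.asarray(time, dtype=float)
    y = np.asarray(series, dtype=float)
    if t.shape != y.shape:
        raise ValidationError("series and time vectors must have equal length")
    mask = window.select(t) & np.isfinite(y)
    if mask.sum() < 2:
        raise InsufficientDataError(
            f"initial rate needs >= 2 usable points in the window, got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(t[mask], y[mask], 1)
    return float(slope)


def fold_change(
    series: Sequence[float],
    time: Sequence[float],
    t_eval: float | None = None,
    config: AnalysisConfig | None = None,
) -> float:
    """Intensity at ``t_eval`` over baseline (first-point) intensity.

    Scale-invariant: multiplying the whole series by c > 0 leaves the fold
    change unchanged. ``t_eval`` defaults to the last time point; times not
    on the grid are linearly interpolated when the config allows.
    """
    config = config or AnalysisConfig()
    t = np.asarray(time, dtype=float)
    y = _apply_background(np.asarray(series, dtype=float), config)
    if t_eval is None:
        t_eval = float(t[-1])
    if t_eval in t:
        value = float(y[np.where(t == t_eval)[0][0]])
    elif config.interpolate_fold_time and t[0] <= t_eval <= t[-1]:
        value = float(np.interp(t_eval, t, y))
    else:
        raise ValidationError(
            f"t_eval={t_eval} not in the time vector and interpolation is disabled"
        )
    baseline = float(y[0])
    if baseline <= 0:
        raise DegenerateInputError(
            f"nonpositive baseline intensity ({baseline}) after background policy"
        )
    return value / baseline


@dataclass
class SveRecord:
    """Efficiency/specificity standard scores for one protease-substrate cell."""

    substrate: str
    protease: str
    efficiency_z: float
    specificity_z: float
    raw_value: float


@dataclass
class KineticDataset:
    """A kinetic screen with its derived rate and fold-change tables."""

    raw: KineticRaw
    rate_table: ScreenMatrix
    fold_table: ScreenMatrix
    class_annotations: dict[str, str] | None = None
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Persist the derived tables (and SvE records) as CSV files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "rate_table": outdir / "rate_table.csv",
            "fold_table": outdir / "fold_table.csv",
            "sve": outdir / "sve.csv",
        }
        write_table(self.rate_table, paths["rate_table"])
        write_table(self.fold_table, paths["fold_table"])
        sve = sve_table(self.fold_table)
        pd.DataFrame(
            {
                "substrate": [r.substrate for r in sve],
                "protease": [r.protease for r in sve],
                "efficiency_z": [r.efficiency_z for r in sve],
                "specificity_z": [r.specificity_z for r in sve],
                "raw_value": [r.raw_value for r in sve],
            }
        ).to_csv(paths["sve"], index=False)
        return paths


def _zscores_guarded(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    mask = np.isfinite(x)
    vals = x[mask]
    if vals.size == 0:
        return out
    sd = np.std(vals, ddof=1) if vals.size > 1 else 0.0
    out[mask] = 0.0 if sd == 0 else (vals - vals.mean()) / sd
    return out


def build_kinetic_dataset(
    raw: KineticRaw,
    config: AnalysisConfig | None = None,
    classes: Mapping[str, str] | None = None,
) -> KineticDataset:
    """Compute rate and fold-change tables for every (substrate, condition).

    Replicates are averaged pointwise before fitting (default) or fitted
    separately and their slopes averaged (``replicate_policy="per_replicate"``).
    Errors from per-series operations are re-raised annotated with the
    offending substrate and condition.
    """
    config = config or AnalysisConfig()
    subs = raw.substrate_labels
    conds = raw.condition_labels
    t = raw.time_points
    rate = pd.DataFrame(np.nan, index=subs, columns=conds)
    fold = pd.DataFrame(np.nan, index=subs, columns=conds)
    t_eval = config.fold_time if config.fold_time is not None else float(t[-1])
    for sub in subs:
        for cond in conds:
            reps = raw.replicates(sub, cond)
            if not reps:
                continue
            try:
                if config.replicate_policy == "per_replicate":
                    slopes = [initial_rate(r, t, config.rate_window) for r in reps]
                    rate.at[sub, cond] = float(np.mean(slopes))
                    folds = [fold_change(r, t, t_eval, config) for r in reps]
                    fold.at[sub, cond] = float(np.mean(folds))
                else:
                    mean_series = np.mean(np.vstack(reps), axis=0)
                    rate.at[sub, cond] = initial_rate(mean_series, t, config.rate_window)
                    fold.at[sub, cond] = fold_change(mean_series, t, t_eval, config)
            except PaaError as exc:
                raise type(exc)(f"substrate {sub!r}, condition {cond!r}: {exc}") from exc
    rate_sm = ScreenMatrix(
        screen_name=f"{raw.screen_name}_rates",
        values=rate,
        measurement_kind=MeasurementKind.initial_rate,
    )
    fold_sm = ScreenMatrix(
        screen_name=f"{raw.screen_name}_fold",
        values=fold,
        measurement_kind=MeasurementKind.fold_change,
    )
    return KineticDataset(
        raw=raw,
        rate_table=rate_sm,
        fold_table=fold_sm,
        class_annotations=dict(classes) if classes else None,
        config=config,
    )


def sve_table(table: ScreenMatrix) -> list[SveRecord]:
    """One SvE record per cell of a summary table.

    Efficiency z is computed within each protease column (across
    substrates), specificity z within each substrate row (across
    proteases). Constant columns/rows get z = 0 (zero-variance guard).
    """
    arr = table.values.to_numpy(dtype=float)
    if arr.size == 0:
        return []
    col_z = np.apply_along_axis(_zscores_guarded, 0, arr)
    row_z = np.apply_along_axis(_zscores_guarded, 1, arr)
    records: list[SveRecord] = []
    for i, sub in enumerate(table.substrate_labels):
        for j, prot in enumerate(table.condition_labels):
            if not np.isfinite(arr[i, j]):
                continue
            records.append(
                SveRecord(
                    substrate=sub,
                    protease=prot,
                    efficiency_z=float(col_z[i, j]),
                    specificity_z=float(row_z[i, j]),
                    raw_value=float(arr[i, j]),
                )
            )
    return records


def cluster_bidirectional(
    table: ScreenMatrix,
    linkage: str = "average",
    metric: str = "euclidean",
    standardize_rows: bool = False,
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Independent agglomerative clustering of rows and of columns.

    Returns ``(row_order, col_order, row_linkage, col_linkage)`` where the
    orders are dendrogram leaf orders for heatmap rendering. With
    ``standardize_rows=True`` rows are z-scored before either clustering
    (the usual convention for activity heatmaps).
    """
    arr = table.values.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise PaaError(f"clustering needs >= 2 rows and >= 2 columns, got {arr.shape}")
    if np.isnan(arr).any():
        raise ValidationError("clustering requires a complete table (no missing cells)")
    if standardize_rows:
        arr = np.apply_along_axis(_zscores_guarded, 1, arr)
    row_Z = sch.linkage(arr, method=linkage, metric=metric)
    col_Z = sch.linkage(arr.T, method=linkage, metric=metric)
    row_order = [table.substrate_labels[i] for i in sch.leaves_list(row_Z)]
    col_order = [table.condition_labels[i] for i in sch.leaves_list(col_Z)]
    return row_order, col_order, row_Z, col_Z


def spearman_matrix(table: ScreenMatrix) -> pd.DataFrame:
    """Pairwise Spearman rank correlation between conditions, over
    substrates.

    Symmetric with unit diagonal; ties receive average ranks. A constant
    column has undefined correlation and yields NaN with a warning.
    """
    import warnings

    df = table.values
    if df.shape[0] < 2:
        raise PaaError("Spearman correlation needs >= 2 substrates")
    conds = list(df.columns)
    n = len(conds)
    out = np.full((n, n), np.nan)
    arrs = [df[c].to_numpy(dtype=float) for c in conds]
    constant = [np.nanstd(a) == 0 for a in arrs]
    for c, flag in zip(conds, constant):
        if flag:
            warnings.warn(f"condition {c!r} is constant; its correlations are undefined")
    for i in range(n):
        for j in range(i, n):
            if i == j:
                out[i, i] = 1.0
                continue
            if constant[i] or constant[j]:
                continue
            rho = scipy.stats.spearmanr(arrs[i], arrs[j], nan_policy="omit").statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=conds, columns=conds)


def class_summary(
    fold_table: ScreenMatrix,
    classes: Mapping[str, str],
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-substrate counts of cleaving proteases by catalytic class.

    A protease "cleaves" a substrate when its fold change is >= the
    threshold (default 1.5). Proteases without an annotation fall into
    class "other".
    """
    norm = {k.strip().casefold(): v for k, v in classes.items()}
    cols = sorted(CATALYTIC_CLASSES)
    counts = pd.DataFrame(0, index=fold_table.substrate_labels, columns=cols)
    for prot in fold_table.condition_labels:
        cls = norm.get(prot.strip().casefold(), "other")
        if cls not in counts.columns:
            raise ValidationError(
                f"unknown catalytic class {cls!r} for protease {prot!r}; "
                f"expected one of {CATALYTIC_CLASSES}"
            )
        hits = fold_table.values[prot] >= threshold
        counts.loc[hits[hits].index, cls] += 1
    return counts


# ---------------------------------------------------------------------------
# plotting (presentation only; all numbers come from the ops above)
# ---------------------------------------------------------------------------

PLOT_KINDS = ("raw_lines", "fold_lines", "heatmap", "sve", "pie", "correlation")


def plot_kinetics(
    ds: KineticDataset,
    kind: str,
    outdir: str | Path,
    *,
    entity: str | None = None,
    threshold: float = 1.5,
) -> list[Path]:
    """Write figure files for a kinetic dataset.

    ``kind`` is one of raw_lines, fold_lines, heatmap, sve, pie,
    correlation. For ``sve`` and ``pie``, ``entity`` restricts the plot to
    one protease/substrate (default: first condition / all substrates).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind {kind!r}; expected one of {PLOT_KINDS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = ds.raw.time_points
    written: list[Path] = []

    if kind in ("raw_lines", "fold_lines"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for cond in ds.raw.condition_labels:
            for sub in ds.raw.substrate_labels:
                reps = ds.raw.replicates(sub, cond)
                if not reps:
                    continue
                y = np.mean(np.vstack(reps), axis=0)
                if kind == "fold_lines":
                    y0 = _apply_background(y, ds.config)
                    y = y0 / max(y0[0], ds.config.eps)
                ax.plot(t, y, label=f"{sub}/{cond}", lw=1)
        ax.set_xlabel("time (min)")
        ax.set_ylabel("intensity" if kind == "raw_lines" else "fold change")
        if len(ds.raw.series) <= 12:
            ax.legend(fontsize=6)
        path = outdir / f"{kind}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    elif kind == "heatmap":
        row_order, col_order, _, _ = cluster_bidirectional(ds.fold_table, standardize_rows=True)
        arr = ds.fold_table.values.loc[row_order, col_order]
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(arr.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=6)
        ax.set_yticks(range(len(row_order)), row_order, fontsize=6)
        fig.colorbar(im, ax=ax, label="fold change")
        path = outdir / "heatmap.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    elif kind == "sve":
        records = sve_table(ds.fold_table)
        target = entity or ds.fold_table.condition_labels[0]
        pts = [r for r in records if r.protease == target] or [
            r for r in records if r.substrate == target
        ]
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(
            [r.efficiency_z for r in pts],
            [r.specificity_z for r in pts],
            c=[r.raw_value for r in pts],
            cmap="viridis",
        )
        ax.axhline(0, color="grey", lw=0.5)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_xlabel("efficiency (z across substrates)")
        ax.set_ylabel("specificity (z across proteases)")
        ax.set_title(f"SvE: {target}")
        path = outdir / f"sve_{target}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    elif kind == "pie":
        classes = ds.class_annotations or {}
        counts = class_summary(ds.fold_table, classes, threshold=threshold)
        target = entity or counts.index[0]
        row = counts.loc[target]
        row = row[row > 0]
        fig, ax = plt.subplots(figsize=(4, 4))
        if row.empty:
            ax.text(0.5, 0.5, "no cleaving proteases", ha="center")
        else:
            ax.pie(row.to_numpy(), labels=list(row.index), autopct="%d%%")
        ax.set_title(f"cleavage susceptibility: {target}")
        path = outdir / f"pie_{target}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    elif kind == "correlation":
        corr = spearman_matrix(ds.rate_table)
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
        ax.set_xticks(range(len(corr)), list(corr.columns), rotation=90, fontsize=6)
        ax.set_yticks(range(len(corr)), list(corr.index), fontsize=6)
        fig.colorbar(im, ax=ax, label="Spearman rho")
        path = outdir / "correlation.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
    return written
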