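"""Readers, writers and validated containers for screen data files.

Three kinds of input flow through the toolkit:

* **screen summary matrices** — substrates (rows) x conditions (columns),
  one activity summary value per cell (raw intensity, fold change, or
  initial rate);
* **sequence maps** — substrate label -> one-letter peptide sequence;
* **kinetic raw files** — per-well fluorescence time courses in wide form,
  one row per (substrate, condition, replicate), one column per time point.

All files are plain CSV (configurable delimiter, UTF-8). Row/column labels
are trimmed of surrounding whitespace and matched case-insensitively, but
their original case is preserved for display. Missing cells become NaN and
are excluded from downstream statistics rather than zero-filled.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "MeasurementKind",
    "ScreenMatrix",
    "SequenceMap",
    "ColorMap",
    "KineticRaw",
    "read_screen_matrix",
    "read_sequence_map",
    "read_color_map",
    "read_kinetic_raw",
    "write_table",
    "write_sequence_map",
    "write_kinetic_raw",
    "normalize_label",
]


class MeasurementKind(str, enum.Enum):
    """What the cells of a :class:`ScreenMatrix` mean."""

    raw_intensity = "raw_intensity"
    fold_change = "fold_change"
    initial_rate = "initial_rate"


def normalize_label(label: str) -> str:
    """Canonical form used for label identity: trimmed and case-folded.

    Idempotent: ``normalize_label(normalize_label(x)) == normalize_label(x)``.
    """
    return str(label).strip().casefold()


def _check_unique(labels: Iterable[str], axis: str) -> None:
    seen: dict[str, str] = {}
    for lab in labels:
        key = normalize_label(lab)
        if key in seen:
            raise ValidationError(
                f"duplicate {axis} label {lab!r} (collides with {seen[key]!r} "
                "after whitespace-trim and case-fold)"
            )
        seen[key] = lab


@dataclass
class ScreenMatrix:
    """One screen's substrate x condition activity summary.

    ``values`` is a pandas DataFrame whose index holds substrate labels and
    whose columns hold condition labels (protease or sample names). Labels
    must be unique within each axis after trimming and case-folding; values
    must be nonnegative for raw intensities and fold changes (NaN allowed,
    meaning "not measured").
    """

    screen_name: str
    values: pd.DataFrame
    measurement_kind: MeasurementKind = MeasurementKind.raw_intensity

    def __post_init__(self) -> None:
        self.measurement_kind = MeasurementKind(self.measurement_kind)
        vals = self.values.copy()
        vals.index = [str(i).strip() for i in vals.index]
        vals.columns = [str(c).strip() for c in vals.columns]
        _check_unique(vals.index, "substrate")
        _check_unique(vals.columns, "condition")
        try:
            vals = vals.astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric cell in screen {self.screen_name!r}: {exc}") from exc
        if self.measurement_kind in (MeasurementKind.raw_intensity, MeasurementKind.fold_change):
            arr = vals.to_numpy()
            if np.nanmin(arr, initial=0.0) < 0:
                r, c = np.argwhere(np.nan_to_num(arr) < 0)[0]
                raise ValidationError(
                    f"negative value at ({vals.index[r]!r}, {vals.columns[c]!r}) "
                    f"in {self.measurement_kind.value} screen {self.screen_name!r}"
                )
        self.values = vals

    @property
    def substrate_labels(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SequenceMap:
    """Mapping from substrate label to one-letter peptide sequence.

    Sequences must be nonempty. Tokens outside the 20 standard amino-acid
    letters are allowed (modified residues, spacers) but collected in
    ``nonstandard`` so callers can warn.
    """

    entries: dict[str, str]
    nonstandard: set[str] = field(default_factory=set)

    _STANDARD = set("ACDEFGHIKLMNPQRSTVWY")

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for label, seq in self.entries.items():
            label = str(label).strip()
            seq = str(seq).strip().upper()
            if not seq:
                raise ValidationError(f"empty sequence for substrate {label!r}")
            key = normalize_label(label)
            if key in {normalize_label(k) for k in clean}:
                prev = next(v for k, v in clean.items() if normalize_label(k) == key)
                if prev != seq:
                    raise ValidationError(
                        f"conflicting sequences for label {label!r}: {prev!r} vs {seq!r}"
                    )
                continue
            clean[label] = seq
            for ch in set(seq) - self._STANDARD:
                self.nonstandard.add(ch)
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: str) -> bool:
        return normalize_label(label) in {normalize_label(k) for k in self.entries}

    def get(self, label: str) -> str | None:
        key = normalize_label(label)
        for k, v in self.entries.items():
            if normalize_label(k) == key:
                return v
        return None

    def items(self):
        return self.entries.items()


class GroupingKind(str, enum.Enum):
    hydrophobicity = "hydrophobicity"
    chemistry = "chemistry"
    identity = "identity"
    custom = "custom"


@dataclass
class ColorMap:
    """Amino-acid letter -> color token, for sequence-aware plots."""

    entries: dict[str, str]
    grouping_kind: GroupingKind = GroupingKind.custom

    def __post_init__(self) -> None:
        self.grouping_kind = GroupingKind(self.grouping_kind)
        for key in self.entries:
            if len(str(key)) != 1:
                raise ValidationError(f"color-map key {key!r} is not a single character")


@dataclass
class KineticRaw:
    """Raw fluorescence time courses for one kinetic screen.

    ``series`` maps (substrate_label, condition_label, replicate_index) to a
    vector of intensities aligned to ``time_points`` (minutes, strictly
    increasing). Replicate indices must be contiguous from 1 for each
    (substrate, condition) pair.
    """

    screen_name: str
    time_points: np.ndarray
    series: dict[tuple[str, str, int], np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points, dtype=float)
        if t.ndim != 1 or len(t) < 1:
            raise ValidationError("time_points must be a nonempty 1-D vector")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time vector must be strictly increasing (minutes)")
        self.time_points = t
        fixed: dict[tuple[str, str, int], np.ndarray] = {}
        reps: dict[tuple[str, str], list[int]] = {}
        for (sub, cond, rep), vals in self.series.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != t.shape:
                raise ValidationError(
                    f"series ({sub!r}, {cond!r}, rep {rep}) has {vals.size} points, "
                    f"expected {t.size}"
                )
            fixed[(str(sub).strip(), str(cond).strip(), int(rep))] = vals
            reps.setdefault((str(sub).strip(), str(cond).strip()), []).append(int(rep))
        for key, idxs in reps.items():
            if sorted(idxs) != list(range(1, len(idxs) + 1)):
                raise ValidationError(
                    f"replicate indices for {key} are {sorted(idxs)}; must be contiguous from 1"
                )
        self.series = fixed

    @property
    def substrate_labels(self) -> list[str]:
        seen: list[str] = []
        for sub, _, _ in self.series:
            if sub not in seen:
                seen.append(sub)
        return seen

    @property
    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for _, cond, _ in self.series:
            if cond not in seen:
                seen.append(cond)
        return seen

    def replicates(self, substrate: str, condition: str) -> list[np.ndarray]:
        out = [
            (rep, vals)
            for (sub, cond, rep), vals in self.series.items()
            if normalize_label(sub) == normalize_label(substrate)
            and normalize_label(cond) == normalize_label(condition)
        ]
        return [vals for _, vals in sorted(out)]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_screen_matrix(
    path: str | Path,
    *,
    screen_name: str | None = None,
    measurement_kind: MeasurementKind | str = MeasurementKind.raw_intensity,
    delimiter: str = ",",
    duplicate_policy: str = "strict",
) -> ScreenMatrix:
    """Read a substrate x condition summary CSV.

    The first row holds condition labels, the first column substrate labels.
    ``duplicate_policy`` is ``"strict"`` (duplicate labels raise) or
    ``"mean"`` (rows/columns with identical normalized labels are averaged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a labelled matrix") from exc
    if df.index.name is None and df.shape[1] == 0 and df.shape[0] > 0:
        raise FormatError(f"{path}: no condition columns found; is the header row missing?")
    df.index = [str(i).strip() for i in df.index]
    df.columns = [str(c).strip() for c in df.columns]
    for col in df.columns:
        bad = df[col].apply(
            lambda v: not (pd.isna(v) or isinstance(v, (int, float, np.number)) or _is_number(v))
        )
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    df = df.apply(pd.to_numeric, errors="coerce")

    if duplicate_policy == "mean":
        df = df.groupby(normalize_label, sort=False).mean() if _has_dups(df.index) else df
        if _has_dups(df.columns):
            df = df.T.groupby(normalize_label, sort=False).mean().T
    elif duplicate_policy != "strict":
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")

    return ScreenMatrix(
        screen_name=screen_name or path.stem,
        values=df,
        measurement_kind=measurement_kind,
    )


def _has_dups(labels: Iterable[str]) -> bool:
    keys = [normalize_label(x) for x in labels]
    return len(keys) != len(set(keys))


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_sequence_map(path: str | Path, *, delimiter: str = ",") -> SequenceMap:
    """Read a two-column (label, sequence) CSV; a header row is optional."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns (label, sequence)")
            rows.append((parts[0], parts[1]))
    if rows and rows[0][0].casefold() in {"label", "substrate", "name"}:
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: no sequence entries found")
    entries: dict[str, str] = {}
    for label, seq in rows:
        if label in entries and entries[label] != seq.upper():
            raise ValidationError(
                f"{path}: conflicting sequences for label {label!r}"
            )
        if not seq:
            raise ValidationError(f"{path}: empty sequence for label {label!r}")
        entries[label] = seq
    return SequenceMap(entries)


def read_color_map(
    path: str | Path,
    *,
    grouping_kind: GroupingKind | str = GroupingKind.custom,
    delimiter: str = ",",
) -> ColorMap:
    """Read an amino-acid -> color CSV (two columns, header optional)."""
    path = Path(path)
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(delimiter)]
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected (amino_acid, color)")
            if parts[0].casefold() in {"amino_acid", "aa", "residue"}:
                continue
            entries[parts[0]] = parts[1]
    return ColorMap(entries, grouping_kind=grouping_kind)


_DEFAULT_LAYOUT = {"substrate": "substrate", "condition": "condition", "replicate": "replicate"}


def read_kinetic_raw(
    path: str | Path,
    layout: Mapping[str, str] | str | Path | None = None,
    *,
    screen_name: str | None = None,
    delimiter: str = ",",
) -> KineticRaw:
    """Read a wide-form kinetic CSV.

    Rows are wells: the layout spec names the columns identifying
    (substrate, condition, replicate); every remaining column header is a
    time point in minutes. ``layout`` may be a mapping or a path to a JSON
    sidecar file with keys ``substrate``, ``condition``, ``replicate``.
    Time columns are sorted into increasing order regardless of file order.
    """
    path = Path(path)
    if isinstance(layout, (str, Path)):
        with open(layout, encoding="utf-8") as fh:
            layout = json.load(fh)
    spec = dict(_DEFAULT_LAYOUT)
    if layout:
        spec.update({k: v for k, v in layout.items() if k in spec})

    with open(path, encoding="utf-8") as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(delimiter)]
    if len(header) != len(set(header)):  # pandas would silently mangle these
        raise ValidationError(f"{path}: duplicate column headers (repeated time point?)")
    df = pd.read_csv(path, sep=delimiter)
    for role, col in spec.items():
        if col not in df.columns:
            raise FormatError(f"{path}: layout column {col!r} (role {role}) not found")
    time_cols = [c for c in df.columns if c not in spec.values()]
    if not time_cols:
        raise FormatError(f"{path}: no time-point columns found")
    try:
        times = np.array([float(c) for c in time_cols])
    except ValueError as exc:
        raise ParseError(f"{path}: time column headers must be numeric minutes: {exc}") from exc
    if len(set(times)) != len(times):
        raise ValidationError(f"{path}: duplicate time points in header")
    order = np.argsort(times)
    times = times[order]
    time_cols = [time_cols[i] for i in order]

    series: dict[tuple[str, str, int], np.ndarray] = {}
    for _, row in df.iterrows():
        key = (
            str(row[spec["substrate"]]).strip(),
            str(row[spec["condition"]]).strip(),
            int(row[spec["replicate"]]),
        )
        if key in series:
            raise ValidationError(f"{path}: duplicate well row for {key}")
        series[key] = row[time_cols].to_numpy(dtype=float)
    return KineticRaw(
        screen_name=screen_name or path.stem, time_points=times, series=series
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(table: ScreenMatrix | pd.DataFrame, path: str | Path, *, delimiter: str = ",") -> None:
    """Write any labelled matrix as CSV; round-trips through read_screen_matrix."""
    df = table.values if isinstance(table, ScreenMatrix) else table
    if not isinstance(df, pd.DataFrame):
        raise TypeError("write_table expects a ScreenMatrix or DataFrame")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index_label="")


def write_sequence_map(seqmap: SequenceMap, path: str | Path, *, delimiter: str = ",") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"label{delimiter}sequence\n")
        for label, seq in seqmap.items():
            fh.write(f"{label}{delimiter}{seq}\n")


def write_kinetic_raw(raw: KineticRaw, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a KineticRaw in the wide CSV form read_kinetic_raw expects."""
    cols = ["substrate", "condition", "replicate"] + [_fmt_time(t) for t in raw.time_points]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(delimiter.join(cols) + "\n")
        for (sub, cond, rep), vals in raw.series.items():
            row = [sub, cond, str(rep)] + [repr(float(v)) for v in vals]
            fh.write(delimiter.join(row) + "\n")


def _fmt_time(t: float) -> str:
    return str(int(t)) if float(t).is_integer() else repr(float(t))
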