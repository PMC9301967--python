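"""Aggregated enzyme-substrate databases: build, index, query, search.

A :class:`SubstrateDatabase` collects one or more screen summary matrices
together with a substrate-name -> peptide-sequence map. Overlapping
substrates or proteases across screens are identified by normalized label
and all their data aggregated, so a single query ("which substrates does
MMP13 cleave well and specifically?") can draw on every screen at once.

Query ranking combines two standard scores computed within each screen:

* **efficiency z** — the z-score of a cell within its protease column
  (across substrates): how strongly this substrate is cleaved relative to
  the rest of the panel;
* **specificity z** — the z-score of the same cell within its substrate
  row (across proteases): how exclusively this protease, rather than
  others, cleaves the substrate.

The combined score for a (substrate, protease) pair is the mean of the two
z's within a screen, averaged over all screens where both are defined.
Constant rows/columns get z = 0 rather than NaN so rankings stay total.

Sequence search offers the Levenshtein similarity ratio
``1 - d(a, b) / max(|a|, |b|)`` and the partial ratio (best ratio of the
shorter sequence against every equal-length window of the longer one),
exact k-mer motif search, and hierarchical clustering of the pairwise
similarity matrix.
"""

from __future__ import annotations

import datetime
import enum
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .errors import NotFoundError, PaaError, ValidationError
from .screen_io import (
    ColorMap,
    MeasurementKind,
    ScreenMatrix,
    SequenceMap,
    normalize_label,
)

__all__ = [
    "SubstrateDatabase",
    "RankedQueryResult",
    "QueryRow",
    "SimilarityHit",
    "build_database",
    "query_protease",
    "query_substrate",
    "levenshtein_distance",
    "similarity_ratio",
    "partial_ratio",
    "query_sequence",
    "search_kmer",
    "similarity_matrix",
    "species_to_species",
    "load_ortholog_table",
    "summarize_database",
]


# ---------------------------------------------------------------------------
# sequence similarity primitives
# ---------------------------------------------------------------------------

def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions or
    substitutions transforming ``a`` into ``b``.

    Classic two-row dynamic program, O(|a|*|b|) time, O(min) space.
    """
    a, b = str(a), str(b)
    if len(a) < len(b):
        a, b = b, a
    if not b:
        return len(a)
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def similarity_ratio(a: str, b: str) -> float:
    """Levenshtein similarity ratio ``1 - d(a,b)/max(|a|,|b|)`` in [0, 1].

    1.0 iff the sequences are identical. Two empty sequences are defined
    as identical (ratio 1.0).
    """
    a, b = str(a), str(b)
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / m


def partial_ratio(a: str, b: str) -> float:
    """Best similarity of the shorter sequence against all equal-length
    contiguous windows of the longer sequence.

    Returns 1.0 whenever the shorter sequence occurs as a substring of the
    longer, which makes the metric robust to flanking spacers (e.g. GG/GS
    termini around a shared cleavage motif).
    """
    a, b = str(a), str(b)
    if not a and not b:
        return 1.0
    short, long = (a, b) if len(a) <= len(b) else (b, a)
    if not short:
        return 0.0
    w = len(short)
    return max(similarity_ratio(short, long[i : i + w]) for i in range(len(long) - w + 1))


# ---------------------------------------------------------------------------
# database container
# ---------------------------------------------------------------------------

@dataclass
class SubstrateDatabase:
    """Aggregation of screens plus sequence map, indexed for queries.

    ``substrate_index`` maps normalized substrate -> screen -> protease ->
    value; ``protease_index`` is the transpose view. Each indexed value is
    exactly one cell of exactly one input screen (no cross-screen
    averaging).
    """

    screens: list[ScreenMatrix]
    sequences: SequenceMap
    color_map: ColorMap | None = None
    protease_classes: dict[str, str] | None = None
    provenance: dict = field(default_factory=dict)

    substrate_index: dict = field(default_factory=dict, repr=False)
    protease_index: dict = field(default_factory=dict, repr=False)
    _display: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.screens:
            raise ValueError("a database needs at least one screen")
        self.substrate_index = {}
        self.protease_index = {}
        self._display = {}
        for sm in self.screens:
            for sub in sm.substrate_labels:
                skey = normalize_label(sub)
                self._display.setdefault(skey, sub)
                for prot in sm.condition_labels:
                    pkey = normalize_label(prot)
                    self._display.setdefault(pkey, prot)
                    val = float(sm.values.at[sub, prot])
                    self.substrate_index.setdefault(skey, {}).setdefault(sm.screen_name, {})[pkey] = val
                    self.protease_index.setdefault(pkey, {}).setdefault(sm.screen_name, {})[skey] = val

    def display_name(self, key: str) -> str:
        return self._display.get(normalize_label(key), key)

    @property
    def substrates(self) -> list[str]:
        return sorted(self.display_name(k) for k in self.substrate_index)

    @property
    def proteases(self) -> list[str]:
        return sorted(self.display_name(k) for k in self.protease_index)

    def sequence_of(self, substrate: str) -> str | None:
        return self.sequences.get(substrate)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        """Serialize the database (screens, sequences, provenance) to JSON."""
        doc = {
            "provenance": self.provenance,
            "sequences": dict(self.sequences.entries),
            "protease_classes": self.protease_classes,
            "screens": [
                {
                    "screen_name": sm.screen_name,
                    "measurement_kind": sm.measurement_kind.value,
                    "substrates": sm.substrate_labels,
                    "proteases": sm.condition_labels,
                    "values": [
                        [None if np.isnan(v) else float(v) for v in row]
                        for row in sm.values.to_numpy()
                    ],
                }
                for sm in self.screens
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SubstrateDatabase":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        screens = [
            ScreenMatrix(
                screen_name=s["screen_name"],
                values=pd.DataFrame(
                    np.array(s["values"], dtype=float),
                    index=s["substrates"],
                    columns=s["proteases"],
                ),
                measurement_kind=s["measurement_kind"],
            )
            for s in doc["screens"]
        ]
        return cls(
            screens=screens,
            sequences=SequenceMap(doc["sequences"]),
            protease_classes=doc.get("protease_classes"),
            provenance=doc.get("provenance", {}),
        )


def build_database(
    screens: Sequence[ScreenMatrix],
    sequences: SequenceMap,
    colors: ColorMap | None = None,
    *,
    protease_classes: Mapping[str, str] | None = None,
    missing_sequence: str = "warn",
) -> SubstrateDatabase:
    """Aggregate screens + sequence map into a queryable database.

    A substrate appearing in several screens must map to a single sequence
    (conflicts raise). Substrates without a sequence are allowed under the
    default ``missing_sequence="warn"`` policy, or rejected with
    ``"error"``.
    """
    screens = list(screens)
    if not screens:
        raise ValueError("at least one screen is required")
    names = [s.screen_name for s in screens]
    if len(set(names)) != len(names):
        raise ValidationError(f"screen names must be unique, got {names}")
    missing = sorted(
        {
            sub
            for sm in screens
            for sub in sm.substrate_labels
            if sequences.get(sub) is None
        }
    )
    if missing:
        msg = f"{len(missing)} substrate(s) without a sequence: {missing[:5]}"
        if missing_sequence == "error":
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)
    prov = {
        "screen_files": names,
        "built_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return SubstrateDatabase(
        screens=screens,
        sequences=sequences,
        color_map=colors,
        protease_classes=dict(protease_classes) if protease_classes else None,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# ranked queries
# ---------------------------------------------------------------------------

def _zscores(values: np.ndarray) -> np.ndarray:
    """Standard scores with the zero-variance guard: constant (or length-1)
    vectors map to all zeros, NaNs propagate."""
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    mask = np.isfinite(x)
    vals = x[mask]
    if vals.size == 0:
        return out
    if vals.size == 1 or np.std(vals, ddof=1) == 0:
        out[mask] = 0.0
        return out
    out[mask] = (vals - vals.mean()) / np.std(vals, ddof=1)
    return out


@dataclass
class QueryRow:
    label: str
    efficiency_z: dict[str, float]  # per screen
    specificity_z: dict[str, float]  # per screen
    combined_score: float
    rank: int


@dataclass
class RankedQueryResult:
    query: str
    direction: str  # "protease->substrates" or "substrate->proteases"
    rows: list[QueryRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [r.label for r in self.rows],
                "combined_score": [r.combined_score for r in self.rows],
                "rank": [r.rank for r in self.rows],
            }
        ).set_index("label")


def _suggestions(name: str, candidates: Iterable[str]) -> list[str]:
    return sorted(
        c for c in candidates if similarity_ratio(normalize_label(name), normalize_label(c)) >= 0.8
    )


def _ranked_query(db: SubstrateDatabase, name: str, top_k: int, axis: str) -> RankedQueryResult:
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    key = normalize_label(name)
    index = db.protease_index if axis == "protease" else db.substrate_index
    if key not in index:
        kind = "protease" if axis == "protease" else "substrate"
        cands = db.proteases if axis == "protease" else db.substrates
        near = _suggestions(name, cands)
        hint = f"; did you mean {near}?" if near else ""
        raise NotFoundError(f"{kind} {name!r} not found in database{hint}")

    # per-screen z-score tables for every screen containing the query
    per_entity: dict[str, QueryRow] = {}
    acc: dict[str, list[float]] = {}
    eff_map: dict[str, dict[str, float]] = {}
    spec_map: dict[str, dict[str, float]] = {}
    for sm in db.screens:
        cols = [normalize_label(c) for c in sm.condition_labels]
        rows = [normalize_label(r) for r in sm.substrate_labels]
        arr = sm.values.to_numpy(dtype=float)
        col_z = np.apply_along_axis(_zscores, 0, arr)  # across substrates
        row_z = np.apply_along_axis(_zscores, 1, arr)  # across proteases
        if axis == "protease":
            if key not in cols:
                continue
            j = cols.index(key)
            for i, rkey in enumerate(rows):
                eff = col_z[i, j]
                spec = row_z[i, j]
                label = db.display_name(rkey)
                if np.isfinite(eff):
                    eff_map.setdefault(label, {})[sm.screen_name] = float(eff)
                if np.isfinite(spec):
                    spec_map.setdefault(label, {})[sm.screen_name] = float(spec)
                if np.isfinite(eff) and np.isfinite(spec):
                    acc.setdefault(label, []).append((float(eff) + float(spec)) / 2.0)
        else:
            if key not in rows:
                continue
            i = rows.index(key)
            for j, ckey in enumerate(cols):
                eff = col_z[i, j]
                spec = row_z[i, j]
                label = db.display_name(ckey)
                if np.isfinite(eff):
                    eff_map.setdefault(label, {})[sm.screen_name] = float(eff)
                if np.isfinite(spec):
                    spec_map.setdefault(label, {})[sm.screen_name] = float(spec)
                if np.isfinite(eff) and np.isfinite(spec):
                    acc.setdefault(label, []).append((float(eff) + float(spec)) / 2.0)

    ordered = sorted(
        acc.items(), key=lambda kv: (-float(np.mean(kv[1])), kv[0])
    )
    rows_out = [
        QueryRow(
            label=label,
            efficiency_z=eff_map.get(label, {}),
            specificity_z=spec_map.get(label, {}),
            combined_score=float(np.mean(scores)),
            rank=r,
        )
        for r, (label, scores) in enumerate(ordered[:top_k], start=1)
    ]
    direction = "protease->substrates" if axis == "protease" else "substrate->proteases"
    return RankedQueryResult(query=db.display_name(key), direction=direction, rows=rows_out)


def query_protease(db: SubstrateDatabase, protease: str, top_k: int = 10) -> RankedQueryResult:
    """Rank substrates by how efficiently *and* specifically the protease
    cleaves them (mean of efficiency z and specificity z, per screen,
    averaged over screens)."""
    return _ranked_query(db, protease, top_k, axis="protease")


def query_substrate(db: SubstrateDatabase, substrate: str, top_k: int = 10) -> RankedQueryResult:
    """Rank proteases by how robustly and specifically they cleave the
    substrate (mirror of :func:`query_protease`)."""
    return _ranked_query(db, substrate, top_k, axis="substrate")


# ---------------------------------------------------------------------------
# sequence queries
# ---------------------------------------------------------------------------

@dataclass
class SimilarityHit:
    substrate_label: str
    sequence: str
    edit_distance: int
    ratio: float
    partial_ratio: float


class SimilarityMetric(str, enum.Enum):
    ratio = "ratio"
    partial_ratio = "partial_ratio"


def query_sequence(
    db: SubstrateDatabase,
    query: str,
    k: int = 5,
    metric: SimilarityMetric | str = SimilarityMetric.ratio,
) -> list[SimilarityHit]:
    """Top-k substrates most similar to the query sequence.

    Hits are sorted by the chosen metric (descending), ties broken by the
    other metric (descending) then by label; both metric values are
    reported on every hit.
    """
    metric = SimilarityMetric(metric)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    items = list(db.sequences.items())
    if not items:
        raise PaaError("database has no sequences to search")
    query = str(query).strip().upper()
    hits = [
        SimilarityHit(
            substrate_label=label,
            sequence=seq,
            edit_distance=levenshtein_distance(query, seq),
            ratio=similarity_ratio(query, seq),
            partial_ratio=partial_ratio(query, seq),
        )
        for label, seq in items
    ]
    primary, secondary = (
        ("ratio", "partial_ratio") if metric is SimilarityMetric.ratio else ("partial_ratio", "ratio")
    )
    hits.sort(
        key=lambda h: (-getattr(h, primary), -getattr(h, secondary), h.substrate_label)
    )
    return hits[:k]


def search_kmer(db: SubstrateDatabase, kmer: str) -> list[tuple[str, str, list[int]]]:
    """All substrates whose sequence contains ``kmer`` as a contiguous,
    case-insensitive substring; 0-based start positions, overlaps included.
    """
    kmer = str(kmer).strip().upper()
    if not kmer:
        raise ValueError("kmer must be nonempty")
    out: list[tuple[str, str, list[int]]] = []
    for label, seq in db.sequences.items():
        positions = [
            i for i in range(len(seq) - len(kmer) + 1) if seq[i : i + len(kmer)] == kmer
        ]
        if positions:
            out.append((label, seq, positions))
    out.sort(key=lambda t: t[0])
    return out


def similarity_matrix(
    db: SubstrateDatabase,
    metric: SimilarityMetric | str = SimilarityMetric.ratio,
    linkage: str = "average",
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Pairwise similarity matrix over all substrate sequences plus a
    hierarchical clustering of it.

    Returns ``(matrix, leaf_order, linkage_matrix)``: the symmetric
    similarity matrix (diagonal 1), the dendrogram leaf order for heatmap
    rendering, and the scipy linkage matrix computed on distance
    ``1 - similarity``.
    """
    metric = SimilarityMetric(metric)
    labels = sorted(db.sequences.entries)
    if len(labels) < 2:
        raise PaaError("similarity matrix needs at least 2 substrates with sequences")
    fn = similarity_ratio if metric is SimilarityMetric.ratio else partial_ratio
    n = len(labels)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = fn(db.sequences.entries[labels[i]], db.sequences.entries[labels[j]])
            mat[i, j] = mat[j, i] = s
    dist = 1.0 - mat
    condensed = dist[np.triu_indices(n, k=1)]
    Z = sch.linkage(condensed, method=linkage)
    order = [labels[i] for i in sch.leaves_list(Z)]
    frame = pd.DataFrame(mat, index=labels, columns=labels)
    return frame, order, Z


# ---------------------------------------------------------------------------
# cross-species mapping
# ---------------------------------------------------------------------------

_SPECIES = ("human", "chimpanzee", "mouse", "rat")


def load_ortholog_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load an ortholog table (columns human, chimpanzee, mouse, rat; empty
    cell = no ortholog).

    With no path, loads the small synthetic ortholog fixture packaged with
    paa, which covers the proteases used in the examples and tutorials; a
    full degradome-scale table can be supplied by the user.
    """
    if path is None:
        ref = resources.files("paa").joinpath("data/orthologs_synthetic.csv")
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, dtype=str, keep_default_na=False)
    else:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SPECIES if c not in table.columns]
    if missing:
        raise ValidationError(f"ortholog table missing columns: {missing}")
    return table


def species_to_species(
    gene: str,
    from_species: str,
    to_species: str,
    table: pd.DataFrame | None = None,
) -> str | None:
    """Map a protease gene symbol between species.

    Returns the ortholog symbol, or ``None`` when the gene is present in the
    table but has no ortholog in the target species (an explicit
    no-ortholog signal, distinct from the gene being absent, which raises
    :class:`NotFoundError`).
    """
    if from_species not in _SPECIES or to_species not in _SPECIES:
        raise ValueError(f"species must be one of {_SPECIES}")
    if table is None:
        table = load_ortholog_table()
    col = table[from_species].map(normalize_label)
    hits = table[col == normalize_label(gene)]
    if hits.empty:
        near = _suggestions(gene, [g for g in table[from_species] if g])
        hint = f"; did you mean {near}?" if near else ""
        raise NotFoundError(f"gene {gene!r} not found for species {from_species!r}{hint}")
    target = str(hits.iloc[0][to_species]).strip()
    return target or None


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_database(db: SubstrateDatabase) -> dict:
    """Per-screen and union substrate/protease counts, plus catalytic-class
    composition when protease classes are annotated."""
    per_screen = {
        sm.screen_name: {
            "n_substrates": len(sm.substrate_labels),
            "n_proteases": len(sm.condition_labels),
        }
        for sm in db.screens
    }
    summary = {
        "per_screen": per_screen,
        "n_unique_substrates": len(db.substrate_index),
        "n_unique_proteases": len(db.protease_index),
    }
    if db.protease_classes:
        comp: dict[str, int] = {}
        classes = {normalize_label(k): v for k, v in db.protease_classes.items()}
        for pkey in db.protease_index:
            cls = classes.get(pkey, "other")
            comp[cls] = comp.get(cls, 0) + 1
        summary["class_composition"] = comp
    return summary
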