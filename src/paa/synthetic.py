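"""Seeded generators for all three input kinds, with known ground truth.

These emulate the structure (not the biophysical detail) of real data:

* **kinetic screens** — per (substrate, protease) saturating-exponential
  progress curves ``F(t) = F0 + A*(1 - exp(-k*t))`` plus Gaussian noise
  truncated at zero. The true initial rate is the derivative at t = 0,
  ``A*k``, so rate-estimation accuracy can be measured exactly.
* **reporter matrices** — lognormal concentrations: per class, each
  reporter's log-mean is shifted by a planted effect multiplier, so
  differential enrichment, classification and feature elimination can be
  validated against the planted structure.
* **substrate libraries** — random peptide sequences in which a stated
  number of sequences carry each motif at a random position (and no
  other sequence does), giving exact ground truth for k-mer search.

All generators are pure functions of (spec, seed): one global seed fans
out to per-component substreams via ``numpy.random.SeedSequence`` spawn
keys, so adding one generator call never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .screen_io import KineticRaw, SequenceMap

__all__ = [
    "KineticTruth",
    "KineticTruthSpec",
    "ReporterTruth",
    "ReporterTruthSpec",
    "gen_kinetic_screen",
    "gen_reporter_dataset",
    "gen_substrate_library",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# substream tags so each generator draws from its own child stream
_KINETIC_KEY = 1
_REPORTER_KEY = 2
_LIBRARY_KEY = 3


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(key,))))


# ---------------------------------------------------------------------------
# kinetic screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticTruthSpec:
    """Ranges the per-cell curve parameters are drawn from.

    Defaults emulate a typical fluorogenic plate read: baselines around
    100 intensity units, amplitudes of a few hundred units, rate constants
    of 0.005-0.05 per minute (half-times of ~15-140 min), and additive
    read noise expressed as a fraction of each cell's amplitude.
    """

    amplitude_range: tuple[float, float] = (200.0, 1000.0)
    rate_range: tuple[float, float] = (0.005, 0.05)
    baseline: float = 100.0
    noise_sd_frac: float = 0.0  # noise sd as a fraction of the cell's amplitude
    n_replicates: int = 1


@dataclass
class KineticTruth:
    """Ground truth for one generated kinetic screen."""

    amplitude: pd.DataFrame  # substrate x protease
    rate_const: pd.DataFrame  # min^-1
    baseline: float
    noise_sd_frac: float
    seed: int

    @property
    def initial_rate(self) -> pd.DataFrame:
        """True initial rate A*k (the derivative of the curve at t = 0)."""
        return self.amplitude * self.rate_const


def gen_kinetic_screen(
    n_substrates: int,
    n_proteases: int,
    spec: KineticTruthSpec | None = None,
    time_points: Sequence[float] | None = None,
    seed: int = 0,
    screen_name: str = "synthetic_screen",
) -> tuple[KineticRaw, KineticTruth]:
    """Generate a fluorogenic kinetic screen with known per-cell truth.

    ``F(t) = F0 + A*(1 - exp(-k*t)) + N(0, sd)``, truncated at 0; ``sd``
    is ``spec.noise_sd_frac * A`` per cell. Default time grid: every 2
    minutes from 0 to 60.
    """
    if n_substrates < 1 or n_proteases < 1:
        raise ValueError("screen dimensions must be >= 1")
    spec = spec or KineticTruthSpec()
    if spec.noise_sd_frac < 0 or spec.baseline < 0 or spec.n_replicates < 1:
        raise ValueError("invalid truth spec")
    t = np.asarray(
        time_points if time_points is not None else np.arange(0.0, 61.0, 2.0), dtype=float
    )
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    rng = _rng(seed, _KINETIC_KEY)
    subs = [f"S{i+1}" for i in range(n_substrates)]
    prots = [f"P{j+1}" for j in range(n_proteases)]
    A = rng.uniform(*spec.amplitude_range, size=(n_substrates, n_proteases))
    k = rng.uniform(*spec.rate_range, size=(n_substrates, n_proteases))
    series: dict[tuple[str, str, int], np.ndarray] = {}
    for i, sub in enumerate(subs):
        for j, prot in enumerate(prots):
            clean = spec.baseline + A[i, j] * (1.0 - np.exp(-k[i, j] * t))
            for rep in range(1, spec.n_replicates + 1):
                noise = (
                    rng.normal(0.0, spec.noise_sd_frac * A[i, j], size=t.shape)
                    if spec.noise_sd_frac > 0
                    else 0.0
                )
                series[(sub, prot, rep)] = np.maximum(clean + noise, 0.0)
    raw = KineticRaw(screen_name=screen_name, time_points=t, series=series)
    truth = KineticTruth(
        amplitude=pd.DataFrame(A, index=subs, columns=prots),
        rate_const=pd.DataFrame(k, index=subs, columns=prots),
        baseline=spec.baseline,
        noise_sd_frac=spec.noise_sd_frac,
        seed=seed,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# reporter matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReporterTruthSpec:
    """Lognormal reporter model.

    Each reporter's baseline concentration is lognormal around
    ``base_mean``; ``effects`` maps a class name to {reporter id or
    0-based index -> multiplier} applied to that class's mean.
    ``noise_sd`` is the log-scale standard deviation (0.2 ~ a 20%
    coefficient of variation, typical for quantified urinary reporters).
    """

    base_mean: float = 1.0
    noise_sd: float = 0.2
    effects: Mapping[str, Mapping[object, float]] = field(default_factory=dict)


@dataclass
class ReporterTruth:
    """Ground truth for one generated reporter matrix."""

    class_means: pd.DataFrame  # class x reporter, linear scale
    noise_sd: float
    seed: int

    def effect_reporters(self, reference: str) -> dict[str, list[str]]:
        """Reporters whose mean differs from the reference class's."""
        ref = self.class_means.loc[reference]
        out = {}
        for cls in self.class_means.index:
            if cls == reference:
                continue
            diff = self.class_means.loc[cls] != ref
            out[cls] = list(self.class_means.columns[diff])
        return out


def gen_reporter_dataset(
    n_per_class: Mapping[str, int],
    n_reporters: int = 14,
    spec: ReporterTruthSpec | None = None,
    seed: int = 0,
):
    """Generate a sample x reporter concentration matrix with class labels.

    ``values = exp(Normal(log(class mean), noise_sd))``; the class mean of
    reporter r is ``base_mean * effects[class][r]`` (multiplier 1 where no
    effect is planted). Returns ``(ReporterDataset, ReporterTruth)``.
    """
    from .invivo import ReporterDataset  # local import to avoid a cycle

    if n_reporters < 1 or not n_per_class:
        raise ValueError("need >= 1 reporter and >= 1 class")
    if any(n < 1 for n in n_per_class.values()):
        raise ValueError("each class needs >= 1 sample")
    spec = spec or ReporterTruthSpec()
    if spec.noise_sd < 0 or spec.base_mean <= 0:
        raise ValueError("invalid truth spec")
    reporters = [f"R{i+1}" for i in range(n_reporters)]
    classes = list(n_per_class)
    means = pd.DataFrame(spec.base_mean, index=classes, columns=reporters, dtype=float)
    for cls, eff in spec.effects.items():
        if cls not in n_per_class:
            raise ValueError(f"effect for unknown class {cls!r}")
        for rep, mult in eff.items():
            if mult <= 0:
                raise ValueError("effect multipliers must be > 0")
            rid = reporters[rep] if isinstance(rep, int) else str(rep)
            if rid not in reporters:
                raise ValueError(f"effect on unknown reporter {rep!r}")
            means.at[cls, rid] *= mult
    rng = _rng(seed, _REPORTER_KEY)
    rows, labels, ids = [], [], []
    counter = 1
    for cls in classes:
        log_mu = np.log(means.loc[cls].to_numpy())
        for _ in range(n_per_class[cls]):
            rows.append(np.exp(rng.normal(log_mu, spec.noise_sd)))
            labels.append(cls)
            ids.append(f"sample_{counter}")
            counter += 1
    values = pd.DataFrame(np.vstack(rows), index=ids, columns=reporters)
    ds = ReporterDataset(values=values, class_labels=pd.Series(labels, index=ids))
    truth = ReporterTruth(class_means=means, noise_sd=spec.noise_sd, seed=seed)
    return ds, truth


# ---------------------------------------------------------------------------
# substrate libraries
# ---------------------------------------------------------------------------

def gen_substrate_library(
    n: int,
    length: int = 8,
    alphabet: str = AMINO_ACIDS,
    motifs: Sequence[tuple[str, int]] = (),
    seed: int = 0,
) -> SequenceMap:
    """Random peptide library with exact motif placement ground truth.

    For each (motif, count), exactly ``count`` sequences contain the motif
    (inserted at a random position) and the remaining sequences contain no
    listed motif at all (enforced by rejection sampling), so k-mer search
    results are known by construction. Labels are S1..Sn.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    motifs = [(str(m).upper(), int(c)) for m, c in motifs]
    for m, c in motifs:
        if len(m) > length:
            raise ValueError(f"motif {m!r} longer than sequence length {length}")
        if not 0 <= c <= n:
            raise ValueError(f"motif count {c} out of range for library of {n}")
    if sum(c for _, c in motifs) > n:
        raise ValueError("motif counts exceed library size")
    rng = _rng(seed, _LIBRARY_KEY)
    letters = np.array(list(alphabet))
    taboo = [m for m, _ in motifs]

    def random_seq(avoid: Sequence[str]) -> str:
        for _ in range(10_000):
            s = "".join(rng.choice(letters, size=length))
            if not any(m in s for m in avoid):
                return s
        raise ValueError("could not sample a motif-free sequence; spec infeasible")

    assignments: list[str | None] = [None] * n
    cursor = 0
    for m, c in motifs:
        for _ in range(c):
            assignments[cursor] = m
            cursor += 1
    entries: dict[str, str] = {}
    for i, motif in enumerate(assignments):
        if motif is None:
            entries[f"S{i+1}"] = random_seq(taboo)
        else:
            others = [m for m in taboo if m != motif]
            for _ in range(10_000):
                pos = int(rng.integers(0, length - len(motif) + 1))
                backbone = random_seq([])
                s = backbone[:pos] + motif + backbone[pos + len(motif) :]
                # the planted motif must occur, other motifs must not, and
                # the plant must not create a second disjoint occurrence
                if all(m not in s for m in others):
                    entries[f"S{i+1}"] = s
                    break
            else:
                raise ValueError(f"could not place motif {motif!r}; spec infeasible")
    return SequenceMap(entries)
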