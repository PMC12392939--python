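"""Pan-genome composition analysis.

Gene families are classified by occupancy (in how many genomes the family has
at least one member): present in all N genomes -> core; in [softcore_min, N-1]
-> softcore; in [2, softcore_min-1] -> dispensable; in exactly one genome ->
private. Classes are mutually exclusive, so the four proportions sum to 100%.

Rarefaction resamples genome subsets of increasing size k and traces the pan
(union) and core (intersection) family counts; the pan curve is fitted with a
Tettelin-style power law P(k) = A_p * k^B_p + C_p and the core curve with an
exponential decay C(k) = A_c * exp(-B_c * k) + C_c. The plateau point is the
smallest subset size from which every further genome adds less than a relative
threshold (default 0.5%) to the pan-genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_formats import OrthogroupTable

CLASSES = ("core", "softcore", "dispensable", "private")


@dataclass
class PresenceAbsenceMatrix:
    """Gene families x genomes occupancy with per-cell gene counts."""

    family_ids: list[str]
    genome_ids: list[str]
    gene_counts: np.ndarray  # F x N int

    def __post_init__(self) -> None:
        self.gene_counts = np.asarray(self.gene_counts, dtype=np.int64)
        if self.gene_counts.shape != (len(self.family_ids),
                                      len(self.genome_ids)):
            raise ValueError("gene_counts shape does not match ids")
        if len(self.genome_ids) < 2:
            raise ValueError("need at least 2 genomes")
        if (self.occupancy.sum(axis=1) == 0).any():
            i = int(np.argmax(self.occupancy.sum(axis=1) == 0))
            raise ValueError(
                f"family {self.family_ids[i]!r} absent from every genome")

    @property
    def occupancy(self) -> np.ndarray:
        return self.gene_counts > 0

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gene_counts, index=self.family_ids,
                            columns=self.genome_ids)


@dataclass
class FamilyClassification:
    """Per-family occupancy class plus class counts and proportions."""

    classes: pd.Series               # family id -> class name
    counts: dict[str, int]
    proportions: dict[str, float]    # % of families, 2 decimals
    gene_proportions: dict[str, float]  # % of genes, 2 decimals

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "families": pd.Series(self.counts),
            "family_pct": pd.Series(self.proportions),
            "gene_pct": pd.Series(self.gene_proportions),
        }).loc[list(CLASSES)]


def classify_families(
    matrix: PresenceAbsenceMatrix, softcore_min: int | None = None
) -> FamilyClassification:
    """Classify families as core / softcore / dispensable / private.

    ``softcore_min`` is the minimum occupancy of the softcore class
    (default N-1, i.e. softcore = present in all but one genome).
    """
    n = matrix.n_genomes
    if n < 3:
        raise ValueError("classification needs at least 3 genomes")
    if softcore_min is None:
        softcore_min = n - 1
    if not (2 <= softcore_min < n):
        raise ValueError(f"softcore_min must be in [2, {n - 1}]")
    occ = matrix.occupancy.sum(axis=1)
    labels = np.full(matrix.n_families, "dispensable", dtype=object)
    labels[occ == n] = "core"
    labels[(occ >= softcore_min) & (occ <= n - 1)] = "softcore"
    labels[occ == 1] = "private"
    classes = pd.Series(labels, index=matrix.family_ids, name="class")
    counts = {c: int((labels == c).sum()) for c in CLASSES}
    total = matrix.n_families
    proportions = {c: round(100.0 * counts[c] / total, 2) for c in CLASSES}
    genes_per_family = matrix.gene_counts.sum(axis=1)
    total_genes = int(genes_per_family.sum())
    gene_props = {
        c: round(100.0 * genes_per_family[labels == c].sum() / total_genes, 2)
        for c in CLASSES}
    return FamilyClassification(classes, counts, proportions, gene_props)


def count_singletons(
    orthogroups: OrthogroupTable,
    gene_universe: Mapping[str, Sequence[str]],
) -> int:
    """Count genes absent from every family (unclustered singletons).

    ``gene_universe`` maps genome id -> all gene ids of that genome; gene ids
    must be disjoint across genomes. A clustered gene missing from its
    genome's universe is an error.
    """
    universe: set[str] = set()
    for genome, genes in gene_universe.items():
        universe.update(genes)
    clustered: set[str] = set()
    for row in orthogroups.members:
        for genes in row:
            clustered.update(genes)
    stray = clustered - universe
    if stray:
        raise ValueError(
            f"gene {sorted(stray)[0]!r} clustered but absent from universe")
    return len(universe - clustered)


@dataclass
class RarefactionResult:
    """Replicate pan/core sizes for each subset size k = 1..N."""

    sizes: list[int]
    pan: list[np.ndarray]      # per k: replicate pan sizes
    core: list[np.ndarray]     # per k: replicate core sizes
    exhaustive: list[bool]     # per k: all C(N,k) subsets enumerated
    reps: int

    @property
    def pan_medians(self) -> np.ndarray:
        return np.array([float(np.median(x)) for x in self.pan])

    @property
    def core_medians(self) -> np.ndarray:
        return np.array([float(np.median(x)) for x in self.core])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, p, c, ex in zip(self.sizes, self.pan, self.core,
                               self.exhaustive):
            for i, (pv, cv) in enumerate(zip(p, c)):
                rows.append((k, i, int(pv), int(cv), ex))
        return pd.DataFrame(
            rows, columns=["k", "replicate", "pan", "core", "exhaustive"])


def rarefy(matrix: PresenceAbsenceMatrix, reps: int = 1000,
           seed: int = 0) -> RarefactionResult:
    """Rarefaction simulation over genome subsets.

    For each subset size k, draws ``reps`` uniform k-subsets (independently;
    the same subset may recur) and records the pan (families present in at
    least one subset genome) and core (present in all) counts. When
    C(N, k) <= reps all subsets are enumerated exactly once instead and the
    size is flagged exhaustive.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    occ = matrix.occupancy.astype(np.float32)
    n = matrix.n_genomes
    sizes, pans, cores, flags = [], [], [], []
    for k in range(1, n + 1):
        n_subsets = math.comb(n, k)
        if n_subsets <= reps:
            subsets = np.array(list(combinations(range(n), k)))
            exhaustive = True
        else:
            subsets = np.array(
                [rng.choice(n, size=k, replace=False) for _ in range(reps)])
            exhaustive = False
        pan = np.empty(len(subsets), dtype=np.int64)
        core = np.empty(len(subsets), dtype=np.int64)
        # chunked F x N @ N x R product keeps memory bounded at full panel scale
        for lo in range(0, len(subsets), 256):
            chunk = subsets[lo:lo + 256]
            ind = np.zeros((n, len(chunk)), dtype=np.float32)
            for j, sub in enumerate(chunk):
                ind[sub, j] = 1.0
            counts = occ @ ind                       # F x chunk
            pan[lo:lo + len(chunk)] = (counts > 0).sum(axis=0)
            core[lo:lo + len(chunk)] = (counts >= k - 0.5).sum(axis=0)
        sizes.append(k)
        pans.append(pan)
        cores.append(core)
        flags.append(exhaustive)
    return RarefactionResult(sizes, pans, cores, flags, reps)


# ---------------------------------------------------------------------------
# Growth-model fitting
# ---------------------------------------------------------------------------

def _power_law(k: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.power(k, b) + c


def _exp_decay(k: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-b * k) + c


@dataclass
class GrowthModelFit:
    pan_params: tuple[float, float, float]   # A_p, B_p, C_p
    core_params: tuple[float, float, float]  # A_c, B_c, C_c
    pan_rss: float
    core_rss: float
    plateau: int | None = None
    converged: bool = True

    def pan_curve(self, k: np.ndarray) -> np.ndarray:
        return _power_law(np.asarray(k, float), *self.pan_params)

    def core_curve(self, k: np.ndarray) -> np.ndarray:
        return _exp_decay(np.asarray(k, float), *self.core_params)


def _fit_curve(model, k, y, starts) -> tuple[tuple[float, ...], float, bool]:
    best, best_rss, ok = None, np.inf, False
    for p0 in starts:
        try:
            res = least_squares(
                lambda p: model(k, *p) - y, p0, method="lm", max_nfev=5000)
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if rss < best_rss:
            best, best_rss, ok = tuple(res.x), rss, res.success
    if best is None:
        return tuple(starts[0]), float(np.sum((model(k, *starts[0]) - y) ** 2)), False
    return best, best_rss, ok


def _jittered_starts(p0: np.ndarray, n: int = 10) -> list[np.ndarray]:
    # deterministic restarts: fixed multiplicative jitter ladder
    rng = np.random.default_rng(12345)
    starts = [p0]
    for _ in range(n - 1):
        starts.append(p0 * rng.uniform(0.5, 1.5, size=p0.shape)
                      + rng.normal(0, 0.1, size=p0.shape))
    return starts


def fit_growth_models(result: RarefactionResult) -> GrowthModelFit:
    """Least-squares fit of the pan power law and core exponential decay.

    Initialization: A from the median range, B from the log-log slope (pan)
    or 0.5 (core), C from the last median; 10 deterministic jittered
    restarts; best RSS wins. Non-convergence is flagged, keeping the best
    attempt's parameters.
    """
    k = np.asarray(result.sizes, dtype=float)
    if len(k) < 4:
        raise ValueError("need at least 4 subset sizes to fit growth models")
    pan = result.pan_medians
    core = result.core_medians

    span = pan[-1] - pan[0]
    a0 = span if span > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dk = np.log(k[1:]) - np.log(k[:-1])
        dy = np.log(np.maximum(pan[1:] - pan[0] + 1, 1e-9)) - np.log(
            np.maximum(pan[:-1] - pan[0] + 1, 1e-9))
        slopes = dy[dk > 0] / dk[dk > 0]
    b0 = float(np.clip(np.median(slopes), 0.05, 2.0)) if len(slopes) else 0.5
    pan_p0 = np.array([a0, b0, pan[-1] - a0 * k[-1] ** b0])
    pan_params, pan_rss, pan_ok = _fit_curve(
        _power_law, k, pan, _jittered_starts(pan_p0))

    c_span = core[0] - core[-1]
    core_p0 = np.array([c_span if c_span > 0 else 1.0, 0.5, core[-1]])
    core_params, core_rss, core_ok = _fit_curve(
        _exp_decay, k, core, _jittered_starts(core_p0))

    plateau = None
    try:
        plateau = detect_plateau(result)
    except ValueError:
        pass
    return GrowthModelFit(
        pan_params=tuple(map(float, pan_params)),
        core_params=tuple(map(float, core_params)),
        pan_rss=pan_rss, core_rss=core_rss,
        plateau=plateau, converged=pan_ok and core_ok)


def detect_plateau(result: RarefactionResult,
                   rel_threshold: float = 0.005) -> int | None:
    """Smallest k >= 2 from which every step grows the pan by < the threshold.

    The condition must hold for all subsequent steps, not just once, so noisy
    medians cannot produce a spurious early plateau. Returns None when growth
    never settles below the threshold.
    """
    medians = result.pan_medians
    if (medians <= 0).any():
        raise ValueError("zero or negative pan median")
    if len(medians) < 2:
        return None
    increments = (medians[1:] - medians[:-1]) / medians[:-1]
    below = increments < rel_threshold
    # find smallest k (index of the first step that starts the all-below tail)
    for i in range(len(below)):
        if below[i:].all():
            return i + 2  # step i is k=i+1 -> k=i+2
    return None
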