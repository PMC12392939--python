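"""Independent oracles used by the unit and acceptance-property tests.

Each oracle recomputes a quantity by the most direct method available
(enumeration, brute force, closed form) without touching the code path it
checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Seq import Seq
from scipy.stats import studentized_range


def classify_by_row_sums(occupancy: np.ndarray, softcore_min: int | None = None
                         ) -> list[str]:
    """Brute-force occupancy classification, row by row."""
    n = occupancy.shape[1]
    if softcore_min is None:
        softcore_min = n - 1
    out = []
    for row in occupancy:
        occ = int(row.sum())
        if occ == n:
            out.append("core")
        elif softcore_min <= occ <= n - 1:
            out.append("softcore")
        elif occ == 1:
            out.append("private")
        else:
            out.append("dispensable")
    return out


def exhaustive_rarefaction_medians(occupancy: np.ndarray
                                   ) -> tuple[np.ndarray, np.ndarray]:
    """Median pan/core over ALL k-subsets, by direct enumeration."""
    n = occupancy.shape[1]
    pan_med, core_med = [], []
    for k in range(1, n + 1):
        pans, cores = [], []
        for sub in combinations(range(n), k):
            cols = occupancy[:, list(sub)]
            pans.append(int(cols.any(axis=1).sum()))
            cores.append(int(cols.all(axis=1).sum()))
        pan_med.append(float(np.median(pans)))
        core_med.append(float(np.median(cores)))
    return np.array(pan_med), np.array(core_med)


def plateau_by_scan(medians: np.ndarray, threshold: float = 0.005
                    ) -> int | None:
    """Brute-force plateau scan: try every k and verify all later steps."""
    for k in range(2, len(medians) + 1):
        ok = True
        for j in range(k, len(medians) + 1):
            inc = (medians[j - 1] - medians[j - 2]) / medians[j - 2]
            if inc >= threshold:
                ok = False
                break
        if ok:
            return k
    return None


def grid_search_rss(model, k: np.ndarray, y: np.ndarray,
                    a_grid, b_grid, c_grid) -> float:
    """Best RSS over a dense parameter grid."""
    best = np.inf
    for a in a_grid:
        for b in b_grid:
            resid = y[None, :] - (a * model(k, b)[None, :]
                                  + np.asarray(c_grid)[:, None])
            rss = (resid ** 2).sum(axis=1).min()
            best = min(best, float(rss))
    return best


def translate_with_snp(gene, genome, pos: int, alt: str) -> str:
    """Full-CDS re-extraction and translation after applying one SNP."""
    seq = genome[gene.chrom]
    mutated = dict(genome)
    mutated[gene.chrom] = seq[:pos - 1] + alt + seq[pos:]
    return str(Seq(gene.coding_sequence(mutated)).translate())


def single_linkage_clusters(records, linked) -> list[frozenset]:
    """Brute-force transitive closure of the pairwise link relation."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if linked(records[i], records[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=min)


def duncan_pairwise_oracle(means_desc: np.ndarray, se: float, df: int,
                           alpha: float = 0.05) -> np.ndarray:
    """Protected all-pairs Duncan decision matrix on descending means.

    Pair (i, j) is declared different iff every span containing it (itself
    included) exceeds that span's least significant range.
    """
    g = len(means_desc)
    _cache: dict[int, float] = {}

    def lsr(p: int) -> float:
        if p not in _cache:
            alpha_p = 1 - (1 - alpha) ** (p - 1)
            _cache[p] = float(studentized_range.ppf(1 - alpha_p, p, df)) * se
        return _cache[p]

    diff = np.zeros((g, g), dtype=bool)
    for i in range(g):
        for j in range(i + 1, g):
            significant = True
            for a in range(0, i + 1):
                for b in range(j, g):
                    p = b - a + 1
                    if means_desc[a] - means_desc[b] <= lsr(p):
                        significant = False
                        break
                if not significant:
                    break
            diff[i, j] = diff[j, i] = significant
    return diff
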