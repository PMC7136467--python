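"""Weir–Cockerham F_ST, Reynolds genetic distances, and neighbor-joining.

Per-locus variance components follow Weir & Cockerham (1984) for diploid
data: ``a`` (among populations), ``b`` (among individuals within
populations), ``c`` (within individuals, i.e. heterozygosity), with
``theta = a / (a + b + c)``.  The multilocus estimator is the ratio of sums
``sum(a) / sum(a + b + c)`` — the combination WC84 recommend — and negative
per-locus components are kept in the sums for unbiasedness.  Reynolds
distance is the Arlequin-style ``-ln(1 - theta)`` on pairwise multilocus
theta (negative estimates clamp to zero at the distance stage only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class FstResult:
    per_locus: pd.DataFrame     # snp, chrom, pos_bp, a, b, c, theta
    theta_multilocus: float
    n_loci_used: int
    n_loci_excluded: int
    labels: tuple


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


@dataclass
class PhyloTree:
    """Unrooted NJ tree; ``newick`` has branch lengths clamped at zero,
    ``raw_lengths`` keeps the unclamped estimates per edge key."""

    newick: str
    labels: list[str]
    raw_lengths: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Weir-Cockerham components
# ---------------------------------------------------------------------------

def _wc_components(ds: GenotypeDataset, pop_rows: list[np.ndarray]):
    """Vectorized per-locus (a, b, c) over all loci for the given groups."""
    r = len(pop_rows)
    L = ds.n_markers
    n_i = np.zeros((r, L))       # genotyped individuals per pop per locus
    p_i = np.zeros((r, L))       # A1 allele frequency
    h_i = np.zeros((r, L))       # observed heterozygote frequency
    for k, rows in enumerate(pop_rows):
        calls = ds.calls[rows]
        obs = calls != MISSING
        cnt = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(cnt > 0,
                              np.where(obs, calls, 0).sum(axis=0) / (2 * cnt),
                              np.nan)
            h_i[k] = np.where(cnt > 0, (calls == 1).sum(axis=0) / cnt, np.nan)
        n_i[k] = cnt

    usable = (n_i >= 2).all(axis=0)
    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i ** 2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    # loci monomorphic across every population have an undefined ratio
    poly = usable & (pbar > 0) & (pbar < 1)
    return a, b, c, poly


def wc_fst(ds: GenotypeDataset, pops: tuple | list) -> FstResult:
    """Per-locus and ratio-of-sums multilocus Weir–Cockerham theta.

    ``pops`` may name populations of ``ds``, or be a list of row-index arrays
    for ad-hoc groupings (e.g. a pooled commercial group).
    """
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    if all(isinstance(p, str) for p in pops):
        pop_rows = [ds.pop_indices(p) for p in pops]
        labels = tuple(pops)
    else:
        pop_rows = [np.asarray(p) for p in pops]
        labels = tuple(f"group{i + 1}" for i in range(len(pops)))
    a, b, c, poly = _wc_components(ds, pop_rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(poly & (denom != 0), a / denom, np.nan)
    per_locus = pd.DataFrame({
        "snp": ds.markers["id"], "chrom": ds.markers["chrom"],
        "pos_bp": ds.markers["pos_bp"],
        "a": np.where(poly, a, np.nan), "b": np.where(poly, b, np.nan),
        "c": np.where(poly, c, np.nan), "theta": theta,
    })
    used = poly & np.isfinite(denom)
    multi = float(a[used].sum() / denom[used].sum()) if used.any() else np.nan
    return FstResult(per_locus=per_locus, theta_multilocus=multi,
                     n_loci_used=int(used.sum()),
                     n_loci_excluded=int((~used).sum()), labels=labels)


def pairwise_fst_matrix(ds: GenotypeDataset, labels: list[str] | None = None):
    """Multilocus theta for every unordered population pair.

    Returns ``(DistanceMatrix, per_population_mean, grand_mean)`` where the
    per-population mean averages each population's off-diagonal entries —
    the breed-level summary used to rank how peripheral a breed is.
    Populations with fewer than 2 members are excluded with a warning.
    """
    import warnings
    if labels is None:
        labels = ds.populations()
    sizes = {p: len(ds.pop_indices(p)) for p in labels}
    small = [p for p, n in sizes.items() if n < 2]
    if small:
        warnings.warn(f"excluding populations with <2 members: {small}")
        labels = [p for p in labels if p not in small]
    if len(labels) < 2:
        raise ValueError("need at least two populations of size >= 2")
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        theta = wc_fst(ds, (labels[i], labels[j])).theta_multilocus
        mat[i, j] = mat[j, i] = theta
    dm = DistanceMatrix(labels=list(labels), values=mat)
    off = mat + np.diag(np.full(n, np.nan))
    per_pop = pd.Series(np.nanmean(off, axis=1), index=labels,
                        name="mean_fst")
    grand = float(mat[np.triu_indices(n, k=1)].mean())
    return dm, per_pop, grand


def reynolds_distance(theta_matrix: DistanceMatrix,
                      cap: float = 10.0) -> DistanceMatrix:
    """Elementwise ``-ln(1 - theta)``; negative estimates clamp to 0 and
    theta >= 1 entries are set to ``cap`` (both with a warning count)."""
    import warnings
    th = theta_matrix.values.copy()
    saturated = th >= 1.0
    th[saturated] = np.nan
    with np.errstate(invalid="ignore"):
        d = -np.log(1.0 - th)
    n_clamped = int((d < 0).sum() // 2)
    d[d < 0] = 0.0
    d[saturated] = cap
    np.fill_diagonal(d, 0.0)
    if n_clamped or saturated.any():
        warnings.warn(f"Reynolds transform: {n_clamped} negative pairs "
                      f"clamped to 0, {int(saturated.sum() // 2)} saturated "
                      f"pairs capped at {cap}")
    return DistanceMatrix(labels=list(theta_matrix.labels), values=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically smallest sorted
    label pair.  Internal nodes carry the sorted concatenation of their leaf
    labels for tie-breaking only; the emitted Newick has no internal labels.
    Branch lengths are clamped at zero in the Newick output; raw values are
    retained in ``raw_lengths``.
    """
    labels = list(D.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(D.values).any():
        raise ValueError("distance matrix has missing entries")
    dist = {(a, b): float(D.values[i, j])
            for i, a in enumerate(labels) for j, b in enumerate(labels)}
    # node -> (newick fragment, sort key)
    nodes = {lbl: (lbl, (lbl,)) for lbl in labels}
    raw_lengths: dict[str, float] = {}

    def d(x, y):
        return dist[(x, y)] if x != y else 0.0

    active = sorted(labels)
    while len(active) > 3:
        n = len(active)
        r = {x: sum(d(x, y) for y in active) for x in active}
        best = None
        for x, y in combinations(active, 2):
            q = (n - 2) * d(x, y) - r[x] - r[y]
            key = tuple(sorted((nodes[x][1], nodes[y][1])))
            if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]):
                best = (q, key, x, y)
        _, _, x, y = best
        lx = d(x, y) / 2 + (r[x] - r[y]) / (2 * (n - 2))
        ly = d(x, y) - lx
        new = f"__{min(x, y)}|{max(x, y)}__"
        raw_lengths[f"{x}"] = lx
        raw_lengths[f"{y}"] = ly
        nodes[new] = (
            f"({nodes[x][0]}:{max(lx, 0.0):.6f},{nodes[y][0]}:{max(ly, 0.0):.6f})",
            tuple(sorted(nodes[x][1] + nodes[y][1])))
        for z in active:
            if z in (x, y):
                continue
            v = (d(x, z) + d(y, z) - d(x, y)) / 2
            dist[(new, z)] = dist[(z, new)] = v
        active = sorted([z for z in active if z not in (x, y)] + [new])

    a, b, c = active
    la = (d(a, b) + d(a, c) - d(b, c)) / 2
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2
    raw_lengths[a], raw_lengths[b], raw_lengths[c] = la, lb, lc
    newick = (f"({nodes[a][0]}:{max(la, 0.0):.6f},"
              f"{nodes[b][0]}:{max(lb, 0.0):.6f},"
              f"{nodes[c][0]}:{max(lc, 0.0):.6f});")
    return PhyloTree(newick=newick, labels=labels, raw_lengths=raw_lengths)
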