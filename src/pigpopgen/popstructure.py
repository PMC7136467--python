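"""Pairwise identical-by-state coancestry and classical (Torgerson) MDS.

IBS between two individuals is the mean, over mutually genotyped loci, of
``1 - |g_i - g_j| / 2`` — 1 for identical genotypes, 0.5 when one allele is
shared, 0 for opposite homozygotes.  The coancestry matrix's complement
``D = 1 - IBS`` is the distance fed to classical multidimensional scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class CoancestryMatrix:
    labels: list[str]
    values: np.ndarray          # n x n IBS proportions, NaN where undefined
    counts: np.ndarray          # n x n loci compared

    def distance(self) -> np.ndarray:
        """Complement distance ``1 - IBS``."""
        return 1.0 - self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class MdsResult:
    coordinates: np.ndarray     # n x d
    eigenvalues: np.ndarray     # d, non-increasing
    negative_eigenvalues: np.ndarray
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim{i + 1}": self.coordinates[:, i]
                for i in range(self.coordinates.shape[1])}
        return pd.DataFrame({"sample_id": self.labels, **cols})


def ibs_matrix(ds: GenotypeDataset) -> CoancestryMatrix:
    """All-pairs IBS proportions, with the per-pair locus count recorded.

    A pair with no mutually genotyped locus gets NaN.  The diagonal is 1 for
    any sample with at least one call.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise IBS")
    g = ds.calls.astype(np.float64)
    obs = (ds.calls != MISSING).astype(np.float64)
    g[ds.calls == MISSING] = 0.0

    counts = obs @ obs.T
    # sum over shared loci of |g_i - g_j|: expand via E[(gi-gj)^2] trick is
    # wrong for L1, so use the three indicator matrices of {0,1,2} instead
    sim = np.zeros_like(counts)
    ind = [(ds.calls == v).astype(np.float64) for v in (0, 1, 2)]
    # |gi-gj| = 0 -> weight 1; 1 -> 0.5; 2 -> 0
    for a in range(3):
        for b in range(3):
            w = 1.0 - abs(a - b) / 2.0
            if w:
                sim += w * (ind[a] @ ind[b].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = np.where(counts > 0, sim / counts, np.nan)
    np.fill_diagonal(ibs, np.where(obs.sum(axis=1) > 0, 1.0, np.nan))
    ibs = (ibs + ibs.T) / 2.0   # exact symmetry against fp noise
    return CoancestryMatrix(labels=list(ds.samples["sample_id"]),
                            values=ibs, counts=counts)


def classical_mds(coancestry: CoancestryMatrix, d: int = 2) -> MdsResult:
    """Torgerson scaling of the complement distance ``1 - IBS``.

    Double-centers ``-D**2 / 2``, eigendecomposes, and returns the top-``d``
    coordinates scaled by sqrt(eigenvalue).  Negative eigenvalues (non-
    Euclidean distances) are reported but never used for coordinates.
    Eigenvector sign is fixed by forcing each axis's largest-magnitude
    loading positive.
    """
    D = coancestry.distance()
    if np.isnan(D).any():
        bad = [coancestry.labels[i]
               for i in np.unique(np.argwhere(np.isnan(D)))]
        raise ValueError(
            f"distance matrix has missing cells; remove samples {bad[:5]}")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if d > n:
        raise ValueError(f"requested dimension {d} exceeds sample count {n}")
    top = eigval[:d]
    coords = eigvec[:, :d] * np.sqrt(np.clip(top, 0.0, None))
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return MdsResult(coordinates=coords, eigenvalues=top,
                     negative_eigenvalues=eigval[eigval < 0],
                     labels=list(coancestry.labels))
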