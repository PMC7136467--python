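"""Selection-signature scans: F_ST outliers, eROHi islands, iHS and Rsb.

Four complementary views of recent selection on a phased SNP panel:

* ``fst_outliers`` — the SNPs most differentiated between a local breed and
  a pooled commercial group (top-30 per-locus Weir–Cockerham theta);
* ``erohi_outliers`` — "ROH islands": SNPs lying inside runs of
  homozygosity in an extreme fraction of a population (Tukey upper-fence
  outliers of the genome-wide incidence distribution by default);
* ``ihs_scan`` — within-population integrated haplotype score: the
  standardized log-ratio of integrated EHH for the two alleles of each SNP;
* ``rsb_scan`` — across-population ratio of integrated site-specific EHH
  (iES), median-centered and variance-scaled genome-wide.

iHS and Rsb report two-sided -log10 p-values under the normal assumption and
flag SNPs at -log10(p) >= 4.0.  True ancestral states are unknown on a SNP
chip, so iHS polarity takes the minor allele as "derived"; |iHS| is
polarity-invariant and p-values are two-sided, so significance calls do not
depend on the choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .differentiation import wc_fst
from .genotype_io import GenotypeDataset
from .synthetic_data import HaplotypePanel


@dataclass
class ScanConfig:
    local_pop: str = ""
    commercial_pops: tuple = ("LDR1", "LDR2", "PIT1", "PIT2")
    top_n_fst: int = 30
    erohi_rule: str = "fence"       # "fence" (Q3 + mult*IQR) or "percentile"
    erohi_fence_mult: float = 1.5
    erohi_percentile: float = 99.0
    maf_min: float = 0.05
    ehh_floor: float = 0.05
    n_freq_bins: int = 20
    min_bin_size: int = 20
    log10p_threshold: float = 4.0
    window_mb: float = 0.1


@dataclass
class EhhDecay:
    core_id: str
    allele: int
    distances_bp: np.ndarray    # signed: negative upstream, positive downstream
    ehh: np.ndarray
    ihh: float                  # trapezoid integral over both directions, bp


# ---------------------------------------------------------------------------
# EHH machinery
# ---------------------------------------------------------------------------

def _homozygosity(group_ids: np.ndarray) -> float:
    _, counts = np.unique(group_ids, return_counts=True)
    n = group_ids.size
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _decay(hap: np.ndarray, pos: np.ndarray, core: int, rows: np.ndarray,
           floor: float, init_gid: np.ndarray | None = None):
    """Walk outward from ``core`` over one chromosome, grouping haplotypes by
    their extended-haplotype identity; returns signed distances and EHH
    values (normalized so the value at the core is 1)."""
    sub = hap[rows]
    dists = [0]
    gid0 = (np.zeros(rows.size, dtype=np.int64) if init_gid is None
            else init_gid.astype(np.int64))
    h0 = _homozygosity(gid0) if init_gid is not None else 1.0
    vals = [1.0]
    for direction in (-1, 1):
        gid = gid0.copy()
        j = core + direction
        while 0 <= j < pos.size:
            gid = gid * 2 + sub[:, j]
            _, gid = np.unique(gid, return_inverse=True)
            e = _homozygosity(gid) / h0 if h0 > 0 else 0.0
            dists.append(int(pos[j] - pos[core]))
            vals.append(e)
            if e < floor:
                break
            j += direction
    order = np.argsort(dists, kind="stable")
    return np.asarray(dists)[order], np.asarray(vals)[order]


def _integrate(dists: np.ndarray, vals: np.ndarray) -> float:
    left = dists <= 0
    right = dists >= 0
    ihh = 0.0
    if left.sum() > 1:
        ihh += np.trapezoid(vals[left][::-1], -dists[left][::-1])
    if right.sum() > 1:
        ihh += np.trapezoid(vals[right], dists[right])
    return float(ihh)


def ehh(panel: HaplotypePanel, core_snp: str, allele: int,
        ehh_floor: float = 0.05) -> EhhDecay:
    """Allele-specific EHH decay around a core SNP.

    EHH at a flanking marker is the probability that two random distinct
    carrier haplotypes are identical over every SNP between the core and
    that marker; the walk truncates below ``ehh_floor`` or at the
    chromosome end.  iHH is the trapezoid integral against physical
    distance, both directions summed.
    """
    hits = np.flatnonzero((panel.markers["id"] == core_snp).to_numpy())
    if hits.size == 0:
        raise KeyError(f"core SNP {core_snp!r} not in panel")
    chrom = int(panel.markers["chrom"].iloc[hits[0]])
    sub = panel.subset_chrom(chrom)
    core = int(np.flatnonzero((sub.markers["id"] == core_snp).to_numpy())[0])
    pos = sub.markers["pos_bp"].to_numpy()
    rows = np.flatnonzero(sub.haplotypes[:, core] == allele)
    if rows.size < 2:
        raise ValueError(
            f"allele {allele} at {core_snp} has fewer than 2 carriers")
    dists, vals = _decay(sub.haplotypes, pos, core, rows, ehh_floor)
    return EhhDecay(core_id=core_snp, allele=allele, distances_bp=dists,
                    ehh=vals, ihh=_integrate(dists, vals))


def _ies(hap: np.ndarray, pos: np.ndarray, core: int,
         floor: float) -> float:
    """Integrated site-specific EHH (all haplotypes, normalized by the core
    SNP's homozygosity)."""
    rows = np.arange(hap.shape[0])
    init = hap[:, core].astype(np.int64)
    dists, vals = _decay(hap, pos, core, rows, floor, init_gid=init)
    return _integrate(dists, vals)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _standardize_binned(stat: np.ndarray, freq: np.ndarray, n_bins: int,
                        min_bin: int):
    """Within-bin standardization over equal-width derived-frequency bins;
    bins below ``min_bin`` SNPs merge with their neighbor."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_of = np.clip(np.digitize(freq, edges) - 1, 0, n_bins - 1)
    occupied = [b for b in range(n_bins) if (bin_of == b).sum() > 0]
    merged: list[list[int]] = []
    for b in occupied:
        if merged and (bin_of == b).sum() < min_bin:
            merged[-1].append(b)
        else:
            merged.append([b])
    if len(merged) > 1 and sum((bin_of == b).sum() for b in merged[0]) < min_bin:
        merged[1] = merged[0] + merged[1]
        merged = merged[1:]
    if any(len(g) > 1 for g in merged):
        warnings.warn("merged sparse frequency bins during standardization")
    z = np.empty_like(stat)
    for group in merged:
        mask = np.isin(bin_of, group)
        mu = stat[mask].mean()
        sd = stat[mask].std(ddof=0)
        z[mask] = 0.0 if sd == 0 else (stat[mask] - mu) / sd
    return z


def _log10_two_sided(z: np.ndarray) -> np.ndarray:
    # -log10 of the two-sided normal p-value, stable for large |z|
    return -(norm.logsf(np.abs(z)) + np.log(2.0)) / np.log(10.0)


def ihs_scan(panel: HaplotypePanel, cfg: ScanConfig | None = None
             ) -> pd.DataFrame:
    """Integrated haplotype score for every SNP above the MAF threshold.

    Columns: snp, chrom, pos_bp, derived_freq, ihs_unstd (ln iHH_A/iHH_D),
    ihs (bin-standardized), log10p, significant.
    """
    cfg = cfg or ScanConfig()
    markers = panel.markers
    freq1 = panel.haplotypes.mean(axis=0)
    chrom_arr = markers["chrom"].to_numpy()
    rows = []
    for c in np.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == c)
        pos = markers["pos_bp"].to_numpy()[cols]
        hap = panel.haplotypes[:, cols]
        for local in range(cols.size):
            idx = cols[local]
            f1 = freq1[idx]
            maf = min(f1, 1 - f1)
            if maf < cfg.maf_min:
                continue
            derived = 1 if f1 <= 0.5 else 0
            ihhs = {}
            for allele in (1 - derived, derived):
                carriers = np.flatnonzero(hap[:, local] == allele)
                if carriers.size < 2:
                    break
                d, v = _decay(hap, pos, local, carriers, cfg.ehh_floor)
                ihhs[allele] = _integrate(d, v)
            if len(ihhs) < 2 or min(ihhs.values()) <= 0:
                continue
            rows.append((markers["id"].iloc[idx], markers["chrom"].iloc[idx],
                         markers["pos_bp"].iloc[idx], maf,
                         float(np.log(ihhs[1 - derived] / ihhs[derived]))))
    out = pd.DataFrame(rows, columns=["snp", "chrom", "pos_bp",
                                      "derived_freq", "ihs_unstd"])
    if out.empty:
        out["ihs"] = out["log10p"] = out["significant"] = []
        return out
    out["ihs"] = _standardize_binned(out["ihs_unstd"].to_numpy(),
                                     out["derived_freq"].to_numpy(),
                                     cfg.n_freq_bins, cfg.min_bin_size)
    out["log10p"] = _log10_two_sided(out["ihs"].to_numpy())
    out["significant"] = out["log10p"] >= cfg.log10p_threshold
    return out


def rsb_scan(panel_a: HaplotypePanel, panel_b: HaplotypePanel,
             cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Across-population Rsb: ln(iES_A / iES_B) per SNP, median-centered and
    sd-scaled genome-wide, with two-sided normal -log10 p-values."""
    cfg = cfg or ScanConfig()
    if not panel_a.markers[["id", "chrom", "pos_bp"]].equals(
            panel_b.markers[["id", "chrom", "pos_bp"]]):
        raise ValueError("panels must share an identical marker map")
    markers = panel_a.markers
    chrom_arr = markers["chrom"].to_numpy()
    rows = []
    n_skipped = 0
    for c in np.unique(chrom_arr):
        cols = np.flatnonzero(chrom_arr == c)
        pos = markers["pos_bp"].to_numpy()[cols]
        hap_a = panel_a.haplotypes[:, cols]
        hap_b = panel_b.haplotypes[:, cols]
        for local in range(cols.size):
            idx = cols[local]
            try:
                ies_a = _ies(hap_a, pos, local, cfg.ehh_floor)
                ies_b = _ies(hap_b, pos, local, cfg.ehh_floor)
            except ValueError:
                n_skipped += 1
                continue
            if ies_a <= 0 or ies_b <= 0:
                n_skipped += 1
                continue
            rows.append((markers["id"].iloc[idx], markers["chrom"].iloc[idx],
                         markers["pos_bp"].iloc[idx],
                         float(np.log(ies_a / ies_b))))
    out = pd.DataFrame(rows, columns=["snp", "chrom", "pos_bp", "rsb_unstd"])
    out.attrs["n_skipped"] = n_skipped
    if out.empty:
        out["rsb"] = out["log10p"] = out["significant"] = []
        return out
    u = out["rsb_unstd"].to_numpy()
    centered = u - np.median(u)
    sd = centered.std(ddof=0)
    out["rsb"] = centered / sd if sd > 0 else np.zeros_like(centered)
    out["log10p"] = _log10_two_sided(out["rsb"].to_numpy())
    out["significant"] = out["log10p"] >= cfg.log10p_threshold
    return out


def fst_outliers(ds: GenotypeDataset, local_pop: str,
                 commercial_pops, top_n: int = 30) -> pd.DataFrame:
    """The ``top_n`` SNPs with the highest per-locus theta between the local
    breed and the pooled commercial group; ties at the cutoff break by
    (chrom, pos) ascending."""
    local_rows = ds.pop_indices(local_pop)
    comm_rows = np.concatenate([ds.pop_indices(p) for p in commercial_pops])
    res = wc_fst(ds, [local_rows, comm_rows])
    tab = res.per_locus.dropna(subset=["theta"]).copy()
    if len(tab) < top_n:
        warnings.warn(f"only {len(tab)} loci with defined theta "
                      f"(requested top {top_n})")
    tab = tab.sort_values(["theta", "chrom", "pos_bp"],
                          ascending=[False, True, True], kind="stable")
    return tab.head(top_n).reset_index(drop=True)


def erohi_outliers(incidence: np.ndarray, markers: pd.DataFrame,
                   cfg: ScanConfig | None = None):
    """SNPs with extreme ROH incidence.

    Default rule: Tukey upper fence Q3 + 1.5*IQR of the genome-wide
    incidence distribution (~99% coverage for Gaussian data); the 99th-
    percentile rule is available via ``cfg.erohi_rule = "percentile"``.
    Returns ``(outlier_frame, islands)`` where islands group contiguous
    flagged SNPs.
    """
    cfg = cfg or ScanConfig()
    incidence = np.asarray(incidence, dtype=float)
    if cfg.erohi_rule == "fence":
        q1, q3 = np.percentile(incidence, [25, 75])
        cutoff = q3 + cfg.erohi_fence_mult * (q3 - q1)
    elif cfg.erohi_rule == "percentile":
        cutoff = np.percentile(incidence, cfg.erohi_percentile)
    else:
        raise ValueError(f"unknown eROHi rule {cfg.erohi_rule!r}")
    flagged = incidence > cutoff
    out = markers.loc[flagged, ["id", "chrom", "pos_bp"]].copy()
    out["incidence"] = incidence[flagged]
    out = out.rename(columns={"id": "snp"}).reset_index(drop=True)

    islands = []
    idx = np.flatnonzero(flagged)
    if idx.size:
        chrom = markers["chrom"].to_numpy()
        start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i == prev + 1 and chrom[i] == chrom[start]:
                prev = i
            else:
                islands.append((chrom[start],
                                markers["pos_bp"].iloc[start],
                                markers["pos_bp"].iloc[prev],
                                prev - start + 1))
                start = prev = i
        islands.append((chrom[start], markers["pos_bp"].iloc[start],
                        markers["pos_bp"].iloc[prev], prev - start + 1))
    islands = pd.DataFrame(islands, columns=["chrom", "start_bp", "end_bp",
                                             "n_snps"])
    return out, islands


def overlap_report(sets: dict[str, set], markers: pd.DataFrame,
                   window_mb: float = 0.1):
    """Cross-method intersections and candidate windows.

    Returns ``(intersections, windows)``: all pairwise and higher-order
    intersections of the named outlier SNP-id sets, and a ±window_mb/2
    window around every outlier SNP listing the markers it contains.
    """
    from itertools import combinations as _comb
    if len(sets) < 2:
        raise ValueError("need at least two named outlier sets")
    names = sorted(sets)
    inter_rows = []
    for k in range(2, len(names) + 1):
        for group in _comb(names, k):
            common = set.intersection(*(set(sets[g]) for g in group))
            inter_rows.append(("+".join(group), len(common),
                               ",".join(sorted(common))))
    intersections = pd.DataFrame(inter_rows,
                                 columns=["methods", "n_shared",
                                          "shared_snps"])
    half_bp = window_mb / 2 * 1e6
    pos_by_id = markers.set_index("id")[["chrom", "pos_bp"]]
    win_rows = []
    all_ids = sorted(set.union(*(set(s) for s in sets.values())))
    for sid in all_ids:
        if sid not in pos_by_id.index:
            continue
        chrom, pos = pos_by_id.loc[sid]
        in_win = markers[(markers["chrom"] == chrom)
                         & (markers["pos_bp"] >= pos - half_bp)
                         & (markers["pos_bp"] <= pos + half_bp)]
        methods = [m for m in names if sid in sets[m]]
        win_rows.append((sid, int(chrom), int(pos),
                         int(pos - half_bp), int(pos + half_bp),
                         ",".join(methods), len(in_win),
                         ",".join(in_win["id"])))
    windows = pd.DataFrame(win_rows, columns=[
        "snp", "chrom", "pos_bp", "win_start_bp", "win_end_bp", "methods",
        "n_markers", "markers"])
    return intersections, windows
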