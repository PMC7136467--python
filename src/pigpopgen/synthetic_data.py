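"""Multi-population genotype and phased-haplotype simulation with ground truth.

The generator produces SNP-chip-like panels under the Balding–Nichols model:
each population's allele frequency at a locus is a Beta draw around a shared
ancestral frequency, concentrated by a per-population drift parameter F.
Admixed individuals draw each allele copy's population of origin from their
ancestry vector Q.  On top of this linkage-free background the generator can
inject two kinds of localized haplotype structure:

* autozygous segments — one haplotype copied onto the other over an interval,
  so that every contained SNP is homozygous (the signal ROH callers measure);
* selective-sweep cores — a fraction of haplotypes in one population share an
  identical core haplotype around a focal SNP (the signal EHH scans measure).

Every draw is a pure function of (config, seed); truth records carry the
simulated Q, F, allele frequencies, segment bounds and sweep placement so
downstream stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import (MARKER_COLUMNS, MISSING, SAMPLE_COLUMNS,
                          GenotypeDataset)

#: autosome lengths in Mb, proportioned like the pig genome and rescaled to
#: the 2,444.5 Mb chip-covered autosomal total (18 autosomes)
GENOME_LENGTH_MB = 2444.5
_RAW_CHROM_MB = np.array([315.3, 162.6, 144.8, 143.5, 111.5, 157.8, 134.8,
                          148.5, 153.7, 79.1, 87.7, 63.6, 218.6, 153.9,
                          157.7, 86.9, 69.7, 61.2])
DEFAULT_CHROM_LENGTHS_MB = tuple(_RAW_CHROM_MB / _RAW_CHROM_MB.sum()
                                 * GENOME_LENGTH_MB)


@dataclass
class RohPlan:
    """Target autozygosity per individual.

    ``target_fraction`` maps sample index (or the string "all") to the
    autozygous genome fraction to inject — either a float, or a
    ``(fraction, long_share)`` pair to override the mixture weight for that
    individual.  Segment lengths are drawn from a two-component mixture:
    Uniform(4, 8) Mb ("remote" inbreeding) and Uniform(8, 30) Mb ("recent"),
    with ``long_share`` the probability of the long component.
    """

    target_fraction: dict = field(default_factory=dict)
    long_share: float = 0.5
    short_range_mb: tuple[float, float] = (4.0, 8.0)
    long_range_mb: tuple[float, float] = (8.0, 30.0)


@dataclass
class SweepPlan:
    """A localized sweep: ``carrier_freq`` of the population's haplotypes share
    an identical core over ±``half_length_mb`` around the focal SNP and carry
    the derived allele there."""

    population: str
    #: marker id; None picks the SNP near the chromosome midpoint whose
    #: derived allele is rarest in the target population (sweeps start from
    #: low-frequency variants)
    focal_snp: str | None = None
    chrom: int = 1
    carrier_freq: float = 0.8
    half_length_mb: float = 5.0


@dataclass
class SimConfig:
    """Study-condition defaults: chip-density panels of strongly drifted
    populations with 16–20 individuals each."""

    n_pops: int = 2
    drift: tuple = (0.2, 0.2)
    n_per_pop: tuple = (20, 20)
    n_snps: int = 45000
    chrom_lengths_mb: tuple = DEFAULT_CHROM_LENGTHS_MB
    pop_labels: tuple | None = None
    admixture_Q: np.ndarray | None = None  # n x K rows summing to 1
    roh_plan: RohPlan | None = None
    sweep_plan: SweepPlan | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.drift) != self.n_pops or len(self.n_per_pop) != self.n_pops:
            raise ValueError("drift and n_per_pop must have n_pops entries")
        for f in self.drift:
            if not 0 < f < 1:
                raise ValueError(f"drift parameter {f} outside (0, 1)")
        if self.pop_labels is None:
            self.pop_labels = tuple(f"POP{k + 1}" for k in range(self.n_pops))
        if self.admixture_Q is not None:
            q = np.asarray(self.admixture_Q, dtype=float)
            if q.shape != (sum(self.n_per_pop), self.n_pops):
                raise ValueError("admixture_Q must be n_total x n_pops")
            if not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("admixture_Q rows must sum to 1")
            self.admixture_Q = q

    @property
    def genome_length_mb(self) -> float:
        return float(sum(self.chrom_lengths_mb))


@dataclass
class HaplotypePanel:
    """Phased haplotypes: two rows per individual, aligned to a marker map."""

    markers: pd.DataFrame
    haplotypes: np.ndarray          # 2n x L, uint8 in {0,1}
    sample_ids: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("need exactly two haplotype rows per individual")
        if self.haplotypes.shape[1] != len(self.markers):
            raise ValueError("haplotype width does not match marker count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def collapse(self) -> np.ndarray:
        """Genotype calls (A1 counts) from summing the two phases."""
        return (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)

    def subset_population(self, label: str) -> "HaplotypePanel":
        keep = [i for i, p in enumerate(self.populations) if p == label]
        rows = np.sort(np.concatenate([[2 * i, 2 * i + 1] for i in keep]))
        return HaplotypePanel(
            markers=self.markers,
            haplotypes=self.haplotypes[rows],
            sample_ids=[self.sample_ids[i] for i in keep],
            populations=[label] * len(keep),
        )

    def subset_chrom(self, chrom: int) -> "HaplotypePanel":
        cols = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
        return HaplotypePanel(
            markers=self.markers.iloc[cols].reset_index(drop=True),
            haplotypes=self.haplotypes[:, cols],
            sample_ids=self.sample_ids,
            populations=self.populations,
        )

    def write_tsv(self, path) -> None:
        """Transposed-haplotype TSV: one row per marker, one column per
        haplotype (sample_id suffixed .1/.2)."""
        cols = [f"{s}.{h}" for s in self.sample_ids for h in (1, 2)]
        df = pd.DataFrame(self.haplotypes.T, columns=cols)
        out = pd.concat([self.markers[["id", "chrom", "pos_bp"]], df], axis=1)
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# frequency model
# ---------------------------------------------------------------------------

def draw_population_freqs(L: int, K: int, F, seed=None, rng=None):
    """Balding–Nichols frequencies: ancestral p̄ ~ U(0.05, 0.95) and
    p_{k,l} ~ Beta(p̄(1−F_k)/F_k, (1−p̄)(1−F_k)/F_k).

    Returns ``(pbar, p)`` with ``p`` shaped (K, L).
    """
    F = np.asarray(F, dtype=float)
    if F.shape != (K,):
        raise ValueError(f"need {K} drift values, got shape {F.shape}")
    if np.any(F <= 0) or np.any(F >= 1):
        raise ValueError("drift parameters must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    pbar = rng.uniform(0.05, 0.95, size=L)
    scale = (1.0 - F) / F                       # (K,)
    alpha = pbar[None, :] * scale[:, None]
    beta = (1.0 - pbar[None, :]) * scale[:, None]
    p = rng.beta(alpha, beta)
    return pbar, np.clip(p, 1e-12, 1 - 1e-12)


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def _place_markers(n_snps: int, chrom_lengths_mb) -> pd.DataFrame:
    """Evenly spaced markers, counts per chromosome proportional to length."""
    lengths = np.asarray(chrom_lengths_mb, dtype=float)
    quota = lengths / lengths.sum() * n_snps
    counts = np.floor(quota).astype(int)
    # largest-remainder apportionment of the leftover markers
    for i in np.argsort(-(quota - counts))[: n_snps - counts.sum()]:
        counts[i] += 1
    rows = []
    snp_no = 0
    for c, (n_c, len_mb) in enumerate(zip(counts, lengths), start=1):
        if n_c == 0:
            continue
        spacing = len_mb * 1e6 / n_c
        pos = (spacing / 2 + spacing * np.arange(n_c)).round().astype(np.int64)
        for p in pos:
            snp_no += 1
            rows.append((f"SNP{snp_no:06d}", c, int(max(p, 1)), "A", "G"))
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def simulate_panel(cfg: SimConfig):
    """Simulate genotypes and phased haplotypes under ``cfg``.

    Returns ``(GenotypeDataset, HaplotypePanel, truth)`` where ``truth`` holds
    the generating Q, drift, frequencies, and any injected ROH/sweep records.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _place_markers(cfg.n_snps, cfg.chrom_lengths_mb)
    L = len(markers)
    n_total = sum(cfg.n_per_pop)
    K = cfg.n_pops

    pbar, p = draw_population_freqs(L, K, cfg.drift, rng=rng)

    if cfg.admixture_Q is not None:
        Q = cfg.admixture_Q
    else:
        Q = np.zeros((n_total, K))
        start = 0
        for k, n_k in enumerate(cfg.n_per_pop):
            Q[start:start + n_k, k] = 1.0
            start += n_k

    pops = [lbl for lbl, n_k in zip(cfg.pop_labels, cfg.n_per_pop)
            for _ in range(n_k)]
    sample_ids = [f"{pop}_{i:03d}" for i, pop in enumerate(pops, start=1)]

    # per-copy ancestry then Bernoulli allele draws; haplotype rows 2i, 2i+1
    Qh = np.repeat(Q, 2, axis=0)                      # (2n, K)
    cum = Qh.cumsum(axis=1)
    u = rng.random((2 * n_total, L))
    z = (u[:, :, None] > cum[:, None, :]).sum(axis=2)  # ancestry per copy/locus
    hap = (rng.random((2 * n_total, L)) < p[z, np.arange(L)[None, :]]
           ).astype(np.uint8)

    panel = HaplotypePanel(markers=markers, haplotypes=hap,
                           sample_ids=sample_ids, populations=pops)
    truth: dict = {"Q": Q, "drift": np.asarray(cfg.drift, dtype=float),
                   "pbar": pbar, "p": p, "ancestry": z,
                   "roh_segments": None, "sweep": None}

    if cfg.roh_plan is not None:
        panel, roh_truth = inject_autozygosity(
            panel, cfg.roh_plan, rng=rng,
            chrom_lengths_mb=cfg.chrom_lengths_mb)
        truth["roh_segments"] = roh_truth
    if cfg.sweep_plan is not None:
        panel, sweep_truth = inject_sweep(panel, cfg.sweep_plan, rng=rng)
        truth["sweep"] = sweep_truth

    calls = panel.collapse()
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = calls.copy()
        calls[mask] = MISSING

    samples = pd.DataFrame(
        {"sample_id": sample_ids, "population": pops,
         "sex": np.zeros(n_total, dtype=int)},
        columns=SAMPLE_COLUMNS)
    ds = GenotypeDataset(markers=markers.copy(), samples=samples, calls=calls)
    return ds, panel, truth


# ---------------------------------------------------------------------------
# structure injection
# ---------------------------------------------------------------------------

def inject_autozygosity(panel: HaplotypePanel, plan: RohPlan, seed=None,
                        rng=None, chrom_lengths_mb=DEFAULT_CHROM_LENGTHS_MB):
    """Copy one phase onto the other over random non-overlapping intervals
    until each planned individual reaches its target autozygous fraction.

    The last segment of each individual is truncated so the injected total
    matches the target closely (never below the 4 Mb short-class floor).
    Returns ``(panel, truth)`` with truth a DataFrame of exact bp bounds.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = np.asarray(chrom_lengths_mb, dtype=float)
    genome_mb = lengths.sum()
    hap = panel.haplotypes.copy()
    chrom_arr = panel.markers["chrom"].to_numpy()
    pos_arr = panel.markers["pos_bp"].to_numpy()

    targets: dict[int, object] = {}
    if "all" in plan.target_fraction:
        targets = {i: plan.target_fraction["all"]
                   for i in range(panel.n_samples)}
    targets.update({int(k): v for k, v in plan.target_fraction.items()
                    if k != "all"})
    records = []
    for ind, spec in sorted(targets.items()):
        if isinstance(spec, tuple):
            frac, long_share = spec
        else:
            frac, long_share = spec, plan.long_share
        if not 0 <= frac < 1:
            raise ValueError(f"target fraction {frac} outside [0, 1)")
        if frac == 0:
            continue
        target_mb = frac * genome_mb
        placed: dict[int, list[tuple[float, float]]] = {}
        total = 0.0
        attempts = 0
        while total < target_mb - 1e-9:
            attempts += 1
            if attempts > 5000:
                raise RuntimeError(
                    f"cannot reach autozygosity target {frac} for individual "
                    f"{ind}; shortfall {target_mb - total:.1f} Mb")
            if rng.random() < long_share:
                seg_len = rng.uniform(*plan.long_range_mb)
            else:
                seg_len = rng.uniform(*plan.short_range_mb)
            remaining = target_mb - total
            if seg_len > remaining:
                seg_len = max(remaining, plan.short_range_mb[0] + 0.05)
            c = rng.choice(len(lengths), p=lengths / genome_mb) + 1
            if seg_len >= lengths[c - 1]:
                continue
            start_mb = rng.uniform(0, lengths[c - 1] - seg_len)
            end_mb = start_mb + seg_len
            if any(s < end_mb and start_mb < e
                   for s, e in placed.get(c, [])):
                continue
            placed.setdefault(c, []).append((start_mb, end_mb))
            total += seg_len
            start_bp = int(round(start_mb * 1e6))
            end_bp = int(round(end_mb * 1e6))
            cols = np.flatnonzero((chrom_arr == c) & (pos_arr >= start_bp)
                                  & (pos_arr <= end_bp))
            hap[2 * ind + 1, cols] = hap[2 * ind, cols]
            records.append((panel.sample_ids[ind], ind, c, start_bp, end_bp,
                            seg_len))
    truth = pd.DataFrame(records, columns=["sample_id", "sample_index",
                                           "chrom", "start_bp", "end_bp",
                                           "length_mb"])
    out = HaplotypePanel(markers=panel.markers, haplotypes=hap,
                         sample_ids=panel.sample_ids,
                         populations=panel.populations)
    return out, truth


def inject_sweep(panel: HaplotypePanel, plan: SweepPlan, seed=None, rng=None):
    """Give ``carrier_freq`` of one population's haplotypes an identical core
    haplotype (and the derived allele) around the focal SNP."""
    if rng is None:
        rng = np.random.default_rng(seed)
    markers = panel.markers
    if plan.focal_snp is not None:
        hits = np.flatnonzero((markers["id"] == plan.focal_snp).to_numpy())
        if hits.size == 0:
            raise KeyError(f"focal SNP {plan.focal_snp!r} not in panel")
        focal = int(hits[0])
    else:
        on_chrom = np.flatnonzero((markers["chrom"] == plan.chrom).to_numpy())
        if on_chrom.size == 0:
            raise KeyError(f"no markers on chromosome {plan.chrom}")
        # middle fifth of the chromosome, rarest derived allele in the pop
        lo, hi = int(on_chrom.size * 0.4), int(on_chrom.size * 0.6) + 1
        mid = on_chrom[lo:hi]
        pop_rows0 = np.array([r for i, p in enumerate(panel.populations)
                              if p == plan.population
                              for r in (2 * i, 2 * i + 1)])
        freqs = panel.haplotypes[np.ix_(pop_rows0, mid)].mean(axis=0)
        focal = int(mid[int(np.argmin(freqs))])
    chrom = int(markers["chrom"].iloc[focal])
    pos = int(markers["pos_bp"].iloc[focal])
    half_bp = int(plan.half_length_mb * 1e6)
    chrom_pos = markers["pos_bp"].to_numpy()
    core_cols = np.flatnonzero(
        (markers["chrom"].to_numpy() == chrom)
        & (chrom_pos >= pos - half_bp) & (chrom_pos <= pos + half_bp))

    pop_rows = np.array([r for i, p in enumerate(panel.populations)
                         if p == plan.population for r in (2 * i, 2 * i + 1)])
    if pop_rows.size == 0:
        raise KeyError(f"no individuals in population {plan.population!r}")
    n_carriers = int(round(plan.carrier_freq * pop_rows.size))
    hap = panel.haplotypes.copy()
    truth = {"focal_index": focal, "focal_id": markers["id"].iloc[focal],
             "chrom": chrom, "pos_bp": pos, "carrier_rows": np.array([], int),
             "core_cols": core_cols}
    if n_carriers > 0:
        carriers = rng.choice(pop_rows, size=n_carriers, replace=False)
        core = hap[carriers[0], core_cols].copy()
        core[core_cols.searchsorted(focal)] = 1      # derived allele at focus
        hap[np.ix_(carriers, core_cols)] = core
        truth["carrier_rows"] = np.sort(carriers)
    out = HaplotypePanel(markers=panel.markers, haplotypes=hap,
                         sample_ids=panel.sample_ids,
                         populations=panel.populations)
    return out, truth


# ---------------------------------------------------------------------------
# study-scale preset
# ---------------------------------------------------------------------------

def _long_draw_prob(length_share: float, short_mean_mb: float = 6.0,
                    long_mean_mb: float = 19.0) -> float:
    """Mixture draw probability giving the requested share of total ROH
    length in the long component (mixture means default to the midpoints of
    the Uniform(4,8) and Uniform(8,30) components)."""
    return (length_share * short_mean_mb
            / (long_mean_mb * (1 - length_share)
               + short_mean_mb * length_share))


def conservation_preset(seed: int = 0, n_snps: int = 45000) -> SimConfig:
    """A panel emulating the study's composition: the two local breeds under
    conservation (one moderately, one extremely inbred) plus two Landrace and
    two Pietrain commercial populations, at chip density over 18 autosomes.

    Autozygosity targets reproduce the study-scale inbreeding contrasts: the
    highly threatened breed at F_ROH ≈ 0.40 (83% of it from long, recent
    segments) against the managed breed at ≈ 0.10.
    """
    labels = ("CROBS", "CROTS", "LDR1", "LDR2", "PIT1", "PIT2")
    n_per_pop = (16, 16, 20, 15, 20, 20)
    drift = (0.20, 0.45, 0.18, 0.18, 0.07, 0.07)
    froh_targets = {"CROBS": (0.098, 0.755), "CROTS": (0.400, 0.830),
                    "LDR1": (0.21, 0.80), "LDR2": (0.21, 0.80),
                    "PIT1": (0.17, 0.80), "PIT2": (0.17, 0.80)}
    target_fraction: dict[int, tuple] = {}
    idx = 0
    for lbl, n_k in zip(labels, n_per_pop):
        frac, share = froh_targets[lbl]
        for _ in range(n_k):
            target_fraction[idx] = (frac, _long_draw_prob(share))
            idx += 1
    plan = RohPlan(target_fraction=target_fraction)
    return SimConfig(n_pops=len(labels), drift=drift, n_per_pop=n_per_pop,
                     n_snps=n_snps, pop_labels=labels, roh_plan=plan,
                     seed=seed)
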