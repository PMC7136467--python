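"""Runs-of-homozygosity calling and ROH-based genomic inbreeding (F_ROH).

A run is called, per individual and chromosome, as a maximal stretch of
consecutive homozygous (or missing, within a class allowance) SNPs that

* contains at least ``min_snps`` markers,
* spans at least the class's minimum length (>4, >8 or >16 Mb classes),
* has no inter-marker gap above ``max_gap_mb``,
* keeps a run-average marker density of at least one SNP per
  ``density_mb_per_snp`` (length / n_snps <= 0.1 Mb), and
* contains at most the class's allowed number of missing calls
  (1, 2 and 4 for the three classes).

Maximality means no single-SNP extension on either side keeps every
constraint.  Class calls are merged by bp-interval union per individual, and
F_ROH is the union length over the chip-covered autosomal genome length
(2,444.5 Mb over 18 autosomes).  The >4 Mb and >8 Mb totals decompose the
coefficient into "remote" inbreeding (4–8 Mb segments, ancestors roughly 13
generations back) and "recent" inbreeding (>8 Mb, within about 7
generations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class RohParams:
    min_snps: int = 15
    max_gap_mb: float = 1.0
    density_mb_per_snp: float = 0.1
    #: (minimum length Mb, allowed missing calls) per class
    classes: tuple = ((4.0, 1), (8.0, 2), (16.0, 4))
    allowed_het: int = 0        # the rule set admits no heterozygotes
    genome_length_mb: float = 2444.5

    def __post_init__(self) -> None:
        lengths = [c[0] for c in self.classes]
        allows = [c[1] for c in self.classes]
        if lengths != sorted(lengths) or allows != sorted(allows):
            raise ValueError("classes must be sorted with non-decreasing "
                             "lengths and allowances")


@dataclass
class RohSegment:
    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_missing: int
    class_label: str

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6


@dataclass
class InbreedingRecord:
    sample_id: str
    froh_gt4: float
    froh_gt8: float
    froh_4to8: float
    froh_gt16: float


def _maximal_runs_in_stretch(pos: np.ndarray, is_missing: np.ndarray,
                             allowed_missing: int, min_snps: int,
                             min_length_mb: float, density: float):
    """All maximal valid subintervals of one het-free, gap-free SNP stretch.

    Yields (start_index, end_index, n_missing) triples.  Works row by row
    over start indices so memory stays O(m); validity of the previous start's
    row decides left-maximality.
    """
    m = pos.size
    cmiss = np.concatenate(([0], np.cumsum(is_missing)))
    prev_row = None
    for s in range(m):
        e = np.arange(s, m)
        n = e - s + 1
        miss_cnt = cmiss[e + 1] - cmiss[s]
        length = (pos[e] - pos[s]) / 1e6
        ok = ((miss_cnt <= allowed_missing) & (n >= min_snps)
              & (length >= min_length_mb) & (length / n <= density))
        row = np.zeros(m, dtype=bool)
        row[s:] = ok
        right_max = row & ~np.append(row[1:], False)
        cand = right_max if prev_row is None else (right_max & ~prev_row)
        for j in np.flatnonzero(cand):
            yield s, int(j), int(cmiss[j + 1] - cmiss[s])
        prev_row = row


def detect_roh(ds: GenotypeDataset, params: RohParams,
               class_index: int) -> list[RohSegment]:
    """Call ROH for one length class over every individual and chromosome."""
    min_len, allowed_missing = params.classes[class_index]
    label = f">{min_len:g}Mb"
    chrom = ds.markers["chrom"].to_numpy()
    pos = ds.markers["pos_bp"].to_numpy()
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(pos))):
        raise ValueError("markers must be sorted by (chrom, pos)")
    segments: list[RohSegment] = []
    max_gap_bp = params.max_gap_mb * 1e6
    for i in range(ds.n_samples):
        sid = ds.samples["sample_id"].iloc[i]
        g = ds.calls[i]
        callable_snp = (g == 0) | (g == 2) | (g == MISSING)
        for c in np.unique(chrom):
            on_c = np.flatnonzero(chrom == c)
            gc = callable_snp[on_c]
            pc = pos[on_c]
            # split at heterozygotes and at gaps exceeding the cap
            breaks = np.flatnonzero(~gc)
            gap_breaks = np.flatnonzero(np.diff(pc) > max_gap_bp) + 1
            cut = np.zeros(pc.size + 1, dtype=bool)
            cut[0] = cut[-1] = True
            cut[breaks] = True
            cut[breaks + 1] = True
            cut[gap_breaks] = True
            bounds = np.flatnonzero(cut)
            for a, b in zip(bounds[:-1], bounds[1:]):
                if b - a < params.min_snps or not gc[a:b].all():
                    continue
                stretch_pos = pc[a:b]
                stretch_miss = (g[on_c[a:b]] == MISSING)
                for s, e, n_miss in _maximal_runs_in_stretch(
                        stretch_pos, stretch_miss, allowed_missing,
                        params.min_snps, min_len,
                        params.density_mb_per_snp):
                    segments.append(RohSegment(
                        sample_id=sid, chrom=int(c),
                        start_bp=int(stretch_pos[s]),
                        end_bp=int(stretch_pos[e]),
                        n_snps=e - s + 1, n_missing=n_miss,
                        class_label=label))
    return segments


def detect_all_classes(ds: GenotypeDataset, params: RohParams | None = None,
                       ) -> dict[int, list[RohSegment]]:
    params = params or RohParams()
    return {k: detect_roh(ds, params, k) for k in range(len(params.classes))}


def merge_class_calls(per_class_segments) -> dict[str, list[tuple]]:
    """Per-individual bp-interval union of segments across classes.

    Accepts an iterable of segment lists (one per class pass) or a dict of
    them; returns ``{sample_id: [(chrom, start_bp, end_bp), ...]}`` with
    overlapping intervals coalesced.
    """
    if isinstance(per_class_segments, dict):
        per_class_segments = per_class_segments.values()
    by_sample: dict[str, list[tuple]] = {}
    for seg_list in per_class_segments:
        for seg in seg_list:
            by_sample.setdefault(seg.sample_id, []).append(
                (seg.chrom, seg.start_bp, seg.end_bp))
    merged: dict[str, list[tuple]] = {}
    for sid, ivs in by_sample.items():
        ivs.sort()
        out: list[list] = []
        for c, s, e in ivs:
            if out and out[-1][0] == c and s <= out[-1][2]:
                out[-1][2] = max(out[-1][2], e)
            else:
                out.append([c, s, e])
        merged[sid] = [tuple(x) for x in out]
    return merged


def froh(union_intervals: list[tuple], params: RohParams | None = None,
         sample_id: str = "") -> InbreedingRecord:
    """F_ROH by length class for one individual's merged intervals.

    ``froh_gtX`` sums union-segment lengths of at least X Mb and divides by
    the chip-covered genome length; ``froh_4to8`` is the difference of the
    >4 Mb and >8 Mb coefficients.
    """
    params = params or RohParams()
    lengths_mb = np.array([(e - s) / 1e6 for _, s, e in union_intervals])
    denom = params.genome_length_mb

    def total(min_mb: float) -> float:
        if lengths_mb.size == 0:
            return 0.0
        return float(lengths_mb[lengths_mb >= min_mb].sum()) / denom

    gt4, gt8, gt16 = (total(c[0]) for c in params.classes)
    return InbreedingRecord(sample_id=sample_id, froh_gt4=gt4, froh_gt8=gt8,
                            froh_4to8=gt4 - gt8, froh_gt16=gt16)


def inbreeding_table(ds: GenotypeDataset, params: RohParams | None = None,
                     ) -> tuple[pd.DataFrame, dict[int, list[RohSegment]]]:
    """Full pipeline: per-class calls, union merge, per-individual F_ROH."""
    params = params or RohParams()
    per_class = detect_all_classes(ds, params)
    union = merge_class_calls(per_class)
    rows = []
    for sid in ds.samples["sample_id"]:
        rec = froh(union.get(sid, []), params, sample_id=sid)
        rows.append((rec.sample_id, rec.froh_gt4, rec.froh_gt8,
                     rec.froh_4to8, rec.froh_gt16))
    table = pd.DataFrame(rows, columns=["sample_id", "froh_gt4", "froh_gt8",
                                        "froh_4to8", "froh_gt16"])
    table["population"] = ds.samples["population"].to_numpy()
    return table, per_class


def roh_incidence(segments: list[RohSegment], ds: GenotypeDataset,
                  population: str) -> np.ndarray:
    """Per-SNP fraction of the population's individuals whose ROH (interval
    union of the supplied segments) covers the SNP position."""
    rows = ds.pop_indices(population)
    ids = set(ds.samples["sample_id"].iloc[rows])
    union = merge_class_calls([[s for s in segments if s.sample_id in ids]])
    chrom = ds.markers["chrom"].to_numpy()
    pos = ds.markers["pos_bp"].to_numpy()
    hits = np.zeros(ds.n_markers, dtype=float)
    for sid in ids:
        covered = np.zeros(ds.n_markers, dtype=bool)
        for c, s, e in union.get(sid, []):
            covered |= (chrom == c) & (pos >= s) & (pos <= e)
        hits += covered
    return hits / len(ids)


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps, s.n_missing,
          round(s.length_mb, 6), s.class_label) for s in segments],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps",
                 "n_missing", "length_mb", "class_label"])
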