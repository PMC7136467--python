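"""PLINK-format genotype I/O, quality control, panel merging and SNP thinning.

Genotypes are stored as counts of the A1 allele (the first allele column of
the ``.bim``/``.map`` pair), with :data:`MISSING` (-1) as the missing sentinel.
The recorded allele pair for each marker is ordered ``(a2, a1)`` so that the
counting allele is always the second symbol of the pair.  Coordinates are
1-based inclusive base pairs throughout; interval lengths in Mb are
``(end - start) / 1e6``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

#: complementary bases, for strand-flip resolution during merges
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

MARKER_COLUMNS = ["id", "chrom", "pos_bp", "a1", "a2"]
SAMPLE_COLUMNS = ["sample_id", "population", "sex"]


class PlinkFormatError(ValueError):
    """Raised when PLINK input files are malformed or mutually inconsistent."""


class EmptyPanelError(ValueError):
    """Raised when an operation would leave a dataset with no SNPs."""


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotypes plus a marker map and sample table.

    Attributes
    ----------
    markers : pandas.DataFrame
        Columns ``id, chrom, pos_bp, a1, a2``; sorted by ``(chrom, pos_bp)``.
    samples : pandas.DataFrame
        Columns ``sample_id, population, sex``.
    calls : numpy.ndarray
        ``n_samples x n_markers`` int8 matrix of A1-allele counts
        ({0,1,2}) with ``MISSING`` for no-calls.
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise PlinkFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.markers["id"].duplicated().any():
            dups = self.markers.loc[self.markers["id"].duplicated(), "id"].tolist()
            raise PlinkFormatError(f"duplicate marker ids: {dups[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_rate_per_snp(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def missing_rate_per_sample(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=1)

    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def pop_indices(self, label: str) -> np.ndarray:
        """Row indices of samples belonging to population ``label``."""
        idx = np.flatnonzero((self.samples["population"] == label).to_numpy())
        if idx.size == 0:
            raise KeyError(f"no samples with population label {label!r}")
        return idx

    def subset_samples(self, rows) -> "GenotypeDataset":
        rows = np.asarray(rows)
        return GenotypeDataset(
            markers=self.markers.reset_index(drop=True),
            samples=self.samples.iloc[rows].reset_index(drop=True),
            calls=self.calls[rows],
        )

    def subset_markers(self, cols) -> "GenotypeDataset":
        cols = np.asarray(cols)
        return GenotypeDataset(
            markers=self.markers.iloc[cols].reset_index(drop=True),
            samples=self.samples.reset_index(drop=True),
            calls=self.calls[:, cols],
        )

    def subset_populations(self, labels) -> "GenotypeDataset":
        rows = np.flatnonzero(self.samples["population"].isin(labels).to_numpy())
        return self.subset_samples(rows)


@dataclass
class QcReport:
    """Accounting of a QC pass: per-axis in/out counts and removal reasons."""

    n_snps_in: int
    n_snps_out: int
    n_samples_in: int
    n_samples_out: int
    removed_snps: dict[str, str] = field(default_factory=dict)  # id -> reason
    removed_samples: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_snps_in == self.n_snps_out + len(self.removed_snps)
        assert self.n_samples_in == self.n_samples_out + len(self.removed_samples)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", k, v) for k, v in self.removed_snps.items()]
        rows += [("sample", k, v) for k, v in self.removed_samples.items()]
        return pd.DataFrame(rows, columns=["axis", "item", "reason"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_pop_table(path) -> dict[str, str]:
    tab = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "population"],
                      dtype=str)
    return dict(zip(tab["sample_id"], tab["population"]))


def _parse_map(path) -> pd.DataFrame:
    """Parse a .map/.bim marker file (without allele columns for .map)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (4, 6):
                raise PlinkFormatError(f"{path}:{ln}: expected 4 or 6 columns")
            chrom_raw, snp_id, _cm, pos = parts[:4]
            try:
                chrom = int(chrom_raw)
            except ValueError:
                chrom = 0  # non-numeric codes (X, Y, MT) flagged for QC removal
            a1, a2 = (parts[4], parts[5]) if len(parts) == 6 else ("0", "0")
            rows.append((snp_id, chrom, int(pos), a1, a2))
    if not rows:
        raise PlinkFormatError(f"{path}: empty marker file")
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def _sort_markers(markers: pd.DataFrame, calls: np.ndarray):
    order = np.lexsort((markers["pos_bp"].to_numpy(), markers["chrom"].to_numpy()))
    return markers.iloc[order].reset_index(drop=True), calls[:, order]


def read_plink(genotype_path, format: str = "text", pop_table=None) -> GenotypeDataset:
    """Read a PLINK fileset into a :class:`GenotypeDataset`.

    Parameters
    ----------
    genotype_path
        Path prefix of the fileset (``prefix.ped``/``prefix.map`` for text,
        ``prefix.bed``/``.bim``/``.fam`` for binary).  A path ending in
        ``.ped`` or ``.bed`` is also accepted.
    format : {"text", "binary"}
    pop_table
        Optional 2-column TSV (sample_id, population).  When absent, the
        family-ID column provides the population label.
    """
    prefix = str(genotype_path)
    for suf in (".ped", ".map", ".bed", ".bim", ".fam"):
        if prefix.endswith(suf):
            prefix = prefix[: -len(suf)]
            break
    if format == "text":
        ds = _read_plink_text(prefix)
    elif format == "binary":
        ds = _read_plink_binary(prefix)
    else:
        raise ValueError(f"unknown format {format!r}")
    if pop_table is not None:
        mapping = _read_pop_table(pop_table)
        missing_ids = set(ds.samples["sample_id"]) - set(mapping)
        if missing_ids:
            raise PlinkFormatError(
                f"population table lacks entries for {sorted(missing_ids)[:5]}")
        ds.samples["population"] = ds.samples["sample_id"].map(mapping)
    return ds


def _read_plink_text(prefix: str) -> GenotypeDataset:
    markers = _parse_map(prefix + ".map")
    n_markers = len(markers)
    sample_rows, call_rows = [], []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"{prefix}.ped:{ln}: expected {6 + 2 * n_markers} fields, "
                    f"got {len(parts)}")
            fid, iid, _pat, _mat, sex, _pheno = parts[:6]
            sample_rows.append((iid, fid, int(sex) if sex.isdigit() else 0))
            call_rows.append(parts[6:])
    if not sample_rows:
        raise PlinkFormatError(f"{prefix}.ped: no samples")

    # determine / check the allele pair at each marker, then count A1 copies
    a1 = markers["a1"].to_numpy(dtype=object)
    a2 = markers["a2"].to_numpy(dtype=object)
    alleles = np.array(call_rows, dtype=object).reshape(len(sample_rows), n_markers, 2)
    for j in range(n_markers):
        seen = [x for x in np.unique(alleles[:, j, :]) if x != "0"]
        if a1[j] == "0":  # .map carries no allele columns: infer, minor first
            if len(seen) > 2:
                raise PlinkFormatError(
                    f"marker {markers['id'][j]}: >2 alleles {seen}")
            if len(seen) == 2:
                counts = [(alleles[:, j, :] == s).sum() for s in seen]
                order = np.argsort(counts, kind="stable")  # minor allele = A1
                a1[j], a2[j] = seen[order[0]], seen[order[1]]
            elif len(seen) == 1:
                a1[j], a2[j] = "0", seen[0]  # monomorphic: A1 unknown
        else:
            extra = set(seen) - {a1[j], a2[j]}
            if extra:
                raise PlinkFormatError(
                    f"marker {markers['id'][j]}: alleles {extra} not in "
                    f"({a1[j]},{a2[j]})")
    markers = markers.assign(a1=a1, a2=a2)

    calls = np.full((len(sample_rows), n_markers), MISSING, dtype=np.int8)
    first = alleles[:, :, 0]
    second = alleles[:, :, 1]
    ok = (first != "0") & (second != "0")
    counted = (first == a1).astype(np.int8) + (second == a1).astype(np.int8)
    calls[ok] = counted[ok]

    samples = pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS)
    markers, calls = _sort_markers(markers, calls)
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit codes -> A1 count: 00=hom A1, 01=missing, 10=het, 11=hom A2
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _read_plink_binary(prefix: str) -> GenotypeDataset:
    markers = _parse_map(prefix + ".bim")
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    if fam.empty:
        raise PlinkFormatError(f"{prefix}.fam: no samples")
    n, m = len(fam), len(markers)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes (not SNP-major)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{prefix}.bed: size mismatch ({body.size} payload bytes, "
            f"expected {bytes_per_snp * m})")
    body = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    calls = _BED_DECODE[codes[:, :n]].T.copy()

    samples = pd.DataFrame({
        "sample_id": fam["iid"],
        "population": fam["fid"],
        "sex": pd.to_numeric(fam["sex"], errors="coerce").fillna(0).astype(int),
    })
    markers, calls = _sort_markers(markers, calls)
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


# ---------------------------------------------------------------------------
# writing (deterministic byte-for-byte given a dataset)
# ---------------------------------------------------------------------------

def write_plink(ds: GenotypeDataset, prefix, format: str = "text") -> None:
    """Write a dataset as PLINK text (.ped/.map) or binary (.bed/.bim/.fam)."""
    prefix = str(prefix)
    if format == "text":
        _write_plink_text(ds, prefix)
    elif format == "binary":
        _write_plink_binary(ds, prefix)
    else:
        raise ValueError(f"unknown format {format!r}")


def _map_lines(ds: GenotypeDataset, with_alleles: bool) -> list[str]:
    lines = []
    for row in ds.markers.itertuples(index=False):
        base = f"{row.chrom}\t{row.id}\t0\t{row.pos_bp}"
        if with_alleles:
            base += f"\t{row.a1}\t{row.a2}"
        lines.append(base + "\n")
    return lines


def _write_plink_text(ds: GenotypeDataset, prefix: str) -> None:
    # .map written with the two allele columns appended (accepted on read
    # alongside the standard 4-column dialect) so the counting allele — and
    # therefore the call coding — survives a text round trip bit-exactly
    with open(prefix + ".map", "w") as fh:
        fh.writelines(_map_lines(ds, with_alleles=True))
    a1 = ds.markers["a1"].to_numpy(dtype=object)
    a2 = ds.markers["a2"].to_numpy(dtype=object)
    # A1 count -> allele pair strings; A1 '0' (monomorphic) writes a2/a2
    with open(prefix + ".ped", "w") as fh:
        for i, s in enumerate(ds.samples.itertuples(index=False)):
            fields = [s.population, s.sample_id, "0", "0", str(s.sex), "-9"]
            g = ds.calls[i]
            for j in range(ds.n_markers):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                elif g[j] == 2:
                    fields += [a1[j], a1[j]]
                elif g[j] == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def _write_plink_binary(ds: GenotypeDataset, prefix: str) -> None:
    with open(prefix + ".bim", "w") as fh:
        fh.writelines(_map_lines(ds, with_alleles=True))
    with open(prefix + ".fam", "w") as fh:
        for s in ds.samples.itertuples(index=False):
            fh.write(f"{s.population} {s.sample_id} 0 0 {s.sex} -9\n")
    n = ds.n_samples
    bytes_per_snp = (n + 3) // 4
    out = bytearray(_BED_MAGIC)
    code_lut = np.zeros(4, dtype=np.uint8)
    for count, code in _BED_ENCODE.items():
        code_lut[count] = code  # MISSING==-1 indexes the last slot
    for j in range(ds.n_markers):
        codes = code_lut[ds.calls[:, j]]
        packed = np.zeros(bytes_per_snp, dtype=np.uint8)
        for shift in range(4):
            chunk = codes[shift::4]
            packed[: chunk.size] |= chunk << (2 * shift)
        out += packed.tobytes()
    Path(prefix + ".bed").write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_snp_qc(ds: GenotypeDataset, max_snp_missing: float = 0.10,
                 gencall_min: float = 0.7, gentrain_min: float = 0.4,
                 scores: pd.DataFrame | None = None,
                 ) -> tuple[GenotypeDataset, QcReport]:
    """Remove non-autosomal/unmapped markers, high-missingness markers, and
    (when a score table is supplied) markers failing Illumina clustering
    quality: GenCall <= 0.7 or GenTrain <= 0.4.

    ``scores`` is a DataFrame with columns ``id`` and any of
    ``gencall``/``gentrain``.
    """
    for thr in (max_snp_missing, gencall_min, gentrain_min):
        if not 0 <= thr <= 1:
            raise ValueError(f"threshold {thr} outside [0, 1]")
    removed: dict[str, str] = {}
    ids = ds.markers["id"].to_numpy()
    chrom = ds.markers["chrom"].to_numpy()
    autosomal = (chrom >= 1) & (chrom <= 18)
    pos_ok = ds.markers["pos_bp"].to_numpy() > 0
    for i in np.flatnonzero(~autosomal):
        removed[ids[i]] = "non-autosomal"
    for i in np.flatnonzero(autosomal & ~pos_ok):
        removed[ids[i]] = "unmapped"
    miss = ds.missing_rate_per_snp()
    for i in np.flatnonzero(autosomal & pos_ok & (miss > max_snp_missing)):
        removed[ids[i]] = "missingness"
    notes = []
    if scores is not None:
        stab = scores.set_index("id")
        for col, thr, reason in (("gencall", gencall_min, "gencall"),
                                 ("gentrain", gentrain_min, "gentrain")):
            if col not in stab.columns:
                continue
            vals = stab[col].reindex(ids)
            bad = (vals <= thr).to_numpy(dtype=bool)
            for i in np.flatnonzero(bad):
                removed.setdefault(ids[i], reason)
    else:
        notes.append("no GenCall/GenTrain score table supplied; "
                     "score filters not applied")
    keep = np.flatnonzero(~np.isin(ids, list(removed)))
    if keep.size == 0:
        raise EmptyPanelError("SNP QC removed every marker")
    report = QcReport(n_snps_in=ds.n_markers, n_snps_out=keep.size,
                      n_samples_in=ds.n_samples, n_samples_out=ds.n_samples,
                      removed_snps=removed, notes=notes)
    return ds.subset_markers(keep), report


def apply_sample_qc(ds: GenotypeDataset, max_sample_missing: float = 0.05,
                    ) -> tuple[GenotypeDataset, QcReport]:
    """Remove samples with a missing-call fraction strictly above threshold."""
    if not 0 <= max_sample_missing <= 1:
        raise ValueError(f"threshold {max_sample_missing} outside [0, 1]")
    miss = ds.missing_rate_per_sample()
    bad = np.flatnonzero(miss > max_sample_missing)
    removed = {ds.samples["sample_id"].iloc[i]: "missingness" for i in bad}
    keep = np.flatnonzero(miss <= max_sample_missing)
    notes = []
    survivors = ds.samples["population"].iloc[keep]
    for pop in ds.samples["population"].unique():
        if pop not in set(survivors):
            notes.append(f"population {pop} lost all members in sample QC")
    report = QcReport(n_snps_in=ds.n_markers, n_snps_out=ds.n_markers,
                      n_samples_in=ds.n_samples, n_samples_out=keep.size,
                      removed_samples=removed, notes=notes)
    return ds.subset_samples(keep), report


def apply_qc(ds: GenotypeDataset, max_snp_missing: float = 0.10,
             max_sample_missing: float = 0.05,
             gencall_min: float = 0.7, gentrain_min: float = 0.4,
             scores: pd.DataFrame | None = None,
             ) -> tuple[GenotypeDataset, list[QcReport]]:
    """Full QC pass in fixed order: autosome/score/missingness SNP filter,
    sample filter, then one SNP-missingness re-check (idempotent)."""
    ds1, rep1 = apply_snp_qc(ds, max_snp_missing, gencall_min, gentrain_min, scores)
    ds2, rep2 = apply_sample_qc(ds1, max_sample_missing)
    ds3, rep3 = apply_snp_qc(ds2, max_snp_missing, gencall_min, gentrain_min, scores)
    return ds3, [rep1, rep2, rep3]


# ---------------------------------------------------------------------------
# merging and thinning
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def intersect_merge(a: GenotypeDataset, b: GenotypeDataset) -> GenotypeDataset:
    """Merge two QC'd panels on their shared marker ids (samples = union).

    Allele codings are harmonized onto panel *a*'s pair, resolving strand
    flips for unambiguous pairs by complementing; A/T and C/G markers whose
    codings disagree cannot be resolved and are dropped with a warning.
    """
    dup = set(a.samples["sample_id"]) & set(b.samples["sample_id"])
    if dup:
        raise ValueError(f"sample ids present in both panels: {sorted(dup)[:5]}")
    shared = a.markers.merge(b.markers, on="id", suffixes=("_a", "_b"))
    if shared.empty:
        raise EmptyPanelError("no shared marker ids between panels")
    bad = (shared["chrom_a"] != shared["chrom_b"]) | \
          (shared["pos_bp_a"] != shared["pos_bp_b"])
    if bad.any():
        raise PlinkFormatError(
            "inconsistent (chrom,pos) for shared markers: "
            f"{shared.loc[bad, 'id'].tolist()[:5]}")

    a_idx = {mid: i for i, mid in enumerate(a.markers["id"])}
    b_idx = {mid: i for i, mid in enumerate(b.markers["id"])}

    def _count_flip(a1_a: str, b1: str, b2: str) -> bool:
        # b's calls count b1 copies (b1 == "0" means monomorphic, all calls 0,
        # i.e. homozygous b2).  Flip whenever b is effectively counting the
        # allele opposite a's counting allele.
        if b1 == "0":
            return b2 == a1_a
        return b1 != a1_a

    keep_ids, flip, drop = [], [], []
    for row in shared.itertuples(index=False):
        pa = {row.a1_a, row.a2_a} - {"0"}
        pb = {row.a1_b, row.a2_b} - {"0"}
        pb_flipped = {_COMPLEMENT.get(x, x) for x in pb}
        if _is_ambiguous(row.a1_a, row.a2_a):
            # strand orientation undecidable from the allele pair alone:
            # keep only when the codings already agree verbatim
            if pb == pa and row.a1_b == row.a1_a:
                keep_ids.append(row.id)
                flip.append(False)
            else:
                drop.append(row.id)
        elif pb <= pa:
            keep_ids.append(row.id)
            flip.append(_count_flip(row.a1_a, row.a1_b, row.a2_b))
        elif pb_flipped <= pa:
            b1 = _COMPLEMENT.get(row.a1_b, row.a1_b) if row.a1_b != "0" else "0"
            b2 = _COMPLEMENT.get(row.a2_b, row.a2_b)
            keep_ids.append(row.id)
            flip.append(_count_flip(row.a1_a, b1, b2))
        else:
            drop.append(row.id)
    if drop:
        warnings.warn(f"dropped {len(drop)} markers with irreconcilable "
                      f"alleles: {drop[:5]}")
    if not keep_ids:
        raise EmptyPanelError("no reconcilable shared markers between panels")

    cols_a = np.array([a_idx[m] for m in keep_ids])
    cols_b = np.array([b_idx[m] for m in keep_ids])
    calls_a = a.calls[:, cols_a]
    calls_b = b.calls[:, cols_b].copy()
    flip = np.asarray(flip)
    if flip.any():
        sub = calls_b[:, flip]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        calls_b[:, flip] = sub
    markers = a.markers.iloc[cols_a].reset_index(drop=True)
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    calls = np.vstack([calls_a, calls_b])
    markers, calls = _sort_markers(markers, calls)
    return GenotypeDataset(markers=markers, samples=samples, calls=calls)


def thin_snps(ds: GenotypeDataset, target_n: int = 15000,
              seed: int = 0) -> GenotypeDataset:
    """Uniform random subsample of markers without replacement, map order kept."""
    if target_n > ds.n_markers:
        raise ValueError(
            f"target_n={target_n} exceeds panel size {ds.n_markers}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(ds.n_markers, size=target_n, replace=False))
    return ds.subset_markers(keep)
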