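"""PLINK I/O, QC rules, merging and thinning."""

import numpy as np
import pandas as pd
import pytest

from pigpopgen import genotype_io as gio
from pigpopgen.genotype_io import (MISSING, EmptyPanelError, PlinkFormatError,
                                   apply_qc, apply_sample_qc, apply_snp_qc,
                                   intersect_merge, read_plink, thin_snps,
                                   write_plink)

from conftest import make_dataset


def _write_text_fixture(tmp_path):
    """Two samples, three SNPs, hand-decodable.

    A1 is inferred as the minor allele (alphabetical tie-break):
      snp1: GG / AA  -> A1=A (tie, alphabetical) -> calls 0, 2
      snp2: AG / GG  -> A1=A                      -> calls 1, 0
      snp3: AA / AG  -> A1=G (A is major 3/4)     -> calls 0, 1
    """
    (tmp_path / "toy.map").write_text(
        "1\tsnp1\t0\t1000\n1\tsnp2\t0\t2000\n1\tsnp3\t0\t3000\n")
    (tmp_path / "toy.ped").write_text(
        "FAM1 s1 0 0 1 -9 G G A G A A\n"
        "FAM2 s2 0 0 2 -9 A A G G A G\n")
    return tmp_path / "toy"


def test_read_plink_text_hand_decoded(tmp_path):
    ds = read_plink(_write_text_fixture(tmp_path), format="text")
    assert np.array_equal(ds.calls, [[0, 1, 0], [2, 0, 1]])
    assert list(ds.samples["population"]) == ["FAM1", "FAM2"]
    assert list(ds.markers["id"]) == ["snp1", "snp2", "snp3"]


def test_read_plink_empty_map_is_error(tmp_path):
    (tmp_path / "e.map").write_text("")
    (tmp_path / "e.ped").write_text("F s 0 0 0 -9\n")
    with pytest.raises(PlinkFormatError):
        read_plink(tmp_path / "e", format="text")


def test_pop_table_overrides_family_id(tmp_path):
    prefix = _write_text_fixture(tmp_path)
    pt = tmp_path / "pops.tsv"
    pt.write_text("s1\tCROBS\ns2\tCROTS\n")
    ds = read_plink(prefix, format="text", pop_table=pt)
    assert list(ds.samples["population"]) == ["CROBS", "CROTS"]


@pytest.mark.parametrize("fmt", ["text", "binary"])
def test_round_trip_exact(tmp_path, fmt):
    rng = np.random.default_rng(7)
    calls = rng.integers(0, 3, size=(5, 40)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    ds = make_dataset(calls, populations=["P1"] * 2 + ["P2"] * 3)
    write_plink(ds, str(tmp_path / "rt"), format=fmt)
    back = read_plink(tmp_path / "rt", format=fmt)
    assert np.array_equal(back.calls, ds.calls)
    assert list(back.markers["id"]) == list(ds.markers["id"])
    assert list(back.samples["population"]) == list(ds.samples["population"])


def test_binary_and_text_encodings_agree(tmp_path):
    calls = np.array([[0, 1, 2, MISSING], [2, 2, 0, 1]], dtype=np.int8)
    ds = make_dataset(calls)
    write_plink(ds, str(tmp_path / "a"), format="text")
    write_plink(ds, str(tmp_path / "a"), format="binary")
    t = read_plink(tmp_path / "a", format="text")
    b = read_plink(tmp_path / "a", format="binary")
    assert np.array_equal(t.calls, b.calls)
    assert t.markers[["id", "chrom", "pos_bp"]].equals(
        b.markers[["id", "chrom", "pos_bp"]])


class TestSnpQc:
    def test_missingness_above_threshold_removed(self):
        calls = np.ones((10, 2), dtype=np.int8)
        calls[:2, 0] = MISSING          # 20% missing at snp1
        ds, report = apply_snp_qc(make_dataset(calls))
        assert report.removed_snps == {"snp1": "missingness"}
        assert ds.n_markers == 1

    def test_gencall_boundary_is_inclusive(self):
        ds0 = make_dataset(np.ones((4, 3), dtype=np.int8))
        scores = pd.DataFrame({"id": ["snp1", "snp2", "snp3"],
                               "gencall": [0.7, 0.71, 0.9],
                               "gentrain": [0.9, 0.4, 0.41]})
        ds, report = apply_snp_qc(ds0, scores=scores)
        # gencall <= 0.7 and gentrain <= 0.4 both fail
        assert report.removed_snps == {"snp1": "gencall", "snp2": "gentrain"}
        assert list(ds.markers["id"]) == ["snp3"]

    def test_without_scores_only_missingness_applies(self):
        ds0 = make_dataset(np.ones((4, 2), dtype=np.int8))
        ds, report = apply_snp_qc(ds0)
        assert ds.n_markers == 2
        assert any("score" in n for n in report.notes)

    def test_non_autosomal_and_unmapped_removed(self):
        ds0 = make_dataset(np.ones((3, 3), dtype=np.int8),
                           chroms=[1, 19, 2], positions=[100, 200, 0])
        ds, report = apply_snp_qc(ds0)
        assert report.removed_snps == {"snp2": "non-autosomal",
                                       "snp3": "unmapped"}

    def test_all_snps_removed_is_error(self):
        calls = np.full((4, 2), MISSING, dtype=np.int8)
        with pytest.raises(EmptyPanelError):
            apply_snp_qc(make_dataset(calls))


class TestSampleQc:
    def test_boundary_exactly_five_percent_retained(self):
        calls = np.ones((2, 100), dtype=np.int8)
        calls[0, :5] = MISSING          # exactly 5%: kept
        calls[1, :6] = MISSING          # 6%: removed
        ds, report = apply_sample_qc(make_dataset(calls))
        assert list(ds.samples["sample_id"]) == ["ind1"]
        assert report.removed_samples == {"ind2": "missingness"}

    def test_fully_typed_dataset_unchanged(self):
        ds0 = make_dataset(np.ones((3, 10), dtype=np.int8))
        ds, report = apply_sample_qc(ds0)
        assert ds.n_samples == 3 and not report.removed_samples

    def test_population_loss_warns_in_report(self):
        calls = np.ones((2, 10), dtype=np.int8)
        calls[1, :] = MISSING
        ds, report = apply_sample_qc(
            make_dataset(calls, populations=["A", "B"]))
        assert any("B" in n for n in report.notes)


def test_qc_is_idempotent():
    rng = np.random.default_rng(3)
    calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.08] = MISSING
    ds1, _ = apply_qc(make_dataset(calls))
    ds2, _ = apply_qc(ds1)
    assert np.array_equal(ds1.calls, ds2.calls)
    assert list(ds1.markers["id"]) == list(ds2.markers["id"])


class TestIntersectMerge:
    def _panel(self, ids, calls, a1="A", a2="G", sample_prefix="x"):
        # position markers by their id number so shared ids agree on pos
        ds = make_dataset(np.asarray(calls, dtype=np.int8),
                          positions=[100_000 * int(i[1:]) for i in ids],
                          alleles=(a1, a2))
        ds.markers["id"] = ids
        ds.samples["sample_id"] = [f"{sample_prefix}{i}"
                                   for i in range(ds.n_samples)]
        return ds

    def test_shared_marker_intersection(self):
        a = self._panel(["m1", "m2", "m3"], [[0, 1, 2]], sample_prefix="a")
        b = self._panel(["m2", "m3", "m4"], [[1, 2, 0]], sample_prefix="b")
        merged = intersect_merge(a, b)
        assert sorted(merged.markers["id"]) == ["m2", "m3"]
        assert merged.n_samples == 2

    def test_strand_flip_complemented(self):
        # same variant typed A/G in panel a and T/C (opposite strand) in b;
        # b counts T which maps to A: counts agree after complementing bases
        a = self._panel(["m1"], [[2], [1]], a1="A", a2="G",
                        sample_prefix="a")
        b = self._panel(["m1"], [[2], [0]], a1="T", a2="C",
                        sample_prefix="b")
        merged = intersect_merge(a, b)
        assert np.array_equal(merged.calls.ravel(), [2, 1, 2, 0])

    def test_strand_flip_with_swapped_counting_allele(self):
        # b typed C/T counting C (= complement of G, a's non-counted allele):
        # b's counts must be inverted
        a = self._panel(["m1"], [[2], [1]], a1="A", a2="G",
                        sample_prefix="a")
        b = self._panel(["m1"], [[2], [0]], a1="C", a2="T",
                        sample_prefix="b")
        merged = intersect_merge(a, b)
        assert np.array_equal(merged.calls.ravel(), [2, 1, 0, 2])

    def test_disjoint_markers_is_error(self):
        a = self._panel(["m1"], [[0]], sample_prefix="a")
        b = self._panel(["m9"], [[0]], sample_prefix="b")
        with pytest.raises(EmptyPanelError):
            intersect_merge(a, b)

    def test_duplicate_sample_id_is_error(self):
        a = self._panel(["m1"], [[0]])
        b = self._panel(["m1"], [[0]])
        with pytest.raises(ValueError, match="sample ids"):
            intersect_merge(a, b)

    def test_marker_content_symmetric(self):
        a = self._panel(["m1", "m2"], [[0, 1]], sample_prefix="a")
        b = self._panel(["m2", "m3"], [[1, 2]], sample_prefix="b")
        ab = intersect_merge(a, b)
        ba = intersect_merge(b, a)
        assert set(ab.markers["id"]) == set(ba.markers["id"])


class TestThinning:
    def test_same_seed_same_subset(self):
        ds = make_dataset(np.zeros((2, 100), dtype=np.int8))
        t1 = thin_snps(ds, 30, seed=5)
        t2 = thin_snps(ds, 30, seed=5)
        assert list(t1.markers["id"]) == list(t2.markers["id"])

    def test_identity_at_full_size_and_order_preserved(self):
        ds = make_dataset(np.zeros((2, 50), dtype=np.int8))
        t = thin_snps(ds, 50, seed=0)
        assert list(t.markers["id"]) == list(ds.markers["id"])
        t2 = thin_snps(ds, 20, seed=1)
        pos = t2.markers["pos_bp"].to_numpy()
        assert (np.diff(pos) > 0).all()

    def test_oversized_target_is_error(self):
        ds = make_dataset(np.zeros((2, 10), dtype=np.int8))
        with pytest.raises(ValueError):
            thin_snps(ds, 11, seed=0)
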