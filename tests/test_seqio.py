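import numpy as np
import pytest

from antiangio import (Dataset, Peptide, clean, make_splits, read_fasta,
                       read_manifest, redundancy_filter, truncate_nt,
                       write_fasta, write_manifest)
from antiangio.seqio import (FastaParseError, NEGATIVE, POSITIVE,
                             ValidationError, derive_round_seed, load_splits,
                             pairwise_identity, save_splits)


def write(tmp_path, text, name="in.fasta"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadFasta:
    def test_single_record(self, tmp_path):
        ds = read_fasta(write(tmp_path, ">p1\nACDE\n"))
        assert len(ds) == 1
        assert ds.peptides[0].id == "p1"
        assert ds.peptides[0].sequence == "ACDE"

    def test_multiline_and_header_token(self, tmp_path):
        ds = read_fasta(write(tmp_path, ">p1 some description\nACDE\nFGHI\n"))
        assert ds.peptides[0].id == "p1"
        assert ds.peptides[0].sequence == "ACDEFGHI"

    def test_lowercase_upper_cased(self, tmp_path):
        ds = read_fasta(write(tmp_path, ">p1\nacde\n"))
        assert ds.peptides[0].sequence == "ACDE"

    def test_empty_file_gives_empty_dataset(self, tmp_path, caplog):
        ds = read_fasta(write(tmp_path, ""))
        assert len(ds) == 0

    def test_nonstandard_residue_named_in_error(self, tmp_path):
        with pytest.raises(ValidationError, match="'X'"):
            read_fasta(write(tmp_path, ">p2\nACXU\n"))

    def test_malformed_reports_line_number(self, tmp_path):
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(write(tmp_path, "ACDE\n>p1\nACDE\n"))

    def test_duplicate_ids_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="duplicate"):
            read_fasta(write(tmp_path, ">p1\nACDE\n>p1\nFGHI\n"))

    def test_label_attached(self, tmp_path):
        ds = read_fasta(write(tmp_path, ">p1\nACDE\n"), label=POSITIVE)
        assert ds.peptides[0].label == POSITIVE


def test_fasta_roundtrip(tmp_path):
    ds = Dataset([Peptide("a", "ACDEFGHIKL"), Peptide("b", "WWYY")])
    out = tmp_path / "out.fasta"
    write_fasta(ds, out)
    back = read_fasta(out)
    assert [p.sequence for p in back] == [p.sequence for p in ds]


def test_manifest_roundtrip(tmp_path):
    ds = Dataset([Peptide("a", "ACDE", POSITIVE), Peptide("b", "WWYY", NEGATIVE)])
    out = tmp_path / "m.csv"
    write_manifest(ds, out)
    back = read_manifest(out)
    assert [(p.id, p.sequence, p.label) for p in back] == \
        [(p.id, p.sequence, p.label) for p in ds]


class TestClean:
    def test_drops_nonstandard(self, tmp_path):
        ds = read_fasta(write(tmp_path, ">a\nACDE\n>b\nACXU\n"), strict=False)
        out = clean(ds)
        assert out.ids == ["a"]

    def test_identity_on_valid_set(self):
        ds = Dataset([Peptide("a", "ACDE"), Peptide("b", "WWYY")])
        assert clean(ds).ids == ds.ids

    def test_all_invalid_gives_empty(self, tmp_path):
        ds = read_fasta(write(tmp_path, ">a\nXXXX\n>b\nAUBZ\n"), strict=False)
        assert len(clean(ds)) == 0

    def test_strict_flag_raises(self, tmp_path):
        ds = read_fasta(write(tmp_path, ">a\nACXE\n"), strict=False)
        with pytest.raises(ValidationError, match="'X'"):
            clean(ds, drop_nonstandard=False)

    def test_idempotent(self, tmp_path):
        ds = read_fasta(write(tmp_path, ">a\nACDE\n>b\nACXU\n"), strict=False)
        once = clean(ds)
        assert clean(once).ids == once.ids


class TestRedundancyFilter:
    def test_borderline_identity_retained(self):
        # 9 of 10 matching positions: identity exactly 0.90, not > threshold
        ds = Dataset([Peptide("a", "ACDEFGHIKL"), Peptide("b", "ACDEFGHIKV")])
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKV") == pytest.approx(0.9)
        assert len(redundancy_filter(ds, 0.90)) == 2

    def test_identical_duplicates_collapse(self):
        ds = Dataset([Peptide("a", "ACDEFGHIKL"), Peptide("b", "ACDEFGHIKL")])
        assert len(redundancy_filter(ds, 0.90)) == 1

    def test_threshold_one_keeps_distinct(self):
        ds = Dataset([Peptide("a", "ACDEFGHIKL"), Peptide("b", "ACDEFGHIKV"),
                      Peptide("c", "WWWWWWWWWW")])
        assert len(redundancy_filter(ds, 1.0)) == 3

    def test_longest_first_representative(self):
        # the longer sequence is kept as representative of the cluster
        ds = Dataset([Peptide("short", "ACDEFGHIK"), Peptide("long", "ACDEFGHIKL")])
        out = redundancy_filter(ds, 0.90)
        assert out.ids == ["long"]

    def test_never_grows_and_deterministic(self, benchmark_like):
        out1 = redundancy_filter(benchmark_like, 0.5)
        out2 = redundancy_filter(benchmark_like, 0.5)
        assert len(out1) <= len(benchmark_like)
        assert out1.ids == out2.ids


class TestTruncate:
    def test_cuts_to_first_15(self):
        ds = Dataset([Peptide("a", "ACDEFGHIKLMNPQRSTVWY")])
        out = truncate_nt(ds, 15)
        assert out.peptides[0].sequence == "ACDEFGHIKLMNPQR"

    def test_short_sequences_unchanged(self):
        ds = Dataset([Peptide("a", "ACDEFGHI")])
        assert truncate_nt(ds, 15).peptides[0].sequence == "ACDEFGHI"

    def test_idempotent(self):
        ds = Dataset([Peptide("a", "ACDEFGHIKLMNPQRSTVWY")])
        once = truncate_nt(ds, 15)
        twice = truncate_nt(once, 15)
        assert [p.sequence for p in twice] == [p.sequence for p in once]

    def test_single_residue(self):
        ds = Dataset([Peptide("a", "ACDE")])
        assert truncate_nt(ds, 1).peptides[0].sequence == "A"


class TestSplits:
    @staticmethod
    def _dataset(n_pos, n_neg):
        peps = [Peptide(f"p{i}", "ACDEFGHIKL", POSITIVE) for i in range(n_pos)]
        peps += [Peptide(f"n{i}", "ACDEFGHIKL", NEGATIVE) for i in range(n_neg)]
        return Dataset(peps)

    def test_exact_stratification(self):
        plans = make_splits(self._dataset(100, 100), rounds=1, train_fraction=0.8,
                            seed=1)
        train = plans[0].train_ids
        assert sum(i.startswith("p") for i in train) == 80
        assert sum(i.startswith("n") for i in train) == 80

    def test_partition_property(self):
        ds = self._dataset(51, 43)
        for plan in make_splits(ds, rounds=5, seed=2):
            train, test = set(plan.train_ids), set(plan.test_ids)
            assert not train & test
            assert train | test == set(ds.ids)

    def test_determinism(self):
        ds = self._dataset(30, 30)
        a = make_splits(ds, rounds=10, seed=9)
        b = make_splits(ds, rounds=10, seed=9)
        assert [p.train_ids for p in a] == [p.train_ids for p in b]

    def test_floor_rule_on_137(self):
        plans = make_splits(self._dataset(137, 137), rounds=1, train_fraction=0.8,
                            seed=0)
        train = plans[0].train_ids
        assert sum(i.startswith("p") for i in train) == 109  # floor(0.8*137)
        assert sum(i.startswith("n") for i in train) == 109

    def test_tiny_class_rejected(self):
        with pytest.raises(ValidationError):
            make_splits(self._dataset(1, 10), rounds=1, seed=0)

    def test_round_reproducible_in_isolation(self):
        ds = self._dataset(30, 30)
        plans = make_splits(ds, rounds=10, seed=5)
        assert plans[6].seed == derive_round_seed(5, 7)
        # regenerating only round 7 yields the identical plan
        solo = make_splits(ds, rounds=7, seed=5)[6]
        assert solo.train_ids == plans[6].train_ids

    def test_json_roundtrip(self, tmp_path):
        plans = make_splits(self._dataset(20, 20), rounds=3, seed=4)
        path = tmp_path / "splits.json"
        save_splits(plans, path)
        assert [p.train_ids for p in load_splits(path)] == \
            [p.train_ids for p in plans]


def test_unlabeled_dataset_rejected_for_training_use():
    ds = Dataset([Peptide("a", "ACDE", POSITIVE), Peptide("b", "WWYY")])
    with pytest.raises(ValidationError):
        ds.require_labels()
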