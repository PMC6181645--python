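import numpy as np
import pandas as pd
import pytest

from tead.library import TELibrary, TERecord
from tead.quant import (
    KmerIndex,
    QuantParams,
    assign_read,
    build_index,
    compute_tpm,
    em_quantify,
    quantify_reads,
    quantify_sample,
)
from tead.simulate import SimulationConfig, simulate_library, simulate_reads, write_fastq
from tests.conftest import random_sequence
from tests.helpers import brute_em, random_em_instance


def canonical(kmer: str) -> str:
    rc = kmer[::-1].translate(str.maketrans("ACGT", "TGCA"))
    return min(kmer, rc)


def brute_force_kmer_sets(lib: TELibrary, k: int) -> dict[str, set[str]]:
    """Exhaustive substring scan: canonical k-mer -> te_ids containing it."""
    out: dict[str, set[str]] = {}
    for rec in lib:
        for i in range(len(rec.sequence) - k + 1):
            kmer = rec.sequence[i : i + k]
            if "N" in kmer:
                continue
            out.setdefault(canonical(kmer), set()).add(rec.te_id)
    return out


class TestBuildIndex:
    def test_repeat_free_sequence_counts(self, rng):
        seq = random_sequence(rng, 20)
        lib = TELibrary([TERecord("A", seq, "non-LTR", "L1")])
        idx = build_index(lib, k=11)
        expected = brute_force_kmer_sets(lib, 11)
        assert len(idx) == len(expected)  # = 10 for a repeat-free sequence
        if len(set(seq[i : i + 11] for i in range(10))) == 10:
            assert len(idx) == 10

    def test_identical_sequences_share_every_kmer(self, rng):
        seq = random_sequence(rng, 60)
        lib = TELibrary(
            [
                TERecord("A", seq, "non-LTR", "L1"),
                TERecord("B", seq, "non-LTR", "L1"),
            ]
        )
        idx = build_index(lib, k=21)
        for arr in idx.lookup.values():
            assert set(arr) == {0, 1}

    def test_matches_bruteforce_substring_oracle(self, rng):
        lib = TELibrary(
            [
                TERecord("A", random_sequence(rng, 120), "non-LTR", "L1"),
                TERecord("B", random_sequence(rng, 90), "LTR", "ERV1"),
                TERecord("C", random_sequence(rng, 200), "LTR", "Gypsy"),
            ]
        )
        idx = build_index(lib, k=13)
        expected = brute_force_kmer_sets(lib, 13)
        assert len(idx) == len(expected)
        for kmer, ids in expected.items():
            assert idx.te_ids_for_kmer(kmer) == ids

    def test_n_kmers_skipped(self):
        lib = TELibrary([TERecord("A", "ACGTACGTACGNACGTACGTACGT", "non-LTR", "L1")])
        idx = build_index(lib, k=11)
        expected = brute_force_kmer_sets(lib, 11)
        assert len(idx) == len(expected)

    @pytest.mark.parametrize("k", [10, 12, 9])
    def test_k_must_be_odd_and_at_least_11(self, k, small_library):
        with pytest.raises(ValueError):
            build_index(small_library, k=k)

    def test_k_longer_than_all_sequences_errors(self, rng):
        lib = TELibrary([TERecord("A", random_sequence(rng, 15), "non-LTR", "L1")])
        with pytest.raises(ValueError, match="no library sequence"):
            build_index(lib, k=21)


class TestAssignRead:
    def test_unique_read_assigns_to_origin(self, small_library):
        idx = build_index(small_library, k=21)
        read = small_library["L1HS"].sequence[50:150]
        assert assign_read(read, idx) == {"L1HS"}

    def test_shared_region_assigns_to_both(self, rng):
        shared = random_sequence(rng, 150)
        lib = TELibrary(
            [
                TERecord("A", shared + random_sequence(rng, 100), "LTR", "ERV1"),
                TERecord("B", shared + random_sequence(rng, 100), "LTR", "ERV1"),
            ]
        )
        idx = build_index(lib, k=21)
        assert assign_read(shared[10:110], idx) == {"A", "B"}

    def test_read_shorter_than_k_unassigned(self, small_library):
        idx = build_index(small_library, k=21)
        assert assign_read("ACGTACGT", idx) == frozenset()

    def test_foreign_read_unassigned(self, small_library, rng):
        idx = build_index(small_library, k=21)
        assert assign_read(random_sequence(rng, 100), idx) == frozenset()

    def test_reverse_complement_read_assigned(self, small_library):
        read = small_library["HERVK"].sequence[100:200]
        rc = read[::-1].translate(str.maketrans("ACGT", "TGCA"))
        idx = build_index(small_library, k=21)
        assert assign_read(rc, idx) == {"HERVK"}

    def test_matches_membership_oracle_on_errorfree_reads(self, rng):
        """Error-free reads vs exhaustive substring-membership oracle.

        Library built so that TEs either contain whole reads or share no
        k-mer: an identical pair plus an unrelated third element.
        """
        seq = random_sequence(rng, 400)
        lib = TELibrary(
            [
                TERecord("A", seq, "LTR", "ERV1"),
                TERecord("B", seq, "LTR", "ERV1"),
                TERecord("C", random_sequence(rng, 400), "non-LTR", "L1"),
            ]
        )
        idx = build_index(lib, k=21)
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(1000):
            rec = lib.records[rng.integers(0, 3)]
            start = rng.integers(0, len(rec) - 100 + 1)
            read = rec.sequence[start : start + 100]
            if rng.random() < 0.5:
                read = read[::-1].translate(comp)
            oracle = {
                r.te_id
                for r in lib
                if read in r.sequence
                or read[::-1].translate(comp) in r.sequence
            }
            assert assign_read(read, idx) == oracle


class TestEmQuantify:
    def _index(self, lengths: dict[str, int]) -> KmerIndex:
        return KmerIndex(k=21, te_ids=list(lengths), te_lengths=lengths, lookup={})

    def test_unique_reads_pull_ambiguous_mass(self):
        """10 unique-to-A + 10 ambiguous reads contract to (A=20, B=0)."""
        idx = self._index({"A": 500, "B": 500})
        sets = [frozenset({"A"})] * 10 + [frozenset({"A", "B"})] * 10
        est = em_quantify(sets, idx, read_length=100)
        assert est.expected_count["A"] == pytest.approx(20.0, abs=1e-5)
        assert est.expected_count["B"] == pytest.approx(0.0, abs=1e-5)

    def test_pure_ambiguity_splits_evenly(self):
        idx = self._index({"A": 500, "B": 500})
        sets = [frozenset({"A", "B"})] * 10
        est = em_quantify(sets, idx, read_length=100)
        assert est.expected_count["A"] == pytest.approx(5.0, abs=1e-9)
        assert est.expected_count["B"] == pytest.approx(5.0, abs=1e-9)

    def test_matches_bruteforce_em_on_random_instances(self):
        """Vectorized EM vs plain-Python 10k-iteration EM on small cases."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            te_ids, lengths, sets = random_em_instance(rng)
            idx = self._index(lengths)
            est = em_quantify(sets, idx, read_length=100, tol=1e-12, max_iter=20000)
            oracle = brute_em(sets, te_ids, lengths, read_length=100)
            for t in te_ids:
                assert est.expected_count[t] == pytest.approx(oracle[t], abs=1e-6)

    def test_count_conservation(self):
        rng = np.random.default_rng(11)
        te_ids, lengths, sets = random_em_instance(rng)
        sets = sets + [frozenset()] * 5  # unassigned reads
        est = em_quantify(sets, self._index(lengths), read_length=100)
        n_assigned = sum(1 for s in sets if s)
        assert est.expected_count.sum() == pytest.approx(n_assigned, abs=1e-6)
        assert est.tpm.sum() == pytest.approx(1e6, abs=1e-3)
        assert est.diagnostics.n_assigned == n_assigned

    def test_loglik_nondecreasing_in_iterations(self):
        rng = np.random.default_rng(23)
        te_ids, lengths, sets = random_em_instance(rng)
        idx = self._index(lengths)
        logliks = [
            em_quantify(sets, idx, read_length=100, tol=1e-300, max_iter=i)
            .diagnostics.final_loglik
            for i in range(1, 12)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(logliks, logliks[1:]))

    def test_all_unassigned_warns_and_zeroes(self):
        idx = self._index({"A": 500})
        with pytest.warns(UserWarning, match="no reads assigned"):
            est = em_quantify([frozenset()] * 3, idx, read_length=100)
        assert (est.expected_count == 0).all()
        assert est.tpm.isna().all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        te_ids, lengths, sets = random_em_instance(rng)
        idx = self._index(lengths)
        a = em_quantify(sets, idx, read_length=100).expected_count
        b = em_quantify(sets[::-1], idx, read_length=100).expected_count
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestComputeTpm:
    def test_single_te(self):
        assert compute_tpm([7.0], [100.0])[0] == pytest.approx(1e6)

    def test_length_normalization(self):
        tpm = compute_tpm([10.0, 10.0], [100.0, 200.0])
        assert tpm[0] == pytest.approx(2e6 / 3)
        assert tpm[1] == pytest.approx(1e6 / 3)

    def test_sums_to_one_million(self, rng):
        tpm = compute_tpm(rng.random(50), rng.integers(50, 500, 50).astype(float))
        assert tpm.sum() == pytest.approx(1e6, abs=1e-3)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="all counts are zero"):
            compute_tpm([0.0, 0.0], [10.0, 10.0])


class TestQuantifySample:
    def test_parameter_recovery_without_sharing(self, tmp_path):
        """Dissimilar TEs at known TPM: estimates match truth closely."""
        cfg = SimulationConfig(
            seed=5,
            n_te=10,
            family_similarity=0.0,
            max_family_size=1,
            te_length_range=(400, 900),
            n_reads=20000,
            error_rate=0.0,
        )
        lib, _ = simulate_library(cfg)
        true_tpm = pd.Series(
            np.linspace(1, 10, 10) * 1e6 / np.linspace(1, 10, 10).sum(),
            index=lib.te_ids,
        )
        fq = tmp_path / "reads.fq"
        simulate_reads(lib, true_tpm, cfg, out_fastq=fq)
        est = quantify_sample(fq, lib, QuantParams(read_length=100))
        r = np.corrcoef(np.log1p(true_tpm), np.log1p(est.tpm))[0, 1]
        assert r > 0.99
        assert est.tpm.sum() == pytest.approx(1e6, abs=1e-3)
        assert est.expected_count.sum() == pytest.approx(
            est.diagnostics.n_assigned, abs=1e-6
        )

    def test_deterministic_rerun(self, tmp_path, small_library):
        fq = tmp_path / "r.fq"
        reads = [small_library["L1HS"].sequence[i : i + 80] for i in range(0, 200, 10)]
        write_fastq(reads, fq)
        a = quantify_sample(fq, small_library, QuantParams(read_length=80))
        b = quantify_sample(fq, small_library, QuantParams(read_length=80))
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_no_matching_reads_warns(self, tmp_path, small_library, rng):
        fq = tmp_path / "bad.fq"
        write_fastq([random_sequence(rng, 100) for _ in range(5)], fq)
        with pytest.warns(UserWarning):
            est = quantify_sample(fq, small_library)
        assert (est.expected_count == 0).all()

    def test_empty_fastq_errors(self, tmp_path, small_library):
        fq = tmp_path / "empty.fq"
        fq.write_text("")
        with pytest.raises(ValueError, match="empty FASTQ"):
            quantify_sample(fq, small_library)

    def test_gzip_fastq(self, tmp_path, small_library):
        import gzip

        reads = [small_library["AluY"].sequence[i : i + 60] for i in range(0, 100, 20)]
        fq = tmp_path / "r.fq.gz"
        with gzip.open(fq, "wt") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@r{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        est = quantify_sample(fq, small_library, QuantParams(read_length=60))
        assert est.expected_count["AluY"] == pytest.approx(5.0, abs=1e-6)
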