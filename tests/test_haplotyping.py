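import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haplogeo.io_model import AlignedSequenceSet, CodedMatrix
from haplogeo.haplotyping import (
    code_indels,
    collapse_haplotypes,
    count_polymorphic_sites,
    pairwise_step_distances,
)


def aligned(*seqs, segments=None):
    records = tuple((f"s{i}", s) for i, s in enumerate(seqs))
    if segments is None:
        segments = (("seg", 1, len(seqs[0])),)
    return AlignedSequenceSet(records, tuple(segments))


def plant_gaps(rng, n_seqs, length, runs):
    """Random alignment with the given shared gap runs, each carried by a
    random nonempty proper subset of sequences."""
    base = rng.choice(list("ACGT"), size=length)
    seqs = [list(base) for _ in range(n_seqs)]
    for start, run_len in runs:
        carriers = rng.choice(n_seqs, size=rng.integers(1, n_seqs), replace=False)
        for c in carriers:
            for p in range(start, start + run_len):
                seqs[c][p] = "-"
    return aligned(*("".join(s) for s in seqs))


class TestCodeIndels:
    def test_single_base_indel(self):
        coded = code_indels(aligned("AATG", "A-TG"))
        origins = [c.origin for c in coded.columns]
        assert origins == ["substitution", "indel_binary", "substitution", "substitution"]
        assert coded.row("s0") == ("A", "1", "T", "G")
        assert coded.row("s1") == ("A", "0", "T", "G")

    def test_multibase_run_collapses(self):
        coded = code_indels(aligned("AACCCGG", "AA---GG"))
        assert coded.n_characters == 5  # 7 - (3 - 1)
        j = [c.origin for c in coded.columns].index("indel_binary")
        assert coded.columns[j].source_span == (3, 5)
        assert coded.states[0, j] == "1" and coded.states[1, j] == "0"

    def test_staggered_runs_split_at_boundaries(self):
        # s0 gaps 2-4, s1 gaps 2-3: atomic sub-runs (2,3) and (4,4).
        coded = code_indels(aligned("A---G", "A--CG"))
        indels = [c for c in coded.columns if c.origin == "indel_binary"]
        assert [c.source_span for c in indels] == [(2, 3), (4, 4)]
        assert coded.row("s0") == ("A", "0", "0", "G")
        assert coded.row("s1") == ("A", "0", "1", "G")

    def test_reference_length_arithmetic(self, rng):
        # Alignment of length 1396 with shared indel runs of lengths
        # {1, 1, 5, 6, 7}: coded length 1396 - (4 + 5 + 6) = 1381.
        runs = [(100, 1), (300, 1), (500, 5), (800, 6), (1200, 7)]
        aln = plant_gaps(rng, 8, 1396, runs)
        coded = code_indels(aln)
        assert coded.n_characters == 1381
        assert coded.total_sites == 1381
        assert sum(c.origin == "indel_binary" for c in coded.columns) == 5

    def test_planted_runs_match_closed_form(self, rng):
        for _ in range(20):
            length = int(rng.integers(50, 120))
            starts = rng.choice(np.arange(0, length - 10, 12), size=3, replace=False)
            runs = [(int(s), int(rng.integers(1, 6))) for s in starts]
            coded = code_indels(plant_gaps(rng, 5, length, runs))
            expected = length - sum(l - 1 for _, l in runs if l > 1)
            assert coded.n_characters == expected

    def test_substitution_states_preserved(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        coded = code_indels(aligned(*seqs))
        assert all(c.origin == "substitution" for c in coded.columns)
        for i, s in enumerate(seqs):
            assert "".join(coded.states[i]) == s


class TestCollapseHaplotypes:
    def test_identical_rows(self):
        m = CodedMatrix([f"i{k}" for k in range(10)],
                        code_indels(aligned("ACGT")).columns,
                        np.array([list("ACGT")] * 10, dtype=object))
        reps, assign = collapse_haplotypes(m)
        assert reps.n_rows == 1
        assert set(assign.individual_to_haplotype.values()) == {"H1"}

    def test_duplicated_distinct_rows(self, rng):
        rows = []
        while len({tuple(r) for r in rows}) < 6:
            rows = [tuple(rng.choice(list("ACGT"), size=12)) for _ in range(6)]
        tripled = [r for r in rows for _ in range(3)]
        m = CodedMatrix(
            [f"i{k}" for k in range(18)],
            code_indels(aligned("".join(rows[0]))).columns,
            np.array(tripled, dtype=object),
        )
        reps, assign = collapse_haplotypes(m)
        assert reps.n_rows == 6
        assert sorted(assign.frequencies().values()) == [3] * 6

    def test_first_appearance_labelling(self):
        m = CodedMatrix(
            ["a", "b", "c"],
            code_indels(aligned("AC")).columns,
            np.array([["A", "C"], ["G", "C"], ["A", "C"]], dtype=object),
        )
        reps, assign = collapse_haplotypes(m)
        assert reps.haplotype_ids == ["H1", "H2"]
        assert assign.individual_to_haplotype == {"a": "H1", "b": "H2", "c": "H1"}

    def test_missing_rows_flagged_ambiguous(self):
        m = CodedMatrix(
            ["a", "b"],
            code_indels(aligned("AC")).columns,
            np.array([["A", "C"], ["A", "N"]], dtype=object),
        )
        reps, assign = collapse_haplotypes(m)
        assert assign.ambiguous == ("b",)
        assert "b" not in assign.individual_to_haplotype

    def test_fixture_reconstitution(self, individuals_matrix):
        reps, assign = collapse_haplotypes(individuals_matrix)
        assert reps.n_rows == 16
        assert len(assign.individual_to_haplotype) == 705

    def test_row_permutation_preserves_haplotype_set(self, individuals_matrix, rng):
        perm = rng.permutation(individuals_matrix.n_rows)
        shuffled = CodedMatrix(
            [individuals_matrix.haplotype_ids[i] for i in perm],
            individuals_matrix.columns,
            individuals_matrix.states[perm],
        )
        a = {tuple(r) for r in collapse_haplotypes(individuals_matrix)[0].states}
        b = {tuple(r) for r in collapse_haplotypes(shuffled)[0].states}
        assert a == b


class TestPolymorphicSites:
    def test_fixture(self, table2):
        assert count_polymorphic_sites(table2) == (23, 5)

    def test_identical_rows(self):
        m = CodedMatrix(["a", "b"], code_indels(aligned("ACGT")).columns,
                        np.array([list("ACGT")] * 2, dtype=object))
        assert count_polymorphic_sites(m).total == 0

    def test_single_row_zero(self):
        m = CodedMatrix(["a"], code_indels(aligned("ACGT")).columns,
                        np.array([list("ACGT")], dtype=object))
        assert count_polymorphic_sites(m).total == 0

    def test_planted_variable_columns(self, rng):
        states = np.array([list("A" * 50) for _ in range(4)], dtype=object)
        variable = rng.choice(50, size=7, replace=False)
        for j in variable:
            states[rng.integers(1, 4), j] = "G"
        m = CodedMatrix([f"h{k}" for k in range(4)],
                        code_indels(aligned("A" * 50)).columns, states)
        assert count_polymorphic_sites(m).total == 7


class TestStepDistances:
    @pytest.mark.parametrize("pair,expected", [
        (("H1", "H2"), 1), (("H1", "H1"), 0), (("H1", "H6"), 2), (("H1", "H7"), 12),
    ])
    def test_fixture_pairs(self, step_distances, pair, expected):
        assert step_distances[pair] == expected

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_loop_oracle(self, data):
        n = data.draw(st.integers(2, 6))
        m = data.draw(st.integers(1, 10))
        rows = [
            [data.draw(st.sampled_from("ACGTN")) for _ in range(m)] for _ in range(n)
        ]
        for j in range(m):  # constructor requires >=1 observed state per column
            if all(rows[i][j] == "N" for i in range(n)):
                rows[0][j] = "A"
        matrix = CodedMatrix(
            [f"h{k}" for k in range(n)],
            code_indels(aligned("A" * m)).columns,
            np.array(rows, dtype=object),
        )
        d = pairwise_step_distances(matrix)
        for i in range(n):
            for j in range(n):
                expected = sum(
                    1
                    for a, b in zip(rows[i], rows[j])
                    if a != "N" and b != "N" and a != b
                )
                assert d.values[i, j] == expected

    def test_triangle_inequality_on_fixture(self, step_distances):
        v = step_distances.values
        n = v.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9
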