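"""Indel coding, haplotype collapsing, polymorphic-site counts and
inter-haplotype step distances."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .io_model import (
    AlignedSequenceSet,
    CharacterColumn,
    CodedMatrix,
    DistanceMatrix,
    FormatError,
)

__all__ = [
    "CodingError",
    "HaplotypeAssignment",
    "PolymorphicSites",
    "code_indels",
    "collapse_haplotypes",
    "count_polymorphic_sites",
    "pairwise_step_distances",
]


class CodingError(ValueError):
    """Raised when gap runs cannot be coded consistently."""


@dataclass(frozen=True)
class HaplotypeAssignment:
    """Mapping of individuals to haplotypes plus representative rows.

    ``ambiguous`` lists individuals excluded from collapsing because their
    rows contain missing data (``N``).
    """

    individual_to_haplotype: Mapping[str, str]
    representatives: CodedMatrix
    ambiguous: tuple[str, ...] = ()

    def frequencies(self) -> dict[str, int]:
        out: dict[str, int] = {h: 0 for h in self.representatives.haplotype_ids}
        for h in self.individual_to_haplotype.values():
            out[h] += 1
        return out


class PolymorphicSites(NamedTuple):
    total: int
    indel_binary: int


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as 0-based half-open intervals."""
    runs = []
    start = None
    for i, c in enumerate(seq):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def code_indels(alignment: AlignedSequenceSet) -> CodedMatrix:
    """Binary-code gap runs and pass substitution columns through.

    Each maximal gap run shared across the sequences that carry it becomes
    one two-state column (``1`` = base(s) present, ``0`` = absent).  Runs
    with staggered boundaries are split at every distinct boundary so each
    resulting sub-run is one character; within a sub-run every sequence is
    then either fully gapped or fully present.  The coded length equals the
    alignment length minus ``sum(run_length - 1)`` over the atomic multi-base
    sub-runs.
    """
    seqs = [s for _, s in alignment.records]
    length = alignment.length

    boundaries: set[int] = set()
    gapped_cols = np.zeros(length, dtype=bool)
    for s in seqs:
        for a, b in _gap_runs(s):
            boundaries.add(a)
            boundaries.add(b)
            gapped_cols[a:b] = True

    # Atomic intervals: between consecutive boundaries, restricted to columns
    # that carry a gap in at least one sequence.
    cut = sorted(boundaries)
    atomic: list[tuple[int, int]] = []
    for a, b in zip(cut, cut[1:]):
        if gapped_cols[a:b].any():
            if not gapped_cols[a:b].all():
                raise CodingError(f"inconsistent gap span ({a + 1},{b})")
            atomic.append((a, b))

    columns: list[CharacterColumn] = []
    states: list[list[str]] = [[] for _ in seqs]
    atomic_iter = iter(atomic)
    next_atomic = next(atomic_iter, None)
    pos = 0
    coded_pos = 0
    while pos < length:
        if next_atomic is not None and pos == next_atomic[0]:
            a, b = next_atomic
            coded_pos += 1
            seg = alignment.segment_of(a + 1)
            columns.append(
                CharacterColumn("indel_binary", coded_pos, seg, source_span=(a + 1, b))
            )
            for i, s in enumerate(seqs):
                chunk = s[a:b]
                if set(chunk) == {"-"}:
                    states[i].append("0")
                elif "-" not in chunk:
                    states[i].append("1")
                else:  # pragma: no cover - excluded by the atomic split
                    raise CodingError(
                        f"sequence {alignment.records[i][0]!r} is partially "
                        f"gapped over span ({a + 1},{b})"
                    )
            pos = b
            next_atomic = next(atomic_iter, None)
        else:
            coded_pos += 1
            seg = alignment.segment_of(pos + 1)
            columns.append(
                CharacterColumn("substitution", coded_pos, seg, source_span=(pos + 1, pos + 1))
            )
            for i, s in enumerate(seqs):
                states[i].append(s[pos])
            pos += 1

    return CodedMatrix(
        alignment.identifiers,
        columns,
        np.array(states, dtype=object),
        total_sites=coded_pos,
    )


def collapse_haplotypes(
    matrix: CodedMatrix, *, label_prefix: str = "H"
) -> tuple[CodedMatrix, HaplotypeAssignment]:
    """Collapse identical coded rows into haplotypes.

    Haplotypes are labelled ``H1, H2, ...`` in first-appearance order of the
    input rows.  Rows containing missing states (``N``) cannot be collapsed
    unambiguously; they are excluded and reported via
    :attr:`HaplotypeAssignment.ambiguous`.
    """
    if matrix.n_rows < 1:
        raise FormatError("cannot collapse an empty matrix")
    seen: dict[tuple, str] = {}
    assignment: dict[str, str] = {}
    ambiguous: list[str] = []
    rep_rows: list[np.ndarray] = []
    rep_ids: list[str] = []
    for ident, row in zip(matrix.haplotype_ids, matrix.states):
        key = tuple(row)
        if "N" in key:
            ambiguous.append(ident)
            continue
        if key not in seen:
            label = f"{label_prefix}{len(seen) + 1}"
            seen[key] = label
            rep_ids.append(label)
            rep_rows.append(row)
        assignment[ident] = seen[key]
    if not rep_ids:
        raise FormatError("all rows are ambiguous (contain missing data)")
    reps = CodedMatrix(
        rep_ids,
        matrix.columns,
        np.array(rep_rows, dtype=object),
        rows_distinct=True,
        total_sites=matrix.total_sites,
    )
    return reps, HaplotypeAssignment(assignment, reps, tuple(ambiguous))


def count_polymorphic_sites(matrix: CodedMatrix) -> PolymorphicSites:
    """Number of columns with >= 2 observed (non-missing) states, together
    with the subcount contributed by binary indel columns."""
    total = 0
    indel = 0
    if matrix.n_rows < 2:
        return PolymorphicSites(0, 0)
    for j, col in enumerate(matrix.columns):
        observed = set(matrix.states[:, j]) - {"N"}
        if len(observed) >= 2:
            total += 1
            if col.origin == "indel_binary":
                indel += 1
    return PolymorphicSites(total, indel)


def pairwise_step_distances(matrix: CodedMatrix) -> DistanceMatrix:
    """Hamming distances (mutational steps) between coded rows.

    Missing states are handled by pairwise deletion: a column with ``N`` in
    either compared row is skipped for that pair.
    """
    n = matrix.n_rows
    states = matrix.states
    missing = states == "N"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(missing[i] | missing[j])
            d[i, j] = d[j, i] = np.sum(states[i, usable] != states[j, usable])
    return DistanceMatrix(matrix.haplotype_ids, d, units="steps")
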