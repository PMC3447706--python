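"""Net between-lineage sequence divergence and molecular-clock dating.

The net distance ``d_A = d_XY - (d_X + d_Y)/2`` removes the within-lineage
polymorphism contribution from the mean between-lineage distance, and the
divergence time follows ``T = d_A / (2 mu)`` under a strict clock.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_model import CodedMatrix, PopulationTable
from .haplotyping import pairwise_step_distances

__all__ = ["DatingResult", "net_between_group_distance", "divergence_time"]

#: Default substitution rate for non-coding plastid spacers/introns,
#: substitutions per site per year.
DEFAULT_MU = 1.01e-9


@dataclass(frozen=True)
class DatingResult:
    d_XY: float
    d_X: float
    d_Y: float
    d_A: float
    n_sites: int
    mu: float | None = None
    T_years: float | None = None

    @property
    def T_mya(self) -> float | None:
        return None if self.T_years is None else self.T_years / 1e6


def _pooled_counts(
    table: PopulationTable, codes: Sequence[str], hap_order: Sequence[str]
) -> np.ndarray:
    sub = table.subset(codes)
    return sub.counts_matrix(hap_order).sum(axis=0)


def net_between_group_distance(
    table: PopulationTable,
    matrix: CodedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_sites: int | None = None,
) -> DatingResult:
    """Frequency-weighted per-site mean pairwise distances between and
    within two disjoint groups of populations, and their net difference.

    ``d_XY`` averages over all cross-group individual pairs; ``d_X`` and
    ``d_Y`` average over distinct within-group individual pairs (self-pairs
    excluded).  Distances are step counts normalised by ``n_sites``
    (defaulting to the coded matrix length).
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if n_sites is None:
        n_sites = matrix.total_sites or matrix.n_characters

    distances = pairwise_step_distances(matrix)
    hap_order = distances.labels
    steps = distances.values
    fa = _pooled_counts(table, group_a, hap_order)
    fb = _pooled_counts(table, group_b, hap_order)
    na, nb = fa.sum(), fb.sum()

    d_xy = float(fa @ steps @ fb / (na * nb)) / n_sites

    def within(f: np.ndarray, n: float) -> float:
        if n < 2:
            warnings.warn("group has a single individual; within-group term is 0")
            return 0.0
        return float(f @ steps @ f / (n * (n - 1))) / n_sites

    d_x = within(fa, na)
    d_y = within(fb, nb)
    return DatingResult(
        d_XY=d_xy, d_X=d_x, d_Y=d_y, d_A=d_xy - (d_x + d_y) / 2.0, n_sites=int(n_sites)
    )


def divergence_time(d_a: float, mu: float = DEFAULT_MU) -> float:
    """Clock dating: ``T = d_A / (2 mu)`` in years."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if d_a < 0:
        raise ValueError("d_A must be nonnegative")
    return d_a / (2.0 * mu)
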