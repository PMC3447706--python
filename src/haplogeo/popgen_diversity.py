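"""Unordered and ordered gene-diversity estimators (h_S, h_T, G_ST and
v_S, v_T, N_ST) with the permutation test for phylogeographic structure.

Estimator conventions
---------------------
Populations are weighted equally.  With observed within-population haplotype
frequencies ``x_k`` and sample sizes ``n_k``:

* within-population diversity ``h_k = n_k (1 - sum_i x_ki^2) / (n_k - 1)``
  (unbiased), and ``h_S`` is their unweighted mean;
* total diversity ``h_T = 1 - mean_{k != l} sum_i x_ki x_li``, the mean
  cross-population gene identity over the K(K-1) ordered distinct
  population pairs (cross-population frequency products are unbiased, so no
  further small-sample correction is needed);
* ``G_ST = 1 - h_S / h_T``.

The ordered statistics replace the identity-mismatch kernel with a
haplotype distance matrix ``pi``:  ``v_k = n_k (x_k' pi x_k) / (n_k - 1)``,
``v_T = mean_{k != l} x_k' pi x_l`` and ``N_ST = 1 - v_S / v_T``.  With
``pi_ij = 1 - delta_ij`` the ordered statistics reduce exactly to the
unordered ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_model import DistanceMatrix, PopulationTable

__all__ = [
    "DiversityResult",
    "gene_diversity_stats",
    "ordered_diversity_stats",
    "permutation_test_nst_gst",
    "diversity_analysis",
]

DEFAULT_PERMUTATIONS = 1000
DEFAULT_SEED = 20120430


@dataclass(frozen=True)
class DiversityResult:
    """Diversity/differentiation summary for one scope (species or region)."""

    scope: str
    n_populations: int
    n_haplotypes: int
    h_S: float
    h_T: float
    G_ST: float | None
    v_S: float | None = None
    v_T: float | None = None
    N_ST: float | None = None
    n_permutations: int = 0
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0,1]")


def _check_table(table: PopulationTable) -> None:
    if table.K < 2:
        raise ValueError("need at least 2 populations")
    if any(r.n < 2 for r in table.records):
        small = [r.code for r in table.records if r.n < 2]
        raise ValueError(f"populations with n < 2: {small}")


def _within_unbiased(freqs: np.ndarray, sizes: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Unbiased within-population mean pairwise kernel value, per population."""
    raw = np.einsum("ki,ij,kj->k", freqs, kernel, freqs)
    return sizes * raw / (sizes - 1)


def _between_pair_mean(freqs: np.ndarray, kernel: np.ndarray) -> float:
    """Mean of x_k' kernel x_l over ordered distinct population pairs."""
    K = freqs.shape[0]
    cross = freqs @ kernel @ freqs.T
    return float((cross.sum() - np.trace(cross)) / (K * (K - 1)))


def gene_diversity_stats(table: PopulationTable) -> tuple[float, float, float | None]:
    """Return ``(h_S, h_T, G_ST)`` under equal population weights.

    ``G_ST`` is ``None`` when ``h_T`` is zero (all populations fixed for the
    same haplotype), in which case differentiation is undefined.
    """
    _check_table(table)
    freqs = table.frequency_matrix()
    sizes = table.sample_sizes()
    mismatch = 1.0 - np.eye(freqs.shape[1])
    h_k = _within_unbiased(freqs, sizes, mismatch)
    h_S = float(h_k.mean())
    h_T = _between_pair_mean(freqs, mismatch)
    g_st = None if h_T <= 0.0 else 1.0 - h_S / h_T
    return h_S, h_T, g_st


def ordered_diversity_stats(
    table: PopulationTable, distances: DistanceMatrix
) -> tuple[float, float, float | None]:
    """Return ``(v_S, v_T, N_ST)`` using inter-haplotype distances."""
    _check_table(table)
    freqs = table.frequency_matrix(distances.labels)
    sizes = table.sample_sizes()
    pi = distances.values
    v_k = _within_unbiased(freqs, sizes, pi)
    v_S = float(v_k.mean())
    v_T = _between_pair_mean(freqs, pi)
    n_st = None if v_T <= 0.0 else 1.0 - v_S / v_T
    return v_S, v_T, n_st


def _nst_from(freqs: np.ndarray, sizes: np.ndarray, pi: np.ndarray) -> float | None:
    v_S = float(_within_unbiased(freqs, sizes, pi).mean())
    v_T = _between_pair_mean(freqs, pi)
    return None if v_T <= 0.0 else 1.0 - v_S / v_T


def permutation_test_nst_gst(
    table: PopulationTable,
    distances: DistanceMatrix,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = DEFAULT_SEED,
) -> float:
    """One-tailed permutation p-value for N_ST > G_ST.

    The null distribution is generated by jointly permuting haplotype labels
    on the distance matrix (rows and columns); G_ST is invariant under this
    permutation, so the statistic is the excess ``N_ST* - G_ST``.  The
    p-value uses the +1 Monte-Carlo correction.
    """
    _check_table(table)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len([h for h in table.haplotypes_present()]) < 3:
        warnings.warn("fewer than 3 haplotypes present: permutation test is degenerate")
    freqs = table.frequency_matrix(distances.labels)
    sizes = table.sample_sizes()
    pi = distances.values
    _, _, g_st = gene_diversity_stats(table)
    n_st = _nst_from(freqs, sizes, pi)
    if g_st is None or n_st is None:
        raise ValueError("N_ST/G_ST undefined: no total diversity")
    observed = n_st - g_st
    n_hap = pi.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_hap)
        pi_star = pi[np.ix_(perm, perm)]
        n_star = _nst_from(freqs, sizes, pi_star)
        if n_star is not None and n_star - g_st >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def diversity_analysis(
    table: PopulationTable,
    distances: DistanceMatrix | None = None,
    scope: str = "Total",
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = DEFAULT_SEED,
) -> DiversityResult:
    """Full unordered + ordered analysis for one scope, with the
    N_ST-vs-G_ST permutation test when distances are supplied."""
    h_S, h_T, g_st = gene_diversity_stats(table)
    v_S = v_T = n_st = p = None
    n_used = 0
    if distances is not None:
        v_S, v_T, n_st = ordered_diversity_stats(table, distances)
        if g_st is not None and n_st is not None:
            p = permutation_test_nst_gst(table, distances, n_perm=n_perm, seed=seed)
            n_used = n_perm
    return DiversityResult(
        scope=scope,
        n_populations=table.K,
        n_haplotypes=len(table.haplotypes_present()),
        h_S=h_S,
        h_T=h_T,
        G_ST=g_st,
        v_S=v_S,
        v_T=v_T,
        N_ST=n_st,
        n_permutations=n_used,
        p_value=p,
    )
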