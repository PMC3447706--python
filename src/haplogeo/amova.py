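"""Three-level analysis of molecular variance (AMOVA) with Phi-statistics
and permutation significance, plus pairwise population F_ST.

Individuals are expanded from haplotype counts and squared inter-individual
distances are taken as the number of differing coded characters between
their haplotypes (the pairwise-difference convention), so sums of squared
deviations follow the standard nested decomposition with unequal sample
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_model import DistanceMatrix, FormatError, GroupingScheme, PopulationTable

__all__ = [
    "AmovaResult",
    "amova_three_level",
    "amova_two_level",
    "pairwise_fst",
]

DEFAULT_PERMUTATIONS = 1023
DEFAULT_SEED = 20120430


@dataclass(frozen=True)
class AmovaResult:
    grouping: str
    sigma_a: float  # among groups
    sigma_b: float  # among populations within groups
    sigma_c: float  # within populations
    df: tuple[int, int, int]
    phi_CT: float
    phi_SC: float
    phi_ST: float
    n_permutations: int = 0
    p_CT: float | None = None
    p_SC: float | None = None
    p_ST: float | None = None

    @property
    def total_variance(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c

    @property
    def percentages(self) -> tuple[float, float, float]:
        tot = self.total_variance
        return (
            100.0 * self.sigma_a / tot,
            100.0 * self.sigma_b / tot,
            100.0 * self.sigma_c / tot,
        )


def _expand(table: PopulationTable, hap_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Individuals as (haplotype index, population index) arrays."""
    hap_idx = {h: i for i, h in enumerate(hap_order)}
    ih, ip = [], []
    for k, rec in enumerate(table.records):
        for h, c in rec.counts.items():
            if c > 0:
                ih.extend([hap_idx[h]] * c)
                ip.extend([k] * c)
    return np.array(ih, dtype=np.intp), np.array(ip, dtype=np.intp)


def _pop_hap_counts(ih: np.ndarray, ip: np.ndarray, K: int, H: int) -> np.ndarray:
    counts = np.zeros((K, H))
    np.add.at(counts, (ip, ih), 1.0)
    return counts


def _ssd_within_units(counts: np.ndarray, delta2: np.ndarray) -> np.ndarray:
    """SSD within each unit (row of a unit x haplotype count matrix)."""
    quad = np.einsum("ki,ij,kj->k", counts, delta2, counts)
    sizes = counts.sum(axis=1)
    return quad / (2.0 * sizes)


def _components(
    counts: np.ndarray, delta2: np.ndarray, group_of_pop: np.ndarray, G: int
) -> tuple[float, float, float, tuple[int, int, int]]:
    """Variance components from a population x haplotype count matrix."""
    K = counts.shape[0]
    nk = counts.sum(axis=1)
    N = nk.sum()

    ssd_wp = _ssd_within_units(counts, delta2).sum()
    group_counts = np.zeros((G, counts.shape[1]))
    np.add.at(group_counts, group_of_pop, counts)
    Ng = group_counts.sum(axis=1)
    ssd_wg = _ssd_within_units(group_counts, delta2).sum()
    total_counts = counts.sum(axis=0, keepdims=True)
    ssd_total = float(_ssd_within_units(total_counts, delta2)[0])
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df = (G - 1, K - G, int(N) - K)
    if df[1] == 0 or df[2] == 0:
        raise ValueError("degenerate design: no within-group or within-population df")

    sum_nk2_over_Ng = sum(
        (nk[group_of_pop == g] ** 2).sum() / Ng[g] for g in range(G)
    )
    n1 = (N - sum_nk2_over_Ng) / df[1]
    n2 = (sum_nk2_over_Ng - (nk**2).sum() / N) / df[0]
    n3 = (N - (Ng**2).sum() / N) / df[0]

    ms_ag = ssd_ag / df[0]
    ms_ap = ssd_ap / df[1]
    ms_wp = ssd_wp / df[2]
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n1
    sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3
    return float(sigma_a), float(sigma_b), float(sigma_c), df


def _phis(sa: float, sb: float, sc: float) -> tuple[float, float, float]:
    tot = sa + sb + sc
    phi_ct = sa / tot if tot else 0.0
    phi_sc = sb / (sb + sc) if (sb + sc) else 0.0
    phi_st = (sa + sb) / tot if tot else 0.0
    return phi_ct, phi_sc, phi_st


def amova_three_level(
    table: PopulationTable,
    distances: DistanceMatrix,
    grouping: GroupingScheme,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = DEFAULT_SEED,
) -> AmovaResult:
    """Excoffier-style nested AMOVA: among groups / among populations within
    groups / within populations.

    Permutation schemes follow the standard conventions: whole populations
    are permuted among groups for ``Phi_CT``, individuals among populations
    within their group for ``Phi_SC``, and individuals among all populations
    for ``Phi_ST``.  Negative variance components are reported as computed,
    never clamped.
    """
    grouping.validate_total(table.codes)
    groups = grouping.groups()
    if len(groups) < 2:
        raise FormatError("need at least 2 groups")
    group_index = {g: i for i, g in enumerate(groups)}
    group_of_pop = np.array([group_index[grouping.assignment[c]] for c in table.codes])
    G = len(groups)

    hap_order = list(distances.labels)
    delta2 = distances.values  # squared distance = number of differences
    ih, ip = _expand(table, hap_order)
    K = table.K
    H = len(hap_order)
    counts = _pop_hap_counts(ih, ip, K, H)
    if np.any(np.bincount(group_of_pop, minlength=G) == 0):
        raise FormatError("a group has no populations")

    sa, sb, sc, df = _components(counts, delta2, group_of_pop, G)
    phi_ct, phi_sc, phi_st = _phis(sa, sb, sc)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_ct = p_sc = p_st = None
    if n_perm > 0:
        hits_ct = hits_sc = hits_st = 0
        nk = counts.sum(axis=1).astype(int)
        for _ in range(n_perm):
            # Phi_CT: permute whole populations among groups.
            g_star = rng.permutation(group_of_pop)
            sa_s, sb_s, sc_s = _components(counts, delta2, g_star, G)[:3]
            if _phis(sa_s, sb_s, sc_s)[0] >= phi_ct - 1e-12:
                hits_ct += 1
            # Phi_SC: permute individuals among populations within groups.
            ip_star = ip.copy()
            for g in range(G):
                pops_g = np.where(group_of_pop == g)[0]
                mask = np.isin(ip, pops_g)
                ip_star[mask] = rng.permutation(ip[mask])
            counts_s = _pop_hap_counts(ih, ip_star, K, H)
            sa_s, sb_s, sc_s = _components(counts_s, delta2, group_of_pop, G)[:3]
            if _phis(sa_s, sb_s, sc_s)[1] >= phi_sc - 1e-12:
                hits_sc += 1
            # Phi_ST: permute individuals among all populations.
            counts_s = _pop_hap_counts(ih, rng.permutation(ip), K, H)
            sa_s, sb_s, sc_s = _components(counts_s, delta2, group_of_pop, G)[:3]
            if _phis(sa_s, sb_s, sc_s)[2] >= phi_st - 1e-12:
                hits_st += 1
        p_ct = (1 + hits_ct) / (n_perm + 1)
        p_sc = (1 + hits_sc) / (n_perm + 1)
        p_st = (1 + hits_st) / (n_perm + 1)

    return AmovaResult(
        grouping=grouping.name,
        sigma_a=sa,
        sigma_b=sb,
        sigma_c=sc,
        df=df,
        phi_CT=phi_ct,
        phi_SC=phi_sc,
        phi_ST=phi_st,
        n_permutations=n_perm,
        p_CT=p_ct,
        p_SC=p_sc,
        p_ST=p_st,
    )


def amova_two_level(
    table: PopulationTable, distances: DistanceMatrix
) -> tuple[float, float, float]:
    """Two-level decomposition (among / within populations); returns
    ``(sigma_among, sigma_within, Phi_ST)``."""
    hap_order = list(distances.labels)
    delta2 = distances.values
    counts = table.counts_matrix(hap_order)
    nk = counts.sum(axis=1)
    N = nk.sum()
    K = counts.shape[0]
    if K < 2:
        raise ValueError("need at least 2 populations")
    ssd_wp = _ssd_within_units(counts, delta2).sum()
    ssd_total = float(_ssd_within_units(counts.sum(axis=0, keepdims=True), delta2)[0])
    ssd_ap = ssd_total - ssd_wp
    n1 = (N - (nk**2).sum() / N) / (K - 1)
    sigma_w = ssd_wp / (N - K)
    sigma_a = (ssd_ap / (K - 1) - sigma_w) / n1
    tot = sigma_a + sigma_w
    phi = sigma_a / tot if tot > 0 else 0.0
    return float(sigma_a), float(sigma_w), float(phi)


def pairwise_fst(
    table: PopulationTable,
    distances: DistanceMatrix | None = None,
    kernel: Literal["steps", "identity"] = "steps",
) -> DistanceMatrix:
    """Pairwise population differentiation as a distance matrix.

    With ``kernel="steps"`` (default) each pair is a two-level AMOVA
    ``Phi_ST`` on the inter-haplotype step distances; ``kernel="identity"``
    uses the 0/1 mismatch kernel (identity-based F_ST).  Values are clamped
    to ``[0, 1]`` for downstream matrix comparison; the unclamped values are
    kept on the returned matrix as ``raw_values``.
    """
    if table.K < 2:
        raise ValueError("need at least 2 populations")
    if kernel == "identity" or distances is None:
        labels = table.haplotype_ids
        values = 1.0 - np.eye(len(labels))
        distances = DistanceMatrix(labels, values * 1.0, units="identity")
    K = table.K
    out = np.zeros((K, K))
    raw = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            pair = table.subset([table.codes[i], table.codes[j]])
            _, _, phi = amova_two_level(pair, distances)
            raw[i, j] = raw[j, i] = phi
            out[i, j] = out[j, i] = min(1.0, max(0.0, phi))
    result = DistanceMatrix(table.codes, out, units="F_ST")
    result.raw_values = raw
    return result
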