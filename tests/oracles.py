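"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions with explicit loops, never
by calling the package code it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# -- diversity ---------------------------------------------------------------

def brute_h_stats(pop_counts: list[dict[str, int]]) -> tuple[float, float]:
    """(h_S, h_T) from the definitions, looping over populations/haplotypes."""
    K = len(pop_counts)
    haps = sorted({h for c in pop_counts for h in c})
    h_ks = []
    freqs = []
    for counts in pop_counts:
        n = sum(counts.values())
        x = {h: counts.get(h, 0) / n for h in haps}
        freqs.append(x)
        h_ks.append(n / (n - 1) * (1.0 - sum(v * v for v in x.values())))
    h_s = sum(h_ks) / K
    tot = 0.0
    for k in range(K):
        for l in range(K):
            if k == l:
                continue
            tot += 1.0 - sum(freqs[k][h] * freqs[l][h] for h in haps)
    h_t = tot / (K * (K - 1))
    return h_s, h_t


def brute_v_stats(
    pop_counts: list[dict[str, int]], pi: dict[tuple[str, str], float]
) -> tuple[float, float]:
    """(v_S, v_T) by looping over every ordered individual pair."""
    K = len(pop_counts)
    individuals = [
        [h for h, c in counts.items() for _ in range(c)] for counts in pop_counts
    ]

    def d(a: str, b: str) -> float:
        if a == b:
            return 0.0
        return pi.get((a, b), pi.get((b, a)))

    v_ks = []
    for ind in individuals:
        n = len(ind)
        tot = sum(d(a, b) for a, b in itertools.permutations(ind, 2))
        v_ks.append(tot / (n * (n - 1)))
    v_s = sum(v_ks) / K
    tot = 0.0
    for k in range(K):
        for l in range(K):
            if k == l:
                continue
            nk, nl = len(individuals[k]), len(individuals[l])
            tot += sum(d(a, b) for a in individuals[k] for b in individuals[l]) / (nk * nl)
    v_t = tot / (K * (K - 1))
    return v_s, v_t


# -- AMOVA -------------------------------------------------------------------

def brute_amova_components(
    hap_of_individual: list[int],
    pop_of_individual: list[int],
    group_of_pop: list[int],
    delta2: np.ndarray,
) -> tuple[float, float, float]:
    """Three-level variance components from explicit SSD double loops."""
    N = len(hap_of_individual)
    pops = sorted(set(pop_of_individual))
    groups = sorted(set(group_of_pop))
    K, G = len(pops), len(groups)
    group_of_individual = [group_of_pop[p] for p in pop_of_individual]

    def ssd(idx: list[int]) -> float:
        tot = 0.0
        for a in idx:
            for b in idx:
                tot += delta2[hap_of_individual[a], hap_of_individual[b]]
        return tot / (2.0 * len(idx))

    everyone = list(range(N))
    ssd_total = ssd(everyone)
    ssd_wp = sum(ssd([i for i in everyone if pop_of_individual[i] == p]) for p in pops)
    ssd_wg = sum(ssd([i for i in everyone if group_of_individual[i] == g]) for g in groups)
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    nk = {p: pop_of_individual.count(p) for p in pops}
    Ng = {g: group_of_individual.count(g) for g in groups}
    sum_nk2_over_Ng = sum(
        sum(nk[p] ** 2 for p in pops if group_of_pop[p] == g) / Ng[g] for g in groups
    )
    n1 = (N - sum_nk2_over_Ng) / (K - G)
    n2 = (sum_nk2_over_Ng - sum(v**2 for v in nk.values()) / N) / (G - 1)
    n3 = (N - sum(v**2 for v in Ng.values()) / N) / (G - 1)

    sigma_c = ssd_wp / (N - K)
    sigma_b = (ssd_ap / (K - G) - sigma_c) / n1
    sigma_a = (ssd_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


def brute_two_level_phist(
    hap_of_individual: list[int], pop_of_individual: list[int], delta2: np.ndarray
) -> float:
    N = len(hap_of_individual)
    pops = sorted(set(pop_of_individual))
    K = len(pops)

    def ssd(idx: list[int]) -> float:
        tot = 0.0
        for a in idx:
            for b in idx:
                tot += delta2[hap_of_individual[a], hap_of_individual[b]]
        return tot / (2.0 * len(idx))

    everyone = list(range(N))
    ssd_total = ssd(everyone)
    ssd_wp = sum(ssd([i for i in everyone if pop_of_individual[i] == p]) for p in pops)
    ssd_ap = ssd_total - ssd_wp
    nk = [pop_of_individual.count(p) for p in pops]
    n1 = (N - sum(v**2 for v in nk) / N) / (K - 1)
    sigma_w = ssd_wp / (N - K)
    sigma_a = (ssd_ap / (K - 1) - sigma_w) / n1
    tot = sigma_a + sigma_w
    return sigma_a / tot if tot > 0 else 0.0


# -- geometry ----------------------------------------------------------------

def law_of_cosines_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance by the spherical law of cosines (independent
    of the haversine implementation under test)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    cosc = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return 6371.0 * math.acos(min(1.0, max(-1.0, cosc)))


# -- permutations ------------------------------------------------------------

def exhaustive_mantel_p(x_matrix: np.ndarray, y_matrix: np.ndarray) -> float:
    """One-tailed Mantel p by full enumeration of label permutations."""
    n = x_matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    y = y_matrix[iu]
    r_obs = np.corrcoef(x_matrix[iu], y)[0, 1]
    hits = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        xs = x_matrix[np.ix_(perm, perm)][iu]
        if np.corrcoef(xs, y)[0, 1] >= r_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def exhaustive_nst_excess_p(
    pop_counts: list[dict[str, int]], hap_order: list[str], pi: np.ndarray
) -> float:
    """Exhaustive null for the N_ST - G_ST excess over all relabelings."""
    mismatch = {}
    for i, a in enumerate(hap_order):
        for j, b in enumerate(hap_order):
            mismatch[(a, b)] = 0.0 if i == j else 1.0

    def nst_minus_gst(perm: tuple[int, ...]) -> float:
        pim = {
            (hap_order[i], hap_order[j]): pi[perm[i], perm[j]]
            for i in range(len(hap_order))
            for j in range(len(hap_order))
        }
        v_s, v_t = brute_v_stats(pop_counts, pim)
        h_s, h_t = brute_v_stats(pop_counts, mismatch)
        return (1 - v_s / v_t) - (1 - h_s / h_t)

    identity = tuple(range(len(hap_order)))
    observed = nst_minus_gst(identity)
    hits = 0
    total = 0
    for perm in itertools.permutations(range(len(hap_order))):
        if nst_minus_gst(perm) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def mc_parsimony_probability(
    steps: int, n_sites: int, n_draws: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo estimate of the all-distinct-sites probability for
    ``steps`` mutations placed uniformly on ``n_sites`` sites."""
    hits = 0
    for _ in range(n_draws):
        draw = rng.integers(0, n_sites, size=steps)
        if len(set(draw.tolist())) == steps:
            hits += 1
    return hits / n_draws
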