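"""Generator of haplotype matrices and population tables with the
statistical structure the analysis pipeline assumes: two deeply split
lineages, a star-like low-diversity northern lineage, a geographically
structured southern lineage with an isolation-by-distance frequency
gradient, and exact planted truth.

Mutations are placed without recurrence (infinite sites), so step distances
equal mutation counts and the planted quantities are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .io_model import (
    AlignedSequenceSet,
    CodedMatrix,
    FormatError,
    PopulationRecord,
    PopulationTable,
)
from .haplotyping import code_indels, pairwise_step_distances

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_phylogeography",
    "haplotype_alignment",
    "individual_alignment",
    "shuffle_haplotype_labels",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    n_pops_north: int = 10
    n_pops_south: int = 10
    n_per_pop: int = 15
    n_sites: int = 1381
    split_steps: int = 11
    within_lineage_steps: int = 1
    ibd_strength: float = 8.0
    star_dominance: float = 0.7
    indel_fraction: float = 0.2
    n_hap_north: int = 6
    n_hap_south: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops_north, self.n_pops_south, self.n_per_pop, self.n_sites) < 1:
            raise FormatError("all counts must be positive")
        if self.split_steps < 1:
            raise FormatError("split_steps must be >= 1")
        if self.ibd_strength < 0:
            raise FormatError("ibd_strength must be >= 0")
        if not (0.0 < self.star_dominance <= 1.0):
            raise FormatError("star_dominance must be in (0, 1]")
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise FormatError("indel_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationTruth:
    bipartition: Mapping[str, str]  # haplotype -> "north" | "south"
    split_steps: int
    d_a_planted: float
    haplotype_sequences: Mapping[str, str]


def _mutate(seq: list[str], sites: list[int], n: int, indel_fraction: float,
            rng: np.random.Generator) -> list[str]:
    """Apply n non-recurrent mutations, consuming sites from the shared pool."""
    out = list(seq)
    for _ in range(n):
        if not sites:
            raise FormatError("more requested mutations than available sites")
        pos = sites.pop()
        if rng.random() < indel_fraction:
            out[pos] = "-"
        else:
            current = out[pos]
            choices = [b for b in "ACGT" if b != current]
            out[pos] = choices[rng.integers(len(choices))]
    return out


def simulate_phylogeography(
    config: SimulationConfig,
) -> tuple[PopulationTable, CodedMatrix, SimulationTruth]:
    """Simulate a two-lineage phylogeography.

    The northern lineage is a star: a dominant central haplotype with rare
    satellites.  The southern lineage is a serial chain of haplotypes whose
    population frequencies follow an exponential isolation-by-distance
    kernel on a one-dimensional transect.  Returns the population table,
    the coded haplotype matrix (indels binary-coded), and the exact planted
    truth including the analytic net divergence ``d_a_planted`` computed
    from expected frequencies.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    root = list(rng.choice(_BASES, size=cfg.n_sites))
    sites = list(rng.permutation(cfg.n_sites))

    n_north = cfg.n_hap_north if cfg.within_lineage_steps > 0 else 1
    n_south = cfg.n_hap_south if cfg.within_lineage_steps > 0 else 1

    north_center = root
    south_anc = _mutate(root, sites, cfg.split_steps, cfg.indel_fraction, rng)

    north_seqs = [north_center]
    for _ in range(n_north - 1):
        north_seqs.append(
            _mutate(north_center, sites, cfg.within_lineage_steps, cfg.indel_fraction, rng)
        )
    south_seqs = [south_anc]
    for _ in range(n_south - 1):
        south_seqs.append(
            _mutate(south_seqs[-1], sites, cfg.within_lineage_steps, cfg.indel_fraction, rng)
        )

    hap_ids = [f"H{i + 1}" for i in range(n_north + n_south)]
    lineage = {h: ("north" if i < n_north else "south") for i, h in enumerate(hap_ids)}
    seqs = {h: "".join(s) for h, s in zip(hap_ids, north_seqs + south_seqs)}

    # Expected (planted) haplotype frequency vector per population.
    def north_probs() -> np.ndarray:
        p = np.zeros(len(hap_ids))
        p[0] = cfg.star_dominance
        if n_north > 1:
            p[1:n_north] = (1.0 - cfg.star_dominance) / (n_north - 1)
        else:
            p[0] = 1.0
        return p / p.sum()

    def south_probs(t: float) -> np.ndarray:
        p = np.zeros(len(hap_ids))
        xi = np.linspace(0.0, 1.0, n_south)
        w = np.exp(-cfg.ibd_strength * np.abs(t - xi))
        p[n_north:] = w / w.sum()
        return p

    records: list[PopulationRecord] = []
    expected: list[np.ndarray] = []
    for k in range(cfg.n_pops_north):
        p = north_probs()
        counts = rng.multinomial(cfg.n_per_pop, p)
        records.append(
            PopulationRecord(
                code=f"NP{k + 1:02d}",
                locality=f"north transect {k + 1}",
                flower_color="R",
                habit="A",
                region="N",
                latitude=40.0,
                longitude=106.0 + 0.4 * k,
                counts={h: int(c) for h, c in zip(hap_ids, counts) if c > 0},
            )
        )
        expected.append(p)
    for k in range(cfg.n_pops_south):
        t = k / max(1, cfg.n_pops_south - 1)
        p = south_probs(t)
        counts = rng.multinomial(cfg.n_per_pop, p)
        records.append(
            PopulationRecord(
                code=f"SP{k + 1:02d}",
                locality=f"south transect {k + 1}",
                flower_color="R",
                habit="P",
                region="S",
                latitude=30.0,
                longitude=99.0 + 0.4 * k,
                counts={h: int(c) for h, c in zip(hap_ids, counts) if c > 0},
            )
        )
        expected.append(p)

    table = PopulationTable(records, hap_ids)
    matrix = code_indels(haplotype_alignment(seqs, cfg.n_sites))
    # Restore haplotype labels (code_indels keeps the alignment order).
    coded = CodedMatrix(
        hap_ids, matrix.columns, matrix.states, total_sites=matrix.total_sites
    )

    # Planted d_A from expected frequencies (plug-in, infinite-sample).
    steps = pairwise_step_distances(coded).values
    exp_north = np.mean(expected[: cfg.n_pops_north], axis=0)
    exp_south = np.mean(expected[cfg.n_pops_north :], axis=0)
    L = coded.total_sites or coded.n_characters
    d_xy = exp_north @ steps @ exp_south / L
    d_x = exp_north @ steps @ exp_north / L
    d_y = exp_south @ steps @ exp_south / L
    truth = SimulationTruth(
        bipartition=lineage,
        split_steps=cfg.split_steps,
        d_a_planted=float(d_xy - (d_x + d_y) / 2.0),
        haplotype_sequences=seqs,
    )
    return table, coded, truth


def haplotype_alignment(seqs: Mapping[str, str], n_sites: int) -> AlignedSequenceSet:
    """One aligned record per haplotype."""
    return AlignedSequenceSet(
        tuple((h, s) for h, s in seqs.items()),
        (("simulated", 1, n_sites),),
    )


def individual_alignment(
    table: PopulationTable, seqs: Mapping[str, str], n_sites: int
) -> AlignedSequenceSet:
    """One aligned record per individual, ids ``<pop>_<i>``; this is the
    705-row-style matrix the haplotype-collapsing stage consumes."""
    records = []
    for rec in table.records:
        i = 0
        for h in table.haplotype_ids:
            for _ in range(rec.counts.get(h, 0)):
                i += 1
                records.append((f"{rec.code}_{i:03d}", seqs[h]))
    return AlignedSequenceSet(tuple(records), (("simulated", 1, n_sites),))


def shuffle_haplotype_labels(
    table: PopulationTable, seed: int | np.random.Generator
) -> PopulationTable:
    """Apply one global random permutation of haplotype labels to every
    population's counts.

    This severs any association between haplotype relatedness and geography
    while preserving all frequency structure, so it realises the null
    hypothesis of the N_ST-vs-G_ST permutation test exactly (used for
    type-I calibration).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(table.haplotype_ids))
    relabel = {
        table.haplotype_ids[i]: table.haplotype_ids[j] for i, j in enumerate(perm)
    }
    records = [
        replace(r, counts={relabel[h]: c for h, c in r.counts.items()})
        for r in table.records
    ]
    return PopulationTable(records, table.haplotype_ids)
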