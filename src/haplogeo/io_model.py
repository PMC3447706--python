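"""Domain types, readers/writers, coordinate parsing, and packaged fixtures.

The central objects are :class:`AlignedSequenceSet` (an aligned multi-FASTA
matrix), :class:`CodedMatrix` (categorical character states per haplotype or
individual, substitutions plus binary-coded indels), :class:`PopulationTable`
(per-population metadata, coordinates and haplotype counts) and
:class:`DistanceMatrix` (symmetric non-negative distances over haplotypes or
populations).  Two fixtures transcribing the published 47-population count
table and the 16-haplotype polymorphic-site table ship with the package and
are loaded with :func:`load_fixture`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlignmentError",
    "FormatError",
    "AlignedSequenceSet",
    "CharacterColumn",
    "CodedMatrix",
    "PopulationRecord",
    "PopulationTable",
    "GroupingScheme",
    "DistanceMatrix",
    "dms_to_decimal",
    "read_fasta_alignment",
    "load_fixture",
    "write_report",
    "read_report",
    "write_network",
]

ALLOWED_BASES = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Raised for ragged or otherwise inconsistent alignments."""


class FormatError(ValueError):
    """Raised for malformed input files or records."""


# ---------------------------------------------------------------------------
# Aligned sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedSequenceSet:
    """An aligned set of equal-length sequences with named segment spans.

    Parameters
    ----------
    records
        ``(identifier, sequence)`` pairs; sequences over ``{A,C,G,T,N,-}``.
    segment_boundaries
        ``(name, start, end)`` 1-based inclusive spans that tile the
        alignment without overlap.
    """

    records: tuple[tuple[str, str], ...]
    segment_boundaries: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence identifiers: {dupes}")
        for ident, seq in self.records:
            bad = set(seq.upper()) - ALLOWED_BASES
            if bad:
                raise FormatError(f"record {ident!r} has invalid symbols {sorted(bad)}")
        length = self.length
        spans = sorted(self.segment_boundaries, key=lambda t: t[1])
        expect = 1
        for name, start, end in spans:
            if start != expect or end < start:
                raise AlignmentError(
                    f"segment {name!r} span ({start},{end}) does not tile the alignment"
                )
            expect = end + 1
        if spans and expect != length + 1:
            raise AlignmentError(
                f"segments cover 1..{expect - 1} but alignment length is {length}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def identifiers(self) -> list[str]:
        return [i for i, _ in self.records]

    def segment_of(self, position: int) -> str:
        """Name of the segment containing a 1-based alignment position."""
        for name, start, end in self.segment_boundaries:
            if start <= position <= end:
                return name
        return ""


def read_fasta_alignment(
    path: str | Path,
    segment_boundaries: Sequence[tuple[str, int, int]] | None = None,
) -> AlignedSequenceSet:
    """Read an aligned multi-FASTA file.

    All records must have identical length; ragged input raises
    :class:`AlignmentError` and duplicate identifiers raise
    :class:`FormatError`.  If ``segment_boundaries`` is omitted the whole
    alignment is one unnamed segment.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if segment_boundaries is None:
        segment_boundaries = [("alignment", 1, len(records[0][1]))]
    return AlignedSequenceSet(tuple(records), tuple(segment_boundaries))


# ---------------------------------------------------------------------------
# Coded character matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterColumn:
    """One coded character: a substitution site or a binary-coded indel."""

    origin: Literal["substitution", "indel_binary"]
    alignment_position: int
    segment: str = ""
    source_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("substitution", "indel_binary"):
            raise FormatError(f"unknown column origin {self.origin!r}")
        if self.alignment_position < 1:
            raise FormatError("alignment_position is 1-based")


class CodedMatrix:
    """Categorical state table: rows are haplotypes (or individuals),
    columns are coded characters.

    ``states`` is an object array of single-character state symbols; any
    symbol is legal (the published table uses opaque markers for some
    indels), ``N`` denotes missing data.  ``total_sites`` optionally records
    the full coded alignment length the columns were drawn from, used for
    per-site normalisation downstream.
    """

    def __init__(
        self,
        haplotype_ids: Sequence[str],
        columns: Sequence[CharacterColumn],
        states: np.ndarray | Sequence[Sequence[str]],
        *,
        rows_distinct: bool = False,
        total_sites: int | None = None,
    ) -> None:
        self.haplotype_ids = list(haplotype_ids)
        self.columns = list(columns)
        self.states = np.asarray(states, dtype=object)
        self.total_sites = total_sites
        if self.states.shape != (len(self.haplotype_ids), len(self.columns)):
            raise FormatError(
                f"state table shape {self.states.shape} does not match "
                f"{len(self.haplotype_ids)} rows x {len(self.columns)} columns"
            )
        if len(set(self.haplotype_ids)) != len(self.haplotype_ids):
            raise FormatError("duplicate row identifiers in coded matrix")
        for j, col in enumerate(self.columns):
            observed = set(self.states[:, j]) - {"N"}
            if not observed:
                raise FormatError(f"column {j} has no observed states")
            if col.origin == "indel_binary" and len(observed) > 2:
                raise FormatError(
                    f"indel column at position {col.alignment_position} has "
                    f"{len(observed)} states; binary expected"
                )
        if rows_distinct:
            rows = [tuple(r) for r in self.states]
            if len(set(rows)) != len(rows):
                raise FormatError("haplotype rows are not distinct")

    @property
    def n_rows(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_characters(self) -> int:
        return len(self.columns)

    def row(self, identifier: str) -> tuple[str, ...]:
        return tuple(self.states[self.haplotype_ids.index(identifier)])

    def subset_rows(self, identifiers: Sequence[str]) -> "CodedMatrix":
        idx = [self.haplotype_ids.index(i) for i in identifiers]
        return CodedMatrix(
            [self.haplotype_ids[i] for i in idx],
            self.columns,
            self.states[idx],
            total_sites=self.total_sites,
        )

    # -- CSV round trip (fixture schema: header cells "<position>:<origin>") --

    def to_csv(self, path: str | Path) -> None:
        header = ["haplotype"] + [
            f"{c.alignment_position}:{'indel' if c.origin == 'indel_binary' else 'sub'}"
            for c in self.columns
        ]
        df = pd.DataFrame(self.states, columns=header[1:])
        df.insert(0, "haplotype", self.haplotype_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, *, segment_boundaries: Sequence[tuple[str, int, int]] = (),
        total_sites: int | None = None,
    ) -> "CodedMatrix":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        if df.columns[0] != "haplotype":
            raise FormatError("coded matrix CSV must start with a 'haplotype' column")
        columns = []
        for name in df.columns[1:]:
            try:
                pos_s, origin_s = name.split(":")
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"bad coded-matrix column header {name!r}") from exc
            origin = "indel_binary" if origin_s == "indel" else "substitution"
            segment = ""
            for seg, start, end in segment_boundaries:
                if start <= pos <= end:
                    segment = seg
            columns.append(CharacterColumn(origin, pos, segment))
        return cls(
            df["haplotype"].tolist(),
            columns,
            df.iloc[:, 1:].to_numpy(dtype=object),
            total_sites=total_sites,
        )


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*(?P<deg>\d{1,3})\s*[°d]\s*
         (?P<min>\d{1,2})\s*['m′]\s*
         (?P<sec>\d{1,2}(?:\.\d+)?)\s*(?:″|"|''|s)?\s*
         (?P<hemi>[NSEW])?\s*$""",
    re.VERBOSE,
)


def dms_to_decimal(text: str) -> float:
    """Convert a degrees-minutes-seconds coordinate string to decimal degrees.

    Accepts e.g. ``30°03'54.2″`` or ``099°08'56.8″E``; a trailing ``S`` or
    ``W`` hemisphere letter negates the value.  Decimal-degree input (a bare
    float string) is passed through.
    """
    try:
        return float(text)
    except ValueError:
        pass
    m = _DMS_RE.match(text)
    if not m:
        raise FormatError(f"cannot parse coordinate {text!r}")
    minutes = int(m.group("min"))
    seconds = float(m.group("sec"))
    if minutes >= 60 or seconds >= 60:
        raise FormatError(f"minutes/seconds out of range in {text!r}")
    value = int(m.group("deg")) + minutes / 60.0 + seconds / 3600.0
    if m.group("hemi") in ("S", "W"):
        value = -value
    return value


@dataclass(frozen=True)
class PopulationRecord:
    code: str
    locality: str
    flower_color: str  # R | Y
    habit: str  # A (annual) | P (perennial)
    region: str  # NEQTP | SEQTP | N
    latitude: float
    longitude: float
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise FormatError(f"{self.code}: latitude {self.latitude} out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise FormatError(f"{self.code}: longitude {self.longitude} out of range")
        if any(c < 0 for c in self.counts.values()):
            raise FormatError(f"{self.code}: negative haplotype count")
        if self.n < 1:
            raise FormatError(f"{self.code}: empty population")

    @property
    def n(self) -> int:
        return sum(self.counts.values())


class PopulationTable:
    """Ordered collection of populations with haplotype counts.

    Population codes are primary keys; ``haplotype_ids`` fixes the column
    order used by :meth:`counts_matrix` and :meth:`frequency_matrix`.
    """

    def __init__(
        self,
        records: Sequence[PopulationRecord],
        haplotype_ids: Sequence[str] | None = None,
    ) -> None:
        self.records = list(records)
        codes = [r.code for r in self.records]
        if len(set(codes)) != len(codes):
            raise FormatError("duplicate population codes")
        if haplotype_ids is None:
            seen: dict[str, None] = {}
            for r in self.records:
                for h in r.counts:
                    seen.setdefault(h, None)
            haplotype_ids = list(seen)
        self.haplotype_ids = list(haplotype_ids)
        for r in self.records:
            unknown = set(r.counts) - set(self.haplotype_ids)
            if unknown:
                raise FormatError(f"{r.code}: counts for unknown haplotypes {sorted(unknown)}")

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def codes(self) -> list[str]:
        return [r.code for r in self.records]

    @property
    def K(self) -> int:
        return len(self.records)

    @property
    def total_individuals(self) -> int:
        return sum(r.n for r in self.records)

    def record(self, code: str) -> PopulationRecord:
        for r in self.records:
            if r.code == code:
                return r
        raise KeyError(code)

    def sample_sizes(self) -> np.ndarray:
        return np.array([r.n for r in self.records], dtype=float)

    def counts_matrix(self, haplotype_order: Sequence[str] | None = None) -> np.ndarray:
        order = list(haplotype_order) if haplotype_order is not None else self.haplotype_ids
        out = np.zeros((len(self.records), len(order)))
        for k, r in enumerate(self.records):
            for h, c in r.counts.items():
                if h in order:
                    out[k, order.index(h)] = c
                elif c > 0:
                    raise FormatError(f"{r.code}: haplotype {h} missing from ordering")
        return out

    def frequency_matrix(self, haplotype_order: Sequence[str] | None = None) -> np.ndarray:
        counts = self.counts_matrix(haplotype_order)
        return counts / counts.sum(axis=1, keepdims=True)

    def haplotypes_present(self) -> list[str]:
        present = set()
        for r in self.records:
            present |= {h for h, c in r.counts.items() if c > 0}
        return [h for h in self.haplotype_ids if h in present]

    def subset(self, codes: Iterable[str]) -> "PopulationTable":
        codes = list(codes)
        return PopulationTable(
            [r for r in self.records if r.code in codes], self.haplotype_ids
        )

    # -- grouping schemes ---------------------------------------------------

    def grouping(self, name: str) -> "GroupingScheme":
        """Built-in total grouping schemes over populations.

        ``three_regions`` uses the region column; ``two_subspecies`` the habit
        column (annual vs perennial); ``two_variants`` the flower colour.
        The lineage grouping is data-derived: see
        :func:`haplogeo.parsimony_network.population_lineages`.
        """
        if name == "three_regions":
            assignment = {r.code: r.region for r in self.records}
        elif name == "two_subspecies":
            assignment = {r.code: r.habit for r in self.records}
        elif name == "two_variants":
            assignment = {r.code: r.flower_color for r in self.records}
        else:
            raise KeyError(f"unknown built-in grouping {name!r}")
        return GroupingScheme(name, assignment)

    # -- CSV round trip (wide haplotype-count columns) ----------------------

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for r in self.records:
            row = {
                "code": r.code,
                "locality": r.locality,
                "flower_color": r.flower_color,
                "habit": r.habit,
                "n": r.n,
                "latitude": r.latitude,
                "longitude": r.longitude,
                "region": r.region,
            }
            for h in self.haplotype_ids:
                row[h] = int(r.counts.get(h, 0))
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        meta = ["code", "locality", "flower_color", "habit", "n", "latitude", "longitude", "region"]
        missing = [c for c in meta if c not in df.columns]
        if missing:
            raise FormatError(f"population table missing columns {missing}")
        hap_cols = [c for c in df.columns if c not in meta]
        records = []
        for _, row in df.iterrows():
            counts = {h: int(row[h]) for h in hap_cols if int(row[h] or 0) > 0}
            rec = PopulationRecord(
                code=row["code"],
                locality=row["locality"],
                flower_color=row["flower_color"],
                habit=row["habit"],
                region=row["region"],
                latitude=dms_to_decimal(row["latitude"]),
                longitude=dms_to_decimal(row["longitude"]),
                counts=counts,
            )
            if rec.n != int(row["n"]):
                raise FormatError(
                    f"{rec.code}: declared n={row['n']} but counts sum to {rec.n}"
                )
            records.append(rec)
        return cls(records, hap_cols)


@dataclass(frozen=True)
class GroupingScheme:
    """A total assignment of population codes (or haplotype ids) to groups."""

    name: str
    assignment: Mapping[str, str]

    def groups(self) -> list[str]:
        out: dict[str, None] = {}
        for g in self.assignment.values():
            out.setdefault(g, None)
        return list(out)

    def members(self, group: str) -> list[str]:
        return [k for k, g in self.assignment.items() if g == group]

    def validate_total(self, keys: Iterable[str]) -> None:
        missing = [k for k in keys if k not in self.assignment]
        if missing:
            raise FormatError(f"grouping {self.name!r} missing labels for {missing}")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """Symmetric non-negative distances over labelled objects."""

    def __init__(self, labels: Sequence[str], values: np.ndarray, units: str = "") -> None:
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        self.units = units
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(f"distance matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T):
            raise FormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise FormatError("distance matrix has a nonzero diagonal")
        if np.any(self.values < -1e-12):
            raise FormatError("distance matrix has negative entries")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.units)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (label order)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

#: Segment layout of the coded fixture matrix (1381 coded characters).
FIXTURE_SEGMENTS: tuple[tuple[str, int, int], ...] = (
    ("trnH-psbA", 1, 372),
    ("trnS-trnfM", 373, 1381),
)
FIXTURE_CODED_LENGTH = 1381


def _data_path(name: str):
    return resources.files("haplogeo.data") / name


def load_fixture(name: str) -> PopulationTable | CodedMatrix:
    """Load a packaged fixture: ``table1`` (47 populations with haplotype
    counts and coordinates) or ``table2`` (16 haplotypes x 23 coded
    characters)."""
    if name == "table1":
        with resources.as_file(_data_path("table1.csv")) as p:
            return PopulationTable.from_csv(p)
    if name == "table2":
        with resources.as_file(_data_path("table2.csv")) as p:
            return CodedMatrix.from_csv(
                p,
                segment_boundaries=FIXTURE_SEGMENTS,
                total_sites=FIXTURE_CODED_LENGTH,
            )
    raise KeyError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# Report / network output
# ---------------------------------------------------------------------------

def write_report(results: Mapping, path: str | Path) -> None:
    """Write a results bundle as deterministic, round-trippable JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_network(network, gml_path: str | Path, tsv_path: str | Path | None = None) -> None:
    """Export a haplotype network as GML plus an edge-list TSV.

    ``network`` is a :class:`haplogeo.parsimony_network.HaplotypeNetwork`;
    GML nodes carry haplotype frequency and region attributes, edges carry
    their mutational step count.
    """
    import networkx as nx

    gml_path = Path(gml_path)
    if tsv_path is None:
        tsv_path = gml_path.with_suffix(".tsv")
    graph = network.graph
    out = nx.Graph()
    for node, attrs in graph.nodes(data=True):
        out.add_node(
            node,
            frequency=int(attrs.get("frequency", 0)),
            regions=",".join(attrs.get("regions", ())),
        )
    for u, v, attrs in graph.edges(data=True):
        out.add_edge(u, v, steps=int(attrs["steps"]), weight=int(attrs["steps"]))
    nx.write_gml(out, str(gml_path))
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("haplotype_a\thaplotype_b\tsteps\n")
        for u, v, attrs in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{int(attrs['steps'])}\n")
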