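"""Domain types and file I/O for the chloroplast haplotype pipeline.

The pipeline works on six non-coding chloroplast regions (*trnL-trnF*,
*atpB-rbcL*, *rps16* intron, *trnG* intron, *psbA-trnH*, *rpl32-trnL*)
sequenced for Himalayan balsam (*Impatiens glandulifera*) populations from
the introduced (British Isles) and native (Himalayan) range.  Everything
downstream consumes three containers defined here:

``RegionAlignment``
    one locus's gapped multiple alignment,
``HaplotypeMatrix``
    an ordered catalogue of variant events plus one state vector per
    haplotype (the published polymorphic-site table),
``PopulationRecord``
    one sampled population with range class, coordinates and observed
    haplotype labels (the published site table).

State-token conventions used throughout the package:

* substitutions: a single upper-case base (``A``/``C``/``G``/``T``);
* indel events: the present (inserted/retained) string, e.g. ``T`` or
  ``ACTAT``, versus ``-`` for the absent state;
* inversion events: the forward or reverse-complement span string;
* ``?``: missing/ambiguous (IUPAC ambiguity codes and ``N`` are folded
  into this token; they never found new states).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger("cpnet")

MISSING = "?"
GAP = "-"

#: canonical study regions and their aligned lengths (bp)
REGION_LENGTHS = {
    "trnL-trnF": 906,
    "atpB-rbcL": 804,
    "rps16": 813,
    "trnG": 632,
    "psbA-trnH": 397,
    "rpl32-trnL": 1047,
}
REGION_ORDER = tuple(REGION_LENGTHS)

_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")


class CpnetError(Exception):
    """Base class for all pipeline errors."""


class AlignmentError(CpnetError):
    """Malformed alignment input (ragged lengths, sample-set mismatch)."""


class TableError(CpnetError):
    """Malformed population or matrix table."""


class IndelMode(str, Enum):
    """How indel events enter mutational distances.

    ``missing``      events where either haplotype carries the absent/missing
                     state are excluded from the comparison.
    ``fifth_state``  the gap state is an ordinary character state.
    ``single_event`` alias of ``fifth_state`` once indel runs have been merged
                     to one event each (one mutational unit per indel).
    """

    missing = "missing"
    fifth_state = "fifth_state"
    single_event = "single_event"


@dataclass(frozen=True)
class RegionAlignment:
    """One region's gapped multiple alignment."""

    region_name: str
    samples: tuple[tuple[str, str], ...]  # (sample_id, gapped sequence)
    aligned_length: int

    def __post_init__(self):
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(
                f"duplicate sample ids in region {self.region_name!r}: {dup}")
        for sid, seq in self.samples:
            if len(seq) != self.aligned_length:
                raise AlignmentError(
                    f"region {self.region_name!r}: record {sid!r} has length "
                    f"{len(seq)}, expected {self.aligned_length}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.samples)

    def sequence(self, sample_id: str) -> str:
        for sid, seq in self.samples:
            if sid == sample_id:
                return seq
        raise KeyError(sample_id)

    def column(self, pos: int) -> str:
        """1-based alignment column as a string over samples."""
        return "".join(seq[pos - 1] for _, seq in self.samples)


@dataclass(frozen=True)
class VariantEvent:
    """One polymorphic event: substitution, indel, or inversion.

    ``span`` is 1-based inclusive within the region's own alignment.
    ``states`` maps haplotype label or sample id to its state token.
    ``detail`` holds the present string for indels and the
    (majority string, minority string) pair for inversions.
    """

    region_name: str
    kind: str  # "substitution" | "indel" | "inversion"
    span: tuple[int, int]
    states: Mapping[str, str]
    detail: object = None

    def __post_init__(self):
        lo, hi = self.span
        if lo > hi or lo < 1:
            raise ValueError(f"invalid span {self.span}")
        if self.kind == "substitution" and hi != lo:
            raise ValueError("substitution spans must have length 1")
        if self.kind == "inversion":
            fwd, rev = self.detail
            if reverse_complement(fwd) != rev:
                raise ValueError(
                    f"inversion detail {self.detail} is not a reverse-"
                    "complement pair")

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0] + 1

    @property
    def is_variable(self) -> bool:
        """>= 2 distinct non-missing state tokens (true for any scanned
        event; collapsed matrices over haplotype subsets may be constant
        at an event)."""
        return len({t for t in self.states.values() if t != MISSING}) >= 2

    def key(self) -> tuple:
        return (self.region_name, self.kind, self.span)

    def relabelled(self, mapping: Mapping[str, str]) -> "VariantEvent":
        return replace(self, states={mapping.get(k, k): v
                                     for k, v in self.states.items()})


@dataclass
class HaplotypeMatrix:
    """Haplotype label -> ordered state vector over a shared event list."""

    events: list[VariantEvent]
    haplotypes: dict[str, tuple[str, ...]]
    sample_assignment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.events)
        for label, vec in self.haplotypes.items():
            if len(vec) != n:
                raise TableError(
                    f"haplotype {label!r} has {len(vec)} states for "
                    f"{n} events")
        for sid, label in self.sample_assignment.items():
            if label not in self.haplotypes:
                raise TableError(
                    f"sample {sid!r} assigned to unknown haplotype {label!r}")

    @property
    def labels(self) -> list[str]:
        return list(self.haplotypes)

    def vector(self, label: str) -> tuple[str, ...]:
        return self.haplotypes[label]

    def frequency(self, label: str) -> int:
        return sum(1 for lab in self.sample_assignment.values()
                   if lab == label)

    def equal_content(self, other: "HaplotypeMatrix") -> bool:
        """Equality on event keys, details and per-haplotype states."""
        if [e.key() for e in self.events] != [e.key() for e in other.events]:
            return False
        if [e.detail for e in self.events] != [e.detail for e in other.events]:
            return False
        return self.haplotypes == other.haplotypes


@dataclass(frozen=True)
class PopulationRecord:
    """One sampled population (a row of the published site table)."""

    population_id: str
    location: str
    country: str
    range_class: str  # "introduced" | "native"
    latitude: float | None
    longitude: float | None
    altitude_m: float | None
    collection_year: int | None
    n_samples: int
    haplotype_labels: tuple[str, ...]
    group_label: str | None = None

    def __post_init__(self):
        if self.range_class not in ("introduced", "native"):
            raise TableError(
                f"{self.population_id}: unknown range_class "
                f"{self.range_class!r}")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise TableError(
                f"{self.population_id}: latitude {self.latitude} out of range")
        if self.longitude is not None and not -180 <= self.longitude <= 180:
            raise TableError(
                f"{self.population_id}: longitude {self.longitude} "
                "out of range")
        if self.n_samples < 1:
            raise TableError(f"{self.population_id}: n_samples must be >= 1")
        if self.n_samples < len(set(self.haplotype_labels)):
            raise TableError(
                f"{self.population_id}: {self.n_samples} samples cannot carry "
                f"{len(set(self.haplotype_labels))} distinct haplotypes")


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalise_base(ch: str) -> str:
    """Fold IUPAC ambiguity codes and N into the missing token."""
    up = ch.upper()
    if up in "ACGT":
        return up
    if up == GAP:
        return GAP
    if up in _IUPAC_AMBIGUOUS:
        return MISSING
    raise AlignmentError(f"unexpected alignment character {ch!r}")


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

def read_region_alignment(path: str | Path,
                          region_name: str | None = None) -> RegionAlignment:
    """Read one aligned FASTA file into a RegionAlignment.

    The region name defaults to the file stem.  Ragged records raise
    ``AlignmentError`` naming the file and offending record.
    """
    path = Path(path)
    name = region_name or path.stem
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path),
                                                             "fasta")]
    if not records:
        return RegionAlignment(name, (), 0)
    length = len(records[0][1])
    for sid, seq in records:
        if len(seq) != length:
            raise AlignmentError(
                f"{path}: record {sid!r} has length {len(seq)}, "
                f"expected {length} (ragged alignment)")
    return RegionAlignment(name, tuple(records), length)


def read_region_alignments(paths: Sequence[str | Path]
                           ) -> list[RegionAlignment]:
    """Read one FASTA per region and verify a shared sample set."""
    alignments = [read_region_alignment(p) for p in paths]
    if alignments:
        ref = set(alignments[0].sample_ids)
        for aln in alignments[1:]:
            ids = set(aln.sample_ids)
            if ids != ref:
                raise AlignmentError(
                    f"sample sets differ between regions "
                    f"{alignments[0].region_name!r} and "
                    f"{aln.region_name!r}: only in first "
                    f"{sorted(ref - ids)}, only in second "
                    f"{sorted(ids - ref)}")
    return alignments


def write_region_alignment(aln: RegionAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.samples:
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Population table
# ---------------------------------------------------------------------------

def _parse_optional_float(cell: str, what: str, row_id: str) -> float | None:
    cell = cell.strip()
    if cell in ("", "-", "–", "—"):
        return None
    try:
        return float(cell)
    except ValueError:
        raise TableError(f"{row_id}: cannot parse {what} {cell!r}") from None


def read_population_table(path: str | Path) -> list[PopulationRecord]:
    """Read the population metadata CSV.

    Expected header: population_id,location,country,range_class,latitude,
    longitude,altitude_m,collection_year,n_samples,haplotypes,group.
    Multiple haplotype labels are separated by ``;``.  Empty cells and
    en-dashes are missing values.
    """
    records: list[PopulationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        required = {"population_id", "range_class", "n_samples", "haplotypes"}
        missing_cols = required - set(reader.fieldnames)
        if missing_cols:
            raise TableError(
                f"{path}: missing columns {sorted(missing_cols)}")
        for row in reader:
            pid = row["population_id"].strip()
            year = _parse_optional_float(row.get("collection_year", ""),
                                         "collection_year", pid)
            labels = tuple(
                lab.strip() for lab in
                re.split(r"[;,]", row["haplotypes"]) if lab.strip())
            records.append(PopulationRecord(
                population_id=pid,
                location=row.get("location", "").strip(),
                country=row.get("country", "").strip(),
                range_class=row["range_class"].strip(),
                latitude=_parse_optional_float(row.get("latitude", ""),
                                               "latitude", pid),
                longitude=_parse_optional_float(row.get("longitude", ""),
                                                "longitude", pid),
                altitude_m=_parse_optional_float(row.get("altitude_m", ""),
                                                 "altitude_m", pid),
                collection_year=int(year) if year is not None else None,
                n_samples=int(row["n_samples"]),
                haplotype_labels=labels,
                group_label=row.get("group", "").strip() or None,
            ))
    return records


# ---------------------------------------------------------------------------
# Haplotype matrix readers/writers
# ---------------------------------------------------------------------------

def _event_header(ev: VariantEvent) -> str:
    return f"{ev.region_name}|{ev.span[0]}|{ev.span[1]}|{ev.kind}"


def _event_from_header(tok: str, states: dict[str, str]) -> VariantEvent:
    try:
        region, lo, hi, kind = tok.split("|")
        span = (int(lo), int(hi))
    except ValueError:
        raise TableError(f"malformed event column header {tok!r}") from None
    detail = None
    if kind == "indel":
        present = sorted({t for t in states.values()
                          if t not in (GAP, MISSING)})
        detail = present[0] if present else None
    elif kind == "inversion":
        strings = sorted({t for t in states.values() if t != MISSING})
        if len(strings) == 2:
            a, b = strings
            if reverse_complement(a) == b:
                # orient so detail[0] is the majority string
                vals = list(states.values())
                fwd = a if vals.count(a) >= vals.count(b) else b
                detail = (fwd, reverse_complement(fwd))
    return VariantEvent(region, kind, span, states, detail)


def write_haplotype_matrix(matrix: HaplotypeMatrix, path: str | Path,
                           dialect: str = "tsv") -> None:
    """Write a haplotype matrix as TSV or as a NEXUS characters block.

    The TSV dialect has one row per haplotype and one column per event,
    with headers ``region|start|end|kind``.  The NEXUS dialect emits a
    ``datatype=standard`` matrix in which each event's state tokens are
    mapped to digit symbols; the token legend is stored in ``[&cpnet ...]``
    comments so the matrix can be read back losslessly.
    """
    if dialect == "tsv":
        _write_matrix_tsv(matrix, path)
    elif dialect == "nexus":
        _write_matrix_nexus(matrix, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_matrix_tsv(matrix: HaplotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["haplotype"] +
                           [_event_header(e) for e in matrix.events]) + "\n")
        for label, vec in matrix.haplotypes.items():
            fh.write("\t".join([label, *vec]) + "\n")


def read_haplotype_matrix(path: str | Path) -> HaplotypeMatrix:
    """Read back a TSV haplotype matrix (inverse of the TSV writer)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TableError(f"{path}: empty matrix file")
    header = lines[0].split("\t")[1:]
    haplotypes: dict[str, tuple[str, ...]] = {}
    for ln in lines[1:]:
        cells = ln.split("\t")
        haplotypes[cells[0]] = tuple(cells[1:])
    events = []
    for j, tok in enumerate(header):
        states = {lab: vec[j] for lab, vec in haplotypes.items()}
        events.append(_event_from_header(tok, states))
    return HaplotypeMatrix(events, haplotypes)


def _write_matrix_nexus(matrix: HaplotypeMatrix, path: str | Path) -> None:
    events = matrix.events
    symbol_maps: list[dict[str, str]] = []
    for j, ev in enumerate(events):
        tokens = sorted({vec[j] for vec in matrix.haplotypes.values()
                         if vec[j] != MISSING})
        if len(tokens) > 10:
            raise TableError(
                f"event {_event_header(ev)} has {len(tokens)} states; "
                "NEXUS digit symbols support at most 10")
        symbol_maps.append({tok: str(i) for i, tok in enumerate(tokens)})
    with open(path, "w") as fh:
        fh.write("#NEXUS\n")
        fh.write("[Haplotype variant-state matrix; one character per "
                 "mutational event]\n")
        for j, (ev, smap) in enumerate(zip(events, symbol_maps)):
            legend = ",".join(f"{sym}={tok}"
                              for tok, sym in sorted(smap.items(),
                                                     key=lambda kv: kv[1]))
            fh.write(f"[&cpnet char {j + 1} {_event_header(ev)} {legend}]\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.haplotypes)};\n")
        fh.write("  TAXLABELS " + " ".join(matrix.haplotypes) + ";\nEND;\n")
        fh.write("BEGIN CHARACTERS;\n")
        fh.write(f"  DIMENSIONS NCHAR={len(events)};\n")
        fh.write("  FORMAT DATATYPE=STANDARD SYMBOLS=\"0123456789\" "
                 "MISSING=?;\n")
        fh.write("  MATRIX\n")
        for label, vec in matrix.haplotypes.items():
            row = "".join(MISSING if t == MISSING else symbol_maps[j][t]
                          for j, t in enumerate(vec))
            fh.write(f"    {label} {row}\n")
        fh.write("  ;\nEND;\n")


def read_haplotype_matrix_nexus(path: str | Path) -> HaplotypeMatrix:
    """Read back a NEXUS matrix written by :func:`write_haplotype_matrix`."""
    legend_re = re.compile(
        r"\[&cpnet char (\d+) (\S+) (\S+)\]")
    headers: dict[int, str] = {}
    legends: dict[int, dict[str, str]] = {}
    rows: dict[str, str] = {}
    in_matrix = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            m = legend_re.match(line)
            if m:
                idx = int(m.group(1)) - 1
                headers[idx] = m.group(2)
                legends[idx] = {}
                for pair in m.group(3).split(","):
                    sym, tok = pair.split("=", 1)
                    legends[idx][sym] = tok
                continue
            if line.upper() == "MATRIX":
                in_matrix = True
                continue
            if in_matrix:
                if line.startswith(";"):
                    in_matrix = False
                    continue
                if line:
                    label, symbols = line.split()
                    rows[label] = symbols
    n = len(headers)
    haplotypes = {
        lab: tuple(MISSING if s == MISSING else legends[j][s]
                   for j, s in enumerate(symbols))
        for lab, symbols in rows.items()}
    events = []
    for j in range(n):
        states = {lab: vec[j] for lab, vec in haplotypes.items()}
        events.append(_event_from_header(headers[j], states))
    return HaplotypeMatrix(events, haplotypes)


# ---------------------------------------------------------------------------
# Packaged fixtures (published polymorphic-site and site tables)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("cpnet.data").joinpath(name)

def load_haplotype_matrix() -> HaplotypeMatrix:
    """The published 23-haplotype x 42-event variant-state matrix."""
    with resources.as_file(_data_path("study_haplotypes.tsv")) as p:
        return read_haplotype_matrix(p)


def load_populations() -> list[PopulationRecord]:
    """The published 52-population site table (introduced + native range)."""
    with resources.as_file(_data_path("study_populations.csv")) as p:
        return read_population_table(p)


def load_relabel_map() -> dict[str, str]:
    """Discovery-order letters -> published letters, for samples expanded
    from the packaged site table in row order."""
    mapping = {}
    with resources.as_file(_data_path("relabel_published.tsv")) as p:
        with open(p) as fh:
            for ln in fh:
                if ln.strip() and not ln.startswith("#"):
                    a, b = ln.split()
                    mapping[a] = b
    return mapping
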