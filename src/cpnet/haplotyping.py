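"""Stages 2 and 4: haplotype collapsing and range-level summaries.

Per-sample state vectors are collapsed into haplotypes by exact match;
letters are assigned deterministically (A, B, C, ... in order of first
appearance) with an optional relabelling map to recover a published
lettering.  Downstream summaries reproduce the population-level statistics
a phylogeographic survey reports: haplotypes per range class (introduced vs
native), within-population fixation, per-haplotype prevalence, and a
geographic export for mapping.
"""

from __future__ import annotations

import csv
import itertools
import json
import logging
import string
from dataclasses import dataclass, field

from .io_model import (
    MISSING,
    CpnetError,
    HaplotypeMatrix,
    PopulationRecord,
    VariantEvent,
)

logger = logging.getLogger("cpnet")


class HaplotypingError(CpnetError):
    pass


def _letters():
    """A, B, ..., Z, AA, AB, ... — deterministic haplotype letters."""
    for size in itertools.count(1):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


# ---------------------------------------------------------------------------
# Samples from the population table
# ---------------------------------------------------------------------------

def samples_from_populations(pops: list[PopulationRecord]
                             ) -> list[tuple[str, str, str]]:
    """Expand population records into (sample_id, population_id, label).

    Sample ids are ``<population>_<i>``.  Listed haplotype labels are dealt
    to samples in order; when a population has more samples than listed
    labels the last label fills the remainder (published tables list each
    label once, with at most as many labels as samples).
    """
    out = []
    for pop in pops:
        labels = pop.haplotype_labels
        if not labels:
            raise HaplotypingError(
                f"population {pop.population_id} lists no haplotypes")
        for i in range(pop.n_samples):
            lab = labels[i] if i < len(labels) else labels[-1]
            out.append((f"{pop.population_id}_{i + 1}",
                        pop.population_id, lab))
    return out


def sample_events(matrix: HaplotypeMatrix,
                  pops: list[PopulationRecord]
                  ) -> tuple[list[VariantEvent], list[str], dict[str, str]]:
    """Per-sample variant events built from a haplotype matrix + site table.

    Returns (events keyed by sample id, ordered sample ids,
    sample -> population mapping).
    """
    triples = samples_from_populations(pops)
    unknown = sorted({lab for _, _, lab in triples}
                     - set(matrix.haplotypes))
    if unknown:
        raise HaplotypingError(
            f"population table references unknown haplotypes: {unknown}")
    samples = [sid for sid, _, _ in triples]
    sample_pop = {sid: pid for sid, pid, _ in triples}
    events = []
    for j, ev in enumerate(matrix.events):
        states = {sid: matrix.haplotypes[lab][j]
                  for sid, _, lab in triples}
        events.append(VariantEvent(ev.region_name, ev.kind, ev.span,
                                   states, ev.detail))
    return events, samples, sample_pop


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

def collapse_haplotypes(events: list[VariantEvent],
                        samples: list[str],
                        relabel_map: dict[str, str] | None = None
                        ) -> HaplotypeMatrix:
    """Collapse per-sample state vectors into haplotypes.

    Samples with identical state vectors share a haplotype (exact match;
    the gap state is a state, so indel variants stay distinct here).  A
    sample whose vector contains the missing token matches nothing: it
    receives its own provisional haplotype and a logged warning, rather
    than being silently merged with its nearest neighbour.  Letters follow
    first appearance in the given sample order; ``relabel_map`` renames
    them afterwards (e.g. to a published lettering).
    """
    for ev in events:
        absent = [s for s in samples if s not in ev.states]
        if absent:
            raise HaplotypingError(
                f"samples missing a state at "
                f"{ev.region_name}:{ev.span[0]}-{ev.span[1]}: {absent[:5]}")
    vectors = {sid: tuple(ev.states[sid] for ev in events)
               for sid in samples}
    letters = _letters()
    by_vector: dict[tuple, str] = {}
    assignment: dict[str, str] = {}
    haplotypes: dict[str, tuple[str, ...]] = {}
    provisional = []
    for sid in samples:
        vec = vectors[sid]
        if MISSING in vec:
            label = next(letters)
            haplotypes[label] = vec
            assignment[sid] = label
            provisional.append(label)
            continue
        if vec not in by_vector:
            label = next(letters)
            by_vector[vec] = label
            haplotypes[label] = vec
        assignment[sid] = by_vector[vec]
    if provisional:
        logger.warning(
            "%d samples with missing states were given provisional "
            "haplotypes flagged for review: %s",
            len(provisional), provisional)
    hap_events = []
    for j, ev in enumerate(events):
        states = {lab: vec[j] for lab, vec in haplotypes.items()}
        hap_events.append(VariantEvent(ev.region_name, ev.kind, ev.span,
                                       states, ev.detail))
    matrix = HaplotypeMatrix(hap_events, haplotypes, assignment)
    if relabel_map:
        matrix = relabel(matrix, relabel_map)
    return matrix


def relabel(matrix: HaplotypeMatrix,
            mapping: dict[str, str]) -> HaplotypeMatrix:
    """Rename haplotype labels with a bijective mapping."""
    new_names = [mapping.get(lab, lab) for lab in matrix.haplotypes]
    if len(set(new_names)) != len(new_names):
        raise HaplotypingError("relabelling map is not injective")
    haplotypes = {mapping.get(lab, lab): vec
                  for lab, vec in matrix.haplotypes.items()}
    events = [ev.relabelled(mapping) for ev in matrix.events]
    assignment = {sid: mapping.get(lab, lab)
                  for sid, lab in matrix.sample_assignment.items()}
    return HaplotypeMatrix(events, haplotypes, assignment)


def match_labels_to_reference(matrix: HaplotypeMatrix,
                              reference: HaplotypeMatrix
                              ) -> dict[str, str]:
    """Map collapsed labels onto a reference lettering by state vector.

    Both matrices must share the same event list (keys, in order); every
    collapsed vector must occur exactly once in the reference.
    """
    if [e.key() for e in matrix.events] != \
            [e.key() for e in reference.events]:
        raise HaplotypingError(
            "matrices are over different event lists; cannot match labels")
    ref_by_vec: dict[tuple, str] = {}
    for lab, vec in reference.haplotypes.items():
        if vec in ref_by_vec:
            raise HaplotypingError(
                f"reference vectors not unique ({ref_by_vec[vec]}/{lab})")
        ref_by_vec[vec] = lab
    mapping = {}
    for lab, vec in matrix.haplotypes.items():
        if vec not in ref_by_vec:
            raise HaplotypingError(
                f"haplotype {lab} has no match in the reference matrix")
        mapping[lab] = ref_by_vec[vec]
    return mapping


def read_relabel_map(path) -> dict[str, str]:
    with open(path) as fh:
        rows = [ln.split() for ln in fh if ln.strip()
                and not ln.startswith("#")]
    return {a: b for a, b in rows}


# ---------------------------------------------------------------------------
# Population / range summaries
# ---------------------------------------------------------------------------

def _sample_pop_map(matrix: HaplotypeMatrix,
                    pops: list[PopulationRecord],
                    sample_populations: dict[str, str] | None
                    ) -> dict[str, str]:
    if sample_populations is not None:
        mapping = dict(sample_populations)
    else:
        pids = sorted((p.population_id for p in pops), key=len, reverse=True)
        mapping = {}
        for sid in matrix.sample_assignment:
            pid = next((p for p in pids if sid.startswith(p + "_")), None)
            if pid is not None:
                mapping[sid] = pid
    known = {p.population_id for p in pops}
    orphans = sorted(set(matrix.sample_assignment) - set(mapping)) + \
        sorted(s for s, p in mapping.items() if p not in known)
    if orphans:
        raise HaplotypingError(
            f"samples with unknown population: {orphans[:10]}")
    return mapping


@dataclass
class RangeSummary:
    """Haplotype counts split by range class."""

    introduced: list[str]
    native: list[str]
    shared: list[str]
    unique_introduced: list[str]
    unique_native: list[str]
    populations_per_haplotype: dict[str, dict[str, int]]

    def as_dict(self) -> dict:
        return {
            "n_haplotypes_introduced": len(self.introduced),
            "n_haplotypes_native": len(self.native),
            "n_shared": len(self.shared),
            "n_unique_introduced": len(self.unique_introduced),
            "n_unique_native": len(self.unique_native),
            "introduced": self.introduced,
            "native": self.native,
            "shared": self.shared,
            "populations_per_haplotype": self.populations_per_haplotype,
        }


def range_summary(matrix: HaplotypeMatrix,
                  pops: list[PopulationRecord],
                  sample_populations: dict[str, str] | None = None
                  ) -> RangeSummary:
    """Haplotypes observed in the introduced vs native range.

    Counts distinct haplotypes per range class, those unique to each class,
    and those shared, plus per-haplotype population counts by range.
    """
    spmap = _sample_pop_map(matrix, pops, sample_populations)
    pop_range = {p.population_id: p.range_class for p in pops}
    hap_pops: dict[str, set[str]] = {}
    for sid, lab in matrix.sample_assignment.items():
        hap_pops.setdefault(lab, set()).add(spmap[sid])
    by_range = {"introduced": set(), "native": set()}
    per_hap: dict[str, dict[str, int]] = {}
    for lab, pids in hap_pops.items():
        classes = {pid: pop_range[pid] for pid in pids}
        per_hap[lab] = {
            "introduced": sum(1 for c in classes.values()
                              if c == "introduced"),
            "native": sum(1 for c in classes.values() if c == "native"),
        }
        for c in set(classes.values()):
            by_range[c].add(lab)
    shared = by_range["introduced"] & by_range["native"]
    return RangeSummary(
        introduced=sorted(by_range["introduced"]),
        native=sorted(by_range["native"]),
        shared=sorted(shared),
        unique_introduced=sorted(by_range["introduced"] - shared),
        unique_native=sorted(by_range["native"] - shared),
        populations_per_haplotype={k: per_hap[k] for k in sorted(per_hap)},
    )


@dataclass
class FixationSummary:
    """Within-population fixation among populations with >= 2 samples."""

    eligible: int
    fixed: int
    polymorphic: list[tuple[str, tuple[str, ...]]]

    def as_dict(self) -> dict:
        return {
            "eligible_populations": self.eligible,
            "fixed_populations": self.fixed,
            "polymorphic_populations": [
                {"population_id": pid, "haplotypes": list(labs)}
                for pid, labs in self.polymorphic],
        }


def fixation_summary(matrix: HaplotypeMatrix,
                     pops: list[PopulationRecord],
                     sample_populations: dict[str, str] | None = None
                     ) -> FixationSummary:
    """Monomorphic vs polymorphic populations among those with >= 2 samples."""
    spmap = _sample_pop_map(matrix, pops, sample_populations)
    pop_haps: dict[str, set[str]] = {}
    pop_n: dict[str, int] = {}
    for sid, lab in matrix.sample_assignment.items():
        pid = spmap[sid]
        pop_haps.setdefault(pid, set()).add(lab)
        pop_n[pid] = pop_n.get(pid, 0) + 1
    eligible = [pid for pid, n in pop_n.items() if n >= 2]
    polymorphic = sorted(
        (pid, tuple(sorted(pop_haps[pid])))
        for pid in eligible if len(pop_haps[pid]) > 1)
    return FixationSummary(
        eligible=len(eligible),
        fixed=len(eligible) - len(polymorphic),
        polymorphic=polymorphic,
    )


@dataclass
class Prevalence:
    """Where one haplotype occurs, split by range class and country."""

    haplotype: str
    populations: dict[str, list[str]]          # range class -> population ids
    range_totals: dict[str, int]               # range class -> total pops
    by_country: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "haplotype": self.haplotype,
            "populations": self.populations,
            "counts": {k: len(v) for k, v in self.populations.items()},
            "range_totals": self.range_totals,
            "by_country": self.by_country,
        }


def haplotype_prevalence(matrix: HaplotypeMatrix,
                         pops: list[PopulationRecord],
                         haplotype_label: str,
                         sample_populations: dict[str, str] | None = None
                         ) -> Prevalence:
    if haplotype_label not in matrix.haplotypes:
        raise HaplotypingError(
            f"unknown haplotype label {haplotype_label!r}")
    spmap = _sample_pop_map(matrix, pops, sample_populations)
    by_pop = {p.population_id: p for p in pops}
    carrying = sorted({spmap[sid]
                       for sid, lab in matrix.sample_assignment.items()
                       if lab == haplotype_label})
    populations = {"introduced": [], "native": []}
    by_country: dict[str, int] = {}
    for pid in carrying:
        rec = by_pop[pid]
        populations[rec.range_class].append(pid)
        by_country[rec.country] = by_country.get(rec.country, 0) + 1
    totals = {
        "introduced": sum(1 for p in pops
                          if p.range_class == "introduced"),
        "native": sum(1 for p in pops if p.range_class == "native"),
    }
    return Prevalence(haplotype_label, populations, totals, by_country)


# ---------------------------------------------------------------------------
# Geographic export
# ---------------------------------------------------------------------------

def export_geography(matrix: HaplotypeMatrix,
                     pops: list[PopulationRecord],
                     path,
                     format: str = "geojson",
                     sample_populations: dict[str, str] | None = None
                     ) -> None:
    """Per-population haplotype content with coordinates (CSV or GeoJSON).

    One feature/row per population carrying coordinates; populations without
    coordinates are skipped with a logged warning naming them.  GeoJSON uses
    WGS84 [longitude, latitude] point order.
    """
    spmap = _sample_pop_map(matrix, pops, sample_populations)
    counts: dict[str, dict[str, int]] = {}
    for sid, lab in matrix.sample_assignment.items():
        pid = spmap[sid]
        counts.setdefault(pid, {})
        counts[pid][lab] = counts[pid].get(lab, 0) + 1
    skipped = [p.population_id for p in pops
               if p.latitude is None or p.longitude is None]
    if skipped:
        logger.warning("populations without coordinates skipped from "
                       "geographic export: %s", skipped)
    rows = [p for p in pops
            if p.latitude is not None and p.longitude is not None]
    if format == "geojson":
        features = []
        for p in rows:
            hap_counts = counts.get(p.population_id, {})
            features.append({
                "type": "Feature",
                "geometry": {"type": "Point",
                             "coordinates": [p.longitude, p.latitude]},
                "properties": {
                    "population_id": p.population_id,
                    "country": p.country,
                    "range_class": p.range_class,
                    "haplotypes": sorted(hap_counts),
                    "haplotype_counts": dict(sorted(hap_counts.items())),
                },
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features},
                      fh, indent=1)
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["population_id", "country", "range_class",
                             "latitude", "longitude", "haplotypes",
                             "haplotype_counts"])
            for p in rows:
                hap_counts = counts.get(p.population_id, {})
                writer.writerow([
                    p.population_id, p.country, p.range_class,
                    p.latitude, p.longitude,
                    ";".join(sorted(hap_counts)),
                    ";".join(f"{k}:{v}"
                             for k, v in sorted(hap_counts.items()))])
    else:
        raise ValueError(f"unknown geography format {format!r}")
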