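"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators live here:

* :func:`synthesize_alignments` — embed a haplotype variant-state matrix into
  invariant random backgrounds, producing full-length per-region alignments
  whose scan reproduces the matrix exactly (the inverse of variant scanning).
  This turns the published polymorphic-site table back into the six-region
  alignment it summarises.
* :func:`simulate_genealogy` — grow a random haplotype genealogy by applying
  one new mutation (substitution, indel, or inversion) per new haplotype,
  emitting alignments plus the ground truth for property-based testing of
  the scanner and network builder.

Neither generator models coalescent history or mutation-rate realism; they
exist to exercise the pipeline against known truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_model import (
    GAP,
    MISSING,
    CpnetError,
    HaplotypeMatrix,
    REGION_LENGTHS,
    REGION_ORDER,
    RegionAlignment,
    VariantEvent,
    reverse_complement,
)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimulationError(CpnetError):
    """Invalid simulation request (overlapping spans, no sequence space)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the genealogy simulator.

    Region lengths default to the six study regions' aligned lengths
    (906/804/813/632/397/1,047 bp).  Exactly ``n_haplotypes - 1`` mutation
    events are required (one per new haplotype): ``n_substitutions +
    n_indels + n_inversions`` must equal that.  Indels are 1-5 bp and
    inversions 3-6 bp by default, bracketing the published event sizes.
    """

    region_lengths: tuple[int, ...] = tuple(REGION_LENGTHS.values())
    region_names: tuple[str, ...] | None = None
    n_haplotypes: int = 8
    n_substitutions: int = 7
    n_indels: int = 0
    n_inversions: int = 0
    indel_lengths: tuple[int, ...] = (1, 2, 3, 4, 5)
    inversion_lengths: tuple[int, ...] = (3, 4, 5, 6)
    samples_per_haplotype: int = 1
    homoplasy_rate: float = 0.0
    seed: int = 0

    def names(self) -> tuple[str, ...]:
        if self.region_names is not None:
            if len(self.region_names) != len(self.region_lengths):
                raise SimulationError("region_names/region_lengths mismatch")
            return self.region_names
        if tuple(self.region_lengths) == tuple(REGION_LENGTHS.values()):
            return REGION_ORDER
        return tuple(f"region{i + 1}" for i in range(len(self.region_lengths)))

    def validate(self) -> None:
        if self.n_haplotypes < 1:
            raise SimulationError("n_haplotypes must be >= 1")
        n_events = self.n_substitutions + self.n_indels + self.n_inversions
        if n_events != self.n_haplotypes - 1:
            raise SimulationError(
                f"{n_events} events requested for {self.n_haplotypes} "
                "haplotypes; need exactly one event per new haplotype")
        if any(length < 4 for length in self.region_lengths):
            raise SimulationError("regions shorter than 4 bp are not useful")
        if not 0.0 <= self.homoplasy_rate <= 1.0:
            raise SimulationError("homoplasy_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """True haplotype states, genealogy edges, and event catalogue."""

    matrix: HaplotypeMatrix
    edges: set[tuple[str, str]]  # (parent label, child label), one per event

    @property
    def events(self) -> list[VariantEvent]:
        return self.matrix.events


# ---------------------------------------------------------------------------
# Alignment synthesis (inverse of scanning)
# ---------------------------------------------------------------------------

def _check_spans(events: list[VariantEvent],
                 lengths: dict[str, int]) -> None:
    by_region: dict[str, list[tuple[int, int]]] = {}
    for ev in events:
        if ev.region_name not in lengths:
            raise SimulationError(
                f"no region length given for {ev.region_name!r}")
        if ev.span[1] > lengths[ev.region_name]:
            raise SimulationError(
                f"event span {ev.span} exceeds region "
                f"{ev.region_name!r} length {lengths[ev.region_name]}")
        by_region.setdefault(ev.region_name, []).append(ev.span)
    for region, spans in by_region.items():
        spans.sort()
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise SimulationError(
                    f"overlapping event spans {a1}-{b1} and {a2}-{b2} "
                    f"in region {region!r}")


def _token_chars(token: str, width: int) -> str:
    if token == GAP:
        return GAP * width
    if token == MISSING:
        return "N" * width
    if len(token) != width:
        raise SimulationError(
            f"state token {token!r} does not fit span width {width}")
    return token


def synthesize_alignments(matrix: HaplotypeMatrix,
                          region_lengths: dict[str, int] | None = None,
                          seed: int = 0) -> list[RegionAlignment]:
    """Embed haplotype states into invariant random backgrounds.

    Each region receives a uniform-random A/C/G/T background drawn from a
    seed stream independent of event placement, then every haplotype's state
    tokens are written into the event spans (insertions as present-vs-gap
    segments, inversions as forward vs reverse-complement segments).  When
    the matrix carries a sample assignment, one alignment row is emitted per
    sample; otherwise one row per haplotype.
    """
    lengths = dict(region_lengths or REGION_LENGTHS)
    regions_in_matrix = []
    for ev in matrix.events:
        if ev.region_name not in regions_in_matrix:
            regions_in_matrix.append(ev.region_name)
    for region in regions_in_matrix:
        if region not in lengths:
            raise SimulationError(f"no length for region {region!r}")
    _check_spans(matrix.events, lengths)

    # stable region order: canonical first, then first-appearance
    ordered = [r for r in REGION_ORDER if r in lengths] + \
              [r for r in lengths if r not in REGION_ORDER]

    if matrix.sample_assignment:
        rows = list(matrix.sample_assignment.items())
    else:
        rows = [(label, label) for label in matrix.haplotypes]

    alignments = []
    for ridx, region in enumerate(ordered):
        rng = np.random.default_rng([seed, ridx])
        length = lengths[region]
        background = "".join(rng.choice(list(_BASES), size=length))
        per_hap: dict[str, str] = {}
        for label, vec in matrix.haplotypes.items():
            chars = list(background)
            for ev, token in zip(matrix.events, vec):
                if ev.region_name != region:
                    continue
                lo, hi = ev.span
                chars[lo - 1:hi] = _token_chars(token, hi - lo + 1)
            per_hap[label] = "".join(chars)
        samples = tuple((sid, per_hap[label]) for sid, label in rows)
        alignments.append(RegionAlignment(region, samples, length))
    return alignments


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------

def _place_span(rng, occupied: dict[str, set[int]],
                lengths: dict[str, int], width: int) -> tuple[str, int]:
    """Pick a region and start for a new event span.

    Spans keep one background column away from region ends and from other
    events, so independent events never fuse into one gap run or one
    substitution cluster during scanning.
    """
    regions = list(lengths)
    weights = np.array([lengths[r] for r in regions], dtype=float)
    weights /= weights.sum()
    for _ in range(2000):
        region = str(rng.choice(regions, p=weights))
        length = lengths[region]
        if length < width + 4:
            continue
        lo = int(rng.integers(2, length - width))
        cols = set(range(lo - 1, lo + width + 1))  # span + 1-col buffer
        if cols & occupied[region]:
            continue
        occupied[region].update(cols)
        return region, lo
    raise SimulationError(
        "insufficient sequence space for requested events")


def _random_inversion_string(rng, width: int) -> str:
    """A span string whose reverse complement differs at every position."""
    chars = [""] * width
    for i in range((width + 1) // 2):
        j = width - 1 - i
        chars[i] = _BASES[rng.integers(4)]
        if i == j:
            continue
        banned = _COMPLEMENT[chars[i]]
        choices = [b for b in _BASES if b != banned]
        chars[j] = choices[rng.integers(3)]
    return "".join(chars)


def simulate_genealogy(config: SimulationConfig
                       ) -> tuple[GroundTruth, list[RegionAlignment]]:
    """Grow a random haplotype genealogy with known mutation events.

    Starting from an ancestral haplotype ``H1``, each new haplotype attaches
    to a uniformly chosen existing haplotype and differs from it by exactly
    one new event at a previously unused locus (homoplasy-free by default;
    with ``homoplasy_rate`` > 0, a substitution may instead strike an
    already-used substitution column).  Returns the ground truth and the
    synthesized per-region alignments; byte-identical output for identical
    config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.names()
    lengths = dict(zip(names, config.region_lengths))
    occupied: dict[str, set[int]] = {r: set() for r in names}

    kinds = (["substitution"] * config.n_substitutions +
             ["indel"] * config.n_indels +
             ["inversion"] * config.n_inversions)
    rng.shuffle(kinds)

    labels = [f"H{i + 1}" for i in range(config.n_haplotypes)]
    # per-haplotype event tokens; events appended as created
    catalogue: list[dict] = []
    hap_tokens: list[list[str]] = [[]]
    edges: set[tuple[str, str]] = set()

    for child_idx in range(1, config.n_haplotypes):
        parent_idx = int(rng.integers(0, child_idx))
        kind = kinds[child_idx - 1]
        parent_tokens = list(hap_tokens[parent_idx])
        # pad parent to current catalogue length (ancestral tokens)
        assert len(parent_tokens) == len(catalogue)

        homoplasy = (kind == "substitution" and config.homoplasy_rate > 0 and
                     rng.random() < config.homoplasy_rate and
                     any(e["kind"] == "substitution" for e in catalogue))
        if homoplasy:
            target = rng.choice([i for i, e in enumerate(catalogue)
                                 if e["kind"] == "substitution"])
            old = parent_tokens[target]
            new = _BASES[rng.integers(4)]
            while new == old:
                new = _BASES[rng.integers(4)]
            child_tokens = parent_tokens
            child_tokens[target] = new
        else:
            if kind == "substitution":
                width = 1
            elif kind == "indel":
                width = int(rng.choice(config.indel_lengths))
            else:
                width = int(rng.choice(config.inversion_lengths))
            region, lo = _place_span(rng, occupied, lengths, width)
            span = (lo, lo + width - 1)
            if kind == "substitution":
                ancestral = None  # background base, filled at realisation
                derived = _BASES[rng.integers(4)]
                entry = {"kind": kind, "region": region, "span": span,
                         "derived": derived}
            elif kind == "indel":
                if rng.random() < 0.5:  # deletion in the child lineage
                    entry = {"kind": kind, "region": region, "span": span,
                             "derived": GAP, "ancestral": None}
                else:  # insertion in the child lineage
                    seg = "".join(rng.choice(list(_BASES), size=width))
                    entry = {"kind": kind, "region": region, "span": span,
                             "derived": seg, "ancestral": GAP}
            else:
                fwd = _random_inversion_string(rng, width)
                entry = {"kind": kind, "region": region, "span": span,
                         "derived": reverse_complement(fwd),
                         "ancestral": fwd}
            catalogue.append(entry)
            for tokens in hap_tokens:
                tokens.append("__ANC__")
            child_tokens = parent_tokens + ["__ANC__"]
            child_tokens[-1] = entry["derived"]
        hap_tokens.append(child_tokens)
        edges.add((labels[parent_idx], labels[child_idx]))

    # pad all haplotypes to full catalogue length
    for tokens in hap_tokens:
        tokens.extend(["__ANC__"] * (len(catalogue) - len(tokens)))

    # realise ancestral tokens: substitutions/deletions use a drawn base or
    # segment; insertions use GAP for non-carriers
    for entry in catalogue:
        lo, hi = entry["span"]
        width = hi - lo + 1
        if entry["kind"] == "substitution":
            anc = _BASES[rng.integers(4)]
            while anc == entry["derived"]:
                anc = _BASES[rng.integers(4)]
            entry["ancestral"] = anc
        elif entry.get("ancestral") is None:  # deletion: ancestral segment
            entry["ancestral"] = "".join(rng.choice(list(_BASES),
                                                    size=width))

    events: list[VariantEvent] = []
    for eidx, entry in enumerate(catalogue):
        states = {}
        for label, tokens in zip(labels, hap_tokens):
            tok = tokens[eidx]
            states[label] = entry["ancestral"] if tok == "__ANC__" else tok
        if entry["kind"] == "indel":
            present = sorted({t for t in states.values() if t != GAP})
            detail = present[0] if len(present) == 1 else None
        elif entry["kind"] == "inversion":
            vals = list(states.values())
            a, b = sorted(set(vals))
            majority = a if vals.count(a) >= vals.count(b) else b
            detail = (majority, reverse_complement(majority))
        else:
            detail = None
        events.append(VariantEvent(entry["region"], entry["kind"],
                                   entry["span"], states, detail))

    # order events by region then span, consistently with scanning
    order = sorted(range(len(events)),
                   key=lambda i: (names.index(events[i].region_name),
                                  events[i].span))
    events = [events[i] for i in order]
    haplotypes = {
        label: tuple(events[k].states[label] for k in range(len(events)))
        for label in labels}
    sample_assignment = {
        f"{label}_{s + 1}": label
        for label in labels
        for s in range(config.samples_per_haplotype)}
    matrix = HaplotypeMatrix(events, haplotypes, sample_assignment)
    truth = GroundTruth(matrix=matrix, edges=edges)
    alignments = synthesize_alignments(
        matrix, lengths, seed=int(np.random.default_rng(
            [config.seed, 9999]).integers(2 ** 31)))
    return truth, alignments
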