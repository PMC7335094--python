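"""Stage 1: turn per-region alignments into an ordered variant-event catalogue.

Three event classes are extracted from each region's gapped alignment:

* **substitutions** — single columns with two or more distinct bases;
* **indel events** — gap runs merged so that one insertion/deletion of any
  length counts as one event ("simple indel coding": a 5-bp insertion is one
  mutation, not five);
* **inversions** (optional) — short spans where one group of sequences reads
  the exact reverse complement of the rest, recoded as a single two-state
  event in place of the substitution columns they would otherwise produce.

Events carry 1-based inclusive spans in their own region's coordinates and a
state token per sample (see :mod:`cpnet.io_model` for token conventions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_model import (
    GAP,
    MISSING,
    AlignmentError,
    CpnetError,
    RegionAlignment,
    VariantEvent,
    normalise_base,
    reverse_complement,
)

logger = logging.getLogger("cpnet")


class CurationError(CpnetError):
    """Automatic inversion calling is ambiguous; manual curation required."""


@dataclass(frozen=True)
class ScanConfig:
    """Options for :func:`scan_all`.

    Inversion detection is off by default so that the scanned catalogue
    matches the granularity of a published polymorphic-site table, where
    inversion columns are listed among the substitutions; switch it on to
    recode each inversion as a single mutational event for network building.
    """

    detect_inversions: bool = False
    inversion_min_len: int = 3
    inversion_max_len: int = 10
    inversion_min_columns: int = 2
    keep_terminal_gaps: bool = False
    region_order: tuple[str, ...] | None = None


def _normalised_rows(aln: RegionAlignment,
                     keep_terminal_gaps: bool) -> dict[str, str]:
    """Uppercase rows with ambiguity codes folded to '?'.

    Leading/trailing gap runs usually reflect incomplete reads rather than
    mutations; unless kept, they are masked to missing.
    """
    rows = {}
    for sid, seq in aln.samples:
        chars = [normalise_base(c) for c in seq]
        if not keep_terminal_gaps:
            i = 0
            while i < len(chars) and chars[i] == GAP:
                chars[i] = MISSING
                i += 1
            j = len(chars) - 1
            while j >= 0 and chars[j] == GAP:
                chars[j] = MISSING
                j -= 1
        rows[sid] = "".join(chars)
    return rows


def find_substitution_sites(aln: RegionAlignment,
                            keep_terminal_gaps: bool = False
                            ) -> list[VariantEvent]:
    """One substitution event per column with >= 2 distinct bases.

    Columns whose only variation involves gaps are left to the indel merger.
    Gapped or ambiguous samples receive the missing token at the event.
    """
    rows = _normalised_rows(aln, keep_terminal_gaps)
    events = []
    for pos in range(1, aln.aligned_length + 1):
        column = {sid: row[pos - 1] for sid, row in rows.items()}
        bases = {c for c in column.values() if c not in (GAP, MISSING)}
        if len(bases) >= 2:
            states = {sid: (c if c in bases else MISSING)
                      for sid, c in column.items()}
            events.append(VariantEvent(aln.region_name, "substitution",
                                       (pos, pos), states))
    return events


def _interior_gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' in a normalised row (1-based inclusive spans)."""
    runs = []
    start = None
    for i, c in enumerate(row, start=1):
        if c == GAP and start is None:
            start = i
        elif c != GAP and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def merge_indel_events(aln: RegionAlignment,
                       keep_terminal_gaps: bool = False
                       ) -> list[VariantEvent]:
    """Merge shared gap runs into single indel events.

    A maximal gap run becomes one multi-column event only when every sequence
    gapped anywhere in its span shares exactly the same run extent (same
    start, same end) — each such run is one historical insertion/deletion.
    Overlapping runs with different extents are decomposed into per-column
    presence/absence events, which keeps every event two-state and
    well-defined when independent indels abut.
    """
    rows = _normalised_rows(aln, keep_terminal_gaps)
    if not rows:
        return []
    run_carriers: dict[tuple[int, int], list[str]] = {}
    for sid, row in rows.items():
        for run in _interior_gap_runs(row):
            run_carriers.setdefault(run, []).append(sid)

    def run_is_clean(span: tuple[int, int]) -> bool:
        lo, hi = span
        for row in rows.values():
            seg = row[lo - 1:hi]
            if GAP in seg and seg != GAP * (hi - lo + 1):
                return False
            if seg == GAP * (hi - lo + 1):
                # fully gapped: must be exactly this maximal run
                if (lo > 1 and row[lo - 2] == GAP) or \
                        (hi < len(row) and row[hi] == GAP):
                    return False
        return True

    events: list[VariantEvent] = []
    percolumn: set[int] = set()
    for span in sorted(run_carriers):
        if run_is_clean(span):
            lo, hi = span
            states = {}
            for sid, row in rows.items():
                seg = row[lo - 1:hi]
                if seg == GAP * (hi - lo + 1):
                    states[sid] = GAP
                elif MISSING in seg:
                    states[sid] = MISSING
                else:
                    states[sid] = seg
            present = sorted({t for t in states.values()
                              if t not in (GAP, MISSING)})
            detail = present[0] if len(present) == 1 else None
            events.append(VariantEvent(aln.region_name, "indel",
                                       span, states, detail))
        else:
            percolumn.update(range(span[0], span[1] + 1))

    for pos in sorted(percolumn):
        column = {sid: row[pos - 1] for sid, row in rows.items()}
        tokens = set(column.values()) - {MISSING}
        if GAP not in tokens or len(tokens) < 2:
            continue
        present = sorted(tokens - {GAP})
        detail = present[0] if len(present) == 1 else None
        events.append(VariantEvent(aln.region_name, "indel",
                                   (pos, pos), column, detail))
    events.sort(key=lambda e: e.span)
    return events


def detect_inversions(aln: RegionAlignment,
                      substitution_events: list[VariantEvent],
                      min_len: int = 3,
                      max_len: int = 10,
                      min_columns: int = 2,
                      keep_terminal_gaps: bool = False
                      ) -> tuple[list[VariantEvent], list[VariantEvent]]:
    """Recode reverse-complement spans as single inversion events.

    Scans every span of ``min_len``..``max_len`` columns containing at least
    ``min_columns`` substitution columns and no gaps.  Where the sequences
    fall into exactly two span-strings, one the exact reverse complement of
    the other, the span becomes one inversion event and the substitution
    events inside it are removed.  Nested candidate spans resolve to the
    largest; partially overlapping candidates raise :class:`CurationError`
    (the published data never needed that path — an automatic rule cannot
    arbitrate it).

    Returns ``(inversions, pruned_substitutions)``.
    """
    rows = _normalised_rows(aln, keep_terminal_gaps)
    sub_cols = {ev.span[0] for ev in substitution_events}
    candidates: list[tuple[int, int]] = []
    length = aln.aligned_length
    for lo in range(1, length + 1):
        for span_len in range(min_len, max_len + 1):
            hi = lo + span_len - 1
            if hi > length:
                break
            n_subs = sum(1 for c in range(lo, hi + 1) if c in sub_cols)
            if n_subs < min_columns:
                continue
            segs = {sid: row[lo - 1:hi] for sid, row in rows.items()}
            if any(GAP in s or MISSING in s for s in segs.values()):
                continue
            distinct = set(segs.values())
            if len(distinct) != 2:
                continue
            a, b = sorted(distinct)
            if reverse_complement(a) != b or a == b:
                continue
            # trim to the variable columns: invariant flanks that happen to
            # be mutually complementary must not widen the reported span
            inside = [c for c in range(lo, hi + 1) if c in sub_cols]
            lo2, hi2 = min(inside), max(inside)
            if hi2 - lo2 + 1 < min_len:
                continue
            if (lo2, hi2) != (lo, hi):
                segs2 = {sid: row[lo2 - 1:hi2] for sid, row in rows.items()}
                d2 = sorted(set(segs2.values()))
                if len(d2) != 2 or reverse_complement(d2[0]) != d2[1]:
                    continue
            if (lo2, hi2) not in candidates:
                candidates.append((lo2, hi2))

    # keep only maximal candidates; partial overlap is a curation problem
    maximal = [c for c in candidates
               if not any(o != c and o[0] <= c[0] and c[1] <= o[1]
                          for o in candidates)]
    maximal.sort()
    for (a1, b1), (a2, b2) in zip(maximal, maximal[1:]):
        if a2 <= b1:
            raise CurationError(
                f"overlapping inversion candidates {a1}-{b1} and {a2}-{b2} "
                f"in region {aln.region_name!r}; manual curation required")

    inversions = []
    absorbed: set[int] = set()
    for lo, hi in maximal:
        segs = {sid: row[lo - 1:hi] for sid, row in rows.items()}
        a, b = sorted(set(segs.values()))
        counts = list(segs.values())
        majority = a if counts.count(a) >= counts.count(b) else b
        minority = reverse_complement(majority)
        inversions.append(VariantEvent(
            aln.region_name, "inversion", (lo, hi), segs,
            (majority, minority)))
        absorbed.update(range(lo, hi + 1))
        logger.info("region %s: inversion %d-%d (%s / %s)",
                    aln.region_name, lo, hi, majority, minority)
    pruned = [ev for ev in substitution_events
              if ev.span[0] not in absorbed]
    return inversions, pruned


def scan_region(aln: RegionAlignment,
                config: ScanConfig = ScanConfig()) -> list[VariantEvent]:
    """All events of one region, ordered by span start."""
    subs = find_substitution_sites(aln, config.keep_terminal_gaps)
    indels = merge_indel_events(aln, config.keep_terminal_gaps)
    inversions: list[VariantEvent] = []
    if config.detect_inversions:
        inversions, subs = detect_inversions(
            aln, subs,
            min_len=config.inversion_min_len,
            max_len=config.inversion_max_len,
            min_columns=config.inversion_min_columns,
            keep_terminal_gaps=config.keep_terminal_gaps)
    events = subs + indels + inversions
    events.sort(key=lambda e: e.span)
    return events


def scan_all(regions: list[RegionAlignment],
             config: ScanConfig = ScanConfig()) -> list[VariantEvent]:
    """Concatenate per-region event lists in region order then span order.

    Regions are processed in the order given by ``config.region_order`` when
    set, otherwise in the study's canonical order for the six study regions
    (falling back to input order for other region names).
    """
    from .io_model import REGION_ORDER

    by_name = {aln.region_name: aln for aln in regions}
    if len(by_name) != len(regions):
        raise AlignmentError("duplicate region names in scan input")
    if config.region_order is not None:
        missing = [r for r in config.region_order if r not in by_name]
        if missing:
            raise AlignmentError(f"region_order names absent from input: "
                                 f"{missing}")
        ordered = [by_name[r] for r in config.region_order]
    elif set(by_name) <= set(REGION_ORDER):
        ordered = sorted(regions, key=lambda a: REGION_ORDER.index(
            a.region_name))
    else:
        ordered = list(regions)
    events: list[VariantEvent] = []
    for aln in ordered:
        events.extend(scan_region(aln, config))
    return events


# ---------------------------------------------------------------------------
# Event-table serialisation (CLI surface)
# ---------------------------------------------------------------------------

def events_to_table(events: list[VariantEvent], path) -> None:
    """Write events as TSV: region, kind, span, detail, then sample states."""
    sample_ids: list[str] = []
    for ev in events:
        for sid in ev.states:
            if sid not in sample_ids:
                sample_ids.append(sid)
    with open(path, "w") as fh:
        fh.write("\t".join(["region", "kind", "span_start", "span_end",
                            "detail", *sample_ids]) + "\n")
        for ev in events:
            if ev.kind == "inversion":
                detail = "/".join(ev.detail)
            else:
                detail = ev.detail or ""
            row = [ev.region_name, ev.kind, str(ev.span[0]),
                   str(ev.span[1]), detail]
            row += [ev.states.get(sid, MISSING) for sid in sample_ids]
            fh.write("\t".join(row) + "\n")


def events_from_table(path) -> list[VariantEvent]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    sample_ids = header[5:]
    events = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        region, kind, lo, hi, detail = cells[:5]
        states = dict(zip(sample_ids, cells[5:]))
        if kind == "inversion":
            det = tuple(detail.split("/"))
        elif kind == "indel":
            det = detail or None
        else:
            det = None
        events.append(VariantEvent(region, kind, (int(lo), int(hi)),
                                   states, det))
    return events
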