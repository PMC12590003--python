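"""FASTQ to filtered sensor-level counts.

The reads are rigid amplicons (``sample_index + flank_5p + tag + flank_3p``),
so quantification is dictionary lookup, not alignment: wells are demultiplexed
on the sample index, the 5' anchor is located at its expected offset (allowing
one mismatch), and the extracted tag is matched against the panel whitelist at
Hamming distance <= 1 by default.  Because tags sit at pairwise distance >= 3,
a single substitution always has a unique nearest tag; reads failing anchor or
tag lookup are tallied per failure category and never redistributed.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import SampleSheet
from .panel import ALPHABET, SensorPanel, hamming

__all__ = [
    "CountMatrix",
    "AssignmentStats",
    "QuantifyError",
    "mismatch_lookup",
    "demultiplex",
    "extract_and_assign",
    "count_tags",
    "quantify_reads",
    "collapse_to_sensors",
    "filter_low_baseline",
]

#: Assignment failure/success categories, in reporting order.
CATEGORIES = ("assigned", "ambiguous", "unassigned_no_anchor", "unassigned_no_tag")

AMBIGUOUS = "__ambiguous__"


class QuantifyError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Integer counts, tags-or-sensors x wells.

    ``level`` is ``"tag"`` or ``"sensor"``; ``stats`` optionally carries the
    per-well :class:`AssignmentStats` table.
    """

    counts: pd.DataFrame
    level: str
    stats: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in ("tag", "sensor"):
            raise ValueError(f"level must be 'tag' or 'sensor', got {self.level!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def wells(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, level: str) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df, level=level)


@dataclass
class AssignmentStats:
    """Per-well read accounting; the four categories partition reads_total,
    and ``corrected`` (distance-1 matches) is a subset of ``assigned``."""

    table: pd.DataFrame  # index well_id; columns reads_total, assigned, corrected, ...

    def verify_partition(self) -> None:
        t = self.table
        total = t[list(CATEGORIES)].sum(axis=1)
        if not (total == t["reads_total"]).all():
            bad = t.index[total != t["reads_total"]].tolist()
            raise QuantifyError(f"assignment categories do not partition reads_total in wells {bad}")


def _neighbors1(seq: str):
    """All sequences at Hamming distance exactly 1."""
    for i, base in enumerate(seq):
        for b in ALPHABET:
            if b != base:
                yield seq[:i] + b + seq[i + 1 :]


def mismatch_lookup(seqs: dict[str, str], max_mm: int) -> dict[str, tuple[str, int]]:
    """Build variant -> (label, distance) lookup for Hamming radius ``max_mm``.

    ``seqs`` maps label -> sequence.  Variants reachable from two labels at
    the same minimal distance map to ``(AMBIGUOUS, d)``; an exact sequence
    always beats a distance-1 neighbor.  Radii above 1 are expanded
    recursively (practical only for short sequences).
    """
    table: dict[str, tuple[str, int]] = {}

    def _put(variant: str, label: str, d: int) -> None:
        if variant in table:
            old_label, old_d = table[variant]
            if d < old_d:
                table[variant] = (label, d)
            elif d == old_d and old_label != label:
                table[variant] = (AMBIGUOUS, d)
        else:
            table[variant] = (label, d)

    for label, seq in seqs.items():
        _put(seq, label, 0)
    frontier = {label: [seq] for label, seq in seqs.items()}
    for d in range(1, max_mm + 1):
        nxt: dict[str, list[str]] = {}
        for label, variants in frontier.items():
            out = set()
            for v in variants:
                for n in _neighbors1(v):
                    _put(n, label, d)
                    out.add(n)
            nxt[label] = list(out)
        frontier = nxt
    return table


def _index_lookup(samples: SampleSheet, max_index_mm: int, *, validate: bool = True):
    idx_map = samples.index_map()  # sequence -> well
    if validate and max_index_mm > 0:
        idxs = list(idx_map)
        for a, b in itertools.combinations(idxs, 2):
            if hamming(a, b) <= 2 * max_index_mm:
                raise QuantifyError(
                    f"sample indices {a} ({idx_map[a]}) and {b} ({idx_map[b]}) collide "
                    f"at mismatch radius {max_index_mm}"
                )
    labelled = {well: seq for seq, well in idx_map.items()}
    return mismatch_lookup(labelled, max_index_mm)


def open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_reads(path):
    """Yield read sequences from a (optionally gzipped) FASTQ file."""
    with open_maybe_gzip(path) as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq


def demultiplex(
    reads,
    samples: SampleSheet,
    max_index_mm: int = 1,
    *,
    _validate: bool = True,
) -> tuple[dict[str, list[str]], int]:
    """Split reads by sample index; returns (well -> reads, orphan count).

    ``reads`` is an iterable of read sequences or a FASTQ path.  A read whose
    leading index matches no well within ``max_index_mm`` — or ties between
    two wells at the same distance — is an orphan.  Refuses to run if two
    indices collide at the configured radius (disable via ``_validate`` only
    in controlled tests).
    """
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = iter_reads(reads)
    lookup = _index_lookup(samples, max_index_mm, validate=_validate)
    ilen = samples.index_length
    by_well: dict[str, list[str]] = {w: [] for w in samples.well_ids}
    orphans = 0
    for seq in reads:
        hit = lookup.get(seq[:ilen])
        if hit is None or hit[0] == AMBIGUOUS:
            orphans += 1
        else:
            by_well[hit[0]].append(seq)
    return by_well, orphans


def extract_and_assign(
    read: str,
    panel: SensorPanel,
    max_tag_mm: int = 1,
    *,
    offset: int = 0,
    _tag_lookup: dict | None = None,
) -> tuple[str, str | None, bool]:
    """Assign one read to a tag; returns (category, tag_id or None, corrected).

    The 5' anchor is expected at ``offset`` (the sample-index length when the
    index is still attached); up to one anchor mismatch is tolerated.  The
    following ``tag_length`` bases are matched against the whitelist at
    Hamming distance <= ``max_tag_mm``; a distance-1 hit is flagged
    ``corrected``; ties are ``ambiguous``.
    """
    f5 = panel.flank_5p
    anchor = read[offset : offset + len(f5)]
    if len(anchor) < len(f5) or hamming(anchor, f5) > 1:
        return "unassigned_no_anchor", None, False
    start = offset + len(f5)
    tag = read[start : start + panel.tag_length]
    if len(tag) < panel.tag_length:
        return "unassigned_no_tag", None, False
    if _tag_lookup is None:
        _tag_lookup = mismatch_lookup({t.tag_id: t.sequence for t in panel.tags}, max_tag_mm)
    hit = _tag_lookup.get(tag)
    if hit is None:
        return "unassigned_no_tag", None, False
    tag_id, dist = hit
    if tag_id == AMBIGUOUS:
        return "ambiguous", None, False
    return "assigned", tag_id, dist > 0


def count_tags(
    assignments: dict[str, list[tuple[str, str | None, bool]]],
    panel: SensorPanel,
) -> tuple[CountMatrix, AssignmentStats]:
    """Tally per-well assignment lists into a tag-level matrix plus stats."""
    wells = list(assignments)
    tag_ids = [t.tag_id for t in panel.tags]
    counts = pd.DataFrame(0, index=pd.Index(tag_ids, name="tag_id"), columns=wells, dtype=int)
    stats_rows = []
    for well, items in assignments.items():
        tallies = dict.fromkeys(CATEGORIES, 0)
        corrected = 0
        for category, tag_id, was_corrected in items:
            tallies[category] += 1
            if category == "assigned":
                counts.loc[tag_id, well] += 1
                corrected += int(was_corrected)
        stats_rows.append(
            {
                "well_id": well,
                "reads_total": len(items),
                "corrected": corrected,
                **tallies,
            }
        )
    stats = AssignmentStats(pd.DataFrame(stats_rows).set_index("well_id"))
    stats.verify_partition()
    cm = CountMatrix(counts=counts, level="tag", stats=stats.table)
    return cm, stats


def quantify_reads(
    reads,
    panel: SensorPanel,
    samples: SampleSheet,
    *,
    max_index_mm: int = 1,
    max_tag_mm: int = 1,
) -> tuple[CountMatrix, AssignmentStats, int]:
    """End-to-end: FASTQ (path or sequence iterable) -> tag-level counts.

    Returns (tag-level CountMatrix, AssignmentStats, orphan count).  Single
    streaming pass; assignment is order-independent by construction.
    """
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = iter_reads(reads)
    idx_lookup = _index_lookup(samples, max_index_mm)
    tag_lookup = mismatch_lookup({t.tag_id: t.sequence for t in panel.tags}, max_tag_mm)
    ilen = samples.index_length

    wells = samples.well_ids
    tag_ids = [t.tag_id for t in panel.tags]
    tag_pos = {t: i for i, t in enumerate(tag_ids)}
    well_pos = {w: j for j, w in enumerate(wells)}
    counts = np.zeros((len(tag_ids), len(wells)), dtype=np.int64)
    stats = {w: dict.fromkeys(("reads_total", "corrected", *CATEGORIES), 0) for w in wells}
    orphans = 0
    for seq in reads:
        hit = idx_lookup.get(seq[:ilen])
        if hit is None or hit[0] == AMBIGUOUS:
            orphans += 1
            continue
        well = hit[0]
        category, tag_id, corrected = extract_and_assign(
            seq, panel, max_tag_mm, offset=ilen, _tag_lookup=tag_lookup
        )
        st = stats[well]
        st["reads_total"] += 1
        st[category] += 1
        if category == "assigned":
            st["corrected"] += int(corrected)
            counts[tag_pos[tag_id], well_pos[well]] += 1

    stats_df = pd.DataFrame(stats).T
    stats_df.index.name = "well_id"
    astats = AssignmentStats(stats_df)
    astats.verify_partition()
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(tag_ids, name="tag_id"), columns=wells),
        level="tag",
        stats=stats_df,
    )
    return cm, astats, orphans


def collapse_to_sensors(
    counts: CountMatrix, panel: SensorPanel
) -> tuple[CountMatrix, pd.DataFrame]:
    """Sum tag counts to sensor level; returns (sensor matrix, control table).

    The control reporter's four tags are returned individually in the side
    table (tags x wells) for size-factor estimation; in the sensor matrix the
    control row is their sum like any other sensor.
    """
    tag_to_sensor = panel.tag_to_sensor()
    unknown = [t for t in counts.counts.index if t not in tag_to_sensor]
    if unknown:
        raise QuantifyError(f"tag_ids not in panel: {unknown}")
    sensor_order = panel.sensor_ids
    grouped = counts.counts.groupby(
        counts.counts.index.map(tag_to_sensor), sort=False
    ).sum()
    grouped = grouped.reindex(sensor_order).fillna(0).astype(int)
    grouped.index.name = "sensor_id"

    ctrl_tags = [t.tag_id for t in panel.control_sensor.tags]
    control_table = counts.counts.reindex(ctrl_tags).fillna(0).astype(int)
    control_table.index.name = "tag_id"

    cm = CountMatrix(counts=grouped, level="sensor", stats=counts.stats)
    return cm, control_table


def filter_low_baseline(
    counts: CountMatrix,
    samples: SampleSheet,
    size_factors: pd.Series,
    min_baseline_mean: float = 10.0,
    *,
    control_sensor: str | None = "MLPmin",
) -> tuple[CountMatrix, list[str]]:
    """Drop sensors whose mean normalized count over vehicle wells is below
    ``min_baseline_mean``; the control reporter is never dropped.

    Returns (filtered matrix, dropped sensor list).  Mirrors the assay's
    baseline-expression exclusion (which removed IL6p).
    """
    if counts.level != "sensor":
        raise QuantifyError("filter_low_baseline expects a sensor-level matrix")
    vehicle = samples.vehicle_wells()
    vehicle = [w for w in vehicle if w in counts.counts.columns]
    if not vehicle:
        raise QuantifyError("no vehicle wells in design: baseline undefined")
    missing = [w for w in vehicle if w not in size_factors.index]
    if missing:
        raise QuantifyError(f"size factors missing for wells {missing}")
    norm = counts.counts[vehicle] / size_factors[vehicle]
    baseline = norm.mean(axis=1)
    dropped = [
        sid
        for sid in counts.counts.index
        if baseline[sid] < min_baseline_mean and sid != control_sensor
    ]
    kept = counts.counts.drop(index=dropped)
    return CountMatrix(counts=kept, level="sensor", stats=counts.stats), dropped
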