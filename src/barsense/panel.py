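"""Sensor panel data model, validation, and TSV I/O.

A panel is a roster of pathway sensors — synthetic transcription-factor
binding-site (TFBS) clusters or human promoters driving a transcribed RNA
barcode — plus one minimal-promoter control reporter (MLPmin) whose barcodes
anchor well-to-well normalization.  Each pathway sensor is represented by two
barcoded constructs and the control by four, so the default panel of
22 pathway sensors + 1 control carries 48 barcode tags.

Barcode tags are fixed-length nucleotide strings kept at pairwise Hamming
distance >= 3, which guarantees that single-substitution sequencing errors
can be corrected unambiguously.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BarcodeTag",
    "Sensor",
    "SensorPanel",
    "ValidationReport",
    "PanelError",
    "PanelGenerationError",
    "hamming",
    "min_pairwise_hamming",
    "load_panel",
    "write_panel",
    "validate_panel",
    "build_default_panel",
    "CATEGORIES",
    "DEFAULT_TAG_LENGTH",
    "DEFAULT_FLANK_5P",
    "DEFAULT_FLANK_3P",
    "CONTROL_SENSOR_ID",
    "NAMED_SENSORS",
]

ALPHABET = "ACGT"

CATEGORIES = (
    "synaptic activity & calcium",
    "MAPK & IEG response",
    "cell fate",
    "cellular stress",
    "immune response",
    "metabolism",
    "stem cell pluripotency",
    "control",
)

CONTROL_SENSOR_ID = "MLPmin"

#: Sensors named in the running text, with their signaling category and class.
NAMED_SENSORS = {
    "EGR1p": ("MAPK & IEG response", "human promoter"),
    "FOSp": ("MAPK & IEG response", "human promoter"),
    "FOSBp": ("MAPK & IEG response", "human promoter"),
    "NR4A1p": ("synaptic activity & calcium", "human promoter"),
    "SRE": ("MAPK & IEG response", "synthetic TFBS"),
    "AP1-RE-v1": ("MAPK & IEG response", "synthetic TFBS"),
    "UPRE-v2": ("synaptic activity & calcium", "synthetic TFBS"),
    "CRE": ("synaptic activity & calcium", "synthetic TFBS"),
    "SARE": ("synaptic activity & calcium", "synthetic TFBS"),
    "IL6p": ("immune response", "human promoter"),
}

#: Categories for the 12 placeholder sensors standing in for the unnamed part
#: of the roster (annotation only; never used by any statistic).
_PLACEHOLDER_CATEGORIES = (
    "cell fate",
    "cell fate",
    "cellular stress",
    "cellular stress",
    "immune response",
    "metabolism",
    "metabolism",
    "stem cell pluripotency",
    "stem cell pluripotency",
    "MAPK & IEG response",
    "synaptic activity & calcium",
    "cell fate",
)

DEFAULT_TAG_LENGTH = 10
DEFAULT_FLANK_5P = "ACGTACGATCGT"  # fixed 12-nt constant anchors
DEFAULT_FLANK_3P = "TCAGGCATTAGC"
MIN_TAG_DISTANCE = 3
N_TAGS_PATHWAY = 2
N_TAGS_CONTROL = 4


class PanelError(ValueError):
    """Raised when a panel file or object violates a structural invariant."""


class PanelGenerationError(RuntimeError):
    """Raised when barcode generation cannot satisfy the distance constraint."""


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_hamming(seqs: list[str]) -> tuple[int, tuple[int, int]]:
    """Minimum pairwise Hamming distance and the (i, j) index pair achieving it."""
    best = (len(seqs[0]) + 1, (-1, -1))
    for i, j in itertools.combinations(range(len(seqs)), 2):
        d = hamming(seqs[i], seqs[j])
        if d < best[0]:
            best = (d, (i, j))
    return best


@dataclass(frozen=True)
class BarcodeTag:
    """A transcribed barcode identifying one sensor construct."""

    tag_id: str
    sequence: str
    sensor_id: str


@dataclass
class Sensor:
    """A pathway sensor (or the control reporter) and its barcode tags."""

    sensor_id: str
    category: str
    sensor_class: str
    tags: list[BarcodeTag] = field(default_factory=list)

    @property
    def is_control(self) -> bool:
        return self.category == "control"


@dataclass
class SensorPanel:
    """The full sensor roster plus the read-layout constants.

    ``flank_5p`` / ``flank_3p`` are the constant anchor sequences surrounding
    the tag in a sequencing read; they are declared in the panel file so that
    simulation and quantification always agree on the read architecture.
    """

    tag_length: int
    flank_5p: str
    flank_3p: str
    sensors: list[Sensor]

    @property
    def tags(self) -> list[BarcodeTag]:
        return [t for s in self.sensors for t in s.tags]

    @property
    def tag_sequences(self) -> list[str]:
        return [t.sequence for t in self.tags]

    @property
    def sensor_ids(self) -> list[str]:
        return [s.sensor_id for s in self.sensors]

    @property
    def control_sensor(self) -> Sensor:
        controls = [s for s in self.sensors if s.is_control]
        if len(controls) != 1:
            raise PanelError(f"expected exactly one control sensor, found {len(controls)}")
        return controls[0]

    @property
    def pathway_sensors(self) -> list[Sensor]:
        return [s for s in self.sensors if not s.is_control]

    def tag_to_sensor(self) -> dict[str, str]:
        return {t.tag_id: t.sensor_id for t in self.tags}

    def whitelist(self) -> dict[str, str]:
        """Map tag sequence -> tag_id."""
        return {t.sequence: t.tag_id for t in self.tags}


@dataclass
class ValidationReport:
    """Per-invariant pass/fail listing produced by :func:`validate_panel`."""

    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks.append((name, passed, detail))

    @property
    def passed(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[tuple[str, str]]:
        return [(name, detail) for name, ok, detail in self.checks if not ok]

    def __str__(self) -> str:
        lines = []
        for name, ok, detail in self.checks:
            mark = "PASS" if ok else "FAIL"
            lines.append(f"[{mark}] {name}" + (f": {detail}" if detail else ""))
        return "\n".join(lines)


def validate_panel(
    panel: SensorPanel,
    *,
    min_distance: int = MIN_TAG_DISTANCE,
    expect_default_structure: bool = True,
) -> ValidationReport:
    """Check every panel invariant and report each one.

    With ``expect_default_structure`` the tag-per-sensor counts of the default
    assay (2 per pathway sensor, 4 for the control) are enforced; panels with
    other layouts can disable it.
    """
    rep = ValidationReport()
    tags = panel.tags

    bad_alpha = [t.tag_id for t in tags if set(t.sequence) - set(ALPHABET)]
    rep.add("tag alphabet A/C/G/T", not bad_alpha, f"offending tags: {bad_alpha}" if bad_alpha else "")

    bad_len = [t.tag_id for t in tags if len(t.sequence) != panel.tag_length]
    rep.add(
        f"tag length == {panel.tag_length}",
        not bad_len,
        f"offending tags: {bad_len}" if bad_len else "",
    )

    seen: dict[str, str] = {}
    dups: list[str] = []
    for t in tags:
        if t.sequence in seen:
            dups.append(f"{seen[t.sequence]}/{t.tag_id}")
        else:
            seen[t.sequence] = t.tag_id
    rep.add("tag sequences unique", not dups, f"duplicate pairs: {dups}" if dups else "")

    if not bad_len and not dups and len(tags) >= 2:
        d, (i, j) = min_pairwise_hamming([t.sequence for t in tags])
        ok = d >= min_distance
        rep.add(
            f"min pairwise Hamming distance >= {min_distance}",
            ok,
            "" if ok else f"closest pair {tags[i].tag_id}/{tags[j].tag_id} at distance {d}",
        )

    controls = [s for s in panel.sensors if s.is_control]
    rep.add(
        "exactly one control sensor",
        len(controls) == 1,
        f"found {len(controls)}: {[s.sensor_id for s in controls]}" if len(controls) != 1 else "",
    )

    if expect_default_structure:
        bad_pathway = [
            s.sensor_id for s in panel.pathway_sensors if len(s.tags) != N_TAGS_PATHWAY
        ]
        rep.add(
            f"pathway sensors carry {N_TAGS_PATHWAY} tags",
            not bad_pathway,
            f"offending sensors: {bad_pathway}" if bad_pathway else "",
        )
        bad_ctrl = [s.sensor_id for s in controls if len(s.tags) != N_TAGS_CONTROL]
        rep.add(
            f"control sensor carries {N_TAGS_CONTROL} tags",
            not bad_ctrl,
            f"offending sensors: {bad_ctrl}" if bad_ctrl else "",
        )

    bad_cat = [s.sensor_id for s in panel.sensors if s.category not in CATEGORIES]
    rep.add("sensor categories recognised", not bad_cat, f"{bad_cat}" if bad_cat else "")

    return rep


# ---------------------------------------------------------------------------
# TSV I/O
#
# Format: '# key=value' header lines (tag_length, flank_5p, flank_3p) followed
# by a tab-separated table with columns
#   sensor_id  category  sensor_class  tag_id  tag_sequence
# one row per tag, sensors kept contiguous and in file order.
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["sensor_id", "category", "sensor_class", "tag_id", "tag_sequence"]


def load_panel(path, *, validate: bool = True) -> SensorPanel:
    """Read a panel TSV, validate it, and return the :class:`SensorPanel`.

    Raises :class:`PanelError` naming the offending rows on any violation.
    """
    header: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise PanelError(f"{path}: no data rows")
    if rows[0] != _PANEL_COLUMNS:
        missing = set(_PANEL_COLUMNS) - set(rows[0])
        raise PanelError(f"{path}: bad column header; missing {sorted(missing)}")
    for key in ("tag_length", "flank_5p", "flank_3p"):
        if key not in header:
            raise PanelError(f"{path}: missing '# {key}=' header line")
    tag_length = int(header["tag_length"])

    sensors: dict[str, Sensor] = {}
    order: list[str] = []
    for i, row in enumerate(rows[1:], 2):
        if len(row) != len(_PANEL_COLUMNS):
            raise PanelError(f"{path}: row {i}: expected {len(_PANEL_COLUMNS)} fields, got {len(row)}")
        sensor_id, category, sensor_class, tag_id, seq = row
        if sensor_id not in sensors:
            sensors[sensor_id] = Sensor(sensor_id, category, sensor_class)
            order.append(sensor_id)
        sensors[sensor_id].tags.append(BarcodeTag(tag_id, seq, sensor_id))

    panel = SensorPanel(
        tag_length=tag_length,
        flank_5p=header["flank_5p"],
        flank_3p=header["flank_3p"],
        sensors=[sensors[s] for s in order],
    )
    if validate:
        rep = validate_panel(panel)
        if not rep.passed:
            msgs = "; ".join(f"{n} ({d})" if d else n for n, d in rep.failures())
            raise PanelError(f"{path}: panel validation failed: {msgs}")
    return panel


def write_panel(panel: SensorPanel, path) -> None:
    """Write a panel to TSV in the canonical header + table layout."""
    with open(path, "w") as fh:
        fh.write(f"# tag_length={panel.tag_length}\n")
        fh.write(f"# flank_5p={panel.flank_5p}\n")
        fh.write(f"# flank_3p={panel.flank_3p}\n")
        fh.write("\t".join(_PANEL_COLUMNS) + "\n")
        for s in panel.sensors:
            for t in s.tags:
                fh.write(f"{s.sensor_id}\t{s.category}\t{s.sensor_class}\t{t.tag_id}\t{t.sequence}\n")


# ---------------------------------------------------------------------------
# Default panel builder
# ---------------------------------------------------------------------------


def generate_tag_set(
    n: int,
    length: int,
    rng: np.random.Generator,
    *,
    min_distance: int = MIN_TAG_DISTANCE,
    max_attempts: int = 20000,
) -> list[str]:
    """Draw ``n`` random tags of ``length`` nt at pairwise Hamming >= min_distance.

    Rejection sampling with a bounded retry budget; raises
    :class:`PanelGenerationError` rather than silently relaxing the distance.
    """
    chosen: list[str] = []
    arrs: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > max_attempts:
            raise PanelGenerationError(
                f"could not place {n} tags of length {length} at distance "
                f">= {min_distance} within {max_attempts} draws"
            )
        cand = rng.integers(0, 4, size=length)
        if arrs and min(int((cand != a).sum()) for a in arrs) < min_distance:
            continue
        arrs.append(cand)
        chosen.append("".join(ALPHABET[b] for b in cand))
    return chosen


def build_default_panel(
    seed: int,
    *,
    tag_length: int = DEFAULT_TAG_LENGTH,
    flank_5p: str = DEFAULT_FLANK_5P,
    flank_3p: str = DEFAULT_FLANK_3P,
) -> SensorPanel:
    """Build the default 23-sensor / 48-tag panel with seeded random barcodes.

    The ten sensors named in the assay description keep their names; twelve
    generically named placeholder sensors complete the roster of 22 pathway
    sensors (the published supplementary roster is not reproduced here), plus
    the MLPmin control on four tags.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    roster: list[tuple[str, str, str]] = [
        (name, cat, cls) for name, (cat, cls) in NAMED_SENSORS.items()
    ]
    for i, cat in enumerate(_PLACEHOLDER_CATEGORIES, 1):
        cls = "synthetic TFBS" if i % 2 else "human promoter"
        roster.append((f"PLACEHOLDER-{i:02d}", cat, cls))
    n_tags = len(roster) * N_TAGS_PATHWAY + N_TAGS_CONTROL
    seqs = generate_tag_set(n_tags, tag_length, rng)

    sensors: list[Sensor] = []
    k = 0
    for sensor_id, category, sensor_class in roster:
        tags = []
        for rep in range(1, N_TAGS_PATHWAY + 1):
            tags.append(BarcodeTag(f"{sensor_id}_bc{rep}", seqs[k], sensor_id))
            k += 1
        sensors.append(Sensor(sensor_id, category, sensor_class, tags))
    ctrl_tags = []
    for rep in range(1, N_TAGS_CONTROL + 1):
        ctrl_tags.append(BarcodeTag(f"{CONTROL_SENSOR_ID}_bc{rep}", seqs[k], CONTROL_SENSOR_ID))
        k += 1
    sensors.append(Sensor(CONTROL_SENSOR_ID, "control", "control", ctrl_tags))

    return SensorPanel(tag_length=tag_length, flank_5p=flank_5p, flank_3p=flank_3p, sensors=sensors)
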