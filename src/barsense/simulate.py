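"""Seeded simulators for barcode count matrices and amplicon FASTQ reads.

The count model mirrors what the differential module estimates: the count of
tag ``t`` (belonging to sensor ``i``) in well ``j`` is drawn

    K_tj ~ NegativeBinomial(mean = s_j * q_i * w_t * 2**LFC_i(cond_j),
                            variance = mu + alpha_i * mu**2)

with per-well size factor ``s_j`` (sequencing depth / cell number), sensor
baseline ``q_i``, within-sensor tag weight ``w_t`` (summing to 1 over a
sensor's tags), and a condition-dependent log2 fold change given by a Hill
dose-response curve:

    LFC_i(cond) = gamma**[cKO] * Lmax * dose**h / (EC50**h + dose**h)

zero for vehicle, attenuated by ``gamma`` in the knockout genotype, and zero
at the 24 h timepoint for transient stimuli.  The control reporter always has
LFC = 0.  Every draw is recorded in a :class:`GroundTruth` object so that
recovery tests never re-derive the truth.

Reads are emitted one per count unit with the rigid amplicon layout

    sample_index + flank_5p + tag + flank_3p

and i.i.d. per-base substitution errors.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SampleSheet, STRATUM_COLUMNS
from .panel import ALPHABET, SensorPanel
from .quantify import CountMatrix

__all__ = [
    "Effect",
    "EffectSpec",
    "GroundTruth",
    "hill_lfc",
    "default_effects",
    "default_baselines",
    "simulate_counts",
    "simulate_reads",
]

DEFAULT_SIZE_FACTOR_SD = 0.3
DEFAULT_DISPERSION = 0.05
DEFAULT_BASELINE_MEAN = 500.0

#: Sensors that respond to each stimulus in the default effect table
#: (MAPK/IEG sensors respond to everything; calcium sensors to all but BDNF).
_MAPK_SENSORS = ("EGR1p", "FOSp", "FOSBp", "SRE", "AP1-RE-v1")
_CALCIUM_SENSORS = ("CRE", "UPRE-v2", "NR4A1p", "SARE")


def hill_lfc(dose: float, lmax: float, ec50: float, hill: float) -> float:
    """Hill-type log2 fold change at ``dose``: Lmax * d^h / (EC50^h + d^h)."""
    if dose <= 0:
        return 0.0
    dh = dose**hill
    return lmax * dh / (ec50**hill + dh)


@dataclass(frozen=True)
class Effect:
    """Dose-response parameters of one (sensor, treatment) pair.

    ``attenuation_gamma`` multiplies Lmax in the knockout genotype;
    ``transient`` zeroes the effect at the 24 h timepoint.
    """

    sensor_id: str
    treatment: str
    lmax: float
    ec50: float
    hill: float = 1.0
    attenuation_gamma: float = 1.0
    transient: bool = True

    def __post_init__(self) -> None:
        if not (self.ec50 > 0 and np.isfinite(self.ec50)):
            raise ValueError(f"effect {self.sensor_id}/{self.treatment}: EC50 must be > 0")
        if not (self.hill > 0 and np.isfinite(self.hill)):
            raise ValueError(f"effect {self.sensor_id}/{self.treatment}: hill must be > 0")
        if not (0.0 <= self.attenuation_gamma <= 1.0):
            raise ValueError(
                f"effect {self.sensor_id}/{self.treatment}: attenuation_gamma must be in [0, 1]"
            )
        if not np.isfinite(self.lmax):
            raise ValueError(f"effect {self.sensor_id}/{self.treatment}: Lmax not finite")

    def lfc(self, dose: float, genotype: str, timepoint_h: float) -> float:
        if self.transient and timepoint_h >= 24:
            return 0.0
        scale = self.attenuation_gamma if genotype == "cKO" else 1.0
        return scale * hill_lfc(dose, self.lmax, self.ec50, self.hill)


class EffectSpec:
    """Lookup table of :class:`Effect` entries; missing pairs mean no effect."""

    def __init__(self, effects: list[Effect] | None = None):
        self._table: dict[tuple[str, str], Effect] = {}
        for e in effects or []:
            self._table[(e.sensor_id, e.treatment)] = e

    def add(self, effect: Effect) -> None:
        self._table[(effect.sensor_id, effect.treatment)] = effect

    def get(self, sensor_id: str, treatment: str) -> Effect | None:
        return self._table.get((sensor_id, treatment))

    def lfc(self, sensor_id: str, treatment: str, dose: float, genotype: str, timepoint_h: float) -> float:
        if treatment == "vehicle" or dose <= 0:
            return 0.0
        e = self.get(sensor_id, treatment)
        return 0.0 if e is None else e.lfc(dose, genotype, timepoint_h)

    def __len__(self) -> int:
        return len(self._table)

    def __iter__(self):
        return iter(self._table.values())


def default_effects(
    panel: SensorPanel,
    *,
    lmax: float = 3.0,
    ec50: float = 1.0,
    hill: float = 1.0,
    attenuation_gamma: float = 0.4,
) -> EffectSpec:
    """Default effect table emulating the assay's response structure.

    MAPK/IEG sensors respond to AMPA, BDNF, BIC and forskolin; calcium
    sensors respond to all but BDNF.  All stimuli are transient (no 24 h
    effect) except forskolin.  Knockout attenuation applies to every stimulus
    except the forskolin technical control.  Magnitudes are illustrative —
    the published per-sensor amplitudes are not reproduced numerically.
    """
    sensor_ids = set(panel.sensor_ids)
    spec = EffectSpec()
    for treatment in ("AMPA", "BDNF", "BIC", "forskolin"):
        responders = set(_MAPK_SENSORS)
        if treatment != "BDNF":
            responders |= set(_CALCIUM_SENSORS)
        transient = treatment != "forskolin"
        gamma = 1.0 if treatment == "forskolin" else attenuation_gamma
        for sid in sorted(responders & sensor_ids):
            spec.add(
                Effect(
                    sensor_id=sid,
                    treatment=treatment,
                    lmax=lmax,
                    ec50=ec50,
                    hill=hill,
                    attenuation_gamma=gamma,
                    transient=transient,
                )
            )
    return spec


def default_baselines(
    panel: SensorPanel,
    *,
    mean: float = DEFAULT_BASELINE_MEAN,
    low_baseline: dict[str, float] | None = None,
) -> dict[str, float]:
    """Constant sensor baselines, with IL6p-style low-expression exceptions."""
    if low_baseline is None:
        low_baseline = {"IL6p": 2.0}
    return {
        sid: float(low_baseline.get(sid, mean))
        for sid in panel.sensor_ids
    }


@dataclass
class GroundTruth:
    """Simulation record for parameter-recovery tests.

    ``size_factors`` are anchored to geometric mean 1, matching the estimator
    convention, so recovered and true values are directly comparable.
    ``lfc`` has one row per sensor x condition with the realized log2 fold
    change.
    """

    size_factors: pd.Series
    baselines: pd.Series
    dispersions: pd.Series
    lfc: pd.DataFrame  # columns: sensor_id, genotype, treatment, dose, timepoint_h, lfc
    seed: int
    tag_weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def lfc_for(self, sensor_id: str, genotype: str, treatment: str, dose: float, timepoint_h) -> float:
        d = self.lfc
        m = (
            (d["sensor_id"] == sensor_id)
            & (d["genotype"] == genotype)
            & (d["treatment"] == treatment)
            & (np.isclose(d["dose"], dose))
            & (d["timepoint_h"] == timepoint_h)
        )
        vals = d.loc[m, "lfc"]
        if len(vals) != 1:
            raise KeyError(
                f"ground truth has {len(vals)} rows for "
                f"{sensor_id}/{genotype}/{treatment}/{dose}/{timepoint_h}"
            )
        return float(vals.iloc[0])

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "size_factors": self.size_factors.to_dict(),
            "baselines": self.baselines.to_dict(),
            "dispersions": self.dispersions.to_dict(),
            "tag_weights": self.tag_weights.to_dict(),
            "lfc": self.lfc.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            size_factors=pd.Series(payload["size_factors"], dtype=float),
            baselines=pd.Series(payload["baselines"], dtype=float),
            dispersions=pd.Series(payload["dispersions"], dtype=float),
            lfc=pd.DataFrame(payload["lfc"]),
            seed=payload["seed"],
            tag_weights=pd.Series(payload["tag_weights"], dtype=float),
        )


def _check_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite simulation parameter: {name}")


def simulate_counts(
    panel: SensorPanel,
    samples: SampleSheet,
    effects: EffectSpec,
    seed: int,
    *,
    baselines: dict[str, float] | float | None = None,
    dispersion: dict[str, float] | float = DEFAULT_DISPERSION,
    size_factor_sd: float = DEFAULT_SIZE_FACTOR_SD,
    size_factors: dict[str, float] | None = None,
    tag_weights: dict[str, float] | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Draw a tag-level NB count matrix plus its :class:`GroundTruth`.

    ``baselines`` and ``dispersion`` may be scalars (applied to every sensor)
    or per-sensor dicts; ``size_factors`` overrides the default log-normal
    draw (sd ``size_factor_sd`` on the log scale, anchored to geometric mean
    1).  ``tag_weights`` are within-sensor relative abundances (default equal
    split).  Dispersion 0 falls back to the Poisson limit.
    """
    wells = samples.well_ids
    tags = panel.tags

    if baselines is None:
        baselines = default_baselines(panel)
    elif np.isscalar(baselines):
        baselines = {sid: float(baselines) for sid in panel.sensor_ids}
    if np.isscalar(dispersion):
        dispersion = {sid: float(dispersion) for sid in panel.sensor_ids}
    for sid in panel.sensor_ids:
        if sid not in baselines:
            raise ValueError(f"no baseline for sensor {sid}")
        if sid not in dispersion:
            raise ValueError(f"no dispersion for sensor {sid}")
        if baselines[sid] < 0:
            raise ValueError(f"baselines[{sid}]: negative baseline")
        if dispersion[sid] < 0:
            raise ValueError(f"dispersion[{sid}]: negative dispersion")
    _check_finite("baselines", list(baselines.values()))
    _check_finite("dispersion", list(dispersion.values()))

    rng = np.random.default_rng(seed)

    if size_factors is None:
        log_s = rng.normal(0.0, size_factor_sd, size=len(wells))
        s = np.exp(log_s - log_s.mean())  # anchor: geometric mean 1
    else:
        s = np.array([size_factors[w] for w in wells], dtype=float)
        _check_finite("size_factors", s)
        if np.any(s <= 0):
            raise ValueError("size_factors: must be positive")
    s_series = pd.Series(s, index=wells, name="size_factor")

    if tag_weights is None:
        # equal split within each sensor (sensors may differ in tag count)
        w_t = {}
        for sensor in panel.sensors:
            for t in sensor.tags:
                w_t[t.tag_id] = 1.0 / len(sensor.tags)
    else:
        w_t = dict(tag_weights)
        for sensor in panel.sensors:
            tot = sum(w_t[t.tag_id] for t in sensor.tags)
            if not np.isclose(tot, 1.0):
                raise ValueError(f"tag_weights for sensor {sensor.sensor_id} sum to {tot}, not 1")

    # realized LFC per sensor x condition
    conditions = samples.data[STRATUM_COLUMNS].drop_duplicates().reset_index(drop=True)
    lfc_rows = []
    lfc_lookup: dict[tuple, dict[str, float]] = {}
    for _, cond in conditions.iterrows():
        key = tuple(cond[c] for c in STRATUM_COLUMNS)
        per_sensor = {}
        for sid in panel.sensor_ids:
            if sid == panel.control_sensor.sensor_id:
                val = 0.0
            else:
                val = effects.lfc(sid, cond["treatment"], cond["dose"], cond["genotype"], cond["timepoint_h"])
            per_sensor[sid] = val
            lfc_rows.append((sid, *key, val))
        lfc_lookup[key] = per_sensor
    lfc_df = pd.DataFrame(lfc_rows, columns=["sensor_id", *STRATUM_COLUMNS, "lfc"])

    # mean matrix tag x well, then a single vectorized NB draw
    tag_ids = [t.tag_id for t in tags]
    sensor_of = np.array([t.sensor_id for t in tags])
    q = np.array([baselines[t.sensor_id] for t in tags])
    w = np.array([w_t[t.tag_id] for t in tags])
    alpha = np.array([dispersion[t.sensor_id] for t in tags])

    lfc_mat = np.zeros((len(tags), len(wells)))
    for j, (_, row) in enumerate(samples.data.iterrows()):
        key = tuple(row[c] for c in STRATUM_COLUMNS)
        per_sensor = lfc_lookup[key]
        lfc_mat[:, j] = [per_sensor[sid] for sid in sensor_of]

    mu = s[None, :] * (q * w)[:, None] * np.exp2(lfc_mat)
    counts = np.zeros(mu.shape, dtype=np.int64)
    pois = alpha < 1e-12
    if pois.any():
        counts[pois, :] = rng.poisson(mu[pois, :])
    if (~pois).any():
        a = alpha[~pois][:, None]
        m = mu[~pois, :]
        r = 1.0 / a
        p = r / (r + m)
        nz = m > 0
        block = np.zeros(m.shape, dtype=np.int64)
        block[nz] = rng.negative_binomial(np.broadcast_to(r, m.shape)[nz], p[nz])
        counts[~pois, :] = block

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(tag_ids, name="tag_id"), columns=wells),
        level="tag",
    )
    truth = GroundTruth(
        size_factors=s_series,
        baselines=pd.Series(baselines, name="baseline"),
        dispersions=pd.Series(dispersion, name="dispersion"),
        lfc=lfc_df,
        seed=seed,
        tag_weights=pd.Series(w_t, name="tag_weight"),
    )
    return cm, truth


_BASE_IDX = {b: i for i, b in enumerate(ALPHABET)}


def _seq_to_codes(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_IDX[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc} in sequence {seq!r}") from exc


def simulate_reads(
    counts: CountMatrix,
    panel: SensorPanel,
    samples: SampleSheet,
    error_rate: float,
    seed: int,
    path,
    *,
    shuffle: bool = True,
) -> int:
    """Write one FASTQ read per count unit; return the number of reads.

    Read layout is ``sample_index + flank_5p + tag + flank_3p`` with i.i.d.
    per-base substitution errors at ``error_rate`` over the whole read and a
    constant quality string.  Before errors, the read count of each
    (well, tag) equals the count matrix exactly.  Gzipped output when ``path``
    ends in ``.gz``.
    """
    if counts.level != "tag":
        raise ValueError("simulate_reads requires a tag-level count matrix")
    if not (0.0 <= error_rate < 0.25):
        raise ValueError(f"error_rate must be in [0, 0.25), got {error_rate}")

    rng = np.random.default_rng(seed)
    index_of_well = dict(zip(samples.data["well_id"], samples.data["sample_index"]))
    tag_seq = {t.tag_id: t.sequence for t in panel.tags}

    flank5 = _seq_to_codes(panel.flank_5p)
    flank3 = _seq_to_codes(panel.flank_3p)

    # build the per-read template table
    templates: list[np.ndarray] = []
    reps: list[int] = []
    for well in counts.counts.columns:
        idx_codes = _seq_to_codes(index_of_well[well])
        col = counts.counts[well]
        for tag_id, n in col.items():
            n = int(n)
            if n <= 0:
                continue
            codes = np.concatenate([idx_codes, flank5, _seq_to_codes(tag_seq[tag_id]), flank3])
            templates.append(codes)
            reps.append(n)
    total = int(sum(reps))
    if total == 0:
        _open(path, "wt").close()
        return 0

    mat = np.repeat(np.stack(templates), reps, axis=0)
    if error_rate > 0:
        hit = rng.random(mat.shape) < error_rate
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=hit.sum()).astype(np.uint8)
        mat[hit] = (mat[hit] + shift) % 4
    if shuffle:
        mat = mat[rng.permutation(total)]

    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    qual = "I" * mat.shape[1]
    with _open(path, "wt") as fh:
        ascii_mat = lut[mat]
        for i in range(total):
            fh.write(f"@read{i}\n{ascii_mat[i].tobytes().decode('ascii')}\n+\n{qual}\n")
    return total


def _open(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
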