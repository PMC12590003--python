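"""Experiment design: the sample sheet describing wells and conditions.

A sample sheet has one row per well with its demultiplexing index and the
condition it encodes: genotype (control vs. conditional knockout), treatment,
dose, timepoint and replicate number.  The default design mirrors the assay's
stimulation matrix: AMPA, BIC and forskolin at 0.1/1/10/100 uM and BDNF at
0.1/1/10/100 ng/mL, plus vehicle, at 4 h and 24 h, four replicates per
stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import generate_tag_set, hamming, min_pairwise_hamming

__all__ = [
    "SampleSheet",
    "DesignError",
    "build_design",
    "build_default_design",
    "load_sample_sheet",
    "write_sample_sheet",
    "TREATMENT_UNITS",
    "DEFAULT_DOSES",
    "STRATUM_COLUMNS",
]

TREATMENT_UNITS = {
    "vehicle": "uM",
    "AMPA": "uM",
    "BIC": "uM",
    "forskolin": "uM",
    "BDNF": "ng/mL",
}

DEFAULT_DOSES = (0.1, 1.0, 10.0, 100.0)
DEFAULT_TIMEPOINTS = (4, 24)
DEFAULT_N_REPLICATES = 4
DEFAULT_INDEX_LENGTH = 8

#: Columns that jointly define a biological stratum (replicates excluded).
STRATUM_COLUMNS = ["genotype", "treatment", "dose", "timepoint_h"]

_COLUMNS = [
    "well_id",
    "sample_index",
    "genotype",
    "treatment",
    "dose",
    "dose_units",
    "timepoint_h",
    "replicate",
]


class DesignError(ValueError):
    """Raised when a sample sheet violates a design invariant."""


@dataclass
class SampleSheet:
    """Thin wrapper around the per-well design table.

    ``data`` has the canonical columns (well_id, sample_index, genotype,
    treatment, dose, dose_units, timepoint_h, replicate), one row per well.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise DesignError(f"sample sheet missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    @property
    def well_ids(self) -> list[str]:
        return list(self.data["well_id"])

    @property
    def index_length(self) -> int:
        lengths = {len(s) for s in self.data["sample_index"]}
        if len(lengths) != 1:
            raise DesignError(f"inconsistent sample_index lengths: {sorted(lengths)}")
        return lengths.pop()

    def index_map(self) -> dict[str, str]:
        return dict(zip(self.data["sample_index"], self.data["well_id"]))

    def vehicle_wells(self, genotype=None, timepoint_h=None) -> list[str]:
        d = self.data[self.data["treatment"] == "vehicle"]
        if genotype is not None:
            d = d[d["genotype"] == genotype]
        if timepoint_h is not None:
            d = d[d["timepoint_h"] == timepoint_h]
        return list(d["well_id"])

    def strata(self):
        """Iterate (stratum key tuple, well_id list) over biological strata."""
        for key, grp in self.data.groupby(STRATUM_COLUMNS, sort=False):
            yield key, list(grp["well_id"])

    def validate(self, *, min_index_distance: int = 3) -> None:
        """Raise :class:`DesignError` on any invariant violation."""
        d = self.data
        dup = d["well_id"][d["well_id"].duplicated()].tolist()
        if dup:
            raise DesignError(f"duplicate well_ids: {dup}")
        _ = self.index_length
        idx = list(d["sample_index"])
        if len(set(idx)) != len(idx):
            raise DesignError("duplicate sample indices")
        if len(idx) >= 2:
            dist, (i, j) = min_pairwise_hamming(idx)
            if dist < min_index_distance:
                raise DesignError(
                    f"sample indices {idx[i]} and {idx[j]} at Hamming distance "
                    f"{dist} < {min_index_distance}"
                )
        # every treated stratum needs a matched vehicle stratum
        treated = d[d["treatment"] != "vehicle"]
        for (gt, tp), _grp in treated.groupby(["genotype", "timepoint_h"]):
            if not self.vehicle_wells(genotype=gt, timepoint_h=tp):
                raise DesignError(
                    f"no vehicle wells matching genotype={gt}, timepoint_h={tp}"
                )


def build_design(
    *,
    genotypes=("control", "cKO"),
    treatments=("AMPA", "BDNF", "BIC", "forskolin"),
    doses=DEFAULT_DOSES,
    timepoints=DEFAULT_TIMEPOINTS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    index_length: int = DEFAULT_INDEX_LENGTH,
    seed: int = 0,
) -> SampleSheet:
    """Build a sample sheet for the given condition grid plus matched vehicles.

    Sample indices are drawn pseudo-randomly at pairwise Hamming distance >= 3
    (so one index substitution is always correctable); wells are named W0001..
    in grid order.  Deterministic for a fixed seed.
    """
    rows = []
    for gt in genotypes:
        for tp in timepoints:
            for rep in range(1, n_replicates + 1):
                rows.append((gt, "vehicle", 0.0, TREATMENT_UNITS["vehicle"], tp, rep))
            for tr in treatments:
                units = TREATMENT_UNITS.get(tr, "uM")
                for dose in doses:
                    for rep in range(1, n_replicates + 1):
                        rows.append((gt, tr, float(dose), units, tp, rep))
    rng = np.random.default_rng(seed)
    indices = generate_tag_set(len(rows), index_length, rng, max_attempts=500000)
    data = pd.DataFrame(
        [
            (f"W{i + 1:04d}", indices[i], *row)
            for i, row in enumerate(rows)
        ],
        columns=_COLUMNS,
    )
    sheet = SampleSheet(data)
    sheet.validate()
    return sheet


def build_default_design(seed: int = 0) -> SampleSheet:
    """The full default stimulation matrix (2 genotypes x 4 treatments x
    4 doses x 2 timepoints x 4 replicates, plus vehicles): 544 wells."""
    return build_design(seed=seed)


def load_sample_sheet(path, *, validate: bool = True) -> SampleSheet:
    data = pd.read_csv(
        path,
        sep="\t",
        dtype={"well_id": str, "sample_index": str, "genotype": str, "treatment": str},
    )
    sheet = SampleSheet(data)
    if validate:
        sheet.validate()
    return sheet


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)
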