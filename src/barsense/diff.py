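"""Control-anchored normalization and negative-binomial Wald testing.

The statistical model
---------------------

Counts of sensor *i* in well *j* are modeled as negative binomial with mean
``s_j * mu_ij`` and variance ``mu + alpha_i * mu**2``:

* **Size factors** ``s_j`` come from the control reporter alone: each well's
  factor is the geometric mean of its four control-tag counts, anchored so
  the factors have geometric mean 1 across wells.  Because the control
  reporter carries no response element, its counts reflect only sequencing
  depth and cell number.
* **Dispersion** ``alpha_i`` is a per-sensor method-of-moments estimate on
  normalized counts, pooling variance within biological strata (replicate
  groups) so that real condition effects never inflate it.  No
  empirical-Bayes shrinkage is applied — with a ~23-sensor panel a shrinkage
  prior is poorly identified.
* **Wald test**: for a contrast (numerator vs. denominator well sets) a
  two-group model ``mu = s_j * q`` (denominator) and ``mu = s_j * q * 2**L``
  (numerator) is fitted by maximum likelihood with ``alpha_i`` plugged in.
  The group means decouple, so each is a one-dimensional Newton solve.  The
  standard error of the log2 fold change L comes from the observed Fisher
  information; ``z = L/SE`` is referred to a standard normal, two-sided.
* **Multiplicity**: Benjamini-Hochberg within a user-defined family (default:
  all sensor x contrast cells of one run).
* **Gating**: significance stars are displayed only where |log2FC| exceeds
  the fold-change gate (default 1.5); BH itself runs on all cells by
  default, with a flag to restrict it to gated cells.

The public surface is both functional (``size_factors``, ``wald_test``, ...)
and object-based: :class:`ResponseModel` bundles counts + design, and
``fit()`` returns a :class:`ResponseResults` carrying estimates,
uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .design import SampleSheet, STRATUM_COLUMNS
from .quantify import CountMatrix

__all__ = [
    "SizeFactors",
    "DispersionEstimate",
    "Contrast",
    "DiffError",
    "size_factors",
    "normalize",
    "estimate_dispersion",
    "wald_test",
    "adjust_bh",
    "gate_significance",
    "dose_response_table",
    "heatmap_matrix",
    "load_contrasts",
    "ResponseModel",
    "ResponseResults",
    "DEFAULT_GATE",
    "DEFAULT_CUTOFFS",
]

LOG2 = np.log(2.0)
DEFAULT_GATE = 1.5
DEFAULT_CUTOFFS = (0.05, 0.01, 0.001, 0.0001)
DEFAULT_FLOOR = 1e-8


class DiffError(ValueError):
    pass


@dataclass
class SizeFactors:
    """Per-well scaling factors; geometric mean anchored to 1."""

    values: pd.Series
    method: str = "control_geomean"

    def __post_init__(self) -> None:
        if (self.values <= 0).any():
            bad = self.values.index[self.values <= 0].tolist()
            raise DiffError(f"non-positive size factors for wells {bad}")


@dataclass
class DispersionEstimate:
    """Per-sensor NB dispersion (variance = mu + alpha * mu**2)."""

    values: pd.Series
    method: str = "pooled_moments"
    floor: float = DEFAULT_FLOOR


@dataclass
class Contrast:
    """Numerator-vs-denominator well selection for one Wald test.

    ``numerator``/``denominator`` map sample-sheet columns to a required
    value (or list of values); ``family`` groups contrasts for BH.
    """

    name: str
    numerator: dict
    denominator: dict
    family: str = "default"

    @staticmethod
    def _select(samples: SampleSheet, predicate: dict) -> list[str]:
        d = samples.data
        mask = pd.Series(True, index=d.index)
        for col, want in predicate.items():
            if col not in d.columns:
                raise DiffError(f"contrast predicate column {col!r} not in sample sheet")
            if isinstance(want, (list, tuple, set)):
                mask &= d[col].isin(list(want))
            else:
                mask &= d[col] == want
        return list(d.loc[mask, "well_id"])

    def wells(self, samples: SampleSheet) -> tuple[list[str], list[str]]:
        num = self._select(samples, self.numerator)
        den = self._select(samples, self.denominator)
        if not num or not den:
            raise DiffError(f"contrast {self.name!r}: empty numerator or denominator well set")
        overlap = set(num) & set(den)
        if overlap:
            raise DiffError(f"contrast {self.name!r}: wells in both groups: {sorted(overlap)}")
        return num, den


def load_contrasts(path) -> list[Contrast]:
    """Read contrasts from YAML: a list of {name, numerator, denominator, family}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for item in raw:
        out.append(
            Contrast(
                name=item["name"],
                numerator=item["numerator"],
                denominator=item["denominator"],
                family=item.get("family", "default"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def size_factors(control_table: pd.DataFrame) -> SizeFactors:
    """Size factors from the control reporter's tag counts (tags x wells).

    Per well: geometric mean of the control-tag counts, with a +0.5
    pseudocount applied to zero counts only; then divided by the grand
    geometric mean across wells so the anchoring invariant (geometric mean
    1) holds.  A well whose control tags are all zero is an error.
    """
    tab = control_table.astype(float)
    all_zero = (tab == 0).all(axis=0)
    if all_zero.any():
        bad = tab.columns[all_zero].tolist()
        raise DiffError(f"wells with all-zero control-tag counts: {bad}")
    vals = tab.to_numpy(copy=True)
    vals[vals == 0] = 0.5
    log_gm = np.log(vals).mean(axis=0)
    s = np.exp(log_gm - log_gm.mean())
    return SizeFactors(pd.Series(s, index=tab.columns, name="size_factor"))


def normalize(counts, s: SizeFactors | pd.Series) -> pd.DataFrame:
    """Divide each well's counts by its size factor."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    sv = s.values if isinstance(s, SizeFactors) else s
    missing = [w for w in df.columns if w not in sv.index]
    if missing:
        raise DiffError(f"size factors missing for wells {missing}")
    return df / sv[df.columns]


def estimate_dispersion(
    counts,
    s: SizeFactors | pd.Series,
    samples: SampleSheet,
    floor: float = DEFAULT_FLOOR,
) -> DispersionEstimate:
    """Per-sensor moments dispersion from within-stratum residuals.

    For each sensor, pooled variance of normalized counts around their
    stratum means (Bessel-corrected, summed over strata with >= 2 wells) and
    the pooled mean give ``alpha = max(floor, (var - mean) / mean**2)``.
    Deterministic; sensors with zero mean are floored with a warning.
    """
    if floor <= 0:
        raise DiffError(f"dispersion floor must be > 0, got {floor}")
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    norm = normalize(df, s)
    groups = []
    for _, wells in samples.strata():
        g = [w for w in wells if w in norm.columns]
        if len(g) >= 2:
            groups.append(g)
    if not groups:
        raise DiffError("no stratum has >= 2 replicate wells: dispersion inestimable")

    used = [w for g in groups for w in g]
    y = norm[used]
    dfree = 0
    ss = np.zeros(len(norm.index))
    for g in groups:
        block = norm[g].to_numpy()
        ss += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        dfree += len(g) - 1
    pooled_var = ss / dfree
    pooled_mean = y.mean(axis=1).to_numpy()

    alpha = np.full(len(norm.index), floor)
    nz = pooled_mean > 0
    alpha[nz] = np.maximum(floor, (pooled_var[nz] - pooled_mean[nz]) / pooled_mean[nz] ** 2)
    if (~nz).any():
        zero_sensors = norm.index[~nz].tolist()
        warnings.warn(f"sensors with zero mean everywhere, dispersion floored: {zero_sensors}")
    return DispersionEstimate(
        pd.Series(alpha, index=norm.index, name="dispersion"), floor=floor
    )


# ---------------------------------------------------------------------------
# NB two-group fit
# ---------------------------------------------------------------------------


def _fit_group_log_mean(k: np.ndarray, s: np.ndarray, r: np.ndarray, max_iter: int = 100):
    """MLE of ln(q) for NB counts ``k`` with means ``q * s_j`` and size ``r``.

    Vectorized over sensors (rows of ``k``); returns (ln_q, converged mask).
    Newton with the observed information; the score in ln(q) is
    ``sum_j [k_j - mu_j (k_j + r)/(mu_j + r)]``.
    """
    ksum = k.sum(axis=1)
    lnq = np.log(np.maximum(ksum, 1e-300) / s.sum())
    ok = np.zeros(len(k), dtype=bool)
    for _ in range(max_iter):
        mu = np.exp(lnq)[:, None] * s[None, :]
        ratio = (k + r[:, None]) / (mu + r[:, None])
        score = (k - mu * ratio).sum(axis=1)
        info = (mu * r[:, None] * (k + r[:, None]) / (mu + r[:, None]) ** 2).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        lnq = lnq + step
        ok = np.abs(score) <= 1e-9 * np.maximum(ksum, 1.0)
        if ok.all():
            break
    return lnq, ok


def _observed_weights(k: np.ndarray, mu: np.ndarray, r: np.ndarray) -> np.ndarray:
    return mu * r[:, None] * (k + r[:, None]) / (mu + r[:, None]) ** 2


def wald_test(
    counts,
    s: SizeFactors | pd.Series,
    alpha: DispersionEstimate | pd.Series,
    contrast: Contrast,
    samples: SampleSheet,
) -> pd.DataFrame:
    """Wald test of one contrast for every sensor.

    Fits the two-group NB model (means ``s_j*q`` vs ``s_j*q*2**L``) by
    maximum likelihood with plug-in dispersion, then ``z = L / SE`` with SE
    from the observed Fisher information on the log2 scale.  When either
    group of a sensor is all zero, a +0.5 pseudocount is added to all of that
    sensor's counts (both groups) before fitting — the only place a
    pseudocount enters.  Non-converged sensors get NA statistics.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    sv = s.values if isinstance(s, SizeFactors) else s
    av = alpha.values if isinstance(alpha, DispersionEstimate) else alpha
    num_wells, den_wells = contrast.wells(samples)
    num_wells = [w for w in num_wells if w in df.columns]
    den_wells = [w for w in den_wells if w in df.columns]
    if not num_wells or not den_wells:
        raise DiffError(f"contrast {contrast.name!r}: wells absent from count matrix")

    k_num = df[num_wells].to_numpy(dtype=float)
    k_den = df[den_wells].to_numpy(dtype=float)
    s_num = sv[num_wells].to_numpy(dtype=float)
    s_den = sv[den_wells].to_numpy(dtype=float)
    r = 1.0 / np.maximum(av.reindex(df.index).to_numpy(dtype=float), 1e-12)

    pseudo = (k_num.sum(axis=1) == 0) | (k_den.sum(axis=1) == 0)
    if pseudo.any():
        k_num[pseudo] += 0.5
        k_den[pseudo] += 0.5

    lnq_den, ok_den = _fit_group_log_mean(k_den, s_den, r)
    lnq_num, ok_num = _fit_group_log_mean(k_num, s_num, r)
    converged = ok_den & ok_num

    log2fc = (lnq_num - lnq_den) / LOG2
    mu_num = np.exp(lnq_num)[:, None] * s_num[None, :]
    mu_den = np.exp(lnq_den)[:, None] * s_den[None, :]
    b = _observed_weights(k_num, mu_num, r).sum(axis=1)
    c = _observed_weights(k_den, mu_den, r).sum(axis=1)
    a = b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(a / (LOG2**2 * b * c))
        z = log2fc / se
    p = 2.0 * sps.norm.sf(np.abs(z))

    bad = ~converged
    for arr in (log2fc, se, z, p):
        arr[bad] = np.nan

    return pd.DataFrame(
        {
            "sensor_id": df.index,
            "contrast": contrast.name,
            "family": contrast.family,
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "p_raw": p,
            "n_num": len(num_wells),
            "n_den": len(den_wells),
            "zero_pseudocount": pseudo,
            "converged": converged,
        }
    )


def adjust_bh(p_raw: pd.Series, families: pd.Series | None = None) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment within each family.

    NaN p values are passed through as NaN and do not count toward the
    family size.
    """
    p_adj = pd.Series(np.nan, index=p_raw.index)
    if families is None:
        families = pd.Series("default", index=p_raw.index)
    for _fam, idx in p_raw.groupby(families).groups.items():
        vals = p_raw.loc[idx]
        mask = vals.notna()
        if mask.sum() == 0:
            continue
        _, adj, _, _ = multipletests(vals[mask], method="fdr_bh")
        p_adj.loc[vals.index[mask]] = adj
    return p_adj


def gate_significance(
    results: pd.DataFrame,
    gate: float = DEFAULT_GATE,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Attach star annotations, displayed only past the fold-change gate.

    A cell gets '*' ... '****' for adjusted p <= 0.05 / 0.01 / 0.001 /
    0.0001, but only when |log2FC| strictly exceeds ``gate``; below the gate
    the label is empty no matter how small p_adj is.
    """
    if list(cutoffs) != sorted(cutoffs, reverse=True):
        raise DiffError("cutoffs must be decreasing")
    out = results.copy()
    labels = []
    for lfc, p_adj in zip(out["log2fc"], out["p_adj"]):
        label = ""
        if np.isfinite(lfc) and np.isfinite(p_adj) and abs(lfc) > gate:
            for n_star, cut in enumerate(cutoffs, start=1):
                if p_adj <= cut:
                    label = "*" * n_star
        labels.append(label)
    out["gated_label"] = labels
    return out


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def dose_response_table(
    norm: pd.DataFrame,
    samples: SampleSheet,
) -> pd.DataFrame:
    """Mean +- SEM response per sensor x genotype x treatment x dose x timepoint.

    The response of a well is its normalized count divided by the mean
    normalized count of the matched vehicle stratum (same genotype and
    timepoint), so vehicle strata average to 1 by construction.
    """
    d = samples.data.set_index("well_id")
    rows = []
    for (gt, tp), cond in d.groupby(["genotype", "timepoint_h"]):
        veh = cond.index[cond["treatment"] == "vehicle"]
        veh = [w for w in veh if w in norm.columns]
        if not veh:
            raise DiffError(f"no vehicle wells for genotype={gt}, timepoint_h={tp}")
        veh_mean = norm[veh].mean(axis=1)
        if (veh_mean == 0).any():
            veh_mean = veh_mean.replace(0, np.nan)
        for (tr, dose), grp in cond.groupby(["treatment", "dose"]):
            wells = [w for w in grp.index if w in norm.columns]
            if not wells:
                continue
            resp = norm[wells].div(veh_mean, axis=0)
            n = len(wells)
            mean = resp.mean(axis=1)
            sem = resp.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else pd.Series(np.nan, index=resp.index)
            for sid in norm.index:
                rows.append(
                    {
                        "sensor_id": sid,
                        "genotype": gt,
                        "treatment": tr,
                        "dose": dose,
                        "timepoint_h": tp,
                        "mean_response": mean[sid],
                        "sem": sem[sid],
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def heatmap_matrix(results: pd.DataFrame, *, sensor_order=None, contrast_order=None) -> pd.DataFrame:
    """Rectangular sensors x contrasts export of log2FC with label columns.

    Produces paired ``<contrast>`` / ``<contrast>_label`` columns in
    deterministic order; duplicate (sensor, contrast) cells are an error and
    missing cells stay NA.
    """
    dup = results.duplicated(subset=["sensor_id", "contrast"])
    if dup.any():
        pairs = results.loc[dup, ["sensor_id", "contrast"]].to_records(index=False).tolist()
        raise DiffError(f"duplicate (sensor, contrast) cells: {pairs}")
    if sensor_order is None:
        sensor_order = list(dict.fromkeys(results["sensor_id"]))
    if contrast_order is None:
        contrast_order = list(dict.fromkeys(results["contrast"]))
    values = results.pivot(index="sensor_id", columns="contrast", values="log2fc")
    labels = results.pivot(index="sensor_id", columns="contrast", values="gated_label")
    values = values.reindex(index=sensor_order, columns=contrast_order)
    labels = labels.reindex(index=sensor_order, columns=contrast_order)
    out = pd.DataFrame(index=values.index)
    for c in contrast_order:
        out[c] = values[c]
        out[f"{c}_label"] = labels[c].fillna("")
    out.index.name = "sensor_id"
    return out


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class ResponseModel:
    """Differential sensor-response model bound to counts and a design.

    Parameters
    ----------
    sensor_counts : CountMatrix or DataFrame
        Sensor-level counts (sensors x wells).
    control_counts : DataFrame
        The control reporter's tag counts (control tags x wells), used
        exclusively for size-factor estimation.
    samples : SampleSheet
        Per-well design.
    dispersion_floor : float
        Lower bound for the moments dispersion estimates.

    Examples
    --------
    >>> model = ResponseModel(sensor_cm, control_table, sheet)
    >>> res = model.fit(contrasts)
    >>> print(res.summary())
    """

    def __init__(
        self,
        sensor_counts,
        control_counts: pd.DataFrame,
        samples: SampleSheet,
        *,
        dispersion_floor: float = DEFAULT_FLOOR,
    ):
        df = sensor_counts.counts if isinstance(sensor_counts, CountMatrix) else sensor_counts
        self.counts = df
        self.control_counts = control_counts
        self.samples = samples
        self.dispersion_floor = dispersion_floor
        self.size_factors: SizeFactors = size_factors(control_counts)
        self.dispersions: DispersionEstimate = estimate_dispersion(
            df, self.size_factors, samples, floor=dispersion_floor
        )

    @classmethod
    def from_quantification(cls, tag_counts: CountMatrix, panel, samples: SampleSheet, **kw):
        """Build from a tag-level matrix by collapsing tags to sensors."""
        from .quantify import collapse_to_sensors

        sensor_cm, control_table = collapse_to_sensors(tag_counts, panel)
        return cls(sensor_cm, control_table, samples, **kw)

    def normalized(self) -> pd.DataFrame:
        return normalize(self.counts, self.size_factors)

    def fit(
        self,
        contrasts: list[Contrast],
        *,
        gate: float = DEFAULT_GATE,
        cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
        bh_on_gated_only: bool = False,
    ) -> "ResponseResults":
        """Run every contrast, BH-adjust within families, and gate labels."""
        pieces = [
            wald_test(self.counts, self.size_factors, self.dispersions, c, self.samples)
            for c in contrasts
        ]
        table = pd.concat(pieces, ignore_index=True)
        if bh_on_gated_only:
            gated_mask = table["log2fc"].abs() > gate
            p_for_bh = table["p_raw"].where(gated_mask)
            table["p_adj"] = adjust_bh(p_for_bh, table["family"])
        else:
            table["p_adj"] = adjust_bh(table["p_raw"], table["family"])
        table = gate_significance(table, gate=gate, cutoffs=cutoffs)
        return ResponseResults(self, table, gate=gate, cutoffs=cutoffs)


@dataclass
class ResponseResults:
    """Fitted differential-response results.

    ``table`` has one row per sensor x contrast with log2FC, SE, Wald z, raw
    and BH-adjusted p, and the gated star annotation.
    """

    model: ResponseModel
    table: pd.DataFrame
    gate: float = DEFAULT_GATE
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS

    @property
    def size_factors(self) -> pd.Series:
        return self.model.size_factors.values

    @property
    def dispersions(self) -> pd.Series:
        return self.model.dispersions.values

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["gated_label"] != ""]

    def heatmap_matrix(self, **kw) -> pd.DataFrame:
        return heatmap_matrix(self.table, **kw)

    def dose_response(self) -> pd.DataFrame:
        return dose_response_table(self.model.normalized(), self.model.samples)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary(self, max_rows: int | None = 40) -> str:
        t = self.table
        n_sig = int((t["gated_label"] != "").sum())
        lines = [
            "Differential sensor response (NB Wald test)",
            "=" * 60,
            f"sensors: {t['sensor_id'].nunique()}   contrasts: {t['contrast'].nunique()}",
            f"fold-change gate: |log2FC| > {self.gate}   BH families: {t['family'].nunique()}",
            f"annotated cells: {n_sig} / {len(t)}",
            "-" * 60,
            f"{'sensor':<14}{'contrast':<24}{'log2FC':>8}{'SE':>7}{'p_adj':>10}  label",
        ]
        show = t.sort_values("p_adj") if max_rows else t
        for _, row in show.head(max_rows or len(t)).iterrows():
            lines.append(
                f"{row['sensor_id']:<14}{row['contrast']:<24}"
                f"{row['log2fc']:>8.2f}{row['se']:>7.2f}{row['p_adj']:>10.2e}  {row['gated_label']}"
            )
        if max_rows and len(t) > max_rows:
            lines.append(f"... ({len(t) - max_rows} more rows)")
        return "\n".join(lines)
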