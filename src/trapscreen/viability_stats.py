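"""Viability statistics: %viability, dose-contrast ΔV, wild-type-null Z-scores.

The cytotoxicity assay measures dead-cell luminescence, then total-cell
luminescence after lysis, so

    %viability = (total − dead) / total

and the per-clone radiation response at dose d is the change relative to
the clone's own unirradiated wells,

    ΔV = V_d − V_0,

with duplicate wells averaged at the %viability level before the
difference is taken.  Wild-type replicate wells carry no gene-trap
insertion, so their ΔV values measure the variability expected by chance;
a clone is scored as

    Z = (ΔV − μ_wt) / σ_wt,

with a two-tailed normal p-value and a hit call at p < α (default 0.01).
Nulls are fitted separately per dose contrast because the chance
variability of ΔV grows with dose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateNullError,
    InsufficientNullError,
    QcError,
    UndefinedWellError,
)
from .screen_data import ScreenDataset

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)
_SMALLEST = np.nextafter(0.0, 1.0)  # smallest positive float; p never renders as 0


@dataclass(frozen=True)
class NullModel:
    """Location/scale of a null distribution plus its provenance.

    ``source`` records how the null was obtained: directly from wild-type
    replicate ΔV values, or from a RANSAC consensus over the clone
    population (expression log-ratios, where no insert-free control is
    possible).
    """

    mu: float
    sigma: float
    n_used: int
    source: Literal["wt_replicates", "ransac_consensus"]
    inlier_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise DegenerateNullError(f"null sigma must be > 0, got {self.sigma}")
        if self.n_used < 2:
            raise InsufficientNullError(f"null fitted on {self.n_used} < 2 values")


@dataclass(frozen=True)
class HitCalls:
    """Hit partition by (dose contrast, direction) with deduplicated union."""

    alpha: float
    partitions: dict[tuple[float, str], tuple[str, ...]]
    unique_genes: frozenset[str]

    @property
    def counts(self) -> dict[tuple[float, str], int]:
        return {k: len(v) for k, v in self.partitions.items()}

    def genes(self, dose: float, direction: str) -> frozenset[str]:
        return frozenset(self.partitions.get((dose, direction), ()))


def percent_viability(dead_rlu: float, total_rlu: float) -> float:
    """Fraction of viable cells implied by dead-cell vs total-cell signal."""
    if total_rlu <= 0:
        raise UndefinedWellError(f"total RLU must be > 0, got {total_rlu}")
    if dead_rlu < 0 or dead_rlu > total_rlu:
        raise QcError(f"dead RLU {dead_rlu} outside [0, total={total_rlu}]")
    return (total_rlu - dead_rlu) / total_rlu


def delta_viability(v_dose: float, v_ref: float) -> float:
    """Signed viability change, irradiated minus unirradiated."""
    return v_dose - v_ref


def fit_wt_null(wt_deltas: Sequence[float]) -> NullModel:
    """Fit the chance-variability null from wild-type replicate ΔV values.

    Location is the sample mean, scale the n−1 sample standard deviation
    (the control sample is small, n = 22 in the original screen).
    """
    values = np.asarray(list(wt_deltas), dtype=float)
    if values.size < 2:
        raise InsufficientNullError(
            f"need ≥ 2 wild-type ΔV values to fit a null, got {values.size}"
        )
    if not np.all(np.isfinite(values)):
        raise InsufficientNullError("non-finite wild-type ΔV values")
    sigma = float(values.std(ddof=1))
    if sigma == 0.0:
        raise DegenerateNullError("wild-type ΔV values are constant; null scale is 0")
    return NullModel(
        mu=float(values.mean()), sigma=sigma, n_used=int(values.size),
        source="wt_replicates",
    )


def z_score(delta_v: float, null: NullModel) -> float:
    """Standardise an observation against a null: (x − μ)/σ."""
    return (delta_v - null.mu) / null.sigma


def two_tailed_p(z: float) -> float:
    """Two-tailed normal p-value, 2·Φ(−|z|), at full tail precision.

    Uses the scipy survival function (accurate far beyond |z| = 6, where
    naive 1 − Φ(z) loses all precision).  Never returns exactly 0 for
    finite z: below the smallest positive float the subnormal floor is
    returned and callers should consult :func:`log10_two_tailed_p`.
    """
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    p = 2.0 * stats.norm.sf(abs(z))
    return float(min(max(p, _SMALLEST), 1.0))


def log10_two_tailed_p(z: float) -> float:
    """log₁₀ of the two-tailed normal p-value, stable under underflow."""
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z}")
    return float(min((math.log(2.0) + stats.norm.logsf(abs(z))) / _LN10, 0.0))


def well_viability(records: pd.DataFrame) -> pd.Series:
    """Vectorised %viability for a well frame; zero-total wells are dropped.

    Dropping (with a warning) rather than raising matches plate-level
    practice: an empty well should not abort a 386-clone run.
    """
    ok = records["total_rlu"] > 0
    if (~ok).any():
        for row in records[~ok].itertuples(index=False):
            logger.warning(
                "dropping undefined well (total RLU = 0): %s at %s Gy rep %s",
                row.clone_id, row.dose_gy, row.replicate,
            )
    sub = records[ok]
    return (sub["total_rlu"] - sub["dead_rlu"]) / sub["total_rlu"]


def viability_deltas(
    dataset: ScreenDataset,
    average: Literal["viability", "rlu"] = "viability",
) -> pd.DataFrame:
    """Per-clone, per-dose-contrast ΔV with duplicates averaged.

    ``average="viability"`` (default) averages duplicate wells at the
    %viability level; ``"rlu"`` averages raw dead/total RLU first and
    computes one viability from the summed signals.

    Returns columns ``clone_id, gene_symbol, is_wildtype, dose_gy, delta_v``
    with one row per clone per non-zero dose.
    """
    rec = dataset.records
    if average == "viability":
        rec = rec.assign(v=np.nan)
        rec.loc[rec["total_rlu"] > 0, "v"] = well_viability(rec).values
        per = (
            rec.dropna(subset=["v"])
            .groupby(["clone_id", "gene_symbol", "is_wildtype", "dose_gy"], sort=True)["v"]
            .mean()
            .reset_index()
        )
    elif average == "rlu":
        summed = (
            rec.groupby(["clone_id", "gene_symbol", "is_wildtype", "dose_gy"], sort=True)[
                ["dead_rlu", "total_rlu"]
            ]
            .mean()
            .reset_index()
        )
        summed = summed[summed["total_rlu"] > 0]
        summed["v"] = (summed["total_rlu"] - summed["dead_rlu"]) / summed["total_rlu"]
        per = summed.drop(columns=["dead_rlu", "total_rlu"])
    else:
        raise ValueError(f"unknown averaging mode {average!r}")

    wide = per.pivot_table(
        index=["clone_id", "gene_symbol", "is_wildtype"], columns="dose_gy", values="v"
    )
    if 0.0 not in wide.columns:
        raise UndefinedWellError("no 0-Gy reference viability available")
    rows = []
    for dose in dataset.dose_set:
        if dose == 0.0 or dose not in wide.columns:
            continue
        dv = wide[dose] - wide[0.0]
        sub = dv.dropna().reset_index()
        sub.columns = ["clone_id", "gene_symbol", "is_wildtype", "delta_v"]
        sub["dose_gy"] = dose
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["clone_id", "gene_symbol", "is_wildtype", "delta_v", "dose_gy"]
    )
    return out[["clone_id", "gene_symbol", "is_wildtype", "dose_gy", "delta_v"]]


def compute_viability_results(
    dataset: ScreenDataset,
    alpha: float = 0.01,
    average: Literal["viability", "rlu"] = "viability",
) -> tuple[pd.DataFrame, dict[float, NullModel]]:
    """Full viability analysis of a screen.

    For every non-zero dose in the dataset: fit the wild-type ΔV null,
    score every mutant clone, and flag hits at p < alpha.  Direction is
    classified by the sign of (ΔV − μ_wt), so a clone that merely tracks
    the wild-type drift is not called directional.

    Returns the per-clone result table and the per-dose null models.
    """
    deltas = viability_deltas(dataset, average=average)
    nulls: dict[float, NullModel] = {}
    frames = []
    for dose, grp in deltas.groupby("dose_gy", sort=True):
        wt = grp[grp["is_wildtype"]]["delta_v"]
        null = fit_wt_null(wt)
        nulls[float(dose)] = null
        clones = grp[~grp["is_wildtype"]].copy()
        z = (clones["delta_v"] - null.mu) / null.sigma
        clones["z"] = z
        clones["p"] = 2.0 * stats.norm.sf(np.abs(z))
        clones["p"] = clones["p"].clip(lower=_SMALLEST)
        clones["log10_p"] = np.minimum(
            (math.log(2.0) + stats.norm.logsf(np.abs(z))) / _LN10, 0.0
        )
        clones["direction"] = np.where(
            clones["delta_v"] > null.mu, "increased", "decreased"
        )
        clones["is_hit"] = clones["p"] < alpha
        frames.append(clones.drop(columns=["is_wildtype"]))
    cols = ["clone_id", "gene_symbol", "dose_gy", "delta_v", "z", "p", "log10_p",
            "direction", "is_hit"]
    if frames:
        results = pd.concat(frames, ignore_index=True)[cols]
    else:
        results = pd.DataFrame(columns=cols)
    return results, nulls


def call_hits(
    results: pd.DataFrame, alpha: float = 0.01, statistic_column: str = "delta_v"
) -> HitCalls:
    """Partition significant results by (dose contrast, direction).

    Works for viability and expression result tables alike; direction is
    taken from the ``direction`` column when present, otherwise from the
    sign of *statistic_column*.
    """
    partitions: dict[tuple[float, str], tuple[str, ...]] = {}
    if len(results) == 0 or alpha <= 0:
        return HitCalls(alpha=alpha, partitions={}, unique_genes=frozenset())
    hits = results[results["p"] < alpha]
    for (dose, direction), grp in hits.groupby(
        ["dose_gy", _direction_series(hits, statistic_column)], sort=True
    ):
        partitions[(float(dose), str(direction))] = tuple(
            sorted(grp["gene_symbol"].unique())
        )
    union = frozenset(g for genes in partitions.values() for g in genes)
    return HitCalls(alpha=alpha, partitions=partitions, unique_genes=union)


def _direction_series(df: pd.DataFrame, statistic_column: str) -> pd.Series:
    if "direction" in df.columns:
        return df["direction"]
    return pd.Series(
        np.where(df[statistic_column] > 0, "increased", "decreased"), index=df.index
    )
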