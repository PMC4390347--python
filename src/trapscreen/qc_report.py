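"""Replicate-concordance QC, ΔΔCt validation arithmetic, and run reports.

Duplicate concordance is the screen's primary data-quality readout: for
each assay and dose the per-clone value from duplicate 1 is correlated
with the value from duplicate 2.  High correlation means between-clone
biology dominates well-to-well noise.

The ΔΔCt helper follows the screen's qPCR convention:

    ΔCt  = Ct(reference gene) − Ct(gene of interest)      per condition
    ΔΔCt = ΔCt(irradiated) − ΔCt(unirradiated)
    fold = 2^ΔΔCt

Note the subtraction orientation — reference minus gene — flips the more
common textbook convention, so a *positive* ΔΔCt means up-regulation.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .screen_data import ScreenDataset


@dataclass(frozen=True)
class QcSummary:
    assay: Literal["viability", "betagal"]
    dose_gy: float
    pearson_r: float  # NaN when undefined
    n_pairs: int
    excluded_wells: int
    reason: str = ""


@dataclass(frozen=True)
class DdctRecord:
    sample_id: str
    gene: str
    ct_gene: float
    ct_reference: float
    condition: Literal["irradiated", "unirradiated"]

    def __post_init__(self) -> None:
        if self.ct_gene <= 0 or self.ct_reference <= 0:
            raise ValidationError(f"Ct values must be positive for {self.sample_id}")

    @property
    def delta_ct(self) -> float:
        # reference minus gene: higher expression -> lower gene Ct -> larger dCt
        return self.ct_reference - self.ct_gene


def _well_metric(dataset: ScreenDataset, assay: str) -> pd.DataFrame:
    rec = dataset.records.copy()
    rec["live_rlu"] = rec["total_rlu"] - rec["dead_rlu"]
    if assay == "viability":
        ok = rec["total_rlu"] > 0
        rec = rec[ok]
        rec["metric"] = rec["live_rlu"] / rec["total_rlu"]
        dropped = int((~ok).sum())
    elif assay == "betagal":
        rec = rec[~rec["is_wildtype"]]
        ok = (rec["live_rlu"] > 0) & rec["betagal_rlu"].notna()
        dropped = int((~ok).sum())
        rec = rec[ok]
        rec["metric"] = rec["betagal_rlu"] / rec["live_rlu"]
    else:
        raise ValueError(f"unknown assay {assay!r}")
    rec.attrs["dropped"] = dropped
    return rec


def duplicate_correlation(
    dataset: ScreenDataset,
    assay: Literal["viability", "betagal"] = "viability",
    method: Literal["pearson", "spearman"] = "pearson",
) -> list[QcSummary]:
    """Between-duplicate correlation of per-clone values, per dose.

    Uses replicates 1 and 2 of each clone (further replicates are
    ignored for the pairing).  Returns one summary per dose; a dose with
    fewer than two complete pairs yields an undefined correlation with
    the reason recorded rather than an exception.
    """
    rec = _well_metric(dataset, assay)
    dropped = rec.attrs.get("dropped", 0)
    out: list[QcSummary] = []
    for dose in dataset.dose_set:
        sub = rec[rec["dose_gy"] == dose]
        wide = sub.pivot_table(index="clone_id", columns="replicate", values="metric")
        if 1 not in wide.columns or 2 not in wide.columns:
            out.append(QcSummary(assay, float(dose), float("nan"), 0, dropped,
                                 "missing duplicate"))
            continue
        pairs = wide[[1, 2]].dropna()
        if len(pairs) < 2:
            out.append(QcSummary(assay, float(dose), float("nan"), len(pairs), dropped,
                                 "fewer than 2 complete duplicate pairs"))
            continue
        if method == "pearson":
            r = stats.pearsonr(pairs[1], pairs[2]).statistic
        else:
            r = stats.spearmanr(pairs[1], pairs[2]).statistic
        out.append(QcSummary(assay, float(dose), float(r), int(len(pairs)), dropped))
    return out


def ddct_fold_change(unirradiated: DdctRecord, irradiated: DdctRecord) -> float:
    """Relative expression fold change between conditions, 2^ΔΔCt.

    With the reference-minus-gene ΔCt orientation used here, ΔΔCt = +2
    means 4-fold up-regulation after irradiation and ΔΔCt = −1 means
    expression halved.
    """
    if unirradiated.gene != irradiated.gene:
        raise ValidationError(
            f"gene mismatch: {unirradiated.gene} vs {irradiated.gene}"
        )
    if unirradiated.condition != "unirradiated" or irradiated.condition != "irradiated":
        raise ValidationError("records passed in the wrong condition order")
    ddct = irradiated.delta_ct - unirradiated.delta_ct
    return float(2.0 ** ddct)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def build_report(
    config: Mapping[str, Any],
    results: Mapping[str, pd.DataFrame],
    qc: Sequence[QcSummary] = (),
    nulls: Mapping[str, Any] | None = None,
) -> dict[str, Any]:
    """Assemble a structured, JSON-serialisable run report.

    Embeds the full configuration (including every seed) and environment
    versions so that a run can be reproduced bit-identically from the
    report alone, plus per-table row counts and the tables themselves.
    """
    import trapscreen

    report = {
        "metadata": {
            "package": "trapscreen",
            "version": trapscreen.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "created_utc": datetime.now(timezone.utc).isoformat(),
        },
        "config": _jsonable(dict(config)),
        "qc": [asdict(q) for q in qc],
        "nulls": _jsonable(nulls or {}),
        "counts": {name: int(len(df)) for name, df in results.items()},
        "tables": {name: _jsonable(df) for name, df in results.items()},
    }
    return report


def render_report(report: Mapping[str, Any]) -> str:
    """Human-readable rendering of a report built by :func:`build_report`."""
    lines = [
        f"trapscreen {report['metadata']['version']} run report",
        f"created: {report['metadata']['created_utc']}",
        "",
        "counts:",
    ]
    for name, count in report["counts"].items():
        lines.append(f"  {name}: {count} rows")
    if report["qc"]:
        lines.append("")
        lines.append("duplicate concordance:")
        for q in report["qc"]:
            r = q["pearson_r"]
            rtxt = "undefined" if r != r else f"{r:.3f}"
            lines.append(
                f"  {q['assay']} @ {q['dose_gy']} Gy: r = {rtxt} (n = {q['n_pairs']})"
            )
    lines.append("")
    lines.append("config: " + json.dumps(report["config"], sort_keys=True))
    return "\n".join(lines)
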