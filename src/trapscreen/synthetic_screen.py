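"""Synthetic dual-assay screens with planted hits.

The generator reproduces the statistical structure the analysis relies
on, at the original study's scale by default: 386 mutant clones (one per
gene) plus 22 wild-type replicate samples, duplicate wells at 0, 0.5 and
4 Gy, a wild-type ΔV null of mean −1.5 % / SD 6.7 % at 0.5 Gy and
−2.7 % / 8.0 % at 4 Gy (back-derived from the published hit tables), a
β-gal log₁₀-ratio null of SD 0.14 / 0.19 per dose, and planted viability
and expression effects for power and recovery experiments.

Generative model per well (clone c, dose d, duplicate j):

* viability  v = clip(base + b_c + [d>0]·(δ_cd + planted ΔV) + w·ε_cdj)
  with clone baseline b_c ~ N(0, clone_viability_sd), dose systematic
  δ_cd ~ N(μ_d, s_d) and well noise ε ~ N(0,1);
* total RLU = rlu_scale · lognormal gain (CV = measurement_cv), shared by
  the dead and total readouts of a well so that dead/total returns the
  drawn viability exactly — luminescence gain varies per well, the
  within-well ratio does not; dead RLU = total · (1 − v);
* β-gal RLU = live RLU · E_c · 10^(η_cd + planted log₁₀ effect + t·ζ_cdj)
  with baseline expression E_c lognormal across clones, dose systematic
  η_cd ~ N(0, u_d) and per-well reporter noise t.

The systematic SDs s_d and u_d are calibrated so that the *duplicate-
averaged* ΔV and log₁₀-ratio nulls seen by the pipeline have exactly the
configured wt_dv_sd_per_dose / expr_log10_sd_per_dose; the well-noise
split additionally sets the between-duplicate concordance.  Wild-type
replicate samples run through the identical model (no reporter, no
effects), so wild-type and null-clone ΔV are exchangeable by
construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .screen_data import PLATE_COLUMNS, ScreenDataset, dataset_from_frame, write_plate_table

logger = logging.getLogger(__name__)

_CLIP_LO, _CLIP_HI = 0.02, 0.98


@dataclass(frozen=True)
class PlantedHit:
    """A true effect planted at one gene and one dose contrast."""

    gene_symbol: str
    dose_gy: float
    dv_effect: float = 0.0
    log10_expr_effect: float = 0.0


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Screen-generator parameters; defaults are the original study's scale.

    Fractions are viability fractions in [0, 1]; expression parameters are
    log₁₀ units.  ``seed`` governs every draw through fixed per-stage
    substreams, so regenerating with the same config is byte-identical.
    """

    n_clones: int = 386
    n_wt_replicates: int = 22
    doses: tuple[float, ...] = (0.0, 0.5, 4.0)
    n_duplicates: int = 2
    wt_dv_mean_per_dose: Mapping[float, float] = field(
        default_factory=lambda: {0.5: -0.015, 4.0: -0.027}
    )
    wt_dv_sd_per_dose: Mapping[float, float] = field(
        default_factory=lambda: {0.5: 0.067, 4.0: 0.080}
    )
    base_viability: float = 0.6
    clone_viability_sd: float = 0.05
    well_viability_sd: float = 0.042
    rlu_scale: float = 50_000.0
    measurement_cv: float = 0.10
    expr_log10_sd_per_dose: Mapping[float, float] = field(
        default_factory=lambda: {0.5: 0.14, 4.0: 0.19}
    )
    clone_expr_log10_sd: float = 0.5
    betagal_well_log10_sd: float = 0.07
    planted_hits: tuple[PlantedHit, ...] = ()
    clones_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 0 or self.n_wt_replicates < 0:
            raise ConfigError("counts must be non-negative")
        if self.n_duplicates < 1:
            raise ConfigError("n_duplicates must be ≥ 1")
        if self.clones_per_gene < 1:
            raise ConfigError("clones_per_gene must be ≥ 1")
        if 0.0 not in self.doses:
            raise ConfigError("dose set must include the 0-Gy reference")
        if any(d < 0 for d in self.doses):
            raise ConfigError("doses must be non-negative")
        if not (0 <= self.base_viability <= 1):
            raise ConfigError("base_viability must be in [0, 1]")
        for name in ("clone_viability_sd", "well_viability_sd", "measurement_cv",
                     "clone_expr_log10_sd", "betagal_well_log10_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be ≥ 0")
        for d in self.nonzero_doses:
            for table, label in (
                (self.wt_dv_sd_per_dose, "wt_dv_sd_per_dose"),
                (self.expr_log10_sd_per_dose, "expr_log10_sd_per_dose"),
            ):
                if d not in table:
                    raise ConfigError(f"{label} has no entry for dose {d}")
                if table[d] <= 0:
                    raise ConfigError(f"{label}[{d}] must be > 0")
            if d not in self.wt_dv_mean_per_dose:
                raise ConfigError(f"wt_dv_mean_per_dose has no entry for dose {d}")
        # the well-noise share of Var(duplicate-averaged ΔV) must leave room
        # for a non-negative systematic component
        noise_var = 2 * self.well_viability_sd**2 / self.n_duplicates
        for d in self.nonzero_doses:
            if self.wt_dv_sd_per_dose[d] ** 2 <= noise_var:
                raise ConfigError(
                    f"well_viability_sd too large: duplicate-averaged ΔV noise "
                    f"alone exceeds wt_dv_sd_per_dose[{d}]"
                )
        expr_noise_var = 2 * self.betagal_well_log10_sd**2 / self.n_duplicates
        for d in self.nonzero_doses:
            if self.expr_log10_sd_per_dose[d] ** 2 <= expr_noise_var:
                raise ConfigError(
                    f"betagal_well_log10_sd too large for expr_log10_sd_per_dose[{d}]"
                )

    @property
    def nonzero_doses(self) -> tuple[float, ...]:
        return tuple(d for d in self.doses if d > 0)

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        n_genes = -(-self.n_clones // self.clones_per_gene)  # ceil division
        return tuple(f"G{i:04d}" for i in range(1, n_genes + 1))


@dataclass(frozen=True)
class GroundTruth:
    """True planted effects per gene and dose, for recovery experiments."""

    effects: pd.DataFrame  # gene_symbol, dose_gy, dv_effect, log10_expr_effect

    def viability_hit_genes(self, dose: float | None = None) -> frozenset[str]:
        df = self.effects
        if dose is not None:
            df = df[df["dose_gy"] == dose]
        return frozenset(df.loc[df["dv_effect"] != 0, "gene_symbol"])

    def expression_hit_genes(self, dose: float | None = None) -> frozenset[str]:
        df = self.effects
        if dose is not None:
            df = df[df["dose_gy"] == dose]
        return frozenset(df.loc[df["log10_expr_effect"] != 0, "gene_symbol"])


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    # fixed per-stage substreams: edits to one stage leave the others' draws intact
    return np.random.default_rng([seed, stage])


def simulate_screen(config: SyntheticScreenConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Generate one screen and its ground truth; deterministic given seed."""
    genes = config.gene_symbols
    planted = {(h.gene_symbol, h.dose_gy): h for h in config.planted_hits}
    unknown = sorted({h.gene_symbol for h in config.planted_hits} - set(genes))
    if unknown:
        raise ConfigError(f"planted hits reference unknown genes: {unknown}")
    bad_dose = sorted({h.dose_gy for h in config.planted_hits} - set(config.nonzero_doses))
    if bad_dose:
        raise ConfigError(f"planted hits reference doses outside the screen: {bad_dose}")

    clone_ids = [f"C{i:04d}" for i in range(1, config.n_clones + 1)]
    clone_genes = [genes[i % len(genes)] for i in range(config.n_clones)] if genes else []
    wt_ids = [f"WT{i:02d}" for i in range(1, config.n_wt_replicates + 1)]

    unit_ids = clone_ids + wt_ids
    unit_genes = clone_genes + ["WT"] * config.n_wt_replicates
    is_wt = np.array(
        [False] * config.n_clones + [True] * config.n_wt_replicates, dtype=bool
    )
    n_units = len(unit_ids)
    doses = tuple(sorted(config.doses))
    n_doses, n_dup = len(doses), config.n_duplicates

    rng_base = _stage_rng(config.seed, 0)
    rng_vsys = _stage_rng(config.seed, 1)
    rng_wnoise = _stage_rng(config.seed, 2)
    rng_gain = _stage_rng(config.seed, 3)
    rng_ebase = _stage_rng(config.seed, 4)
    rng_esys = _stage_rng(config.seed, 5)
    rng_enoise = _stage_rng(config.seed, 6)

    b = rng_base.normal(0.0, config.clone_viability_sd, size=n_units)
    noise_var = 2 * config.well_viability_sd**2 / n_dup
    expr_noise_var = 2 * config.betagal_well_log10_sd**2 / n_dup

    # systematic per-(unit, dose) components, calibrated so duplicate-averaged
    # ΔV / log-ratio nulls have exactly the configured SDs
    delta = np.zeros((n_units, n_doses))
    eta = np.zeros((n_units, n_doses))
    dv_eff = np.zeros((n_units, n_doses))
    ex_eff = np.zeros((n_units, n_doses))
    for k, d in enumerate(doses):
        if d == 0:
            continue
        s_sys = math.sqrt(config.wt_dv_sd_per_dose[d] ** 2 - noise_var)
        delta[:, k] = rng_vsys.normal(config.wt_dv_mean_per_dose[d], s_sys, size=n_units)
        u_sys = math.sqrt(config.expr_log10_sd_per_dose[d] ** 2 - expr_noise_var)
        eta[:, k] = rng_esys.normal(0.0, u_sys, size=n_units)
        for i in range(n_units):
            if is_wt[i]:
                continue
            hit = planted.get((unit_genes[i], d))
            if hit is not None:
                dv_eff[i, k] = hit.dv_effect
                ex_eff[i, k] = hit.log10_expr_effect

    eps = rng_wnoise.normal(0.0, 1.0, size=(n_units, n_doses, n_dup))
    v = (
        config.base_viability
        + b[:, None, None]
        + (delta + dv_eff)[:, :, None]
        + config.well_viability_sd * eps
    )
    n_clipped = int(((v < _CLIP_LO) | (v > _CLIP_HI)).sum())
    if n_clipped:
        logger.warning("clipped %d well viabilities into [%.2f, %.2f]",
                       n_clipped, _CLIP_LO, _CLIP_HI)
    v = np.clip(v, _CLIP_LO, _CLIP_HI)

    # shared per-well lognormal gain: dead/total preserves the drawn viability
    cv = config.measurement_cv
    if cv > 0:
        log_sd = math.sqrt(math.log(1 + cv**2))
        gain = rng_gain.lognormal(-(log_sd**2) / 2, log_sd, size=(n_units, n_doses, n_dup))
    else:
        gain = np.ones((n_units, n_doses, n_dup))
    total = config.rlu_scale * gain
    dead = total * (1.0 - v)
    live = total - dead

    e_base = 10.0 ** rng_ebase.normal(0.0, config.clone_expr_log10_sd, size=n_units)
    zeta = rng_enoise.normal(0.0, 1.0, size=(n_units, n_doses, n_dup))
    log10_expr = (
        np.log10(e_base)[:, None, None]
        + (eta + ex_eff)[:, :, None]
        + config.betagal_well_log10_sd * zeta
    )
    betagal = live * 10.0**log10_expr
    betagal[is_wt] = np.nan

    idx_u, idx_d, idx_j = np.meshgrid(
        np.arange(n_units), np.arange(n_doses), np.arange(n_dup), indexing="ij"
    )
    frame = pd.DataFrame(
        {
            "clone_id": np.array(unit_ids, dtype=object)[idx_u.ravel()],
            "gene_symbol": np.array(unit_genes, dtype=object)[idx_u.ravel()],
            "dose_gy": np.array(doses)[idx_d.ravel()],
            "replicate": idx_j.ravel() + 1,
            "dead_rlu": dead.ravel(),
            "total_rlu": total.ravel(),
            "betagal_rlu": betagal.ravel(),
            "is_wildtype": is_wt[idx_u.ravel()],
        },
        columns=list(PLATE_COLUMNS),
    )

    truth_rows = [
        {
            "gene_symbol": g,
            "dose_gy": d,
            "dv_effect": planted.get((g, d), PlantedHit(g, d)).dv_effect,
            "log10_expr_effect": planted.get((g, d), PlantedHit(g, d)).log10_expr_effect,
        }
        for g in genes
        for d in config.nonzero_doses
    ]
    truth = GroundTruth(
        effects=pd.DataFrame(
            truth_rows,
            columns=["gene_symbol", "dose_gy", "dv_effect", "log10_expr_effect"],
        )
    )
    return dataset_from_frame(frame), truth


def config_to_dict(config: SyntheticScreenConfig) -> dict:
    d = asdict(config)
    d["planted_hits"] = [asdict(h) for h in config.planted_hits]
    d["doses"] = list(config.doses)
    for key in ("wt_dv_mean_per_dose", "wt_dv_sd_per_dose", "expr_log10_sd_per_dose"):
        d[key] = {float(k): float(v) for k, v in d[key].items()}
    return d


def config_from_dict(d: Mapping) -> SyntheticScreenConfig:
    d = dict(d)
    d["planted_hits"] = tuple(PlantedHit(**h) for h in d.get("planted_hits", ()))
    d["doses"] = tuple(float(x) for x in d.get("doses", (0.0, 0.5, 4.0)))
    for key in ("wt_dv_mean_per_dose", "wt_dv_sd_per_dose", "expr_log10_sd_per_dose"):
        if key in d:
            d[key] = {float(k): float(v) for k, v in d[key].items()}
    return SyntheticScreenConfig(**d)


def emit_fixture(
    config: SyntheticScreenConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write a simulated screen to disk: plate table, ground truth, config.

    Files regenerate identically from the emitted config snapshot.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dataset, truth = simulate_screen(config)
    paths = {
        "plate": out_dir / "plate.tsv",
        "truth": out_dir / "ground_truth.tsv",
        "config": out_dir / "config.yaml",
    }
    write_plate_table(dataset, paths["plate"])
    truth.effects.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    return paths


def load_fixture_config(path: str | Path) -> SyntheticScreenConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
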