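"""Readers/writers, run configuration, subject aggregation and pipeline.

Cell tables follow the generic digital-pathology export contract
(comma-separated, UTF-8, header row, "." decimal): one row per detected
cell with columns ``core_id, tma, x_um, y_um, phenotype`` and an
optional ``compartment`` column.  Coordinates are stored in µm; pixel
units must be converted explicitly by the caller (no silent default).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .exceptions import ParameterError, PipelineError
from .spatial import (
    DiscWindow,
    EnvelopeBand,
    CrossKEstimate,
    MarkedPointPattern,
    Window,
    cross_k,
    default_distance_grid,
    envelope,
    family_envelope,
    filter_cores,
)
from .transcriptomics import GeneSet

log = logging.getLogger(__name__)

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "write_crossk_table",
    "aggregate_subject",
    "ef5_positivity",
    "EF5Result",
    "RunConfig",
    "run_pipeline",
]

CELL_COLUMNS = ["core_id", "tma", "x_um", "y_um", "phenotype", "compartment"]


# ---------------------------------------------------------------------------
# Cell tables


def read_cell_table(
    path: str | Path,
    mapping: Mapping[str, str] | None = None,
    window: Window | None = None,
) -> list[MarkedPointPattern]:
    """Read a per-cell CSV into one pattern per (tma, core_id).

    ``mapping`` translates source phenotype labels to {CD8, CAIX,
    other}; unmapped labels become "other" (count logged).  Unless a
    window is supplied, each core's window is the disc centred at the
    point centroid with radius equal to the maximum distance from the
    centroid.
    """
    df = pd.read_csv(path)
    if df.empty:
        log.warning("cell table %s is empty", path)
        return []
    required = ["core_id", "tma", "x_um", "y_um", "phenotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError(f"cell table missing required columns: {missing}")
    for c in ("x_um", "y_um"):
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            raise ParameterError(
                f"non-numeric coordinates in column {c!r} at rows "
                f"{df.index[bad].tolist()[:10]}"
            )
        df[c] = pd.to_numeric(df[c])
    if mapping:
        known = df["phenotype"].isin(mapping.keys())
        n_unmapped = int((~known).sum())
        if n_unmapped:
            log.info("read_cell_table: %d unmapped label(s) set to 'other'", n_unmapped)
        df["phenotype"] = df["phenotype"].map(mapping).fillna("other")

    patterns = []
    for (tma, core), grp in df.groupby(["tma", "core_id"], sort=True):
        pts = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        if window is None:
            centroid = pts.mean(axis=0)
            radius = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1)).max())
            win: Window = DiscWindow(center=tuple(centroid), radius=max(radius, 1e-6) * (1 + 1e-9))
        else:
            win = window
        comp = (
            grp["compartment"].to_numpy(dtype=object)
            if "compartment" in grp.columns
            else None
        )
        patterns.append(
            MarkedPointPattern(
                points=pts,
                marks=grp["phenotype"].to_numpy(dtype=object),
                window=win,
                compartments=comp,
                core_id=str(core),
                tma_id=str(tma),
            )
        )
    return patterns


def write_cell_table(patterns: Sequence[MarkedPointPattern], path: str | Path) -> None:
    rows = []
    for p in patterns:
        for k in range(p.n_points):
            rows.append(
                {
                    "core_id": p.core_id,
                    "tma": p.tma_id,
                    "x_um": p.points[k, 0],
                    "y_um": p.points[k, 1],
                    "phenotype": p.marks[k],
                    "compartment": (
                        p.compartments[k] if p.compartments is not None else ""
                    ),
                }
            )
    pd.DataFrame(rows, columns=CELL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Expression matrices and gene sets


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × samples TSV with gene identifiers in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            sets.append(GeneSet(name=name, genes=tuple(dict.fromkeys(genes))))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "tmakit"] + list(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# Cross-K tidy output


def write_crossk_table(
    estimates: Sequence[CrossKEstimate],
    bands: Sequence[EnvelopeBand] | None,
    path: str | Path,
) -> None:
    """Tidy CSV: core_id, tma, d, k_hat, k_theo[, lo, hi]."""
    frames = []
    band_by_core = {}
    if bands:
        band_by_core = {(b.tma_id, b.core_id): b for b in bands}
    for est in estimates:
        df = pd.DataFrame(
            {
                "core_id": est.core_id,
                "tma": est.tma_id,
                "d": est.distances,
                "k_hat": est.k_hat,
                "k_theo": est.k_theo,
            }
        )
        b = band_by_core.get((est.tma_id, est.core_id))
        if b is not None:
            df["lo"] = b.lo
            df["hi"] = b.hi
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Subject-level aggregation and the PET positivity rule


def aggregate_subject(summaries: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of per-core densities per subject (core count kept)."""
    if "subject_id" not in summaries.columns:
        raise ParameterError("summaries need a subject_id column")
    dens_cols = [c for c in summaries.columns if "_density_" in c]
    agg = summaries.groupby("subject_id")[dens_cols].mean()
    agg["n_cores"] = summaries.groupby("subject_id").size()
    return agg.reset_index()


class EF5Result(NamedTuple):
    ratio: float
    positive: bool


def ef5_positivity(
    suv_tumor: float, suv_muscle: float, threshold: float = 1.5
) -> EF5Result:
    """PET tumor-to-muscle uptake positivity: positive iff T/M > threshold.

    The inequality is strict: a ratio exactly at the threshold is
    negative.
    """
    if suv_muscle <= 0:
        raise ParameterError("muscle SUV must be positive")
    ratio = suv_tumor / suv_muscle
    return EF5Result(ratio=ratio, positive=ratio > threshold)


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass
class RunConfig:
    """End-to-end synthetic pipeline configuration."""

    seed: int = 0
    out_dir: str = "tmakit_run"
    # synthetic cohort geometry
    n_subjects: int = 40
    cores_per_subject: int = 2
    core: dict = field(default_factory=dict)  # CoreSimConfig overrides
    cohort: dict = field(default_factory=dict)  # CohortSimConfig overrides
    # spatial parameters
    d_max: float = 200.0
    d_step: float = 2.0
    n_sim: int = 199
    level: float = 0.99
    null_model: str = "random_labeling"
    correction: str = "translation"
    density_threshold: float = 4e-5
    compartment: str | None = None
    # survival / count models
    ties: str = "efron"
    family: str = "negative_binomial"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate → densities → spatial → association → survival.

    Writes all stage outputs plus a JSON manifest into
    ``config.out_dir`` and returns a result dictionary with the main
    in-memory objects.  Any stage failure raises a stage-named
    :class:`PipelineError`.
    """
    from .association import bootstrap_ci, fit_count_model, spearman, summarize_cores
    from .survival import fit_cox
    from .synthetic import (
        CohortSimConfig,
        CoreSimConfig,
        simulate_cohort,
        simulate_core,
        survival_from_covariates,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=4)
    result: dict = {"config": config}

    # --- stage: simulate cores -------------------------------------------
    try:
        patterns = []
        subject_of: dict[tuple, str] = {}
        core_seed_rng = np.random.default_rng(seeds[0])
        for s in range(config.n_subjects):
            sid = f"S{s:04d}"
            tma = "A" if s % 2 == 0 else "B"
            for c in range(config.cores_per_subject):
                cfg = CoreSimConfig(
                    **{
                        **config.core,
                        "seed": int(core_seed_rng.integers(0, 2**31 - 1)),
                    }
                )
                p = simulate_core(cfg)
                p.core_id = f"{sid}_c{c}"
                p.tma_id = tma
                patterns.append(p)
                subject_of[(tma, p.core_id)] = sid
        write_cell_table(patterns, out / "cells.csv")
        log.info("stage simulate: %d cores, %d cells", len(patterns),
                 sum(p.n_points for p in patterns))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context wrapper
        raise PipelineError("simulate", str(exc)) from exc
    result["patterns"] = patterns

    # --- stage: densities --------------------------------------------------
    try:
        summaries = summarize_cores(patterns, subject_ids=subject_of)
        summaries.to_csv(out / "core_summaries.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("densities", str(exc)) from exc
    result["summaries"] = summaries

    # --- stage: spatial -----------------------------------------------------
    try:
        grid = default_distance_grid(config.d_max, config.d_step)
        filt = filter_cores(
            patterns,
            threshold=config.density_threshold,
            compartment=config.compartment,
        )
        env_rng = np.random.default_rng(seeds[1])
        bands, estimates = [], []
        for p in filt.kept:
            pat = (
                p.subset_compartment(config.compartment)
                if config.compartment
                else p
            )
            est = cross_k(pat, distances=grid, correction=config.correction)
            band = envelope(
                pat,
                distances=grid,
                n_sim=config.n_sim,
                level=config.level,
                null_model=config.null_model,
                correction=config.correction,
                rng=env_rng,
            )
            estimates.append(est)
            bands.append(band)
        fam = {}
        for tma in sorted({b.tma_id for b in bands}):
            sub = [b for b in bands if b.tma_id == tma]
            fam[tma] = family_envelope(sub)
        write_crossk_table(estimates, bands, out / "crossk.csv")
        log.info(
            "stage spatial: %d evaluable cores (%d dropped)",
            len(filt.kept), len(filt.dropped),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("spatial", str(exc)) from exc
    result["filter"] = filt
    result["estimates"] = estimates
    result["bands"] = bands
    result["family_envelopes"] = fam

    # --- stage: association -----------------------------------------------
    try:
        assoc_rows = []
        boot_rng = np.random.default_rng(seeds[2])
        for comp in ("all", "tumor", "stroma"):
            x = summaries[f"caix_density_{comp}"].to_numpy(dtype=float)
            y = summaries[f"cd8_density_{comp}"].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            rho, pval = spearman(x[ok], y[ok])
            lo, hi = bootstrap_ci(x[ok], y[ok], B=1000, rng=boot_rng)
            assoc_rows.append(
                {"compartment": comp, "rho": rho, "p": pval, "lo": lo, "hi": hi}
            )
        assoc = pd.DataFrame(assoc_rows)
        assoc.to_csv(out / "association.csv", index=False)
        nb_fit = None
        if summaries["tma"].nunique() >= 2:
            nb_fit = fit_count_model(summaries, family=config.family)
            nb_fit.params.rename("estimate").to_frame().assign(
                se=nb_fit.bse, p=nb_fit.pvalues
            ).to_csv(out / "count_model.csv", index_label="term")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("association", str(exc)) from exc
    result["association"] = assoc
    result["count_model"] = nb_fit

    # --- stage: survival -----------------------------------------------------
    try:
        per_subject = aggregate_subject(summaries)
        cohort_cfg = CohortSimConfig(
            **{
                **config.cohort,
                "n_subjects": config.n_subjects,
                "seed": int(seeds[3]),
            }
        )
        cohort = simulate_cohort(cohort_cfg)
        # measured (per-mm²) densities from the cores replace the drawn ones
        cohort = cohort.drop(columns=["cd8_density", "caix_density"]).merge(
            per_subject[["subject_id", "cd8_density_all", "caix_density_all"]],
            on="subject_id",
            how="inner",
        )
        cohort = cohort.rename(
            columns={"cd8_density_all": "cd8_density", "caix_density_all": "caix_density"}
        )
        cohort["cd8_density"] *= 1e6  # µm² -> mm² density scale
        cohort["caix_density"] *= 1e6
        from .synthetic import _design_from_cohort  # same coding as generator

        design = _design_from_cohort(
            cohort,
            ["age", "stage", "grade", "debulking", "family_history",
             "cd8_density", "caix_density"],
        )
        surv_rng = np.random.default_rng(int(seeds[3]) + 1)
        time, event, _ = survival_from_covariates(
            design,
            dict(cohort_cfg.log_hazard_coefs),
            cohort_cfg.baseline_shape,
            cohort_cfg.baseline_scale,
            cohort_cfg.censoring_rate,
            surv_rng,
        )
        cohort["time"], cohort["event"] = time, event
        cohort.to_csv(out / "cohort.csv", index=False)
        from .survival import build_design as _bd

        candidates = ["age", "stage", "grade", "debulking", "family_history",
                      "cd8_density", "caix_density"]
        usable = [
            c for c in candidates
            if _bd(cohort, [c]).nunique().gt(1).all()
            and _bd(cohort, [c]).shape[1] > 0
        ]
        if usable != candidates:
            log.info("stage survival: dropping non-varying covariate(s): %s",
                     sorted(set(candidates) - set(usable)))
        try:
            cox = fit_cox(cohort, usable, ties=config.ties)
            if cox.flagged:
                raise ParameterError(cox.flagged)
        except (ParameterError, np.linalg.LinAlgError):
            # small cohorts can make the full factor design collinear
            minimal = [c for c in ("age", "cd8_density", "caix_density")
                       if c in usable]
            log.info("stage survival: full design collinear; refitting with %s",
                     minimal)
            cox = fit_cox(cohort, minimal, ties=config.ties)
        cox.summary().to_csv(out / "cox.csv", index_label="term")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("survival", str(exc)) from exc
    result["cohort"] = cohort
    result["cox"] = cox

    # --- manifest -----------------------------------------------------------
    manifest = {
        "tmakit_version": _pkg_version,
        "seed": config.seed,
        "stage_seeds": [int(s) for s in seeds],
        "parameters": dataclasses.asdict(config),
        "n_cores": len(patterns),
        "n_evaluable_cores": len(filt.kept),
        "n_dropped_cores": len(filt.dropped),
        "n_subjects": int(cohort.shape[0]),
        "n_events": int(cohort["event"].sum()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result["manifest"] = manifest
    return result
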