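"""End-to-end runner: species table + tree + fossil specs -> retrodictions.

Stages (each logged, each failing with a stage-named error):

1. read inputs (species CSV, Newick tree)
2. hemodynamics: foramen area -> lumen radius -> blood flow for any taxon
   that lacks a measured flow
3. allometry: phylogenetic exponent b from the clade exponents (or override)
4. response transform: log10 mass-independent MMR, log10 flow
5. fossil grafting onto the extant tree
6. eigenvector basis (optionally grid-searching the steepness a by AICc)
   and forward AICc selection with flow as co-predictor
7. fossil retrodiction with back-transformed intervals
8. validation: LOOCV paired test and Shapiro-Wilk residual normality
9. report files: retrodictions.csv, model.csv, validation.csv, manifest.json
"""
from __future__ import annotations

import contextlib
import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allometry import phylogenetic_exponent
from .config import RunConfig
from .hemodynamics import ForamenMeasurement, flow_from_foramen
from .inference import (
    FitResult,
    Retrodiction,
    ValidationReport,
    forward_select,
    loocv,
    retrodict,
)
from .pem import PEMBasis, build_pem, location_scores, unrepresented_length
from .phylo import GraftSpec, PhyloTree, brownian_rate, graft_fossil, read_newick

__all__ = ["PipelineError", "PipelineResults", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)

_GRID_A = [round(0.1 * i, 1) for i in range(10)]
_REQUIRED_COLS = {"taxon", "clade", "mass_g", "mmr_mlo2_h"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@contextlib.contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{name}': {exc}") from exc
    logger.info("stage %s: done", name)


@dataclasses.dataclass
class PipelineResults:
    config: RunConfig
    species: pd.DataFrame
    extant_tree: PhyloTree
    grafted_tree: PhyloTree
    b: float
    basis: PEMBasis
    fit: FitResult
    retrodictions: list[Retrodiction]
    validation: ValidationReport
    steepness: float                # the a actually used (after grid search)


def run_pipeline(config: RunConfig) -> PipelineResults:
    with _stage("read inputs"):
        config.check_files()
        df = pd.read_csv(config.species_csv)
        missing = _REQUIRED_COLS - set(df.columns)
        if missing:
            raise ValueError(f"species CSV lacks columns: {sorted(missing)}")
        if df["taxon"].duplicated().any():
            raise ValueError("duplicate taxa in species CSV")
        df = df.set_index("taxon")
        for col in ("q_ml_s", "foramen_area_mm2", "lumen_fraction"):
            if col not in df.columns:
                df[col] = math.nan
        tree = read_newick(Path(config.tree_newick).read_text())

    with _stage("hemodynamics"):
        frac_default = config.hemodynamics.lumen_fraction
        for taxon, row in df.iterrows():
            if math.isnan(row["q_ml_s"]) and not math.isnan(row["foramen_area_mm2"]):
                frac = row["lumen_fraction"]
                frac = frac_default if math.isnan(frac) else float(frac)
                est = flow_from_foramen(
                    ForamenMeasurement(str(taxon), float(row["foramen_area_mm2"]), frac)
                )
                df.loc[taxon, "q_ml_s"] = est.flow_ml_s
                logger.info(
                    "hemodynamics: %s area=%.4g mm^2 -> r=%.4g mm, Q=%.4g mL/s",
                    taxon, row["foramen_area_mm2"], est.radius_mm, est.flow_ml_s,
                )
        fossil_q: dict[str, float] = {}
        for fossil in config.fossils:
            if fossil.q_ml_s is not None:
                fossil_q[fossil.label] = fossil.q_ml_s
            else:
                frac = fossil.lumen_fraction or frac_default
                est = flow_from_foramen(
                    ForamenMeasurement(fossil.label, fossil.foramen_area_mm2, frac)
                )
                fossil_q[fossil.label] = est.flow_ml_s
                logger.info(
                    "hemodynamics: fossil %s area=%.4g mm^2 -> Q=%.4g mL/s",
                    fossil.label, fossil.foramen_area_mm2, est.flow_ml_s,
                )
        # fossils given as CSV rows (response missing) also contribute specs?
        # No: fossil placement always comes from config.fossils.

    with _stage("allometry"):
        tips = set(tree.tip_labels())
        extant = df[df["mmr_mlo2_h"].notna()]
        not_in_tree = sorted(set(extant.index) - tips)
        if not_in_tree:
            raise ValueError(f"extant taxa absent from the tree: {not_in_tree}")
        no_response = sorted(tips - set(extant.index))
        if no_response:
            raise ValueError(
                f"tree tips without usable species data: {no_response}"
            )
        if config.allometry.b_override is not None:
            b = float(config.allometry.b_override)
            logger.info("allometry: using fixed exponent b=%.4f", b)
        else:
            clades = extant["clade"].to_dict()
            b = phylogenetic_exponent(tree, config.allometry.clade_exponents, clades)
            logger.info("allometry: phylogenetic exponent b=%.6f (%.2f)", b, round(b, 2))

    with _stage("response transform"):
        bad = extant[(extant["mass_g"] <= 0) | (extant["mmr_mlo2_h"] <= 0)
                     | (extant["q_ml_s"] <= 0) | extant["q_ml_s"].isna()
                     | extant["mass_g"].isna()]
        if len(bad):
            raise ValueError(
                f"extant taxa with missing/non-positive mass, MMR or flow: "
                f"{sorted(bad.index)}"
            )
        work = extant.copy()
        work["log_mmr_mi"] = np.log10(
            work["mmr_mlo2_h"] / work["mass_g"] ** b
        )
        work["log_q"] = np.log10(work["q_ml_s"])

    with _stage("fossil grafting"):
        grafted = tree
        for fossil in config.fossils:
            spec = GraftSpec(
                label=fossil.label,
                attach=fossil.attach,
                attach_time=fossil.attach_time,
                stem_length=fossil.stem_length,
                tip_age=fossil.tip_age,
            )
            grafted = graft_fossil(grafted, spec)
            logger.info("grafted fossil %s at %s", fossil.label, fossil.attach)

    with _stage("eigenvector model"):
        def fit_at(a: float) -> tuple[PEMBasis, FitResult]:
            basis = build_pem(tree, a=a, psi=config.pem.psi)
            y = work.loc[basis.tip_labels, "log_mmr_mi"].to_numpy(float)
            z = work.loc[basis.tip_labels, "log_q"].to_numpy(float)
            return basis, forward_select(y, basis, z)

        if config.pem.grid_search_a:
            best = None
            for a in _GRID_A:
                basis_a, fit_a = fit_at(a)
                logger.info("grid search: a=%.1f AICc=%.3f", a, fit_a.aicc)
                if best is None or fit_a.aicc < best[2].aicc:
                    best = (a, basis_a, fit_a)
            steepness, basis, fit = best
            logger.info("grid search selected a=%.1f", steepness)
        else:
            steepness = config.pem.a
            basis, fit = fit_at(steepness)
        logger.info(
            "model: eigenvectors %s, adj R^2=%.4f, AICc=%.4f",
            list(fit.indices), fit.adj_r2, fit.aicc,
        )

    with _stage("retrodiction"):
        retros = []
        rate = None
        if config.inference.interval == "prediction":
            rate = brownian_rate(tree, work["log_mmr_mi"].to_dict())
            logger.info("response Brownian rate estimate: %.3e per Myr", rate)
        for fossil in config.fossils:
            scores = location_scores(basis, grafted, fossil.label)
            stem_var = 0.0
            if rate is not None:
                stem = unrepresented_length(grafted, fossil.label)
                stem_var = rate * config.pem.psi**2 * stem ** (1.0 - steepness)
            retros.append(
                retrodict(
                    fit,
                    scores,
                    z_fossil=math.log10(fossil_q[fossil.label]),
                    stem_variance=stem_var,
                    level=config.inference.level,
                    kind=config.inference.interval,
                    label=fossil.label,
                    b=b,
                    extant_scores=basis.U,
                )
            )

    with _stage("validation"):
        report = loocv(
            work,
            tree,
            a=steepness,
            psi=config.pem.psi,
            test=config.inference.loocv_test,
            full_fit=fit,
        )

    return PipelineResults(
        config=config,
        species=work,
        extant_tree=tree,
        grafted_tree=grafted,
        b=b,
        basis=basis,
        fit=fit,
        retrodictions=retros,
        validation=report,
        steepness=steepness,
    )


def write_report(results: PipelineResults, outdir: str | Path | None = None) -> dict[str, Path]:
    """Write retrodictions/model/validation CSVs plus a manifest.

    All outputs are computed before any file is opened; if a write fails,
    files already written for this report are removed so no partial report
    remains.  The manifest contains the config echo, package versions and
    the seed (no timestamps), so identical runs are byte-identical.
    """
    out = Path(outdir) if outdir is not None else Path(results.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fit, rep = results.fit, results.validation

    retro_df = pd.DataFrame(
        {
            "label": [r.label for r in results.retrodictions],
            "point": [r.point for r in results.retrodictions],
            "lower": [r.lower for r in results.retrodictions],
            "upper": [r.upper for r in results.retrodictions],
            "point_log10": [r.point_log10 for r in results.retrodictions],
            "lower_log10": [r.lower_log10 for r in results.retrodictions],
            "upper_log10": [r.upper_log10 for r in results.retrodictions],
            "b": [r.b for r in results.retrodictions],
            "level": [r.level for r in results.retrodictions],
            "interval": [r.kind for r in results.retrodictions],
        }
    )
    model_row = {
        "selected_eigenvectors": ",".join(str(i) for i in fit.indices),
        "n": fit.n,
        "k": fit.k,
        "rss": fit.rss,
        "adj_r2": fit.adj_r2,
        "aicc": fit.aicc,
        "f_pvalue": fit.f_pvalue,
        "b": results.b,
        "b_rounded": round(results.b, 2),
        "a": results.steepness,
        "psi": results.config.pem.psi,
    }
    for name, c in zip(fit.coef_names, fit.coef):
        model_row[f"coef_{name}"] = c
    model_df = pd.DataFrame([model_row])

    val_df = rep.to_frame()
    val_df["paired_test"] = rep.test_name
    val_df["paired_statistic"] = rep.statistic
    val_df["paired_pvalue"] = rep.pvalue
    val_df["zero_variance"] = rep.zero_variance
    val_df["shapiro_w"] = rep.shapiro_w
    val_df["shapiro_p"] = rep.shapiro_p

    manifest = {
        "package": "paleomet",
        "version": __version__,
        "versions": _lib_versions(),
        "seed": results.config.seed,
        "config": json.loads(results.config.model_dump_json()),
    }

    paths = {
        "retrodictions": out / "retrodictions.csv",
        "model": out / "model.csv",
        "validation": out / "validation.csv",
        "manifest": out / "manifest.json",
    }
    written: list[Path] = []
    try:
        retro_df.to_csv(paths["retrodictions"], index=False)
        written.append(paths["retrodictions"])
        model_df.to_csv(paths["model"], index=False)
        written.append(paths["model"])
        val_df.to_csv(paths["validation"], index=False)
        written.append(paths["validation"])
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(paths["manifest"])
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return paths


def _lib_versions() -> dict[str, str]:
    import dendropy
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "dendropy": dendropy.__version__,
    }
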