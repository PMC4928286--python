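"""End-to-end analysis pipeline with run manifests.

One call executes the full workflow on a beta matrix: bootstrap selection
of K, deconvolution at K* = max(2, K_hat), row-variance interpretation
(plus CpG-set enrichment when sets are supplied), and phenotype
association/mediation.  Every stage writes delimited tables into the
output directory and a JSON manifest records the command, parameters,
seed, input checksums and package version so the run can be reproduced
exactly.  Stages never mutate their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import estimate_pi0, mediation_comparison, permutation_test
from .deconvolution import DeconvolutionFit, MethylomeMatrix, ProportionMatrix, fit_k_sequence
from .interpretation import CpGSet, row_variances, set_enrichment
from .io import (BetaMatrix, CovariateTable, filter_cpgs, load_annotation,
                 load_beta_matrix, load_covariates, read_cpg_list)
from .model_selection import FitParams, select_K

logger = logging.getLogger("methmix")

_FLOAT_FMT = "%.10g"

__all__ = ["RunManifest", "run_pipeline", "write_fit", "write_matrix"]


@dataclass
class RunManifest:
    command: str
    parameters: dict
    seed: int
    input_checksums: dict
    version: str = __version__
    timestamp: str = ""
    stages: list[str] = field(default_factory=list)

    def write(self, out_dir: Path) -> None:
        with open(Path(out_dir) / "manifest.json", "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_matrix(values: np.ndarray, index, columns, path, index_label: str) -> None:
    pd.DataFrame(values, index=index, columns=columns).to_csv(
        path, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)


def write_fit(fit: DeconvolutionFit, out_dir, seed: int | None = None) -> None:
    """Serialize a deconvolution fit: M and Omega tables plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_matrix(fit.M.values, fit.M.cpg_ids, fit.M.type_labels,
                 out_dir / "methylomes.tsv", "cpg_id")
    write_matrix(fit.Omega.values, fit.Omega.specimen_ids, fit.Omega.type_labels,
                 out_dir / "proportions.tsv", "specimen_id")
    meta = {"K": fit.M.K, "rss": fit.rss, "n_iter": fit.n_iter,
            "converged": fit.converged, "restart_index": fit.restart_index}
    if seed is not None:
        meta["seed"] = seed
    with open(out_dir / "fit.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_sets(paths) -> list[CpGSet]:
    sets = []
    for p in paths:
        p = Path(p)
        sets.append(CpGSet(p.stem, tuple(read_cpg_list(p))))
    return sets


def run_pipeline(config: dict | str, out_dir) -> Path:
    """Run select-K -> deconvolve at K* -> interpretation -> association.

    ``config`` is a dict or a path to a JSON file naming the input files
    and stage parameters (keys: beta, covariates, optional annotation,
    drop_chromosomes, categorical, covariate_list, cpg_sets, k_max,
    n_boot, n_permutations, n_iter, n_restarts, seed, delimiter).
    Identical config and seed produce identical output tables.
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        with open(config_path) as fh:
            config = json.load(fh)
    cfg = dict(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    delim = cfg.get("delimiter", "\t")

    checksums = {}
    for key in ("beta", "covariates", "annotation"):
        if cfg.get(key):
            checksums[key] = _sha256(cfg[key])
    manifest = RunManifest("pipeline", cfg, seed, checksums,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    t0 = time.time()
    beta = load_beta_matrix(cfg["beta"], delim)
    covariates = load_covariates(cfg["covariates"], delim,
                                 categorical=cfg.get("categorical"))
    missing = [s for s in beta.specimen_ids if s not in covariates.specimen_ids]
    if missing:
        raise ValueError(f"covariate table missing specimens: {missing}")
    covariates = CovariateTable(covariates.data.loc[beta.specimen_ids],
                                dict(covariates.categorical))
    annotation = load_annotation(cfg["annotation"], delim) if cfg.get("annotation") else None
    beta = filter_cpgs(beta, annotation,
                       drop_chromosomes=cfg.get("drop_chromosomes", ("Y", "chrY")),
                       max_missing_fraction=cfg.get("max_missing_fraction", 0.5))
    logger.info("loaded %d CpGs x %d specimens (%.1fs)", *beta.shape, time.time() - t0)
    manifest.stages.append("load_and_filter")

    # stage 1: number of cell types
    t0 = time.time()
    fp = FitParams(n_iter=int(cfg.get("n_iter", 25)),
                   n_restarts=int(cfg.get("n_restarts", 5)),
                   boot_iter=int(cfg.get("boot_iter", 10)))
    profile = select_K(beta, K_max=int(cfg.get("k_max", 10)),
                       n_boot=int(cfg.get("n_boot", 50)), seed=seed, fit_params=fp)
    draws = pd.DataFrame([
        {"K": K, "bootstrap": b, "deviance": dev}
        for K in profile.K_values for b, dev in enumerate(profile.deviance_draws[K])
    ])
    draws.to_csv(out_dir / "deviance_draws.tsv", sep="\t", index=False,
                 float_format=_FLOAT_FMT)
    profile.summary.to_csv(out_dir / "deviance_summary.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FMT)
    logger.info("selected K_hat=%d (%.1fs)", profile.K_hat, time.time() - t0)
    manifest.stages.append("select_k")

    # stage 2: deconvolution at K* = max(2, K_hat), reusing the nested chain
    t0 = time.time()
    K_star = max(2, profile.K_hat)
    fits = fit_k_sequence(beta, range(2, max(profile.K_values) + 1),
                          n_iter=fp.n_iter, n_restarts=fp.n_restarts, seed=seed)
    fit_star = fits[K_star]
    write_fit(fit_star, out_dir, seed=seed)
    logger.info("deconvolved at K*=%d, rss=%.4g (%.1fs)", K_star, fit_star.rss,
                time.time() - t0)
    manifest.stages.append("deconvolve")

    # stage 3: discriminating loci and CpG-set enrichment
    t0 = time.time()
    rv = row_variances(fit_star.M)
    pd.DataFrame({"cpg_id": rv.cpg_ids, "s2": rv.s2, "high": rv.high_flags}).to_csv(
        out_dir / "row_variances.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    set_paths = cfg.get("cpg_sets") or []
    if set_paths:
        rows = []
        for cs in _load_sets(set_paths):
            er = set_enrichment(rv, cs)
            rows.append({"set": er.set_name, "a": er.a, "b": er.b, "c": er.c,
                         "d": er.d, "odds_ratio": er.odds_ratio, "p": er.p_value,
                         "log10_p": np.log10(max(er.p_value, 1e-300))})
        pd.DataFrame(rows).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
    logger.info("interpretation stage done (%.1fs)", time.time() - t0)
    manifest.stages.append("interpretation")

    # stage 4: phenotype association and mediation
    t0 = time.time()
    cov_list = cfg.get("covariate_list") or list(covariates.data.columns)
    perm_rows = []
    for cov in cov_list:
        res = permutation_test(None, covariates, cov,
                               n_permutations=int(cfg.get("n_permutations", 1000)),
                               seed=seed, fits=fits)
        perm_rows.append({"covariate": cov, "statistic": res.observed_statistic,
                          "n_permutations": res.n_permutations, "p": res.p_value})
    pd.DataFrame(perm_rows).to_csv(out_dir / "permutation_tests.tsv", sep="\t",
                                   index=False, float_format=_FLOAT_FMT)
    beta_reg = beta
    if beta.missing_mask.any():
        # CpG-wise regression needs complete rows: impute row observed means
        filled = beta.values.copy()
        row_means = np.where(np.isnan(filled), 0.5, filled).mean(axis=1)
        rm = np.nanmean(np.where(np.isnan(filled), np.nan, filled), axis=1)
        row_means = np.where(np.isnan(rm), row_means, rm)
        mask = np.isnan(filled)
        filled[mask] = np.broadcast_to(row_means[:, None], filled.shape)[mask]
        beta_reg = BetaMatrix(filled, list(beta.cpg_ids), list(beta.specimen_ids))
    med = mediation_comparison(beta_reg, covariates, fit_star.Omega, covariates=cov_list)
    med_out = med.copy()
    med_out.loc[len(med_out)] = {"covariate": "(omega omnibus)",
                                 "pi0_unadjusted": np.nan,
                                 "pi0_adjusted": med.attrs["pi0_omega"]}
    med_out.to_csv(out_dir / "pi0_comparison.tsv", sep="\t", index=False,
                   float_format=_FLOAT_FMT)
    logger.info("association stage done (%.1fs)", time.time() - t0)
    manifest.stages.append("association")

    manifest.write(out_dir)
    return out_dir
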