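"""Accuracy/bias evaluation, cross-validation and the end-to-end pipeline.

Accuracy is the Pearson correlation between GEBV and a reference — the
pedigree-model EBV when truth is unavailable, the simulated TBV when it
is.  Bias is the slope of the regression of the reference on the GEBV
(unbiased predictions give b = 1).  The pipeline chains simulation,
growth-curve extrapolation, pedigree BLUP, the three Bayesian marker
models, genotype-probability peeling, the low-density scenarios and the
final report into one reproducible run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import genoprob, growthcurve, lowdensity, pedigree_blup, samplers, simdata
from .config import PipelineConfig

logger = logging.getLogger("gebvpipe")

ALL_STAGES = ("simulate", "fit-growth", "ebv", "train", "genoprob",
              "predict", "evaluate")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def accuracy(gebv, reference) -> float:
    """Pearson correlation between predicted and reference breeding values."""
    g = np.asarray(gebv, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(g) != len(r) or len(g) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(r))):
        raise ValueError("non-finite values in accuracy inputs")
    if g.std() == 0.0 or r.std() == 0.0:
        raise ValueError("zero variance in accuracy inputs")
    return float(np.corrcoef(g, r)[0, 1])


def bias_regression(reference, gebv) -> float:
    """Slope of reference on GEBV: cov(reference, gebv) / var(gebv)."""
    g = np.asarray(gebv, dtype=float)
    r = np.asarray(reference, dtype=float)
    if g.var() == 0.0:
        raise ValueError("zero variance in GEBV")
    return float(np.cov(r, g)[0, 1] / np.var(g, ddof=1))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(y: pd.Series, X: np.ndarray,
                   chain_config: samplers.ChainConfig, n_reps: int = 10,
                   train_frac: float = 0.9, seed: int = 0,
                   reference: pd.Series | None = None) -> pd.DataFrame:
    """Repeated random-split validation within the phenotyped set.

    Each replicate retrains the marker model on ``train_frac`` of the
    records and predicts the held-out rest; accuracy is the correlation
    of the held-out GEBV with the held-out phenotypes (and with
    ``reference`` — e.g. TBV — when supplied).
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must lie strictly between 0 and 1")
    n = len(y)
    n_train = int(round(train_frac * n))
    if n_train < 2 or n - n_train < 3:
        raise ValueError("split leaves too few records for training or testing")
    rng = np.random.default_rng(seed)
    rows = []
    yv = y.to_numpy(dtype=float)
    for rep in range(n_reps):
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        cfg = replace(chain_config, seed=int(
            np.random.SeedSequence([seed, rep]).generate_state(1)[0] % (2**31)))
        summ = samplers.run_chain(yv[tr], X[tr], cfg)
        gebv_te = X[te] @ summ.beta_mean
        row = {"rep": rep, "n_test": len(te),
               "accuracy_pheno": accuracy(gebv_te, yv[te])}
        if reference is not None:
            row["accuracy_ref"] = accuracy(
                gebv_te, reference.loc[y.index[te]].to_numpy())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _stage_seed(base: int, tag: str) -> int:
    h = int(hashlib.sha256(f"{base}:{tag}".encode()).hexdigest()[:8], 16)
    return h % (2**31)


def run_pipeline(config: PipelineConfig, outdir, stages=ALL_STAGES) -> dict:
    """Run the requested stages, reading any prerequisite artifacts from
    ``outdir`` and writing all outputs (and a JSON run log) back to it."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    artifacts: dict = {}
    log: dict = {"seed": config.seed, "config_hash": config.content_hash(),
                 "stages": list(stages), "inputs": {}}

    def need(fname: str) -> Path:
        p = out / fname
        if not p.exists():
            raise FileNotFoundError(
                f"stage prerequisite {fname!r} missing from {out}")
        log["inputs"][fname] = _file_hash(p)
        return p

    if "simulate" in stages:
        logger.info("simulating population (seed=%d)", config.seed)
        ped = simdata.simulate_pedigree(config.n_sires, config.n_dams,
                                        config.n_offspring,
                                        seed=_stage_seed(config.seed, "ped"))
        mmap = simdata.default_marker_map(config.n_markers, config.n_chrom,
                                          config.chrom_length)
        geno = simdata.simulate_genomes(ped, mmap, config.founder_freq,
                                        seed=_stage_seed(config.seed, "geno"))
        pheno, truth = simdata.simulate_phenotypes(
            ped, geno, n_qtl=config.n_qtl, h2=config.h2,
            growth_base=simdata.GompertzParams(config.growth_A, config.growth_b,
                                               config.growth_k),
            genetic_cv=config.genetic_cv, effect_shape=config.effect_shape,
            seed=_stage_seed(config.seed, "pheno"))
        simdata.write_pedigree(ped, out / "pedigree.tsv")
        simdata.write_map(mmap, out / "map.tsv")
        simdata.write_genotypes(geno, out / "genotypes.tsv")
        simdata.write_phenotypes(pheno, out / "phenotypes.csv")
        simdata.write_truth(truth, out / "tbv.csv", out / "qtl.csv")
        pd.DataFrame({
            "id": np.concatenate([truth.train_ids, truth.predict_ids]),
            "set": ["train"] * len(truth.train_ids)
                   + ["predict"] * len(truth.predict_ids),
        }).to_csv(out / "sets.csv", index=False)

    if set(stages) - {"simulate"}:
        ped = simdata.read_pedigree(need("pedigree.tsv"))
        mmap = simdata.read_map(need("map.tsv"))
        geno = simdata.read_genotypes(need("genotypes.tsv"))
        pheno = simdata.read_phenotypes(need("phenotypes.csv"))
        sets = pd.read_csv(need("sets.csv"))
        train_ids = sets.loc[sets["set"] == "train", "id"].to_numpy(np.int64)
        pred_ids = sets.loc[sets["set"] == "predict", "id"].to_numpy(np.int64)

    if "fit-growth" in stages:
        logger.info("fitting growth curves for %d individuals", len(pheno))
        fits = growthcurve.fit_growth_table(pheno, predict_at=config.predict_at)
        growthcurve.write_fits(fits, out / "fits.csv")

    def trait_values(trait: str) -> pd.Series:
        if trait in pheno.columns:
            return pd.Series(pheno[trait].to_numpy(),
                             index=pheno["id"].to_numpy(np.int64), name=trait)
        fits = growthcurve.read_fits(need("fits.csv"))
        if trait not in fits.columns:
            raise KeyError(f"trait {trait!r} not in phenotypes or fits")
        return pd.Series(fits[trait].to_numpy(),
                         index=fits["id"].to_numpy(np.int64), name=trait)

    if "ebv" in stages:
        for trait in config.traits:
            yv = trait_values(trait)
            res = pedigree_blup.solve_animal_model(yv, ped, h2=config.ebv_h2)
            pedigree_blup.write_ebv(res, out / f"ebv_{trait}.csv", trait=trait)
            logger.info("EBV solved for %s (mean=%.3f)", trait, res.mean)

    if "train" in stages:
        Xtrain = geno.subset_individuals(train_ids).codes
        for trait in config.traits:
            yv = trait_values(trait).loc[train_ids].to_numpy()
            for method in config.methods:
                cc = samplers.ChainConfig(
                    method=method, n_iter=config.n_iter,
                    burn_in=config.burn_in, thin=config.thin,
                    seed=_stage_seed(config.seed, f"chain:{method}:{trait}"))
                summ = samplers.run_chain(yv, Xtrain, cc)
                samplers.write_effects(summ, geno.markers,
                                       out / f"effects_{method}_{trait}.tsv")
                samplers.write_diagnostics(
                    summ, out / f"diagnostics_{method}_{trait}.json")
                logger.info("trained %s on %s (ESS sigma2_e=%.0f)",
                            method, trait, summ.ess["sigma2_e"])

    if "genoprob" in stages:
        # mask the prediction set entirely: probabilities for their
        # genotypes come from pedigree + genotyped ancestors/sibs only
        masked = simdata.GenotypeMatrix(geno.ids, geno.markers,
                                        geno.codes.copy())
        pred_rows = np.isin(masked.ids, pred_ids)
        masked.codes[pred_rows] = np.nan
        probs = genoprob.genotype_probability_table(ped, masked)
        np.save(out / "probs.npy", probs)  # run-time cache
        genoprob.write_probabilities(probs[pred_rows], pred_ids, geno.markers,
                                     out / "probabilities.tsv")
        logger.info("genotype probabilities peeled for %d markers", geno.m)

    if "predict" in stages:
        geno_pred = geno.subset_individuals(pred_ids)
        probs_path = out / "probs.npy"
        probs_all = np.load(probs_path) if probs_path.exists() else None
        if probs_all is not None:
            pred_rows = np.isin(geno.ids, pred_ids)
            probs_pred = probs_all[pred_rows]
        else:
            probs_pred = None
        results = []
        for trait in config.traits:
            for method in config.methods:
                eff = samplers.read_effects(
                    need(f"effects_{method}_{trait}.tsv"))
                beta = eff["beta_mean"].to_numpy()
                results.append(lowdensity.compute_gebv(
                    geno_pred.codes, beta, geno_pred.ids, scenario="ALL",
                    method=method, trait=trait))
                for spec in lowdensity.scenario_catalogue():
                    if spec.use_genotype_probabilities and probs_pred is None:
                        continue
                    results.append(lowdensity.scenario_gebv(
                        spec, geno_pred, beta, mmap, probs=probs_pred,
                        method=method, trait=trait))
        lowdensity.write_gebv(results, out / "gebv.csv")
        logger.info("GEBV computed for %d scenario combinations", len(results))

    if "evaluate" in stages:
        gebv = lowdensity.read_gebv(need("gebv.csv"))
        truth = simdata.read_truth(need("tbv.csv"), need("qtl.csv"))
        rows = []
        for (method, trait), sub in gebv.groupby(["method", "trait"]):
            ebv = pedigree_blup.read_ebv(need(f"ebv_{trait}.csv"))
            full = sub[sub["scenario"] == "ALL"].set_index("id")["gebv"]
            ids = full.index.to_numpy()
            ref_ebv = ebv.loc[ids].to_numpy()
            ref_tbv = truth.tbv.loc[ids].to_numpy()
            base_ebv = accuracy(full, ref_ebv)
            base_tbv = accuracy(full, ref_tbv)
            for scen, ss in sub.groupby("scenario"):
                g = ss.set_index("id")["gebv"].loc[ids]
                acc_e = accuracy(g, ref_ebv)
                acc_t = accuracy(g, ref_tbv)
                rows += [
                    dict(method=method, trait=trait, scenario=scen,
                         metric="corr_ebv", value=acc_e),
                    dict(method=method, trait=trait, scenario=scen,
                         metric="corr_tbv", value=acc_t),
                    dict(method=method, trait=trait, scenario=scen,
                         metric="bias_b", value=bias_regression(ref_ebv, g)),
                    dict(method=method, trait=trait, scenario=scen,
                         metric="delta_ebv", value=acc_e - base_ebv),
                    dict(method=method, trait=trait, scenario=scen,
                         metric="delta_tbv", value=acc_t - base_tbv),
                    dict(method=method, trait=trait, scenario=scen,
                         metric="n", value=float(len(ids))),
                ]
        report = pd.DataFrame(rows)
        report.to_csv(out / "report.csv", index=False)
        summary = {
            f"{r.method}|{r.trait}|{r.scenario}|{r.metric}": r.value
            for r in report.itertuples()
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2))
        artifacts["report"] = report
        logger.info("report written with %d rows", len(report))

    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return artifacts
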