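"""End-to-end orchestration: simulate -> QC -> kinship -> REML ->
BayesC-pi GWAS -> cross-validated prediction.

A single global seed deterministically derives per-stage seeds (counter
based), so re-running any stage of a run reproduces it bit-for-bit.  Every
stage writes its outputs once into the run directory and appends a manifest
entry (parameters, seeds, output digests).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .bayescpi import BayesCPi, ChainConfig
from .data import GenotypeMatrix
from .exceptions import ConfigError, DataError
from .gwas import permutation_threshold, report_significant
from .kinship import a_matrix, grm_vanraden1
from .prediction import cross_validate, make_folds
from .qc import QCThresholds, run_qc
from .syndata import SimConfig, simulate_cohort
from .varcomp import MixedREML

log = logging.getLogger("bovigen")

STAGES = ("simulate", "qc", "kinship", "varcomp", "gwas", "predict")


@dataclass
class RunConfig:
    """Whole-pipeline configuration.

    ``scale="paper"`` uses the production chain/permutation sizes (45 000
    iterations, 1000 permutations); ``scale="desk"`` caps them at
    workstation size (chain <= 5000, n_perm <= 100).
    """

    outdir: str = "bovigen_run"
    seed: int = 0
    scale: str = "desk"
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    chain: dict = field(default_factory=dict)
    n_perm: int = 100
    alpha: float = 0.05
    cv_folds: int = 10
    cv_methods: tuple = ("pblup", "gblup", "bayescpi")
    marbling: bool = False

    def validate(self) -> None:
        if self.scale not in ("paper", "desk"):
            raise ConfigError("scale must be 'paper' or 'desk'")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.scale == "desk":
            if self.n_perm > 100:
                raise ConfigError("desk scale caps n_perm at 100")
            if self.chain.get("n_iter", 5000) > 5000:
                raise ConfigError("desk scale caps chain length at 5000")

    def chain_config(self, seed: int) -> ChainConfig:
        defaults = (dict(n_iter=45_000, burn_in=5_000) if self.scale == "paper"
                    else dict(n_iter=3_000, burn_in=600))
        defaults.update(self.chain)
        return ChainConfig(seed=seed, thin=1, **defaults)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "scale": config.scale, "stages": {}}
    manifest_path = outdir / "manifest.json"

    state: dict = {}

    def finish(stage: str, params: dict, outputs: dict, t0: float) -> None:
        entry = {
            "params": params,
            "outputs": {k: {"path": str(p), "sha256": _digest(Path(p))}
                        for k, p in outputs.items()},
            "wall_s": round(time.time() - t0, 3),
        }
        manifest["stages"][stage] = entry
        manifest_path.write_text(json.dumps(manifest, indent=1))
        log.info("stage=%s outputs=%s wall=%.2fs", stage,
                 list(outputs), entry["wall_s"])

    try:
        if "simulate" in config.stages:
            t0 = time.time()
            sim = SimConfig(**{"seed": _stage_seed(config.seed, "simulate"),
                               **config.sim})
            geno, ped, traits, truth = simulate_cohort(sim)
            bio.write_ped_map(geno, ped, outdir / "cohort")
            bio.write_trait_csv(traits, outdir / "traits.csv")
            bio.write_truth_json(truth, sim, outdir / "truth.json")
            state.update(genotypes=geno, pedigree=ped, traits=traits)
            finish("simulate", sim.to_dict(),
                   {"ped": outdir / "cohort.ped", "map": outdir / "cohort.map",
                    "traits": outdir / "traits.csv",
                    "truth": outdir / "truth.json"}, t0)
        else:
            geno, ped = bio.read_ped_map(outdir / "cohort")
            traits = bio.read_trait_csv(outdir / "traits.csv")
            state.update(genotypes=geno, pedigree=ped, traits=traits)

        if "qc" in config.stages:
            t0 = time.time()
            thr = QCThresholds(**config.qc)
            clean, report = run_qc(state["genotypes"], thr,
                                   seed=_stage_seed(config.seed, "qc"))
            state["genotypes"] = clean
            (outdir / "qc_report.json").write_text(
                json.dumps(report.to_dict(), indent=1))
            finish("qc", asdict(thr), {"report": outdir / "qc_report.json"}, t0)
        elif state["genotypes"].has_missing and any(
                s in config.stages
                for s in ("kinship", "varcomp", "gwas", "predict")):
            raise DataError(
                "genotypes contain missing calls; enable the qc stage or "
                "provide imputed input"
            )

        geno: GenotypeMatrix = state["genotypes"]
        traits: pd.DataFrame = state["traits"]

        if "kinship" in config.stages:
            t0 = time.time()
            grm = grm_vanraden1(geno)
            amat = a_matrix(state["pedigree"])
            bio.write_matrix_tsv(grm, outdir / "grm.tsv")
            bio.write_matrix_tsv(amat, outdir / "amat.tsv")
            state.update(grm=grm, amat=amat)
            finish("kinship", {}, {"grm": outdir / "grm.tsv",
                                   "amat": outdir / "amat.tsv"}, t0)

        if "varcomp" in config.stages:
            t0 = time.time()
            model = MixedREML.from_trait_table(traits, state["grm"],
                                               marbling=config.marbling)
            reml = model.fit()
            y_star = reml.adjust()
            state.update(reml=reml, y_star=y_star)
            (outdir / "varcomp.json").write_text(
                json.dumps(reml.to_dict(), indent=1))
            y_star.rename_axis("animal_id").reset_index().to_csv(
                outdir / "y_star.csv", index=False)
            finish("varcomp", {"marbling": config.marbling},
                   {"varcomp": outdir / "varcomp.json",
                    "y_star": outdir / "y_star.csv"}, t0)

        if "gwas" in config.stages:
            t0 = time.time()
            reml = state["reml"]
            y = state["y_star"].to_numpy()
            cc = config.chain_config(_stage_seed(config.seed, "gwas"))
            model = BayesCPi(y, geno, sigma2_u_hat=reml.sigma2_a,
                             sigma2_0_hat=reml.sigma2_e)
            post = model.fit(cc)
            perm = permutation_threshold(
                y, geno, alpha=config.alpha, n_perm=config.n_perm,
                chain=cc, seed=_stage_seed(config.seed, "gwas-perm"),
                sigma2_u_hat=reml.sigma2_a, sigma2_0_hat=reml.sigma2_e)
            hits = report_significant(post, perm.threshold,
                                      sigma2_u_hat=reml.sigma2_a,
                                      allele_freqs=geno.allele_freqs())
            post.to_frame().to_csv(outdir / "posterior.tsv", sep="\t",
                                   index=False)
            hits.to_csv(outdir / "significant_snps.tsv", sep="\t", index=False)
            from .plotting import manhattan_ppi

            manhattan_ppi(post.to_frame(), threshold=perm.threshold,
                          out=outdir / "manhattan.png")
            state.update(posterior=post, perm=perm)
            finish("gwas", {"alpha": config.alpha, "n_perm": config.n_perm,
                            "threshold": perm.threshold},
                   {"posterior": outdir / "posterior.tsv",
                    "significant": outdir / "significant_snps.tsv"}, t0)

        if "predict" in config.stages:
            t0 = time.time()
            reml = state["reml"]
            traits_idx = traits.set_index("animal_id")
            breeds = traits_idx.loc[state["pedigree"]["animal_id"], "breed"]
            folds = make_folds(state["pedigree"], breeds.to_numpy(),
                               k=config.cv_folds,
                               seed=_stage_seed(config.seed, "folds"))
            report = cross_validate(
                state["y_star"].to_numpy(), folds, h2=reml.h2,
                sigma2_a=reml.sigma2_a, sigma2_e=reml.sigma2_e,
                grm=state.get("grm"), a_mat=state.get("amat"),
                genotypes=geno, methods=tuple(config.cv_methods),
                chain=config.chain_config(0),
                seed=_stage_seed(config.seed, "cv"))
            report.per_fold.to_csv(outdir / "cv_per_fold.tsv", sep="\t",
                                   index=False)
            report.aggregate().to_csv(outdir / "cv_aggregate.tsv", sep="\t",
                                      index=False)
            finish("predict", {"k": config.cv_folds,
                               "methods": list(config.cv_methods)},
                   {"per_fold": outdir / "cv_per_fold.tsv",
                    "aggregate": outdir / "cv_aggregate.tsv"}, t0)
    except Exception:
        manifest["failed"] = True
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise
    return manifest
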