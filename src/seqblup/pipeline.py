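"""End-to-end orchestration: QC -> panels -> Yc -> GRMs -> REML -> CV.

Configured through :class:`PipelineConfig` (usually parsed from YAML).
All randomness flows from one root seed; every artifact directory gets
the resolved config, its hash, and a per-stage log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as sio
from .errors import ConfigurationError
from .grm import compute_grm
from .panels import INDEL, SNP, qc_filter, thin_variants
from .pheno import adjust_phenotypes
from .predict import cross_validate
from .simdata import SimConfig, TraitConfig, simulate_genotypes, simulate_phenotypes
from .varcomp import h2_profile

logger = logging.getLogger("seqblup")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved pipeline settings.

    Either ``genotypes``/``phenotypes`` point at input files, or
    ``simulate`` holds simulator settings (n_individuals, n_snp, ...,
    trait options) for a self-contained run.
    """

    out_dir: str = "results"
    genotypes: str | None = None  # dosage file (or VCF)
    phenotypes: str | None = None
    simulate: dict | None = None
    traits: list = field(default_factory=lambda: ["trait"])
    panel_sizes: list = field(default_factory=lambda: [1000, 5000])
    models: list = field(default_factory=lambda: ["gblup"])
    adjust_method: str = "animal_model"
    min_call_rate: float = 0.9
    min_maf: float = 0.01
    cv_k: int = 5
    cv_reps: int = 5
    seed: int = 1

    def __post_init__(self):
        if self.cv_k < 2:
            raise ConfigurationError("cv_k must be >= 2")
        if any(s <= 0 for s in self.panel_sizes):
            raise ConfigurationError("panel sizes must be positive")
        for m in self.models:
            if m not in ("gblup", "multiblup"):
                raise ConfigurationError(f"unknown model {m!r}")
        if self.simulate is None and (self.genotypes is None or self.phenotypes is None):
            raise ConfigurationError(
                "either input paths or a 'simulate' block is required"
            )
        if self.genotypes is not None and not Path(self.genotypes).exists():
            raise ConfigurationError(f"genotype file not found: {self.genotypes}")
        if self.phenotypes is not None and not Path(self.phenotypes).exists():
            raise ConfigurationError(f"phenotype file not found: {self.phenotypes}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        trait_opts = sim.pop("trait", {})
        sc = SimConfig(seed=cfg.seed, **sim)
        gm, _ = simulate_genotypes(sc)
        tc = TraitConfig(seed=cfg.seed + 1, **trait_opts)
        pt, truth = simulate_phenotypes(gm, gm.variants, tc)
        return gm, pt, truth
    if str(cfg.genotypes).endswith(".vcf"):
        gm = sio.read_vcf(cfg.genotypes)
    else:
        gm = sio.read_dosage(cfg.genotypes)
    pt = sio.read_phenotypes(cfg.phenotypes, traits=cfg.traits)
    return gm, pt, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns a map of artifact paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(
            {**asdict(cfg), "config_hash": cfg.config_hash()}, fh, sort_keys=True
        )
    stage = "load"
    artifacts = {"config": str(out / "resolved_config.yaml")}
    try:
        gm, pt, truth = _load_or_simulate(cfg)
        logger.info("loaded %d samples x %d variants", gm.n_samples, gm.n_variants)

        stage = "qc"
        gm, report = qc_filter(
            gm, cfg.min_call_rate, cfg.min_maf, return_report=True
        )
        logger.info(
            "qc: %d -> %d variants (call rate removed %d, maf removed %d)",
            report.n_input,
            report.n_retained,
            report.n_removed_call_rate,
            report.n_removed_maf,
        )

        stage = "panels"
        panels = {}
        for size in sorted(cfg.panel_sizes):
            if size > gm.n_variants:
                logger.warning("panel %d exceeds %d variants; skipped", size, gm.n_variants)
                continue
            panels[f"{size}"] = thin_variants(gm, "exact", size, seed=cfg.seed)
        panels["full"] = gm.variants

        stage = "grm"
        grms = {label: compute_grm(gm.subset_by_panel(p)) for label, p in panels.items()}
        full_grm = grms["full"]

        stage = "pheno"
        yc_by_trait = {}
        for trait in pt.traits:
            yc = adjust_phenotypes(pt, trait, method=cfg.adjust_method, grm=full_grm)
            yc_by_trait[trait] = yc
            pt.data[f"{trait}_Yc"] = yc
        sio.write_phenotypes(pt, out / "phenotypes_corrected.tsv")
        artifacts["phenotypes"] = str(out / "phenotypes_corrected.tsv")

        stage = "reml"
        h2_rows = []
        for trait, yc in yc_by_trait.items():
            tab = h2_profile(yc, grms)
            tab.insert(0, "trait", trait)
            h2_rows.append(tab)
        import pandas as pd

        h2_table = pd.concat(h2_rows, ignore_index=True)
        h2_table.to_csv(out / "heritability.tsv", sep="\t", index=False)
        artifacts["heritability"] = str(out / "heritability.tsv")

        stage = "cv"
        cv_rows, round_rows = [], []
        for trait, yc in yc_by_trait.items():
            for label, grm in grms.items():
                for model in cfg.models:
                    if model == "multiblup":
                        sub = gm.subset_by_panel(panels[label])
                        f_idx = np.flatnonzero(sub.variants.vtype == INDEL)
                        r_idx = np.flatnonzero(sub.variants.vtype == SNP)
                        if f_idx.size == 0 or r_idx.size == 0:
                            continue
                        cv_grms = [
                            compute_grm(sub.subset_variants(f_idx)),
                            compute_grm(sub.subset_variants(r_idx)),
                        ]
                    else:
                        cv_grms = [grm]
                    res = cross_validate(
                        yc, cv_grms, model=model, k=cfg.cv_k,
                        reps=cfg.cv_reps, seed=cfg.seed,
                    )
                    cv_rows.append(
                        {
                            "trait": trait,
                            "model": model,
                            "panel": label,
                            **res.summary,
                        }
                    )
                    rec = res.records.copy()
                    rec.insert(0, "panel", label)
                    rec.insert(0, "model", model)
                    rec.insert(0, "trait", trait)
                    round_rows.append(rec)
        pd.DataFrame(cv_rows).to_csv(out / "cv_summary.tsv", sep="\t", index=False)
        pd.concat(round_rows, ignore_index=True).to_csv(
            out / "cv_rounds.tsv", sep="\t", index=False
        )
        artifacts["cv_summary"] = str(out / "cv_summary.tsv")
        artifacts["cv_rounds"] = str(out / "cv_rounds.tsv")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}; partial outputs in {out}"
        ) from exc
    return artifacts
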