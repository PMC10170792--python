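"""Synthetic genotype/phenotype generator with controllable structure.

Generates biallelic SNP and INDEL dosages for an admixed population of
several subpopulations (Balding-Nichols allele-frequency divergence),
block-wise LD from a latent-Gaussian threshold model, additive polygenic
phenotypes with categorical fixed effects, and corrupted genotype copies
for imputation-accuracy evaluation.  Everything is deterministic given
the configured seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError, DataError
from .panels import INDEL, SNP, GenotypeMatrix, VariantPanel
from .pheno import PhenotypeTable

__all__ = [
    "SimConfig",
    "TraitConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "corrupt_genotypes",
    "hold_out_samples",
    "default_fixed_effects",
]

_POS_SPACING = 1000  # bp between adjacent simulated variants


@dataclass
class SimConfig:
    """Parameters of the genotype simulator."""

    n_individuals: int
    n_snp: int
    n_indel: int = 0
    n_subpop: int = 3
    fst: float = 0.02
    block_size: int = 20
    within_block_corr: float = 0.7
    maf_range: tuple = (0.01, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0 or self.n_snp < 0 or self.n_indel < 0:
            raise ConfigurationError("counts must be positive")
        if self.n_snp + self.n_indel <= 0:
            raise ConfigurationError("need at least one variant")
        if self.n_subpop <= 0:
            raise ConfigurationError("n_subpop must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigurationError("fst must lie in [0, 1)")
        if self.block_size <= 0:
            raise ConfigurationError("block_size must be positive")
        if self.block_size > self.n_snp + self.n_indel:
            raise ConfigurationError(
                f"block_size {self.block_size} exceeds variant count "
                f"{self.n_snp + self.n_indel}"
            )
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ConfigurationError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < min <= max <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")


def default_fixed_effects(seed: int = 0) -> dict:
    """Factor -> per-level effect values matching the default design
    (farm: 4 levels, sex: 2, slaughter batch: 13)."""
    rng = np.random.default_rng(seed)
    return {
        "farm": list(np.round(rng.normal(0.0, 1.0, 4), 3)),
        "sex": list(np.round(rng.normal(0.0, 0.5, 2), 3)),
        "batch": list(np.round(rng.normal(0.0, 0.8, 13), 3)),
    }


@dataclass
class TraitConfig:
    """Parameters of the additive-phenotype simulator."""

    h2_snp: float = 0.3
    h2_indel: float = 0.0
    n_causal_snp: int = 100
    n_causal_indel: int = 0
    fixed_effects: dict = field(default_factory=default_fixed_effects)
    residual_var: float = 1.0
    intercept: float = 0.0
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self):
        if self.h2_snp < 0 or self.h2_indel < 0:
            raise ConfigurationError("heritabilities must be non-negative")
        if self.h2_snp + self.h2_indel >= 1.0:
            raise ConfigurationError("h2_snp + h2_indel must be < 1")
        if self.residual_var <= 0:
            raise ConfigurationError("residual_var must be positive")


@dataclass
class SimTruth:
    """Ground truth carried alongside a simulated phenotype."""

    true_breeding_values: pd.DataFrame  # columns: bv_snp, bv_indel, bv_total
    causal_effects: pd.DataFrame  # columns: variant_id, vtype, effect
    true_h2: dict  # component -> realized variance fraction
    fixed_effect_values: dict  # factor -> level effects


def _balding_nichols(p_anc: np.ndarray, fst: float, n_subpop: int, rng) -> np.ndarray:
    """Per-subpopulation allele frequencies, shape (n_subpop, m)."""
    if fst == 0.0:
        return np.tile(p_anc, (n_subpop, 1))
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    freqs = rng.beta(a, b, size=(n_subpop, p_anc.size))
    return np.clip(freqs, 1e-6, 1.0 - 1e-6)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, VariantPanel]:
    """Draw a structured dosage matrix and its variant panel.

    Haplotypes come from a latent-Gaussian threshold model: within each
    block of ``cfg.block_size`` consecutive variants the latent values
    share a compound-symmetric correlation ``cfg.within_block_corr``;
    blocks are independent.  Subpopulation allele frequencies are
    Balding-Nichols draws around a shared ancestral frequency.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snp + cfg.n_indel
    n = cfg.n_individuals

    lo, hi = cfg.maf_range
    p_anc = rng.uniform(lo, hi, m)
    freqs = _balding_nichols(p_anc, cfg.fst, cfg.n_subpop, rng)

    # near-equal split of individuals over subpopulations
    sizes = np.full(cfg.n_subpop, n // cfg.n_subpop)
    sizes[: n % cfg.n_subpop] += 1
    subpop = np.repeat(np.arange(cfg.n_subpop), sizes)

    thresholds = norm.ppf(freqs)  # (n_subpop, m); latent < t -> allele 1
    rho = cfg.within_block_corr
    n_blocks = int(np.ceil(m / cfg.block_size))
    dosage = np.zeros((n, m))
    for _hap in range(2):
        shared = np.repeat(
            rng.standard_normal((n, n_blocks)), cfg.block_size, axis=1
        )[:, :m]
        latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal((n, m))
        dosage += (latent < thresholds[subpop, :]).astype(float)

    if cfg.missing_rate > 0:
        mask = rng.random((n, m)) < cfg.missing_rate
        dosage[mask] = np.nan

    is_indel = np.zeros(m, dtype=bool)
    if cfg.n_indel:
        is_indel[rng.choice(m, size=cfg.n_indel, replace=False)] = True
    pos = (np.arange(m) + 1) * _POS_SPACING
    table = pd.DataFrame(
        {
            "variant_id": [
                f"1:{p}:{'A' if not ind else 'A'}:{'G' if not ind else 'AT'}"
                for p, ind in zip(pos, is_indel)
            ],
            "chrom": "1",
            "pos": pos,
            "vtype": np.where(is_indel, INDEL, SNP),
            "ref": "A",
            "alt": np.where(is_indel, "AT", "G"),
        }
    )
    panel = VariantPanel(table)
    info = pd.DataFrame({"subpop": [f"S{k + 1}" for k in subpop]})
    gm = GenotypeMatrix(
        [f"ind{i:05d}" for i in range(n)], panel, dosage, sample_info=info
    ).with_stats()
    return gm, gm.variants


def _component_bv(
    gm: GenotypeMatrix, vtype: str, n_causal: int, target_var: float, rng
) -> tuple[np.ndarray, pd.DataFrame]:
    """Additive component: causal draw, exact in-sample variance rescale."""
    cand = np.flatnonzero(gm.variants.vtype == vtype)
    if n_causal > cand.size:
        raise ConfigurationError(
            f"{n_causal} causal {vtype}s requested but only {cand.size} available"
        )
    n = gm.n_samples
    empty = pd.DataFrame(columns=["variant_id", "vtype", "effect"])
    if n_causal == 0 or target_var == 0.0:
        return np.zeros(n), empty
    causal = np.sort(rng.choice(cand, size=n_causal, replace=False))
    X = gm.dosage[:, causal].copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= col_mean
    beta = rng.standard_normal(n_causal)
    bv = X @ beta
    sd = bv.std()
    if sd == 0:
        raise DataError("causal genotypes are monomorphic; cannot scale effects")
    scale = np.sqrt(target_var) / sd
    bv *= scale
    effects = pd.DataFrame(
        {
            "variant_id": gm.variants.variant_ids[causal],
            "vtype": vtype,
            "effect": beta * scale,
        }
    )
    return bv - bv.mean(), effects


def simulate_phenotypes(
    gm: GenotypeMatrix, panel: VariantPanel, tc: TraitConfig
) -> tuple[PhenotypeTable, SimTruth]:
    """Additive phenotype: intercept + fixed effects + BVs + residual.

    Per-component breeding values are rescaled so their in-sample
    variance exactly equals the component's share of the phenotypic
    variance implied by ``residual_var`` and the target heritabilities.
    """
    rng = np.random.default_rng(tc.seed)
    sub = gm.subset_by_panel(panel) if panel is not gm.variants else gm
    n = sub.n_samples
    h2_tot = tc.h2_snp + tc.h2_indel
    sigma_p2 = tc.residual_var / (1.0 - h2_tot)

    bv_snp, eff_snp = _component_bv(
        sub, SNP, tc.n_causal_snp, tc.h2_snp * sigma_p2, rng
    )
    bv_indel, eff_indel = _component_bv(
        sub, INDEL, tc.n_causal_indel, tc.h2_indel * sigma_p2, rng
    )

    fixed_part = np.zeros(n)
    factors = {}
    for factor, effects in tc.fixed_effects.items():
        levels = rng.integers(0, len(effects), size=n)
        factors[factor] = levels
        fixed_part += np.asarray(effects)[levels]

    resid = rng.normal(0.0, np.sqrt(tc.residual_var), n)
    y = tc.intercept + fixed_part + bv_snp + bv_indel + resid

    data = {"sample_id": sub.sample_ids, tc.trait_name: y}
    for factor, levels in factors.items():
        data[factor] = [f"{factor}{v + 1}" for v in levels]
    pt = PhenotypeTable(
        pd.DataFrame(data), traits=[tc.trait_name], factors=list(factors)
    )

    genetic_part = y - fixed_part - tc.intercept
    var_g = genetic_part.var()
    truth = SimTruth(
        true_breeding_values=pd.DataFrame(
            {
                "sample_id": sub.sample_ids,
                "bv_snp": bv_snp,
                "bv_indel": bv_indel,
                "bv_total": bv_snp + bv_indel,
            }
        ),
        causal_effects=pd.concat(
            [e for e in (eff_snp, eff_indel) if len(e)], ignore_index=True
        )
        if len(eff_snp) + len(eff_indel)
        else eff_snp,
        true_h2={
            "snp": float(bv_snp.var() / var_g) if var_g > 0 else 0.0,
            "indel": float(bv_indel.var() / var_g) if var_g > 0 else 0.0,
            "target_snp": tc.h2_snp,
            "target_indel": tc.h2_indel,
        },
        fixed_effect_values=dict(tc.fixed_effects),
    )
    return pt, truth


def corrupt_genotypes(
    gm: GenotypeMatrix,
    error_rate: float,
    mode: Literal["uniform", "maf_weighted"] = "uniform",
    seed: int = 0,
) -> GenotypeMatrix:
    """Replace a fraction of calls with Hardy-Weinberg draws.

    ``uniform`` corrupts every variant at ``error_rate``; ``maf_weighted``
    concentrates errors on high-MAF variants (per-variant rate
    proportional to MAF, scaled so the mean rate stays ``error_rate``).
    The replacement genotype is drawn from the variant's own HWE
    distribution, independent of the true call.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ConfigurationError("error_rate must lie in [0, 1]")
    if mode not in ("uniform", "maf_weighted"):
        raise ConfigurationError(f"unknown corruption mode {mode!r}")
    out = gm.dosage.copy()
    if error_rate == 0.0:
        return GenotypeMatrix(
            list(gm.sample_ids), gm.variants.copy(), out, gm.sample_info
        )
    rng = np.random.default_rng(seed)
    p = gm.alt_freq()
    maf = np.minimum(p, 1.0 - p)
    if mode == "uniform":
        rates = np.full(gm.n_variants, error_rate)
    else:
        mean_maf = maf[~np.isnan(maf)].mean()
        rates = np.clip(error_rate * np.nan_to_num(maf) / max(mean_maf, 1e-12), 0, 1)
    hit = rng.random(out.shape) < rates[None, :]
    hit &= ~np.isnan(out)
    # HWE genotype draw per variant: P(0)=(1-p)^2, P(1)=2p(1-p), P(2)=p^2
    u = rng.random(out.shape)
    p2 = np.nan_to_num(p)[None, :]
    draw = (u < p2**2) * 2.0 + ((u >= p2**2) & (u < p2**2 + 2 * p2 * (1 - p2))) * 1.0
    out[hit] = draw[hit]
    return GenotypeMatrix(list(gm.sample_ids), gm.variants.copy(), out, gm.sample_info)


def hold_out_samples(
    gm: GenotypeMatrix, fraction: float = 0.2, seed: int = 0
) -> tuple[list, list]:
    """Random disjoint/exhaustive split; returns (held, kept) id lists."""
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must lie in (0, 1)")
    n = gm.n_samples
    if n < 2:
        raise DataError("need at least 2 samples to hold any out")
    n_held = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    held_idx = np.sort(rng.choice(n, size=n_held, replace=False))
    held_set = set(held_idx.tolist())
    held = [gm.sample_ids[i] for i in held_idx]
    kept = [s for i, s in enumerate(gm.sample_ids) if i not in held_set]
    return held, kept
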