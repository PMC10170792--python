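"""Imputation-accuracy metrics: concordance rate and dosage r^2.

Metrics are computed per variant on hard genotype calls {0,1,2},
averaged per MAF bin (0.01 wide by default) and genome-wide.  The
genome-wide summary is the unweighted mean of per-variant values; a
call-weighted alternative for the concordance rate is available behind
a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .panels import GenotypeMatrix

__all__ = [
    "ImputationAccuracy",
    "concordance",
    "dosage_r2",
    "bin_by_maf",
    "evaluate_imputation",
    "plot_accuracy",
]


@dataclass
class ImputationAccuracy:
    per_variant: pd.DataFrame  # variant_id, maf, concordance, r2, n_compared
    bins: pd.DataFrame
    overall_concordance: float
    overall_r2: float
    overall_concordance_weighted: float | None = None


def _align(observed: GenotypeMatrix, imputed: GenotypeMatrix):
    """Align the two matrices on shared sample and variant ids."""
    shared_samples = [s for s in observed.sample_ids if s in set(imputed.sample_ids)]
    obs_v = observed.variants.variant_ids
    imp_v = set(imputed.variants.variant_ids)
    shared_variants = [v for v in obs_v if v in imp_v]
    if not shared_samples or not shared_variants:
        raise DataError("no overlapping samples/variants between matrices")
    obs = observed.subset_samples(shared_samples)
    imp = imputed.subset_samples(shared_samples)
    vidx_obs = {v: i for i, v in enumerate(obs.variants.variant_ids)}
    vidx_imp = {v: i for i, v in enumerate(imp.variants.variant_ids)}
    oi = np.array([vidx_obs[v] for v in shared_variants])
    ii = np.array([vidx_imp[v] for v in shared_variants])
    return obs.subset_variants(oi), imp.subset_variants(ii)


def concordance(
    observed: GenotypeMatrix, imputed: GenotypeMatrix
) -> tuple[pd.DataFrame, float]:
    """Per-variant and overall concordance rate.

    A call pair counts when both the observed and the imputed genotype
    are non-missing; per-variant CR is the fraction of exactly equal
    calls, overall CR the unweighted mean over defined variants.
    """
    obs, imp = _align(observed, imputed)
    both = ~np.isnan(obs.dosage) & ~np.isnan(imp.dosage)
    n_cmp = both.sum(axis=0)
    eq = (obs.dosage == imp.dosage) & both
    with np.errstate(invalid="ignore"):
        cr = np.where(n_cmp > 0, eq.sum(axis=0) / np.maximum(n_cmp, 1), np.nan)
    table = pd.DataFrame(
        {
            "variant_id": obs.variants.variant_ids,
            "maf": obs.maf(),
            "concordance": cr,
            "n_compared": n_cmp,
        }
    )
    overall = float(np.nanmean(cr)) if np.isfinite(cr).any() else np.nan
    return table, overall


def dosage_r2(
    observed: GenotypeMatrix, imputed: GenotypeMatrix
) -> tuple[pd.DataFrame, float]:
    """Per-variant and overall squared Pearson correlation of dosages.

    Needs at least 3 comparable pairs and non-zero variance on both
    sides; variants failing that are reported as NaN and excluded from
    the overall mean.
    """
    obs, imp = _align(observed, imputed)
    m = obs.n_variants
    r2 = np.full(m, np.nan)
    both = ~np.isnan(obs.dosage) & ~np.isnan(imp.dosage)
    for j in range(m):
        ok = both[:, j]
        if ok.sum() < 3:
            continue
        x, y = obs.dosage[ok, j], imp.dosage[ok, j]
        if x.std() == 0 or y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2[j] = r * r
    table = pd.DataFrame(
        {
            "variant_id": obs.variants.variant_ids,
            "maf": obs.maf(),
            "r2": r2,
            "n_compared": both.sum(axis=0),
        }
    )
    overall = float(np.nanmean(r2)) if np.isfinite(r2).any() else np.nan
    return table, overall


def bin_by_maf(per_variant: pd.DataFrame, bin_width: float = 0.01) -> pd.DataFrame:
    """Mean per-variant statistics in half-open MAF bins over [0, 0.5].

    Bins are [k*w, (k+1)*w), the last one closed at 0.5; empty bins are
    present with count 0.
    """
    if not 0 < bin_width <= 0.5:
        raise ConfigurationError("bin_width must lie in (0, 0.5]")
    n_bins = int(np.ceil(0.5 / bin_width - 1e-9))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 0.5)
    maf = per_variant["maf"].to_numpy(float)
    idx = np.clip(np.floor(maf / bin_width).astype(int), 0, n_bins - 1)
    stat_cols = [c for c in ("concordance", "r2") if c in per_variant.columns]
    rows = []
    for b in range(n_bins):
        sel = (idx == b) & np.isfinite(maf)
        row = {
            "maf_bin_low": edges[b],
            "maf_bin_high": edges[b + 1],
            "n_variants": int(sel.sum()),
        }
        for c in stat_cols:
            vals = per_variant.loc[sel, c].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            row[f"mean_{c}"] = float(vals.mean()) if vals.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_imputation(
    observed: GenotypeMatrix,
    imputed: GenotypeMatrix,
    bin_width: float = 0.01,
) -> ImputationAccuracy:
    """Full evaluation: per-variant CR and r^2, MAF bins, overall means."""
    cr_table, overall_cr = concordance(observed, imputed)
    r2_table, overall_r2 = dosage_r2(observed, imputed)
    per_variant = cr_table.merge(
        r2_table[["variant_id", "r2"]], on="variant_id", how="left"
    )
    # call-weighted alternative: total correct / total compared
    eq_total = (per_variant["concordance"] * per_variant["n_compared"]).sum()
    n_total = per_variant["n_compared"].sum()
    weighted = float(eq_total / n_total) if n_total else np.nan
    return ImputationAccuracy(
        per_variant=per_variant,
        bins=bin_by_maf(per_variant, bin_width),
        overall_concordance=overall_cr,
        overall_r2=overall_r2,
        overall_concordance_weighted=weighted,
    )


def plot_accuracy(result: ImputationAccuracy, path: str) -> None:
    """Two-panel summary: CR and r^2 vs MAF; variant-count histogram."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = result.bins
    mid = (bins["maf_bin_low"] + bins["maf_bin_high"]) / 2
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    ax1.plot(mid, bins["mean_concordance"], marker="o", ms=3, label="concordance")
    if "mean_r2" in bins:
        ax1.plot(mid, bins["mean_r2"], marker="s", ms=3, label="r$^2$")
    ax1.set_ylabel("accuracy")
    ax1.legend()
    ax2.bar(mid, bins["n_variants"], width=mid.diff().fillna(0.01).min() * 0.9)
    ax2.set_xlabel("MAF")
    ax2.set_ylabel("variants")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
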