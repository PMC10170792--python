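"""Phenotype handling: fixed-effect correction and trait summaries.

The corrected phenotype of a trait is the raw value minus the fitted
fixed-effect part (farm, sex, slaughter batch by default), with the
grand mean restored so corrected values stay on the trait scale.  Two
estimators of the fixed effects are provided: ordinary least squares
(``fixed_only``) and generalized least squares under an animal model
with a genomic covariance (``animal_model``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = ["PhenotypeTable", "adjust_phenotypes", "summarize_traits"]


@dataclass
class PhenotypeTable:
    """Per-animal trait values plus fixed-effect factor levels.

    ``data`` must contain a ``sample_id`` column, one column per trait,
    and one column per factor (string levels).
    """

    data: pd.DataFrame
    traits: list = field(default_factory=list)
    factors: list = field(default_factory=lambda: ["farm", "sex", "batch"])

    def __post_init__(self):
        if "sample_id" not in self.data.columns:
            raise DataError("phenotype table needs a 'sample_id' column")
        for c in list(self.traits) + list(self.factors):
            if c not in self.data.columns:
                raise DataError(f"phenotype table missing column {c!r}")
        for f in self.factors:
            if self.data[f].isna().any():
                raise DataError(f"factor {f!r} has missing levels")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list:
        return self.data["sample_id"].tolist()

    def trait_values(self, trait: str) -> np.ndarray:
        if trait not in self.data.columns:
            raise DataError(f"unknown trait {trait!r}")
        return self.data[trait].to_numpy(float)

    def design_matrix(self, add_intercept: bool = True):
        """Reference-coded indicator matrix for the factors.

        Returns (X, column labels).  Raises on rank deficiency, naming
        the aliased columns.
        """
        cols = [np.ones(len(self.data))] if add_intercept else []
        labels = ["intercept"] if add_intercept else []
        for f in self.factors:
            levels = sorted(self.data[f].astype(str).unique())
            for lv in levels[1:]:  # first level is the reference
                cols.append((self.data[f].astype(str) == lv).to_numpy(float))
                labels.append(f"{f}[{lv}]")
        X = np.column_stack(cols) if cols else np.ones((len(self.data), 1))
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # identify aliased columns by greedy QR-style elimination
            aliased = []
            keep: list[int] = []
            for j in range(X.shape[1]):
                trial = X[:, keep + [j]]
                if np.linalg.matrix_rank(trial) == len(keep) + 1:
                    keep.append(j)
                else:
                    aliased.append(labels[j])
            raise DataError(f"confounded fixed effects; aliased columns: {aliased}")
        return X, labels


def adjust_phenotypes(
    pt: PhenotypeTable,
    trait: str,
    method: str = "animal_model",
    grm=None,
) -> np.ndarray:
    """Corrected phenotypes: y - X @ beta_hat, grand mean restored.

    ``fixed_only`` estimates beta by OLS; ``animal_model`` by GLS under
    y ~ N(X beta, sigma2_g * G + sigma2_e * I), with the variances
    themselves REML-estimated on the same data.  Either way only the
    fixed part is subtracted.
    """
    y = pt.trait_values(trait)
    if np.isnan(y).any():
        raise DataError(f"trait {trait!r} has missing values; drop them first")
    X, _ = pt.design_matrix()
    if method == "fixed_only":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    elif method == "animal_model":
        if grm is None:
            raise ConfigurationError("animal_model requires a GRM")
        from .varcomp import reml_fit  # deferred: varcomp is heavier

        grm_sub = grm.align(pt.sample_ids)
        est = reml_fit(y, [grm_sub], covariates=X)
        V = (
            est.components["g1"] * grm_sub.values
            + est.components["e"] * np.eye(len(y))
        )
        Vi_X = np.linalg.solve(V, X)
        beta = np.linalg.solve(X.T @ Vi_X, Vi_X.T @ y)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    yc = y - X @ beta
    return yc - yc.mean() + y.mean()


def summarize_traits(pt: PhenotypeTable) -> pd.DataFrame:
    """Per-trait n, mean, SD, min, max; missing values excluded."""
    rows = []
    for trait in pt.traits:
        v = pt.data[trait].to_numpy(float)
        v = v[~np.isnan(v)]
        rows.append(
            {
                "trait": trait,
                "n": int(v.size),
                "mean": float(v.mean()) if v.size else np.nan,
                "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
                "min": float(v.min()) if v.size else np.nan,
                "max": float(v.max()) if v.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
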