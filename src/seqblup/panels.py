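"""Genotype containers, QC filtering, and marker-panel construction.

The central objects are :class:`VariantPanel` (ordered variant metadata)
and :class:`GenotypeMatrix` (samples x variants dosage matrix with the
panel attached).  Dosages are stored as float64 with ``NaN`` marking
missing calls; observed values are 0, 1, or 2 copies of the alternate
allele.

Panel construction mirrors common chip/WGS practice: call-rate and MAF
filtering, random density thinning (per-variant Bernoulli or exact
subset size), greedy sliding-window LD pruning, and intersection of two
variant sets on (chromosome, position, ref, alt) keys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "VariantPanel",
    "GenotypeMatrix",
    "QCReport",
    "qc_filter",
    "thin_variants",
    "ld_prune",
    "intersect_panels",
]

SNP = "SNP"
INDEL = "INDEL"

_PANEL_COLUMNS = ["variant_id", "chrom", "pos", "vtype", "ref", "alt"]


class VariantPanel:
    """Ordered set of variants with metadata.

    Backed by a :class:`pandas.DataFrame` with columns ``variant_id``,
    ``chrom``, ``pos`` (1-based), ``vtype`` (``SNP``/``INDEL``), ``ref``,
    ``alt`` and optionally ``maf`` and ``call_rate``.
    """

    def __init__(self, table: pd.DataFrame, validate: bool = True):
        missing = [c for c in _PANEL_COLUMNS if c not in table.columns]
        if missing:
            raise DataError(f"variant table missing columns: {missing}")
        self.table = table.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        ids = self.table["variant_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique().tolist())
            raise DataError(f"duplicate variant ids: {dups[:10]}")
        bad = ~self.table["vtype"].isin([SNP, INDEL])
        if bad.any():
            raise DataError(
                f"unknown variant types: {self.table.loc[bad, 'vtype'].unique()}"
            )
        for _, sub in self.table.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise DataError("positions must be non-decreasing within chromosome")
        if "maf" in self.table.columns:
            maf = self.table["maf"].to_numpy(float)
            ok = np.isnan(maf) | ((maf >= 0) & (maf <= 0.5 + 1e-12))
            if not ok.all():
                raise DataError("maf values must lie in [0, 0.5]")

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariantPanel):
            return NotImplemented
        return list(self.variant_ids) == list(other.variant_ids)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.table["variant_id"].to_numpy()

    @property
    def vtype(self) -> np.ndarray:
        return self.table["vtype"].to_numpy()

    def keys(self) -> pd.Index:
        """(chrom, pos, ref, alt) match keys, one per variant."""
        t = self.table
        return pd.MultiIndex.from_arrays(
            [t["chrom"], t["pos"], t["ref"], t["alt"]]
        )

    def subset(self, indices: np.ndarray) -> "VariantPanel":
        return VariantPanel(self.table.iloc[np.asarray(indices)], validate=False)

    def type_counts(self) -> dict:
        vc = self.table["vtype"].value_counts()
        return {SNP: int(vc.get(SNP, 0)), INDEL: int(vc.get(INDEL, 0))}

    def copy(self) -> "VariantPanel":
        return VariantPanel(self.table.copy(), validate=False)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix (0/1/2, NaN = missing)."""

    sample_ids: list
    variants: VariantPanel
    dosage: np.ndarray
    sample_info: pd.DataFrame | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise DataError("dosage must be a 2-D array")
        n, m = self.dosage.shape
        if n != len(self.sample_ids):
            raise DataError(
                f"{len(self.sample_ids)} sample ids but {n} dosage rows"
            )
        if m != len(self.variants):
            raise DataError(f"{len(self.variants)} variants but {m} dosage columns")
        obs = self.dosage[~np.isnan(self.dosage)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise DataError("observed dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def with_stats(self) -> "GenotypeMatrix":
        """Return self with maf/call_rate cached into the variant table."""
        t = self.variants.table.copy()
        t["maf"] = self.maf()
        t["call_rate"] = self.call_rate()
        return GenotypeMatrix(
            self.sample_ids, VariantPanel(t, validate=False), self.dosage,
            self.sample_info,
        )

    def subset_variants(self, indices: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(indices)
        return GenotypeMatrix(
            self.sample_ids,
            self.variants.subset(idx),
            self.dosage[:, idx],
            self.sample_info,
        )

    def subset_by_panel(self, panel: VariantPanel) -> "GenotypeMatrix":
        """Restrict to the variants of ``panel`` in panel order."""
        lookup = {v: i for i, v in enumerate(self.variants.variant_ids)}
        try:
            idx = np.array([lookup[v] for v in panel.variant_ids], dtype=int)
        except KeyError as exc:
            raise DataError(f"panel variant absent from matrix: {exc}") from exc
        return self.subset_variants(idx)

    def subset_samples(self, ids: Sequence) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in ids], dtype=int)
        info = None
        if self.sample_info is not None:
            info = self.sample_info.iloc[idx].reset_index(drop=True)
        return GenotypeMatrix(list(ids), self.variants, self.dosage[idx], info)


@dataclass
class QCReport:
    n_input: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_retained: int
    params: dict = field(default_factory=dict)


def qc_filter(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.9,
    min_maf: float = 0.01,
    return_report: bool = False,
):
    """Drop variants with call rate or MAF not exceeding the thresholds.

    Inequalities are strict: a variant is kept only if its call rate is
    strictly greater than ``min_call_rate`` and its MAF strictly greater
    than ``min_maf``.  The sample set is never altered.
    """
    for name, v in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
    cr = gm.call_rate()
    maf = gm.maf()
    cr_ok = cr > min_call_rate
    maf_ok = np.nan_to_num(maf, nan=0.0) > min_maf
    keep = cr_ok & maf_ok
    report = QCReport(
        n_input=gm.n_variants,
        n_removed_call_rate=int((~cr_ok).sum()),
        n_removed_maf=int((~maf_ok).sum()),
        n_retained=int(keep.sum()),
        params={"min_call_rate": min_call_rate, "min_maf": min_maf},
    )
    if not keep.any():
        warnings.warn("qc_filter removed every variant", stacklevel=2)
    out = gm.subset_variants(np.flatnonzero(keep)).with_stats()
    return (out, report) if return_report else out


def thin_variants(
    gm: GenotypeMatrix,
    mode: Literal["bernoulli", "exact"],
    fraction_or_count,
    seed: int = 0,
) -> VariantPanel:
    """Random density thinning; genomic order is preserved.

    ``bernoulli`` keeps each variant independently with the given
    probability; ``exact`` draws a uniform subset of exactly the
    requested size.
    """
    m = gm.n_variants
    rng = np.random.default_rng(seed)
    if mode == "bernoulli":
        frac = float(fraction_or_count)
        if not 0.0 < frac <= 1.0:
            raise ConfigurationError(f"fraction must lie in (0, 1], got {frac}")
        keep = np.flatnonzero(rng.random(m) < frac) if frac < 1.0 else np.arange(m)
    elif mode == "exact":
        count = int(fraction_or_count)
        if count > m:
            raise ConfigurationError(f"requested {count} variants but only {m} present")
        if count <= 0:
            raise ConfigurationError("count must be positive")
        keep = np.sort(rng.choice(m, size=count, replace=False))
    else:
        raise ConfigurationError(f"unknown thinning mode {mode!r}")
    return gm.variants.subset(keep)


def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """Squared dosage correlation among columns, pairwise-complete."""
    k = block.shape[1]
    if not np.isnan(block).any():
        sd = block.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(block, rowvar=False)
        c = np.atleast_2d(c)
        c[sd == 0, :] = np.nan
        c[:, sd == 0] = np.nan
        return c**2
    r2 = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            ok = ~np.isnan(block[:, i]) & ~np.isnan(block[:, j])
            if ok.sum() < 2:
                continue
            x, y = block[ok, i], block[ok, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            r2[i, j] = r2[j, i] = r * r
    np.fill_diagonal(r2, 1.0)
    return r2


def _prune_window(
    r2: np.ndarray,
    local_idx: np.ndarray,
    maf: np.ndarray,
    pos: np.ndarray,
    threshold: float,
    removed: set,
) -> None:
    """Greedy removal within one window; mutates ``removed`` (global idx)."""
    alive = [i for i in range(len(local_idx)) if local_idx[i] not in removed]
    while True:
        worst, pair = -1.0, None
        for a_i, i in enumerate(alive):
            for j in alive[a_i + 1 :]:
                v = r2[i, j]
                if not np.isnan(v) and v >= threshold and v > worst:
                    worst, pair = v, (i, j)
        if pair is None:
            return
        i, j = pair
        gi, gj = local_idx[i], local_idx[j]
        # drop the lower-MAF member; on ties the later-positioned one
        if maf[gi] < maf[gj]:
            drop = i
        elif maf[gj] < maf[gi]:
            drop = j
        else:
            drop = i if pos[gi] > pos[gj] else j
        removed.add(local_idx[drop])
        alive.remove(drop)


def ld_prune(
    gm: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_threshold: float = 0.6,
) -> VariantPanel:
    """Sliding-window greedy LD pruning on squared dosage correlation.

    Windows of ``window`` variants advance by ``step``; within a window,
    while any retained pair has r^2 >= ``r2_threshold`` one member is
    removed (lower MAF first, later position on ties).  Monomorphic
    variants have undefined r^2 and are never removed here.
    """
    if window < 2:
        raise ConfigurationError("window must span at least 2 variants")
    if step < 1:
        raise ConfigurationError("step must be >= 1")
    if not 0.0 < r2_threshold <= 1.0:
        raise ConfigurationError("r2_threshold must lie in (0, 1]")
    maf = gm.maf()
    pos = gm.variants.table["pos"].to_numpy()
    chroms = gm.variants.table["chrom"].to_numpy()
    removed: set = set()
    for chrom in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        start = 0
        while True:
            widx = cidx[start : start + window]
            if len(widx) >= 2:
                r2 = _pairwise_r2(gm.dosage[:, widx])
                _prune_window(r2, widx, maf, pos, r2_threshold, removed)
            if start + window >= len(cidx):
                break
            start += step
    keep = np.array([i for i in range(gm.n_variants) if i not in removed], dtype=int)
    return gm.variants.subset(keep)


def intersect_panels(a: VariantPanel, b: VariantPanel) -> VariantPanel:
    """Variants present in both panels, matched on (chrom, pos, ref, alt).

    Output preserves the order of ``a``.
    """
    ka, kb = a.keys(), b.keys()
    for name, k in (("a", ka), ("b", kb)):
        dup = k[k.duplicated()]
        if len(dup):
            raise DataError(
                f"duplicate (chrom,pos,ref,alt) keys in panel {name}: "
                f"{list(dup[:5])}"
            )
    mask = ka.isin(kb)
    return a.subset(np.flatnonzero(mask))
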