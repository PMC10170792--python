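"""Genomic relationship matrices from dosage data.

The default construction centers dosages by twice the in-sample allele
frequency and uses one shared denominator:

    G = W W^T / (2 * sum_i p_i (1 - p_i)),   W[.,i] = M[.,i] - 2 p_i

(``vanraden1``).  A per-marker standardized variant (``vanraden2``) is
provided for comparison.  Missing dosages are mean-imputed (2 p_i, i.e.
zero after centering); monomorphic markers are excluded.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError
from .panels import GenotypeMatrix

__all__ = ["GRM", "compute_grm", "combine_grms"]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with provenance."""

    sample_ids: list
    values: np.ndarray
    n_markers: int
    algorithm: str
    allele_freqs: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise DataError(
                f"GRM shape {self.values.shape} does not match {n} sample ids"
            )
        if not np.isfinite(self.values).all():
            raise DataError("GRM contains non-finite entries")
        if np.abs(self.values - self.values.T).max() > 1e-12:
            raise DataError("GRM is not symmetric")
        if self.n_markers <= 0:
            raise DataError("n_markers must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def align(self, ids) -> "GRM":
        """Sub-GRM restricted to ``ids`` in the given order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            idx = np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise DataError(f"sample absent from GRM: {exc}") from exc
        return GRM(
            list(ids),
            self.values[np.ix_(idx, idx)],
            self.n_markers,
            self.algorithm,
            self.allele_freqs,
        )

    # -- GCTA-compatible binary triplet ------------------------------
    def write_gcta(self, prefix: str | Path) -> None:
        """Write <prefix>.grm.bin / .grm.N.bin / .grm.id.

        Lower triangle (diagonal included), row-major, little-endian
        float32; the N file repeats the marker count per element.
        """
        prefix = str(prefix)
        n = self.n_samples
        tri = self.values[np.tril_indices(n)].astype("<f4")
        tri.tofile(prefix + ".grm.bin")
        np.full(tri.size, self.n_markers, dtype="<f4").tofile(prefix + ".grm.N.bin")
        with open(prefix + ".grm.id", "w") as fh:
            for s in self.sample_ids:
                fh.write(f"{s}\t{s}\n")

    @classmethod
    def read_gcta(cls, prefix: str | Path, algorithm: str = "vanraden1") -> "GRM":
        prefix = str(prefix)
        ids = []
        with open(prefix + ".grm.id") as fh:
            for line in fh:
                parts = line.split()
                ids.append(parts[1] if len(parts) > 1 else parts[0])
        n = len(ids)
        tri = np.fromfile(prefix + ".grm.bin", dtype="<f4").astype(float)
        if tri.size != n * (n + 1) // 2:
            raise DataError("GRM binary size does not match id count")
        values = np.zeros((n, n))
        values[np.tril_indices(n)] = tri
        values = values + np.tril(values, -1).T
        nmark = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
        m = int(round(float(nmark[0]))) if nmark.size else 1
        return cls(ids, values, max(m, 1), algorithm)

    def write_text(self, path: str | Path) -> None:
        """Plain-text lower triangle: id1, id2, n_markers, value."""
        with open(path, "w") as fh:
            fh.write("id1\tid2\tn_markers\tvalue\n")
            for i in range(self.n_samples):
                for j in range(i + 1):
                    fh.write(
                        f"{self.sample_ids[i]}\t{self.sample_ids[j]}\t"
                        f"{self.n_markers}\t{self.values[i, j]:.10g}\n"
                    )


def compute_grm(gm: GenotypeMatrix, algorithm: str = "vanraden1") -> GRM:
    """Build a GRM from a dosage matrix.

    Allele frequencies come from the in-sample non-missing dosages.
    Monomorphic markers are dropped; at least one polymorphic marker is
    required.
    """
    if algorithm not in ("vanraden1", "vanraden2"):
        raise ConfigurationError(f"unknown GRM algorithm {algorithm!r}")
    M = gm.dosage
    p = gm.alt_freq()
    poly = ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise DataError("all markers are monomorphic; GRM undefined")
    M = M[:, poly]
    p = p[poly]
    W = M - 2.0 * p[None, :]
    W[np.isnan(W)] = 0.0  # missing -> 2p before centering
    if algorithm == "vanraden1":
        denom = 2.0 * np.sum(p * (1.0 - p))
        G = (W @ W.T) / denom
    else:
        W = W / np.sqrt(2.0 * p * (1.0 - p))[None, :]
        G = (W @ W.T) / p.size
    G = (G + G.T) / 2.0
    return GRM(list(gm.sample_ids), G, int(p.size), algorithm, allele_freqs=p)


def combine_grms(grms: list[GRM], weights: list[float]) -> GRM:
    """Weighted average of GRMs on an identical sample set."""
    if len(grms) != len(weights) or not grms:
        raise ConfigurationError("need one weight per GRM")
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ConfigurationError("weights must be >= 0 with positive sum")
    ids = grms[0].sample_ids
    for g in grms[1:]:
        if list(g.sample_ids) != list(ids):
            raise DataError("GRM sample ids do not match")
    w = w / w.sum()
    values = sum(wi * g.values for wi, g in zip(w, grms))
    m = int(round(sum(wi * g.n_markers for wi, g in zip(w, grms))))
    return GRM(list(ids), values, max(m, 1), "combined")
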