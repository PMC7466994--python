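"""Marker QC and the pooled genomic relationship matrix.

With population allele frequencies (one pooled value per population and
marker, not individual genotypes) the relationship matrix is

    G = M M' / K,    K = 0.5 * sum_j xbar_j (1 - xbar_j),

where M is the frequency matrix with each column centered on its mean
xbar_j and K scales by the summed genetic variance.  Individual-level LD is
not observable from pools; correlation between frequency columns of
same-scaffold marker pairs, binned by bp distance, serves as its proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from poolgp.dataio import AlleleFrequencyMatrix


@dataclass
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix between populations."""

    pop_ids: list[str]
    G: np.ndarray
    K: float

    def __post_init__(self) -> None:
        self.pop_ids = [str(p) for p in self.pop_ids]
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.pop_ids)
        if self.G.shape != (n, n):
            raise ValueError(f"G shape {self.G.shape} != ({n}, {n})")
        if self.K <= 0:
            raise ValueError("scaling constant K must be > 0")
        asym = float(np.abs(self.G - self.G.T).max())
        if asym > 1e-10:
            raise ValueError(f"G not symmetric (max asymmetry {asym:.2e})")
        scale = max(1.0, float(np.abs(np.diag(self.G)).max()))
        min_eig = float(np.linalg.eigvalsh(self.G).min())
        if min_eig < -1e-8 * scale:
            raise ValueError(f"G not positive semidefinite (min eigenvalue {min_eig:.2e})")

    @property
    def n(self) -> int:
        return len(self.pop_ids)


def filter_markers(
    freqs: AlleleFrequencyMatrix, maf_min: float = 0.05, min_pops: int = 10
) -> AlleleFrequencyMatrix:
    """Keep markers whose minor allele frequency exceeds *maf_min* in at
    least *min_pops* populations.

    The MAF condition min(x, 1-x) > maf_min is evaluated per population on
    non-missing values only (the filter precedes imputation).  Order is
    preserved; the result may have zero markers.
    """
    x = freqs.values
    with np.errstate(invalid="ignore"):
        maf = np.minimum(x, 1.0 - x)
        passing = (maf > maf_min) & ~np.isnan(x)
    keep = passing.sum(axis=0) >= min_pops
    kept_ids = [m for m, k in zip(freqs.marker_ids, keep) if k]
    return freqs.subset_markers(kept_ids)


def impute_missing(freqs: AlleleFrequencyMatrix) -> AlleleFrequencyMatrix:
    """Replace each missing cell by its marker's mean over non-missing values."""
    values = freqs.values.copy()
    mask = np.isnan(values)
    if not mask.any():
        return AlleleFrequencyMatrix(
            pop_ids=list(freqs.pop_ids),
            marker_ids=list(freqs.marker_ids),
            values=values,
            marker_map=freqs.marker_map.copy(),
        )
    all_missing = mask.all(axis=0)
    if all_missing.any():
        bad = [m for m, a in zip(freqs.marker_ids, all_missing) if a]
        raise ValueError(f"markers with no observed values: {bad[:5]}")
    col_means = np.nanmean(values, axis=0)
    values[mask] = np.broadcast_to(col_means, values.shape)[mask]
    return AlleleFrequencyMatrix(
        pop_ids=list(freqs.pop_ids),
        marker_ids=list(freqs.marker_ids),
        values=values,
        marker_map=freqs.marker_map.copy(),
    )


def kinship(freqs: AlleleFrequencyMatrix) -> KinshipMatrix:
    """Pooled genomic relationship matrix G = MM'/K.

    M is the frequency matrix with columns centered on their means; K is
    half the summed per-marker variance term xbar_j (1 - xbar_j).  Requires
    a complete (imputed) matrix.
    """
    x = freqs.values
    if np.isnan(x).any():
        raise ValueError("frequencies contain missing values; impute first")
    xbar = x.mean(axis=0)
    K = 0.5 * float((xbar * (1.0 - xbar)).sum())
    if K <= 0.0:
        raise ValueError("all markers fixed: scaling constant K = 0")
    M = x - xbar
    G = (M @ M.T) / K
    G = 0.5 * (G + G.T)
    return KinshipMatrix(pop_ids=list(freqs.pop_ids), G=G, K=K)


def correlation_decay(
    freqs: AlleleFrequencyMatrix,
    max_pairs_per_scaffold: int = 500,
    bins: np.ndarray | list[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Within-scaffold squared frequency correlation, binned by bp distance.

    For each scaffold with >= 2 markers, same-scaffold marker pairs are
    enumerated (subsampled to *max_pairs_per_scaffold* with *seed*), the
    squared Pearson correlation of the two frequency columns computed on
    populations where both are observed, and pairs binned by bp distance.

    Returns a table with columns bin_mid_bp, mean_r2, mean_abs_r, n_pairs.
    """
    if bins is None:
        bins = [0, 100, 500, 1000, 5000, 10_000, 20_000, 50_000]
    bins = np.asarray(bins, dtype=float)
    rng = np.random.default_rng(seed)
    scafs = freqs.marker_map["scaffold"].to_numpy()
    pos = freqs.marker_map["pos_bp"].to_numpy(dtype=float)
    dists: list[float] = []
    r2s: list[float] = []
    for scaf in pd.unique(scafs):
        idx = np.flatnonzero(scafs == scaf)
        if idx.size < 2:
            continue
        iu, ju = np.triu_indices(idx.size, k=1)
        n_pairs = iu.size
        if n_pairs > max_pairs_per_scaffold:
            sel = rng.choice(n_pairs, size=max_pairs_per_scaffold, replace=False)
            iu, ju = iu[sel], ju[sel]
        for a, b in zip(idx[iu], idx[ju]):
            xa, xb = freqs.values[:, a], freqs.values[:, b]
            ok = ~(np.isnan(xa) | np.isnan(xb))
            if ok.sum() < 3:
                continue
            va, vb = xa[ok], xb[ok]
            if va.std() == 0.0 or vb.std() == 0.0:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            dists.append(abs(pos[a] - pos[b]))
            r2s.append(r * r)
    if not dists:
        return pd.DataFrame(columns=["bin_mid_bp", "mean_r2", "mean_abs_r", "n_pairs"])
    d = np.asarray(dists)
    r2 = np.asarray(r2s)
    which = np.digitize(d, bins, right=False)
    rows = []
    for k in range(1, len(bins)):
        sel = which == k
        if sel.sum() == 0:
            continue
        rows.append(
            {
                "bin_mid_bp": 0.5 * (bins[k - 1] + bins[k]),
                "mean_r2": float(r2[sel].mean()),
                "mean_abs_r": float(np.sqrt(r2[sel]).mean()),
                "n_pairs": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
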