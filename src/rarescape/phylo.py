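"""Phylogenetic distances, niche estimation, phylogenetic signal and ßMNTD.

The phylogenetic-turnover metric ßMNTD implemented here is the
abundance-weighted mean distance from every taxon in one sample to its
nearest relative in the other sample; it is the observed statistic that the
null models in :mod:`rarescape.assembly` standardize into ßNTI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    SaturationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import EnvTable, OtuTable, PhyloTree


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with labeled axes.

    ``metric`` tags provenance: one of ``cophenetic``, ``sequence_ml``,
    ``bray_curtis``, ``bmntd``, ``gower``, ``euclidean_rank``.
    """

    ids: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        self.ids = list(map(str, self.ids))
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise FormatError(f"distance matrix shape {vals.shape} != ({n}, {n})")
        finite = vals[np.isfinite(vals)]
        if finite.size != vals.size and self.metric != "gower":
            # Gower matrices may carry NaN for pairs with no shared traits.
            raise FormatError("distance matrix contains non-finite values")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(vals - vals.T)) if n else 0.0
        if n and asym > 1e-12:
            raise FormatError(f"distance matrix asymmetric by {asym}")
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        self.values = vals

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {x: i for i, x in enumerate(self.ids)}
        missing = [x for x in ids if x not in pos]
        if missing:
            raise KeyError(f"ids absent from distance matrix: {missing[:5]!r}")
        return np.asarray([pos[x] for x in ids], dtype=np.intp)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = self.index_of(ids)
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) entries in row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.index.name = "id"
        return df.reset_index()

    @classmethod
    def from_condensed(cls, ids: Sequence[str], condensed: np.ndarray,
                       metric: str = "unknown") -> "DistanceMatrix":
        n = len(ids)
        vals = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        vals[iu] = condensed
        vals += vals.T
        return cls(list(ids), vals, metric)


def cophenetic_distance(tree: "PhyloTree") -> DistanceMatrix:
    """Tip-to-tip path-length distances (sum of branch lengths)."""
    if tree.n_tips < 2:
        raise InsufficientDataError("need >= 2 tips for cophenetic distances")
    dm = tree.tree.tip_tip_distances()
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float), "cophenetic")


def sequence_ml_distance(aligned_sequences: dict[str, str]) -> DistanceMatrix:
    """Jukes-Cantor ML distance between equal-length aligned sequences.

    Gapped or ambiguous columns are pairwise-deleted; d = -3/4 ln(1 - 4p/3)
    with p the proportion of differing comparable sites.  p >= 0.75 is
    outside the model's domain and raises :class:`SaturationError`.
    """
    ids = list(aligned_sequences)
    seqs = [str(aligned_sequences[i]).upper() for i in ids]
    if len(ids) < 2:
        raise InsufficientDataError("need >= 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise FormatError("sequences must be aligned to equal length")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(ids), length)
    valid = np.isin(arr, [b"A", b"C", b"G", b"T"])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = int(both.sum())
            if m == 0:
                raise EmptyInputError(f"no comparable sites between {ids[i]} and {ids[j]}")
            p = float((arr[i, both] != arr[j, both]).sum()) / m
            if p >= 0.75:
                raise SaturationError(
                    f"p={p:.3f} between {ids[i]} and {ids[j]} saturates the JC model"
                )
            d[i, j] = d[j, i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    return DistanceMatrix(ids, d, "sequence_ml")


def niche_values(table: "OtuTable", env: "EnvTable") -> pd.DataFrame:
    """Abundance-weighted mean environment per OTU ("niche value").

    niche(o, v) = sum_s counts[s,o] * env[s,v] / sum_s counts[s,o], over
    samples where variable v is non-missing.  OTUs absent from every sample
    with data are excluded (returned frame simply lacks their row).
    """
    env_sub = env.subset(table.sample_ids)
    counts = table.counts.astype(float)
    out = {}
    for var in env_sub.variables:
        v = env_sub.values[var].to_numpy()
        ok = np.isfinite(v)
        w = counts[ok, :]
        tot = w.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[var] = np.where(tot > 0, (w * v[ok, None]).sum(axis=0) / np.where(tot > 0, tot, 1), np.nan)
    niche = pd.DataFrame(out, index=table.otu_ids)
    niche.index.name = "otu_id"
    return niche[~niche.isna().all(axis=1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return np.nan
    return float((x * y).sum() / denom)


def phylo_signal_correlogram(
    phylo_dist: DistanceMatrix,
    niche: pd.DataFrame,
    n_classes: int = 10,
    n_perm: int = 999,
    seed: int | None = None,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mantel correlogram of niche distance against phylogenetic distance.

    Phylogenetic distances are binned into ``n_classes`` equal-frequency
    classes.  Per class c and niche variable v, the statistic is the
    *negated* Pearson correlation between the class-membership indicator and
    the niche distance |niche_i - niche_j| over all pairs, so that r > 0 in
    the shortest class means close relatives have similar niches
    (phylogenetic signal).  p-values come from permuting taxa labels of the
    niche vector.  The composite row ``_multivariate`` uses the Euclidean
    distance over all z-scored variables.
    """
    otus = [o for o in phylo_dist.ids if o in set(niche.index)]
    if len(otus) < 3:
        raise InsufficientDataError("need >= 3 OTUs shared by tree and niche table")
    pd_sub = phylo_dist.subset(otus)
    n = len(otus)
    iu = np.triu_indices(n, k=1)
    pvec = pd_sub.values[iu]
    # equal-frequency class edges on pairwise phylogenetic distances
    qs = np.quantile(pvec, np.linspace(0, 1, n_classes + 1))
    cls = np.clip(np.searchsorted(qs, pvec, side="right") - 1, 0, n_classes - 1)

    sub = niche.loc[otus]
    if variables is None:
        variables = list(sub.columns)
    zs = (sub - sub.mean()) / sub.std(ddof=0).replace(0, np.nan)

    rng = np.random.default_rng(seed)
    rows = []
    targets: list[tuple[str, np.ndarray]] = []
    for var in variables:
        targets.append((var, sub[var].to_numpy(dtype=float)[:, None]))
    comp = zs[list(variables)].fillna(0.0).to_numpy(dtype=float)
    targets.append(("_multivariate", comp))

    indicators = [(cls == c).astype(float) for c in range(n_classes)]
    for var, vals in targets:
        diff = np.sqrt(((vals[:, None, :] - vals[None, :, :]) ** 2).sum(axis=2))
        nvec = diff[iu]
        r_obs = np.array([
            -_pearson(ind, nvec) if ind.sum() else np.nan for ind in indicators
        ])
        counts = np.ones(n_classes)
        # permute taxa labels of the niche values, recompute per-class r
        for _ in range(n_perm):
            p = rng.permutation(n)
            nperm = diff[np.ix_(p, p)][iu]
            for c, ind in enumerate(indicators):
                if np.isnan(r_obs[c]):
                    continue
                r_p = -_pearson(ind, nperm)
                if abs(r_p) >= abs(r_obs[c]) - 1e-15:
                    counts[c] += 1
        for c, ind in enumerate(indicators):
            if ind.sum() == 0:
                continue
            rows.append({
                "variable": var, "class": c, "d_upper": qs[c + 1],
                "n_pairs": int(ind.sum()), "r": r_obs[c],
                "p": np.nan if np.isnan(r_obs[c]) else counts[c] / (n_perm + 1),
            })
    return pd.DataFrame(rows)


def has_phylo_signal(correlogram: pd.DataFrame, variable: str = "_multivariate",
                     alpha: float = 0.05) -> bool:
    """Signal declared when the shortest distance class has r > 0, p < alpha."""
    sub = correlogram[correlogram["variable"] == variable]
    if sub.empty:
        raise EmptyInputError(f"variable {variable!r} absent from correlogram")
    first = sub.sort_values("class").iloc[0]
    return bool(first["r"] > 0 and first["p"] < alpha)


# ---------------------------------------------------------------------------
# ßMNTD
# ---------------------------------------------------------------------------


def _bmntd_from_parts(
    rel: np.ndarray, present: list[np.ndarray], dvals: np.ndarray
) -> np.ndarray:
    """Vectorized ßMNTD over all sample pairs.

    ``minD[m, i]`` = distance from OTU i to its nearest OTU present in
    sample m; then ßMNTD = (F minD' + (F minD')') / 2 since minD[m, i] = 0
    whenever i is itself present in m (zero diagonal of ``dvals``).
    """
    n_samples, n_otus = rel.shape
    minD = np.empty((n_samples, n_otus))
    for m in range(n_samples):
        idx = present[m]
        if idx.size == 0:
            minD[m] = np.nan
        else:
            minD[m] = dvals[:, idx].min(axis=1)
    a = rel @ minD.T
    return (a + a.T) / 2.0


def bmntd(
    table: "OtuTable",
    phylo_dist: DistanceMatrix,
    abundance_weighted: bool = True,
) -> DistanceMatrix:
    """Between-sample mean-nearest-taxon phylogenetic turnover (ßMNTD).

    For samples k, m:
    ßMNTD(k,m) = 1/2 [ sum_{i in k} f_ik min_{j in m} d_ij
                     + sum_{j in m} f_jm min_{i in k} d_ij ]
    with f the within-sample relative abundance (or uniform weights over
    present taxa when ``abundance_weighted=False``).  Empty samples are
    excluded.
    """
    nonempty = table.sample_sums() > 0
    if nonempty.sum() < 2:
        raise InsufficientDataError("need >= 2 non-empty samples for ßMNTD")
    tbl = table.subset_samples([s for s, ok in zip(table.sample_ids, nonempty) if ok])
    idx = phylo_dist.index_of(tbl.otu_ids)
    dvals = phylo_dist.values[np.ix_(idx, idx)]
    if abundance_weighted:
        rel = tbl.relative_abundance()
    else:
        pres = (tbl.counts > 0).astype(float)
        rel = pres / pres.sum(axis=1, keepdims=True)
    present = [np.flatnonzero(tbl.counts[m] > 0) for m in range(tbl.n_samples)]
    vals = _bmntd_from_parts(rel, present, dvals)
    return DistanceMatrix(tbl.sample_ids, vals, "bmntd")
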