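"""Null-model inference of community assembly processes.

Per sample pair this module computes ßNTI (observed ßMNTD standardized
against tip-label-shuffling nulls) and the abundance-based Raup-Crick
metric on Bray-Curtis turnover, classifies each pair into one of five
processes, maps processes onto rarity types, summarizes windows and
taxonomic divisions, and runs a distance-based PERMANOVA of phylogenetic
turnover against environmental predictors.

Conventions (documented deviations from loose verbal definitions):

* ßNTI is a z-score, (obs - null mean) / null sd — the |ßNTI| > 2 rule only
  makes sense for a standardized statistic.
* "Random shuffling of the branches of the tree" is implemented as a
  uniform permutation of tip labels (taxa shuffle).
* Classification uses strict inequalities at |2| and |0.95|; boundary
  values fall to the non-selection / non-dispersal side.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import (
    ClassificationError,
    EmptySummaryError,
    InsufficientDataError,
)
from .io_formats import EnvTable, OtuTable, division_of
from .phylo import DistanceMatrix, _bmntd_from_parts
from .rarity import RacWindow

VARIABLE_SELECTION = "VariableSelection"
HOMOGENEOUS_SELECTION = "HomogeneousSelection"
DISPERSAL_LIMITATION = "DispersalLimitation"
HOMOGENIZING_DISPERSAL = "HomogenizingDispersal"
UNDOMINATED = "Undominated"

PROCESSES = (
    VARIABLE_SELECTION,
    HOMOGENEOUS_SELECTION,
    DISPERSAL_LIMITATION,
    HOMOGENIZING_DISPERSAL,
    UNDOMINATED,
)

CONDITIONALLY_RARE = "ConditionallyRare"
PERMANENTLY_RARE = "PermanentlyRare"
TRANSIENTLY_RARE = "TransientlyRare"

RARITY_TYPES = (CONDITIONALLY_RARE, PERMANENTLY_RARE, TRANSIENTLY_RARE)

_PROCESS_TO_RARITY = {
    VARIABLE_SELECTION: CONDITIONALLY_RARE,
    HOMOGENEOUS_SELECTION: PERMANENTLY_RARE,
    HOMOGENIZING_DISPERSAL: PERMANENTLY_RARE,
    DISPERSAL_LIMITATION: TRANSIENTLY_RARE,
    UNDOMINATED: TRANSIENTLY_RARE,
}


def _nonempty(table: OtuTable) -> OtuTable:
    keep = table.sample_sums() > 0
    return table.subset_samples(
        [s for s, ok in zip(table.sample_ids, keep) if ok]
    )


def bnti(
    table: OtuTable,
    phylo_dist: DistanceMatrix,
    n_null: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """ßNTI per sample pair from tip-shuffling null models of ßMNTD.

    Each of the ``n_null`` randomizations applies one uniform permutation of
    tip labels across all tips of ``phylo_dist`` and recomputes ßMNTD for
    every pair (nulls shared across pairs within a round).  A degenerate
    null (sd = 0) yields bnti = 0 with ``degenerate_null=True``.
    """
    tbl = _nonempty(table)
    if tbl.n_samples < 2:
        raise InsufficientDataError("need >= 2 non-empty samples for ßNTI")
    idx = phylo_dist.index_of(tbl.otu_ids)
    dall = phylo_dist.values
    dvals = dall[np.ix_(idx, idx)]
    if abundance_weighted:
        rel = tbl.relative_abundance()
    else:
        pres = (tbl.counts > 0).astype(float)
        rel = pres / pres.sum(axis=1, keepdims=True)
    present = [np.flatnonzero(tbl.counts[m] > 0) for m in range(tbl.n_samples)]
    obs = _bmntd_from_parts(rel, present, dvals)

    rng = np.random.default_rng(seed)
    n_tips = dall.shape[0]
    s1 = np.zeros_like(obs)
    s2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_tips)
        dp = dall[np.ix_(perm[idx], perm[idx])]
        nv = _bmntd_from_parts(rel, present, dp)
        s1 += nv
        s2 += nv * nv
    mean = s1 / n_null
    var = np.maximum(s2 / n_null - mean * mean, 0.0)
    sd = np.sqrt(var)

    rows = []
    for i, j in combinations(range(tbl.n_samples), 2):
        degenerate = sd[i, j] <= 1e-12
        z = 0.0 if degenerate else (obs[i, j] - mean[i, j]) / sd[i, j]
        rows.append({
            "sample_i": tbl.sample_ids[i],
            "sample_j": tbl.sample_ids[j],
            "bmntd_obs": obs[i, j],
            "null_mean": mean[i, j],
            "null_sd": sd[i, j],
            "bnti": z,
            "degenerate_null": bool(degenerate),
        })
    return pd.DataFrame(rows)


def _null_community_matrix(
    rng: np.random.Generator,
    richness: np.ndarray,
    totals: np.ndarray,
    occ_freq: np.ndarray,
    pool_rel: np.ndarray,
) -> np.ndarray:
    """One round of null communities preserving per-sample richness and reads.

    Taxa are drawn without replacement with probability proportional to
    metacommunity occurrence frequency; each drawn taxon receives one read
    and the remaining reads are allocated multinomially proportional to
    metacommunity relative abundance.
    """
    n_samples = richness.size
    n_otus = occ_freq.size
    out = np.zeros((n_samples, n_otus))
    candidates = np.flatnonzero(occ_freq > 0)
    p_occ = occ_freq[candidates] / occ_freq[candidates].sum()
    for s in range(n_samples):
        k = int(richness[s])
        if k == 0:
            continue
        drawn = rng.choice(candidates, size=min(k, candidates.size),
                           replace=False, p=p_occ)
        out[s, drawn] = 1.0
        remaining = int(totals[s]) - drawn.size
        if remaining > 0:
            w = pool_rel[drawn]
            if w.sum() <= 0:
                w = np.ones_like(w)
            out[s, drawn] += rng.multinomial(remaining, w / w.sum())
    return out


def raup_crick_bray(
    table: OtuTable, n_null: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Abundance-based Raup-Crick metric on Bray-Curtis turnover.

    rc = 2 * [(#null < obs) + 0.5 * (#null = obs)] / n_null - 1, in [-1, 1];
    negative values mean the pair is more similar than the null expectation.
    """
    tbl = _nonempty(table)
    if tbl.n_samples < 2:
        raise InsufficientDataError("need >= 2 non-empty samples for Raup-Crick")
    counts = tbl.counts
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    occ_freq = (counts > 0).sum(axis=0).astype(float)
    pool = counts.sum(axis=0).astype(float)
    pool_rel = pool / pool.sum()

    obs = squareform(pdist(tbl.relative_abundance(), metric="braycurtis"))
    rng = np.random.default_rng(seed)
    n_s = tbl.n_samples
    lt = np.zeros((n_s, n_s))
    eq = np.zeros((n_s, n_s))
    for _ in range(n_null):
        null = _null_community_matrix(rng, richness, totals, occ_freq, pool_rel)
        sums = null.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        null_bc = squareform(pdist(null / sums, metric="braycurtis"))
        close = np.isclose(null_bc, obs, rtol=0, atol=1e-12)
        lt += (null_bc < obs) & ~close
        eq += close
    rc = 2.0 * (lt + 0.5 * eq) / n_null - 1.0

    rows = []
    for i, j in combinations(range(n_s), 2):
        rows.append({
            "sample_i": tbl.sample_ids[i],
            "sample_j": tbl.sample_ids[j],
            "bray_obs": obs[i, j],
            "rc": rc[i, j],
        })
    return pd.DataFrame(rows)


def classify_pair(
    bnti_value: float,
    rc_value: float,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> str:
    """Five-way assembly-process classification of one sample pair.

    bnti > 2 -> variable selection; bnti < -2 -> homogeneous selection;
    |bnti| <= 2 with rc > 0.95 -> dispersal limitation, rc < -0.95 ->
    homogenizing dispersal; otherwise undominated (drift).  Strict
    inequalities: boundary values are not selection/dispersal.
    """
    if not (np.isfinite(bnti_value) and np.isfinite(rc_value)):
        raise ClassificationError(
            f"non-finite statistics (bnti={bnti_value}, rc={rc_value})"
        )
    if bnti_value > bnti_threshold:
        return VARIABLE_SELECTION
    if bnti_value < -bnti_threshold:
        return HOMOGENEOUS_SELECTION
    if rc_value > rc_threshold:
        return DISPERSAL_LIMITATION
    if rc_value < -rc_threshold:
        return HOMOGENIZING_DISPERSAL
    return UNDOMINATED


def pairwise_turnover(
    table: OtuTable,
    phylo_dist: DistanceMatrix,
    n_null: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = True,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """ßNTI + Raup-Crick + process label for every sample pair."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    # stateless children so repeated calls with the same seed are identical
    s_bnti = np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (0,))
    s_rc = np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (1,))
    left = bnti(table, phylo_dist, n_null=n_null,
                seed=s_bnti, abundance_weighted=abundance_weighted)
    right = raup_crick_bray(table, n_null=n_null, seed=s_rc)
    merged = left.merge(right, on=["sample_i", "sample_j"], how="inner")
    merged["n_null"] = n_null
    merged["process"] = [
        classify_pair(b, r, bnti_threshold, rc_threshold)
        for b, r in zip(merged["bnti"], merged["rc"])
    ]
    return merged


def map_rarity_types(process: str, subset_is_abundant: bool = False) -> str | None:
    """Rarity type implied by a dominant process (None for abundant subsets)."""
    if process not in _PROCESS_TO_RARITY:
        raise ClassificationError(f"unknown process label {process!r}")
    if subset_is_abundant:
        return None
    return _PROCESS_TO_RARITY[process]


def summarize_window_processes(
    pairs: pd.DataFrame,
    window: RacWindow | None = None,
    n_samples: int | None = None,
    subset_is_abundant: bool = False,
) -> pd.DataFrame:
    """One summary row: per-process pair fractions (sum to 1) for a window."""
    if pairs is None or len(pairs) == 0:
        raise EmptySummaryError("no classified pairs to summarize")
    fracs = pairs["process"].value_counts(normalize=True)
    row: dict[str, object] = {}
    if window is not None:
        row.update({"window": window.label,
                    "start_rank": window.start_rank,
                    "end_rank": window.end_rank,
                    "n_otus": window.n_otus})
    row["n_pairs"] = int(len(pairs))
    if n_samples is not None:
        row["n_samples"] = int(n_samples)
    for p in PROCESSES:
        row[p] = float(fracs.get(p, 0.0))
    plurality = max(PROCESSES, key=lambda p: row[p])
    row["plurality_process"] = plurality
    rt = map_rarity_types(plurality, subset_is_abundant)
    row["rarity_type"] = rt if rt is not None else ""
    return pd.DataFrame([row])


def per_division_assembly(
    table: OtuTable,
    taxonomy: Mapping[str, str] | None = None,
    phylo_dist: DistanceMatrix | None = None,
    min_otus: int = 20,
    n_null: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the pair-level pipeline on each taxonomic Division's OTU subset.

    Divisions with fewer than ``min_otus`` OTUs in the table are skipped;
    "unclassified" at Division rank forms its own pseudo-group.  Each
    division uses the same base seed, so its summary equals a standalone
    run on the pre-restricted table.
    """
    if taxonomy is None:
        taxonomy = table.taxonomy or {}
    if phylo_dist is None:
        raise InsufficientDataError("phylo_dist is required")
    divisions: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        divisions.setdefault(division_of(taxonomy.get(otu)), []).append(otu)

    out = []
    skipped = []
    for division in sorted(divisions):
        otus = divisions[division]
        if len(otus) < min_otus:
            skipped.append(division)
            continue
        sub = _nonempty(table.subset_otus(otus))
        if sub.n_samples < 2:
            skipped.append(division)
            continue
        pairs = pairwise_turnover(sub, phylo_dist, n_null=n_null, seed=seed)
        summary = summarize_window_processes(pairs, n_samples=sub.n_samples)
        summary.insert(0, "division", division)
        summary.insert(1, "n_otus_division", len(otus))
        out.append(summary)
    if skipped:
        warnings.warn(
            f"divisions skipped (< {min_otus} OTUs or < 2 samples): {skipped}",
            stacklevel=2,
        )
    if not out:
        warnings.warn("no division passed the OTU threshold", stacklevel=2)
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# PERMANOVA (adonis-style, sequential sums of squares)
# ---------------------------------------------------------------------------


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d * d
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(
    dist: DistanceMatrix,
    env: EnvTable,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Distance-based PERMANOVA of ``dist`` against the env table's columns.

    Numeric predictors are z-scored, entered sequentially (type-I) in column
    order on the Gower-centered inner-product matrix; p-values by free
    permutation of sample labels, p = (#perm F >= obs F + 1) / (n_perm + 1).
    Constant or collinear predictors are dropped with a warning.
    """
    ids = [s for s in dist.ids if s in set(env.sample_ids)]
    if len(ids) < 4:
        raise InsufficientDataError("need >= 4 samples shared by dist and env")
    d = dist.subset(ids).values
    ev = env.subset(ids).values
    n = len(ids)

    cols: list[str] = []
    xs = [np.ones((n, 1))]
    for c in ev.columns:
        if len(cols) >= n - 2:  # keep >= 1 residual df
            warnings.warn(f"predictor {c!r} dropped: no residual df left",
                          stacklevel=2)
            continue
        v = ev[c].to_numpy(dtype=float)
        if np.isnan(v).any():
            # free permutation requires complete cases; impute nothing, drop
            warnings.warn(f"predictor {c!r} has missing values; dropped", stacklevel=2)
            continue
        sd = v.std(ddof=0)
        if sd == 0:
            warnings.warn(f"constant predictor {c!r} dropped", stacklevel=2)
            continue
        z = (v - v.mean()) / sd
        cand = np.hstack(xs + [z[:, None]])
        if np.linalg.matrix_rank(cand) <= np.linalg.matrix_rank(np.hstack(xs)):
            warnings.warn(f"collinear predictor {c!r} dropped", stacklevel=2)
            continue
        xs.append(z[:, None])
        cols.append(c)
    if not cols:
        raise InsufficientDataError("no usable predictors")

    g = _gower_center(d)
    hats = [_hat(np.hstack(xs[: k + 1])) for k in range(len(xs))]
    deltas = [hats[k] - hats[k - 1] for k in range(1, len(hats))]
    h_full = hats[-1]
    resid = np.eye(n) - h_full
    df_res = n - len(cols) - 1

    def f_stats(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([float((dh * gm).sum()) for dh in deltas])
        ss_res = float((resid * gm).sum())
        f = (ss_terms / 1.0) / (ss_res / df_res)
        return f, ss_res

    f_obs, ss_res = f_stats(g)
    ss_terms_obs = np.array([float((dh * g).sum()) for dh in deltas])
    ss_total = float(np.trace(g))

    rng = np.random.default_rng(seed)
    hits = np.ones(len(cols))
    for _ in range(n_perm):
        p = rng.permutation(n)
        f_p, _ = f_stats(g[np.ix_(p, p)])
        hits += f_p >= f_obs - 1e-12
    pvals = hits / (n_perm + 1)

    return pd.DataFrame({
        "term": cols,
        "df": 1,
        "sum_sq": ss_terms_obs,
        "r_squared": ss_terms_obs / ss_total if ss_total > 0 else np.nan,
        "pseudo_F": f_obs,
        "p_value": pvals,
    })
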