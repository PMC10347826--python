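"""Trait encoding, Gower distances and the rarity/trait/phylogeny correlations.

The 13 morpho-trophic traits are two numeric size bounds plus eleven ordered
categoricals whose modality orders are declared in a shipped, editable YAML
(:data:`DEFAULT_MODALITY_ORDER_PATH`).  Distance-matrix correlations use the
random-subset procedure (999 subsets of 100 OTUs by default) over
upper-triangle entries; trait-versus-rarity screens use tie-corrected
Spearman correlation within each OTU's dominant size fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import (
    EmptyInputError,
    FormatError,
    InsufficientDataError,
    ParameterError,
    UnknownModalityError,
)
from .phylo import DistanceMatrix, _pearson

if TYPE_CHECKING:  # pragma: no cover
    from .rarity import RankAbundanceCurve

NUMERIC_TRAITS = ("SizeMin", "SizeMax")

CATEGORICAL_TRAITS = (
    "CellCover", "CellShape", "Spicule", "CellSymmetry", "CellPolarity",
    "Colony", "Motility", "Ingestion", "Symbiosis", "RestingStage",
    "PlastOrigin",
)

TRAIT_COLUMNS = NUMERIC_TRAITS + CATEGORICAL_TRAITS

FRACTION_TIE_ORDER = ("micro", "nano", "pico")  # ties resolved in this order


def default_modality_orders() -> dict[str, list[str]]:
    """Load the shipped modality-order configuration."""
    with resources.files("rarescape.data").joinpath("modality_orders.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {k: [str(m) for m in v] for k, v in raw.items()}


def load_modality_orders(path) -> dict[str, list[str]]:
    """Read a modality-order YAML; missing traits fall back to the defaults."""
    orders = default_modality_orders()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for k, v in raw.items():
        orders[str(k)] = [str(m) for m in v]
    return orders


@dataclass
class TraitTable:
    """13 morpho-trophic traits per OTU with declared modality orders."""

    otu_ids: list[str]
    data: pd.DataFrame  # index = otu_ids, columns = TRAIT_COLUMNS
    modality_orders: dict[str, list[str]]

    def __post_init__(self) -> None:
        self.otu_ids = list(map(str, self.otu_ids))
        df = pd.DataFrame(self.data)
        df.index = pd.Index(self.otu_ids)
        missing_cols = [c for c in TRAIT_COLUMNS if c not in df.columns]
        if missing_cols:
            raise FormatError(f"trait table missing columns: {missing_cols}")
        df = df[list(TRAIT_COLUMNS)]
        for c in NUMERIC_TRAITS:
            try:
                df[c] = df[c].astype(float)
            except (TypeError, ValueError) as exc:
                raise FormatError(f"non-numeric value in {c}: {exc}") from exc
        bad_size = (df["SizeMin"] > df["SizeMax"]).fillna(False)
        if bad_size.any():
            rows = list(df.index[bad_size])
            raise ValueError(f"SizeMin > SizeMax for OTUs {rows[:5]!r}")
        for c in CATEGORICAL_TRAITS:
            order = self.modality_orders.get(c)
            if order is None:
                raise UnknownModalityError(f"no declared modality order for {c!r}")
            vals = df[c].dropna().astype(str)
            unknown = sorted(set(vals) - set(order))
            if unknown:
                raise UnknownModalityError(
                    f"modalities {unknown!r} of trait {c!r} not in declared "
                    f"order {order!r}"
                )
        if len(df) and df.isna().all(axis=1).any():
            # tolerate but drop fully-unannotated OTUs
            df = df[~df.isna().all(axis=1)]
            self.otu_ids = list(df.index)
        self.data = df

    def trophic_group(self) -> pd.Series:
        """phototroph / heterotroph / other, derived from PlastOrigin+Ingestion."""
        plast = self.data["PlastOrigin"].astype("string")
        ingest = self.data["Ingestion"].astype("string")
        group = pd.Series("other", index=self.data.index, dtype=object)
        group[plast.isin(["Endosymbiotic", "Constitutive"])] = "phototroph"
        hetero = ingest.notna() & plast.isin(["None", "Kleptoplastidic"])
        group[hetero] = "heterotroph"
        return group


def read_trait_table(path, modality_order_path=None) -> TraitTable:
    """Read a trait TSV (first column OTU id) with optional order overrides."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     na_values=["", "NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    orders = (load_modality_orders(modality_order_path)
              if modality_order_path is not None else default_modality_orders())
    return TraitTable(list(df.index), df, orders)


def write_trait_table(traits: TraitTable, path) -> None:
    out = traits.data.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def encode_traits(traits: TraitTable) -> pd.DataFrame:
    """Ordered categoricals -> integer codes 0..k-1; numerics unchanged."""
    out = {}
    for c in NUMERIC_TRAITS:
        out[c] = traits.data[c].astype(float)
    for c in CATEGORICAL_TRAITS:
        order = traits.modality_orders[c]
        code = {m: float(i) for i, m in enumerate(order)}
        col = traits.data[c]
        out[c] = pd.Series(
            [code[str(v)] if pd.notna(v) else np.nan for v in col],
            index=traits.data.index, dtype=float,
        )
    return pd.DataFrame(out, index=traits.data.index)


def gower_distance(encoded: pd.DataFrame) -> DistanceMatrix:
    """Gower dissimilarity over mixed encoded traits, in [0, 1].

    Per-trait distance |xi - xj| / range (observed range over non-missing
    values); the Gower distance of a pair is the mean over traits
    non-missing in both OTUs, NaN (flagged) when no trait is shared.
    """
    if encoded.shape[0] < 2:
        raise InsufficientDataError("need >= 2 OTUs for Gower distances")
    x = encoded.to_numpy(dtype=float)
    n, t = x.shape
    rng_ = np.nanmax(x, axis=0) - np.nanmin(x, axis=0)
    rng_[~np.isfinite(rng_)] = 0.0
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for k in range(t):
        col = x[:, k]
        ok = np.isfinite(col)
        both = np.outer(ok, ok)
        if rng_[k] > 0:
            diff = np.abs(col[:, None] - col[None, :]) / rng_[k]
            diff = np.where(both, diff, 0.0)
            num += np.nan_to_num(diff)
        den += both
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(encoded.index), d, "gower")


# ---------------------------------------------------------------------------
# random-subset distance-matrix correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationSummary:
    """Mean Pearson correlation/linear fit across random OTU subsets."""

    analysis: str
    n_subsets: int
    subset_size: int
    mean_r: float
    mean_r2: float
    mean_slope: float
    mean_intercept: float
    median_p: float
    n_skipped: int
    per_subset: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "analysis": self.analysis,
            "n_subsets": self.n_subsets,
            "subset_size": self.subset_size,
            "mean_r": self.mean_r,
            "mean_r2": self.mean_r2,
            "mean_slope": self.mean_slope,
            "mean_intercept": self.mean_intercept,
            "median_p": self.median_p,
            "n_skipped": self.n_skipped,
        }])


def _pearson_p(r: float, n: int) -> float:
    if not np.isfinite(r) or n < 3:
        return np.nan
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def _subset_correlation(
    xmat: DistanceMatrix,
    ymat: DistanceMatrix,
    ids: Sequence[str],
    n_subsets: int,
    subset_size: int,
    seed,
    analysis: str,
) -> CorrelationSummary:
    if len(ids) < subset_size:
        raise ParameterError(
            f"subset_size {subset_size} exceeds available OTUs ({len(ids)})"
        )
    rng = np.random.default_rng(seed)
    ids = list(ids)
    rows = []
    skipped = 0
    for b in range(n_subsets):
        pick = rng.choice(len(ids), size=subset_size, replace=False)
        sub_ids = [ids[i] for i in pick]
        xv = xmat.subset(sub_ids).condensed()
        yv = ymat.subset(sub_ids).condensed()
        ok = np.isfinite(xv) & np.isfinite(yv)
        xv, yv = xv[ok], yv[ok]
        if xv.size < 3 or xv.std() == 0 or yv.std() == 0:
            skipped += 1
            continue
        r = _pearson(xv, yv)
        slope, intercept = np.polyfit(xv, yv, 1)
        rows.append({"subset": b, "r": r, "r2": r * r,
                     "slope": slope, "intercept": intercept,
                     "p": _pearson_p(r, xv.size)})
    per = pd.DataFrame(rows)
    if per.empty:
        raise InsufficientDataError("every subset was degenerate")
    return CorrelationSummary(
        analysis=analysis,
        n_subsets=n_subsets,
        subset_size=subset_size,
        mean_r=float(per["r"].mean()),
        mean_r2=float(per["r2"].mean()),
        mean_slope=float(per["slope"].mean()),
        mean_intercept=float(per["intercept"].mean()),
        median_p=float(per["p"].median()),
        n_skipped=skipped,
        per_subset=per,
    )


def trait_phylo_correlation(
    phylo_dist: DistanceMatrix,
    trait_dist: DistanceMatrix,
    n_subsets: int = 999,
    subset_size: int = 100,
    seed=None,
    group_ids: Sequence[str] | None = None,
) -> CorrelationSummary:
    """Mean Pearson correlation between phylogenetic and trait distances.

    ``group_ids`` restricts the OTU pool (e.g. phototrophs only, via
    :meth:`TraitTable.trophic_group`).
    """
    shared = [o for o in phylo_dist.ids if o in set(trait_dist.ids)]
    if group_ids is not None:
        gs = set(map(str, group_ids))
        shared = [o for o in shared if o in gs]
    return _subset_correlation(phylo_dist, trait_dist, shared,
                               n_subsets, subset_size, seed, "trait_phylo")


def rarity_phylo_correlation(
    phylo_dist: DistanceMatrix,
    rac: "RankAbundanceCurve",
    n_subsets: int = 999,
    subset_size: int = 100,
    seed=None,
    log_abundance: bool = True,
) -> dict[str, CorrelationSummary]:
    """Correlate phylogeny with rank and (log10) total-read abundance.

    Rank and abundance are each converted to one-dimensional Euclidean
    distance matrices |xi - xj| over the OTUs shared with the tree.
    """
    shared = [o for o in rac.otu_ids if o in set(phylo_dist.ids)]
    if len(shared) < subset_size:
        raise ParameterError("fewer shared OTUs than subset_size")
    pos = {o: i for i, o in enumerate(rac.otu_ids)}
    ranks = np.array([pos[o] + 1 for o in shared], dtype=float)
    reads = np.array([rac.total_reads[pos[o]] for o in shared], dtype=float)
    abund = np.log10(reads) if log_abundance else reads
    out = {}
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    seeds = ss.spawn(2)
    for name, vec, sd in (("rank", ranks, seeds[0]), ("abundance", abund, seeds[1])):
        mat = DistanceMatrix(shared, np.abs(vec[:, None] - vec[None, :]),
                             "euclidean_rank")
        out[name] = _subset_correlation(phylo_dist, mat, shared, n_subsets,
                                        subset_size, sd, f"rarity_phylo_{name}")
    return out


# ---------------------------------------------------------------------------
# trait-versus-rarity Spearman screens
# ---------------------------------------------------------------------------


def assign_dominant_fraction(totals: Mapping[str, Mapping[str, float]]) -> pd.Series:
    """Assign each OTU to the size fraction where it is most abundant.

    ``totals`` maps fraction -> {otu_id: total reads}.  Ties break by the
    fixed order micro > nano > pico; OTUs with zero reads everywhere are
    excluded.
    """
    fractions = [f for f in FRACTION_TIE_ORDER if f in totals]
    if not fractions:
        raise EmptyInputError("no fraction totals provided")
    all_otus = sorted({o for f in fractions for o in totals[f]})
    rows = {}
    for o in all_otus:
        reads = [float(totals[f].get(o, 0)) for f in fractions]
        best = max(reads)
        if best <= 0:
            continue
        rows[o] = fractions[int(np.argmax(reads))]  # argmax = first max = tie order
    return pd.Series(rows, dtype=object, name="fraction")


def trait_rarity_correlation(
    encoded: pd.DataFrame,
    racs: Mapping[str, "RankAbundanceCurve"],
    occurrences: Mapping[str, Mapping[str, int]],
    assignment: pd.Series,
    min_otus: int = 10,
) -> pd.DataFrame:
    """Spearman rho of each trait against rank/abundance/occurrence per fraction.

    OTUs enter only the fraction they were sorted into
    (:func:`assign_dominant_fraction`).  Cells with fewer than ``min_otus``
    non-missing OTUs or a constant trait get NaN rho and a flag.
    """
    rows = []
    for fraction, rac in racs.items():
        occ = occurrences.get(fraction, {})
        pos = {o: i for i, o in enumerate(rac.otu_ids)}
        members = [o for o in rac.otu_ids
                   if assignment.get(o) == fraction and o in set(encoded.index)]
        ranks = np.array([pos[o] + 1 for o in members], dtype=float)
        abund = np.array([rac.total_reads[pos[o]] for o in members], dtype=float)
        occv = np.array([float(occ.get(o, np.nan)) for o in members])
        metrics = {"rank": ranks, "abundance": abund, "occurrence": occv}
        for trait in encoded.columns:
            tv = encoded.loc[members, trait].to_numpy(dtype=float)
            for metric, mv in metrics.items():
                ok = np.isfinite(tv) & np.isfinite(mv)
                row = {"fraction": fraction, "trait": trait, "metric": metric,
                       "n": int(ok.sum())}
                if ok.sum() < min_otus or np.std(tv[ok]) == 0 or np.std(mv[ok]) == 0:
                    row.update({"rho": np.nan, "p": np.nan, "flag": "degenerate"})
                else:
                    rho, p = stats.spearmanr(tv[ok], mv[ok])
                    row.update({"rho": float(rho), "p": float(p), "flag": ""})
                rows.append(row)
    return pd.DataFrame(rows)
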