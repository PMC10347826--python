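"""Ground-truth generators: trees, conserved niches/traits, metacommunities.

Every generator is a pure function of (parameters, seed).  Metacommunities
are assembled under one of five known regimes — variable selection,
homogeneous selection, dispersal limitation, homogenizing dispersal, drift —
so the inference in :mod:`rarescape.assembly` can be validated by parameter
recovery: the generating regime should be the plurality classification
among sample pairs.

Generative model: a lognormal regional pool sets expected relative
abundances (emulating the power-law-like decay of real rank abundance
curves); selection multiplies the pool by a Gaussian niche filter around
phylogenetically conserved (Brownian) optima; dispersal limitation drifts
per-deme pools apart with weak migration; homogenizing dispersal samples
every community from the fully mixed pool at high depth; drift adds
unstructured per-sample lognormal noise.  Reads are drawn multinomially.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import skbio

from .errors import InsufficientDataError, ParameterError
from .io_formats import (
    ENV_VARIABLES,
    EnvTable,
    OtuTable,
    PhyloTree,
    write_otu_table,
    write_tree,
)
from .traits import (
    CATEGORICAL_TRAITS,
    TraitTable,
    default_modality_orders,
    write_trait_table,
)

PROCESS_NAMES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

EXPECTED_PLURALITY = {
    "variable_selection": "VariableSelection",
    "homogeneous_selection": "HomogeneousSelection",
    "dispersal_limitation": "DispersalLimitation",
    "homogenizing_dispersal": "HomogenizingDispersal",
    "drift": "Undominated",
}


@dataclass
class SyntheticScenario:
    """Parameters of one assembly-regime simulation."""

    process: str
    n_otus: int = 200
    n_samples: int = 16
    n_fractions: int = 1
    env_gradient: tuple[float, float] = (5.0, 25.0)
    niche_breadth: float = 1.5
    brownian_rate: float = 6.0
    migration: float = 0.05
    n_demes: int = 4
    deme_jitter_sd: float = 2.5
    deme_keep_frac: float = 0.5
    drift_sd: float = 0.1
    niche_delta: float = 0.3
    anchored_niche_sd: float = 0.06
    selection_jitter_sd: float = 1.0
    mu_pool: float = 0.0
    s_pool: float = 1.5
    reads_per_sample: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in PROCESS_NAMES:
            raise ParameterError(f"unknown process {self.process!r}")
        if not (0.0 <= self.migration <= 1.0):
            raise ParameterError("migration must be in [0, 1]")
        if self.n_otus <= 0 or self.n_samples <= 0 or self.reads_per_sample <= 0:
            raise ParameterError("counts must be positive")
        if self.niche_breadth <= 0 or self.brownian_rate <= 0 or self.s_pool <= 0:
            raise ParameterError("scale parameters must be positive")


@dataclass
class SyntheticTruth:
    """What the generator knows: regime, optima, tree, expected call."""

    process: str
    expected_plurality: str
    seed: int
    niche_optima: dict[str, float] = field(default_factory=dict)
    spatial_positions: dict[str, float] = field(default_factory=dict)
    newick: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# tree + Brownian traits
# ---------------------------------------------------------------------------


def simulate_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int | None = None,
    max_retries: int = 100,
) -> PhyloTree:
    """Birth-death tree with ``n_tips`` extant tips, scaled to unit height."""
    if n_tips < 3:
        raise ParameterError("need n_tips >= 3")
    if birth_rate <= 0 or death_rate < 0:
        raise ParameterError("birth_rate > 0 and death_rate >= 0 required")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        tree = _grow_birth_death(rng, n_tips, birth_rate, death_rate)
        if tree is not None:
            return tree
    raise InsufficientDataError(
        f"birth-death simulation went extinct {max_retries} times"
    )


def _grow_birth_death(rng, n_tips, b, d):
    root = skbio.TreeNode(name=None)
    root.start = 0.0
    left, right = skbio.TreeNode(), skbio.TreeNode()
    left.start = right.start = 0.0
    root.extend([left, right])
    active = [left, right]
    t = 0.0
    n_dead = 0
    while len(active) < n_tips:
        rate = len(active) * (b + d)
        t += rng.exponential(1.0 / rate)
        k = int(rng.integers(len(active)))
        node = active[k]
        active[k] = active[-1]  # swap-pop: O(1) removal
        active.pop()
        node.length = t - node.start
        if rng.random() < b / (b + d):
            c1, c2 = skbio.TreeNode(), skbio.TreeNode()
            c1.start = c2.start = t
            node.extend([c1, c2])
            active.extend([c1, c2])
        else:
            node.name = f"DEAD{n_dead:04d}"
            n_dead += 1
            if len(active) < 2:
                return None
    names = []
    for i, node in enumerate(active):
        node.length = t - node.start
        node.name = f"OTU{i + 1:05d}"
        names.append(node.name)
    if n_dead:
        root = root.shear(names)
    root.length = None
    # all extant tips sit at the same time; rescale height to exactly 1
    # (shearing extinct lineages can shorten the root-to-tip path)
    tip0 = next(iter(root.tips()))
    height = tip0.accumulate_to_ancestor(root)
    for node in root.traverse(include_self=False):
        node.length = (node.length or 0.0) / height
    return PhyloTree(root)


def _brownian_tip_values(tree: PhyloTree, rate: float, rng,
                         delta: float = 1.0) -> pd.Series:
    """One Brownian-motion realization along the tree, value per tip.

    ``delta`` < 1 applies an early-burst depth transform (branch time t
    mapped to t**delta on the height-normalized tree): most trait variance
    then accumulates near the root, making values strongly clade-structured.
    """
    depths: dict[int, float] = {id(tree.tree): 0.0}
    vals: dict[int, float] = {id(tree.tree): 0.0}
    height = max(
        (sum(a.length or 0.0 for a in t.ancestors() if a.parent is not None)
         + (t.length or 0.0))
        for t in tree.tree.tips()
    )
    height = height or 1.0

    def f(t: float) -> float:
        return (t / height) ** delta

    out = {}
    for node in tree.tree.preorder(include_self=False):
        d0 = depths[id(node.parent)]
        d1 = d0 + (node.length or 0.0)
        depths[id(node)] = d1
        dt = max(f(d1) - f(d0), 0.0)
        vals[id(node)] = vals[id(node.parent)] + rng.normal(0.0, rate * np.sqrt(dt))
        if node.is_tip():
            out[node.name] = vals[id(node)]
    return pd.Series(out, dtype=float)


def _bin_equal_frequency(values: pd.Series, levels: list[str]) -> pd.Series:
    """Bin continuous values into len(levels) ordered modalities, near-equal sizes."""
    k = len(levels)
    order = np.argsort(values.to_numpy(), kind="stable")
    codes = np.empty(len(values), dtype=int)
    # deal positions round-robin into k nearly equal blocks
    edges = np.linspace(0, len(values), k + 1).astype(int)
    for c in range(k):
        codes[order[edges[c]: edges[c + 1]]] = c
    return pd.Series([levels[c] for c in codes], index=values.index, dtype=object)


def simulate_niches_traits(
    tree: PhyloTree,
    sigma_bm: float = 6.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    env_variables: tuple[str, ...] = ("temperature", "salinity", "NOX"),
    niche_delta: float = 0.3,
) -> tuple[pd.DataFrame, TraitTable, pd.DataFrame]:
    """Phylogenetically conserved niche optima and traits (Brownian motion).

    Niche optima use an early-burst transform (``niche_delta`` < 1) so that
    conservatism holds at deep clade level, as the inference framework
    assumes; traits use plain Brownian motion.  Returns (optima per env
    variable, TraitTable with ordinal traits binned at equal-frequency cut
    points, continuous latent trait values).
    """
    rng = np.random.default_rng(seed)
    tips = tree.tip_names
    optima = {}
    for var in env_variables:
        bm = _brownian_tip_values(tree, sigma_bm, rng, delta=niche_delta)
        optima[var] = bm + rng.normal(0.0, noise_sd, size=len(bm))
    optima_df = pd.DataFrame(optima).loc[tips]
    optima_df.index.name = "otu_id"

    orders = default_modality_orders()
    continuous = {}
    data = {}
    base_size = _brownian_tip_values(tree, sigma_bm, rng)
    base_size = base_size + rng.normal(0.0, noise_sd, size=len(base_size))
    size_min = np.exp(base_size / max(base_size.abs().max(), 1.0) + 1.0)
    span = np.exp(rng.normal(0.0, 0.3, size=len(size_min)))
    data["SizeMin"] = pd.Series(size_min, index=base_size.index)
    data["SizeMax"] = data["SizeMin"] * (1.0 + span)
    continuous["SizeMin"] = data["SizeMin"]
    for trait in CATEGORICAL_TRAITS:
        bm = _brownian_tip_values(tree, sigma_bm, rng)
        bm = bm + rng.normal(0.0, noise_sd, size=len(bm))
        continuous[trait] = bm
        data[trait] = _bin_equal_frequency(bm.loc[tips], orders[trait])
    traits = TraitTable(tips, pd.DataFrame(data).loc[tips], orders)
    cont = pd.DataFrame(continuous).loc[tips]
    return optima_df, traits, cont


# ---------------------------------------------------------------------------
# metacommunity assembly
# ---------------------------------------------------------------------------


def _sample_env(scenario: SyntheticScenario, rng, n: int) -> pd.DataFrame:
    lo, hi = scenario.env_gradient
    mid = 0.5 * (lo + hi)
    env = {}
    if scenario.process == "variable_selection":
        env["temperature"] = np.linspace(lo, hi, n)
    elif scenario.process == "homogeneous_selection":
        # constant filter anchored near the gradient's low end, where
        # Brownian optima are clade-clustered, so selection is also
        # phylogenetically clustering
        env["temperature"] = (lo + 0.05 * (hi - lo)
                              + rng.normal(0.0, 0.01 * (hi - lo), size=n))
    else:
        env["temperature"] = mid + rng.normal(0.0, 0.02 * (hi - lo), size=n)
    baselines = {"salinity": 34.0, "NOX": 5.0, "PO4": 0.4, "NH4": 1.0, "SiOH4": 4.0}
    for var in ENV_VARIABLES:
        if var == "temperature":
            continue
        env[var] = baselines[var] * np.exp(rng.normal(0.0, 0.1, size=n))
    return pd.DataFrame(env)


def simulate_metacommunity(
    scenario: SyntheticScenario,
    tree: PhyloTree,
    optima: pd.DataFrame,
) -> tuple[OtuTable, EnvTable, SyntheticTruth]:
    """Assemble counts under the scenario's regime (multinomial reads).

    Size fractions are independent replicates with fraction-specific pools;
    fraction f contributes ``n_samples`` samples labeled ``<fraction>_sNN``.
    """
    tips = tree.tip_names
    if len(tips) != scenario.n_otus:
        raise ParameterError(
            f"tree has {len(tips)} tips but scenario declares {scenario.n_otus}"
        )
    opt = optima["temperature"].reindex(tips).to_numpy(dtype=float)
    # map conserved optima linearly onto the environmental gradient so the
    # niche filter can act over the whole sampled range
    lo, hi = scenario.env_gradient
    span = opt.max() - opt.min()
    if span > 0:
        opt = lo + (opt - opt.min()) / span * (hi - lo)
    # all niche dimensions, normalized to [0, 1], for the anchored
    # multidimensional filter of the homogeneous-selection regime
    opt_nd = optima.reindex(tips).to_numpy(dtype=float)
    rng_nd = opt_nd.max(axis=0) - opt_nd.min(axis=0)
    rng_nd[rng_nd == 0] = 1.0
    opt_nd = (opt_nd - opt_nd.min(axis=0)) / rng_nd
    ss = np.random.SeedSequence([int(scenario.seed), 0xC0FFEE])
    frac_seeds = ss.spawn(scenario.n_fractions)
    fractions = ["micro", "nano", "pico"][: max(1, scenario.n_fractions)]

    all_counts = []
    all_samples: list[str] = []
    all_fraction: list[str] = []
    env_frames = []
    positions: dict[str, float] = {}

    for fraction, fseed in zip(fractions, frac_seeds):
        rng = np.random.default_rng(fseed)
        n = scenario.n_samples
        pool = rng.lognormal(scenario.mu_pool, scenario.s_pool, size=len(tips))
        env = _sample_env(scenario, rng, n)
        sample_ids = [f"{fraction}_s{i + 1:03d}" for i in range(n)]
        x = rng.random(n)  # spatial positions on [0, 1)

        if scenario.process == "dispersal_limitation":
            demes = np.minimum(
                (x * scenario.n_demes).astype(int), scenario.n_demes - 1
            )
            deme_pools = []
            for _ in range(scenario.n_demes):
                jitter = np.exp(rng.normal(0.0, scenario.deme_jitter_sd, len(tips)))
                mask = rng.random(len(tips)) < scenario.deme_keep_frac
                local = pool * jitter * mask
                if local.sum() <= 0:
                    local = pool.copy()
                deme_pools.append(
                    scenario.migration * pool
                    + (1.0 - scenario.migration) * local
                )
            weights = np.stack([deme_pools[d] for d in demes])
        elif scenario.process == "variable_selection":
            temp = env["temperature"].to_numpy()
            filt = np.exp(
                -((temp[:, None] - opt[None, :]) ** 2)
                / (2.0 * scenario.niche_breadth**2)
            )
            weights = pool[None, :] * filt
        elif scenario.process == "homogeneous_selection":
            # stable conditions matching one guild's multidimensional niche:
            # anchor the filter at a randomly chosen taxon's optimum, so
            # selection retains a phylogenetically clustered set; per-sample
            # lognormal jitter adds demographic noise without moving the
            # filter
            anchor = int(rng.integers(len(tips)))
            target = opt_nd[anchor]
            filt = np.exp(
                -((opt_nd - target[None, :]) ** 2).sum(axis=1)
                / (2.0 * scenario.anchored_niche_sd**2)
            )
            jitter = np.exp(
                rng.normal(0.0, scenario.selection_jitter_sd, (n, len(tips)))
            )
            weights = pool[None, :] * filt[None, :] * jitter
            env["temperature"] = (lo + target[0] * (hi - lo)
                                  + rng.normal(0.0, 0.01 * (hi - lo), size=n))
        elif scenario.process == "drift":
            jitter = np.exp(rng.normal(0.0, scenario.drift_sd, (n, len(tips))))
            weights = pool[None, :] * jitter
        else:  # homogenizing_dispersal: fully mixed pool
            weights = np.broadcast_to(pool, (n, len(tips))).copy()

        counts = np.zeros((n, len(tips)), dtype=np.int64)
        for s in range(n):
            w = weights[s]
            if not np.isfinite(w).all() or w.sum() <= 0:
                w = pool
            counts[s] = rng.multinomial(scenario.reads_per_sample, w / w.sum())
        all_counts.append(counts)
        all_samples.extend(sample_ids)
        all_fraction.extend([fraction] * n)
        env.index = pd.Index(sample_ids)
        env_frames.append(env)
        positions.update(dict(zip(sample_ids, x.tolist())))

    table = OtuTable(
        sample_ids=all_samples,
        otu_ids=list(tips),
        counts=np.vstack(all_counts),
        fraction=all_fraction,
    )
    env_table = EnvTable(all_samples, pd.concat(env_frames))
    truth = SyntheticTruth(
        process=scenario.process,
        expected_plurality=EXPECTED_PLURALITY[scenario.process],
        seed=scenario.seed,
        niche_optima={o: float(v) for o, v in zip(tips, opt)},
        spatial_positions=positions,
        newick=tree.to_newick(),
    )
    return table, env_table, truth


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

_PRESETS = {
    "tiny": dict(n_otus=12, n_samples=6, n_fractions=1, reads_per_sample=500),
    "small": dict(n_otus=500, n_samples=30, n_fractions=3, reads_per_sample=20000),
    "paper_like": dict(n_otus=20000, n_samples=100, n_fractions=3,
                       reads_per_sample=100000, s_pool=2.5),
}


def scenario_preset(process: str, scale: str, seed: int) -> SyntheticScenario:
    if scale not in _PRESETS:
        raise ParameterError(f"unknown preset scale {scale!r}")
    params = dict(_PRESETS[scale])
    if process == "homogeneous_selection" and scale != "tiny":
        # low sequencing depth keeps per-sample richness well below the
        # pool size, which is where the clustered-vs-null contrast of the
        # tip-shuffle test is strongest
        params["reads_per_sample"] = 300
    return SyntheticScenario(process=process, seed=seed, **params)


def generate_dataset(scenario: SyntheticScenario):
    """Tree + niches/traits + metacommunity for one scenario (pure in seed)."""
    ss = np.random.SeedSequence([int(scenario.seed), 0xDA7A])
    tree_seed, trait_seed = ss.spawn(2)
    tree = simulate_tree(scenario.n_otus, seed=tree_seed)
    optima, traits, continuous = simulate_niches_traits(
        tree, sigma_bm=scenario.brownian_rate, seed=trait_seed,
        niche_delta=scenario.niche_delta,
    )
    table, env, truth = simulate_metacommunity(scenario, tree, optima)
    return table, env, tree, optima, traits, continuous, truth


def generate_fixture(
    name: str,
    scale: str = "tiny",
    seed: int = 0,
    out_dir: str | os.PathLike = ".",
) -> dict[str, str]:
    """Write a deterministic on-disk bundle for one scenario preset.

    Files: otu.tsv, metadata.tsv, tree.nwk, env.tsv, traits.tsv, truth.json.
    ``name`` is the generating process.
    """
    if name not in PROCESS_NAMES:
        raise ParameterError(f"unknown scenario name {name!r}")
    scenario = scenario_preset(name, scale, seed)
    table, env, tree, optima, traits, _, truth = generate_dataset(scenario)
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, f)
             for k, f in (("otu", "otu.tsv"), ("metadata", "metadata.tsv"),
                          ("tree", "tree.nwk"), ("env", "env.tsv"),
                          ("traits", "traits.tsv"), ("truth", "truth.json"))}
    write_otu_table(table, paths["otu"], metadata_path=paths["metadata"])
    write_tree(tree, paths["tree"])
    env_out = env.values.copy()
    env_out.index.name = "sample_id"
    env_out.to_csv(paths["env"], sep="\t", float_format="%.10g")
    write_trait_table(traits, paths["traits"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
        fh.write("\n")
    return paths
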