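# rarescape

Rarity-gradient analysis of microbial (protist) metabarcoding communities:

- **rank abundance curves** (RACs) per plankton size fraction, a
  multivariate abundant/rare cutoff, and overlapping rank windows
  (5000-OTU windows stepping by 2500, with an end-anchored final window)
  that define a gradient from abundant to rare taxa;
- **null-model inference of community assembly processes** per sample
  pair: abundance-weighted ßMNTD standardized against tip-shuffling nulls
  (ßNTI) and an abundance-based Raup-Crick metric on Bray-Curtis turnover,
  classified into variable selection / homogeneous selection / dispersal
  limitation / homogenizing dispersal / undominated, and mapped onto
  conditionally / permanently / transiently rare types;
- per-window and per-taxonomic-division process summaries, and a
  distance-based PERMANOVA of phylogenetic turnover against environmental
  predictors;
- **trait / phylogeny / rarity correlations**: Gower distances over 13
  ordered morpho-trophic traits, random-subset Pearson correlations of
  distance matrices, and Spearman screens of traits against
  rank/abundance/occurrence within each OTU's dominant size fraction;
- a **synthetic-data module** that generates birth-death trees,
  phylogenetically conserved niches/traits, and metacommunities assembled
  under each of the five regimes, so every inference stage can be
  validated by parameter recovery.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite: the published
sliding-window worked example (N = 71,380 → last two windows of 3,880 and
2,500 OTUs), brute-force oracle equivalence for ßMNTD / Gower / Spearman /
PERMANOVA, null-model calibration (including an exhaustive Raup-Crick
enumeration and a 1000-replicate PERMANOVA type-I check), five-scenario
parameter recovery, and trait-phylogeny correlation properties.

## CLI

```bash
# synthetic fixture with known assembly regime
rarescape simulate --scenario homogeneous_selection --scale small --seed 7 --out data/

# rank windows for a ranked list of 71,380 OTUs
rarescape rarity windows --n 71380

# RAC / abundant cutoff
rarescape rarity rac --table otu.tsv --metadata metadata.tsv --fraction nano --out rac.tsv
rarescape rarity cutoff --table otu.tsv --metadata metadata.tsv --fraction nano --threshold 0.95 --out cutoff.tsv

# per-pair ßNTI + Raup-Crick + process labels
rarescape assembly infer --table otu.tsv --metadata metadata.tsv --tree tree.nwk \
    --nnull 999 --seed 42 --out pairs.tsv

# PERMANOVA of ßMNTD against environment
rarescape assembly permanova --table otu.tsv --metadata metadata.tsv \
    --tree tree.nwk --env env.tsv --out permanova.tsv

# trait-vs-rarity Spearman screen
rarescape traits screen --traits traits.tsv --table otu.tsv --metadata metadata.tsv --out screen.tsv

# full pipeline from YAML
rarescape run --config config.yaml
rarescape report --out-dir out/
```

A minimal `config.yaml`:

```yaml
otu_path: data/otu.tsv
metadata_path: data/metadata.tsv
tree_path: data/tree.nwk
env_path: data/env.tsv
traits_path: data/traits.tsv
out_dir: out
n_null: 999
seed: 42
toggles: {assembly: true, permanova: true, traits: true}
```

Outputs per fraction: `rac.tsv`, `windows.tsv`, `abundant_otus.tsv`,
`pairs.tsv`, `window_processes.tsv`, optional `division_processes.tsv`,
`permanova.tsv`, `rarity_phylo.tsv`; run-level `trait_phylo.json`,
`trait_rarity.tsv`, `run.log`, `report.json`.

## File formats

OTU tables as TSV (OTU rows × sample columns; orientation auto-detected)
or BIOM 1.0 JSON; trees as Newick; sample metadata (`fraction` column),
environmental and trait tables as TSV; modality orders for the ordered
categorical traits in an editable YAML
(`src/rarescape/data/modality_orders.yaml`); results as TSV/JSON.

## Conventions worth knowing

- The low-evidence OTU filter removes an OTU only when it occurs in < 2
  samples **and** has < 3 total reads (AND rule; an OR variant is behind a
  flag).
- ßNTI is a z-score (divided by the null SD); tree randomization is a
  uniform tip-label shuffle; classification uses strict inequalities at
  |2| and |0.95|.
- RAC ties break lexicographically by OTU id, making windows
  deterministic.
- The multivariate abundant/rare cutoff correlates truncated-table
  Bray-Curtis matrices with the full-table matrix (Mantel-Pearson) on a
  geometric grid of head sizes and takes the smallest k reaching the
  threshold (default 0.95).
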