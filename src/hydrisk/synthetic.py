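"""Synthetic worlds with the statistical structure the analysis assumes.

The generator produces, from a single seed: an ultrametric genus-level
phylogeny with species attached as shallow polytomies; spatially
autocorrelated environmental fields; niche-derived species ranges; hydraulic
traits (P_min, P50, P88, in MPa, negative) evolved with phylogenetic signal
plus a linear environmental dependence and noise; sparse observation of those
traits; and pixel-level drought-mortality events drawn from a logistic model
on assemblage risk metrics. Ground truth is recorded so every downstream
stage can be tested against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .grids import EnvLayerStack, cell_rowcol

__all__ = [
    "SyntheticWorldConfig",
    "Phylogeny",
    "SpeciesRangeSet",
    "SyntheticWorld",
    "simulate_phylogeny",
    "simulate_environment",
    "simulate_niches_and_ranges",
    "simulate_traits",
    "apply_missingness",
    "simulate_mortality",
    "simulate_world",
    "yule_forward_leaf_count",
    "brownian_tips",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _default_mortality_coefs() -> dict[str, float]:
    # Risk rises with the number of species past their hydraulic limit and
    # with a more negative worst-case safety margin in the assemblage.
    # Coefficients are on raw metric scales; the intercept centers the
    # default world at roughly a 10% event rate over woody pixels.
    return {"intercept": -4.7, "n_hsm_neg": 0.025, "min_hsm": -0.9}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """All knobs of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    n_genera: int = 100
    species_per_genus_mean: float = 5.0
    species_per_genus_dispersion: float = 2.0
    tree_depth: float = 100.0
    grid_shape: tuple[int, int] = (40, 40)
    n_env_layers: int = 6
    env_corr_length: float = 5.0
    env_sd: float = 1.0
    bm_rate_pmin: float = 0.02  # MPa^2 per unit branch length
    bm_rate_p50: float = 0.02
    env_effect: tuple[float, ...] = (2.0, 0.6, 0.0, 0.0, 0.0, 0.0)  # MPa per env unit
    trait_corr: float = 0.8
    p88_offset_mean: float = 1.5  # MPa, > 0
    noise_sd: float = 0.25  # MPa
    observed_fraction: float = 0.2
    niche_signal: float = 0.5
    niche_breadth: float = 1.0  # env units on layer 1
    pmin_root: float = -6.5  # MPa
    p50_root: float = -7.5
    mortality_coefs: Mapping[str, float] = field(default_factory=_default_mortality_coefs)
    species_temperature: float = 3.0  # MPa; event-attribution weight exp(-HSM/tau)
    n_biomes: int = 4
    n_pfts: int = 3

    def validate(self) -> None:
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        if self.tree_depth <= 0:
            raise ValueError("tree_depth must be > 0")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")
        if not (0 < self.observed_fraction <= 1):
            raise ValueError("observed_fraction must be in (0, 1]")
        if self.p88_offset_mean <= 0:
            raise ValueError("p88_offset_mean must be > 0")
        if not (-1 < self.trait_corr < 1):
            raise ValueError("trait_corr must be in (-1, 1)")


# --------------------------------------------------------------------------
# phylogeny
# --------------------------------------------------------------------------

@dataclass
class Phylogeny:
    """Species-level tree plus its genus backbone and the species->genus map.

    Leaf labels of ``genus_tree`` are genus names; leaf labels of ``tree``
    are species names. Gymnosperm/angiosperm clades are the two subtrees at
    the backbone root.
    """

    tree: dendropy.Tree
    genus_tree: dendropy.Tree
    species_to_genus: dict[str, str]
    clade_of_genus: dict[str, str]

    @property
    def species(self) -> list[str]:
        return sorted(self.species_to_genus)

    @property
    def genera(self) -> list[str]:
        return sorted({t.label for t in self.genus_tree.taxon_namespace})

    def clade_of_species(self, sp: str) -> str:
        return self.clade_of_genus[self.species_to_genus[sp]]


def yule_forward_leaf_count(t: float, birth_rate: float, rng: np.random.Generator) -> int:
    """Number of lineages at time t under a pure-birth process started from 1."""
    k, now = 1, 0.0
    while True:
        now += rng.exponential(1.0 / (k * birth_rate))
        if now > t:
            return k
        k += 1


def _yule_backbone(n_leaves: int, depth: float, rng: np.random.Generator) -> dendropy.Tree:
    """Ultrametric pure-birth tree conditioned on n_leaves, rescaled to depth."""
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    if n_leaves == 1:
        tree.seed_node.taxon = taxa.new_taxon("G0001")
        tree.seed_node.edge.length = depth
        return tree

    # grow with unit birth rate; node ages recorded, then rescaled
    root = tree.seed_node
    root.birth_time = 0.0
    active: list[dendropy.Node] = [root]
    now = 0.0
    while len(active) < n_leaves:
        k = len(active)
        if k > 1:  # the root split defines time zero (no stem edge)
            now += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        node.split_time = now
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = now
            node.add_child(child)
            active.append(child)
    present = now + rng.exponential(1.0 / n_leaves)

    scale = depth / present
    for node in tree.preorder_node_iter():
        end = getattr(node, "split_time", present)
        node.edge.length = (end - node.birth_time) * scale
    root.edge.length = None
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(f"G{i + 1:04d}")
    return tree


def simulate_phylogeny(
    n_genera: int,
    species_per_genus: float | tuple[float, float] | Sequence[int],
    tree_depth: float,
    seed: int | np.random.Generator = 0,
    species_depth_fraction: float = 0.1,
) -> Phylogeny:
    """Yule genus backbone with species polytomies attached at shallow depth.

    ``species_per_genus`` may be a mean, a (mean, dispersion) pair for a
    negative-binomial draw (shifted so every genus has >= 1 species), or an
    explicit per-genus count list. Species diverge at
    ``species_depth_fraction * tree_depth`` before the present, so every
    species leaf sits at depth ``tree_depth``.
    """
    if n_genera < 1:
        raise ValueError("n_genera must be >= 1")
    if tree_depth <= 0:
        raise ValueError("tree_depth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sub_depth = species_depth_fraction * tree_depth
    genus_tree = _yule_backbone(n_genera, tree_depth - sub_depth, rng)
    genera = [t.label for t in genus_tree.taxon_namespace]

    if isinstance(species_per_genus, (int, float)):
        mean, disp = float(species_per_genus), None
    elif len(species_per_genus) == 2 and not isinstance(species_per_genus[0], (list, np.ndarray)):
        mean, disp = float(species_per_genus[0]), float(species_per_genus[1])
    else:
        mean, disp = None, None
    if mean is not None:
        extra = max(mean - 1.0, 0.0)
        if disp is None or extra == 0:
            counts = 1 + rng.poisson(extra, size=n_genera)
        else:
            p = disp / (disp + extra)
            counts = 1 + rng.negative_binomial(disp, p, size=n_genera)
    else:
        counts = np.asarray(species_per_genus, dtype=int)
        if len(counts) != n_genera or (counts < 1).any():
            raise ValueError("explicit species counts must give >= 1 per genus")

    # species tree: clone backbone, then attach polytomies
    sp_tree = dendropy.Tree(genus_tree)  # deep clone with own namespace copy
    sp_taxa = dendropy.TaxonNamespace()
    species_to_genus: dict[str, str] = {}
    for leaf in list(sp_tree.leaf_node_iter()):
        genus = leaf.taxon.label
        k = int(counts[genera.index(genus)])
        leaf.taxon = None
        if k == 1:
            sp = f"{genus}_sp1"
            leaf.edge.length += sub_depth
            leaf.taxon = sp_taxa.new_taxon(sp)
            species_to_genus[sp] = genus
        else:
            for j in range(k):
                sp = f"{genus}_sp{j + 1}"
                child = dendropy.Node()
                child.edge.length = sub_depth
                child.taxon = sp_taxa.new_taxon(sp)
                leaf.add_child(child)
                species_to_genus[sp] = genus
    sp_tree.taxon_namespace = sp_taxa

    # two major clades = the two subtrees at the backbone root
    root_children = genus_tree.seed_node.child_nodes()
    clade_of_genus: dict[str, str] = {}
    if len(root_children) >= 2:
        gymno = {lf.taxon.label for lf in root_children[0].leaf_iter()}
    else:
        gymno = set()
    for g in genera:
        clade_of_genus[g] = "gymnosperm" if g in gymno else "angiosperm"
    return Phylogeny(sp_tree, genus_tree, species_to_genus, clade_of_genus)


def brownian_tips(
    tree: dendropy.Tree,
    rate: float,
    rng: np.random.Generator,
    root_state: float = 0.0,
) -> pd.Series:
    """Brownian-motion tip values: each edge adds N(0, rate * length)."""
    values: dict[int, float] = {id(tree.seed_node): root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        parent = values[id(node.parent_node)]
        values[id(node)] = parent + rng.normal(0.0, np.sqrt(max(rate, 0.0) * length))
    out = {
        leaf.taxon.label: values[id(leaf)]
        for leaf in tree.leaf_node_iter()
    }
    return pd.Series(out).sort_index()


# --------------------------------------------------------------------------
# environment
# --------------------------------------------------------------------------

def simulate_environment(
    grid_shape: tuple[int, int],
    n_layers: int,
    corr_length: float,
    sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> EnvLayerStack:
    """Gaussian random fields: kernel-smoothed white noise, standardized.

    Smoothing uses a Gaussian kernel of scale ``corr_length`` with wrapped
    boundaries, so the lag-h autocorrelation is exp(-h^2 / (4 corr_length^2)).
    Each layer is standardized to mean 0 and standard deviation ``sd``.
    """
    from scipy.ndimage import gaussian_filter

    nrows, ncols = grid_shape
    if nrows < 1 or ncols < 1:
        raise ValueError("grid must have at least one cell")
    if corr_length < 0:
        raise ValueError("corr_length must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layers = np.empty((n_layers, nrows, ncols))
    for i in range(n_layers):
        white = rng.standard_normal((nrows, ncols))
        fld = gaussian_filter(white, sigma=corr_length, mode="wrap") if corr_length > 0 else white
        fld = fld - fld.mean()
        s = fld.std()
        layers[i] = (fld / s * sd) if (s > 0 and sd > 0) else np.zeros_like(fld)
    names = [f"env{i + 1}" for i in range(n_layers)]
    return EnvLayerStack(layers, names)


def proxy_climate_layers(
    env: EnvLayerStack,
    n_layers: int = 4,
    corr: float = 0.75,
    corr_length: float = 5.0,
    seed: int | np.random.Generator = 0,
    source_layer: int = 0,
) -> EnvLayerStack:
    """Separately-sourced climate layers for the occurrence models.

    The mortality and projection analyses use climate variables that are
    distinct from the layers entering the trait-imputation PCA — real
    predictors like maximum temperature or an aridity index are correlated
    with, but not identical to, the drivers of community composition. Each
    proxy is ``corr`` times the standardized source layer plus an
    independent smooth field, standardized to mean 0, sd 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    src = env.layers[source_layer]
    src = (src - src.mean()) / max(src.std(), 1e-12)
    noise = simulate_environment(env.grid_shape, n_layers, corr_length, 1.0, rng)
    mixed = corr * src[None, :, :] + np.sqrt(max(1 - corr**2, 0.0)) * noise.layers
    mixed -= mixed.mean(axis=(1, 2), keepdims=True)
    mixed /= mixed.std(axis=(1, 2), keepdims=True)
    names = [f"clim{i + 1}" for i in range(n_layers)]
    return EnvLayerStack(mixed, names)


def _categorical_layer(
    grid_shape: tuple[int, int],
    n_levels: int,
    corr_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spatially contiguous integer categories from a quantile-binned field."""
    fld = simulate_environment(grid_shape, 1, corr_length, 1.0, rng).layers[0]
    qs = np.quantile(fld, np.linspace(0, 1, n_levels + 1)[1:-1])
    return np.digitize(fld, qs)


# --------------------------------------------------------------------------
# niches and ranges
# --------------------------------------------------------------------------

@dataclass
class SpeciesRangeSet:
    """Per-species occupied cells on a reference grid (cell-index lists)."""

    grid_shape: tuple[int, int]
    cells: dict[str, np.ndarray]
    widened: list[str] = field(default_factory=list)
    optima: pd.Series | None = None

    @property
    def species(self) -> list[str]:
        return sorted(self.cells)


def simulate_niches_and_ranges(
    phylogeny: Phylogeny,
    env: EnvLayerStack,
    niche_signal: float = 0.5,
    niche_breadth: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> SpeciesRangeSet:
    """Ranges as the cells whose layer-1 value is within breadth of a niche
    optimum evolved on the tree.

    The optimum mixes a Brownian component (weight ``niche_signal``) with an
    independent normal deviate, standardized against layer 1's distribution
    so ranges land on the grid. Species whose range would be empty get their
    breadth widened to the nearest cell and are flagged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = env.layers[0].ravel()
    depth = max(tree_depth_of(phylogeny.tree), 1e-12)
    bm = brownian_tips(phylogeny.tree, 1.0 / depth, rng)  # unit variance at tips
    species = bm.index.to_numpy()
    iid = rng.standard_normal(len(species))
    s = float(np.clip(niche_signal, 0.0, 1.0))
    z = np.sqrt(s) * (bm.to_numpy() - bm.mean()) / max(bm.std(), 1e-12) + np.sqrt(1 - s) * iid
    optima = axis.mean() + axis.std() * z

    cells: dict[str, np.ndarray] = {}
    widened: list[str] = []
    dist = np.abs(axis[None, :] - optima[:, None])
    for i, sp in enumerate(species):
        occ = np.flatnonzero(dist[i] <= niche_breadth)
        if occ.size == 0:
            occ = np.array([int(np.argmin(dist[i]))])
            widened.append(sp)
        cells[sp] = occ
    return SpeciesRangeSet(env.grid_shape, cells, widened, pd.Series(optima, index=species))


def tree_depth_of(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


# --------------------------------------------------------------------------
# traits
# --------------------------------------------------------------------------

def simulate_traits(
    phylogeny: Phylogeny,
    species_env_means: pd.DataFrame,
    config: SyntheticWorldConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Ground-truth trait table: BM + linear environment + noise.

    P_min and P50 share a latent Brownian component with mixing weight
    ``trait_corr``, giving their phylogenetic parts that correlation. P88 is
    P50 minus a positive offset. Negativity of P50/P88 is enforced, if ever
    violated, by a recorded location shift (not truncation).
    """
    cfg = config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        cfg.seed if seed is None else seed
    )
    species = phylogeny.species
    if not set(species) <= set(species_env_means.index):
        missing = sorted(set(species) - set(species_env_means.index))
        raise ValueError(f"env means missing for species: {missing[:5]}...")
    env = species_env_means.loc[species]

    w = abs(cfg.trait_corr)
    sign = 1.0 if cfg.trait_corr >= 0 else -1.0
    shared = brownian_tips(phylogeny.tree, 1.0, rng).loc[species]
    own_min = brownian_tips(phylogeny.tree, 1.0, rng).loc[species]
    own_50 = brownian_tips(phylogeny.tree, 1.0, rng).loc[species]
    bm_min = np.sqrt(cfg.bm_rate_pmin) * (np.sqrt(w) * shared + np.sqrt(1 - w) * own_min)
    bm_50 = np.sqrt(cfg.bm_rate_p50) * (sign * np.sqrt(w) * shared + np.sqrt(1 - w) * own_50)

    beta = np.zeros(env.shape[1])
    beta[: len(cfg.env_effect)] = cfg.env_effect[: env.shape[1]]
    env_part = env.to_numpy() @ beta

    p_min = cfg.pmin_root + bm_min.to_numpy() + env_part + rng.normal(0, cfg.noise_sd, len(species))
    p_50 = cfg.p50_root + bm_50.to_numpy() + env_part + rng.normal(0, cfg.noise_sd, len(species))
    offset = np.abs(rng.normal(cfg.p88_offset_mean, 0.2 * cfg.p88_offset_mean, len(species)))
    shift_50 = max(0.0, p_50.max() + 0.1)
    p_50 = p_50 - shift_50
    p_88 = p_50 - offset
    shift_min = max(0.0, p_min.max() + 0.05)
    p_min = p_min - shift_min

    table = pd.DataFrame(
        {
            "genus": [phylogeny.species_to_genus[s] for s in species],
            "clade": [phylogeny.clade_of_species(s) for s in species],
            "p_min": p_min,
            "p50": p_50,
            "p88": p_88,
        },
        index=pd.Index(species, name="species"),
    )
    truth = {
        "env_effect": beta.tolist(),
        "trait_corr": cfg.trait_corr,
        "bm_rate_pmin": cfg.bm_rate_pmin,
        "bm_rate_p50": cfg.bm_rate_p50,
        "noise_sd": cfg.noise_sd,
        "p88_offset_mean": cfg.p88_offset_mean,
        "shift_p50": shift_50,
        "shift_pmin": shift_min,
        "pmin_root": cfg.pmin_root,
        "p50_root": cfg.p50_root,
    }
    return table, truth


def apply_missingness(
    truth: pd.DataFrame,
    observed_fraction: float,
    seed: int | np.random.Generator = 0,
    trait_columns: Sequence[str] = ("p_min", "p50", "p88"),
) -> pd.DataFrame:
    """Retain each trait cell independently with probability observed_fraction.

    Genus and clade columns are never masked. The observation mask is stored
    as boolean ``<trait>_observed`` columns.
    """
    if not (0 < observed_fraction <= 1):
        raise ValueError("observed_fraction must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = truth.copy()
    for col in trait_columns:
        keep = rng.random(len(out)) < observed_fraction
        out[col] = out[col].where(keep)
        out[f"{col}_observed"] = keep
    return out


# --------------------------------------------------------------------------
# mortality
# --------------------------------------------------------------------------

def simulate_mortality(
    assemblage,
    coefs: Mapping[str, float],
    seed: int | np.random.Generator = 0,
    occupancy=None,
    species: Sequence[str] | None = None,
    species_hsm: pd.Series | None = None,
    temperature: float = 3.0,
    max_species_per_event: int = 3,
) -> pd.DataFrame:
    """Bernoulli mortality per woody pixel from a logistic model on metrics.

    ``coefs`` maps metric layer names (plus "intercept") to logit-scale
    coefficients. A pixel is "woody" when richness >= 1. Each event is
    attributed to 1..k occupying species sampled with weight
    exp(-HSM / temperature) when occupancy and HSM are supplied.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nrows, ncols = assemblage.grid_shape
    eta = np.full(nrows * ncols, float(coefs.get("intercept", 0.0)))
    for name, c in coefs.items():
        if name == "intercept":
            continue
        if name not in assemblage:
            raise KeyError(f"metric {name!r} missing from assemblage grid")
        eta = eta + c * np.nan_to_num(assemblage[name].ravel(), nan=0.0)
    richness = (
        assemblage["richness"].ravel()
        if "richness" in assemblage
        else np.ones(nrows * ncols)
    )
    woody = richness >= 1
    prob = 1.0 / (1.0 + np.exp(-eta))
    events = woody & (rng.random(nrows * ncols) < prob)
    cells = np.flatnonzero(events)

    rows = []
    occ_csc = occupancy.tocsc() if occupancy is not None else None
    for cell in cells:
        r, c = cell_rowcol(cell, ncols)
        labels: list[str | None] = [None]
        if occ_csc is not None and species is not None and species_hsm is not None:
            idx = occ_csc.indices[occ_csc.indptr[cell]: occ_csc.indptr[cell + 1]]
            if idx.size:
                hsm = species_hsm.reindex([species[i] for i in idx]).to_numpy(dtype=float)
                wgt = np.exp(-np.nan_to_num(hsm, nan=0.0) / max(temperature, 1e-9))
                wgt = wgt / wgt.sum()
                k = int(rng.integers(1, min(max_species_per_event, idx.size) + 1))
                pick = rng.choice(idx, size=k, replace=False, p=wgt)
                labels = [species[i] for i in pick]
        for lab in labels:
            rows.append({"x": c + 0.5, "y": r + 0.5, "cell": int(cell), "species": lab})
    out = pd.DataFrame(rows, columns=["x", "y", "cell", "species"])
    out.attrs["truth_coefs"] = dict(coefs)
    out.attrs["event_rate_woody"] = float(events[woody].mean()) if woody.any() else 0.0
    return out


# --------------------------------------------------------------------------
# world assembly
# --------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    phylogeny: Phylogeny
    env: EnvLayerStack
    biome: np.ndarray
    pft: np.ndarray
    ranges: SpeciesRangeSet
    species_env_means: pd.DataFrame
    traits_truth: pd.DataFrame
    traits_observed: pd.DataFrame
    occupancy: object  # scipy.sparse species x cells
    assemblage: object  # AssemblageGrid on ground-truth HSM
    mortality: pd.DataFrame
    truth: dict


def simulate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Full deterministic world build from config.seed."""
    from . import assemblage as asm
    from . import envfeat

    cfg = config
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(7)]

    phylo = simulate_phylogeny(
        cfg.n_genera,
        (cfg.species_per_genus_mean, cfg.species_per_genus_dispersion),
        cfg.tree_depth,
        rngs[0],
    )
    env = simulate_environment(
        cfg.grid_shape, cfg.n_env_layers, cfg.env_corr_length, cfg.env_sd, rngs[1]
    )
    biome = _categorical_layer(cfg.grid_shape, cfg.n_biomes, cfg.env_corr_length, rngs[2])
    pft = _categorical_layer(cfg.grid_shape, cfg.n_pfts, cfg.env_corr_length, rngs[2])
    ranges = simulate_niches_and_ranges(
        phylo, env, cfg.niche_signal, cfg.niche_breadth, rngs[3]
    )
    env_means = envfeat.extract_species_env(env, ranges)
    truth_traits, truth = simulate_traits(phylo, env_means, cfg, rngs[4])
    observed = apply_missingness(truth_traits, cfg.observed_fraction, rngs[5])

    occupancy, species = asm.rasterize_ranges(ranges, cfg.grid_shape)
    from .impute import compute_hsm

    truth_hsm = compute_hsm(truth_traits)
    grid = asm.compute_assemblage_grid(occupancy, species, truth_hsm, cfg.grid_shape)
    mortality = simulate_mortality(
        grid,
        cfg.mortality_coefs,
        rngs[6],
        occupancy=occupancy,
        species=species,
        species_hsm=truth_hsm["hsm"],
        temperature=cfg.species_temperature,
    )
    truth = dict(truth)
    truth["mortality_coefs"] = dict(cfg.mortality_coefs)
    truth["config"] = asdict(cfg)
    truth["event_rate_woody"] = mortality.attrs.get("event_rate_woody", 0.0)
    return SyntheticWorld(
        cfg, phylo, env, biome, pft, ranges, env_means, truth_traits, observed,
        occupancy, grid, mortality, truth,
    )
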