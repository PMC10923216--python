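"""Synthetic multi-site amplicon communities with known ground truth.

The generator emulates a multi-site fish gill microbiota survey: a handful
of sites with unbalanced sample sizes, heavy-tailed compositional
abundances, variable sequencing depth (including a controlled fraction of
samples under the 10,000-count floor), a site-composition gradient with
correlated environmental covariates, planted indicator taxa, and per-site
latent-factor correlation modules that differ in connectivity between
sites.

Model: per sample, the latent log-abundance of each taxon is

    x = e_s * (mu + beta * g_s * v + shift_ind + sd * u)

where ``mu`` is a heavy-tailed taxon baseline, ``g_s`` the site's position
on the composition gradient, ``v`` a fixed taxon direction, ``shift_ind``
the log fold-change of planted indicators at their target site, ``e_s`` a
per-site evenness factor (>1 spreads log-abundances, lowering Pielou
evenness), and ``u`` a unit-variance deviation that is shared latent-factor
plus noise for taxa in an active correlation module and pure noise
otherwise.  Proportions are the softmax of ``x`` (logistic-normal), and
counts are multinomial at a lognormal depth.  The softmax closure induces
weak spurious negative correlation between unrelated taxa; with the default
community sizes this stays well below the 0.4 network edge threshold.

Every component draws from its own sub-stream of the root seed, so adding
one component never perturbs the draws of another.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    DistanceMatrix,
    FeatureTable,
    GillnetError,
    PhyloTree,
    SampleMetadata,
    TaxonomyMap,
)
from . import io as gio

__all__ = ["SimulationConfig", "ModuleSpec", "IndicatorSpec", "EnvVarSpec",
           "PlantedTruth", "SimulatedDataset", "simulate_tree",
           "simulate_communities", "scenario_presets", "write_dataset",
           "network_recovery_config", "DYSBIOTIC_SITE", "RESILIENT_SITE"]

LOW_DEPTH_FLOOR = 10_000


@dataclasses.dataclass
class IndicatorSpec:
    """A planted indicator: taxa enriched (by ``fold_change``) and forced
    present (at ``prevalence``) in one target site."""
    taxa: list
    site: str
    fold_change: float = 4.0
    prevalence: float = 0.9


@dataclasses.dataclass
class ModuleSpec:
    """A latent-factor correlation module.

    Taxa in the module share one latent factor wherever the module is
    active; ``signs`` (+1/-1 per taxon) set the loading signs, so opposite
    signs plant negative correlations.  ``target_rho`` is the absolute
    pairwise *Spearman* correlation of the latent log-abundances (the
    quantity the pipeline's rank correlations estimate); loadings are
    calibrated through the Gaussian rank-correlation identity
    rho_pearson = 2 sin(pi rho_spearman / 6).  ``sites=None`` means active
    everywhere.
    """
    taxa: list
    target_rho: float = 0.7
    signs: list | None = None
    sites: list | None = None


@dataclasses.dataclass
class EnvVarSpec:
    """An environmental covariate loading on the site gradient."""
    name: str
    loading: float
    noise_sd: float
    offset: float = 0.0
    scale: float = 1.0
    nonnegative: bool = False


@dataclasses.dataclass
class SimulationConfig:
    seed: int = 0
    n_sites: int = 5
    samples_per_site: list = dataclasses.field(
        default_factory=lambda: [10, 10, 10, 10, 10])
    n_taxa: int = 60
    depth_lognormal: tuple = (np.log(20_000.0), 0.4)
    fraction_low_depth: float = 0.0
    site_effect_size: float = 0.0
    gradient: list | None = None
    base_log_sd: float = 1.2
    sample_noise_sd: float = 1.0
    evenness_factor: list | None = None
    module_abundance_boost: float = 1.0
    indicator_abundance_boost: float = 0.5
    taxa_per_genus: int = 2
    indicator_spec: list = dataclasses.field(default_factory=list)
    module_spec: list = dataclasses.field(default_factory=list)
    env_spec: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if self.n_sites < 1 or self.n_taxa < 3:
            raise GillnetError("need at least 1 site and 3 taxa")
        if len(self.samples_per_site) != self.n_sites:
            raise GillnetError("samples_per_site length must equal n_sites")
        if any(n < 1 for n in self.samples_per_site):
            raise GillnetError("every site needs at least one sample")
        if self.gradient is None:
            if self.n_sites == 1:
                self.gradient = [0.0]
            else:
                self.gradient = list(np.linspace(-1.5, 1.5, self.n_sites))
        if len(self.gradient) != self.n_sites:
            raise GillnetError("gradient length must equal n_sites")
        if self.evenness_factor is None:
            self.evenness_factor = [1.0] * self.n_sites
        if len(self.evenness_factor) != self.n_sites:
            raise GillnetError("evenness_factor length must equal n_sites")
        if not 0.0 <= self.fraction_low_depth < 1.0:
            raise GillnetError("fraction_low_depth must be in [0, 1)")
        for spec in self.indicator_spec:
            if spec.fold_change <= 1.0:
                raise GillnetError("indicator fold_change must exceed 1")
        for spec in self.module_spec:
            if not 0.0 < spec.target_rho < 1.0:
                raise GillnetError("module target_rho must be in (0, 1)")
        # a taxon may not be both a planted indicator and a module member:
        # the two plants prescribe conflicting distributions
        ind_taxa = {t for s in self.indicator_spec for t in s.taxa}
        mod_taxa = [t for s in self.module_spec for t in s.taxa]
        if len(mod_taxa) != len(set(mod_taxa)):
            raise GillnetError("a taxon appears in more than one module")
        clash = ind_taxa & set(mod_taxa)
        if clash:
            raise GillnetError(
                f"taxa planted both as indicator and module member: {sorted(clash)[:5]}")

    @property
    def site_names(self) -> list:
        return [f"site{i + 1}" for i in range(self.n_sites)]

    @property
    def taxon_names(self) -> list:
        return [f"asv{i:04d}" for i in range(self.n_taxa)]


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth emitted alongside a simulated dataset."""

    indicators: list               # (taxon, site) pairs
    module_edges: list             # (genus_a, genus_b, sign, sites or None)
    env_loadings: dict             # variable -> loading on the gradient
    gradient: dict                 # site -> gradient position
    evenness_factor: dict          # site -> factor (>1 = less even)
    taxon_to_genus: dict
    site_of_sample: dict

    def true_edge_set(self, site: str) -> set:
        edges = set()
        for a, b, sign, sites in self.module_edges:
            if sites is None or site in sites:
                edges.add((min(a, b), max(a, b), sign))
        return edges

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)


@dataclasses.dataclass
class SimulatedDataset:
    table: FeatureTable
    taxonomy: TaxonomyMap
    metadata: SampleMetadata
    tree: PhyloTree
    truth: PlantedTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int | None = None,
                  labels: Sequence[str] | None = None,
                  branch_scale: float = 0.1):
    """Random bifurcating rooted tree by sequential random joins.

    Branch lengths are exponential with mean ``branch_scale``.  Returns
    ``(tree, distance_matrix)`` where the matrix holds the tree's leaf path
    distances — an additive metric by construction, so neighbor joining
    must invert it exactly.
    """
    if n_taxa < 3:
        raise GillnetError("need at least 3 taxa for a tree")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"asv{i:04d}" for i in range(n_taxa)]
    frags = list(labels)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        li, lj = rng.exponential(branch_scale, size=2)
        merged = f"({frags[i]}:{li:.12g},{frags[j]}:{lj:.12g})"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    tree = PhyloTree.from_newick(frags[0] + ";")
    return tree, tree.path_distance_matrix()


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------

def _substreams(seed: int) -> dict:
    names = ("tree", "baseline", "direction", "factors", "noise", "depth",
             "env", "indicators", "taxonomy", "morphometrics")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child)
            for name, child in zip(names, children)}


def _assign_taxonomy(config: SimulationConfig) -> tuple[TaxonomyMap, dict]:
    """Synthetic lineages; module and indicator taxa get their own genus so
    that planted structure survives genus-level aggregation."""
    taxa = config.taxon_names
    special = [t for spec in config.module_spec for t in spec.taxa]
    special += [t for spec in config.indicator_spec for t in spec.taxa]
    special_set = set(special)
    genus_of: dict = {}
    counter = 0
    for taxon in taxa:
        if taxon in special_set:
            genus_of[taxon] = f"Genus_{counter:04d}"
            counter += 1
    pending = [t for t in taxa if t not in special_set]
    for i in range(0, len(pending), max(config.taxa_per_genus, 1)):
        name = f"Genus_{counter:04d}"
        counter += 1
        for taxon in pending[i:i + max(config.taxa_per_genus, 1)]:
            genus_of[taxon] = name
    genera = sorted(set(genus_of.values()))
    family_of = {g: f"Family_{i // 5:03d}" for i, g in enumerate(genera)}
    phylum_of = {g: f"Phylum_{i % 8:02d}" for i, g in enumerate(genera)}
    rows = {}
    for taxon in taxa:
        g = genus_of[taxon]
        rows[taxon] = {
            "kingdom": "Kingdom_00",
            "phylum": phylum_of[g],
            "class": f"Class_{int(phylum_of[g][-2:]):02d}",
            "order": f"Order_{int(family_of[g][-3:]) // 2:03d}",
            "family": family_of[g],
            "genus": g,
            "species": f"{g}_sp_{taxon}",
        }
    return TaxonomyMap(pd.DataFrame.from_dict(rows, orient="index")), genus_of


def _draw_depths(rng: np.random.Generator, n: int, meanlog: float,
                 sdlog: float, fraction_low: float) -> np.ndarray:
    depths = np.maximum(np.round(rng.lognormal(meanlog, sdlog, size=n)), 1)
    if fraction_low <= 0:
        return depths.astype(int)
    n_low = int(round(fraction_low * n))
    low_idx = rng.choice(n, size=n_low, replace=False)
    low_mask = np.zeros(n, dtype=bool)
    low_mask[low_idx] = True
    for i in range(n):
        want_low = low_mask[i]
        d = depths[i]
        for _ in range(1000):
            if (d < LOW_DEPTH_FLOOR) == want_low:
                break
            d = max(round(rng.lognormal(meanlog, sdlog)), 1)
        else:  # conditioning failed; force deterministically
            d = LOW_DEPTH_FLOOR // 2 if want_low else LOW_DEPTH_FLOOR
        depths[i] = d
    return depths.astype(int)


def simulate_communities(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full dataset (counts, taxonomy, metadata, tree) plus truth."""
    rngs = _substreams(config.seed)
    taxa = config.taxon_names
    sites = config.site_names
    n_taxa = config.n_taxa
    taxon_index = {t: i for i, t in enumerate(taxa)}

    for spec in config.indicator_spec:
        if spec.site not in sites:
            raise GillnetError(f"indicator site {spec.site!r} unknown")
        for t in spec.taxa:
            if t not in taxon_index:
                raise GillnetError(f"indicator taxon {t!r} unknown")
    for spec in config.module_spec:
        for t in spec.taxa:
            if t not in taxon_index:
                raise GillnetError(f"module taxon {t!r} unknown")
        if spec.sites is not None:
            unknown = set(spec.sites) - set(sites)
            if unknown:
                raise GillnetError(f"module site(s) unknown: {sorted(unknown)}")

    tree, _ = simulate_tree(
        n_taxa, seed=int(rngs["tree"].integers(2 ** 31)), labels=taxa)
    taxonomy, genus_of = _assign_taxonomy(config)

    # taxon baselines (heavy-tailed across taxa) and gradient direction
    mu = rngs["baseline"].normal(0.0, config.base_log_sd, size=n_taxa)
    for spec in config.module_spec:
        for t in spec.taxa:
            mu[taxon_index[t]] += config.module_abundance_boost
    for spec in config.indicator_spec:
        for t in spec.taxa:
            mu[taxon_index[t]] += config.indicator_abundance_boost
    # gradient responses model congeneric strain replacement: within each
    # background genus the loadings are bounded and sum to zero, so the
    # sequence-level composition turns over along the gradient while
    # genus-level site means stay flat — planted indicators remain the only
    # genus-level site signal.  Planted (module/indicator) taxa do not
    # respond to the gradient at all.
    special_taxa = {t for spec in config.module_spec for t in spec.taxa}
    special_taxa |= {t for spec in config.indicator_spec for t in spec.taxa}
    v = np.zeros(n_taxa)
    members_of: dict = {}
    for t in taxa:
        members_of.setdefault(genus_of[t], []).append(t)
    for genus in sorted(members_of):
        members = [t for t in members_of[genus] if t not in special_taxa]
        if len(members) < 2:
            continue
        mags = rngs["direction"].uniform(0.5, 1.0, size=len(members))
        signs = np.array([1 if i % 2 == 0 else -1
                          for i in range(len(members))], dtype=float)
        load = mags * signs
        # abundance-weighted zero-sum: the genus total stays flat (to first
        # order) even when one strain dominates the genus
        weights = np.exp([mu[taxon_index[t]] for t in members])
        load -= float(weights @ load) / float(weights.sum())
        for t, w in zip(members, load):
            v[taxon_index[t]] = w

    # per-module loading magnitude achieving the target latent correlation
    loadings = np.zeros(n_taxa)
    factor_of = np.full(n_taxa, -1)
    active_sites: list = []
    for m, spec in enumerate(config.module_spec):
        rho_pearson = 2.0 * np.sin(np.pi * spec.target_rho / 6.0)
        lam = np.sqrt(rho_pearson / (1.0 - rho_pearson))
        signs = spec.signs if spec.signs is not None else [1] * len(spec.taxa)
        if len(signs) != len(spec.taxa):
            raise GillnetError("module signs length must match taxa length")
        for t, s in zip(spec.taxa, signs):
            loadings[taxon_index[t]] = lam * (1 if s >= 0 else -1)
            factor_of[taxon_index[t]] = m
        active_sites.append(None if spec.sites is None else set(spec.sites))

    sample_ids = []
    site_of = {}
    for s, name in enumerate(sites):
        for r in range(config.samples_per_site[s]):
            sid = f"{name}_s{r + 1:03d}"
            sample_ids.append(sid)
            site_of[sid] = name
    n_samples = len(sample_ids)

    # latent log-abundances
    noise_rng = rngs["noise"]
    factor_rng = rngs["factors"]
    counts = np.zeros((n_taxa, n_samples))
    latent = np.zeros((n_taxa, n_samples))
    for j, sid in enumerate(sample_ids):
        s = sites.index(site_of[sid])
        eps = noise_rng.normal(0.0, 1.0, size=n_taxa)
        fvals = factor_rng.normal(0.0, 1.0, size=max(len(config.module_spec), 1))
        u = eps.copy()
        for m in range(len(config.module_spec)):
            here = (active_sites[m] is None) or (sites[s] in active_sites[m])
            members = factor_of == m
            if here:
                lam = np.abs(loadings[members])
                sgn = np.sign(loadings[members])
                u[members] = ((sgn * lam * fvals[m] + eps[members])
                              / np.sqrt(lam ** 2 + 1.0))
        x = mu + config.site_effect_size * config.gradient[s] * v
        for spec in config.indicator_spec:
            if spec.site == sites[s]:
                for t in spec.taxa:
                    x = x.copy()
                    x[taxon_index[t]] += np.log(spec.fold_change)
        x = config.evenness_factor[s] * (x + config.sample_noise_sd * u)
        latent[:, j] = x

    depth_rng = rngs["depth"]
    depths = _draw_depths(depth_rng, n_samples, config.depth_lognormal[0],
                          config.depth_lognormal[1], config.fraction_low_depth)
    for j in range(n_samples):
        z = latent[:, j] - latent[:, j].max()
        p = np.exp(z)
        p /= p.sum()
        counts[:, j] = depth_rng.multinomial(depths[j], p)

    # force indicator prevalence at the target site
    ind_rng = rngs["indicators"]
    for spec in config.indicator_spec:
        cols = [j for j, sid in enumerate(sample_ids)
                if site_of[sid] == spec.site]
        n_force = int(round(spec.prevalence * len(cols)))
        chosen = ind_rng.choice(len(cols), size=n_force, replace=False)
        for t in spec.taxa:
            ti = taxon_index[t]
            for c in chosen:
                if counts[ti, cols[c]] == 0:
                    counts[ti, cols[c]] = 1

    table = FeatureTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))

    # metadata: gradient-driven environment plus fish morphometrics
    env_rng = rngs["env"]
    morpho_rng = rngs["morphometrics"]
    meta_rows = {}
    for j, sid in enumerate(sample_ids):
        s = sites.index(site_of[sid])
        g = config.gradient[s]
        row = {
            "community": sites[s],
            "location": f"{sites[s]}_loc",
            "water_type": "Freshwater" if s % 2 == 0 else "Saltwater",
            "latitude": round(60.0 - 3.0 * g, 3),
            "longitude": round(-100.0 + 8.0 * s, 3),
        }
        for spec in config.env_spec:
            val = spec.offset + spec.scale * (
                spec.loading * g + env_rng.normal(0.0, spec.noise_sd))
            if spec.nonnegative:
                val = max(val, 0.0)
            row[spec.name] = round(val, 4)
        weight = morpho_rng.lognormal(np.log(900.0), 0.25)
        k_true = morpho_rng.normal(1.13, 0.08)
        row["weight"] = round(weight, 1)
        row["fork_length"] = round((100.0 * weight / max(k_true, 0.5)) ** (1 / 3), 2)
        meta_rows[sid] = row
    metadata = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))

    module_edges = []
    for m, spec in enumerate(config.module_spec):
        signs = spec.signs if spec.signs is not None else [1] * len(spec.taxa)
        for a in range(len(spec.taxa)):
            for b in range(a + 1, len(spec.taxa)):
                ga = genus_of[spec.taxa[a]]
                gb = genus_of[spec.taxa[b]]
                sign = 1 if signs[a] * signs[b] > 0 else -1
                module_edges.append(
                    (min(ga, gb), max(ga, gb), sign,
                     None if spec.sites is None else sorted(spec.sites)))
    truth = PlantedTruth(
        indicators=[(t, spec.site) for spec in config.indicator_spec
                    for t in spec.taxa],
        module_edges=module_edges,
        env_loadings={spec.name: spec.loading for spec in config.env_spec},
        gradient=dict(zip(sites, map(float, config.gradient))),
        evenness_factor=dict(zip(sites, map(float, config.evenness_factor))),
        taxon_to_genus=genus_of,
        site_of_sample=site_of,
    )
    return SimulatedDataset(table=table, taxonomy=taxonomy, metadata=metadata,
                            tree=tree, truth=truth, config=config)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_DEFAULT_ENV = [
    EnvVarSpec("air_temperature", loading=0.9, noise_sd=0.3, offset=6.0, scale=5.0),
    EnvVarSpec("water_temperature", loading=0.8, noise_sd=0.5, offset=6.0, scale=3.0),
    EnvVarSpec("salinity", loading=0.5, noise_sd=0.8, offset=15.0, scale=8.0,
               nonnegative=True),
    EnvVarSpec("pH", loading=0.3, noise_sd=0.8, offset=7.8, scale=0.3),
    EnvVarSpec("chlorophyll_a", loading=0.2, noise_sd=0.8, offset=1.5, scale=1.0,
               nonnegative=True),
    EnvVarSpec("O2_concentration", loading=-0.6, noise_sd=0.6, offset=10.0,
               scale=2.0, nonnegative=True),
]

STUDY_SAMPLES_PER_SITE = [63, 24, 13, 25, 15]


def scenario_presets(name: str, seed: int = 20240801) -> SimulationConfig:
    """Named, fully specified simulation scenarios.

    ``null``: five balanced sites with no site effect, no indicators and no
    modules — the type-I-error scenario.  ``biogeography``: the unbalanced
    study design with a diffuse composition gradient, gradient-loaded
    environment and twelve planted indicator taxa.  ``dysbiosis``: the same
    design with correlation modules at every site except one planted
    dysbiotic site (which also gets an evenness penalty), and extra modules
    at one densely connected resilient site.
    """
    if name == "null":
        return SimulationConfig(
            seed=seed, n_sites=5, samples_per_site=[10] * 5, n_taxa=60,
            depth_lognormal=(float(np.log(20_000.0)), 0.4),
            fraction_low_depth=0.0, site_effect_size=0.0,
            sample_noise_sd=1.0, base_log_sd=1.2,
            env_spec=[dataclasses.replace(e) for e in _DEFAULT_ENV],
        )
    if name == "biogeography":
        taxa = [f"asv{i:04d}" for i in range(150)]
        per_site = (2, 2, 2, 2, 4)  # most indicators at the last site
        indicators = []
        cursor = 0
        for s, count in enumerate(per_site):
            for _ in range(count):
                indicators.append(IndicatorSpec(
                    taxa=[taxa[cursor]], site=f"site{s + 1}",
                    fold_change=4.0, prevalence=0.9))
                cursor += 1
        return SimulationConfig(
            seed=seed, n_sites=5,
            samples_per_site=list(STUDY_SAMPLES_PER_SITE), n_taxa=150,
            depth_lognormal=(float(np.log(30_000.0)), 0.4),
            fraction_low_depth=4 / 140, site_effect_size=0.45,
            sample_noise_sd=0.5, base_log_sd=1.2,
            taxa_per_genus=6,  # background genera aggregate several ASVs
            indicator_spec=indicators,
            env_spec=[dataclasses.replace(e) for e in _DEFAULT_ENV],
        )
    if name == "dysbiosis":
        taxa = [f"asv{i:04d}" for i in range(140)]
        healthy = ["site1", "site3", "site4", "site5"]
        modules = []
        # tight guilds (latent |rho| = 0.9) so that module edges stay
        # recoverable after FDR over ~7,000 pairs even at the smallest site;
        # one module in five carries an anti-correlated member, putting the
        # negative-edge fraction near the few percent typical of gill
        # co-activity networks
        for m in range(8):  # shared across all healthy sites
            members = taxa[m * 10:(m + 1) * 10]
            signs = ([-1] + [1] * 9) if m % 5 == 0 else [1] * 10
            modules.append(ModuleSpec(
                taxa=members, target_rho=0.9, signs=signs,
                sites=list(healthy)))
        for m in range(8, 10):  # extra density at the resilient site
            members = taxa[m * 10:(m + 1) * 10]
            modules.append(ModuleSpec(
                taxa=members, target_rho=0.9, signs=[1] * 10,
                sites=["site1"]))
        return SimulationConfig(
            seed=seed, n_sites=5,
            samples_per_site=list(STUDY_SAMPLES_PER_SITE), n_taxa=140,
            depth_lognormal=(float(np.log(30_000.0)), 0.35),
            fraction_low_depth=4 / 140, site_effect_size=0.25,
            sample_noise_sd=1.0, base_log_sd=1.2,
            module_abundance_boost=2.0,  # module taxa are the active guilds
            evenness_factor=[1.0, 1.7, 1.0, 1.0, 1.0],  # site2 planted dysbiotic
            module_spec=modules,
            env_spec=[dataclasses.replace(e) for e in _DEFAULT_ENV],
        )
    raise GillnetError(f"unknown scenario preset: {name!r}")


DYSBIOTIC_SITE = "site2"
RESILIENT_SITE = "site1"


def network_recovery_config(seed: int, target_rho: float = 0.7,
                            n_samples: int = 30) -> SimulationConfig:
    """Single-site benchmark for co-activity edge recovery.

    Two 8-taxon modules (one containing anti-correlated members) with
    planted rank correlation ``target_rho`` among ``n_samples`` samples,
    inside a large aggregated background (240 taxa, 28 strains per
    background genus) that keeps compositional-closure correlations well
    under the 0.4 edge threshold.
    """
    taxa = [f"asv{i:04d}" for i in range(240)]
    modules = [
        ModuleSpec(taxa=taxa[0:8], target_rho=target_rho, signs=[1] * 8),
        ModuleSpec(taxa=taxa[8:16], target_rho=target_rho,
                   signs=[-1, 1, 1, 1, -1, 1, 1, 1]),
    ]
    return SimulationConfig(
        seed=seed, n_sites=1, samples_per_site=[n_samples], n_taxa=240,
        depth_lognormal=(float(np.log(100_000.0)), 0.3),
        module_spec=modules, module_abundance_boost=0.5,
        base_log_sd=0.8, taxa_per_genus=28)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict:
    """Write the dataset in the pipeline's input formats; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "feature_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    gio.write_feature_table(dataset.table, paths["table"])
    gio.write_taxonomy(dataset.taxonomy, paths["taxonomy"])
    gio.write_metadata(dataset.metadata, paths["metadata"])
    gio.write_tree(dataset.tree, paths["tree"])
    paths["truth"].write_text(dataset.truth.to_json(indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
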