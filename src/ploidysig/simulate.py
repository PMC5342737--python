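"""Synthetic cross-species expression data with planted ploidy signal.

The generator emulates the statistical structure the analysis assumes: a
log2-additive model per gene ``x = mu_g + tau_g*T + sigma_g*S + delta_g*P + eps``
with ±1 factor codings for tissue (T), species (S) and ploidy class (P), a
dominant shared baseline, a planted ploidy-responsive gene subset enriched for
a planted interactome, annotated gene modules, and a clique-structured
interaction graph.  The reciprocal design plants polyploidy in species A heart
and species B liver, mirroring the human/mouse heart-liver contrast in which
species- and tissue-specific effects cancel between the two comparisons.

Every artifact draws from its own RNG stream spawned from the master seed, so
adding an artifact never perturbs the others, and identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import (
    EdgeList,
    ExpressionMatrix,
    GeneSetCollection,
    OrthologTable,
    SampleSheet,
    edge_list_from_records,
)

SPECIES = ("HS", "MM")
TISSUES = ("heart", "liver")

# (species, tissue) -> ploidy class under the reciprocal design
RECIPROCAL_PLOIDY = {
    ("HS", "heart"): "polyploid",
    ("HS", "liver"): "diploid",
    ("MM", "heart"): "diploid",
    ("MM", "liver"): "polyploid",
}


@dataclass
class SynthConfig:
    """Parameters of the generative model (all effect sizes in log2 units)."""

    n_genes: int = 5000
    reps_per_condition: int = 4
    mu_sd: float = 2.0          # spread of gene baselines (shared component)
    tissue_sd: float = 1.0
    species_sd: float = 0.25
    ploidy_delta: float = 1.0   # planted effect magnitude
    frac_ploidy_up: float = 0.025
    frac_ploidy_down: float = 0.025
    noise_sd: float = 0.5
    interactome_frac: float = 0.19   # background interactome rate
    interactome_odds: float = 4.0    # odds ratio planted vs non-planted
    n_terms: int = 50
    term_size: int = 40
    planted_term_count: int = 5
    edge_cliques: int = 2
    clique_size: int = 5
    edge_noise: int = 200
    seed: int = 0

    def validate(self) -> None:
        c = self
        if c.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if c.reps_per_condition < 1:
            raise ConfigError("reps_per_condition must be >= 1")
        for name in ("mu_sd", "tissue_sd", "species_sd", "ploidy_delta", "noise_sd"):
            if getattr(c, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("frac_ploidy_up", "frac_ploidy_down"):
            v = getattr(c, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if c.frac_ploidy_up + c.frac_ploidy_down >= 1:
            raise ConfigError("frac_ploidy_up + frac_ploidy_down must be < 1")
        if not 0 < c.interactome_frac < 1:
            raise ConfigError("interactome_frac must be in (0, 1)")
        if c.interactome_odds <= 0:
            raise ConfigError("interactome_odds must be > 0")
        if c.term_size > c.n_genes:
            raise ConfigError("term_size must not exceed n_genes")
        if c.planted_term_count > c.n_terms:
            raise ConfigError("planted_term_count must not exceed n_terms")
        for name in ("n_terms", "term_size", "planted_term_count",
                     "edge_cliques", "clique_size", "edge_noise"):
            if getattr(c, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if c.edge_cliques * c.clique_size > c.n_genes:
            raise ConfigError("edge_cliques * clique_size must not exceed n_genes")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown synthetic config keys {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SynthTruth:
    """Planted ground truth used by the recovery tests."""

    ploidy_up: frozenset
    ploidy_down: frozenset
    interactome: frozenset
    planted_terms: frozenset = frozenset()
    planted_cliques: list = field(default_factory=list)
    universe: tuple = ()

    def to_json_dict(self) -> dict:
        return {
            "ploidy_up": sorted(self.ploidy_up),
            "ploidy_down": sorted(self.ploidy_down),
            "interactome": sorted(self.interactome),
            "planted_terms": sorted(self.planted_terms),
            "planted_cliques": [sorted(c) for c in self.planted_cliques],
            "universe": list(self.universe),
        }


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------

_STREAMS = ("baseline", "truth", "noise", "interactome", "terms", "edges")


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _group_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def _planted_indices(cfg: SynthConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Indices of up- and down-planted genes; shared stream so the
    cross-species and two-condition datasets plant the same genes."""
    n_up = round(cfg.frac_ploidy_up * cfg.n_genes)
    n_down = round(cfg.frac_ploidy_down * cfg.n_genes)
    perm = rng.permutation(cfg.n_genes)
    return np.sort(perm[:n_up]), np.sort(perm[n_up:n_up + n_down])


def _delta_vector(cfg: SynthConfig, up_idx, down_idx) -> np.ndarray:
    delta = np.zeros(cfg.n_genes)
    delta[up_idx] = cfg.ploidy_delta
    delta[down_idx] = -cfg.ploidy_delta
    return delta


def _draw_interactome(cfg: SynthConfig, planted_mask: np.ndarray, rng) -> np.ndarray:
    """Bernoulli membership with background rate interactome_frac and odds
    ratio interactome_odds for planted genes."""
    p0 = cfg.interactome_frac
    odds1 = cfg.interactome_odds * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    probs = np.where(planted_mask, p1, p0)
    return rng.random(cfg.n_genes) < probs


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_cross_species_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, SampleSheet, OrthologTable, SynthTruth]:
    """Simulate the four-condition reciprocal heart/liver design.

    Matrix rows are ortholog group ids (the shared universe); the returned
    ortholog table maps each group to per-species gene ids.
    """
    config.validate()
    rng = _streams(config.seed)
    genes = _group_ids(config.n_genes)

    mu = rng["baseline"].normal(0.0, config.mu_sd, config.n_genes) + 8.0
    tau = rng["baseline"].normal(0.0, config.tissue_sd, config.n_genes)
    sig = rng["baseline"].normal(0.0, config.species_sd, config.n_genes)

    up_idx, down_idx = _planted_indices(config, rng["truth"])
    delta = _delta_vector(config, up_idx, down_idx)
    planted = np.zeros(config.n_genes, bool)
    planted[up_idx] = planted[down_idx] = True
    member = _draw_interactome(config, planted, rng["interactome"])

    columns, rows = [], []
    data = {}
    for species in SPECIES:
        for tissue in TISSUES:
            t_code = +1 if tissue == "heart" else -1
            s_code = +1 if species == "HS" else -1
            ploidy = RECIPROCAL_PLOIDY[(species, tissue)]
            p_code = +1 if ploidy == "polyploid" else -1
            mean = mu + tau * t_code + sig * s_code + delta * p_code
            for rep in range(1, config.reps_per_condition + 1):
                sid = f"{species}_{tissue}_r{rep}"
                eps = rng["noise"].normal(0.0, config.noise_sd, config.n_genes)
                data[sid] = mean + eps
                columns.append(sid)
                rows.append((sid, species, tissue, ploidy, rep))

    matrix = ExpressionMatrix(pd.DataFrame(data, index=genes))
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "species", "tissue", "ploidy_class", "replicate"]
    ))
    orth = OrthologTable(pd.DataFrame({
        "group_id": genes,
        "gene_a": [f"HS_{g}" for g in genes],
        "gene_b": [f"MM_{g}" for g in genes],
    }))
    truth = SynthTruth(
        ploidy_up=frozenset(genes[i] for i in up_idx),
        ploidy_down=frozenset(genes[i] for i in down_idx),
        interactome=frozenset(g for g, m in zip(genes, member) if m),
        universe=tuple(genes),
    )
    return matrix, sheet, orth, truth


def generate_two_condition_dataset(
    config: SynthConfig,
) -> tuple[ExpressionMatrix, SampleSheet, SynthTruth]:
    """Simulate a purified 2n-vs-4n dataset (decidua-like, one tissue).

    Rows are species-B gene ids (``MM_G…``) so the dataset maps onto the
    cross-species ortholog table generated from the same config; the planted
    gene indices coincide with the cross-species dataset at the same seed.
    """
    config.validate()
    rng = _streams(config.seed)
    groups = _group_ids(config.n_genes)
    genes = [f"MM_{g}" for g in groups]

    # independent baseline stream position from the cross-species call is not
    # needed: the two datasets represent different experiments
    mu = rng["baseline"].normal(0.0, config.mu_sd, config.n_genes) + 8.0
    up_idx, down_idx = _planted_indices(config, rng["truth"])
    delta = _delta_vector(config, up_idx, down_idx)
    planted = np.zeros(config.n_genes, bool)
    planted[up_idx] = planted[down_idx] = True
    member = _draw_interactome(config, planted, rng["interactome"])

    data, rows = {}, []
    for ploidy, p_code in (("diploid", -1), ("polyploid", +1)):
        label = "2n" if ploidy == "diploid" else "4n"
        for rep in range(1, config.reps_per_condition + 1):
            sid = f"MM_decidua_{label}_r{rep}"
            eps = rng["noise"].normal(0.0, config.noise_sd, config.n_genes)
            data[sid] = mu + delta * p_code + eps
            rows.append((sid, "MM", "decidua", ploidy, rep))

    matrix = ExpressionMatrix(pd.DataFrame(data, index=genes))
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "species", "tissue", "ploidy_class", "replicate"]
    ))
    truth = SynthTruth(
        ploidy_up=frozenset(genes[i] for i in up_idx),
        ploidy_down=frozenset(genes[i] for i in down_idx),
        interactome=frozenset(g for g, m in zip(genes, member) if m),
        universe=tuple(genes),
    )
    return matrix, sheet, truth


def generate_annotations_and_network(
    config: SynthConfig, truth: SynthTruth
) -> tuple[GeneSetCollection, EdgeList]:
    """Gene-set annotations and a clique-structured weighted edge list.

    ``planted_term_count`` terms draw >=80% of members from the planted
    ploidy-responsive genes; cliques (weight 0.95) are placed on planted
    up-genes when possible, noise edges get weights uniform on [0.4, 0.9].
    """
    config.validate()
    if not truth.universe:
        raise ConfigError("truth carries no gene universe")
    rng = _streams(config.seed)
    universe = list(truth.universe)
    planted = sorted(truth.ploidy_up | truth.ploidy_down)

    terms: dict = {}
    t_rng = rng["terms"]
    n_from_planted = int(np.ceil(0.8 * config.term_size))
    for i in range(1, config.n_terms + 1):
        term = f"T{i:03d}"
        if i <= config.planted_term_count and len(planted) >= n_from_planted:
            core = list(t_rng.choice(planted, n_from_planted, replace=False))
            rest_pool = [g for g in universe if g not in set(core)]
            rest = list(t_rng.choice(rest_pool, config.term_size - n_from_planted,
                                     replace=False))
            members = core + rest
            desc = "planted ploidy module"
        else:
            members = list(t_rng.choice(universe, config.term_size, replace=False))
            desc = "background module"
        terms[term] = (desc, frozenset(members))
    collection = GeneSetCollection(terms)
    planted_terms = frozenset(
        f"T{i:03d}" for i in range(1, config.planted_term_count + 1)
        if len(planted) >= n_from_planted
    )

    e_rng = rng["edges"]
    records, cliques = [], []
    clique_pool = sorted(truth.ploidy_up) if len(truth.ploidy_up) >= (
        config.edge_cliques * config.clique_size) else universe
    chosen = e_rng.choice(len(clique_pool),
                          config.edge_cliques * config.clique_size, replace=False)
    for c in range(config.edge_cliques):
        nodes = [clique_pool[j] for j in
                 chosen[c * config.clique_size:(c + 1) * config.clique_size]]
        cliques.append(frozenset(nodes))
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                records.append((nodes[i], nodes[j], 0.95))
    n_noise = 0
    clique_pairs = {tuple(sorted(p)) for r in records for p in [(r[0], r[1])]}
    while n_noise < config.edge_noise:
        a, b = e_rng.choice(len(universe), 2, replace=False)
        pair = tuple(sorted((universe[a], universe[b])))
        if pair in clique_pairs:
            continue
        w = e_rng.uniform(0.4, 0.9)
        records.append((pair[0], pair[1], w))
        clique_pairs.add(pair)
        n_noise += 1
    edges = edge_list_from_records(records)
    return collection, edges, planted_terms, cliques


def generate_annotations(config: SynthConfig, truth: SynthTruth):
    """Convenience wrapper returning (collection, edges) and an updated truth."""
    collection, edges, planted_terms, cliques = generate_annotations_and_network(
        config, truth
    )
    new_truth = SynthTruth(
        ploidy_up=truth.ploidy_up,
        ploidy_down=truth.ploidy_down,
        interactome=truth.interactome,
        planted_terms=planted_terms,
        planted_cliques=list(cliques),
        universe=truth.universe,
    )
    return collection, edges, new_truth
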