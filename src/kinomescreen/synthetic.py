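"""Ground-truth generators for every pipeline stage.

The screen generator emulates a kinome-wide plate-based RNAi screen: 96-well
plates carrying 714 genes x 3 siRNA duplexes, four images per well averaging
~700 cells, a baseline mitotic index of 5%, multiplicative log-normal plate
effects on cell counts, spiked low-/high-MI hit genes (41 at x0.2 and 50 at
x3 by default), one strong positive-control well per plate (a Plk1-like
mitotic-arrest phenotype) and untreated / lipofectant-only negative controls.
Counts are Poisson by default (negative binomial behind a flag); the DAPI
intensity is proportional to the DAPI count with multiplicative noise so the
first-percentile intensity filter removes genuinely sparse wells.

Companion generators produce two-channel fluorescence image pairs with
planted nuclei, scale-free typed interactomes with optionally planted
modules, and flat annotation tables with planted enriched terms. Every
generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import io as kio
from .exceptions import ConfigError, PlacementError

__all__ = [
    "ControlConfig",
    "ScreenConfig",
    "InteractomeConfig",
    "PlantedModule",
    "generate_screen",
    "generate_image_pair",
    "generate_interactome",
    "generate_annotations",
    "default_fer_crkl_module",
]


# ---------------------------------------------------------------------------
# Screen generator


@dataclass(frozen=True)
class ControlConfig:
    """Per-plate control wells.

    ``positive_effect`` multiplies the baseline MI in positive-control wells
    (a Plk1-like siRNA arrests cells in mitosis, so the MI rises several
    fold); negative controls sit at baseline.
    """

    n_positive: int = 1
    n_negative_untreated: int = 1
    n_negative_lipo: int = 1
    positive_effect: float = 4.0

    @property
    def n_wells(self) -> int:
        return self.n_positive + self.n_negative_untreated + self.n_negative_lipo


@dataclass(frozen=True)
class ScreenConfig:
    n_genes: int = 714
    duplexes_per_gene: int = 3
    images_per_well: int = 4
    wells_per_plate: int = 96
    mean_cells_per_image: float = 700.0
    baseline_mi: float = 0.05
    plate_effect_sd: float = 0.1
    count_noise: str = "poisson"  # or "negbin"
    negbin_dispersion: float = 0.1
    n_low_hits: int = 41
    low_effect: float = 0.2
    n_high_hits: int = 50
    high_effect: float = 3.0
    intensity_gain: float = 10.0
    intensity_noise_sd: float = 0.05
    controls: ControlConfig = field(default_factory=ControlConfig)
    seed: int = 0

    def __post_init__(self):
        if self.low_effect <= 0 or self.high_effect <= 0:
            raise ConfigError("effect multipliers must be positive")
        if self.n_low_hits + self.n_high_hits > self.n_genes:
            raise ConfigError("planted hits exceed the number of genes")
        if not 0 < self.baseline_mi < 1:
            raise ConfigError("baseline_mi must lie in (0, 1)")
        if self.count_noise not in ("poisson", "negbin"):
            raise ConfigError("count_noise must be 'poisson' or 'negbin'")
        if self.controls.n_wells >= self.wells_per_plate:
            raise ConfigError("controls leave no sample wells on a plate")


def _well_ids(n_wells: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOP"
    ids = [f"{r}{c:02d}" for r, c in itertools.product(letters, range(1, 13))]
    return ids[:n_wells]


def _draw_counts(rng: np.random.Generator, lam: np.ndarray, config: ScreenConfig) -> np.ndarray:
    if config.count_noise == "poisson":
        return rng.poisson(lam)
    shape = 1.0 / config.negbin_dispersion
    return rng.poisson(rng.gamma(shape, lam / shape))


def generate_screen(
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one full screen.

    Returns ``(layout, measurements, truth)``. The truth table records each
    gene's MI multiplier, hit status and group; the layout and measurement
    tables round-trip through :mod:`kinomescreen.io` unchanged.
    """
    config = config or ScreenConfig()
    rng = np.random.default_rng(config.seed)

    genes = [f"KIN{i:04d}" for i in range(1, config.n_genes + 1)]
    hit_idx = rng.choice(config.n_genes, config.n_low_hits + config.n_high_hits, replace=False)
    multiplier = np.ones(config.n_genes)
    multiplier[hit_idx[: config.n_low_hits]] = config.low_effect
    multiplier[hit_idx[config.n_low_hits:]] = config.high_effect
    group = np.full(config.n_genes, "none", dtype=object)
    group[hit_idx[: config.n_low_hits]] = "low"
    group[hit_idx[config.n_low_hits:]] = "high"
    truth = pd.DataFrame(
        {
            "gene_symbol": genes,
            "mi_multiplier": multiplier,
            "is_hit": group != "none",
            "group": group,
        }
    )

    ctrl = config.controls
    samples_per_plate = config.wells_per_plate - ctrl.n_wells
    n_sample_wells = config.n_genes * config.duplexes_per_gene
    n_plates = math.ceil(n_sample_wells / samples_per_plate)
    well_ids = _well_ids(config.wells_per_plate)

    sample_iter = iter(
        (gene, f"{gene}_d{d}")
        for gene in genes
        for d in range(1, config.duplexes_per_gene + 1)
    )
    layout_rows = []
    for p in range(1, n_plates + 1):
        plate = f"P{p:02d}"
        roles = (
            [kio.POSITIVE_CONTROL] * ctrl.n_positive
            + [kio.NEGATIVE_CONTROL_UNTREATED] * ctrl.n_negative_untreated
            + [kio.NEGATIVE_CONTROL_LIPO] * ctrl.n_negative_lipo
        )
        for well, role in zip(well_ids, roles):
            layout_rows.append((plate, well, "", "", role))
        for well in well_ids[len(roles):]:
            nxt = next(sample_iter, None)
            if nxt is None:
                layout_rows.append((plate, well, "", "", kio.EMPTY))
            else:
                gene, duplex = nxt
                layout_rows.append((plate, well, gene, duplex, kio.SAMPLE))
    layout = pd.DataFrame(
        layout_rows, columns=["plate_id", "well_id", "gene_symbol", "duplex_id", "role"]
    )

    plate_effect = np.exp(rng.normal(0.0, config.plate_effect_sd, n_plates))
    plate_effect_map = {f"P{p:02d}": plate_effect[p - 1] for p in range(1, n_plates + 1)}
    mult_map = dict(zip(genes, multiplier))

    wells = layout.loc[layout["role"] != kio.EMPTY].reset_index(drop=True)
    well_mult = np.ones(len(wells))
    is_sample = wells["role"] == kio.SAMPLE
    well_mult[is_sample.to_numpy()] = wells.loc[is_sample, "gene_symbol"].map(mult_map)
    well_mult[(wells["role"] == kio.POSITIVE_CONTROL).to_numpy()] = ctrl.positive_effect

    reps = config.images_per_well
    meas = wells.loc[wells.index.repeat(reps)].reset_index(drop=True)
    meas["image_index"] = np.tile(np.arange(1, reps + 1), len(wells))
    lam = (
        config.mean_cells_per_image
        * meas["plate_id"].map(plate_effect_map).to_numpy()
    )
    dapi = _draw_counts(rng, lam, config)
    mi = config.baseline_mi * np.repeat(well_mult, reps)
    ph3 = rng.poisson(dapi * mi)
    intensity = (
        dapi
        * config.intensity_gain
        * np.exp(rng.normal(0.0, config.intensity_noise_sd, len(meas)))
    )
    measurements = pd.DataFrame(
        {
            "plate_id": meas["plate_id"],
            "well_id": meas["well_id"],
            "image_index": meas["image_index"],
            "dapi_count": dapi.astype(int),
            "dapi_intensity": np.round(intensity, 3),
            "ph3_count": ph3.astype(int),
        }
    )
    return layout, measurements, truth


# ---------------------------------------------------------------------------
# Image pairs


def generate_image_pair(
    n_nuclei: int,
    n_mitotic: int,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    spot_sigma: float = 3.0,
    spot_amplitude: float = 180.0,
    background_level: float = 20.0,
    gradient_strength: float = 0.5,
    noise_sd: float = 2.0,
    min_distance: float | None = None,
    max_tries: int = 200_000,
):
    """Two-channel image with planted, non-touching Gaussian nuclei.

    The DAPI channel carries ``n_nuclei`` spots on a smooth uneven
    illumination field (linear ramp scaled by ``gradient_strength``); the
    pH3 channel lights a random subset of ``n_mitotic`` of them on a dimmer
    field. Spot centers are rejection-sampled with a minimum pairwise
    distance (default ``6 * spot_sigma``) so planted counts are exact ground
    truth. Returns ``(dapi, ph3, truth)`` with truth holding both centroid
    arrays. ``(0, 0)`` yields blank (all-zero) images.
    """
    if n_mitotic > n_nuclei:
        raise ConfigError("n_mitotic cannot exceed n_nuclei")
    h, w = shape
    if n_nuclei == 0:
        empty = np.zeros(shape)
        return empty, empty.copy(), {
            "nuclei_centers": np.empty((0, 2)),
            "mitotic_centers": np.empty((0, 2)),
        }
    rng = np.random.default_rng(seed)
    min_distance = 6.0 * spot_sigma if min_distance is None else min_distance
    margin = 4.0 * spot_sigma
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n_nuclei} non-touching objects in {shape}"
            )
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_distance**2 for r0, c0 in centers):
            centers.append((r, c))
    centers_arr = np.array(centers)
    mitotic_idx = rng.choice(n_nuclei, n_mitotic, replace=False)

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    ramp = (rows / h + cols / w) / 2.0
    dapi = background_level * (1.0 + gradient_strength * ramp)
    ph3 = 0.5 * background_level * (1.0 + gradient_strength * (1.0 - ramp))

    def _stamp(img, center):
        r0, c0 = center
        rad = int(math.ceil(4 * spot_sigma))
        rlo, rhi = int(r0) - rad, int(r0) + rad + 1
        clo, chi = int(c0) - rad, int(c0) + rad + 1
        rr = np.arange(max(rlo, 0), min(rhi, h))[:, None]
        cc = np.arange(max(clo, 0), min(chi, w))[None, :]
        img[max(rlo, 0): min(rhi, h), max(clo, 0): min(chi, w)] += (
            spot_amplitude
            * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * spot_sigma**2))
        )

    for center in centers:
        _stamp(dapi, center)
    for i in mitotic_idx:
        _stamp(ph3, centers[i])
    dapi = np.clip(dapi + rng.normal(0, noise_sd, shape), 0, None)
    ph3 = np.clip(ph3 + rng.normal(0, noise_sd, shape), 0, None)
    truth = {
        "nuclei_centers": centers_arr,
        "mitotic_centers": centers_arr[np.sort(mitotic_idx)],
    }
    return dapi, ph3, truth


# ---------------------------------------------------------------------------
# Interactomes


@dataclass(frozen=True)
class PlantedModule:
    """Two seed kinases wired to a common set of partner proteins."""

    seeds: tuple[str, str]
    partners: tuple[str, ...]

    def protein_names(self) -> list[str]:
        return [*self.seeds, *self.partners]


def default_fer_crkl_module() -> PlantedModule:
    """The receptor module used throughout the tests: two cytosolic tyrosine
    kinases jointly wired to three EGF-receptor-family members."""
    return PlantedModule(seeds=("CRKL", "FER"), partners=("EGFR", "ERBB2", "ERBB3"))


@dataclass(frozen=True)
class InteractomeConfig:
    n_proteins: int = 2000
    attachment_m: int = 2
    relation_mix: tuple[float, float, float, float] = (0.45, 0.2, 0.2, 0.15)
    planted_modules: tuple[PlantedModule, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.attachment_m < 1:
            raise ConfigError("attachment_m must be >= 1")
        if abs(sum(self.relation_mix) - 1.0) > 1e-9:
            raise ConfigError("relation_mix must sum to 1")
        named = {p for m in self.planted_modules for p in m.protein_names()}
        if len(named) > self.n_proteins:
            raise ConfigError("planted modules name more proteins than n_proteins")


def generate_interactome(
    config: InteractomeConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Scale-free typed interactome via preferential attachment.

    A Barabasi-Albert backbone (``n_proteins`` nodes, ``attachment_m`` edges
    per arriving node) gives the heavy-tailed degree sequence; each backbone
    edge draws its relation class from ``relation_mix``. Planted modules are
    wired exactly as specified (class ``interacting_phospho``) on named
    nodes chosen at random, overriding colliding backbone edges. Returns
    ``(interactions, truth)`` where truth records the node-name assignment,
    backbone edge count and planted edges.
    """
    config = config or InteractomeConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    graph = nx.barabasi_albert_graph(n, config.attachment_m, seed=int(rng.integers(2**31)))

    names = {i: f"P{i:04d}" for i in range(n)}
    named = []
    for module in config.planted_modules:
        named.extend(module.protein_names())
    if named:
        chosen = rng.choice(n, len(named), replace=False)
        for node, name in zip(chosen, named):
            names[int(node)] = name.upper()
    name_of = {v: k for k, v in names.items()}

    relation_names = [kio.RELATION_NAMES[c] for c in (1, 2, 3, 4)]
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    classes = rng.choice(4, size=len(edges), p=config.relation_mix)
    records = {
        (names[u], names[v]) if names[u] <= names[v] else (names[v], names[u]):
            relation_names[c]
        for (u, v), c in zip(edges, classes)
    }
    planted_edges = []
    for module in config.planted_modules:
        for seed_name in module.seeds:
            for partner in module.partners:
                a, b = sorted((seed_name.upper(), partner.upper()))
                records[(a, b)] = "interacting_phospho"
                planted_edges.append((a, b))
    interactions = pd.DataFrame(
        [(s, t, r) for (s, t), r in sorted(records.items())],
        columns=["source", "target", "relation"],
    )
    truth = {
        "names": names,
        "node_of_name": name_of,
        "n_backbone_edges": len(edges),
        "planted_edges": planted_edges,
        "planted_modules": list(config.planted_modules),
    }
    return interactions, truth


# ---------------------------------------------------------------------------
# Annotations


def generate_annotations(
    universe,
    planted,
    seed: int = 0,
    n_background_terms: int = 20,
    background_annotation_rate: float = 0.08,
    namespace: str = "biological_process",
) -> tuple[pd.DataFrame, dict]:
    """Flat annotation table with planted enriched terms.

    ``planted`` is a list of ``(term_id, gene_subset, background_rate)``:
    the term annotates its subset fully, plus every other universe gene
    independently with ``background_rate``. ``n_background_terms``
    uninformative terms annotate genes uniformly at
    ``background_annotation_rate``. Returns ``(annotations, truth)``.
    """
    uni = [str(g).upper() for g in universe]
    uni_set = set(uni)
    rng = np.random.default_rng(seed)
    rows = []
    truth_terms = {}
    for term_id, subset, bg_rate in planted:
        subset = [str(g).upper() for g in subset]
        missing = sorted(set(subset) - uni_set)
        if missing:
            raise ConfigError(f"planted genes outside universe: {', '.join(missing)}")
        annotated = set(subset)
        others = [g for g in uni if g not in annotated]
        if bg_rate > 0 and others:
            extra = np.array(others)[rng.random(len(others)) < bg_rate]
            annotated |= set(extra.tolist())
        for g in sorted(annotated):
            rows.append((g, term_id, f"planted term {term_id}", namespace))
        truth_terms[term_id] = sorted(annotated)
    for i in range(1, n_background_terms + 1):
        term_id = f"BG{i:04d}"
        mask = rng.random(len(uni)) < background_annotation_rate
        for g in np.array(uni)[mask]:
            rows.append((g, term_id, f"background term {i}", namespace))
        truth_terms[term_id] = sorted(np.array(uni)[mask].tolist())
    annotations = pd.DataFrame(
        rows, columns=["gene_symbol", "term_id", "term_name", "namespace"]
    )
    return annotations, {"terms": truth_terms}
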