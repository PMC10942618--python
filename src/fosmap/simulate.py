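"""Synthetic study generator with planted structure.

Emulates the statistical shape of a whole-brain c-Fos pairing study in
prairie voles: a balanced 2-sex x 2-partner-type x 4-timepoint x 6-block
design of co-housed pairs, overdispersed (negative-binomial) region counts
with pairing effects planted in a subset of "bonding" regions organized
into clusters, cluster-correlated noise, an ejaculation-coupled latent
shared within mate pairs, behavior measures tied to the same quantities,
and a connectivity matrix denser within planted clusters.

Every generator is a pure function of (config, seed) and returns its
ground truth alongside the data, so downstream recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .core import (
    AnimalDesign,
    AtlasNode,
    AtlasTree,
    BehaviorTable,
    ConnectivityMatrix,
    CountMatrix,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "generate_atlas",
    "generate_design",
    "generate_behavior",
    "generate_counts",
    "generate_connectivity",
    "generate_dataset",
    "null_config",
    "coordination_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic data-generating process.

    Defaults mirror the study design (12 pairs per partner-type x
    timepoint cell, 6 blocks -> 192 animals) and a planted bonding network
    of 7 clusters x 4 regions among 68 leaf regions. Effect sizes are on
    the log-mean scale of the count model; ``dispersion`` is the
    negative-binomial size parameter theta (count variance =
    mu + mu^2/theta). ``partner_effect``/``quad_time_effect`` are sized so
    a single region's parametric model-comparison test has power ~0.9 at
    the study's sample size (see docs/methods.md for the calibration).
    """

    seed: int = 0
    n_major_clusters: int = 7
    rois_per_cluster: int = 4
    extra_null_rois: int = 40
    pairs_per_cell: int = 12
    n_blocks: int = 6
    baseline_log_mean: float = math.log(50.0)
    dispersion: float = 8.0
    partner_effect: float = 0.16
    quad_time_effect: float = 0.16
    cluster_noise_sd: float = 0.5
    pair_factor_scale: float = 0.25
    pair_latent_jitter: float = 0.2
    ejac_rate: float = 6.0
    within_density_mean: float = 0.3
    between_density_mean: float = 0.05
    conn_noise_sd: float = 0.05
    nuisance_scale: float | None = None  # defaults to 0.1 * partner_effect

    def __post_init__(self):
        for name in ("dispersion",):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in (
            "cluster_noise_sd",
            "pair_factor_scale",
            "pair_latent_jitter",
            "ejac_rate",
            "conn_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 <= self.between_density_mean <= 1 and 0 <= self.within_density_mean <= 1):
            raise ValidationError("density means must lie in [0, 1]")
        if self.within_density_mean < self.between_density_mean:
            raise ValidationError(
                "within_density_mean must be >= between_density_mean for planted modularity"
            )
        if self.n_major_clusters < 1 or self.rois_per_cluster < 2:
            raise ValidationError("need n_major_clusters >= 1 and rois_per_cluster >= 2")
        if self.pairs_per_cell % 2 != 0:
            raise ValidationError(
                "pairs_per_cell must be even (sibling pairs split into FF and MM halves)"
            )

    @property
    def nuisance(self) -> float:
        return 0.1 * self.partner_effect if self.nuisance_scale is None else self.nuisance_scale

    def to_dict(self) -> dict:
        return asdict(self)


def null_config(seed: int = 0, n_rois: int = 200, **overrides) -> SimulationConfig:
    """A global-null configuration: no planted effects of any kind.

    All regions are exchangeable under partner-label permutation, which is
    the construction used for type-I-error calibration.
    """
    return SimulationConfig(
        seed=seed,
        n_major_clusters=1,
        rois_per_cluster=2,
        extra_null_rois=n_rois - 2,
        partner_effect=0.0,
        quad_time_effect=0.0,
        cluster_noise_sd=0.0,
        pair_factor_scale=0.0,
        **overrides,
    )


def coordination_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A shared-factor configuration emphasizing within-pair coordination.

    A strong ejaculation-coupled latent is shared by the two members of a
    mate pair while other noise sources are kept small, so the within-pair
    count correlation in bonding regions is high and collapses once
    ejaculation counts are partialed out.
    """
    return SimulationConfig(
        seed=seed,
        pairs_per_cell=50,
        pair_factor_scale=0.33,
        pair_latent_jitter=0.05,
        cluster_noise_sd=0.04,
        dispersion=60.0,
        baseline_log_mean=math.log(80.0),
        **overrides,
    )


# ---------------------------------------------------------------------------


def generate_atlas(config: SimulationConfig) -> tuple[AtlasTree, dict[str, int]]:
    """Three-level atlas: root -> cluster parents -> leaf ROIs, plus null leaves.

    Returns the tree and the planted leaf -> cluster map (bonding leaves
    only; null leaves hang off a separate 'background' parent and carry no
    cluster label).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    nodes = [AtlasNode("root", "root", "whole brain", None, 10_000_000)]
    cluster_map: dict[str, int] = {}
    for c in range(config.n_major_clusters):
        parent = f"C{c + 1}"
        nodes.append(AtlasNode(parent, parent, f"planted cluster {c + 1}", "root", 100_000))
        for r in range(config.rois_per_cluster):
            leaf = f"{parent}_R{r + 1}"
            vol = int(rng.integers(500, 5000))
            nodes.append(AtlasNode(leaf, leaf, f"bonding region {leaf}", parent, vol))
            cluster_map[leaf] = c + 1
    if config.extra_null_rois:
        nodes.append(AtlasNode("BG", "BG", "background regions", "root", 1_000_000))
        for r in range(config.extra_null_rois):
            leaf = f"N{r + 1}"
            vol = int(rng.integers(500, 5000))
            nodes.append(AtlasNode(leaf, leaf, f"null region {leaf}", "BG", vol))
    return AtlasTree(nodes), cluster_map


def generate_design(config: SimulationConfig) -> list[AnimalDesign]:
    """Balanced paired design.

    Per timepoint: ``pairs_per_cell`` mate pairs (one F + one M each) and
    ``pairs_per_cell`` sibling pairs (half FF, half MM), distributed
    round-robin over blocks.
    """
    rows: list[AnimalDesign] = []
    for t in (1, 2, 3, 4):
        pair_idx = 0
        for m in range(config.pairs_per_cell):
            block = (pair_idx % config.n_blocks) + 1
            pid = f"T{t}_mate{m + 1}"
            rows.append(AnimalDesign(f"{pid}_F", "F", "mate", t, block, pid))
            rows.append(AnimalDesign(f"{pid}_M", "M", "mate", t, block, pid))
            pair_idx += 1
        for s in range(config.pairs_per_cell):
            block = (pair_idx % config.n_blocks) + 1
            sex = "F" if s < config.pairs_per_cell // 2 else "M"
            pid = f"T{t}_sib{s + 1}"
            rows.append(AnimalDesign(f"{pid}_a", sex, "sibling", t, block, pid))
            rows.append(AnimalDesign(f"{pid}_b", sex, "sibling", t, block, pid))
            pair_idx += 1
    return rows


def _pair_table(design: list[AnimalDesign]) -> pd.DataFrame:
    recs = {}
    for r in design:
        recs.setdefault(r.pair_id, {"partner": r.partner, "timepoint": r.timepoint})
    return pd.DataFrame.from_dict(recs, orient="index")


def generate_behavior(
    design: list[AnimalDesign], config: SimulationConfig
) -> tuple[BehaviorTable, dict]:
    """Behavior measures tied to partner status, timepoint and mating.

    Ejaculation counts are Poisson(``ejac_rate``) for mate pairs at the
    2.5 and 6 hr timepoints and exactly zero otherwise (mating is rare at
    0 and 22 hr, and absent in same-sex sibling pairs). The remaining
    measures are linear-Gaussian functions of partner status, the
    bond-formation window, and the pair's ejaculation count.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    pairs = _pair_table(design)
    mating = (pairs["partner"] == "mate") & pairs["timepoint"].isin([2, 3])
    ejac = pd.Series(0, index=pairs.index, dtype=int)
    ejac[mating] = rng.poisson(config.ejac_rate, size=int(mating.sum()))

    rows = []
    for r in design:
        e = float(ejac[r.pair_id])
        is_mate = 1.0 if r.partner == "mate" else 0.0
        window = 1.0 if r.timepoint in (2, 3) else 0.0
        rows.append(
            {
                "animal_id": r.animal_id,
                "velocity": 10.0 + 1.0 * is_mate + rng.normal(0, 2.0),
                "net_move": (0.5 if r.sex == "M" else -0.5) * is_mate + rng.normal(0, 1.0),
                "approach": 5.0 + 2.0 * is_mate * window + 0.2 * e + rng.normal(0, 1.5),
                "usv_count": 20.0 + 15.0 * is_mate + 1.0 * e + rng.normal(0, 5.0),
                "mount": 2.0 * is_mate * window + 0.5 * e + abs(rng.normal(0, 0.5)),
                "huddle": 15.0 + 5.0 * is_mate * (1 - window) + rng.normal(0, 3.0),
                "ejaculation": e,
            }
        )
    df = pd.DataFrame(rows).set_index("animal_id")
    levels = {
        "velocity": "individual",
        "net_move": "individual",
        "approach": "individual",
        "usv_count": "dyad",
        "mount": "dyad",
        "huddle": "dyad",
        "ejaculation": "dyad",
    }
    # dyad-level measures: average the two members' draws so both carry one value
    pair_of = {r.animal_id: r.pair_id for r in design}
    pid_series = pd.Series({a: pair_of[a] for a in df.index})
    for m, lvl in levels.items():
        if lvl == "dyad":
            df[m] = df.groupby(pid_series)[m].transform("mean")
    df["ejaculation"] = df["ejaculation"].round().astype(float)
    truth = {"ejaculations": ejac.to_dict()}
    return BehaviorTable(df, levels), truth


def generate_counts(
    design: list[AnimalDesign],
    atlas: AtlasTree,
    cluster_map: dict[str, int],
    behavior: BehaviorTable,
    config: SimulationConfig,
) -> tuple[CountMatrix, dict]:
    """Negative-binomial counts with planted pairing effects.

    Log-mean for animal i at region r:

        eta = baseline + nuisance(sex, timepoint, block)
              + [bonding r, mates only]  partner_effect
                                         + quad_time_effect * 1{t in {2,3}}
                                         + shared pair term
              + cluster/idiosyncratic noise

    The shared pair term is ``pair_factor_scale * (z_e + jitter * u_p)``
    where z_e is the pair's ejaculation count standardized across mate
    pairs and u_p ~ N(0,1) is a per-pair latent: both members of a mate
    pair receive the same value in every bonding region, which is what
    makes within-pair counts correlate and makes that correlation collapse
    when ejaculation is partialed out. Bonding regions in the same planted
    cluster additionally share a per-animal cluster latent scaled by
    ``cluster_noise_sd``; null regions get an independent per-animal noise
    of the same scale. Counts are NB(mean=exp(eta), size=dispersion).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    bonding = sorted(cluster_map, key=lambda k: (cluster_map[k], k))
    null_rois = [l for l in atlas.leaves() if l not in cluster_map]
    rois = bonding + null_rois
    n = len(design)
    ns = config.nuisance

    sex = np.array([1.0 if r.sex == "M" else 0.0 for r in design])
    T = np.array([float(r.timepoint) for r in design])
    block = np.array([float(r.block) for r in design])
    mate = np.array([1.0 if r.partner == "mate" else 0.0 for r in design])
    window = np.isin(T, (2.0, 3.0)).astype(float)

    base = (
        config.baseline_log_mean
        + ns * sex
        + ns * (T - 2.5) / 2.0
        + ns * ((T - 2.5) ** 2 - 1.25) / 2.0
        + ns * (block - (1 + config.n_blocks) / 2.0) / config.n_blocks
    )

    # shared pair term (mates only, every bonding region)
    pair_ids = [r.pair_id for r in design]
    upairs = sorted(set(pair_ids))
    mate_pairs = sorted({r.pair_id for r in design if r.partner == "mate"})
    ej = behavior.df["ejaculation"]
    pair_ej = {p: 0.0 for p in upairs}
    for r in design:
        pair_ej[r.pair_id] = float(ej[r.animal_id])
    ev = np.array([pair_ej[p] for p in mate_pairs])
    z = (ev - ev.mean()) / ev.std() if ev.std() > 0 else np.zeros_like(ev)
    u = rng.normal(size=len(mate_pairs))
    shared = dict(
        zip(mate_pairs, config.pair_factor_scale * (z + config.pair_latent_jitter * u))
    )
    pair_term = np.array([shared.get(p, 0.0) for p in pair_ids])

    eta = np.tile(base[:, None], (1, len(rois)))
    clusters = sorted(set(cluster_map.values()))
    cl_latent = rng.normal(scale=config.cluster_noise_sd, size=(n, len(clusters)))
    cl_index = {c: k for k, c in enumerate(clusters)}
    for j, roi in enumerate(bonding):
        eta[:, j] += mate * (config.partner_effect + config.quad_time_effect * window)
        eta[:, j] += mate * pair_term
        eta[:, j] += cl_latent[:, cl_index[cluster_map[roi]]]
    if null_rois:
        eta[:, len(bonding):] += rng.normal(
            scale=config.cluster_noise_sd, size=(n, len(null_rois))
        )

    mu = np.exp(eta)
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    cm = CountMatrix(
        pd.DataFrame(counts, index=[r.animal_id for r in design], columns=rois)
    )
    truth = {
        "bonding_rois": bonding,
        "null_rois": null_rois,
        "cluster_map": dict(cluster_map),
        "pair_shared_term": {p: float(v) for p, v in shared.items()},
        "ejaculation_z": dict(zip(mate_pairs, map(float, z))),
    }
    return cm, truth


def generate_connectivity(
    atlas: AtlasTree, cluster_map: dict[str, int], config: SimulationConfig
) -> ConnectivityMatrix:
    """Leaf-by-leaf density matrix denser within planted clusters.

    density(i, j), i != j, is Normal(within|between mean, conn_noise_sd)
    clipped to [0, 1] depending on whether i and j share a planted
    cluster; the diagonal is the NaN sentinel consumers must skip.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    rois = sorted(cluster_map, key=lambda k: (cluster_map[k], k)) + [
        l for l in atlas.leaves() if l not in cluster_map
    ]
    m = len(rois)
    labels = np.array([cluster_map.get(r, 0) for r in rois])
    same = (labels[:, None] == labels[None, :]) & (labels[:, None] > 0)
    mean = np.where(same, config.within_density_mean, config.between_density_mean)
    dens = mean + rng.normal(scale=config.conn_noise_sd, size=(m, m)) if config.conn_noise_sd else mean.astype(float).copy()
    dens = np.clip(dens, 0.0, 1.0)
    np.fill_diagonal(dens, np.nan)
    return ConnectivityMatrix(pd.DataFrame(dens, index=rois, columns=rois))


def generate_dataset(config: SimulationConfig) -> dict:
    """All five inputs plus the planted truth, keyed by name."""
    atlas, cluster_map = generate_atlas(config)
    design = generate_design(config)
    behavior, btruth = generate_behavior(design, config)
    counts, ctruth = generate_counts(design, atlas, cluster_map, behavior, config)
    conn = generate_connectivity(atlas, cluster_map, config)
    truth = {**ctruth, **btruth, "config": config.to_dict()}
    return {
        "atlas": atlas,
        "design": design,
        "behavior": behavior,
        "counts": counts,
        "connectivity": conn,
        "truth": truth,
    }
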