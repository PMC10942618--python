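"""End-to-end pipeline: simulate -> screen -> select -> cluster -> connectivity
-> CCA -> pair similarity, as one reproducible seeded run.

A single root seed is split deterministically per stage (so a stage rerun
in isolation with its own seed reproduces the full run's result). All
stage outputs are written as CSV next to a JSON run report; identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .behavior import cca, pair_similarity, partial_pair_similarity
from .cluster import (
    activity_profiles,
    cluster_connectivity_test,
    nmds_embed,
    ward_cluster,
)
from .core import FosmapError, ValidationError, load_atlas, save_atlas
from .glm import permutation_screen
from .selection import select_exclusive_rois
from .simulate import SimulationConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("fosmap")

_STAGES = ("simulate", "screen", "select", "cluster", "connectivity", "cca", "pairsim")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "fosmap_run"
    #: simulation parameters (used when the simulate stage is enabled)
    simulation: dict = field(default_factory=dict)
    #: input paths (used when simulate is disabled): atlas, design, counts,
    #: behavior, connectivity
    inputs: dict = field(default_factory=dict)
    n_perm: int = 10_000
    q_threshold: float = 0.1
    k_clusters: int = 8
    alpha: float = 0.05
    #: timepoints pooled as the bond-formation window
    timepoints: tuple[int, ...] = (2, 3)
    exclude_clusters: tuple[int, ...] = ()
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if not 0 < self.q_threshold < 1:
            raise ValidationError("q_threshold must lie in (0, 1)")
        for s in self.stages:
            if s not in _STAGES:
                raise ValidationError(f"unknown stage {s!r}")
        self.stages = {s: self.stages.get(s, True) for s in _STAGES}
        self.timepoints = tuple(self.timepoints)
        self.exclude_clusters = tuple(self.exclude_clusters)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValidationError(f"bad run config: {exc}") from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        d["exclude_clusters"] = list(self.exclude_clusters)
        return d


def _stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage 31-bit seed derived from the root seed."""
    h = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _require(report: dict, stage: str, needed: str):
    if needed not in report["stages"]:
        raise FosmapError(
            f"stage {stage!r} requires output of disabled/missing stage {needed!r}"
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir")  # hash the analysis parameters, not the destination
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    report: dict = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "stages": {},
    }
    log.info("run seed=%s config_hash=%s", config.seed, report["config_hash"])

    truth = None
    try:
        # ------------------------------------------------------- simulate/load
        if config.stages["simulate"]:
            sim_cfg = SimulationConfig(
                **{"seed": _stage_seed(config.seed, "simulate"), **config.simulation}
            )
            data = generate_dataset(sim_cfg)
            atlas, design = data["atlas"], data["design"]
            counts, behavior, conn = data["counts"], data["behavior"], data["connectivity"]
            truth = data["truth"]
            save_atlas(atlas, out / "atlas.json")
            fio.write_design(design, out / "design.csv")
            fio.write_counts(counts, out / "counts.csv")
            fio.write_behavior(behavior, out / "behavior.csv")
            fio.write_connectivity(conn, out / "connectivity.csv")
            with open(out / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(truth, fh, indent=1, sort_keys=True)
            report["stages"]["simulate"] = {
                "n_animals": len(design),
                "n_rois": counts.shape[1],
                "n_bonding_rois": len(truth["bonding_rois"]),
            }
        else:
            atlas = load_atlas(config.inputs["atlas"])
            design = fio.read_design(config.inputs["design"])
            counts = fio.read_counts(config.inputs["counts"])
            behavior = fio.read_behavior(config.inputs["behavior"]) if "behavior" in config.inputs else None
            conn = fio.read_connectivity(config.inputs["connectivity"]) if "connectivity" in config.inputs else None
            tpath = config.inputs.get("truth")
            if tpath:
                truth = json.loads(Path(tpath).read_text())
            report["stages"]["load"] = {"n_animals": len(design), "n_rois": counts.shape[1]}

        # ------------------------------------------------------------- screen
        if config.stages["screen"]:
            screen, skipped = permutation_screen(
                counts, design, n_perm=config.n_perm, seed=_stage_seed(config.seed, "screen")
            )
            sdf = pd.DataFrame(
                {
                    "roi_id": [r.roi_id for r in screen],
                    "f_stat": [r.f_stat for r in screen],
                    "direction": [r.direction for r in screen],
                    "p_perm": [r.p_perm for r in screen],
                    "q_value": [r.q_value for r in screen],
                }
            )
            sdf.to_csv(out / "screen.csv", index=False)
            n_sig = int((sdf["q_value"] < config.q_threshold).sum())
            block = {"n_screened": len(screen), "n_skipped": len(skipped),
                     "n_significant": n_sig, "n_perm": config.n_perm}
            if truth is not None:
                bond = set(truth["bonding_rois"])
                called = set(sdf.loc[sdf["q_value"] < config.q_threshold, "roi_id"])
                tp = len(called & bond)
                block["sensitivity"] = tp / len(bond) if bond else None
                block["empirical_fdr"] = (len(called) - tp) / max(len(called), 1)
            report["stages"]["screen"] = block
        else:
            screen = None

        # ------------------------------------------------------------- select
        if config.stages["select"]:
            _require(report, "select", "screen")
            selection = select_exclusive_rois(screen, atlas, config.q_threshold)
            pd.DataFrame({"roi_id": selection.chosen_rois}).to_csv(
                out / "chosen.csv", index=False
            )
            pd.DataFrame(selection.dropped, columns=["roi_id", "reason"]).to_csv(
                out / "dropped.csv", index=False
            )
            report["stages"]["select"] = {"n_chosen": len(selection.chosen_rois)}
            chosen = selection.chosen_rois
        else:
            chosen = None

        # ------------------------------------------------------------ cluster
        if config.stages["cluster"]:
            _require(report, "cluster", "select")
            if len(chosen) < 2:
                raise FosmapError("cluster stage needs at least 2 chosen ROIs")
            k = min(config.k_clusters, len(chosen))
            profiles = activity_profiles(counts, chosen, scale=True)
            assignment = ward_cluster(profiles, k=k)
            from scipy.spatial.distance import pdist, squareform

            D = squareform(pdist(profiles.to_numpy()))
            coords, stress = nmds_embed(
                D, seed=_stage_seed(config.seed, "cluster"), n_restarts=4
            )
            assignment.mds_coords = {
                r: (float(c[0]), float(c[1])) for r, c in zip(chosen, coords)
            }
            assignment.mds_stress = stress
            cdf = pd.DataFrame(
                {
                    "roi_id": chosen,
                    "cluster": [assignment.labels[r] for r in chosen],
                    "mds_x": [assignment.mds_coords[r][0] for r in chosen],
                    "mds_y": [assignment.mds_coords[r][1] for r in chosen],
                }
            )
            cdf.to_csv(out / "clusters.csv", index=False)
            sizes = cdf["cluster"].value_counts().sort_index()
            block = {"k": k, "cluster_sizes": sizes.to_dict(), "mds_stress": stress}
            if truth is not None and truth.get("cluster_map"):
                from sklearn.metrics import adjusted_rand_score

                common = [r for r in chosen if r in truth["cluster_map"]]
                if len(common) >= 2:
                    block["ari_vs_planted"] = float(
                        adjusted_rand_score(
                            [truth["cluster_map"][r] for r in common],
                            [assignment.labels[r] for r in common],
                        )
                    )
            report["stages"]["cluster"] = block
        else:
            assignment = None

        # ------------------------------------------------------- connectivity
        if config.stages["connectivity"]:
            _require(report, "connectivity", "cluster")
            if conn is None:
                raise FosmapError("connectivity stage needs a connectivity matrix input")
            ct = cluster_connectivity_test(
                conn,
                assignment,
                atlas,
                n_perm=config.n_perm,
                seed=_stage_seed(config.seed, "connectivity"),
                exclude_clusters=list(config.exclude_clusters),
            )
            report["stages"]["connectivity"] = {
                "observed_density": ct.observed_density,
                "p_value": ct.p_value,
                "clusters_used": ct.clusters_used,
            }
            pd.DataFrame({"null_density": ct.null_densities}).to_csv(
                out / "connectivity_null.csv", index=False
            )
        # ---------------------------------------------------------------- cca
        if config.stages["cca"]:
            _require(report, "cca", "select")
            if behavior is None:
                raise FosmapError("cca stage needs a behavior table input")
            X = behavior.df.loc[[r.animal_id for r in design]]
            Y = counts.df.loc[[r.animal_id for r in design], chosen].astype(float)
            res = cca(X, Y)
            res.wilks.assign(canonical_r=res.canonical_correlations).to_csv(
                out / "cca_factors.csv"
            )
            res.loadings_x.to_csv(out / "cca_loadings_behavior.csv")
            res.loadings_y.to_csv(out / "cca_loadings_roi.csv")
            scores = pd.DataFrame(
                np.column_stack([res.scores_x[:, 0], res.scores_y[:, 0]]),
                index=X.index,
                columns=["cc1_behavior", "cc1_brain"],
            )
            scores.to_csv(out / "cca_scores.csv", index_label="animal_id")
            top_x = res.loadings_x["CC1"].abs().idxmax()
            report["stages"]["cca"] = {
                "canonical_correlations": [float(v) for v in res.canonical_correlations[:3]],
                "cc1_p": float(res.wilks.loc["CC1", "p"]),
                "cc1_top_behavior": str(top_x),
            }
            cc1_brain = scores[["cc1_brain"]]
        else:
            cc1_brain = None

        # ------------------------------------------------------------ pairsim
        if config.stages["pairsim"]:
            _require(report, "pairsim", "select")
            sim = pair_similarity(counts, design, chosen, timepoints=config.timepoints)
            sim.r.to_csv(out / "pair_similarity.csv")
            block = {
                "n_pairs": sim.n_pairs,
                "mean_diagonal_r": float(np.nanmean(np.diag(sim.r.to_numpy()))),
            }
            if behavior is not None and "ejaculation" in behavior.df.columns:
                pair_of = {r.animal_id: r.pair_id for r in design}
                ej = behavior.df["ejaculation"].groupby(
                    pd.Series({a: pair_of[str(a)] for a in behavior.df.index})
                ).first()
                psim = partial_pair_similarity(
                    counts, design, chosen, ej, timepoints=config.timepoints,
                    covariate_name="ejaculation",
                )
                psim.r.to_csv(out / "pair_similarity_partial.csv")
                block["mean_abs_partial_diagonal_r"] = float(
                    np.nanmean(np.abs(np.diag(psim.r.to_numpy())))
                )
            if cc1_brain is not None:
                cs = pair_similarity(cc1_brain, design, ["cc1_brain"],
                                     timepoints=config.timepoints)
                block["cc1_pair_r"] = float(cs.r.iloc[0, 0])
            report["stages"]["pairsim"] = block
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
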