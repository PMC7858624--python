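"""End-to-end experiment orchestration.

``run_experiment`` drives the whole analysis from one config: generate the
synthetic corpus, build sub-datasets, train single-cohort / universal /
discrimination models, compute the four similarity matrices and their Ward
dendrograms, sweep super-cohort counts S, evaluate every partition, and
apply the CI-gated selection. Every stage is seeded from the config's
master seed; completed stages are checkpointed under the output directory
and reloaded (not recomputed) when re-run with an unchanged config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from supercohort import aggregation, prep, similarity, synthetic
from supercohort.model import AugmentationConfig, TrainingConfig
from supercohort.synthetic import GenerationConfig

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "embed_features", "STAGES"]

log = logging.getLogger("supercohort")

STAGES = ("generate", "prepare", "train-singles", "train-universal",
          "train-discriminators", "matrices", "aggregate", "sweep",
          "select", "report")

_CONDITIONS = ("negative", "positive", "general")


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; ``seed`` is mandatory and feeds every
    source of randomness."""

    seed: int
    n_cohorts: int = 6
    layout: object = "balanced"  # "balanced" | "random" | nested tuple tree
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    n_subdatasets: int = 5
    n_train_pos: int = 18
    n_train_neg: int = 18
    n_heldout_pos: int = 18
    n_heldout_neg: int = 18
    profile: str = "desk"  # "desk" | "full"
    matrix_kinds: tuple[str, ...] = ("detection_C", "disc_negative",
                                     "disc_positive", "disc_general")
    S_values: tuple[int, ...] | None = None  # None = 1..n_cohorts
    eval_patches_per_slide: int = 100
    two_sided_gate: bool = False
    embed: bool = False
    outdir: str = "results"

    def validate(self) -> None:
        if self.n_cohorts < 2:
            raise ValueError("n_cohorts must be >= 2")
        if self.profile not in ("desk", "full"):
            raise ValueError("profile must be desk or full")
        bad = set(self.matrix_kinds) - set(similarity.KINDS)
        if bad:
            raise ValueError(f"unknown matrix kinds: {sorted(bad)}")
        if self.S_values is not None and any(
                not 1 <= s <= self.n_cohorts for s in self.S_values):
            raise ValueError("every S must be in [1, n_cohorts]")
        if self.n_subdatasets < 1:
            raise ValueError("n_subdatasets must be >= 1")
        self.generation.validate()

    def training_config(self) -> TrainingConfig:
        return TrainingConfig.desk() if self.profile == "desk" else TrainingConfig()

    @property
    def s_sweep(self) -> tuple[int, ...]:
        return self.S_values or tuple(range(1, self.n_cohorts + 1))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layout"] = _layout_to_jsonable(self.layout)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "generation" in d and isinstance(d["generation"], dict):
            d["generation"] = GenerationConfig(**d["generation"])
        if "matrix_kinds" in d:
            d["matrix_kinds"] = tuple(d["matrix_kinds"])
        if d.get("S_values") is not None:
            d["S_values"] = tuple(d["S_values"])
        if "layout" in d:
            d["layout"] = _layout_from_jsonable(d["layout"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _layout_to_jsonable(layout):
    if isinstance(layout, (tuple, list)):
        return [_layout_to_jsonable(x) for x in layout]
    return layout


def _layout_from_jsonable(layout):
    if isinstance(layout, list):
        return tuple(_layout_from_jsonable(x) for x in layout)
    return layout


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    dataset: synthetic.MultiCohortDataset
    subdatasets: list
    matrices: dict
    dendrograms: dict
    evaluations: dict          # (kind, S) -> PartitionEvaluation
    reference: aggregation.PartitionEvaluation
    universal: aggregation.PartitionEvaluation
    selection: aggregation.SelectionResult
    tradeoff: pd.DataFrame


class _Runner:
    def __init__(self, config: ExperimentConfig, force: bool = False) -> None:
        config.validate()
        self.cfg = config
        self.force = force
        self.out = Path(config.outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.ckpt = self.out / "checkpoints"
        self.ckpt.mkdir(exist_ok=True)
        self.state: dict = {"model_cache": {}}
        self.train_cfg = config.training_config()
        self.aug = AugmentationConfig()

    # -- checkpoint plumbing ------------------------------------------------
    def _ckpt_path(self, stage: str) -> Path:
        return self.ckpt / f"{stage}-{self.cfg.digest()}.pkl"

    def _done(self, stage: str) -> bool:
        return not self.force and self._ckpt_path(stage).exists()

    def _save(self, stage: str, payload) -> None:
        with open(self._ckpt_path(stage), "wb") as fh:
            pickle.dump(payload, fh)

    def _load(self, stage: str):
        with open(self._ckpt_path(stage), "rb") as fh:
            return pickle.load(fh)

    def _sub_seed(self, *tokens: int) -> int:
        return int(np.random.SeedSequence((self.cfg.seed, *tokens))
                   .generate_state(1)[0] % 2**31)

    # -- stages -------------------------------------------------------------
    def generate(self) -> None:
        if self._done("generate"):
            self.state.update(self._load("generate"))
            return
        cfg = self.cfg
        hierarchy = synthetic.generate_planted_hierarchy(
            cfg.n_cohorts, cfg.layout, seed=self._sub_seed(1))
        dataset = synthetic.generate_dataset(hierarchy, cfg.generation,
                                             seed=self._sub_seed(2))
        synthetic.save_dataset(dataset, str(self.out / "dataset"))
        log.info("generate: %d cohorts, digest %s", cfg.n_cohorts,
                 synthetic.dataset_digest(dataset)[:12])
        self.state["dataset"] = dataset
        self._save("generate", {"dataset": dataset})

    def prepare(self) -> None:
        if self._done("prepare"):
            self.state.update(self._load("prepare"))
            return
        cfg = self.cfg
        subs = prep.sample_subdatasets(
            self.state["dataset"], cfg.n_subdatasets, cfg.n_train_pos,
            cfg.n_train_neg, cfg.n_heldout_pos, cfg.n_heldout_neg,
            seed=self._sub_seed(3))
        pd.concat([s.to_manifest() for s in subs]).to_csv(
            self.out / "subdatasets.csv", index=False)
        self.state["subdatasets"] = subs
        self._save("prepare", {"subdatasets": subs})

    def _train_partition(self, partition):
        return aggregation.train_supercohort_models(
            partition, self.state["subdatasets"], self.train_cfg, self.aug,
            master_seed=self.cfg.seed, cache=self.state["model_cache"])

    def train_singles(self) -> None:
        if self._done("train-singles"):
            self.state.update(self._load("train-singles"))
            return
        n = self.cfg.n_cohorts
        part = aggregation.SuperCohortPartition(
            n, tuple((c,) for c in range(n)), ("singles", n))
        self.state["single_models"] = self._train_partition(part)
        self.state["single_partition"] = part
        self._save("train-singles", {
            "single_models": self.state["single_models"],
            "single_partition": part,
            "model_cache": self.state["model_cache"]})

    def train_universal(self) -> None:
        if self._done("train-universal"):
            self.state.update(self._load("train-universal"))
            return
        n = self.cfg.n_cohorts
        part = aggregation.SuperCohortPartition(
            1, (tuple(range(n)),), ("universal", 1))
        self.state["universal_models"] = self._train_partition(part)
        self.state["universal_partition"] = part
        self._save("train-universal", {
            "universal_models": self.state["universal_models"],
            "universal_partition": part,
            "model_cache": self.state["model_cache"]})

    def train_discriminators(self) -> None:
        if self._done("train-discriminators"):
            self.state.update(self._load("train-discriminators"))
            return
        disc: dict[str, list] = {}
        for ci, cond in enumerate(_CONDITIONS):
            if f"disc_{cond}" not in self.cfg.matrix_kinds:
                continue
            disc[cond] = []
            for sub in self.state["subdatasets"]:
                seed = self._sub_seed(700 + ci, sub.index)
                model, rec = similarity.train_cohort_discriminator(
                    sub, cond, self.train_cfg.with_seed(seed), self.aug)
                disc[cond].append((model, sub))
                log.info("discriminator %s sub %d: %d epochs, val acc %.3f",
                         cond, sub.index, rec.epochs_trained, rec.best_val_accuracy)
        self.state["discriminators"] = disc
        self._save("train-discriminators", {"discriminators": disc})

    def matrices(self) -> None:
        if self._done("matrices"):
            self.state.update(self._load("matrices"))
            return
        cfg = self.cfg
        mats: dict[str, similarity.SimilarityMatrix] = {}
        if "detection_C" in cfg.matrix_kinds:
            single = {(g[0], idx): m for g, per in self.state["single_models"].items()
                      for idx, (m, _) in per.items()}
            mats["detection_C"] = similarity.cross_cohort_detection_matrix(
                single, self.state["subdatasets"])
        for ci, cond in enumerate(_CONDITIONS):
            kind = f"disc_{cond}"
            if kind not in cfg.matrix_kinds:
                continue
            mats[kind] = similarity.discrimination_confidence_matrix(
                self.state["discriminators"][cond], cond,
                patches_per_slide=cfg.eval_patches_per_slide,
                seed=self._sub_seed(800 + ci))
        for kind, m in mats.items():
            m.to_csv(str(self.out / f"matrix_{kind}.csv"))
        self.state["matrices"] = mats
        self._save("matrices", {"matrices": mats})

    def aggregate(self) -> None:
        if self._done("aggregate"):
            self.state.update(self._load("aggregate"))
            return
        dends = {kind: aggregation.build_dendrogram(m)
                 for kind, m in self.state["matrices"].items()}
        for kind, d in dends.items():
            (self.out / f"tree_{kind}.nwk").write_text(d.to_newick() + "\n")
        self.state["dendrograms"] = dends
        self._save("aggregate", {"dendrograms": dends})

    def sweep(self) -> None:
        if self._done("sweep"):
            self.state.update(self._load("sweep"))
            return
        subs = self.state["subdatasets"]
        evals: dict[tuple[str, int], aggregation.PartitionEvaluation] = {}
        for kind, dend in self.state["dendrograms"].items():
            for S in self.cfg.s_sweep:
                part = aggregation.cut_to_supercohorts(dend, S)
                models = self._train_partition(part)
                evals[(kind, S)] = aggregation.evaluate_partition(models, part, subs)
        self.state["evaluations"] = evals

        n = self.cfg.n_cohorts
        self.state["reference"] = aggregation.evaluate_partition(
            self.state["single_models"], self.state["single_partition"], subs)
        self.state["universal_eval"] = aggregation.evaluate_partition(
            self.state["universal_models"], self.state["universal_partition"], subs)
        self._save("sweep", {k: self.state[k] for k in
                             ("evaluations", "reference", "universal_eval",
                              "model_cache")})

    def select(self) -> None:
        if self._done("select"):
            self.state.update(self._load("select"))
            return
        sel = aggregation.select_partitions(
            self.state["evaluations"], self.state["reference"],
            two_sided_gate=self.cfg.two_sided_gate)
        self.state["selection"] = sel
        self._save("select", {"selection": sel})

    def report(self) -> None:
        evals = self.state["evaluations"]
        ref = self.state["reference"]
        uni = self.state["universal_eval"]
        sel = self.state["selection"]
        rows = []
        for (kind, S), ev in sorted(evals.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            rows.append({"kind": kind, "S": S, "mean_auroc": ev.mean_auroc,
                         "ci_halfwidth": ev.ci_halfwidth,
                         "total_epochs": ev.total_training_time_epochs,
                         "qualifies": (kind, S) in sel.qualifying})
        tradeoff = pd.DataFrame(rows)
        tradeoff.to_csv(self.out / "tradeoff.csv", index=False)
        selection = {
            "reference_mean_auroc": ref.mean_auroc,
            "reference_ci_halfwidth": ref.ci_halfwidth,
            "universal_mean_auroc": uni.mean_auroc,
            "threshold": sel.threshold,
            "qualifying": [list(k) for k in sel.qualifying],
            "min_time_choice": list(sel.min_time_choice) if sel.min_time_choice else None,
            "best_performance_choice": (list(sel.best_performance_choice)
                                        if sel.best_performance_choice else None),
            "empty": sel.empty,
        }
        (self.out / "selection.json").write_text(json.dumps(selection, indent=2))
        lines = [
            f"cohorts: {self.cfg.n_cohorts}, sub-datasets: {self.cfg.n_subdatasets}, "
            f"seed: {self.cfg.seed}",
            f"cohort-specific (S={self.cfg.n_cohorts}) mean AUROC: "
            f"{ref.mean_auroc:.4f} +- {ref.ci_halfwidth:.4f} "
            f"({ref.total_training_time_epochs:.1f} epochs)",
            f"universal (S=1) mean AUROC: {uni.mean_auroc:.4f} +- "
            f"{uni.ci_halfwidth:.4f} ({uni.total_training_time_epochs:.1f} epochs)",
        ]
        if sel.min_time_choice:
            k = tuple(sel.min_time_choice)
            ev = evals[k]
            lines.append(
                f"min-time qualifying choice {k}: mean AUROC {ev.mean_auroc:.4f}, "
                f"{ev.total_training_time_epochs:.1f} epochs "
                f"({100 * (1 - ev.total_training_time_epochs / max(ref.total_training_time_epochs, 1e-9)):.0f}%"
                " less training than cohort-specific)")
        if sel.best_performance_choice:
            k = tuple(sel.best_performance_choice)
            ev = evals[k]
            lines.append(f"best qualifying choice {k}: mean AUROC {ev.mean_auroc:.4f}")
        (self.out / "summary.txt").write_text("\n".join(lines) + "\n")
        self.state["tradeoff"] = tradeoff

    def run(self, until: str = "report") -> ExperimentResult:
        order = list(STAGES)
        if until not in order:
            raise ValueError(f"unknown stage {until!r}")
        fns = {"generate": self.generate, "prepare": self.prepare,
               "train-singles": self.train_singles,
               "train-universal": self.train_universal,
               "train-discriminators": self.train_discriminators,
               "matrices": self.matrices, "aggregate": self.aggregate,
               "sweep": self.sweep, "select": self.select, "report": self.report}
        for stage in order[: order.index(until) + 1]:
            fns[stage]()
        st = self.state
        return ExperimentResult(
            self.cfg, st.get("dataset"), st.get("subdatasets", []),
            st.get("matrices", {}), st.get("dendrograms", {}),
            st.get("evaluations", {}), st.get("reference"),
            st.get("universal_eval"), st.get("selection"),
            st.get("tradeoff"))


def run_experiment(config: ExperimentConfig, until: str = "report",
                   force: bool = False) -> ExperimentResult:
    """Run the pipeline up to ``until`` (default: everything), reusing
    checkpointed stages for unchanged configs unless ``force``."""
    return _Runner(config, force=force).run(until)


def embed_features(features: np.ndarray, n_neighbors: int = 20,
                   min_dist: float = 0.5, seed: int = 0) -> np.ndarray:
    """Optional 2-D UMAP embedding of penultimate-layer features, for
    qualitative inspection only. Requires umap-learn."""
    features = np.asarray(features)
    if features.shape[0] < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 rows")
    try:
        import umap
    except ImportError as exc:
        raise ImportError("umap-learn is not installed; embedding skipped") from exc
    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        n_components=2, random_state=seed)
    return np.asarray(reducer.fit_transform(features))
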