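"""Model/Results facade over the multi-agent diagnosis pipeline.

``MultiAgentDiagnosisModel`` is built from labelled data (or directly from
the synthetic generator) and configured by an :class:`ExperimentConfig`;
``fit()`` runs CTDE Q-learning and returns a :class:`DiagnosisResults`
carrying the trained agents, the per-episode training log, prediction and
evaluation methods, a text ``summary()`` and checkpointing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .agents import (
    SpatialQNet,
    TemporalQNet,
    load_checkpoint,
    save_checkpoint,
)
from .config import ExperimentConfig
from .descriptors import VOCABULARY
from .environment import PatchGrid, positional_embedding
from .errors import ConfigurationError, DomainError
from .evaluation import EvaluationReport, evaluate_model
from .fusion import make_fusion
from .manifest import load_dataset
from .synthetic import generate_lesion, make_pseudo_sequence
from .training import (
    Prediction,
    TrainConfig,
    TrainingSample,
    build_samples,
    predict,
    train,
)


def synthesize_dataset(
    n_per_class: int,
    seed: int,
    sequences: bool = False,
    n_classes: int = 2,
) -> list:
    """Generate a seeded two-class dataset of images or pseudo-sequences."""
    items = []
    for class_id in range(n_classes):
        for i in range(n_per_class):
            img = generate_lesion(class_id, seed=seed * 1_000_003 + i, )
            if sequences:
                items.append(make_pseudo_sequence(img, seed=seed * 1_000_003 + i))
            else:
                items.append(img)
    return items


class MultiAgentDiagnosisModel:
    """Two Q-agents (spatial CNN + temporal text encoder) fused by VDN."""

    def __init__(
        self,
        samples: list[TrainingSample],
        config: ExperimentConfig | None = None,
        vocab_size: int = len(VOCABULARY),
    ) -> None:
        if not samples:
            raise DomainError("no training samples")
        self.samples = samples
        self.config = config or ExperimentConfig()
        self.vocab_size = vocab_size
        self.grid = PatchGrid(
            image_size=self.config.env.image_size,
            patch_size=self.config.env.patch_size,
            stride=self.config.env.stride,
        )

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_synthetic(
        cls,
        n_per_class: int = 200,
        seed: int = 0,
        sequences: bool = False,
        config: ExperimentConfig | None = None,
    ) -> "MultiAgentDiagnosisModel":
        items = synthesize_dataset(n_per_class, seed, sequences=sequences)
        return cls(build_samples(items), config=config)

    @classmethod
    def from_manifest(
        cls, manifest_path, config: ExperimentConfig | None = None
    ) -> "MultiAgentDiagnosisModel":
        return cls(build_samples(load_dataset(manifest_path)), config=config)

    # -- fitting ------------------------------------------------------------
    def _train_config(self, **overrides) -> TrainConfig:
        c = self.config
        kwargs = dict(
            gamma=c.env.gamma,
            tau=c.train.tau,
            epsilon_start=c.train.epsilon_start,
            epsilon_end=c.train.epsilon_end,
            epsilon_decay_frac=c.train.epsilon_decay_frac,
            batch_size=c.train.batch_size,
            replay_capacity=c.train.replay_capacity,
            warmup_transitions=c.train.warmup_transitions,
            target_sync=c.train.target_sync,
            learning_rate=c.train.learning_rate,
            episodes=c.train.episodes,
            train_every=c.train.train_every,
            t_max=c.env.t_max,
            pos_frequencies=c.env.pos_frequencies,
            seed=c.train.seed,
        )
        kwargs.update(overrides)
        return TrainConfig(**kwargs)

    def fit(self, **overrides) -> "DiagnosisResults":
        """Run CTDE Q-learning; keyword overrides map to TrainConfig fields."""
        tc = self._train_config(**overrides)
        result = train(
            self.samples,
            tc,
            vocab_size=self.vocab_size,
            fusion_kind=self.config.fusion.rule,
            spatial_backbone=self.config.agents.spatial_backbone,
            temporal_backbone=self.config.agents.temporal_backbone,
            grid=self.grid,
        )
        return DiagnosisResults(
            spatial=result.spatial,
            temporal=result.temporal,
            fusion=result.fusion,
            log=result.log,
            train_config=tc,
            experiment_config=self.config,
            grid=self.grid,
        )


@dataclass
class DiagnosisResults:
    """Trained team plus training diagnostics."""

    spatial: SpatialQNet
    temporal: TemporalQNet
    fusion: object
    log: pd.DataFrame
    train_config: TrainConfig
    experiment_config: ExperimentConfig
    grid: PatchGrid

    # -- inference ----------------------------------------------------------
    def predict_one(self, sample: TrainingSample) -> Prediction:
        return predict(
            sample, self.spatial, self.temporal, self.fusion,
            grid=self.grid, t_max=self.train_config.t_max,
            pos_frequencies=self.train_config.pos_frequencies,
            tau=self.train_config.tau,
        )

    def predict(self, samples) -> tuple[np.ndarray, np.ndarray]:
        """Greedy class decisions and class-probability rows per sample."""
        preds = np.empty(len(samples), dtype=int)
        probs = np.empty((len(samples), self.temporal.n_classes))
        for i, s in enumerate(samples):
            p = self.predict_one(s)
            preds[i] = p.predicted_class
            probs[i] = p.probabilities
        return preds, probs

    def evaluate(self, samples, prevalence: float | None = None) -> EvaluationReport:
        ev = self.experiment_config.eval
        return evaluate_model(
            self.spatial, self.temporal, self.fusion, samples,
            positive_class=ev.positive_class,
            prevalence=ev.prevalence if prevalence is None else prevalence,
            tau=self.train_config.tau,
            grid=self.grid,
            t_max=self.train_config.t_max,
            pos_frequencies=self.train_config.pos_frequencies,
        )

    def accuracy(self, samples) -> float:
        preds, _ = self.predict(samples)
        return float(np.mean(preds == np.array([s.label for s in samples])))

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        tail = self.log.tail(max(len(self.log) // 10, 1))
        n_params = sum(
            p.size
            for net in (self.spatial, self.temporal)
            for _, p, _ in net.named_parameters()
        )
        lines = [
            "Multi-Agent Diagnosis Results",
            "=" * 46,
            f"{'episodes':30s} {len(self.log):>15d}",
            f"{'spatial backbone':30s} {self.spatial.backbone_name:>15s}",
            f"{'temporal backbone':30s} {self.temporal.backbone_name:>15s}",
            f"{'fusion rule':30s} {self.fusion.kind:>15s}",
            f"{'trainable parameters':30s} {n_params:>15d}",
            f"{'discount gamma':30s} {self.train_config.gamma:>15.3f}",
            f"{'final epsilon':30s} {self.log['epsilon'].iloc[-1]:>15.3f}",
            f"{'mean return (last 10%)':30s} {tail['return'].mean():>15.4f}",
            f"{'mean episode length (last 10%)':30s} {tail['steps'].mean():>15.2f}",
            f"{'last TD loss':30s} {self.log['loss'].iloc[-1]:>15.5f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        modules = {"spatial": self.spatial, "temporal": self.temporal}
        if list(self.fusion.named_parameters()):
            modules["fusion"] = self.fusion
        metadata = {
            "package_version": _pkg_version,
            "n_classes": self.temporal.n_classes,
            "vocab_size": self.temporal.vocab_size,
            "spatial_backbone": self.spatial.backbone_name,
            "temporal_backbone": self.temporal.backbone_name,
            "fusion": self.fusion.kind,
            "pos_frequencies": self.train_config.pos_frequencies,
            "t_max": self.train_config.t_max,
            "tau": self.train_config.tau,
            "seed": self.train_config.seed,
            "grid": {
                "image_size": self.grid.image_size,
                "patch_size": self.grid.patch_size,
                "stride": self.grid.stride,
            },
        }
        save_checkpoint(path, modules, metadata)

    @classmethod
    def load(cls, path, experiment_config: ExperimentConfig | None = None) -> "DiagnosisResults":
        states, meta = load_checkpoint(path)
        if not meta:
            raise ConfigurationError("checkpoint metadata sidecar missing")
        grid = PatchGrid(**meta["grid"])
        rng = np.random.default_rng(meta.get("seed", 0))
        pos_dim = positional_embedding((0, 0), grid, meta["pos_frequencies"]).shape[0]
        spatial = SpatialQNet(
            meta["n_classes"], pos_dim, rng, backbone=meta["spatial_backbone"],
            patch_size=grid.patch_size,
        )
        temporal = TemporalQNet(
            meta["vocab_size"], meta["n_classes"], rng,
            backbone=meta["temporal_backbone"],
        )
        fusion = make_fusion(
            meta["fusion"], meta["n_classes"], rng,
            d_spatial=spatial.backbone.out_dim, d_temporal=temporal.d_hidden,
        )
        spatial.load_state_dict(states["spatial"])
        temporal.load_state_dict(states["temporal"])
        if "fusion" in states:
            fusion.load_state_dict(states["fusion"])
        cfg = experiment_config or ExperimentConfig()
        tc = TrainConfig(
            t_max=meta["t_max"], pos_frequencies=meta["pos_frequencies"],
            tau=meta["tau"], seed=meta.get("seed", 0),
        )
        return DiagnosisResults(
            spatial=spatial, temporal=temporal, fusion=fusion,
            log=pd.DataFrame(columns=["episode", "return", "loss", "epsilon", "steps"]),
            train_config=tc, experiment_config=cfg, grid=grid,
        )
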