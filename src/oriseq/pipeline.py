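"""End-to-end ORI prediction pipeline.

fit: train the neural extractor on the training windows, compute the
four feature blocks (DL, CKSNAP, PCPseDNC, DCC), fuse them in canonical
order, fit the Shapley selector on the training rows only, and train the
final boosted classifier on the selected columns.  predict_proba applies
the frozen extractor, encoders, mask and classifier to new windows.

Any block can be switched off (per-encoder baselines, DL-only, etc.) and
selection can be bypassed; this is how ablation studies are configured.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .encoders import CKSNAPEncoder, DCCEncoder, FeatureBlock, PCPseDNCEncoder
from .fusion import FusedMatrix, fuse
from .model import OrderedBoostedClassifier
from .neural import ArchConfig, NeuralSequenceExtractor, TrainConfig
from .selection import ShapleyFeatureSelector


@dataclass
class PipelineConfig:
    """Everything needed to build an OriPipeline, JSON-serializable."""

    use_dl: bool = True
    use_cksnap: bool = True
    use_pcpsednc: bool = True
    use_dcc: bool = True
    use_selection: bool = True
    top_k: int | None = None
    arch: ArchConfig = field(default_factory=ArchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    cksnap_k_values: tuple = (0, 1, 2, 3, 4, 5)
    pse_lambda: int = 2
    pse_w: float = 0.1
    dcc_max_lag: int = 2
    classifier_params: dict = field(default_factory=dict)
    seed: int = 0


class OriPipeline(ClassifierMixin, BaseEstimator):
    """Sequence-in, probability-out classifier composing all stages."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config

    def _cfg(self) -> PipelineConfig:
        return self.config if self.config is not None else PipelineConfig()

    def _blocks(self, seqs, fit_extractor=False, y=None) -> list[FeatureBlock]:
        cfg = self._cfg()
        blocks: list[FeatureBlock] = []
        if cfg.use_dl:
            if fit_extractor:
                train = TrainConfig(**{**vars(cfg.train), "seed": cfg.train.seed + cfg.seed})
                self.extractor_ = NeuralSequenceExtractor(arch=cfg.arch, train=train)
                self.extractor_.fit(seqs, y)
            blocks.append(
                FeatureBlock(
                    "DL",
                    list(self.extractor_.get_feature_names_out()),
                    self.extractor_.transform(seqs),
                )
            )
        if cfg.use_cksnap:
            blocks.append(self.cksnap_.encode_block(seqs))
        if cfg.use_pcpsednc:
            blocks.append(self.pcpsednc_.encode_block(seqs))
        if cfg.use_dcc:
            blocks.append(self.dcc_.encode_block(seqs))
        if not blocks:
            raise ValueError("all feature blocks disabled")
        return blocks

    def fit(self, X, y):
        cfg = self._cfg()
        y = np.asarray(y).ravel()
        self.cksnap_ = CKSNAPEncoder(k_values=cfg.cksnap_k_values)
        self.pcpsednc_ = PCPseDNCEncoder(lam=cfg.pse_lambda, w=cfg.pse_w)
        self.dcc_ = DCCEncoder(max_lag=cfg.dcc_max_lag)
        blocks = self._blocks(list(X), fit_extractor=True, y=y)
        fused = fuse(blocks)
        self.registry_ = fused.registry
        if cfg.use_selection:
            self.selector_ = ShapleyFeatureSelector(
                top_k=cfg.top_k,
                model_params=dict(cfg.classifier_params),
                seed=cfg.seed,
            ).fit(fused, y)
            Xsel = self.selector_.transform(fused)
        else:
            self.selector_ = None
            Xsel = fused.matrix
        params = dict(cfg.classifier_params)
        params.setdefault("seed", cfg.seed)
        self.classifier_ = OrderedBoostedClassifier(**params).fit(Xsel, y)
        self.classes_ = self.classifier_.classes_
        return self

    def _features(self, X) -> np.ndarray:
        fused = fuse(self._blocks(list(X)))
        if self.selector_ is not None:
            return self.selector_.transform(fused)
        return fused.matrix

    def fused_matrix(self, X) -> FusedMatrix:
        """Pre-selection fused features for new windows (for attribution)."""
        return fuse(self._blocks(list(X)))

    def predict_proba(self, X) -> np.ndarray:
        return self.classifier_.predict_proba(self._features(X))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    # -- bundle persistence (text formats only) ------------------------

    def save(self, directory) -> None:
        """Write config JSON, extractor bundle, selection mask + registry
        copy, and the classifier engine blob to a directory."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = self._cfg()
        meta = asdict(cfg)
        meta["registry"] = [
            {"block": e.block, "start": e.start, "stop": e.stop,
             "feature_names": list(e.feature_names)}
            for e in self.registry_
        ]
        meta["selected_mask"] = (
            self.selector_.report_.selected_mask.astype(int).tolist()
            if self.selector_ is not None
            else None
        )
        (d / "pipeline.json").write_text(json.dumps(meta, indent=2))
        if cfg.use_dl:
            self.extractor_.save(d / "extractor")
        self.classifier_.save(d / "classifier")

    @classmethod
    def load(cls, directory) -> "OriPipeline":
        from .fusion import RegistryEntry
        from .neural import NeuralSequenceExtractor

        d = Path(directory)
        meta = json.loads((d / "pipeline.json").read_text())
        registry = [
            RegistryEntry(e["block"], e["start"], e["stop"], tuple(e["feature_names"]))
            for e in meta.pop("registry")
        ]
        mask = meta.pop("selected_mask")
        arch = ArchConfig(
            **{
                **meta["arch"],
                "conv_branches": tuple(map(tuple, meta["arch"]["conv_branches"])),
                "gru_units": tuple(meta["arch"]["gru_units"]),
            }
        )
        cfg = PipelineConfig(
            **{
                **meta,
                "arch": arch,
                "train": TrainConfig(**meta["train"]),
                "cksnap_k_values": tuple(meta["cksnap_k_values"]),
            }
        )
        pipe = cls(config=cfg)
        pipe.registry_ = registry
        pipe.cksnap_ = CKSNAPEncoder(k_values=cfg.cksnap_k_values)
        pipe.pcpsednc_ = PCPseDNCEncoder(lam=cfg.pse_lambda, w=cfg.pse_w)
        pipe.dcc_ = DCCEncoder(max_lag=cfg.dcc_max_lag)
        if cfg.use_dl:
            pipe.extractor_ = NeuralSequenceExtractor.load(d / "extractor")
        if mask is not None:
            sel = ShapleyFeatureSelector(top_k=int(np.sum(mask)))
            from .selection import AttributionReport

            m = np.asarray(mask, dtype=bool)
            sel.report_ = AttributionReport(
                0.0, np.zeros((0, len(m))), np.zeros(len(m)), selected_mask=m
            )
            sel.n_features_in_ = len(m)
            pipe.selector_ = sel
        else:
            pipe.selector_ = None
        pipe.classifier_ = OrderedBoostedClassifier.load(d / "classifier")
        pipe.classes_ = pipe.classifier_.classes_
        return pipe
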