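"""Run configuration: one YAML/JSON block per pipeline stage.

The defaults reproduce the proposed network's reference hyper-parameter
column exactly: five stride-2 conv layers of 32 filters, Leaky-ReLU 0.2,
He-normal init, no pooling, no dropout, 64 MI bins, Adam at learning
rate 1e-4 for 500 epochs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .localization_network import NetworkConfig
from .mi_loss import MILossConfig
from .trainer import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    mode: str = "2d"
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: MILossConfig = field(default_factory=MILossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    corpus_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self):
        if self.mode != "2d":
            raise ValueError("only the 2d mode is implemented")
        # the train block owns the loss config used during optimization
        self.train.loss = self.loss

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "network": asdict(self.network),
            "loss": asdict(self.loss),
            "train": {
                k: v for k, v in asdict(self.train).items() if k != "loss"
            },
            "corpus_dir": self.corpus_dir,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        net = payload.get("network", {})
        if "input_size" in net:
            net = {**net, "input_size": tuple(net["input_size"])}
        if "conv_filters" in net:
            net = {**net, "conv_filters": tuple(net["conv_filters"])}
        return cls(
            mode=payload.get("mode", "2d"),
            network=NetworkConfig(**net),
            loss=MILossConfig(**payload.get("loss", {})),
            train=TrainConfig(**payload.get("train", {})),
            corpus_dir=payload.get("corpus_dir"),
            output_dir=payload.get("output_dir"),
        )


def load_config(path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    return RunConfig.from_dict(payload or {})


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))
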