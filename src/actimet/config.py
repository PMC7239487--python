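"""Run configuration: one object that seeds and parameterises every stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import SessionParams


def _default_model_specs() -> list[dict]:
    # free-living arm: per-model best k; retrained-lab arm: the laboratory
    # architectures refit on free-living data with a pooled k=20 selection
    return [
        {"algorithm": "rf", "site": "hip", "provenance": "free_living", "k": 20},
        {"algorithm": "ann", "site": "hip", "provenance": "free_living", "k": 15},
        {"algorithm": "rf", "site": "wrist", "provenance": "free_living", "k": 15},
        {"algorithm": "svm_rbf", "site": "wrist", "provenance": "free_living", "k": 15},
        {"algorithm": "rf", "site": "hip", "provenance": "retrained_lab", "k": 20},
        {"algorithm": "ann", "site": "hip", "provenance": "retrained_lab", "k": 20},
        {"algorithm": "rf", "site": "wrist", "provenance": "retrained_lab", "k": 20},
        {"algorithm": "svm_rbf", "site": "wrist", "provenance": "retrained_lab", "k": 20},
    ]


@dataclass
class RunConfig:
    """Parameters of a full study replication."""

    seed: int = 0
    n_train: int = 15
    n_holdout: int = 10
    session_length_s: float = 1200.0
    session: SessionParams = field(default_factory=SessionParams)
    selection_k: tuple[int, ...] = (10, 15, 20)
    selection_method: str = "f_quotient"
    nested_selection: bool = True
    model_specs: list[dict] = field(default_factory=_default_model_specs)
    hyperparameter_overrides: dict = field(default_factory=dict)
    sync_tolerance_s: float = 0.0
    bland_altman_at_kcal: tuple[float, ...] = (10.0, 30.0, 50.0)
    write_raw: bool = False
    out_dir: str = "runs/default"

    def __post_init__(self) -> None:
        if self.n_train < 2:
            raise ValueError("n_train must be >= 2")
        if self.n_holdout < 0:
            raise ValueError("n_holdout must be >= 0")
        if self.session_length_s <= 0:
            raise ValueError("session_length_s must be positive")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session"] = dataclasses.asdict(self.session)
        return d

    def config_hash(self) -> str:
        """Hash of the analytic parameters (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("write_raw", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        # accept flat dotted keys (session.tau_s: 20) alongside nested dicts
        nested: dict = {}
        for key, value in data.items():
            if "." in key:
                head, tail = key.split(".", 1)
                nested.setdefault(head, {})[tail] = value
            else:
                nested[key] = value
        session = nested.pop("session", {})
        if isinstance(session, SessionParams):
            params = session
        else:
            params = SessionParams(**session)
        for key in ("selection_k", "bland_altman_at_kcal"):
            if key in nested and isinstance(nested[key], list):
                nested[key] = tuple(nested[key])
        return cls(session=params, **nested)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
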