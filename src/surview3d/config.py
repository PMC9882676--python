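"""Structured run configuration: one flat YAML file drives the pipeline.

``RunConfig`` nests the phantom dataset settings, projector geometry
overrides, network scale, training protocol and evaluation thresholds, and
round-trips losslessly through YAML. ``validate_config`` reports *all*
violations at once.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .networks import NetworkScaleConfig
from .phantoms import DEFAULT_JITTER, ThoraxPhantomSpec
from .training import TrainConfig


@dataclass
class PhantomDatasetConfig:
    n: int = 12
    seed: int = 0
    jitter: dict = field(default_factory=lambda: dict(DEFAULT_JITTER))
    base: ThoraxPhantomSpec = field(default_factory=ThoraxPhantomSpec)

    def validate(self) -> list[str]:
        errors = []
        if self.n < 1:
            errors.append("phantom.n must be >= 1")
        for k, v in self.jitter.items():
            if not 0.0 <= float(v) <= 0.5:
                errors.append(f"phantom.jitter[{k!r}] must be in [0, 0.5], got {v}")
        try:
            self.base.validate()
        except ValueError as err:
            errors.append(f"phantom.base: {err}")
        return errors


@dataclass
class GeometryConfig:
    source_to_isocenter_mm: float = 600.0
    source_to_detector_mm: float = 1100.0
    detector_pixels: tuple[int, int] = (128, 128)
    i0: float = 1.0

    def validate(self) -> list[str]:
        errors = []
        if not self.source_to_detector_mm > self.source_to_isocenter_mm > 0:
            errors.append(
                "geometry: need source_to_detector_mm > source_to_isocenter_mm > 0"
            )
        if any(int(p) < 1 for p in self.detector_pixels):
            errors.append(f"geometry.detector_pixels must be positive, got {self.detector_pixels}")
        if self.i0 <= 0:
            errors.append("geometry.i0 must be > 0")
        return errors

    def overrides(self) -> dict:
        return {
            "source_to_isocenter_mm": self.source_to_isocenter_mm,
            "source_to_detector_mm": self.source_to_detector_mm,
            "detector_pixels": tuple(int(p) for p in self.detector_pixels),
            "i0": self.i0,
        }


@dataclass
class EvaluationConfig:
    lung_threshold_hu: float = -320.0
    body_threshold_hu: float = -500.0
    window: tuple[float, float] = (-1000.0, 1000.0)

    def validate(self) -> list[str]:
        errors = []
        if not self.window[0] < self.window[1]:
            errors.append(f"evaluation.window is degenerate: {self.window}")
        if self.lung_threshold_hu <= self.body_threshold_hu:
            errors.append("evaluation.lung_threshold_hu must exceed body_threshold_hu")
        return errors


@dataclass
class RunConfig:
    phantom: PhantomDatasetConfig = field(default_factory=PhantomDatasetConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    network: NetworkScaleConfig = field(default_factory=NetworkScaleConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    arch: str = "dual"  # single | dual | both
    out_dir: str = "runs/demo"
    make_figures: bool = False

    def validate(self) -> list[str]:
        errors = []
        errors += self.phantom.validate()
        errors += self.geometry.validate()
        errors += self.network.validate()
        errors += self.train.validate()
        errors += self.evaluation.validate()
        if self.arch not in ("single", "dual", "both"):
            errors.append(f"arch must be single|dual|both, got {self.arch!r}")
        rows, cols = self.geometry.detector_pixels
        if (int(rows), int(cols)) != (self.network.input_size, self.network.input_size):
            errors.append(
                f"geometry.detector_pixels {self.geometry.detector_pixels} must equal the "
                f"network input size {self.network.input_size}"
            )
        if int(self.train.split[2]) >= self.phantom.n:
            errors.append("train.split test_count must be < phantom.n")
        return errors

    def require_valid(self) -> "RunConfig":
        errors = self.validate()
        if errors:
            raise ValueError("invalid RunConfig:\n  - " + "\n  - ".join(errors))
        return self

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        return _clean(dataclasses.asdict(self))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def _tup(v):
            return tuple(_tup(x) for x in v) if isinstance(v, list) else v

        raw = dict(raw)
        phantom_raw = dict(raw.pop("phantom", {}))
        base_raw = phantom_raw.pop("base", {})
        phantom = PhantomDatasetConfig(
            base=ThoraxPhantomSpec(**{k: _tup(v) for k, v in base_raw.items()}),
            **{k: (_tup(v) if k != "jitter" else dict(v)) for k, v in phantom_raw.items()},
        )
        geometry = GeometryConfig(**{k: _tup(v) for k, v in raw.pop("geometry", {}).items()})
        network = NetworkScaleConfig(**raw.pop("network", {}))
        train = TrainConfig(**{k: _tup(v) for k, v in raw.pop("train", {}).items()})
        evaluation = EvaluationConfig(**{k: _tup(v) for k, v in raw.pop("evaluation", {}).items()})
        return cls(
            phantom=phantom,
            geometry=geometry,
            network=network,
            train=train,
            evaluation=evaluation,
            **raw,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls.from_dict(raw or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML config; raises with every violation listed."""
    config = RunConfig.from_yaml(path)
    config.require_valid()
    return config
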