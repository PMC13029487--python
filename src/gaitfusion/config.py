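"""Pipeline configuration: one flat, YAML-serializable record of every
tunable the two-stage pipeline exposes."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .detector import DetectorThresholds
from .dynamic_branch import (DEFAULT_GBDT_GRID, DEFAULT_RF_GRID,
                             EnsembleConfig)
from .nn import DualBranchNetSpec
from .preprocessing import SGConfig
from .static_branch import DEFAULT_SVM_GRID

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the data itself.

    ``modality`` selects the sensing configuration ("fused", "pressure",
    "imu"); with "imu" the pressure-based stage-1 router cannot run and
    every window falls through to the dynamic branch, which is then trained
    with the static classes folded in as extra classes.
    """

    modality: str = "fused"
    include_addons: bool = False
    sg_half_width: int = 5
    sg_degree: int = 3
    t_energy: float = 2000.0
    t_ratio: float = 6.5
    contact_frac: float = 0.05
    svm_grid: dict = field(default_factory=lambda: dict(DEFAULT_SVM_GRID))
    use_deep: bool = False
    weight_mode: str = "accuracy"
    calibration_fraction: float = 0.2
    rf_n_estimators: int = 150
    rf_grid: dict = field(default_factory=lambda: dict(DEFAULT_RF_GRID))
    gbdt_grid: dict = field(default_factory=lambda: dict(DEFAULT_GBDT_GRID))
    net_max_epochs: int = 100
    net_filters: int = 16
    pca_variance: float | None = None

    def sg_config(self) -> SGConfig:
        return SGConfig(half_width=self.sg_half_width, degree=self.sg_degree)

    def detector_thresholds(self) -> DetectorThresholds:
        return DetectorThresholds(t_energy=self.t_energy, t_ratio=self.t_ratio)

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            use_deep=self.use_deep,
            weight_mode=self.weight_mode,
            calibration_fraction=self.calibration_fraction,
            rf_n_estimators=self.rf_n_estimators,
            rf_grid=dict(self.rf_grid),
            gbdt_grid=dict(self.gbdt_grid),
            net_spec=DualBranchNetSpec(max_epochs=self.net_max_epochs,
                                       n_filters=self.net_filters),
        )

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config)))
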