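"""Configuration objects for the simulator and the pipeline.

All tunables live in dataclasses that round-trip through YAML.  Group labels
are "TC" (typical controls) and "WS" (Williams syndrome) throughout.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict

import yaml

from .layout import ChannelLayout

GROUPS = ("TC", "WS")
MOTION_CONDITIONS = ("M_SL", "M_SR")
COLOR_CONDITION = "P_CHANGE"
CONDITIONS = MOTION_CONDITIONS + (COLOR_CONDITION,)


@dataclass
class ComponentSpec:
    """One evoked component planted by the simulator.

    latency_ms : peak latency of the Gaussian-in-time kernel.
    width_ms   : Gaussian standard deviation.
    amplitude_uV : window-mean amplitude as seen through the default
        measurement chain (baseline + zero-phase low-pass + inclusive
        window mean), either a scalar or a per-group mapping.
    electrode_role : which layout set carries the component.
    conditions : conditions in which the component appears.
    polarity is carried by the sign of amplitude_uV.
    """

    latency_ms: float
    width_ms: float
    amplitude_uV: float | dict
    electrode_role: str
    conditions: tuple[str, ...]
    window_ms: tuple[float, float]

    def amplitude_for(self, group: str) -> float:
        if isinstance(self.amplitude_uV, dict):
            return float(self.amplitude_uV[group])
        return float(self.amplitude_uV)


def default_components() -> dict[str, ComponentSpec]:
    """P1 (motion, positive), N1 (color, negative), N2 (motion, negative)."""
    return {
        "P1": ComponentSpec(155.0, 15.0, 4.0, "occipital_set",
                            MOTION_CONDITIONS, (130.0, 170.0)),
        "N1": ComponentSpec(148.0, 15.0, -4.0, "occipital_set",
                            (COLOR_CONDITION,), (130.0, 170.0)),
        "N2": ComponentSpec(190.0, 15.0, -5.0, "hemisphere_sets",
                            MOTION_CONDITIONS, (155.0, 195.0)),
    }


@dataclass
class SimulationConfig:
    """Ground-truth cohort generator settings.

    The defaults emulate the study cohort: two groups (TC n=27, WS n=29),
    300 trials per condition at 250 Hz, epochs spanning -100..1000 ms,
    opposite-sign mean laterality per group, and molecular covariates
    with a configurable population correlation to the true LI.
    """

    n_per_group: dict = field(default_factory=lambda: {"TC": 27, "WS": 29})
    n_trials: int = 300
    sampling_rate: float = 250.0
    epoch_window: tuple[float, float] = (-100.0, 1000.0)
    # mean true LI per group, microvolts (signs follow the reported
    # direction of effects; magnitudes are free defaults)
    group_means: dict = field(default_factory=lambda: {"TC": -1.5, "WS": 0.8})
    # SD of total sensitivity T (Gamma-distributed), microvolts
    sensitivity_scale: float = 0.8
    # per-group (mean, concentration) of the Beta allocation of total
    # sensitivity to the left hemisphere; pi < 0.5 => RH-dominant
    allocation_params: dict = field(
        default_factory=lambda: {"TC": (0.33, 8.0), "WS": (0.58, 9.0)})
    left_handed: dict = field(default_factory=lambda: {"TC": 2, "WS": 8})
    n_female: dict = field(default_factory=lambda: {"TC": 15, "WS": 18})
    component_params: dict = field(default_factory=default_components)
    noise_sd: float = 6.0
    pink_fraction: float = 0.2
    eog_noise_scale: float = 0.3
    artifact_rate: float = 0.4
    artifact_amplitudes: dict = field(default_factory=lambda: {
        "blink": 300.0, "hem": 60.0, "spike": 250.0})
    rho_expression: float = 0.465
    rho_methylation: float = -0.4
    expression_features: dict = field(default_factory=lambda: {
        "BUD23": None, "BCL7B": 0.3, "BAZ1B": 0.3, "HPRT1": 0.0, "ACTB": 0.0})
    methylation_features: dict = field(default_factory=lambda: {
        "cg12099727": None, "cg09265173": 0.3})
    expression_batch_scales: dict = field(default_factory=lambda: {
        "batch1": (1.0, 0.2), "batch2": (5.0, 1.0)})
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"n_per_group[{g}] must be >= 2")
            for counts, label in ((self.left_handed, "left_handed"),
                                  (self.n_female, "n_female")):
                if counts.get(g, 0) > n:
                    raise ValueError(
                        f"{label}[{g}]={counts[g]} exceeds group size {n}")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        for name, rho in (("rho_expression", self.rho_expression),
                          ("rho_methylation", self.rho_methylation)):
            if not math.isfinite(rho) or abs(rho) > 1:
                raise ValueError(f"{name} must be finite with |rho| <= 1")
        for val in (self.sensitivity_scale, self.noise_sd,
                    self.pink_fraction):
            if not math.isfinite(val):
                raise ValueError("non-finite config value")
        t0, t1 = self.epoch_window
        for name, spec in self.component_params.items():
            if not t0 <= spec.latency_ms < t1:
                raise ValueError(
                    f"component {name} latency {spec.latency_ms} ms outside "
                    f"epoch window {self.epoch_window}")
        if not (t0 <= -100.0 and t1 > 0.0):
            raise ValueError("epoch window must span the baseline")


def scaled_config(n_per_group: dict, **overrides) -> SimulationConfig:
    """A SimulationConfig for a smaller/larger cohort, with the demographic
    counts (left-handed, female) scaled proportionally from the defaults."""
    base = SimulationConfig()
    left, fem = {}, {}
    for g, n in n_per_group.items():
        n0 = base.n_per_group.get(g, n)
        left[g] = min(n, round(base.left_handed.get(g, 0) * n / n0))
        fem[g] = min(n, round(base.n_female.get(g, 0) * n / n0))
    return SimulationConfig(n_per_group=dict(n_per_group), left_handed=left,
                            n_female=fem, **overrides)


@dataclass
class PreprocessConfig:
    """Preprocessing chain settings (defaults follow the study's recipe)."""

    lowpass_hz: float = 30.0
    filter_order: int = 4
    baseline_window: tuple[float, float] = (-100.0, 0.0)
    amp_threshold_uV: float = 200.0
    heog_threshold_uV: float = 40.0
    veog_threshold_uV: float = 100.0
    min_trials: int = 40
    # stage order; low-pass is applied to averages, not single trials
    order: tuple[str, ...] = ("rereference", "baseline", "reject",
                              "average", "lowpass")


@dataclass
class AnalysisPlanRow:
    feature: str
    phenotype: str  # LI, S_R, S_L or a covariate column
    tail: str = "two"  # two | one_pos | one_neg


def default_plan() -> list[AnalysisPlanRow]:
    # expression is predicted to fall with LI reversal: positive r with LI,
    # negative with S_R loss, positive with S_L gain (directional tests)
    return [
        AnalysisPlanRow("BUD23", "LI", "one_pos"),
        AnalysisPlanRow("BUD23", "S_R", "one_neg"),
        AnalysisPlanRow("BUD23", "S_L", "one_pos"),
        AnalysisPlanRow("BCL7B", "LI", "two"),
        AnalysisPlanRow("BAZ1B", "LI", "two"),
        AnalysisPlanRow("HPRT1", "LI", "two"),
        AnalysisPlanRow("ACTB", "LI", "two"),
        AnalysisPlanRow("cg12099727", "LI", "one_neg"),
        AnalysisPlanRow("cg09265173", "LI", "two"),
    ]


@dataclass
class PipelineConfig:
    """Everything a full run needs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    epsilon_uV: float = 0.0          # laterality dead-band
    z_reference: str = "combined"    # combined | within_group
    adjust_method: str = "bonferroni"
    plan: list[AnalysisPlanRow] = field(default_factory=default_plan)
    seed: int = 0
    log_level: str = "INFO"

    # ------------------------------------------------------------- YAML I/O
    def to_dict(self) -> dict:
        d = asdict(self)
        d["layout"] = self.layout.to_dict()
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plainify(self.to_dict()), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "layout" in d:
            d["layout"] = ChannelLayout.from_dict(d["layout"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            pp = dict(d["preprocess"])
            if "baseline_window" in pp:
                pp["baseline_window"] = tuple(pp["baseline_window"])
            if "order" in pp:
                pp["order"] = tuple(pp["order"])
            d["preprocess"] = PreprocessConfig(**pp)
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            if "epoch_window" in sim:
                sim["epoch_window"] = tuple(sim["epoch_window"])
            if "component_params" in sim:
                sim["component_params"] = {
                    k: v if isinstance(v, ComponentSpec) else ComponentSpec(
                        latency_ms=v["latency_ms"], width_ms=v["width_ms"],
                        amplitude_uV=v["amplitude_uV"],
                        electrode_role=v["electrode_role"],
                        conditions=tuple(v["conditions"]),
                        window_ms=tuple(v["window_ms"]))
                    for k, v in sim["component_params"].items()}
            if "allocation_params" in sim:
                sim["allocation_params"] = {
                    g: tuple(v) for g, v in sim["allocation_params"].items()}
            d["simulation"] = SimulationConfig(**sim)
        if "plan" in d:
            d["plan"] = [r if isinstance(r, AnalysisPlanRow)
                         else AnalysisPlanRow(**r) for r in d["plan"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @classmethod
    def load(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_yaml(fh.read())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _plainify(obj):
    """Recursively convert tuples to lists for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    return obj
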