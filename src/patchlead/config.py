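"""Run configuration: every protocol constant as a named, overridable default.

The defaults encode the full-scale protocol — 10 s at 250 Hz, 5 s training
half, 250-sample windows slid 1 sample, a 3×50 LSTM trained 500 epochs with
Adam at 1e-3 and batch 50 — and the printed diagnostic thresholds.  Unknown
keys are rejected; a config round-trips through ``to_dict``/``from_dict``
unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


class ConfigError(ValueError):
    pass


@dataclass
class SynthSection:
    duration_s: float = 10.0
    fs_hz: float = 250.0
    heart_rate_bpm: float = 60.0
    kappa: float = 0.3
    nonlinearity: float = 0.0
    noise_white_uv: float = 5.0
    wander_uv: float = 30.0
    wander_hz: float = 0.25
    rr_jitter: float = 0.03
    pathologies: list = field(default_factory=list)


@dataclass
class FilterSection:
    low_hz: float = 0.05
    high_hz: float = 100.0
    enabled: bool = True


@dataclass
class SplitSection:
    train_s: float = 5.0


@dataclass
class WindowSection:
    len_samples: int = 250
    step_samples: int = 1


@dataclass
class LRSection:
    ridge: float = 0.0


@dataclass
class LSTMSection:
    n_layers: int = 3
    hidden: int = 50
    batch: int = 50
    epochs: int = 500
    learning_rate: float = 0.001
    predict_step: int = 1


@dataclass
class DiagnoseSection:
    wide_qrs_ms: float = 120.0
    st_mv: float = 0.1
    st_delay_after_j_s: float = 0.080
    q_fraction_of_r: float = 0.25
    q_duration_ms: float = 40.0
    lvh_mv: float = 3.5


_SECTIONS = {
    "synth": SynthSection,
    "filter": FilterSection,
    "split": SplitSection,
    "window": WindowSection,
    "lr": LRSection,
    "lstm": LSTMSection,
    "diagnose": DiagnoseSection,
}


@dataclass
class RunConfig:
    synth: SynthSection = field(default_factory=SynthSection)
    filter: FilterSection = field(default_factory=FilterSection)
    split: SplitSection = field(default_factory=SplitSection)
    window: WindowSection = field(default_factory=WindowSection)
    lr: LRSection = field(default_factory=LRSection)
    lstm: LSTMSection = field(default_factory=LSTMSection)
    diagnose: DiagnoseSection = field(default_factory=DiagnoseSection)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        for name, section_cls in _SECTIONS.items():
            sub = d.pop(name, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ConfigError(
                    f"unknown key(s) in section {name!r}: {sorted(unknown)}")
            kwargs[name] = section_cls(**sub)
        seed = d.pop("seed", 0)
        if d:
            raise ConfigError(f"unknown top-level key(s): {sorted(d)}")
        return cls(seed=int(seed), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls.from_dict(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)
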