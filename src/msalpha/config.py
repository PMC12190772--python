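"""Run configuration: every analysis constant in one serializable object.

The TOML layout groups settings by stage; defaults are the analysis-standard
values (1-45 Hz band, 4 s epochs, ±200 µV bad-channel rule, 1000 GFP peaks
with 10 ms spacing and the 20 µV / ±1 SD rules, k range 2-8 with 50
restarts and 2000 iterations, 2 s Hamming Welch windows, the [1,40] Hz
knee-free parameterization with peak width limits [1,10], alpha band 8-12
Hz, FDR family size 6).
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig", "load_config", "save_config", "default_config_toml"]


@dataclass
class PreprocessConfig:
    notch_hz: float = 50.0
    band_low: float = 1.0
    band_high: float = 45.0
    epoch_length_s: float = 4.0
    bad_channel_uv: float = 200.0
    artifact_amplitude_uv: float = 400.0
    artifact_gradient_uv_per_ms: float = 100.0


@dataclass
class MicrostateConfig:
    n_peaks: int = 1000
    min_interval_ms: float = 10.0
    min_peak_uv: float = 20.0
    sd_band: float = 1.0
    k_min: int = 2
    k_max: int = 8
    n_init: int = 50
    max_iter: int = 2000
    fixed_k: int = 0  # 0 = choose by criterion table
    min_segment_ms: float = 0.0


@dataclass
class SpectralConfig:
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    fit_lo: float = 1.0
    fit_hi: float = 40.0
    peak_width_lo: float = 1.0
    peak_width_hi: float = 10.0
    max_n_peaks: int = 10
    peak_threshold: float = 1.0
    min_peak_height: float = 0.0
    alpha_lo: float = 8.0
    alpha_hi: float = 12.0


@dataclass
class StatsConfig:
    fdr_family_size: int = 6
    ms_instance_limit: int = 3
    tp_instance_limit: int = 4


@dataclass
class SimulateConfig:
    n_per_group: int = 10
    n_channels: int = 32
    fs: float = 250.0
    duration_s: float = 60.0
    k: int = 5
    snr: float = 4.0


@dataclass
class RunConfig:
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    microstate: MicrostateConfig = field(default_factory=MicrostateConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        p, m, s = self.preprocess, self.microstate, self.spectral
        if not 0 < p.band_low < p.band_high:
            raise ValueError("preprocess band edges invalid")
        if m.k_max < m.k_min or m.k_min < 2:
            raise ValueError("microstate k range invalid")
        if m.n_init < 1 or m.max_iter < 1 or m.n_peaks < 1:
            raise ValueError("microstate iteration settings invalid")
        if not 0 < s.fit_lo < s.fit_hi:
            raise ValueError("spectral fit range invalid")
        if not s.alpha_lo < s.alpha_hi:
            raise ValueError("alpha band invalid")
        if self.stats.fdr_family_size < 1:
            raise ValueError("FDR family size must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs: dict = {"seed": d.get("seed", 0)}
        for name, sub_cls in [
            ("preprocess", PreprocessConfig),
            ("microstate", MicrostateConfig),
            ("spectral", SpectralConfig),
            ("stats", StatsConfig),
            ("simulate", SimulateConfig),
        ]:
            if name in d:
                kwargs[name] = sub_cls(**d[name])
        return cls(**kwargs)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, float):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the configuration as TOML (round-trips through load_config)."""
    d = cfg.to_dict()
    lines = [f"seed = {d.pop('seed')}"]
    for section, values in d.items():
        lines.append(f"\n[{section}]")
        for key, v in values.items():
            lines.append(f"{key} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> RunConfig:
    with open(path, "rb") as fh:
        return RunConfig.from_dict(tomllib.load(fh))


def default_config_toml() -> str:
    """The complete default configuration as a TOML string."""
    import tempfile

    with tempfile.NamedTemporaryFile("r", suffix=".toml") as fh:
        save_config(RunConfig(), fh.name)
        return Path(fh.name).read_text()
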