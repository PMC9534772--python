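"""Run configuration.

Defaults are the design parameters of the sequential smFISH workflow:
35-nt binding sites at 45–75% GC with no 5-base homopolymer, 15-nt
off-target match cutoff, expansion when a gene yields 40 or fewer probes,
probe sets trimmed to 40 toward 55% GC, 20-nt readouts at 45–60% GC
rejected above 14 nt of transcriptome homology, 15-nt readout sites in the
primary probe (total assembled length 141 nt), three fluorophore channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class DesignConfig:
    window: int = 35
    gc_min: float = 45.0
    gc_max: float = 75.0
    max_homopolymer_run: int = 4  # runs of max_homopolymer_run+1 fail
    offtarget_k: int = 15
    expansion_threshold: int = 40  # expand when final exonic count <= this
    max_probes: int = 40
    gc_target: float = 55.0
    readout_length: int = 20
    readout_gc_min: float = 45.0
    readout_gc_max: float = 60.0
    readout_max_homology: int = 14
    readout_site_len: int = 15
    channels: list[str] = field(default_factory=lambda: ["AF647", "AF488", "AF546"])
    seed: int = 0
    intron_reversal_mode: str = "reverse"  # or "revcomp"
    cross_check: bool = False  # mutual readout orthogonality
    ortho_k: int = 12
    step: int = 1

    def validate(self) -> "DesignConfig":
        if not (self.gc_min <= self.gc_target <= self.gc_max):
            raise ConfigError(
                f"require gc_min <= gc_target <= gc_max, got "
                f"gc_min={self.gc_min}, gc_target={self.gc_target}, gc_max={self.gc_max}"
            )
        if self.readout_gc_min > self.readout_gc_max:
            raise ConfigError(
                f"readout_gc_min={self.readout_gc_min} > readout_gc_max={self.readout_gc_max}"
            )
        for name in (
            "window",
            "offtarget_k",
            "max_probes",
            "readout_length",
            "readout_site_len",
            "ortho_k",
            "step",
        ):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if self.max_homopolymer_run < 1:
            raise ConfigError(
                f"max_homopolymer_run must be positive, got {self.max_homopolymer_run}"
            )
        if self.readout_site_len > self.readout_length:
            raise ConfigError(
                f"readout_site_len={self.readout_site_len} exceeds "
                f"readout_length={self.readout_length}"
            )
        if self.intron_reversal_mode not in ("reverse", "revcomp"):
            raise ConfigError(
                f"intron_reversal_mode must be 'reverse' or 'revcomp', "
                f"got {self.intron_reversal_mode!r}"
            )
        if not self.channels:
            raise ConfigError("channels must be non-empty")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DesignConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
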