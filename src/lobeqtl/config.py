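"""Run configuration for the end-to-end pipeline.

Defaults are the study's analysis settings: 25 harmonics, 256
imputations, 1000 permutations at alpha 0.05, 1 cM scan step, a 10 cM CIM
window with 4 marker covariates, 47 individuals per phenotypic tail, and
one million candidate-test resamples.  Simulation sizes default to the
study populations (367 F2, 344 F17 males, census 500).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    # morphometrics
    n_harmonics: int = 25
    n_outline_points: int = 128
    jitter_sd: float = 5e-5
    # scans
    n_imputations: int = 256
    n_permutations: int = 1000
    alpha: float = 0.05
    step: float = 1.0
    cim_window: float = 10.0
    cim_covariates: int = 4
    epsilon: float = 1e-4
    # populations
    n_f2: int = 367
    n_f17: int = 344
    census: int = 500
    tail_count: int = 47
    heritability: float = 0.265
    paired_corr: float = 0.85
    # candidate test
    n_resamples: int = 1_000_000
    candidate_file: str | None = None

    def __post_init__(self):
        checks = [
            (self.n_harmonics >= 1, "need at least one harmonic"),
            (self.n_outline_points >= 32, "need at least 32 outline points"),
            (self.n_imputations >= 1, "need at least one imputation"),
            (self.n_permutations >= 1, "need at least one permutation"),
            (0 < self.alpha < 1, "alpha must be in (0, 1)"),
            (self.step > 0, "scan step must be positive"),
            (self.cim_window > 0, "CIM window must be positive"),
            (self.cim_covariates >= 0, "CIM covariate count must be nonnegative"),
            (0 <= self.epsilon < 0.5, "genotyping error rate must be in [0, 0.5)"),
            (self.n_f2 >= 2 and self.n_f17 >= 2, "population sizes must be at least 2"),
            (self.census >= 2, "census must be at least 2"),
            (2 * self.tail_count <= self.n_f17, "tails cannot exceed the F17 population"),
            (0 < self.heritability < 1, "heritability must be in (0, 1)"),
            (0 <= self.paired_corr <= 1, "paired-lobe correlation must be in [0, 1]"),
            (self.n_resamples >= 1, "need at least one resample"),
            (self.jitter_sd >= 0, "jitter SD must be nonnegative"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def to_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d):
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def digest(self):
        """Stable hash of the full configuration, recorded in every output."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kw):
        return dataclasses.replace(self, **kw)
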