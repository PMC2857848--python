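"""Flat key = value configuration for the pipeline.

A config file is plain text, one ``key = value`` per line, ``#`` comments
allowed.  Defaults reproduce the reference study conditions: 5 sires, 20
dams, 2000 offspring (half phenotyped), 453 SNPs on five 1-Morgan
chromosomes, and 15000-iteration chains with 5500 burn-in thinned by 30.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields

from .samplers import METHODS, ChainConfig


@dataclass
class PipelineConfig:
    # population
    n_sires: int = 5
    n_dams: int = 20
    n_offspring: int = 2000
    n_markers: int = 453
    n_chrom: int = 5
    chrom_length: float = 1.0
    founder_freq: float = 0.5
    # trait architecture
    n_qtl: int = 10
    h2: float = 0.5
    genetic_cv: float = 0.10
    effect_shape: float = 0.4
    # growth base curve
    growth_A: float = 100.0
    growth_b: float = 3.0
    growth_k: float = 0.01
    predict_at: float = 600.0
    # chains
    methods: tuple = METHODS
    n_iter: int = 15000
    burn_in: int = 5500
    thin: int = 30
    # evaluation
    traits: tuple = ("t530", "t600")
    ebv_h2: float = 0.5
    cv_reps: int = 10
    cv_train_frac: float = 0.9
    seed: int = 1

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")

    def content_hash(self) -> str:
        text = ";".join(f"{f.name}={getattr(self, f.name)}"
                        for f in fields(self))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _coerce(value: str, target):
    if isinstance(target, bool):
        return value.strip().lower() in ("1", "true", "yes", "on")
    if isinstance(target, int):
        return int(value)
    if isinstance(target, float):
        return float(value)
    if isinstance(target, tuple):
        return tuple(v.strip() for v in value.split(",") if v.strip())
    return value.strip()


def parse_config_text(text: str) -> dict:
    out = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def load_chain_config(path=None, text: str | None = None,
                      overrides: dict | None = None) -> ChainConfig:
    """Build a :class:`~gebvpipe.samplers.ChainConfig` from flat key = value
    text (method, n_iter, burn_in, thin, seed and the method
    hyperparameters v, s2, A_upper, a, b)."""
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw.update(parse_config_text(fh.read()))
    if text is not None:
        raw.update(parse_config_text(text))
    if overrides:
        raw.update({k: str(v) for k, v in overrides.items() if v is not None})
    kwargs: dict = {}
    ints = {"n_iter", "burn_in", "thin", "seed"}
    floats = {"v", "s2", "A_upper", "a", "b", "metropolis_step",
              "expected_marker_var"}
    for key, value in raw.items():
        if key == "method":
            kwargs[key] = value
        elif key in ints:
            kwargs[key] = int(value)
        elif key in floats:
            kwargs[key] = float(value)
        else:
            raise KeyError(f"unknown chain config key {key!r}")
    return ChainConfig(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw.update(parse_config_text(fh.read()))
    if overrides:
        raw.update({k: str(v) for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig()
    known = {f.name: getattr(cfg, f.name) for f in fields(cfg)}
    kwargs = {}
    for key, value in raw.items():
        if key not in known:
            raise KeyError(f"unknown config key {key!r}")
        kwargs[key] = _coerce(value, known[key])
    return PipelineConfig(**kwargs)
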