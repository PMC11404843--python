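"""Configuration loading, experiment presets, and result I/O.

Experiment presets mirror the study designs: payoff-vs-group-size curves by
bias type and by bias strength, final-gap distributions, the bias-strength
sweep for regime/optimum analysis, and the polarization runs. Learning-rate
pairs that were printed as decimals are stored verbatim rather than
re-derived through the ratio.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agents import BiasSpec
from .environment import ConfigurationError, SCARCITY_PRESETS
from .simulation import ExperimentConfig, SweepCell

__all__ = [
    "EXPERIMENT_PRESETS",
    "ExperimentPreset",
    "experiment_preset",
    "load_config",
    "read_results",
    "write_results",
]

# Printed learning-rate pairs (alpha_plus, alpha_minus), stored verbatim.
RATES_UNBIASED = (0.1, 0.1)
RATES_WEAK = (0.15, 0.05)
RATES_MEDIUM = (0.17, 0.03)
RATES_STRONG = (0.18, 0.02)
RATES_DISCONF_WEAK = (0.05, 0.15)
RATES_DISCONF_MEDIUM = (0.03, 0.17)
RATES_DISCONF_STRONG = (0.02, 0.18)

DEFAULT_BETA = 4.0

#: Bias-strength grid for the regime / optimal-bias sweeps.
BIAS_STRENGTH_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)


@dataclass(frozen=True)
class ExperimentPreset:
    """A named experiment design expanding to a list of sweep cells."""

    name: str
    description: str
    cells: tuple[SweepCell, ...]


def _explicit(rates: tuple[float, float]) -> BiasSpec:
    return BiasSpec(scheme="explicit", alpha_plus=rates[0], alpha_minus=rates[1])


def _cell_seeds(base_seed: int, count: int) -> list[int]:
    """Stable per-cell seeds derived from the base seed."""
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(count)]


def _fig1_bias_type(seed: int) -> tuple[SweepCell, ...]:
    cells = []
    labels = [("confirmatory", RATES_WEAK), ("unbiased", RATES_UNBIASED),
              ("disconfirmatory", RATES_DISCONF_WEAK)]
    combos = [
        (preset, bias_label, rates, n)
        for preset in SCARCITY_PRESETS
        for bias_label, rates in labels
        for n in range(1, 21)
    ]
    seeds = _cell_seeds(seed, len(combos))
    for s, (preset, bias_label, rates, n) in zip(seeds, combos):
        cells.append(SweepCell(
            label={"experiment": "fig1_bias_type", "preset": preset,
                   "bias_type": bias_label},
            config=ExperimentConfig(task=preset, n=n, trials=100,
                                    bias=_explicit(rates), beta=DEFAULT_BETA,
                                    n_sims=500, seed=s),
        ))
    return tuple(cells)


def _fig1_bias_strength(seed: int) -> tuple[SweepCell, ...]:
    cells = []
    conditions = [
        ("weak", "confirmatory", RATES_WEAK),
        ("weak", "disconfirmatory", RATES_DISCONF_WEAK),
        ("medium", "confirmatory", RATES_MEDIUM),
        ("medium", "disconfirmatory", RATES_DISCONF_MEDIUM),
        ("strong", "confirmatory", RATES_STRONG),
        ("strong", "disconfirmatory", RATES_DISCONF_STRONG),
        ("none", "unbiased", RATES_UNBIASED),
    ]
    combos = [(cond, n) for cond in conditions for n in range(1, 11)]
    seeds = _cell_seeds(seed, len(combos))
    for s, ((strength, bias_label, rates), n) in zip(seeds, combos):
        cells.append(SweepCell(
            label={"experiment": "fig1_bias_strength", "preset": "rich",
                   "strength": strength, "bias_type": bias_label},
            config=ExperimentConfig(task="rich", n=n, trials=200,
                                    bias=_explicit(rates), beta=DEFAULT_BETA,
                                    n_sims=500, seed=s),
        ))
    return tuple(cells)


def _fig2(seed: int) -> tuple[SweepCell, ...]:
    cells = []
    combos = [(n, b) for n in (2, 5) for b in (1.0, 3.0, 9.0)]
    seeds = _cell_seeds(seed, len(combos))
    for s, (n, b) in zip(seeds, combos):
        cells.append(SweepCell(
            label={"experiment": "fig2", "preset": "rich"},
            config=ExperimentConfig(task="rich", n=n, trials=1000,
                                    bias=BiasSpec(scheme="fixed_sum", b=b),
                                    beta=DEFAULT_BETA, n_sims=1000, seed=s),
        ))
    return tuple(cells)


def _bias_strength_sweep(seed: int, experiment: str) -> tuple[SweepCell, ...]:
    cells = []
    combos = [
        (preset, n, b)
        for preset in SCARCITY_PRESETS
        for n in (2, 5)
        for b in BIAS_STRENGTH_GRID
    ]
    seeds = _cell_seeds(seed, len(combos))
    for s, (preset, n, b) in zip(seeds, combos):
        cells.append(SweepCell(
            label={"experiment": experiment, "preset": preset},
            config=ExperimentConfig(task=preset, n=n, trials=1000,
                                    bias=BiasSpec(scheme="fixed_minus", b=b),
                                    beta=DEFAULT_BETA, n_sims=1000, seed=s),
        ))
    return tuple(cells)


_PRESET_BUILDERS = {
    "fig1_bias_type": (
        "Payoff vs group size (1..20) × bias type × scarcity; T=100, 500 sims",
        _fig1_bias_type,
    ),
    "fig1_bias_strength": (
        "Payoff vs group size (1..10) × bias strength, rich; T=200, 500 sims",
        _fig1_bias_strength,
    ),
    "fig2": (
        "Final-gap distributions, rich, n∈{2,5}, b∈{1,3,9} fixed-sum; T=1000, 1000 sims",
        _fig2,
    ),
    "fig3": (
        "Bias-strength sweep b=1..5 (fixed alpha_minus), all presets, n∈{2,5}; T=1000, 1000 sims",
        lambda seed: _bias_strength_sweep(seed, "fig3"),
    ),
    "fig4": (
        "Same sweep as fig3; analyze gap differences (polarization)",
        lambda seed: _bias_strength_sweep(seed, "fig4"),
    ),
}

EXPERIMENT_PRESETS = tuple(_PRESET_BUILDERS)


def experiment_preset(name: str, seed: int = 0) -> ExperimentPreset:
    """Expand a named experiment design into concrete sweep cells."""
    try:
        description, builder = _PRESET_BUILDERS[name]
    except KeyError:
        valid = ", ".join(EXPERIMENT_PRESETS)
        raise ConfigurationError(
            f"unknown experiment preset {name!r}; valid: {valid}"
        ) from None
    return ExperimentPreset(name=name, description=description,
                            cells=builder(seed))


def _parse_bias(raw: object) -> BiasSpec:
    if isinstance(raw, BiasSpec):
        return raw
    if not isinstance(raw, dict):
        raise ConfigurationError(f"bias must be a mapping, got {type(raw).__name__}")
    if "alpha_plus" in raw or "alpha_minus" in raw:
        spec = BiasSpec(scheme="explicit",
                        alpha_plus=raw.get("alpha_plus"),
                        alpha_minus=raw.get("alpha_minus"))
    else:
        spec = BiasSpec(scheme=raw.get("scheme", "fixed_sum"), b=raw.get("b"))
    try:
        spec.resolve()
    except ValueError as exc:
        raise ConfigurationError(f"bias: {exc}") from exc
    return spec


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment configuration from YAML or JSON.

    Required keys: ``preset`` (or ``task: [p1, p2]``), ``n``, ``bias``.
    Optional with defaults: ``beta`` (4.0), ``trials`` (1000), ``n_sims``
    (1000), ``seed`` (0), ``record``, ``q0``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping in {path}")
    errors = []
    task = raw.get("preset", raw.get("task"))
    if task is None:
        errors.append("missing 'preset' (or 'task')")
    if "n" not in raw:
        errors.append("missing 'n' (group size)")
    if "bias" not in raw:
        errors.append("missing 'bias'")
    if errors:
        raise ConfigurationError(
            f"invalid config {path}: " + "; ".join(errors)
        )
    if isinstance(task, list):
        task = tuple(task)
    try:
        return ExperimentConfig(
            task=task,
            n=int(raw["n"]),
            trials=int(raw.get("trials", 1000)),
            bias=_parse_bias(raw["bias"]),
            beta=float(raw.get("beta", DEFAULT_BETA)),
            n_sims=int(raw.get("n_sims", 1000)),
            seed=int(raw.get("seed", 0)),
            record=tuple(raw.get("record", ("payoffs",))),
            q0=float(raw.get("q0", 0.0)),
        )
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def _config_hash(metadata: dict) -> str:
    blob = json.dumps(metadata, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(
    table: pd.DataFrame,
    metadata: dict,
    out_dir: str | Path,
    stem: str | None = None,
) -> tuple[Path, Path]:
    """Write a tidy result table plus JSON metadata (seed, parameters).

    File names derive from a hash of the metadata, so identical runs
    produce byte-identical files at identical paths.
    """
    if table.empty:
        raise ValueError("refusing to write empty results")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"results-{_config_hash(metadata)}"
    csv_path = out_dir / f"{stem}.csv"
    meta_path = out_dir / f"{stem}.meta.json"
    table.to_csv(csv_path, index=False)
    meta_path.write_text(json.dumps(metadata, indent=2, sort_keys=True, default=str))
    return csv_path, meta_path


def read_results(csv_path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Load a result table and its sidecar metadata."""
    csv_path = Path(csv_path)
    if not csv_path.exists():
        raise ConfigurationError(f"results file not found: {csv_path}")
    table = pd.read_csv(csv_path)
    meta_path = csv_path.parent / (csv_path.stem + ".meta.json")
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return table, metadata
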