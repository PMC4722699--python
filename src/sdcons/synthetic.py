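"""Synthetic score-table generator with planted actives.

Every other module is testable without any external download by emulating
the statistical structure the analysis assumes: unimodal score
distributions with a stand-out good tail, a small planted active fraction
(0.5 % by default), and weak inter-program rank correlation.

The mechanism is a single latent-signal model.  Each molecule has a latent
goodness g ~ N(0, 1); program p observes

    z_p = w * g + (1 - w) * eps_p + s_p * 1{active}

with independent noise eps_p ~ N(0, 1), shared-signal weight w in [0, 1]
and per-program sensitivity s_p >= 0 (the mean z-shift of actives).  w
controls the inter-program correlation continuously between independence
(w = 0) and identical rankings (w = 1); the default w = 0.3 yields the weak
r ~ 0.15 regime typical of divergent docking programs.  Raw scores are an
affine map of z respecting each program's declared direction, so
standardization recovers z up to the active perturbation of mean/SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .benchmark import TargetBundle
from .errors import ConfigurationError
from .score_io import (
    HIGHER_BETTER,
    LOWER_BETTER,
    ActivityLabels,
    ScoreEntry,
    ScoreTable,
    write_activity_labels,
    write_score_table,
)


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic target library.

    sensitivity may be a scalar (shared by all programs) or one value per
    program.  ``nuisance_weight`` optionally adds a shared molecule-size-like
    covariate to the programs named in ``nuisance_programs`` (emulating
    scoring functions that correlate with atom count); off by default.
    """

    n_molecules: int = 2000
    active_fraction: float = 0.005
    k_programs: int = 4
    sensitivity: float | Sequence[float] = 2.0
    shared_signal_weight: float = 0.3
    directions: Optional[Sequence[str]] = None
    program_names: Optional[Sequence[str]] = None
    nuisance_weight: float = 0.0
    nuisance_programs: Optional[Sequence[str]] = None
    seed: int = 0
    target_name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_molecules < 4:
            raise ConfigurationError("n_molecules must be >= 4")
        if not 0 < self.active_fraction < 1:
            raise ConfigurationError(
                f"active_fraction must be in (0, 1), got {self.active_fraction}"
            )
        if self.k_programs < 2:
            raise ConfigurationError("k_programs must be >= 2")
        if not 0 <= self.shared_signal_weight <= 1:
            raise ConfigurationError("shared_signal_weight must be in [0, 1]")
        if round(self.n_molecules * self.active_fraction) < 1:
            raise ConfigurationError(
                "active_fraction too small: no actives would be planted"
            )

    @property
    def sensitivities(self) -> list[float]:
        if np.isscalar(self.sensitivity):
            s = [float(self.sensitivity)] * self.k_programs
        else:
            s = [float(v) for v in self.sensitivity]
        if len(s) != self.k_programs:
            raise ConfigurationError(
                f"need one sensitivity per program ({self.k_programs}), got {len(s)}"
            )
        if any(v < 0 for v in s):
            raise ConfigurationError("sensitivities must be >= 0")
        return s

    @property
    def resolved_directions(self) -> list[str]:
        if self.directions is None:
            # mixed directions by default so both conventions are exercised
            return [LOWER_BETTER] * (self.k_programs - 1) + [HIGHER_BETTER]
        d = list(self.directions)
        if len(d) != self.k_programs:
            raise ConfigurationError("need one direction per program")
        return d

    @property
    def resolved_names(self) -> list[str]:
        if self.program_names is None:
            return [f"prog{chr(ord('A') + i)}" for i in range(self.k_programs)]
        names = list(self.program_names)
        if len(names) != self.k_programs:
            raise ConfigurationError("need one name per program")
        return names


def generate_target(config: GeneratorConfig) -> TargetBundle:
    """Generate one target bundle (k score tables + labels), seeded."""
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    ids = [f"mol{i:06d}" for i in range(n)]
    n_act = int(round(n * config.active_fraction))
    active_idx = rng.choice(n, size=n_act, replace=False)
    active_mask = np.zeros(n)
    active_mask[active_idx] = 1.0
    actives = {ids[i] for i in active_idx}

    latent = rng.standard_normal(n)
    nuisance = rng.standard_normal(n)
    w = config.shared_signal_weight
    names = config.resolved_names
    directions = config.resolved_directions
    sens = config.sensitivities
    nuis_targets = set(
        config.nuisance_programs
        if config.nuisance_programs is not None
        else names[:2]
    )

    tables = []
    for name, direction, s in zip(names, directions, sens):
        eps = rng.standard_normal(n)
        z = w * latent + (1 - w) * eps + s * active_mask
        if config.nuisance_weight > 0 and name in nuis_targets:
            z = z + config.nuisance_weight * nuisance
        if direction == LOWER_BETTER:
            center = rng.uniform(-9.0, -5.0)
            spread = rng.uniform(0.8, 1.8)
            scores = center - spread * z
        else:
            center = rng.uniform(40.0, 60.0)
            spread = rng.uniform(5.0, 15.0)
            scores = center + spread * z
        entries = [ScoreEntry(m, float(sc)) for m, sc in zip(ids, scores)]
        tables.append(ScoreTable(name, config.target_name, direction, entries))

    labels = ActivityLabels(config.target_name, actives, set(ids))
    return TargetBundle(config.target_name, tables, labels)


def generate_cohort(
    n_targets: int,
    config_template: Optional[GeneratorConfig] = None,
    per_target_jitter: float = 0.4,
    seed: int = 0,
) -> list[TargetBundle]:
    """Generate independent target bundles with jittered sensitivities.

    Per-target jitter (a truncated-at-zero normal perturbation of each
    program's sensitivity, SD ``per_target_jitter``) makes method rankings
    differ across targets, as program performance does on real cohorts.
    """
    if n_targets < 1:
        raise ConfigurationError("n_targets must be >= 1")
    if per_target_jitter < 0:
        raise ConfigurationError("per_target_jitter must be >= 0")
    template = config_template or GeneratorConfig()
    master = np.random.default_rng(seed)
    bundles = []
    base_sens = template.sensitivities
    for i in range(n_targets):
        jittered = tuple(
            max(0.0, s + per_target_jitter * master.standard_normal())
            for s in base_sens
        )
        child_seed = int(master.integers(0, 2**31 - 1))
        cfg = replace(
            template,
            sensitivity=jittered,
            seed=child_seed,
            target_name=f"t{i:03d}",
        )
        bundles.append(generate_target(cfg))
    return bundles


def write_cohort(bundles: Sequence[TargetBundle], out_dir: str | Path) -> Path:
    """Write a cohort as CSV files plus a YAML manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"targets": []}
    for bundle in bundles:
        entry: dict = {
            "name": bundle.target_name,
            "labels": f"{bundle.target_name}_labels.csv",
            "tables": [],
        }
        write_activity_labels(bundle.labels, out_dir / entry["labels"])
        for t in bundle.tables:
            fname = f"{bundle.target_name}_{t.program_name}.csv"
            write_score_table(t, out_dir / fname)
            entry["tables"].append(
                {"program": t.program_name, "path": fname, "direction": t.direction}
            )
        manifest["targets"].append(entry)
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path
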