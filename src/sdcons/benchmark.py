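"""Multi-target benchmark orchestration.

Mirrors the protocol used to compare consensus methods against single
programs on a cohort of targets: dilute each library to a realistic active
density (0.5 % by default), run every method at each candidate selection
size n_test, and summarize three criteria per n_test — the fraction of
targets with at least one hit (T_h>0), the mean corrected yield <Y_C> with
its standard error, and the net balance Delta_p of each method against a
reference method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import metrics as mtr
from .errors import (
    ConfigurationError,
    InfeasibleConsensusError,
    ValidationError,
)
from .score_io import (
    ActivityLabels,
    ScoreEntry,
    ScoreTable,
    read_activity_labels,
    read_score_table,
)

logger = logging.getLogger(__name__)

DEFAULT_DENSITY = 0.005
METHOD_VSDC = "vSDC"
METHOD_USC = "USC"
METHOD_SDC = "SDC"


@dataclass
class TargetBundle:
    """One target: k score tables (one per program) plus activity labels."""

    target_name: str
    tables: list[ScoreTable]
    labels: ActivityLabels

    def __post_init__(self) -> None:
        if len(self.tables) < 2:
            raise ValidationError(
                f"target {self.target_name!r} needs >= 2 score tables"
            )
        for t in self.tables:
            stray = t.id_set() - self.labels.library
            if stray:
                raise ValidationError(
                    f"target {self.target_name!r}: table {t.program_name!r} has "
                    f"ids outside the labelled library: {sorted(stray)[:5]}"
                )

    @property
    def program_names(self) -> list[str]:
        return [t.program_name for t in self.tables]


@dataclass
class BenchmarkSummary:
    """Per-n_test criterion curves for each method over a cohort.

    ``summary`` is tidy: one row per (method, n_test) with T_h>0, mean Y_C,
    its SEM and Delta_p against ``reference``.  ``outcomes`` holds the
    per-target records the summary was computed from.
    """

    methods: list[str]
    n_test_grid: list[int]
    reference: str
    summary: pd.DataFrame
    outcomes: pd.DataFrame


def dilute_actives(
    labels: ActivityLabels, density: float = DEFAULT_DENSITY, seed: int = 0
) -> ActivityLabels:
    """Randomly remove actives until their density is at most ``density``.

    Removed actives leave the library entirely (they are eliminated, not
    relabelled), so the retained count A is the largest integer with
    A / (N_inactive + A) <= density.  Libraries already at or below the
    density are returned unchanged.  Deterministic under ``seed``.
    """
    if not 0 < density < 1:
        raise ConfigurationError(f"density must be in (0, 1), got {density}")
    n_inactive = len(labels.library) - labels.n_actives
    if labels.n_actives / max(len(labels.library), 1) <= density:
        return labels
    a_keep = math.floor(density * n_inactive / (1.0 - density))
    if a_keep < 1:
        raise ConfigurationError(
            f"target {labels.target_name!r}: diluting to density {density} would "
            f"leave no actives ({n_inactive} inactives)"
        )
    a_keep = min(a_keep, labels.n_actives)
    rng = np.random.default_rng(seed)
    kept = set(rng.choice(sorted(labels.actives), size=a_keep, replace=False))
    removed = labels.actives - kept
    return ActivityLabels(
        labels.target_name, kept, labels.library - removed
    )


def dilute_bundle(
    bundle: TargetBundle, density: float = DEFAULT_DENSITY, seed: int = 0
) -> TargetBundle:
    """Dilute a bundle's labels and drop the removed actives from every table."""
    new_labels = dilute_actives(bundle.labels, density, seed)
    removed = bundle.labels.library - new_labels.library
    if not removed:
        return bundle
    tables = []
    for t in bundle.tables:
        entries = [e for e in t.entries if e.molecule_id not in removed]
        tables.append(ScoreTable(t.program_name, t.target_name, t.direction, entries))
    return TargetBundle(bundle.target_name, tables, new_labels)


def _table_by_program(bundle: TargetBundle, program: str) -> ScoreTable:
    for t in bundle.tables:
        if t.program_name == program:
            return t
    raise ConfigurationError(
        f"no table for program {program!r} in target {bundle.target_name!r}"
    )


def run_methods(
    bundle: TargetBundle,
    n_test: int,
    methods: Sequence[str],
    x_sdc: float = cns.SDC_DEFAULT_X,
    match_sdc_ncm: bool = False,
    vsdc_kwargs: Optional[dict] = None,
) -> list[mtr.SelectionOutcome]:
    """Run the requested methods on one target at one selection size.

    ``methods`` entries are ``"vSDC"``, ``"USC"``, ``"SDC"`` or a program
    name (meaning that program's top-n baseline).  With ``match_sdc_ncm``
    single-program baselines are evaluated at the target's SDC nCM instead
    of ``n_test`` (the fixed-cutoff comparison protocol).  A vSDC selection
    that is infeasible for this target degrades to a flagged zero-hit
    outcome instead of aborting a cohort sweep.
    """
    vsdc_kwargs = dict(vsdc_kwargs or {})
    outcomes: list[mtr.SelectionOutcome] = []
    sdc_ncm: Optional[int] = None
    if match_sdc_ncm or METHOD_SDC in methods:
        sdc_result = cns.sdc(bundle.tables, x=x_sdc)
        sdc_ncm = sdc_result.nCM
    for method in methods:
        if method == METHOD_VSDC:
            try:
                sel = cns.vsdc(bundle.tables, n_test, **vsdc_kwargs)
            except InfeasibleConsensusError as exc:
                logger.warning(
                    "vSDC infeasible for target %s at n_test=%d: %s",
                    bundle.target_name, n_test, exc,
                )
                outcomes.append(
                    mtr.SelectionOutcome(
                        target_name=bundle.target_name,
                        n_test=n_test,
                        h=0,
                        A=bundle.labels.n_actives,
                        method=METHOD_VSDC,
                        infeasible=True,
                    )
                )
                continue
        elif method == METHOD_USC:
            if n_test < len(bundle.tables):
                outcomes.append(
                    mtr.SelectionOutcome(
                        target_name=bundle.target_name,
                        n_test=n_test,
                        h=0,
                        A=bundle.labels.n_actives,
                        method=METHOD_USC,
                        infeasible=True,
                    )
                )
                continue
            sel = cns.usc(bundle.tables, n_test)
        elif method == METHOD_SDC:
            sel = cns.sdc(bundle.tables, x=x_sdc)
        else:
            table = _table_by_program(bundle, method)
            n = sdc_ncm if match_sdc_ncm else n_test
            if n == 0:
                outcomes.append(
                    mtr.SelectionOutcome(
                        target_name=bundle.target_name,
                        n_test=0, h=0, A=bundle.labels.n_actives, method=method,
                    )
                )
                continue
            sel = cns.top_n(table, min(n, len(table)))
            sel = replace(sel, method=method)
        outcomes.append(mtr.count_hits(sel, bundle.labels))
    return outcomes


def default_methods(bundles: Sequence[TargetBundle]) -> list[str]:
    """vSDC, USC and one top-n baseline per program of the first bundle."""
    return [METHOD_VSDC, METHOD_USC] + bundles[0].program_names


def sweep(
    bundles: Sequence[TargetBundle],
    n_test_grid: Sequence[int] = tuple(range(1, 51)),
    methods: Optional[Sequence[str]] = None,
    reference: str = METHOD_VSDC,
    usc_paper_mode: bool = False,
    x_sdc: float = cns.SDC_DEFAULT_X,
    vsdc_kwargs: Optional[dict] = None,
) -> BenchmarkSummary:
    """Evaluate every method at every n_test over a cohort of targets.

    With ``usc_paper_mode`` the USC value at an n_test that is not a
    multiple of the program count k is the average of the evaluations at the
    two nearest multiples (e.g. the mean of n_test = 48 and 52 for
    n_test = 50 with k = 4); hit counts then become fractional.
    """
    if not bundles:
        raise ConfigurationError("sweep needs at least one target bundle")
    n_test_grid = list(n_test_grid)
    if not n_test_grid:
        raise ConfigurationError("n_test grid is empty")
    if any(n < 1 for n in n_test_grid):
        raise ConfigurationError("all n_test values must be >= 1")
    methods = list(methods) if methods is not None else default_methods(bundles)
    if reference not in methods:
        raise ConfigurationError(
            f"reference {reference!r} is not among the methods {methods}"
        )

    k = len(bundles[0].tables)
    rows = []
    for bundle in bundles:
        cache: dict[tuple[str, int], mtr.SelectionOutcome] = {}

        def outcome_at(method: str, n: int) -> mtr.SelectionOutcome:
            key = (method, n)
            if key not in cache:
                (res,) = run_methods(
                    bundle, n, [method], x_sdc=x_sdc, vsdc_kwargs=vsdc_kwargs
                )
                cache[key] = res
            return cache[key]

        for n_test in n_test_grid:
            for method in methods:
                if method == METHOD_USC and usc_paper_mode and n_test % k:
                    lo = max(k, k * (n_test // k))
                    hi = lo + k
                    o_lo, o_hi = outcome_at(method, lo), outcome_at(method, hi)
                    h = 0.5 * (o_lo.h + o_hi.h)
                    yc = 0.5 * (
                        _safe_yc(o_lo) + _safe_yc(o_hi)
                    )
                    hit_ind = 0.5 * ((o_lo.h > 0) + (o_hi.h > 0))
                    rows.append(
                        dict(
                            target=bundle.target_name, method=method, n_test=n_test,
                            h=h, A=bundle.labels.n_actives, Y_C=yc,
                            hit=hit_ind, infeasible=o_lo.infeasible or o_hi.infeasible,
                            x_used=np.nan,
                        )
                    )
                    continue
                o = outcome_at(method, n_test)
                rows.append(
                    dict(
                        target=bundle.target_name, method=method, n_test=n_test,
                        h=float(o.h), A=o.A, Y_C=_safe_yc(o),
                        hit=float(o.h > 0), infeasible=o.infeasible,
                        x_used=np.nan if o.x_used is None else o.x_used,
                    )
                )
    outcomes = pd.DataFrame(rows)

    summary_rows = []
    for n_test in n_test_grid:
        at_n = outcomes[outcomes.n_test == n_test]
        ref_h = at_n[at_n.method == reference].set_index("target").h
        for method in methods:
            sub = at_n[at_n.method == method].set_index("target")
            yc = sub.Y_C.to_numpy()
            sem = float(yc.std(ddof=1) / math.sqrt(len(yc))) if len(yc) > 1 else 0.0
            wins = int((sub.h > ref_h).sum())
            losses = int((sub.h < ref_h).sum())
            summary_rows.append(
                dict(
                    method=method,
                    n_test=n_test,
                    T_h_gt0=float(sub.hit.mean()),
                    mean_Y_C=float(yc.mean()),
                    sem_Y_C=sem,
                    delta_p=(wins - losses) / len(sub),
                )
            )
    summary = pd.DataFrame(summary_rows)
    return BenchmarkSummary(
        methods=methods,
        n_test_grid=n_test_grid,
        reference=reference,
        summary=summary,
        outcomes=outcomes,
    )


def _safe_yc(outcome: mtr.SelectionOutcome) -> float:
    """Y_C, with the empty-selection convention Y_C = 0 (no molecule tested)."""
    if outcome.n_test == 0:
        return 0.0
    return mtr.corrected_yield(outcome).Y_C


def load_manifest(path: str | Path) -> list[TargetBundle]:
    """Load a YAML benchmark manifest into target bundles.

    Schema::

        targets:
          - name: t000
            labels: t000_labels.csv
            tables:
              - {program: progA, path: t000_progA.csv, direction: lower_better}

    Paths are resolved relative to the manifest file.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "targets" not in doc:
        raise ConfigurationError(f"{path}: manifest must have a 'targets' list")
    root = path.parent
    bundles = []
    for tgt in doc["targets"]:
        name = tgt.get("name")
        if not name:
            raise ConfigurationError(f"{path}: every target needs a name")
        if "labels" not in tgt:
            raise ConfigurationError(f"{path}: target {name!r} has no labels file")
        labels_path = root / tgt["labels"]
        if not labels_path.exists():
            raise ConfigurationError(
                f"{path}: target {name!r}: labels file not found: {labels_path}"
            )
        labels = read_activity_labels(labels_path, target_name=name)
        tables = []
        for spec in tgt.get("tables", []):
            tables.append(
                read_score_table(
                    root / spec["path"],
                    program_name=spec["program"],
                    direction=spec["direction"],
                    id_column=spec.get("id_column", "id"),
                    score_column=spec.get("score_column", "score"),
                    parent_column=spec.get("parent_column"),
                    target_name=name,
                )
            )
        bundles.append(TargetBundle(name, tables, labels))
    return bundles
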