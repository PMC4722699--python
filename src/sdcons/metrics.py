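"""Early-recognition metrics for small selections.

Classic whole-library indicators (ROC-AUC, BEDROC) are uninformative when an
experimentalist can only assay a handful of molecules, so comparisons here
use selection-level quantities:

* yield of actives            Y   = h / n_test
* docking enrichment          E   = h / A
* corrected yield             Y_C = h / min(A, n_test)
* targets-with-hits fraction  T_h>0 = n_p^{h>0} / N_p
* net balance                 Delta_p = (n_p^{m>ref} - n_p^{ref>m}) / N_p

where h is the number of actives retrieved in the selection and A the number
of actives in the library.  min(A, n_test) is the maximum number of
*findable* hits, which makes Y_C well behaved in both regimes (n_test << A
and n_test > A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .consensus import ConsensusResult, rank_molecules
from .errors import ConfigurationError, UndefinedMetricError, ValidationError
from .score_io import ActivityLabels, ScoreTable


@dataclass
class SelectionOutcome:
    """Hit count for one method on one target: (n_test, h, A)."""

    target_name: str
    n_test: int
    h: int
    A: int
    method: str = ""
    infeasible: bool = False
    x_used: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_test < 0 or self.h < 0 or self.A < 0:
            raise ConfigurationError("n_test, h and A must be non-negative")
        if self.h > min(self.n_test, self.A):
            raise ConfigurationError(
                f"h={self.h} exceeds min(n_test={self.n_test}, A={self.A})"
            )


@dataclass(frozen=True)
class MetricsRecord:
    Y: float
    E: float
    Y_C: float


@dataclass(frozen=True)
class CohortRecord:
    n_p_with_hits: int
    N_p: int
    T_h_gt0: float


@dataclass(frozen=True)
class ComparisonRecord:
    n_p_method_gt: int
    n_p_ref_gt: int
    N_p: int
    delta_p: float


def count_hits(selection: ConsensusResult, labels: ActivityLabels) -> SelectionOutcome:
    """Count actives among the selected molecules."""
    unknown = set(selection.members) - labels.library
    if unknown:
        raise ValidationError(
            f"selection contains ids not in the library of "
            f"{labels.target_name!r}: {sorted(unknown)[:5]}"
        )
    h = len(set(selection.members) & labels.actives)
    return SelectionOutcome(
        target_name=labels.target_name,
        n_test=len(selection.members),
        h=h,
        A=labels.n_actives,
        method=selection.method,
        x_used=selection.x_used,
    )


def corrected_yield(outcome: SelectionOutcome) -> MetricsRecord:
    """Y, E and the corrected yield Y_C for one selection outcome.

    A target with no actives has no findable hits, so A = 0 raises
    :class:`UndefinedMetricError` (such targets must be excluded upstream;
    the dilution protocol guarantees A >= 1).
    """
    if outcome.A == 0:
        raise UndefinedMetricError(
            f"target {outcome.target_name!r} has no actives: Y_C undefined"
        )
    if outcome.n_test < 1:
        raise ConfigurationError("corrected_yield needs n_test >= 1")
    y = outcome.h / outcome.n_test
    e = outcome.h / outcome.A
    y_c = outcome.h / min(outcome.A, outcome.n_test)
    return MetricsRecord(Y=y, E=e, Y_C=y_c)


def targets_with_hits(outcomes: Sequence[SelectionOutcome]) -> CohortRecord:
    """Fraction of targets with at least one hit (one outcome per target)."""
    if not outcomes:
        raise ConfigurationError("targets_with_hits needs at least one outcome")
    n_with = sum(1 for o in outcomes if o.h > 0)
    return CohortRecord(n_with, len(outcomes), n_with / len(outcomes))


def net_balance(
    outcomes_method: Sequence[SelectionOutcome],
    outcomes_ref: Sequence[SelectionOutcome],
) -> ComparisonRecord:
    """Net fraction of targets on which the method out-hits the reference.

    Ties contribute to neither count but remain in the denominator N_p.
    """
    by_target_m = {o.target_name: o for o in outcomes_method}
    by_target_r = {o.target_name: o for o in outcomes_ref}
    if set(by_target_m) != set(by_target_r) or len(by_target_m) != len(outcomes_method):
        raise ValidationError("method and reference outcome lists must cover the same targets")
    n_m = n_r = 0
    for name, om in by_target_m.items():
        orf = by_target_r[name]
        if om.h > orf.h:
            n_m += 1
        elif orf.h > om.h:
            n_r += 1
    n_p = len(by_target_m)
    return ComparisonRecord(n_m, n_r, n_p, (n_m - n_r) / n_p)


def rank_correlation(tableA: ScoreTable, tableB: ScoreTable) -> float:
    """Spearman rank correlation between two programs on their common molecules.

    Both rankings are direction-normalized to "better = higher goodness"
    before correlating, so identical rankings give rho = 1 regardless of the
    raw score directions.  Ties are handled by average ranks.
    """
    common = sorted(tableA.id_set() & tableB.id_set())
    if len(common) < 3:
        raise ValidationError(
            f"need >= 3 common molecules for a rank correlation, got {len(common)}"
        )
    score_a = {e.molecule_id: e.score for e in tableA.entries}
    score_b = {e.molecule_id: e.score for e in tableB.entries}
    ga = np.array([tableA.direction_sign * score_a[m] for m in common])
    gb = np.array([tableB.direction_sign * score_b[m] for m in common])
    rho = stats.spearmanr(ga, gb).statistic
    return float(rho)


def correlation_matrix(tables: Sequence[ScoreTable]):
    """Pairwise Spearman matrix over programs (diagonal = 1)."""
    import pandas as pd

    names = [t.program_name for t in tables]
    mat = np.eye(len(tables))
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            r = rank_correlation(tables[i], tables[j])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)


def enrichment_curve(
    table: ScoreTable, labels: ActivityLabels, points: int = 100
) -> list[tuple[float, float]]:
    """Cumulative enrichment E = h/A along the ranked library.

    Returns (fraction_screened, E) at ``points`` evenly spaced fractions
    ending at 1.  Monotone non-decreasing with endpoint E = 1.
    """
    if labels.n_actives == 0:
        raise UndefinedMetricError("enrichment curve undefined with A = 0")
    if points < 1:
        raise ConfigurationError("points must be >= 1")
    ids = table.id_set()
    missing = labels.actives - ids
    if missing:
        raise ValidationError(
            f"actives missing from the score table: {sorted(missing)[:5]}"
        )
    ranked = [mid for mid, _ in rank_molecules(table)]
    is_active = np.array([m in labels.actives for m in ranked], dtype=int)
    cum = np.cumsum(is_active)
    n = len(ranked)
    a = labels.n_actives
    curve = []
    for j in range(1, points + 1):
        frac = j / points
        idx = int(frac * n)  # number of molecules screened
        e = float(cum[idx - 1] / a) if idx >= 1 else 0.0
        curve.append((frac, e))
    return curve
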