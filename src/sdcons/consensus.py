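"""Standard-deviation consensus algorithms.

The central idea: for each docking program, standardize its score
distribution over the whole library and call a molecule a *stand-out* when
its goodness z-score is at least ``x`` standard deviations above the mean.
A *consensus molecule* is stand-out in every program considered.  Three
constructions are provided:

* :func:`sdc` — fixed cutoff (x = 2 by default); the number of consensus
  molecules (nCM) varies by target.
* :func:`vsdc` — the selection size ``n_test`` is fixed by the user and the
  multiplier x is lowered from 3.5 in steps of 0.001 until the intersection
  reaches it.
* :func:`usc` — the complementary union construction: the top n_test/k
  molecules of each program, topped up round-robin to exactly n_test.

Different programs rarely make the same mistake, so intersecting their
stand-out sets suppresses false positives that any single ranking would
promote.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateDistributionError,
    InfeasibleConsensusError,
)
from .score_io import ScoreTable

SDC_DEFAULT_X = 2.0
VSDC_X_START = 3.5
VSDC_X_STEP = 0.001
VSDC_X_MIN = -10.0


@dataclass
class StandardizedTable:
    """Goodness z-scores for one program.

    z = direction_sign * (score - mean) / sd, so a larger z is always a
    better molecule regardless of the raw score direction.  ``mean`` and
    ``sd`` (sample SD, n-1 denominator) are kept in original score units.
    """

    program_name: str
    ids: list[str]
    z: np.ndarray
    mean: float
    sd: float
    _zmap: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._zmap:
            self._zmap = dict(zip(self.ids, self.z.tolist()))

    def z_of(self, molecule_id: str) -> Optional[float]:
        return self._zmap.get(molecule_id)


@dataclass
class StandoutSet:
    """Molecules whose z-score reaches ``x`` for one program.

    ``cutoff_c`` is the cutoff expressed in original score units (x * SD
    away from the mean).  Membership is boundary-inclusive: z >= x.
    """

    program_name: str
    x: float
    cutoff_c: float
    members: frozenset[str]


@dataclass
class ConsensusResult:
    """A selected molecule set with its provenance.

    ``members`` is ordered (best first); ``nCM`` is its size; ``x_used``
    records the SD multiplier that produced an SDC/vSDC selection;
    ``per_program_cutoffs`` maps program -> x_used * SD in score units.
    """

    method: str
    members: list[str]
    nCM: int
    x_used: Optional[float] = None
    per_program_cutoffs: dict = field(default_factory=dict)
    trimmed: bool = False
    target_name: str = ""

    def __post_init__(self) -> None:
        if self.nCM != len(self.members):
            raise ConfigurationError("nCM must equal the number of members")


@dataclass
class VennPartition:
    """Exact counts of the 2^k - 1 disjoint regions of k stand-out sets."""

    programs: list[str]
    region_counts: dict[frozenset, int]

    def common_to(self, programs: Sequence[str]) -> int:
        """Total molecules shared by (at least) the given programs."""
        want = frozenset(programs)
        return sum(
            n for region, n in self.region_counts.items() if want <= region
        )

    def set_size(self, program: str) -> int:
        return self.common_to([program])


def standardize(table: ScoreTable) -> StandardizedTable:
    """Standardize a program's scores into goodness z-scores.

    Uses the sample standard deviation (n-1).  Raises
    :class:`DegenerateDistributionError` when every score is identical.
    """
    if len(table.entries) < 2:
        raise DegenerateDistributionError(
            f"program {table.program_name!r} has fewer than 2 scored molecules; "
            f"standard deviation undefined"
        )
    ids = [e.molecule_id for e in table.entries]
    scores = np.asarray([e.score for e in table.entries], dtype=float)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0.0:
        raise DegenerateDistributionError(
            f"all {len(ids)} scores of program {table.program_name!r} are "
            f"identical ({mean}); z-scores undefined"
        )
    z = table.direction_sign * (scores - mean) / sd
    return StandardizedTable(table.program_name, ids, z, mean, sd)


def standout_set(std_table: StandardizedTable, x: float) -> StandoutSet:
    """Molecules with z >= x for one program (boundary inclusive)."""
    if not math.isfinite(x):
        raise ConfigurationError(f"cutoff multiplier x must be finite, got {x}")
    members = frozenset(
        mid for mid, z in zip(std_table.ids, std_table.z) if z >= x
    )
    return StandoutSet(std_table.program_name, x, x * std_table.sd, members)


def _warn_unshared(std_tables: Sequence[StandardizedTable]) -> set[str]:
    """Intersection of id sets; warn about ids not scored by every program."""
    id_sets = [set(t.ids) for t in std_tables]
    common = set.intersection(*id_sets)
    n_unshared = len(set.union(*id_sets)) - len(common)
    if n_unshared:
        warnings.warn(
            f"{n_unshared} molecule ids are not shared by all {len(std_tables)} "
            f"programs and can never be consensus members",
            stacklevel=3,
        )
    return common


def _sum_z_order(members: Sequence[str], std_tables: Sequence[StandardizedTable]) -> list[str]:
    """Order members by decreasing summed z across programs, ties lexicographic."""
    def key(mol: str):
        total = sum(t.z_of(mol) for t in std_tables)
        return (-total, mol)

    return sorted(members, key=key)


def sdc(tables: Sequence[ScoreTable], x: float = SDC_DEFAULT_X) -> ConsensusResult:
    """Fixed-cutoff standard deviation consensus.

    Intersects the per-program stand-out sets at the given multiplier
    (default x = 2).  nCM varies freely with the target.  Members are
    ordered by decreasing summed z.
    """
    if len(tables) < 2:
        raise ConfigurationError("SDC needs at least 2 score tables")
    std_tables = [standardize(t) for t in tables]
    _warn_unshared(std_tables)
    sets = [standout_set(s, x) for s in std_tables]
    members = frozenset.intersection(*[s.members for s in sets])
    ordered = _sum_z_order(members, std_tables)
    cutoffs = {s.program_name: s.cutoff_c for s in sets}
    return ConsensusResult(
        method="SDC",
        members=ordered,
        nCM=len(ordered),
        x_used=x,
        per_program_cutoffs=cutoffs,
        target_name=tables[0].target_name,
    )


def vsdc(
    tables: Sequence[ScoreTable],
    n_test: int,
    x_start: float = VSDC_X_START,
    x_step: float = VSDC_X_STEP,
    trim: bool = True,
    x_min: float = VSDC_X_MIN,
) -> ConsensusResult:
    """Variable standard deviation consensus.

    Scans the multiplier grid {x_start, x_start - x_step, ...} downward and
    stops at the first (largest) x at which the intersection of the k
    stand-out sets holds at least ``n_test`` molecules.  Because the
    intersection grows in jumps, the stopping set may overshoot; with
    ``trim=True`` (default) it is trimmed to exactly ``n_test`` by keeping
    the members with the highest summed z (ties lexicographic).  A single
    table is accepted as a degenerate mode and reduces to top-n by z.
    """
    if n_test < 1:
        raise ConfigurationError(f"n_test must be >= 1, got {n_test}")
    if x_step <= 0:
        raise ConfigurationError(f"x_step must be > 0, got {x_step}")
    if len(tables) < 1:
        raise ConfigurationError("vSDC needs at least one score table")
    std_tables = [standardize(t) for t in tables]
    if len(std_tables) > 1:
        common = _warn_unshared(std_tables)
    else:
        common = set(std_tables[0].ids)
    if len(common) < n_test:
        raise InfeasibleConsensusError(
            f"n_test={n_test} exceeds the {len(common)} molecules present in "
            f"all tables (maximum achievable nCM = {len(common)})",
            max_achievable=len(common),
        )
    common_ids = sorted(common)
    minz = np.min(
        np.array([[t.z_of(m) for m in common_ids] for t in std_tables]), axis=0
    )
    # the intersection at cutoff x is exactly {m : min_p z_p(m) >= x}, so the
    # n_test-th largest min-z is the feasibility threshold for x
    thr = float(np.sort(minz)[::-1][n_test - 1])
    if thr >= x_start:
        k = 0
    else:
        k = max(0, int(math.ceil((x_start - thr) / x_step)))
        # settle float fuzz so the answer is identical to a literal grid scan
        while k > 0 and thr >= x_start - (k - 1) * x_step:
            k -= 1
        while thr < x_start - k * x_step:
            k += 1
    x_used = x_start - k * x_step
    if x_used < x_min:
        achievable = int(np.count_nonzero(minz >= x_min))
        raise InfeasibleConsensusError(
            f"reached the multiplier floor x_min={x_min} with only {achievable} "
            f"consensus molecules (< n_test={n_test})",
            max_achievable=achievable,
        )
    raw_members = [m for m, z in zip(common_ids, minz) if z >= x_used]
    ordered = _sum_z_order(raw_members, std_tables)
    trimmed = False
    if trim and len(ordered) > n_test:
        ordered = ordered[:n_test]
        trimmed = True
    cutoffs = {t.program_name: x_used * t.sd for t in std_tables}
    return ConsensusResult(
        method="vSDC",
        members=ordered,
        nCM=len(ordered),
        x_used=x_used,
        per_program_cutoffs=cutoffs,
        trimmed=trimmed,
        target_name=tables[0].target_name,
    )


def usc(tables: Sequence[ScoreTable], n_test: int) -> ConsensusResult:
    """United subset consensus: union of each program's top n_test/k list.

    Takes the top floor(n_test/k) ranked molecules of each program, forms
    their union, then tops up round-robin over programs in input order (each
    contributing its next-best not-yet-selected molecule) until exactly
    ``n_test`` members are selected, or the pooled library runs out.
    """
    k = len(tables)
    if k < 1:
        raise ConfigurationError("USC needs at least one score table")
    if n_test < k:
        raise ConfigurationError(
            f"USC needs n_test >= number of programs ({k}), got {n_test}"
        )
    ranked = [[mid for mid, _ in rank_molecules(t)] for t in tables]
    base = n_test // k
    selected: list[str] = []
    seen: set[str] = set()
    for lst in ranked:
        for mid in lst[:base]:
            if mid not in seen:
                seen.add(mid)
                selected.append(mid)
    pointers = [base] * k
    pooled = set().union(*[set(lst) for lst in ranked])
    while len(selected) < n_test and len(seen) < len(pooled):
        for p, lst in enumerate(ranked):
            i = pointers[p]
            while i < len(lst) and lst[i] in seen:
                i += 1
            pointers[p] = i + 1
            if i < len(lst):
                seen.add(lst[i])
                selected.append(lst[i])
                if len(selected) >= n_test:
                    break
    return ConsensusResult(
        method="USC",
        members=selected,
        nCM=len(selected),
        target_name=tables[0].target_name,
    )


def venn_partition(standout_sets: Sequence[StandoutSet]) -> VennPartition:
    """Partition k stand-out sets into their 2^k - 1 disjoint regions."""
    from itertools import combinations

    if len(standout_sets) < 2:
        raise ConfigurationError("a Venn partition needs at least 2 sets")
    programs = [s.program_name for s in standout_sets]
    membership: dict[str, frozenset] = {}
    for s in standout_sets:
        for mol in s.members:
            membership[mol] = membership.get(mol, frozenset()) | {s.program_name}
    counts: dict[frozenset, int] = {}
    for r in range(1, len(programs) + 1):
        for combo in combinations(programs, r):
            counts[frozenset(combo)] = 0
    for region in membership.values():
        counts[region] += 1
    return VennPartition(programs, counts)


def rank_molecules(table: ScoreTable) -> list[tuple[str, int]]:
    """Dense 1-based ranking, best first; ties broken lexicographically."""
    sign = table.direction_sign
    ordered = sorted(table.entries, key=lambda e: (-sign * e.score, e.molecule_id))
    return [(e.molecule_id, i + 1) for i, e in enumerate(ordered)]


def top_n(table: ScoreTable, n: int) -> ConsensusResult:
    """Single-program baseline: the first n molecules of the ranking."""
    if not 1 <= n <= len(table):
        raise ConfigurationError(
            f"n must be in [1, {len(table)}], got {n}"
        )
    members = [mid for mid, _ in rank_molecules(table)[:n]]
    return ConsensusResult(
        method="top_n_single",
        members=members,
        nCM=n,
        target_name=table.target_name,
    )


def venn_to_frame(partition: VennPartition):
    """Tidy export of a Venn partition: region label ('+'-joined) and count."""
    import pandas as pd

    order = {p: i for i, p in enumerate(partition.programs)}
    rows = []
    for region, n in partition.region_counts.items():
        label = "+".join(sorted(region, key=order.get))
        rows.append({"region": label, "n_programs": len(region), "count": n})
    rows.sort(key=lambda r: (r["n_programs"], r["region"]))
    return pd.DataFrame(rows)
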