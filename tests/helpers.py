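"""Shared test utilities: generators and independent oracles.

Oracles here deliberately re-derive quantities from first principles
(literal grid scans, set algebra, hand-rolled rank statistics) so they stay
independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np

from sdcons.score_io import HIGHER_BETTER, LOWER_BETTER, ScoreEntry, ScoreTable


def make_table(pairs, direction=LOWER_BETTER, program="prog", target="t"):
    return ScoreTable(
        program, target, direction, [ScoreEntry(m, float(s)) for m, s in pairs]
    )


def make_correlated_tables(rng, n, k, w=0.4, n_active=0, sensitivity=0.0):
    """k score tables over a shared latent signal, mixed score directions."""
    ids = [f"m{i:04d}" for i in range(n)]
    latent = rng.standard_normal(n)
    active = np.zeros(n)
    if n_active:
        active[rng.choice(n, size=n_active, replace=False)] = 1.0
    tables = []
    for p in range(k):
        eps = rng.standard_normal(n)
        z = w * latent + (1 - w) * eps + sensitivity * active
        direction = HIGHER_BETTER if p % 2 else LOWER_BETTER
        scores = z if direction == HIGHER_BETTER else -z
        tables.append(
            ScoreTable(
                f"p{p}", "t", direction,
                [ScoreEntry(m, float(s)) for m, s in zip(ids, scores)],
            )
        )
    actives = {ids[i] for i in np.flatnonzero(active)}
    return tables, actives


def goodness_z(table):
    """Independent z-score computation (same stated convention: sample SD)."""
    scores = np.array([e.score for e in table.entries])
    sign = 1 if table.direction == HIGHER_BETTER else -1
    return (
        [e.molecule_id for e in table.entries],
        sign * (scores - np.mean(scores)) / np.std(scores, ddof=1),
    )


def brute_force_standout(table, x):
    ids, z = goodness_z(table)
    return {m for m, zz in zip(ids, z) if zz >= x}


def brute_force_sdc(tables, x=2.0):
    sets = [brute_force_standout(t, x) for t in tables]
    return set.intersection(*sets)


def brute_force_vsdc(tables, n_test, x_start=3.5, x_step=0.001):
    """Literal downward grid scan; returns (x_used, member set)."""
    k = 0
    while True:
        x = x_start - k * x_step
        inter = set.intersection(*[brute_force_standout(t, x) for t in tables])
        if len(inter) >= n_test:
            return x, inter
        k += 1
        if x < -20:  # pragma: no cover - guards a broken test setup
            raise AssertionError("oracle scan ran away")


def brute_force_usc(tables, n_test):
    """Independent re-implementation of the union + round-robin top-up."""
    def ranked_ids(table):
        sign = 1 if table.direction == HIGHER_BETTER else -1
        return [
            e.molecule_id
            for e in sorted(table.entries, key=lambda e: (-sign * e.score, e.molecule_id))
        ]

    lists = [ranked_ids(t) for t in tables]
    base = n_test // len(tables)
    out, seen = [], set()
    for lst in lists:
        for m in lst[:base]:
            if m not in seen:
                seen.add(m)
                out.append(m)
    ptr = [base] * len(lists)
    pooled = set().union(*map(set, lists))
    while len(out) < n_test and seen != pooled:
        for i, lst in enumerate(lists):
            j = ptr[i]
            while j < len(lst) and lst[j] in seen:
                j += 1
            ptr[i] = j + 1
            if j < len(lst):
                seen.add(lst[j])
                out.append(lst[j])
                if len(out) == n_test:
                    break
    return out


def spearman_oracle(a, b):
    """Spearman rho from the definition: Pearson on average ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    ra, rb = avg_ranks(a), avg_ranks(b)
    return float(np.corrcoef(ra, rb)[0, 1])
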