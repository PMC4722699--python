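"""Worked-example inputs from reference four-program docking screens.

These small printed tables come from real consensus-docking campaigns with
Glide, Surflex, FlexX and Gold: a ~14,300-unique-compound institutional
library screened against calcineurin (Cn) and, on its experimentally
assayed 8,152-compound subset, against an allosteric site of Cdk2.  They
let the selection and hit-counting machinery be exercised against known
outcomes without any docking engine: per-program ranks of the confirmed
active molecules, the hit ranks observed in each program's early top list,
and the two-/three-program overlap counts of the 2xSD stand-out sets.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .consensus import StandoutSet
from .score_io import LOWER_BETTER, ScoreEntry, ScoreTable

CN_LIBRARY_SIZE = 14_307
CDK2_LIBRARY_SIZE = 8_152

#: Per-program rank of each confirmed Cn active among the consensus molecules.
CN_ACTIVE_RANKS: dict[str, dict[str, int]] = {
    "cn_ligand_1": {"Glide": 116, "Surflex": 1, "FlexX": 47, "Gold": 206},
    "cn_ligand_2": {"Glide": 10, "Surflex": 3, "FlexX": 68, "Gold": 77},
    "cn_ligand_3": {"Glide": 131, "Surflex": 6745, "FlexX": 31, "Gold": 97},
}

#: Ranks at which each program placed Cdk2 actives inside its own top-22 list
#: (Glide's first hit fell outside, at rank 31).
CDK2_EARLY_HIT_RANKS: dict[str, tuple[int, ...]] = {
    "Glide": (31,),
    "Surflex": (2, 4, 18),
    "FlexX": (5, 22),
    "Gold": (6, 7),
}

#: Disjoint region counts of the Cn 2xSD Venn diagram covering every region
#: that contains both Surflex and Gold.
CN_VENN_REGIONS: dict[frozenset, int] = {
    frozenset({"Surflex", "Gold", "FlexX", "Glide"}): 14,
    frozenset({"Surflex", "Gold", "FlexX"}): 39,
    frozenset({"Surflex", "Gold", "Glide"}): 21,
    frozenset({"Surflex", "Gold"}): 134,
}


def table_from_ranks(
    program: str,
    active_ranks: Mapping[str, int],
    library_size: int,
    target_name: str = "",
) -> ScoreTable:
    """Build a score table in which named molecules occupy given ranks.

    Scores are the rank values themselves with ``lower_better`` direction,
    so ``rank_molecules`` reproduces the prescribed ranking exactly; filler
    molecules (``fill<rank>``) occupy every other position.
    """
    by_rank = {}
    for mol, rank in active_ranks.items():
        if not 1 <= rank <= library_size:
            raise ValueError(f"rank {rank} outside library of {library_size}")
        if rank in by_rank:
            raise ValueError(f"two molecules at rank {rank}")
        by_rank[rank] = mol
    entries = [
        ScoreEntry(by_rank.get(rank, f"fill{rank:06d}"), float(rank))
        for rank in range(1, library_size + 1)
    ]
    return ScoreTable(program, target_name, LOWER_BETTER, entries)


def standout_sets_from_regions(
    region_counts: Mapping[frozenset, int],
    programs: Sequence[str],
) -> list[StandoutSet]:
    """Materialize stand-out sets realizing exact disjoint region counts.

    Molecules are synthetic placeholders; only the set structure matters.
    """
    members: dict[str, set[str]] = {p: set() for p in programs}
    i = 0
    for region, count in region_counts.items():
        for _ in range(count):
            mol = f"cpd{i:05d}"
            i += 1
            for p in region:
                members[p].add(mol)
    return [
        StandoutSet(p, x=2.0, cutoff_c=float("nan"), members=frozenset(members[p]))
        for p in programs
    ]
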