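"""Reading, validating and writing the tabular inputs and outputs.

The toolkit consumes the *output rankings* of docking programs, not chemical
structures: one delimited text table per program per target, holding a
molecule identifier, a score and (optionally) a parent-compound identifier
used to collapse enantiomers/tautomers/protomers onto unique compounds.
Score direction is declared per table because docking scores are
heterogeneous — free-energy-like scores are best when lowest, fitness scores
when highest.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import ConfigurationError, ParseError, ValidationError

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"
_DIRECTIONS = (LOWER_BETTER, HIGHER_BETTER)

# label tokens accepted in activity files
_ACTIVE_TOKENS = {"1", "active"}
_INACTIVE_TOKENS = {"0", "inactive"}


@dataclass(frozen=True)
class ScoreEntry:
    """One scored molecule: ``(molecule_id, score, parent_id)``."""

    molecule_id: str
    score: float
    parent_id: Optional[str] = None


@dataclass
class ScoreTable:
    """One program's scores for one target's library.

    ``direction`` states whether a lower or a higher score is better; every
    downstream operation (ranking, standardization) respects it.  Molecule ids
    must be unique, except that structure variants sharing a ``parent_id`` may
    coexist until :func:`collapse_variants` merges them.
    """

    program_name: str
    target_name: str
    direction: str
    entries: list[ScoreEntry]

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTIONS:
            raise ConfigurationError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )
        if len(self.entries) < 1:
            raise ValidationError(
                f"score table {self.program_name!r}/{self.target_name!r} is empty"
            )
        seen: dict[str, ScoreEntry] = {}
        for e in self.entries:
            if not math.isfinite(e.score):
                raise ValidationError(
                    f"non-finite score {e.score!r} for molecule {e.molecule_id!r}"
                )
            if e.molecule_id in seen:
                if e.parent_id is None or seen[e.molecule_id].parent_id is None:
                    raise ValidationError(
                        f"duplicate molecule_id {e.molecule_id!r} without a parent id"
                    )
            else:
                seen[e.molecule_id] = e

    @property
    def direction_sign(self) -> int:
        """+1 when larger raw scores are better, -1 when smaller are better."""
        return 1 if self.direction == HIGHER_BETTER else -1

    def __len__(self) -> int:
        return len(self.entries)

    def id_set(self) -> set[str]:
        return {e.molecule_id for e in self.entries}

    def scores(self) -> list[float]:
        return [e.score for e in self.entries]


@dataclass
class ActivityLabels:
    """Active/inactive annotation for one target's library.

    ``actives`` is a subset of ``library``; its size is the A of the
    enrichment denominator (E = h/A).
    """

    target_name: str
    actives: set[str]
    library: set[str]

    def __post_init__(self) -> None:
        stray = self.actives - self.library
        if stray:
            raise ValidationError(
                f"actives not in library for target {self.target_name!r}: "
                f"{sorted(stray)[:5]}"
            )

    @property
    def n_actives(self) -> int:
        return len(self.actives)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _iter_data_rows(path: Path, delimiter_holder: dict) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    with open(path, "r", newline="") as fh:
        delim = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
                delimiter_holder["delimiter"] = delim
            yield lineno, next(csv.reader([line], delimiter=delim))


def read_score_table(
    path: str | Path,
    program_name: str,
    direction: str,
    id_column: str = "id",
    score_column: str = "score",
    parent_column: Optional[str] = None,
    target_name: str = "",
) -> ScoreTable:
    """Read one program's score table from a headered CSV/TSV file.

    The delimiter (comma or tab) is auto-detected from the header line and
    ``#``-prefixed comment lines are ignored.  Rows with non-numeric scores
    raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"score file not found: {path}")
    holder: dict = {}
    rows = _iter_data_rows(path, holder)
    try:
        _, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in header]
    wanted = [id_column, score_column] + ([parent_column] if parent_column else [])
    for col in wanted:
        if col not in header:
            raise ConfigurationError(
                f"{path}: column {col!r} not found in header {header}"
            )
    idx_id = header.index(id_column)
    idx_score = header.index(score_column)
    idx_parent = header.index(parent_column) if parent_column else None

    entries: list[ScoreEntry] = []
    for lineno, fields in rows:
        if len(fields) < len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields")
        mol = fields[idx_id].strip()
        raw_score = fields[idx_score].strip()
        try:
            score = float(raw_score)
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric score {raw_score!r}"
            )
        parent = None
        if idx_parent is not None:
            parent = fields[idx_parent].strip() or None
        entries.append(ScoreEntry(mol, score, parent))

    try:
        return ScoreTable(program_name, target_name, direction, entries)
    except ValidationError as exc:
        if parent_column is None and "duplicate molecule_id" in str(exc):
            raise ValidationError(
                f"{path}: duplicate molecule ids but no parent column declared "
                f"({exc})"
            )
        raise


def collapse_variants(table: ScoreTable) -> ScoreTable:
    """Collapse structure variants onto their parent compounds.

    Each group of entries sharing a ``parent_id`` is replaced by a single
    entry carrying the *best* score of the group under the table's direction
    (consensus and hit counting operate on unique compounds, and ranking by
    score makes best-of-variants the only consistent choice).  Entries without
    a parent pass through as their own parent, which makes the operation
    idempotent.
    """
    sign = table.direction_sign
    best: dict[str, float] = {}
    for e in table.entries:
        key = e.parent_id if e.parent_id is not None else e.molecule_id
        if key not in best or sign * e.score > sign * best[key]:
            best[key] = e.score
    entries = [ScoreEntry(mid, s, None) for mid, s in sorted(best.items())]
    return ScoreTable(table.program_name, table.target_name, table.direction, entries)


def read_activity_labels(path: str | Path, target_name: str = "") -> ActivityLabels:
    """Read a two-column (molecule_id, label) activity file.

    Labels may be ``0``/``1`` or ``active``/``inactive`` (case-insensitive).
    An optional header row is detected by its second field not being a label
    token.  The library is the full set of listed ids.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"activity file not found: {path}")
    holder: dict = {}
    actives: set[str] = set()
    library: set[str] = set()
    first = True
    for lineno, fields in _iter_data_rows(path, holder):
        if len(fields) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        mol, token = fields[0].strip(), fields[1].strip().lower()
        if first:
            first = False
            if token not in _ACTIVE_TOKENS | _INACTIVE_TOKENS:
                continue  # header row
        if token in _ACTIVE_TOKENS:
            actives.add(mol)
        elif token in _INACTIVE_TOKENS:
            pass
        else:
            raise ParseError(
                f"{path}: line {lineno}: unknown activity label {fields[1]!r}"
            )
        library.add(mol)
    return ActivityLabels(target_name or path.stem, actives, library)


def write_activity_labels(labels: ActivityLabels, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("id,label\n")
        for mol in sorted(labels.library):
            fh.write(f"{mol},{1 if mol in labels.actives else 0}\n")


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a table in the same CSV dialect :func:`read_score_table` accepts."""
    path = Path(path)
    has_parent = any(e.parent_id is not None for e in table.entries)
    with open(path, "w", newline="") as fh:
        fh.write(f"# program={table.program_name}\n")
        fh.write(f"# target={table.target_name}\n")
        fh.write(f"# direction={table.direction}\n")
        fh.write("id,score,parent\n" if has_parent else "id,score\n")
        for e in table.entries:
            if has_parent:
                fh.write(f"{e.molecule_id},{e.score!r},{e.parent_id or ''}\n")
            else:
                fh.write(f"{e.molecule_id},{e.score!r}\n")


def write_consensus(result, path: str | Path, tables: Sequence[ScoreTable] = ()) -> None:
    """Write a consensus selection as a '#'-headed CSV.

    Metadata lines carry the method, the SD multiplier actually used and nCM.
    When the originating score tables are supplied, each member row also
    carries the per-program standardized score and rank.
    """
    from . import consensus as _consensus  # deferred: consensus imports this module

    path = Path(path)
    std_tables = []
    ranks = []
    for t in tables:
        std = _consensus.standardize(t)
        std_tables.append(std)
        ranks.append(dict(_consensus.rank_molecules(t)))
    with open(path, "w", newline="") as fh:
        fh.write(f"# method={result.method}\n")
        x = "" if result.x_used is None else f"{result.x_used:.6g}"
        fh.write(f"# x_used={x}\n")
        fh.write(f"# nCM={result.nCM}\n")
        fh.write(f"# trimmed={str(result.trimmed).lower()}\n")
        for t, std in zip(tables, std_tables):
            cut = result.per_program_cutoffs.get(t.program_name, "")
            cut = f"{cut:.6g}" if cut != "" else ""
            fh.write(
                f"# program={t.program_name} direction={t.direction} "
                f"mean={std.mean:.6g} sd={std.sd:.6g} cutoff={cut}\n"
            )
        cols = ["molecule_id"]
        for t in tables:
            cols += [f"z_{t.program_name}", f"rank_{t.program_name}"]
        fh.write(",".join(cols) + "\n")
        for mol in result.members:
            row = [mol]
            for std, rk in zip(std_tables, ranks):
                z = std.z_of(mol)
                row.append("" if z is None else f"{z:.9g}")
                row.append("" if mol not in rk else str(rk[mol]))
            fh.write(",".join(row) + "\n")


def read_consensus(path: str | Path) -> tuple[list[str], dict]:
    """Read back a consensus file: returns (member ids in file order, metadata)."""
    path = Path(path)
    meta: dict = {}
    members: list[str] = []
    with open(path) as fh:
        header_seen = False
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                for tok in body.split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta.setdefault(k, v)
                continue
            if not header_seen:
                header_seen = True
                continue
            members.append(line.split(",")[0])
    return members, meta
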