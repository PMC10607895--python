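"""Four-level hierarchical ingredient taxonomy.

Level 1 holds the coarsest categories (e.g. Crop / Livestock / Seafood),
level 4 the leaf ingredient categories.  Every category below level 1 has
exactly one parent at the level above, so each leaf determines a unique
ancestor chain.  Category ids are dense, 0-based and assigned per level in
file order, which keeps label indices reproducible across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

N_LEVELS = 4


class TaxonomyError(ValueError):
    """Raised for unparseable or structurally invalid taxonomy sources."""


class HierarchicalLabel(NamedTuple):
    """One category id per level; (y4 -> y3 -> y2 -> y1) is a parent chain."""

    y1: int
    y2: int
    y3: int
    y4: int

    def at_level(self, level: int) -> int:
        if level not in (1, 2, 3, 4):
            raise ValueError(f"level must be 1..4, got {level}")
        return self[level - 1]


@dataclass
class IngredientTaxonomy:
    """Category registries per level plus child->parent id links.

    ``names[l]`` lists the category names of level ``l+1`` (0-based list
    index); ``parent[l]`` maps each id of level ``l+2`` to its parent id at
    level ``l+1`` (so ``parent`` has three entries, for levels 2, 3, 4).
    """

    names: list[list[str]]
    parent: list[list[int]] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        c = tuple(len(level) for level in self.names)
        if len(c) != N_LEVELS:
            raise TaxonomyError(f"expected {N_LEVELS} levels, found {len(c)}")
        return c  # type: ignore[return-value]

    @property
    def num_leaves(self) -> int:
        return len(self.names[N_LEVELS - 1])

    def id_of(self, level: int, name: str) -> int:
        try:
            return self.names[level - 1].index(name)
        except ValueError:
            raise TaxonomyError(f"unknown level-{level} category {name!r}") from None

    def name_of(self, level: int, cat_id: int) -> str:
        return self.names[level - 1][cat_id]

    def parent_of(self, level: int, cat_id: int) -> int:
        """Parent id (at ``level - 1``) of category ``cat_id`` at ``level``."""
        if level not in (2, 3, 4):
            raise ValueError("parent_of is defined for levels 2..4")
        return self.parent[level - 2][cat_id]


def validate_taxonomy(tax: IngredientTaxonomy) -> list[str]:
    """Return a list of invariant violations; empty iff the taxonomy is valid."""
    report: list[str] = []
    if len(tax.names) != N_LEVELS:
        report.append(f"expected {N_LEVELS} levels, found {len(tax.names)}")
        return report
    for li, level_names in enumerate(tax.names, start=1):
        if not level_names:
            report.append(f"level {li} is empty")
        seen: set[str] = set()
        for name in level_names:
            if name in seen:
                report.append(f"duplicate category name {name!r} at level {li}")
            seen.add(name)
    if len(tax.parent) != N_LEVELS - 1:
        report.append(
            f"expected {N_LEVELS - 1} parent maps, found {len(tax.parent)}"
        )
        return report
    for li in (2, 3, 4):
        links = tax.parent[li - 2]
        n_child = len(tax.names[li - 1])
        n_parent = len(tax.names[li - 2])
        if len(links) != n_child:
            report.append(
                f"level {li} has {n_child} categories but {len(links)} parent links"
            )
        for cid, pid in enumerate(links):
            if cid >= n_child:
                break
            if not 0 <= pid < n_parent:
                child = tax.names[li - 1][cid] if cid < n_child else f"#{cid}"
                report.append(
                    f"category {child!r} at level {li} has missing parent (id {pid})"
                )
    return report


def lift_label(tax: IngredientTaxonomy, leaf: int) -> HierarchicalLabel:
    """Lift a level-4 (leaf) id to its unique ancestor chain."""
    if not 0 <= leaf < tax.num_leaves:
        raise TaxonomyError(f"unknown level-4 id {leaf}")
    y4 = leaf
    y3 = tax.parent_of(4, y4)
    y2 = tax.parent_of(3, y3)
    y1 = tax.parent_of(2, y2)
    return HierarchicalLabel(y1=y1, y2=y2, y3=y3, y4=y4)


def _rows_from_tsv(text: str) -> list[tuple[int, str, str | None]]:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise TaxonomyError(
                f"line {lineno}: expected 'level<TAB>name[<TAB>parent]', got {line!r}"
            )
        try:
            level = int(parts[0])
        except ValueError:
            raise TaxonomyError(f"line {lineno}: bad level {parts[0]!r}") from None
        parent = parts[2].strip() if len(parts) == 3 and parts[2].strip() else None
        rows.append((level, parts[1].strip(), parent))
    return rows


def _rows_from_json(text: str) -> list[tuple[int, str, str | None]]:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise TaxonomyError(f"JSON parse failure: {exc}") from exc
    if not isinstance(data, list):
        raise TaxonomyError("JSON taxonomy must be a list of entries")
    rows = []
    for entry in data:
        if not isinstance(entry, dict) or "level" not in entry or "name" not in entry:
            raise TaxonomyError(f"bad taxonomy entry: {entry!r}")
        rows.append((int(entry["level"]), str(entry["name"]), entry.get("parent")))
    return rows


def build_taxonomy(rows: Sequence[tuple[int, str, str | None]]) -> IngredientTaxonomy:
    """Assemble and validate a taxonomy from (level, name, parent-name) rows."""
    names: list[list[str]] = [[] for _ in range(N_LEVELS)]
    parent_names: list[dict[str, str]] = [{} for _ in range(N_LEVELS)]
    for level, name, parent in rows:
        if not 1 <= level <= N_LEVELS:
            raise TaxonomyError(f"category {name!r}: level {level} out of range 1..4")
        if name in names[level - 1]:
            if parent is not None and parent_names[level - 1].get(name) != parent:
                raise TaxonomyError(f"category {name!r} at level {level} has multiple parents")
            raise TaxonomyError(f"duplicate category {name!r} at level {level}")
        if level == 1:
            if parent is not None:
                raise TaxonomyError(f"level-1 category {name!r} must not have a parent")
        elif parent is None:
            raise TaxonomyError(f"category {name!r} at level {level} is an orphan (no parent)")
        names[level - 1].append(name)
        if parent is not None:
            parent_names[level - 1][name] = parent

    parent: list[list[int]] = []
    for level in (2, 3, 4):
        links = []
        for name in names[level - 1]:
            pname = parent_names[level - 1][name]
            if pname not in names[level - 2]:
                raise TaxonomyError(
                    f"category {name!r} at level {level} names unknown parent {pname!r}"
                )
            links.append(names[level - 2].index(pname))
        parent.append(links)

    tax = IngredientTaxonomy(names=names, parent=parent)
    problems = validate_taxonomy(tax)
    if problems:
        raise TaxonomyError("; ".join(problems))
    return tax


def load_taxonomy(source: str | Path) -> IngredientTaxonomy:
    """Load a taxonomy from a TSV or JSON edge-list file.

    TSV rows are ``level<TAB>name<TAB>parent-name`` (parent omitted at
    level 1); JSON is a list of ``{"level": int, "name": str, "parent": str}``
    entries.  Ids are assigned per level in file order, 0-based.
    """
    path = Path(source)
    if not path.exists():
        raise TaxonomyError(f"taxonomy file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        rows = _rows_from_json(text)
    else:
        rows = _rows_from_tsv(text)
    if not rows:
        raise TaxonomyError(f"taxonomy file {path} is empty")
    return build_taxonomy(rows)


def write_taxonomy(tax: IngredientTaxonomy, path: str | Path) -> None:
    """Write a taxonomy as the TSV edge list accepted by :func:`load_taxonomy`."""
    lines = []
    for name in tax.names[0]:
        lines.append(f"1\t{name}")
    for level in (2, 3, 4):
        for cid, name in enumerate(tax.names[level - 1]):
            pname = tax.name_of(level - 1, tax.parent_of(level, cid))
            lines.append(f"{level}\t{name}\t{pname}")
    Path(path).write_text("\n".join(lines) + "\n")


def balanced_taxonomy(counts: Sequence[int] = (3, 13, 32, 110)) -> IngredientTaxonomy:
    """Synthesize a valid taxonomy with the given per-level counts.

    Children are distributed round-robin over the parents of the level above,
    so any non-decreasing count vector yields a valid tree.  Useful for tests
    and synthetic datasets; the real category list is user-supplied data.
    """
    if len(counts) != N_LEVELS:
        raise TaxonomyError(f"need {N_LEVELS} counts, got {len(counts)}")
    if any(c <= 0 for c in counts):
        raise TaxonomyError("all level counts must be positive")
    if any(counts[i] > counts[i + 1] for i in range(N_LEVELS - 1)):
        raise TaxonomyError("counts must be non-decreasing from level 1 to 4")
    names = [[f"L{li + 1}_{i:03d}" for i in range(c)] for li, c in enumerate(counts)]
    parent = [
        [i % counts[li] for i in range(counts[li + 1])] for li in range(N_LEVELS - 1)
    ]
    return IngredientTaxonomy(names=names, parent=parent)
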