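"""Tree-structured analysis design built from sample names.

Sample names like ``lineA_treat1_rep2`` encode a hierarchy (cell line /
treatment / replicate).  Splitting every name on a separator yields a
rooted tree whose leaves are the samples; choosing a *level* slices the
samples into groups (level 0 groups by the first component, level 1 by the
first two, and so on).  Every analysis in the package operates on the
groups of one chosen level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import DesignError

DEFAULT_SEPARATOR = "_"


@dataclass
class DesignNode:
    name: str
    children: dict[str, "DesignNode"] = field(default_factory=dict)
    sample: str | None = None  # set at leaves only

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class AnalysisDesign:
    """Rooted tree of sample-name components.

    ``depth`` is the number of name components (= number of levels); valid
    levels are ``0 .. depth - 1``.
    """

    root: DesignNode
    depth: int
    sample_names: list[str]
    separator: str = DEFAULT_SEPARATOR


@dataclass
class GroupAssignment:
    """Samples partitioned into groups at one level of the design."""

    level: int
    groups: dict[str, list[str]]

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    @property
    def samples(self) -> list[str]:
        return [s for members in self.groups.values() for s in members]


def build_design(sample_names: list[str], separator: str = DEFAULT_SEPARATOR) -> AnalysisDesign:
    """Assemble the analysis-design tree from sample names.

    Every name must decompose into the same number of separator-delimited
    components; ragged or duplicate names raise :class:`DesignError`.
    """
    if not sample_names:
        raise DesignError("at least one sample name is required")
    if any(not name for name in sample_names):
        raise DesignError("sample names must be nonempty")
    seen = set()
    dupes = [n for n in sample_names if n in seen or seen.add(n)]
    if dupes:
        raise DesignError(f"duplicate sample names: {sorted(set(dupes))}")

    parts = {name: name.split(separator) for name in sample_names}
    depths = {len(p) for p in parts.values()}
    if len(depths) != 1:
        common = max(depths, key=lambda d: sum(len(p) == d for p in parts.values()))
        offenders = sorted(n for n, p in parts.items() if len(p) != common)
        raise DesignError(
            f"sample names split into differing numbers of components "
            f"(separator {separator!r}); offending names: {offenders}"
        )
    depth = depths.pop()

    root = DesignNode(name="")
    for name in sample_names:
        node = root
        for component in parts[name]:
            node = node.children.setdefault(component, DesignNode(name=component))
        node.sample = name
    return AnalysisDesign(root=root, depth=depth, sample_names=list(sample_names), separator=separator)


def groups_at_level(design: AnalysisDesign, level: int) -> GroupAssignment:
    """Partition the samples into groups by their first ``level + 1`` name
    components.

    Group names are the joined prefix components, which guarantees
    uniqueness; samples within a group keep their input order.
    """
    if not 0 <= level < design.depth:
        raise DesignError(
            f"level {level} out of range; valid levels are 0..{design.depth - 1}"
        )
    groups: dict[str, list[str]] = {}
    for name in design.sample_names:
        key = design.separator.join(name.split(design.separator)[: level + 1])
        groups.setdefault(key, []).append(name)
    return GroupAssignment(level=level, groups=groups)
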