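"""Enzyme Commission (EC) numbers and multi-label annotation sets.

EC numbers are four-level hierarchical codes ``a.b.c.d`` classifying the
reaction an enzyme catalyzes; level 1 is the broadest class and level 4 the
most specific. Partially specified codes (levels 1-3) arise when truncating a
full code to a coarser resolution. Components are usually integers but
preliminary entries such as ``n1`` occur in real lists, so components are kept
as opaque string tokens compared by equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set

__all__ = [
    "ECNumber",
    "AnnotationSet",
    "parse_ec",
    "truncate_ec",
    "common_level",
]


class ECParseError(ValueError):
    """Raised when a string cannot be interpreted as an EC number."""


def _sort_key(ec: "ECNumber") -> tuple:
    # numeric components sort numerically, alphanumeric ones after them
    key = []
    for tok in ec.components:
        try:
            key.append((0, int(tok), ""))
        except ValueError:
            key.append((1, 0, tok))
    return tuple(key)


@dataclass(frozen=True, order=False)
class ECNumber:
    """An EC code of 1 to 4 populated components.

    Parameters
    ----------
    components : tuple of str
        The populated components, most general first. Length equals the
        level of the code.
    """

    components: tuple

    def __post_init__(self):
        if not 1 <= len(self.components) <= 4:
            raise ECParseError(
                f"EC number must have 1-4 components, got {len(self.components)}"
            )
        for tok in self.components:
            if not tok:
                raise ECParseError("EC number contains an empty component")
        object.__setattr__(self, "components", tuple(str(t) for t in self.components))

    @property
    def level(self) -> int:
        """Number of populated components (1 = class, 4 = serial number)."""
        return len(self.components)

    def truncate(self, level: int) -> "ECNumber":
        """Return the code truncated to the first ``level`` components."""
        if not 1 <= level <= self.level:
            raise ValueError(
                f"cannot truncate level-{self.level} code {self} to level {level}"
            )
        return ECNumber(self.components[:level])

    def __str__(self) -> str:
        return ".".join(self.components)

    def __repr__(self) -> str:
        return f"ECNumber({str(self)!r})"

    def __lt__(self, other: "ECNumber") -> bool:
        return _sort_key(self) < _sort_key(other)


def parse_ec(text: str) -> ECNumber:
    """Parse a dot-separated EC code string.

    Raises
    ------
    ECParseError
        If the string is empty, has more than four components, or contains
        empty components (e.g. ``"1..3.4"``).
    """
    if not isinstance(text, str) or not text.strip():
        raise ECParseError(f"not an EC number: {text!r}")
    tokens = text.strip().split(".")
    if len(tokens) > 4 or any(not t for t in tokens):
        raise ECParseError(f"malformed EC number: {text!r}")
    return ECNumber(tuple(tokens))


def truncate_ec(ec: ECNumber, level: int) -> ECNumber:
    """Truncate ``ec`` to its first ``level`` components."""
    return ec.truncate(level)


def common_level(a: ECNumber, b: ECNumber) -> int:
    """Length of the longest shared prefix of two level-4 codes (0-4)."""
    n = 0
    for x, y in zip(a.components, b.components):
        if x != y:
            break
        n += 1
    return n


class AnnotationSet:
    """Ground-truth label sets over a fixed universe of EC codes.

    Each protein carries a non-empty set of level-4 EC numbers (enzymes with
    more than one are "promiscuous"). The label universe is the sorted list
    of distinct codes appearing in any label set, fixing a deterministic
    column order for score matrices.

    Parameters
    ----------
    labels_of : mapping of protein ID -> iterable of ECNumber
        Must be non-empty per protein.
    universe : sequence of ECNumber, optional
        Explicit label universe; defaults to the sorted union of all label
        sets. Every label must be a member.
    """

    def __init__(
        self,
        labels_of: Mapping[str, Iterable[ECNumber]],
        universe: Sequence[ECNumber] | None = None,
    ):
        self.proteins: List[str] = list(labels_of)
        self.labels_of: Dict[str, Set[ECNumber]] = {}
        for pid, labels in labels_of.items():
            s = set(labels)
            if not s:
                raise ValueError(f"protein {pid!r} has an empty label set")
            self.labels_of[pid] = s
        if universe is None:
            universe = sorted(set().union(*self.labels_of.values()))
        else:
            universe = list(universe)
            known = set(universe)
            for pid, s in self.labels_of.items():
                missing = s - known
                if missing:
                    raise ValueError(
                        f"protein {pid!r} has labels outside the universe: "
                        f"{sorted(str(m) for m in missing)}"
                    )
        self.universe: List[ECNumber] = universe

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, pid: str) -> bool:
        return pid in self.labels_of

    def __getitem__(self, pid: str) -> Set[ECNumber]:
        return self.labels_of[pid]

    def truncated(self, level: int) -> "AnnotationSet":
        """Annotation set with every label truncated to ``level`` and
        deduplicated; used to derive coarse ground truth from level-4 codes."""
        return AnnotationSet(
            {
                pid: {ec.truncate(min(level, ec.level)) for ec in labels}
                for pid, labels in self.labels_of.items()
            }
        )

    def subset(self, proteins: Sequence[str]) -> "AnnotationSet":
        """Restrict to the given proteins, keeping the full universe."""
        return AnnotationSet(
            {pid: self.labels_of[pid] for pid in proteins}, universe=self.universe
        )

    def indicator_matrix(self, universe: Sequence[ECNumber] | None = None):
        """Boolean membership matrix, rows = proteins, cols = universe order."""
        import numpy as np

        universe = self.universe if universe is None else list(universe)
        col = {ec: j for j, ec in enumerate(universe)}
        mat = np.zeros((len(self.proteins), len(universe)), dtype=bool)
        for i, pid in enumerate(self.proteins):
            for ec in self.labels_of[pid]:
                j = col.get(ec)
                if j is not None:
                    mat[i, j] = True
        return mat
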