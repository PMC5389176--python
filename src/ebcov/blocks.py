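"""Block structures: partitions of variables into co-regulated groups.

A block structure is a partition of the ``p`` variables (genes) into
disjoint, exhaustive groups.  Biologically a block stands for a
transcriptional unit — an operon in prokaryotes, or a set of genes under
one transcription factor — whose members are expected to co-express.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["BlockStructure", "blocks_from_list", "read_groups_file"]


@dataclass(frozen=True)
class BlockStructure:
    """A partition of ``p`` variables into disjoint, exhaustive blocks.

    Parameters
    ----------
    p
        Number of variables.
    blocks
        Tuple of blocks; each block is a sorted tuple of 0-based variable
        indices.  Blocks are ordered by their smallest member.
    labels
        Optional variable identifiers, aligned with indices ``0..p-1``.
    """

    p: int
    blocks: tuple[tuple[int, ...], ...]
    labels: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for block in self.blocks:
            if len(block) == 0:
                raise ValueError("empty block in BlockStructure")
            for i in block:
                if not 0 <= i < self.p:
                    raise ValueError(f"index {i} outside 0..{self.p - 1}")
                if i in seen:
                    raise ValueError(f"index {i} appears in more than one block")
                seen.add(i)
        if len(seen) != self.p:
            missing = sorted(set(range(self.p)) - seen)
            raise ValueError(f"blocks do not cover all variables; missing {missing}")
        if self.labels is not None and len(self.labels) != self.p:
            raise ValueError("labels length does not match p")

    @classmethod
    def from_blocks(
        cls,
        p: int,
        blocks: Iterable[Iterable[int]],
        labels: Sequence[str] | None = None,
    ) -> "BlockStructure":
        """Normalize arbitrary block iterables: sort members, order blocks
        by smallest member."""
        norm = sorted((tuple(sorted(b)) for b in blocks), key=lambda b: b[0])
        return cls(p=p, blocks=tuple(norm), labels=tuple(labels) if labels else None)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)

    def membership(self) -> list[int]:
        """Block index of every variable, as a length-``p`` list."""
        member = [0] * self.p
        for k, block in enumerate(self.blocks):
            for i in block:
                member[i] = k
        return member

    def same_block_mask(self, include_diagonal: bool = True):
        """Boolean ``p×p`` matrix, True where the pair lies inside one block."""
        import numpy as np

        member = np.asarray(self.membership())
        mask = member[:, None] == member[None, :]
        if not include_diagonal:
            np.fill_diagonal(mask, False)
        return mask

    def permute(self, perm: Sequence[int]) -> "BlockStructure":
        """Relabel variables so old index ``i`` becomes ``perm[i]``."""
        perm = list(perm)
        if sorted(perm) != list(range(self.p)):
            raise ValueError("perm is not a permutation of 0..p-1")
        new_blocks = [[perm[i] for i in block] for block in self.blocks]
        new_labels = None
        if self.labels is not None:
            new_labels = [""] * self.p
            for i, lab in enumerate(self.labels):
                new_labels[perm[i]] = lab
        return BlockStructure.from_blocks(self.p, new_blocks, new_labels)


def blocks_from_list(
    assignments: Sequence[Iterable[str]], labels: Sequence[str]
) -> BlockStructure:
    """Build a :class:`BlockStructure` from named variable groups.

    ``assignments`` lists groups of variable identifiers (e.g. genes known to
    share a transcriptional unit).  Identifiers not listed in any group
    become singleton blocks.

    Raises
    ------
    ValueError
        If an identifier is unknown or occurs in more than one group.
    """
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    if len(index) != len(labels):
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        raise ValueError(f"duplicate variable labels: {dupes}")

    assigned: set[int] = set()
    blocks: list[list[int]] = []
    for group in assignments:
        members: list[int] = []
        for name in group:
            if name not in index:
                raise ValueError(f"unknown identifier in group assignment: {name!r}")
            i = index[name]
            if i in assigned:
                raise ValueError(
                    f"identifier {name!r} assigned to more than one group"
                )
            assigned.add(i)
            members.append(i)
        if members:
            blocks.append(members)
    for i in range(len(labels)):
        if i not in assigned:
            blocks.append([i])
    return BlockStructure.from_blocks(len(labels), blocks, labels)


def read_groups_file(path, labels: Sequence[str]) -> BlockStructure:
    """Read group assignments from a plain-text file.

    One block per line; identifiers separated by whitespace or commas;
    lines starting with ``#`` (and blank lines) are ignored.
    """
    groups: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            names = [tok for tok in line.replace(",", " ").split() if tok]
            if names:
                groups.append(names)
    return blocks_from_list(groups, labels)
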