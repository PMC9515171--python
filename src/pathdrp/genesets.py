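"""GMT gene-set collections and the pre-scoring size filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]  # ordered, unique

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene-set names: {dupes}")
        empty = [s.name for s in self.sets if len(s) == 0]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-delimited GMT file: name, description, member genes...

    Duplicate member genes within a line are deduplicated (first occurrence
    kept); a line with fewer than 3 fields or a repeated set name is an error.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            uniq = tuple(dict.fromkeys(genes))
            if len(uniq) < len(genes):
                logger.info("%s:%d: deduplicated %d repeated genes in %s",
                            path, lineno, len(genes) - len(uniq), name)
            sets.append(GeneSet(name, desc, uniq))
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in c:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


def filter_by_size(
    c: GeneSetCollection, universe: Sequence[str] | Iterable[str], min_size: int = 5
) -> GeneSetCollection:
    """Intersect each set with the measured gene universe; drop small sets.

    A set is kept iff min_size <= |set ∩ universe| < |universe|.  Sets that
    cover the whole universe are uninformative for the enrichment walk (the
    non-member term would divide by zero), so they are dropped too.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("empty gene universe")
    uset = set(universe)
    kept: list[GeneSet] = []
    for s in c:
        inter = tuple(dict.fromkeys(g for g in s.genes if g in uset))
        if len(inter) < min_size:
            continue
        if len(set(inter)) == len(uset):
            logger.info("filter_by_size: %s spans the whole universe; dropped", s.name)
            continue
        kept.append(GeneSet(s.name, s.description, inter))
    if not kept:
        raise ValueError("no scorable gene sets after size filtering")
    dropped = len(c) - len(kept)
    if dropped:
        logger.info("filter_by_size: dropped %d of %d sets", dropped, len(c))
    return GeneSetCollection(kept)
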