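"""Scored somatic-mutation catalogs.

A catalog is a table of point mutations, each carrying a pathogenicity score
in [0, 1] (FATHMM-MKL style, as distributed with COSMIC).  Scores partition
the catalog into three classes:

* ``neutral``        score <= 0.5
* ``driver``         0.5 < score <= 0.7
* ``strong_driver``  score > 0.7

A mutation is *pathogenic* (fitness-relevant) iff its score exceeds 0.5; the
boundaries are strict on the pathogenic side, so 0.5 is neutral and 0.7 is an
ordinary driver.  The simulator samples uniformly within a partition: the
score shapes the selection coefficient of the receiving clone, not the
probability of being drawn.
"""

from __future__ import annotations

import enum
import io
import math
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MutationClass",
    "ScoredMutation",
    "MutationCatalog",
    "CatalogError",
    "classify_mutation",
    "load_catalog",
    "sample_mutation",
]


class CatalogError(ValueError):
    """Malformed catalog input or invalid sampling request."""


class MutationClass(str, enum.Enum):
    NEUTRAL = "neutral"
    DRIVER = "driver"
    STRONG_DRIVER = "strong_driver"


def classify_mutation(score: float) -> MutationClass:
    """Classify a pathogenicity score (strict thresholds at 0.5 and 0.7)."""
    if not (isinstance(score, (int, float)) and math.isfinite(score)):
        raise CatalogError(f"score must be a finite number, got {score!r}")
    if not (0.0 <= score <= 1.0):
        raise CatalogError(f"score must be in [0, 1], got {score}")
    if score <= 0.5:
        return MutationClass.NEUTRAL
    if score <= 0.7:
        return MutationClass.DRIVER
    return MutationClass.STRONG_DRIVER


@dataclass(frozen=True)
class ScoredMutation:
    mutation_id: str
    score: float
    gene: str | None = None
    site: str | None = None

    @property
    def mutation_class(self) -> MutationClass:
        return classify_mutation(self.score)

    @property
    def is_pathogenic(self) -> bool:
        return self.score > 0.5


@dataclass
class MutationCatalog:
    """A validated catalog with its class partitions.

    ``neutral_ids`` / ``driver_ids`` / ``strong_driver_ids`` are disjoint,
    exhaustive index partitions into ``entries``.
    """

    entries: list[ScoredMutation]
    neutral_ids: list[int] = field(default_factory=list)
    driver_ids: list[int] = field(default_factory=list)
    strong_driver_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.neutral_ids or self.driver_ids or self.strong_driver_ids):
            self._build_partitions()

    def _build_partitions(self) -> None:
        self.neutral_ids, self.driver_ids, self.strong_driver_ids = [], [], []
        buckets = {
            MutationClass.NEUTRAL: self.neutral_ids,
            MutationClass.DRIVER: self.driver_ids,
            MutationClass.STRONG_DRIVER: self.strong_driver_ids,
        }
        for i, e in enumerate(self.entries):
            buckets[e.mutation_class].append(i)
        self._pathogenic = self.driver_ids + self.strong_driver_ids

    @property
    def pathogenic_ids(self) -> list[int]:
        return self.driver_ids + self.strong_driver_ids

    def __len__(self) -> int:
        return len(self.entries)

    def partition_sizes(self) -> tuple[int, int, int]:
        return (
            len(self.neutral_ids),
            len(self.driver_ids),
            len(self.strong_driver_ids),
        )

    def filter_site(self, site: str) -> "MutationCatalog":
        """Optional histology restriction: keep entries whose ``site`` label
        matches (entries without a site label are dropped)."""
        kept = [e for e in self.entries if e.site == site]
        if not kept:
            raise CatalogError(f"no catalog entries for site {site!r}")
        return MutationCatalog(entries=kept)


_REQUIRED = ("mutation_id", "score")
_OPTIONAL = ("gene", "site")


def load_catalog(path: str | os.PathLike | io.TextIOBase) -> MutationCatalog:
    """Load a catalog from a tab-separated file.

    The file must be UTF-8 with a header naming at least ``mutation_id`` and
    ``score`` (optional ``gene``, ``site``); ``#`` lines are comments.  Rows
    with out-of-range scores, malformed fields, or duplicate IDs raise
    :class:`CatalogError` naming the offending line.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = "<stream>"
    else:
        name = os.fspath(path)
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    header: list[str] | None = None
    entries: list[ScoredMutation] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            missing = [c for c in _REQUIRED if c not in header]
            if missing:
                raise CatalogError(
                    f"{name}:{lineno}: header missing column(s) {missing}"
                )
            continue
        if len(fields) != len(header):
            raise CatalogError(
                f"{name}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        row = dict(zip(header, fields))
        mid = row["mutation_id"].strip()
        if not mid:
            raise CatalogError(f"{name}:{lineno}: empty mutation_id")
        if mid in seen:
            raise CatalogError(f"{name}:{lineno}: duplicate mutation_id {mid!r}")
        seen.add(mid)
        try:
            score = float(row["score"])
        except ValueError:
            raise CatalogError(
                f"{name}:{lineno}: score {row['score']!r} is not a number"
            ) from None
        if not (0.0 <= score <= 1.0):
            raise CatalogError(
                f"{name}:{lineno}: score {score} outside [0, 1]"
            )
        entries.append(
            ScoredMutation(
                mutation_id=mid,
                score=score,
                gene=row.get("gene") or None,
                site=row.get("site") or None,
            )
        )
    if header is None:
        raise CatalogError(f"{name}: no header line found")
    if not entries:
        raise CatalogError(f"{name}: no entries")
    return MutationCatalog(entries=entries)


def sample_mutation(
    cat: MutationCatalog, want_driver: bool, rng: np.random.Generator
) -> ScoredMutation:
    """Uniform draw from the pathogenic partition (driver plus strong driver)
    when ``want_driver``, else from the neutral partition."""
    pool = cat.pathogenic_ids if want_driver else cat.neutral_ids
    if not pool:
        kind = "pathogenic" if want_driver else "neutral"
        raise CatalogError(f"catalog has no {kind} entries to sample")
    return cat.entries[pool[int(rng.integers(len(pool)))]]
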