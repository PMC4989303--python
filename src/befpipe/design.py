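"""Random-partitions experimental design.

At each richness level the full isolate pool is split into disjoint
communities of exactly that size, so every isolate is represented once per
level.  This decouples species richness from composition: contrasts between
richness levels are not confounded by which isolates happen to be included,
because all of them are, at every level.  A pool of 16 isolates at levels
{1, 2, 4, 8, 16} yields 16 + 8 + 4 + 2 + 1 = 31 communities per partition;
three independent partitions give the canonical 93 microcosms.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class DesignError(ValueError):
    """Raised when a requested design is structurally impossible."""


@dataclass(frozen=True)
class Isolate:
    """A pool member: an opaque label, its genus, and its terminal
    restriction fragment (tRF).  Distinct isolates may share a fragment."""

    isolate_id: str
    genus: str
    trf_fragment: int


class IsolatePool:
    """The fixed pool of isolates available to the experiment."""

    def __init__(self, isolates: Sequence[Isolate]):
        ids = [iso.isolate_id for iso in isolates]
        if len(set(ids)) != len(ids):
            raise DesignError("isolate_ids must be unique")
        if len(ids) < 2:
            raise DesignError("pool must contain at least 2 isolates")
        self._isolates = tuple(isolates)
        self._by_id = {iso.isolate_id: iso for iso in isolates}

    def __len__(self) -> int:
        return len(self._isolates)

    def __iter__(self) -> Iterator[Isolate]:
        return iter(self._isolates)

    def __getitem__(self, isolate_id: str) -> Isolate:
        return self._by_id[isolate_id]

    def __contains__(self, isolate_id: str) -> bool:
        return isolate_id in self._by_id

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(iso.isolate_id for iso in self._isolates)

    def fragment_map(self) -> dict[int, frozenset[str]]:
        """fragment -> set of isolate_ids producing it."""
        out: dict[int, set[str]] = {}
        for iso in self._isolates:
            out.setdefault(iso.trf_fragment, set()).add(iso.isolate_id)
        return {frag: frozenset(v) for frag, v in out.items()}

    @classmethod
    def treehole_default(cls) -> "IsolatePool":
        """The default 16-isolate pool, mirroring a beech treehole culture
        collection: Pseudomonas dominated (n=7), eight further genera, and
        two tRF collisions (two Pseudomonas pairs indistinguishable after
        HhaI/RsaI digestion)."""
        spec = [
            ("ACI01", "Acinetobacter", 151),
            ("BAC01", "Bacillus", 204),
            ("EPI01", "Epilithomonas", 233),
            ("FLA01", "Flavobacterium", 88),
            ("MIC01", "Microbacterium", 341),
            ("MIC02", "Microbacterium", 367),
            ("PED01", "Pedobacter", 121),
            ("PSE01", "Pseudomonas", 490),
            ("PSE02", "Pseudomonas", 490),   # shares tRF with PSE01
            ("PSE03", "Pseudomonas", 213),
            ("PSE04", "Pseudomonas", 213),   # shares tRF with PSE03
            ("PSE05", "Pseudomonas", 462),
            ("PSE06", "Pseudomonas", 509),
            ("PSE07", "Pseudomonas", 533),
            ("SPH01", "Sphingomonas", 176),
            ("STA01", "Staphylococcus", 276),
        ]
        return cls([Isolate(i, g, f) for i, g, f in spec])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isolate_id": [i.isolate_id for i in self._isolates],
                "genus": [i.genus for i in self._isolates],
                "trf_fragment": [i.trf_fragment for i in self._isolates],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "IsolatePool":
        return cls(
            [
                Isolate(str(r.isolate_id), str(r.genus), int(r.trf_fragment))
                for r in frame.itertuples()
            ]
        )


@dataclass(frozen=True)
class Community:
    community_id: str
    members: frozenset[str]

    @property
    def richness(self) -> int:
        return len(self.members)


@dataclass
class PartitionDesign:
    """One partition: at each richness level, a disjoint cover of the pool."""

    partition_id: int
    richness_levels: tuple[int, ...]
    communities: list[Community]
    replicates: int = 1
    pool_ids: tuple[str, ...] = field(default_factory=tuple)

    def communities_at(self, level: int) -> list[Community]:
        return [c for c in self.communities if c.richness == level]

    @property
    def n_communities(self) -> int:
        return len(self.communities)

    def microcosms(self) -> Iterator[tuple[str, int, Community]]:
        """Yield (microcosm_id, replicate, community) for every microcosm."""
        for rep in range(1, self.replicates + 1):
            for comm in self.communities:
                yield f"{comm.community_id}.r{rep}", rep, comm


def expected_community_count(pool_size: int, levels: Sequence[int]) -> int:
    """Sum over levels of pool_size / level (each level covers the pool)."""
    return sum(pool_size // lv for lv in levels)


def generate_partition(
    pool: IsolatePool,
    richness_levels: Sequence[int],
    seed: int,
    partition_id: int = 1,
    replicates: int = 1,
) -> PartitionDesign:
    """Randomly partition the pool into disjoint communities at each level.

    The pool is shuffled once per level with a generator seeded by `seed`
    and chunked consecutively, so the same seed reproduces the design
    byte-for-byte.  Community IDs follow ``P{partition}.R{richness}.{index}``
    and never depend on randomization order beyond the chunking itself.
    """
    levels = tuple(richness_levels)
    if len(set(levels)) != len(levels) or list(levels) != sorted(levels):
        raise DesignError("richness levels must be distinct and ascending")
    size = len(pool)
    for lv in levels:
        if lv < 1 or size % lv != 0:
            raise DesignError(
                f"richness level {lv} does not divide pool size {size}"
            )
    rng = np.random.default_rng(seed)
    communities: list[Community] = []
    for lv in levels:
        order = list(pool.ids)
        rng.shuffle(order)
        for k in range(size // lv):
            members = frozenset(order[k * lv : (k + 1) * lv])
            communities.append(
                Community(f"P{partition_id}.R{lv}.{k + 1}", members)
            )
    return PartitionDesign(
        partition_id=partition_id,
        richness_levels=levels,
        communities=communities,
        replicates=replicates,
        pool_ids=pool.ids,
    )


def build_experiment(
    pool: IsolatePool,
    richness_levels: Sequence[int],
    n_partitions: int = 3,
    replicates: int = 1,
    seed: int = 0,
) -> list[PartitionDesign]:
    """Independently randomized partitions; each spawned from its own
    seed stream so partitions are independent but jointly reproducible."""
    if n_partitions < 1 or replicates < 1:
        raise DesignError("n_partitions and replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_partitions)
    return [
        generate_partition(
            pool,
            richness_levels,
            seed=child,
            partition_id=p + 1,
            replicates=replicates,
        )
        for p, child in enumerate(children)
    ]


def validate_design(design: PartitionDesign, pool: IsolatePool | None = None) -> list[str]:
    """Return human-readable invariant violations (empty list == valid).

    Violations are data, not exceptions: externally supplied designs are
    audited, and every violation names the level/isolate involved.
    """
    violations: list[str] = []
    pool_ids = set(pool.ids) if pool is not None else set(design.pool_ids)
    if not pool_ids:
        pool_ids = set().union(*(c.members for c in design.communities))
    size = len(pool_ids)
    for comm in design.communities:
        stray = comm.members - pool_ids
        if stray:
            violations.append(
                f"community {comm.community_id}: members not in pool: "
                f"{sorted(stray)}"
            )
    for lv in design.richness_levels:
        comms = design.communities_at(lv)
        if size % lv == 0 and len(comms) != size // lv:
            violations.append(
                f"level {lv}: expected {size // lv} communities, found {len(comms)}"
            )
        seen: dict[str, int] = {}
        for comm in comms:
            for iso in comm.members:
                seen[iso] = seen.get(iso, 0) + 1
        for iso in sorted(pool_ids):
            n = seen.get(iso, 0)
            if n == 0:
                violations.append(f"level {lv}: isolate {iso} missing")
            elif n > 1:
                violations.append(
                    f"level {lv}: isolate {iso} appears {n} times"
                )
    expected = expected_community_count(size, design.richness_levels)
    if design.n_communities != expected:
        violations.append(
            f"total communities {design.n_communities} != expected {expected}"
        )
    return violations


# ---------------------------------------------------------------------------
# Tabular round-trip

def design_to_frame(designs: Iterable[PartitionDesign]) -> pd.DataFrame:
    """Long design table: one row per microcosm."""
    rows = []
    for d in designs:
        for microcosm_id, rep, comm in d.microcosms():
            rows.append(
                {
                    "microcosm_id": microcosm_id,
                    "partition_id": d.partition_id,
                    "replicate": rep,
                    "community_id": comm.community_id,
                    "richness": comm.richness,
                    "members": ";".join(sorted(comm.members)),
                }
            )
    return pd.DataFrame(rows)


def design_from_frame(frame: pd.DataFrame) -> list[PartitionDesign]:
    designs = []
    for pid, grp in frame.groupby("partition_id", sort=True):
        comms = {}
        for r in grp.itertuples():
            comms[r.community_id] = Community(
                str(r.community_id), frozenset(str(r.members).split(";"))
            )
        levels = tuple(sorted({c.richness for c in comms.values()}))
        designs.append(
            PartitionDesign(
                partition_id=int(pid),
                richness_levels=levels,
                communities=list(comms.values()),
                replicates=int(grp["replicate"].max()),
            )
        )
    return designs


def members_of(design_frame: pd.DataFrame) -> dict[str, list[str]]:
    """microcosm_id -> sorted member isolate ids."""
    return {
        str(r.microcosm_id): sorted(str(r.members).split(";"))
        for r in design_frame.itertuples()
    }
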