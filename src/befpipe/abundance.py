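"""tRFLP fragment intensities -> per-isolate relative and absolute abundances.

Community fingerprints give one intensity per terminal restriction
fragment, but several isolates can share a fragment.  Two attribution
rules resolve the collision:

* ``equal`` (the null hypothesis): a shared fragment's intensity is split
  equally among the member isolates that produce it;
* ``random`` (the most extreme alternative): the whole intensity is
  assigned to a single member producer chosen uniformly at random.

Both rules conserve total signal; over many random draws the ``random``
rule averages to the ``equal`` one.  Fragments no community member can
produce are a contamination diagnostic: they are reported, excluded from
attribution, and the remaining profile is renormalized.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .assays import ASSAY_CELLS, TRF_PREFIX, CONTROL_ID
from .design import IsolatePool


class AttributionError(ValueError):
    pass


class FragmentMap:
    """fragment id -> isolates producing it (several isolates may share)."""

    def __init__(self, mapping: Mapping[int, Iterable[str]]):
        self._map = {int(f): frozenset(isos) for f, isos in mapping.items()}
        seen: dict[str, int] = {}
        for frag, isos in self._map.items():
            for iso in isos:
                if iso in seen:
                    raise AttributionError(
                        f"isolate {iso} mapped to fragments {seen[iso]} and {frag}"
                    )
                seen[iso] = frag

    @classmethod
    def from_pool(cls, pool: IsolatePool) -> "FragmentMap":
        return cls(pool.fragment_map())

    def producers(self, fragment: int) -> frozenset[str]:
        return self._map.get(int(fragment), frozenset())

    def fragment_of(self, isolate_id: str) -> int:
        for frag, isos in self._map.items():
            if isolate_id in isos:
                return frag
        raise KeyError(isolate_id)

    @property
    def has_collisions(self) -> bool:
        return any(len(isos) > 1 for isos in self._map.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"trf_fragment": frag, "isolate_id": iso}
            for frag, isos in sorted(self._map.items())
            for iso in sorted(isos)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FragmentMap":
        grouped = frame.groupby("trf_fragment")["isolate_id"].apply(set)
        return cls(grouped.to_dict())


def _attributable(
    profile: Mapping[int, float],
    members: frozenset[str],
    fmap: FragmentMap,
) -> tuple[dict[int, float], float]:
    """Keep fragments some member can produce; return them plus the
    excluded (contaminant) intensity fraction."""
    total = float(sum(profile.values()))
    if total <= 0:
        raise AttributionError("profile has no positive intensity")
    kept: dict[int, float] = {}
    stray = 0.0
    for frag, inten in profile.items():
        if inten < 0:
            raise AttributionError(f"negative intensity for fragment {frag}")
        if fmap.producers(frag) & members:
            kept[frag] = float(inten)
        else:
            stray += float(inten)
    if stray > 0:
        warnings.warn(
            f"{stray / total:.1%} of profile intensity on fragments no "
            "member produces; excluded and renormalized",
            stacklevel=3,
        )
    if not kept or sum(kept.values()) <= 0:
        raise AttributionError("no attributable intensity for this community")
    return kept, stray / total


def attribute_equal(
    profile: Mapping[int, float],
    members: Iterable[str],
    fmap: FragmentMap,
) -> dict[str, float]:
    """Equal-sharing rule; returns relative abundances summing to 1."""
    members = frozenset(members)
    kept, _ = _attributable(profile, members, fmap)
    norm = sum(kept.values())
    ra = {iso: 0.0 for iso in sorted(members)}
    for frag, inten in kept.items():
        owners = sorted(fmap.producers(frag) & members)
        for iso in owners:
            ra[iso] += inten / norm / len(owners)
    return ra


def attribute_random(
    profile: Mapping[int, float],
    members: Iterable[str],
    fmap: FragmentMap,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Whole-fragment random assignment; returns relative abundances."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    members = frozenset(members)
    kept, _ = _attributable(profile, members, fmap)
    norm = sum(kept.values())
    ra = {iso: 0.0 for iso in sorted(members)}
    for frag in sorted(kept):
        owners = sorted(fmap.producers(frag) & members)
        winner = owners[rng.integers(len(owners))] if len(owners) > 1 else owners[0]
        ra[winner] += kept[frag] / norm
    return ra


def absolute_counts(
    ra: Mapping[str, float], cells_per_ml: float
) -> dict[str, float]:
    """Absolute per-isolate counts: total cell density times relative
    tRFLP intensity (cells ml^-1)."""
    if cells_per_ml < 0:
        raise AttributionError("cells_per_ml must be >= 0")
    return {iso: r * cells_per_ml for iso, r in ra.items()}


def abundance_table(
    measurements: pd.DataFrame,
    members_by_microcosm: Mapping[str, list[str]],
    fmap: FragmentMap,
    rule: str = "equal",
    seed: int = 0,
    detection_floor: float = 0.005,
) -> pd.DataFrame:
    """Per-microcosm x day x isolate relative abundances and counts.

    Intensities below ``detection_floor`` (as a fraction of the profile
    total) are zeroed as baseline noise before normalization.  Output
    columns: microcosm_id, day, isolate_id, relative_abundance,
    absolute_count (cells ml^-1), plus the excluded stray fraction.
    """
    if rule not in ("equal", "random"):
        raise AttributionError(f"unknown attribution rule {rule!r}")
    rng = np.random.default_rng(seed)
    trf = measurements[
        measurements["assay"].str.startswith(TRF_PREFIX)
        & (measurements["microcosm_id"] != CONTROL_ID)
    ]
    cells = (
        measurements[measurements["assay"] == ASSAY_CELLS]
        .set_index(["microcosm_id", "day"])["value"]
        .to_dict()
    )
    rows = []
    for (mid, day), grp in trf.groupby(["microcosm_id", "day"], sort=True):
        profile = {
            int(a.removeprefix(TRF_PREFIX)): v
            for a, v in zip(grp["assay"], grp["value"])
        }
        total = sum(profile.values())
        profile = {
            f: (v if v >= detection_floor * total else 0.0)
            for f, v in profile.items()
        }
        profile = {f: v for f, v in profile.items() if v > 0}
        members = frozenset(members_by_microcosm[str(mid)])
        kept, stray = _attributable(profile, members, fmap)
        if rule == "equal":
            ra = attribute_equal(kept, members, fmap)
        else:
            ra = attribute_random(kept, members, fmap, seed=rng)
        density = cells.get((mid, day), float("nan"))
        counts = absolute_counts(ra, density) if np.isfinite(density) else {}
        for iso in sorted(members):
            rows.append(
                {
                    "microcosm_id": mid,
                    "day": day,
                    "isolate_id": iso,
                    "relative_abundance": ra.get(iso, 0.0),
                    "absolute_count": counts.get(iso, float("nan")),
                    "stray_fraction": stray,
                }
            )
    return pd.DataFrame(rows)
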