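"""Loreau-Hector additive partitioning of the net biodiversity effect.

For a mixture of N isolates with monoculture functioning ``M_i``, observed
total functioning ``P_obs`` and relative abundances ``ra_i``:

* observed yields        ``Y_obs_i = ra_i * P_obs``
* relative yields        ``RY_obs_i = Y_obs_i / M_i``; expected ``1/N``
  (the seeded proportion: inocula are split equally)
* deviations             ``dRY_i = RY_obs_i - 1/N``
* net effect             ``deltaY = sum_i Y_obs_i - sum_i M_i / N``
* complementarity        ``N * mean(dRY) * mean(M)``
* selection              ``N * cov(dRY, M)``

The covariance is the population form (divide by N, not N-1): only then
does ``deltaY = complementarity + selection`` hold as an algebraic
identity, because ``N * cov_pop(dRY, M) + N * mean(dRY) * mean(M)
= sum_i dRY_i * M_i = deltaY``.  Using the sample covariance here is a
classic implementation bug.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm


class PartitioningError(ValueError):
    pass


def additive_partition(
    members: list[str],
    monocultures: Mapping[str, float],
    p_observed: float,
    ra: Mapping[str, float],
) -> dict:
    """Partition one mixture's net effect into complementarity + selection.

    Isolates whose monoculture functioning is zero (or missing) are
    excluded -- their relative yield is undefined -- with N adjusted and
    the exclusion recorded in the result.
    """
    if len(members) < 2:
        raise PartitioningError("additive partition requires richness >= 2")
    excluded = [
        m
        for m in members
        if m not in monocultures
        or not np.isfinite(monocultures[m])
        or monocultures[m] <= 0
    ]
    used = [m for m in members if m not in excluded]
    if len(used) < 2:
        raise PartitioningError(
            f"fewer than 2 isolates with positive monoculture values "
            f"(excluded: {excluded})"
        )
    n = len(used)
    m_vec = np.array([monocultures[m] for m in used], dtype=float)
    y_obs = np.array([ra.get(m, 0.0) * p_observed for m in used], dtype=float)
    ry_obs = y_obs / m_vec
    d_ry = ry_obs - 1.0 / n
    mean_dry = d_ry.mean()
    mean_m = m_vec.mean()
    complementarity = n * mean_dry * mean_m
    selection = n * float(np.cov(d_ry, m_vec, ddof=0)[0, 1])
    delta_y = float(y_obs.sum() - m_vec.sum() / n)
    return {
        "n": n,
        "delta_y": delta_y,
        "complementarity": complementarity,
        "selection": selection,
        "d_ry": dict(zip(used, d_ry)),
        "excluded": excluded,
    }


def partition_table(
    functioning: pd.DataFrame,
    abundance: pd.DataFrame,
    design_frame: pd.DataFrame,
    measure: str = "per_capita",
) -> pd.DataFrame:
    """Additive partition for every mixture microcosm x day."""
    from .interactions import MEASURES, monoculture_table

    col = MEASURES[measure]
    mono = monoculture_table(functioning, design_frame, measure)
    func = functioning.set_index(["microcosm_id", "day"])
    ra_lookup = abundance.set_index(["microcosm_id", "day", "isolate_id"])[
        "relative_abundance"
    ]
    mixtures = design_frame[design_frame["richness"] > 1]
    rows = []
    for row in mixtures.itertuples():
        members = sorted(str(row.members).split(";"))
        mono_pr = mono[
            (mono["partition_id"] == row.partition_id)
            & (mono["replicate"] == row.replicate)
        ]
        for day, m_day in mono_pr.groupby("day"):
            key = (row.microcosm_id, day)
            if key not in func.index:
                continue
            p_obs = float(func.loc[key, col])
            if not np.isfinite(p_obs):
                continue
            m_values = dict(zip(m_day["isolate_id"], m_day["M"]))
            ra = {
                iso: float(ra_lookup.get((row.microcosm_id, day, iso), 0.0))
                for iso in members
            }
            res = additive_partition(members, m_values, p_obs, ra)
            rows.append(
                {
                    "microcosm_id": row.microcosm_id,
                    "day": day,
                    "richness": row.richness,
                    "n_used": res["n"],
                    "delta_y": res["delta_y"],
                    "complementarity": res["complementarity"],
                    "selection": res["selection"],
                    "n_excluded": len(res["excluded"]),
                }
            )
    return pd.DataFrame(rows)


def partition_vs_richness(results: pd.DataFrame) -> pd.DataFrame:
    """Per-day OLS slope of each partition component against richness.

    Effect sizes only; a day with a single richness level gets NaN slopes
    and a flag rather than an error.
    """
    rows = []
    for day, grp in results.groupby("day", sort=True):
        rec: dict = {"day": day, "n": len(grp)}
        single = grp["richness"].nunique() < 2
        rec["flag"] = "single_richness_level" if single else ""
        for comp in ("complementarity", "selection"):
            if single:
                rec[f"slope_{comp}"] = float("nan")
                continue
            X = sm.add_constant(grp["richness"].astype(float))
            fit = sm.OLS(grp[comp].astype(float), X, missing="drop").fit()
            rec[f"slope_{comp}"] = float(fit.params["richness"])
        rows.append(rec)
    return pd.DataFrame(rows)
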