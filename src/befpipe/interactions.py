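"""Monoculture-based predictions, log response ratios, and pairwise
interaction classification.

For a mixture of N isolates the expected functioning under independence is
built from same-day monocultures: under the ``equal_abundance`` model each
isolate is assumed to hold 1/N of the community, so
``P_pred = sum_i M_i / N`` with per-isolate share ``M_i / N``; the ``sum``
model skips the 1/N scaling (``P_pred = sum_i M_i``).  Each isolate's
observed contribution is its relative abundance times the observed total,
``P_obs_i = ra_i * P_observed``.  The log response ratio
``ln(P_obs / P_pred)`` is negative when an isolate (or the community)
under-performs its monoculture expectation, zero under independence.

Pairs: every unordered member pair inherits its two isolates' whole-
community log ratios (an attribution convention, not a causal pairwise
estimate) and is classified with a small neutral band epsilon:
both below -eps -> antagonism, both above +eps -> mutualism, opposite
signs beyond the band -> exploitation, otherwise neutral.
"""
from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

PREDICTION_MODELS = ("equal_abundance", "sum")
CLASSES = ("antagonism", "mutualism", "exploitation", "neutral")

#: default functioning measure: per-capita respiration (pg CO2 cell^-1 day^-1)
MEASURES = {
    "per_capita": "per_capita_pg_cell_day",
    "total": "co2_rate_ug_day",
}


class InteractionError(ValueError):
    pass


def monoculture_table(
    functioning: pd.DataFrame,
    design_frame: pd.DataFrame,
    measure: str = "per_capita",
) -> pd.DataFrame:
    """Extract M_i: each isolate's monoculture functioning per day.

    Monocultures are matched within their partition and replicate, so a
    mixture is always compared against monocultures grown alongside it.
    Output: partition_id, replicate, isolate_id, day, M.
    """
    col = MEASURES[measure]
    mono = design_frame[design_frame["richness"] == 1]
    merged = mono.merge(functioning, on="microcosm_id")
    out = merged[["partition_id", "replicate", "members", "day", col]].rename(
        columns={"members": "isolate_id", col: "M"}
    )
    return out.reset_index(drop=True)


def predict_functioning(
    members: list[str],
    monocultures: Mapping[str, float],
    model: str = "equal_abundance",
) -> tuple[float, dict[str, float]]:
    """(P_predicted, per-isolate P_pred_i) from monoculture values."""
    if model not in PREDICTION_MODELS:
        raise InteractionError(f"unknown prediction model {model!r}")
    missing = [m for m in members if m not in monocultures
               or not np.isfinite(monocultures[m])]
    if missing:
        raise InteractionError(
            f"missing monoculture value for isolate(s) {missing}"
        )
    n = len(members)
    share = 1.0 / n if model == "equal_abundance" else 1.0
    per = {m: share * float(monocultures[m]) for m in members}
    return sum(per.values()), per


def observed_contributions(
    p_observed: float, ra: Mapping[str, float]
) -> dict[str, float]:
    """P_obs_i = ra_i * P_observed (conserves the total exactly)."""
    return {iso: r * p_observed for iso, r in ra.items()}


def response_ratios(
    functioning: pd.DataFrame,
    abundance: pd.DataFrame,
    design_frame: pd.DataFrame,
    model: str = "equal_abundance",
    measure: str = "per_capita",
    floor: float | None = None,
) -> pd.DataFrame:
    """Per-isolate and community log response ratios for every mixture.

    ``floor`` replaces non-positive observed contributions before the log
    (rows are flagged ``floored``); the default is half the smallest
    positive per-isolate contribution in the data set, since ln(0) is
    undefined and undetected isolates would otherwise drop out.
    """
    col = MEASURES[measure]
    mono = monoculture_table(functioning, design_frame, measure)
    mixtures = design_frame[design_frame["richness"] > 1]
    func = functioning.set_index(["microcosm_id", "day"])
    ra_lookup = abundance.set_index(["microcosm_id", "day", "isolate_id"])[
        "relative_abundance"
    ]

    records = []
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
            p_obs_total = float(func.loc[key, col])
            m_values = dict(zip(m_day["isolate_id"], m_day["M"]))
            p_pred_total, p_pred = predict_functioning(
                members, m_values, model
            )
            ra = {
                iso: float(
                    ra_lookup.get((row.microcosm_id, day, iso), 0.0)
                )
                for iso in members
            }
            p_obs = observed_contributions(p_obs_total, ra)
            for iso in members:
                records.append(
                    {
                        "microcosm_id": row.microcosm_id,
                        "partition_id": row.partition_id,
                        "replicate": row.replicate,
                        "day": day,
                        "richness": row.richness,
                        "isolate_id": iso,
                        "p_pred": p_pred[iso],
                        "p_obs": p_obs[iso],
                        "p_pred_community": p_pred_total,
                        "p_obs_community": p_obs_total,
                    }
                )
    table = pd.DataFrame(records)
    if table.empty:
        raise InteractionError("no mixture records to analyse")

    positive = table.loc[table["p_obs"] > 0, "p_obs"]
    if floor is None:
        floor = 0.5 * positive.min() if not positive.empty else 1e-12
    table["floored"] = table["p_obs"] <= 0
    obs = table["p_obs"].where(table["p_obs"] > 0, floor)
    with np.errstate(divide="ignore"):
        table["log_rr"] = np.log(obs / table["p_pred"])
        table["community_log_rr"] = np.log(
            table["p_obs_community"] / table["p_pred_community"]
        )
    table.loc[~np.isfinite(table["log_rr"]), "log_rr"] = np.nan
    return table


def classify_pair(log_rr_i: float, log_rr_j: float, epsilon: float) -> str:
    if log_rr_i < -epsilon and log_rr_j < -epsilon:
        return "antagonism"
    if log_rr_i > epsilon and log_rr_j > epsilon:
        return "mutualism"
    if (log_rr_i > epsilon and log_rr_j < -epsilon) or (
        log_rr_i < -epsilon and log_rr_j > epsilon
    ):
        return "exploitation"
    return "neutral"


def pairwise_expand(
    interactions: pd.DataFrame, epsilon: float = 0.05
) -> pd.DataFrame:
    """One row per unordered member pair per microcosm x day.

    Each isolate's whole-community log response ratio is reused for all
    its pairs, matching how pairwise interaction plots are constructed
    from per-isolate ratios.
    """
    rows = []
    for (mid, day), grp in interactions.groupby(
        ["microcosm_id", "day"], sort=True
    ):
        vals = dict(zip(grp["isolate_id"], grp["log_rr"]))
        richness = int(grp["richness"].iloc[0])
        if richness < 2:
            continue
        for iso_i, iso_j in combinations(sorted(vals), 2):
            ri, rj = vals[iso_i], vals[iso_j]
            rows.append(
                {
                    "microcosm_id": mid,
                    "day": day,
                    "richness": richness,
                    "isolate_i": iso_i,
                    "isolate_j": iso_j,
                    "log_rr_i": ri,
                    "log_rr_j": rj,
                    "class": classify_pair(ri, rj, epsilon)
                    if np.isfinite(ri) and np.isfinite(rj)
                    else "neutral",
                }
            )
    return pd.DataFrame(rows)


def succession_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-day interaction summaries: mean, s.e., variance of the pooled
    pair log ratios; class frequencies; and a symmetry statistic (the
    Pearson correlation of log_rr_i with log_rr_j over symmetrized pairs).

    Effect sizes only -- no significance machinery.
    """
    rows = []
    for day, grp in pairs.groupby("day", sort=True):
        pooled = pd.concat([grp["log_rr_i"], grp["log_rr_j"]]).dropna()
        if len(pooled) < 2:
            raise InteractionError(f"fewer than 2 pair values on day {day}")
        # pair values within a microcosm share the community measurement,
        # so the s.e. of the mean is cluster-robust by microcosm
        long = pd.concat(
            [
                grp[["microcosm_id", "log_rr_i"]].rename(
                    columns={"log_rr_i": "v"}
                ),
                grp[["microcosm_id", "log_rr_j"]].rename(
                    columns={"log_rr_j": "v"}
                ),
            ]
        ).dropna(subset=["v"])
        grand = long["v"].mean()
        m_total = len(long)
        dev = long.groupby("microcosm_id")["v"].agg(["sum", "count"])
        se_cluster = float(
            np.sqrt(((dev["sum"] - dev["count"] * grand) ** 2).sum())
            / m_total
        )
        x = pd.concat([grp["log_rr_i"], grp["log_rr_j"]])
        y = pd.concat([grp["log_rr_j"], grp["log_rr_i"]])
        ok = np.isfinite(x) & np.isfinite(y)
        symmetry = (
            float(np.corrcoef(x[ok], y[ok])[0, 1])
            if ok.sum() >= 2 and x[ok].std() > 0
            else float("nan")
        )
        freqs = grp["class"].value_counts(normalize=True)
        rows.append(
            {
                "day": day,
                "n_pairs": len(grp),
                "mean_log_rr": pooled.mean(),
                "se_log_rr": se_cluster,
                "var_log_rr": pooled.var(ddof=1),
                "symmetry_corr": symmetry,
                **{f"freq_{c}": float(freqs.get(c, 0.0)) for c in CLASSES},
            }
        )
    return pd.DataFrame(rows)
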