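"""Normalization of vertebral strength across spinal levels.

Two normalizations relative to L1 are provided.  The adjacent-ratio graph
averages within-subject strength ratios of anatomically adjacent,
nonfractured vertebrae (one edge per adjacent level pair) and accumulates
them along the unique chain to the reference level; it uses only relative
within-subject information and is robust to scan coverage.  The population
normalization compares each level's mean strength to the cohort mean L1
strength directly.  Group differences (fractured vs. non-fractured) are
tested with one-sided Mann-Whitney U tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .levels_order import LEVEL_ORDER, level_index

__all__ = [
    "LevelGraph",
    "adjacent_ratio_graph",
    "population_relative_to_l1",
    "stratify",
    "fracture_group_test",
    "records_frame",
]

SMALL_SAMPLE_N = 3  # strata below this subject count are flagged


def records_frame(records) -> pd.DataFrame:
    """Normalize a record list / DataFrame to the canonical columns."""
    df = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    required = {"subject", "level", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if "fractured" not in df.columns:
        df["fractured"] = False
    for lv in df["level"].unique():
        level_index(lv)
    return df


@dataclass
class LevelGraph:
    """Adjacent-level strength-ratio graph relative to a reference level."""

    nodes: list
    edge_mean_ratio: dict         # (upper, lower) -> mean(S_upper / S_lower)
    edge_n: dict                  # (upper, lower) -> number of subject pairs
    cumulative_pct_vs_ref: dict   # level -> percent difference vs reference
    reference: str = "L1"
    unreachable: list = field(default_factory=list)

    def __post_init__(self):
        for pair, r in self.edge_mean_ratio.items():
            if r <= 0:
                raise ValueError(f"nonpositive edge ratio for {pair}")


def adjacent_ratio_graph(records, reference: str = "L1",
                         mean: str = "arithmetic") -> LevelGraph:
    """Build the adjacent-ratio graph and accumulate percent differences.

    Edge ratio = mean over subjects of (strength at the upper level /
    strength at the lower level), computed within subject and only when
    both vertebrae of the pair are nonfractured.  ``mean`` may be
    ``"arithmetic"`` (default) or ``"geometric"``.
    """
    df = records_frame(records)
    levels = sorted(df["level"].unique(), key=level_index)
    if reference not in levels:
        raise ValueError(f"reference level {reference} absent from the records")

    clean = df[~df["fractured"]]
    pivot = clean.pivot_table(index="subject", columns="level", values="value")

    edge_ratio, edge_n = {}, {}
    for upper, lower in zip(levels, levels[1:]):
        if level_index(lower) != level_index(upper) + 1:
            continue
        if upper not in pivot.columns or lower not in pivot.columns:
            continue
        both = pivot[[upper, lower]].dropna()
        if len(both) == 0:
            continue
        ratios = (both[upper] / both[lower]).to_numpy()
        edge_ratio[(upper, lower)] = (
            float(np.exp(np.log(ratios).mean())) if mean == "geometric"
            else float(ratios.mean())
        )
        edge_n[(upper, lower)] = len(both)

    cumulative, unreachable = {reference: 0.0}, []
    ref_i = level_index(reference)
    # walk the chain outward from the reference in both directions
    for direction in (-1, +1):
        acc = 1.0
        i = ref_i
        while True:
            nxt = i + direction
            chain_broken = (
                nxt < 0 or nxt >= len(LEVEL_ORDER) or LEVEL_ORDER[nxt] not in levels
            )
            if not chain_broken:
                upper, lower = (LEVEL_ORDER[nxt], LEVEL_ORDER[i]) if direction < 0 else (
                    LEVEL_ORDER[i], LEVEL_ORDER[nxt])
                chain_broken = (upper, lower) not in edge_ratio
            if chain_broken:
                # levels farther out in this direction have no ratio chain
                unreachable.extend(
                    lv for lv in levels
                    if (level_index(lv) - ref_i) * direction > (i - ref_i) * direction
                )
                break
            r = edge_ratio[(upper, lower)]
            acc = acc * r if direction < 0 else acc / r
            i = nxt
            cumulative[LEVEL_ORDER[i]] = (acc - 1.0) * 100.0

    return LevelGraph(levels, edge_ratio, edge_n, cumulative, reference,
                      sorted(set(unreachable), key=level_index))


def population_relative_to_l1(records, reference: str = "L1") -> dict:
    """Percent difference of each level's mean strength vs the cohort mean
    strength at the reference level."""
    df = records_frame(records)
    ref = df.loc[df["level"] == reference, "value"]
    if len(ref) == 0:
        raise ValueError(f"no {reference} records in the cohort")
    ref_mean = ref.mean()
    out = {}
    for lv, grp in df.groupby("level"):
        out[lv] = float((grp["value"].mean() / ref_mean - 1.0) * 100.0)
    return dict(sorted(out.items(), key=lambda kv: level_index(kv[0])))


def stratify(records, by: str = "sex", exclude_fractures: bool = False,
             reference: str = "L1") -> dict:
    """Run both normalizations per stratum of ``by`` (sex or fracture status).

    Returns ``{stratum: {"graph": LevelGraph, "population": dict,
    "n_subjects": int, "small_sample": bool}}``; empty strata are omitted
    with a warning.
    """
    df = records_frame(records)
    if by not in df.columns:
        raise ValueError(f"grouping column '{by}' absent from the records")
    if exclude_fractures:
        frac_subjects = df.loc[df["fractured"], "subject"].unique()
        df = df[~df["subject"].isin(frac_subjects)]
    out = {}
    for stratum, grp in df.groupby(by):
        n = grp["subject"].nunique()
        if n == 0 or reference not in set(grp["level"]):
            warnings.warn(f"stratum '{stratum}' empty or missing {reference}; omitted",
                          stacklevel=2)
            continue
        out[stratum] = {
            "graph": adjacent_ratio_graph(grp, reference=reference),
            "population": population_relative_to_l1(grp, reference=reference),
            "n_subjects": int(n),
            "small_sample": n < SMALL_SAMPLE_N,
        }
    return out


def fracture_group_test(fracture_values, control_values) -> dict:
    """One-sided Mann-Whitney U test: fracture-group strength lower.

    Exact enumeration for small tie-free groups (n <= 8 each), normal
    approximation with tie correction otherwise.  With every value tied
    across both groups the test is undefined; p = 0.5 is returned with a
    warning flag.
    """
    a = np.asarray(fracture_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied across both groups; p undefined", stacklevel=2)
        return {"p": 0.5, "U": len(a) * len(b) / 2.0, "tie_warning": True}
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="less", method=method)
    return {"p": float(res.pvalue), "U": float(res.statistic), "tie_warning": False}
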