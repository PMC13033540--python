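"""Group-level statistics: per-group/site summary tables, pairwise
rank-sum comparisons with Bonferroni correction and significance
labels, and variance-equality testing for morphometric ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .rank_tests import (
    bonferroni_adjust,
    levene_test,
    significance_label,
    wilcoxon_rank_sum,
)
from .roi import SITES, SiteMeasurement, summarize_roi

__all__ = [
    "AnimalRecord",
    "GroupComparison",
    "GroupSummaryRow",
    "animal_site_means",
    "compare_groups_per_site",
    "comparisons_to_frame",
    "summarize_groups",
    "subgroup_boxplot_data",
    "wilcoxon_rank_sum",
    "bonferroni_adjust",
    "significance_label",
    "levene_test",
]


@dataclass
class AnimalRecord:
    """One cohort animal: id, severity group (0 healthy .. 3 severe
    shell softening) and optional passive metadata."""

    animal_id: int | str
    group: int
    age_years: float | None = None
    body_mass_g: float | None = None
    sex: str | None = None
    bloodwork: dict | None = None

    def __post_init__(self):
        if self.group not in (0, 1, 2, 3):
            raise ValueError("group must be 0..3")
        if self.body_mass_g is not None and self.body_mass_g <= 0:
            raise ValueError("body mass must be positive when present")


@dataclass(frozen=True)
class GroupComparison:
    """One pairwise site-level test result."""

    site: str
    group_a: int
    group_b: int
    raw_p: float
    adj_p: float
    label: str


@dataclass(frozen=True)
class GroupSummaryRow:
    group: int
    site: str
    mean: float
    median: float
    sd: float
    maximum: float
    p99: float
    minimum: float
    p1: float
    pixel_count: int


def _group_lookup(animals) -> dict:
    """Accept a dict animal_id->group, a list of AnimalRecord, or a DataFrame."""
    if isinstance(animals, dict):
        return animals
    if isinstance(animals, pd.DataFrame):
        return dict(zip(animals["animal_id"], animals["group"]))
    return {a.animal_id: a.group for a in animals}


def animal_site_means(
    measurements: list[SiteMeasurement], animals
) -> pd.DataFrame:
    """One mean BMD per (animal, site), sides pooled by concatenating
    pixel populations.  Only retained measurements contribute."""
    groups = _group_lookup(animals)
    pooled: dict[tuple, list[np.ndarray]] = {}
    for m in measurements:
        if m.status != "retained":
            continue
        pooled.setdefault((m.animal_id, m.site), []).append(m.pixel_values)
    rows = [
        {
            "animal_id": animal_id,
            "group": groups[animal_id],
            "site": site,
            "mean_bmd": float(np.concatenate(chunks).mean()),
            "pixel_count": int(sum(c.size for c in chunks)),
        }
        for (animal_id, site), chunks in sorted(pooled.items(), key=lambda kv: (str(kv[0][0]), kv[0][1]))
    ]
    return pd.DataFrame(rows)


def compare_groups_per_site(
    measurements: list[SiteMeasurement],
    animals,
    unit: str = "animal_mean",
    bonferroni_m: int = 6,
    label_map=None,
) -> list[GroupComparison]:
    """All pairwise group comparisons at each site.

    ``unit="animal_mean"`` (default) compares one mean value per animal
    per site, sides pooled; ``unit="pooled_pixels"`` compares the raw
    pooled pixel populations.  Bonferroni uses ``bonferroni_m`` as the
    family size per site (6 pairwise comparisons within a site by
    default; pass 18 to correct across sites).
    """
    if unit not in ("animal_mean", "pooled_pixels"):
        raise ValueError(f"unknown comparison unit {unit!r}")
    groups = _group_lookup(animals)
    if unit == "animal_mean":
        frame = animal_site_means(measurements, animals)
        def site_units(site, g):
            sel = frame[(frame["site"] == site) & (frame["group"] == g)]
            return sel["mean_bmd"].to_numpy()
    else:
        def site_units(site, g):
            vals = [
                m.pixel_values
                for m in measurements
                if m.status == "retained" and m.site == site and groups[m.animal_id] == g
            ]
            return np.concatenate(vals) if vals else np.empty(0)

    present_groups = sorted(set(groups.values()))
    comparisons: list[GroupComparison] = []
    for site in SITES:
        for ga, gb in combinations(present_groups, 2):
            xa, xb = site_units(site, ga), site_units(site, gb)
            if xa.size == 0 or xb.size == 0:
                warnings.warn(
                    f"skipping {site} {ga} vs {gb}: a group has no units", stacklevel=2
                )
                continue
            _, raw_p = wilcoxon_rank_sum(xa, xb)
            adj_p = float(bonferroni_adjust([raw_p], m=bonferroni_m)[0])
            label = (
                significance_label(adj_p)
                if label_map is None
                else significance_label(adj_p, label_map)
            )
            comparisons.append(
                GroupComparison(
                    site=site, group_a=ga, group_b=gb, raw_p=raw_p, adj_p=adj_p, label=label
                )
            )
    return comparisons


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site": c.site,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "raw_p": c.raw_p,
                "adj_p": c.adj_p,
                "label": c.label,
            }
            for c in comparisons
        ]
    )


def summarize_groups(
    measurements: list[SiteMeasurement], animals, round_display: bool = False
) -> pd.DataFrame:
    """Per-(group, site) statistics over the pooled pixel values of all
    retained ROIs.  ``round_display`` rounds mean/median/max/min to
    integers and SD/percentiles to one decimal for table display; all
    computation is at full precision."""
    groups = _group_lookup(animals)
    pooled: dict[tuple, list[np.ndarray]] = {}
    for m in measurements:
        if m.status != "retained":
            continue
        pooled.setdefault((groups[m.animal_id], m.site), []).append(m.pixel_values)
    rows = []
    for (g, site), chunks in sorted(pooled.items()):
        s = summarize_roi(np.concatenate(chunks))
        row = {
            "group": g,
            "site": site,
            "mean": s.mean,
            "median": s.median,
            "sd": s.sd,
            "maximum": s.maximum,
            "p99": s.p99,
            "minimum": s.minimum,
            "p1": s.p1,
            "pixel_count": s.pixel_count,
        }
        if round_display:
            for k in ("mean", "median", "maximum", "minimum"):
                row[k] = round(row[k])
            for k in ("sd", "p99", "p1"):
                row[k] = round(row[k], 1)
        rows.append(row)
    return pd.DataFrame(rows)


def subgroup_boxplot_data(
    measurements: list[SiteMeasurement], animals, partition
) -> dict[str, dict]:
    """Per-site, per-stratum lists of animal-level means for box plots.

    ``partition`` maps an animal id to exactly one stratum label.  No
    test is attached; empty strata are simply absent.
    """
    frame = animal_site_means(measurements, animals)
    strata = {a: partition(a) for a in frame["animal_id"].unique()}
    if any(s is None for s in strata.values()):
        raise ValueError("partition must assign every animal to a stratum")
    out: dict[str, dict] = {}
    for site in SITES:
        sel = frame[frame["site"] == site]
        per_stratum: dict = {}
        for _, row in sel.iterrows():
            per_stratum.setdefault(strata[row["animal_id"]], []).append(row["mean_bmd"])
        if per_stratum:
            out[site] = per_stratum
    return out
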