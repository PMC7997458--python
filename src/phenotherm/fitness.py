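"""Fruit set, seed set, ovule counts and the autonomous-selfing contrast.

Fruit set is the proportion of retrieved flowers in a batch that set
fruit; seed set is the number of seeds per formed fruit.  Because seed
per fruit can be capped by ovule supply, ovule counts per flower are
summarised alongside.  Pollinator-excluded batches quantify autonomous
self-pollination, contrasted with open-pollinated batches via a 2×2
chi-square test.  Seasonal site summaries weight batch fruit set by
floral abundance so the estimate reflects when most flowers were open.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .longevity import abundance_weighted_mean
from .phenology import RankSiteTest, rank_site_test

__all__ = [
    "SelfingContrast",
    "SiteComparisons",
    "fruit_set",
    "fruit_set_table",
    "weighted_fruit_set",
    "selfing_contrast",
    "site_comparisons",
]

logger = logging.getLogger(__name__)


def fruit_set(fruits: int, retrieved: int) -> float:
    """Proportion of retrieved flowers that set fruit."""
    if retrieved <= 0:
        raise ValueError("no retrieved flowers")
    if fruits < 0 or fruits > retrieved:
        raise ValueError("fruit count outside [0, retrieved]")
    return fruits / retrieved


def fruit_set_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-batch fruit set from columns site, batch, treatment, retrieved, fruits.

    Batches with zero retrieved flowers are excluded with a log entry,
    mirroring field loss handling.
    """
    frame = records.copy()
    empty = frame["retrieved"] <= 0
    if empty.any():
        for _, row in frame[empty].iterrows():
            logger.info("excluding batch %s (%s): no retrieved flowers", row["batch"], row["site"])
        frame = frame[~empty]
    frame["fruit_set"] = frame["fruits"] / frame["retrieved"]
    return frame


def weighted_fruit_set(
    proportions: Sequence[float], weights: Sequence[float], normalized: bool = True
) -> float:
    """Abundance-weighted seasonal fruit set, in percent."""
    return 100.0 * abundance_weighted_mean(proportions, weights, normalized=normalized)


@dataclasses.dataclass(frozen=True)
class SelfingContrast:
    chi2: float
    pvalue: float
    prop_excluded: float
    prop_open: float
    table: tuple


def selfing_contrast(
    excluded: tuple[int, int], open_pollinated: tuple[int, int]
) -> SelfingContrast:
    """2×2 chi-square of fruit formation, pollinator-excluded vs open.

    Arguments are (fruits, retrieved) per treatment.  Pearson chi-square
    without continuity correction; proportions reported alongside.
    """
    (fe, re_), (fo, ro) = excluded, open_pollinated
    if re_ <= 0 or ro <= 0:
        raise ValueError("retrieved counts must be positive")
    table = np.array([[fe, re_ - fe], [fo, ro - fo]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero-margin contingency table")
    chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return SelfingContrast(
        float(chi2), float(p), fe / re_, fo / ro, tuple(map(tuple, table.astype(int)))
    )


@dataclasses.dataclass(frozen=True)
class SiteComparisons:
    fruit_anova_f: float
    fruit_anova_p: float
    fruit_tukey: pd.DataFrame
    ovule_anova_f: float
    ovule_anova_p: float
    ovule_tukey: pd.DataFrame
    seed_rank: RankSiteTest


def _one_way(groups: Mapping[str, Sequence[float]]):
    labels = [g for g in groups if len(groups[g]) > 0]
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    f, p = scipy.stats.f_oneway(*arrays)
    values = np.concatenate(arrays)
    codes = np.concatenate([[g] * len(a) for g, a in zip(labels, arrays)])
    tukey = pairwise_tukeyhsd(values, codes)
    frame = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    return float(f), float(p), frame


def site_comparisons(
    fruit_set_by_site: Mapping[str, Sequence[float]],
    seeds_by_site: Mapping[str, Sequence[float]],
    ovules_by_site: Mapping[str, Sequence[float]],
) -> SiteComparisons:
    """Site effects: one-way ANOVA + Tukey for fruit set and ovules, rank
    test (Kruskal–Wallis with Dunn follow-up) for seeds per fruit."""
    if len(fruit_set_by_site) < 2:
        raise ValueError("need >= 2 sites")
    ff, fp, ftk = _one_way(fruit_set_by_site)
    of, op_, otk = _one_way(ovules_by_site)
    seed_rank = rank_site_test(seeds_by_site)
    return SiteComparisons(ff, fp, ftk, of, op_, otk, seed_rank)
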