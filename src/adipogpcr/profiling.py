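"""Cross-condition set analysis of expression profiles.

Venn partitions of detected gene sets, depot-exclusive gene lists, and
top-N rankings (by expression level or by between-condition enrichment).
A gene counts as "detected" when its class is Expressed or Trace; the
``expressed`` stratum restricts to the Expressed class only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

from .qpcr import CLASSES, ExpressionProfile

__all__ = [
    "ProfilingError",
    "VennPartition",
    "EnrichmentRanking",
    "detected_set",
    "venn_partition",
    "exclusive_genes",
    "top_n_expressed",
    "top_n_enriched",
]

log = logging.getLogger(__name__)

#: Floor (in % of housekeeping) applied to ratios so enrichment over an
#: absent gene stays bounded; equals the trace threshold.
ABSENT_FLOOR = 0.01

_STRATA = ("detected", "expressed")


class ProfilingError(ValueError):
    """Raised on incompatible profiles or invalid ranking requests."""


@dataclass
class VennPartition:
    """Disjoint region -> gene set cover of 2-3 condition sets.

    Region keys are frozensets of condition labels: the genes present in
    exactly those conditions.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset, list[str]]
    stratum: str

    def sizes(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(len(self.labels), 0, -1):
            for combo in combinations(self.labels, r):
                key = frozenset(combo)
                genes = self.regions.get(key, [])
                rows.append(
                    {
                        "region": "&".join(sorted(combo)),
                        "n_genes": len(genes),
                        "genes": ",".join(genes),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class EnrichmentRanking:
    """Ordered genes with the statistic that ranked them."""

    table: pd.DataFrame
    statistic: str

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _check_same_universe(profiles: list[ExpressionProfile]) -> None:
    first = profiles[0].table.index
    for p in profiles[1:]:
        if not first.equals(p.table.index):
            raise ProfilingError(
                "profiles cover different gene universes; "
                "re-profile against a common manifest"
            )


def detected_set(profile: ExpressionProfile, stratum: str = "detected") -> set[str]:
    """Genes detected in a profile under the requested stratum."""
    if stratum not in _STRATA:
        raise ProfilingError(f"unknown stratum {stratum!r}; use one of {_STRATA}")
    cls = profile.table["expression_class"]
    if stratum == "expressed":
        keep = cls == CLASSES[0]
    else:
        keep = cls != CLASSES[2]
    return set(profile.table.index[keep])


def venn_partition(
    profiles: list[ExpressionProfile], stratum: str = "detected"
) -> VennPartition:
    """Partition 2-3 condition gene sets into disjoint Venn regions."""
    if not 2 <= len(profiles) <= 3:
        raise ProfilingError("venn_partition takes 2 or 3 profiles")
    _check_same_universe(profiles)
    labels = tuple(p.condition for p in profiles)
    if len(set(labels)) != len(labels):
        raise ProfilingError("condition labels must be distinct")
    sets = {p.condition: detected_set(p, stratum) for p in profiles}
    union = set().union(*sets.values())
    regions: dict[frozenset, list[str]] = {}
    for gene in union:
        key = frozenset(lbl for lbl in labels if gene in sets[lbl])
        regions.setdefault(key, []).append(gene)
    for genes in regions.values():
        genes.sort()
    return VennPartition(labels=labels, regions=regions, stratum=stratum)


def exclusive_genes(
    profile_a: ExpressionProfile, profile_b: ExpressionProfile
) -> tuple[list[str], list[str]]:
    """Genes detected in exactly one of two conditions (a-only, b-only)."""
    _check_same_universe([profile_a, profile_b])
    set_a = detected_set(profile_a)
    set_b = detected_set(profile_b)
    return sorted(set_a - set_b), sorted(set_b - set_a)


def top_n_expressed(profile: ExpressionProfile, n: int) -> EnrichmentRanking:
    """Top-n detected genes by relative expression, ties alphabetical."""
    if n < 1:
        raise ProfilingError("n must be >= 1")
    det = sorted(detected_set(profile))
    sub = profile.table.loc[det]
    if n > len(sub):
        log.warning(
            "requested top %d but only %d detected genes in %s",
            n, len(sub), profile.condition,
        )
    ranked = sub.sort_values(
        ["relative_expression_pct"], ascending=False, kind="stable"
    ).head(n)
    table = pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "gene": ranked.index,
            "relative_expression_pct": ranked["relative_expression_pct"].to_numpy(),
        }
    )
    return EnrichmentRanking(table=table, statistic="relative_expression_pct")


def top_n_enriched(
    profile_a: ExpressionProfile,
    profile_b: ExpressionProfile,
    n: int,
    floor: float = ABSENT_FLOOR,
) -> EnrichmentRanking:
    """Top-n genes enriched in condition a over b among shared detections.

    The statistic is the ratio r_a / r_b with both values floored at the
    trace threshold, bounding enrichment over barely-detected genes.
    """
    if n < 1:
        raise ProfilingError("n must be >= 1")
    _check_same_universe([profile_a, profile_b])
    shared = sorted(detected_set(profile_a) & detected_set(profile_b))
    if not shared:
        log.warning(
            "no genes detected in both %s and %s",
            profile_a.condition, profile_b.condition,
        )
        table = pd.DataFrame(columns=["rank", "gene", "r_a", "r_b", "ratio"])
        return EnrichmentRanking(table=table, statistic="ratio")
    r_a = profile_a.table.loc[shared, "relative_expression_pct"].clip(lower=floor)
    r_b = profile_b.table.loc[shared, "relative_expression_pct"].clip(lower=floor)
    ratio = (r_a / r_b).sort_values(ascending=False, kind="stable").head(n)
    table = pd.DataFrame(
        {
            "rank": range(1, len(ratio) + 1),
            "gene": ratio.index,
            "r_a": r_a[ratio.index].to_numpy(),
            "r_b": r_b[ratio.index].to_numpy(),
            "ratio": ratio.to_numpy(),
        }
    )
    return EnrichmentRanking(table=table, statistic="ratio")
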