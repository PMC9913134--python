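"""Shared statistical core: fold changes, t-tests, FDR, volcano tables.

Fold changes are log2 throughout. For qPCR data the fold change between
conditions is the difference of mean dCt values (one cycle = one log2
unit, positive = up in the condition of interest); for RNA-seq it is the
log2 ratio of pseudocounted mean CPM. Per-gene tests are two-tailed
Student t-tests with pooled variance (Welch available behind a flag),
and multiplicity is handled with the Benjamini-Hochberg step-up.

Published volcano plots flag genes with -log10(p) above 1.3, which
admits p = 0.05 itself (-log10(0.05) ~= 1.301); the default raw-p rule
reproduces that convention exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsError",
    "SignificanceRule",
    "RAW_P_VOLCANO",
    "FDR_05",
    "FDR_01",
    "TTestOutcome",
    "delta_delta_ct_logfc",
    "log_cpm_fc",
    "gene_wise_ttest",
    "bh_adjust",
    "build_contrast",
    "volcano_table",
    "top_changed",
    "write_contrast",
]

log = logging.getLogger(__name__)

#: Smallest p reported when a degenerate-variance gene differs in mean.
P_FLOOR = np.nextafter(0.0, 1.0)

DIRECTIONS = ("up", "down", "unchanged")


class StatsError(ValueError):
    """Raised on invalid statistical input."""


@dataclass(frozen=True)
class SignificanceRule:
    """How a contrast's significance flag is decided.

    mode
        ``"raw_p"`` thresholds the raw p-value; ``"fdr"`` thresholds the
        BH-adjusted p-value.
    alpha
        Significance level.
    neglog_cutoff
        If set, the flag is ``-log10(p or padj) > neglog_cutoff`` instead
        of ``p < alpha`` — the volcano-plot convention, which with cutoff
        1.3 includes p = 0.05 itself.
    """

    mode: str = "raw_p"
    alpha: float = 0.05
    neglog_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("raw_p", "fdr"):
            raise StatsError(f"unknown significance mode {self.mode!r}")
        if not 0 < self.alpha < 1:
            raise StatsError("alpha must lie in (0, 1)")

    def is_significant(self, p: np.ndarray, padj: np.ndarray) -> np.ndarray:
        target = np.asarray(padj if self.mode == "fdr" else p, dtype=float)
        if self.neglog_cutoff is not None:
            with np.errstate(divide="ignore"):
                return -np.log10(target) > self.neglog_cutoff
        return target < self.alpha


#: Rule of the differentiation volcano: raw p, -log10(p) > 1.3.
RAW_P_VOLCANO = SignificanceRule(mode="raw_p", alpha=0.05, neglog_cutoff=1.3)
#: FDR < 0.05 rule used for the human obesity contrasts.
FDR_05 = SignificanceRule(mode="fdr", alpha=0.05)
#: FDR < 0.01 rule used for the mouse high-fat-diet contrast.
FDR_01 = SignificanceRule(mode="fdr", alpha=0.01)


@dataclass
class TTestOutcome:
    t: float
    p: float
    degenerate: bool = False


def delta_delta_ct_logfc(dct_cond: float, dct_ref: float):
    """log2 fold change from mean dCt values: dct_ref - dct_cond.

    One PCR cycle is one doubling, so a condition whose dCt is one cycle
    lower than the reference is up two-fold (+1).
    """
    return np.asanyarray(dct_ref, dtype=float) - np.asanyarray(dct_cond, dtype=float)


def log_cpm_fc(mean_cpm_cond, mean_cpm_ref, pseudocount: float = 1.0):
    """log2 of the pseudocounted CPM ratio, condition over reference."""
    if pseudocount <= 0:
        raise StatsError("pseudocount must be > 0")
    a = np.asanyarray(mean_cpm_cond, dtype=float)
    b = np.asanyarray(mean_cpm_ref, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise StatsError("mean CPM must be non-negative")
    return np.log2((a + pseudocount) / (b + pseudocount))


def gene_wise_ttest(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = True,
) -> TTestOutcome:
    """Two-tailed two-sample t-test (pooled variance by default).

    Degenerate variance (both groups constant) is reported rather than
    propagated as NaN: equal means give t = 0, p = 1; unequal means give
    the smallest representable p with the ``degenerate`` flag set.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 replicates")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise StatsError("replicate values must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestOutcome(t=0.0, p=1.0, degenerate=True)
        t = float("inf") if a.mean() > b.mean() else float("-inf")
        return TTestOutcome(t=t, p=P_FLOOR, degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TTestOutcome(t=float(t), p=float(p), degenerate=False)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _directions(log2_fc: np.ndarray) -> np.ndarray:
    return np.select(
        [log2_fc > 0, log2_fc < 0], [DIRECTIONS[0], DIRECTIONS[1]],
        default=DIRECTIONS[2],
    )


def build_contrast(
    genes: Sequence[str],
    log2_fc: Sequence[float],
    p: Sequence[float],
    rule: SignificanceRule,
    degenerate: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Assemble a per-gene contrast table with BH adjustment and flags.

    Columns: ``gene, log2_fc, p, padj, neglog10, direction, significant``
    (plus ``degenerate`` when provided). BH runs over exactly the genes
    in this contrast.
    """
    fc = np.asarray(log2_fc, dtype=float)
    praw = np.asarray(p, dtype=float)
    padj = bh_adjust(praw)
    target = padj if rule.mode == "fdr" else praw
    with np.errstate(divide="ignore"):
        neglog = -np.log10(target)
    out = pd.DataFrame(
        {
            "gene": list(genes),
            "log2_fc": fc,
            "p": praw,
            "padj": padj,
            "neglog10": neglog,
            "direction": _directions(fc),
            "significant": rule.is_significant(praw, padj),
        }
    )
    if degenerate is not None:
        out["degenerate"] = np.asarray(degenerate, dtype=bool)
    return out


def volcano_table(contrasts: pd.DataFrame, rule: SignificanceRule) -> pd.DataFrame:
    """(Re-)annotate a contrast table under a significance rule."""
    if contrasts.empty:
        return contrasts.assign(neglog10=[], direction=[], significant=[])
    out = contrasts.copy()
    target = out["padj"] if rule.mode == "fdr" else out["p"]
    with np.errstate(divide="ignore"):
        out["neglog10"] = -np.log10(target.to_numpy(dtype=float))
    out["direction"] = _directions(out["log2_fc"].to_numpy(dtype=float))
    out["significant"] = rule.is_significant(
        out["p"].to_numpy(dtype=float), out["padj"].to_numpy(dtype=float)
    )
    return out


def top_changed(contrasts: pd.DataFrame, n: int, direction: str) -> list[str]:
    """Top-n significant genes by |log2_fc| in one direction.

    Ties on |log2_fc| break alphabetically.
    """
    if n < 1:
        raise StatsError("n must be >= 1")
    if direction not in ("up", "down"):
        raise StatsError("direction must be 'up' or 'down'")
    sub = contrasts[
        contrasts["significant"] & (contrasts["direction"] == direction)
    ].copy()
    if sub.empty:
        log.warning("no significant %s-regulated genes", direction)
        return []
    sub["abs_fc"] = sub["log2_fc"].abs()
    sub = sub.sort_values(["gene"]).sort_values(
        "abs_fc", ascending=False, kind="stable"
    )
    return list(sub["gene"].head(n))


def write_contrast(contrasts: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "log2_fc", "p", "padj", "neglog10", "direction", "significant"]
    extra = [c for c in contrasts.columns if c not in cols]
    contrasts[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.6g")
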