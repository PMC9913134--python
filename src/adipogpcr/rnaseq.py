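"""RNA-seq branch: counts -> CPM, panel subsetting, strata, contrasts.

Mirrors the qPCR pipeline on counts-per-million data. Stratification
reuses the housekeeping-relative scheme: a gene's relative expression is
its mean CPM as a percentage of the mean CPM of the 15 housekeeping
genes, classified with the same 0.1 % / 0.01 % thresholds, so one
definition of Expressed / Trace / Absent holds across platforms.

Group contrasts (e.g. metabolically healthy lean vs obese cohorts, or
chow vs high-fat-diet mice) run per-gene t-tests on log2(CPM+1) with
Benjamini-Hochberg adjustment within each contrast; fold changes are
log2 ratios of pseudocounted linear mean CPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import PanelManifest
from .qpcr import CLASSES, ClassificationScheme, ExpressionProfile
from . import stats as _stats

__all__ = [
    "RnaseqError",
    "CountsMatrix",
    "GroupDesign",
    "read_counts_matrix",
    "cpm_normalize",
    "subset_gpcrs",
    "classify_rnaseq",
    "contrast_groups",
]

log = logging.getLogger(__name__)


class RnaseqError(ValueError):
    """Raised on malformed count input or an invalid design."""


@dataclass
class CountsMatrix:
    """Gene x sample non-negative integer counts with group labels."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise RnaseqError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise RnaseqError("counts must be integers")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise RnaseqError(f"samples without a group label: {sorted(missing)}")

    def samples_for(self, group: str) -> list[str]:
        mask = self.sample_meta["group"] == group
        return [s for s in self.counts.columns if s in self.sample_meta.index[mask]]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["group"]))


@dataclass
class GroupDesign:
    """Pairwise contrasts (condition, reference) over labeled groups."""

    contrasts: list[tuple[str, str]]
    min_group_size: int = 2

    @classmethod
    def all_pairs(cls, groups: Sequence[str]) -> "GroupDesign":
        """Every ordered pair (later group vs earlier reference)."""
        pairs = [
            (groups[j], groups[i])
            for i in range(len(groups))
            for j in range(i + 1, len(groups))
        ]
        return cls(contrasts=pairs)

    def validate(self, counts: CountsMatrix) -> None:
        seen = set()
        for cond, ref in self.contrasts:
            if cond == ref:
                raise RnaseqError(f"contrast {cond!r} vs itself")
            for grp in (cond, ref):
                if grp in seen:
                    continue
                n = len(counts.samples_for(grp))
                if n < self.min_group_size:
                    raise RnaseqError(
                        f"group {grp!r} has {n} samples; "
                        f">= {self.min_group_size} required"
                    )
                seen.add(grp)


def read_counts_matrix(path: str | Path, meta_path: str | Path) -> CountsMatrix:
    """Read a genes x samples count TSV plus a sample->group metadata TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise RnaseqError(f"non-numeric count in {path}") from exc
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(meta.columns):
        raise RnaseqError("metadata must have columns sample, group")
    meta = meta.set_index("sample")
    return CountsMatrix(counts=counts, sample_meta=meta)


def cpm_normalize(counts: CountsMatrix) -> pd.DataFrame:
    """Counts-per-million: each sample column scaled to sum to 1e6."""
    colsums = counts.counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise RnaseqError(f"all-zero sample columns: {sorted(zero.index)}")
    return counts.counts * 1e6 / colsums


def subset_gpcrs(
    cpm: pd.DataFrame, manifest: PanelManifest
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict a CPM matrix to the receptor panel (case-insensitive).

    Returns the subset — with a zero row for every panel gene absent from
    the matrix — and the list of those absent genes.
    """
    by_fold = {}
    for g in cpm.index:
        by_fold.setdefault(str(g).casefold(), g)
    rows, missing = [], []
    index = []
    for sym in manifest.gpcr_symbols:
        src = by_fold.get(sym.casefold())
        if src is None:
            missing.append(sym)
            rows.append(np.zeros(cpm.shape[1]))
        else:
            rows.append(cpm.loc[src].to_numpy(dtype=float))
        index.append(sym)
    if missing:
        log.info("%d panel genes absent from matrix (zero-filled): %s",
                 len(missing), missing[:10])
    sub = pd.DataFrame(rows, index=index, columns=cpm.columns)
    return sub, missing


def classify_rnaseq(
    cpm: pd.DataFrame,
    manifest: PanelManifest,
    scheme: ClassificationScheme = ClassificationScheme(),
    samples: Sequence[str] | None = None,
) -> ExpressionProfile:
    """Stratify panel genes by CPM relative to the housekeeping mean.

    r(gene) = 100 * mean-CPM(gene) / mean over housekeeping genes of
    their mean CPM, computed over ``samples`` (default: all columns).
    """
    if samples is not None:
        cpm = cpm[list(samples)]
    by_fold = {str(g).casefold(): g for g in cpm.index}
    hk = [by_fold[s.casefold()] for s in manifest.housekeeping_symbols
          if s.casefold() in by_fold]
    if not hk:
        raise RnaseqError("no housekeeping genes present in CPM matrix")
    hk_mean = float(cpm.loc[hk].mean(axis=1).mean())
    if hk_mean <= 0:
        raise RnaseqError("housekeeping mean CPM is zero")
    panel, _ = subset_gpcrs(cpm, manifest)
    r = 100.0 * panel.mean(axis=1) / hk_mean
    classes = pd.Series(
        np.select(
            [r >= scheme.expressed_threshold, r >= scheme.trace_threshold],
            [CLASSES[0], CLASSES[1]],
            default=CLASSES[2],
        ),
        index=panel.index,
    )
    table = pd.DataFrame(
        {
            "relative_expression_pct": r,
            "expression_class": classes,
            "n_replicates": panel.shape[1],
        }
    )
    return ExpressionProfile(condition="all" if samples is None else "subset",
                             table=table, replicate_values=panel)


def contrast_groups(
    cpm: pd.DataFrame,
    counts_meta: pd.DataFrame,
    design: GroupDesign,
    rule: _stats.SignificanceRule = _stats.FDR_05,
    pseudocount: float = 1.0,
) -> dict[tuple[str, str], pd.DataFrame]:
    """One contrast table per (condition, reference) pair.

    Tests run on per-sample log2(CPM+1); fold changes are log2 ratios of
    linear mean CPM with the same pseudocount; BH adjustment is applied
    within each contrast over the genes of the matrix.
    """
    groups = {
        grp: [s for s in cpm.columns
              if s in counts_meta.index and counts_meta.loc[s, "group"] == grp]
        for grp in dict.fromkeys(counts_meta["group"])
    }
    results: dict[tuple[str, str], pd.DataFrame] = {}
    log_cpm = np.log2(cpm + pseudocount)
    for cond, ref in design.contrasts:
        for grp in (cond, ref):
            if len(groups.get(grp, [])) < design.min_group_size:
                raise RnaseqError(
                    f"group {grp!r} has fewer than {design.min_group_size} samples"
                )
        sc, sr = groups[cond], groups[ref]
        fc = _stats.log_cpm_fc(
            cpm[sc].mean(axis=1).to_numpy(),
            cpm[sr].mean(axis=1).to_numpy(),
            pseudocount,
        )
        pvals, degen = [], []
        a_mat = log_cpm[sc].to_numpy()
        b_mat = log_cpm[sr].to_numpy()
        for i in range(cpm.shape[0]):
            res = _stats.gene_wise_ttest(a_mat[i], b_mat[i])
            pvals.append(res.p)
            degen.append(res.degenerate)
        results[(cond, ref)] = _stats.build_contrast(
            list(cpm.index), fc, pvals, rule, degenerate=degen
        )
    return results
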