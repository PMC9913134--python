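"""TaqMan-array quantification relative to a housekeeping reference.

A gene's relative expression in a sample is

    r = 100 * 2**(-(Ct_gene - Ct_ref))        [% of housekeeping mean]

where ``Ct_ref`` is the arithmetic mean cycle threshold of the detected
housekeeping genes in that sample (arithmetic mean on the Ct scale, i.e.
geometric mean in linear expression space) and amplification efficiency
is taken as perfect doubling. Relative expression is averaged over
replicate samples of a condition on the linear scale and then stratified:

* ``Expressed``  r >= 0.1 % of the housekeeping mean
* ``Trace``      0.01 % <= r < 0.1 %
* ``Absent``     r < 0.01 %, or the gene was undetermined in every replicate

With a housekeeping mean Ct near 20 these percentage cutoffs land at
whole-cycle thresholds of Ct 30 and Ct 33.

Undetermined wells are held at the instrument ceiling (Ct 40) so every
well yields a finite value; the undetermined mask is kept alongside so
all-undetermined genes can be forced to ``Absent`` regardless of the
sentinel arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import PanelManifest

__all__ = [
    "CT_SENTINEL",
    "UNDETERMINED",
    "CLASSES",
    "QpcrError",
    "CtMatrix",
    "HousekeepingReference",
    "ClassificationScheme",
    "ExpressionProfile",
    "read_ct_table",
    "housekeeping_reference",
    "relative_expression",
    "classify_expression",
    "ct_class_boundaries",
    "profile_condition",
    "summarize_categories",
    "write_profile",
]

log = logging.getLogger(__name__)

#: Instrument ceiling; undetermined wells are held at this Ct.
CT_SENTINEL = 40.0
#: Literal accepted in Ct tables for wells that never crossed threshold.
UNDETERMINED = "Undetermined"
#: Stratification labels, from high to low expression.
CLASSES = ("Expressed", "Trace", "Absent")

#: Minimum housekeeping genes that must be detected for a usable sample.
MIN_HOUSEKEEPING_DETECTED = 8


class QpcrError(ValueError):
    """Raised on malformed Ct input or an unusable sample."""


@dataclass
class CtMatrix:
    """Gene x sample cycle-threshold values with an undetermined mask.

    ``values`` and ``undetermined`` share index (gene) and columns
    (sample); ``sample_meta`` is indexed by sample with at least a
    ``condition`` column.
    """

    values: pd.DataFrame
    undetermined: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.undetermined.index) or not (
            self.values.columns.equals(self.undetermined.columns)
        ):
            raise QpcrError("values and undetermined mask must be aligned")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise QpcrError(f"samples missing from metadata: {sorted(missing)}")
        det = self.values.to_numpy()[~self.undetermined.to_numpy()]
        if det.size and (np.any(det <= 0) or np.any(det > CT_SENTINEL)):
            raise QpcrError(f"determined Ct values must lie in (0, {CT_SENTINEL}]")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        mask = self.sample_meta["condition"] == condition
        return [s for s in self.values.columns if s in self.sample_meta.index[mask]]


@dataclass
class HousekeepingReference:
    """Per-sample reference Ct: mean over detected housekeeping genes."""

    reference_ct: pd.Series
    n_used: pd.Series


@dataclass(frozen=True)
class ClassificationScheme:
    """Percentage-of-housekeeping thresholds for the three strata.

    Boundaries are inclusive upward: r exactly at a threshold joins the
    higher class.
    """

    expressed_threshold: float = 0.1
    trace_threshold: float = 0.01

    def __post_init__(self) -> None:
        if not self.expressed_threshold > self.trace_threshold > 0:
            raise QpcrError("thresholds must satisfy expressed > trace > 0")


@dataclass
class ExpressionProfile:
    """Per-gene relative expression and class for one condition.

    ``table`` is indexed by gene with columns ``relative_expression_pct``,
    ``expression_class`` and ``n_replicates``; ``replicate_values`` keeps
    the per-sample r values the mean was taken over.
    """

    condition: str
    table: pd.DataFrame
    replicate_values: pd.DataFrame = field(repr=False, default=None)

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def class_of(self, gene: str) -> str:
        return self.table.loc[gene, "expression_class"]

    def r_of(self, gene: str) -> float:
        return float(self.table.loc[gene, "relative_expression_pct"])


def _parse_ct(raw: object, row_no: int) -> tuple[float, bool]:
    """Return (ct, undetermined) for one well; validate range."""
    if isinstance(raw, str) and raw.strip().casefold() == UNDETERMINED.casefold():
        return CT_SENTINEL, True
    try:
        ct = float(raw)
    except (TypeError, ValueError) as exc:
        raise QpcrError(f"row {row_no}: unreadable Ct value {raw!r}") from exc
    if math.isnan(ct):
        return CT_SENTINEL, True
    if not 0 < ct <= CT_SENTINEL:
        raise QpcrError(
            f"row {row_no}: Ct {ct} outside (0, {CT_SENTINEL}]"
        )
    return ct, False


def read_ct_table(
    path: str | Path,
    manifest: PanelManifest,
    meta_path: str | Path | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> CtMatrix:
    """Read a long-form Ct table (columns ``sample,gene,Ct``) into a matrix.

    Genes not on the manifest (receptors or housekeeping) are logged and
    dropped; manifest genes never assayed appear as undetermined rows.
    Sample metadata may come from a TSV (``sample<TAB>condition<TAB>replicate``)
    or be passed directly; without either, every sample is assigned the
    condition ``"all"``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample", "gene", "Ct"}
    if not required.issubset(df.columns):
        raise QpcrError(f"Ct table must have columns {sorted(required)}")

    dup = df.duplicated(subset=["sample", "gene"])
    if dup.any():
        first = df[dup].iloc[0]
        raise QpcrError(
            f"duplicate well for sample {first['sample']!r}, gene {first['gene']!r}"
        )

    keep_rows = []
    dropped: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = manifest.lookup(row.gene)
        if rec is None:
            dropped.add(row.gene)
            continue
        ct, undet = _parse_ct(row.Ct, row_no)
        keep_rows.append((rec.symbol, row.sample, ct, undet))
    if dropped:
        log.info("dropped %d genes absent from manifest: %s",
                 len(dropped), sorted(dropped))
    if not keep_rows:
        raise QpcrError("no manifest genes found in Ct table")

    long = pd.DataFrame(keep_rows, columns=["gene", "sample", "ct", "undet"])
    samples = list(dict.fromkeys(long["sample"]))
    genes = [
        s for s in manifest.gpcr_symbols + manifest.housekeeping_symbols
    ]
    values = long.pivot(index="gene", columns="sample", values="ct")
    values = values.reindex(index=genes, columns=samples)
    undet = long.pivot(index="gene", columns="sample", values="undet")
    undet = undet.reindex(index=genes, columns=samples)
    # wells never assayed count as undetermined at the sentinel
    undet = undet.where(values.notna(), True).astype(bool)
    values = values.fillna(CT_SENTINEL).astype(float)

    if sample_meta is None:
        if meta_path is not None:
            sample_meta = pd.read_csv(meta_path, sep="\t", dtype=str)
            if "sample" not in sample_meta.columns or "condition" not in sample_meta.columns:
                raise QpcrError("metadata must have columns sample, condition")
            sample_meta = sample_meta.set_index("sample")
        else:
            sample_meta = pd.DataFrame({"condition": "all"}, index=samples)
    return CtMatrix(values=values, undetermined=undet, sample_meta=sample_meta)


def housekeeping_reference(
    ct: CtMatrix,
    housekeeping: Sequence[str],
    min_detected: int = MIN_HOUSEKEEPING_DETECTED,
) -> HousekeepingReference:
    """Per-sample arithmetic mean Ct over detected housekeeping genes.

    A sample with fewer than ``min_detected`` detected housekeeping genes
    cannot be anchored and is rejected.
    """
    hk = [g for g in housekeeping if g in ct.values.index]
    if not hk:
        raise QpcrError("no housekeeping genes present in Ct matrix")
    vals = ct.values.loc[hk]
    detected = ~ct.undetermined.loc[hk]
    n_used = detected.sum(axis=0)
    bad = n_used[n_used < min_detected]
    if len(bad):
        raise QpcrError(
            f"samples with < {min_detected} detected housekeeping genes: "
            f"{sorted(bad.index)}"
        )
    ref = vals.where(detected).mean(axis=0)
    return HousekeepingReference(reference_ct=ref, n_used=n_used)


def relative_expression(ct_gene, reference_ct):
    """Expression as a percentage of the housekeeping mean: 100 * 2**(-dCt).

    Accepts scalars or aligned arrays/Series; strictly decreasing in
    ``ct_gene`` and invariant to a shift applied to both arguments.
    """
    delta = np.asanyarray(ct_gene, dtype=float) - np.asanyarray(
        reference_ct, dtype=float
    )
    out = 100.0 * np.exp2(-delta)
    if out.ndim == 0:
        return float(out)
    return out


def classify_expression(r, scheme: ClassificationScheme = ClassificationScheme()):
    """Stratify relative expression into Expressed / Trace / Absent."""
    arr = np.asanyarray(r, dtype=float)
    if np.any(arr < 0):
        raise QpcrError("relative expression must be non-negative")
    out = np.select(
        [arr >= scheme.expressed_threshold, arr >= scheme.trace_threshold],
        [CLASSES[0], CLASSES[1]],
        default=CLASSES[2],
    )
    if arr.ndim == 0:
        return str(out)
    return out


def ct_class_boundaries(
    reference_ct: float, scheme: ClassificationScheme = ClassificationScheme()
) -> tuple[float, float]:
    """Ct values at which the class boundaries fall for a given reference.

    Solving 100 * 2**(-(ct - ref)) = threshold gives
    ct = ref + log2(100 / threshold); with a reference Ct of 20 the
    default thresholds land at Ct ~= 30 (Expressed/Trace) and ~= 33
    (Trace/Absent).
    """
    ct_expressed = reference_ct + math.log2(100.0 / scheme.expressed_threshold)
    ct_trace = reference_ct + math.log2(100.0 / scheme.trace_threshold)
    return ct_expressed, ct_trace


def profile_condition(
    ct: CtMatrix,
    condition: str,
    housekeeping: Sequence[str],
    scheme: ClassificationScheme = ClassificationScheme(),
    genes: Iterable[str] | None = None,
) -> ExpressionProfile:
    """Average replicate-level relative expression and classify.

    r is computed per replicate sample, averaged on the linear scale, and
    the class assigned to the mean. Genes undetermined in every replicate
    are reported ``Absent`` whatever the sentinel arithmetic gives.
    """
    samples = ct.samples_for(condition)
    if not samples:
        raise QpcrError(f"condition {condition!r} not present in sample metadata")
    ref = housekeeping_reference(ct, housekeeping)
    if genes is None:
        gene_index = ct.values.index.difference(pd.Index(housekeeping), sort=False)
    else:
        gene_index = pd.Index([g for g in genes if g in ct.values.index])
    sub = ct.values.loc[gene_index, samples]
    rep_r = pd.DataFrame(
        relative_expression(sub.to_numpy(), ref.reference_ct[samples].to_numpy()),
        index=gene_index,
        columns=samples,
    )
    mean_r = rep_r.mean(axis=1)
    classes = pd.Series(
        classify_expression(mean_r.to_numpy(), scheme), index=gene_index
    )
    never_detected = ct.undetermined.loc[gene_index, samples].all(axis=1)
    classes[never_detected] = CLASSES[2]
    table = pd.DataFrame(
        {
            "relative_expression_pct": mean_r,
            "expression_class": classes,
            "n_replicates": len(samples),
        }
    )
    return ExpressionProfile(condition=condition, table=table, replicate_values=rep_r)


def summarize_categories(
    profile: ExpressionProfile, manifest: PanelManifest
) -> dict[str, int]:
    """Counts of Expressed / Trace / Absent over the whole receptor panel.

    Panel genes missing from the profile (never assayed) count as Absent,
    so the three counts always sum to ``manifest.panel_size``.
    """
    counts = dict.fromkeys(CLASSES, 0)
    for gene in manifest.gpcr_symbols:
        if gene in profile.table.index:
            counts[profile.class_of(gene)] += 1
        else:
            counts[CLASSES[2]] += 1
    return counts


def condition_contrast(
    ct: CtMatrix,
    condition: str,
    reference: str,
    housekeeping: Sequence[str],
    rule=None,
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene dCt contrast between two conditions with replicate t-tests.

    The log2 fold change is the difference of mean dCt (reference minus
    condition; one cycle = one doubling) and the p-value a two-tailed
    pooled-variance t-test over replicate dCt values. Genes undetected in
    a replicate enter with the sentinel dCt, which bounds their fold
    change; degenerate-variance genes are flagged, not dropped.
    """
    from . import stats as _stats

    if rule is None:
        rule = _stats.RAW_P_VOLCANO
    samples_c = ct.samples_for(condition)
    samples_r = ct.samples_for(reference)
    for label, smp in ((condition, samples_c), (reference, samples_r)):
        if len(smp) < 2:
            raise QpcrError(
                f"condition {label!r} needs >= 2 replicates for a t-test"
            )
    ref = housekeeping_reference(ct, housekeeping)
    if genes is None:
        gene_index = ct.values.index.difference(pd.Index(housekeeping), sort=False)
    else:
        gene_index = pd.Index([g for g in genes if g in ct.values.index])
    dct = ct.values.loc[gene_index] - ref.reference_ct
    rows_fc, rows_p, rows_deg = [], [], []
    for gene in gene_index:
        a = dct.loc[gene, samples_c].to_numpy(dtype=float)
        b = dct.loc[gene, samples_r].to_numpy(dtype=float)
        res = _stats.gene_wise_ttest(a, b)
        rows_fc.append(_stats.delta_delta_ct_logfc(a.mean(), b.mean()))
        rows_p.append(res.p)
        rows_deg.append(res.degenerate)
    return _stats.build_contrast(
        list(gene_index), rows_fc, rows_p, rule, degenerate=rows_deg
    )


def write_profile(profile: ExpressionProfile, path: str | Path) -> None:
    """Write a per-condition profile as TSV."""
    out = profile.table.reset_index(names="gene")
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
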