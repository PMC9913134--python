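"""Synthetic Ct tables and count matrices with known ground truth.

The qPCR generator plants an expression class per receptor gene and
draws its Ct inside the corresponding band (relative to a housekeeping
mean of Ct 20, the expressed/trace boundaries fall near Ct 30 and 33),
keeping a two-sigma margin from class boundaries so that replicate noise
(normal on the Ct scale, default sigma 0.2 cycles — typical TaqMan
replicate variation) rarely flips a class. Genes planted Absent are
emitted as undetermined wells with probability one half, otherwise with
a Ct beyond the absent boundary.

The RNA-seq generator draws negative-binomial counts with variance
mu + phi * mu**2 and multiplies the mean by 2**log2_fc for planted genes
in non-reference groups; housekeeping genes get high, stable means so
the CPM-relative stratification has a realistic anchor.

Both generators are deterministic given a seed and return the truth
alongside the data so recovery can be scored end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import PanelManifest
from .qpcr import (
    CLASSES,
    CT_SENTINEL,
    ClassificationScheme,
    CtMatrix,
    ct_class_boundaries,
)
from .rnaseq import CountsMatrix

__all__ = [
    "SimulationError",
    "SyntheticTruth",
    "generate_ct_experiment",
    "generate_counts_experiment",
    "truth_report",
    "write_ct_table",
    "write_counts_experiment",
]

DEFAULT_CLASS_PROPORTIONS = {"Expressed": 0.6, "Trace": 0.15, "Absent": 0.25}
#: Probability an Absent gene is emitted as an undetermined well.
P_UNDETERMINED = 0.5
#: Margin (in multiples of sigma) kept between a planted mean Ct and the
#: nearest class boundary.
BAND_MARGIN_SIGMAS = 2.0
#: Dynamic-range floor for Expressed genes (cycles below the reference).
EXPRESSED_CT_SPAN = 8.0


class SimulationError(ValueError):
    """Raised on invalid generator parameters."""


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic experiment."""

    kind: str
    seed: int
    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def generate_ct_experiment(
    manifest: PanelManifest,
    class_proportions: Mapping[str, float] | None = None,
    hk_mean_ct: float = 20.0,
    sigma: float = 0.2,
    n_replicates: int = 2,
    seed: int = 0,
    condition: str = "A",
    scheme: ClassificationScheme = ClassificationScheme(),
) -> tuple[CtMatrix, SyntheticTruth]:
    """Simulate one condition of a TaqMan array run.

    Each receptor gene is assigned a class by ``class_proportions``
    (default 60/15/25 % Expressed/Trace/Absent, the rough split seen in
    adipose depots), given a mean Ct uniform inside its class band, and
    observed ``n_replicates`` times with N(0, sigma) cycle noise.
    Housekeeping genes are drawn near ``hk_mean_ct`` with the same noise.
    """
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    if set(props) != set(CLASSES):
        raise SimulationError(f"class_proportions must have keys {CLASSES}")
    total = sum(props.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9) or any(
        v < 0 for v in props.values()
    ):
        raise SimulationError("class proportions must be non-negative and sum to 1")
    if sigma < 0:
        raise SimulationError("sigma must be >= 0")
    if n_replicates < 1:
        raise SimulationError("n_replicates must be >= 1")

    rng = np.random.default_rng(seed)
    genes = manifest.gpcr_symbols
    hk = manifest.housekeeping_symbols
    ct_expressed, ct_trace = ct_class_boundaries(hk_mean_ct, scheme)
    margin = BAND_MARGIN_SIGMAS * sigma
    bands = {
        "Expressed": (ct_expressed - EXPRESSED_CT_SPAN, ct_expressed - margin),
        "Trace": (ct_expressed + margin, ct_trace - margin),
        "Absent": (ct_trace + margin, CT_SENTINEL - margin),
    }
    for cls, (lo, hi) in bands.items():
        if lo >= hi:
            raise SimulationError(
                f"sigma {sigma} leaves no room inside the {cls} band"
            )

    planted = rng.choice(
        CLASSES, size=len(genes), p=[props[c] for c in CLASSES]
    )
    mean_ct = np.empty(len(genes))
    for cls in CLASSES:
        idx = planted == cls
        lo, hi = bands[cls]
        mean_ct[idx] = rng.uniform(lo, hi, size=idx.sum())
    undet_gene = (planted == "Absent") & (
        rng.uniform(size=len(genes)) < P_UNDETERMINED
    )

    samples = [f"{condition}_r{i + 1}" for i in range(n_replicates)]
    values = np.empty((len(genes) + len(hk), n_replicates))
    undet = np.zeros_like(values, dtype=bool)
    noise = rng.normal(0.0, sigma, size=(len(genes), n_replicates))
    values[: len(genes)] = np.clip(
        mean_ct[:, None] + noise, 1e-3, CT_SENTINEL
    )
    values[: len(genes)][undet_gene] = CT_SENTINEL
    undet[: len(genes)][undet_gene] = True
    hk_noise = rng.normal(0.0, sigma, size=(len(hk), n_replicates))
    values[len(genes):] = np.clip(hk_mean_ct + hk_noise, 1e-3, CT_SENTINEL)

    index = pd.Index(list(genes) + list(hk), name="gene")
    ct = CtMatrix(
        values=pd.DataFrame(values, index=index, columns=samples),
        undetermined=pd.DataFrame(undet, index=index, columns=samples),
        sample_meta=pd.DataFrame(
            {
                "condition": condition,
                "replicate": [str(i + 1) for i in range(n_replicates)],
            },
            index=pd.Index(samples, name="sample"),
        ),
    )
    truth = SyntheticTruth(
        kind="qpcr",
        seed=seed,
        table=pd.DataFrame(
            {
                "gene": genes,
                "condition": condition,
                "planted_class": planted,
                "mean_ct": mean_ct,
                "all_undetermined": undet_gene,
            }
        ),
        params={
            "hk_mean_ct": hk_mean_ct,
            "sigma": sigma,
            "n_replicates": n_replicates,
            "class_proportions": props,
            "condition": condition,
        },
    )
    return ct, truth


def _nb_draw(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion: var = mu + phi mu^2."""
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_counts_experiment(
    manifest: PanelManifest,
    group_sizes: Mapping[str, int] | None = None,
    baseline_mu: float = 100.0,
    dispersion: float = 0.05,
    planted_fc_table: Mapping[str, float | Mapping[str, float]] | None = None,
    hk_mu: float = 20000.0,
    hk_dispersion: float = 0.005,
    seed: int = 0,
) -> tuple[CountsMatrix, SyntheticTruth]:
    """Simulate a gene x sample count matrix with planted fold changes.

    The first key of ``group_sizes`` is the reference group. A planted
    value may be a single log2 fold change (applied to every
    non-reference group) or a per-group mapping. Housekeeping genes get
    a high mean ``hk_mu`` in every group with their own small dispersion
    ``hk_dispersion`` — they are stable by definition, and they dominate
    the library total, so giving them receptor-level dispersion would
    let library-size noise leak into every CPM.
    """
    groups = dict(group_sizes or {"control": 10, "treated": 10})
    if len(groups) < 2:
        raise SimulationError("need at least two groups")
    if any(n < 2 for n in groups.values()):
        raise SimulationError("each group needs >= 2 samples")
    if dispersion <= 0 or hk_dispersion <= 0:
        raise SimulationError("dispersion must be > 0")
    planted = dict(planted_fc_table or {})
    genes = manifest.gpcr_symbols
    hk = manifest.housekeeping_symbols
    known = {g.casefold() for g in genes}
    for g in planted:
        if g.casefold() not in known:
            raise SimulationError(f"planted fold change for unknown gene {g!r}")

    group_names = list(groups)
    reference = group_names[0]
    rng = np.random.default_rng(seed)

    def fc_of(gene: str, group: str) -> float:
        if group == reference:
            return 0.0
        val = planted.get(gene, 0.0)
        if isinstance(val, Mapping):
            return float(val.get(group, 0.0))
        return float(val)

    samples, labels = [], []
    for grp, n in groups.items():
        samples += [f"{grp}_s{i + 1}" for i in range(n)]
        labels += [grp] * n
    all_genes = list(genes) + list(hk)
    counts = np.empty((len(all_genes), len(samples)), dtype=np.int64)
    truth_rows = []
    col = 0
    for grp, n in groups.items():
        mu = np.array([baseline_mu * 2.0 ** fc_of(g, grp) for g in genes])
        counts[: len(genes), col: col + n] = _nb_draw(
            rng, np.repeat(mu[:, None], n, axis=1), dispersion
        )
        counts[len(genes):, col: col + n] = _nb_draw(
            rng, np.full((len(hk), n), hk_mu), hk_dispersion
        )
        col += n
    for g in genes:
        truth_rows.append(
            {
                "gene": g,
                "baseline_mu": baseline_mu,
                **{
                    f"log2_fc_{grp}": fc_of(g, grp)
                    for grp in group_names[1:]
                },
            }
        )
    matrix = CountsMatrix(
        counts=pd.DataFrame(
            counts, index=pd.Index(all_genes, name="gene"), columns=samples
        ),
        sample_meta=pd.DataFrame(
            {"group": labels}, index=pd.Index(samples, name="sample")
        ),
    )
    truth = SyntheticTruth(
        kind="rnaseq",
        seed=seed,
        table=pd.DataFrame(truth_rows),
        params={
            "group_sizes": groups,
            "baseline_mu": baseline_mu,
            "dispersion": dispersion,
            "hk_mu": hk_mu,
            "reference": reference,
        },
    )
    return matrix, truth


def truth_report(truth: SyntheticTruth, results) -> dict:
    """Score pipeline output against planted truth.

    For qPCR truth, ``results`` is an ExpressionProfile; the report gives
    overall and per-class recovery accuracy. For RNA-seq truth,
    ``results`` is a contrast DataFrame for one non-reference group vs
    the reference; the report gives fold-change bias and RMSE over
    planted genes plus sensitivity (planted genes flagged significant)
    and specificity (null genes not flagged).
    """
    if truth.kind == "qpcr":
        profile = results
        t = truth.table.set_index("gene")
        missing = t.index.difference(profile.table.index)
        if len(missing):
            raise SimulationError(f"results lack genes: {list(missing)[:5]}")
        pred = profile.table.loc[t.index, "expression_class"]
        correct = pred == t["planted_class"]
        report = {
            "n_genes": int(len(t)),
            "accuracy": float(correct.mean()),
        }
        for cls in CLASSES:
            mask = t["planted_class"] == cls
            if mask.any():
                report[f"accuracy_{cls}"] = float(correct[mask].mean())
        return report
    if truth.kind == "rnaseq":
        contrast = results.set_index("gene")
        t = truth.table.set_index("gene")
        fc_cols = [c for c in t.columns if c.startswith("log2_fc_")]
        if len(fc_cols) != 1:
            raise SimulationError(
                "truth_report needs a single-contrast truth table; "
                f"found columns {fc_cols}"
            )
        missing = t.index.difference(contrast.index)
        if len(missing):
            raise SimulationError(f"results lack genes: {list(missing)[:5]}")
        planted_fc = t[fc_cols[0]]
        est = contrast.loc[t.index, "log2_fc"]
        sig = contrast.loc[t.index, "significant"].astype(bool)
        is_de = planted_fc != 0
        err = est - planted_fc
        report = {
            "n_genes": int(len(t)),
            "n_planted": int(is_de.sum()),
            "fc_bias": float(err[is_de].mean()) if is_de.any() else 0.0,
            "fc_rmse": float(np.sqrt((err[is_de] ** 2).mean()))
            if is_de.any() else 0.0,
            "sensitivity": float(sig[is_de].mean()) if is_de.any() else float("nan"),
            "specificity": float((~sig[~is_de]).mean())
            if (~is_de).any() else float("nan"),
            "direction_recovery": float(
                (np.sign(est[is_de]) == np.sign(planted_fc[is_de])).mean()
            ) if is_de.any() else float("nan"),
        }
        return report
    raise SimulationError(f"unknown truth kind {truth.kind!r}")


def concat_ct(matrices: Sequence[CtMatrix]) -> CtMatrix:
    """Column-concatenate per-condition Ct matrices over one gene universe."""
    first = matrices[0].values.index
    for m in matrices[1:]:
        if not first.equals(m.values.index):
            raise SimulationError("Ct matrices cover different gene sets")
    return CtMatrix(
        values=pd.concat([m.values for m in matrices], axis=1),
        undetermined=pd.concat([m.undetermined for m in matrices], axis=1),
        sample_meta=pd.concat([m.sample_meta for m in matrices], axis=0),
    )


def write_ct_table(ct: CtMatrix, path: str | Path, meta_path: str | Path) -> None:
    """Write a CtMatrix in the long CSV dialect the reader consumes."""
    rows = []
    for gene in ct.values.index:
        for sample in ct.values.columns:
            if bool(ct.undetermined.loc[gene, sample]):
                rows.append((sample, gene, "Undetermined"))
            else:
                rows.append((sample, gene, f"{ct.values.loc[gene, sample]:.4f}"))
    pd.DataFrame(rows, columns=["sample", "gene", "Ct"]).to_csv(path, index=False)
    ct.sample_meta.reset_index().to_csv(meta_path, sep="\t", index=False)


def write_counts_experiment(
    matrix: CountsMatrix, path: str | Path, meta_path: str | Path
) -> None:
    """Write counts and metadata in the TSV dialects the reader consumes."""
    matrix.counts.to_csv(path, sep="\t")
    matrix.sample_meta.reset_index().to_csv(meta_path, sep="\t", index=False)
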