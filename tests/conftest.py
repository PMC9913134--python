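import pandas as pd
import pytest

from adipogpcr.panel import GeneRecord, PanelManifest, bundled_manifest

HK_MOUSE = ["Actb", "B2m", "Gapdh", "Gusb", "Hmbs", "Hprt1", "Ipo8", "Pgk1",
            "Polr2a", "Ppia", "Rplp2", "Tbp", "Tfrc", "Ubc", "Ywhaz"]

TOY_GPCRS = ["Adora1", "Ffar3", "Fzd4", "Gprc5b", "Lpar1"]


@pytest.fixture(scope="session")
def mouse_manifest():
    return bundled_manifest("mouse")


@pytest.fixture(scope="session")
def human_manifest():
    return bundled_manifest("human")


@pytest.fixture()
def toy_manifest():
    """A 5-receptor manifest with the full housekeeping set."""
    records = [
        GeneRecord(symbol=g, species="mouse", role="gpcr",
                   ortholog_symbol=g.upper())
        for g in TOY_GPCRS
    ] + [
        GeneRecord(symbol=g, species="mouse", role="housekeeping",
                   ortholog_symbol=g.upper())
        for g in HK_MOUSE
    ]
    return PanelManifest(records=records, species="mouse")


def make_ct_matrix(gene_ct: dict, hk_ct: float = 20.0, conditions=("A",),
                   n_replicates: int = 1, undetermined: set | None = None):
    """Build a CtMatrix by hand: constant Ct per gene across replicates."""
    from adipogpcr.qpcr import CtMatrix

    undetermined = undetermined or set()
    samples, cond_labels = [], []
    for cond in conditions:
        for i in range(n_replicates):
            samples.append(f"{cond}_r{i + 1}")
            cond_labels.append(cond)
    genes = list(gene_ct) + HK_MOUSE
    values = pd.DataFrame(
        [[gene_ct[g]] * len(samples) for g in gene_ct]
        + [[hk_ct] * len(samples) for _ in HK_MOUSE],
        index=genes, columns=samples, dtype=float,
    )
    undet = pd.DataFrame(
        [[g in undetermined] * len(samples) for g in genes],
        index=genes, columns=samples,
    )
    meta = pd.DataFrame(
        {"condition": cond_labels,
         "replicate": [s.split("_r")[-1] for s in samples]},
        index=pd.Index(samples, name="sample"),
    )
    return CtMatrix(values=values, undetermined=undet, sample_meta=meta)
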