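"""Gene panel resources: the non-visual GPCR panel and housekeeping set.

Every downstream stage subsets against a :class:`PanelManifest`, which
pairs the receptor panel of one species (352 genes in mouse, 356 in
human) with the 15-gene housekeeping set used as the quantification
reference. Manifests are plain TSV resource files, so the bundled panels
can be swapped for a different gene universe without touching pipeline
code.

Mouse and human symbols follow the usual case conventions (mouse
title-case, human upper-case); ortholog links are stored explicitly in
the manifest so that exceptions (e.g. mouse ``Agtr1a`` <-> human
``AGTR1``) and species-specific genes are handled without guesswork.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "GeneRecord",
    "PanelManifest",
    "OrthologMap",
    "PanelError",
    "load_panel",
    "bundled_manifest",
    "housekeeping_set",
    "map_orthologs",
    "HOUSEKEEPING_COUNT",
]

#: Number of reference genes the quantification scheme expects.
HOUSEKEEPING_COUNT = 15

_SPECIES = ("mouse", "human")
_ROLES = ("gpcr", "housekeeping")
_REQUIRED_COLUMNS = ("symbol", "species", "role")


class PanelError(ValueError):
    """Raised when a manifest violates a panel invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene in a panel manifest."""

    symbol: str
    species: str
    role: str
    family: str = ""
    ortholog_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PanelError("gene symbol must be non-empty")
        if self.species not in _SPECIES:
            raise PanelError(f"unknown species {self.species!r} for {self.symbol}")
        if self.role not in _ROLES:
            raise PanelError(f"unknown role {self.role!r} for {self.symbol}")


@dataclass
class PanelManifest:
    """A validated gene universe for one species.

    Attributes
    ----------
    records
        All :class:`GeneRecord` entries (receptors and housekeeping genes).
    species
        ``"mouse"`` or ``"human"``.
    """

    records: list[GeneRecord]
    species: str
    _by_symbol: dict[str, GeneRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rec in self.records:
            if rec.species != self.species:
                raise PanelError(
                    f"record {rec.symbol!r} has species {rec.species!r}, "
                    f"manifest is {self.species!r}"
                )
            key = rec.symbol.casefold()
            if key in seen:
                raise PanelError(f"duplicate symbol in manifest: {rec.symbol!r}")
            seen[key] = rec.symbol
        n_hk = len(self.housekeeping_symbols)
        if n_hk != HOUSEKEEPING_COUNT:
            raise PanelError(
                f"manifest must list exactly {HOUSEKEEPING_COUNT} housekeeping "
                f"genes, found {n_hk}"
            )
        self._by_symbol = {r.symbol.casefold(): r for r in self.records}

    @property
    def gpcr_symbols(self) -> list[str]:
        return [r.symbol for r in self.records if r.role == "gpcr"]

    @property
    def housekeeping_symbols(self) -> list[str]:
        return sorted(r.symbol for r in self.records if r.role == "housekeeping")

    @property
    def panel_size(self) -> int:
        """Number of receptor (non-housekeeping) genes on the panel."""
        return len(self.gpcr_symbols)

    def lookup(self, symbol: str) -> GeneRecord | None:
        """Case-insensitive record lookup."""
        return self._by_symbol.get(symbol.casefold())

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self._by_symbol


@dataclass
class OrthologMap:
    """Result of a cross-species symbol mapping."""

    mapping: dict[str, str]
    unmapped: list[str]


def load_panel(path: str | Path, species: str) -> PanelManifest:
    """Read and validate a panel manifest TSV.

    The file must carry at least the columns ``symbol``, ``species`` and
    ``role``; ``family`` and ``ortholog_symbol`` are optional.
    """
    if species not in _SPECIES:
        raise PanelError(f"unknown species {species!r}")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"manifest {path} lacks columns {missing}")
    records = [
        GeneRecord(
            symbol=row["symbol"],
            species=row["species"],
            role=row["role"],
            family=row.get("family", ""),
            ortholog_symbol=row.get("ortholog_symbol", ""),
        )
        for row in df.to_dict("records")
    ]
    return PanelManifest(records=records, species=species)


def bundled_manifest(species: str) -> PanelManifest:
    """Load the panel manifest shipped with the package."""
    if species not in _SPECIES:
        raise PanelError(f"unknown species {species!r}")
    ref = resources.files("adipogpcr.data") / f"panel_{species}.tsv"
    with resources.as_file(ref) as path:
        return load_panel(path, species)


def housekeeping_set(manifest: PanelManifest) -> list[str]:
    """The 15 housekeeping symbols, alphabetically ordered."""
    return manifest.housekeeping_symbols


def map_orthologs(
    symbols: Iterable[str],
    from_species: str,
    to_species: str,
    manifest: PanelManifest,
) -> OrthologMap:
    """Map gene symbols across species using the manifest's ortholog links.

    ``manifest`` must be the manifest of ``from_species``; the link is the
    record's ``ortholog_symbol`` field. Symbols that are not on the panel,
    or whose record carries no ortholog, are returned in ``unmapped``
    rather than silently dropped.
    """
    if manifest.species != from_species:
        raise PanelError(
            f"manifest species {manifest.species!r} does not match "
            f"from_species {from_species!r}"
        )
    if to_species == from_species:
        raise PanelError("from_species and to_species must differ")
    if to_species not in _SPECIES:
        raise PanelError(f"unknown species {to_species!r}")
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for sym in symbols:
        rec = manifest.lookup(sym)
        if rec is None or not rec.ortholog_symbol:
            unmapped.append(sym)
        else:
            mapping[sym] = rec.ortholog_symbol
    return OrthologMap(mapping=mapping, unmapped=unmapped)
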