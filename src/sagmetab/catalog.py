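"""Pathway catalog: definitions of single-step and multi-step metabolic pathways.

A catalog entry describes how to decide, from a genome's KEGG-ortholog (KO)
inventory, whether the genome encodes a given metabolic potential:

* ``single_step`` pathways list one or more alternative gene sets; a set is
  satisfied when at least half of its member symbols are detected (accessory
  subunits are excluded from the count).
* ``multi_step`` pathways list diagnostic key enzymes plus an ordered list of
  reaction steps (each step is a list of alternative symbols); the pathway is
  called present only when the key enzymes are detected and the fraction of
  satisfied steps strictly exceeds the completeness threshold (default 0.5).

Catalogs are stored as YAML; a bundled fixture catalog spanning carbon,
nitrogen, sulfur and trace-gas metabolisms ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import yaml

from .errors import CatalogError

__all__ = ["PathwayDef", "PathwayCatalog", "load_catalog", "fixture_catalog"]


@dataclass(frozen=True)
class PathwayDef:
    """One catalog entry.

    Parameters
    ----------
    pathway_id:
        Unique identifier (used as the matrix column name).
    name:
        Human-readable display name.
    kind:
        ``"single_step"`` or ``"multi_step"``.
    gene_sets:
        For single-step pathways: alternative gene sets, each a tuple of
        KO symbols.  The pathway is present when any one set is satisfied.
    accessory:
        Symbols excluded from the "half or more" count of a gene set.
    key_enzymes:
        For multi-step pathways: diagnostic marker symbols.
    key_mode:
        ``"all"`` (every key enzyme required; default) or ``"any"``.
    steps:
        For multi-step pathways: ordered steps, each a tuple of alternative
        symbols.
    threshold:
        Strict lower bound on the satisfied-step fraction, in (0, 1).
    """

    pathway_id: str
    name: str = ""
    kind: str = "single_step"
    gene_sets: tuple[tuple[str, ...], ...] = ()
    accessory: tuple[str, ...] = ()
    key_enzymes: tuple[str, ...] = ()
    key_mode: str = "all"
    steps: tuple[tuple[str, ...], ...] = ()
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("single_step", "multi_step"):
            raise CatalogError(
                f"pathway {self.pathway_id!r}: unknown kind {self.kind!r}"
            )
        if self.kind == "single_step":
            if not self.gene_sets or any(len(s) == 0 for s in self.gene_sets):
                raise CatalogError(
                    f"pathway {self.pathway_id!r}: single_step requires at "
                    "least one non-empty gene set"
                )
        else:
            if not self.steps or any(len(s) == 0 for s in self.steps):
                raise CatalogError(
                    f"pathway {self.pathway_id!r}: multi_step requires at "
                    "least one non-empty step"
                )
            if not (0.0 < self.threshold < 1.0):
                raise CatalogError(
                    f"pathway {self.pathway_id!r}: threshold must lie in "
                    f"(0, 1), got {self.threshold}"
                )
            if self.key_mode not in ("all", "any"):
                raise CatalogError(
                    f"pathway {self.pathway_id!r}: key_mode must be 'all' "
                    f"or 'any', got {self.key_mode!r}"
                )

    @property
    def symbols(self) -> frozenset[str]:
        """Every symbol the definition can reference (incl. accessory)."""
        out: set[str] = set(self.accessory) | set(self.key_enzymes)
        for s in self.gene_sets:
            out.update(s)
        for s in self.steps:
            out.update(s)
        return frozenset(out)


class PathwayCatalog:
    """An ordered, id-unique collection of :class:`PathwayDef`."""

    def __init__(self, pathways: Sequence[PathwayDef]):
        seen: set[str] = set()
        for p in pathways:
            if p.pathway_id in seen:
                raise CatalogError(f"duplicate pathway id {p.pathway_id!r}")
            seen.add(p.pathway_id)
        self._pathways: tuple[PathwayDef, ...] = tuple(pathways)
        self._by_id = {p.pathway_id: p for p in self._pathways}

    def __len__(self) -> int:
        return len(self._pathways)

    def __iter__(self) -> Iterator[PathwayDef]:
        return iter(self._pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __getitem__(self, pathway_id: str) -> PathwayDef:
        try:
            return self._by_id[pathway_id]
        except KeyError:
            raise CatalogError(f"unknown pathway id {pathway_id!r}") from None

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(p.pathway_id for p in self._pathways)

    @property
    def symbols(self) -> frozenset[str]:
        """Union of all symbols referenced anywhere in the catalog."""
        out: set[str] = set()
        for p in self._pathways:
            out |= p.symbols
        return frozenset(out)


def _parse_entry(entry: dict, symbol_map: dict[str, str] | None) -> PathwayDef:
    def remap(sym: str) -> str:
        return symbol_map.get(sym, sym) if symbol_map else sym

    def remap_sets(raw) -> tuple[tuple[str, ...], ...]:
        return tuple(tuple(remap(s) for s in group) for group in (raw or ()))

    return PathwayDef(
        pathway_id=str(entry["id"]),
        name=str(entry.get("name", "")),
        kind=str(entry.get("kind", "single_step")),
        gene_sets=remap_sets(entry.get("gene_sets")),
        accessory=tuple(remap(s) for s in entry.get("accessory", ())),
        key_enzymes=tuple(remap(s) for s in entry.get("key_enzymes", ())),
        key_mode=str(entry.get("key_mode", "all")),
        steps=remap_sets(entry.get("steps")),
        threshold=float(entry.get("threshold", 0.5)),
    )


def load_catalog(
    path: str | Path,
    symbol_map: dict[str, str] | None = None,
) -> PathwayCatalog:
    """Load a pathway catalog from YAML.

    ``symbol_map`` optionally maps free-text gene symbols used in the catalog
    to KO identifiers; matching against annotations is exact on the mapped
    symbols.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _catalog_from_doc(doc, symbol_map)


def _catalog_from_doc(doc, symbol_map=None) -> PathwayCatalog:
    if not isinstance(doc, dict) or "pathways" not in doc:
        raise CatalogError("catalog YAML must contain a top-level 'pathways' list")
    entries = doc["pathways"] or []
    return PathwayCatalog([_parse_entry(e, symbol_map) for e in entries])


def fixture_catalog() -> PathwayCatalog:
    """The bundled ~16-pathway fixture catalog used in tests and examples."""
    text = resources.files("sagmetab.data").joinpath("catalog.yaml").read_text()
    return _catalog_from_doc(yaml.safe_load(text))
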