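"""Rule-based pathway presence/absence calling from KO inventories.

A genome is represented here by its KO copy-count profile (a mapping from KO
identifier to the number of annotated gene copies).  Two calling rules are
applied, mirroring the presence criteria used for SAG functional annotation:

* single-step reactions: any alternative gene set with at least half of its
  (non-accessory) member symbols detected establishes presence;
* multi-step pathways: all diagnostic key enzymes must be detected and the
  fraction of satisfied steps must strictly exceed the completeness
  threshold.

Each call carries a detection count ``d`` (the copy number of the satisfying
gene complex, taken as the minimum copy count over the symbols that establish
presence); multi-copy complexes therefore yield ``d > 1`` and can push the
completeness-corrected proportion of genomes above 100%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .catalog import PathwayCatalog, PathwayDef
from .errors import CatalogError

__all__ = ["PathwayCall", "call_single_step", "call_multi_step", "call_all", "ko_profile"]

KoProfile = Mapping[str, int]


@dataclass(frozen=True)
class PathwayCall:
    """Presence call for one genome x pathway cell.

    ``count`` is the detection count d (0 when absent); ``satisfied`` records
    provenance: indices of satisfied gene sets (single-step) or of satisfied
    steps (multi-step).
    """

    genome_id: str
    pathway_id: str
    present: bool
    count: int
    satisfied: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        assert self.present == (self.count >= 1)


def ko_profile(ko_ids: Iterable[str]) -> Counter:
    """Build a KO copy-count profile from an iterable of per-gene KO ids."""
    return Counter(k for k in ko_ids if k)


def _set_detection(profile: KoProfile, symbols: tuple[str, ...],
                   accessory: frozenset[str]) -> tuple[bool, int]:
    """Evaluate one gene set: (satisfied, min copy count among detected)."""
    members = [s for s in symbols if s not in accessory]
    if not members:
        return False, 0
    copies = [profile.get(s, 0) for s in members]
    detected = [c for c in copies if c > 0]
    # inclusive "half or more of the genes"
    if len(detected) * 2 >= len(members) and detected:
        return True, min(detected)
    return False, 0


def call_single_step(profile: KoProfile, pathway: PathwayDef,
                     genome_id: str = "") -> PathwayCall:
    """Call a single-step reaction on one genome.

    A gene set is satisfied when at least half (inclusive) of its
    non-accessory symbols are detected; the pathway is present when any
    alternative set is satisfied.  d = max over satisfied sets of the
    minimum copy count among the set's detected members.
    """
    if pathway.kind != "single_step":
        raise CatalogError(f"{pathway.pathway_id!r} is not single_step")
    accessory = frozenset(pathway.accessory)
    best = 0
    satisfied: list[int] = []
    for i, gene_set in enumerate(pathway.gene_sets):
        ok, d = _set_detection(profile, gene_set, accessory)
        if ok:
            satisfied.append(i)
            best = max(best, d)
    return PathwayCall(genome_id, pathway.pathway_id, best >= 1, best,
                       tuple(satisfied))


def call_multi_step(profile: KoProfile, pathway: PathwayDef,
                    genome_id: str = "") -> PathwayCall:
    """Call a multi-step pathway on one genome.

    Present iff the key enzymes are detected (all of them by default, any of
    them in ``key_mode: any`` catalogs) and satisfied_steps / total_steps is
    strictly greater than the threshold.  A step is satisfied when any of its
    alternative symbols is detected.  d = min copy count across the detected
    key enzymes when present.
    """
    if pathway.kind != "multi_step":
        raise CatalogError(f"{pathway.pathway_id!r} is not multi_step")
    key_copies = [profile.get(s, 0) for s in pathway.key_enzymes]
    if pathway.key_mode == "all":
        keys_ok = all(c > 0 for c in key_copies) and bool(key_copies)
        d_key = min(key_copies) if keys_ok else 0
    else:
        detected = [c for c in key_copies if c > 0]
        keys_ok = bool(detected)
        d_key = min(detected) if keys_ok else 0

    satisfied = tuple(
        i for i, step in enumerate(pathway.steps)
        if any(profile.get(s, 0) > 0 for s in step)
    )
    frac = len(satisfied) / len(pathway.steps)
    present = keys_ok and frac > pathway.threshold
    return PathwayCall(genome_id, pathway.pathway_id, present,
                       d_key if present else 0, satisfied if present else ())


def call_pathway(profile: KoProfile, pathway: PathwayDef,
                 genome_id: str = "") -> PathwayCall:
    """Dispatch on the pathway kind."""
    if pathway.kind == "single_step":
        return call_single_step(profile, pathway, genome_id)
    return call_multi_step(profile, pathway, genome_id)


def call_all(profiles: Mapping[str, KoProfile],
             catalog: PathwayCatalog) -> pd.DataFrame:
    """Call every pathway on every genome.

    Returns an integer DataFrame of detection counts d, genomes as rows
    (sorted by id, so the result is invariant to input order) and pathways
    as columns (catalog order).  Presence corresponds to ``d >= 1``.
    """
    genome_ids = sorted(profiles)
    data = {
        p.pathway_id: [call_pathway(profiles[g], p, g).count for g in genome_ids]
        for p in catalog
    }
    out = pd.DataFrame(data, index=pd.Index(genome_ids, name="genome_id"),
                       columns=list(catalog.ids), dtype=int)
    return out
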