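"""Monophyly testing (genealogical sorting index) and habitat keyword flags.

The genealogical sorting index (GSI) quantifies how exclusively a labelled
group of leaves clusters on a rooted tree.  Let U be the group's uniting
nodes: every internal node on a path from a group leaf up to the group's
most recent common ancestor (inclusive).  With k group members on an
L-leaf tree,

    gs     = (k - 1) / sum_{u in U} (children(u) - 1)
    gs_min = (k - 1) / (L - 1)
    gsi    = (gs - gs_min) / (1 - gs_min)

For any clade shape (polytomies included) a monophyletic group has
sum (children - 1) = k - 1 exactly, so gsi = 1; when the group's uniting
nodes span every internal node the sum equals L - 1, giving gsi = 0.  The
statistic depends only on the topology; branch lengths and child rotations
are irrelevant.  Significance comes from a leaf-label permutation null with
the group size held fixed.

Habitat classification turns free-text genome metadata into habitat flags by
case-insensitive whole-word keyword matching, then maps the set of raised
flags to a habitat class through an ordered combination table.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import yaml

__all__ = ["GsiResult", "gsi", "gsi_permutation_test", "load_tree",
           "HabitatRuleSet", "classify_habitat"]


def load_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or a Newick string."""
    text = None
    p = Path(str(source))
    try:
        if p.exists():
            text = p.read_text()
    except OSError:
        pass
    if text is None:
        text = str(source)
    tree = dendropy.Tree.get(data=text, schema="newick")
    tree.is_rooted = True
    return tree


def _tree_arrays(tree: dendropy.Tree):
    """Flatten a dendropy tree into parent/child index arrays.

    Unifurcations are suppressed so the (children - 1) degree terms are
    well defined.
    """
    tree = tree.clone(depth=1)
    tree.suppress_unifurcations()
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    n_children = np.zeros(len(nodes), dtype=np.int64)
    labels: dict[str, int] = {}
    for n in nodes:
        i = index[id(n)]
        if n.parent_node is not None:
            parent[i] = index[id(n.parent_node)]
        kids = n.child_nodes()
        n_children[i] = len(kids)
        if not kids:
            if n.taxon is None or n.taxon.label is None:
                raise ValueError("every leaf must be labelled")
            if n.taxon.label in labels:
                raise ValueError(f"duplicate leaf label {n.taxon.label!r}")
            labels[n.taxon.label] = i
    return parent, n_children, labels


def _gsi_from_arrays(parent: np.ndarray, n_children: np.ndarray,
                     leaf_idx: np.ndarray) -> float:
    n_leaves = int(np.sum(n_children == 0))
    k = leaf_idx.size
    # count group-leaf descendants per node by walking each leaf to the root
    group_count = np.zeros(parent.size, dtype=np.int64)
    for leaf in leaf_idx:
        node = int(parent[leaf])
        while node != -1:
            group_count[node] += 1
            node = int(parent[node])
    # MRCA: deepest node covering the whole group; preorder guarantees the
    # last index with full count among root-path candidates is the deepest
    covering = np.flatnonzero(group_count == k)
    mrca = int(covering.max())
    # uniting nodes: internal nodes inside the MRCA subtree with >=1 group
    # descendant -- exactly the nodes on the leaf->MRCA paths
    in_subtree = np.zeros(parent.size, dtype=bool)
    in_subtree[mrca] = True
    for i in range(mrca + 1, parent.size):   # preorder: parents precede kids
        if parent[i] != -1 and in_subtree[parent[i]]:
            in_subtree[i] = True
    uniting = (group_count >= 1) & in_subtree & (n_children > 0)
    s = int(np.sum(n_children[uniting] - 1))
    gs = (k - 1) / s
    gs_min = (k - 1) / (n_leaves - 1)
    if gs_min >= 1.0:
        # degenerate normalisation (e.g. star tree): exclusivity is the
        # only remaining signal
        leaves_under_mrca = int(np.sum((n_children == 0) & in_subtree))
        return 1.0 if leaves_under_mrca == k else 0.0
    return (gs - gs_min) / (1.0 - gs_min)


def _validate_group(labels: Mapping[str, int], group: Iterable[str]) -> np.ndarray:
    group = list(dict.fromkeys(group))
    missing = [g for g in group if g not in labels]
    if missing:
        raise ValueError(f"group members not on the tree: {missing[:5]}")
    if len(group) < 2:
        raise ValueError("group must contain at least two leaves")
    if len(group) >= len(labels):
        raise ValueError("group must be a proper subset of the leaves")
    return np.array([labels[g] for g in group], dtype=np.int64)


def gsi(tree: dendropy.Tree | str, group: Iterable[str]) -> float:
    """Genealogical sorting index of ``group`` on a rooted tree in [0, 1]."""
    if not isinstance(tree, dendropy.Tree):
        tree = load_tree(tree)
    parent, n_children, labels = _tree_arrays(tree)
    leaf_idx = _validate_group(labels, group)
    return _gsi_from_arrays(parent, n_children, leaf_idx)


@dataclass(frozen=True)
class GsiResult:
    group: tuple[str, ...]
    statistic: float
    permutations: int
    p_value: float


def gsi_permutation_test(
    tree: dendropy.Tree | str,
    group: Iterable[str],
    permutations: int = 10000,
    seed: int | np.random.Generator = 0,
) -> GsiResult:
    """Permutation test of group monophyly.

    The null shuffles leaf labels uniformly with the group size fixed
    (equivalently: draws a uniformly random group of the same size);
    p = (1 + #{gsi_perm >= gsi_obs}) / (permutations + 1).
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    if not isinstance(tree, dendropy.Tree):
        tree = load_tree(tree)
    parent, n_children, labels = _tree_arrays(tree)
    leaf_idx = _validate_group(labels, group)
    obs = _gsi_from_arrays(parent, n_children, leaf_idx)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_leaves = np.array(sorted(labels.values()), dtype=np.int64)
    k = leaf_idx.size
    count = 0
    for _ in range(permutations):
        perm = rng.choice(all_leaves, size=k, replace=False)
        if _gsi_from_arrays(parent, n_children, perm) >= obs:
            count += 1
    p = (1.0 + count) / (permutations + 1.0)
    return GsiResult(tuple(sorted(map(str, group))), float(obs),
                     int(permutations), float(p))


# --------------------------------------------------------------------------
# habitat keyword flags


def _fold(text: str) -> str:
    text = unicodedata.normalize("NFKD", text)
    return "".join(ch for ch in text if not unicodedata.combining(ch)).lower()


@dataclass(frozen=True)
class HabitatRuleSet:
    """Keyword flags plus an ordered flag-combination -> habitat table.

    ``flags`` maps a flag name to its keyword list (stored lowercase);
    ``combinations`` is an ordered sequence of (required flag set, habitat
    class); the first row whose flags are all raised wins, so more specific
    rows belong earlier.
    """

    flags: tuple[tuple[str, tuple[str, ...]], ...]
    combinations: tuple[tuple[frozenset[str], str], ...]

    def __post_init__(self) -> None:
        declared = {name for name, _ in self.flags}
        for required, habitat in self.combinations:
            unknown = required - declared
            if unknown:
                raise ValueError(
                    f"combination {habitat!r} references undeclared flags "
                    f"{sorted(unknown)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HabitatRuleSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: dict) -> "HabitatRuleSet":
        flags = tuple(
            (str(name), tuple(_fold(k) for k in keywords))
            for name, keywords in (doc.get("flags") or {}).items()
        )
        combos = tuple(
            (frozenset(str(f) for f in row["flags"]), str(row["habitat"]))
            for row in (doc.get("combinations") or ())
        )
        return cls(flags, combos)

    @classmethod
    def fixture(cls) -> "HabitatRuleSet":
        text = resources.files("sagmetab.data").joinpath(
            "habitat_rules.yaml").read_text()
        return cls._from_doc(yaml.safe_load(text))


def classify_habitat(
    metadata: str | Sequence[str],
    rules: HabitatRuleSet,
) -> tuple[frozenset[str], str]:
    """Flag and classify one genome's free-text metadata.

    Fields are concatenated, ASCII-folded and matched case-insensitively on
    whole words (so "lake" never matches "flake").  Returns (raised flags,
    habitat class); an empty or unmatched text classifies as
    ``"unclassified"``.
    """
    if isinstance(metadata, str):
        fields = [metadata]
    else:
        fields = [f for f in metadata if f]
    text = _fold(" \n ".join(fields))
    words = set(re.findall(r"[a-z0-9]+(?:[-_'][a-z0-9]+)*", text))
    raised = frozenset(
        name
        for name, keywords in rules.flags
        if any(
            (" " not in kw and kw in words)
            or (" " in kw and re.search(rf"\b{re.escape(kw)}\b", text))
            for kw in keywords
        )
    )
    for required, habitat in rules.combinations:
        if required <= raised:
            return raised, habitat
    return raised, "unclassified"
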