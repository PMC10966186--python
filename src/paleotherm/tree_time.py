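"""Cladogram parsing, stratigraphic tip-age sampling, and time-scaling.

Fossil cladograms carry no branch lengths; ages come from stratigraphic
ranges. Each repetition draws one age per tip uniformly within its
first/last-appearance interval, dates internal nodes by the oldest
descendant rule, and then repairs the inevitable zero-length branches with
one of two deterministic algorithms:

``equal``
    undatable nodes are respaced evenly between the nearest strictly older
    dated ancestor and the oldest tip that pinned their age (the root gains
    a configurable buffer so there is time to share);
``mbl``
    ancestral nodes are pushed older until every branch is at least a
    minimum duration (1 Myr by default).

Ages are in Ma before present; durations in Myr (parent age − child age).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "StratRange",
    "TimeScaledTree",
    "read_newick",
    "read_ranges",
    "node_id",
    "assign_node_ids",
    "leaf_labels",
    "mrca_id",
    "sample_tip_ages",
    "timescale_basic",
    "timescale_equal",
    "timescale_mbl",
    "timescale",
]


@dataclass(frozen=True)
class StratRange:
    """Stratigraphic range of one taxon: first/last appearance in Ma."""

    taxon: str
    fad: float
    lad: float

    def __post_init__(self) -> None:
        if not (self.fad >= self.lad >= 0.0):
            raise ValueError(
                f"{self.taxon}: need fad >= lad >= 0, got "
                f"fad={self.fad}, lad={self.lad}"
            )

    @property
    def is_extant(self) -> bool:
        return self.fad == self.lad == 0.0


# ---------------------------------------------------------------------------
# Topology I/O and node identity
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick cladogram, preserving all labels.

    Accepts quoted labels, internal-node labels and non-ASCII characters
    (e.g., dagger-prefixed fossil names). Branch lengths, if present, are
    ignored downstream. A path or a literal Newick string is accepted.
    """
    text = None
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick in {source!r}: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels: {dup}")
    assign_node_ids(tree)
    return tree


def assign_node_ids(tree: dendropy.Tree) -> None:
    """Attach a stable ``id`` to every node.

    Leaves are identified by their taxon label; internal nodes by their
    Newick label when present, else ``node<k>`` with ``k`` the pre-order
    index. Topology is fixed across repetitions, so ids are stable.
    """
    seen: set[str] = set()
    for k, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            nid = node.taxon.label
        elif node.label:
            nid = node.label
        else:
            nid = f"node{k}"
        if nid in seen:
            raise ValueError(f"duplicate node identifier {nid!r}")
        seen.add(nid)
        node.id = nid


def node_id(node: dendropy.Node) -> str:
    return node.id


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def mrca_id(tree: dendropy.Tree, taxa: Sequence[str]) -> str:
    """Identifier of the most recent common ancestor of the given leaves."""
    node = tree.mrca(taxon_labels=list(taxa))
    if node is None:
        raise ValueError(f"no MRCA found for {list(taxa)}")
    return node.id


def read_ranges(path: str | Path) -> list[StratRange]:
    """Read a TSV/CSV with columns ``taxon``, ``fad_ma``, ``lad_ma``."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    for col in ("taxon", "fad_ma", "lad_ma"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return [
        StratRange(taxon=str(r.taxon), fad=float(r.fad_ma), lad=float(r.lad_ma))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Tip-age sampling
# ---------------------------------------------------------------------------

def sample_tip_ages(
    ranges: Iterable[StratRange],
    rng_seed: int,
    tips: Sequence[str] | None = None,
) -> dict[str, float]:
    """Draw one age per taxon uniformly on [lad, fad].

    Extant taxa (fad = lad = 0) get exactly 0. Draws are made in sorted
    taxon order so the mapping depends only on the seed and the set of
    ranges, not on input order. If ``tips`` is given, every tip must have
    a range.
    """
    by_taxon = {r.taxon: r for r in ranges}
    if tips is not None:
        missing = sorted(set(tips) - set(by_taxon))
        if missing:
            raise ValueError(f"no stratigraphic range for tip(s): {missing}")
    rng = np.random.default_rng(rng_seed)
    ages: dict[str, float] = {}
    for taxon in sorted(by_taxon):
        r = by_taxon[taxon]
        if r.fad == r.lad:
            ages[taxon] = r.lad
        else:
            ages[taxon] = float(rng.uniform(r.lad, r.fad))
    return ages


# ---------------------------------------------------------------------------
# Time-scaling
# ---------------------------------------------------------------------------

@dataclass
class TimeScaledTree:
    """A topology with one age (Ma) per node and positive branch durations."""

    tree: dendropy.Tree
    ages: dict[str, float]
    method: str = "basic"

    def age(self, nid: str) -> float:
        return self.ages[nid]

    def branch_durations(self) -> dict[str, float]:
        """Duration (Myr) of the branch subtending each non-root node."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                out[node.id] = self.ages[node.parent_node.id] - self.ages[node.id]
        return out

    def validate(self, min_len: float = 0.0) -> None:
        for nid, dur in self.branch_durations().items():
            if not dur > 0.0 or dur < min_len - 1e-9:
                raise ValueError(
                    f"branch above {nid!r} has duration {dur}; must be "
                    f"strictly positive" + (f" and >= {min_len}" if min_len else "")
                )

    def as_newick(self) -> str:
        """Newick string with durations as branch lengths, labels preserved."""
        clone = self.tree.clone(depth=1)
        assign_node_ids(clone)
        for node in clone.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = self.ages[node.parent_node.id] - self.ages[node.id]
        return clone.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()


def _check_tip_ages(tree: dendropy.Tree, tip_ages: Mapping[str, float]) -> None:
    missing = [lf.taxon.label for lf in tree.leaf_node_iter()
               if lf.taxon.label not in tip_ages]
    if missing:
        raise ValueError(f"no age for tip(s): {sorted(missing)}")


def timescale_basic(
    tree: dendropy.Tree, tip_ages: Mapping[str, float]
) -> dict[str, float]:
    """Oldest-descendant dating: node age = max over descendant tip ages.

    May produce zero-duration branches (repaired by ``equal`` or ``mbl``).
    """
    _check_tip_ages(tree, tip_ages)
    ages: dict[str, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node.id] = float(tip_ages[node.taxon.label])
        else:
            ages[node.id] = max(ages[c.id] for c in node.child_nodes())
    return ages


def timescale_equal(
    tree: dendropy.Tree,
    tip_ages: Mapping[str, float],
    root_buffer: float = 10.0,
    node_ages: Mapping[str, float] | None = None,
) -> TimeScaledTree:
    """Even respacing of undatable nodes between dated bounds.

    A node is *dated* when its age is strictly older than all of its
    children's ages; under oldest-descendant dating every internal node on
    the path to its oldest tip is undated. Each maximal chain of undated
    nodes is respaced evenly between the nearest strictly older dated
    ancestor and the node/tip whose age pinned the chain. The root, which
    is always pinned by the oldest tip overall, is first pushed older by
    ``root_buffer`` Myr to create sharable time.

    ``node_ages`` may supply externally computed starting ages (e.g., for
    trees that already carry partial dates); otherwise the basic rule is
    applied.
    """
    ages = dict(node_ages) if node_ages is not None else timescale_basic(tree, tip_ages)
    root = tree.seed_node

    def is_dated(node: dendropy.Node) -> bool:
        if node.is_leaf():
            return True
        return ages[node.id] > max(ages[c.id] for c in node.child_nodes())

    if not is_dated(root):
        if root_buffer <= 0.0:
            raise ValueError(
                "cannot date root: root age is pinned by its oldest tip and "
                "root_buffer is 0"
            )
        ages[root.id] += root_buffer

    # Top-down repair: each undated child of a dated anchor starts a chain
    # that follows equal-age children down to the pinning node/tip.
    stack = [root]
    while stack:
        anchor = stack.pop()
        for child in anchor.child_nodes():
            if is_dated(child):
                stack.append(child)
                continue
            chain = [child]
            while True:
                cur = chain[-1]
                a = ages[cur.id]
                pins = [c for c in cur.child_nodes() if ages[c.id] == a]
                # prefer a dated pin (tip or externally dated node)
                dated_pins = [c for c in pins if is_dated(c)]
                if dated_pins:
                    bottom = dated_pins[0]
                    break
                chain.append(pins[0])
            top_age = ages[anchor.id]
            bottom_age = ages[bottom.id]
            k = len(chain)
            step = (top_age - bottom_age) / (k + 1)
            for i, node in enumerate(chain, start=1):
                ages[node.id] = top_age - i * step
            stack.extend(chain)
            stack.append(bottom)

    ts = TimeScaledTree(tree=tree, ages=ages, method="equal")
    ts.validate()
    return ts


def timescale_mbl(
    tree: dendropy.Tree,
    tip_ages: Mapping[str, float],
    min_len: float = 1.0,
    node_ages: Mapping[str, float] | None = None,
) -> TimeScaledTree:
    """Minimum-branch-length dating: push parents older until every branch
    is at least ``min_len`` Myr. Tip ages are never moved.

    ``node_ages`` may supply starting internal ages (kept when they already
    satisfy the minimum); otherwise the oldest-descendant rule applies.
    """
    if not min_len > 0.0:
        raise ValueError(f"min_len must be positive, got {min_len}")
    _check_tip_ages(tree, tip_ages)
    ages: dict[str, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node.id] = float(tip_ages[node.taxon.label])
        else:
            floor = max(ages[c.id] + min_len for c in node.child_nodes())
            start = node_ages.get(node.id, -np.inf) if node_ages else -np.inf
            ages[node.id] = max(start, floor)
    ts = TimeScaledTree(tree=tree, ages=ages, method="mbl")
    ts.validate(min_len=min_len)
    return ts


def timescale(
    tree: dendropy.Tree,
    tip_ages: Mapping[str, float],
    method: str,
    root_buffer: float = 10.0,
    min_len: float = 1.0,
) -> TimeScaledTree:
    """Dispatch to one of the dating algorithms by name."""
    if method == "equal":
        return timescale_equal(tree, tip_ages, root_buffer=root_buffer)
    if method == "mbl":
        return timescale_mbl(tree, tip_ages, min_len=min_len)
    raise ValueError(f"unknown dating method {method!r} (use 'equal' or 'mbl')")
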