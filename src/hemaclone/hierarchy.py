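"""Clonal-hierarchy bookkeeping and cohort-level statistics.

A patient's clones form a rooted tree of genetic descent: the founder clone
has depth 1 and a clone carrying k additional mutations has depth 1 + k.
A clone is *significant* at a snapshot if it comprises at least a threshold
fraction (default 1%, motivated by sequencing sensitivity) of the total cell
mass -- healthy plus leukemic, mitotic plus post-mitotic.  Cohort statistics
(clone counts, hierarchy depth, self-renewal by order of emergence) operate
on collections of simulated patients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import CloneParams, SystemState

__all__ = [
    "CloneNode",
    "HierarchyTree",
    "CohortResult",
    "significant_clones",
    "hierarchy_depth",
    "clone_order_statistics",
    "welch_t_test",
    "canonical_topology",
    "depth_vs_max_self_renewal",
    "cohort_summary",
]


@dataclass
class CloneNode:
    """Genealogy record of one clone.

    ``mass_fractions`` and ``significant`` are keyed by snapshot label
    (e.g. ``"depletion_05"``, ``"terminal"``).  ``established`` is False for
    clones that failed the extinction filter and were never introduced to
    the ODE system; ``alive`` is False for established clones pruned after
    decaying.
    """

    id: int
    parent: int | None
    birth_time: float
    depth: int
    params: CloneParams
    established: bool = True
    alive: bool = True
    mass_fractions: dict = field(default_factory=dict)
    significant: dict = field(default_factory=dict)

    def is_significant(self, mode: str = "any") -> bool:
        """Patient-level significance: at any snapshot, or terminal-only."""
        if mode == "any":
            return any(self.significant.values())
        if mode == "terminal":
            return bool(self.significant.get("terminal", False))
        raise ValueError(f"unknown significance mode {mode!r}")


class HierarchyTree:
    """Rooted tree of clones; the root is the founder (depth 1)."""

    def __init__(self) -> None:
        self.nodes: dict[int, CloneNode] = {}
        self.root_id: int | None = None

    def add(self, node: CloneNode) -> None:
        if node.parent is None:
            if self.root_id is not None:
                raise ValueError("tree already has a root")
            if node.depth != 1:
                raise ValueError("the founder clone has depth 1")
            self.root_id = node.id
        else:
            parent = self.nodes[node.parent]
            if node.depth != parent.depth + 1:
                raise ValueError("child depth must be parent depth + 1")
            if node.birth_time < parent.birth_time:
                raise ValueError("birth times must be non-decreasing along lineages")
        if node.id in self.nodes:
            raise ValueError(f"duplicate clone id {node.id}")
        self.nodes[node.id] = node

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, cid: int) -> bool:
        return cid in self.nodes

    @property
    def root(self) -> CloneNode:
        if self.root_id is None:
            raise ValueError("empty tree")
        return self.nodes[self.root_id]

    def children(self, cid: int) -> list[int]:
        return [n.id for n in self.nodes.values() if n.parent == cid]

    def established_nodes(self) -> list[CloneNode]:
        return [n for n in self.nodes.values() if n.established]

    def significant_ids(self, mode: str = "any") -> set[int]:
        return {n.id for n in self.nodes.values() if n.established and n.is_significant(mode)}

    def _has_significance_records(self) -> bool:
        return any(n.significant for n in self.nodes.values())

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "root": self.root_id,
            "nodes": [
                {
                    "id": n.id,
                    "parent": n.parent,
                    "birth_time": n.birth_time,
                    "depth": n.depth,
                    "a_max": n.params.a_max,
                    "p": n.params.p,
                    "d": n.params.d,
                    "established": n.established,
                    "alive": n.alive,
                    "mass_fractions": n.mass_fractions,
                    "significant": n.significant,
                }
                for n in sorted(self.nodes.values(), key=lambda n: n.id)
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "HierarchyTree":
        tree = cls()
        for rec in sorted(payload["nodes"], key=lambda r: r["depth"]):
            tree.add(
                CloneNode(
                    id=rec["id"],
                    parent=rec["parent"],
                    birth_time=rec["birth_time"],
                    depth=rec["depth"],
                    params=CloneParams(a_max=rec["a_max"], p=rec["p"], d=rec["d"]),
                    established=rec["established"],
                    alive=rec["alive"],
                    mass_fractions=dict(rec["mass_fractions"]),
                    significant=dict(rec["significant"]),
                )
            )
        return tree


def significant_clones(state: SystemState, threshold: float) -> set[int]:
    """Clones whose total mass is at least ``threshold`` of all cell mass.

    The total includes healthy and leukemic cells, mitotic and post-mitotic.
    A clone exactly at the threshold is included ("at least").  An empty
    system yields an empty set.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    total = state.total_cells()
    if total <= 0.0:
        return set()
    return {
        cid
        for cid, _, cs in state.clones
        if (cs.mitotic + cs.post_mitotic) >= threshold * total
    }


def _eligible_ids(tree: HierarchyTree, significant_only: bool, mode: str) -> set[int]:
    if not significant_only:
        return {n.id for n in tree.established_nodes()}
    if not tree._has_significance_records():
        # bare genealogies (no snapshots attached) fall back to all clones
        return {n.id for n in tree.established_nodes()}
    return tree.significant_ids(mode)


def hierarchy_depth(
    tree: HierarchyTree, significant_only: bool = True, mode: str = "any"
) -> int:
    """Maximal depth over (significant) clones; 0 if no clone qualifies.

    Trees without any significance records (bare genealogies) are treated as
    all-significant so that topology-only trees report their full depth.
    """
    if len(tree) == 0:
        raise ValueError("empty tree")
    ids = _eligible_ids(tree, significant_only, mode)
    if not ids:
        return 0
    return max(tree.nodes[i].depth for i in ids)


def canonical_topology(
    tree: HierarchyTree, significant_only: bool = True, mode: str = "any"
) -> str:
    """Canonical string of the rooted *unordered* tree topology.

    Two trees map to the same string iff they are isomorphic as rooted
    unordered trees (recursive sorted-children encoding).  With
    ``significant_only`` the tree is first contracted: every insignificant
    node is removed and each significant node is re-attached to its nearest
    significant ancestor.  If the founder itself is insignificant the
    contraction can yield several roots; the forest is then encoded as the
    children of a virtual root.  An empty (no eligible clones) tree encodes
    as the empty string.
    """
    if len(tree) == 0:
        raise ValueError("empty tree")
    eligible = _eligible_ids(tree, significant_only, mode)
    if not eligible:
        return ""
    children: dict[int | None, list[int]] = {}
    for cid in eligible:
        anc = tree.nodes[cid].parent
        while anc is not None and anc not in eligible:
            anc = tree.nodes[anc].parent
        children.setdefault(anc, []).append(cid)

    def encode(cid: int) -> str:
        subs = sorted(encode(c) for c in children.get(cid, []))
        return "(" + ",".join(subs) + ")"

    roots = sorted(encode(r) for r in children.get(None, []))
    if len(roots) == 1:
        return roots[0]
    return "(" + ",".join(roots) + ")"


def welch_t_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample t-test with Welch (unequal-variance) dof.

    Degenerate inputs with zero variance in both samples return p = 1 when
    the means agree (identical constant samples) and p = 0 otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# cohort-level statistics
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    """A collection of simulated disease courses with derived statistics."""

    patients: list
    config: object = None
    master_seed: int | None = None

    def __len__(self) -> int:
        return len(self.patients)

    def summary(self, mode: str = "any") -> pd.DataFrame:
        return cohort_summary(self, mode=mode)


def _ordered_significant(patient, mode: str = "any") -> list[CloneNode]:
    """Significant clones of one patient, ordered by time of emergence."""
    tree: HierarchyTree = patient.hierarchy
    ids = tree.significant_ids(mode)
    nodes = [tree.nodes[i] for i in ids]
    return sorted(nodes, key=lambda n: (n.birth_time, n.id))


def cohort_summary(cohort: CohortResult, mode: str = "any") -> pd.DataFrame:
    """One row per patient: outcome, clone counts, depth, max self-renewal."""
    rows = []
    for i, pat in enumerate(cohort.patients):
        tree: HierarchyTree = pat.hierarchy
        sig = _ordered_significant(pat, mode)
        established = tree.established_nodes()
        founder = tree.root
        rows.append(
            {
                "patient": i,
                "seed": pat.seed,
                "status": pat.status,
                "death_time": pat.death_time,
                "n_mutation_events": pat.n_mutation_events,
                "n_clones": len(established),
                "n_significant": len(sig),
                "depth": max((n.depth for n in sig), default=0),
                "depth_all": max((n.depth for n in established), default=0),
                "max_a_significant": max((n.params.a_max for n in sig), default=np.nan),
                "founder_a": founder.params.a_max,
                "founder_p": founder.params.p,
            }
        )
    return pd.DataFrame(rows)


def clone_order_statistics(
    cohort: CohortResult,
    mode: str = "any",
    n_significant: int | None = None,
    group_mode: str = "terminal",
) -> pd.DataFrame:
    """Traits of significant clones by order of emergence.

    Returns a long-format table (patient, rank, a_max, p, depth, birth_time)
    where rank 1 is the earliest-emerging significant clone.  When
    ``n_significant`` is given, the table is restricted to the subgroup of
    patients harboring exactly that many significant clones, with
    significance for the subgrouping assessed in ``group_mode``
    (terminal-only by default, matching end-of-simulation subgroups).
    """
    rows = []
    for i, pat in enumerate(cohort.patients):
        if n_significant is not None:
            if len(_ordered_significant(pat, group_mode)) != n_significant:
                continue
        for rank, node in enumerate(_ordered_significant(pat, mode), start=1):
            rows.append(
                {
                    "patient": i,
                    "rank": rank,
                    "clone_id": node.id,
                    "birth_time": node.birth_time,
                    "a_max": node.params.a_max,
                    "p": node.params.p,
                    "depth": node.depth,
                }
            )
    return pd.DataFrame(rows, columns=["patient", "rank", "clone_id", "birth_time", "a_max", "p", "depth"])


def fraction_second_exceeds_first(cohort: CohortResult, mode: str = "any") -> tuple[float, int]:
    """Fraction of patients whose 2nd significant clone (by emergence) has a
    higher self-renewal rate than the 1st, among patients with >= 2
    significant clones.  Returns (fraction, number of eligible patients)."""
    n_eligible = 0
    n_higher = 0
    for pat in cohort.patients:
        sig = _ordered_significant(pat, mode)
        if len(sig) < 2:
            continue
        n_eligible += 1
        if sig[1].params.a_max > sig[0].params.a_max:
            n_higher += 1
    frac = n_higher / n_eligible if n_eligible else np.nan
    return frac, n_eligible


def depth_vs_max_self_renewal(cohort: CohortResult, mode: str = "any") -> dict:
    """Association between hierarchy depth and maximal self-renewal.

    Groups patients (with at least one significant clone) by hierarchy depth
    and reports the per-depth distribution of the maximum a_max over
    significant clones, pairwise Welch tests between depth groups, and the
    Pearson correlation between the total number of significant clones and
    the maximal self-renewal rate.
    """
    by_depth: dict[int, list[float]] = {}
    n_sig_list, max_a_list = [], []
    for pat in cohort.patients:
        sig = _ordered_significant(pat, mode)
        if not sig:
            continue
        depth = max(n.depth for n in sig)
        max_a = max(n.params.a_max for n in sig)
        by_depth.setdefault(depth, []).append(max_a)
        n_sig_list.append(len(sig))
        max_a_list.append(max_a)
    if len(by_depth) < 2:
        raise ValueError("need at least 2 distinct depths")
    pairwise = {}
    for d1, d2 in itertools.combinations(sorted(by_depth), 2):
        if len(by_depth[d1]) >= 2 and len(by_depth[d2]) >= 2:
            pairwise[(d1, d2)] = welch_t_test(by_depth[d1], by_depth[d2])
    if len(n_sig_list) >= 3 and np.std(n_sig_list) > 0 and np.std(max_a_list) > 0:
        r, p = stats.pearsonr(n_sig_list, max_a_list)
        corr = (float(r), float(p))
    else:
        corr = (np.nan, np.nan)
    return {
        "by_depth": by_depth,
        "per_depth_mean": {d: float(np.mean(v)) for d, v in sorted(by_depth.items())},
        "pairwise_welch": pairwise,
        "count_vs_max_a_corr": corr,
    }
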