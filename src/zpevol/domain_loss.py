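"""Clade-level detection of domain-specific sequence loss.

Per-sequence, per-domain gap proportions are mapped onto the phylogeny and
scanned for *maximal* clades in which the focal domain is essentially
absent (high tip-median gap) while every other domain remains present (low
tip-median gap).  The clade median resists single aberrant tips, and
isolated high-gap tips that do not sit inside a qualifying clade are
reported separately as outliers — likely artifactual truncations rather
than evolutionary domain losses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .alignment import GapProfile
from .rooting import mad_root
from .trees import Node, Tree

logger = logging.getLogger(__name__)


class InputError(ValueError):
    pass


@dataclass
class LossCall:
    clade_tips: FrozenSet[str]
    domain_id: str
    clade_median_gap: float
    other_domain_median_gap: float
    n_tips: int


@dataclass
class OutlierTip:
    name: str
    domain_id: str
    gap: float


def annotate_tips(tree: Tree, gap_profiles: Mapping[str, GapProfile]) -> Tree:
    """Attach per-domain gap fractions to every tip (copy).

    A tip without a profile is a hard error; silent defaults would turn
    missing data into spurious domain presence.
    """
    out = tree.copy()
    for tip in out.tips():
        if tip.name not in gap_profiles:
            raise InputError(f"no gap profile for tip {tip.name!r}")
        prof = gap_profiles[tip.name]
        for d, v in prof.per_domain.items():
            tip.annotations[f"gap_{d}"] = float(v)
    return out


def detect_loss_clades(
    annotated_tree: Tree,
    domain_id: str,
    tau_high: float = 0.70,
    tau_low: float = 0.30,
    min_tips: int = 4,
) -> Tuple[List[LossCall], List[OutlierTip]]:
    """Find maximal clades with domain-specific loss; flag stray tips.

    A clade qualifies when its tip-median gap for ``domain_id`` is at
    least ``tau_high``, its tip-median gap for every other domain is at
    most ``tau_low``, and it spans at least ``min_tips`` tips.  Qualifying
    clades nested inside other qualifying clades are absorbed (maximality).
    High-gap tips outside every call are returned as outliers, never as
    loss calls.
    """
    if not (0 < tau_low < tau_high < 1):
        raise ValueError("need 0 < tau_low < tau_high < 1")
    tree = annotated_tree
    if not tree.is_rooted:
        logger.info("input tree unrooted; applying MAD rooting before the scan")
        tree = mad_root(tree)[0]

    key = f"gap_{domain_id}"
    tips = tree.tips()
    if not tips:
        raise InputError("tree has no tips")
    domains = sorted(
        {k[4:] for t in tips for k in t.annotations if k.startswith("gap_")}
    )
    if domain_id not in domains:
        raise InputError(f"tips carry no annotation for domain {domain_id!r}")
    others = [d for d in domains if d != domain_id]

    calls: List[LossCall] = []

    def tipvals(node: Node, dom: str) -> List[float]:
        return [t.annotations[f"gap_{dom}"] for t in Tree(node).tips()]

    def qualifies(node: Node) -> Optional[LossCall]:
        vals = tipvals(node, domain_id)
        if len(vals) < min_tips:
            return None
        med = float(np.median(vals))
        if med < tau_high:
            return None
        other_meds = [float(np.median(tipvals(node, d))) for d in others]
        worst = max(other_meds) if other_meds else 0.0
        if worst > tau_low:
            return None
        return LossCall(
            frozenset(t.name for t in Tree(node).tips()),
            domain_id,
            med,
            worst,
            len(vals),
        )

    def scan(node: Node) -> None:
        call = qualifies(node)
        if call is not None:
            calls.append(call)
            return  # maximality: do not descend into a called clade
        for c in node.children:
            scan(c)

    scan(tree.root)
    called = set().union(*(c.clade_tips for c in calls)) if calls else set()
    outliers = [
        OutlierTip(t.name, domain_id, t.annotations[key])
        for t in tips
        if t.name not in called and t.annotations[key] >= tau_high
    ]
    calls.sort(key=lambda c: sorted(c.clade_tips))
    outliers.sort(key=lambda o: o.name)
    return calls, outliers


def subfamily_summary(
    subfamily_map: Mapping[str, str],
    replicate_gap_profiles: Sequence[Mapping[str, GapProfile]],
) -> List[dict]:
    """Per-subfamily per-domain gap statistics across replicates.

    For each replicate, the gap fractions of a subfamily's sequences are
    averaged; the table then reports the min, max, and mean of those
    per-replicate means — the "range depending on alignment replicate"
    view of domain loss.
    """
    if not replicate_gap_profiles:
        raise InputError("no replicate profiles given")
    seqs = set(replicate_gap_profiles[0])
    unassigned = sorted(seqs - set(subfamily_map))
    if unassigned:
        raise InputError(f"sequences without a subfamily: {unassigned[:5]}")
    domains = sorted(
        {d for profs in replicate_gap_profiles for p in profs.values() for d in p.per_domain}
    )
    subfamilies = sorted(set(subfamily_map.values()))
    rows = []
    for sf in subfamilies:
        members = sorted(s for s in seqs if subfamily_map[s] == sf)
        for dom in domains:
            per_rep = []
            for profs in replicate_gap_profiles:
                vals = [profs[m].per_domain[dom] for m in members]
                per_rep.append(float(np.mean(vals)))
            rows.append(
                {
                    "subfamily": sf,
                    "domain": dom,
                    "n_sequences": len(members),
                    "min": float(np.min(per_rep)),
                    "max": float(np.max(per_rep)),
                    "mean": float(np.mean(per_rep)),
                }
            )
    return rows
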