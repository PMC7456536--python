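"""Synthetic gene-family fixtures with planted, recountable truth.

The generator emulates the statistical regime the downstream analysis
assumes: an ancient gene family of paralogous subfamilies sampled across
many species, replicate alignments of the same sequences that differ by
small gap/flank jitter, subfamily-restricted loss of the N-terminal (ZP-N)
domain, Type 1/2/3 cysteine-column layouts, and per-protein coordinate sets
in which planted disulfide partners sit close together in space while all
other cysteine pairs are kept far apart.

Every output is a pure function of (spec, seed): randomness is drawn from
``numpy.random.Generator`` streams split deterministically per operation
with a counter-based scheme, so two runs with the same spec produce
byte-identical bundles.

Defaults are a desk-scale rendition of the real-data regime: ~7% background
missing data, loss-clade gap fractions drawn from [0.80, 0.99], alignments
of 240 columns containing the full cysteine registry (max column 218), and
ten alignment replicates.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .alignment import Alignment, write_alignment
from .connectivity import (
    DEFAULT_REGISTRY,
    TYPE_DISULFIDES,
    CysteineRegistry,
    StructureModel,
)
from .trees import Node, Tree, write_newick


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residues used when a type layout requires the *absence* of a cysteine.
NON_CYS = "KASTNDEQ"


class ParameterError(ValueError):
    """Invalid synthetic-data parameters."""


class GenerationError(RuntimeError):
    """Generation failed (e.g. infeasible coordinate placement)."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fixture bundle.

    The defaults define the study conditions: six ancient subfamilies
    sampled in five species each, two of them having lost the ZP-N domain,
    with types assigned in contiguous blocks so each type forms a clade.
    """

    n_subfamilies: int = 6
    n_species: int = 5
    seq_length: int = 240
    subs_rate: float = 1.0
    gap_jitter_sd: float = 1.0
    n_replicates: int = 10
    loss_subfamilies: Tuple[Tuple[int, str], ...] = ((1, "ZP-N"), (4, "ZP-N"))
    type_assignments: Optional[Tuple[Tuple[int, str], ...]] = None
    background_gap_frac: float = 0.07
    seed: int = 0

    def resolved_types(self) -> Dict[int, str]:
        if self.type_assignments is not None:
            out = dict(self.type_assignments)
            bad = [i for i in out if not 0 <= i < self.n_subfamilies]
            if bad:
                raise ParameterError(f"type assignment for unknown subfamily {bad}")
            if set(out.values()) - {"Type1", "Type2", "Type3"}:
                raise ParameterError("types must be Type1/Type2/Type3")
            for i in range(self.n_subfamilies):
                out.setdefault(i, "Type1")
            return out
        # contiguous thirds: ancestral Type1 block, then Type2, then Type3
        out = {}
        third = max(1, self.n_subfamilies // 3)
        for i in range(self.n_subfamilies):
            out[i] = "Type1" if i < third else ("Type2" if i < 2 * third else "Type3")
        return out

    def validate(self, registry: CysteineRegistry = DEFAULT_REGISTRY) -> None:
        if self.n_subfamilies < 1 or self.n_species < 3:
            raise ParameterError("need n_subfamilies >= 1 and n_species >= 3")
        if self.n_replicates < 2:
            raise ParameterError("need n_replicates >= 2")
        if self.seq_length < 220 or self.seq_length < registry.max_column():
            raise ParameterError(
                f"seq_length {self.seq_length} must be >= 220 and cover the "
                f"registry (max column {registry.max_column()})"
            )
        for sf, dom in self.loss_subfamilies:
            if not 0 <= sf < self.n_subfamilies:
                raise ParameterError(f"loss subfamily {sf} does not exist")
            if dom not in ("ZP-N", "ZP-C"):
                raise ParameterError(f"unknown domain {dom!r}")
        self.resolved_types()


@dataclass
class SyntheticTruth:
    """Planted ground truth, recountable against the emitted files."""

    true_tree: Tree
    tip_types: Dict[str, str]
    loss_tips: Set[str]
    planted_disulfides: Dict[str, List[Tuple[int, int]]]
    type_switches: int
    subfamily_of: Dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "true_tree": self.true_tree.to_newick(),
            "tip_types": dict(sorted(self.tip_types.items())),
            "loss_tips": sorted(self.loss_tips),
            "planted_disulfides": {
                k: sorted(map(list, v))
                for k, v in sorted(self.planted_disulfides.items())
            },
            "type_switches": self.type_switches,
            "subfamily_of": dict(sorted(self.subfamily_of.items())),
        }


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-operation stream from the top-level seed."""
    return np.random.default_rng(np.random.SeedSequence([int(spec_seed), int(stream)]))


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

_DEEP_SCALE = 5.0        # inter-subfamily branches are this much longer
_WITHIN_LEN = 0.06       # expected within-subfamily branch length


def _random_binary_topology(labels: Sequence[str], rng: np.random.Generator) -> Node:
    """Random binary tree grown by sequential tip attachment."""
    nodes = [Node(name=labels[0]), Node(name=labels[1])]
    root = Node(children=nodes)
    edges = list(nodes)
    for lab in labels[2:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent
        parent.remove_child(target)
        mid = Node()
        mid.add_child(target)
        new_tip = Node(name=lab)
        mid.add_child(new_tip)
        parent.add_child(mid)
        edges.extend([new_tip, mid])
    return root


def simulate_family_tree(spec: SyntheticSpec) -> Tree:
    """Simulate the family tree: subfamily clades over a deep backbone.

    Tips are named ``SF<i>_SP<j>``; each subfamily forms a clade; branches
    on the inter-subfamily backbone are five times longer than the
    within-subfamily expectation.  Returned unrooted (basal trifurcation)
    whenever topology permits.
    """
    spec.validate()
    rng = _rng(spec.seed, 1)
    types = spec.resolved_types()

    def draw_len(scale: float) -> float:
        return float(rng.gamma(2.0, scale / 2.0)) + 0.01 * scale

    # Subfamilies sharing a connectivity type are kept monophyletic: the
    # backbone nests the type blocks as (T1, (T2, T3)), mirroring an
    # ancestral Type 1 state with nested derived types.
    blocks: List[List[str]] = []
    for tname in ("Type1", "Type2", "Type3"):
        labs = [f"SF{i}" for i in range(spec.n_subfamilies) if types[i] == tname]
        if labs:
            blocks.append(labs)

    def block_subtree(labels: List[str]) -> Node:
        if len(labels) == 1:
            return Node(name=labels[0])
        return _random_binary_topology(labels, rng)

    if len(blocks) == 1:
        root = block_subtree(blocks[0])
        if root.is_tip:
            root = Node(children=[root])
    else:
        sub = block_subtree(blocks[-1])
        for labs in reversed(blocks[:-1]):
            sub = Node(children=[block_subtree(labs), sub])
        root = sub
    # assign deep branch lengths on the backbone
    backbone_tree = Tree(root)
    for nd in backbone_tree.preorder():
        if nd is not root:
            nd.length = draw_len(_WITHIN_LEN * _DEEP_SCALE)

    # graft a species clade in place of each subfamily placeholder tip
    for tip in list(backbone_tree.tips()):
        i = int(tip.name[2:])
        labels = [f"SF{i}_SP{j}" for j in range(spec.n_species)]
        sub = _random_binary_topology(labels, rng)
        for nd in Tree(sub).preorder():
            if nd is not sub:
                nd.length = draw_len(_WITHIN_LEN)
        tip.name = None
        for c in list(sub.children):
            sub.remove_child(c)
            tip.add_child(c)

    tree = Tree(root)
    # unroot: basal trifurcation representation
    from .trees import unroot as _unroot

    out = _unroot(tree) if len(root.children) == 2 else tree
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _type_layout(type_: str, registry: CysteineRegistry) -> Tuple[Set[int], Set[int]]:
    """(columns that must carry C, columns that must not) for a type."""
    must = set()
    for name in ("Cys1", "Cys2", "Cys3", "Cys4", "Cys5", "Cys6", "Cys7", "CysB"):
        must.add(registry.site_columns(name)[0])
    must.add(registry.site_columns("Cys8")[-1])     # use column 218
    must_not = set()
    for name in ("AB_loop", "FBN1_partner"):
        must_not.update(registry.site_columns(name))
    a = registry.site_columns("CysA")[0]
    ihp_a, ihp_b = (registry.site_columns("IHP_A")[0], registry.site_columns("IHP_B")[0])
    t3 = registry.site_columns("T3_partner")[0]
    if type_ == "Type1":
        must.add(a)
        must_not.update({ihp_a, ihp_b, t3})
    elif type_ == "Type2":
        must.update({a, ihp_a, ihp_b})
        must_not.add(t3)
    elif type_ == "Type3":
        must.update({ihp_a, ihp_b, t3})
        must_not.add(a)
    else:
        raise ParameterError(f"unknown type {type_!r}")
    must_not.add(registry.site_columns("Cys8")[0])  # keep 215 clear; Cys8 sits at 218
    return must, must_not


def _registry_columns(registry: CysteineRegistry) -> Set[int]:
    out: Set[int] = set()
    for name in registry.columns:
        out.update(registry.site_columns(name))
    return out


def evolve_sequences(
    tree: Tree,
    spec: SyntheticSpec,
    registry: CysteineRegistry = DEFAULT_REGISTRY,
) -> Dict[str, str]:
    """Evolve tip sequences down the tree under a Poisson process.

    Substitution events arrive as Poisson(branch length * rate) per site
    and draw the replacement uniformly from the 20 amino acids (a
    Jukes-Cantor-like process, so expectations are analytic).  Registry
    columns are held invariant and then overwritten per tip according to
    the subfamily's type layout: required sites get C, required-absent
    sites a fixed non-cysteine residue.
    """
    spec.validate(registry)
    if registry.max_column() >= spec.seq_length:
        raise ParameterError("registry columns must fit within seq_length")
    rng = _rng(spec.seed, 2)
    L = spec.seq_length
    reg_cols = _registry_columns(registry)
    guard = registry.tolerance + _MAX_SHIFT + 5
    guard_cols = [
        c
        for c in range(1, L + 1)
        if c not in reg_cols and any(abs(c - r) <= guard for r in reg_cols)
    ]
    free = np.array([c for c in range(1, L + 1) if c not in reg_cols])
    root_seq = np.array(list(AMINO_ACIDS))[rng.integers(20, size=L)]
    types = spec.resolved_types()

    seqs: Dict[str, str] = {}

    def walk(node: Node, seq: np.ndarray) -> None:
        seq = seq.copy()
        t = (node.length or 0.0) * spec.subs_rate
        if t > 0:
            n_events = rng.poisson(t, size=free.size)
            hit = free[n_events > 0]
            if hit.size:
                seq[hit - 1] = np.array(list(AMINO_ACIDS))[
                    rng.integers(20, size=hit.size)
                ]
        if node.is_tip:
            # stray cysteines close to registry columns would be picked up
            # by the tolerance window during presence scoring; keep a clear
            # margin (wide enough that replicate jitter cannot close it)
            for c in guard_cols:
                if seq[c - 1] == "C":
                    seq[c - 1] = "S"
            sf = int(node.name.split("_")[0][2:])
            must, must_not = _type_layout(types[sf], registry)
            for c in must:
                seq[c - 1] = "C"
            for i, c in enumerate(sorted(must_not)):
                seq[c - 1] = NON_CYS[i % len(NON_CYS)]
            seqs[node.name] = "".join(seq)
        else:
            for child in node.children:
                walk(child, seq)

    for child in tree.root.children:
        walk(child, root_seq)
    return seqs


# ---------------------------------------------------------------------------
# Background gaps and domain loss
# ---------------------------------------------------------------------------

_GAP_MARGIN = 6     # background gap blocks keep this distance from registry cols


def plant_background_gaps(
    sequences: Mapping[str, str],
    spec: SyntheticSpec,
    registry: CysteineRegistry = DEFAULT_REGISTRY,
) -> Dict[str, str]:
    """Insert short gap blocks so each row carries the background missing
    fraction (default ~7%, matching a 6-8% regime).

    Blocks are 2-5 columns long and stay at least ``_GAP_MARGIN`` columns
    away from every registry column so replicate jitter can never push a
    registry cysteine off its column.
    """
    rng = _rng(spec.seed, 3)
    L = spec.seq_length
    reg = _registry_columns(registry)
    allowed = np.zeros(L + 1, dtype=bool)
    for c in range(1, L + 1):
        if all(abs(c - r) >= _GAP_MARGIN for r in reg):
            allowed[c] = True
    out: Dict[str, str] = {}
    target = spec.background_gap_frac * L
    for name in sorted(sequences):
        seq = list(sequences[name])
        placed = 0
        attempts = 0
        while placed < target and attempts < 500:
            attempts += 1
            block = int(rng.integers(2, 6))
            start = int(rng.integers(1, L - block + 1))
            cols = range(start, start + block)
            if not all(allowed[c] and seq[c - 1] != "-" for c in cols):
                continue
            # keep one non-gap column between blocks so runs stay separable
            lo, hi = max(1, start - 1), min(L, start + block)
            if any(seq[c - 1] == "-" for c in (lo, hi)):
                continue
            for c in cols:
                seq[c - 1] = "-"
            placed += block
        out[name] = "".join(seq)
    return out


def plant_domain_loss(
    sequences: Mapping[str, str],
    loss_tips: Set[str],
    domain_interval: Tuple[int, int],
    seed: int,
    noise: bool = True,
    gap_range: Tuple[float, float] = (0.80, 0.99),
) -> Dict[str, str]:
    """Replace a domain interval with gaps in every loss tip.

    With ``noise`` on, each loss tip's realized gap proportion over the
    interval is drawn uniformly from ``gap_range`` and realized exactly
    (a fixed number of interval positions is gapped); with noise off the
    whole interval is gapped.  Non-loss tips are untouched.
    """
    start, end = domain_interval
    if start > end or start < 1:
        raise ParameterError(f"empty or invalid interval {domain_interval}")
    rng = _rng(seed, 4)
    width = end - start + 1
    out: Dict[str, str] = {}
    for name in sorted(sequences):
        seq = sequences[name]
        if end > len(seq):
            raise ParameterError("interval outside sequence length")
        if name not in loss_tips:
            out[name] = seq
            continue
        chars = list(seq)
        if noise:
            u = rng.uniform(*gap_range)
            k = int(round(u * width))
            k = min(max(k, int(np.ceil(gap_range[0] * width))),
                    int(np.floor(gap_range[1] * width)))
            positions = rng.choice(np.arange(start, end + 1), size=k, replace=False)
        else:
            positions = np.arange(start, end + 1)
        for c in positions:
            chars[c - 1] = "-"
        out[name] = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# Replicate alignments
# ---------------------------------------------------------------------------

_MAX_SHIFT = 3
_MAX_FLANK_TRIM = 3


def _gap_runs(seq: str) -> List[Tuple[int, int]]:
    """Maximal gap runs as 0-based [start, end) intervals."""
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "-":
            j = i
            while j < len(seq) and seq[j] == "-":
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _shift_run(chars: List[str], start: int, end: int, k: int) -> None:
    """Slide the gap run [start, end) by k columns, displacing residues."""
    block = end - start
    if k > 0:
        moved = chars[end : end + k]
        chars[start : start + k] = moved
        chars[start + k : end + k] = ["-"] * block
    elif k < 0:
        moved = chars[start + k : start]
        chars[end + k : end] = moved
        chars[start + k : end + k] = ["-"] * block


def emit_replicate_alignments(
    sequences: Mapping[str, str], spec: SyntheticSpec
) -> List[Alignment]:
    """Replicate alignments differing by gap-block jitter and flank trims.

    Replicate 0 is the unperturbed alignment.  Each further replicate
    independently slides every gap run by a discretized Normal(0,
    ``gap_jitter_sd``) offset (clamped to +/-3 and applied only when the
    landing zone is clear) and trims 0-3 columns off the trailing flank.
    All replicates keep the same sequence names.
    """
    if spec.n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    rng = _rng(spec.seed, 5)
    names = sorted(sequences)
    base_rows = [(nm, sequences[nm]) for nm in names]
    replicates = [Alignment(list(base_rows), replicate_id="rep0")]
    L = len(base_rows[0][1])
    for rep in range(1, spec.n_replicates):
        rows = []
        trim = int(rng.integers(0, _MAX_FLANK_TRIM + 1)) if spec.gap_jitter_sd > 0 else 0
        for nm in names:
            chars = list(sequences[nm])
            if spec.gap_jitter_sd > 0:
                for start, end in _gap_runs(sequences[nm]):
                    k = int(round(rng.normal(0.0, spec.gap_jitter_sd)))
                    k = max(-_MAX_SHIFT, min(_MAX_SHIFT, k))
                    if k == 0:
                        continue
                    if k > 0 and (end + k > L or "-" in chars[end : end + k]):
                        continue
                    if k < 0 and (start + k < 0 or "-" in chars[start + k : start]):
                        continue
                    _shift_run(chars, start, end, k)
            rows.append((nm, "".join(chars[: L - trim])))
        replicates.append(Alignment(rows, replicate_id=f"rep{rep}"))
    return replicates


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------

_GRID_SPACING = 24.0
_PAIR_RANGE = (2.0, 6.0)
_DECOY_MIN = 10.0


def synthesize_coordinates(
    aligned_sequence: str,
    planted_pairs: Sequence[Tuple[int, int]],
    seed: int,
) -> Tuple[StructureModel, str, str]:
    """Build a coordinate set realizing the planted disulfide geometry.

    Every residue gets a CA atom; cysteines also get CB and SG placed so
    the side-chain centroid sits exactly at a planned point.  Planted pair
    centroids are separated by a distance drawn uniformly from 2-6 A;
    cysteine pairs not planted end up at least 10 A apart (enforced by
    placing pair/singleton groups on a coarse spatial grid and verified
    before returning).  Returns the model plus PDB and mapping-TSV text.
    """
    seq = aligned_sequence.upper()
    residues = [(i + 1, ch) for i, ch in enumerate(seq) if ch not in "-.X?"]
    if not residues:
        raise GenerationError("empty sequence: no residues to place")
    col_of_residue = {}
    res_num = 0
    for col, ch in residues:
        res_num += 1
        col_of_residue[res_num] = col
    col_to_res = {c: r for r, c in col_of_residue.items()}
    cys_cols = sorted(c for c, ch in ((col, ch) for col, ch in residues) if ch == "C")
    for a, b in planted_pairs:
        for c in (a, b):
            if c not in col_to_res or seq[c - 1] != "C":
                raise GenerationError(f"planted pair column {c} is not a cysteine")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    # group cysteines: planted pairs together, the rest as singletons
    in_pair = {c for p in planted_pairs for c in p}
    groups: List[Tuple[int, ...]] = [tuple(sorted(p)) for p in planted_pairs]
    groups += [(c,) for c in cys_cols if c not in in_pair]

    centroid: Dict[int, np.ndarray] = {}
    for attempt in range(1000):
        centroid.clear()
        for gi, grp in enumerate(groups):
            base = np.array(
                [(gi % 4) * _GRID_SPACING, ((gi // 4) % 4) * _GRID_SPACING,
                 (gi // 16) * _GRID_SPACING]
            )
            if len(grp) == 1:
                centroid[grp[0]] = base
            else:
                d = rng.uniform(*_PAIR_RANGE)
                v = rng.normal(size=3)
                v = v / np.linalg.norm(v) * (d / 2.0)
                centroid[grp[0]] = base - v
                centroid[grp[1]] = base + v
        ok = True
        for i, a in enumerate(cys_cols):
            for b in cys_cols[i + 1:]:
                if (a, b) in groups or (b, a) in groups:
                    continue
                if np.linalg.norm(centroid[a] - centroid[b]) < _DECOY_MIN:
                    ok = False
        if ok:
            break
    else:
        raise GenerationError("could not place cysteines after 1000 attempts")

    from Bio.SeqUtils import seq3

    atoms: Dict[int, Dict[str, np.ndarray]] = {}
    res_names: Dict[int, str] = {}
    delta = np.array([0.0, 0.0, 1.0])
    for rnum, (col, ch) in enumerate(residues, start=1):
        try:
            res_names[rnum] = seq3(ch).upper()
        except Exception:
            res_names[rnum] = "UNK"
        if ch == "C":
            c = centroid[col]
            atoms[rnum] = {
                "CA": c + np.array([1.5, 0.0, 0.0]),
                "CB": c + delta,
                "SG": c - delta,
            }
        else:
            atoms[rnum] = {"CA": np.array([-50.0, 3.8 * rnum, 0.0])}

    model = StructureModel(atoms, res_names, col_of_residue, chain_id="A")
    pdb_text = _format_pdb(model)
    map_text = "residue_number\talignment_column\n" + "".join(
        f"{r}\t{c}\n" for r, c in sorted(col_of_residue.items())
    )
    return model, pdb_text, map_text


def _format_pdb(model: StructureModel) -> str:
    lines = []
    serial = 0
    elements = {"CA": "C", "CB": "C", "SG": "S"}
    for res in sorted(model.atoms):
        for atom_name in ("CA", "CB", "SG"):
            if atom_name not in model.atoms[res]:
                continue
            serial += 1
            x, y, z = model.atoms[res][atom_name]
            lines.append(
                f"ATOM  {serial:5d} {atom_name:^4s}{model.residue_names[res]:>4s} "
                f"{model.chain_id}{res:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {elements[atom_name]:>2s}\n"
            )
    lines.append("END\n")
    return "".join(lines)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

#: (signal peptide, R/K cleavage site, GPI anchor) prevalence per group,
#: mirroring the observed regime: ordinary modules are usually cleaved and
#: rarely GPI-anchored, standalone-ZP-C subfamilies mostly keep the signal
#: peptide but lose the cleavage site, and one loss subfamily is GPI-rich.
FEATURE_PREVALENCE = {
    "background": (0.66, 0.66, 0.05),
    "loss": (0.79, 0.10, 0.57),
}


def make_feature_table(
    truth: "SyntheticTruth", spec: SyntheticSpec
) -> List[dict]:
    rng = _rng(spec.seed, 6)
    rows = []
    for tip in sorted(truth.subfamily_of):
        sf = truth.subfamily_of[tip]
        group = "loss" if tip in truth.loss_tips else "background"
        p_sig, p_clv, p_gpi = FEATURE_PREVALENCE[group]
        rows.append(
            {
                "name": tip,
                "subfamily": f"SF{sf}",
                "signal_peptide": bool(rng.random() < p_sig),
                "rk_cleavage_site": bool(rng.random() < p_clv),
                "gpi_anchor": bool(rng.random() < p_gpi),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

def build_truth(tree: Tree, spec: SyntheticSpec) -> SyntheticTruth:
    types = spec.resolved_types()
    tip_types: Dict[str, str] = {}
    subfamily_of: Dict[str, int] = {}
    for nm in tree.tip_names():
        sf = int(nm.split("_")[0][2:])
        subfamily_of[nm] = sf
        tip_types[nm] = types[sf]
    loss_tips = {
        nm
        for nm, sf in subfamily_of.items()
        if any(sf == lsf for lsf, _ in spec.loss_subfamilies)
    }
    # ZP-C disulfide pairs survive ZP-N loss, so every tip keeps its
    # type-implied pairs
    planted = {nm: list(TYPE_DISULFIDES[tip_types[nm]]) for nm in subfamily_of}
    # each type is monophyletic by construction, so the planted number of
    # type-switch branches is simply the number of type boundaries
    switches = len(set(tip_types.values())) - 1
    return SyntheticTruth(tree, tip_types, loss_tips, planted, switches, subfamily_of)


@dataclass
class FixtureBundle:
    spec: SyntheticSpec
    truth: SyntheticTruth
    replicates: List[Alignment]
    structures: Dict[str, StructureModel]
    features: List[dict]
    path: Optional[str] = None


def make_fixture_bundle(
    spec: SyntheticSpec,
    out_dir: Optional[str] = None,
    write_structures: bool = True,
    registry: CysteineRegistry = DEFAULT_REGISTRY,
) -> FixtureBundle:
    """Generate a complete fixture bundle; optionally write it to disk.

    On disk: ``alignment_rep<k>.fasta`` per replicate, ``true_tree.nwk``,
    ``structures/<tip>.pdb`` + ``<tip>.map.tsv``, ``features.tsv``, and
    ``truth.json``.  Identical (spec, seed) give byte-identical bundles.
    """
    spec.validate(registry)
    tree = simulate_family_tree(spec)
    truth = build_truth(tree, spec)
    seqs = evolve_sequences(tree, spec, registry)
    seqs = plant_background_gaps(seqs, spec, registry)
    zpn = (1, 80)
    seqs = plant_domain_loss(seqs, truth.loss_tips, zpn, spec.seed)
    replicates = emit_replicate_alignments(seqs, spec)

    structures: Dict[str, StructureModel] = {}
    pdb_texts: Dict[str, Tuple[str, str]] = {}
    if write_structures:
        for tip in sorted(seqs):
            pairs = [
                (a, b)
                for a, b in truth.planted_disulfides[tip]
                if seqs[tip][a - 1] == "C" and seqs[tip][b - 1] == "C"
            ]
            model, pdb_text, map_text = synthesize_coordinates(
                seqs[tip], pairs, seed=(spec.seed * 100003 + hash_tip(tip)) % (2**31)
            )
            structures[tip] = model
            pdb_texts[tip] = (pdb_text, map_text)

    features = make_feature_table(truth, spec)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for i, aln in enumerate(replicates):
            write_alignment(aln, os.path.join(out_dir, f"alignment_rep{i}.fasta"))
        write_newick(tree, os.path.join(out_dir, "true_tree.nwk"))
        if write_structures:
            sdir = os.path.join(out_dir, "structures")
            os.makedirs(sdir, exist_ok=True)
            for tip, (pdb_text, map_text) in pdb_texts.items():
                with open(os.path.join(sdir, f"{tip}.pdb"), "w") as fh:
                    fh.write(pdb_text)
                with open(os.path.join(sdir, f"{tip}.map.tsv"), "w") as fh:
                    fh.write(map_text)
        with open(os.path.join(out_dir, "features.tsv"), "w") as fh:
            cols = ["name", "subfamily", "signal_peptide", "rk_cleavage_site", "gpi_anchor"]
            fh.write("\t".join(cols) + "\n")
            for row in features:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    return FixtureBundle(spec, truth, replicates, structures, features, out_dir)


def hash_tip(name: str) -> int:
    """Stable small integer from a tip name (process-independent)."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % 1_000_003
    return h
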