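"""Cysteine connectivity: registry columns, disulfide geometry, type calls.

The ZP module carries a registry of homologous cysteine alignment columns.
ZP-N contributes Cys1-Cys4; ZP-C carries the canonical Cys5-Cys8 plus
CysA/CysB, and several lineage-specific sites: a pair bridging the IHP
motif in betaA to betaB (columns 105/134), the betaC partner that replaces
CysA in Type 3 modules (column 140), an AB-loop pair (117/129), and the
betaF partner unique to the FBN-1 subfamily (203).  Cys8 floats between two
columns (215/218) depending on alignment replicate.

Connectivity types follow the wiring of the ZP-C disulfides:

* **Type 1** — ancestral: Cys5-Cys7, Cys6-Cys8, CysA-CysB only.
* **Type 2** — Type 1 plus the novel IHP pair (105-134).
* **Type 3** — like Type 2 but CysA is gone and CysB instead partners the
  betaC cysteine at column 140 (disulfide reshuffling).

Spatial plausibility of a bond is judged by the distance between cysteine
side-chain centroids (mean of CB and SG) measured on per-protein structural
models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Sequence, Tuple, Union

import numpy as np

from .trees import Node, Tree


class StructureError(ValueError):
    """Malformed structure file or residue/column mapping."""


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

ColumnSpec = Union[int, Tuple[int, ...]]


@dataclass(frozen=True)
class CysteineRegistry:
    """Named homologous cysteine alignment columns with a tolerance window.

    A site is "present" in a sequence when a C occurs within ``tolerance``
    columns of (any of) its registry column(s); the window absorbs
    replicate-alignment jitter.
    """

    columns: Mapping[str, ColumnSpec]
    tolerance: int = 2

    def max_column(self) -> int:
        out = 0
        for spec in self.columns.values():
            cols = spec if isinstance(spec, tuple) else (spec,)
            out = max(out, max(cols))
        return out

    def site_columns(self, name: str) -> Tuple[int, ...]:
        spec = self.columns[name]
        return spec if isinstance(spec, tuple) else (spec,)


DEFAULT_REGISTRY = CysteineRegistry(
    columns={
        # ZP-N
        "Cys1": 1,
        "Cys2": 29,
        "Cys3": 48,
        "Cys4": 80,
        # ZP-C canonical
        "Cys5": 146,
        "Cys6": 164,
        "Cys7": 201,
        "Cys8": (215, 218),
        "CysA": 206,
        "CysB": 210,
        # lineage-specific sites
        "IHP_A": 105,
        "IHP_B": 134,
        "T3_partner": 140,
        "AB_loop": (117, 129),
        "FBN1_partner": 203,
    },
    tolerance=2,
)

#: Disulfide pairs implied by each connectivity type, as column pairs.
TYPE_DISULFIDES: Dict[str, List[Tuple[int, int]]] = {
    "Type1": [(146, 201), (164, 218), (206, 210)],
    "Type2": [(146, 201), (164, 218), (206, 210), (105, 134)],
    "Type3": [(146, 201), (164, 218), (105, 134), (140, 210)],
}


def presence_vector(
    aligned_sequence: str, registry: CysteineRegistry = DEFAULT_REGISTRY
) -> Dict[str, bool]:
    """Presence/absence of each registry site in one aligned sequence.

    Present iff a C occurs within ``registry.tolerance`` columns of the
    site's column; sites with alternative columns are present if any
    alternative matches.
    """
    seq = aligned_sequence.upper()
    if len(seq) < registry.max_column():
        raise ValueError(
            f"sequence length {len(seq)} shorter than registry span "
            f"{registry.max_column()}"
        )
    w = registry.tolerance
    out: Dict[str, bool] = {}
    for name in registry.columns:
        hit = False
        for col in registry.site_columns(name):
            lo = max(1, col - w)
            hi = min(len(seq), col + w)
            if "C" in seq[lo - 1 : hi]:
                hit = True
                break
        out[name] = hit
    return out


@dataclass
class ConnectivityCall:
    module: str
    type_: str                      # Type1 | Type2 | Type3 | atypical
    flags: List[str] = field(default_factory=list)


def classify_type(presence: Mapping[str, bool], module: str = "") -> ConnectivityCall:
    """Classify a module's ZP-C connectivity type from site presence.

    The IHP pair (105+134) separates Type 2/3 from Type 1; within the
    IHP-positive group, loss of CysA together with presence of the betaC
    partner (140) marks Type 3.  Losses of otherwise conserved bonds are
    reported as flags, and patterns fitting no rule are "atypical".
    """
    required = {"IHP_A", "IHP_B", "CysA", "CysB", "Cys5", "Cys7", "T3_partner"}
    missing = required - set(presence)
    if missing:
        raise ValueError(f"incomplete presence vector: missing {sorted(missing)}")
    flags: List[str] = []
    if not presence["Cys5"] and not presence["Cys7"]:
        flags.append("Cys5-Cys7 loss")
    if not presence["CysA"] and not presence["CysB"]:
        flags.append("CysA-CysB loss")

    ihp = presence["IHP_A"] and presence["IHP_B"]
    if ihp:
        if not presence["CysA"] and presence["T3_partner"]:
            type_ = "Type3" if presence["CysB"] else "atypical"
        elif presence["CysA"]:
            type_ = "Type2"
        else:
            type_ = "atypical"
    else:
        if presence["T3_partner"] and not presence["CysA"]:
            type_ = "atypical"
        else:
            type_ = "Type1"
    return ConnectivityCall(module, type_, flags)


# ---------------------------------------------------------------------------
# Structure models
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Per-residue atom coordinates plus a residue -> alignment-column map."""

    atoms: Dict[int, Dict[str, np.ndarray]]   # residue number -> atom name -> xyz
    residue_names: Dict[int, str]             # residue number -> 3-letter code
    residue_to_column: Dict[int, int]
    chain_id: str = "A"

    def __post_init__(self):
        cols = list(self.residue_to_column.values())
        if len(cols) != len(set(cols)):
            raise StructureError("residue -> column map is not injective")
        for res in self.residue_to_column:
            if res not in self.atoms:
                raise StructureError(f"map references residue {res} absent from structure")
        self.column_to_residue = {c: r for r, c in self.residue_to_column.items()}

    def residue_for_column(self, column: int) -> int:
        if column not in self.column_to_residue:
            raise KeyError(f"alignment column {column} is not mapped to a residue")
        return self.column_to_residue[column]


def read_structure(pdb_path, map_path) -> StructureModel:
    """Read a single-chain PDB plus its residue/column TSV sidecar.

    The TSV needs columns ``residue_number`` and ``alignment_column``.
    Unmapped residues are retained (they simply cannot be queried by
    column); a map row naming an absent residue is an input error.
    """
    atoms: Dict[int, Dict[str, np.ndarray]] = {}
    res_names: Dict[int, str] = {}
    chain = "A"
    with open(pdb_path) as fh:
        for line in fh:
            if not line.startswith("ATOM"):
                continue
            try:
                atom_name = line[12:16].strip()
                res_name = line[17:20].strip()
                chain = line[21].strip() or "A"
                res_num = int(line[22:26])
                xyz = np.array(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
            except ValueError as exc:
                raise StructureError(f"bad ATOM record in {pdb_path}: {line!r}") from exc
            atoms.setdefault(res_num, {})[atom_name] = xyz
            res_names[res_num] = res_name
    if not atoms:
        raise StructureError(f"no ATOM records in {pdb_path}")

    mapping: Dict[int, int] = {}
    with open(map_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            ri = header.index("residue_number")
            ci = header.index("alignment_column")
        except ValueError as exc:
            raise StructureError(
                f"{map_path}: need residue_number and alignment_column columns"
            ) from exc
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                mapping[int(parts[ri])] = int(parts[ci])
            except (ValueError, IndexError) as exc:
                raise StructureError(f"{map_path}:{ln}: malformed row") from exc
    return StructureModel(atoms, res_names, mapping, chain_id=chain)


def cys_centroid(model: StructureModel, column: int) -> np.ndarray:
    """Side-chain centroid (mean of CB and SG) of the cysteine at a column.

    Falls back to CA with a warning when no side-chain atoms were modeled.
    """
    res = model.residue_for_column(column)
    if model.residue_names.get(res, "CYS") != "CYS":
        raise TypeError(
            f"residue {res} at column {column} is {model.residue_names[res]}, not CYS"
        )
    side = [model.atoms[res][a] for a in ("CB", "SG") if a in model.atoms[res]]
    if side:
        return np.mean(side, axis=0)
    if "CA" in model.atoms[res]:
        warnings.warn(
            f"residue {res}: no side-chain atoms, using CA as centroid", stacklevel=2
        )
        return model.atoms[res]["CA"]
    raise StructureError(f"residue {res} has no usable atoms")


def pair_distance(model: StructureModel, col_a: int, col_b: int) -> float:
    """Euclidean distance (Angstrom) between two cysteine centroids."""
    return float(np.linalg.norm(cys_centroid(model, col_a) - cys_centroid(model, col_b)))


@dataclass
class DisulfideCall:
    columns: Tuple[int, int]
    distance: float
    status: str                     # called | proximal | not_called


def call_disulfides(
    model: StructureModel,
    cys_columns: Sequence[int],
    call_thresh: float = 8.0,
    proximal_thresh: float = 10.0,
) -> List[DisulfideCall]:
    """Greedy non-overlapping disulfide pairing from centroid distances.

    Repeatedly pairs the closest remaining cysteine pair whose centroid
    distance is at most ``call_thresh``; each cysteine joins at most one
    called pair.  Remaining pairs within ``proximal_thresh`` are reported
    as "proximal", the rest as "not_called".
    """
    if call_thresh <= 0 or proximal_thresh < call_thresh:
        raise ValueError("need 0 < call_thresh <= proximal_thresh")
    cols = sorted(set(cys_columns))
    dists = {}
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            dists[(a, b)] = pair_distance(model, a, b)
    used: set = set()
    calls: List[DisulfideCall] = []
    for (a, b), d in sorted(dists.items(), key=lambda kv: (kv[1], kv[0])):
        if d > call_thresh:
            break
        if a in used or b in used:
            continue
        used.update((a, b))
        calls.append(DisulfideCall((a, b), d, "called"))
    # pairs among cysteines not consumed by a called pair
    for (a, b), d in sorted(dists.items()):
        if a in used or b in used:
            continue
        if d <= proximal_thresh:
            calls.append(DisulfideCall((a, b), d, "proximal"))
        else:
            calls.append(DisulfideCall((a, b), d, "not_called"))
    calls.sort(key=lambda c: c.columns)
    return calls


# ---------------------------------------------------------------------------
# Fitch small parsimony
# ---------------------------------------------------------------------------

def fitch_parsimony(
    tree: Tree, tip_labels: Mapping[str, str]
) -> Tuple[int, Dict[str, str]]:
    """Minimum state changes and one optimal ancestral labeling (Fitch).

    The tree must be rooted; every tip needs a label.  The returned mapping
    keys tips by name and internal nodes by a stable preorder id
    ``node<i>``.  Tie-break in the top-down pass: keep the parent's state
    when possible, otherwise take the lexicographically smallest state in
    the node's Fitch set (the root also takes the smallest).
    """
    tips = tree.tips()
    missing = [t.name for t in tips if t.name not in tip_labels]
    if missing:
        raise ValueError(f"unlabeled tips: {missing[:5]}")

    sets: Dict[Node, FrozenSet[str]] = {}
    changes = 0
    for nd in tree.postorder():
        if nd.is_tip:
            sets[nd] = frozenset([tip_labels[nd.name]])
            continue
        inter = None
        union: FrozenSet[str] = frozenset()
        for c in nd.children:
            inter = sets[c] if inter is None else inter & sets[c]
            union = union | sets[c]
        if inter:
            sets[nd] = inter
        else:
            # multifurcations: count the minimum number of children whose
            # sets must be abandoned (most-frequent-state rule)
            states: Dict[str, int] = {}
            for c in nd.children:
                for s in sets[c]:
                    states[s] = states.get(s, 0) + 1
            mx = max(states.values())
            sets[nd] = frozenset(s for s, k in states.items() if k == mx)
            changes += len(nd.children) - mx

    labeling: Dict[str, str] = {}
    assigned: Dict[Node, str] = {}
    ids: Dict[Node, str] = {}
    for i, nd in enumerate(tree.preorder()):
        if not nd.is_tip:
            ids[nd] = f"node{i}"
    for nd in tree.preorder():
        if nd.is_tip:
            labeling[nd.name] = tip_labels[nd.name]
            continue
        if nd is tree.root:
            state = min(sets[nd])
        else:
            pstate = assigned[nd.parent]
            state = pstate if pstate in sets[nd] else min(sets[nd])
        assigned[nd] = state
        labeling[ids[nd]] = state
    return changes, labeling
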