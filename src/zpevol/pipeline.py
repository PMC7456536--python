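"""End-to-end orchestration plus the small tabular utilities around it.

``run_pipeline`` drives the full analysis from a YAML/JSON config:
synthesize (optional) -> alignment profiles -> trees (read or NJ fallback)
-> consensus with BRP/TBE -> MAD + midpoint rooting -> gap mapping and
loss-clade calls -> connectivity typing and parsimony -> summaries, and
writes a single JSON report recording every threshold and seed used.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (
    DEFAULT_ANCHORS,
    consensus_sequence,
    gap_profile_table,
    locate_domain_map,
    mean_gap_profiles,
    read_alignment,
)
from .connectivity import (
    classify_type,
    fitch_parsimony,
    presence_vector,
)
from .domain_loss import annotate_tips, detect_loss_clades
from .rooting import mad_root, root_comparison
from .support import majority_rule_consensus, nj_tree, rf_normalized
from .synthetic import SyntheticSpec, make_fixture_bundle
from .trees import Tree, read_newick_trees, write_newick

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


# ---------------------------------------------------------------------------
# Similarity-hit filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitRecord:
    query: str
    subject: str
    e_value: float
    query_coverage: float

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError(f"negative E-value for {self.query}->{self.subject}")
        if not 0 <= self.query_coverage <= 1:
            raise ValueError(
                f"coverage {self.query_coverage} outside [0,1] "
                f"for {self.query}->{self.subject}"
            )


def filter_hits(
    records: Sequence[HitRecord], e_max: float = 1e-10, cov_min: float = 0.75
) -> List[HitRecord]:
    """Keep hits with E-value strictly below ``e_max`` and coverage at
    least ``cov_min``; input order is preserved."""
    return [r for r in records if r.e_value < e_max and r.query_coverage >= cov_min]


def read_hit_table(path) -> List[HitRecord]:
    """Read a BLAST-tabular-style TSV with named columns.

    Needs columns ``query``, ``subject``, ``e_value``, ``query_coverage``
    (coverage as a fraction in [0,1]).  Malformed rows raise with their
    line number.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"query", "subject", "e_value", "query_coverage"}
    if not needed <= set(df.columns):
        raise PipelineError(f"hit table {path} lacks columns {sorted(needed - set(df.columns))}")
    out = []
    for idx, row in df.iterrows():
        try:
            out.append(
                HitRecord(
                    str(row["query"]),
                    str(row["subject"]),
                    float(row["e_value"]),
                    float(row["query_coverage"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise PipelineError(f"{path}: line {idx + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# Isoform selection
# ---------------------------------------------------------------------------

DEFAULT_ISOFORM_PATTERN = r"^(?P<gene>.+?)[._]?t\d+$"


def select_longest_isoform(
    sequences: Sequence[Tuple[str, str]],
    pattern: str = DEFAULT_ISOFORM_PATTERN,
) -> List[Tuple[str, str]]:
    """One sequence per gene, keeping the longest isoform.

    Gene identity comes from a configurable name-suffix regex (default:
    trailing ``t<k>``, optionally dot/underscore separated).  Length is
    ungapped; ties go to the lexicographically smallest name.  Names not
    matching the pattern pass through untouched, since isoforms can only
    be collapsed where the naming scheme marks them.
    """
    rx = re.compile(pattern)
    groups: Dict[str, Tuple[str, str]] = {}
    passthrough: List[Tuple[str, str]] = []
    order: List[str] = []
    for name, seq in sequences:
        m = rx.match(name)
        if not m:
            passthrough.append((name, seq))
            continue
        gene = m.group("gene")
        cand = (name, seq)
        if gene not in groups:
            groups[gene] = cand
            order.append(gene)
        else:
            cur_name, cur_seq = groups[gene]
            key_new = (-len(seq.replace("-", "")), name)
            key_cur = (-len(cur_seq.replace("-", "")), cur_name)
            if key_new < key_cur:
                groups[gene] = cand
    return passthrough + [groups[g] for g in order]


# ---------------------------------------------------------------------------
# Feature prevalence
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ("signal_peptide", "rk_cleavage_site", "gpi_anchor")


def summarize_features(
    feature_table: pd.DataFrame, focal_subfamilies: Sequence[str]
) -> pd.DataFrame:
    """Per-feature prevalence for each focal subfamily and the complement.

    Returns one row per group with group size and the fraction of ``True``
    per feature; an empty group reports NaN prevalence.
    """
    if feature_table.empty:
        raise PipelineError("empty feature table")
    missing = [c for c in FEATURE_COLUMNS + ("subfamily",) if c not in feature_table.columns]
    if missing:
        raise PipelineError(f"feature table lacks columns {missing}")
    df = feature_table.copy()
    for c in FEATURE_COLUMNS:
        if df[c].dtype == object:
            df[c] = df[c].astype(str).str.lower().isin(["true", "1", "yes"])
    rows = []

    def one(name: str, sub: pd.DataFrame) -> dict:
        row = {"group": name, "n": len(sub)}
        for c in FEATURE_COLUMNS:
            row[c] = float(sub[c].mean()) if len(sub) else float("nan")
        return row

    for sf in focal_subfamilies:
        rows.append(one(sf, df[df["subfamily"] == sf]))
    rest = df[~df["subfamily"].isin(focal_subfamilies)]
    rows.append(one("rest_of_data_set", rest))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = {
    "tau_high": 0.70,
    "tau_low": 0.30,
    "min_tips": 4,
    "call_thresh": 8.0,
    "proximal_thresh": 10.0,
    "consensus_majority": 0.5,
    "anchor_window": 3,
    "e_max": 1e-10,
    "cov_min": 0.75,
}


def load_config(path) -> dict:
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


def run_pipeline(config_path, out_dir: Optional[str] = None) -> dict:
    """Run every stage described by a config file and write a JSON report.

    The report records the package version, the resolved thresholds and
    seed, and per-stage results; any stage failure raises
    :class:`PipelineError` tagged with the stage name (partial output is
    written to ``report.partial.json`` so it can never be mistaken for a
    complete report).
    """
    cfg = load_config(config_path)
    out_dir = out_dir or cfg.get("out_dir") or "zpevol_out"
    os.makedirs(out_dir, exist_ok=True)
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds", {}))
    seed = int(cfg.get("seed", 0))
    report: dict = {
        "version": __version__,
        "seed": seed,
        "thresholds": thresholds,
        "stages": {},
    }

    def fail(stage: str, exc: Exception) -> "PipelineError":
        partial = os.path.join(out_dir, "report.partial.json")
        with open(partial, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
        return PipelineError(f"[{stage}] {exc}")

    # --- stage: inputs -----------------------------------------------------
    try:
        if "synthetic" in cfg:
            spec_kwargs = dict(cfg["synthetic"])
            spec_kwargs.setdefault("seed", seed)
            if "loss_subfamilies" in spec_kwargs:
                spec_kwargs["loss_subfamilies"] = tuple(
                    (int(a), str(b)) for a, b in spec_kwargs["loss_subfamilies"]
                )
            spec = SyntheticSpec(**spec_kwargs)
            bundle = make_fixture_bundle(spec, os.path.join(out_dir, "bundle"))
            replicates = bundle.replicates
            structures = bundle.structures
            feature_df = pd.DataFrame(bundle.features)
            truth = bundle.truth
            report["stages"]["synthesize"] = {
                "n_tips": len(truth.tip_types),
                "n_replicates": len(replicates),
            }
        else:
            truth = None
            structures = {}
            paths = cfg.get("alignments", [])
            if not paths:
                raise ValueError("config needs either 'synthetic' or 'alignments'")
            replicates = [
                read_alignment(p, replicate_id=f"rep{i}") for i, p in enumerate(paths)
            ]
            feature_df = (
                pd.read_csv(cfg["features"], sep="\t") if "features" in cfg else None
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise fail("inputs", exc) from exc

    # --- stage: profiles ---------------------------------------------------
    try:
        anchors = tuple(cfg.get("anchors", DEFAULT_ANCHORS))
        domain_maps = [
            locate_domain_map(a, anchors, window=thresholds["anchor_window"])
            for a in replicates
        ]
        consensus_seq, cys_count = consensus_sequence(replicates[0])
        profiles = mean_gap_profiles(replicates, domain_maps)
        pd.DataFrame(gap_profile_table(profiles.values())).to_csv(
            os.path.join(out_dir, "gap_profiles.tsv"), sep="\t", index=False
        )
        report["stages"]["profiles"] = {
            "n_cols_rep0": replicates[0].n_cols,
            "consensus_cysteines": cys_count,
            "anchors": list(anchors),
        }
    except Exception as exc:
        raise fail("profiles", exc) from exc

    # --- stage: trees ------------------------------------------------------
    try:
        if "trees" in cfg:
            trees: List[Tree] = []
            for p in cfg["trees"]:
                trees.extend(read_newick_trees(p))
        else:
            logger.info("no trees supplied; building NJ trees per replicate")
            trees = [nj_tree(a.rows) for a in replicates]
        report["stages"]["trees"] = {"n_trees": len(trees), "source": "input" if "trees" in cfg else "nj"}
    except Exception as exc:
        raise fail("trees", exc) from exc

    # --- stage: consensus --------------------------------------------------
    try:
        if len(trees) >= 2:
            sup = majority_rule_consensus(trees)
            write_newick(
                sup.tree,
                os.path.join(out_dir, "consensus.nwk"),
            )
            pd.DataFrame(sup.support_table()).to_csv(
                os.path.join(out_dir, "branch_support.tsv"), sep="\t", index=False
            )
            brps = [b.brp for b in sup.branches]
            tbes = [b.tbe for b in sup.branches]
            rf_pairs = [
                rf_normalized(trees[i], trees[j])
                for i in range(min(len(trees), 5))
                for j in range(i + 1, min(len(trees), 5))
            ]
            report["stages"]["consensus"] = {
                "n_branches": len(sup.branches),
                "brp_min": min(brps) if brps else None,
                "tbe_min": min(tbes) if tbes else None,
                "rf_normalized_range": [min(rf_pairs), max(rf_pairs)] if rf_pairs else None,
            }
        else:
            logger.info("single tree: consensus stage skipped")
            report["stages"]["consensus"] = {"skipped": "only one tree supplied"}
        # rooting and the loss scan work on the focal (first-replicate)
        # tree, which carries branch lengths; the consensus tree does not
        main_tree = trees[0]
    except Exception as exc:
        raise fail("consensus", exc) from exc

    # --- stage: rooting ----------------------------------------------------
    try:
        comparison = root_comparison(main_tree)
        rooted, best, _ = mad_root(main_tree)
        write_newick(rooted, os.path.join(out_dir, "rooted.nwk"))
        report["stages"]["rooting"] = {
            "mad_deviation": best.deviation,
            "roots_agree": comparison.same_branch,
        }
    except Exception as exc:
        raise fail("rooting", exc) from exc

    # --- stage: loss scan --------------------------------------------------
    try:
        annotated = annotate_tips(rooted, profiles)
        calls, outliers = detect_loss_clades(
            annotated,
            "ZP-N",
            tau_high=thresholds["tau_high"],
            tau_low=thresholds["tau_low"],
            min_tips=int(thresholds["min_tips"]),
        )
        pd.DataFrame(
            [
                {
                    "tips": ";".join(sorted(c.clade_tips)),
                    "domain": c.domain_id,
                    "median_gap": c.clade_median_gap,
                    "other_median_gap": c.other_domain_median_gap,
                    "n_tips": c.n_tips,
                }
                for c in calls
            ]
        ).to_csv(os.path.join(out_dir, "loss_calls.tsv"), sep="\t", index=False)
        report["stages"]["loss_scan"] = {
            "n_calls": len(calls),
            "n_outliers": len(outliers),
            "call_tip_sets": [sorted(c.clade_tips) for c in calls],
        }
        if truth is not None:
            called = set().union(*(c.clade_tips for c in calls)) if calls else set()
            report["stages"]["loss_scan"]["matches_truth"] = called == truth.loss_tips
    except Exception as exc:
        raise fail("loss_scan", exc) from exc

    # --- stage: connectivity -----------------------------------------------
    try:
        rep0 = replicates[0]
        types: Dict[str, str] = {}
        for name in rep0.names():
            call = classify_type(presence_vector(rep0.sequence(name)), module=name)
            types[name] = call.type_
        changes, _ = fitch_parsimony(rooted, types)
        conn = {"type_counts": {t: sum(1 for v in types.values() if v == t) for t in sorted(set(types.values()))},
                "parsimony_changes": changes}
        if truth is not None:
            conn["type_recovery"] = float(
                np.mean([types[n] == truth.tip_types[n] for n in types])
            )
        report["stages"]["connectivity"] = conn
    except Exception as exc:
        raise fail("connectivity", exc) from exc

    # --- stage: summaries --------------------------------------------------
    try:
        if feature_df is not None:
            focal_cfg = cfg.get("focal_subfamilies")
            if focal_cfg is None and truth is not None:
                focal_cfg = sorted(
                    {f"SF{truth.subfamily_of[t]}" for t in truth.loss_tips}
                )
            if focal_cfg:
                summary = summarize_features(feature_df, focal_cfg)
                summary.to_csv(
                    os.path.join(out_dir, "feature_prevalence.tsv"),
                    sep="\t",
                    index=False,
                )
                report["stages"]["summaries"] = {
                    "groups": summary["group"].tolist(),
                }
    except Exception as exc:
        raise fail("summaries", exc) from exc

    report_path = os.path.join(out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return report
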