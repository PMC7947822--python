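"""Applying trained models to real data.

This module consumes already-built upstream products — per-gene expression
tables (tab-separated, log10 scale or flagged linear), duplicate
parent/child/ancestor triplet lists, single-copy ortholog tables, and Newick
gene trees with branch lengths — extracts scaled duplication times, tailors a
training set to the empirical single-copy background, trains the classifier
and predictor, and emits per-duplicate retention calls and parameter
estimates.  Ortholog identification, alignment, and tree inference happen
upstream and are out of scope here.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .background import SingleCopyGene, background_summaries
from .experiments import PARAM_NAMES, generate_training_set
from .features import FEATURE_VERSION, assemble_feature_matrix
from .netmodel import NetworkConfig, classify, predict_parameters, train
from .ou_model import CLASS_LABELS, ParameterRanges

logger = logging.getLogger(__name__)

__all__ = [
    "DuplicateTriplet",
    "TreeTimeEstimate",
    "read_expression_table",
    "read_duplicate_triplets",
    "read_single_copy_table",
    "extract_tree_times",
    "run_empirical_pipeline",
]

#: clamp for degenerate scaled duplication times
TPC_EPS = 1e-3


@dataclass(frozen=True)
class DuplicateTriplet:
    """Parent/child duplicate pair plus the single-copy ancestral ortholog."""

    parent_id: str
    child_id: str
    ancestor_id: str
    tree_file: str | None = None

    def __post_init__(self) -> None:
        ids = {self.parent_id, self.child_id, self.ancestor_id}
        if len(ids) != 3:
            raise ValueError(f"triplet IDs must be distinct, got {ids}")


@dataclass(frozen=True)
class TreeTimeEstimate:
    """Scaled duplication time extracted from a gene tree (root height 1)."""

    t_pc: float
    raw_tpc: float
    raw_tpca: float
    t_pca: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.t_pc < 1.0:
            raise ValueError(f"t_pc must be in (0, 1), got {self.t_pc}")


def read_expression_table(
    path: str | Path,
    log_transform: bool = False,
    low_expression_threshold: float | None = None,
) -> pd.DataFrame:
    """Read a tab-separated expression table (gene_id + m numeric columns).

    ``log_transform=True`` flags a linear-scale file: values are
    log10-transformed on read (zeros/negatives are a hard error).  When a
    threshold is given, genes whose expression is below it in every tissue are
    dropped and the count logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected gene_id plus >=1 expression column")
    gene_col = df.columns[0]
    dup = df[gene_col].duplicated()
    if dup.any():
        line = int(dup.idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}:{line}: duplicate gene ID {df[gene_col][dup].iloc[0]!r}")
    expr = df.set_index(gene_col)
    for col in expr.columns:
        coerced = pd.to_numeric(expr[col], errors="coerce")
        bad = coerced.isna() & expr[col].notna()
        if bad.any() or expr[col].isna().any():
            row = int(np.flatnonzero(coerced.isna())[0]) + 2
            raise ValueError(f"{path}:{row}: non-numeric value in column {col!r}")
        expr[col] = coerced
    if low_expression_threshold is not None:
        keep = (expr >= low_expression_threshold).any(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("%s: dropped %d gene(s) below %g in all tissues",
                        path, n_dropped, low_expression_threshold)
        expr = expr[keep]
    if log_transform:
        if (expr <= 0).any().any():
            raise ValueError(f"{path}: non-positive values cannot be log10-transformed")
        expr = np.log10(expr)
    return expr


def read_duplicate_triplets(path: str | Path) -> list[DuplicateTriplet]:
    """TSV with columns parent_id, child_id, ancestor_id and optional tree_file."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"parent_id", "child_id", "ancestor_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    has_tree = "tree_file" in df.columns
    return [
        DuplicateTriplet(
            parent_id=r.parent_id,
            child_id=r.child_id,
            ancestor_id=r.ancestor_id,
            tree_file=getattr(r, "tree_file", None) if has_tree else None,
        )
        for r in df.itertuples()
    ]


def read_single_copy_table(path: str | Path, m: int) -> list[SingleCopyGene]:
    """TSV with gene_id, then m species-1 columns, then m species-2 columns."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 1 + 2 * m:
        raise ValueError(f"{path}: expected 1 + 2*{m} columns, got {df.shape[1]}")
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    return [SingleCopyGene(s1=row[:m], s2=row[m:]) for row in vals]


def extract_tree_times(
    newick_path: str | Path,
    triplet: DuplicateTriplet,
    strict_ultrametric: bool = False,
) -> TreeTimeEstimate:
    """Scaled duplication time from a gene tree containing the three tips.

    The tree is implicitly rooted on the ancestor tip's pendant branch, with
    the root placed so the ancestor-side and duplicate-side mean tip heights
    agree.  Node heights are mean root-to-tip path lengths below the node
    (trees need not be ultrametric), so with pairwise path distances d:

        TPC  = d(P,C) / 2
        TPCA = (len_A + TPC) / 2,  len_A = [d(P,A) + d(C,A) - d(P,C)] / 2

    and t_pc = TPC / TPCA, clamped away from {0, 1}.
    """
    tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    missing = [
        g for g in (triplet.parent_id, triplet.child_id, triplet.ancestor_id)
        if g not in taxa
    ]
    if missing:
        raise ValueError(
            f"{newick_path}: tip(s) {missing} missing for triplet "
            f"({triplet.parent_id},{triplet.child_id},{triplet.ancestor_id})"
        )
    d_pc = pdm.patristic_distance(taxa[triplet.parent_id], taxa[triplet.child_id])
    d_pa = pdm.patristic_distance(taxa[triplet.parent_id], taxa[triplet.ancestor_id])
    d_ca = pdm.patristic_distance(taxa[triplet.child_id], taxa[triplet.ancestor_id])

    len_p = (d_pc + d_pa - d_ca) / 2.0
    len_c = (d_pc + d_ca - d_pa) / 2.0
    len_a = (d_pa + d_ca - d_pc) / 2.0
    if len_a < 0 or len_p < -1e-9 or len_c < -1e-9:
        raise ValueError(
            f"{newick_path}: distances violate the ((P,C),A) topology for triplet "
            f"({triplet.parent_id},{triplet.child_id},{triplet.ancestor_id})"
        )
    if strict_ultrametric and abs(len_p - len_c) > 1e-9:
        raise ValueError(f"{newick_path}: tree is not ultrametric below the (P,C) node")

    tpc = d_pc / 2.0
    tpca = (len_a + tpc) / 2.0
    if tpca <= 0:
        raise ValueError(f"{newick_path}: nonpositive root height")
    t_pc = tpc / tpca
    if not TPC_EPS < t_pc < 1.0 - TPC_EPS:
        warnings.warn(
            f"{newick_path}: degenerate scaled duplication time {t_pc:.3g}; clamped",
            stacklevel=2,
        )
        t_pc = float(np.clip(t_pc, TPC_EPS, 1.0 - TPC_EPS))
    return TreeTimeEstimate(t_pc=t_pc, raw_tpc=tpc, raw_tpca=tpca)


def _lookup_expression(
    expr: pd.DataFrame, gene_ids: list[str], source: str
) -> np.ndarray:
    missing = [g for g in gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"gene(s) missing from {source} expression table: {missing}")
    return expr.loc[gene_ids].to_numpy(dtype=float)


def run_empirical_pipeline(
    expr_species1: str | Path,
    expr_species2: str | Path,
    duplicates: str | Path,
    single_copy: str | Path,
    trees_dir: str | Path,
    out_dir: str | Path,
    rng_seed: int = 0,
    m: int | None = None,
    n_per_class: int = 10_000,
    config_overrides: dict | None = None,
    classifier_reg: tuple[float, float] = (1.778e-4, 1.0),
    predictor_reg: tuple[float, float] = (7.499e-8, 0.8),
    log_transform: bool = False,
    low_expression_threshold: float | None = None,
) -> pd.DataFrame:
    """End-to-end empirical analysis.

    Builds the single-copy background, extracts tree times, generates a
    tailored balanced training set, trains the classifier and predictor
    (``classifier_reg``/``predictor_reg`` are (lambda, gamma) pairs), then
    scores every duplicate triplet.  Writes ``calls.tsv``, ``params.tsv`` and
    ``manifest.json`` under ``out_dir`` and returns the calls table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)

    expr1 = read_expression_table(expr_species1, log_transform, low_expression_threshold)
    expr2 = read_expression_table(expr_species2, log_transform, low_expression_threshold)
    if m is None:
        m = expr1.shape[1]
    if expr1.shape[1] != m or expr2.shape[1] != m:
        raise ValueError("expression tables disagree on the number of tissues")
    trips = read_duplicate_triplets(duplicates)
    singles = read_single_copy_table(single_copy, m)
    background = background_summaries(singles)

    trees_dir = Path(trees_dir)
    times = []
    for trip in trips:
        tree_file = trip.tree_file or f"{trip.parent_id}.nwk"
        tree_path = trees_dir / tree_file
        if not tree_path.exists():
            raise ValueError(f"missing gene tree for triplet {trip.parent_id}: {tree_path}")
        times.append(extract_tree_times(tree_path, trip))
    tpc_pool = np.array([t.t_pc for t in times])

    training = generate_training_set(
        background,
        n_per_class=n_per_class,
        m=m,
        tree_time_pool=tpc_pool,
        ranges=ParameterRanges(),
        rng_seed=rng,
    )
    overrides = config_overrides or {}
    clf_cfg = NetworkConfig(
        task="classify",
        input_dim=training.X.shape[1],
        output_dim=5,
        lambda_=classifier_reg[0],
        gamma=classifier_reg[1],
        **overrides,
    )
    pred_cfg = NetworkConfig(
        task="predict",
        input_dim=training.X.shape[1],
        output_dim=5 * m,
        lambda_=predictor_reg[0],
        gamma=predictor_reg[1],
        **overrides,
    )
    clf = train(training.X, training.class_labels, clf_cfg,
                rng_seed=int(rng.integers(2**31 - 1)))
    pred = train(training.X, training.params, pred_cfg,
                 rng_seed=int(rng.integers(2**31 - 1)))

    e_p = _lookup_expression(expr1, [t.parent_id for t in trips], "species-1")
    e_c = _lookup_expression(expr1, [t.child_id for t in trips], "species-1")
    e_a = _lookup_expression(expr2, [t.ancestor_id for t in trips], "species-2")
    triplets = np.empty((len(trips), 3 * m))
    triplets[:, 0::3] = e_p
    triplets[:, 1::3] = e_c
    triplets[:, 2::3] = e_a
    X = assemble_feature_matrix(triplets, tpc_pool, background)

    probs, called = classify(clf, X)
    estimates = predict_parameters(pred, X)

    calls = pd.DataFrame(
        {
            "parent_id": [t.parent_id for t in trips],
            "child_id": [t.child_id for t in trips],
            "ancestor_id": [t.ancestor_id for t in trips],
            "t_pc": tpc_pool,
            "call": [CLASS_LABELS[c] for c in called],
        }
    )
    for i, name in enumerate(CLASS_LABELS):
        calls[f"prob_{name}"] = probs[:, i]
    calls.to_csv(out_dir / "calls.tsv", sep="\t", index=False)

    param_cols = [f"{p}_t{j + 1}" for j in range(m) for p in PARAM_NAMES]
    params_df = pd.DataFrame(estimates, columns=param_cols)
    params_df.insert(0, "parent_id", calls["parent_id"])
    params_df.to_csv(out_dir / "params.tsv", sep="\t", index=False)

    manifest = {
        "package_version": __version__,
        "feature_version": FEATURE_VERSION,
        "seed": rng_seed,
        "m": m,
        "n_duplicates": len(trips),
        "n_single_copy": len(singles),
        "n_per_class": n_per_class,
        "classifier_reg": list(classifier_reg),
        "predictor_reg": list(predictor_reg),
        "config_overrides": {k: v for k, v in overrides.items()},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return calls
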