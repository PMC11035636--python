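"""End-to-end pipeline: read → recovery-correct → merge adducts →
annotate → network → composition → information theory → statistics.

A single declarative :class:`RunConfig` carries every stage parameter;
the defaults are the study's stated settings (cosine 0.5, ≥5 matched
ions, top-10 neighbors, analog Δm/z ≤ 500, component cap 100, presence
threshold 0.01% of total lipids).  A run writes all stage outputs plus
a JSON manifest (package version, parameters, input checksums) that
suffices to re-run identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_all, load_default_rules, load_rules
from .composition import (
    PRESENCE_THRESHOLD,
    aggregate_classes,
    call_presence,
    correct_recovery,
    merge_adducts,
    relative_abundance,
    upset_counts_frame,
)
from .infotheory import bootstrap_errorbars, compute_indices
from .io import read_feature_table, read_mgf
from .networking import build_network, network_summary
from .stats import hellinger, pca, tukey_hsd, zscore_cluster

logger = logging.getLogger("halolipidome")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    mgf_path: str
    table_path: str
    metadata_path: str
    out_dir: str
    internal_standard_id: str | None = "IS_DGTS_d9"
    rules_path: str | None = None
    # networking
    cosine_min: float = 0.5
    min_matched: int = 5
    top_k: int = 10
    max_delta: float = 500.0
    max_component: int = 100
    fragment_tol: float = 0.01
    # composition
    adduct_mz_tol: float = 0.01
    adduct_rt_tol: float = 10.0
    presence_threshold: float = PRESENCE_THRESHOLD
    presence_mode: str = "mean"
    # information theory
    lipid_universe: str = "annotated"  # "annotated" | "all"
    # statistics
    alpha: float = 0.05
    tukey_class: str = "PGP-Me"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write outputs under ``config.out_dir``.

    Returns a summary dict (also written as ``manifest.json``).  Any
    stage failure raises with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        "mgf": Path(config.mgf_path),
        "table": Path(config.table_path),
        "metadata": Path(config.metadata_path),
    }
    for name, path in inputs.items():
        if not path.exists():
            raise FileNotFoundError(f"[input] missing {name} file: {path}")

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # annotate failures with the stage name
            raise RuntimeError(f"[{name}] {exc}") from exc

    spectra = stage("read_mgf", read_mgf, inputs["mgf"])
    table = stage("read_table", read_feature_table, inputs["table"], inputs["metadata"])
    logger.info("loaded %d spectra, table %dx%d", len(spectra), table.n_features, table.n_samples)

    if config.internal_standard_id and config.internal_standard_id in table.abundance.index:
        table = stage("recovery_correction", correct_recovery, table, config.internal_standard_id)
    merged, merge_report = stage(
        "adduct_merging", merge_adducts, table, config.adduct_mz_tol, config.adduct_rt_tol
    )
    merge_report.to_csv(out / "adduct_merges.csv", index=False)

    kept = set(merged.abundance.index)
    merged_spectra = [s for s in spectra if s.feature_id in kept]
    rules = load_rules(config.rules_path) if config.rules_path else load_default_rules()
    annotations = stage("annotation", annotate_all, merged_spectra, rules, config.fragment_tol)
    ann_frame = pd.DataFrame(
        {
            "feature_id": list(annotations),
            "lipid_class": [a.lipid_class for a in annotations.values()],
            "core": [a.core for a in annotations.values()],
            "isoprenoid_units": [a.isoprenoid_units for a in annotations.values()],
            "double_bonds": [a.double_bonds for a in annotations.values()],
            "formula": [a.annotated_formula for a in annotations.values()],
        }
    ).set_index("feature_id")
    ann_frame.to_csv(out / "annotations.csv")

    net = stage(
        "networking",
        build_network,
        merged_spectra,
        merged,
        cosine_min=config.cosine_min,
        min_matched=config.min_matched,
        top_k=config.top_k,
        max_delta=config.max_delta,
        max_component=config.max_component,
        fragment_tol=config.fragment_tol,
    )
    net.to_graphml(out / "network.graphml")
    net.to_edgelist_tsv(out / "network_edges.tsv")
    n_nodes, n_in_components, n_singletons = network_summary(net)

    profile = stage("composition", relative_abundance, merged)
    profile.relative_abundance.to_csv(out / "relative_abundance.csv", index_label="feature_id")
    class_ab = stage("class_aggregation", aggregate_classes, profile, annotations)
    class_ab.to_csv(out / "class_abundance.csv", index_label="lipid_class")
    presence = stage(
        "presence", call_presence, profile,
        threshold=config.presence_threshold, mode=config.presence_mode,
    )
    presence.to_csv(out / "presence.csv", index_label="feature_id")
    upset = upset_counts_frame(presence)
    upset.to_csv(out / "upset_counts.csv", index=False)

    if config.lipid_universe == "annotated":
        universe = [f for f, a in annotations.items() if a.lipid_class != "unknown"]
    else:
        universe = None
    indices = stage("infotheory", compute_indices, profile, universe)
    pd.DataFrame({"H": indices.H, "delta": indices.delta}).to_csv(
        out / "diversity_specialization.csv", index_label="sample_id"
    )
    indices.S.to_csv(out / "lipid_specificity.csv", index_label="feature_id")
    groups = merged.groups()
    errorbars = bootstrap_errorbars(profile, groups, universe, n_boot=200, seed=config.seed)
    errorbars.to_csv(out / "group_errorbars.csv")

    X = profile.relative_abundance.T  # samples × features
    hell = stage("hellinger", hellinger, X)
    ordination = stage("pca", pca, hell)
    ordination.scores.to_csv(out / "pca_scores.csv", index_label="sample_id")
    ordination.loadings.to_csv(out / "pca_loadings.csv", index_label="feature_id")
    pd.Series(
        ordination.explained_variance_ratio,
        index=ordination.scores.columns,
        name="explained_variance_ratio",
    ).to_csv(out / "pca_variance.csv")

    clustering = stage("clustering", zscore_cluster, class_ab)
    clustering["Z"].to_csv(out / "class_zscores.csv", index_label="lipid_class")

    tukey_out = None
    if config.tukey_class in class_ab.index:
        sample_groups = merged.sample_meta["group"].astype(str)
        result = stage(
            "tukey",
            tukey_hsd,
            class_ab.loc[config.tukey_class].to_numpy(),
            sample_groups.to_numpy(),
            config.alpha,
        )
        result.pairwise.to_csv(out / "tukey_pairwise.csv", index=False)
        tukey_out = {"letters": result.letters}

    manifest = {
        "package": "halolipidome",
        "version": __version__,
        "python": platform.python_version(),
        "parameters": dataclasses.asdict(config),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
        "n_spectra": len(spectra),
        "n_features_merged": merged.n_features,
        "n_samples": merged.n_samples,
        "network": {
            "nodes": n_nodes,
            "in_components": n_in_components,
            "singletons": n_singletons,
            "edges": net.graph.number_of_edges(),
            "components_ge2": sum(1 for c in net.components if len(c) > 1),
        },
        "pc12_variance_pct": float(
            100.0 * ordination.explained_variance_ratio[: 2].sum()
        ),
        "tukey": tukey_out,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
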