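"""Abundance normalization, adduct merging and set-intersection analysis.

Peak areas are first corrected for sample recovery against a spiked
internal standard (DGTS-d9 in this system: every sample column is
divided by its standard response), protonated/ammoniated ion forms of
the same component ([M+H]+ / [M+NH4]+, Δm/z 17.02655) are merged by
summing their abundances, and per-sample responses are closed to
relative abundances.  Downstream summaries: lipid-class aggregation,
presence/absence calls at a relative-abundance threshold (default
0.01% of total lipids — a feature below the threshold is treated as
absent), and UpSet-style counts of features over group-membership
patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import LipidAnnotation
from .io import FeatureTable, ValidationError

__all__ = [
    "CompositionProfile",
    "NH4_H_DELTA",
    "PRESENCE_THRESHOLD",
    "correct_recovery",
    "merge_adducts",
    "relative_abundance",
    "aggregate_classes",
    "call_presence",
    "upset_counts",
]

#: Monoisotopic mass of NH3: the precursor gap between [M+H]+ and [M+NH4]+.
NH4_H_DELTA = 17.02655

#: Default presence threshold: 0.01% of total lipid relative abundance.
PRESENCE_THRESHOLD = 1e-4


@dataclass
class CompositionProfile:
    """Relative-abundance views of a feature table.

    ``relative_abundance`` columns each sum to 1 (or stay all-zero for
    an empty sample); ``class_abundance`` and ``presence`` are filled by
    :func:`aggregate_classes` and :func:`call_presence`.
    """

    relative_abundance: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    class_abundance: pd.DataFrame | None = None
    presence: pd.DataFrame | None = None


def correct_recovery(table: FeatureTable, internal_standard_id: str) -> FeatureTable:
    """Divide each sample column by its internal-standard response.

    The standard row is removed from the analytical table.  A zero or
    missing standard response is an error naming the offending sample.
    """
    ab = table.abundance
    if internal_standard_id not in ab.index:
        raise ValidationError(f"internal standard {internal_standard_id!r} not in table")
    standard = ab.loc[internal_standard_id]
    bad = standard[standard <= 0].index.tolist()
    if bad:
        raise ValidationError(
            f"internal standard {internal_standard_id!r} non-positive in samples: {bad}"
        )
    corrected = ab.drop(index=internal_standard_id).divide(standard, axis=1)
    return FeatureTable(
        abundance=corrected,
        feature_meta=table.feature_meta.drop(index=internal_standard_id, errors="ignore"),
        sample_meta=table.sample_meta.copy(),
    )


def merge_adducts(
    table: FeatureTable, mz_tol: float = 0.01, rt_tol: float = 10.0
) -> tuple[FeatureTable, pd.DataFrame]:
    """Merge paired [M+H]+ / [M+NH4]+ features into single components.

    A pair qualifies when the precursor difference is ``NH4_H_DELTA``
    within ``mz_tol`` and the retention times agree within ``rt_tol``
    seconds.  Ambiguous many-to-many candidates are resolved greedily by
    smallest mass error, then smallest Δrt.  The merged component keeps
    the [M+H]+ feature's id and sums the pair's abundances per sample;
    features with unknown adducts are never merged.  Returns the merged
    table and a report of the merges performed.
    """
    meta = table.feature_meta
    if "precursor_mz" not in meta.columns:
        raise ValidationError("feature metadata lacks 'precursor_mz' (needed for merging)")
    adduct = meta.get("adduct", pd.Series("unknown", index=meta.index))
    rt = meta.get("retention_time", pd.Series(0.0, index=meta.index)).astype(float)
    mz = meta["precursor_mz"].astype(float)

    protonated = [f for f in table.feature_ids if adduct.get(f) == "M+H"]
    ammoniated = [f for f in table.feature_ids if adduct.get(f) == "M+NH4"]
    candidates = []
    for h in protonated:
        for nh4 in ammoniated:
            mass_err = abs((mz[nh4] - mz[h]) - NH4_H_DELTA)
            rt_err = abs(rt[nh4] - rt[h])
            if mass_err <= mz_tol and rt_err <= rt_tol:
                candidates.append((mass_err, rt_err, h, nh4))
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))

    used_h: set[str] = set()
    used_n: set[str] = set()
    merges = []
    for mass_err, rt_err, h, nh4 in candidates:
        if h in used_h or nh4 in used_n:
            continue
        used_h.add(h)
        used_n.add(nh4)
        merges.append({"kept": h, "merged": nh4, "mass_error": mass_err, "rt_delta": rt_err})

    ab = table.abundance.copy()
    drop = []
    for m in merges:
        ab.loc[m["kept"]] += ab.loc[m["merged"]]
        drop.append(m["merged"])
    ab = ab.drop(index=drop)
    merged = FeatureTable(
        abundance=ab,
        feature_meta=meta.drop(index=drop),
        sample_meta=table.sample_meta.copy(),
    )
    report = pd.DataFrame(merges, columns=["kept", "merged", "mass_error", "rt_delta"])
    return merged, report


def relative_abundance(table: FeatureTable) -> CompositionProfile:
    """Close every sample column to proportions (sum 1).

    All-zero samples stay all-zero and trigger a warning.
    """
    ab = table.abundance
    totals = ab.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"samples with zero total abundance: {empty}", stacklevel=2)
    rel = ab.divide(totals.replace(0.0, np.nan), axis=1).fillna(0.0)
    return CompositionProfile(relative_abundance=rel, sample_meta=table.sample_meta.copy())


def aggregate_classes(
    profile: CompositionProfile, annotations: Mapping[str, LipidAnnotation]
) -> pd.DataFrame:
    """Sum relative abundances into a lipid-class × sample matrix.

    Unannotated features fall into class ``unknown``.  Per-sample class
    shares sum to 1 wherever the sample is non-empty.  The result is
    also stored on ``profile.class_abundance``.
    """
    rel = profile.relative_abundance
    labels = pd.Series(
        [annotations[f].lipid_class if f in annotations else "unknown" for f in rel.index],
        index=rel.index,
    )
    class_ab = rel.groupby(labels).sum()
    class_ab = class_ab.sort_index()
    profile.class_abundance = class_ab
    return class_ab


def _group_map(profile: CompositionProfile, groups: Mapping[str, Sequence[str]] | None) -> dict[str, list[str]]:
    if groups is None:
        if "group" not in profile.sample_meta.columns:
            raise ValidationError("no grouping given and sample metadata lacks 'group'")
        out: dict[str, list[str]] = {}
        for sample, grp in profile.sample_meta["group"].items():
            out.setdefault(str(grp), []).append(sample)
        return out
    return {g: list(s) for g, s in groups.items()}


def call_presence(
    profile: CompositionProfile,
    groups: Mapping[str, Sequence[str]] | None = None,
    threshold: float = PRESENCE_THRESHOLD,
    mode: str = "mean",
) -> pd.DataFrame:
    """Boolean presence per feature per group.

    A feature is present in a group when its replicate-mean relative
    abundance is >= ``threshold`` (``mode="mean"``, the default) or when
    any single replicate reaches the threshold (``mode="any"``).  A
    value exactly at the threshold counts as present (absence is defined
    as *less than* the threshold).
    """
    rel = profile.relative_abundance
    gmap = _group_map(profile, groups)
    for g, samples in gmap.items():
        if not samples:
            raise ValidationError(f"group {g!r} has no samples")
        missing = [s for s in samples if s not in rel.columns]
        if missing:
            raise ValidationError(f"group {g!r}: unknown samples {missing}")
    presence = pd.DataFrame(False, index=rel.index, columns=list(gmap))
    for g, samples in gmap.items():
        sub = rel[samples]
        if mode == "mean":
            presence[g] = sub.mean(axis=1) >= threshold
        elif mode == "any":
            presence[g] = (sub >= threshold).any(axis=1)
        else:
            raise ValueError(f"unknown presence mode {mode!r}")
    profile.presence = presence
    return presence


def upset_counts(presence: pd.DataFrame) -> dict[frozenset[str], int]:
    """Count features per exact group-membership pattern.

    Keys are frozensets of group names; a feature contributes to exactly
    one non-empty pattern (features absent everywhere contribute to
    none), so the counts partition the features present in >= 1 group.
    """
    if presence.shape[1] < 1:
        raise ValidationError("presence matrix needs at least one group")
    counts: dict[frozenset[str], int] = {}
    for _, row in presence.iterrows():
        pattern = frozenset(presence.columns[row.to_numpy(dtype=bool)])
        if pattern:
            counts[pattern] = counts.get(pattern, 0) + 1
    return counts


def upset_counts_frame(presence: pd.DataFrame) -> pd.DataFrame:
    """Long-format UpSet counts (one row per membership pattern)."""
    counts = upset_counts(presence)
    rows = [
        {"pattern": "&".join(sorted(p)), "degree": len(p), "count": c}
        for p, c in counts.items()
    ]
    return (
        pd.DataFrame(rows, columns=["pattern", "degree", "count"])
        .sort_values(["degree", "pattern"])
        .reset_index(drop=True)
    )
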