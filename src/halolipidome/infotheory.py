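"""Information-theoretic lipidome diversity and specialization indices.

For a frequency matrix P (m lipids × t samples, columns summing to 1):

* lipidome diversity  H_j = −Σ_i P_ij·log2(P_ij)      (Shannon entropy, bits)
* mean lipid frequency P_i = (1/t)·Σ_j P_ij
* lipid specificity    S_i = (1/t)·Σ_j (P_ij/P_i)·log2(P_ij/P_i)
* conditional term    S_ij = (P_ij/P_i)·log2(P_ij/P_i)
* lipidome specialization δ_j = Σ_i P_ij·S_i

with 0·log2(0) := 0 by continuity.  H_j is bounded by log2(m); S_i and
δ_j are bounded by log2(t): a lipid occurring in exactly one of t
samples attains S_i = log2(t), a lipid equally frequent everywhere has
S_i = 0, and δ_j is a convex combination of the S_i.  A highly
specialized sample concentrates its abundance on lipids found (almost)
nowhere else.

Base-2 logarithms throughout; every index is reported in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CompositionProfile
from .io import ValidationError

__all__ = [
    "FrequencyMatrix",
    "InfoTheoryResult",
    "frequency_matrix",
    "diversity",
    "specificity",
    "specialization",
    "compute_indices",
    "bootstrap_errorbars",
]


@dataclass
class FrequencyMatrix:
    """Column-stochastic lipid frequency matrix P (lipids × samples)."""

    P: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.P.to_numpy(dtype=float)
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValidationError("frequency matrix must be finite and non-negative")
        sums = values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("frequency matrix columns must sum to 1")

    @property
    def m(self) -> int:
        return self.P.shape[0]

    @property
    def t(self) -> int:
        return self.P.shape[1]

    def mean_frequency(self) -> pd.Series:
        """P_i: per-lipid mean frequency across samples."""
        return self.P.mean(axis=1)


@dataclass
class InfoTheoryResult:
    H: pd.Series            # per-sample diversity (bits)
    S: pd.Series            # per-lipid specificity (bits)
    S_cond: pd.DataFrame    # lipid × sample specificity terms (bits)
    delta: pd.Series        # per-sample specialization (bits)


def frequency_matrix(
    profile: CompositionProfile,
    universe: Sequence[str] | None = None,
) -> FrequencyMatrix:
    """Restrict relative abundances to a lipid universe and re-close columns.

    ``universe=None`` keeps all features.  Samples whose restricted
    total is zero are an error (their frequency column is undefined).
    """
    rel = profile.relative_abundance
    if universe is not None:
        keep = [f for f in rel.index if f in set(universe)]
        if not keep:
            raise ValidationError("lipid universe shares no features with the profile")
        rel = rel.loc[keep]
    totals = rel.sum(axis=0)
    empty = totals[totals <= 0].index.tolist()
    if empty:
        raise ValidationError(f"samples with zero total in the lipid universe: {empty}")
    return FrequencyMatrix(P=rel.divide(totals, axis=1))


def _xlog2x(x: np.ndarray) -> np.ndarray:
    """x·log2(x) with the 0·log2(0) := 0 convention."""
    out = np.zeros_like(x, dtype=float)
    mask = x > 0
    out[mask] = x[mask] * np.log2(x[mask])
    return out


def diversity(freq: FrequencyMatrix) -> pd.Series:
    """Per-sample Shannon diversity H_j in bits."""
    values = freq.P.to_numpy(dtype=float)
    H = -_xlog2x(values).sum(axis=0)
    return pd.Series(H, index=freq.P.columns, name="H")


def specificity(freq: FrequencyMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Per-lipid specificity S_i and the per-sample terms S_ij.

    Lipids with zero mean frequency (absent everywhere) are dropped with
    a warning — their specificity is undefined.
    """
    P = freq.P
    Pi = P.mean(axis=1)
    absent = Pi[Pi == 0].index.tolist()
    if absent:
        warnings.warn(f"dropping lipids absent in every sample: {len(absent)}", stacklevel=2)
        P = P.drop(index=absent)
        Pi = Pi.drop(index=absent)
    ratio = P.divide(Pi, axis=0).to_numpy(dtype=float)
    terms = _xlog2x(ratio)
    S_cond = pd.DataFrame(terms, index=P.index, columns=P.columns)
    S = pd.Series(terms.mean(axis=1), index=P.index, name="S")
    return S, S_cond


def specialization(freq: FrequencyMatrix, S: pd.Series) -> pd.Series:
    """Per-sample specialization δ_j = Σ_i P_ij·S_i (bits).

    ``S`` must cover every lipid that carries frequency mass; lipids
    missing from ``S`` are tolerated only if absent everywhere (the
    convention under which :func:`specificity` drops them).
    """
    stray = S.index.difference(freq.P.index)
    if len(stray):
        raise ValidationError(f"specificity given for unknown lipids: {list(stray)[:5]}")
    extra = freq.P.index.difference(S.index)
    if len(extra) and not (freq.P.loc[extra].to_numpy() == 0).all():
        raise ValidationError(
            "specificity missing for lipids with non-zero frequency "
            f"(e.g. {list(extra)[:5]})"
        )
    P = freq.P.loc[S.index]
    delta = P.mul(S, axis=0).sum(axis=0)
    delta.name = "delta"
    return delta


def compute_indices(
    profile: CompositionProfile,
    universe: Sequence[str] | None = None,
) -> InfoTheoryResult:
    """Convenience wrapper: H, S, S_ij and δ from a composition profile."""
    freq = frequency_matrix(profile, universe)
    H = diversity(freq)
    S, S_cond = specificity(freq)
    delta = specialization(freq, S)
    return InfoTheoryResult(H=H, S=S, S_cond=S_cond, delta=delta)


def bootstrap_errorbars(
    profile: CompositionProfile,
    groups: Mapping[str, Sequence[str]],
    universe: Sequence[str] | None = None,
    n_boot: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Group mean ± sd of H and δ across replicates.

    The sd of single-replicate groups is reported as missing (NaN),
    never as zero.  With ``n_boot > 0``, a seeded bootstrap over
    replicates adds ``H_boot_sd`` / ``delta_boot_sd`` columns
    (reproducible bit-for-bit for a fixed seed).
    """
    result = compute_indices(profile, universe)
    rng = np.random.default_rng(seed)
    rows = []
    for group, samples in groups.items():
        samples = list(samples)
        missing = [s for s in samples if s not in result.H.index]
        if missing:
            raise ValidationError(f"group {group!r}: unknown samples {missing}")
        H = result.H[samples]
        delta = result.delta[samples]
        row = {
            "group": group,
            "n": len(samples),
            "H_mean": float(H.mean()),
            "H_sd": float(H.std(ddof=1)) if len(samples) > 1 else np.nan,
            "delta_mean": float(delta.mean()),
            "delta_sd": float(delta.std(ddof=1)) if len(samples) > 1 else np.nan,
        }
        if n_boot > 0:
            idx = rng.integers(0, len(samples), size=(n_boot, len(samples)))
            H_means = H.to_numpy()[idx].mean(axis=1)
            d_means = delta.to_numpy()[idx].mean(axis=1)
            row["H_boot_sd"] = float(H_means.std(ddof=0))
            row["delta_boot_sd"] = float(d_means.std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
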