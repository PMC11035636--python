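"""Ground-truthed synthetic lipidome generator.

Emulates the statistical structure of a haloarchaeal symbiont–host
co-cultivation study: three culture conditions (pure host, pure
symbiont, co-culture) sampled over a timepoint series with technical
replicates; ~246 lipid species spread over the archaeal lipid class
taxonomy; group-exclusive species blocks (the symbiont carrying a
strict subset of host lipids plus a few private menaquinones); planted
per-group class-share vectors (e.g. PGP-Me dominating the symbiont at
~44% of total lipids while bacterioruberin is nearly excluded);
paired [M+H]+/[M+NH4]+ adduct features; a spiked internal-standard row;
and multiplicative log-normal replicate noise.

MS² spectra are generated from the same rule templates the annotation
module ships: class-diagnostic head-group reporter ions, family-shared
core fragments (the AR ion at m/z 653.681 and the lysoAR-glycerol ion
at 373.368 for bilayer lipids), a neutral-loss (water) peak that tracks
the precursor, and two low-mass "gradient" peaks whose intensities
rotate slowly along the within-class species series, so spectral
similarity decays smoothly with structural distance — same-class
spectra network together, different classes never share the five
matched peaks an edge requires.

All randomness flows from a single integer seed through named
sub-streams, so a design realizes bit-identically for a fixed seed.
Ground truth (true annotations, presence sets, class shares, noiseless
frequency profile and the implied diversity/specialization ranking) is
returned alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    CHAIN_EXTENSION_MASS,
    H2_MASS,
    ISOPRENE_UNIT_MASS,
    METHYLENE_MASS,
    DiagnosticRule,
    LipidAnnotation,
    load_default_rules,
    load_family_fragments,
)
from .composition import NH4_H_DELTA, CompositionProfile
from .io import FeatureTable, MsSpectrum

__all__ = ["SimulationDesign", "default_design", "simulate_lipidome", "simulate_spectra"]

WATER_MASS = 18.01056
INTERNAL_STANDARD_ID = "IS_DGTS_d9"

#: Species counts per class; the totals track the printed class taxonomy
#: (246 species overall) with the undetailed remainder assigned to the
#: menaquinone subtypes, PA and squalene.
DEFAULT_CLASS_SPECIES = {
    "AR": 8, "PG": 25, "PGS": 13, "PA": 4, "PGP-Me": 22, "PGPG": 11,
    "CL": 41, "1G": 2, "2G": 2, "S": 3, "MK": 39, "DMK": 25, "MMK": 20,
    "DMMK": 14, "bacterioruberin": 15, "squalene": 2,
}

#: Group-exclusivity blocks: membership pattern -> species count.
#: Host carries 165 species, the symbiont a 110-species subset-like
#: complement, co-cultures the widest set; 86 species are common to all,
#: 20 occur in host and co-culture but never the symbiont, and 3 are
#: private to the symbiont.
DEFAULT_EXCLUSIVITY = {
    ("host", "symbiont", "coculture"): 86,
    ("host", "coculture"): 20,
    ("host", "symbiont"): 14,
    ("host",): 45,
    ("coculture",): 71,
    ("symbiont",): 3,
    ("symbiont", "coculture"): 7,
}

_HOST_SHARES = {
    "AR": 0.030, "PG": 0.140, "PGS": 0.070, "PA": 0.010, "PGP-Me": 0.170,
    "PGPG": 0.050, "CL": 0.150, "1G": 0.025, "2G": 0.025, "S": 0.025,
    "MK": 0.092, "DMK": 0.060, "MMK": 0.050, "DMMK": 0.040,
    "bacterioruberin": 0.028, "squalene": 0.005,
}
_SYMBIONT_SHARES = {
    "AR": 0.020, "PG": 0.200, "PGS": 0.050, "PA": 0.005, "PGP-Me": 0.440,
    "PGPG": 0.030, "CL": 0.020, "1G": 0.012, "2G": 0.012, "S": 0.012,
    "MK": 0.090, "DMK": 0.045, "MMK": 0.030, "DMMK": 0.020,
    "bacterioruberin": 0.002, "squalene": 0.002,
}
_COCULTURE_SHARES = {
    "AR": 0.025, "PG": 0.200, "PGS": 0.060, "PA": 0.008, "PGP-Me": 0.250,
    "PGPG": 0.040, "CL": 0.010, "1G": 0.018, "2G": 0.018, "S": 0.018,
    "MK": 0.126, "DMK": 0.070, "MMK": 0.055, "DMMK": 0.040,
    "bacterioruberin": 0.036, "squalene": 0.004,
}

#: Smallest planted species-level relative abundance; kept above the
#: 0.01% presence threshold so planted presence is exact at zero noise.
_SPECIES_SHARE_FLOOR = 1.5e-4


def _normalize(shares: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(shares.values()))
    return {k: v / total for k, v in shares.items()}


@dataclass
class SimulationDesign:
    """Parameters of one synthetic study.

    ``class_shares`` vectors must each sum to 1; ``exclusivity`` block
    counts must sum to the total species count of ``class_species``.
    """

    groups: tuple[str, ...] = ("host", "symbiont", "coculture")
    timepoints_h: tuple[float, ...] = (0.0, 6.0, 12.0, 24.0, 48.0)
    replicates: int = 3
    class_species: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SPECIES)
    )
    exclusivity: dict[tuple[str, ...], int] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSIVITY)
    )
    class_shares: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "host": _normalize(_HOST_SHARES),
            "symbiont": _normalize(_SYMBIONT_SHARES),
            "coculture": _normalize(_COCULTURE_SHARES),
        }
    )
    abundance_sigma: float = 0.25       # log-normal sd of replicate noise
    adduct_probability: float = 0.5     # chance a species shows an [M+NH4]+ twin
    adduct_split: float = 0.7           # abundance fraction on the [M+H]+ form
    mz_jitter_sd: float = 0.002         # Th, fragment m/z jitter
    spurious_peak_rate: float = 1.0     # mean spurious peaks per spectrum
    total_abundance: float = 1e8        # per-sample total peak area scale
    internal_standard_level: float = 1e6
    seed: int = 0

    def validate(self) -> None:
        total_species = sum(self.class_species.values())
        block_total = sum(self.exclusivity.values())
        if block_total != total_species:
            raise ValueError(
                f"exclusivity blocks cover {block_total} species, design has {total_species}"
            )
        seen: set[str] = set()
        for pattern in self.exclusivity:
            unknown = set(pattern) - set(self.groups)
            if unknown:
                raise ValueError(f"exclusivity pattern names unknown groups: {unknown}")
        for grp in self.groups:
            if grp not in self.class_shares:
                raise ValueError(f"no class-share vector for group {grp!r}")
            total = sum(self.class_shares[grp].values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"class shares of {grp!r} sum to {total}, not 1")
        for p in (self.adduct_probability, self.adduct_split):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.abundance_sigma < 0 or self.mz_jitter_sd < 0 or self.spurious_peak_rate < 0:
            raise ValueError("noise parameters must be non-negative")


def default_design(seed: int = 0, **overrides) -> SimulationDesign:
    """The default study-scale design (246 species, 3 × 5 × 3 samples)."""
    design = replace(SimulationDesign(seed=seed), **overrides)
    design.validate()
    return design


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["allocation", "weights", "adducts", "abundance", "spectra"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _generating_rules(rules: Sequence[DiagnosticRule]) -> dict[str, DiagnosticRule]:
    out: dict[str, DiagnosticRule] = {}
    for rule in rules:
        if rule.generate and rule.lipid_class not in out:
            out[rule.lipid_class] = rule
    return out


def _species_precursor(rule: DiagnosticRule, k: int) -> tuple[float, LipidAnnotation]:
    """Precursor m/z and true annotation of the k-th species of a class."""
    cls = rule.lipid_class
    if rule.decode == "mk":
        n = 4 + k // 3
        m = max(0, n + (0, -1, 1)[k % 3])
        mz = rule.base_mz + (n - 8) * ISOPRENE_UNIT_MASS + (n - m) * H2_MASS
        ann = LipidAnnotation(
            lipid_class=cls, core="none", isoprenoid_units=n, double_bonds=m,
            rule_name=rule.name,
        )
    elif rule.decode == "bilayer":
        ext, methyl = k // 4, k % 4
        mz = rule.base_mz + CHAIN_EXTENSION_MASS * ext + METHYLENE_MASS * methyl
        ann = LipidAnnotation(
            lipid_class=cls, core="EXT-AR" if ext > 0 else "AR", rule_name=rule.name,
        )
    else:
        mz = rule.base_mz + METHYLENE_MASS * 2 * k
        ann = LipidAnnotation(lipid_class=cls, core=rule.core, rule_name=rule.name)
    if abs(mz - rule.base_mz) <= 1e-6:
        ann.annotated_formula = rule.formula
    return mz, ann


def _allocate_blocks(
    design: SimulationDesign, class_order: Sequence[str]
) -> dict[str, list[tuple[str, ...]]]:
    """Assign each class's species to exclusivity blocks.

    Largest-remainder allocation against the blocks' remaining quotas,
    class by class, so every class spreads across membership patterns
    roughly proportionally.  Fully deterministic.
    """
    blocks = list(design.exclusivity.items())
    remaining = [count for _, count in blocks]
    out: dict[str, list[tuple[str, ...]]] = {}
    for cls in class_order:
        n = design.class_species[cls]
        total_left = sum(remaining)
        ideal = [n * q / total_left for q in remaining]
        alloc = [min(math.floor(x), remaining[i]) for i, x in enumerate(ideal)]
        leftover = n - sum(alloc)
        order = sorted(
            range(len(blocks)),
            key=lambda i: (-(ideal[i] - math.floor(ideal[i])), i),
        )
        idx = 0
        while leftover > 0:
            i = order[idx % len(order)]
            if alloc[i] < remaining[i]:
                alloc[i] += 1
                leftover -= 1
            idx += 1
        assignment: list[tuple[str, ...]] = []
        for i, (pattern, _) in enumerate(blocks):
            assignment.extend([pattern] * alloc[i])
            remaining[i] -= alloc[i]
        out[cls] = assignment
    return out


def _species_plan(design: SimulationDesign, rng_weights: np.random.Generator) -> pd.DataFrame:
    rules = _generating_rules(load_default_rules())
    missing = [c for c in design.class_species if c not in rules]
    if missing:
        raise ValueError(f"no spectral template rule for classes: {missing}")
    class_order = list(design.class_species)
    block_assignment = _allocate_blocks(design, class_order)
    rows = []
    counter = 0
    for cls in class_order:
        rule = rules[cls]
        for k in range(design.class_species[cls]):
            counter += 1
            mz, ann = _species_precursor(rule, k)
            rows.append(
                {
                    "species_id": f"L{counter:04d}",
                    "lipid_class": cls,
                    "class_index": k,
                    "precursor_mz": mz,
                    "retention_time": 180.0 + 2.7 * counter,
                    "pattern": block_assignment[cls][k],
                    "annotation": ann,
                }
            )
    plan = pd.DataFrame(rows).set_index("species_id")
    # per-(class, group) species weights: uniform(0.5, 1.5) draws, fixed per design
    plan["raw_weight"] = rng_weights.uniform(0.5, 1.5, size=len(plan))
    return plan


def _group_species_shares(design: SimulationDesign, plan: pd.DataFrame) -> pd.DataFrame:
    """Noiseless per-group species relative abundances (columns sum to 1)."""
    shares = pd.DataFrame(0.0, index=plan.index, columns=list(design.groups))
    for grp in design.groups:
        present = plan[[grp in pat for pat in plan["pattern"]]]
        class_vec = {
            cls: s for cls, s in design.class_shares[grp].items()
            if (present["lipid_class"] == cls).any()
        }
        norm = sum(class_vec.values())
        for cls, cls_share in class_vec.items():
            cls_share = cls_share / norm
            members = present[present["lipid_class"] == cls]
            w = members["raw_weight"].to_numpy()
            w = w / w.sum()
            s = cls_share * w
            # lift tiny species above the presence floor, preserving the class total
            floor = _SPECIES_SHARE_FLOOR
            if np.any(s < floor):
                if floor * len(s) > cls_share:
                    raise ValueError(
                        f"class {cls!r} share {cls_share:.2e} in group {grp!r} cannot "
                        f"support {len(s)} species above the presence floor"
                    )
                low = s < floor
                deficit = (floor - s[low]).sum()
                s[low] = floor
                s[~low] -= deficit * s[~low] / s[~low].sum()
            shares.loc[members.index, grp] = s
    return shares


def simulate_lipidome(design: SimulationDesign) -> tuple[FeatureTable, dict]:
    """Realize a feature table plus complete ground truth.

    Feature abundances are ``total_abundance × planted species share ×
    exp(σ·z)`` per sample (z standard normal; exactly the planted shares
    at σ = 0).  Species drawn for adduct pairing appear as two features —
    the [M+H]+ form keeping the species id and a ``<id>_NH4`` twin at
    +17.02655 Th — whose abundances split ``adduct_split : 1 −
    adduct_split``.  An internal-standard row is included for recovery
    correction.

    The truth mapping carries: ``plan`` (per-species class, precursor,
    block pattern), ``annotations``, ``presence`` sets and ``pattern_counts``,
    per-group ``class_shares`` and ``species_shares`` (noiseless), the
    noiseless per-sample profile, per-sample ``delta``/``H`` at zero noise
    and the implied ``delta_ranking`` of groups.
    """
    design.validate()
    streams = _streams(design.seed)
    plan = _species_plan(design, streams["weights"])
    shares = _group_species_shares(design, plan)

    samples = [
        (f"{grp}_{tp:g}h_r{rep}", grp, tp, rep)
        for grp in design.groups
        for tp in design.timepoints_h
        for rep in range(1, design.replicates + 1)
    ]
    sample_ids = [s[0] for s in samples]
    sample_meta = pd.DataFrame(
        {
            "group": [s[1] for s in samples],
            "timepoint_h": [s[2] for s in samples],
            "replicate": [s[3] for s in samples],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    rng_ab = streams["abundance"]
    sigma = design.abundance_sigma
    noiseless = pd.DataFrame(
        {sid: shares[grp].to_numpy() for sid, grp, _, _ in samples},
        index=shares.index,
    )
    if sigma > 0:
        noise = np.exp(sigma * rng_ab.standard_normal(noiseless.shape))
        depth = np.exp(sigma * rng_ab.standard_normal(len(sample_ids)))
    else:
        noise = np.ones(noiseless.shape)
        depth = np.ones(len(sample_ids))
    species_ab = noiseless.to_numpy() * noise * (design.total_abundance * depth)[None, :]
    species_table = pd.DataFrame(species_ab, index=shares.index, columns=sample_ids)

    # adduct pairing: split selected species into M+H / M+NH4 feature pairs
    rng_ad = streams["adducts"]
    paired = rng_ad.random(len(plan)) < design.adduct_probability
    feature_rows, meta_rows = [], []
    for i, sid in enumerate(plan.index):
        base = species_table.loc[sid]
        mz = plan.at[sid, "precursor_mz"]
        rt = plan.at[sid, "retention_time"]
        if paired[i]:
            feature_rows.append((sid, base * design.adduct_split))
            meta_rows.append((sid, mz, "M+H", rt, plan.at[sid, "lipid_class"]))
            feature_rows.append((f"{sid}_NH4", base * (1 - design.adduct_split)))
            meta_rows.append(
                (f"{sid}_NH4", mz + NH4_H_DELTA, "M+NH4", rt, plan.at[sid, "lipid_class"])
            )
        else:
            feature_rows.append((sid, base))
            meta_rows.append((sid, mz, "M+H", rt, plan.at[sid, "lipid_class"]))

    if sigma > 0:
        is_row = design.internal_standard_level * np.exp(
            sigma * rng_ab.standard_normal(len(sample_ids))
        )
    else:
        is_row = np.full(len(sample_ids), design.internal_standard_level)
    feature_rows.append((INTERNAL_STANDARD_ID, pd.Series(is_row, index=sample_ids)))
    meta_rows.append((INTERNAL_STANDARD_ID, 744.661, "unknown", 150.0, "internal_standard"))

    abundance = pd.DataFrame(
        {fid: row for fid, row in feature_rows}
    ).T
    abundance.columns = sample_ids
    feature_meta = pd.DataFrame(
        meta_rows, columns=["feature_id", "precursor_mz", "adduct", "retention_time", "lipid_class"]
    ).set_index("feature_id")
    table = FeatureTable(abundance=abundance, feature_meta=feature_meta, sample_meta=sample_meta)

    presence = {
        grp: frozenset(plan.index[[grp in pat for pat in plan["pattern"]]])
        for grp in design.groups
    }
    pattern_counts: dict[frozenset[str], int] = {}
    for pat in plan["pattern"]:
        key = frozenset(pat)
        pattern_counts[key] = pattern_counts.get(key, 0) + 1
    class_shares_true = {
        grp: shares[grp].groupby(plan["lipid_class"]).sum().sort_index()
        for grp in design.groups
    }

    from .infotheory import compute_indices  # local import avoids a cycle

    noiseless_profile = CompositionProfile(
        relative_abundance=noiseless, sample_meta=sample_meta
    )
    ideal = compute_indices(noiseless_profile)
    delta_by_group = ideal.delta.groupby(sample_meta["group"]).mean()
    delta_ranking = list(delta_by_group.sort_values(ascending=False).index)

    truth = {
        "plan": plan,
        "annotations": {sid: plan.at[sid, "annotation"] for sid in plan.index},
        "presence": presence,
        "pattern_counts": pattern_counts,
        "class_shares": class_shares_true,
        "species_shares": shares,
        "noiseless_profile": noiseless,
        "H": ideal.H,
        "delta": ideal.delta,
        "delta_group_means": delta_by_group,
        "delta_ranking": delta_ranking,
        "adduct_paired": {
            sid: bool(flag) for sid, flag in zip(plan.index, paired)
        },
    }
    return table, truth


def _class_template(
    rule: DiagnosticRule,
    families: Mapping[str, list[tuple[float, float]]],
    class_index: int,
) -> list[tuple[float, float]]:
    peaks: dict[float, float] = {}
    for mz, inten in families.get(rule.family, []):
        peaks[mz] = max(peaks.get(mz, 0.0), inten)
    for mz, inten in rule.required_fragments + rule.extra_fragments:
        peaks[mz] = max(peaks.get(mz, 0.0), inten)
    return sorted(peaks.items())


def simulate_spectra(design: SimulationDesign, truth: Mapping) -> list[MsSpectrum]:
    """MS² spectra for every feature of a simulated table.

    Each species gets its class template (family + diagnostic + gradient
    peaks), a water-loss peak tracking the precursor, Gaussian m/z
    jitter and Poisson spurious peaks; ammoniated twins replicate the
    fragment list at the shifted precursor.
    """
    design.validate()
    rng = _streams(design.seed)["spectra"]
    rules = _generating_rules(load_default_rules())
    families = load_family_fragments()
    plan: pd.DataFrame = truth["plan"]
    class_order = list(design.class_species)
    missing = [c for c in class_order if c not in rules]
    if missing:
        raise ValueError(f"no spectral template rule for classes: {missing}")
    class_sizes = design.class_species
    spectra: list[MsSpectrum] = []
    for sid in plan.index:
        cls = plan.at[sid, "lipid_class"]
        rule = rules[cls]
        cls_idx = class_order.index(cls)
        template = _class_template(rule, families, cls_idx)
        k = int(plan.at[sid, "class_index"])
        n_cls = max(1, class_sizes[cls] - 1)
        phi = 1.4 * k / n_cls
        g1 = 30.10 + 1.51 * cls_idx
        peaks = list(template)
        if math.cos(phi) > 1e-9:
            peaks.append((g1, 80.0 * math.cos(phi)))
        if math.sin(phi) > 1e-9:
            peaks.append((g1 + 0.777, 80.0 * math.sin(phi)))
        precursor = float(plan.at[sid, "precursor_mz"])
        peaks.append((precursor - WATER_MASS, 12.0))
        rt = float(plan.at[sid, "retention_time"])
        for adduct, fid, prec in (
            ("M+H", sid, precursor),
            ("M+NH4", f"{sid}_NH4", precursor + NH4_H_DELTA),
        ):
            if adduct == "M+NH4" and not truth["adduct_paired"].get(sid, False):
                continue
            mz = np.array([p[0] for p in peaks], dtype=float)
            inten = np.array([p[1] for p in peaks], dtype=float)
            if adduct == "M+NH4":
                # the water-loss peak tracks this form's own precursor
                mz = mz.copy()
                mz[np.argmin(np.abs(mz - (precursor - WATER_MASS)))] = prec - WATER_MASS
            if design.mz_jitter_sd > 0:
                mz = mz + rng.normal(0.0, design.mz_jitter_sd, size=mz.shape)
            if design.spurious_peak_rate > 0:
                n_extra = rng.poisson(design.spurious_peak_rate)
                if n_extra:
                    extra_mz = rng.uniform(50.0, max(60.0, prec - 25.0), size=n_extra)
                    extra_inten = rng.uniform(2.0, 15.0, size=n_extra)
                    mz = np.concatenate([mz, extra_mz])
                    inten = np.concatenate([inten, extra_inten])
            spectra.append(
                MsSpectrum(
                    feature_id=fid,
                    precursor_mz=prec,
                    peaks=np.column_stack([mz, inten]),
                    charge=1,
                    retention_time=rt,
                    adduct=adduct,
                )
            )
    return spectra
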