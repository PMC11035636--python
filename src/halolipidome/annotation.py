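"""Rule-based archaeal lipid class annotation.

Haloarchaeal membranes are built on archaeol (AR) — a glycerol diether
with two C20 (or one C25, "extended") isoprenoid chains — decorated
with phospho- and glyco- head groups (PG, PGS, PA, PGP-Me, PGPG, CL,
1G, 2G, S), plus non-bilayer lipids: menaquinones (MK and the
demethyl/methyl variants DMK, MMK, DMMK), the C50 carotenoid
bacterioruberin, and squalene.

Classes are assigned from MS² evidence with an ordered list of
:class:`DiagnosticRule` objects: the first rule whose required fragment
ions are all present (within tolerance, and whose precursor window
matches if one is given) wins.  The default rule set is shipped as
editable JSON (``data/default_rules.json``) anchored on the diagnostic
masses of this system — the AR core ion at m/z 653.681, the
lysoAR-glycerol ion at 373.368, and one exemplar precursor per class.

Menaquinone species are written MK(n:m): n isoprenoid units in the side
chain, m double bonds.  For MK-family and AR-based classes the
precursor mass is additionally decoded into integer structural
increments (isoprenoid units / saturation for MK; chain extension and
methylation for AR cores).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FeatureTable, MsSpectrum

__all__ = [
    "LipidAnnotation",
    "DiagnosticRule",
    "load_rules",
    "load_default_rules",
    "annotate",
    "annotate_all",
    "saturation_profile",
    "ISOPRENE_UNIT_MASS",
    "H2_MASS",
    "CHAIN_EXTENSION_MASS",
    "METHYLENE_MASS",
]

LIPID_CLASSES = (
    "AR", "PG", "PGS", "PA", "PGP-Me", "PGPG", "CL", "1G", "2G", "S",
    "MK", "DMK", "MMK", "DMMK", "bacterioruberin", "squalene", "unknown",
)

#: Monoisotopic mass increments used to decode structural variants.
ISOPRENE_UNIT_MASS = 68.06260  # C5H8, one isoprenoid unit in a quinone side chain
H2_MASS = 2.01565              # one double-bond equivalent
CHAIN_EXTENSION_MASS = 70.07825  # C5H10, C20 -> C25 chain extension on a saturated ether chain
METHYLENE_MASS = 14.01565      # CH2 homologue step


@dataclass
class LipidAnnotation:
    lipid_class: str = "unknown"
    core: str = "none"  # AR | EXT-AR | lysoAR | none
    isoprenoid_units: int = 0
    double_bonds: int = 0
    annotated_formula: str = ""
    rule_name: str = ""

    def mk_label(self) -> str:
        """MK(n:m)-style label for quinone classes, else the class name."""
        if self.lipid_class in {"MK", "DMK", "MMK", "DMMK"}:
            return f"{self.lipid_class}({self.isoprenoid_units}:{self.double_bonds})"
        return self.lipid_class


@dataclass
class DiagnosticRule:
    """One class-assignment rule.

    ``required_fragments`` are (m/z, reference intensity) pairs — the
    intensity is only used when the rule doubles as a spectral template
    for simulation.  A rule must carry at least one required fragment or
    a precursor window.
    """

    name: str
    lipid_class: str
    core: str = "none"
    family: str = ""
    base_mz: float = 0.0
    formula: str = ""
    required_fragments: list[tuple[float, float]] = field(default_factory=list)
    extra_fragments: list[tuple[float, float]] = field(default_factory=list)
    precursor_window: tuple[float, float] | None = None
    decode: str | None = None
    generate: bool = True

    def __post_init__(self) -> None:
        if not self.required_fragments and self.precursor_window is None:
            raise ValueError(f"rule {self.name!r}: needs fragments or a precursor window")

    def matches(self, spectrum: MsSpectrum, fragment_tol: float) -> bool:
        if self.precursor_window is not None:
            lo, hi = self.precursor_window
            if not (lo <= spectrum.precursor_mz <= hi):
                return False
        mz = spectrum.mz
        for frag_mz, _ in self.required_fragments:
            if mz.size == 0 or np.min(np.abs(mz - frag_mz)) > fragment_tol:
                return False
        return True


def _parse_rules(payload: Mapping) -> tuple[list[DiagnosticRule], dict[str, list[tuple[float, float]]]]:
    families = {
        name: [(float(mz), float(inten)) for mz, inten in peaks]
        for name, peaks in payload.get("family_fragments", {}).items()
    }
    rules = []
    for entry in payload["rules"]:
        window = entry.get("precursor_window")
        rules.append(
            DiagnosticRule(
                name=entry["name"],
                lipid_class=entry["lipid_class"],
                core=entry.get("core", "none"),
                family=entry.get("family", ""),
                base_mz=float(entry.get("base_mz", 0.0)),
                formula=entry.get("formula", ""),
                required_fragments=[(float(m), float(i)) for m, i in entry.get("required_fragments", [])],
                extra_fragments=[(float(m), float(i)) for m, i in entry.get("extra_fragments", [])],
                precursor_window=tuple(window) if window else None,
                decode=entry.get("decode"),
                generate=bool(entry.get("generate", True)),
            )
        )
    return rules, families


def load_rules(path: str | Path) -> list[DiagnosticRule]:
    """Load an ordered rule list from a JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    return _parse_rules(payload)[0]


def load_default_rules() -> list[DiagnosticRule]:
    """The shipped default rule set (anchored on the printed exemplar masses)."""
    payload = json.loads(
        resources.files("halolipidome.data").joinpath("default_rules.json").read_text()
    )
    return _parse_rules(payload)[0]


def load_family_fragments() -> dict[str, list[tuple[float, float]]]:
    """Family-shared fragment sets from the default rule file (for templates)."""
    payload = json.loads(
        resources.files("halolipidome.data").joinpath("default_rules.json").read_text()
    )
    return _parse_rules(payload)[1]


def _decode_bilayer(precursor: float, base: float) -> tuple[str, int, int]:
    """Decode chain extension / methylation steps of an AR-based lipid.

    Returns (core, extensions, methylations); core becomes EXT-AR once a
    C5 extension is present.
    """
    best, best_err = (0, 0), np.inf
    for ext in range(0, 13):
        for methyl in range(0, 4):
            err = abs(precursor - (base + CHAIN_EXTENSION_MASS * ext + METHYLENE_MASS * methyl))
            if err < best_err:
                best, best_err = (ext, methyl), err
    ext, methyl = best
    core = "EXT-AR" if ext > 0 else "AR"
    return core, ext, methyl


def _decode_mk(precursor: float, base: float) -> tuple[int, int]:
    """Decode MK(n:m) from the precursor mass relative to the MK(8:8) anchor.

    Saturating one double bond adds H2; each extra isoprenoid unit adds
    C5H8.  m is constrained to {n-1, n, n+1}, the range seen in this
    system.
    """
    best, best_err = (8, 8), np.inf
    for n in range(2, 21):
        for rel in (-1, 0, 1):
            m = n + rel
            if m < 0:
                continue
            expected = base + (n - 8) * ISOPRENE_UNIT_MASS + (n - m) * H2_MASS
            err = abs(precursor - expected)
            if err < best_err:
                best, best_err = (n, m), err
    return best


def annotate(
    spectrum: MsSpectrum,
    rules: Sequence[DiagnosticRule] | None = None,
    fragment_tol: float = 0.01,
) -> LipidAnnotation:
    """Assign a lipid class to one spectrum (first matching rule wins)."""
    if rules is None:
        rules = load_default_rules()
    if not rules:
        raise ValueError("annotate requires a non-empty rule list")
    for rule in rules:
        if not rule.matches(spectrum, fragment_tol):
            continue
        ann = LipidAnnotation(
            lipid_class=rule.lipid_class,
            core=rule.core,
            rule_name=rule.name,
        )
        if abs(spectrum.precursor_mz - rule.base_mz) <= fragment_tol:
            ann.annotated_formula = rule.formula
        if rule.decode == "mk":
            ann.isoprenoid_units, ann.double_bonds = _decode_mk(
                spectrum.precursor_mz, rule.base_mz
            )
        elif rule.decode == "bilayer":
            ann.core, _, _ = _decode_bilayer(spectrum.precursor_mz, rule.base_mz)
            if rule.core == "lysoAR":
                ann.core = "lysoAR"
        return ann
    return LipidAnnotation()


def annotate_all(
    spectra: Sequence[MsSpectrum],
    rules: Sequence[DiagnosticRule] | None = None,
    fragment_tol: float = 0.01,
) -> dict[str, LipidAnnotation]:
    """Annotate a spectrum collection, keyed by feature id."""
    if rules is None:
        rules = load_default_rules()
    return {s.feature_id: annotate(s, rules, fragment_tol) for s in spectra}


def saturation_profile(
    table: FeatureTable,
    annotations: Mapping[str, LipidAnnotation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Abundance-weighted saturation summary per class per sample.

    Returns ``(mean_db, mk_categories)``:

    * ``mean_db`` — classes × samples matrix of abundance-weighted mean
      double-bond counts (classes with zero abundance in a sample are NaN).
    * ``mk_categories`` — rows ``n:n-1`` / ``n:n`` / ``n:n+1`` × samples:
      relative weight of menaquinone-family features whose double-bond
      count sits one below, at, or one above their isoprenoid-unit count.
    """
    ab = table.abundance
    classes = sorted({annotations[f].lipid_class for f in ab.index if f in annotations})
    mean_db = pd.DataFrame(np.nan, index=classes, columns=ab.columns, dtype=float)
    for cls in classes:
        feats = [f for f in ab.index if f in annotations and annotations[f].lipid_class == cls]
        weights = ab.loc[feats]
        dbs = np.array([annotations[f].double_bonds for f in feats], dtype=float)
        totals = weights.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_db.loc[cls] = (weights.mul(dbs, axis=0).sum(axis=0) / totals).where(totals > 0)

    mk_feats = [
        f for f in ab.index
        if f in annotations and annotations[f].lipid_class in {"MK", "DMK", "MMK", "DMMK"}
    ]
    cats = ["n:n-1", "n:n", "n:n+1"]
    mk = pd.DataFrame(0.0, index=cats, columns=ab.columns)
    for f in mk_feats:
        ann = annotations[f]
        rel = ann.double_bonds - ann.isoprenoid_units
        if rel in (-1, 0, 1):
            mk.loc[cats[rel + 1]] += table.abundance.loc[f]
    totals = mk.sum(axis=0)
    mk = mk.divide(totals.replace(0.0, np.nan), axis=1).fillna(0.0)
    return mean_db, mk
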