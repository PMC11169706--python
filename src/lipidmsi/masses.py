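"""Exact-mass arithmetic for lipid adduct ions.

Positive-mode MALDI lipidomics on an FTICR instrument resolves lipid species
to sub-ppm mass accuracy, so annotation reduces to exact-mass matching of
observed m/z against theoretical adduct masses built from monoisotopic atomic
masses.  This module keeps the atomic constants explicit — including the
electron — because a cation's m/z differs from the neutral-fragment sum by one
electron mass (~0.55 mDa, i.e. ~0.7 ppm at m/z 800), which matters at the
tolerances used here (±0.005 Da matching, sub-ppm mass errors).

Conventions:

* ``[M+H]+`` is M plus a proton (equivalently M + H − e⁻).
* ``[M+Na]+`` / ``[M+K]+`` are cationization: M plus the metal atom minus one
  electron (not proton displacement).
* ``[M]+.`` is the radical cation, M minus one electron; the DAN matrix dimer
  lock mass is modeled as the C20H18N4 radical cation (two DAN minus H2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "MONOISOTOPIC_MASSES",
    "ElementMassTable",
    "Formula",
    "AdductSpec",
    "ADDUCTS",
    "LipidEntry",
    "AnnotationMatch",
    "formula_mass",
    "adduct_mz",
    "ppm_error",
    "annotate",
    "load_lipid_table",
    "load_reference_annotations",
    "annotation_report",
]

#: CODATA/AME monoisotopic atomic masses, Da.
MONOISOTOPIC_MASSES: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS: float = 0.00054857990907
#: Proton mass defined as mass(H) − mass(e⁻) so that protonation and
#: H-atom-plus-electron-removal are numerically identical operations.
PROTON_MASS: float = MONOISOTOPIC_MASSES["H"] - ELECTRON_MASS


@dataclass(frozen=True)
class ElementMassTable:
    """Monoisotopic element masses plus proton and electron masses (Da)."""

    masses: Mapping[str, float] = field(default_factory=lambda: dict(MONOISOTOPIC_MASSES))
    proton: float = PROTON_MASS
    electron: float = ELECTRON_MASS

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("element masses must be strictly positive")
        if abs(self.masses["H"] - self.electron - self.proton) > 1e-9:
            raise ValueError("proton mass inconsistent with mass(H) - mass(e-)")

    def __getitem__(self, symbol: str) -> float:
        try:
            return self.masses[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol: {symbol!r}") from None


DEFAULT_MASS_TABLE = ElementMassTable()

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Elemental composition as symbol → non-negative integer count."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, n in self.counts.items():
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {sym} must be a non-negative integer, got {n!r}")

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``C42H82NO8P``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at position {pos}")
            if not m.group(0):
                break
            sym = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[sym] = counts.get(sym, 0) + n
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        order = sorted(self.counts, key=lambda s: (s != "C", s != "H", s))
        return "".join(
            f"{s}{self.counts[s]}" if self.counts[s] != 1 else s
            for s in order
            if self.counts[s] > 0
        )

    def is_empty(self) -> bool:
        return not any(self.counts.values())


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged positive adduct: name, added atoms, electrons removed.

    m/z = formula mass + added-formula mass − electrons_removed × mass(e⁻),
    divided by charge (always +1 in scope).
    """

    name: str
    added: Formula
    charge: int = 1
    electrons_removed: int = 1

    def __post_init__(self) -> None:
        if self.charge != 1:
            raise ValueError(f"only +1 adducts are in scope, got charge {self.charge}")


ADDUCTS: dict[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", Formula({"H": 1})),
    "[M+Na]+": AdductSpec("[M+Na]+", Formula({"Na": 1})),
    "[M+K]+": AdductSpec("[M+K]+", Formula({"K": 1})),
    "[M]+.": AdductSpec("[M]+.", Formula({})),
}


@dataclass(frozen=True)
class LipidEntry:
    """One lipid species: shorthand name, class, elemental formula."""

    name: str
    lipid_class: str
    formula: Formula
    confirmation: str = ""

    def __post_init__(self) -> None:
        if self.formula.is_empty():
            raise ValueError(f"lipid {self.name!r} has an empty formula")


@dataclass(frozen=True)
class AnnotationMatch:
    """Match of an observed m/z to a lipid/adduct theoretical mass."""

    query_mz: float
    entry: LipidEntry
    adduct: AdductSpec
    theoretical_mz: float
    delta_da: float
    delta_ppm: float


def formula_mass(formula: Formula, masses: ElementMassTable = DEFAULT_MASS_TABLE) -> float:
    """Monoisotopic mass of a neutral formula in Da (empty formula → 0.0)."""
    return sum(n * masses[sym] for sym, n in formula.counts.items() if n)


def adduct_mz(
    formula: Formula,
    adduct: AdductSpec,
    masses: ElementMassTable = DEFAULT_MASS_TABLE,
) -> float:
    """Theoretical m/z of a singly charged positive adduct of ``formula``."""
    if adduct.charge == 0:
        raise ValueError("adduct charge must be nonzero")
    m = formula_mass(formula, masses) + formula_mass(adduct.added, masses)
    m -= adduct.electrons_removed * masses.electron
    return m / adduct.charge


def ppm_error(experimental: float, theoretical: float) -> float:
    """Signed relative mass error, (exp − theo)/theo × 1e6."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return (experimental - theoretical) / theoretical * 1e6


def annotate(
    query_mz: float,
    lipids: Iterable[LipidEntry],
    adducts: Sequence[AdductSpec] | None = None,
    tolerance_da: float = 0.005,
    masses: ElementMassTable = DEFAULT_MASS_TABLE,
) -> list[AnnotationMatch]:
    """All (lipid, adduct) pairs within ±tolerance of the query m/z.

    Sorted by absolute Da error; ties broken by lipid name then adduct name.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be positive")
    if adducts is None:
        adducts = [ADDUCTS["[M+H]+"], ADDUCTS["[M+Na]+"], ADDUCTS["[M+K]+"]]
    out: list[AnnotationMatch] = []
    for entry in lipids:
        for adduct in adducts:
            theo = adduct_mz(entry.formula, adduct, masses)
            delta = query_mz - theo
            if abs(delta) <= tolerance_da:
                out.append(
                    AnnotationMatch(
                        query_mz=query_mz,
                        entry=entry,
                        adduct=adduct,
                        theoretical_mz=theo,
                        delta_da=delta,
                        delta_ppm=ppm_error(query_mz, theo),
                    )
                )
    out.sort(key=lambda m: (abs(m.delta_da), m.entry.name, m.adduct.name))
    return out


def _read_bundled(name: str) -> pd.DataFrame:
    with resources.files("lipidmsi.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_lipid_table(path: str | None = None) -> list[LipidEntry]:
    """Load a lipid table (name, lipid_class, formula, confirmation TSV).

    With no path, loads the bundled table of brain lipids covered by the
    discriminant models (LPC, LPC-O, PC, SM, HexCer species).
    """
    df = pd.read_csv(path, sep="\t") if path else _read_bundled("lipid_table.tsv")
    entries = [
        LipidEntry(
            name=row["name"],
            lipid_class=row["lipid_class"],
            formula=Formula.parse(row["formula"]),
            confirmation=str(row.get("confirmation", "")),
        )
        for _, row in df.iterrows()
    ]
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise ValueError("lipid names must be unique within a table")
    return entries


def load_reference_annotations() -> pd.DataFrame:
    """Bundled reference report: experimental m/z, adduct identities and
    injured/sham fold changes per ROI for the discriminant lipid panel."""
    df = _read_bundled("reference_annotations.tsv")
    for col in [c for c in df.columns if c.startswith("fc_")]:
        df[col] = pd.to_numeric(df[col], errors="coerce")  # 'ND' → NaN
    return df


def annotation_report(
    queries: Sequence[float],
    lipids: Iterable[LipidEntry],
    adducts: Sequence[AdductSpec] | None = None,
    tolerance_da: float = 0.005,
) -> pd.DataFrame:
    """Annotate a list of observed m/z values; one row per query (top match,
    or empty identity when nothing falls within tolerance)."""
    lipids = list(lipids)
    rows = []
    for q in queries:
        matches = annotate(q, lipids, adducts, tolerance_da)
        if matches:
            best = matches[0]
            rows.append(
                {
                    "query_mz": q,
                    "name": best.entry.name,
                    "adduct": best.adduct.name,
                    "theoretical_mz": best.theoretical_mz,
                    "delta_da": best.delta_da,
                    "ppm_error": best.delta_ppm,
                    "n_matches": len(matches),
                }
            )
        else:
            rows.append(
                {
                    "query_mz": q,
                    "name": "",
                    "adduct": "",
                    "theoretical_mz": float("nan"),
                    "delta_da": float("nan"),
                    "ppm_error": float("nan"),
                    "n_matches": 0,
                }
            )
    return pd.DataFrame(rows)
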