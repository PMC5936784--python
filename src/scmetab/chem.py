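"""Molecular formula handling, monoisotopic masses, and adduct m/z.

This is the chemistry kernel of the package: every downstream stage —
spectrum simulation, annotation of aligned features, and metabolome
stoichiometry — reduces to parsing Hill-style formulas, summing packaged
monoisotopic atomic masses, and shifting neutral masses by singly charged
positive-mode adducts (+H+, +NH4+, +Na+, +K+).

Only z = +1 cations are modeled; the adduct shift is electron-corrected
(the ion is the neutral plus the adduct composition minus one electron),
which matters at the 0.01 Da tolerances used for annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, Mapping

ELECTRON_MASS = 0.00054858  # Da

#: Spacing between successive isotopologue peaks at z=1 (13C - 12C), Da.
ISOTOPE_SPACING = 1.00336

#: Natural abundance of 13C, used by the isotope-envelope model.
C13_ABUNDANCE = 0.0107


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("scmetab.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


def _load_atomic_masses() -> Dict[str, float]:
    return {row[0]: float(row[1]) for row in _load_table("atomic_masses.tsv")}


ATOMIC_MASSES: Dict[str, float] = _load_atomic_masses()


class FormulaError(ValueError):
    """Raised for malformed or unknown molecular formula input."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition, e.g. ``Formula.parse("C33H36N4O6")``.

    ``counts`` maps element symbols to positive integer multiplicities.
    The empty composition is valid ("null formula") and has mass 0.
    """

    counts: Mapping[str, int]

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a plain Hill-style formula string.

        Element symbols with optional integer multiplicities; an absent
        multiplicity means 1. Parentheses, hydrates and isotope labels are
        not supported.
        """
        s = text.strip()
        if not s:
            raise FormulaError("empty formula string")
        counts: Dict[str, int] = {}
        pos = 0
        while pos < len(s):
            m = _TOKEN.match(s, pos)
            if m is None or m.start() != pos:
                raise FormulaError(f"invalid token at {s[pos:]!r} in formula {text!r}")
            symbol, digits = m.group(1), m.group(2)
            if symbol not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol {symbol!r} in formula {text!r}")
            n = int(digits) if digits else 1
            if n == 0:
                raise FormulaError(f"zero multiplicity for {symbol!r} in formula {text!r}")
            counts[symbol] = counts.get(symbol, 0) + n
            pos = m.end()
        return cls(dict(counts))

    def __str__(self) -> str:
        return format_formula(self)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    def count(self, element: str) -> int:
        return element_count(self, element)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string into a :class:`Formula`."""
    return Formula.parse(text)


def format_formula(f: Formula) -> str:
    """Render a formula in Hill order (C, H, then alphabetical)."""

    def key(el: str):
        return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

    parts = []
    for el in sorted(f.counts, key=key):
        n = f.counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(f: Formula) -> float:
    """Sum of packaged monoisotopic atomic masses, in Da."""
    total = 0.0
    for el, n in f.counts.items():
        try:
            total += n * ATOMIC_MASSES[el]
        except KeyError:
            raise FormulaError(f"no packaged monoisotopic mass for element {el!r}")
    return total


def element_count(f: Formula, element: str) -> int:
    """Number of atoms of ``element`` in the formula (0 if absent)."""
    if element not in ATOMIC_MASSES:
        raise FormulaError(f"unknown element symbol {element!r}")
    return int(f.counts.get(element, 0))


@dataclass(frozen=True)
class AdductSpec:
    """A positive-mode counter-ion: name, electron-corrected m/z shift, charge."""

    name: str
    mass_shift: float  # Da, already electron-corrected
    charge: int = 1


def _load_adducts() -> Dict[str, AdductSpec]:
    specs = {}
    for name, composition, charge in _load_table("adducts.tsv"):
        z = int(charge)
        shift = monoisotopic_mass(Formula.parse(composition)) - z * ELECTRON_MASS
        specs[name] = AdductSpec(name=name, mass_shift=shift, charge=z)
    return specs


ADDUCTS: Dict[str, AdductSpec] = _load_adducts()

#: The four supported adducts in ascending mass-shift order.
ADDUCT_NAMES = tuple(sorted(ADDUCTS, key=lambda n: ADDUCTS[n].mass_shift))


def get_adduct(name: str) -> AdductSpec:
    try:
        return ADDUCTS[name]
    except KeyError:
        raise FormulaError(
            f"unsupported adduct {name!r}; supported: {', '.join(ADDUCT_NAMES)}"
        )


def adduct_mz(f: Formula, adduct: AdductSpec | str) -> float:
    """m/z of the singly charged ion [M + adduct]+ for neutral formula ``f``."""
    spec = get_adduct(adduct) if isinstance(adduct, str) else adduct
    if spec.charge != 1:
        raise FormulaError("only singly charged adducts are supported")
    return monoisotopic_mass(f) + spec.mass_shift


def resolve_adducts(adducts: Iterable[AdductSpec | str] | None) -> list[AdductSpec]:
    """Normalize an adduct selection; ``None`` means all four supported ones."""
    if adducts is None:
        return [ADDUCTS[n] for n in ADDUCT_NAMES]
    return [get_adduct(a) if isinstance(a, str) else a for a in adducts]
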