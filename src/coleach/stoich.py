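"""Leaching stoichiometry: reaction balance checks, mole budgets, leach yields.

The chemistry of pyrite-driven co-leaching rests on a small set of reactions:
oxygen-driven pyrite oxidation, microbial ferrous-iron oxidation, ferric
attack on pyrite, and ferric / acid dissolution of zero-valent metals from
circuit-board dust::

    2 FeS2 + 7 O2 + 2 H2O      -> 2 Fe+2 + 4 SO4-2 + 4 H+1
    4 Fe+2 + O2 + 4 H+1        -> 4 Fe+3 + 2 H2O
    FeS2 + 14 Fe+3 + 8 H2O     -> 15 Fe+2 + 2 SO4-2 + 16 H+1
    Me + 2 Fe+3                -> Me+2 + 2 Fe+2
    2 Me + 2 H2SO4 + O2        -> 2 MeSO4 + 2 H2O
    Ni + 1/2 O2 + H2SO4        -> NiSO4 + H2O

``Me`` is a placeholder divalent metal that concrete metals (Cu, Ni, Zn)
instantiate.  Budgets (protons, ferrous/ferric iron, oxygen) are derived
from the parsed reactions, so the balance checker and the budget routines
share one source of truth.

The control-corrected leach yield of a metal from the dust fraction is

    Ym = (m_LE - m_LC) / (Xi * V_total * omega) * 100 %

with m_LE / m_LC the metal mass (g) in the experimental / control liquid
phase, Xi the dust concentration (g/L), V_total the liquid volume (L) and
omega the metal's mass fraction in the dust.  m_LE and m_LC are masses:
multiply a measured concentration by the liquid volume first.  Yields
outside [0, 100] are reported unclipped with a flag — they diagnose control
mismatch or sampling error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources

__all__ = [
    "Species",
    "Reaction",
    "LeachYieldInput",
    "LeachYieldResult",
    "parse_species",
    "parse_reaction",
    "check_balance",
    "canonical_reactions",
    "pyrite_budget",
    "metal_leach_demand",
    "leach_yield",
    "PCB_MASS_FRACTIONS",
]

# Element symbols that may appear in this chemistry, plus the generic
# divalent-metal placeholder "Me".
_KNOWN_ELEMENTS = {
    "H", "O", "S", "Fe", "Cu", "Ni", "Zn", "Al", "Pb", "Sn", "Cd",
    "Ag", "Au", "Si", "K", "N", "P", "Mg", "Cl", "Ca", "Me",
}

#: Metal mass fractions of the circuit-board dust sample (dimensionless).
PCB_MASS_FRACTIONS = {
    "Si": 0.10,
    "Fe": 0.08,
    "Cu": 0.026,
    "Al": 0.020,
    "Pb": 0.017,
    "Zn": 0.010,
    "Ni": 0.005,
    "Sn": 0.005,
    "Cd": 0.0004,
    "Ag": 0.00026,
    "Au": 0.00001,
}


@dataclass(frozen=True)
class Species:
    """A charged species: element -> count map plus integer charge."""

    formula: tuple[tuple[str, int], ...]  # sorted (element, count) pairs
    charge: int = 0

    @property
    def elements(self) -> dict[str, int]:
        return dict(self.formula)

    def __str__(self) -> str:
        body = "".join(
            f"{el}{n if n > 1 else ''}" for el, n in self.formula
        )
        if self.charge:
            body += f"{'+' if self.charge > 0 else '-'}{abs(self.charge)}"
        return body


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_SUFFIX = re.compile(r"([+-]\d+)$")


def parse_species(text: str) -> Species:
    """Parse a species like ``FeS2``, ``SO4-2``, ``H+1`` or ``Me``.

    The charge is a trailing signed integer (``Fe+3``); its absence means a
    neutral species.  Raises ``ValueError`` on unknown element symbols or
    malformed formulas.
    """
    text = text.strip()
    charge = 0
    m = _CHARGE_SUFFIX.search(text)
    if m:
        charge = int(m.group(1))
        text = text[: m.start()]
    if not text:
        raise ValueError("empty species formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, num = m.group(1), m.group(2)
        if el not in _KNOWN_ELEMENTS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return Species(formula=tuple(sorted(counts.items())), charge=charge)


@dataclass(frozen=True)
class Reaction:
    """A chemical equation with positive rational coefficients."""

    reactants: tuple[tuple[Species, Fraction], ...]
    products: tuple[tuple[Species, Fraction], ...]
    label: str = ""

    def coefficient(self, species_text: str, side: str = "any") -> Fraction:
        """Coefficient of a species (0 if absent); ``side`` in {reactants, products, any}."""
        target = parse_species(species_text)
        total = Fraction(0)
        if side in ("reactants", "any"):
            total += sum((c for s, c in self.reactants if s == target), Fraction(0))
        if side in ("products", "any"):
            total += sum((c for s, c in self.products if s == target), Fraction(0))
        return total


def _parse_side(text: str) -> tuple[tuple[Species, Fraction], ...]:
    terms = []
    for term in text.split(" + "):
        term = term.strip()
        if not term:
            raise ValueError(f"empty term in reaction side {text!r}")
        m = re.match(r"^(\d+/\d+|\d+(?:\.\d+)?)\s+(.*)$|^(\d+/\d+|\d+(?:\.\d+)?)(?=[A-Z])(.*)$", term)
        if m:
            coef_text = m.group(1) or m.group(3)
            rest = (m.group(2) or m.group(4)).strip()
            coef = Fraction(coef_text)
        else:
            coef = Fraction(1)
            rest = term
        if coef <= 0:
            raise ValueError(f"coefficient must be positive in {term!r}")
        terms.append((parse_species(rest), coef))
    return tuple(terms)


def parse_reaction(text: str, label: str = "") -> Reaction:
    """Parse ``"FeS2 + 14 Fe+3 + 8 H2O -> 15 Fe+2 + 2 SO4-2 + 16 H+1"``.

    Terms are separated by ``" + "`` (spaces required, so ``Fe+3`` charges
    survive); coefficients may be integers, decimals or fractions (``1/2``).
    """
    if "->" not in text:
        raise ValueError(f"reaction {text!r} lacks '->'")
    lhs, rhs = text.split("->", 1)
    return Reaction(reactants=_parse_side(lhs), products=_parse_side(rhs), label=label)


@dataclass
class BalanceReport:
    """Per-element and charge residuals (reactants minus products)."""

    element_residuals: dict[str, Fraction] = field(default_factory=dict)
    charge_residual: Fraction = Fraction(0)

    @property
    def balanced(self) -> bool:
        return self.charge_residual == 0 and all(
            v == 0 for v in self.element_residuals.values()
        )


def check_balance(rxn: Reaction) -> BalanceReport:
    """Element and charge residuals of a reaction; all zero iff balanced."""
    residuals: dict[str, Fraction] = {}
    charge = Fraction(0)
    for side, sign in ((rxn.reactants, 1), (rxn.products, -1)):
        for species, coef in side:
            charge += sign * coef * species.charge
            for el, n in species.formula:
                residuals[el] = residuals.get(el, Fraction(0)) + sign * coef * n
    return BalanceReport(element_residuals=residuals, charge_residual=charge)


_CANONICAL: dict[str, Reaction] | None = None


def canonical_reactions() -> dict[str, Reaction]:
    """The packaged reaction set, parsed from ``data/reactions.txt``.

    Keys: ``pyrite_O2``, ``ferrous_oxidation``, ``pyrite_ferric``,
    ``metal_ferric``, ``metal_acid_O2``, ``nickel_acid``.
    """
    global _CANONICAL
    if _CANONICAL is None:
        text = resources.files("coleach.data").joinpath("reactions.txt").read_text()
        rxns: dict[str, Reaction] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, eq = line.split(":", 1)
            rxns[label.strip()] = parse_reaction(eq.strip(), label=label.strip())
        _CANONICAL = rxns
    return _CANONICAL


def instantiate_metal(rxn: Reaction, metal: str) -> Reaction:
    """Replace the placeholder ``Me`` with a concrete divalent metal symbol."""
    if metal not in _KNOWN_ELEMENTS or metal == "Me":
        raise ValueError(f"unknown metal symbol {metal!r}")

    def swap(side):
        out = []
        for sp, coef in side:
            counts = {metal if el == "Me" else el: n for el, n in sp.formula}
            out.append((Species(tuple(sorted(counts.items())), sp.charge), coef))
        return tuple(out)

    return Reaction(swap(rxn.reactants), swap(rxn.products), label=f"{rxn.label}[{metal}]")


def _ratio(rxn: Reaction, species: str, side: str, per: str) -> float:
    return float(rxn.coefficient(species, side) / rxn.coefficient(per, "reactants"))


def pyrite_budget(mol_FeS2: float, pathway: str) -> dict[str, float]:
    """Mole budget of pyrite dissolution via one of two pathways.

    ``direct_O2`` (oxygen attack): per mol FeS2, 2 H+ and 1 Fe2+ produced,
    3.5 O2 consumed.  ``ferric`` (ferric attack): per mol FeS2, 16 H+ and
    15 Fe2+ produced, 14 Fe3+ consumed.  Returns a dict with keys
    ``H_plus_produced``, ``Fe2_produced``, ``Fe3_consumed``, ``O2_consumed``.
    """
    if mol_FeS2 < 0:
        raise ValueError(f"mol_FeS2 must be >= 0, got {mol_FeS2}")
    rxns = canonical_reactions()
    if pathway == "direct_O2":
        r = rxns["pyrite_O2"]
        return {
            "H_plus_produced": mol_FeS2 * _ratio(r, "H+1", "products", "FeS2"),
            "Fe2_produced": mol_FeS2 * _ratio(r, "Fe+2", "products", "FeS2"),
            "Fe3_consumed": 0.0,
            "O2_consumed": mol_FeS2 * _ratio(r, "O2", "reactants", "FeS2"),
        }
    if pathway == "ferric":
        r = rxns["pyrite_ferric"]
        return {
            "H_plus_produced": mol_FeS2 * _ratio(r, "H+1", "products", "FeS2"),
            "Fe2_produced": mol_FeS2 * _ratio(r, "Fe+2", "products", "FeS2"),
            "Fe3_consumed": mol_FeS2 * _ratio(r, "Fe+3", "reactants", "FeS2"),
            "O2_consumed": 0.0,
        }
    raise ValueError(f"unknown pathway {pathway!r}; use 'direct_O2' or 'ferric'")


def metal_leach_demand(mol_metal: float, route: str) -> dict[str, float]:
    """Lixiviant demand to dissolve ``mol_metal`` of zero-valent metal.

    Routes: ``ferric`` (2 mol Fe3+ per mol Me), ``acid_O2`` (1 mol H2SO4 and
    1/2 mol O2 per mol Me), ``nickel_acid`` (same ratios, nickel-specific
    equation).  Returns a dict with keys ``Fe3``, ``H2SO4``, ``O2``.
    """
    if mol_metal < 0:
        raise ValueError(f"mol_metal must be >= 0, got {mol_metal}")
    rxns = canonical_reactions()
    if route == "ferric":
        r = rxns["metal_ferric"]
        return {
            "Fe3": mol_metal * _ratio(r, "Fe+3", "reactants", "Me"),
            "H2SO4": 0.0,
            "O2": 0.0,
        }
    if route in ("acid_O2", "nickel_acid"):
        r = rxns["metal_acid_O2" if route == "acid_O2" else "nickel_acid"]
        per = "Me" if route == "acid_O2" else "Ni"
        return {
            "Fe3": 0.0,
            "H2SO4": mol_metal * _ratio(r, "H2SO4", "reactants", per),
            "O2": mol_metal * _ratio(r, "O2", "reactants", per),
        }
    raise ValueError(
        f"unknown route {route!r}; use 'ferric', 'acid_O2' or 'nickel_acid'"
    )


@dataclass(frozen=True)
class LeachYieldInput:
    """Inputs of the control-corrected leach-yield formula.

    m_LE / m_LC: metal mass (g) in the experimental / control liquid phase;
    Xi: dust concentration in the reactor (g/L); V_total: liquid volume (L);
    omega: mass fraction of the target metal in the dust (0 < omega < 1).
    """

    m_LE: float
    m_LC: float
    Xi: float
    V_total: float
    omega: float

    def __post_init__(self) -> None:
        if self.m_LE < 0 or self.m_LC < 0:
            raise ValueError("metal masses must be >= 0")
        if not 0 < self.omega < 1:
            raise ValueError(f"omega must be in (0, 1), got {self.omega}")
        if self.Xi * self.V_total * self.omega <= 0:
            raise ValueError("Xi * V_total * omega must be > 0 (zero denominator)")


@dataclass(frozen=True)
class LeachYieldResult:
    percent: float
    in_range: bool  # False when outside [0, 100]


def leach_yield(inp: LeachYieldInput) -> LeachYieldResult:
    """Control-corrected leach yield, percent.

    ``Ym = (m_LE - m_LC) / (Xi * V_total * omega) * 100``.  Values outside
    [0, 100] (negative: control exceeded experiment; >100: mass-balance
    inconsistency) are returned unclipped with ``in_range=False``.
    """
    ym = (inp.m_LE - inp.m_LC) / (inp.Xi * inp.V_total * inp.omega) * 100.0
    return LeachYieldResult(percent=ym, in_range=0.0 <= ym <= 100.0)
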