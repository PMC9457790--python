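"""Stoichiometry of the nitrate-reducing Fe(II) oxidation (NRFO) reaction network.

Two reactions drive Fe(II) loss in anoxic nitrate-amended incubations of
nitrate-reducing bacteria:

* enzymatic NRFO — microbial nitrate reduction to nitrite with Fe(II) as the
  electron donor::

      NO3- + 2 Fe2+ + 2 H+  ->  2 Fe3+ + NO2- + H2O

* chemodenitrification — the abiotic reduction of (typically biogenic)
  nitrite by Fe(II), yielding N2O::

      2 NO2- + 4 Fe2+ + 6 H+  ->  N2O + 4 Fe3+ + 3 H2O

All coefficients are exact rationals (:class:`fractions.Fraction`) so the
conversion ratios consumed by the mass-balance estimator carry no float
error.  Electron accounting uses only the N and Fe oxidation states; O and H
are redox-inert in both reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Mapping, Optional, Union

__all__ = [
    "Species",
    "Reaction",
    "BalanceReport",
    "SPECIES",
    "ENZYMATIC_NITRATE_REDUCTION",
    "CHEMODENITRIFICATION",
    "GOETHITE_CHEMODENITRIFICATION",
    "check_balance",
    "fe_per_nitrate_enzymatic",
    "chem_ratios",
]

Coefficient = Union[int, str, Fraction, Rational]


@dataclass(frozen=True)
class Species:
    """A chemical species with element composition, charge and (where
    redox-active here) the N or Fe oxidation state."""

    name: str
    elements: Mapping[str, int]
    charge: int
    n_oxidation_state: Optional[int] = None
    fe_oxidation_state: Optional[int] = None

    def __post_init__(self) -> None:
        for element, count in self.elements.items():
            if not (isinstance(count, int) and count > 0):
                raise ValueError(
                    f"species {self.name!r}: element count for {element} "
                    f"must be a positive integer, got {count!r}"
                )
        if "N" in self.elements and self.n_oxidation_state is None:
            raise ValueError(f"species {self.name!r} contains N but has no N oxidation state")
        if "Fe" in self.elements and self.fe_oxidation_state is None:
            raise ValueError(f"species {self.name!r} contains Fe but has no Fe oxidation state")


#: The predefined species of the NRFO network.  FeO(OH) (goethite-like
#: Fe(III) oxyhydroxide) is definable so mineral-product variants of
#: chemodenitrification can be expressed and balance-checked, but the
#: canonical network tracks dissolved Fe3+.
SPECIES: dict[str, Species] = {
    s.name: s
    for s in [
        Species("NO3-", {"N": 1, "O": 3}, -1, n_oxidation_state=+5),
        Species("NO2-", {"N": 1, "O": 2}, -1, n_oxidation_state=+3),
        Species("N2O", {"N": 2, "O": 1}, 0, n_oxidation_state=+1),
        Species("N2", {"N": 2}, 0, n_oxidation_state=0),
        Species("Fe2+", {"Fe": 1}, +2, fe_oxidation_state=+2),
        Species("Fe3+", {"Fe": 1}, +3, fe_oxidation_state=+3),
        Species("H+", {"H": 1}, +1),
        Species("H2O", {"H": 2, "O": 1}, 0),
        Species("FeO(OH)", {"Fe": 1, "O": 2, "H": 1}, 0, fe_oxidation_state=+3),
    ]
}


def _as_fraction(value: Coefficient) -> Fraction:
    if isinstance(value, float):
        raise TypeError(
            f"stoichiometric coefficients must be exact rationals, got float {value!r}; "
            "pass an int, Fraction or string like '1/2'"
        )
    return Fraction(value)


def _coerce_side(side: Mapping[str, Coefficient], label: str, which: str) -> dict[str, Fraction]:
    out: dict[str, Fraction] = {}
    for name, coeff in side.items():
        if name not in SPECIES:
            raise KeyError(
                f"reaction {label!r}: unknown species {name!r} among {which}; "
                f"known species: {sorted(SPECIES)}"
            )
        frac = _as_fraction(coeff)
        if frac <= 0:
            raise ValueError(f"reaction {label!r}: coefficient of {name!r} must be > 0, got {frac}")
        out[name] = frac
    return out


@dataclass(frozen=True)
class Reaction:
    """A redox reaction over the predefined species, with exact rational
    stoichiometric coefficients."""

    label: str
    reactants: Mapping[str, Coefficient]
    products: Mapping[str, Coefficient]

    def __post_init__(self) -> None:
        reactants = _coerce_side(self.reactants, self.label, "reactants")
        products = _coerce_side(self.products, self.label, "products")
        both = set(reactants) & set(products)
        if both:
            raise ValueError(f"reaction {self.label!r}: species on both sides: {sorted(both)}")
        object.__setattr__(self, "reactants", reactants)
        object.__setattr__(self, "products", products)

    def coefficient(self, name: str) -> Fraction:
        """Coefficient of ``name`` regardless of side."""
        if name in self.reactants:
            return self.reactants[name]
        if name in self.products:
            return self.products[name]
        raise KeyError(f"species {name!r} not in reaction {self.label!r}")


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of mass / charge / electron balance checks on a reaction."""

    element_balanced: Mapping[str, bool]
    charge_balanced: bool
    electron_balanced: bool
    discrepancies: Mapping[str, tuple[Fraction, Fraction]] = field(default_factory=dict)

    @property
    def is_balanced(self) -> bool:
        return (
            all(self.element_balanced.values())
            and self.charge_balanced
            and self.electron_balanced
        )


def _side_totals(side: Mapping[str, Fraction]):
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    # weighted sum of oxidation numbers over the redox-active elements
    n_ox = Fraction(0)
    fe_ox = Fraction(0)
    for name, coeff in side.items():
        sp = SPECIES[name]
        for element, count in sp.elements.items():
            elements[element] = elements.get(element, Fraction(0)) + coeff * count
        charge += coeff * sp.charge
        if sp.n_oxidation_state is not None:
            n_ox += coeff * sp.elements["N"] * sp.n_oxidation_state
        if sp.fe_oxidation_state is not None:
            fe_ox += coeff * sp.elements["Fe"] * sp.fe_oxidation_state
    return elements, charge, n_ox, fe_ox


def check_balance(reaction: Reaction) -> BalanceReport:
    """Check per-element mass balance, net charge balance and electron
    balance of a reaction.

    Electron balance requires the electrons released by Fe oxidation
    (Fe2+ -> Fe3+, 1 e- each) to equal the electrons taken up by the change
    in N oxidation state, both weighted by coefficients.
    """
    l_elems, l_charge, l_nox, l_feox = _side_totals(reaction.reactants)
    r_elems, r_charge, r_nox, r_feox = _side_totals(reaction.products)

    element_balanced: dict[str, bool] = {}
    discrepancies: dict[str, tuple[Fraction, Fraction]] = {}
    for element in sorted(set(l_elems) | set(r_elems)):
        left = l_elems.get(element, Fraction(0))
        right = r_elems.get(element, Fraction(0))
        ok = left == right
        element_balanced[element] = ok
        if not ok:
            discrepancies[element] = (left, right)

    # electrons donated by Fe oxidation minus electrons accepted by N reduction
    donated = r_feox - l_feox
    accepted = l_nox - r_nox
    return BalanceReport(
        element_balanced=element_balanced,
        charge_balanced=l_charge == r_charge,
        electron_balanced=donated == accepted,
        discrepancies=discrepancies,
    )


#: Enzymatic NRFO: microbial nitrate reduction to nitrite with Fe(II) as donor.
ENZYMATIC_NITRATE_REDUCTION = Reaction(
    label="enzymatic nitrate reduction by Fe(II)",
    reactants={"NO3-": 1, "Fe2+": 2, "H+": 2},
    products={"Fe3+": 2, "NO2-": 1, "H2O": 1},
)

#: Chemodenitrification: abiotic nitrite reduction by Fe(II) to N2O.
CHEMODENITRIFICATION = Reaction(
    label="chemodenitrification",
    reactants={"NO2-": 2, "Fe2+": 4, "H+": 6},
    products={"N2O": 1, "Fe3+": 4, "H2O": 3},
)

#: A mineral-product chemodenitrification variant sometimes written with
#: goethite (FeO(OH)) as the Fe(III) sink.  As printed here it is
#: Fe-unbalanced (4 Fe on the left, 10 on the right) and is kept only as a
#: balance-checker test case, not as part of the canonical network.
GOETHITE_CHEMODENITRIFICATION = Reaction(
    label="goethite chemodenitrification (as printed; Fe-unbalanced)",
    reactants={"Fe2+": 4, "NO2-": 2, "H2O": 5},
    products={"FeO(OH)": 10, "N2O": 1, "H+": 6},
)


def fe_per_nitrate_enzymatic() -> Fraction:
    """Moles of Fe(II) oxidized per mole of NO3- reduced to NO2- when Fe(II)
    is the sole electron donor (exactly 2, from the enzymatic reaction)."""
    rxn = ENZYMATIC_NITRATE_REDUCTION
    return rxn.reactants["Fe2+"] / rxn.reactants["NO3-"]


def chem_ratios() -> dict[str, Fraction]:
    """Conversion ratios of chemodenitrification.

    Returns
    -------
    dict with exact rational values:
        ``fe_per_nitrite``  mol Fe(II) oxidized per mol NO2- reduced (2),
        ``n2o_per_nitrite`` mol N2O produced per mol NO2- reduced (1/2),
        ``fe_per_n2o``      mol Fe(II) oxidized per mol N2O produced (4).
    """
    rxn = CHEMODENITRIFICATION
    fe = rxn.reactants["Fe2+"]
    no2 = rxn.reactants["NO2-"]
    n2o = rxn.products["N2O"]
    return {
        "fe_per_nitrite": fe / no2,
        "n2o_per_nitrite": n2o / no2,
        "fe_per_n2o": fe / n2o,
    }
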