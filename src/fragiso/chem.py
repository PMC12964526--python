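"""Elemental formulas, nuclide data, the SMX fragment catalog, and
isotope label / mass-balance arithmetic.

All exact masses are in unified atomic mass units (u), abundances are atom
fractions, and delta values are per mil (1e-3 relative deviations of isotope
ratios).  A positive ion's m/z subtracts one electron mass per charge.

The fragment catalog models sulfamethoxazole (SMX, C10H11N3O3S) and its two
HCD fragment cations: F92 (aniline-derived, C6H6N+) and F99
(aminomethylisoxazole-derived, C4H7N2O+).  For each fragment three
isotopologues are monitored: the all-light base peak, the singly
13C-substituted species, and the singly 15N-substituted species.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import AmbiguousPeakError, ValidationError

__all__ = [
    "ELECTRON_MASS_U",
    "NATURAL_13C_ATOM_FRACTION",
    "NATURAL_15N_ATOM_FRACTION",
    "HEAVY_MASS_NUMBER",
    "IsotopeTable",
    "DEFAULT_ISOTOPES",
    "ElementalFormula",
    "IsotopologueSpec",
    "MoleculeDef",
    "SMX",
    "smx_catalog",
    "monoisotopic_mz",
    "match_peak",
    "stochastic_isotopologue_ratio",
    "natural_per_atom_ratio",
    "position_enrichment_from_mixing",
    "fragment_calc_from_bulk",
    "bulk_from_fragments",
    "exact_bulk_from_fragments",
]

#: CODATA electron mass in u.
ELECTRON_MASS_U = 5.48579909065e-4

#: Default atom fractions used by the label-mixing arithmetic (overridable).
NATURAL_13C_ATOM_FRACTION = 0.0107
NATURAL_15N_ATOM_FRACTION = 0.003663

#: Heavy mass number monitored for each element of interest.
HEAVY_MASS_NUMBER = {"C": 13, "N": 15}

# element -> ((mass number, exact mass / u, natural atom fraction), ...)
# AME2020 masses, IUPAC representative abundances.
_NUCLIDES: dict[str, tuple[tuple[int, float, float], ...]] = {
    "H": ((1, 1.00782503207, 0.999885), (2, 2.01410177785, 0.000115)),
    "C": ((12, 12.0, 0.9893), (13, 13.00335483507, 0.0107)),
    "N": ((14, 14.00307400443, 0.99636), (15, 15.00010889888, 0.00364)),
    "O": (
        (16, 15.99491461957, 0.99757),
        (17, 16.99913175650, 0.00038),
        (18, 17.99915961286, 0.00205),
    ),
    "S": (
        (32, 31.97207117440, 0.9499),
        (33, 32.97145890980, 0.0075),
        (34, 33.96786700400, 0.0425),
        (36, 35.96708071000, 0.0001),
    ),
}


@dataclass(frozen=True)
class IsotopeTable:
    """Exact masses and natural abundances per nuclide, plus electron mass."""

    nuclides: Mapping[str, tuple[tuple[int, float, float], ...]]
    electron_mass: float = ELECTRON_MASS_U

    def __post_init__(self) -> None:
        for element, rows in self.nuclides.items():
            total = sum(abundance for _, _, abundance in rows)
            if abs(total - 1.0) > 1e-6:
                raise ValidationError(
                    f"isotope abundances of {element!r} sum to {total}, not 1"
                )

    def isotopes(self, element: str) -> tuple[tuple[int, float, float], ...]:
        try:
            return self.nuclides[element]
        except KeyError:
            raise ValidationError(f"unknown element {element!r}") from None

    def mass(self, element: str, mass_number: int) -> float:
        for a, mass, _ in self.isotopes(element):
            if a == mass_number:
                return mass
        raise ValidationError(f"unknown nuclide {mass_number}{element}")

    def abundance(self, element: str, mass_number: int) -> float:
        for a, _, abundance in self.isotopes(element):
            if a == mass_number:
                return abundance
        raise ValidationError(f"unknown nuclide {mass_number}{element}")

    def principal(self, element: str) -> tuple[int, float, float]:
        """Most abundant (light, for CHNOS) isotope of an element."""
        return max(self.isotopes(element), key=lambda row: row[2])


DEFAULT_ISOTOPES = IsotopeTable(_NUCLIDES)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Atom counts per element symbol, e.g. ``{"C": 6, "H": 6, "N": 1}``."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValidationError("empty elemental formula")
        for element, count in self.counts.items():
            if not isinstance(count, int) or count < 0:
                raise ValidationError(
                    f"atom count of {element!r} must be a non-negative integer, got {count!r}"
                )
        if all(count == 0 for count in self.counts.values()):
            raise ValidationError("formula must contain at least one atom")

    @classmethod
    def from_string(cls, formula: str) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``"C10H11N3O3S"``."""
        counts: dict[str, int] = {}
        position = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != position:
                raise ValidationError(f"cannot parse formula {formula!r}")
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            position = match.end()
        if position != len(formula) or not counts:
            raise ValidationError(f"cannot parse formula {formula!r}")
        return cls(counts)

    def n(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __str__(self) -> str:
        return "".join(
            f"{el}{c if c != 1 else ''}" for el, c in self.counts.items() if c > 0
        )


@dataclass(frozen=True)
class IsotopologueSpec:
    """A monitored fragment-ion species with explicit heavy substitutions.

    ``substitutions`` maps element symbol -> (heavy mass number, count of
    substituted atoms); all remaining atoms are the principal isotope.
    ``label`` is the key used in scan tables.
    """

    fragment_name: str
    formula: ElementalFormula
    substitutions: Mapping[str, tuple[int, int]]
    charge: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValidationError(
                f"{self.fragment_name}: charge must be >= 1, got {self.charge}"
            )
        for element, (_, count) in self.substitutions.items():
            if count < 0 or count > self.formula.n(element):
                raise ValidationError(
                    f"{self.fragment_name}: {count} substituted {element} atoms "
                    f"exceed formula count {self.formula.n(element)}"
                )
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if not self.substitutions:
            return self.fragment_name
        parts = [
            f"{a}{el}" for el, (a, count) in self.substitutions.items() if count > 0
        ]
        return f"{self.fragment_name}-" + "-".join(parts)


@dataclass(frozen=True)
class MoleculeDef:
    """A molecule plus its fragment partition (per-element atom counts)."""

    name: str
    formula: ElementalFormula
    fragments: Mapping[str, Mapping[str, int]]

    def __post_init__(self) -> None:
        for element in self.formula.counts:
            total = sum(frag.get(element, 0) for frag in self.fragments.values())
            if total > self.formula.n(element):
                raise ValidationError(
                    f"{self.name}: fragment {element} atoms ({total}) exceed "
                    f"molecule count ({self.formula.n(element)})"
                )

    def fragment_count(self, fragment_name: str, element: str) -> int:
        try:
            fragment = self.fragments[fragment_name]
        except KeyError:
            raise ValidationError(
                f"{self.name}: unknown fragment {fragment_name!r}"
            ) from None
        return fragment.get(element, 0)


#: Sulfamethoxazole and its two monitored HCD fragments.  The partition
#: lists skeletal C/N/O atoms only: the fragment cations pick up protons
#: during ionization, so H is not conserved between molecule and fragments.
SMX = MoleculeDef(
    name="SMX",
    formula=ElementalFormula.from_string("C10H11N3O3S"),
    fragments={
        "F92": {"C": 6, "N": 1},
        "F99": {"C": 4, "N": 2, "O": 1},
    },
)


def smx_catalog() -> list[IsotopologueSpec]:
    """The six monitored SMX fragment isotopologues (base, 13C1, 15N1 each)."""
    specs: list[IsotopologueSpec] = []
    for fragment_name, formula_string in (("F92", "C6H6N"), ("F99", "C4H7N2O")):
        formula = ElementalFormula.from_string(formula_string)
        specs.append(IsotopologueSpec(fragment_name, formula, {}))
        specs.append(IsotopologueSpec(fragment_name, formula, {"C": (13, 1)}))
        specs.append(IsotopologueSpec(fragment_name, formula, {"N": (15, 1)}))
    return specs


def monoisotopic_mz(
    spec: IsotopologueSpec, table: IsotopeTable = DEFAULT_ISOTOPES
) -> float:
    """Exact m/z of an isotopologue: summed nuclide masses with heavy
    substitutions applied, minus one electron mass per positive charge,
    divided by the charge."""
    mass = 0.0
    for element, count in spec.formula.counts.items():
        heavy_number, heavy_count = spec.substitutions.get(element, (0, 0))
        light_number, light_mass, _ = table.principal(element)
        mass += (count - heavy_count) * light_mass
        if heavy_count:
            mass += heavy_count * table.mass(element, heavy_number)
    mass -= spec.charge * table.electron_mass
    return mass / spec.charge


def match_peak(
    observed_mz: float,
    catalog: Iterable[IsotopologueSpec],
    tolerance_ppm: float,
    table: IsotopeTable = DEFAULT_ISOTOPES,
) -> IsotopologueSpec | None:
    """Assign an observed m/z to the unique catalog species within tolerance.

    Returns None if nothing matches; raises AmbiguousPeakError when two
    species fall inside the tolerance window.
    """
    if tolerance_ppm <= 0:
        raise ValidationError(f"tolerance_ppm must be > 0, got {tolerance_ppm}")
    matches = [
        spec
        for spec in catalog
        if abs(monoisotopic_mz(spec, table) - observed_mz) / observed_mz * 1e6
        <= tolerance_ppm
    ]
    if len(matches) > 1:
        labels = ", ".join(spec.label for spec in matches)
        raise AmbiguousPeakError(
            f"m/z {observed_mz} matches more than one species at "
            f"{tolerance_ppm} ppm: {labels}"
        )
    return matches[0] if matches else None


def stochastic_isotopologue_ratio(
    formula: ElementalFormula, element: str, per_atom_ratio: float
) -> float:
    """Expected singly-substituted/unsubstituted abundance ratio under a
    uniform stochastic distribution of the heavy isotope: n_atoms * ratio."""
    n_atoms = formula.n(element)
    if n_atoms == 0:
        raise ValidationError(f"element {element!r} absent from formula {formula}")
    if per_atom_ratio <= 0:
        raise ValidationError(f"per_atom_ratio must be > 0, got {per_atom_ratio}")
    return n_atoms * per_atom_ratio


def natural_per_atom_ratio(
    element: str, table: IsotopeTable = DEFAULT_ISOTOPES
) -> float:
    """Natural heavy/light single-atom isotope ratio (e.g. 13C/12C)."""
    heavy = HEAVY_MASS_NUMBER.get(element)
    if heavy is None:
        raise ValidationError(f"no monitored heavy isotope for element {element!r}")
    return table.abundance(element, heavy) / table.principal(element)[2]


def position_enrichment_from_mixing(
    labeled_moles: float,
    unlabeled_moles: float,
    label_atom_fraction: float,
    natural_atom_fraction: float,
) -> float:
    """Delta enrichment (per mil) at the labeled position after mixing
    labeled and unlabeled material.

    Atom fractions at the labeled position are mixed mole-weighted, converted
    to isotope ratios R = x/(1-x), and compared with the natural ratio.
    """
    if labeled_moles <= 0 or unlabeled_moles <= 0:
        raise ValidationError("labeled_moles and unlabeled_moles must be > 0")
    for name, x in (
        ("label_atom_fraction", label_atom_fraction),
        ("natural_atom_fraction", natural_atom_fraction),
    ):
        if not 0.0 < x < 1.0:
            raise ValidationError(f"{name} must lie in (0, 1), got {x}")
    if label_atom_fraction <= natural_atom_fraction:
        warnings.warn(
            "label atom fraction does not exceed natural abundance: "
            "this mixture is a depletion standard",
            stacklevel=2,
        )
    spike = labeled_moles / (labeled_moles + unlabeled_moles)
    x_mixed = spike * label_atom_fraction + (1.0 - spike) * natural_atom_fraction
    r_mixed = x_mixed / (1.0 - x_mixed)
    r_natural = natural_atom_fraction / (1.0 - natural_atom_fraction)
    return (r_mixed / r_natural - 1.0) * 1000.0


def fragment_calc_from_bulk(
    delta_bulk_shift: float,
    molecule: MoleculeDef,
    fragment_name: str,
    element: str,
) -> float:
    """Convert a compound-average delta shift into the fragment-level shift,
    assuming the label sits wholly inside the named fragment.

    First-order delta mass balance: shift * n_element(molecule) / n_element(fragment).
    """
    n_fragment = molecule.fragment_count(fragment_name, element)
    if n_fragment == 0:
        raise ValidationError(
            f"fragment {fragment_name!r} contains no {element} atoms"
        )
    return delta_bulk_shift * molecule.formula.n(element) / n_fragment


def bulk_from_fragments(
    fragment_deltas: Mapping[str, float],
    molecule: MoleculeDef,
    element: str,
) -> float:
    """Atom-count-weighted mean of fragment deltas (first-order mass balance).

    Requires the named fragments to partition every atom of ``element`` in
    the molecule.
    """
    n_total = molecule.formula.n(element)
    n_covered = sum(
        molecule.fragment_count(name, element) for name in fragment_deltas
    )
    if n_covered != n_total:
        raise ValidationError(
            f"fragments cover {n_covered} of {n_total} {element} atoms in "
            f"{molecule.name}; partition incomplete"
        )
    return (
        sum(
            molecule.fragment_count(name, element) * delta
            for name, delta in fragment_deltas.items()
        )
        / n_total
    )


def exact_bulk_from_fragments(
    fragment_deltas: Mapping[str, float],
    molecule: MoleculeDef,
    element: str,
    reference_ratio: float | None = None,
) -> float:
    """Exact (ratio-space) bulk delta from fragment deltas; test oracle for
    the first-order approximation in :func:`bulk_from_fragments`."""
    if reference_ratio is None:
        reference_ratio = natural_per_atom_ratio(element)
    n_total = molecule.formula.n(element)
    n_covered = sum(
        molecule.fragment_count(name, element) for name in fragment_deltas
    )
    if n_covered != n_total:
        raise ValidationError(
            f"fragments cover {n_covered} of {n_total} {element} atoms in "
            f"{molecule.name}; partition incomplete"
        )
    heavy_atoms = 0.0
    for name, delta in fragment_deltas.items():
        ratio = reference_ratio * (1.0 + delta / 1000.0)
        heavy_atoms += molecule.fragment_count(name, element) * ratio / (1.0 + ratio)
    x_bulk = heavy_atoms / n_total
    r_bulk = x_bulk / (1.0 - x_bulk)
    return (r_bulk / reference_ratio - 1.0) * 1000.0
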