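"""Mass-action reaction schemes for myoglobin oxidation chemistry.

A scheme lists the chemical species at a point in the meat (the three
myoglobin redox forms plus dissolved oxygen), an integer stoichiometric
matrix, rate constants at a reference temperature, and a single activation
energy used to rescale every rate constant with storage temperature.

Units convention: myoglobin forms are dimensionless fractions that sum to 1
at every point; dissolved oxygen is in mol·m⁻³. Rate-constant units are
therefore mixed and documented per reaction in the scheme file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

R_GAS = 8.314
"""Molar gas constant, J·mol⁻¹·K⁻¹."""

MYOGLOBIN_FORM = "myoglobin-form"
DISSOLVED_GAS = "dissolved-gas"

__all__ = [
    "Species",
    "ReactionScheme",
    "SchemeError",
    "load_scheme",
    "default_scheme",
    "default_scheme_path",
    "mass_action_rates",
    "arrhenius_scale",
    "R_GAS",
]


class SchemeError(ValueError):
    """Raised when a reaction scheme violates a structural invariant."""


@dataclass(frozen=True)
class Species:
    """One chemical species tracked by the model.

    Only dissolved gases may be flagged diffusive; in the beef model that is
    dissolved O₂, which diffuses inward from the exposed surface while the
    myoglobin forms stay where they are (bound to the muscle matrix).
    """

    name: str
    role: Literal["myoglobin-form", "dissolved-gas", "other"] = "other"
    diffusive: bool = False


@dataclass(frozen=True)
class ReactionScheme:
    """Validated mass-action scheme with temperature scaling.

    Attributes
    ----------
    species : tuple of Species, length M
    stoich : (M, N) integer array; negative entries are consumed reactants
        (their magnitude is the reaction order), positive entries products.
    k_ref : (N,) rate constants at ``T_ref_K``.
    T_ref_K : reference temperature in kelvin.
    D_O2 : diffusivity of dissolved oxygen, m²·s⁻¹.
    Ea_J_mol : single activation energy applied to every reaction, J·mol⁻¹.
    o2_solubility : dissolved-O₂ surface concentration per headspace
        percentage point, mol·m⁻³·%⁻¹ (Henry-law style coefficient).
    reaction_names : optional labels, length N.
    """

    species: tuple[Species, ...]
    stoich: np.ndarray
    k_ref: np.ndarray
    T_ref_K: float
    D_O2: float
    Ea_J_mol: float
    o2_solubility: float = 0.0135
    reaction_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        stoich = np.asarray(self.stoich, dtype=int)
        k_ref = np.asarray(self.k_ref, dtype=float)
        object.__setattr__(self, "stoich", stoich)
        object.__setattr__(self, "k_ref", k_ref)
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise SchemeError("species names must be unique")
        M = len(self.species)
        if stoich.ndim != 2 or stoich.shape[0] != M:
            raise SchemeError(
                f"stoich must have one row per species ({M}), got {stoich.shape}"
            )
        N = stoich.shape[1]
        if k_ref.shape != (N,):
            raise SchemeError(f"k_ref must have length {N}, got {k_ref.shape}")
        if np.any(k_ref < 0):
            raise SchemeError("rate constants k_ref must be non-negative")
        if self.D_O2 < 0:
            raise SchemeError("D_O2 must be non-negative")
        if self.T_ref_K <= 0:
            raise SchemeError("T_ref_K must be positive")
        if self.o2_solubility < 0:
            raise SchemeError("o2_solubility must be non-negative")
        if np.any((stoich < 0).sum(axis=0) == 0):
            bad = int(np.flatnonzero((stoich < 0).sum(axis=0) == 0)[0])
            raise SchemeError(f"reaction {bad} consumes nothing (no negative entry)")
        mb = self.myoglobin_indices
        col_sums = stoich[mb, :].sum(axis=0)
        if np.any(col_sums != 0):
            bad = int(np.flatnonzero(col_sums != 0)[0])
            raise SchemeError(
                "myoglobin-form stoichiometry must sum to zero in every "
                f"reaction (total myoglobin conserved); reaction {bad} sums "
                f"to {int(col_sums[bad])}"
            )
        for sp in self.species:
            if sp.diffusive and sp.role != DISSOLVED_GAS:
                raise SchemeError(f"only dissolved gases may diffuse ({sp.name})")
        if not self.reaction_names:
            object.__setattr__(
                self, "reaction_names", tuple(f"r{j}" for j in range(N))
            )
        elif len(self.reaction_names) != N:
            raise SchemeError("reaction_names length must equal reaction count")

    # -- lookups -----------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)

    @property
    def myoglobin_indices(self) -> np.ndarray:
        return np.array(
            [i for i, sp in enumerate(self.species) if sp.role == MYOGLOBIN_FORM],
            dtype=int,
        )

    @property
    def diffusive_indices(self) -> np.ndarray:
        return np.array(
            [i for i, sp in enumerate(self.species) if sp.diffusive], dtype=int
        )

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    @property
    def orders(self) -> np.ndarray:
        """(M, N) reaction orders: magnitude of negative stoichiometry."""
        return np.maximum(-self.stoich, 0)

    def with_ea(self, Ea_J_mol: float) -> "ReactionScheme":
        """Copy of the scheme with a different activation energy."""
        return replace(self, Ea_J_mol=float(Ea_J_mol))


# -- file format -----------------------------------------------------------


class _SpeciesModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    role: Literal["myoglobin-form", "dissolved-gas", "other"] = "other"
    diffusive: bool = False


class _ReactionModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str = ""
    reactants: dict[str, int]
    products: dict[str, int] = Field(default_factory=dict)
    k_ref: float
    units: str = ""


class _SchemeFileModel(BaseModel):
    """Strict schema of the on-disk scheme file (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    species: list[_SpeciesModel]
    reactions: list[_ReactionModel]
    T_ref_C: float
    D_O2_m2_s: float
    Ea_kJ_mol: float
    o2_solubility_mol_m3_per_pct: float = 0.0135
    description: str = ""


def load_scheme(path: str | Path) -> ReactionScheme:
    """Load and validate a reaction scheme from a YAML/JSON file.

    The file lists ``species[]``, ``reactions[]`` (reactants and products
    with multiplicities plus ``k_ref``), ``T_ref_C``, ``D_O2_m2_s`` and
    ``Ea_kJ_mol``; unknown keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scheme file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        model = _SchemeFileModel.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemeError(f"malformed scheme file {path}: {loc}: {first['msg']}") from exc

    species = tuple(
        Species(name=s.name, role=s.role, diffusive=s.diffusive) for s in model.species
    )
    names = [s.name for s in species]
    M, N = len(species), len(model.reactions)
    stoich = np.zeros((M, N), dtype=int)
    for j, rxn in enumerate(model.reactions):
        for mapping, sign in ((rxn.reactants, -1), (rxn.products, +1)):
            for nm, mult in mapping.items():
                if nm not in names:
                    raise SchemeError(
                        f"reaction {rxn.name or j} references unknown species {nm!r}"
                    )
                if mult <= 0:
                    raise SchemeError(
                        f"reaction {rxn.name or j}: multiplicity for {nm} must be >= 1"
                    )
                stoich[names.index(nm), j] += sign * mult
    return ReactionScheme(
        species=species,
        stoich=stoich,
        k_ref=np.array([r.k_ref for r in model.reactions], dtype=float),
        T_ref_K=model.T_ref_C + 273.15,
        D_O2=model.D_O2_m2_s,
        Ea_J_mol=model.Ea_kJ_mol * 1e3,
        o2_solubility=model.o2_solubility_mol_m3_per_pct,
        reaction_names=tuple(r.name or f"r{j}" for j, r in enumerate(model.reactions)),
    )


def default_scheme_path() -> Path:
    """Path of the bundled 4-reaction stand-in scheme file."""
    return Path(resources.files("myocolor") / "data" / "default_scheme.yaml")


def default_scheme() -> ReactionScheme:
    """The bundled 4-reaction stand-in scheme (see its file for tuning notes)."""
    return load_scheme(default_scheme_path())


# -- kinetics --------------------------------------------------------------


def mass_action_rates(
    C: np.ndarray, scheme: ReactionScheme, k: np.ndarray
) -> np.ndarray:
    """Mass-action time derivatives dCᵢ/dt = Σⱼ aᵢⱼ kⱼ Π Cᵢ^(−aᵢⱼ).

    The product runs over the reactant species of each reaction, with the
    reaction order given by the magnitude of the negative stoichiometric
    coefficient.

    Parameters
    ----------
    C : (M,) or (M, n) array of concentrations (n = spatial nodes).
    k : (N,) rate constants.

    Returns
    -------
    Array of the same shape as ``C``.
    """
    C = np.asarray(C, dtype=float)
    k = np.asarray(k, dtype=float)
    if C.shape[0] != scheme.n_species:
        raise ValueError(
            f"C has {C.shape[0]} species rows, scheme has {scheme.n_species}"
        )
    if k.shape != (scheme.n_reactions,):
        raise ValueError(
            f"k must have length {scheme.n_reactions}, got {k.shape}"
        )
    orders = scheme.orders
    flat = C.ndim == 1
    Cm = C[:, None] if flat else C
    n = Cm.shape[1]
    rates = np.empty((scheme.n_reactions, n), dtype=float)
    for j in range(scheme.n_reactions):
        r = np.full(n, k[j])
        for i in np.flatnonzero(orders[:, j]):
            o = orders[i, j]
            r = r * (Cm[i] if o == 1 else Cm[i] ** o)
        rates[j] = r
    dC = scheme.stoich @ rates
    return dC[:, 0] if flat else dC


def arrhenius_scale(
    scheme: ReactionScheme, T_K: float, Ea_J_mol: float | None = None
) -> np.ndarray:
    """Rate constants at temperature ``T_K`` (kelvin).

    Uses the relative Arrhenius form
    ``k(T) = k(T_ref) · exp(−(Ea/R)·(1/T − 1/T_ref))``,
    which returns exactly ``k_ref`` at the reference temperature. A single
    activation energy is applied to every reaction.
    """
    if T_K <= 0:
        raise ValueError("absolute temperature must be positive")
    Ea = scheme.Ea_J_mol if Ea_J_mol is None else float(Ea_J_mol)
    factor = np.exp(-(Ea / R_GAS) * (1.0 / T_K - 1.0 / scheme.T_ref_K))
    return scheme.k_ref * factor
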