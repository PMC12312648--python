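"""Bond-graph representation of biochemical reaction networks.

A network is a list of species (energy-storing C components, or chemostatted
Se components) and a list of flux-generating elements (Re components and the
bespoke transcription / lumped-elongation components).  Junction structure
(0/1 junctions and TF transformers) is folded into the forward/reverse
stoichiometric matrices at compile time: a 1-junction sums the chemical
potentials feeding a reaction, a 0-junction sums the fluxes feeding a
species, and a TF of modulus ``s`` multiplies both — which is exactly what
the matrices encode.

Species carry a thermodynamic constant ``K`` (per molecule) and an amount
``x`` (molecules); the dimensionless chemical potential is ``ln(K x)`` in
units of kB·T.  Reaction fluxes follow the Marcelin–de Donder form
``v = r (exp(mu_f) - exp(mu_r))``, which guarantees that the per-reaction
dissipation ``(mu_f - mu_r)·v`` is non-negative and that detailed balance
holds at equilibrium regardless of the rate parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import sympy

from .errors import ConfigurationError, StateError, UnsupportedLawError

SPECIES_KINDS = ("dynamic", "chemostat_amount", "chemostat_potential")
REACTION_LAWS = ("mass_action", "transcription", "elongation")

#: amounts below this are treated as zero when taking logarithms
_LOG_FLOOR = 1e-300


def chemical_potential(K: float, x: float) -> float:
    """Dimensionless chemical potential ``ln(K x)`` of a species.

    Parameters
    ----------
    K : thermodynamic constant (per molecule), must be positive.
    x : amount (molecules), must be positive.
    """
    if K <= 0:
        raise StateError(f"thermodynamic constant must be positive, got K={K}")
    if x <= 0:
        raise StateError(f"chemical potential undefined at non-positive amount x={x}")
    return math.log(K * x)


def reaction_flux(r: float, mu_f: float, mu_r: float) -> float:
    """Marcelin–de Donder flux ``r (exp(mu_f) - exp(mu_r))``.

    The flux has the sign of ``mu_f - mu_r``; overflow in either exponential
    raises :class:`StateError` rather than returning a non-finite number.
    """
    if r <= 0:
        raise ConfigurationError(f"rate parameter must be positive, got r={r}")
    with np.errstate(over="raise"):
        try:
            v = r * (np.exp(mu_f) - np.exp(mu_r))
        except FloatingPointError as exc:
            raise StateError(
                f"overflow evaluating flux at mu_f={mu_f}, mu_r={mu_r}"
            ) from exc
    return float(v)


@dataclass
class SpeciesSpec:
    """One chemical species (bond-graph C or Se component).

    ``kind`` selects dynamic accumulation, a fixed-amount chemostat (Se whose
    K·x stays constant) or a fixed-potential chemostat (``mu_clamp`` supplies
    the dimensionless potential directly; the amount is irrelevant).
    """

    name: str
    K: float
    x0: float = 0.0
    kind: str = "dynamic"
    mu_clamp: Optional[float] = None

    def __post_init__(self):
        if self.K <= 0:
            raise ConfigurationError(f"species {self.name!r}: K must be > 0, got {self.K}")
        if self.kind not in SPECIES_KINDS:
            raise ConfigurationError(f"species {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "chemostat_potential":
            if self.mu_clamp is None:
                raise ConfigurationError(
                    f"species {self.name!r}: chemostat_potential requires mu_clamp"
                )
        elif self.x0 < 0:
            raise ConfigurationError(f"species {self.name!r}: x0 must be >= 0, got {self.x0}")

    @property
    def is_dynamic(self) -> bool:
        return self.kind == "dynamic"


@dataclass
class ReactionSpec:
    """One flux-generating element (Re, Tc or lumped-elongation component).

    ``forward_stoich`` / ``reverse_stoich`` map species names to positive
    integer coefficients; TF transformers are represented by coefficients
    larger than one.  ``law_params`` carries the parameter record of the
    non-mass-action laws (see :mod:`genebond.rate_laws`).
    """

    name: str
    rate_param: float
    forward_stoich: Dict[str, int]
    reverse_stoich: Dict[str, int]
    law: str = "mass_action"
    law_params: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.rate_param <= 0:
            raise ConfigurationError(
                f"reaction {self.name!r}: rate_param must be > 0, got {self.rate_param}"
            )
        if self.law not in REACTION_LAWS:
            raise ConfigurationError(f"reaction {self.name!r}: unknown law {self.law!r}")
        for side, stoich in (("forward", self.forward_stoich), ("reverse", self.reverse_stoich)):
            for name, coeff in stoich.items():
                if int(coeff) != coeff or coeff <= 0:
                    raise ConfigurationError(
                        f"reaction {self.name!r}: {side} stoichiometry of {name!r} "
                        f"must be a positive integer, got {coeff}"
                    )


class NetworkSpec:
    """A compiled bond-graph network.

    Compiles the species/reaction lists into forward and reverse
    stoichiometric matrices ``Sf``, ``Sr`` (species × reactions) and the net
    matrix ``N = Sr - Sf``, and provides the rate field, mass-action
    constants, conserved moieties and dissipation accounting.
    """

    def __init__(self, species: Sequence[SpeciesSpec], reactions: Sequence[ReactionSpec]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate species names in network")
        rnames = [r.name for r in reactions]
        if len(set(rnames)) != len(rnames):
            raise ConfigurationError("duplicate reaction names in network")
        self.species: List[SpeciesSpec] = list(species)
        self.reactions: List[ReactionSpec] = list(reactions)
        self._index = {s.name: i for i, s in enumerate(self.species)}

        ns, nr = len(self.species), len(self.reactions)
        self.Sf = np.zeros((ns, nr))
        self.Sr = np.zeros((ns, nr))
        for j, rxn in enumerate(self.reactions):
            for side, S in ((rxn.forward_stoich, self.Sf), (rxn.reverse_stoich, self.Sr)):
                for name, coeff in side.items():
                    if name not in self._index:
                        raise ConfigurationError(
                            f"reaction {rxn.name!r} references unknown species {name!r}"
                        )
                    S[self._index[name], j] = coeff
        self.N = self.Sr - self.Sf

        self._K = np.array([s.K for s in self.species])
        self._dynamic = np.array([s.is_dynamic for s in self.species])
        self._clamped_mu = np.array(
            [s.mu_clamp if s.kind == "chemostat_potential" else np.nan for s in self.species]
        )
        self._rates = np.array([r.rate_param for r in self.reactions])
        self._mass_action = np.array([r.law == "mass_action" for r in self.reactions])
        self._special = [
            (j, r) for j, r in enumerate(self.reactions) if r.law != "mass_action"
        ]
        # bind the special laws once; avoids dispatch inside the RHS
        from . import rate_laws as _rl  # deferred to avoid a circular import

        self._special_eval = []
        for j, rxn in enumerate(self.reactions):
            if rxn.law == "transcription":
                self._special_eval.append((j, _rl.make_transcription_flux(self, rxn)))
            elif rxn.law == "elongation":
                self._special_eval.append((j, _rl.make_elongation_flux(self, rxn)))

    # ------------------------------------------------------------------ basics
    @property
    def species_names(self) -> List[str]:
        return [s.name for s in self.species]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"no species named {name!r} in network") from None

    def reaction_index(self, name: str) -> int:
        for j, r in enumerate(self.reactions):
            if r.name == name:
                return j
        raise KeyError(f"no reaction named {name!r} in network")

    def initial_state(self, overrides: Optional[Mapping[str, float]] = None) -> np.ndarray:
        """State vector of initial amounts (clamped-potential species get x0)."""
        x0 = np.array([s.x0 for s in self.species], dtype=float)
        if overrides:
            for name, value in overrides.items():
                x0[self.species_index(name)] = value
        return x0

    # -------------------------------------------------------------- potentials
    def activities(self, x: np.ndarray) -> np.ndarray:
        """Per-species ``exp(mu) = K·x`` (or ``exp(mu_clamp)`` for clamps).

        Amounts are floored at zero so that transient solver undershoot does
        not produce negative activities.
        """
        a = self._K * np.maximum(np.asarray(x, dtype=float), 0.0)
        clamped = ~np.isnan(self._clamped_mu)
        if clamped.any():
            a = np.where(clamped, np.exp(np.where(clamped, self._clamped_mu, 0.0)), a)
        return a

    def potentials(self, x: np.ndarray) -> np.ndarray:
        """Dimensionless chemical potentials; ``-inf`` at zero amounts."""
        a = self.activities(x)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(a, 0.0))

    # ------------------------------------------------------------------ fluxes
    def fluxes(self, x: np.ndarray) -> np.ndarray:
        """Per-reaction net flux at state ``x`` (molecules/min)."""
        a = self.activities(x)
        log_a = np.log(np.maximum(a, _LOG_FLOOR))
        zero = a <= 0.0

        expo_f = self.Sf.T @ log_a
        expo_r = self.Sr.T @ log_a
        # special-law columns are overwritten below; keep their exponents benign
        expo_f[~self._mass_action] = 0.0
        expo_r[~self._mass_action] = 0.0
        with np.errstate(over="raise"):
            try:
                prod_f = np.exp(expo_f)
                prod_r = np.exp(expo_r)
            except FloatingPointError as exc:
                raise StateError("overflow evaluating reaction activities") from exc
        # a zero reactant kills the corresponding one-way term exactly
        if zero.any():
            prod_f[(self.Sf.T @ zero.astype(float)) > 0] = 0.0
            prod_r[(self.Sr.T @ zero.astype(float)) > 0] = 0.0

        v = self._rates * (prod_f - prod_r)
        for j, fn in self._special_eval:
            v[j] = fn(x, a)
        if not np.all(np.isfinite(v)):
            bad = [self.reactions[j].name for j in np.flatnonzero(~np.isfinite(v))]
            raise StateError(f"non-finite flux in reactions {bad}")
        return v

    def rate_field(self) -> Callable[[float, np.ndarray], np.ndarray]:
        """Return the ODE right-hand side ``f(t, x) = N·v(x)``.

        Rows of chemostatted species (either flavour) are zeroed so their
        amounts never change, while they still contribute potential to every
        flux they touch.
        """
        N = self.N.copy()
        N[~self._dynamic, :] = 0.0

        def rhs(t: float, x: np.ndarray) -> np.ndarray:
            return N @ self.fluxes(x)

        return rhs

    # ------------------------------------------------------- derived quantities
    def to_mass_action(self) -> List[Tuple[float, float]]:
        """Per-reaction kinetic constants ``(k_f, k_r)``.

        ``k_f = r ∏ K_i^{s_f}`` and ``k_r = r ∏ K_i^{s_r}``: standard mass
        action with these constants reproduces the bond-graph flux exactly.
        Only defined when every reaction is mass action.
        """
        out = []
        for j, rxn in enumerate(self.reactions):
            if rxn.law != "mass_action":
                raise UnsupportedLawError(
                    f"reaction {rxn.name!r} has law {rxn.law!r}; "
                    "kinetic constants are only defined for mass action"
                )
            kf = rxn.rate_param * float(np.prod(self._K ** self.Sf[:, j]))
            kr = rxn.rate_param * float(np.prod(self._K ** self.Sr[:, j]))
            out.append((kf, kr))
        return out

    def conserved_moieties(self) -> List[np.ndarray]:
        """Integer basis of the left null space of ``N`` (dynamic species only).

        Chemostatted rows are removed before the null-space computation, since
        a clamped species breaks any conservation law through it.  Each basis
        vector ``g`` satisfies ``gᵀN = 0`` and is returned over the full
        species ordering (zeros at chemostat positions), scaled to the
        smallest integer entries with the first nonzero entry positive.
        """
        cached = getattr(self, "_moiety_cache", None)
        if cached is not None:
            return [g.copy() for g in cached]
        dyn = np.flatnonzero(self._dynamic)
        if dyn.size == 0:
            return []
        N_dyn = sympy.Matrix(self.N[dyn, :])
        basis = N_dyn.T.nullspace()
        out = []
        for vec in basis:
            denoms = [sympy.fraction(sympy.nsimplify(e, rational=True))[1] for e in vec]
            scale = sympy.lcm([sympy.Integer(d) for d in denoms]) if denoms else 1
            ivec = [sympy.nsimplify(e * scale, rational=True) for e in vec]
            g = sympy.gcd([e for e in ivec if e != 0] or [1])
            ivec = [e / g for e in ivec]
            first = next((e for e in ivec if e != 0), 1)
            if first < 0:
                ivec = [-e for e in ivec]
            full = np.zeros(self.n_species)
            full[dyn] = [float(e) for e in ivec]
            out.append(full)
        self._moiety_cache = out
        return [g.copy() for g in out]

    def power_dissipation(self, x: np.ndarray) -> np.ndarray:
        """Per-reaction dissipation ``(mu_f - mu_r)·v`` in kB·T per minute.

        Non-negative up to roundoff for every law, since the flux sign always
        matches the potential drop.
        """
        a = self.activities(x)
        if np.any(~np.isfinite(a)):
            raise StateError("non-finite activity in dissipation evaluation")
        log_a = np.log(np.maximum(a, _LOG_FLOOR))
        mu_f = self.Sf.T @ log_a
        mu_r = self.Sr.T @ log_a
        v = self.fluxes(x)
        diss = (mu_f - mu_r) * v
        # equilibrium with an empty side (floored log) can give 0 * large; clean it
        diss[v == 0.0] = 0.0
        return diss

    # --------------------------------------------------------------- utilities
    def with_overrides(
        self,
        species: Optional[Mapping[str, Mapping]] = None,
    ) -> "NetworkSpec":
        """Copy of the network with per-species field overrides (x0, kind, ...)."""
        new_species = []
        for s in self.species:
            fields = dict(name=s.name, K=s.K, x0=s.x0, kind=s.kind, mu_clamp=s.mu_clamp)
            if species and s.name in species:
                fields.update(species[s.name])
            new_species.append(SpeciesSpec(**fields))
        return NetworkSpec(new_species, self.reactions)
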