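"""Non-mass-action rate laws: transcription, lumped elongation, degradation.

Transcription is an enzyme-catalysed conversion of energy (A) into mRNA (M)
under non-competitive inhibition, with the quasi-steady-state rate

    v = r̄ (e^muA - e^muM) / [(1 + e^muA/RbA + e^muM/RbM)(1 + e^(h·muI)/RbI)]

where the Hill modulus h enters as a TF of modulus h on the inhibitor
potential (h = 1 recovers plain non-competitive inhibition).

Lumped elongation replaces the chain of m per-step reactions
C_i + A <-> C_{i+1} (constants kf, kr) between the boundary complexes by the
closed-form quasi-steady-state flux

    v_el = kr (C_first·Â^m - C_last) (1 - Â) / (1 - Â^m),     Â = (kf/kr)·A

which equals the exact steady-state flux of the explicit chain.  The
singularity at Â = 1 is removable (limit kr (C_first - C_last)/m) and the
implementation switches branches near it; for |ln Â|·m large the expression
is evaluated with Â^{-m} (or Â^{m}) on the side that underflows harmlessly,
so the law is finite for chains of thousands of steps.

Degradation is a plain mass-action Re from the species into a clamped
low-potential sink, parameterized so the forward flux is r_deg·x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import ConfigurationError
from . import network as _net

#: half-width of the Â=1 branch switch of the elongation law
_AHAT_SWITCH = 1e-6


@dataclass
class TranscriptionParams:
    """Parameters of the transcription component (rate r̄, affinities Rb·)."""

    r_bar: float
    RbA: float
    RbM: float
    RbI: float
    h: int = 2

    def __post_init__(self):
        for name in ("r_bar", "RbA", "RbM", "RbI"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"transcription parameter {name} must be > 0")
        if int(self.h) != self.h or self.h < 1:
            raise ConfigurationError(f"Hill coefficient h must be a positive integer, got {self.h}")


@dataclass
class ElongationParams:
    """Parameters of the lumped elongation component.

    kf, kr are the per-step chain constants, m the number of lumped steps
    (m = n - 1 for a single lump).  ``r_el`` is the bond-graph rate parameter
    of the equivalent three-port component; it is only needed by the
    potential-based form and is provisional (the kinetic form is canonical).
    """

    kf: float
    kr: float
    m: int
    r_el: float | None = None

    def __post_init__(self):
        if self.kf <= 0 or self.kr <= 0:
            raise ConfigurationError("elongation constants kf, kr must be > 0")
        if int(self.m) != self.m or self.m < 1:
            raise ConfigurationError(f"lumped step count m must be a positive integer, got {self.m}")


@dataclass
class DegradationParams:
    """First-order degradation into a clamped low-potential sink.

    ``r_deg`` is the effective first-order constant (1/min): the emitted Re
    has its bond-graph rate parameter chosen so that the forward flux equals
    r_deg·x.  The sink potential defaults to -40 kB·T, low enough that the
    reverse leak is below 1e-9 of the forward flux at typical protein
    potentials (around -14 kB·T).
    """

    r_deg: float
    sink_potential: float = -40.0

    def __post_init__(self):
        if self.r_deg <= 0:
            raise ConfigurationError(f"degradation constant must be > 0, got {self.r_deg}")


# --------------------------------------------------------------------- rates
def transcription_rate(p: TranscriptionParams, mu_A: float, mu_M: float, mu_I: float) -> float:
    """Transcription flux given energy, mRNA and inhibitor potentials.

    Monotone non-increasing in ``mu_I``, saturating at ``r̄·RbA`` for large
    ``mu_A``; the flux sign equals the sign of ``mu_A - mu_M``.
    """
    eA = math.exp(mu_A)
    eM = math.exp(mu_M)
    inhibition = 1.0 + math.exp(p.h * mu_I) / p.RbI if mu_I != -math.inf else 1.0
    return p.r_bar * (eA - eM) / ((1.0 + eA / p.RbA + eM / p.RbM) * inhibition)


def _geometric_sum(ahat: float, m: int) -> float:
    """Sum_{k=0}^{m-1} Â^k, stable across the removable point Â = 1."""
    eps = ahat - 1.0
    if abs(eps) < _AHAT_SWITCH:
        if eps == 0.0:
            return float(m)
        # (Â^m - 1)/(Â - 1) via expm1/log1p: accurate arbitrarily close to 1
        return math.expm1(m * math.log1p(eps)) / eps
    # fall through to the caller's overflow-safe closed forms
    raise AssertionError("only called near Â = 1")


def elongation_rate(p: ElongationParams, C_first: float, C_last: float, A: float) -> float:
    """Quasi-steady-state flux through a lumped chain of ``m`` elongation steps.

    Equals the steady-state flux of the explicit chain
    ``C_first -> X_1 -> ... -> X_{m-1} -> C_last`` with per-step forward rate
    kf·A and reverse rate kr, for any boundary amounts.
    """
    if C_first < 0 or C_last < 0 or A < 0:
        raise ConfigurationError("elongation amounts must be non-negative")
    ahat = (p.kf / p.kr) * A
    if ahat <= 0:
        # no energy: the chain only runs backwards from C_last
        return -p.kr * C_last
    m = int(p.m)
    if abs(ahat - 1.0) < _AHAT_SWITCH:
        # v = kr (C_first Â^m - C_last) / S,  S = geometric sum
        s = _geometric_sum(ahat, m)
        ahat_m = math.exp(m * math.log1p(ahat - 1.0))
        return p.kr * (C_first * ahat_m - C_last) / s
    if ahat > 1.0:
        u = ahat ** (-m) if m * math.log(ahat) < 700 else 0.0
        return p.kr * (C_first - C_last * u) * (ahat - 1.0) / (1.0 - u)
    t = ahat ** m if m * abs(math.log(ahat)) < 700 else 0.0
    return p.kr * (C_first * t - C_last) * (1.0 - ahat) / (1.0 - t)


def elongation_rate_from_potentials(
    p: ElongationParams,
    mu_first: float,
    mu_last: float,
    mu_A: float,
    K_first: float,
    K_last: float,
    K_A: float,
) -> float:
    """Three-port potential form of the elongation component.

    Thin translation layer: potentials are converted back to amounts
    (x = e^mu / K) and fed to the kinetic form, guaranteeing identical
    numerics.  The parameter mapping of a direct potential-based rate law is
    provisional; this wrapper is the supported interface.
    """
    return elongation_rate(
        p,
        math.exp(mu_first) / K_first,
        math.exp(mu_last) / K_last,
        math.exp(mu_A) / K_A,
    )


def degradation_reaction(
    species: "_net.SpeciesSpec",
    p: DegradationParams,
    name: str | None = None,
    sink_name: str | None = None,
) -> Tuple["_net.ReactionSpec", "_net.SpeciesSpec"]:
    """Mass-action Re from ``species`` into a clamped low-potential sink.

    The bond-graph rate parameter is ``r_deg / K_species`` so the forward
    flux is exactly ``r_deg·x`` while the element stays within the
    thermodynamic formalism (degradation is modelled as energy-free).
    """
    if not species.is_dynamic:
        raise ConfigurationError(f"cannot attach degradation to chemostat {species.name!r}")
    sink = _net.SpeciesSpec(
        name=sink_name or f"{species.name}_sink",
        K=1.0,
        kind="chemostat_potential",
        mu_clamp=p.sink_potential,
    )
    rxn = _net.ReactionSpec(
        name=name or f"deg_{species.name}",
        rate_param=p.r_deg / species.K,
        forward_stoich={species.name: 1},
        reverse_stoich={sink.name: 1},
        law="mass_action",
    )
    return rxn, sink


# ---------------------------------------------------- network-law factories
def make_transcription_flux(net: "_net.NetworkSpec", rxn: "_net.ReactionSpec"):
    """Bind a transcription reaction to species indices for fast evaluation.

    The reaction must have a single forward species (energy), a single
    reverse species (mRNA) and an ``inhibitor`` species named in
    ``law_params``.  Activities stand in for ``exp(mu)`` so zero amounts are
    handled without logarithms.
    """
    lp = dict(rxn.law_params)
    try:
        inhibitor = lp.pop("inhibitor")
    except KeyError:
        raise ConfigurationError(
            f"transcription reaction {rxn.name!r} needs law_params['inhibitor']"
        ) from None
    p = TranscriptionParams(**lp)
    (iA,) = [net.species_index(n) for n in rxn.forward_stoich]
    (iM,) = [net.species_index(n) for n in rxn.reverse_stoich]
    iI = net.species_index(inhibitor)
    r_scale = rxn.rate_param  # multiplies r̄ so the file format stays uniform

    def flux(x, a):
        inhibition = 1.0 + a[iI] ** p.h / p.RbI
        return (
            r_scale
            * p.r_bar
            * (a[iA] - a[iM])
            / ((1.0 + a[iA] / p.RbA + a[iM] / p.RbM) * inhibition)
        )

    return flux


def make_elongation_flux(net: "_net.NetworkSpec", rxn: "_net.ReactionSpec"):
    """Bind a lumped-elongation reaction to species indices.

    Stoichiometry: forward {C_first: 1, A: m}, reverse {C_last: 1}; the
    energy species is named in ``law_params['energy']``.  The law consumes
    raw amounts, so clamped species contribute their effective amount
    ``exp(mu)/K``.
    """
    lp = dict(rxn.law_params)
    try:
        energy = lp.pop("energy")
    except KeyError:
        raise ConfigurationError(
            f"elongation reaction {rxn.name!r} needs law_params['energy']"
        ) from None
    p = ElongationParams(**lp)
    iA = net.species_index(energy)
    firsts = [n for n in rxn.forward_stoich if n != energy]
    if len(firsts) != 1 or len(rxn.reverse_stoich) != 1:
        raise ConfigurationError(
            f"elongation reaction {rxn.name!r} must be C_first + m·A -> C_last"
        )
    iC1 = net.species_index(firsts[0])
    (iCn,) = [net.species_index(n) for n in rxn.reverse_stoich]
    K = np.array([s.K for s in net.species])

    def flux(x, a):
        # effective amounts: a/K equals x for amount species and exp(mu)/K for clamps
        return elongation_rate(p, a[iC1] / K[iC1], a[iCn] / K[iCn], a[iA] / K[iA])

    return flux
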