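"""Gene-expression modules and their composition into synthetic circuits.

A gene-expression module chains a transcription component (energy A -> mRNA,
modulated by an inhibitor port), a reduced translation block and first-order
degradation of mRNA and protein.  Modules expose the shared species A
(energy), R (ribosomes) and the inhibitor port; composition merges shared
species by name (0-junction semantics: one potential, fluxes sum), so
resource competition and retroactivity between genes are emergent rather
than modelled explicitly.

The toggle switch wires two modules with mutual inhibition (each gene's
protein is the other's inhibitor port); the repressilator wires three in a
ring 1 -| 2 -| 3 -| 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .errors import CompositionError, ConfigurationError
from .network import NetworkSpec, ReactionSpec, SpeciesSpec
from .rate_laws import DegradationParams, TranscriptionParams, degradation_reaction
from .translation import TranslationParams, build_reduced_translation, build_full_translation


@dataclass
class GeneParams:
    """Everything needed to build one gene-expression module."""

    tc: TranscriptionParams
    tl: TranslationParams
    deg_m: DegradationParams
    deg_p: DegradationParams
    name: str = "g1"


@dataclass
class CircuitSpec:
    """A set of genes plus the inhibition wiring and shared pools.

    ``inhibition_map`` maps a gene name to the gene whose protein represses
    it.  ``pools`` overrides the shared amounts (keys 'A' and 'R').
    """

    genes: List[GeneParams]
    inhibition_map: Dict[str, str] = field(default_factory=dict)
    pools: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigurationError("gene names must be unique")
        for target, source in self.inhibition_map.items():
            if target not in names or source not in names:
                raise ConfigurationError(
                    f"inhibition_map entry {target!r} <- {source!r} names an unknown gene"
                )


def _gene_module_parts(
    g: GeneParams,
    pools: Optional[Mapping[str, float]],
    inhibitor: Optional[str],
    inhibitor_mu: float,
    use_full_translation: bool,
) -> Tuple[List[SpeciesSpec], List[ReactionSpec]]:
    """Species and reactions of one gene; the inhibitor may be a foreign name."""
    prefix = f"{g.name}_"
    build = build_full_translation if use_full_translation else build_reduced_translation
    pool_amounts = dict(pools or {})
    mrna0 = pool_amounts.pop("M", 0.0)
    net = build(
        g.tl,
        pools={"M": mrna0, **pool_amounts},
        energy_chemostat=True,
        protein_clamp_mu=None,
        prefix=prefix,
    )
    species = list(net.species)
    reactions = list(net.reactions)

    if inhibitor is None:
        inhibitor = f"{prefix}I"
        mu = inhibitor_mu if math.isfinite(inhibitor_mu) else -700.0
        species.append(
            SpeciesSpec(inhibitor, K=1.0, kind="chemostat_potential", mu_clamp=mu)
        )

    reactions.append(
        ReactionSpec(
            f"{prefix}transcription",
            1.0,
            {"A": 1},
            {f"{prefix}M": 1},
            law="transcription",
            law_params={
                "r_bar": g.tc.r_bar,
                "RbA": g.tc.RbA,
                "RbM": g.tc.RbM,
                "RbI": g.tc.RbI,
                "h": g.tc.h,
                "inhibitor": inhibitor,
            },
        )
    )

    by_name = {s.name: s for s in species}
    for target, p_deg in ((f"{prefix}M", g.deg_m), (f"{prefix}P", g.deg_p)):
        rxn, sink = degradation_reaction(by_name[target], p_deg)
        reactions.append(rxn)
        species.append(sink)
    return species, reactions


def build_gene_expression(
    g: GeneParams,
    pools: Optional[Mapping[str, float]] = None,
    inhibitor_mu: float = -math.inf,
    use_full_translation: bool = False,
) -> NetworkSpec:
    """One gene: transcription, (reduced) translation and degradation.

    Ports A, R and the inhibitor are shared species; everything else is
    prefixed with the gene name.  A clamped external inhibitor species
    ``<gene>_I`` is created at potential ``inhibitor_mu`` (-inf disables
    inhibition and is encoded as a very low clamp).  Circuits replace the
    external inhibitor by another gene's protein via the circuit builders.
    """
    species, reactions = _gene_module_parts(
        g, pools, None, inhibitor_mu, use_full_translation
    )
    return NetworkSpec(species, reactions)


def compose(
    modules: Sequence[NetworkSpec],
    shared: Optional[Mapping[str, str]] = None,
) -> NetworkSpec:
    """Merge modules, identifying shared species by name (0-junction semantics).

    ``shared`` optionally renames species before merging (old name -> shared
    name).  Shared species must agree on K, kind and clamp; their initial
    amount is taken from the first module that declares them.  Reaction names
    must be globally unique.
    """
    rename = dict(shared or {})
    species: Dict[str, SpeciesSpec] = {}
    reactions: List[ReactionSpec] = []
    seen_rxn = set()
    for net in modules:
        for s in net.species:
            name = rename.get(s.name, s.name)
            if name in species:
                prev = species[name]
                if not (
                    math.isclose(prev.K, s.K, rel_tol=1e-12)
                    and prev.kind == s.kind
                    and (prev.mu_clamp == s.mu_clamp)
                ):
                    raise CompositionError(
                        f"shared species {name!r} has conflicting definitions "
                        f"(K {prev.K} vs {s.K}, kind {prev.kind} vs {s.kind})"
                    )
            else:
                species[name] = replace(s, name=name)
        for r in net.reactions:
            if r.name in seen_rxn:
                raise CompositionError(f"duplicate reaction name {r.name!r} in composition")
            seen_rxn.add(r.name)
            fwd = {rename.get(k, k): v for k, v in r.forward_stoich.items()}
            rev = {rename.get(k, k): v for k, v in r.reverse_stoich.items()}
            lp = dict(r.law_params)
            for key in ("inhibitor", "energy"):
                if key in lp:
                    lp[key] = rename.get(lp[key], lp[key])
            reactions.append(replace(r, forward_stoich=fwd, reverse_stoich=rev, law_params=lp))
    return NetworkSpec(list(species.values()), reactions)


def _build_wired_circuit(
    c: CircuitSpec, use_full_translation: bool = False
) -> NetworkSpec:
    """Merge gene modules; foreign inhibitor ports resolve at compile time."""
    species: List[SpeciesSpec] = []
    reactions: List[ReactionSpec] = []
    seen: Dict[str, SpeciesSpec] = {}
    for g in c.genes:
        source = c.inhibition_map.get(g.name)
        sp, rx = _gene_module_parts(
            g,
            c.pools,
            f"{source}_P" if source else None,
            -math.inf,
            use_full_translation,
        )
        for s in sp:
            if s.name in seen:
                prev = seen[s.name]
                if not math.isclose(prev.K, s.K, rel_tol=1e-12) or prev.kind != s.kind:
                    raise CompositionError(
                        f"shared species {s.name!r} has conflicting definitions"
                    )
            else:
                seen[s.name] = s
                species.append(s)
        reactions.extend(rx)
    return NetworkSpec(species, reactions)


def build_toggle_switch(
    c: CircuitSpec, use_full_translation: bool = False
) -> NetworkSpec:
    """Two mutually repressing genes sharing the energy and ribosome pools."""
    if len(c.genes) != 2:
        raise ConfigurationError("toggle switch requires exactly 2 genes")
    g1, g2 = (g.name for g in c.genes)
    spec = replace(c, inhibition_map={g1: g2, g2: g1})
    return _build_wired_circuit(spec, use_full_translation)


def build_repressilator(
    c: CircuitSpec, use_full_translation: bool = False
) -> NetworkSpec:
    """Three genes in a repression ring 1 -| 2 -| 3 -| 1."""
    if len(c.genes) != 3:
        raise ConfigurationError("repressilator requires exactly 3 genes")
    g1, g2, g3 = (g.name for g in c.genes)
    spec = replace(c, inhibition_map={g2: g1, g3: g2, g1: g3})
    return _build_wired_circuit(spec, use_full_translation)


def steady_state_excess_energy(
    g: GeneParams, x_R: float, mu_I: float = -math.inf
) -> Tuple[float, float]:
    """Closed-form steady-state mRNA and protein numbers at excess energy.

    Assumes the transcription component is energy-saturated, mRNA feedback on
    transcription is negligible, ribosome binding is effectively irreversible
    and few ribosomes are sequestered in complexes.  Then

        xM = r̄ RbA / (r_deg,M (1 + e^{h·muI}/RbI))
        xP = kb xR xM / r_deg,P

    with kb the kinetic ribosome-binding constant.  Useful as an independent
    cross-check of simulated steady states.
    """
    inhibition = 1.0 + (math.exp(g.tc.h * mu_I) / g.tc.RbI if math.isfinite(mu_I) else 0.0)
    xM = g.tc.r_bar * g.tc.RbA / (g.deg_m.r_deg * inhibition)
    xP = g.tl.kb * x_R * xM / g.deg_p.r_deg
    return xM, xP
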