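"""Full and reduced (lumped) models of translation.

The full model tracks every ribosome position along the transcript:

    M + R        <->  C0            (binding: kb / ku)
    C0 + A       <->  C1 + M        (first elongation step: kf1 / kr1;
                                     the mRNA is released so further
                                     ribosomes can initiate)
    C_i + A      <->  C_{i+1}       (n-1 chain steps: kf / kr)
    C_n          <->  R + P         (termination: kt / kz)

with n the number of ATP molecules consumed per protein (four per amino
acid).  The reduced model replaces C1..C_{n-1} by one or a few lumped
complexes whose interconversion follows the closed-form quasi-steady-state
elongation law, so its state dimension is independent of n.

Kinetic constants are converted to bond-graph parameters (species constants
K and reaction rate parameters r) by a gauge construction: K_M and K_R are
free choices, K_A = kf/kr makes every chain step share one complex constant,
and detailed balance then fixes K of every complex and of the protein.  As a
result the protein's thermodynamic constant is not a free parameter — it is
pinned by the energetics of the synthesis route.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .network import NetworkSpec, ReactionSpec, SpeciesSpec

#: ATP molecules hydrolysed per amino acid added during translation
ATP_PER_AMINO_ACID = 4


def n_from_protein_length(amino_acids: int) -> int:
    """ATP molecules per protein for a transcript of the given length."""
    if amino_acids < 1:
        raise ConfigurationError("protein length must be at least one amino acid")
    return ATP_PER_AMINO_ACID * int(amino_acids)


@dataclass
class TranslationParams:
    """Kinetic constants of the translation scheme.

    ku/kb: ribosome-mRNA unbinding/binding; kf1/kr1: first elongation step;
    kf/kr: per-step chain constants; kt/kz: termination forward/reverse;
    n: ATP per protein (>= 2); n_lumps: lumped complexes in the reduced model.
    K_M and K_R are the free thermodynamic gauge constants of the mRNA and
    ribosome pools (every other K follows from detailed balance).
    """

    kb: float
    ku: float
    kf1: float
    kr1: float
    kf: float
    kr: float
    kt: float
    kz: float
    n: int
    n_lumps: int = 1
    K_M: float = 1e-4
    K_R: float = 1e-4

    def __post_init__(self):
        for name in ("kb", "ku", "kf1", "kr1", "kf", "kr", "kt", "kz", "K_M", "K_R"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"translation constant {name} must be > 0")
        if int(self.n) != self.n or self.n < 2:
            raise ConfigurationError(f"ATP count n must be an integer >= 2, got {self.n}")
        if int(self.n_lumps) != self.n_lumps or not 1 <= self.n_lumps <= self.n - 1:
            raise ConfigurationError(
                f"n_lumps must be an integer in [1, n-1], got {self.n_lumps}"
            )

    # ------------------------------------------------- bond-graph gauge
    def thermodynamic_constants(self) -> Dict[str, float]:
        """K for every pool species, the complexes and the rate parameters.

        Returns a dict with K_M, K_R, K_A, K_C0, K_C (all chain complexes
        share one constant), K_P, and the bond-graph rate parameters
        r_bind, r_first, r_chain, r_term.
        """
        K_A = self.kf / self.kr
        r_bind = self.kb / (self.K_M * self.K_R)
        K_C0 = self.ku / r_bind
        r_first = self.kf1 / (K_C0 * K_A)
        K_C = self.kr1 / (r_first * self.K_M)
        r_chain = self.kr / K_C
        r_term = self.kt / K_C
        K_P = self.kz / (r_term * self.K_R)
        return {
            "K_M": self.K_M,
            "K_R": self.K_R,
            "K_A": K_A,
            "K_C0": K_C0,
            "K_C": K_C,
            "K_P": K_P,
            "r_bind": r_bind,
            "r_first": r_first,
            "r_chain": r_chain,
            "r_term": r_term,
        }


#: default pool amounts: 10 mRNA, 5000 ribosomes, energy-rich A, protein
#: potential clamped at -15 kB·T to approximate immediate product removal
DEFAULT_POOLS: Dict[str, float] = {"M": 10.0, "R": 5000.0, "A": 5.8e6, "P": 0.0}

#: complexes start at a small seed amount, representing an inactivated state
COMPLEX_SEED = 1e-3


def _pool_species(
    p: TranslationParams,
    pools: Mapping[str, float],
    energy_chemostat: bool,
    protein_clamp_mu: Optional[float],
    prefix: str,
) -> List[SpeciesSpec]:
    k = p.thermodynamic_constants()
    amounts = dict(DEFAULT_POOLS)
    amounts.update(pools or {})
    species = [
        SpeciesSpec(f"{prefix}M", K=k["K_M"], x0=amounts["M"]),
        SpeciesSpec("R", K=k["K_R"], x0=amounts["R"]),
        SpeciesSpec(
            "A",
            K=k["K_A"],
            x0=amounts["A"],
            kind="chemostat_amount" if energy_chemostat else "dynamic",
        ),
    ]
    if protein_clamp_mu is not None:
        species.append(
            SpeciesSpec(f"{prefix}P", K=k["K_P"], kind="chemostat_potential", mu_clamp=protein_clamp_mu)
        )
    else:
        species.append(SpeciesSpec(f"{prefix}P", K=k["K_P"], x0=amounts["P"]))
    return species


def build_full_translation(
    p: TranslationParams,
    pools: Optional[Mapping[str, float]] = None,
    energy_chemostat: bool = True,
    protein_clamp_mu: Optional[float] = -15.0,
    prefix: str = "",
) -> NetworkSpec:
    """Explicit translation network with all n+1 ribosome-mRNA complexes.

    Species: M, R, A, P and C0..Cn (n+5 total); reactions: binding, first
    elongation, n-1 chain steps and termination (n+2 total).  The ribosome
    moiety R + sum(C_i) is conserved.
    """
    if p.n < 2:
        raise ConfigurationError("full translation model requires n >= 2")
    k = p.thermodynamic_constants()
    species = _pool_species(p, pools or {}, energy_chemostat, protein_clamp_mu, prefix)
    species.append(SpeciesSpec(f"{prefix}C0", K=k["K_C0"], x0=COMPLEX_SEED))
    species += [
        SpeciesSpec(f"{prefix}C{i}", K=k["K_C"], x0=COMPLEX_SEED) for i in range(1, p.n + 1)
    ]
    reactions = [
        ReactionSpec(
            f"{prefix}bind",
            k["r_bind"],
            {f"{prefix}M": 1, "R": 1},
            {f"{prefix}C0": 1},
        ),
        ReactionSpec(
            f"{prefix}elong_first",
            k["r_first"],
            {f"{prefix}C0": 1, "A": 1},
            {f"{prefix}C1": 1, f"{prefix}M": 1},
        ),
    ]
    reactions += [
        ReactionSpec(
            f"{prefix}elong_{i}",
            k["r_chain"],
            {f"{prefix}C{i}": 1, "A": 1},
            {f"{prefix}C{i + 1}": 1},
        )
        for i in range(1, p.n)
    ]
    reactions.append(
        ReactionSpec(
            f"{prefix}termination",
            k["r_term"],
            {f"{prefix}C{p.n}": 1},
            {"R": 1, f"{prefix}P": 1},
        )
    )
    return NetworkSpec(species, reactions)


def lump_lengths(m: int, n_lumps: int) -> List[int]:
    """Partition of the m chain steps over the lumps, as even as possible.

    Earlier lumps take the remainder, e.g. m=10, 2 lumps -> [5, 5];
    m=11, 2 lumps -> [6, 5].
    """
    if not 1 <= n_lumps <= m:
        raise ConfigurationError(f"cannot split {m} steps into {n_lumps} lumps")
    base, extra = divmod(m, n_lumps)
    return [base + (1 if i < extra else 0) for i in range(n_lumps)]


def build_reduced_translation(
    p: TranslationParams,
    pools: Optional[Mapping[str, float]] = None,
    energy_chemostat: bool = True,
    protein_clamp_mu: Optional[float] = -15.0,
    prefix: str = "",
) -> NetworkSpec:
    """Lumped translation network; state dimension independent of n.

    For a single lump: species M, R, A, P, C0, Cx, Cn (7) and four flux
    elements (binding; C0 + A <-> Cx + M with the per-step chain constants;
    the lumped elongation law over m = n - 1 steps; termination).  With k
    lumps the m steps are partitioned over k chained elongation components.
    """
    k = p.thermodynamic_constants()
    m = p.n - 1
    lengths = lump_lengths(m, p.n_lumps)
    species = _pool_species(p, pools or {}, energy_chemostat, protein_clamp_mu, prefix)
    species.append(SpeciesSpec(f"{prefix}C0", K=k["K_C0"], x0=COMPLEX_SEED))
    lump_names = (
        [f"{prefix}Cx"]
        if p.n_lumps == 1
        else [f"{prefix}Cx{i + 1}" for i in range(p.n_lumps)]
    )
    # lump j seeds the mass of its member complexes from the full model
    for name, length in zip(lump_names, lengths):
        species.append(SpeciesSpec(name, K=k["K_C"], x0=COMPLEX_SEED * length))
    species.append(SpeciesSpec(f"{prefix}Cn", K=k["K_C"], x0=COMPLEX_SEED))

    reactions = [
        ReactionSpec(
            f"{prefix}bind",
            k["r_bind"],
            {f"{prefix}M": 1, "R": 1},
            {f"{prefix}C0": 1},
        ),
        # scheme annotation: C0 + A <-> Cx + M with per-step constants kf, kr
        ReactionSpec(
            f"{prefix}elong_first",
            k["r_first"],
            {f"{prefix}C0": 1, "A": 1},
            {lump_names[0]: 1, f"{prefix}M": 1},
        ),
    ]
    chain = lump_names + [f"{prefix}Cn"]
    for j, length in enumerate(lengths):
        reactions.append(
            ReactionSpec(
                f"{prefix}elongation" if p.n_lumps == 1 else f"{prefix}elongation_{j + 1}",
                p.kr,
                {chain[j]: 1, "A": length},
                {chain[j + 1]: 1},
                law="elongation",
                law_params={"kf": p.kf, "kr": p.kr, "m": length, "energy": "A"},
            )
        )
    reactions.append(
        ReactionSpec(
            f"{prefix}termination",
            k["r_term"],
            {f"{prefix}Cn": 1},
            {"R": 1, f"{prefix}P": 1},
        )
    )
    return NetworkSpec(species, reactions)


def lump_initial_conditions(
    full_state: Sequence[float], n_lumps: int
) -> np.ndarray:
    """Aggregate full-chain intermediate amounts C1..C_{n-1} into lump amounts.

    Each lump amount is the sum of its member complexes, so total complex
    mass is preserved exactly.
    """
    full_state = np.asarray(full_state, dtype=float)
    if np.any(full_state < 0):
        raise ConfigurationError("complex amounts must be non-negative")
    m = full_state.size
    lengths = lump_lengths(m, n_lumps)
    out = np.empty(n_lumps)
    start = 0
    for i, length in enumerate(lengths):
        out[i] = full_state[start : start + length].sum()
        start += length
    return out


def translation_rate(net: NetworkSpec, x: np.ndarray, prefix: str = "") -> float:
    """Net termination flux (proteins per minute) at state ``x``."""
    j = net.reaction_index(f"{prefix}termination")
    return float(net.fluxes(x)[j])
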