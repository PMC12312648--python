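"""Default *E. coli*-scale parameter set.

The defaults are documented placeholders calibrated once against published
single-cell scales rather than fitted to data: an energy-rich cell holds
A = 5.8e6 ATP-equivalents and ~5000 free ribosomes; an induced gene settles
near 41 mRNA and ~1e4 protein copies; mRNA half-life is 2.5 min and the median
protein half-life 4 min; elongation runs at about 4800 ATP per ribosome per
minute (20 amino acids/s at 4 ATP per residue); a default protein of 300
amino acids costs n = 1200 ATP.  See docs/methods.md for the calibration
reasoning.
"""

from __future__ import annotations

import math

from .circuits import CircuitSpec, GeneParams
from .rate_laws import DegradationParams, TranscriptionParams
from .translation import TranslationParams, n_from_protein_length

#: energy-rich ATP pool (molecules per cell)
ENERGY_RICH_A = 5.8e6
#: free ribosomes per cell (median)
DEFAULT_RIBOSOMES = 5000.0
#: ATP consumed per ribosome per minute at full speed
ELONGATION_ATP_PER_MIN = 4800.0
#: default protein length (amino acids) and ATP cost
DEFAULT_PROTEIN_AA = 300
DEFAULT_N = n_from_protein_length(DEFAULT_PROTEIN_AA)

#: steady-state targets of an induced gene used for the calibration
_TARGET_MRNA = 41.0
_TARGET_PROTEIN = 10351.0

#: half-lives (minutes)
MRNA_HALF_LIFE = 2.5
PROTEIN_HALF_LIFE = 4.0

_R_DEG_M = math.log(2.0) / MRNA_HALF_LIFE
_R_DEG_P = math.log(2.0) / PROTEIN_HALF_LIFE

# per-step chain constants: forward saturates at ELONGATION_ATP_PER_MIN in an
# energy-rich cell; the reverse constant sets the energy half-saturation
# scale (translation stalls around Â ~ 1, i.e. A ~ kr/kf)
_KF = ELONGATION_ATP_PER_MIN / ENERGY_RICH_A
_KR = 40.0

# ribosome binding tuned so the induced gene reaches the target protein count:
# at steady state v_tl = r_deg,P * xP ~= kb * xM * xR
_KB = _R_DEG_P * _TARGET_PROTEIN / (_TARGET_MRNA * DEFAULT_RIBOSOMES)

# protein thermodynamic constant implied by the synthesis route (used to
# express the inhibition affinity in terms of a half-inhibiting copy number)
_K_P = TranslationParams(
    kb=_KB, ku=1.0, kf1=_KF, kr1=_KR, kf=_KF, kr=_KR, kt=1000.0, kz=1e-9, n=DEFAULT_N
).thermodynamic_constants()["K_P"]

#: protein copy number at which repression is half-maximal
INHIBITION_HALF_POINT = 300.0


def default_translation_params(n: int = DEFAULT_N, n_lumps: int = 1) -> TranslationParams:
    return TranslationParams(
        kb=_KB,
        ku=1.0,
        kf1=_KF,
        kr1=_KR,
        kf=_KF,
        kr=_KR,
        kt=1000.0,
        kz=1e-9,
        n=n,
        n_lumps=n_lumps,
    )


def default_transcription_params(h: int = 2) -> TranscriptionParams:
    # r_bar * RbA is the saturated transcription rate; 41 mRNA * r_deg,M
    return TranscriptionParams(
        r_bar=_TARGET_MRNA * _R_DEG_M,
        RbA=1.0,
        RbM=1.0,
        RbI=(_K_P * INHIBITION_HALF_POINT) ** h,
        h=h,
    )


def default_gene_params(
    name: str = "g1",
    n: int = DEFAULT_N,
    n_lumps: int = 1,
    h: int = 2,
    protein_half_life: float = PROTEIN_HALF_LIFE,
) -> GeneParams:
    return GeneParams(
        tc=default_transcription_params(h=h),
        tl=default_translation_params(n=n, n_lumps=n_lumps),
        deg_m=DegradationParams(r_deg=_R_DEG_M),
        deg_p=DegradationParams(r_deg=math.log(2.0) / protein_half_life),
        name=name,
    )


def default_pools(x_A: float = ENERGY_RICH_A, x_R: float = DEFAULT_RIBOSOMES) -> dict:
    return {"A": x_A, "R": x_R}


def default_toggle_spec(**pool_overrides) -> CircuitSpec:
    return CircuitSpec(
        genes=[default_gene_params("g1"), default_gene_params("g2")],
        pools={**default_pools(), **pool_overrides},
    )


def default_repressilator_spec(**pool_overrides) -> CircuitSpec:
    return CircuitSpec(
        genes=[default_gene_params(f"g{i}") for i in (1, 2, 3)],
        pools={**default_pools(), **pool_overrides},
    )


#: asymmetric default initial conditions (molecules)
TOGGLE_IC_HIGH_P1 = {"g1_P": 10000.0, "g2_P": 0.0}
TOGGLE_IC_HIGH_P2 = {"g1_P": 0.0, "g2_P": 10000.0}
REPRESSILATOR_IC = {"g1_P": 4000.0, "g2_P": 0.0, "g3_P": 0.0}
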