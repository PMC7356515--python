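"""Hill interaction surfaces and the aggregate combined effect.

Two interacting agents with normalized levels ``Un_A`` and ``Un_B`` are
treated as a single virtual agent through the interaction index

    I = Un_A + Un_B + sigma * Un_A * Un_B

and mapped to an effect fraction through the sigmoid Hill surface

    Effect = Emax * I**gamma / (1 + I**gamma).

Levels are normalized to potency, i.e. divided by the agent's half-effect
level (C50), so a level of 1 marks the half-effect point.  ``sigma``
quantifies synergy between the pair (isoboles bow inward for sigma > 0) and
``gamma`` the sigmoidicity of the response.

The aggregate effect combines three tumor–drug surfaces and three
drug–drug surfaces by arithmetic means:

    Et_all = (Et_a + Et_i + Et_r) / 3
    Ed_all = (E_ai + E_ar + E_ir) / 3
    E      = (Et_all + Ed_all) / 2

Tumor–drug terms are gated on drug presence: a therapy channel whose serum
and effect-site levels are both exactly zero contributes no tumor–drug
effect, so the untreated model reduces to pure exponential growth.  (The
tumor's own normalized level is positive even without treatment; without
the gate the surface would report a spurious kill at zero dose.)  Drug–drug
terms vanish on their own when both levels are zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import CombinedParameters

__all__ = [
    "NormalizedPair",
    "EffectBreakdown",
    "interaction_index",
    "hill_surface",
    "normalize_levels",
    "combined_effect",
    "surface_grid",
]


@dataclass(frozen=True)
class NormalizedPair:
    """Dimensionless potency-normalized levels of two interacting agents."""

    Un_A: float
    Un_B: float

    def __post_init__(self) -> None:
        if self.Un_A < 0 or self.Un_B < 0:
            raise ValueError("normalized levels must be >= 0")


@dataclass(frozen=True)
class EffectBreakdown:
    """All pairwise effect terms and their aggregates, as fractions.

    ``Et_*`` are tumor–drug effects, ``E_**`` drug–drug effects, ``Et_all``
    and ``Ed_all`` their arithmetic means and ``E`` the combined effect
    (converted to a kill rate downstream by ``unit_rate``).
    """

    Et_a: float
    Et_i: float
    Et_r: float
    E_ai: float
    E_ar: float
    E_ir: float
    Et_all: float
    Ed_all: float
    E: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.Et_a,
            self.Et_i,
            self.Et_r,
            self.E_ai,
            self.E_ar,
            self.E_ir,
            self.Et_all,
            self.Ed_all,
            self.E,
        )


def interaction_index(pair: NormalizedPair, sigma: float) -> float:
    """Interaction index I = Un_A + Un_B + sigma*Un_A*Un_B of a pair.

    Grouped as sigma*(Un_A*Un_B) so the value is exactly symmetric under
    relabeling of the two agents.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return pair.Un_A + pair.Un_B + sigma * (pair.Un_A * pair.Un_B)


def hill_surface(i: float, gamma: float, emax: float = 1.0) -> float:
    """Sigmoid effect emax * i**gamma / (1 + i**gamma); 0 at i = 0.

    For i <= 1 the direct form is used (i**gamma underflows harmlessly to
    0); for i > 1 the equivalent emax / (1 + i**(-gamma)) saturates to
    emax without overflow at large indices.
    """
    if i < 0:
        raise ValueError("interaction index must be >= 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if not 0.0 <= emax <= 1.0:
        raise ValueError("emax must lie in [0, 1]")
    if i == 0.0:
        return 0.0
    if i <= 1.0:
        powered = i ** gamma
        return emax * powered / (1.0 + powered)
    return emax / (1.0 + i ** (-gamma))


def normalize_levels(
    state: Sequence[float], params: CombinedParameters
) -> dict[str, float]:
    """Potency-normalized levels {tumor, AG, IM, RT} at a model state.

    ``state`` is the 8-vector (x1, x2, x3, xe3, x4, xe4, x5, xe5).  The
    tumor level is its volume as a percent of the initial volume divided by
    C50_t; drug levels are effect-site levels over their C50; the RT level
    is the effect-site drive (Gy/day-equivalent) over C50_r, which absorbs
    the Gy -> model-unit conversion.
    """
    x1, _, _, xe3, _, xe4, _, xe5 = state
    return {
        "tumor": (100.0 * x1 / params.V0) / params.C50_t,
        "AG": xe3 / params.C50_a,
        "IM": xe4 / params.C50_i,
        "RT": xe5 / params.C50_r,
    }


def _pair_effect(un_a: float, un_b: float, sigma: float, gamma: float, emax: float) -> float:
    i = un_a + un_b + sigma * (un_a * un_b)
    if i <= 0.0:
        return 0.0
    if i <= 1.0:
        powered = i ** gamma
        return emax * powered / (1.0 + powered)
    return emax / (1.0 + i ** (-gamma))


def combined_effect(
    state: Sequence[float],
    params: CombinedParameters,
    inputs: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> EffectBreakdown:
    """Evaluate every pairwise surface and aggregate to the combined E.

    Tumor–drug terms use the drug's Emax; drug–drug terms use the mean of
    the pair's Emax values.  A tumor–drug term is zero when its drug
    channel holds no drug at all (serum and effect-site both zero and no
    infusion running).  ``inputs`` carries the instantaneous (u_a, u_i,
    u_r) infusion rates so that a channel counts as present from the
    start of its first administration day, keeping the right-hand side
    smooth along treated trajectories.
    """
    x1, _, x3, xe3, x4, xe4, x5, xe5 = state
    u_a_in, u_i_in, u_r_in = inputs
    levels = normalize_levels(state, params)
    un_t = levels["tumor"]
    un_a, un_i, un_r = levels["AG"], levels["IM"], levels["RT"]
    s, g = params.sigma, params.gamma

    has_a = x3 > 0.0 or xe3 > 0.0 or u_a_in > 0.0
    has_i = x4 > 0.0 or xe4 > 0.0 or u_i_in > 0.0
    has_r = x5 > 0.0 or xe5 > 0.0 or u_r_in > 0.0

    et_a = _pair_effect(un_t, un_a, s, g, params.Emax_a) if has_a else 0.0
    et_i = _pair_effect(un_t, un_i, s, g, params.Emax_i) if has_i else 0.0
    et_r = _pair_effect(un_t, un_r, s, g, params.Emax_r) if has_r else 0.0

    e_ai = _pair_effect(un_a, un_i, s, g, 0.5 * (params.Emax_a + params.Emax_i))
    e_ar = _pair_effect(un_a, un_r, s, g, 0.5 * (params.Emax_a + params.Emax_r))
    e_ir = _pair_effect(un_i, un_r, s, g, 0.5 * (params.Emax_i + params.Emax_r))

    et_all = (et_a + et_i + et_r) / 3.0
    ed_all = (e_ai + e_ar + e_ir) / 3.0
    return EffectBreakdown(
        Et_a=et_a,
        Et_i=et_i,
        Et_r=et_r,
        E_ai=e_ai,
        E_ar=e_ar,
        E_ir=e_ir,
        Et_all=et_all,
        Ed_all=ed_all,
        E=0.5 * (et_all + ed_all),
    )


def surface_grid(
    sigma: float,
    gamma: float,
    emax: float = 1.0,
    max_level: float = 4.0,
    points: int = 41,
) -> pd.DataFrame:
    """Evaluate one pairwise surface on a square grid for isobole plotting.

    Returns a tidy frame with columns Un_A, Un_B, Effect.
    """
    levels = np.linspace(0.0, max_level, points)
    rows = [
        (ua, ub, _pair_effect(ua, ub, sigma, gamma, emax))
        for ua in levels
        for ub in levels
    ]
    return pd.DataFrame(rows, columns=["Un_A", "Un_B", "Effect"])
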