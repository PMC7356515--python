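"""Shared fixtures, including the independent explicit-Euler reference.

The Euler oracle reimplements the model equations directly from their
mathematical statement (no reuse of the package's RHS code) and integrates
them with brute-force explicit Euler at a 1e-4 day step, providing an
integrator-and-implementation-independent reference trajectory.
"""

from __future__ import annotations

import pytest

from minpkpd import default_combined_parameters, default_lq_parameters
from minpkpd.experiments import protocol_schedules
from minpkpd.schedules import Channel


@pytest.fixture
def params():
    return default_combined_parameters()


@pytest.fixture
def lq():
    return default_lq_parameters()


def euler_reference_endpoint(params, schedules, horizon=30, h=1e-4):
    """Explicit-Euler endpoint state, written independently of the package.

    Implements: tumor balance dx1=(a-n)x1-E*x1, dx2=n*x1+E*x1; first-order
    serum kinetics with constant daily infusion rates; effect-site states
    driven by the tumor-drug effect times the serum level; Hill-surface
    pairwise effects over potency-normalized levels with interaction index
    Un_A+Un_B+sigma*Un_A*Un_B, tumor-drug terms active only while the drug
    channel holds drug; aggregate E = (mean tumor-drug + mean drug-drug)/2.
    """
    p = params
    ua = schedules[Channel.AG].daily_amounts(horizon)
    ui = schedules[Channel.IM].daily_amounts(horizon)
    ur = schedules[Channel.RT].daily_amounts(horizon)

    def hill(i, g):
        return 0.0 if i <= 0.0 else 1.0 / (1.0 + i ** (-g))

    def deriv(y, ra, ri, rr):
        x1, x2, x3, xe3, x4, xe4, x5, xe5 = y
        un_t = (100.0 * x1 / p.V0) / p.C50_t
        un_a, un_i, un_r = xe3 / p.C50_a, xe4 / p.C50_i, xe5 / p.C50_r
        s, g = p.sigma, p.gamma

        def index(a, b):
            return a + b + s * a * b

        et_a = p.Emax_a * hill(index(un_t, un_a), g) if (x3 > 0 or xe3 > 0) else 0.0
        et_i = p.Emax_i * hill(index(un_t, un_i), g) if (x4 > 0 or xe4 > 0) else 0.0
        et_r = p.Emax_r * hill(index(un_t, un_r), g) if (x5 > 0 or xe5 > 0) else 0.0
        e_ai = 0.5 * (p.Emax_a + p.Emax_i) * hill(index(un_a, un_i), g)
        e_ar = 0.5 * (p.Emax_a + p.Emax_r) * hill(index(un_a, un_r), g)
        e_ir = 0.5 * (p.Emax_i + p.Emax_r) * hill(index(un_i, un_r), g)
        eff = 0.5 * ((et_a + et_i + et_r) / 3.0 + (e_ai + e_ar + e_ir) / 3.0)
        kill = eff * p.unit_rate
        return (
            (p.a - p.n) * x1 - kill * x1,
            p.n * x1 + kill * x1,
            -p.c_a * x3 + ra,
            -p.c_a * xe3 + et_a * x3,
            -p.c_i * x4 + ri,
            -p.c_i * xe4 + et_i * x4,
            -p.c_r * x5 + rr,
            -p.c_r * xe5 + et_r * x5,
        )

    nsub = int(round(1.0 / h))
    y = (p.V0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    for day in range(horizon):
        ra, ri, rr = ua[day], ui[day], ur[day]
        for _ in range(nsub):
            d = deriv(y, ra, ri, rr)
            y = tuple(y[i] + h * d[i] for i in range(8))
    return y


@pytest.fixture(scope="session")
def euler_protocol1_endpoint():
    """Day-30 Euler-oracle state for Protocol 1 under default parameters."""
    return euler_reference_endpoint(
        default_combined_parameters(), protocol_schedules(1)
    )
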