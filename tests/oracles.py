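"""Independent brute-force oracles, deliberately coded without reusing any
package internals beyond plain parameter values."""

import math

import numpy as np
from scipy import integrate


def replay_nll_oracle(data, beta, acp, acm, aup, aum):
    """Dict-based likelihood replay: straightforward transliteration of the
    delta rules and softmax, summing -log P(observed choice)."""
    q = {}
    nll = 0.0
    for _, row in data.iterrows():
        key = (row["session"], row["context_instance"])
        if key not in q:
            q[key] = {0: 0.0, 1: 0.0}
        c = int(row["choice"])
        u = 1 - c
        num = math.exp(beta * q[key][c])
        den = num + math.exp(beta * q[key][u])
        nll -= math.log(num / den)
        pe_c = row["outcome_chosen"] - q[key][c]
        if pe_c > 0:
            q[key][c] += acp * pe_c
        elif pe_c < 0:
            q[key][c] += acm * pe_c
        r_u = row["outcome_unchosen"]
        if not (isinstance(r_u, float) and math.isnan(r_u)):
            pe_u = r_u - q[key][u]
            if pe_u > 0:
                q[key][u] += aup * pe_u
            elif pe_u < 0:
                q[key][u] += aum * pe_u
    return nll


def bms_attributions_oracle(log_evidence):
    """Exact per-subject model posteriors for a 2-model problem under a
    uniform Dirichlet(1, 1) prior on the population frequencies, by
    numerical quadrature over the frequency simplex."""
    lme = np.asarray(log_evidence, dtype=float)
    assert lme.shape[1] == 2
    p = np.exp(lme - lme.max(axis=1, keepdims=True))

    def lik(r):
        return float(np.prod(r * p[:, 0] + (1.0 - r) * p[:, 1]))

    z, _ = integrate.quad(lik, 0.0, 1.0)
    out = np.empty(p.shape[0])
    for n in range(p.shape[0]):
        num, _ = integrate.quad(
            lambda r: r * p[n, 0] / (r * p[n, 0] + (1.0 - r) * p[n, 1]) * lik(r),
            0.0,
            1.0,
        )
        out[n] = num / z
    return out
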