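"""HKY85 substitution model: rate matrix and closed-form transition probabilities.

States are ordered A, C, G, T.  The rate matrix is normalised so that one
time unit corresponds to one expected substitution per site at the
stationary frequencies; branch "distances" passed to
:func:`hky_transition_matrix` are therefore expected substitutions per site.
With ``kappa=1`` and uniform frequencies the model reduces to Jukes-Cantor.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hky_rate_matrix",
    "hky_transition_matrix",
    "jc_expected_difference",
]

# transition (purine<->purine, pyrimidine<->pyrimidine) partner in ACGT order
_TS_PARTNER = {0: 2, 2: 0, 1: 3, 3: 1}


def _beta(kappa: float, freqs: np.ndarray) -> float:
    a, c, g, t = freqs
    pr, py = a + g, c + t
    return 1.0 / (2.0 * (kappa * (a * g + c * t) + pr * py))


def hky_rate_matrix(kappa: float, freqs) -> np.ndarray:
    """Normalised HKY instantaneous rate matrix (ACGT order)."""
    freqs = np.asarray(freqs, dtype=float)
    beta = _beta(kappa, freqs)
    q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = kappa if _TS_PARTNER[i] == j else 1.0
            q[i, j] = beta * rate * freqs[j]
        q[i, i] = -q[i].sum()
    return q


def hky_transition_matrix(d: float, kappa: float, freqs) -> np.ndarray:
    """P(d) = expm(Q d) in closed form for the HKY model.

    ``d`` is the branch length in expected substitutions per site.
    """
    freqs = np.asarray(freqs, dtype=float)
    a, c, g, t = freqs
    pr, py = a + g, c + t
    group = np.array([pr, py, pr, py])  # stationary mass of j's purine/pyrimidine group
    beta = _beta(kappa, freqs)
    e2 = np.exp(-beta * d)
    p = np.empty((4, 4))
    for j in range(4):
        gj = group[j]
        e3 = np.exp(-beta * d * (gj * kappa + (1.0 - gj)))
        for i in range(4):
            if i == j:
                p[i, j] = (
                    freqs[j]
                    + freqs[j] * (1.0 / gj - 1.0) * e2
                    + ((gj - freqs[j]) / gj) * e3
                )
            elif _TS_PARTNER[i] == j:
                p[i, j] = (
                    freqs[j]
                    + freqs[j] * (1.0 / gj - 1.0) * e2
                    - (freqs[j] / gj) * e3
                )
            else:
                p[i, j] = freqs[j] * (1.0 - e2)
    return p


def jc_expected_difference(d: float) -> float:
    """Expected per-site mismatch at distance ``d`` under Jukes-Cantor."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
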