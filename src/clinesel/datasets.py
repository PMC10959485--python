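"""Published worked-example numbers from a Scots pine common-garden study.

A 500-family open-pollinated progeny trial of *Pinus sylvestris* (one focal
southeastern-Finland population plus five latitudinal populations) published
family-level variance components, genetic correlations, and Lande-Arnold
selection gradients for budset timing (BST, days), first-year height (FYH,
mm), fall frost injury (FFI, ordinal 0-4), and seed weight (SW, per 200
seeds).  These printed estimates serve as worked-example inputs: the
heritability arithmetic, the Fisher-z intervals, and the canonical
eigen-analysis can all be recomputed from them and checked against the
printed results.

Trait order everywhere: BST, FYH, FFI, SW.
"""

from __future__ import annotations

import numpy as np

TRAITS = ("BST", "FYH", "FFI", "SW")

#: Focal-population phenotypic and additive variances (greenhouse scale).
PUBLISHED_VARIANCE_COMPONENTS = {
    "BST": {"VP": 83.6, "VA": 40.4},
    "FYH": {"VP": 250.3, "VA": 141.5},
    "FFI": {"VP": 0.83, "VA": 0.27},
}

#: Published narrow-sense heritabilities (focal population diagonal).
PUBLISHED_H2 = {"BST": 0.48, "FYH": 0.57, "FFI": 0.33}

#: (r, n) pairs with their printed 95% confidence bounds.
PUBLISHED_CORRELATION_CIS = [
    {"r": 0.14, "n": 500, "ci": (0.05, 0.22)},   # within-focal BST-FYH
    {"r": 0.76, "n": 50, "ci": (0.61, 0.86)},    # between-population BST-FYH
]

# family-level selection gradients under the two fitness definitions:
# beta from the linear-only model; gamma (full convention: diagonal gamma_ii,
# off-diagonal gamma_ik) from the full quadratic model.
_BETA = {
    "height-including-dead": [-1.50e-03, 4.21e-03, -8.58e-04, 5.04e-05],
    "survival-proportion": [-1.50e-02, 2.95e-02, -7.39e-03, 4.61e-03],
}
_GAMMA_DIAG = {
    "height-including-dead": [-2.11e-04, -1.08e-03, -5.68e-03, 8.38e-06],
    "survival-proportion": [-1.09e-02, -2.62e-02, -5.39e-02, -1.02e-02],
}
_GAMMA_OFF = {  # keys are (i, k) index pairs in trait order
    "height-including-dead": {(0, 1): -1.48e-03, (0, 2): 1.13e-03,
                              (0, 3): 2.06e-03, (1, 2): 3.34e-03,
                              (1, 3): -3.37e-04, (2, 3): -2.80e-03},
    "survival-proportion": {(0, 1): -1.45e-02, (0, 2): 1.28e-02,
                            (0, 3): 1.23e-02, (1, 2): 3.80e-02,
                            (1, 3): -2.00e-03, (2, 3): -2.88e-02},
}

#: Extreme eigenvalues of the halved-convention surface matrix as published.
PUBLISHED_EXTREME_EIGENVALUES = {
    "height-including-dead": {"min": -4.34e-03, "max": 1.60e-03},
    "survival-proportion": {"min": -4.65e-02, "max": 9.44e-03},
}

#: Published loading of FFI on the most curved (most negative) axis.
PUBLISHED_FFI_LOADING = {"height-including-dead": 0.825,
                         "survival-proportion": 0.780}


def published_selection_gradients(definition: str = "height-including-dead") -> dict:
    """Return ``{"beta": (4,), "gamma_full": (4, 4)}`` for a fitness definition."""
    if definition not in _BETA:
        raise KeyError(f"unknown fitness definition {definition!r}")
    beta = np.array(_BETA[definition])
    gamma = np.diag(np.array(_GAMMA_DIAG[definition]))
    for (i, k), v in _GAMMA_OFF[definition].items():
        gamma[i, k] = gamma[k, i] = v
    return {"beta": beta, "gamma_full": gamma, "traits": TRAITS}
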