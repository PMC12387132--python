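"""Construct taxonomy and the reference standardized solution.

The package works with eight CHC (Cattell-Horn-Carroll) broad cognitive
abilities and five narrow reading skills.  ``REFERENCE_LOADINGS`` and
``REFERENCE_PATHS`` hold the standardized solution of the consensus
integrated cognitive-reading model estimated from a large cross-battery
subtest-correlation database: g-loadings for the broad abilities and the
direct structural paths onto the reading skills (visual processing carries
no reading paths in the final model).  They serve as the default generating
values for the synthetic-data module and as the worked-example inputs for
the effect-decomposition machinery.
"""

from __future__ import annotations

import numpy as np

#: CHC broad abilities, Stratum II.
BROAD_ABILITIES: tuple[str, ...] = ("Gc", "Gf", "Gv", "Ga", "Gl", "Gr", "Gwm", "Gs")

#: Narrow reading skills in cascade (topological) order: phonological
#: decoding feeds lexical decoding, both feed decoding speed, and so on up
#: to reading comprehension.
READING_SKILLS: tuple[str, ...] = ("PD", "LD", "DS", "RF", "RC")

#: All thirteen constructs, broads first.
CONSTRUCTS: tuple[str, ...] = BROAD_ABILITIES + READING_SKILLS

#: Reading-skill cascade edges (source, target).
CASCADE_EDGES: tuple[tuple[str, str], ...] = (
    ("PD", "LD"),
    ("PD", "DS"),
    ("PD", "RF"),
    ("PD", "RC"),
    ("LD", "DS"),
    ("LD", "RF"),
    ("LD", "RC"),
    ("DS", "RF"),
    ("DS", "RC"),
    ("RF", "RC"),
)

#: Standardized g-loadings of the broad abilities (reference solution).
REFERENCE_LOADINGS: dict[str, float] = {
    "Gc": 0.70,
    "Gf": 0.64,
    "Gv": 0.56,
    "Ga": 0.59,
    "Gl": 0.56,
    "Gr": 0.43,
    "Gwm": 0.59,
    "Gs": 0.47,
}

#: Standardized direct paths (predictor -> outcome) of the reference
#: solution.  Gv predicts no reading skill; within the cascade every listed
#: edge is present.
REFERENCE_PATHS: dict[tuple[str, str], float] = {
    ("Gc", "PD"): 0.14, ("Gc", "LD"): 0.20, ("Gc", "DS"): -0.02,
    ("Gc", "RF"): 0.07, ("Gc", "RC"): 0.20,
    ("Gf", "PD"): 0.09, ("Gf", "LD"): 0.04, ("Gf", "DS"): 0.01,
    ("Gf", "RF"): 0.03, ("Gf", "RC"): 0.07,
    ("Ga", "PD"): 0.29, ("Ga", "LD"): 0.05, ("Ga", "DS"): 0.03,
    ("Ga", "RF"): -0.01, ("Ga", "RC"): 0.09,
    ("Gl", "PD"): 0.09, ("Gl", "LD"): 0.00, ("Gl", "DS"): -0.02,
    ("Gl", "RF"): 0.02, ("Gl", "RC"): 0.06,
    ("Gr", "PD"): 0.09, ("Gr", "LD"): 0.04, ("Gr", "DS"): 0.11,
    ("Gr", "RF"): 0.06, ("Gr", "RC"): 0.01,
    ("Gwm", "PD"): 0.13, ("Gwm", "LD"): 0.04, ("Gwm", "DS"): -0.04,
    ("Gwm", "RF"): 0.06, ("Gwm", "RC"): 0.03,
    ("Gs", "PD"): 0.03, ("Gs", "LD"): 0.07, ("Gs", "DS"): 0.20,
    ("Gs", "RF"): 0.11, ("Gs", "RC"): 0.00,
    ("PD", "LD"): 0.55, ("PD", "DS"): 0.33, ("PD", "RF"): 0.01,
    ("PD", "RC"): 0.05,
    ("LD", "DS"): 0.36, ("LD", "RF"): 0.22, ("LD", "RC"): 0.31,
    ("DS", "RF"): 0.37, ("DS", "RC"): 0.04,
    ("RF", "RC"): 0.12,
}


def reference_lambda() -> np.ndarray:
    """g-loadings as a vector in ``BROAD_ABILITIES`` order."""
    return np.array([REFERENCE_LOADINGS[b] for b in BROAD_ABILITIES])


def reference_b_matrix() -> np.ndarray:
    """Direct-path matrix B (13x13, ``B[i, j]`` = path j -> i) in
    ``CONSTRUCTS`` order, reference solution."""
    idx = {c: i for i, c in enumerate(CONSTRUCTS)}
    B = np.zeros((len(CONSTRUCTS), len(CONSTRUCTS)))
    for (src, dst), value in REFERENCE_PATHS.items():
        B[idx[dst], idx[src]] = value
    return B
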