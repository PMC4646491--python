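"""Cytospin morphology-class count simulation.

Manual cytospin scoring assigns each cell to one morphological class
(round nucleus, polarized nucleus, extruding, segmented nucleus,
reticulocyte, free nucleus).  Per experiment the number of enumerated
cells varies (a slide yields on the order of 100-700 scoreable cells);
class counts are a single multinomial draw per experiment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MORPHOLOGY_CLASSES = (
    "round_nucleus",
    "polarized_nucleus",
    "extruding",
    "segmented_nucleus",
    "reticulocyte",
    "free_nucleus",
)


def simulate_morphology_counts(
    class_probs: dict[str, float],
    n_cells: int | tuple[int, int] = (112, 541),
    n_experiments: int = 4,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate per-experiment cytospin class counts.

    Parameters
    ----------
    class_probs
        Mapping class -> probability; must sum to 1.
    n_cells
        Either a fixed count per experiment or an inclusive (low, high)
        range from which each experiment's enumerated-cell total is
        drawn uniformly.
    n_experiments, seed
        Number of independent experiments and RNG seed.

    Returns
    -------
    DataFrame with columns experiment_id, class, count.
    """
    probs = np.array(list(class_probs.values()), dtype=float)
    if np.any(probs < 0):
        raise ValueError("class probabilities must be non-negative")
    if not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError(f"class probabilities must sum to 1, got {probs.sum()}")
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = list(class_probs)
    rows = []
    for exp in range(1, n_experiments + 1):
        if isinstance(n_cells, tuple):
            lo, hi = n_cells
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid n_cells range {n_cells}")
            n = int(rng.integers(lo, hi + 1))
        else:
            if n_cells < 1:
                raise ValueError("n_cells must be >= 1")
            n = int(n_cells)
        counts = rng.multinomial(n, probs)
        for cls, c in zip(classes, counts):
            rows.append((f"exp{exp}", cls, int(c)))
    return pd.DataFrame(rows, columns=["experiment_id", "class", "count"])
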