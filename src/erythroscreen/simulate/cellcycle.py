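"""BrdU / 7-AAD cell-cycle event simulation.

S-phase cells incorporate BrdU during the pulse and carry intermediate
DNA content; G0/G1 cells are BrdU-negative with 2N DNA; G2/M cells are
BrdU-negative with 4N DNA.  The DNA (7-AAD) channel is linear, with the
2N mode at 200 units, matching the channel model used everywhere else in
the simulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..channels import CHANNELS, EVENT_COLUMNS

# BrdU on the transformed scale; DNA linear.
BRDU_NEG = (1.5, 0.30)
BRDU_POS = (4.5, 0.35)
DNA_2N = (200.0, 12.0)
DNA_4N = (400.0, 20.0)
# channels not informative for cell-cycle gating are drawn from the
# orthochromatic erythroblast model so the table is a full event table
_BACKGROUND = {
    "FSC": (5.0, 0.30),
    "SSC": (4.5, 0.30),
    "Hoechst": (5.0, 0.35),
    "Ter119": (5.2, 0.30),
    "CD44": (2.0, 0.35),
    "PI": (1.0, 0.35),
}


def simulate_cellcycle_events(
    fraction_s: float,
    fraction_g2m: float,
    n_cells: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a BrdU-pulsed, 7-AAD-stained event table.

    ``fraction_s`` of cells are S-phase (BrdU+, DNA between 2N and 4N),
    ``fraction_g2m`` are G2/M (BrdU-, 4N); the remainder are G0/G1
    (BrdU-, 2N).  Each event carries its phase in ``truth_label``.
    """
    for name, v in (("fraction_s", fraction_s), ("fraction_g2m", fraction_g2m)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if fraction_s + fraction_g2m > 1.0 + 1e-12:
        raise ValueError("fraction_s + fraction_g2m must be <= 1")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(
        n_cells, [fraction_s, fraction_g2m, 1.0 - fraction_s - fraction_g2m]
    )
    n_s, n_g2m, n_g1 = (int(c) for c in counts)

    frames = []
    for label, n in (("S", n_s), ("G2M", n_g2m), ("G0G1", n_g1)):
        if n == 0:
            continue
        data = {ch: rng.normal(loc, sc, size=n) for ch, (loc, sc) in _BACKGROUND.items()}
        if label == "S":
            data["BrdU"] = rng.normal(*BRDU_POS, size=n)
            # DNA replicated partway through the pulse: uniform between 2N and 4N
            data["DNA"] = rng.uniform(DNA_2N[0] * 1.1, DNA_4N[0] * 0.95, size=n)
        elif label == "G2M":
            data["BrdU"] = rng.normal(*BRDU_NEG, size=n)
            data["DNA"] = rng.normal(*DNA_4N, size=n)
        else:
            data["BrdU"] = rng.normal(*BRDU_NEG, size=n)
            data["DNA"] = rng.normal(*DNA_2N, size=n)
        data["DNA"] = np.clip(data["DNA"], 0.0, None)
        data["truth_label"] = np.repeat(label, n)
        frames.append(pd.DataFrame(data))
    events = pd.concat(frames, ignore_index=True)
    events.insert(0, "event_id", np.arange(len(events)))
    return events[list(EVENT_COLUMNS)]
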