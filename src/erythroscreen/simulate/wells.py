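"""Event-level simulation of single assay wells.

A well starts from ``n_cells`` sorted orthochromatic erythroblasts.  By
readout time each live cell has enucleated with probability
``true_enucleation_prob``; an enucleation splits one cell into two
particles, a reticulocyte and a free (extruded) nucleus, both of which
appear as separate events on the cytometer.  A ``dead_fraction`` of the
input cells die and become PI-bright events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..channels import CHANNELS, EVENT_COLUMNS
from .populations import POPULATIONS, PopulationSpec, default_population_specs


@dataclass(frozen=True)
class WellTruth:
    """Ground truth for one simulated well."""

    well_id: str
    compound_id: str
    true_enucleation_prob: float
    dead_fraction: float = 0.05
    n_cells: int = 30_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.true_enucleation_prob <= 1.0):
            raise ValueError(
                f"true_enucleation_prob must be in [0, 1], got {self.true_enucleation_prob}"
            )
        if not (0.0 <= self.dead_fraction <= 1.0):
            raise ValueError(f"dead_fraction must be in [0, 1], got {self.dead_fraction}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")


def draw_well_counts(
    truth: WellTruth, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Draw (n_dead, n_ortho, n_enucleated) for a well.

    This is the single source of stochastic cell-fate draws: the
    event-level simulator and the counts-only fast path both call it, so
    the two paths agree event-for-event on a shared stream.
    """
    n_dead = int(rng.binomial(truth.n_cells, truth.dead_fraction))
    n_live = truth.n_cells - n_dead
    n_enuc = int(rng.binomial(n_live, truth.true_enucleation_prob))
    return n_dead, n_live - n_enuc, n_enuc


def simulate_well_events(
    truth: WellTruth,
    specs: dict[str, PopulationSpec] | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate the event table recorded for one well.

    Returns a DataFrame with one row per detected particle: every live
    un-enucleated cell yields one ``orthochromatic_erythroblast`` event,
    every enucleation yields one ``reticulocyte`` plus one
    ``free_nucleus`` event, and dead cells yield ``dead_cell`` events.
    Each event carries its ground-truth label in ``truth_label``.
    """
    specs = default_population_specs() if specs is None else specs
    unknown = set(specs) - set(POPULATIONS)
    if unknown:
        raise ValueError(f"unknown populations in specs: {sorted(unknown)}")
    needed = {"orthochromatic_erythroblast", "reticulocyte", "free_nucleus", "dead_cell"}
    missing = needed - set(specs)
    if missing:
        raise ValueError(f"specs missing populations: {sorted(missing)}")

    rng = _as_rng(seed)
    n_dead, n_ortho, n_enuc = draw_well_counts(truth, rng)

    blocks = [
        ("orthochromatic_erythroblast", n_ortho),
        ("reticulocyte", n_enuc),
        ("free_nucleus", n_enuc),
        ("dead_cell", n_dead),
    ]
    frames = []
    for name, n in blocks:
        if n == 0:
            continue
        data = specs[name].sample(n, rng)
        data["truth_label"] = np.repeat(name, n)
        frames.append(pd.DataFrame(data))
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame({ch: np.array([], dtype=float) for ch in CHANNELS})
        events["truth_label"] = np.array([], dtype=object)
    events.insert(0, "event_id", np.arange(len(events)))
    return events[list(EVENT_COLUMNS)]


def simulate_mixed_events(
    composition: dict[str, float],
    n_cells: int,
    specs: dict[str, PopulationSpec] | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate a mixed suspension (e.g. whole dissociated spleen).

    ``composition`` maps population name to its fraction of ``n_cells``;
    fractions must sum to 1.  Used to exercise the sort gate against a
    realistic mixture of orthochromatic and late erythroblasts,
    reticulocytes, free nuclei and dead cells.
    """
    specs = default_population_specs() if specs is None else specs
    fracs = np.array(list(composition.values()), dtype=float)
    if not np.isclose(fracs.sum(), 1.0, atol=1e-8):
        raise ValueError(f"composition fractions must sum to 1, got {fracs.sum()}")
    unknown = set(composition) - set(POPULATIONS)
    if unknown:
        raise ValueError(f"unknown populations: {sorted(unknown)}")
    rng = _as_rng(seed)
    counts = rng.multinomial(n_cells, fracs)
    frames = []
    for name, n in zip(composition, counts):
        if n == 0:
            continue
        data = specs[name].sample(int(n), rng)
        data["truth_label"] = np.repeat(name, int(n))
        frames.append(pd.DataFrame(data))
    events = pd.concat(frames, ignore_index=True)
    events.insert(0, "event_id", np.arange(len(events)))
    return events[list(EVENT_COLUMNS)]


def _as_rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
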