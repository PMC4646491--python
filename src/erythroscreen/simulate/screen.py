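"""Whole-screen simulation: duplicate 96-well plates with known truth.

The screen design mirrors a primary phenotypic screen of a 324-compound
library against ex-vivo orthochromatic erythroblasts: compounds at a
single concentration (default 1 uM), 30,000 cells per well, DMSO
negative-control and cytochalasin D positive-control wells on every
plate, and the whole set of plates repeated once on a separate day so
every compound is read in two biological replicates.

Noise model: each physical plate run draws one between-day offset
(additive on the percentage scale) shared by all its wells, and every
well adds an independent within-plate error.  Both default magnitudes
are chosen so that duplicate runs are highly reproducible (replicate
Pearson r above 0.8 at realistic inhibitor effect sizes) without being
noiseless.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .populations import PopulationSpec, default_population_specs
from .wells import WellTruth, draw_well_counts, simulate_well_events

MECHANISMS = ("none", "arrest", "delay", "toxic")

#: Fraction of enucleation remaining in cytochalasin D wells (near-complete block).
CYTOD_RESIDUAL_PROB = 0.02


@dataclass(frozen=True)
class CompoundProfile:
    """Ground-truth effect of one library compound."""

    compound_id: str
    mechanism: str = "none"
    max_inhibition: float = 0.0  # relative reduction of enucleation at saturation
    ec50: float = 0.25  # uM
    toxicity: float = 0.0  # extra fraction of cells rendered PI+
    recovery_halftime: float = 1.5  # h; delay mechanism only

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        for name in ("max_inhibition", "toxicity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be positive, got {self.ec50}")
        if self.mechanism == "none" and self.max_inhibition != 0.0:
            raise ValueError("mechanism 'none' requires max_inhibition == 0")

    def dose_effect(self, concentration_uM: float) -> float:
        """Fractional occupancy at a concentration (Hill slope 1)."""
        if concentration_uM < 0:
            raise ValueError("concentration must be non-negative")
        if concentration_uM == 0:
            return 0.0
        return concentration_uM / (concentration_uM + self.ec50)

    def inhibition_at(self, concentration_uM: float) -> float:
        """Relative reduction of enucleation probability at a concentration."""
        return self.max_inhibition * self.dose_effect(concentration_uM)


ROWS = string.ascii_uppercase[:8]  # A..H
N_COLS = 12

#: Default control layout: column 1 split between the two control roles.
DEFAULT_NEG_WELLS = ("A1", "B1", "C1", "D1")
DEFAULT_POS_WELLS = ("E1", "F1", "G1", "H1")


@dataclass(frozen=True)
class ScreenDesign:
    """Design parameters of a duplicate single-concentration screen."""

    n_compounds: int = 324
    concentration: float = 1.0  # uM
    n_replicates: int = 2
    baseline_enucleation: float = 0.65  # DMSO-well truth at the 5 h readout
    baseline_dead_fraction: float = 0.05
    between_day_sd: float = 4.0  # percentage points, one draw per plate run
    within_plate_sd: float = 3.0  # percentage points, per well
    n_cells_per_well: int = 30_000
    neg_control_wells: tuple[str, ...] = DEFAULT_NEG_WELLS
    pos_control_wells: tuple[str, ...] = DEFAULT_POS_WELLS
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.neg_control_wells) & set(self.pos_control_wells):
            raise ValueError("control well sets must be disjoint")
        if not (0.0 <= self.baseline_enucleation <= 1.0):
            raise ValueError("baseline_enucleation must be in [0, 1]")
        if self.n_compounds < 1 or self.n_replicates < 1:
            raise ValueError("n_compounds and n_replicates must be >= 1")

    @property
    def compound_wells_per_plate(self) -> int:
        return len(ROWS) * N_COLS - len(self.neg_control_wells) - len(self.pos_control_wells)

    @property
    def n_batches(self) -> int:
        per = self.compound_wells_per_plate
        return (self.n_compounds + per - 1) // per


def all_wells() -> list[str]:
    return [f"{r}{c}" for r, c in itertools.product(ROWS, range(1, N_COLS + 1))]


def plate_layout(design: ScreenDesign, library: list[CompoundProfile]) -> pd.DataFrame:
    """Assign compounds and controls to wells across batches.

    Returns one row per (batch, well): batch, well_id, role, compound_id,
    concentration.  The same layout is reused for every replicate, as a
    repeated plate run on a separate day would be.
    """
    if len(library) != design.n_compounds:
        raise ValueError(
            f"library size {len(library)} does not match design.n_compounds {design.n_compounds}"
        )
    controls = set(design.neg_control_wells) | set(design.pos_control_wells)
    compound_wells = [w for w in all_wells() if w not in controls]
    rows = []
    lib_iter = iter(library)
    for batch in range(1, design.n_batches + 1):
        for w in design.neg_control_wells:
            rows.append((batch, w, "neg_control", "DMSO", 0.0))
        for w in design.pos_control_wells:
            rows.append((batch, w, "pos_control", "CytoD", design.concentration))
        for w in compound_wells:
            prof = next(lib_iter, None)
            if prof is None:
                break
            rows.append((batch, w, "compound", prof.compound_id, design.concentration))
    return pd.DataFrame(
        rows, columns=["batch", "well_id", "role", "compound_id", "concentration"]
    )


def make_library(
    n_compounds: int = 324,
    n_arrest: int = 13,
    n_delay: int = 12,
    n_toxic: int = 6,
    min_inhibition: float = 0.5,
    max_inhibition: float = 1.0,
    screen_concentration: float = 1.0,
    seed: int = 0,
) -> list[CompoundProfile]:
    """Build a ground-truth library with a known inhibitor spike-in.

    Inhibitor ``max_inhibition`` values are spread uniformly over
    [min_inhibition, max_inhibition]; with the default ec50 of 0.25 uM a
    1 uM screen sees 80% of that, i.e. relative reductions of 40-80%.
    Toxic compounds kill cells without blocking enucleation in the
    survivors.  Positions in the library are shuffled deterministically.
    """
    n_hits = n_arrest + n_delay
    if n_hits + n_toxic > n_compounds:
        raise ValueError("more special compounds than library slots")
    rng = np.random.default_rng(seed)
    mechs = ["arrest"] * n_arrest + ["delay"] * n_delay
    strengths = np.linspace(min_inhibition, max_inhibition, num=max(n_hits, 1))
    profiles = [
        CompoundProfile(
            compound_id="",  # assigned after shuffling
            mechanism=m,
            max_inhibition=float(s),
            recovery_halftime=float(rng.uniform(0.8, 2.0)),
        )
        for m, s in zip(mechs, strengths)
    ]
    profiles += [
        CompoundProfile("", mechanism="toxic", max_inhibition=0.0, toxicity=0.6)
        for _ in range(n_toxic)
    ]
    profiles += [
        CompoundProfile("", mechanism="none") for _ in range(n_compounds - len(profiles))
    ]
    order = rng.permutation(len(profiles))
    shuffled = [profiles[i] for i in order]
    return [
        CompoundProfile(
            compound_id=f"CPD{i + 1:03d}",
            mechanism=p.mechanism,
            max_inhibition=p.max_inhibition,
            ec50=p.ec50,
            toxicity=p.toxicity,
            recovery_halftime=p.recovery_halftime,
        )
        for i, p in enumerate(shuffled)
    ]


def _well_rng(master_seed: int, replicate: int, batch: int, well_index: int) -> np.random.Generator:
    # deterministic independent stream per (master, plate, well)
    ss = np.random.SeedSequence([master_seed, replicate, batch, well_index])
    return np.random.default_rng(ss)


def simulate_screen(
    design: ScreenDesign,
    library: list[CompoundProfile],
    seed: int | None = None,
    mode: str = "counts",
    specs: dict[str, PopulationSpec] | None = None,
):
    """Simulate the full duplicate screen.

    Parameters
    ----------
    design, library
        Screen design and ground-truth compound library.
    seed
        Master seed; defaults to ``design.seed``.  Per-plate and per-well
        streams are derived deterministically from it.
    mode
        ``"counts"`` (fast path) draws per-well cell fates and returns
        gated-count-equivalent readouts without sampling channel
        intensities.  ``"events"`` additionally returns the per-well
        event tables; both modes share the per-well fate draws, so the
        counts agree event-for-event.

    Returns
    -------
    wells : DataFrame
        One row per (replicate, batch, well): plate_id, well_id, role,
        compound_id, counts (n_enucleated, n_nucleated, n_live, n_total)
        and the underlying truth columns.
    events : dict[(plate_id, well_id), DataFrame] | None
        Event tables in ``mode="events"``, else None.
    """
    if mode not in ("counts", "events"):
        raise ValueError(f"mode must be 'counts' or 'events', got {mode!r}")
    master = design.seed if seed is None else int(seed)
    layout = plate_layout(design, library)
    by_id = {p.compound_id: p for p in library}
    specs = default_population_specs() if specs is None else specs

    day_rng = np.random.default_rng(np.random.SeedSequence([master, 987_654_321]))
    rows = []
    events: dict[tuple[str, str], pd.DataFrame] = {}
    for rep in range(1, design.n_replicates + 1):
        for batch in sorted(layout["batch"].unique()):
            plate_id = f"R{rep}-P{batch}"
            day_offset = day_rng.normal(0.0, design.between_day_sd) / 100.0
            plate_wells = layout[layout["batch"] == batch]
            for widx, rec in enumerate(plate_wells.itertuples(index=False)):
                rng = _well_rng(master, rep, int(batch), widx)
                well_noise = rng.normal(0.0, design.within_plate_sd) / 100.0
                if rec.role == "neg_control":
                    p_clean, dead = design.baseline_enucleation, design.baseline_dead_fraction
                elif rec.role == "pos_control":
                    p_clean, dead = CYTOD_RESIDUAL_PROB, design.baseline_dead_fraction
                else:
                    prof = by_id[rec.compound_id]
                    p_clean = design.baseline_enucleation * (
                        1.0 - prof.inhibition_at(rec.concentration)
                    )
                    dead = min(1.0, design.baseline_dead_fraction + prof.toxicity)
                p_true = float(np.clip(p_clean + day_offset + well_noise, 0.0, 1.0))
                truth = WellTruth(
                    well_id=rec.well_id,
                    compound_id=rec.compound_id,
                    true_enucleation_prob=p_true,
                    dead_fraction=dead,
                    n_cells=design.n_cells_per_well,
                )
                if mode == "events":
                    tbl = simulate_well_events(truth, specs=specs, seed=rng)
                    events[(plate_id, rec.well_id)] = tbl
                    lbl = tbl["truth_label"]
                    n_dead = int((lbl == "dead_cell").sum())
                    n_ortho = int((lbl == "orthochromatic_erythroblast").sum())
                    n_enuc = int((lbl == "reticulocyte").sum())
                else:
                    n_dead, n_ortho, n_enuc = draw_well_counts(truth, rng)
                n_total = truth.n_cells + n_enuc  # enucleation splits 1 cell -> 2 events
                rows.append(
                    {
                        "plate_id": plate_id,
                        "replicate": rep,
                        "batch": int(batch),
                        "well_id": rec.well_id,
                        "role": rec.role,
                        "compound_id": rec.compound_id,
                        "concentration": rec.concentration,
                        "n_enucleated": n_enuc,
                        "n_nucleated": n_ortho,
                        "n_live": n_total - n_dead,
                        "n_total": n_total,
                        "true_enucleation_prob": p_true,
                        "true_dead_fraction": dead,
                    }
                )
    wells = pd.DataFrame(rows)
    return wells, (events if mode == "events" else None)


def screen_truth_record(design: ScreenDesign, library: list[CompoundProfile]) -> dict:
    """JSON-serialisable ground-truth record for a simulated screen."""
    return {
        "design": {
            "n_compounds": design.n_compounds,
            "concentration_uM": design.concentration,
            "n_replicates": design.n_replicates,
            "baseline_enucleation": design.baseline_enucleation,
            "between_day_sd_pct": design.between_day_sd,
            "within_plate_sd_pct": design.within_plate_sd,
            "n_cells_per_well": design.n_cells_per_well,
            "seed": design.seed,
        },
        "compounds": {
            p.compound_id: {
                "mechanism": p.mechanism,
                "max_inhibition": p.max_inhibition,
                "ec50_uM": p.ec50,
                "toxicity": p.toxicity,
                "recovery_halftime_h": p.recovery_halftime,
                "inhibition_at_screen_conc": p.inhibition_at(design.concentration),
            }
            for p in library
        },
    }
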