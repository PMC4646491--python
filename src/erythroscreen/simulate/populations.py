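"""Ground-truth population channel models for the event-level simulator.

Each biological population seen in the enucleation assay (orthochromatic
erythroblasts, reticulocytes, extruded free nuclei, less mature "late"
erythroblasts, and dead cells) is modelled as a single Gaussian component
per channel on the transformed intensity scale (DNA stays linear).  The
locations encode the qualitative structure of the assay:

* reticulocytes are Ter119-positive but Hoechst-negative and smaller
  (lower FSC/SSC) than the erythroblasts they derive from;
* free nuclei are Hoechst-bright and, by default, Ter119-low so they fall
  outside both terms of the net-enucleation denominator;
* late erythroblasts sit above the orthochromatic sort gate on CD44;
* dead cells are PI-bright.

Gate thresholds elsewhere in the package default to midpoints between the
relevant population locations of this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..channels import CHANNELS

POPULATIONS = (
    "orthochromatic_erythroblast",
    "reticulocyte",
    "free_nucleus",
    "late_erythroblast",
    "dead_cell",
)


@dataclass(frozen=True)
class ChannelParam:
    """Location and spread of one channel for one population."""

    loc: float
    scale: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.loc):
            raise ValueError(f"channel location must be finite, got {self.loc}")
        if not (self.scale > 0):
            raise ValueError(f"channel spread must be positive, got {self.scale}")


@dataclass(frozen=True)
class PopulationSpec:
    """Per-channel intensity model for one ground-truth population."""

    name: str
    channel_params: dict[str, ChannelParam] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in POPULATIONS:
            raise ValueError(
                f"unknown population {self.name!r}; expected one of {POPULATIONS}"
            )
        missing = set(CHANNELS) - set(self.channel_params)
        if missing:
            raise ValueError(f"population {self.name!r} missing channels {sorted(missing)}")

    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Draw ``n`` events from this population's channel model."""
        out: dict[str, np.ndarray] = {}
        for ch in CHANNELS:
            p = self.channel_params[ch]
            vals = rng.normal(p.loc, p.scale, size=n)
            if ch == "DNA":  # linear channel; negative signal is unphysical
                vals = np.clip(vals, 0.0, None)
            out[ch] = vals
        return out


def _cp(**kw: tuple[float, float]) -> dict[str, ChannelParam]:
    return {ch: ChannelParam(*kw[ch]) for ch in kw}


def default_population_specs(
    free_nuclei_ter119_positive: bool = False,
) -> dict[str, PopulationSpec]:
    """Default channel model for the five assay populations.

    Parameters
    ----------
    free_nuclei_ter119_positive
        The Ter119 status of extruded nuclei inside the analysis gate is
        ambiguous on a real machine (membrane-wrapped nuclei retain some
        Ter119).  By default free nuclei are emitted Ter119-low, so they
        enter neither term of the net-enucleation ratio; set True to emit
        them Ter119-positive instead, in which case they are counted as
        nucleated erythroid events.
    """
    specs = {
        "orthochromatic_erythroblast": PopulationSpec(
            "orthochromatic_erythroblast",
            _cp(
                FSC=(5.0, 0.30),
                SSC=(4.5, 0.30),
                Hoechst=(5.0, 0.35),
                Ter119=(5.2, 0.30),
                CD44=(2.0, 0.35),
                PI=(1.0, 0.35),
                BrdU=(1.5, 0.30),
                DNA=(200.0, 12.0),
            ),
        ),
        "reticulocyte": PopulationSpec(
            "reticulocyte",
            _cp(
                FSC=(4.2, 0.30),
                SSC=(3.7, 0.30),
                Hoechst=(0.8, 0.35),
                Ter119=(5.0, 0.30),
                CD44=(1.6, 0.35),
                PI=(1.0, 0.35),
                BrdU=(1.5, 0.30),
                DNA=(15.0, 8.0),
            ),
        ),
        "free_nucleus": PopulationSpec(
            "free_nucleus",
            _cp(
                FSC=(3.4, 0.30),
                SSC=(3.0, 0.30),
                Hoechst=(5.4, 0.35),
                Ter119=(1.2, 0.35),
                CD44=(1.0, 0.35),
                PI=(1.0, 0.35),
                BrdU=(1.5, 0.30),
                DNA=(200.0, 12.0),
            ),
        ),
        "late_erythroblast": PopulationSpec(
            "late_erythroblast",
            _cp(
                FSC=(5.3, 0.30),
                SSC=(4.8, 0.30),
                Hoechst=(5.0, 0.35),
                Ter119=(4.8, 0.30),
                CD44=(4.2, 0.35),
                PI=(1.0, 0.35),
                BrdU=(1.5, 0.30),
                DNA=(200.0, 12.0),
            ),
        ),
        "dead_cell": PopulationSpec(
            "dead_cell",
            _cp(
                FSC=(4.6, 0.45),
                SSC=(4.6, 0.45),
                Hoechst=(5.0, 0.50),
                Ter119=(4.5, 0.60),
                CD44=(2.5, 0.60),
                PI=(4.5, 0.40),
                BrdU=(1.5, 0.30),
                DNA=(200.0, 30.0),
            ),
        ),
    }
    # invariant checks encoded by the assay biology
    retic, ortho = specs["reticulocyte"], specs["orthochromatic_erythroblast"]
    assert retic.channel_params["FSC"].loc < ortho.channel_params["FSC"].loc
    assert retic.channel_params["SSC"].loc < ortho.channel_params["SSC"].loc
    if free_nuclei_ter119_positive:
        fn = specs["free_nucleus"]
        params = dict(fn.channel_params)
        params["Ter119"] = ChannelParam(5.0, 0.30)
        specs["free_nucleus"] = replace(fn, channel_params=params)
    return specs
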