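"""Flow-cytometry gating: geometric gates, hierarchies, and the assay's
standard gate set (live gate, enucleation classification, orthochromatic
sort gate, BrdU/7-AAD cell-cycle gating).

Conventions
-----------
* Gates evaluate on transformed intensities (identity by default, since
  the simulator emits already-transformed values; asinh available for
  linear-scale input).
* Rectangle bounds are half-open, ``min <= x < max``, so adjacent gates
  partition without double counting.  Unbounded sides use +/-inf.
* Polygon membership uses the even-odd rule with boundary points counted
  as inside.
* Default thresholds sit at the midpoint, on the transformed scale,
  between the two relevant population locations of the default simulator
  channel model; every threshold is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .channels import TRANSFORMS
from .simulate.populations import default_population_specs


class MissingChannelError(KeyError):
    """A gate references a channel absent from the event table."""


# ---------------------------------------------------------------------------
# geometric gates


@dataclass(frozen=True)
class Gate:
    """A 1-D threshold / 2-D rectangle or polygon gate.

    Exactly one of ``rect`` or ``polygon`` is set.  ``rect`` maps each
    gated channel to (min, max) with half-open membership; 1-D threshold
    gates are rectangles over a single channel.  ``polygon`` is a vertex
    list in (channel_x, channel_y) space.
    """

    name: str
    channel_x: str
    channel_y: str | None = None
    rect: dict[str, tuple[float, float]] | None = None
    polygon: tuple[tuple[float, float], ...] | None = None
    transform: str = "identity"
    cofactor: float = 150.0

    def __post_init__(self) -> None:
        if (self.rect is None) == (self.polygon is None):
            raise ValueError(f"gate {self.name!r}: set exactly one of rect or polygon")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.rect is not None:
            for ch, (lo, hi) in self.rect.items():
                if not lo < hi:
                    raise ValueError(
                        f"gate {self.name!r}: rectangle min must be < max on {ch}, got [{lo}, {hi})"
                    )
        if self.polygon is not None:
            if self.channel_y is None:
                raise ValueError(f"gate {self.name!r}: polygon gates need channel_y")
            verts = np.asarray(self.polygon, dtype=float)
            if len(verts) < 3:
                raise ValueError(f"gate {self.name!r}: polygon needs >= 3 vertices")
            # non-collinearity: some vertex lies off the line through the first edge
            v = verts - verts[0]
            cross_z = v[1, 0] * v[2:, 1] - v[1, 1] * v[2:, 0]
            if np.allclose(cross_z, 0.0):
                raise ValueError(f"gate {self.name!r}: polygon vertices are collinear")

    @property
    def channels(self) -> tuple[str, ...]:
        if self.rect is not None:
            return tuple(self.rect)
        return (self.channel_x, self.channel_y)  # type: ignore[return-value]

    def membership(self, events: pd.DataFrame) -> np.ndarray:
        """Boolean membership vector for each event row."""
        tf = TRANSFORMS[self.transform]
        missing = [ch for ch in self.channels if ch not in events.columns]
        if missing:
            raise MissingChannelError(
                f"gate {self.name!r} needs channels {missing} absent from the event table"
            )
        if self.rect is not None:
            mask = np.ones(len(events), dtype=bool)
            for ch, (lo, hi) in self.rect.items():
                x = tf(events[ch].to_numpy(), self.cofactor)
                mask &= (x >= lo) & (x < hi)
            return mask
        x = tf(events[self.channel_x].to_numpy(), self.cofactor)
        y = tf(events[self.channel_y].to_numpy(), self.cofactor)
        return points_in_polygon(x, y, np.asarray(self.polygon, dtype=float))


def points_in_polygon(x: np.ndarray, y: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Vectorized even-odd polygon test; boundary points count as inside."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    on_edge = np.zeros(x.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        within = (
            (x >= min(x1, x2)) & (x <= max(x1, x2)) & (y >= min(y1, y2)) & (y <= max(y1, y2))
        )
        on_edge |= (cross == 0.0) & within
        # even-odd ray cast: horizontal ray to +inf, half-open in y
        crosses = (y1 <= y) != (y2 <= y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at_y = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < x_at_y)
    return inside | on_edge


def point_in_polygon_scalar(px: float, py: float, verts: np.ndarray) -> bool:
    """Per-point reference evaluation of the same even-odd + boundary rule."""
    return bool(points_in_polygon(np.array([px]), np.array([py]), verts)[0])


def apply_gate(events: pd.DataFrame, gate: Gate) -> tuple[pd.DataFrame, int]:
    """Return (member subset, member count) for one gate."""
    mask = gate.membership(events)
    subset = events.loc[mask]
    return subset, int(mask.sum())


# ---------------------------------------------------------------------------
# hierarchies


@dataclass
class GatingHierarchy:
    """An ordered tree of gates rooted at the full event table ("root")."""

    gates: list[tuple[Gate, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {"root"}
        for gate, parent in self.gates:
            if parent not in known:
                raise ValueError(
                    f"gate {gate.name!r} has unknown parent {parent!r} "
                    "(parents must be declared first; tree is rooted at 'root')"
                )
            if gate.name in known:
                raise ValueError(f"duplicate gate name {gate.name!r}")
            known.add(gate.name)

    def apply(self, events: pd.DataFrame) -> pd.DataFrame:
        """Gate the table top-down; returns per-node counts and parent fractions."""
        subsets: dict[str, pd.DataFrame] = {"root": events}
        rows = [("root", "", len(events), 1.0)]
        for gate, parent in self.gates:
            sub, count = apply_gate(subsets[parent], gate)
            subsets[gate.name] = sub
            parent_n = len(subsets[parent])
            rows.append((gate.name, parent, count, count / parent_n if parent_n else np.nan))
        return pd.DataFrame(rows, columns=["population", "parent", "count", "fraction_of_parent"])

    def subset(self, events: pd.DataFrame, name: str) -> pd.DataFrame:
        """Events inside the named node (conjunction along its ancestry)."""
        subsets: dict[str, pd.DataFrame] = {"root": events}
        for gate, parent in self.gates:
            subsets[gate.name], _ = apply_gate(subsets[parent], gate)
            if gate.name == name:
                return subsets[name]
        if name == "root":
            return events
        raise KeyError(f"no gate named {name!r}")


def load_gating_file(path: str | Path) -> GatingHierarchy:
    """Read a gating hierarchy from YAML/JSON.

    Expected layout: a list of mappings with keys ``name``, ``parent``
    (default "root"), ``transform`` (default identity), and either
    ``rect: {channel: [min, max]}`` (nulls for unbounded sides) or
    ``polygon: {channel_x, channel_y, vertices: [[x, y], ...]}``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValueError("gating file must contain a list of gate definitions")
    gates: list[tuple[Gate, str]] = []
    for item in raw:
        name = item["name"]
        parent = item.get("parent", "root")
        transform = item.get("transform", "identity")
        cofactor = float(item.get("cofactor", 150.0))
        if "rect" in item:
            rect = {}
            for ch, (lo, hi) in item["rect"].items():
                rect[ch] = (
                    -np.inf if lo is None else float(lo),
                    np.inf if hi is None else float(hi),
                )
            gate = Gate(
                name=name,
                channel_x=next(iter(rect)),
                channel_y=None,
                rect=rect,
                transform=transform,
                cofactor=cofactor,
            )
        elif "polygon" in item:
            poly = item["polygon"]
            gate = Gate(
                name=name,
                channel_x=poly["channel_x"],
                channel_y=poly["channel_y"],
                polygon=tuple((float(a), float(b)) for a, b in poly["vertices"]),
                transform=transform,
                cofactor=cofactor,
            )
        else:
            raise ValueError(f"gate {name!r}: needs 'rect' or 'polygon'")
        gates.append((gate, parent))
    return GatingHierarchy(gates)


# ---------------------------------------------------------------------------
# assay-standard gates and thresholds


def _midpoint(pop_a: str, pop_b: str, channel: str, specs) -> float:
    a = specs[pop_a].channel_params[channel].loc
    b = specs[pop_b].channel_params[channel].loc
    return 0.5 * (a + b)


def default_thresholds() -> dict[str, float]:
    """Assay thresholds derived from the default simulator channel model.

    Each lies at the midpoint between the two populations the threshold
    separates; DNA's 4N cut is 1.5x the 2N modal signal, the standard
    cytometry convention for a linear DNA channel.
    """
    specs = default_population_specs()
    return {
        "PI": _midpoint("orthochromatic_erythroblast", "dead_cell", "PI", specs),
        "Hoechst": _midpoint("reticulocyte", "orthochromatic_erythroblast", "Hoechst", specs),
        "Ter119": _midpoint("free_nucleus", "reticulocyte", "Ter119", specs),
        "CD44": _midpoint("orthochromatic_erythroblast", "late_erythroblast", "CD44", specs),
        "BrdU": 3.0,  # midpoint of the BrdU-neg (1.5) and BrdU-pos (4.5) modes
        "DNA_4N": 1.5 * specs["orthochromatic_erythroblast"].channel_params["DNA"].loc,
    }


def gate_live(events: pd.DataFrame, pi_threshold: float | None = None) -> tuple[pd.DataFrame, float]:
    """PI dead-cell exclusion.

    Returns (live subset, dead fraction).  The dead fraction doubles as
    the assay's cytotoxicity readout: it separates compounds that block
    enucleation mechanistically from ones that simply kill the cells.
    """
    if "PI" not in events.columns:
        raise MissingChannelError("event table has no PI channel")
    thr = default_thresholds()["PI"] if pi_threshold is None else pi_threshold
    dead = events["PI"].to_numpy() >= thr
    live = events.loc[~dead]
    frac = float(dead.mean()) if len(events) else float("nan")
    return live, frac


def classify_enucleation(
    live_events: pd.DataFrame,
    ter119_threshold: float | None = None,
    hoechst_threshold: float | None = None,
) -> tuple[int, int]:
    """Count enucleated (Ter119+/Hoechst-) vs nucleated (Ter119+/Hoechst+).

    Input must already be live-gated.  Ter119-negative events (debris,
    Ter119-low free nuclei) are counted in neither class.
    """
    for ch in ("Ter119", "Hoechst"):
        if ch not in live_events.columns:
            raise MissingChannelError(f"event table has no {ch} channel")
    thr = default_thresholds()
    t_thr = thr["Ter119"] if ter119_threshold is None else ter119_threshold
    h_thr = thr["Hoechst"] if hoechst_threshold is None else hoechst_threshold
    ter_pos = live_events["Ter119"].to_numpy() >= t_thr
    hoechst_pos = live_events["Hoechst"].to_numpy() >= h_thr
    n_enucleated = int((ter_pos & ~hoechst_pos).sum())
    n_nucleated = int((ter_pos & hoechst_pos).sum())
    return n_enucleated, n_nucleated


def gate_orthochromatic_sort(
    events: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The sort gate: PI- / Hoechst+ / Ter119-high / CD44-low.

    Emulates the isolation of orthochromatic erythroblasts from
    dissociated spleen: dead cells and already-enucleated (Hoechst-
    negative) cells are excluded, then the Ter119-high / CD44-low gate
    selects the orthochromatic population.  Also returns the adjacent
    CD44-high "late erythroblast" gate used for comparison.
    """
    for ch in ("Ter119", "CD44", "Hoechst", "PI"):
        if ch not in events.columns:
            raise MissingChannelError(f"event table has no {ch} channel")
    thr = default_thresholds()
    if thresholds:
        thr.update(thresholds)
    live, _ = gate_live(events, thr["PI"])
    nucleated = live.loc[live["Hoechst"].to_numpy() >= thr["Hoechst"]]
    ter_hi = nucleated.loc[nucleated["Ter119"].to_numpy() >= thr["Ter119"]]
    cd44 = ter_hi["CD44"].to_numpy()
    ortho = ter_hi.loc[cd44 < thr["CD44"]]
    late = ter_hi.loc[cd44 >= thr["CD44"]]
    return ortho, late


def cellcycle_fractions(
    events: pd.DataFrame,
    brdu_threshold: float | None = None,
    dna_4n_threshold: float | None = None,
) -> dict[str, float]:
    """BrdU / DNA-content fractions: S, G0/G1, G2/M, non-proliferating.

    S = BrdU+; G0/G1 = BrdU- with sub-4N DNA; G2/M = BrdU- with >= 4N
    DNA.  The three phases sum to 1; non_proliferating = G0/G1 + G2/M.
    """
    for ch in ("BrdU", "DNA"):
        if ch not in events.columns:
            raise MissingChannelError(f"event table has no {ch} channel")
    thr = default_thresholds()
    b_thr = thr["BrdU"] if brdu_threshold is None else brdu_threshold
    d_thr = thr["DNA_4N"] if dna_4n_threshold is None else dna_4n_threshold
    n = len(events)
    if n == 0:
        raise ValueError("empty event table")
    brdu_pos = events["BrdU"].to_numpy() >= b_thr
    four_n = events["DNA"].to_numpy() >= d_thr
    s = float(brdu_pos.mean())
    g2m = float((~brdu_pos & four_n).mean())
    g0g1 = float((~brdu_pos & ~four_n).mean())
    return {"S": s, "G0G1": g0g1, "G2M": g2m, "non_proliferating": g0g1 + g2m}


def gate_counts_for_well(events: pd.DataFrame, thresholds: dict[str, float] | None = None) -> dict:
    """Full per-well gating used by the screen: live gate then
    enucleation classification; returns the count set the screen
    statistic needs."""
    thr = default_thresholds()
    if thresholds:
        thr.update(thresholds)
    live, dead_frac = gate_live(events, thr["PI"])
    n_enuc, n_nuc = classify_enucleation(live, thr["Ter119"], thr["Hoechst"])
    return {
        "n_enucleated": n_enuc,
        "n_nucleated": n_nuc,
        "n_live": len(live),
        "n_total": len(events),
        "dead_fraction": dead_frac,
    }
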