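"""Screen statistics: net enucleation, plate-median normalization,
z-scores, replicate reproducibility, hit calling and plate QC.

The primary readout of each well is the net enucleation percentage,

    net % = 100 * n_enucleated / (n_enucleated + n_nucleated),

with enucleated = Ter119+/Hoechst- and nucleated = Ter119+/Hoechst+
events after dead-cell exclusion.  Within each plate, compound-well
percentages are centered by the plate median and scaled into z-scores;
a compound is a potential hit when its z-score falls below the threshold
(default -1) in either of the two replicate runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class DegeneratePlateError(ValueError):
    """All compound wells identical: plate scale is zero, z-scores undefined."""


#: QC flag thresholds (fractions / event counts), overridable per call.
DEFAULT_MIN_EVENTS = 1000
DEFAULT_MAX_DEAD_FRACTION = 0.5


def net_enucleation(n_enucleated: int, n_nucleated: int) -> float:
    """Net enucleation percentage of a well.

    Returns ``100 * a / (a + b)``; NaN (missing, not zero) when the
    erythroid denominator is empty.
    """
    if n_enucleated < 0 or n_nucleated < 0:
        raise ValueError(f"counts must be non-negative, got ({n_enucleated}, {n_nucleated})")
    denom = n_enucleated + n_nucleated
    if denom == 0:
        return float("nan")
    return 100.0 * n_enucleated / denom


def wells_to_results(
    wells: pd.DataFrame,
    min_events: int = DEFAULT_MIN_EVENTS,
    max_dead_fraction: float = DEFAULT_MAX_DEAD_FRACTION,
) -> pd.DataFrame:
    """Attach the net-enucleation statistic and QC flags to per-well counts.

    Input needs columns plate_id, well_id, role, compound_id,
    n_enucleated, n_nucleated, n_live, n_total.  Wells flagged
    ``low_event`` (too few total events) get a missing statistic; wells
    flagged ``high_death`` keep theirs (cytotoxicity is a readout, not a
    voiding condition) but carry the flag into the hit report.
    """
    out = wells.copy()
    out["net_enucleation_pct"] = [
        net_enucleation(a, b) for a, b in zip(out["n_enucleated"], out["n_nucleated"])
    ]
    dead_frac = 1.0 - out["n_live"] / out["n_total"].replace(0, np.nan)
    out["dead_fraction"] = dead_frac
    flags = []
    for _, row in out.iterrows():
        f = []
        if row["n_total"] < min_events:
            f.append("low_event")
        if row["dead_fraction"] >= max_dead_fraction:
            f.append("high_death")
        flags.append(";".join(f))
    out["qc_flags"] = flags
    out.loc[out["qc_flags"].str.contains("low_event"), "net_enucleation_pct"] = np.nan
    return out


def normalize_plate(
    plate: pd.DataFrame,
    scale_mode: str = "sd",
) -> pd.DataFrame:
    """Plate-median normalization and z-scores for one plate.

    Compound wells only enter the location and scale estimates; control
    wells are extreme by construction and would otherwise corrupt both.
    ``scale_mode`` is ``"sd"`` (sample standard deviation of the
    median-centered compound wells) or ``"mad"`` (1.4826 * MAD, robust).
    Missing wells propagate as missing.  Returns the plate with added
    ``centered`` and ``zscore`` columns and ``plate_median`` /
    ``plate_scale`` attrs.
    """
    if scale_mode not in ("sd", "mad"):
        raise ValueError(f"scale_mode must be 'sd' or 'mad', got {scale_mode!r}")
    out = plate.copy()
    is_compound = out["role"] == "compound"
    values = out.loc[is_compound, "net_enucleation_pct"].to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 3:
        raise ValueError(
            f"need >= 3 non-missing compound wells to normalize a plate, got {finite.size}"
        )
    med = float(np.median(finite))
    centered_finite = finite - med
    if scale_mode == "sd":
        scale = float(np.std(centered_finite, ddof=1))
    else:
        scale = float(1.4826 * np.median(np.abs(centered_finite)))
    if scale == 0.0:
        raise DegeneratePlateError(
            "all compound wells identical; plate scale is zero"
        )
    out["centered"] = out["net_enucleation_pct"] - med
    out["zscore"] = out["centered"] / scale
    # controls are reported on the compound-well scale but never define it
    out.attrs["plate_median"] = med
    out.attrs["plate_scale"] = scale
    return out


def call_hits(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    threshold: float = -1.0,
) -> pd.DataFrame:
    """Either-replicate hit calling on per-compound z-scores.

    Inputs are per-replicate tables with columns compound_id, zscore
    (compound wells only).  A compound is a potential hit when its
    z-score is strictly below ``threshold`` in either replicate; a
    compound missing in one replicate is called on the other and
    flagged ``single_replicate``.
    """
    z1 = rep1.set_index("compound_id")["zscore"]
    z2 = rep2.set_index("compound_id")["zscore"]
    if set(z1.index) != set(z2.index):
        raise ValueError("replicates cover different compound sets")
    z2 = z2.reindex(z1.index)
    hit1 = (z1 < threshold).fillna(False)
    hit2 = (z2 < threshold).fillna(False)
    flags = np.where(z1.isna() | z2.isna(), "single_replicate", "")
    return pd.DataFrame(
        {
            "compound_id": z1.index,
            "z_rep1": z1.to_numpy(),
            "z_rep2": z2.to_numpy(),
            "is_potential_hit": (hit1 | hit2).to_numpy(),
            "flag": flags,
        }
    ).reset_index(drop=True)


def replicate_correlation(x, y) -> float:
    """Pearson r between replicate readouts over shared non-missing wells."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("replicate vectors differ in length")
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError(f"need >= 3 shared non-missing pairs, got {int(keep.sum())}")
    r, _ = stats.pearsonr(x[keep], y[keep])
    return float(r)


@dataclass(frozen=True)
class QCReport:
    plate_id: str
    mean_neg: float
    sd_neg: float
    n_neg: int
    mean_pos: float
    sd_pos: float
    n_pos: int
    z_prime: float
    passed: bool


def z_prime_factor(mean_neg: float, sd_neg: float, mean_pos: float, sd_pos: float) -> float:
    """Z'-factor: 1 - 3(sd_neg + sd_pos) / |mean_neg - mean_pos|.

    Returns -inf when the control means coincide (zero assay window).
    """
    window = abs(mean_neg - mean_pos)
    if window == 0.0:
        return float("-inf")
    return 1.0 - 3.0 * (sd_neg + sd_pos) / window


def plate_qc(plate: pd.DataFrame, fail_below: float = 0.0) -> QCReport:
    """Control-separation QC for one plate, on raw enucleation %.

    Z' < ``fail_below`` flags the plate as failing; downstream hit
    calling still runs (the flag is advisory, matching screening
    practice of reviewing rather than auto-discarding flagged plates).
    """
    plate_id = str(plate["plate_id"].iloc[0]) if "plate_id" in plate.columns else ""
    neg = plate.loc[plate["role"] == "neg_control", "net_enucleation_pct"].dropna()
    pos = plate.loc[plate["role"] == "pos_control", "net_enucleation_pct"].dropna()
    for name, vals in (("neg_control", neg), ("pos_control", pos)):
        if len(vals) < 2:
            raise ValueError(f"plate {plate_id!r}: need >= 2 {name} wells, got {len(vals)}")
    zp = z_prime_factor(neg.mean(), neg.std(ddof=1), pos.mean(), pos.std(ddof=1))
    return QCReport(
        plate_id=plate_id,
        mean_neg=float(neg.mean()),
        sd_neg=float(neg.std(ddof=1)),
        n_neg=len(neg),
        mean_pos=float(pos.mean()),
        sd_pos=float(pos.std(ddof=1)),
        n_pos=len(pos),
        z_prime=float(zp),
        passed=bool(zp >= fail_below),
    )


@dataclass
class ScreenAnalysis:
    """Results of a full duplicate-screen analysis."""

    plates: pd.DataFrame  # all wells with centered values and z-scores
    hits: pd.DataFrame  # per-compound HitCall table
    qc: list[QCReport]
    replicate_r_raw: float  # Pearson r on raw per-compound %
    replicate_r_centered: float  # Pearson r after plate-median centering


def analyze_screen(
    well_results: pd.DataFrame,
    scale_mode: str = "sd",
    hit_threshold: float = -1.0,
) -> ScreenAnalysis:
    """Normalize every plate, correlate replicates, and call hits.

    ``well_results`` holds both replicates of every plate (columns
    plate_id, replicate, well_id, role, compound_id,
    net_enucleation_pct, qc_flags optional).  Plates are normalized
    independently; per-compound z-scores are then paired across the two
    replicates for the either-replicate hit rule.

    Replicate reproducibility is reported twice: Pearson r on raw
    percentages pooled over compounds, and on plate-median-centered
    values.  The centered form removes between-day plate offsets (which
    shift every well of a run equally) and is the one quoted as the
    screen's reproducibility.
    """
    reps = sorted(well_results["replicate"].unique())
    if len(reps) != 2:
        raise ValueError(f"expected exactly 2 replicates, found {reps}")
    normed = []
    qc_reports = []
    for plate_id, plate in well_results.groupby("plate_id", sort=True):
        norm = normalize_plate(plate, scale_mode=scale_mode)
        has_controls = (
            (norm["role"] == "neg_control").sum() >= 2
            and (norm["role"] == "pos_control").sum() >= 2
        )
        if has_controls:  # a transcribed export may omit control wells
            qc_reports.append(plate_qc(norm))
        normed.append(norm)
    plates = pd.concat(normed, ignore_index=True)

    comp = plates.loc[plates["role"] == "compound"]
    rep_tabs = {
        r: comp.loc[comp["replicate"] == r, ["compound_id", "net_enucleation_pct", "centered", "zscore"]]
        .set_index("compound_id")
        .sort_index()
        for r in reps
    }
    a, b = (rep_tabs[r] for r in reps)
    if not a.index.equals(b.index):
        raise ValueError("replicates cover different compound sets")
    r_raw = replicate_correlation(a["net_enucleation_pct"], b["net_enucleation_pct"])
    r_centered = replicate_correlation(a["centered"], b["centered"])
    hits = call_hits(
        a.reset_index()[["compound_id", "zscore"]],
        b.reset_index()[["compound_id", "zscore"]],
        threshold=hit_threshold,
    )
    return ScreenAnalysis(
        plates=plates,
        hits=hits,
        qc=qc_reports,
        replicate_r_raw=r_raw,
        replicate_r_centered=r_centered,
    )


def recount_screen(
    raw: pd.DataFrame,
    hit_threshold: float = -1.0,
) -> dict[str, pd.DataFrame]:
    """Recount potential hits from a transcribed raw-readout table.

    ``raw`` is a per-well table (plate_id, replicate, well_id, role,
    compound_id, net_enucleation_pct) as transcribed from a screen's raw
    data export.  The recount is run under both plate-scale conventions
    (SD and 1.4826*MAD of the median-centered compound wells) since a
    raw export does not record which one produced the published
    z-scores; the caller compares the two hit totals against the
    published count.  Returns ``{"sd": hit_table, "mad": hit_table}``.
    """
    out = {}
    for mode in ("sd", "mad"):
        analysis = analyze_screen(raw, scale_mode=mode, hit_threshold=hit_threshold)
        out[mode] = analysis.hits
    return out
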