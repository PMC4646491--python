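# Methods

## The assay being modelled

Orthochromatic erythroblasts — the last nucleated stage of erythroid
terminal differentiation — are sorted from dissociated spleen by
Ter119-high / CD44-low expression, excluding Hoechst-negative (already
enucleated) and PI-positive (dead) cells. Plated at 30,000 cells/well in
96-well plates with a compound library at a single concentration
(default 1 µM), they enucleate over the following hours; at the ~5 h
readout each well's net enucleation percentage is measured by flow
cytometry. Each enucleation converts one cell into **two** particles, a
Ter119⁺/Hoechst⁻ reticulocyte and a Hoechst-bright free nucleus, which
is why event counts exceed plated-cell counts and why the free nucleus's
gating fate matters (see below).

## Synthetic event model

Each population (orthochromatic erythroblast, reticulocyte, free
nucleus, late erythroblast, dead cell) is a single Gaussian component
per channel on an asinh-like transformed scale; the DNA (7-AAD) channel
is kept linear with the 2N mode at 200 units so that DNA-content gating
at 1.5× the 2N mode (the standard 4N cut for linear DNA signals)
behaves as on a real instrument. There is no spectral spillover or
compensation: gates are defined in the same transformed space the events
are generated in, so spillover would add a parameter without adding a
testable behaviour. Population separations are 4–6 population-SDs at
the default thresholds, giving a per-event misclassification floor below
10⁻⁴ — real cytometry is messier, so passing tests here demonstrate the
*statistics* of the pipeline, not robustness to poorly resolved
populations, autofluorescence or doublets.

**Free nuclei** are emitted Ter119-low by default, so they fall outside
both terms of the net-enucleation ratio. A membrane-wrapped extruded
nucleus can retain Ter119 on a real machine; setting
`default_population_specs(free_nuclei_ter119_positive=True)` moves them
into the nucleated term, which deflates the measured percentage. The
default was chosen so that the measured statistic is an unbiased
estimate of the per-cell enucleation probability, which is what the
recovery tests quantify.

## Well and screen generation

Per well, cell fates are two binomial draws (dead, then enucleated among
live) from a dedicated RNG stream derived from
`(master seed, replicate, plate, well index)`; channel intensities are
drawn afterwards on the same stream. The counts-only fast path stops
after the fate draws, so event-mode and counts-mode runs of the same
seed agree count-for-count — this is what makes the "gate the events"
and "use pre-gated counts" analysis paths land on identical hit lists.

Default study conditions: 324 compounds, 2 replicates run as separate
plate sets (4 plates of 88 compound wells each, 4 DMSO + 4 cytochalasin
D control wells in column 1 of every plate; control count and placement
are configurable because real layouts vary), baseline enucleation 0.65
at the readout (between the hourly rise and the ~0.70 plateau at 6 h),
cytochalasin D residual 0.02, baseline dead fraction 0.05. Noise is
additive on the percentage scale: one between-day offset per plate run
(SD 4 points) shared by all its wells, plus independent per-well error
(SD 3 points). These magnitudes give duplicate correlations above 0.8
at realistic inhibitor effect sizes while keeping a visible day effect.
The default library spikes in 25 inhibitors (13 arrest, 12 delay) with
saturating inhibition 0.5–1.0 and EC50 0.25 µM — i.e. 40–80 % relative
reduction at the 1 µM screen — plus 6 toxic compounds that kill cells
(PI⁺) without blocking enucleation in the survivors.

Compound effects enter as `p = baseline · (1 − max_inhibition ·
c/(c+EC50))`, a Hill curve with slope 1; toxicity adds to the dead
fraction. Probabilities are clipped to [0, 1] after noise.

## Kinetics, washout, cell cycle, morphology

The control time course rises linearly at `plateau / t_plateau`
(defaults 0.70 / 6 h) and then plateaus. An *arrest* compound applies a
constant fractional suppression; a *delay* compound applies the same
suppression at the 5 h anchor but decays it with a half-time (default
~1.5 h), so the treated culture converges to control by 10 h. Curves
are forced non-decreasing (enucleation is irreversible). Washout
restarts an arrested culture at the control rise rate from its
suppressed level; an irreversible compound stays flat. Replicate noise
is Gaussian (SD 3 points) per experiment and timepoint.

Cell-cycle tables place S-phase cells BrdU⁺ with DNA uniform between
2N and 4N (partial replication during the pulse), G0/G1 at 2N and G2/M
at 4N, both BrdU⁻. Cytospin counts are one multinomial draw per
experiment with the enumerated-cell total uniform over a configurable
range (default 112–541, typical of manual slide scoring).

## Analysis conventions

* **Gate geometry** — rectangle bounds are half-open `[min, max)` so
  adjacent gates partition without double counting; polygon membership
  is even-odd with boundary points inside. Thresholds default to the
  midpoint between the two populations they separate, on the
  transformed scale, and every one is overridable (real gate positions
  are instrument- and staining-dependent).
* **Plate statistics** — only compound wells enter the plate median and
  scale; controls are extreme by construction and would shrink every
  z-score. The scale is the sample SD of median-centered compound
  wells by default, with a 1.4826·MAD robust mode; both are exposed
  because raw screen exports do not record which convention produced
  published z-scores, so recounts are attempted under both.
* **Hit rule** — strictly `z < −1`; a tie at −1 is not a hit. A
  compound with a missing z in one replicate is called on the other and
  flagged.
* **Replicate correlation** — Pearson r is reported on raw and on
  plate-median-centered percentages. Within one plate pair the day
  offset is a constant shift and cancels in r; pooled across plates it
  does not, so the centered value is the one quoted as the screen's
  reproducibility.
* **Missing wells** — a well with an empty erythroid denominator or a
  low-event QC flag is missing, never zero, and never imputed; it drops
  out of plate statistics. High-death wells keep their value (death is
  a readout) but carry the flag.
* **Paired t-test** — two-sided on per-experiment differences, stars
  `*` p<0.05 … `****` p<0.0001, uncorrected by default (per-compound
  stars convention); Benjamini–Hochberg available but off. Degenerate
  zero-variance differences report p=1 (zero mean) or p=0 (nonzero)
  with a flag rather than erroring, since n as small as 2–4 makes this
  reachable.
* **Delay vs arrest** — paired tests at 5 h and 10 h (α = 0.05):
  suppressed at 5 h only → delay; at both → arrest; otherwise
  no_effect. "Suppressed" additionally requires the treated mean below
  control, which halves the null misfire rate of the 10 h test.
* **Dose trend** — one-sided Spearman (decreasing), chosen over a 4PL
  EC50 fit because 3–5 concentrations with n = 3 experiments support a
  monotonicity verdict but not stable curve parameters.
* **Washout** — recovered when treated comes within 10 percentage
  points of control at the final post-washout timepoint; the margin
  absorbs replicate noise without accepting a still-arrested culture.

## Problem sizes

The default simulated screen is analysed in counts mode (the fate draws
are the same as event mode, so nothing is lost statistically);
event-level simulation is used for single-well recovery (30,000 cells)
and small multi-plate consistency checks. Monte-Carlo suites use 10,000
null screens for the hit-rate closed form and 500 repetitions per
mechanism for classification accuracy — sizes at which the Monte-Carlo
error is several times smaller than the margins being tested.

## Known limitations

* Single-Gaussian channel model: no spillover, autofluorescence,
  doublets, debris, or acquisition drift; gating robustness to those is
  untested by design.
* No spatial plate effects (edge effects, gradients), hence no B-score
  or loess correction.
* Mechanism classification is significance-based and inherits α-level
  misfires: a delay compound is misread as arrest when the 10 h test
  fires spuriously (~α/2 of runs).
* The washout model restarts at the full control rate immediately;
  compounds with slow target re-engagement kinetics would recover later
  than simulated.
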