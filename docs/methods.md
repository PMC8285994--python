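# Methods

This note documents the models, numerical choices and limitations behind
`cncenum`: what the simulator assumes, how quantification and gating are
defined, and what the test suite does and does not demonstrate about real
chip data.

## The enumeration problem

The assay loads an enriched nucleated-cell suspension from peripheral blood
onto a PDMS microwell array (30 µm diameter, 20 µm deep wells; the physical
device carries on the order of 10⁵ wells, analyzed in blocks), images it in
two rounds, and counts cells with the NeuN⁺/CD45⁻/DAPI⁺ phenotype. The
rare class (circulating neural cells, CNCs) sits against a ~10–100× larger
leukocyte background, so the decisive methodological element is that every
chip calibrates its own gate from its own leukocytes rather than from any
external standard.

## Chip simulator (`chipsim`)

### Geometry

Square well grid (the well lattice of the physical device is not otherwise
constrained), configurable pitch ≥ diameter. The default desk-scale layout is
100 blocks × 64 wells = 6,400 wells at 40 µm pitch, 1 µm/px — block count is
the analysis-relevant granularity, and a full-size layout remains a
configuration option (`n_blocks`/`wells_per_block` accept any factorizable
counts). Coordinates are 0-based pixels, origin top-left, x = column.

### Population model

Defaults encode the assay's study conditions:

| parameter | default | meaning / rationale |
|---|---|---|
| `mean_cells_per_well` | 1.5 | Poisson occupancy; midpoint of the stated 1–2 cells/well |
| `cnc_prevalence` | 0.19 | mouse-chip CNC fraction scale; patient scale (~0.02) by config |
| `live_fraction` | 0.604 | 2-NBDG⁺ fraction among CNCs (reported survival ratio) |
| `leuko_live_fraction` | 0.95 | most leukocytes take up glucose |
| `debris_rate` | 0.02 | DAPI-dim objects exercising the exclusion gate |
| intensity laws | log-normal | fluorescence intensities are right-skewed, nonnegative; medians 100 (leukocyte NeuN), 900 (CNC NeuN), 1500 (leukocyte CD45), 25 (CNC CD45), 1200 (DAPI), 600 (2-NBDG), a.u. on a 16-bit scale |
| `background_level`, `read_noise_sd` | 100, 5 a.u. | flat background + Gaussian read noise |
| `psf_sigma_um`, `spot_radius_um` | 0.75, 3.0 | spot edge softness and nuclear footprint |
| `cell_diameter_um` | 9.0 | monolayer exclusion distance |

Model validation enforces self-consistency: the CNC NeuN median must exceed
the leukocyte mean + 3 SD, otherwise the configured population could not be
separated by its own gate and every downstream number would be meaningless.

Per-well counts are exactly Poisson (the occupancy law is a tested property).
Within a well, centers keep at least one cell diameter of separation —
rejection sampling for ≤ 3 cells, a jittered center+ring template for crowded
wells — because cells in a monolayer physically exclude each other; the
constraint is relaxed only when a drawn count cannot be packed, so occupancy
stays Poisson at the cost of occasional tight pairs.

### Rendering

Cells are rendered as smoothed top-hat spots: intensity
`a · ½ erfc((d − r₀)/(√2 σ))` with plateau `a` equal to the true channel
amplitude, disk radius `r₀`, edge width `σ`. The plateau (rather than a pure
Gaussian) is deliberate: it is a fair model of a ~6 µm nucleus sampled at
1 µm/px, it makes plateau photometry well-posed (measured mean ≈ amplitude),
and it keeps touching well-mates separable. Rounds render their physical
channel sets — live: CD45 + 2-NBDG (only cells with uptake), no DAPI before
fixation; fixed: DAPI + NeuN + CD45, no 2-NBDG after permeabilization. Both
rounds share cell positions (cells are immobilized in wells); integer-pixel
jitter is available to exercise matching. Images are quantized to uint16 at
render time so the in-memory arrays equal their TIFF round-trips bit for bit.

## Quantification (`wellquant`)

The source assay read intensities manually in ImageJ; a reproducible pipeline
needs explicit choices, all validated against simulator truth:

* **Detection**: threshold at background + 3 robust noise SDs
  (median/MAD), with a small floor for noise-free synthetic scenes;
  minimum object area 20 px² at 1 µm/px (≈ 20 µm², below any nucleus, above
  noise specks); hole filling; watershed on the smoothed intensity seeded by
  local maxima with a 3 px minimum peak distance. The 3 px spacing matters:
  wider peak footprints let a bright cell suppress a dim neighbor one cell
  diameter away, silently merging pairs.
* **Well assignment**: nearest well center within the well radius; objects
  outside every well are flagged (`well_id = -1`), never dropped.
* **Background**: per-well local median of non-object pixels (wells shade
  illumination differently; a global background would bias dim wells).
* **Intensity**: "plateau mean" — within each object, pixels above 70% of the
  object's amplitude in the segmentation channel are averaged per channel,
  background-subtracted and floored at 0. This leaves a stable multiplicative
  footprint factor (≈ 0.9) common to all cells on a chip. It cancels exactly
  in the leukocyte-anchored gate, which is the point of anchoring: both μ_L,
  σ_L and every cell's NeuN scale by the same factor.
* **Round matching**: greedy nearest-centroid within the same well, 3 px
  tolerance (registration jitter is sub-pixel to ~1 px), ambiguities by
  distance then lowest cell id. Fixed-round cells without a live partner keep
  2-NBDG missing — which downstream counts as not-live, the correct reading
  for a cell that showed no uptake signal.

## Gating (`gatecore`)

* NeuN cut-off: mean + k·SD (k = 3, sample SD with n−1) over the CD45⁺/DAPI⁺
  reference population, fitted per chip, never pooled across samples. The
  "±3 SD" of the assay is implemented one-sided (upper cut-off): the lower
  bound plays no role in calling NeuN⁺ cells. Raw-intensity statistics by
  default; a log1p option exists because the scale of the original
  computation is not documented.
* CD45 threshold (`auto`): Otsu's split on log1p intensities, accepted only
  when the implied classes are credibly separated (inter-class mean gap >
  2× the summed class SDs). When the negative class is too rare for a
  variance split — precisely the rare-cell regime, where Otsu lands inside
  the leukocyte mode — the threshold anchors on the dominant leukocyte mode:
  log-median − 4 robust (MAD) SDs. Plain `otsu` and `fixed` are available.
  The same guarded method thresholds 2-NBDG (rare *low* class: dead cells).
* DAPI threshold: 3× the fixed-round image noise SD on the measured
  (background-subtracted) scale by default; overridable. With DAPI-based
  segmentation this gate is nearly tautological on simulated data — it
  matters for ingested tables from other segmenters.
* Strict inequalities at every boundary; missing intensities never pass a
  gate. "Total counted cells" includes the DAPI⁺/CD45⁻/NeuN-low class.
* Null calibration: by construction, CD45⁻ cells drawn from the reference
  Gaussian are called at the one-sided 3σ tail (0.135%); this is a tested
  property at n = 100,000.

## Enumeration and statistics (`enumstats`)

* `CNCs/mL` is the exact quotient; display rounding (half away from zero, one
  decimal) is presentation-only. The published mouse enumeration table is
  packaged verbatim (counts, volumes, severities, printed densities); its
  printed density column mixes round-half-up and truncation, so
  reproduction tests compare at the printed precision under either
  convention rather than emulating an inconsistent rule.
* Severity is ordinal: `/` = 0, `+` = 1, `++` = 2; reperfusion times map to
  days (4 h = 1/6). OLS via standard closed forms; a constant predictor is an
  error, not a zero slope.
* Two-group comparison: two-tailed Student's t with pooled variance by
  default (the assay's stated test); Welch by flag. SD and SEM are both
  always reported, matching the two dispersion conventions used for
  different figures.
* The synthetic cohort generator draws negative-binomial counts
  (gamma shape 2 by default): per-subject heterogeneity at the reported
  cohort scales spans an order of magnitude around the group mean, which
  Poisson counts cannot produce. Survival ratios are pooled-cell (live CNCs
  over all CNCs across the sample), not per-patient-averaged; the
  alternative is a flag away at the call site since the input is per-cell.

## Reproducibility (`pipeline`)

One mandatory seed; per-stage generators split from it with
`numpy.random.SeedSequence.spawn`, so stages are independently reproducible.
Config is YAML with recursive unknown-key rejection and value validation that
reports every offender at once. Every run writes a manifest with a SHA-256
per output file; identical configs produce byte-identical CSV/JSON outputs
(timestamps live only in the manifest itself).

## Problem sizes

The test suite and the acceptance script run desk-scale versions of the study
conditions, chosen so statistical checks have real power: distributional
properties at 10,000 wells; recovery, precision and spike-in checks on full
100-block chips (~9,500 cells); null calibration at 100,000 cells; cohort
power over 200 replicates at n = 38 vs 25. Unit tests use 64–324-well chips.

## What passing tests do and do not show

The simulator is the oracle, so green tests demonstrate that the pipeline
recovers what this forward model generates: flat background, Gaussian read
noise, isotropic plateau spots, perfectly regular well grids, no
autofluorescence structure, no focus drift, no well-to-well illumination
gradients beyond what the per-well background removes, and a debris class
that is simply DAPI-dim. Real chips violate several of these (uneven
illumination, out-of-focus wells given 20 µm depth, cell clumps, stain
carry-over between rounds); the quantification defaults are starting points
there, not guarantees. The gate itself is distribution-free in the only sense
that matters — it is anchored to the chip's own leukocytes — but its 3σ null
rate is exact only for a Gaussian reference; heavier-tailed real leukocyte
NeuN distributions will call more false positives at the same k, which is
visible in the CD45⁺ population itself and can be countered by raising k.

## Known limitations

* No physical optics: no depth/defocus model for the 20 µm wells, bright
  field is a flat placeholder.
* No upstream enrichment chemistry (RBC lysis, magnetic depletion, density
  gradients) — enrichment provenance is metadata only.
* Segmentation is top-hat-spot-shaped; heavily overlapping or irregular
  nuclei from real images may need a different segmenter, whose output can
  enter through the canonical per-cell CSV.
* Multi-marker panels (MAP2/Nestin) are not modeled separately; the same
  gate logic applies by renaming channels.
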