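# Methods

## The measurement model

The package quantifies transient transfection per viable single cell from
flow-cytometry event data.  Each event carries scatter pulse parameters
(FSC-A, FSC-H, SSC-A) and fluorescence channels with assigned *roles*: the
covalently labeled plasmid (`dna_label`, typically FITC), the expressed
protein (`protein`, a fluorescent protein or antibody conjugate), and an
optional dead-cell dye (`viability`).  Roles are explicit configuration and
never inferred from dye names, because the same assay is run with different
protein fluorochromes (mCherry directly, or CF647/APC via an antibody).

No spectral compensation is applied anywhere: the assay design assumes
fluorochromes without meaningful overlap, and run-config validation rejects
role maps that put the protein readout on a FITC-adjacent detector.  All
medians, thresholds and calibrations operate on untransformed
acquisition-scale (linear) values; `transform_channel` (log10 with floor,
asinh) exists for gate geometry and display only, and every transform is
strictly monotone, so event order per channel is preserved.

## Gating

Manual gates are replaced by deterministic parametric rules so a run is
reproducible from its recorded parameters:

- **Singlets** — keep events with FSC-H/FSC-A within `median · (1 ± w)`,
  default `w = 0.15`.  Doublets sum pulse area over two cells while height
  tracks the larger one, roughly halving the ratio, so the band separates
  them cleanly; the width is a tunable config value since instruments
  differ.
- **Intact cells** — an FSC-A/SSC-A percentile box (defaults 2nd–99.5th per
  axis), fitted on a reference (untransfected) table when provided, else on
  the sample.  A degenerate axis passes everything with a warning.
- **Viable cells** — either (a) dye: events above the `p`-th percentile
  (default 99.5) of a *dye-negative* control on the viability channel are
  dead; or (b) scatter: events with FSC-A below the reference 10th
  percentile AND SSC-A above the reference 75th percentile are dead.  The
  scatter dead-region is this package's concretization of "low forward
  scatter, high side scatter"; the two percentile defaults were chosen once
  against the synthetic-data generator's default conditions.

Stages nest by construction (viable ⊆ intact ⊆ singlet).  Percentiles use
linear interpolation between order statistics throughout, for determinism.

The dye threshold control deserves a note: a 24-hour untransfected culture
itself contains a few percent dead cells, which would drag a 99.5th
percentile into the dead cluster.  The pipeline therefore thresholds on the
**zero-timepoint control** — cells harvested before transfection toxicity
develops — which is dye-negative by construction.  When no viability
channel is mapped (electroporation, where exclusion dyes cannot be used),
the pipeline automatically falls back to scatter viability.

## Readouts

Per sample, on viable singlets:

- The DNA positivity threshold is the 99.9th percentile of the
  unlabeled-plasmid control's viable events on the FITC channel; the
  protein threshold comes from the zero-timepoint control likewise.  The
  percentile and the tie rule (a value equal to the threshold is negative)
  are this package's determinism choices; by construction a control run
  against itself is ≤ 0.1% positive.
- Quadrants: Q2 = double positive, Q1 = DNA only, Q3 = protein only,
  Q4 = double negative; `pct_dna_pos = Q1+Q2`, `pct_protein_pos = Q2+Q3`.
  Q3 is scientifically meaningful — cells expressing protein whose labeled
  plasmid is no longer detectable (e.g. FITC quenching in acidic
  compartments, which this package does not attempt to correct).
- ΔMFI: median(sample) − median(matched control).  MFI is the **median** by
  default (a mean option exists but is never the default).  Negative ΔMFI
  is reported with a warning, never clipped: clipping would bias CV
  statistics across assays.
- Controls are gated with gates fitted on themselves, not on the sample,
  because transfection perturbs scatter.
- Toxicity: % dead among intact singlets, the same quantity in the
  untransfected control, their difference (excess death), and — when both
  dye and DNA channels exist — the dye-positive fraction of DNA-positive
  cells (direct toxicity of the internalized complex).

## MESF standardization and copy number

Bead peaks are located by deterministic one-dimensional k-cluster
partitioning of log10(MFI+1) (quantile-initialized Lloyd iterations),
per-cluster medians on the linear scale, rank-matched to the kit's known
values; a blank population, when declared, is the lowest cluster and is
dropped.  Adjacent peak medians within 10% relative trigger a
calibration-quality error (merged populations).  The standard curve is
ordinary least squares in log10–log10 with equal peak weights; fits with
r² < 0.98 are rejected.  Medians are used for bead peaks for consistency
with the cell-side MFI statistic.

Conversion applies only to positive blank-corrected MFIs (log of a
non-positive value is undefined; the MESF field is absent otherwise), and
values outside the calibrated peak range are flagged as extrapolated.
With labeling density `bp_per_label` (default 40 bp per fluorophore):

    labels/plasmid = length_bp / bp_per_label
    copies/cell    = MESF_FITC / (labels/plasmid)
    moles/cell     = copies / N_A

No MESF kits exist for fluorescent proteins such as mCherry, so the protein
readout is standardized only when a protein-channel calibration is
supplied; otherwise ΔMFI is the per-cell expression measure.

## Study statistics

- **Time-course peaks**: argmax of ΔMFI over the measured timepoints only
  (no interpolation), ties to the earliest time.
- **Normalization**: values × 100 / mean of the experiment's own control,
  allowing pooling across methods with different absolute scales.
- **Inter-assay CV**: 100·sd/mean per sample across assays, sample sd
  (n−1 denominator — recorded in report metadata since either convention is
  defensible); mean and range reported; non-positive means yield undefined
  CVs that are excluded with a warning.
- **Correlations**: Spearman with average-rank ties; exact permutation
  p-value for n ≤ 9 (full enumeration), t-approximation above.
- **Group comparisons**: Kruskal-Wallis (≥ 2 groups) and Mann-Whitney
  (exactly 2), average-rank tie correction, asymptotic p-values (no
  continuity correction).  `cv_anova` runs one-way ANOVA on per-sample CVs
  grouped by readout to ask which readout is most reproducible; normality
  of CVs is deliberately not checked, matching field practice.

## The synthetic-data generator

`flowfect.simulate` draws mixtures of five components — transfected,
protein-only, untransfected-viable, dead, debris — with lognormal scatter
and fluorescence.  Defaults (versioned in
`src/flowfect/data/default_simulation.json`) encode the study conditions of
a 293T-like chemical transfection:

| parameter | default | rationale |
|---|---|---|
| transfected fraction | 0.70 | efficient reagent in a permissive line |
| dead fraction (sample) | 0.15 | transfection toxicity in the 10–40% range |
| dead fraction (untransfected) | 0.05 | healthy culture, viability > 85% |
| debris fraction | 0.03 | anchors the intact gate's lower percentile |
| doublet fraction | 0.05 | typical for adherent-cell suspensions |
| FITC / protein shift | ×30 / ×25 | positive clouds ~1.5 decades above autofluorescence |
| DNA–protein rank correlation | 0.7 | uptake predicts expression per cell |
| dead-cell scatter | FSC ×0.4, SSC ×2.5 | shrunken, granular dead phenotype |
| viability dye shift | ×100 | two-decade dye separation |
| uptake peak / protein t50, Hill | 12 h / 16 h, 2 | uptake peaks at 12 h; expression saturates by 48 h |

Fluorescence is lognormal; the transfected population's DNA/protein pair is
drawn through a Gaussian copula with correlation `2·sin(π·ρ_s/6)` so the
emitted Spearman matches the configured target.  Doublets are formed by
summing two singlets' area channels (scatter *and* fluorescence) with pulse
height the pairwise max — exactly the geometry the singlet gate exploits.
A brightness shift of 1 (unlabeled plasmid, zero timepoint) uses the
autofluorescence spread, not the positive-population spread: an unlabeled
cell's FITC distribution *is* autofluorescence.  Controls and timepoints
use substreams derived from the root seed; identical configs are
bit-reproducible.

What the generator does **not** emulate: heavy-tailed instrument noise,
laser drift, spectral spillover, acquisition-time artifacts, pH-dependent
FITC quenching, and cell-cycle or promoter-activity heterogeneity beyond
the lognormal spreads.  Passing closed-loop tests therefore demonstrates
the pipeline's correctness on its stated model, not robustness to every
real-instrument pathology.

## Numerical and design choices

- FCS support is 3.0/3.1 list-mode; files are written as $DATATYPE F
  (float32), so round trips preserve values to float32 relative precision
  (~1e-7), not absolutely.
- The event reader drops rows containing non-finite values and counts them
  (`n_read = n_kept + n_dropped`).
- Bead-peak clustering, gate fitting and percentiles are fully
  deterministic; no randomized initialization anywhere in the analysis
  path.
- `correlate_readouts` raises on constant vectors rather than returning a
  NaN, so silent undefined correlations cannot propagate into reports.
- The per-sample pipeline quarantines samples that fail (bad file, missing
  channel) and continues; configuration problems are listed exhaustively
  before a run starts.
- Problem sizes used by the validation suite and `scripts/acceptance.py`
  (20 000-event samples, 100-sample quadrant sweeps, 500 null datasets for
  test calibration, 10 bead seeds) were chosen as the smallest sizes at
  which binomial/Monte-Carlo error is comfortably inside the assertion
  bands.

## Known limitations

- The scatter dead-region percentiles (10/75) were tuned against the
  generator's default dead-cell phenotype; instruments or cell types with a
  different dead-scatter signature need retuning.
- MESF is reported as absent for non-positive ΔMFI; heavily quenched
  samples therefore yield % positivity and ΔMFI but no copy number.
- Inter-assay CV from three assays has a wide sampling distribution; the
  reported range matters as much as the mean.
- Quadrant readouts assume the positivity thresholds transfer from controls
  to sample, i.e. autofluorescence is not shifted by treatment.
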