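# flowfect

Flow-cytometric quantification of transfection efficiency, for labs that
deliver plasmid DNA (or RNA) into cells and need to know — per viable cell —
how much nucleic acid went in, how much encoded protein came out, and what
the transfection cost in toxicity.

The method implemented here uses a plasmid covalently labeled with a
fluorophore (e.g. FITC at roughly one label per 40 bp) together with a
spectrally separated protein signal (a fluorescent protein such as mCherry,
or a dye-conjugated antibody), so that a single tube yields **two
independent readouts** of transfection efficiency on the same cells:

- **uptake**: % of viable cells positive for the labeled plasmid
  (quadrants Q1+Q2 of the DNA x protein plot), and the blank-corrected
  median FITC intensity (ΔMFI);
- **expression**: % of viable cells positive for the protein (Q2+Q3), and
  its ΔMFI.

Gating follows the standard hierarchy — singlets by the FSC-H/FSC-A pulse
ratio, intact cells by an FSC-A/SSC-A box, then dead-cell removal by a
viability dye or (when dyes cannot be used, e.g. electroporation) by a
low-FSC/high-SSC scatter region.  Positivity thresholds come from matched
negative controls: cells transfected with *unlabeled* plasmid define the
FITC background, a *zero-timepoint* harvest defines the protein background,
and an untransfected tube defines baseline death.

ΔMFI values can be standardized to **MESF** (Molecules of Equivalent
Soluble Fluorochrome) with calibration beads: a log-log least-squares line
`log10(MESF) = a + b * log10(MFI)` over the detected bead peaks.  Because the
labeling density is known, FITC-MESF converts directly into **plasmid copies
per cell**:

    copies = MESF_FITC / (length_bp / bp_per_label),   moles = copies / N_A

Study-level tools cover time-course peak finding (uptake typically peaks
hours before expression saturates), normalization to each experiment's own
control for pooling, inter-assay coefficients of variation, Spearman
correlations between readouts, and Kruskal-Wallis / Mann-Whitney group
comparisons.

A seeded synthetic-cytometry generator (`flowfect.simulate`) produces event
tables with known ground truth — viable/dead/debris mixtures, area-additive
doublets, copula-correlated DNA/protein signal, kinetic trajectories and
MESF bead acquisitions — so every stage of the pipeline is validated
closed-loop.

## Worked example

```python
import flowfect as ff

cfg = ff.SimulationConfig(n_events=20000, seed=7, transfected_fraction=0.30)
sample, truth = ff.simulate_sample(cfg)
controls = ff.simulate_controls(cfg)

beads = ff.simulate_beads(1.0, 2.0, [50, 200, 800, 3200, 12800],
                          cv_per_peak=0.05, seed=7)
cal = ff.calibrate_beads(beads)

ro = ff.transfection_readouts(sample, controls, calibration=cal)
tox = ff.toxicity_readout(sample, controls.untransfected,
                          dye_reference=controls.zero_timepoint)

spec = ff.PlasmidSpec("pUltraHot", length_bp=8314, bp_per_label=40)
copies, moles = ff.plasmids_per_cell(ro.mesf_dna, spec)
```

Output:

```
%DNA+ (Q1+Q2):      29.7
%protein+ (Q2+Q3):  29.6
dMFI DNA:           25.3
MESF(FITC):         2544
labels/plasmid:     207.85
plasmid copies/cell:12.2
%dead (dye):        15.7  (control 4.6)
```

The simulated ground truth was a 30% transfected fraction with 15% dead
cells against a 5% baseline: the quadrant readouts recover the fraction to
within a few tenths of a point, and the bead curve (slope 1, intercept 2,
i.e. MESF = 100 x MFI) turns the DNA ΔMFI into an absolute per-cell copy
number for the 8314-bp plasmid.

## Command line

```sh
flowfect simulate -o simdir --seed 3 --format csv   # sample + controls + truth
flowfect calibrate --beads beads.fcs --kit kit.json -o cal.json
flowfect run -c run.yaml -o outdir                  # report.json, readouts.csv
flowfect report -r outdir/report.json -o tables/    # re-derive flat tables
```

`run.yaml` lists the sample manifest (paths, assay ids, timepoints), the
three control files, the channel role map (`{"FSC-A": "fsc_a", ...}`), gate
parameters, and optionally a plasmid spec and bead kit.  Reports echo every
tunable parameter and are bit-for-bit reproducible apart from the
timestamp.

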