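# synaptoquant

Quantification of trans-synaptic vesicle (tSV) transfer from T cells to
bead-supported lipid bilayers (BSLBs), with calibrated absolute molecule
counting from flow cytometry, dose-response comparison across T-cell
populations, nano-flow-cytometry vesicle sizing, and synapse-image
fluorescence quantification.

## The problem

When a T cell forms an immunological synapse with a BSLB — a 5 µm silica
bead carrying a fluid lipid bilayer that presents His-tagged ligands such as
an α-CD3ε Fab surrogate antigen — it deposits vesicles and their membrane
cargo onto the bead. Flow cytometry reads both partners after gentle
dissociation, but raw fluorescence is instrument-dependent. This package
implements the calibration and statistics that turn event listings into
biology:

- **cGMFI** — geometric mean fluorescence intensity, background-corrected by
  subtracting the isotype-control or antigen-null signal.
- **MESF calibration** — a ladder of beads carrying known Molecules of
  Equivalent Soluble Fluorochrome is regressed against cGMFI; the slope
  converts sample cGMFI to fluorochromes, and the antibody's
  fluorophore-to-protein ratio (F/P) converts fluorochromes to molecules:
  `molec./event = fluorochromes / (F/P)`.
- **Normalized synaptic transfer**
  `NST% = 100 · BSLB cGMFI / (BSLB cGMFI + cell cGMFI)`
  and **percent of transfer maximum**
  `Tmax% = 100 · BSLB cGMFI / max BSLB cGMFI` over a declared reference
  series.
- **Surface densities** in molec./µm² using the bead area π·d² ≈ 78.54 µm²
  and the 0.82 µm² vesicle-patch area.
- **Dose-response analysis** — four-parameter logistic fits
  `y = bottom + (top − bottom)/(1 + (EC50/dose)^hill)` of transfer versus
  surrogate-antigen density, with extra-sum-of-squares F tests comparing
  EC50/Tmax between populations and Holm-Šídák-corrected multiple t tests
  per dose.
- **Vesicle sizing** — side scatter mapped to diameter through silica
  standards (68/91/113/155 nm), size-bin frequencies and medians; particle
  concentration via a counting standard.
- **Synapse imaging** — contact segmentation from the reflection (IRM)
  channel and background-subtracted integrated fluorescence per contact,
  normalized to an internal control group.

No raw cytometry data ship with the package; a synthetic-data generator
(`synaptoquant.simulate`) emulates every input — log-normal event noise,
MESF ladders, 2-fold titration co-cultures with a known logistic transfer
curve, vesicle scatter mixtures, IRM/TIRF image pairs — and returns the
ground truth it drew from, so every stage is testable end to end.

## Worked example

```sh
synaptoquant simulate --seed 1 --out sim
synaptoquant quantify --events sim/events.csv --mesf sim/mesf_ladder.csv \
    --levels 0,1e3,1e4,1e5,1e6 --marker CD40L:AF647:2.0 --out quant
synaptoquant doseresponse --records quant/transfer_records.csv \
    --parameterization 3pl --out dr
```

The first command simulates a co-culture of three T-cell populations (TH,
Treg, CTL) across a 2-fold α-CD3ε-Fab titration (0–1000 molec./µm²) plus an
MESF bead ladder; the second gates single cells and single BSLBs, fits the
calibration (`calibration slope 0.4985 (R²=1.0000)`) and writes one transfer
record per marker × dose × population. For CTL the records read:

```
 dose  molecules_per_BSLB  nst_percent  tmax_percent  density_patch
  0.0                 0.0          0.0           0.0            0.0
  7.8               998.1          3.3           6.8         1217.2
 62.5              7736.5         25.7          52.6         9434.7
250.0             13060.8         43.4          88.9        15927.8
1000.0            14695.4         48.8         100.0        17921.2
```

i.e. at saturating antigen a CTL deposits ~14,700 CD40L molecules per BSLB
(48.8% of its conserved CD40L pool, read as NST%), an effective density of
~17,900 molec./µm² on the 0.82 µm² vesicle patches. The third command fits
the logistic curves and compares populations:

```
population   ec50     tmax  hill        (truth: CTL 60, TH 250, Treg 125)
       CTL  59.84 15053.88  1.30
        TH 245.33 19908.88  1.21
      Treg 127.25  9101.08  1.09
F = 79489.1, p = 8.5e-39   (populations share no common curve)
```

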