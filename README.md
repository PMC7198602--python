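# nucleoring

Quantitative analysis of ring-shaped nucleolar chromatin foci in two-channel
3D super-resolution image stacks — and a synthetic-scene simulator that makes
every stage testable without microscope data.

Active ribosomal RNA genes, visualized by labelling the architectural
transcription factor UBF or RNA polymerase I, appear in 3D-SIM images as
loop-shaped foci of roughly 170–240 nm diameter scattered through the
nucleolus with random 3D orientations.  Two quantitative questions follow
from such images, and this package implements both analyses end to end:

1. **Colocalization.**  How strongly do two labels (e.g. UBF and the Pol I
   subunit RPA194) co-occur, and is the co-occurrence concentrated in the
   nucleolus?  The package computes, per nested region of interest (cell ⊃
   nucleus ⊃ nucleolus, plus the extranucleolar remainder): the Pearson
   correlation coefficient (PCC) of voxel intensities, the Manders split
   coefficients M1/M2, the Manders overlap coefficient
   MOC = Σ(I₁I₂)/√(ΣI₁²·ΣI₂²), automatic thresholding after Costes
   (descend along the orthogonal-regression line I₂ = a·I₁ + b until the
   sub-threshold PCC ≤ 0), and a Costes block-permutation significance test.

2. **Ring geometry and compaction.**  How large are the loops, and what does
   that imply about DNA folding?  Each detected focus is rotated in 3D so
   the ring lies flat, and its diameter is the mean of peak-to-peak distances
   of intensity line profiles at three angles 60° apart.  A loop of diameter
   d holding an L-bp DNA region (0.33 nm per nucleotide) is then compacted
   by a factor (0.33·L)/(π·d); for 15 kb in a 240 nm loop that is ~4950 nm
   of DNA in a ~750 nm circumference, a 6–7-fold linear compaction, and
   about one gene-sized unit per loop.

The synthetic-data module renders Gaussian-tube rings of known diameter and
orientation, applies an anisotropic Gaussian PSF proxy (axial resolution
worse than lateral, as in reconstructed SIM data), adds Poisson + read
noise, controls the fraction of channel-2 structures co-occurring with
channel 1, and builds the nested ROI masks — so the whole analysis can be
exercised, and its estimators validated, against known ground truth.

## Layout

- `src/nucleoring/` — the library: `synthetic_data`, `image_io`,
  `colocalization`, `ring_geometry`, `compaction_model`, `reporting`, `cli`.
- `analysis/01_simulate.py … 05_report.py` — numbered drivers that run the
  analyses on simulated data and write tables/figures under `results/`.
- `scripts/acceptance.py` — recomputes the headline bookkeeping quantity
  from scratch (see below).
- `docs/methods.md` — the model, estimators, defaults and known limitations.

## Worked example

```bash
python analysis/02_colocalization.py
```

simulates twelve two-channel cells whose co-occurring structures are
confined to the nucleolus over independent background, runs the full
per-ROI battery, and prints:

```
                  pcc     m1     m2    moc  costes_p
roi
cell            0.665  0.599  0.579  0.726     0.005
extranucleolar  0.414  0.463  0.460  0.548     0.005
nucleolus       0.707  0.817  0.833  0.786     0.005
nucleus         0.663  0.655  0.630  0.734     0.005

MOC medians: nucleolus 0.786 vs extranucleolar 0.548 -> notches distinct
```

Co-occurrence (MOC, M1/M2) and intensity correlation (PCC) are highest in
the nucleolar ROI, and the notched-box comparison (notch = ±1.58·IQR/√n,
non-overlap ≈ 95% confidence for a median difference) calls the nucleolar
vs extranucleolar MOC medians distinct — the expected signature of genuine
co-assembly of the two labels on nucleolar structures.

```bash
python analysis/04_compaction.py
```

prints the compaction arithmetic:

```
15 kb at 0.33 nm/nt -> contour 4950 nm; 240 nm loop circumference 754.0 nm; compaction 6.57-fold
genes per loop at 6-7-fold compaction: 0.91 - 1.07
```

`analysis/03_ring_diameters.py` measures simulated 240 ± 60 nm and
168 ± 47 nm ring populations with the three-angle procedure.  Its printed
summary also shows how the anisotropic axial PSF limits which orientations
and sizes pass quality control — discussed in `docs/methods.md`.

A `nucleoring` command-line interface exposes the same stages
(`simulate`, `coloc`, `rings`, `compaction`, `run`) for use on your own
OME-TIFF stacks and label-image ROI masks.

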