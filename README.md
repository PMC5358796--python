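# osteochondral

Quantitative histomorphometry of the osteochondral unit in osteoarthritis
(OA), for researchers who grade knee sections and want the subchondral
bone side of the story in numbers. Cartilage grading scales (OARSI 0–6)
describe the articular surface; this package implements the measurement
chain for a four-stage subchondral bone grade (0 = thin porous plate with
open fenestrae … 3 = massive sclerosis under worn cartilage) and the image
analysis that goes with it:

* **Bone–cartilage interface (BCI) segmentation** — a thick (7 px) band
  drawn around the interface is classified bone/cartilage (Otsu within the
  band) and thinned to the ~3-px interface mask.
* **Local-angle analysis by local binary patterns (LBP)** — each interface
  pixel's eight neighbours are thresholded at its intensity; the pattern
  maps to an axial orientation θ ∈ [0°, 180°). The angle distribution is
  reduced to two descriptors:
  * entropy H = −Σᵢ pᵢ log₂ pᵢ of the B-bin angle histogram (disorder of
    the interface, rises with fibrillation), and
  * homogeneity Σᵢⱼ P(i,j)/(1 + d(i,j)) of the angle-level co-occurrence
    matrix (ALCM) over adjacent interface pixels, with circular bin
    distance d (continuity of the interface, falls with fibrillation).
* **Layer morphometry** — thickness of uncalcified cartilage, calcified
  cartilage and subchondral plate as vertical chords at five randomly
  selected, evenly distributed columns; per-grade mean ± SE and fold
  changes versus grade 0.
* **Grading statistics** — inter-rater ICC(3,1), one-way ANOVA with Tukey
  HSD, Welch t-tests between severity groups, and OLS regression of the
  interface descriptors on OARSI grade.
* **Synthetic data** — layered osteochondral phantoms (grade-dependent
  thicknesses, interface roughness, open fenestrae) and simulated study
  tables (20 patients × 3 harvest sites, replicate rater scores) so the
  whole pipeline is testable without any slide scans. Generator means/SDs
  are the published group statistics for human tibial plateau samples.

See `docs/methods.md` for the model details and the design choices.

## Worked example

```python
import osteochondral as oc

profiles = oc.default_grade_profiles()          # grades 0-3, published stats
image, layers = oc.generate_section(
    profiles[2], width_px=384, height_px=384, pixel_size=8.0, seed=7
)
band = oc.band_from_layermap(layers)            # 7-px band around the BCI
interface = oc.extract_interface(oc.classify_band(image, band), band)
desc = oc.describe_interface(image, interface)
print(f"entropy = {desc.entropy:.3f} bits, homogeneity = {desc.homogeneity:.3f}")

cols = oc.sample_points(layers.shape[1], k=5, seed=7)
plate = oc.layer_thickness(layers, cols, "subchondral_plate")
print([round(v) for v in plate.points_um], round(plate.mean_um, 1))
```

prints

```
entropy = 2.971 bits, homogeneity = 0.608
[384, 368, 440, 496, 448] 427.2
```

— a grade-2 phantom: the fibrillated interface is disordered (2.97 of a
possible 3 bits; a grade-0 phantom averages ≈1.6 bits) with low angle
continuity, and the five-point plate thickness (427 µm here) sits in the
published grade-2 range (473 ± 229 µm). Statistics on a whole simulated
study:

```python
table = oc.generate_study_table(n_patients=20, seed=0)
report = oc.reproduce_study(table)     # summaries, ANOVA/Tukey, regressions, ICC
```

The same stages are exposed on the command line:

```bash
osteochondral simulate section --grade 2 --seed 7 --out sec/
osteochondral segment --image sec/section.png --band sec/band.png --out sec/interface.png
osteochondral metrics --image sec/section.png --mask sec/interface.png --out sec/desc.json
osteochondral simulate study --patients 20 --seed 0 --out study.csv
osteochondral stats --table study.csv --out report.json
osteochondral run --seed 0 --out run/        # full pipeline with artifacts
osteochondral reproduce                      # cohort summary + fold changes
```

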