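# pelletmorph

Quantitative morphology of filamentous-fungal pellets in submerged culture.

Filamentous fungi such as *Aspergillus niger* grow in shake flasks as
roughly spherical pellets. Pellet diameter, the heterogeneity of the
population, and the internal core architecture all shape mass transfer and
product titres, so process development needs them measured reproducibly.
`pelletmorph` implements a complete analysis pipeline for this problem:

- **2D segmentation** (`pelletmorph.segment2d`): pellets are segmented from
  the red channel of stereomicrographs by opening/closing-by-reconstruction
  (disk structuring elements of 10 px and 5 px), regional grey-level maxima
  as markers, and marker-controlled watershed on the negated Euclidean
  distance transform. Border-touching objects and objects whose
  area-equivalent diameter ED = 2·√(A/π) falls outside 100–3000 µm are
  discarded.
- **Population statistics** (`pelletmorph.popstats`): each replicate flask
  is summarised by the median ED and the interquartile range (IQR) as the
  intra-flask heterogeneity measure; populations with fewer than 30 pellets
  are excluded. Flask-to-flask variation is the distribution-free overlap
  coefficient of number-density histograms over 80 fixed diameter classes
  (0–4000 µm, 50 µm bins):

      OVL(A, B) = Σᵢ min(f_A(dᵢ), f_B(dᵢ)),  i = 1..80

- **Diameter regression** (`pelletmorph.regress`): ordinary least squares of
  ln(median ED) on ln(spore concentration), ln(shaking frequency A), talc
  concentration T and a baffle indicator, with residual diagnostics,
  variance inflation factors and backward elimination. The reduced model
  back-transforms to the prediction

      PD (µm) = exp(15.863 − 1.7769·ln A − 0.10856·T)

  valid for predicted diameters of roughly 150–1200 µm.
- **3D internal architecture** (`pelletmorph.micro3d`): from labelled voxel
  volumes (hyphae/spore/talc), the radial solid fraction about the mass
  centre (50 µm inner sphere, 25 µm shells), DBSCAN spore-core detection
  (cores need ≥100 spores), volume-equivalent diameter, skeleton metrics
  (total hyphal length, tips, branch points), and assignment to Class I
  (one central core), Class II (multiple cores) or Class III (fusion of
  mature pellets, heuristic).
- **Synthetic data** (`pelletmorph.synthgen`): seeded generators for
  micrographs, 3D pellet volumes and regression tables with exact ground
  truth, so the whole pipeline is testable without any microscope.

## Worked example

```python
import numpy as np
from pelletmorph import synthgen, segment2d, popstats, regress

# one synthetic replicate flask: 60 pellets, median 500 µm
spec = synthgen.PopulationSpec(components=((1.0, 500.0, 0.25),), n_pellets=60)
diameters = synthgen.gen_population_diameters(spec, seed=42)
rgb, truth = synthgen.render_micrograph(diameters, pixel_size=10.0, seed=42)

population = segment2d.run_pipeline(
    segment2d.ImageSample(rgb=rgb, pixel_size=10.0, sample_id="demo")
)
summary = popstats.summarize(population.diameters)
print(f"pellets analysed: {summary.n}")
print(f"median ED: {summary.median_ed:.0f} um, IQR: {summary.iqr:.0f} um, "
      f"modality: {summary.modality_flag}")

other = synthgen.gen_population_diameters(spec, seed=43)
ovl = popstats.ovl_pair(
    popstats.q0_histogram(population.diameters), popstats.q0_histogram(other)
)
print(f"replicate OVL: {ovl:.2f}")

print(f"predicted median diameter at 250 rpm, 5 g/L talc: "
      f"{regress.predict_diameter(agitation=250.0, talc=5.0):.0f} um")
```

prints

```
pellets analysed: 60
median ED: 469 um, IQR: 141 um, modality: unimodal
replicate OVL: 0.72
predicted median diameter at 250 rpm, 5 g/L talc: 247 um
```

All 60 rendered pellets are recovered; the median ED of 469 µm reflects the
particular 60-pellet draw (the population median is 500 µm), the IQR
quantifies its spread, and the OVL of 0.72 is the histogram overlap of two
independently drawn replicates of the same condition. The prediction
equation gives the expected median diameter for a cultivation at 250 rpm
with 5 g L⁻¹ talc microparticles.

A command-line interface mirrors the library
(`pelletmorph simulate2d|segment|popstats|regress|simulate3d|micro3d|run-2d-study|run-3d-study`);
see `pelletmorph --help`.

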