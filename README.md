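# sarcoquant

Whole-section, operator-independent quantification of sarcolemmal protein
intensity in transverse skeletal-muscle sections.

## The problem

Dystrophin quantification matters clinically: Duchenne muscular dystrophy
(DMD) muscle lacks dystrophin, Becker (BMD) muscle carries reduced or
internally deleted protein, and therapies aim to restore it.  The historical
readout sampled a few dozen fibres per biopsy through operator-chosen regions
of interest.  `sarcoquant` implements the whole-section alternative: identify
*every* myofibre in a scanned transverse section from a membrane-marker
channel (spectrin or laminin), build a sarcolemma mask per fibre, and
quantify the target protein (e.g. dystrophin) in each one — thousands to
tens of thousands of fibres per section — then summarise and compare
sections and patient groups.  Because real sections have no ground truth, the
package also ships a seeded synthetic-section generator that renders
tessellated polygonal fibres with bright rims, rim gaps, non-fibre distractor
structures (vessels, nerve bundles, spindles, connective patches, folds) and
realistic noise, with every true quantity recorded.

## The method in brief

- **Segmentation** — ridge-enhance the membrane channel (Sato filter),
  binarise the rim network, take connected components of tissue minus
  network as fibre candidates, and reject non-fibre structures by area,
  solidity, border contact and interior brightness.
- **The 20 % rim rule** — measure per candidate the fraction of its boundary
  supported by membrane signal; fibres missing less than 20 % of their rim
  are retained (rim reconstructed by the traced closure), fibres missing at
  least 20 % are excluded as damaged or degenerating.
- **Quantification** — per fibre: mean target intensity over a thin
  sarcolemmal ring (b_in = b_out = 0.5 µm about the boundary) and over the
  eroded cytoplasm; area (µm²) and minimum Feret diameter (µm); everything
  in the detector's arbitrary units (au), never rescaled.
- **Statistics** — per-section N, mean, SD, SEM, CV% = 100·SD/mean, dynamic
  range; absolute/cumulative fibre-count (%) distribution curves; group
  fold-changes and percent reductions from unweighted section means, with
  Mann-Whitney and ANOVA tests.  A legacy 40-fibre sampled-ROI emulation is
  included for comparison with the older protocol.

See `docs/methods.md` for the full model, parameter table and limitations.

## Worked example

```python
from sarcoquant import (SyntheticSpec, generate_section, segment_section,
                        build_compartments, quantify_all, summarize_section)

spec = SyntheticSpec(image_shape=(1536, 1536), seed=11)   # 768 x 768 um section
section, truth = generate_section(spec)                   # two-channel image + ground truth
result = segment_section(section)                         # fibre label map + audit
masks = build_compartments(result.labels, section.pixel_size_um)
table = quantify_all(section, result.label_map, masks)    # one row per fibre
summary = summarize_section(table["sarc_mean_target"])
```

which prints, formatted:

```
true fibres rendered : 132
fibres accepted      : 131
mean +/- SEM (au)    : 18065 +/- 285
CV%                  : 18.0
dynamic range (au)   : 11145 - 26734
median fibre area    : 2181 um^2
median min Feret     : 47.0 um
```

One rendered fibre drew a rim gap above 20 % and was excluded by the rim
rule; the recovered section mean (18 065 au) sits within 0.4 % of the
generator's drawn mean rim intensity (18 000 au), and the per-fibre CV
reflects the drawn 20 % spread plus measurement noise.  The same stages are
available as a CLI:

```bash
sarcoquant simulate --seed 11 --out sim/
sarcoquant segment  --image sim/section.ome.tif --out seg/
sarcoquant quantify --image sim/section.ome.tif --labels seg/labels.tif --out quant/
sarcoquant summarize --table quant/fibre_table.csv --out summary.json
sarcoquant run --config pipeline.yaml --out out/      # all stages, one config
```

Real scans enter through `read_section` (TIFF / OME-TIFF, channel roles by
name or plane index, pixel size from metadata or given explicitly).

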