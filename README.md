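# hairtube

Semi-automatic quantification of small-mammal hair density on scanned
adhesive tapes from rodent hair tubes, with a jittered reproducibility
protocol, synthetic benchmark generators, and the field-validation
statistics used to compare hair-tube indices against wildlife-camera
counts.

Hair tubes are baited open-ended tubes lined with double-sided sticky
tape; animals passing through leave dorsal guard hair behind. The hair
density of a scanned tape is a non-invasive activity index for the
small-mammal community. This package classifies every pixel of a scan
(tape on a red background, 8-bit RGB) as **background**, **tape**, or
**hair** using calibrated inclusive RGB ranges, cleans the mask in
pixel space (closing of the background class, removal of sub-hair
specks), and reports per region of interest

```
density (%) = 100 · n_hair / (n_hair + n_tape)
```

i.e. hair as a share of the *effective* (tape + hair) pixels. The
*calculated* value of a tape is the mean over 10 region re-selections
with ±3 px edge jitter, with its standard error from the replicate
spread. For field surveys, tube sides and transects are averaged into
one datapoint per habitat replicate and repetition, camera sightings
are deduplicated with a 10-minute quiet-window rule, both variables
are Johnson-normalized, and Spearman's ρ is reported per habitat.

See `docs/methods.md` for the model, parameter defaults and their
rationale, and known limitations.

## Worked example

Generate a synthetic sheet with pixel-exact ground truth, process it,
and run the reproducibility protocol:

```python
from hairtube import (TapeSpec, PerturbationSpec, generate_sheet,
                      process_sheet, replicate_density, default_calibration)

spec = TapeSpec(target_density=2.0, seed=7)   # one 700x400 px tape section
sheet = generate_sheet(spec)
region = spec.tape_regions[0]

result = process_sheet(sheet.image, default_calibration(), [region])[0]
print(sheet.region_densities["tape"], result.density_percent)

summary = replicate_density(sheet.image, default_calibration(), region,
                            PerturbationSpec(jitter=3, repetitions=10, seed=1))
print(summary.mean, summary.sd, summary.se)
```

Output:

```
2.0035714285714286 2.0042857142857144
2.0080649636517944 0.004674724413656911 0.0014782776580750973
```

The generator stopped adding strands when the truth density first
reached the 2% target (realized truth 2.0036%); the single-run
pipeline estimated 2.0043%, an error of 0.0007 percentage points.
Across ten jittered region re-selections the calculated value is
2.008% with an SE of 0.0015 percentage points
— the estimate is insensitive to realistic variation in how the region
is drawn.

The same pipeline is available from the shell:

```sh
hairtube synth  --out-dir demo --seed 7
hairtube process --image demo/sheet.png --config run.yaml --out densities.csv
hairtube repro   --image demo/sheet.png --config run.yaml --reps 10 --out repro.csv
hairtube survey  --out-dir survey --seed 7
hairtube stats   --tapes survey/tapes.csv --events survey/events.csv --out corr.csv
```

where `run.yaml` names the calibration (defaults, explicit ranges, or
single-class patches), the labelled regions, optional overrides for
interfering elements, and the refinement parameters; the schema is
documented in `hairtube/config.py`. `process` writes one CSV row per
region (counts, density, flags); `--xlsx` adds a spreadsheet export.

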