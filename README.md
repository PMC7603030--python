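# secrflux

Quantification of secretory-pathway dynamics from live-cell fluorescence
imaging: the ER-to-Golgi **transport index** with its four-level
transport-efficiency classification, **vesicle motility** (MeanSpeed,
MeanDisplacement) from 200 ms time-lapse movies, **form-factor** and
microtubule-mask morphology readouts, and **ratiometric biosensor** trace
metrics (FRET ATP sensors, Fura-2). A synthetic-microscopy generator with
exact ground truth makes every stage verifiable by parameter recovery, so
the pipeline can be validated end-to-end without any raw recordings.

Intended users: cell biologists quantifying synchronized cargo release
(conditional-aggregation "hook" constructs released by a solubilizer
ligand) and organelle/vesicle dynamics from two-channel TIFF stacks, and
method developers who need a ground-truthed benchmark for such pipelines.

## The transport index

For a cell ROI R with Golgi mask G(t) segmented per timepoint from the red
Golgi-marker channel (rolling-ball background subtraction, Otsu threshold
within the ROI, two binary erosions), the transport index at time t after
solubilizer addition is the normalized integrated-density ratio in the
cargo channel:

    TI(t) = ( Σ_G(t) I_cargo / Σ_{R∖G(t)} I_cargo ) / ratio(t=0),    TI(0) = 1.

Cells are classified at a cargo-specific decision time — soluble bulk-flow
cargo at 30 min with bounds 10/5/2, transmembrane COPII-sorted cargo at
15 min with bounds 10/7/4 — into very_high / high / moderate / none.
On synthetic cells where a fraction f(t) of cargo is planted in the Golgi,
TI obeys the closed form f(t)(1−f0)/(f0(1−f(t))), which the pipeline
recovers to machine precision on noise-free data.

Vesicle motility follows the fixed sequence background subtraction →
exponential photobleaching correction → movie-wide Otsu threshold →
5–30 px size filter → nearest-neighbour linking; MeanSpeed is the
arithmetic mean over tracked vesicles of each track's mean speed, and
MeanDisplacement the mean straight-line distance between a track's first
and last positions. See `docs/methods.md` for all models and conventions.

## Worked example

Simulate a single cell with "very high" planted transport kinetics under
Poisson noise, then quantify it:

```
$ secrflux simulate transport --transport-class very_high --noise poisson \
      --seed 42 --out-dir demo/sim
wrote transport series (1 cell(s)) to demo/sim

$ secrflux transport-index --cargo-tiff demo/sim/transport_stack.tif \
      --marker-tiff demo/sim/transport_stack.tif \
      --roi-tiff demo/sim/cell_masks.tif \
      --background-radius 25 --out-dir demo/out
analyzed 1 cell(s); results in demo/out

$ cat demo/out/transport_index.csv
cell_label,time_min,raw_ratio,ti,class
1,0,0.0226739,1,very_high
1,3,0.0940794,4.14924,very_high
1,7,0.168662,7.43862,very_high
1,15,0.254469,11.223,very_high
1,30,0.327286,14.4345,very_high
```

The raw ratio is the cell's Golgi/non-Golgi integrated cargo intensity; the
`ti` column normalizes it to the initiation timepoint, so it starts at
exactly 1 and reaches 14.4 at 30 min — above the ≥ 10 bound, hence the
`very_high` class. Every run also writes a `manifest.json` recording all
resolved parameters, input digests, seed and package version.

Other commands: `secrflux simulate {vesicles,filaments,trace}`,
`secrflux motility`, `secrflux formfactor`, `secrflux microtubules`,
`secrflux trace`, `secrflux report`. The same functionality is available as
a library under `secrflux.transport`, `secrflux.motility`,
`secrflux.morphology`, `secrflux.traces`, `secrflux.ops` and
`secrflux.simulate`.

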