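# gliavasc

Quantification of blood–brain-barrier (BBB) leakage and microglia–vessel
interaction in two-photon fluorescence image stacks, with a synthetic
phantom generator that provides exact ground truth for every stage.

## What it measures, and for whom

In vivo two-photon imaging of the cortex with intravenously injected
dextran-conjugated fluorophores (10/40/70 kDa) probes BBB integrity: an
intact barrier confines all three tracers to the vessel lumen, while a
compromised barrier lets small dextrans escape into the parenchyma.  In the
same preparations, reporter-labelled microglia can be scored for how many
of them sit directly on vessels, how ramified they are, and how motile
their processes remain.  This package implements the image quantification
for that kind of experiment:

- **Vessel delineation** — Kapur maximum-entropy threshold of the projected
  dextran channel, interior hole filling ("include holes"), and removal of
  connected components below 40 µm² ("Analyze Particles, 40–Infinity").
- **Leakage index** — mean fluorescence outside the delineated vessels, per
  dextran size, expressed relative to a control group whose averaged index
  is 1.00 by construction; vessels are always defined on the impermeant
  70 kDa channel.
- **Vessel-associated microglia** — a dual-channel line profile from the
  soma center to the nearest vessel surface; each channel has its own
  standard deviation subtracted (negatives clamped to zero) and the cell is
  vessel-associated when the gap between the green-extinction point and the
  red-rise point is strictly below 1 µm (4 px at 0.254 µm/px).
- **Colocalization** — Pearson correlation of paired pixel intensities in
  an ROI (e.g. microglial vs astrocytic-end-feet markers).
- **Morphometry** — process counts and geodesic skeleton lengths, soma
  areas, CD68 puncta counting (positive when strictly more than two
  puncta), pericyte coverage (% of vessel surface overlapped by the
  marker), and process-tip motility in registered time-lapses.
- **Preprocessing** — translation registration by cross-correlation,
  maximum-intensity projection, and selection of the 100–200 µm cortical
  depth window.

No imaging data are required: `gliavasc.synthgen` renders calibrated
phantom stacks — tubular vessels, ramified microglia at controlled gaps,
per-channel leak halos whose integrated extravascular intensity exactly
equals a configured leak fraction, intracellular puncta, frame jitter and
process movement, with optional Poisson + Gaussian noise — and returns the
ground truth alongside, so every estimator is validated by parameter
recovery.

## Worked example

```python
import gliavasc as gv

cfg = gv.SceneConfig(seed=0,
                     cells=gv.CellSpec(count=4, gaps_um=(0.0, 0.5, 2.0, 5.0)),
                     leak_fraction_per_channel={10: 0.3, 70: 0.0})
stack, truth = gv.generate_scene(cfg)
proj = dict(zip(stack.channel_labels, gv.z_project_max(stack)))

vm = gv.vessel_mask(proj["dextran_70kDa"], stack.pixel_size_um)
print(f"vessel components: {len(vm.components)}, area {vm.area_um2:.1f} um^2")

for cell in truth.cells:
    call = gv.call_contact_for_cell(proj["microglia"], proj["dextran_70kDa"],
                                    cell.center_zyx_px[1:], vm.mask,
                                    stack.pixel_size_um, cell_id=cell.cell_id)
    print(f"cell {call.cell_id}: gap {call.gap_um:.2f} um -> "
          f"{'vessel-associated' if call.is_contact else 'parenchymal'}")

m10 = gv.extravascular_mean(proj["dextran_10kDa"], vm)
m70 = gv.extravascular_mean(proj["dextran_70kDa"], vm)
print(f"extravascular mean: 10 kDa {m10:.2f}, 70 kDa {m70:.2f}")
```

prints

```
vessel components: 1, area 600.0 um^2
cell 0: gap 0.00 um -> vessel-associated
cell 1: gap 0.50 um -> vessel-associated
cell 2: gap 2.00 um -> parenchymal
cell 3: gap 5.00 um -> parenchymal
extravascular mean: 10 kDa 11.01, 70 kDa 10.00
```

The two cells placed closer than 1 µm to the vessel wall are called
vessel-associated; the 10 kDa channel, configured to leak 30 % of its
intravascular signal, shows parenchymal fluorescence above the background
(10.0) while the impermeant 70 kDa channel does not.

A `gliavasc` console script exposes the stages (`simulate`, `segment`,
`leakage`, `contact`, `morphometry`, `run`); `gliavasc run --manifest
manifest.yaml --out report/` executes the whole pipeline over a YAML
manifest of TIFF stacks and writes per-image, per-cell and per-group CSVs
plus a run log, with every row carrying the configuration hash.

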