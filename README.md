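# granulemap

Object-based colocalization and per-cell quantification of mitochondrial
RNA-granule (MRG) foci in multi-channel fluorescence microscopy, with a
ground-truthed synthetic image generator.

## Who this is for

Mitochondrial gene expression is organised in punctate structures:
nascent RNA concentrates in MRGs, complementary heavy- and light-strand
transcripts hybridise into dsRNA foci, and mtDNA is packaged in
nucleoids. Studies of these structures repeatedly need the same
measurements from super-resolution (STED) and confocal images:

- how much two kinds of foci overlap, object by object — e.g. what
  fraction of dsRNA foci colocalise fully, partially, or not at all
  with BrU-labelled nascent RNA;
- focus shape: area, major/minor axis, eccentricity;
- foci per µm² of mitochondrial network per cell;
- per-cell mean and integrated intensities inside the mitochondrial
  mask, stratified by cell-cycle phase called from DAPI / EdU /
  cyclin-A.

`granulemap` packages that pipeline — binary mitochondrial mask,
thresholded ROIs, mask-containment filtering, pixel-exact overlap with
three-way categorization, per-cell metrics, phase gating — as a tested
library and CLI, plus a generator that renders synthetic frames with
exact ground truth so every stage can be validated.

## The measurement

For a query focus $q$ (a connected set of above-threshold pixels) and
the union $R$ of reference-channel foci, the overlap percentage is

$$\mathrm{ovl}(q) = 100 \cdot \frac{|q \cap R|}{|q|}$$

counted in pixels (exact integers), with category
*none* at $\mathrm{ovl}=0$, *complete* at $\mathrm{ovl} \ge 100 -
\varepsilon$ (default $\varepsilon = 1$), *partial* otherwise. Shape
descriptors come from the moment-equivalent ellipse: axes
$4\sqrt{\lambda_{1,2}}$ of the pixel covariance, eccentricity
$\sqrt{1 - (b/a)^2}$. Per-cell foci density is the contained-focus
count divided by the cell's mitochondrial-network area in µm².
Phases are gated S → G2 → G1 by nuclear EdU, then cyclin-A, then DAPI.
See `docs/methods.md` for the full model, defaults, and caveats.

## Worked example

Generate a noiseless STED-like frame (100 dsRNA and 100 BrU foci inside
a tubular mitochondrial mask, planted at the 3/65/32 complete / partial
/ none composition), segment it, and summarise the overlap:

```python
import granulemap as gm
from granulemap.segment import segment_mask, label_foci, filter_by_mask
from granulemap.colocal import compute_overlap, shape_descriptors, summarize

params = gm.GeneratorParams(seed=42).noiseless()   # STED-like defaults
frame, truth = gm.generate_frame(params)

mito = segment_mask(frame.channel("mito"), method="absolute",
                    threshold=60.0, pixel_size=params.pixel_size)
foci = {}
for ch in ("dsRNA", "BrU"):
    mask = segment_mask(frame.channel(ch), method="absolute",
                        threshold=100.0, pixel_size=params.pixel_size)
    foci[ch] = filter_by_mask(label_foci(mask, channel=ch), mito)

records = compute_overlap(foci["dsRNA"], foci["BrU"], frame.shape)
summary = summarize(records)
areas = [shape_descriptors(f).area_um2 for f in foci["dsRNA"]]

print(f"dsRNA foci measured : {summary.n_foci}")
print(f"mean dsRNA area     : {sum(areas)/len(areas):.4f} um^2")
print(f"complete / partial / none overlap vs BrU: "
      f"{summary.pct_complete:.0f}% / {summary.pct_partial:.0f}% / {summary.pct_none:.0f}%")
```

prints

```
dsRNA foci measured : 100
mean dsRNA area     : 0.0189 um^2
complete / partial / none overlap vs BrU: 3% / 65% / 32%
```

All 100 planted foci are recovered; the mean segmented area matches the
generator's 0.019 µm² dsRNA calibration, and the recovered composition
equals the planted one exactly (at noiseless settings recovery is
pixel-perfect; under the default noise model it stays within about one
percentage point per category, averaged over seeds).

## Command line

```sh
granulemap simulate --config params.yaml --seed 1 --out sim/   # frames + truth CSVs
granulemap colocalize --frame sim/sim-000001.tif --out out/    # overlap tables
granulemap quantify --frames sim/ --config cfg.yaml --out out/ # per-cell metrics
granulemap run --config cfg.yaml --seed 1 --out out/           # end to end
```

All parameters live in a YAML config (channel→role map, thresholds,
containment rule, completeness tolerance, unsharp-mask settings); CLI
flags override with a logged warning. Outputs are CSV tables
(per-focus, per-cell, overlap and group summaries) with the package
version and a config hash embedded as header comments, plus a run log
recording every threshold and rule applied and per-stage focus counts.

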