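# periscope

Quantification of peripheral heterochromatin organisation from 3D
fluorescence microscopy and single-molecule localization data.

In many cell types a layer of H3K9me2-marked heterochromatin — the
lamina-associated domains (LADs) — lines the inner face of the nuclear
lamina. Testing whether a genomic locus sits in that layer, or how much of a
chromatin signal is concentrated there, requires a small set of image
measurements that are usually performed interactively in commercial
software. `periscope` implements them as a reproducible, scriptable
pipeline:

* **3D segmentation** of the nucleus (DNA counterstain), the nuclear lamina
  shell (lamin immunofluorescence), and the peripheral heterochromatin band
  (H3K9me2), with anisotropic physical voxel spacing throughout;
* **signed spot-to-lamina distances**: DNA-FISH spots (nominal 250 nm) are
  detected at their intensity mass centres and assigned the signed Euclidean
  distance *d* from the lamina inner edge (positive toward the nuclear
  interior; spots embedded in the lamina get *d* < 0). A spot is
  **peripheral** when *d* ≤ *T*, where *T* is the thickness of the
  peripheral heterochromatin layer (measured per cell from the H3K9me2 band
  inner edge, or configured);
* **peripheral signal fractions**: the proportion of a channel's total
  nuclear intensity inside a lamina/H3K9me2-derived periphery mask, plus
  line intensity profiles and per-condition normalisation;
* **Voronoi cluster analysis of STORM localizations**: each 2D localization
  receives its region-clipped Voronoi polygon area; multiscale density
  thresholds are calibrated against a Monte-Carlo uniform (complete spatial
  randomness) null, starting from ρ₁ = δ = A/n, with subsequent thresholds
  at the crossing of the observed and reference area distributions;
  clusters are connected components over Delaunay edges;
* **nonparametric statistics**: two-tailed Mann-Whitney U (exact null for
  small tie-free samples) and Kruskal-Wallis with Dunn's post-hoc contrasts,
  plus the 5/25/50/75/95-percentile box summaries.

Because real microscopy data for this analysis is rarely shareable, the
package ships a first-class synthetic-data generator: ellipsoidal nuclei
with a lamina shell and a peripheral band of known thickness, FISH spots
placed at exactly known signed distances (via a nearest-point solve on the
ellipsoid surface), PSF blur and Poisson + Gaussian camera noise, and STORM
point clouds mixing uniform background with Gaussian clusters. Every stage
of the pipeline is tested against this ground truth.

## Worked example

Simulate a small cohort in which LAD-like probes are placed in the
peripheral layer with probability 0.8 and non-LAD probes with probability
0.1, then run the full measurement chain:

```python
from periscope import (NucleusParams, generate_nucleus_image, segment_nucleus,
                       segment_lamina, measure_layer_thickness, detect_spots,
                       spot_distances, classify_spots, summarize_cells, mann_whitney)

calls = []
for i in range(5):
    params = NucleusParams(seed=i, n_lad_spots=40, n_nonlad_spots=40,
                           f_lad_peripheral=0.8, f_nonlad_peripheral=0.1)
    channels, truth = generate_nucleus_image(params)
    nucleus = segment_nucleus(channels["dna"])
    lamina = segment_lamina(channels["lamina"], nucleus)
    layer = measure_layer_thickness(channels["h3k9me2"], lamina)
    for key, label in (("lad_fish", "LAD"), ("nonlad_fish", "nonLAD")):
        spots = detect_spots(channels[key], nucleus, 0.25, cell_id=f"cell{i}", channel=label)
        spots = spot_distances(spots, lamina)
        calls.extend(classify_spots(spots, layer))

cells, cohort = summarize_cells(calls)
print("measured layer thickness T:", round(layer.thickness_T, 3), "um")
for ch in ("LAD", "nonLAD"):
    lo, hi = cohort.range_percent_peripheral[ch]
    print(f"{ch}: {cohort.mean_percent_peripheral[ch]:.1f}% peripheral "
          f"(range {lo:.0f}-{hi:.0f}%), median d = "
          f"{cohort.distance_percentiles[ch][50]:.2f} um")
test = mann_whitney([c.percent_peripheral["LAD"] for c in cells],
                    [c.percent_peripheral["nonLAD"] for c in cells],
                    labels=("LAD", "nonLAD"))
print(test.summary())
```

Output:

```
measured layer thickness T: 0.361 um
LAD: 79.3% peripheral (range 62-92%), median d = 0.16 um
nonLAD: 16.6% peripheral (range 12-21%), median d = 0.56 um
Mann-Whitney U (asymptotic-tie-corrected): statistic=25, p=0.01167 *
  LAD: n=5, median=82.5
  nonLAD: n=5, median=17.5
```

The cohort mean of per-cell percent-peripheral recovers the generating
probabilities (80% / 10%, the non-LAD estimate running a few points high at
this small cohort size); the measured layer thickness is the per-cell *T*
used for classification; and the two probe sets separate significantly even
with five cells.

The same workflows are available from the shell:

```bash
periscope simulate      --config run.yaml --seed 1 --out sim/
periscope spots         --config run.yaml --seed 1 --out results/
periscope storm-cluster --config run.yaml --seed 7 --out storm/
periscope stats         --config run.yaml --out stats/
```

Outputs are CSV (spot, cell and localization tables) and JSON (cohort and
threshold summaries), each carrying the config hash, seed, and package
version; re-running with the same config and seed reproduces every artifact
bit-identically.

## Documentation

`docs/methods.md` describes the models, the estimators, the synthetic-data
generator and its limits, and the numerical choices in detail.
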