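# nucleograph

Interpreting the electron density of nucleic acids — especially in maps
phased by protein molecular replacement, where the DNA/RNA regions are
noisy and unmodelled — is a long-standing weak spot of automated
crystallographic model building. `nucleograph` attacks the problem in two
stages:

1. **Semantic segmentation.** A 3-D U-Net classifies every point of an
   electron-density map by whether it lies within 1.5 Å of one of the three
   nucleotide moieties — the phosphate group, the sugar ring or the
   nitrogenous base — producing one probability map per moiety.
2. **Phosphate-guided model building.** The predicted phosphate map is
   reduced to one estimated phosphorus position per predicted blob
   (threshold 0.1, gradient ascent to local maxima, 1.5 Å merging, density
   refinement); triplets of positions with inter-point distances ≤ 8 Å and
   an interior angle of 150° ± 50° anchor rigid superpositions of
   trinucleotide template fragments, which are scored against the density,
   joined into chains, and emitted as a backbone model.

A synthetic-data module generates idealized DNA/RNA duplexes,
Gaussian-atom density maps at controllable quality and matching
ground-truth target maps, so the entire pipeline — training included — runs
and is tested at desk scale on one CPU.

## The model

The network maps a `(32, 32, 32, 1)` cube of density on a 0.7 Å orthogonal
grid to a `(32, 32, 32, 2)` softmax pair *(p, 1 − p)* per point. Five
downsampling blocks (two convolution → instance-norm → ReLU blocks, then
2×2×2 max pooling) take the data from 1 → 16 → 32 → 64 → 128 → 256 filters
while the spatial edge shrinks 32 → 1; a bottleneck of two unnormalized
convolution blocks produces the `(1, 1, 1, 512)` deep representation; five
upsampling blocks (transposed convolution, skip concatenation, two
convolution blocks) mirror the encoder back to 16 filters at full
resolution, and a 1×1×1 convolution with softmax emits the two channels.
Training uses the focal cross-entropy loss (α = 0.25, γ = 2) with Adam,
drawing randomly rotated and translated cubes from three cycled map
sources; the early curriculum restricts sampling to cubes containing at
least one positive target point.

Whole-map inference resamples the input onto the 0.7 Å working grid, tiles
it into 32³ chunks overlapping by 16 points (with a 16-point margin so
every point is predicted more than once), classifies each chunk by argmax,
averages overlapping votes, and re-interpolates trilinearly onto the
input map's own grid. The spread of the per-chunk votes gives a
point-wise variance map (`-variance`); skipping the argmax gives raw
probabilities (`-raw`).

The network itself is implemented in NumPy with analytic gradients
(verified against finite differences in the test suite), so the package
has no deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from nucleograph import (DuplexSpec, DensitySpec, make_duplex, make_density,
                         interpolate_to_ortho, make_target_map,
                         OracleNetwork, predict, atom_inclusion, build_model)

duplex = make_duplex(DuplexSpec(n_base_pairs=10), seed=11)   # 405 atoms
dmap = make_density(duplex, DensitySpec(), seed=11)          # CCP4-style map
ortho = interpolate_to_ortho(dmap, 0.7)
truth = make_target_map(duplex, ortho, "phosphate")

pred = predict(dmap, OracleNetwork(truth.values))
print(atom_inclusion(pred, duplex, "phosphate"))             # 100.0

built, points, chains = build_model(pred, dmap)
planted = np.array([a.pos for a in duplex.atoms if a.name == "P"])
print(len(points), len(planted))                             # 22 20
```

With a ground-truth oracle standing in for the trained network, every
phosphate-group atom of the planted duplex lies in positive predicted
density (inclusion 100.0%), and the builder recovers one phosphorus
estimate per planted phosphate (22 points for 20 planted, the two extra
coming from blob merging at the strand ends; all 20 planted positions are
matched within 1.5 Å).

Training a reduced network (depth 3, 8 first-layer filters) from scratch
on three synthetic map sources and predicting a held-out 10 bp duplex:

```python
from nucleograph.benchmark import train_phosphate_benchmark
bench = train_phosphate_benchmark(seed=1)
print(bench.inclusion_by_blur)   # {0.0: 99.0, 1.5: 86.0, 3.0: 30.0}
```

Held-out phosphate atom inclusion reaches 99% on the clean map and falls
monotonically as the map is degraded with extra blur and noise — the
pattern expected of a resolution sweep.

A thin CLI wraps the same stages: `nucleograph predict`, `nucleograph
build`, `nucleograph evaluate`, `nucleograph fixtures`.

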