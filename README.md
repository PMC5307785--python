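# petresponse

Automatic assessment of oncological treatment response from paired
pre/post-treatment PET/CT lesion images: region-growing segmentation, a
171-entry texture descriptor suite, SMOTE/PCA preprocessing, six classifier
families evaluated by leave-one-out, and rank-based classifier comparison
(Friedman chi-square, Iman–Davenport F-ratio, Bonferroni–Dunn critical
difference).

Because the original patient data is not publicly deposited, the package
ships a first-class synthetic cohort generator that emulates the study's
class structure — four response classes (negative / neutral /
positive-partial / positive-complete) with default counts 2/6/27/28 —
so every downstream stage is fully testable offline.

## Package layout

| module | contents |
| --- | --- |
| `petresponse.synthetic` | cohort generator: paired lesion images, analytic ground-truth masks, 8 clinical variables per patient |
| `petresponse.segmentation` | min–max normalization to [0, 1]; seeded 2-D region growing at 40% of the seed intensity, 4-connectivity |
| `petresponse.features` | 171 descriptors: histogram (4), GLCM (22), GLRL (11), Daubechies-4 wavelets (28), Gabor bank (48), uniform LBP (58) |
| `petresponse.cohort` | 350-entry patient vectors (8 clinical + 171 pre + 171 post), exact CSV round-trip |
| `petresponse.preprocessing` | SMOTE (6 synthetic samples for each of the 2 rarest classes by default) and PCA (2 components by default) |
| `petresponse.classifiers` | kNN, MLP1, MLP2, LVQ1, RBF network, PNN with their frozen hyperparameter grids |
| `petresponse.evaluation` | leave-one-out per-class accuracy, tie-averaged ranking, Friedman/Iman–Davenport statistic, F critical values, Bonferroni–Dunn comparison, experiment driver |
| `petresponse.cli` | `petresponse` command-line interface |

A benchmark fixture with reference per-class accuracy tables is bundled
(`petresponse/data/benchmark_accuracies.json`) so the comparison-statistics
stage is testable independently of any training run
(`petresponse.load_benchmark_accuracies()`).

## Command line

```bash
petresponse synth --config cohort.json --out cohort/ --seed 1
petresponse segment --image cohort/P000_pre.png --threshold 0.4 --out mask.png
petresponse features --image cohort/P000_pre.png --mask mask.png --out row.csv
petresponse preprocess --in dataset.csv --smote 6x2 --pca 2 --seed 0 --out reduced.csv
petresponse experiment --in dataset.csv --variant smote+pca --seed 0 --out results.json
petresponse compare --accuracies table.csv --baseline kNN --out comparison.json
petresponse pipeline --config pipeline.json --out run/
```

Exit codes: 0 success, 2 configuration error, 3 data error.  Every
artifact-producing command writes a manifest (config snapshot, seed,
SHA-256 digests); `pipeline` resumes from intermediates whose digests
still match.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes brute-force oracle comparisons for every descriptor
family, a flood-fill oracle for region growing, an eigendecomposition
oracle for PCA, an independent Friedman implementation, and an end-to-end
criterion: on the default high-separation synthetic cohort, SMOTE + PCA +
LVQ reaches per-class leave-one-out accuracy >= 0.9 for all four classes
over three seeds.

## Conventions worth knowing

- The per-family descriptor lists (4/22/11/28/48/58) are frozen package
  conventions, documented in `petresponse.features`; gray levels are
  quantized to 16 before GLCM/GLRL; LBP uses 8 neighbors at radius 1.
- Per-class "accuracy" is per-class recall under leave-one-out.
- SMOTE runs before PCA in the combined variant; both are fit inside each
  leave-one-out training fold.
- The Bonferroni–Dunn critical difference uses the standard formula
  `CD = q_alpha * sqrt(k(k+1)/(6N))` (≈ 3.41 for k = 6, N = 4 at
  alpha = 0.05); `--cd-override` substitutes any externally supplied value.
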