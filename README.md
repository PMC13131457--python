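# evquant

Quantitative image analysis of extracellular-vesicle (EV) uptake and
EV–mitochondria spatial apposition in multi-channel fluorescence
micrographs, plus a ground-truthed synthetic-micrograph generator for
validating every stage.

`evquant` is aimed at cell biologists quantifying labeled EVs (e.g.
CD9-tGFP puncta) taken up by target cells. It answers two questions:

1. **How many EV puncta does each cell contain?** Somata are segmented from
   a cytoplasmic marker channel, puncta are detected by intensity
   thresholding with size/shape filtering, and each punctum is assigned to
   the soma containing its centroid. Results are reported as particles per
   cell and particle density (particles/μm² of soma area), with Pearson
   correlations against soma size.
2. **Are EV puncta closer to mitochondria than chance predicts?** Both
   channels are segmented, and for each punctum the edge-to-edge distance
   to the mitochondrial mask is measured (minimum boundary pixel
   separation; 0 nm = contact). Apposition is summarized in cumulative
   bins (contact, ≤100, ≤200, ≤500, ≤1000 nm) and tested against a Monte
   Carlo randomization null that re-places each punctum's segmented shape
   uniformly within the cellular region of interest while leaving the
   mitochondrial geometry untouched. Conditions are compared with
   Mann-Whitney U and Fisher's exact tests, and distance distributions are
   characterized by Sarle's bimodality coefficient (BC > 0.555 ⇒ bimodal)
   and 1- vs 2-component Gaussian-mixture selection by BIC
   (ΔBIC = BIC₂ − BIC₁ < 0 ⇒ two components).

## The statistics at the core

For a punctum *P* and organelle mask *M* on a grid with pixel size *s* nm,
let *d* be the minimum center-to-center distance (in px) from any pixel of
*P* to any pixel of *M*. Then

```
edge distance = 0            if d ≤ √2   (overlap or 8-adjacency = contact)
              = (d − 1) · s  otherwise
```

The randomization test reports the add-one empirical p-value
`p = (1 + #{null ≥/≤ observed}) / (1 + n_iterations)`, one-sided toward
proximity, with per-bin observed vs expected fractions and fold
enrichment. Sarle's coefficient is
`BC = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3)))` with bias-corrected sample
skewness g₁ and excess kurtosis g₂; its uniform-distribution benchmark
5/9 ≈ 0.555 is the decision threshold.

## Worked example

Simulate a field whose ground truth is 60% of 50 puncta in contact with
the mitochondrial network, then analyze it:

```bash
evquant simulate apposition --out demo --n-puncta 50 \
    --contact-fraction 0.6 --size 512 --seed 11
# wrote demo/field.tiff (contact fraction 0.60)

cat > demo/config.toml <<'EOF'
pixel_size_nm = 65.0
channel_names = ["ev", "mitochondria"]
seed = 3
[[images]]
path = "demo/field.tiff"
condition = "demo"
[threshold.ev]
method = "absolute"
absolute_value = 60.0
[threshold.mitochondria]
method = "absolute"
absolute_value = 60.0
[monte_carlo]
iterations = 1000
pooled_iterations = 10000
EOF

evquant apposition --config demo/config.toml --out demo/results
# demo: n=50, mean edge 395 nm, contact 60%
```

The run writes `edge_distances.csv` (per-punctum distances),
`apposition_summary.json` (cumulative bin fractions, Monte Carlo
observed/expected/fold-enrichment and empirical p per bin, bimodality and
mixture-selection results) and `run_log.jsonl` recording the numeric
threshold applied to every image. "Contact 60%" means 30 of the 50
detected puncta have zero boundary separation from the mitochondrial
mask — matching the simulated ground truth; the Monte Carlo p-value tells
you how improbable that degree of proximity is under random placement.

The same workflow drives soma quantification
(`evquant simulate somata`, `evquant soma-quant`) and distribution-shape
statistics on any distance table (`evquant stats`).

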