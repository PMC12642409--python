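# synpid

Synergy/redundancy decomposition and spatial correlation-length analysis of
binary neural activity rasters.

Mesoscale two-photon recordings make it possible to watch thousands of
cortical neurons at once across millimetres of tissue. Two questions such
data raise: how far do pairwise correlations reach (the correlation length,
a signature of dynamics near criticality), and what *kind* of statistical
interaction carries them — redundant information that either neuron provides
alone, or synergistic information only available from neurons jointly?
`synpid` implements the full analysis chain for those questions, from a
binarized (or binarizable) activity raster with neuron positions to
condition-level statistics, together with a synthetic-data generator with
planted ground truth so every stage can be validated end to end.

## The measures

For a neuron pair (X, Y) with binary states, the time-delayed mutual
information at lag τ,

    TDMI = I(X_t, Y_t ; X_{t+τ}, Y_{t+τ}),

is decomposed with the minimum-mutual-information (MMI) redundancy into
four non-negative parts — redundant (RI), unique (UI(X), UI(Y)) and
synergistic (SI) information:

    RI    = min( I(X_t ; F), I(Y_t ; F) ),      F = (X_{t+τ}, Y_{t+τ})
    UI(X) = I(X_t ; F) − RI,   UI(Y) = I(Y_t ; F) − RI
    SI    = TDMI − max( I(X_t ; F), I(Y_t ; F) )

Raw components are biased by rates and sample size, so they are Z-scored
against null processes matched on TDMI (NuMIT): random binary-pair Markov
kernels observed through calibrated flip noise.

Spatial structure is summarized by binning a per-pair scalar (Pearson r, or
Z-scored synergy/redundancy) in log-spaced distance bins and fitting

    C(d) = C∞ + (C0 − C∞) e^(−d/λ),

giving the correlation length λ and the effective information length
λ_eff = (1/C0) ∫_{d0}^{dmax} C(d) dd (defaults d0 = 100 µm,
dmax = 1500 µm). Finally, k-nearest-neighbour graphs built from the
Z-scored synergy and redundancy values are combined into a two-layer
network whose shortest paths are classified as complementary, shared, or
unique, and recording-level summaries are compared between conditions with
exhaustive permutation tests and Hedges' g.

## Worked example

```python
import synpid

# 1. simulate a recording with a known 500 um correlation length
params = synpid.GeneratorParams(
    n_neurons=200, n_timepoints=20_000, lambda_true=500.0,
    c0_true=0.1, c_inf_true=0.01, seed=7,
)
positions, raster = synpid.simulate_dataset(params)

# 2. recover the correlation length from the binned Pearson curve
from synpid.spatial import (bin_by_distance, effective_length,
                            fit_exponential_decay, pairwise_pearson)
curve = bin_by_distance(pairwise_pearson(raster), positions,
                        min_pairs_per_bin=20)
fit = fit_exponential_decay(curve)
eff = effective_length(fit, d0=100, dmax=1500)
print(f"lambda = {fit.lam:.1f} um   C0 = {fit.c0:.4f}   "
      f"C_inf = {fit.c_inf:.4f}   lambda_eff = {eff.lambda_eff:.1f} um")

# 3. PID + NuMIT of a planted purely synergistic pair
xor_params = synpid.GeneratorParams(
    n_neurons=10, n_timepoints=8000, c0_true=0.0, c_inf_true=0.0,
    persistence=0.0, firing_prob=0.5, xor_triplets=[(0, 1, 1)], seed=5,
)
_, xor_raster = synpid.simulate_dataset(xor_params)
pid = synpid.pid_mmi(synpid.estimate_pair_joint(xor_raster[:, 0],
                                                xor_raster[:, 1], tau=1))
z = synpid.numit_normalize(pid, n_null=100, seed=2)
print(f"TDMI = {pid.tdmi:.3f} bits   SI = {pid.si:.3f}   RI = {pid.ri:.4f}")
print(f"z_synergy = {z.z_si:.2f}   z_redundancy = {z.z_ri:.2f}")

# 4. condition comparison on fitted lambdas (5 recordings per condition)
res = synpid.compare_conditions([310, 290, 305, 330, 296],
                                [515, 587, 560, 540, 498])
print(f"mean difference = {res.mean_difference:.1f} um   "
      f"p = {res.p_value:.4f} ({res.method})   g = {res.hedges_g:.2f}")
```

Output:

```
lambda = 462.9 um   C0 = 0.1026   C_inf = 0.0109   lambda_eff = 465.5 um
TDMI = 0.738 bits   SI = 0.738   RI = 0.0005
z_synergy = 3.43   z_redundancy = -2.12
mean difference = -233.8 um   p = 0.0079 (exhaustive)   g = -7.75
```

The planted 500 µm correlation length is recovered within 8% from 20,000
frames of 200 binary neurons; the XOR-coupled pair is essentially purely
synergistic (SI ≈ TDMI, redundancy at noise level), and its synergy
Z-score stands well above its redundancy Z-score. The 5-vs-5 permutation
test reports p = 2/252 ≈ 0.0079, the exhaustive two-sided floor for that
design.

## Command line

Every stage is exposed as a subcommand of `synpid`:

```bash
synpid simulate --out data/ --seed 1            # positions + raster (+ traces)
synpid binarize --traces data/traces.csv --out data/raster.csv
synpid pid      --raster data/raster.csv --positions data/positions.csv \
                --out data/pid.csv
synpid numit    --pid data/pid.csv --n-null 100 --out data/z.csv
synpid correlate --raster data/raster.csv --positions data/positions.csv \
                 --metric pearson --out out/
synpid network  --zscores data/z.csv --k 10 --out out/
synpid stats    --group-a 310,290,305 --group-b 515,587,560
synpid run      --config config.yaml            # the whole chain
```

All file formats are delimited text: rasters/traces with a header of neuron
ids and one row per timepoint, positions as `neuron_id,x_um,y_um`, edge
lists as `i,j`.

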