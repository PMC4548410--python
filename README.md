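# sacphys

Analysis tools for paired-recording connectivity and direction selectivity
in the retinal starburst amacrine cell (SAC) circuit — with seeded
synthetic-data generators that reproduce the statistical structure of the
recordings, so every analysis stage is testable end to end.

SACs are radially symmetric retinal interneurons whose dendrites are the
direction-selective subunits of the circuit that lets ganglion cells report
motion direction. Probing that circuit electrophysiologically raises four
recurring quantitative tasks, and this package implements each as a tested,
reusable component:

1. **Synaptic connection detection** in voltage-clamp paired recordings. A
   directed pair (presynaptic step from V_h = −70 to +20 mV for 200 ms,
   postsynaptic cell held at +30 mV) is *connected* when, on the
   trial-averaged trace, (1) the peak in the first 30 ms after stimulus
   onset exceeds 2 SD of the 50 ms pre-stimulus baseline, (2) a deflection
   is present in ≥ 80 % of trials, and (3) the current has latency < 12 ms
   (Boltzmann rising-phase fit) and 10–90 % rise time < 4 ms.
2. **Autapse detection**: after a brief step to +60 mV and return to
   −20 mV, the intrinsic transient is fit with a double exponential
   I(t) = offset + A₁e^(−t/τ₁) + A₂e^(−t/τ₂); residuals exceeding 2 SD of
   the pre-stimulus baseline mark candidate autaptic currents, which must
   then pass the same three criteria on the residual trace.
3. **Direction-selectivity statistics** for spike trains recorded over 8
   motion directions θ ∈ {0°, 45°, …, 315°}: peak firing rates from 50 ms
   peristimulus histograms, and the vector-sum index
   DSI = |Σᵢ rᵢ e^(iθᵢ)| / Σᵢ rᵢ with its preferred angle, deviation from
   ventral, ON/OFF comparisons, and ventral projection.
4. **Population statistics**: distance-binned connection probabilities with
   binomial errors; a Monte-Carlo null for reciprocal connectivity (each
   pair simulated as two independent Bernoulli(p̂) connections, expected
   category fractions (p̂², 2p̂(1−p̂), (1−p̂)²)); density recovery profiles
   of cell mosaics; and the circle-intersection model of dendritic overlap,
   A(d) = 2R² cos⁻¹(d/2R) − (d/2)√(4R²−d²) for two fields of radius R at
   soma distance d.

The synthetic-data module (`sacphys.synth`) generates currents (~15 pA
GABAergic postsynaptic currents at ~7 ms latency on Gaussian noise, ~20 pA
autaptic events on intrinsic transients that decay within 100 ms),
von-Mises-tuned Poisson spike trains, exclusion-zone mosaics, and
distance/genotype/age-structured connectivity tables — always with planted
ground truth in metadata.

## Worked example

```python
import sacphys as sp

# a connected pair at study conditions: 10 sweeps, 15 pA PSC, 2 pA noise
rec = sp.simulate_paired_recording(connected=True, seed=1)
res = sp.detect_connection(rec)
print(f"verdict={res.verdict}  peak={res.peak_pA:.1f} pA  "
      f"latency={res.latency_ms:.2f} ms  rise={res.rise_10_90_ms:.2f} ms  "
      f"trial_fraction={res.trial_fraction:.1f}")

# direction tuning of a simulated ventral-preferring ganglion cell
sts = sp.simulate_direction_response(sp.TuningParams(kappa=2.0), n_reps=8, seed=2)
tuning = sp.analyze_tuning(sts)
print(f"DSI={tuning.dsi_magnitude:.2f}  preferred={tuning.preferred_angle_deg:.0f} deg  "
      f"deviation from ventral={tuning.deviation_from_ventral_deg:.0f} deg")

# reciprocity null for a distance-structured population
table = sp.simulate_population_connectivity(sp.PopulationModel(), 1000, seed=3)
null = sp.reciprocity_null(table, n_sim=100_000, seed=4)
bi, uni, none = null.counts_observed
print(f"p_hat={null.p_hat:.3f}  observed (bi, uni, none)=({bi}, {uni}, {none})")
print(f"null means={tuple(round(m, 1) for m in null.null_means)}  "
      f"p(unidirectional)={null.p_values['unidirectional']:.4f}")
```

prints

```
verdict=True  peak=12.3 pA  latency=6.98 ms  rise=1.99 ms  trial_fraction=0.8
DSI=0.63  preferred=269 deg  deviation from ventral=1 deg
p_hat=0.409  observed (bi, uni, none)=(186, 446, 368)
null means=(167.3, 483.4, 349.4)  p(unidirectional)=0.0201
```

The detector recovers the planted 7 ms latency and sub-4 ms rise; the
simulated cell is sharply tuned within 1° of ventral; and the population
shows *fewer unidirectional pairs than the independence null expects* —
the signature of reciprocity that arises here because both directions of a
pair share the same distance-dependent connection probability.

## Command line

```bash
sacphys report --config config.yaml          # full pipeline -> report bundle
sacphys simulate --config config.yaml --out data/
sacphys detect-connections --input data/pairs --out detections.csv
sacphys detect-autapses --input data/autapse_cells --out autapses.csv
sacphys tuning --input spiketrains/ --out tuning.csv
sacphys reciprocity --input table.csv --nsim 100000 --seed 1 --out null.json
sacphys drp --input points.csv --bin 10 --rmax 150 --out drp.json
```

`sacphys report` consumes a YAML config (cohorts by genotype × age,
generator parameters, seed) and writes a deterministic bundle of CSV/JSON
artifacts plus a JSON-lines run log; rerunning the same config reproduces
`summary.json` byte for byte.

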