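# dnattract

Analysis toolkit for **polyamine-mediated, sequence-dependent attraction
between DNA duplexes** — the phenomenon where spermine (Sm⁴⁺) turns the
usually repulsive interaction between two double helices attractive, more
strongly for AT-rich and methylated sequences than for GC-rich ones,
because thymine/5-methylcytosine methyl groups sterically block the
major-groove N7 cation hotspots and relocate spermine into the
inter-helical "bridging" region.

The package reimplements the three analysis layers such a combined
simulation + single-molecule study needs, each paired with a seeded
synthetic-data generator that emulates the statistical structure of the
corresponding raw data, so every estimator can be validated by parameter
recovery:

1. **Free energies** — umbrella-sampling window series along the
   inter-duplex distance d, and a weighted-histogram (WHAM)
   reconstruction of the interaction free energy ΔG(d), reported in
   kcal/mol per helical turn relative to maximum separation.  The
   headline statistic is the well depth |ΔG_min| (at d ≈ 25–30 Å),
   with built-in reference profiles of depths
   (A)20 1.8 > (AT)10 1.5 ≈ (GmC)10 1.5 > (GC)10 0.8 > (G)20 0.5.
2. **Cation structure** — a coarse-grained Metropolis Monte Carlo of
   4-bead spermine chains around two duplexes, plus the bridging
   statistic N_spm (amine nitrogens in a 10 Å × 20 Å prism centred
   between the helices), groove occupancy, and z-averaged density maps.
3. **smFRET binding statistics** — a vesicle trace generator
   (100 ms/frame, 2 min observation, photobleaching, mixed dye
   compositions) and the trace-classification pipeline: single-pair
   selection by bleaching-step analysis, binding classification (FRET
   jump above 0.5, or sustained level ≥ 0.25), binding fractions with
   triplicate s.e.m., titration-peak and parallel-preference statistics.

See `docs/methods.md` for the models, parameters and their rationale.

## Worked example

Recover the (AT)10 well depth from synthetic umbrella data at the
standard protocol (20 windows at 23–42 Å, k = 4.780 kcal mol⁻¹ Å⁻²,
2×10⁴ samples/window):

```python
from dnattract import (reference_pmf, wham_reconstruct,
                       per_turn_factor, builtin_sequence)
from dnattract.synth import sample_umbrella_series

seq = builtin_sequence("AT10")
windows = sample_umbrella_series(reference_pmf("AT10"),
                                 turns=per_turn_factor(seq),
                                 n_samples=20000, seed=1)
est = wham_reconstruct(windows, bin_width=0.2, tol=1e-7,
                       turns=2.0, pin=42.0, depth_range=(23, 42))
print(f"depth = {est.depth_hat:.2f} kcal/mol/turn at {est.d_min_hat:.1f} A")
```

prints

```
depth = 1.47 kcal/mol/turn at 27.1 A
```

i.e. the planted 1.5 kcal/mol-per-turn well is recovered to within the
±0.03 seed-to-seed scatter of the protocol, with the minimum inside the
expected 25–30 Å range.

The same round-trip logic drives the other stages, e.g.

```bash
dnattract run-pmf  --seed 1 --out runs/pmf    # all five sequences + rank order
dnattract run-fret --seed 1 --out runs/fret   # titration peak + preference
dnattract simulate-ions --sequence GC10 --d 28 --n-frames 200 \
    --seed 1 --out gc10.xyz
dnattract bridging --frames gc10.xyz
```

## Layout

```
src/dnattract/
  duplex.py      sequences, methylation, groove-site geometry
  refpmf.py      parametric reference free-energy profiles
  synth/         generators: umbrella.py, ions.py, traces.py
  wham.py        WHAM reconstruction + block-bootstrap errors
  ioncount.py    bridging counts, groove occupancy, density maps
  stepfind.py    photobleaching step detection
  fret.py        trace selection/classification, binding statistics
  pipeline.py    end-to-end orchestration + config
  cli.py         `dnattract` command-line interface
```
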