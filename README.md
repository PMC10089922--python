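# fretkit

Burst-wise analysis of diffusion-based single-molecule FRET (smFRET)
measurements with alternating excitation — and a synthetic photon-stream
generator that provides ground truth for every estimator in the package.

Single molecules carrying a donor/acceptor dye pair diffuse through a
confocal volume and emit photon bursts.  Alternating the excitation between
the two dyes (µs-ALEX or ns-PIE) yields three intensity channels per burst
— donor and acceptor emission after donor excitation, and acceptor emission
after acceptor excitation — from which species can be sorted by
stoichiometry and *accurate* FRET efficiencies obtained after four
corrections:

    E_app = I_AemDex / (I_DemDex + I_AemDex)
    F_A|D = II_AemDex − α·II_DemDex − δ·II_AemAex
    E = F_A|D / (γ·II_DemDex + F_A|D)
    S = (γ·II_DemDex + F_A|D) / (γ·II_DemDex + F_A|D + II_AemAex/β)

with α the donor spectral crosstalk, δ the direct acceptor excitation,
γ the acceptor/donor detection–quantum-yield ratio, β the excitation-flux
normalization, and II the background-corrected counts.  Accurate E converts
to an interdye distance via the Förster relation R⟨E⟩ = R₀(1/E − 1)^(1/6),
and the γ uncertainty propagates as ΔE = E(1 − E)·Δγ/γ.

The package covers the full workflow for this kind of experiment:

- **photon_data** — photon-stream container, µs-ALEX/PIE excitation
  assignment, minimal Photon-HDF5 and CSV I/O
- **simulate** — burst-wise photon-stream generator (species mixtures,
  crosstalk/direct excitation/γ asymmetry, background, multi-state kinetics
  with state-dependent donor lifetimes, polarized decays) with exact
  implied corrections as ground truth
- **bursts** — background estimation, all-photon sliding-window burst
  search, stoichiometry-based species selection, burst statistics
- **corrections** — α/δ from the donor-/acceptor-only populations, β/γ from
  the global 1/S-vs-E regression or the static-FRET-line (lifetime) route
- **populations** — Gaussian fitting, cross-replicate consensus statistics,
  distance conversion
- **dynamics** — burst variance analysis (BVA), E–τ analysis with
  linker-corrected static and two-state dynamic FRET lines, dynamic shifts
  and distance-fluctuation amplitudes, dynamic photon distribution analysis
  (PDA), filtered fluorescence correlation spectroscopy (FCS), and
  maximum-entropy inversion of donor decays into distance distributions
- **structure** — accessible-volume (AV/AV3) and accessible-contact-volume
  (ACV) dye clouds on PDB structures, model-vs-experiment distance tables
- **anisotropy** — time-resolved anisotropy fits, combined residual
  anisotropy, κ²-based distance uncertainty and the dye-artifact filter

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a calibration measurement pair (two static populations at E = 0.3
and 0.7, consensus-style dye physics), run the full pipeline, and recover
the correction factors:

```python
from fretkit.presets import run_correction_recovery

r = run_correction_recovery(seed=1, n_bursts=10000)
print(f"alpha {r.recovered.alpha:.4f}  (truth {r.truth.alpha:.2f})")
print(f"delta {r.recovered.delta:.4f}  (truth {r.truth.delta:.2f})")
print(f"beta  {r.recovered.beta:.3f}   (truth {r.truth.beta:.2f})")
print(f"gamma {r.recovered.gamma:.4f}  (truth {r.truth.gamma:.2f})")
print("E", [f"{e:.4f}" for e in r.e_recovered], "truth", r.e_true)
```

prints

```
alpha 0.0507  (truth 0.05)
delta 0.1223  (truth 0.12)
beta  1.591   (truth 1.60)
gamma 0.4022  (truth 0.40)
E ['0.3032', '0.7011'] truth (0.3, 0.7)
```

i.e. all four correction factors and the accurate efficiencies come back
from the raw photon stream within their benchmark tolerances (±0.005,
±0.01, ±0.08, ±0.02 and ±0.01 respectively).

A command-line interface exposes the main steps (`fretkit simulate`,
`analyze`, `bva`, `etau`, `pda`, `fcs`, `mem`, `av`, `report`); run
`fretkit --help`.

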