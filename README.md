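# smchrom

Single-molecule imaging analysis of liquid-chromatography stationary
phases: simulate single-molecule adsorption movies inside porous
particles, super-resolve the analyte positions, quantify how much of a
particle's cross-section the analyte can actually reach, extract
adsorption/desorption kinetics from dwell times, and predict ensemble
elution-peak shapes from those dwell times with the stochastic theory of
chromatography.

## Who this is for

Separation scientists and microscopists who characterize porous
stationary-phase particles (fully porous or superficially porous silica,
polymer-functionalized media) by in-situ single-molecule localization
microscopy, and who want a reproducible route from raw movies to the
metrics that matter for a separation: pore accessibility and mass-transfer
kinetics. Because the package ships a full generative simulator, every
stage can also be exercised and validated without any experimental data.

## The quantities at the core

* **Accessible-depth limit (d99).** Each localization is assigned a depth
  from the particle edge via the normalized elliptical radius
  ρ = √((x′/a)² + (y′/b)²) of the fitted outline, quoted as a percent of
  the particle radius r = (a+b)/2. d99 is the 99th percentile of the depth
  distribution — the depth beyond which 99% of analytes do not reach. For
  a uniformly probed annulus of fractional depth f the closed form is
  d99 = 100·(1 − √(1 − 0.99·(1 − (1−f)²))) %r: 90 %r for a full disc,
  ≈37 %r for a 0.5-µm shell on a 1.35-µm-radius particle.
* **Accessible-area ratio (A_p/A_i).** The map area covered by
  localizations (A_p) over the fitted cross-section A_i = πab. For a
  uniformly probed shell it approaches 1 − (1−f)².
* **Dwell-time kinetics.** Localizations are linked frame-to-frame into
  adsorption events; the dwell time t_D = (frame span) × Δt gives the
  desorption rate k_d = 1/t_D. Heterogeneous surfaces are an *n*-site
  mixture of first-order site classes. Per-site adsorption free energies
  use ΔG = −RT ln K_eq with K_eq = k_a/(k_d·C/C°), C° = 1 M.
* **Stochastic-theory elution.** A molecule's retention time is the
  mobile-phase transit time t_M plus a Poisson(n̄) number of adsorption
  sojourns. With the empirical dwell characteristic function
  φ_s(ω) = ⟨e^{iωt_D}⟩ the peak's CF is
  Φ(ω) = e^{iωt_M}·exp(n̄(φ_s(ω) − 1)), inverted by FFT. The first two
  cumulants are exactly t_M + n̄·E[t_D] and n̄·E[t_D²]; rare long dwells
  produce the positive skew (tailing) of strong adsorption. Peaks are
  summarized by the method of moments: area, center, variance, skew.

## Worked example

Simulate a superficially porous particle (1.7-µm solid core, 0.5-µm
porous shell), run the full pipeline, and read off the metrics:

```python
from smchrom.config import RunConfig
from smchrom.pipeline import run_pipeline
from smchrom.geometry import annulus_d99, core_shell_geometry

radius_um, f = core_shell_geometry(core_diameter_um=1.7, shell_um=0.5)
print(f"SPP outer radius: {radius_um:.2f} um; geometric depth limit: {100*f:.1f} %r")
print(f"annulus d99 closed form: {annulus_d99(f):.1f} %r")

cfg = RunConfig(seed=1, outdir="smchrom_demo")
cfg.particle.a_nm = cfg.particle.b_nm = 1350.0
cfg.particle.accessible_fraction = f
products = run_pipeline(cfg)

res = products["access"]["result"]
print(f"pipeline d99: {res.d99_percent_r:.1f} %r from {res.n_localizations} localizations")
print(f"accessible-area ratio Ap/Ai: {res.ratio:.2f}")
kin = products["kinetics"]["summary"]
print(f"{kin['n_events']} adsorption events, mean dwell {kin['mean_dwell_s']*1e3:.0f} ms")
mom = products["elute"]["moments"]
print(f"modeled elution peak: center {mom.center_s:.1f} s, skew {mom.skew:.2f}")
```

Output (about a minute; four rendered 2000-frame movies are localized):

```
SPP outer radius: 1.35 um; geometric depth limit: 37.0 %r
annulus d99 closed form: 36.6 %r
pipeline d99: 36.2 %r from 6701 localizations
accessible-area ratio Ap/Ai: 0.57
1421 adsorption events, mean dwell 153 ms
modeled elution peak: center 15.3 s, skew 0.37
```

Reading: the imaging pipeline recovers the geometric accessibility of the
shell (36.2 %r vs. the 36.6 %r closed form and the 37 %r shell/radius
ratio); the area ratio is a few points below the geometric 0.60 because
30-nm map pixels cannot be credited exactly on the shell boundaries; the
153-ms mean dwell reflects the simulated three-class site mixture; and the
modeled peak tails to the right (skew > 0), as adsorption-dominated peaks
do.

The same run from a shell:

```bash
smchrom run --set particle.a_nm=1350 --set particle.b_nm=1350 \
            --set particle.accessible_fraction=0.37 --outdir smchrom_demo
smchrom moments smchrom_demo/elution_profile.csv   # works on any time,signal CSV
```

All artifacts (TIFF movies with JSON sidecars, localization/event/site
CSVs, accessibility and moments JSON, a manifest with the config hash and
seed) land in the output directory; re-running the same config reproduces
them byte for byte.

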