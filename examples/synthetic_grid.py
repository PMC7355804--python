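"""Generate a synthetic solubility grid from the Jouyban-Acree-Van't Hoff
law and check that refitting recovers the generating coefficients."""

from cosolvency import GeneratorConfig, fit_ja_vant_hoff, generate

cfg = GeneratorConfig(noise_sigma=0.01, seed=7)  # 1% lognormal noise on x
ds = generate(cfg)
print(f"generated {len(ds)} records over {len(ds.m_levels)} blends x "
      f"{len(ds.temperatures)} temperatures")

fit = fit_ja_vant_hoff(ds)
print("\ncoefficient   truth      recovered")
for name, truth, est in [
    ("A1", cfg.A1, fit.A1), ("B1", cfg.B1, fit.B1),
    ("A2", cfg.A2, fit.A2), ("B2", cfg.B2, fit.B2),
    ("J0", cfg.J[0], fit.J[0]),
]:
    print(f"  {name:4s}   {truth:10.2f}   {est:10.2f}")
print(f"\nrefit %RMSD = {fit.rmsd_pct:.2f} (noise floor for sigma = 0.01 is ~1%)")

# With 1% multiplicative noise the pure-solvent Van't Hoff coefficients and
# the interaction term all come back close to truth; at sigma = 0 the
# recovery is exact to 1e-8.
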