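"""Estimate field metabolic rate from a doubly-labeled-water study.

Builds one synthetic two-pool isotope washout study with known truth, runs the
full estimation chain (dilution spaces -> turnover rates -> CO2 production ->
watts), and compares the estimate against the planted values.
"""

from divefmr.dlw import OnshoreRateSpec, process_study
from divefmr.simulate import SimConfig, simulate_isotope_study

cfg = SimConfig(seed=42)
study, truth = simulate_isotope_study(cfg, animal_index=2, noise=True)

result = process_study(
    study,
    onshore=OnshoreRateSpec(basal_multiple=1.5),
    analytical_sd_ppm=cfg.analytical_sd_ppm,
    n_draws=5000,
)

print(f"animal {study.animal_id}: {study.mass_initial_kg:.1f} -> "
      f"{study.mass_final_kg:.1f} kg over {study.interval_days:.1f} days")
print(f"body water pool (18O space):  {result.n_o_mol:8.0f} mol "
      f"({result.tbw_percent:.1f}% of body mass)")
print(f"turnover rates:               k_o={result.k_o:.4f}, k_d={result.k_d:.4f} /day")
print(f"CO2 production (two-pool):    {result.rco2_speakman_ml_g_hr:.3f} ml/g/hr "
      f"[95% MC interval {result.ci_low:.3f}-{result.ci_high:.3f}; "
      f"truth {truth.rco2_ml_g_hr:.3f}]")
print(f"CO2 production (single-pool): {result.rco2_nagy_ml_g_hr:.3f} ml/g/hr")
print(f"field metabolic rate:         {result.fmr_w_speakman:.1f} W "
      f"({result.fmr_wkg_speakman:.2f} W/kg)")
print(f"water influx:                 {result.influx_ml_kg_day:.0f} ml/kg/day "
      f"[truth {truth.influx_ml_kg_day:.0f}]")
print(f"at-sea FMR (onshore = 1.5x basal): {result.at_sea_fmr_wkg:.2f} W/kg")
print()
print("The Monte-Carlo interval reflects assay noise on the six serum")
print("enrichments; the point estimates recover the planted truth within it.")
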