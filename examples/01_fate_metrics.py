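"""Fate metrics for a single chemical.

Builds one semi-volatile, persistent chemical record and computes its
multimedia fate metrics: overall persistence (Pov), characteristic travel
distances in air and water (CTD) and transfer efficiency (TE).
"""

from exposcreen import ChemicalRecord, compute_fate_metrics, default_environment

record = ChemicalRecord(
    chem_id="EX-1",
    name="semi-volatile persistent example",
    log_kow=6.0,      # hydrophobic
    log_kaw=-4.0,     # semi-volatile
    t_half_air=5000,  # hours
    t_half_water=5000,
    t_half_soil=5000,
)

metrics = compute_fate_metrics(record, default_environment())

print(f"Pov       = {metrics.pov_days:10.1f} days")
print(f"CTD_air   = {metrics.ctd_air_km:10.1f} km")
print(f"CTD_water = {metrics.ctd_water_km:10.1f} km")
print(f"TE        = {metrics.te_percent:10.3f} %")
print()
print("Pov is the mass-weighted residence time against degradation; the")
print("CTDs are how far the chemical travels in air/water before its mass")
print("falls to 1/e; TE is the fraction of air emissions deposited in a")
print("remote region. High values on all four mark a long-range hazard.")
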